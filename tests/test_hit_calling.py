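"""Bin assignment, hit thresholds, enhancer logic and expression triage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycoscreen import (BinScheme, DEFAULT_SCHEME, assign_bin,
                         call_drug_enhancers, call_glycolysis_hits,
                         call_viability_hits, expression_triage)
from glycoscreen.hit_calling import (ENHANCER_PAIRS_LACTATE,
                                     ENHANCER_PAIRS_VIABILITY, LACTATE_BINS,
                                     VIABILITY_BINS, is_enhancer_by_index,
                                     is_enhancer_pair, severity_index)
from glycoscreen.plate_model import ExpressionProfile


class TestAssignBin:
    @pytest.mark.parametrize("fc,param,expected", [
        (0.45, "lactate", "LAC4"),       # hit-eligible, FC < 0.5
        (0.24, "lactate", "LAC5"),
        (1.2, "lactate", "LAC1"),
        (0.1, "t48_count", "LC"),        # low-count exclusion bin
        (0.9, "viability", "Hi"),
        (0.05, "viability", "CV3"),
        (-0.3, "viability", "LC"),       # net cell death
    ])
    def test_examples(self, fc, param, expected):
        assert assign_bin(fc, DEFAULT_SCHEME, param) == expected

    @pytest.mark.parametrize("edge,param,expected", [
        (0.5, "lactate", "LAC3"),        # boundary goes to the lower-severity side
        (0.25, "lactate", "LAC4"),
        (0.8, "viability", "Hi"),
        (0.0, "viability", "CV3"),
        (0.2, "t48_count", "CV2"),
    ])
    def test_boundary_rule(self, edge, param, expected):
        assert assign_bin(edge, DEFAULT_SCHEME, param) == expected

    def test_undefined_fc_has_no_bin(self):
        assert assign_bin(np.nan, DEFAULT_SCHEME, "lactate") is None

    @given(st.floats(-1.0, 3.0), st.sampled_from(["viability", "lactate"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_and_monotonicity(self, fc, param):
        label = assign_bin(fc, DEFAULT_SCHEME, param)
        labels = DEFAULT_SCHEME.labels(param)
        assert label in labels
        # monotone: a smaller FC never maps to a less severe bin
        other = assign_bin(fc - 0.1, DEFAULT_SCHEME, param)
        assert severity_index(other, param) >= severity_index(label, param)

    def test_hit_eligible_lactate_bins_cover_below_half(self):
        for fc in (0.499, 0.3, 0.1, 0.01):
            assert assign_bin(fc, DEFAULT_SCHEME, "lactate") in ("LAC4", "LAC5")
        assert assign_bin(0.5, DEFAULT_SCHEME, "lactate") not in ("LAC4", "LAC5")


class TestHitThresholds:
    def test_strict_viability_threshold(self):
        assert call_viability_hits([-1.6])[0]
        assert not call_viability_hits([-1.5])[0]
        assert not call_viability_hits([np.nan])[0]

    def test_glycolysis_hit_requires_cells(self):
        z = [-2.0, -2.0]
        t48 = [0.5, 0.1]
        flags = call_glycolysis_hits(z, t48)
        assert flags[0] and not flags[1]

    def test_hit_sets_shrink_with_tighter_threshold(self, rng):
        z = rng.normal(0, 1, 500)
        loose = z < -1.5
        tight = z < -2.0
        assert set(np.where(tight)[0]) <= set(np.where(loose)[0])


class TestEnhancerLogic:
    @pytest.mark.parametrize("cb,db,param,expected", [
        ("Hi", "LC", "viability", True),
        ("Hi", "CV2", "viability", True),
        ("CV1", "CV2", "viability", False),
        ("CV2", "CV3", "viability", False),   # only one level worse
        ("CV2", "LC", "viability", True),
        ("LAC2", "LAC4", "lactate", True),
        ("LAC3", "LAC4", "lactate", False),
        ("LAC3", "LAC5", "lactate", True),
    ])
    def test_enumerated_pairs(self, cb, db, param, expected):
        assert is_enhancer_pair(cb, db, param) is expected

    def test_pair_table_matches_quoted_rules(self):
        assert ENHANCER_PAIRS_VIABILITY == {
            ("Hi", "CV2"), ("Hi", "CV3"), ("Hi", "LC"),
            ("CV1", "CV3"), ("CV1", "LC"), ("CV2", "LC")}
        assert ENHANCER_PAIRS_LACTATE == {
            ("LAC1", "LAC3"), ("LAC1", "LAC4"), ("LAC1", "LAC5"),
            ("LAC2", "LAC4"), ("LAC2", "LAC5"), ("LAC3", "LAC5")}

    def test_rules_agree_exhaustively(self):
        for param, labels in (("viability", VIABILITY_BINS),
                              ("lactate", LACTATE_BINS)):
            for cb, db in itertools.product(labels, labels):
                assert (is_enhancer_pair(cb, db, param)
                        == is_enhancer_by_index(cb, db, param)), (cb, db)

    def test_undefined_bins_never_enhance(self):
        flags = call_drug_enhancers(["Hi", None], ["LC", "LC"], "viability")
        assert flags[0] and not flags[1]

    def test_both_rules_in_caller(self):
        cb = ["Hi", "CV1", "LAC1"]
        db = ["LC", "CV2", "LAC1"]
        pairs = call_drug_enhancers(cb[:2], db[:2], "viability", rule="pairs")
        index = call_drug_enhancers(cb[:2], db[:2], "viability", rule="index")
        assert (pairs == index).all()


@pytest.fixture(scope="module")
def profile():
    # expression value == gene id makes percentile bookkeeping transparent
    ids = np.arange(1, 10001)
    return ExpressionProfile(pd.Series(ids.astype(float), index=ids))


class TestExpressionTriage:

    def test_removal_counts_match_oracle(self, profile):
        threshold = profile.percentile(12)
        hits = list(range(1, 501)) + list(range(5000, 5500))
        res = expression_triage(hits, profile, percentile=12)
        oracle = sum(1 for g in hits if g < threshold)
        assert res.n_removed == oracle
        assert res.n_input == len(hits)
        assert len(res.retained) == len(hits) - oracle

    def test_percentile_zero_removes_nothing(self, profile):
        hits = [1, 2, 3, 9999]
        res = expression_triage(hits, profile, percentile=0)
        assert res.n_removed == 0

    def test_triage_never_adds_genes(self, profile, rng):
        hits = rng.choice(10000, size=300, replace=False) + 1
        res = expression_triage(hits, profile)
        assert set(res.retained) <= set(int(h) for h in hits)
        assert len(res.retained) + len(res.removed) == len(hits)

    def test_missing_gene_policy(self, profile):
        res = expression_triage([123456], profile, percentile=12)
        assert res.missing == (123456,)
        assert res.retained == (123456,)      # default: keep and flag
        res2 = expression_triage([123456], profile, missing_policy="remove")
        assert res2.retained == ()

    def test_status_label(self, profile):
        res = expression_triage([1], profile, percentile=12)
        assert res.removed == (1,)


class TestBinSchemeValidation:
    def test_edges_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            BinScheme(lactate_edges=(0.25, 0.5, 0.75, 1.0))

    def test_edge_count_checked(self):
        with pytest.raises(ValueError, match="fewer"):
            BinScheme(viability_edges=(0.8, 0.4))
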