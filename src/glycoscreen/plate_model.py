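"""384-well plate domain model and tabular I/O for siRNA screen data.

Geometry follows the standard high-throughput screening convention: 16 rows
(A..P) by 24 columns. siRNA controls occupy columns 2 and 23 (8 PLK1 kill
controls, 8 PDK1 lactate controls and 16 non-targeting wells per plate),
column 24 holds media-only wells used as the lactate-assay background, and
library siRNAs fill the remaining 21 columns, giving 336 library positions
per plate.

All tables are exchanged as long-format delimited text, one row per well,
with missing values written as empty fields. Lines starting with ``#`` are
treated as comments (the pipeline writes provenance headers that way).
"""

from __future__ import annotations

import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24
MEDIA_COLUMN = 24
CONTROL_COLUMNS = (2, 23)
#: Library columns: everything except the two control columns and the media column.
LIBRARY_COLUMNS = tuple(c for c in range(1, N_COLS + 1)
                        if c not in CONTROL_COLUMNS and c != MEDIA_COLUMN)
WELLS_PER_PLATE = N_ROWS * N_COLS
LIBRARY_WELLS_PER_PLATE = N_ROWS * len(LIBRARY_COLUMNS)  # 336

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


class WellRole(str, Enum):
    """Functional role of a well on an assay plate."""

    LIBRARY = "library"
    PLK1 = "control_PLK1"
    PDK1 = "control_PDK1"
    NT = "control_NT"
    MEDIA = "media_only"
    EMPTY = "empty"


class Arm(str, Enum):
    """Treatment arm of the screen.

    ``T0`` plates are fixed at the pre-treatment timepoint and carry counts
    only; ``control`` is the 0.1% DMSO vehicle arm and ``drug`` the 300 nM
    vemurafenib (IC25) arm, both read out 48 h after treatment.
    """

    T0 = "T0"
    CONTROL = "control"
    DRUG = "drug"


ARM_VALUES = tuple(a.value for a in Arm)
T48_ARMS = (Arm.CONTROL.value, Arm.DRUG.value)

CONTROL_ROLES = (WellRole.PLK1.value, WellRole.PDK1.value, WellRole.NT.value)

SCREEN_COLUMNS = [
    "library_plate", "arm", "replicate", "well", "row", "col", "role",
    "catalog_id", "entrez_id", "duplex", "cell_count", "absorbance",
]


class ScreenTableError(ValueError):
    """Raised for malformed screen tables; carries offending line numbers."""

    def __init__(self, message: str, lines: Sequence[int] = ()):
        self.lines = list(lines)
        if self.lines:
            message = f"{message} (lines {', '.join(map(str, self.lines))})"
        super().__init__(message)


def format_well(row: str | int, col: int) -> str:
    """Return the canonical well name, e.g. ``("A", 1) -> "A01"``."""
    if isinstance(row, (int, np.integer)):
        row = ROWS[row]
    return f"{row}{int(col):02d}"


def parse_well(well: str) -> tuple[str, int]:
    """Split a well name into (row letter, 1-based column).

    Raises ``ValueError`` for anything outside the 16 x 24 grid.
    """
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise ValueError(f"invalid well address {well!r}")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= N_COLS:
        raise ValueError(f"column out of range in well {well!r}")
    return row, col


def default_control_positions() -> dict[str, str]:
    """Map well -> control role for columns 2 and 23.

    The deposited records do not state the within-column arrangement, so the
    default interleaves non-targeting wells with the positive controls:
    column 2 alternates NT/PLK1 down the rows, column 23 alternates PDK1/NT.
    This yields 16 NT, 8 PLK1 and 8 PDK1 wells per plate and spreads every
    control type across plate rows.
    """
    positions: dict[str, str] = {}
    for i, r in enumerate(ROWS):
        positions[format_well(r, 2)] = (
            WellRole.NT.value if i % 2 == 0 else WellRole.PLK1.value)
        positions[format_well(r, 23)] = (
            WellRole.PDK1.value if i % 2 == 0 else WellRole.NT.value)
    return positions


def build_layout(
    n_library_plates: int,
    genes: pd.DataFrame | None = None,
    deconvolution: bool = False,
    control_positions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Construct plate layouts for a screen.

    Parameters
    ----------
    n_library_plates : int
        Number of 384-well library plates.
    genes : DataFrame, optional
        Library annotation with columns ``catalog_id``, ``entrez_id`` and
        optionally ``gene_symbol`` and ``duplex``. One row per reagent
        (per SMARTpool, or per duplex in deconvolution mode). Reagents are
        placed in row-major order across the library columns, plate by
        plate. ``None`` gives control/media-only plates.
    deconvolution : bool
        If True, ``genes`` must carry a ``duplex`` column in 1..4 and every
        gene must contribute exactly 4 duplex entries.
    control_positions : mapping, optional
        Well -> role override for the control columns.

    Returns
    -------
    DataFrame with one row per well per plate: ``plate``, ``well``, ``row``,
    ``col``, ``role``, ``catalog_id``, ``entrez_id``, ``gene_symbol``,
    ``duplex``.
    """
    if n_library_plates < 1:
        raise ValueError("n_library_plates must be >= 1")
    controls = dict(control_positions or default_control_positions())
    _validate_control_positions(controls)

    if genes is None:
        genes = pd.DataFrame(columns=["catalog_id", "entrez_id"])
    genes = genes.reset_index(drop=True).copy()
    if "gene_symbol" not in genes.columns:
        genes["gene_symbol"] = ""
    if "duplex" not in genes.columns:
        genes["duplex"] = 0
    if deconvolution:
        per_gene = genes.groupby("entrez_id")["duplex"].agg(["size", "nunique"])
        bad = per_gene[(per_gene["size"] != 4) | (per_gene["nunique"] != 4)]
        if len(bad):
            raise ValueError(
                f"deconvolution requires exactly 4 distinct duplexes per gene; "
                f"{len(bad)} genes violate this")
    dup_key = genes[["catalog_id", "duplex"]].apply(tuple, axis=1)
    if dup_key.duplicated().any():
        raise ValueError("(catalog_id, duplex) pairs must be unique")

    capacity = n_library_plates * LIBRARY_WELLS_PER_PLATE
    if len(genes) > capacity:
        raise ValueError(
            f"{len(genes)} library entries exceed capacity "
            f"{capacity} of {n_library_plates} plate(s)")

    records = []
    gi = 0
    for plate in range(1, n_library_plates + 1):
        for ri, r in enumerate(ROWS):
            for c in range(1, N_COLS + 1):
                well = format_well(r, c)
                role = WellRole.LIBRARY.value
                cat, ent, sym, dup = "", pd.NA, "", 0
                if c == MEDIA_COLUMN:
                    role = WellRole.MEDIA.value
                elif c in CONTROL_COLUMNS:
                    role = controls[well]
                elif gi < len(genes):
                    g = genes.iloc[gi]
                    cat, ent = g["catalog_id"], g["entrez_id"]
                    sym, dup = g["gene_symbol"], int(g["duplex"])
                    gi += 1
                else:
                    role = WellRole.EMPTY.value
                records.append((plate, well, r, c, role, cat, ent, sym, dup))
    out = pd.DataFrame(records, columns=[
        "plate", "well", "row", "col", "role",
        "catalog_id", "entrez_id", "gene_symbol", "duplex"])
    out["entrez_id"] = out["entrez_id"].astype("Int64")
    return out


def _validate_control_positions(controls: Mapping[str, str]) -> None:
    counts = {WellRole.NT.value: 0, WellRole.PLK1.value: 0, WellRole.PDK1.value: 0}
    for well, role in controls.items():
        _, col = parse_well(well)
        if col not in CONTROL_COLUMNS:
            raise ValueError(f"control well {well} outside columns {CONTROL_COLUMNS}")
        if role not in counts:
            raise ValueError(f"unknown control role {role!r}")
        counts[role] += 1
    if (counts[WellRole.NT.value] != 16 or counts[WellRole.PLK1.value] != 8
            or counts[WellRole.PDK1.value] != 8):
        raise ValueError(f"control counts must be 16 NT / 8 PLK1 / 8 PDK1, got {counts}")


# ---------------------------------------------------------------------------
# Screen measurement tables

def write_screen_table(df: pd.DataFrame, path: str | Path,
                       header_comment: str | None = None) -> None:
    """Write per-well measurements as long-format CSV (empty field = missing)."""
    df = df.loc[:, SCREEN_COLUMNS]
    _write_csv(df, path, header_comment)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format per-well measurement table.

    Malformed rows are rejected with their 1-based file line numbers.
    """
    df, line_no = _read_csv_with_lines(path)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenTableError(f"missing columns: {missing}")

    bad: dict[str, list[int]] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        if mask.any():
            bad.setdefault(reason, []).extend(line_no[mask.to_numpy()].tolist())

    flag(~df["arm"].isin(ARM_VALUES), "unknown arm")
    cc = pd.to_numeric(df["cell_count"], errors="coerce")
    flag(df["cell_count"].notna() & cc.isna(), "non-numeric cell_count")
    flag(cc.notna() & (cc < 0), "negative cell_count")
    flag((df["arm"] == Arm.T0.value) & df["absorbance"].notna(),
         "T0 rows must not carry absorbance")
    well_ok = df["well"].astype(str).str.upper().str.match(_WELL_RE.pattern)
    flag(~well_ok, "invalid well address")
    dup = df.duplicated(subset=["library_plate", "arm", "replicate", "well"], keep=False)
    flag(dup & df.duplicated(subset=["library_plate", "arm", "replicate", "well"]),
         "duplicate (plate, arm, replicate, well)")

    if bad:
        reasons = "; ".join(f"{k}" for k in bad)
        lines = sorted({ln for lns in bad.values() for ln in lns})
        raise ScreenTableError(f"malformed rows: {reasons}", lines)

    df["cell_count"] = cc
    df["absorbance"] = pd.to_numeric(df["absorbance"], errors="coerce")
    df["library_plate"] = df["library_plate"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["col"] = df["col"].astype(int)
    df["duplex"] = df["duplex"].fillna(0).astype(int)
    df["entrez_id"] = pd.to_numeric(df["entrez_id"], errors="coerce").astype("Int64")
    for c in ("catalog_id", "row", "well", "role", "arm"):
        df[c] = df[c].fillna("").astype(str)
    return df


RESULTS_COLUMNS = [
    "catalog_id", "entrez_id", "gene_symbol",
    "t48_raw_control", "t48_raw_drug", "t0_raw",
    "t48_fc_control", "t48_fc_drug",
    "deltat_fc_control", "deltat_fc_drug",
    "lactate_fc_control", "lactate_fc_drug",
    "z_t48_control", "z_t48_drug",
    "z_deltat_control", "z_deltat_drug",
    "z_lactate_control", "z_lactate_drug",
    "bin_t48_control", "bin_t48_drug",
    "bin_deltat_control", "bin_deltat_drug",
    "bin_lactate_control", "bin_lactate_drug",
    "low_cell_control", "low_cell_drug",
    "viability_hit", "glycolysis_hit",
    "viability_enhancer", "glycolysis_enhancer",
    "triage_status", "exclusion_reason",
]


def write_results_table(metrics: pd.DataFrame, path: str | Path,
                        header_comment: str | None = None) -> None:
    """Write the per-gene results table with a fixed column order.

    Genes excluded from the lactate analysis keep their row; lactate columns
    are emitted as empty fields and the exclusion reason is recorded.
    """
    out = metrics.copy()
    for c in RESULTS_COLUMNS:
        if c not in out.columns:
            out[c] = pd.NA
    _write_csv(out[RESULTS_COLUMNS], path, header_comment)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df, _ = _read_csv_with_lines(path)
    df["entrez_id"] = pd.to_numeric(df["entrez_id"], errors="coerce").astype("Int64")
    return df


# ---------------------------------------------------------------------------
# Expression profile

class ExpressionProfile:
    """Per-gene normalized expression values keyed by Entrez Gene ID."""

    def __init__(self, values: Mapping[int, float] | pd.Series):
        s = pd.Series(values, dtype=float)
        if s.index.duplicated().any():
            raise ValueError("duplicate Entrez IDs in expression profile")
        if len(s) == 0:
            raise ValueError("empty expression profile")
        self._values = s

    def __len__(self) -> int:
        return len(self._values)

    @property
    def values(self) -> pd.Series:
        return self._values

    def value(self, entrez_id: int) -> float:
        return float(self._values.get(entrez_id, np.nan))

    def percentile(self, q: float) -> float:
        """Empirical percentile of the expression distribution (linear interpolation)."""
        return float(np.percentile(self._values.to_numpy(), q))

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionProfile":
        df, _ = _read_csv_with_lines(path)
        return cls(pd.Series(df["expression_value"].to_numpy(),
                             index=df["entrez_id"].astype(int).to_numpy()))

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame({"entrez_id": self._values.index,
                           "expression_value": self._values.to_numpy()})
        _write_csv(df, path)


# ---------------------------------------------------------------------------
# Shared CSV helpers

def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep="")


def _read_csv_with_lines(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a CSV, returning the frame and each data row's file line number."""
    path = Path(path)
    data_lines = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.lstrip().startswith("#") or not line.strip():
                continue
            data_lines.append(i)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    # first retained line is the header
    return df, np.asarray(data_lines[1:1 + len(df)])
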