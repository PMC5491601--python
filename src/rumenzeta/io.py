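"""Typed readers/writers for the two experimental blocks of the batch-culture
fermentation design.

The design crosses 4 initial surface-tension (ST) levels of the culture medium
with 3 specific-surface-area (SSA) levels of the fibre substrate, 3 replicates
each.  Electrokinetic variables (electrophoretic mobility, zeta potential),
surface tension during fermentation (gamma) and optional covariates (pH,
digestibility, ammonia-N) are sampled on the t1 grid {6, 12, 24, 36, 48, 72} h;
the six volatile fatty acid (VFA) concentrations are sampled on the t2 grid
{6, 12, 24, 48} h.

Tables are plain CSV (comma separated, '.' decimal mark, one header row).
Bundled fixtures transcribe the published condition-level means of both blocks
(the printed tables average 3 replicates, so the fixtures carry replicate=1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DesignValidationError, ParseError, SchemaError

__all__ = [
    "Condition",
    "ExperimentDesign",
    "TimeScale1Record",
    "TimeScale2Record",
    "DesignReport",
    "BlockReport",
    "DEFAULT_DESIGN",
    "T1_COLUMNS",
    "T2_COLUMNS",
    "VFA_NAMES",
    "read_t1_table",
    "read_t2_table",
    "write_t1_table",
    "write_t2_table",
    "validate_design",
    "load_t1_means",
    "load_t2_means",
    "load_t1_means_frame",
    "read_figshare_workbook",
]

#: canonical column order of the two CSV schemas
T1_COLUMNS = (
    "ssa_m2_per_g", "st_mN_per_m", "replicate", "t1_h",
    "mobility", "zeta_mV", "gamma_mN_per_m", "ph", "digestibility", "nh3n",
)
T1_REQUIRED = T1_COLUMNS[:7]
T1_OPTIONAL = ("ph", "digestibility", "nh3n")

VFA_NAMES = ("c2", "c3", "c4", "ic4", "c5", "ic5")
T2_COLUMNS = ("ssa_m2_per_g", "st_mN_per_m", "replicate", "t2_h") + VFA_NAMES


@dataclass(frozen=True, order=True)
class Condition:
    """One of the combinatorial treatments: an (SSA, ST) level pair.

    ssa: specific surface area of the fibre substrate, m^2/g.
    st:  initial surface tension of the culture medium, mN/m.
    """

    ssa: float
    st: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Complete factorial layout of the study.

    Defaults follow the published design: SSA levels 3.37/3.73/4.44 m^2/g, ST
    levels as measured after surfactant dosing (53.95/46.09/42.78/36.07 mN/m),
    3 replicates, t1 grid of six and t2 grid of four sampling hours.
    """

    ssa_levels: tuple[float, ...] = (3.37, 3.73, 4.44)
    st_levels: tuple[float, ...] = (53.95, 46.09, 42.78, 36.07)
    replicates: int = 3
    t1_grid: tuple[float, ...] = (6.0, 12.0, 24.0, 36.0, 48.0, 72.0)
    t2_grid: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0)

    def conditions(self) -> list[Condition]:
        """All SSA x ST combinations, SSA-major (the printed table order)."""
        return [Condition(ssa, st) for ssa in self.ssa_levels for st in self.st_levels]

    @property
    def n_conditions(self) -> int:
        return len(self.ssa_levels) * len(self.st_levels)

    @property
    def n_t1_cases(self) -> int:
        return self.n_conditions * self.replicates * len(self.t1_grid)

    @property
    def n_t2_cases(self) -> int:
        return self.n_conditions * self.replicates * len(self.t2_grid)


DEFAULT_DESIGN = ExperimentDesign()


@dataclass(frozen=True)
class TimeScale1Record:
    """One t1-block case: electrokinetics + gamma (+ optional covariates).

    mobility is in 1e-8 m^2 V^-1 s^-1 (equivalently um.cm/V/s), zeta in mV,
    gamma in mN/m.  pH is unitless; digestibility and ammonia-N are carried as
    opaque pass-through values in the units of the source table.
    """

    condition: Condition
    replicate: int
    t1: float
    mobility: float
    zeta: float
    gamma: float
    ph: float | None = None
    digestibility: float | None = None
    nh3n: float | None = None


@dataclass(frozen=True)
class TimeScale2Record:
    """One t2-block case: the six VFA molar concentrations (mM).

    Order of ``vfa``: acetic (c2), propionic (c3), butyric (c4), isobutyric
    (ic4), valeric (c5), isovaleric (ic5).
    """

    condition: Condition
    replicate: int
    t2: float
    vfa: tuple[float, float, float, float, float, float]


# ---------------------------------------------------------------------------
# reading


def _normalise_cell(text: str) -> str:
    # unicode minus / en-dash as printed in transcribed tables -> ASCII hyphen
    return text.replace("−", "-").replace("–", "-").strip()


def _parse_float(raw, row: int, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise ParseError(f"row {row}, column '{column}': missing value")
    try:
        return float(_normalise_cell(str(raw)))
    except ValueError:
        raise ParseError(
            f"row {row}, column '{column}': cannot parse {raw!r} as a number"
        ) from None


def _parse_optional(raw, row: int, column: str) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    text = _normalise_cell(str(raw))
    if text == "" or text.lower() == "nan":
        return None
    return _parse_float(text, row, column)


def _snap_level(value: float, levels: Sequence[float], tol: float,
                row: int, name: str) -> float:
    nearest = min(levels, key=lambda lv: abs(lv - value))
    if abs(nearest - value) <= tol:
        return nearest
    raise DesignValidationError(
        f"row {row}: {name}={value} is not within {tol} of any design level {levels}"
    )


def _check_grid(value: float, grid: Sequence[float], row: int, name: str) -> float:
    for g in grid:
        if math.isclose(value, g, rel_tol=0.0, abs_tol=1e-9):
            return float(g)
    raise DesignValidationError(
        f"row {row}: {name}={value} is not on the grid {tuple(grid)}"
    )


def _load_frame(path, schema: Mapping[str, str] | None, required: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if schema:  # user column name -> canonical name
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' missing from {path.name}")
    return df


def read_t1_table(
    path,
    schema: Mapping[str, str] | None = None,
    design: ExperimentDesign | None = DEFAULT_DESIGN,
    level_tol: float = 0.05,
) -> list[TimeScale1Record]:
    """Read a t1-block CSV into records, preserving row order.

    ``schema`` maps canonical column names to the file's column names when they
    differ.  SSA/ST values are snapped to the design's canonical levels within
    ``level_tol`` (absolute); time points must sit on the design's t1 grid.
    Pass ``design=None`` to accept arbitrary levels and times.
    """
    df = _load_frame(path, schema, T1_REQUIRED)
    records: list[TimeScale1Record] = []
    for i, rowdata in enumerate(df.itertuples(index=False), start=1):
        row = rowdata._asdict()
        ssa = _parse_float(row["ssa_m2_per_g"], i, "ssa_m2_per_g")
        st = _parse_float(row["st_mN_per_m"], i, "st_mN_per_m")
        t1 = _parse_float(row["t1_h"], i, "t1_h")
        if design is not None:
            ssa = _snap_level(ssa, design.ssa_levels, level_tol, i, "ssa")
            st = _snap_level(st, design.st_levels, level_tol, i, "st")
            t1 = _check_grid(t1, design.t1_grid, i, "t1_h")
        mobility = _parse_float(row["mobility"], i, "mobility")
        zeta = _parse_float(row["zeta_mV"], i, "zeta_mV")
        if mobility * zeta < 0:
            raise DesignValidationError(
                f"row {i}: mobility ({mobility}) and zeta ({zeta}) differ in sign"
            )
        records.append(TimeScale1Record(
            condition=Condition(ssa, st),
            replicate=int(_parse_float(row["replicate"], i, "replicate")),
            t1=t1,
            mobility=mobility,
            zeta=zeta,
            gamma=_parse_float(row["gamma_mN_per_m"], i, "gamma_mN_per_m"),
            ph=_parse_optional(row.get("ph"), i, "ph"),
            digestibility=_parse_optional(row.get("digestibility"), i, "digestibility"),
            nh3n=_parse_optional(row.get("nh3n"), i, "nh3n"),
        ))
    return records


def read_t2_table(
    path,
    schema: Mapping[str, str] | None = None,
    design: ExperimentDesign | None = DEFAULT_DESIGN,
    level_tol: float = 0.05,
) -> list[TimeScale2Record]:
    """Read a t2-block (VFA) CSV into records; see :func:`read_t1_table`."""
    df = _load_frame(path, schema, T2_COLUMNS)
    records: list[TimeScale2Record] = []
    for i, rowdata in enumerate(df.itertuples(index=False), start=1):
        row = rowdata._asdict()
        ssa = _parse_float(row["ssa_m2_per_g"], i, "ssa_m2_per_g")
        st = _parse_float(row["st_mN_per_m"], i, "st_mN_per_m")
        t2 = _parse_float(row["t2_h"], i, "t2_h")
        if design is not None:
            ssa = _snap_level(ssa, design.ssa_levels, level_tol, i, "ssa")
            st = _snap_level(st, design.st_levels, level_tol, i, "st")
            t2 = _check_grid(t2, design.t2_grid, i, "t2_h")
        vfa = []
        for name in VFA_NAMES:
            value = _parse_float(row[name], i, name)
            if value < 0:
                raise DesignValidationError(
                    f"row {i}: VFA concentration {name}={value} is negative"
                )
            vfa.append(value)
        records.append(TimeScale2Record(
            condition=Condition(ssa, st),
            replicate=int(_parse_float(row["replicate"], i, "replicate")),
            t2=t2,
            vfa=tuple(vfa),
        ))
    return records


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float | None) -> str:
    # shortest representation that round-trips the float exactly
    return "" if x is None else repr(float(x))


def write_t1_table(records: Iterable[TimeScale1Record], path) -> None:
    """Write records as the canonical t1 CSV (exact float round-trip)."""
    rows = []
    for r in records:
        rows.append({
            "ssa_m2_per_g": _fmt(r.condition.ssa),
            "st_mN_per_m": _fmt(r.condition.st),
            "replicate": str(r.replicate),
            "t1_h": _fmt(r.t1),
            "mobility": _fmt(r.mobility),
            "zeta_mV": _fmt(r.zeta),
            "gamma_mN_per_m": _fmt(r.gamma),
            "ph": _fmt(r.ph),
            "digestibility": _fmt(r.digestibility),
            "nh3n": _fmt(r.nh3n),
        })
    pd.DataFrame(rows, columns=list(T1_COLUMNS)).to_csv(path, index=False)


def write_t2_table(records: Iterable[TimeScale2Record], path) -> None:
    """Write records as the canonical t2 CSV (exact float round-trip)."""
    rows = []
    for r in records:
        row = {
            "ssa_m2_per_g": _fmt(r.condition.ssa),
            "st_mN_per_m": _fmt(r.condition.st),
            "replicate": str(r.replicate),
            "t2_h": _fmt(r.t2),
        }
        row.update({name: _fmt(v) for name, v in zip(VFA_NAMES, r.vfa)})
        rows.append(row)
    pd.DataFrame(rows, columns=list(T2_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design validation


@dataclass(frozen=True)
class BlockReport:
    """Expected-vs-observed cell accounting for one block."""

    expected_n: int
    observed_n: int
    missing: tuple[tuple[Condition, int, float], ...]

    @property
    def complete(self) -> bool:
        return not self.missing


@dataclass(frozen=True)
class DesignReport:
    t1: BlockReport
    t2: BlockReport

    @property
    def complete(self) -> bool:
        return self.t1.complete and self.t2.complete


def _block_report(cells_observed, design: ExperimentDesign, grid) -> BlockReport:
    expected = [
        (cond, rep, float(t))
        for cond in design.conditions()
        for rep in range(1, design.replicates + 1)
        for t in grid
    ]
    observed = set(cells_observed)
    missing = tuple(cell for cell in expected if cell not in observed)
    return BlockReport(expected_n=len(expected), observed_n=len(observed),
                       missing=missing)


def validate_design(
    t1_records: Sequence[TimeScale1Record],
    t2_records: Sequence[TimeScale2Record],
    design: ExperimentDesign = DEFAULT_DESIGN,
) -> DesignReport:
    """Report expected vs observed (condition, replicate, time) cells per block.

    Never raises on incompleteness; inspect ``report.complete`` / ``.missing``.
    """
    t1_cells = [(r.condition, r.replicate, float(r.t1)) for r in t1_records]
    t2_cells = [(r.condition, r.replicate, float(r.t2)) for r in t2_records]
    return DesignReport(
        t1=_block_report(t1_cells, design, design.t1_grid),
        t2=_block_report(t2_cells, design, design.t2_grid),
    )


# ---------------------------------------------------------------------------
# bundled fixtures (published condition-level means; replicate column = 1)


def _data_path(name: str):
    return resources.files("rumenzeta.data").joinpath(name)


def load_t1_means() -> list[TimeScale1Record]:
    """The published t1-block condition means (72 records = 12 conditions x 6
    times).  These are means of 3 replicates, stored with replicate=1; analyses
    that need replicate-level spread require synthetic or supplementary data.
    """
    with resources.as_file(_data_path("t1_block_means.csv")) as p:
        return read_t1_table(p)


def load_t2_means() -> list[TimeScale2Record]:
    """The published t2-block condition means (48 records = 12 conditions x 4
    times); see :func:`load_t1_means`."""
    with resources.as_file(_data_path("t2_block_means.csv")) as p:
        return read_t2_table(p)


def load_t1_means_frame() -> pd.DataFrame:
    """Raw fixture table including the published standardized-value columns
    (``mobility_std``, ``zeta_std``), for cross-checks against the source."""
    with resources.as_file(_data_path("t1_block_means.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# optional workbook layout


def read_figshare_workbook(path, design: ExperimentDesign | None = DEFAULT_DESIGN):
    """Best-effort reader for the authors' supplementary workbook layout.

    Expects an .xlsx with one sheet per block whose headers can be mapped onto
    the canonical CSV schemas (case-insensitive match on the canonical names).
    Returns ``(t1_records, t2_records)``.  Requires an engine that pandas can
    use for xlsx (openpyxl).
    """
    sheets = pd.read_excel(path, sheet_name=None)
    t1_records: list[TimeScale1Record] = []
    t2_records: list[TimeScale2Record] = []
    import tempfile

    for name, df in sheets.items():
        cols = {str(c).strip().lower(): c for c in df.columns}
        if all(k in cols for k in T1_REQUIRED):
            kind, required = "t1", T1_COLUMNS
        elif all(k in cols for k in T2_COLUMNS):
            kind, required = "t2", T2_COLUMNS
        else:
            continue
        out = df.rename(columns={v: k for k, v in cols.items()})
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            out.to_csv(fh.name, index=False)
            if kind == "t1":
                t1_records.extend(read_t1_table(fh.name, design=design))
            else:
                t2_records.extend(read_t2_table(fh.name, design=design))
    return t1_records, t2_records
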