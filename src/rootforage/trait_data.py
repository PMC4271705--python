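"""Literature trait tables: reading, unit normalization, translation, summaries.

Uptake studies report Michaelis-Menten parameters in a zoo of units.
Everything here is normalized at ingest to the package's canonical
units — µmol g⁻¹ min⁻¹ for Vmax and µmol L⁻¹ (µM) for Km — using exact
rational conversion factors, after which records can be translated
per-record into Holling traits (a = Vmax/Km, h = 1/Vmax) and summarized
by nutrient form and weight basis.

Per-record translation matters: summary statistics of a and h must be
computed from individually translated records, because e.g. the median
of Vmax/Km over records is not the ratio of medians.

The expected CSV layout (the supplementary-data emulation) has header
columns ``species, family, nutrient, basis, v_max, v_max_units, k_m,
k_m_units, study_id`` (``family`` optional); alternative headers can be
mapped via ``column_map``.  Fresh- and dry-weight records carry their
basis as a tag and are summarized separately, never silently pooled.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, StructuralError, UnitError
from .kinetics import ForagerTraits, UptakeKinetics, mm_to_holling

__all__ = [
    "TraitRecord",
    "TraitTable",
    "ParseReport",
    "CANONICAL_VMAX_UNIT",
    "CANONICAL_KM_UNIT",
    "vmax_conversion_factor",
    "km_conversion_factor",
    "supported_units",
    "normalize_units",
    "read_trait_table",
    "translate_table",
    "summarize",
    "CV_DEFINITIONS",
]

CANONICAL_VMAX_UNIT = "umol g-1 min-1"
CANONICAL_KM_UNIT = "uM"

NUTRIENTS = ("NO3", "NH4")
BASES = ("dry", "fresh")

# --- unit registry -------------------------------------------------------
# Unit strings are canonicalized (micro sign -> u, superscripts -> -1,
# "/x" -> "x-1") and then parsed token-wise against these exact factors.

_AMOUNT = {  # factor to µmol
    "mol": Fraction(10**6),
    "mmol": Fraction(10**3),
    "umol": Fraction(1),
    "nmol": Fraction(1, 10**3),
    "pmol": Fraction(1, 10**6),
}
_PER_MASS = {  # per-mass token -> factor to per-g
    "g-1": Fraction(1),
    "mg-1": Fraction(10**3),
    "ug-1": Fraction(10**6),
    "kg-1": Fraction(1, 10**3),
}
_PER_TIME = {  # per-time token -> factor to per-min
    "min-1": Fraction(1),
    "s-1": Fraction(60),
    "sec-1": Fraction(60),
    "h-1": Fraction(1, 60),
    "hr-1": Fraction(1, 60),
    "d-1": Fraction(1, 1440),
}
_PER_VOLUME = {  # per-volume token -> factor to per-L
    "l-1": Fraction(1),
    "ml-1": Fraction(10**3),
    "m-3": Fraction(1, 10**3),
    "dm-3": Fraction(1),
}
_MOLARITY = {  # standalone molarity token -> factor to µM
    "m": Fraction(10**6),
    "mm": Fraction(10**3),
    "um": Fraction(1),
    "nm": Fraction(1, 10**3),
}

_CANON_REPLACEMENTS = [
    ("µ", "u"),  # micro sign
    ("μ", "u"),  # greek mu
    ("⁻¹", "-1"),
    ("⋅", " "),
    ("·", " "),
    ("**-1", "-1"),
    ("^-1", "-1"),
]


def _canon_tokens(unit: str) -> list[str]:
    s = unit.strip()
    for old, new in _CANON_REPLACEMENTS:
        s = s.replace(old, new)
    s = s.lower()
    # "umol/g/min" -> "umol g-1 min-1"
    parts = s.split("/")
    s = parts[0] + " " + " ".join(
        p.strip() + ("-1" if not p.strip().endswith("-1") else "") for p in parts[1:]
    )
    return s.split()


def vmax_conversion_factor(unit: str) -> Fraction:
    """Exact factor taking a Vmax in ``unit`` to µmol g⁻¹ min⁻¹."""
    tokens = _canon_tokens(unit)
    amount = mass = time = None
    for tok in tokens:
        if tok in _AMOUNT and amount is None:
            amount = _AMOUNT[tok]
        elif tok in _PER_MASS and mass is None:
            mass = _PER_MASS[tok]
        elif tok in _PER_TIME and time is None:
            time = _PER_TIME[tok]
        else:
            raise UnitError(
                f"cannot interpret token {tok!r} in Vmax unit {unit!r}; "
                f"supported units: {supported_units()['v_max']}"
            )
    if amount is None or mass is None or time is None:
        raise UnitError(
            f"Vmax unit {unit!r} must combine an amount, a per-mass and a "
            f"per-time token, e.g. {CANONICAL_VMAX_UNIT!r}"
        )
    return amount * mass * time


def km_conversion_factor(unit: str) -> Fraction:
    """Exact factor taking a Km (or concentration) in ``unit`` to µM."""
    tokens = _canon_tokens(unit)
    if len(tokens) == 1 and tokens[0] in _MOLARITY:
        return _MOLARITY[tokens[0]]
    amount = volume = None
    for tok in tokens:
        if tok in _AMOUNT and amount is None:
            amount = _AMOUNT[tok]
        elif tok in _PER_VOLUME and volume is None:
            volume = _PER_VOLUME[tok]
        else:
            raise UnitError(
                f"cannot interpret token {tok!r} in Km unit {unit!r}; "
                f"supported units: {supported_units()['k_m']}"
            )
    if amount is None or volume is None:
        raise UnitError(
            f"Km unit {unit!r} must be a molarity (M, mM, uM, nM) or an "
            f"amount per volume, e.g. 'umol L-1'"
        )
    return amount * volume


def supported_units() -> dict[str, str]:
    """Human-readable description of the unit registry."""
    return {
        "v_max": (
            f"<amount:{'/'.join(_AMOUNT)}> <per-mass:{'/'.join(_PER_MASS)}> "
            f"<per-time:{'/'.join(_PER_TIME)}>"
        ),
        "k_m": (
            f"molarity ({'/'.join(m.upper() for m in _MOLARITY)}) or "
            f"<amount:{'/'.join(_AMOUNT)}> <per-volume:{'/'.join(_PER_VOLUME)}>"
        ),
    }


# --- records and tables --------------------------------------------------

@dataclass(frozen=True)
class TraitRecord:
    """One literature observation of Michaelis-Menten uptake parameters."""

    species: str
    nutrient: str  # "NO3" or "NH4"
    basis: str     # "dry" or "fresh" root weight
    v_max: float
    v_max_units: str
    k_m: float
    k_m_units: str
    study_id: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.species or not str(self.species).strip():
            raise StructuralError("species name is empty")
        if self.nutrient not in NUTRIENTS:
            raise StructuralError(
                f"nutrient must be one of {NUTRIENTS}, got {self.nutrient!r}"
            )
        if self.basis not in BASES:
            raise StructuralError(f"basis must be one of {BASES}, got {self.basis!r}")
        for name in ("v_max", "k_m"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be positive and finite, got {v!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.species, self.nutrient, self.basis, self.study_id)

    @property
    def is_canonical(self) -> bool:
        return (
            self.v_max_units == CANONICAL_VMAX_UNIT
            and self.k_m_units == CANONICAL_KM_UNIT
        )

    def kinetics(self) -> UptakeKinetics:
        if not self.is_canonical:
            raise UnitError(
                "record is not in canonical units; call normalize_units first"
            )
        return UptakeKinetics(v_max=self.v_max, k_m=self.k_m)


def normalize_units(rec: TraitRecord) -> TraitRecord:
    """Return the record with Vmax in µmol g⁻¹ min⁻¹ and Km in µM.

    Idempotent: a record already in canonical units is returned with the
    same values.
    """
    fv = vmax_conversion_factor(rec.v_max_units)
    fk = km_conversion_factor(rec.k_m_units)
    return replace(
        rec,
        v_max=float(rec.v_max * fv),
        v_max_units=CANONICAL_VMAX_UNIT,
        k_m=float(rec.k_m * fk),
        k_m_units=CANONICAL_KM_UNIT,
    )


@dataclass
class ParseReport:
    """Row-level problems found while reading a trait table."""

    path: str = ""
    n_read: int = 0
    n_valid: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line, message)

    @property
    def ok(self) -> bool:
        return not self.errors

    def render(self) -> str:
        lines = [
            f"trait table: {self.path}",
            f"rows read: {self.n_read}, valid: {self.n_valid}",
        ]
        for lineno, msg in self.errors:
            lines.append(f"  line {lineno}: {msg}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TraitTable:
    """A validated collection of :class:`TraitRecord` with provenance."""

    records: tuple[TraitRecord, ...]
    provenance: ParseReport = field(default_factory=ParseReport, compare=False)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise StructuralError("a trait table needs at least one record")
        seen: set[tuple[str, str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise StructuralError(f"duplicate record key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, records: Iterable[TraitRecord]) -> "TraitTable":
        return cls(records=tuple(records))

    def normalized(self) -> "TraitTable":
        return TraitTable(
            records=tuple(normalize_units(r) for r in self.records),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "family": [r.family for r in self.records],
                "nutrient": [r.nutrient for r in self.records],
                "basis": [r.basis for r in self.records],
                "v_max": [r.v_max for r in self.records],
                "v_max_units": [r.v_max_units for r in self.records],
                "k_m": [r.k_m for r in self.records],
                "k_m_units": [r.k_m_units for r in self.records],
                "study_id": [r.study_id for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


_REQUIRED_COLUMNS = (
    "species",
    "nutrient",
    "basis",
    "v_max",
    "v_max_units",
    "k_m",
    "k_m_units",
    "study_id",
)


def read_trait_table(
    path: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    on_error: str = "collect",
) -> TraitTable:
    """Read and validate a delimited trait table.

    Parameters
    ----------
    path
        CSV file with a header row (or an open text buffer).
    column_map
        Optional mapping from this file's column names to the expected
        ones, for supplementary files with different headers.
    on_error
        ``"collect"`` (default) drops invalid rows and records them in
        the parse report; ``"raise"`` raises on the first invalid row.

    Raises
    ------
    StructuralError
        If a required column is missing, the file is empty, or no valid
        rows remain.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"trait table is missing required columns: {missing}")

    report = ParseReport(path=str(getattr(path, "name", path)), n_read=len(df))
    records: list[TraitRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            rec = _row_to_record(row)
        except (StructuralError, DomainError, UnitError, ValueError) as exc:
            if on_error == "raise":
                raise StructuralError(f"line {lineno}: {exc}") from exc
            report.errors.append((lineno, str(exc)))
            continue
        if rec.key in seen:
            msg = f"duplicate record key {rec.key}"
            if on_error == "raise":
                raise StructuralError(f"line {lineno}: {msg}")
            report.errors.append((lineno, msg))
            continue
        seen.add(rec.key)
        records.append(rec)
    report.n_valid = len(records)
    if not records:
        raise StructuralError(
            f"no valid rows in trait table {report.path!r}:\n{report.render()}"
        )
    return TraitTable(records=tuple(records), provenance=report)


def _row_to_record(row: pd.Series) -> TraitRecord:
    def cell(name: str) -> str:
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            raise StructuralError(f"missing {name}")
        return str(v).strip()

    v_max = float(cell("v_max"))
    k_m = float(cell("k_m"))
    # validate units eagerly so bad unit strings are reported per-row
    v_max_units = cell("v_max_units")
    k_m_units = cell("k_m_units")
    vmax_conversion_factor(v_max_units)
    km_conversion_factor(k_m_units)
    family = str(row.get("family", "") or "")
    if family.lower() == "nan":
        family = ""
    return TraitRecord(
        species=cell("species"),
        nutrient=cell("nutrient").upper().replace("-", "").replace("+", ""),
        basis=cell("basis").lower(),
        v_max=v_max,
        v_max_units=v_max_units,
        k_m=k_m,
        k_m_units=k_m_units,
        study_id=cell("study_id"),
        family=family,
    )


# --- translation and summaries ------------------------------------------

def translate_table(t: TraitTable | pd.DataFrame) -> pd.DataFrame:
    """Append per-record Holling traits to a canonical-unit trait table.

    Each record is translated individually (a = Vmax/Km, h = 1/Vmax)
    *before* any summarizing; original columns are preserved.  Accepts a
    :class:`TraitTable` (normalized first if needed) or a DataFrame
    already in canonical units; an empty DataFrame yields an empty
    result.
    """
    if isinstance(t, TraitTable):
        df = t.normalized().to_frame()
    else:
        df = t.copy()
        if len(df) == 0:
            out = df.copy()
            out["a"] = pd.Series(dtype=float)
            out["h"] = pd.Series(dtype=float)
            return out
    traits = [
        mm_to_holling(UptakeKinetics(v_max=v, k_m=k))
        for v, k in zip(df["v_max"].astype(float), df["k_m"].astype(float))
    ]
    out = df.copy()
    out["v_max"] = df["v_max"].astype(float)
    out["k_m"] = df["k_m"].astype(float)
    out["a"] = [tr.a for tr in traits]
    out["h"] = [tr.h for tr in traits]
    return out


def _cv_sd_mean(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if len(x) < 2 or m == 0:
        return float("nan") if len(x) < 2 else 0.0
    return float(np.std(x, ddof=1) / m)


def _cv_se_mean(x: np.ndarray) -> float:
    c = _cv_sd_mean(x)
    return c / np.sqrt(len(x)) if np.isfinite(c) else c


def _cv_sd_log1p(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(np.log1p(x), ddof=1))


#: Pluggable coefficient-of-variation definitions.  The literature
#: summaries this layout mirrors never state their CV definition, so the
#: choice is exposed: sample SD/mean (default), SE/mean, or the SD of
#: ln(x+1)-transformed values.
CV_DEFINITIONS = {
    "sd_mean": _cv_sd_mean,
    "se_mean": _cv_se_mean,
    "sd_log1p": _cv_sd_log1p,
}

_PARAMS = ("a", "h", "v_max", "k_m")


def summarize(
    translated: pd.DataFrame,
    group_keys: Sequence[str] = ("nutrient", "basis"),
    cv: str = "sd_mean",
) -> pd.DataFrame:
    """Per-group summary statistics of all four uptake/foraging parameters.

    For each group defined by ``group_keys`` and each parameter in
    (a, h, v_max, k_m): min, max, mean, median, cv and n.  Records from
    different studies of the same species remain separate data points.
    Groups absent from the data are simply absent from the output.
    """
    if cv not in CV_DEFINITIONS:
        raise DomainError(f"unknown cv definition {cv!r}; choose from {list(CV_DEFINITIONS)}")
    cv_fn = CV_DEFINITIONS[cv]
    missing = [k for k in group_keys if k not in translated.columns]
    if missing:
        raise StructuralError(f"group keys absent from table: {missing}")
    missing_p = [p for p in _PARAMS if p not in translated.columns]
    if missing_p:
        raise StructuralError(
            f"table lacks translated parameter columns {missing_p}; "
            "run translate_table first"
        )
    rows = []
    for keys, grp in translated.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for param in _PARAMS:
            x = grp[param].astype(float).to_numpy()
            rows.append(
                {
                    **dict(zip(group_keys, keys)),
                    "parameter": param,
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                    "mean": float(np.mean(x)),
                    "median": float(np.median(x)),
                    "cv": cv_fn(x),
                    "n": int(len(x)),
                }
            )
    return pd.DataFrame(rows)
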