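"""Composite UHDRS, disease burden score, and the clinical covariate table.

The composite UHDRS (cUHDRS) is a multidomain progression measure for
Huntington's disease combining one functional scale (Total Functional
Capacity, TFC), one motor scale (Total Motor Score, TMS) and two cognitive
scales (Symbol Digit Modalities Test, SDMT; Stroop Word Reading, SWR)::

    cUHDRS = (TFC - 10.4)/1.9 - (TMS - 29.7)/14.9
           + (SDMT - 28.4)/11.3 + (SWR - 66.1)/20.1 + 10

Higher scores indicate better function on every scale except TMS (and the
disease burden score), which increase with motor impairment.

The disease burden score (DBS) quantifies cumulative exposure to the
effects of mutant huntingtin as ``Age * (CAG - 35.5)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "ClinicalTable",
    "ClinicalFormatError",
    "cuhdrs",
    "disease_burden",
    "load_clinical_table",
]

# Centering constants and scale factors of the four cUHDRS components.
_CUHDRS_TERMS = {
    "tfc": (10.4, 1.9, +1.0),
    "tms": (29.7, 14.9, -1.0),
    "sdmt": (28.4, 11.3, +1.0),
    "swr": (66.1, 20.1, +1.0),
}

GROUPS = ("control", "carrier")
SEXES = ("F", "M")


class ClinicalFormatError(ValueError):
    """A clinical covariate table violates the documented format."""


def cuhdrs(tfc: float, tms: float, sdmt: float, swr: float) -> float:
    """Composite UHDRS from its four subscale scores.

    Linear in each component: unit-increase effects are +1/1.9 (TFC),
    -1/14.9 (TMS), +1/11.3 (SDMT), +1/20.1 (SWR). Returns 10 exactly at
    the centering point (10.4, 29.7, 28.4, 66.1).
    """
    vals = {"tfc": tfc, "tms": tms, "sdmt": sdmt, "swr": swr}
    total = 10.0
    for name, x in vals.items():
        x = float(x)
        if not math.isfinite(x):
            raise ValueError(f"cUHDRS component {name!r} must be finite, got {x!r}")
        center, scale, sign = _CUHDRS_TERMS[name]
        total += sign * (x - center) / scale
    return total


def disease_burden(age: float, cag: float) -> float:
    """Disease burden score ``age * (cag - 35.5)``.

    ``age`` is in years and must be positive; ``cag`` is the CAG repeat
    length of the expanded HTT allele. Carriers are expected to have
    CAG >= 36; smaller values are allowed but logged, since the score is
    occasionally evaluated for intermediate alleles.
    """
    age = float(age)
    cag = float(cag)
    if not math.isfinite(age) or not math.isfinite(cag):
        raise ValueError("age and cag must be finite")
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if cag < 36:
        logger.warning("disease_burden called with cag=%s < 36 (sub-carrier range)", cag)
    return age * (cag - 35.5)


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's clinical covariates at baseline."""

    subject_id: str
    group: str  # "control" | "carrier"
    age: float  # years
    sex: str  # "M" | "F"
    site: str
    cag: float | None = None  # carriers only
    tfc: float | None = None  # 0..13
    tms: float | None = None  # >= 0
    sdmt: float | None = None  # >= 0
    swr: float | None = None  # >= 0

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.group not in GROUPS:
            problems.append(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            problems.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (math.isfinite(self.age) and self.age > 0):
            problems.append(f"age must be positive and finite, got {self.age!r}")
        if self.tfc is not None and not (0 <= self.tfc <= 13):
            problems.append(f"tfc must be in [0, 13], got {self.tfc}")
        for name in ("tms", "sdmt", "swr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name} must be >= 0, got {v}")
        if self.cag is None and self.group == "carrier":
            problems.append("carrier record lacks a CAG repeat length")
        return problems

    @property
    def cuhdrs(self) -> float | None:
        """cUHDRS of this record, or None if any component is missing."""
        comps = (self.tfc, self.tms, self.sdmt, self.swr)
        if any(c is None for c in comps):
            return None
        return cuhdrs(*comps)

    @property
    def dbs(self) -> float | None:
        """Disease burden score, or None if CAG is absent (controls)."""
        if self.cag is None:
            return None
        return disease_burden(self.age, self.cag)


@dataclass
class ClinicalTable:
    """Ordered collection of clinical records, one row per subject."""

    records: list[ClinicalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ClinicalFormatError(f"duplicate subject_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def get(self, subject_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def subset(self, subject_ids: Iterable[str]) -> "ClinicalTable":
        wanted = list(subject_ids)
        return ClinicalTable([self.get(s) for s in wanted])

    def carriers(self) -> "ClinicalTable":
        return ClinicalTable([r for r in self.records if r.group == "carrier"])

    def to_frame(self) -> pd.DataFrame:
        """Covariate DataFrame with derived cuhdrs and dbs columns appended."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "age": r.age,
                    "sex": r.sex,
                    "site": r.site,
                    "cag": r.cag,
                    "tfc": r.tfc,
                    "tms": r.tms,
                    "sdmt": r.sdmt,
                    "swr": r.swr,
                    "cuhdrs": r.cuhdrs,
                    "dbs": r.dbs,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.to_frame().drop(columns=["cuhdrs", "dbs"])
        df.to_csv(path, index=False)

    def design_columns(
        self, subject_ids: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Nuisance design block: age plus dummy-coded sex and site.

        Categorical levels are ordered alphabetically; the first level is
        the reference. Single-level categoricals contribute no column (the
        synthetic default has one site, which would otherwise be collinear
        with the intercept); dropping it is logged.
        """
        recs = self.records if subject_ids is None else [self.get(s) for s in subject_ids]
        cols: list[np.ndarray] = [np.array([r.age for r in recs], float)]
        names = ["age"]
        for attr in ("sex", "site"):
            levels = sorted({getattr(r, attr) for r in recs})
            if len(levels) < 2:
                logger.info("nuisance covariate %r has a single level; dropped", attr)
                continue
            for lvl in levels[1:]:
                cols.append(np.array([1.0 if getattr(r, attr) == lvl else 0.0 for r in recs]))
                names.append(f"{attr}={lvl}")
        return np.column_stack(cols), names


_REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "site")
_NUMERIC_COLUMNS = ("age", "cag", "tfc", "tms", "sdmt", "swr")


def load_clinical_table(path) -> ClinicalTable:
    """Read and validate a clinical covariate CSV.

    The file must be comma-delimited UTF-8 with a header row naming, at
    least, subject_id/group/age/sex/site (case-insensitive); the score
    columns cag/tfc/tms/sdmt/swr may be empty per cell (missing values).
    Rows violating record invariants are reported with their row numbers.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalFormatError(f"missing required column(s): {missing}")

    bad_cells = []
    records = []
    problems = []
    for idx, row in df.iterrows():
        numeric: dict[str, float | None] = {}
        for col in _NUMERIC_COLUMNS:
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                numeric[col] = None
                continue
            try:
                numeric[col] = float(raw)
            except ValueError:
                bad_cells.append(f"row {idx + 2}, column {col!r}: {raw!r}")
        if bad_cells:
            continue
        if numeric["age"] is None:
            bad_cells.append(f"row {idx + 2}, column 'age': missing")
            continue
        rec = ClinicalRecord(
            subject_id=str(row["subject_id"]).strip(),
            group=str(row["group"]).strip().lower(),
            age=numeric["age"],
            sex=str(row["sex"]).strip().upper(),
            site=str(row["site"]).strip(),
            cag=numeric["cag"],
            tfc=numeric["tfc"],
            tms=numeric["tms"],
            sdmt=numeric["sdmt"],
            swr=numeric["swr"],
        )
        for p in rec.validate():
            problems.append(f"row {idx + 2} (subject {rec.subject_id}): {p}")
        records.append(rec)

    if bad_cells:
        raise ClinicalFormatError("unparseable numeric cell(s): " + "; ".join(bad_cells))
    if problems:
        raise ClinicalFormatError("invariant violation(s): " + "; ".join(problems))
    return ClinicalTable(records)
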