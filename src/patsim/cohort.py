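"""Patient cohorts: in-memory containers, delimited-text I/O, feature screening.

A cohort is one row per de-identified patient: an identifier, age in
years, sex, a semicolon-separated set of ICD-10 diagnosis codes, a fixed
panel of continuous laboratory values, and an optional binary disease
label (1 = case). Files are plain CSV with header
``id,age,sex,icd_codes,<lab columns...>[,label]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .icd import ICDCode, parse_icd_code

#: ICD-10 chapters excluded from study cohorts by default when filtering:
#: pregnancy (O), perinatal (P), injury/poisoning (S, T) and supplementary
#: classification (V, Y) codes.
DEFAULT_CHAPTER_BLACKLIST = frozenset("OPSTVY")

SEX_VALUES = ("male", "female")


@dataclass(frozen=True)
class Patient:
    """One EMR record: demographics, diagnosis code set, lab panel, label."""

    id: str
    age: float
    sex: str
    diagnoses: frozenset[ICDCode]
    labs: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"patient {self.id}: age must be positive, got {self.age}")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"patient {self.id}: sex must be one of {SEX_VALUES}")
        object.__setattr__(self, "labs", np.asarray(self.labs, dtype=float))
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"patient {self.id}: label must be 0/1 or None")


@dataclass
class Cohort:
    """A list of patients sharing one ordered lab panel."""

    patients: list[Patient]
    lab_names: list[str]

    def __post_init__(self) -> None:
        m = len(self.lab_names)
        seen: set[str] = set()
        for p in self.patients:
            if p.id in seen:
                raise ValueError(f"duplicate patient id {p.id!r}")
            seen.add(p.id)
            if p.labs.shape != (m,):
                raise ValueError(
                    f"patient {p.id}: expected {m} lab values, got {p.labs.shape}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def n_labs(self) -> int:
        return len(self.lab_names)

    @property
    def disease_universe(self) -> frozenset[ICDCode]:
        """Every diagnosis code observed in the cohort."""
        out: set[ICDCode] = set()
        for p in self.patients:
            out |= p.diagnoses
        return frozenset(out)

    @property
    def labels(self) -> np.ndarray:
        """0/1 label vector; raises if any patient is unlabeled."""
        if any(p.label is None for p in self.patients):
            raise ValueError("cohort contains unlabeled patients")
        return np.array([p.label for p in self.patients], dtype=int)

    @property
    def lab_matrix(self) -> np.ndarray:
        """(n_patients, n_labs) matrix in cohort order."""
        return np.vstack([p.labs for p in self.patients]) if self.patients else (
            np.empty((0, self.n_labs))
        )

    def subset(self, ids: Iterable[str]) -> "Cohort":
        """Sub-cohort restricted to ``ids``, in the order given."""
        by_id = {p.id: p for p in self.patients}
        return Cohort([by_id[i] for i in ids], list(self.lab_names))

    def filter_chapters(
        self, blacklist: frozenset[str] = DEFAULT_CHAPTER_BLACKLIST
    ) -> "Cohort":
        """Drop patients carrying any diagnosis from a blacklisted chapter."""
        keep = [
            p
            for p in self.patients
            if not any(c.text[0] in blacklist for c in p.diagnoses)
        ]
        return Cohort(keep, list(self.lab_names))


_META_COLS = ["id", "age", "sex", "icd_codes"]


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, canonicalizing and validating every row.

    Raises :class:`ValueError` naming the offending row for missing lab
    values, duplicate ids, unparsable codes or non-positive ages.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns {missing}")
    has_label = "label" in df.columns
    lab_names = [c for c in df.columns if c not in _META_COLS + ["label"]]

    patients: list[Patient] = []
    for row_no, rec in enumerate(df.to_dict("records"), start=2):
        labs = np.array([rec[c] for c in lab_names], dtype=float)
        if np.isnan(labs).any():
            bad = lab_names[int(np.isnan(labs).argmax())]
            raise ValueError(f"row {row_no}: missing lab value in column {bad!r}")
        codes_cell = rec["icd_codes"]
        if not isinstance(codes_cell, str) or not codes_cell.strip():
            raise ValueError(f"row {row_no}: empty diagnosis code set")
        try:
            codes = frozenset(
                parse_icd_code(tok) for tok in codes_cell.split(";") if tok.strip()
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
        age = float(rec["age"])
        if age <= 0:
            raise ValueError(f"row {row_no}: non-positive age {age}")
        label = None
        if has_label and not pd.isna(rec["label"]):
            label = int(rec["label"])
        try:
            patients.append(
                Patient(str(rec["id"]), age, str(rec["sex"]), codes, labs, label)
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
    return Cohort(patients, lab_names)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips exactly.

    Diagnosis codes are serialized sorted, ';'-joined; lab values with
    full float repr so the round trip is bit-identical.
    """
    has_label = any(p.label is not None for p in cohort.patients)
    cols = _META_COLS + cohort.lab_names + (["label"] if has_label else [])
    rows = []
    for p in cohort.patients:
        rec = {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "icd_codes": ";".join(sorted(c.text for c in p.diagnoses)),
        }
        rec.update({name: repr(float(v)) for name, v in zip(cohort.lab_names, p.labs)})
        if has_label:
            rec["label"] = p.label
        rows.append(rec)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def screen_diagnosis_features(
    cohort: Cohort, min_prevalence: float = 0.01, alpha: float = 0.05
) -> frozenset[ICDCode]:
    """Two-stage diagnosis feature screen for modeling.

    Stage 1 drops codes present in fewer than ``min_prevalence`` of the
    cohort (default 1%). Stage 2 keeps, among the survivors, codes whose
    2x2 presence-by-label chi-squared test gives P < ``alpha`` (default
    0.05) — i.e. codes whose occurrence rate differs between classes.
    The retained set is used as binary indicator features.
    """
    y = cohort.labels  # raises on unlabeled cohort
    n = len(cohort)
    retained: set[ICDCode] = set()
    for code in cohort.disease_universe:
        present = np.array([code in p.diagnoses for p in cohort.patients])
        if present.sum() / n < min_prevalence:
            continue
        table = np.array(
            [
                [(present & (y == 1)).sum(), (~present & (y == 1)).sum()],
                [(present & (y == 0)).sum(), (~present & (y == 0)).sum()],
            ]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue  # degenerate margin: no association testable
        _, p_value, _, _ = chi2_contingency(table)
        if p_value < alpha:
            retained.add(code)
    return frozenset(retained)
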