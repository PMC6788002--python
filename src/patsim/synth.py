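"""Synthetic EMR cohort generator.

Emulates the statistical structure of a hospital diabetes case-control
study population so the whole pipeline is testable without any real
data: two balanced classes (DM / non-DM) with class-specific age
distributions (63.0 +/- 11.6 vs 57.2 +/- 17.1 years) and male fractions
(62.6% vs 73.5%), a 77-item laboratory panel with a small subset of
class-informative glucose-related items, and per-patient ICD-10
diagnosis sets drawn from a ~20-code universe spanning several chapters
and all depths of prefix sharing, with class-skewed comorbidity
prevalences. DM-class patients always carry at least one code from the
label-defining E10-E14 block; controls never do.

What this emulates — and what it does not — is discussed in the
package's methods note: labs are conditionally independent Gaussians,
diagnoses are (near-)independent Bernoullis, and there is no
longitudinal or missing-data structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import Cohort, Patient
from .icd import ICDCode, parse_icd_code

#: The label-defining diabetes code block (ICD-10 E10-E14).
DM_PREFIXES = ("E10", "E11", "E12", "E13", "E14")

#: Default code universe: (code, prevalence in DM class, prevalence in
#: controls). The E10-E14 block is exclusive to the DM class; comorbidity
#: prevalences are skewed the way chronic diseases co-occur with diabetes
#: (hypertensive/ischemic heart disease, dyslipidemia, obesity, renal
#: disease more common; respiratory/hepatic roughly balanced). Pairs are
#: arranged so the hierarchy is exercised at every depth (E109/E119 share
#: E1; I251/I259 share I25; E115/E119 share E11 yet map to different CCS
#: categories; E142/E115 share only E1 yet map to the same category).
DEFAULT_CODE_PREVALENCE: tuple[tuple[str, float, float], ...] = (
    ("E109", 0.45, 0.0),
    ("E119", 0.45, 0.0),
    ("E115", 0.15, 0.0),
    ("E142", 0.15, 0.0),
    ("E039", 0.08, 0.05),
    ("E669", 0.20, 0.08),
    ("E780", 0.30, 0.15),
    ("E785", 0.15, 0.08),
    ("I209", 0.15, 0.10),
    ("I251", 0.45, 0.30),
    ("I259", 0.12, 0.08),
    ("I509", 0.12, 0.07),
    ("I639", 0.10, 0.07),
    ("J189", 0.06, 0.07),
    ("J449", 0.08, 0.10),
    ("J459", 0.04, 0.05),
    ("K219", 0.08, 0.08),
    ("K739", 0.04, 0.05),
    ("K769", 0.10, 0.12),
    ("N189", 0.12, 0.04),
    ("N390", 0.08, 0.06),
    ("G459", 0.06, 0.04),
    ("M819", 0.06, 0.05),
    ("D649", 0.10, 0.08),
    ("F329", 0.04, 0.05),
)

_INFORMATIVE_LAB_NAMES = (
    "serum_glucose",
    "urine_glucose",
    "glycated_hemoglobin",
    "triglycerides",
    "hdl_cholesterol",
    "serum_chloride",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributional targets for the generated case-control cohort."""

    n_per_class: int = 500
    age_mean_dm: float = 63.0
    age_sd_dm: float = 11.6
    age_mean_ctrl: float = 57.2
    age_sd_ctrl: float = 17.1
    age_min: float = 18.0
    male_frac_dm: float = 0.626
    male_frac_ctrl: float = 0.735
    n_labs: int = 77
    n_informative_labs: int = 6
    lab_effect_size: float = 0.8
    code_prevalence: tuple[tuple[str, float, float], ...] = DEFAULT_CODE_PREVALENCE
    diagnoses_min: int = 1
    diagnoses_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.male_frac_dm, self.male_frac_ctrl):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("male fractions must lie in [0, 1]")
        for _, p_dm, p_ctrl in self.code_prevalence:
            if not (0.0 <= p_dm <= 1.0 and 0.0 <= p_ctrl <= 1.0):
                raise ValueError("code prevalences must lie in [0, 1]")
        if not 1 <= self.n_informative_labs <= self.n_labs:
            raise ValueError("n_informative_labs must lie in [1, n_labs]")
        if not 1 <= self.diagnoses_min <= self.diagnoses_max:
            raise ValueError("invalid diagnoses_per_patient range")
        if self.diagnoses_max > len(self.code_prevalence):
            raise ValueError("diagnoses_max exceeds the code universe size")
        # a DM patient must be able to carry a label-defining code
        if not any(
            code.startswith(DM_PREFIXES) and p_dm > 0
            for code, p_dm, _ in self.code_prevalence
        ):
            raise ValueError("code universe has no E10-E14 code with DM prevalence > 0")

    @property
    def lab_names(self) -> list[str]:
        names = list(_INFORMATIVE_LAB_NAMES[: self.n_informative_labs])
        while len(names) < self.n_informative_labs:
            names.append(f"informative_{len(names) + 1:02d}")
        names += [f"lab_{i:02d}" for i in range(len(names) + 1, self.n_labs + 1)]
        return names[: self.n_labs]

    @property
    def code_universe(self) -> list[ICDCode]:
        return [parse_icd_code(c) for c, _, _ in self.code_prevalence]


def default_config() -> SyntheticConfig:
    """The packaged default study conditions."""
    return SyntheticConfig()


def _truncated_normal_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float
) -> np.ndarray:
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_diagnoses(
    rng: np.random.Generator,
    prevalences: np.ndarray,
    codes: list[ICDCode],
    is_dm: bool,
    dm_mask: np.ndarray,
    lo: int,
    hi: int,
) -> frozenset[ICDCode]:
    present = rng.random(len(codes)) < prevalences
    # label-defining guarantee: every DM patient carries >= 1 E10-E14 code
    if is_dm and not present[dm_mask].any():
        w = prevalences * dm_mask
        present[rng.choice(len(codes), p=w / w.sum())] = True
    # respect the diagnoses-per-patient range
    if present.sum() < lo:
        absent = np.flatnonzero(~present)
        w = np.maximum(prevalences[absent], 1e-9)
        extra = rng.choice(absent, size=lo - present.sum(), replace=False, p=w / w.sum())
        present[extra] = True
    if present.sum() > hi:
        # drop uniformly, but never a DM patient's only label-defining code
        protected = np.flatnonzero(present & dm_mask)[0] if is_dm else -1
        droppable = np.array([i for i in np.flatnonzero(present) if i != protected])
        drop = rng.choice(droppable, size=int(present.sum()) - hi, replace=False)
        present[drop] = False
    return frozenset(c for c, p in zip(codes, present) if p)


def generate_cohort(config: SyntheticConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a labeled synthetic cohort under ``config`` (reproducible).

    ``seed`` overrides ``config.seed``. Class 1 is DM. Ages come from
    per-class normals truncated at ``age_min``; sex from per-class
    Bernoullis; labs from unit-variance Gaussians on an arbitrary raw
    scale, the informative items shifted upward by ``lab_effect_size``
    standard deviations in the DM class; diagnosis sets from per-code
    Bernoullis with class-specific prevalence, adjusted to the
    configured per-patient range.
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codes = config.code_universe
    prev = np.array([(p_dm, p_ctrl) for _, p_dm, p_ctrl in config.code_prevalence])
    dm_mask = np.array([c.text.startswith(DM_PREFIXES) for c in codes])

    # raw lab scale: deterministic per-item location/scale so files look
    # like un-normalized measurements and exercise the z-scoring path
    idx = np.arange(config.n_labs)
    lab_loc = 5.0 + 2.0 * idx
    lab_scale = 1.0 + 0.1 * (idx % 7)
    informative = idx < config.n_informative_labs

    patients: list[Patient] = []
    n = config.n_per_class
    width = len(str(2 * n))
    for cls, (age_mu, age_sd, male_frac) in enumerate(
        [
            (config.age_mean_ctrl, config.age_sd_ctrl, config.male_frac_ctrl),
            (config.age_mean_dm, config.age_sd_dm, config.male_frac_dm),
        ]
    ):
        ages = _truncated_normal_ages(rng, n, age_mu, age_sd, config.age_min)
        males = rng.random(n) < male_frac
        shift = config.lab_effect_size * lab_scale * informative if cls == 1 else 0.0
        labs = rng.normal(lab_loc + shift, lab_scale, size=(n, config.n_labs))
        for i in range(n):
            diagnoses = _draw_diagnoses(
                rng,
                prev[:, 0] if cls == 1 else prev[:, 1],
                codes,
                cls == 1,
                dm_mask,
                config.diagnoses_min,
                config.diagnoses_max,
            )
            pid = f"{'d' if cls == 1 else 'c'}{i + 1:0{width}d}"
            patients.append(
                Patient(
                    id=pid,
                    age=float(np.round(ages[i], 1)),
                    sex="male" if males[i] else "female",
                    diagnoses=diagnoses,
                    labs=np.round(labs[i], 4),
                    label=cls,
                )
            )
    return Cohort(patients, config.lab_names)


def planted_structure_report(
    cohort: Cohort, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Per-class descriptive summary used to verify the generator's targets.

    One row per characteristic: age (mean, sd), male proportion, each
    lab item's per-class mean and pooled-SD standardized mean
    difference, and each observed code's per-class prevalence.
    """
    y = cohort.labels  # raises on unlabeled cohorts
    dm = [p for p, lab in zip(cohort.patients, y) if lab == 1]
    ctrl = [p for p, lab in zip(cohort.patients, y) if lab == 0]
    rows: list[dict] = []

    def _row(kind, name, v_dm, v_ctrl, extra=None):
        rows.append(
            dict(kind=kind, name=name, dm=v_dm, ctrl=v_ctrl, smd=extra)
        )

    ages_dm = np.array([p.age for p in dm])
    ages_ctrl = np.array([p.age for p in ctrl])
    _row("age_mean", "age", ages_dm.mean(), ages_ctrl.mean())
    _row("age_sd", "age", ages_dm.std(ddof=1), ages_ctrl.std(ddof=1))
    _row(
        "male_frac",
        "sex",
        np.mean([p.sex == "male" for p in dm]),
        np.mean([p.sex == "male" for p in ctrl]),
    )
    L_dm = np.vstack([p.labs for p in dm])
    L_ctrl = np.vstack([p.labs for p in ctrl])
    for j, name in enumerate(cohort.lab_names):
        sd_pool = np.sqrt(
            (L_dm[:, j].var(ddof=1) + L_ctrl[:, j].var(ddof=1)) / 2.0
        )
        smd = (L_dm[:, j].mean() - L_ctrl[:, j].mean()) / sd_pool
        _row("lab_mean", name, L_dm[:, j].mean(), L_ctrl[:, j].mean(), smd)
    universe = (
        config.code_universe if config is not None else sorted(
            cohort.disease_universe, key=lambda c: c.text
        )
    )
    for code in universe:
        _row(
            "code_prevalence",
            code.text,
            np.mean([code in p.diagnoses for p in dm]),
            np.mean([code in p.diagnoses for p in ctrl]),
        )
    return pd.DataFrame(rows)
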