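"""Virtual cohorts and simulated trials for the rabeprazole study design.

The generator emulates a 45-subject (24 male / 21 female) single-dose
10 mg design: body surface area is drawn log-normally around the reported
gender medians (1.87 m^2 male, 1.58 m^2 female), height per gender is
normal, and body weight is back-derived from BSA and height through the
DuBois relation so that weight and BSA stay coherent.  Trial simulation
draws log-normal etas, solves the structural model, applies log-additive
residual error and censors below the LLOQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TrialDataset
from .model import apply_residual_error, solve_profile
from .params import (
    CovariateConfig,
    DoseEvent,
    PopulationParameters,
    SubjectCovariates,
    individual_parameters,
)
from .pd import EffectMetrics, EffectProfile, SigmoidEmaxParams, effect_at_concentration, effect_metrics

__all__ = [
    "CohortSpec",
    "DEFAULT_SCHEDULE",
    "generate_cohort",
    "simulate_trial",
    "simulate_population_pd",
    "simulate_stratum_conc",
]

#: sampling schedule (h): dense over the 0-5 h absorption window
DEFAULT_SCHEDULE = (
    0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 8.0, 10.0, 12.0
)


@dataclass(frozen=True)
class CohortSpec:
    """Demographic and design parameters of a virtual cohort."""

    n_male: int = 24
    n_female: int = 21
    bsa_median_male: float = 1.87
    bsa_median_female: float = 1.58
    bsa_cv: float = 0.08
    height_mean_male: float = 174.0
    height_mean_female: float = 161.0
    height_sd: float = 5.0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    dose_mg: float = 10.0
    lloq: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort counts must be >= 0")
        sched = np.asarray(self.schedule, float)
        if sched[0] != 0 or (len(sched) > 1 and not np.all(np.diff(sched) > 0)):
            raise ValueError("schedule must be strictly increasing and start at 0")


def _dubois_weight(bsa: np.ndarray, height_cm: np.ndarray) -> np.ndarray:
    """Invert DuBois BSA = 0.007184 * W^0.425 * H^0.725 for weight (kg)."""
    return (bsa / (0.007184 * height_cm**0.725)) ** (1.0 / 0.425)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subject covariate table: ID, gender, bsa, height, weight.

    BSA is log-normal with the gender-specific median and CV; zero CV
    collapses every subject onto the median exactly.
    """
    rng = rng or np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.bsa_cv**2))
    rows = []
    sid = 1
    for gender, n, med, hmean in (
        ("male", spec.n_male, spec.bsa_median_male, spec.height_mean_male),
        ("female", spec.n_female, spec.bsa_median_female, spec.height_mean_female),
    ):
        bsa = med * np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.full(n, med)
        height = rng.normal(hmean, spec.height_sd, size=n)
        weight = _dubois_weight(bsa, height)
        for b, h, w in zip(bsa, height, weight):
            rows.append({"ID": sid, "gender": gender, "bsa": float(b),
                         "height": float(h), "weight": float(w)})
            sid += 1
    return pd.DataFrame(rows)


def _draw_eta(pop: PopulationParameters, rng: np.random.Generator) -> dict[str, float]:
    return {
        name: float(rng.normal(0.0, np.sqrt(pop.omega2[name])))
        for name in pop.eta_names
    }


def simulate_trial(
    cohort: pd.DataFrame,
    pop: PopulationParameters,
    spec: CohortSpec,
    config: CovariateConfig | None = None,
    seed: int | None = None,
    residual_error: bool = True,
) -> TrialDataset:
    """Simulate a complete trial dataset (NONMEM convention) from a cohort.

    Per subject: draw etas from N(0, omega^2), build individual
    parameters, solve the profile on the schedule, apply log-additive
    error (optional) and censor observations below the LLOQ to zero.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    config = config or CovariateConfig()
    dose = DoseEvent.from_mg(spec.dose_mg)
    times = np.asarray(spec.schedule, float)
    obs_times = times[times > 0]  # the time-0 sample is pre-dose
    rows = []
    for rec in cohort.itertuples():
        cov = SubjectCovariates(gender=rec.gender, bsa=rec.bsa, body_weight=rec.weight)
        eta = _draw_eta(pop, rng)
        ind = individual_parameters(pop, cov, eta, config)
        profile = solve_profile(ind, dose, obs_times)
        conc = (
            apply_residual_error(profile, pop.sigma, rng)
            if residual_error
            else profile.conc.copy()
        )
        conc = np.where(conc < spec.lloq, 0.0, conc)
        sex = 0 if rec.gender == "male" else 1
        base = {"ID": rec.ID, "SEX": sex, "WT": rec.weight, "BSA": rec.bsa}
        rows.append({**base, "TIME": 0.0, "AMT": dose.amount, "DV": 0.0,
                     "EVID": 1, "MDV": 1})
        for t, c in zip(obs_times, conc):
            rows.append({**base, "TIME": t, "AMT": 0.0, "DV": float(c),
                         "EVID": 0, "MDV": int(c <= 0)})
    df = pd.DataFrame(rows)[["ID", "TIME", "AMT", "DV", "EVID", "MDV", "SEX", "WT", "BSA"]]
    return TrialDataset(df, lloq=spec.lloq)


# ---------------------------------------------------------------------------
# Population PD simulation
# ---------------------------------------------------------------------------

def simulate_stratum_conc(
    pop: PopulationParameters,
    gender: str,
    bsa: float,
    n_subjects: int,
    grid: np.ndarray,
    rng: np.random.Generator,
    dose_mg: float = 10.0,
    config: CovariateConfig | None = None,
) -> np.ndarray:
    """(n_subjects, len(grid)) noise-free concentration curves with IIV."""
    config = config or CovariateConfig()
    dose = DoseEvent.from_mg(dose_mg)
    cov = SubjectCovariates(gender=gender, bsa=bsa)
    out = np.empty((n_subjects, grid.size))
    for i in range(n_subjects):
        eta = _draw_eta(pop, rng)
        ind = individual_parameters(pop, cov, eta, config)
        out[i] = solve_profile(ind, dose, grid).conc
    return out


@dataclass
class StratumPD:
    median_profile: EffectProfile
    metrics: EffectMetrics
    percentile_metrics: dict[str, EffectMetrics] = field(default_factory=dict)


def simulate_population_pd(
    pop: PopulationParameters,
    pd_params: SigmoidEmaxParams,
    strata: dict[str, tuple[str, float]] | None = None,
    n_subjects: int = 500,
    window: tuple[float, float] = (0.0, 10.0),
    dt: float = 0.01,
    seed: int = 0,
    dose_mg: float = 10.0,
    config: CovariateConfig | None = None,
    threshold: float = 4.0,
    n_replicate_cohorts: int = 0,
    replicate_size: int = 45,
) -> dict[str, StratumPD]:
    """Gender-stratified population PK-PD simulation of gastric pH.

    Each stratum (name -> (gender, BSA)) simulates ``n_subjects`` virtual
    subjects with PK inter-individual variability only (the PD model has
    no subject-level random effects), maps concentration to pH, forms the
    pointwise-median pH profile and extracts its effect metrics — the
    analogue of a median (50th percentile) population prediction.  When
    ``n_replicate_cohorts`` > 0, small replicate cohorts of
    ``replicate_size`` subjects provide 5%/95% percentile-profile
    analogues.  A stratum whose median profile never crosses the
    threshold reports duration 0 and no onset.
    """
    if n_subjects < 100:
        raise ValueError("n_subjects must be >= 100 per stratum")
    strata = strata or {"male": ("male", 1.87), "female": ("female", 1.58)}
    grid = np.arange(window[0], window[1] + dt / 2, dt)
    results: dict[str, StratumPD] = {}
    rng = np.random.default_rng(seed)
    for name, (gender, bsa) in strata.items():
        conc = simulate_stratum_conc(
            pop, gender, bsa, n_subjects, grid, rng, dose_mg, config
        )
        ph = effect_at_concentration(conc, pd_params)
        median_ph = np.median(ph, axis=0)
        profile = EffectProfile(times=grid, pH=median_ph)
        metrics = effect_metrics(profile, threshold=threshold, window=window)
        pctl: dict[str, EffectMetrics] = {}
        if n_replicate_cohorts > 0:
            med_profiles = np.empty((n_replicate_cohorts, grid.size))
            for r in range(n_replicate_cohorts):
                sub = rng.choice(n_subjects, size=replicate_size, replace=True)
                med_profiles[r] = np.median(ph[sub], axis=0)
            for label, q in (("p5", 5.0), ("p50", 50.0), ("p95", 95.0)):
                prof = EffectProfile(times=grid, pH=np.percentile(med_profiles, q, axis=0))
                pctl[label] = effect_metrics(prof, threshold=threshold, window=window)
        results[name] = StratumPD(
            median_profile=profile, metrics=metrics, percentile_metrics=pctl
        )
    return results
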