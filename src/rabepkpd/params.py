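"""Parameter containers for the rabeprazole population PK model.

The structural model is a two-compartment disposition with three sequential
first-order absorption depots and an absorption lag time, parameterized
apparent-oral (/F).  Inter-individual variability (IIV) is log-normal
(exponential eta model) and the residual error is log-additive.

Units follow the package convention: amounts in ng, volumes in L,
clearances in L/h, rate constants 1/h, times in h, concentrations in ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

#: Parameters that may carry inter-individual variability.
ETA_NAMES = ("Vc", "CLc", "Ka1", "Ka2", "Ka3", "Tlag")

#: Structural (typical-value) parameter names, fixed order.
STRUCTURAL_NAMES = ("Vc", "CLc", "Vp", "CLp", "Ka1", "Ka2", "Ka3", "Tlag")

MG_TO_NG = 1.0e6


@dataclass(frozen=True)
class PopulationParameters:
    """Typical values, covariate coefficients, IIV variances and residual SD.

    ``omega2`` maps parameter name -> log-scale IIV variance; only the keys
    in :data:`ETA_NAMES` are allowed and the peripheral-compartment
    parameters (Vp, CLp) deliberately carry no IIV.  ``sigma`` is the SD of
    the log-additive residual error (dimensionless on the log scale).
    """

    tvVc: float
    tvCLc: float
    tvVp: float
    tvCLp: float
    tvKa1: float
    tvKa2: float
    tvKa3: float
    tvTlag: float
    dTlagdGender: float = 0.0
    dKa3dBSA: float = 0.0
    omega2: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 0.1

    def __post_init__(self) -> None:
        for name in STRUCTURAL_NAMES:
            value = getattr(self, "tv" + name)
            if not value > 0:
                raise ValueError(f"typical value tv{name} must be > 0, got {value}")
        for key, value in self.omega2.items():
            if key not in ETA_NAMES:
                raise ValueError(f"IIV not supported on parameter {key!r}")
            if value < 0:
                raise ValueError(f"omega2[{key!r}] must be >= 0, got {value}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def typical(self, name: str) -> float:
        return getattr(self, "tv" + name)

    def with_updates(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)

    @property
    def eta_names(self) -> tuple[str, ...]:
        """Parameters with strictly positive IIV variance, in canonical order."""
        return tuple(n for n in ETA_NAMES if self.omega2.get(n, 0.0) > 0.0)


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics of one subject: gender, BSA (m^2), body weight (kg)."""

    gender: Literal["male", "female"]
    bsa: float
    body_weight: float = 70.0
    biochemistry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if not self.bsa > 0:
            raise ValueError(f"bsa must be > 0, got {self.bsa}")
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")


@dataclass(frozen=True)
class CovariateConfig:
    """How covariates enter the individual-parameter model.

    ``form='exponential'`` is the default multiplicative-exponential
    convention on log-normal parameters, P_i = tvP * exp(coef * x + eta);
    ``form='additive'`` shifts the typical value, P_i = (tvP + coef * x) *
    exp(eta).  Gender is coded male=``gender_male_code`` (default 0),
    female=``gender_female_code`` (default 1); BSA is centred at
    ``bsa_ref`` (default 1.73 m^2, the midpoint of the reported
    gender-median BSAs).
    """

    form: Literal["exponential", "additive"] = "exponential"
    gender_male_code: float = 0.0
    gender_female_code: float = 1.0
    bsa_ref: float = 1.73

    def gender_code(self, gender: str) -> float:
        return self.gender_male_code if gender == "male" else self.gender_female_code

    def covariate_value(self, covariate: str, cov: "SubjectCovariates") -> float:
        """Numeric design value for a named covariate."""
        if covariate == "gender":
            return self.gender_code(cov.gender)
        if covariate == "bsa":
            return cov.bsa - self.bsa_ref
        if covariate == "body_weight":
            return cov.body_weight
        try:
            return float(cov.biochemistry[covariate])
        except KeyError:
            raise KeyError(f"unknown covariate {covariate!r}") from None


@dataclass(frozen=True)
class IndividualParameters:
    """Post-covariate, post-eta parameter set for one subject."""

    Vc: float
    CLc: float
    Vp: float
    CLp: float
    Ka1: float
    Ka2: float
    Ka3: float
    Tlag: float

    def __post_init__(self) -> None:
        for name in STRUCTURAL_NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STRUCTURAL_NAMES])


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose, amount in ng (10 mg = 1.0e7 ng)."""

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")

    @classmethod
    def from_mg(cls, mg: float, time: float = 0.0) -> "DoseEvent":
        return cls(amount=mg * MG_TO_NG, time=time)


def individual_parameters(
    pop: PopulationParameters,
    cov: SubjectCovariates,
    eta: Mapping[str, float] | None = None,
    config: CovariateConfig | None = None,
) -> IndividualParameters:
    """Combine typical values, covariate effects and etas into one subject's set.

    The final covariate model places gender on Tlag and BSA on Ka3:

    - exponential form: ``Tlag_i = tvTlag * exp(dTlagdGender*g + eta_Tlag)``,
      ``Ka3_i = tvKa3 * exp(dKa3dBSA*(BSA - bsa_ref) + eta_Ka3)``
    - additive form:    ``Tlag_i = (tvTlag + dTlagdGender*g) * exp(eta_Tlag)``
      and analogously for Ka3.

    All parameters without a covariate follow ``P_i = tvP * exp(eta_P)``.
    """
    eta = dict(eta or {})
    config = config or CovariateConfig()
    unknown = set(eta) - set(ETA_NAMES)
    if unknown:
        raise ValueError(f"unknown eta keys: {sorted(unknown)}")

    g = config.gender_code(cov.gender)
    dbsa = cov.bsa - config.bsa_ref

    values: dict[str, float] = {}
    for name in STRUCTURAL_NAMES:
        tv = pop.typical(name)
        e = eta.get(name, 0.0)
        shift = 0.0
        if name == "Tlag":
            shift = pop.dTlagdGender * g
        elif name == "Ka3":
            shift = pop.dKa3dBSA * dbsa
        if config.form == "exponential":
            values[name] = tv * np.exp(shift + e)
        else:  # additive shift on the typical value
            base = tv + shift
            if base <= 0:
                raise ValueError(
                    f"additive covariate shift drives {name} non-positive ({base})"
                )
            values[name] = base * np.exp(e)
    return IndividualParameters(**values)
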