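"""Access to the packaged published parameter values (final PK and PD model)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .params import PopulationParameters
from .pd import SigmoidEmaxParams


@lru_cache(maxsize=1)
def _load_raw() -> dict:
    with resources.files("rabepkpd.data").joinpath("published_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def published_pk() -> PopulationParameters:
    """Final published population PK parameter set for 10 mg oral rabeprazole."""
    raw = _load_raw()["pk"]
    return PopulationParameters(
        tvVc=raw["tvVc"], tvCLc=raw["tvCLc"], tvVp=raw["tvVp"], tvCLp=raw["tvCLp"],
        tvKa1=raw["tvKa1"], tvKa2=raw["tvKa2"], tvKa3=raw["tvKa3"],
        tvTlag=raw["tvTlag"], dTlagdGender=raw["dTlagdGender"],
        dKa3dBSA=raw["dKa3dBSA"], omega2=dict(raw["omega2"]), sigma=raw["sigma"],
    )


def published_pd() -> SigmoidEmaxParams:
    """Published sigmoid-Emax-with-baseline gastric-pH parameter set."""
    raw = _load_raw()["pd"]
    return SigmoidEmaxParams(
        E0=raw["E0"], Emax=raw["Emax"], gamma=raw["gamma"], EC50=raw["EC50"]
    )


def published_cohort_defaults() -> dict:
    """Demographics of the study cohort the synthetic generator emulates."""
    return dict(_load_raw()["cohort"])
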