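"""Alternative absorption structures sharing the two-compartment disposition.

These variants back the structural model-selection demonstration: a plain
first-order input, first-order with lag, sequential k-depot chains (k = 2
or 3), a non-sequential two-depot split, Weibull-input absorption and a
transit-compartment (mean-transit-time) model.  Saturable and zero-order
inputs, and chains longer than three depots, are out of scope.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .model import ConcentrationProfile, _chain_amount_expm, chain_conc
from .params import DoseEvent

__all__ = ["structural_variant_solve", "VARIANTS"]

VARIANTS = (
    "first_order",
    "first_order_lag",
    "sequential_k_depots",
    "nonsequential_two_depot",
    "weibull",
    "mtt",
)


def _disposition(params: dict) -> tuple[float, float, float, float]:
    vc = params["Vc"]
    k10 = params["CLc"] / vc
    k12 = params["CLp"] / vc
    k21 = params["CLp"] / params["Vp"]
    return vc, k10, k12, k21


def _chain_profile(rates, params, dose, times, tlag) -> np.ndarray:
    vc, k10, k12, k21 = _disposition(params)
    tau = np.asarray(times, float) - dose.time - tlag
    return chain_conc(
        np.asarray(rates, float), k10, k12, k21, vc, dose.amount, tau[None, :]
    )[0]


def _input_driven_profile(params, dose, times, tlag, input_rate) -> np.ndarray:
    """Integrate dAc/dt = input(t) - (k10+k12) Ac + k21 Ap numerically."""
    vc, k10, k12, k21 = _disposition(params)
    times = np.asarray(times, float)
    tau = times - dose.time - tlag

    def rhs(t, y):
        ac, ap = y
        return [input_rate(t) - (k10 + k12) * ac + k21 * ap, k12 * ac - k21 * ap]

    pos = np.unique(tau[tau > 0])
    conc = np.zeros_like(tau)
    if pos.size:
        sol = solve_ivp(
            rhs, (0.0, pos[-1]), [0.0, 0.0], method="LSODA", t_eval=pos,
            rtol=1e-10, atol=dose.amount * 1e-13, max_step=0.05,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        lookup = dict(zip(pos, sol.y[0] / (vc * 1000.0)))
        conc[tau > 0] = [lookup[t] for t in tau[tau > 0]]
    return np.maximum(conc, 0.0)


def structural_variant_solve(
    variant: str, params: dict, dose: DoseEvent, times
) -> ConcentrationProfile:
    """Solve one absorption-structure variant.

    ``params`` always carries the disposition set {Vc, CLc, Vp, CLp} plus
    the variant-specific absorption parameters:

    - ``first_order``: Ka
    - ``first_order_lag``: Ka, Tlag
    - ``sequential_k_depots``: k (2..3), Ka1..Kak, Tlag
    - ``nonsequential_two_depot``: Ka_a, Ka_b, frac in (0,1), Tlag
    - ``weibull``: shape, scale (h), Tlag
    - ``mtt``: n_transit, mtt (h), Tlag
    """
    times = np.asarray(times, float)
    if np.any(times < 0):
        raise ValueError("negative times are not allowed")
    tlag = float(params.get("Tlag", 0.0))

    if variant == "first_order":
        conc = _chain_profile([params["Ka"]], params, dose, times, 0.0)
    elif variant == "first_order_lag":
        conc = _chain_profile([params["Ka"]], params, dose, times, tlag)
    elif variant == "sequential_k_depots":
        k = int(params["k"])
        if k not in (2, 3):
            raise ValueError(f"sequential chain length must be 2 or 3, got {k}")
        rates = [params[f"Ka{i + 1}"] for i in range(k)]
        conc = _chain_profile(rates, params, dose, times, tlag)
    elif variant == "nonsequential_two_depot":
        frac = params["frac"]
        if not 0.0 < frac < 1.0:
            raise ValueError(f"split fraction must be in (0, 1), got {frac}")
        dose_a = DoseEvent(amount=dose.amount * frac, time=dose.time)
        dose_b = DoseEvent(amount=dose.amount * (1.0 - frac), time=dose.time)
        conc = _chain_profile([params["Ka_a"]], params, dose_a, times, tlag)
        conc = conc + _chain_profile([params["Ka_b"]], params, dose_b, times, tlag)
    elif variant == "weibull":
        shape, scale = params["shape"], params["scale"]
        if shape <= 0 or scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        # fraction absorbed F(t) = 1 - exp(-(t/scale)^shape); input = D*F'(t)
        def input_rate(t, D=dose.amount):
            if t <= 0:
                return 0.0
            z = (t / scale) ** shape
            return D * shape / scale * (t / scale) ** (shape - 1.0) * np.exp(-z)

        conc = _input_driven_profile(params, dose, times, tlag, input_rate)
    elif variant == "mtt":
        n = int(params["n_transit"])
        mtt = params["mtt"]
        if n < 1 or mtt <= 0:
            raise ValueError("mtt variant needs n_transit >= 1 and mtt > 0")
        ktr = (n + 1) / mtt
        rates = np.full(n + 1, ktr)  # equal-rate chain -> degenerate spectrum
        vc, k10, k12, k21 = _disposition(params)
        tau = times - dose.time - tlag
        amount = _chain_amount_expm(rates, k10, k12, k21, dose.amount, tau)
        conc = np.maximum(amount / (vc * 1000.0), 0.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ConcentrationProfile(times=times, conc=conc)
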