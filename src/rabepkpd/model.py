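"""Structural PK model: sequential absorption chain into a two-compartment body.

After the absorption lag the drug moves through a chain of first-order
depots (dosing depot -> depot 1 -> depot 2 -> central) and distributes
between a central and a peripheral compartment:

    dA0/dt = -Ka1*A0
    dA1/dt =  Ka1*A0 - Ka2*A1
    dA2/dt =  Ka2*A1 - Ka3*A2
    dAc/dt =  Ka3*A2 - (k10 + k12)*Ac + k21*Ap
    dAp/dt =  k12*Ac - k21*Ap

with micro-constants k10 = CLc/Vc, k12 = CLp/Vc, k21 = CLp/Vp and
C(t) = Ac / (Vc * 1000) in ng/mL.  The system is linear, so the central
amount is a sum of exponentials; the analytic solver uses the closed-form
partial-fraction (residue) expansion with a matrix-exponential fallback
when rate constants (nearly) coincide, and the ODE solver uses LSODA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import DoseEvent, IndividualParameters

__all__ = [
    "ConcentrationProfile",
    "solve_profile",
    "solve_states",
    "apply_residual_error",
    "chain_conc",
    "disposition_eigenvalues",
]

#: relative eigenvalue spacing below which the residue expansion is abandoned
DEGENERATE_RTOL = 1.0e-7


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration (ng/mL) on a strictly increasing time grid (h)."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        if times.ndim != 1 or times.shape != conc.shape:
            raise ValueError("times and conc must be aligned 1-D arrays")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "conc", conc)

    def auc(self) -> float:
        """Trapezoidal AUC over the profile's own grid (ng*h/mL)."""
        return float(np.trapezoid(self.conc, self.times))


def disposition_eigenvalues(k10: float, k12: float, k21: float) -> tuple[float, float]:
    """Hybrid rate constants (alpha, beta) of the two-compartment disposition."""
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


def chain_conc(
    rates: np.ndarray,
    k10: np.ndarray,
    k12: np.ndarray,
    k21: np.ndarray,
    vc: np.ndarray,
    dose: np.ndarray,
    tau: np.ndarray,
    degenerate: str = "expm",
) -> np.ndarray:
    """Closed-form central concentration for an m-depot chain, vectorized.

    Parameters are broadcast along the leading (batch) axis: ``rates`` has
    shape (..., m), scalars shape (...,) and ``tau`` shape (..., T) with
    tau = t - dose_time - Tlag.  Returns conc (ng/mL) of shape (..., T),
    zero wherever tau <= 0.  Rows whose rate spectrum is (nearly)
    degenerate are recomputed with a matrix exponential.

    In Laplace space  Ac(s) = D * (prod a_i) * (s + k21) /
    [ prod_i (s + a_i) * (s + alpha) * (s + beta) ],  so with the pooled
    spectrum lam = (a_1..a_m, alpha, beta),

        Ac(t) = D * prod(a) * sum_i  (k21 - lam_i) * exp(-lam_i * t)
                                     / prod_{j != i} (lam_j - lam_i).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    k10, k12, k21, vc, dose = np.broadcast_arrays(
        np.asarray(k10, float), np.asarray(k12, float), np.asarray(k21, float),
        np.asarray(vc, float), np.asarray(dose, float),
    )
    batch = np.broadcast_shapes(rates.shape[:-1], k10.shape)
    rates = np.broadcast_to(rates, batch + rates.shape[-1:])
    k10, k12, k21, vc, dose = (
        np.broadcast_to(a, batch) for a in (k10, k12, k21, vc, dose)
    )
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)

    lam = np.concatenate(
        [rates, alpha[..., None], beta[..., None]], axis=-1
    )  # (..., M)
    M = lam.shape[-1]
    eye = np.eye(M, dtype=bool)

    if degenerate == "jitter":
        # split (near-)coincident rates apart by a relative 1e-6 spread so the
        # residue expansion stays well-conditioned; the profile perturbation is
        # O(1e-6) relative, below the resolution the likelihood can see
        diff = lam[..., None, :] - lam[..., :, None]
        gap = np.where(eye, np.inf, np.abs(diff)).min(axis=(-2, -1))
        bad = gap < DEGENERATE_RTOL * np.abs(lam).max(axis=-1)
        if np.any(bad):
            lam = np.array(lam, copy=True)
            spread = 1.0 + 1e-6 * np.arange(M)
            lam[bad] = lam[bad] * spread

    diff = lam[..., None, :] - lam[..., :, None]  # diff[i, j] = lam_j - lam_i
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom = np.where(eye, 1.0, diff).prod(axis=-1)  # (..., M)
        coef = dose[..., None] * rates.prod(axis=-1)[..., None] * (
            k21[..., None] - lam
        ) / denom  # residue coefficients, (..., M)

    tau = np.asarray(tau, dtype=float)
    tau = np.broadcast_to(tau, batch + tau.shape[-1:])
    pos = np.maximum(tau, 0.0)
    with np.errstate(invalid="ignore", over="ignore"):
        amount = np.einsum(
            "...m,...tm->...t", coef, np.exp(-lam[..., None, :] * pos[..., :, None])
        )
    amount = np.where(tau > 0, amount, 0.0)

    # route near-degenerate spectra through the exact matrix exponential
    gap = np.where(eye, np.inf, np.abs(diff)).min(axis=(-2, -1))
    bad = (gap < DEGENERATE_RTOL * np.abs(lam).max(axis=-1)) & (degenerate == "expm")
    if np.any(bad):
        amount = np.array(amount, copy=True)
        for idx in np.argwhere(np.reshape(bad, batch)):
            key = tuple(idx)
            amount[key] = _chain_amount_expm(
                rates[key], k10[key], k12[key], k21[key], dose[key], tau[key]
            )
    conc = amount / (vc[..., None] * 1000.0)
    return np.maximum(conc, 0.0)


def _chain_matrix(rates: np.ndarray, k10: float, k12: float, k21: float) -> np.ndarray:
    """Rate matrix for m depots + central + peripheral (+ elimination sink)."""
    m = len(rates)
    n = m + 3
    A = np.zeros((n, n))
    for i, r in enumerate(rates):
        A[i, i] = -r
        A[i + 1, i] = r
    A[m, m] += -(k10 + k12)
    A[m, m + 1] = k21
    A[m + 1, m] = k12
    A[m + 1, m + 1] = -k21
    A[m + 2, m] = k10  # cumulative eliminated amount
    return A


def _chain_amount_expm(rates, k10, k12, k21, dose, tau) -> np.ndarray:
    A = _chain_matrix(np.asarray(rates, float), k10, k12, k21)
    y0 = np.zeros(A.shape[0])
    y0[0] = dose
    out = np.zeros_like(np.asarray(tau, float))
    for i, t in np.ndenumerate(tau):
        if t > 0:
            out[i] = (expm(A * t) @ y0)[len(rates)]
    return out


def solve_profile(
    ind: IndividualParameters,
    dose: DoseEvent,
    times,
    method: str = "analytic",
) -> ConcentrationProfile:
    """Solve the three-depot chain / two-compartment model at the given times.

    ``method='analytic'`` uses the residue expansion (matrix-exponential
    fallback for degenerate rates); ``method='ode'`` integrates the system
    with LSODA at tight tolerances.  Concentration is exactly zero for all
    times <= dose.time + Tlag.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative times are not allowed")
    k10 = ind.CLc / ind.Vc
    k12 = ind.CLp / ind.Vc
    k21 = ind.CLp / ind.Vp
    rates = np.array([ind.Ka1, ind.Ka2, ind.Ka3])
    tau = times - dose.time - ind.Tlag

    if method == "analytic":
        conc = chain_conc(rates, k10, k12, k21, ind.Vc, dose.amount, tau[None, :])[0]
    elif method == "ode":
        conc = _solve_ode(rates, k10, k12, k21, ind.Vc, dose.amount, tau)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ConcentrationProfile(times=times, conc=conc)


def _solve_ode(rates, k10, k12, k21, vc, dose, tau) -> np.ndarray:
    A = _chain_matrix(rates, k10, k12, k21)[:-1, :-1]
    y0 = np.zeros(A.shape[0])
    y0[0] = dose
    pos = np.unique(tau[tau > 0])
    conc = np.zeros_like(tau)
    if pos.size:
        sol = solve_ivp(
            lambda t, y: A @ y,
            (0.0, pos[-1]),
            y0,
            method="LSODA",
            t_eval=pos,
            rtol=1e-11,
            atol=dose * 1e-14,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust on linear systems
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        lookup = dict(zip(pos, sol.y[len(rates)] / (vc * 1000.0)))
        conc[tau > 0] = [lookup[t] for t in tau[tau > 0]]
    return np.maximum(conc, 0.0)


def solve_states(ind: IndividualParameters, dose: DoseEvent, times) -> dict[str, np.ndarray]:
    """All compartment amounts (ng) plus cumulative eliminated amount.

    Returned keys: A0, A1, A2, Ac, Ap, eliminated.  Used for mass-balance
    checks; computed with the exact matrix exponential.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative times are not allowed")
    k10 = ind.CLc / ind.Vc
    k12 = ind.CLp / ind.Vc
    k21 = ind.CLp / ind.Vp
    A = _chain_matrix(np.array([ind.Ka1, ind.Ka2, ind.Ka3]), k10, k12, k21)
    y0 = np.zeros(A.shape[0])
    y0[0] = dose.amount
    tau = times - dose.time - ind.Tlag
    out = np.zeros((A.shape[0], times.size))
    for j, t in enumerate(tau):
        if t > 0:
            out[:, j] = expm(A * t) @ y0
        else:
            out[:, j] = y0
    names = ["A0", "A1", "A2", "Ac", "Ap", "eliminated"]
    return {n: out[i] for i, n in enumerate(names)}


def apply_residual_error(
    profile: ConcentrationProfile, sigma: float, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Log-additive residual error: C_obs = C_pred * exp(eps), eps ~ N(0, sigma^2).

    Pre-lag (zero) predictions stay exactly zero — samples taken before
    absorption starts remain undetectable.  Identical seed, identical output.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    eps = rng.normal(0.0, sigma, size=profile.conc.shape)
    return np.where(profile.conc > 0, profile.conc * np.exp(eps), 0.0)
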