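"""Basic diagnostic figures: VPC bands, gastric-pH profiles, screen heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

__all__ = ["plot_vpc", "plot_ph_profiles", "plot_correlation_heatmap", "plot_gof"]


def plot_vpc(bands: pd.DataFrame, path, log_scale: bool = True):
    """Observed vs simulated percentile bands from a VPC table."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = 0.5 * (bands.t_lo + bands.t_hi)
    ax.fill_between(t, bands.sim_p5_ci_lo, bands.sim_p5_ci_hi, alpha=0.25,
                    color="tab:blue", label="sim 5th/95th 95% CI")
    ax.fill_between(t, bands.sim_p95_ci_lo, bands.sim_p95_ci_hi, alpha=0.25,
                    color="tab:blue")
    ax.fill_between(t, bands.sim_p50_ci_lo, bands.sim_p50_ci_hi, alpha=0.3,
                    color="tab:red", label="sim median 95% CI")
    for col, style in (("sim_p5", "k--"), ("sim_p50", "k-"), ("sim_p95", "k--")):
        ax.plot(t, bands[col], style, lw=1)
    for col, marker in (("obs_p5", "v"), ("obs_p50", "o"), ("obs_p95", "^")):
        ax.plot(t, bands[col], marker, color="tab:green", ms=4, ls="none")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ph_profiles(profiles: dict[str, tuple[np.ndarray, np.ndarray]], path,
                     threshold: float = 4.0):
    """Median gastric-pH profiles per stratum with the pH-4 reference line."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, (t, ph) in profiles.items():
        ax.plot(t, ph, label=name)
    ax.axhline(threshold, color="green", ls=":", lw=1, label=f"pH {threshold:g}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("gastric pH")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(matrix: pd.DataFrame, path, threshold: float = 0.3):
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * matrix.shape[1],
                                    1.0 + 0.5 * matrix.shape[0]))
    sns.heatmap(matrix.astype(float), vmin=-1, vmax=1, center=0, annot=True,
                fmt=".2f", cmap="coolwarm", cbar_kws={"label": "Pearson r"},
                ax=ax)
    for (i, j), v in np.ndenumerate(matrix.to_numpy(dtype=float)):
        if np.isfinite(v) and abs(v) >= threshold:
            ax.add_patch(plt.Rectangle((j, i), 1, 1, fill=False,
                                       edgecolor="yellow", lw=2))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gof(residuals: pd.DataFrame, path):
    """CWRES vs time and QQ panel."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(residuals.TIME, residuals.CWRES, "o", ms=3, alpha=0.6)
    axes[0].axhline(0, color="k", lw=1)
    for y in (-4, 4):
        axes[0].axhline(y, color="red", ls="--", lw=1)
    axes[0].set_xlabel("time (h)")
    axes[0].set_ylabel("CWRES")
    ordered = residuals.sort_values("CWRES")
    axes[1].plot(ordered.qq_theoretical, ordered.CWRES, "o", ms=3, alpha=0.6)
    lim = max(4.0, residuals.CWRES.abs().max())
    axes[1].plot([-lim, lim], [-lim, lim], "k--", lw=1)
    axes[1].set_xlabel("theoretical quantile")
    axes[1].set_ylabel("CWRES quantile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
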