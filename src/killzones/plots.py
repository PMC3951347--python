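"""Figure helpers: envelope plots and coefficient comparison plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .point_pattern import Envelope
from .regression import RegressionResult

__all__ = ["envelope_plot", "coefficient_plot"]


def envelope_plot(env: Envelope, path: str | Path, title: str = "") -> None:
    """Observed L(t) against the CSR rank envelope, with the CSR
    expectation at 0 and clustered distances shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    km = env.t_grid / 1000.0
    ax.fill_between(km, env.lower, env.upper, color="0.85", label="CSR envelope")
    ax.axhline(0.0, color="k", lw=0.8)
    if env.l_obs is not None:
        ax.plot(km, env.l_obs, "ko-", ms=3, lw=1, label="observed L(t)")
    clustered = env.classification == "clustered"
    if clustered.any():
        ax.fill_between(km, *ax.get_ylim(), where=clustered, color="0.7", alpha=0.3)
    ax.set_xlabel("distance t (km)")
    ax.set_ylabel("L(t) (m)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def coefficient_plot(fits: dict[str, RegressionResult], path: str | Path) -> None:
    """Standardized coefficients with SE bars, per class, side by side."""
    fig, ax = plt.subplots(figsize=(7, 4))
    first = next(iter(fits.values()))
    terms = [t for t in first.terms if t != "const"]
    x = np.arange(len(terms))
    width = 0.8 / max(len(fits), 1)
    for k, (label, fit) in enumerate(fits.items()):
        betas = [fit.params.get(t, np.nan) for t in terms]
        ses = [fit.se.get(t, np.nan) for t in terms]
        ax.errorbar(x + (k - (len(fits) - 1) / 2) * width, betas, yerr=ses,
                    fmt="o", capsize=3, label=label)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(terms, rotation=30, ha="right")
    ax.set_ylabel("standardized coefficient")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
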