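"""Matplotlib rendering of calibration and Bland–Altman plot data."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .evaluate import BlandAltmanData, CalibrationCurve


def plot_calibration(curve: CalibrationCurve, path, title: str = "Calibration") -> None:
    """Observed counts on x, predicted on y, identity reference, 95% band."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(curve.points["observed"], curve.points["predicted"], s=8, alpha=0.3, color="grey")
    ax.plot(curve.grid, curve.fitted, color="C0", label="smoothed")
    ax.fill_between(curve.grid, curve.lower, curve.upper, color="C0", alpha=0.2, label="95% band")
    lims = [0, max(float(curve.points["observed"].max()), float(curve.points["predicted"].max()), 1)]
    ax.plot(lims, lims, color="black", linestyle="--", linewidth=1, label="identity")
    ax.set_xlabel("Observed event count")
    ax.set_ylabel("Predicted event count")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bland_altman(ba: BlandAltmanData, path, title: str = "Bland-Altman") -> None:
    """Difference vs mean with mean-difference and 1.96-SD limit lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.mean, ba.difference, s=8, alpha=0.4, color="grey")
    ax.axhline(ba.mean_difference, color="black", label="mean difference")
    ax.axhline(ba.upper_limit, color="black", linestyle=":", label="limits of agreement")
    ax.axhline(ba.lower_limit, color="black", linestyle=":")
    ax.set_xlabel("Mean of observed and predicted counts")
    ax.set_ylabel("Predicted - observed count")
    suffix = " (suppressed: narrow observed range)" if ba.suppressed else ""
    ax.set_title(title + suffix)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
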