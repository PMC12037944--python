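"""Residual diagnostics of a forecasting run.

After a model is selected, its one-step forecast residuals are inspected:
standardize, test normality (Shapiro–Wilk and Kolmogorov–Smirnov against the
standard normal), measure lag-1 autocorrelation with the Durbin–Watson
statistic, and bin a histogram of standardized residuals for visual
comparison across users.

The Durbin–Watson statistic,

    d = sum_{t=2..n} (e_t − e_{t−1})² / sum_{t=1..n} e_t²,

lies in [0, 4] and is ≈ 2(1 − r₁) for large samples (r₁ the lag-1 residual
autocorrelation): values below 1.5 indicate positive autocorrelation, above
2.5 negative, and the interval [1.5, 2.5] is treated as no evidence of
autocorrelation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .engine import ForecastResult

__all__ = [
    "DiagnosticsReport",
    "standardize_residuals",
    "durbin_watson",
    "classify_dw",
    "normality_tests",
    "residual_report",
]

#: Durbin–Watson classification boundaries (inclusive = no autocorrelation).
DW_LOWER = 1.5
DW_UPPER = 2.5

#: Fixed histogram grid for standardized residuals: width 0.25 over [−4, 4]
#: plus one overflow bin at each end, so panels are comparable across users.
HIST_INNER_EDGES = np.round(np.arange(-4.0, 4.0 + 0.25, 0.25), 10)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Normality + autocorrelation summary of one residual series."""

    sw_p: float
    ks_p: float
    dw: float
    dw_class: str
    std_residuals: np.ndarray
    hist_bins: np.ndarray
    hist_counts: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.sw_p <= 1.0 and 0.0 <= self.ks_p <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if not (0.0 <= self.dw <= 4.0):
            raise ValueError("Durbin-Watson statistic must lie in [0, 4]")
        if int(self.hist_counts.sum()) != len(self.std_residuals):
            raise ValueError("histogram counts must sum to the residual count")

    def to_dict(self) -> dict:
        return {
            "sw_p": float(self.sw_p),
            "ks_p": float(self.ks_p),
            "dw": float(self.dw),
            "dw_class": self.dw_class,
            "n_residuals": int(len(self.std_residuals)),
            "std_convention": "sample (ddof=1)",
            "hist_bins": [float(b) for b in self.hist_bins],
            "hist_counts": [int(c) for c in self.hist_counts],
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def standardize_residuals(residuals: np.ndarray) -> np.ndarray:
    """Centre and scale to unit variance (sample convention, ddof=1)."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals to standardize")
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals have zero variance; standardization undefined")
    return (e - e.mean()) / sd


def durbin_watson(residuals: np.ndarray) -> float:
    """Durbin–Watson statistic: Σ(e_t − e_{t−1})² / Σ e_t²."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValueError("all-zero residuals: Durbin-Watson undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def classify_dw(dw: float) -> str:
    """Map a DW value to {positive_autocorr, none, negative_autocorr}.

    Boundaries are inclusive on the "no autocorrelation" side: exactly 1.5
    or 2.5 classifies as none.
    """
    if not (0.0 <= dw <= 4.0):
        raise ValueError(f"Durbin-Watson statistic {dw} outside [0, 4]")
    if dw < DW_LOWER:
        return "positive_autocorr"
    if dw > DW_UPPER:
        return "negative_autocorr"
    return "none"


def normality_tests(std_residuals: np.ndarray) -> tuple[float, float]:
    """(Shapiro–Wilk p, Kolmogorov–Smirnov p vs. the standard normal)."""
    e = np.asarray(std_residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals for the normality tests")
    sw_p = float(stats.shapiro(e).pvalue)
    ks_p = float(stats.kstest(e, "norm").pvalue)
    return sw_p, ks_p


def _histogram(std_residuals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([[-np.inf], HIST_INNER_EDGES, [np.inf]])
    counts, _ = np.histogram(std_residuals, bins=edges)
    return edges, counts


def residual_report(result: ForecastResult) -> DiagnosticsReport:
    """Full diagnostics of a forecast run's residuals (successful steps)."""
    residuals = result.residual[result.ok]
    if len(residuals) < 3:
        raise ValueError("need at least 3 successful steps for diagnostics")
    std = standardize_residuals(residuals)
    sw_p, ks_p = normality_tests(std)
    dw = durbin_watson(residuals)
    edges, counts = _histogram(std)
    return DiagnosticsReport(
        sw_p=sw_p,
        ks_p=ks_p,
        dw=dw,
        dw_class=classify_dw(dw),
        std_residuals=std,
        hist_bins=edges,
        hist_counts=counts,
    )


def plot_residual_histograms(
    reports: dict[str, DiagnosticsReport], path: str | Path, ncols: int = 4
) -> None:
    """Multi-panel standardized-residual histogram figure, one panel/user."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(reports)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False
    )
    centers = (HIST_INNER_EDGES[:-1] + HIST_INNER_EDGES[1:]) / 2
    for ax, (label, rep) in zip(axes.flat, sorted(reports.items())):
        inner = rep.hist_counts[1:-1]  # drop overflow bins for display
        ax.bar(centers, inner, width=0.25, color="steelblue", edgecolor="none")
        ax.set_title(f"{label}  DW={rep.dw:.2f}", fontsize=8)
        ax.set_xlim(-4, 4)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.supxlabel("standardized residual")
    fig.supylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
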