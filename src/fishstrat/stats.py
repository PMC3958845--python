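"""Depth-trend regression for biovolume and areal-density profiles.

Vertical stratification is tested by ordinary least squares of biovolume
fraction (or areal density) on section depth z, optionally restricted to a
depth window (e.g. the 180–400 µm range in which anammox abundance rises).
Significance is a two-sided t-test on the slope, which for simple linear
regression is equivalent to the overall F-test, reported with R², n and the
significance level α.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DepthProfile",
    "RegressionResult",
    "fit_depth_regression",
    "trend_recovery_experiment",
    "plot_depth_regression",
]


@dataclass
class DepthProfile:
    """Per-depth observations of one probe's biovolume fraction."""

    probe: str
    depths_um: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.depths_um.shape != self.fractions.shape:
            raise ValueError("depths and fractions differ in length")
        if (self.depths_um < 0).any():
            raise ValueError("depths must be >= 0")

    def window(self, z_lo: float, z_hi: float) -> "DepthProfile":
        keep = (self.depths_um >= z_lo) & (self.depths_um <= z_hi)
        return DepthProfile(self.probe, self.depths_um[keep], self.fractions[keep])


@dataclass
class RegressionResult:
    """OLS depth-trend fit: slope (fraction per µm), R², n, p, α, window."""

    probe: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float
    alpha: float
    window_um: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        lo, hi = self.window_um
        star = "significant" if self.significant else "not significant"
        return (
            f"{self.probe}: slope {self.slope:.3e} per um over {lo:.0f}-{hi:.0f} um, "
            f"R2 = {self.r_squared:.2f}, n = {self.n}, p = {self.p_value:.2e} "
            f"({star} at alpha = {self.alpha:g})"
        )


def fit_depth_regression(
    profile: DepthProfile,
    window: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS of fraction on depth within ``window`` (inclusive).

    Requires at least 3 observations in the window so the slope t-test has
    positive degrees of freedom.
    """
    if window is not None:
        profile = profile.window(*window)
        lo, hi = float(window[0]), float(window[1])
    else:
        lo = float(profile.depths_um.min()) if profile.depths_um.size else 0.0
        hi = float(profile.depths_um.max()) if profile.depths_um.size else 0.0
    finite = np.isfinite(profile.fractions)
    z = profile.depths_um[finite]
    y = profile.fractions[finite]
    if z.size < 3:
        raise ValueError(
            f"need >= 3 observations in depth window [{lo:g}, {hi:g}] um, got {z.size}"
        )
    if np.ptp(y) == 0.0:
        # flat data: slope 0 with no explained variance; OLS would give 0/0
        return RegressionResult(
            probe=profile.probe,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            n=int(z.size),
            p_value=1.0,
            alpha=alpha,
            window_um=(lo, hi),
        )
    X = sm.add_constant(z)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        probe=profile.probe,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=int(z.size),
        p_value=float(fit.pvalues[1]),
        alpha=alpha,
        window_um=(lo, hi),
    )


def trend_recovery_experiment(
    config,
    seeds: Sequence[int],
    windows: dict[str, tuple[float, float] | None] | None = None,
    alpha: float = 0.05,
    cutoff: int = 30,
) -> dict:
    """Full-pipeline parameter-recovery harness.

    For each seed, a synthetic stack is generated with ``config`` (reseeded),
    quantified section by section through the measurement pipeline
    (thresholding, noise reduction, segmentation, dual-channel artifact
    removal, congruency rejection, biovolume fractions), and the depth-trend
    regressions are fitted per probe within the given windows (None = full
    range; the key ``"areal_density"`` fits the biomass areal density).

    Returns a dict with the per-run results table (``runs``: seed, probe,
    slope, R², p, significant) and per-probe aggregates (``summary``: mean
    R², fraction of runs with negative/positive slope, rejection rate at α).
    """
    from dataclasses import replace as _replace

    from .pipeline import measure_stack
    from .synthetic import generate_compartment_stack

    windows = windows or {"aob": None, "amx": None}
    rows = []
    for seed in seeds:
        cfg = _replace(config, seed=int(seed))
        images, gt = generate_compartment_stack(cfg)
        measured = measure_stack(images, cutoff=cutoff)
        for probe, window in windows.items():
            prof = DepthProfile(
                probe,
                measured["depth_um"].to_numpy(),
                measured[probe].to_numpy(),
            )
            res = fit_depth_regression(prof, window=window, alpha=alpha)
            rows.append(
                {
                    "seed": seed,
                    "probe": probe,
                    "slope": res.slope,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n": res.n,
                    "significant": res.significant,
                }
            )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby("probe")
        .agg(
            mean_r_squared=("r_squared", "mean"),
            negative_slope_rate=("slope", lambda s: float((s < 0).mean())),
            positive_slope_rate=("slope", lambda s: float((s > 0).mean())),
            rejection_rate=("significant", "mean"),
            n_runs=("seed", "count"),
        )
        .reset_index()
    )
    return {"runs": runs, "summary": summary, "alpha": alpha}


def plot_depth_regression(
    profile: DepthProfile, result: RegressionResult, path: str | None = None
):
    """Scatter of fraction vs depth with the fitted trend line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(profile.depths_um, profile.fractions, "o", label=profile.probe)
    lo, hi = result.window_um
    zz = np.linspace(lo, hi, 50)
    ax.plot(zz, result.intercept + result.slope * zz, "-", label="OLS fit")
    ax.set_xlabel("depth z (um)")
    ax.set_ylabel("biovolume fraction")
    ax.legend()
    ax.set_title(result.summary(), fontsize=8)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
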