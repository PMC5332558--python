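"""Cohort wave-fronts from meta-gene profiles.

Instead of calling per-gene fronts, this route works on the cohort
average: the untreated meta-profile is subtracted from each treated
profile, the signed difference is smoothed with a loess (locally
weighted, degree-1) line, and the wave-front is estimated where the
fitted line crosses zero on its way down — UV-treated samples show
excess promoter-proximal signal and a deficit further downstream, so
the crossing tracks how far the (slow) wave has advanced. The estimate
is then refined to the first downstream position where the fitted
line's derivative has dropped to half its value at the crossing, which
places the front past the steep part of the transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .coverage import MetaProfile
from .wavefront import ElongationRateEstimate, fit_rate

DEFAULT_SPAN = 0.05  # fraction of the window; ~6 kb — must stay well below
# the smallest front of interest or the early-recovery bump smooths away
DEFAULT_GRID = 100  # bp between evaluation points of the fitted line
DEFAULT_MIN_OFFSET = 1_000  # skip the promoter peak's own sign flips


@dataclass
class DifferenceProfile:
    """Treated − untreated meta-profile difference with its loess fit."""

    offsets: np.ndarray  # bp from TSS, on the evaluation grid
    difference: np.ndarray  # grid-binned signed difference
    fitted: np.ndarray  # loess-fitted curve on the grid
    span: float
    sample: object = None


def difference_profile(
    treated: MetaProfile,
    untreated: MetaProfile,
    span: float = DEFAULT_SPAN,
    grid: int = DEFAULT_GRID,
) -> DifferenceProfile:
    """Signed per-offset difference (treated − untreated), mean-binned to
    a coarse grid and loess-smoothed.

    Raises on mismatched offset grids. The sign convention puts UV excess
    near the TSS positive and the downstream deficit negative, so the
    front shows up as a downward zero crossing.
    """
    if treated.offsets.size != untreated.offsets.size or not np.array_equal(
        treated.offsets, untreated.offsets
    ):
        raise ValueError("meta-profiles are on different offset grids")
    diff = treated.depth - untreated.depth
    offs = treated.offsets
    n_bins = offs.size // grid
    used = n_bins * grid
    binned = diff[:used].reshape(n_bins, grid).mean(axis=1)
    centers = offs[:used].reshape(n_bins, grid).mean(axis=1)
    fitted = lowess(binned, centers, frac=span, return_sorted=False)
    return DifferenceProfile(
        offsets=centers,
        difference=binned,
        fitted=np.asarray(fitted, dtype=float),
        span=span,
        sample=treated.sample,
    )


def loess_wavefront(
    diff: DifferenceProfile,
    min_offset: float = DEFAULT_MIN_OFFSET,
    half_ratio: float = 0.5,
) -> Tuple[float, float, bool]:
    """Front estimates from the fitted difference curve.

    Returns ``(initial, refined, refined_found)``. The initial estimate
    is the first downward zero crossing of the fitted line at offsets
    beyond ``min_offset`` (linearly interpolated between grid points);
    the refined estimate is the first grid offset after it where the
    absolute derivative of the fit is at most ``half_ratio`` times its
    absolute value at the initial estimate. If the derivative never
    drops that far, the initial estimate is returned with
    ``refined_found=False``.

    Raises ``ValueError("no front detectable")`` when the fitted curve
    never crosses zero downstream of ``min_offset``.
    """
    x = diff.offsets
    y = diff.fitted
    # candidate crossings: y[i] >= 0 > y[i+1], with the crossing beyond min_offset
    cross = None
    for i in range(x.size - 1):
        if y[i] >= 0 > y[i + 1]:
            if y[i] == y[i + 1]:
                xc = x[i]
            else:
                xc = x[i] + (x[i + 1] - x[i]) * y[i] / (y[i] - y[i + 1])
            if xc > min_offset:
                cross = (i, float(xc))
                break
    if cross is None:
        raise ValueError("no front detectable")
    i0, initial = cross

    deriv = np.gradient(y, x)
    d0 = float(np.interp(initial, x, deriv))
    target = abs(d0) * half_ratio
    after = np.flatnonzero(x > initial)
    for j in after:
        if abs(deriv[j]) <= target:
            return initial, float(x[j]), True
    return initial, initial, False


def cohort_rate_from_math_fronts(
    times_hr: Sequence[float], fronts_bp: Sequence[float]
) -> ElongationRateEstimate:
    """Best-fit elongation rate (kb/min) through meta-profile front
    estimates taken at times given in hours."""
    times_min = [60.0 * t for t in times_hr]
    est = fit_rate(times_min, fronts_bp)
    est.method = "mathematical"
    return est


def plot_difference(diff: DifferenceProfile, front: Optional[float] = None, path=None):
    """Convenience plot of the binned difference, its loess fit, and the
    called front. Requires matplotlib (optional dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(diff.offsets, diff.difference, ".", ms=2, alpha=0.4, label="difference")
    ax.plot(diff.offsets, diff.fitted, "-", lw=1.5, label=f"loess (span {diff.span})")
    ax.axhline(0.0, color="k", lw=0.5)
    if front is not None:
        ax.axvline(front, color="r", ls="--", lw=1, label=f"front {front/1000:.1f} kb")
    ax.set_xlabel("offset from TSS (bp)")
    ax.set_ylabel("treated − untreated depth")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
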