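"""Closed-form assay statistics: ΔΔCT fold change, fractionation
enrichment, and the EU low/high transcription ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"CT values must be finite, got {v!r}")


def livak_fold_change(
    ct_target_variable: float,
    ct_reference_variable: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the ΔΔCT (Livak) method.

    ΔΔCT = (CT_target − CT_ref)_variable − (CT_target − CT_ref)_control;
    fold change = 2^(−ΔΔCT).
    """
    _check_finite(
        ct_target_variable, ct_reference_variable, ct_target_control, ct_reference_control
    )
    ddct = (ct_target_variable - ct_reference_variable) - (
        ct_target_control - ct_reference_control
    )
    return 2.0 ** (-ddct)


def fraction_enrichment(ct_fraction: float, ct_reference_fraction: float) -> float:
    """Subcellular-fractionation enrichment: 2^(−(CT_fraction − CT_ref)).
    No reference-gene normalization — the comparison is between equal
    input fractions of the same sample."""
    _check_finite(ct_fraction, ct_reference_fraction)
    return 2.0 ** (-(ct_fraction - ct_reference_fraction))


def mean_fold_change(fold_changes: Sequence[float]) -> Tuple[float, float]:
    """Average replicate fold changes on the linear scale; returns
    (mean, SEM). Geometric averaging is available via log-transforming
    inputs upstream."""
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size == 0:
        raise ValueError("no fold changes")
    sem = float(fc.std(ddof=1) / math.sqrt(fc.size)) if fc.size > 1 else 0.0
    return float(fc.mean()), sem


@dataclass
class NucleusIntensitySet:
    """Per-nucleus mean EU intensities with the low/high thresholds that
    split non-recovering from highly transcribing cells. Thresholds are
    explicit inputs — they are set per experiment from the intensity
    histogram, never inferred silently."""

    intensities: np.ndarray
    low_threshold: float
    high_threshold: float
    sample: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 1:
            raise ValueError("need at least one nucleus")
        if self.low_threshold > self.high_threshold:
            raise ValueError("low threshold must be <= high threshold")

    def low_fraction(self) -> float:
        return float((self.intensities < self.low_threshold).mean())

    def high_fraction(self) -> float:
        return float((self.intensities > self.high_threshold).mean())


def low_high_ratio(
    sample: NucleusIntensitySet, control: NucleusIntensitySet
) -> float:
    """Proportion of low-transcription nuclei over high-transcription
    nuclei, normalized to the same ratio in the control set (control = 1).

    Raises when a high-fraction denominator or the control ratio is zero
    (thresholds outside the data range leave the ratio undefined).
    """
    s_high = sample.high_fraction()
    c_high = control.high_fraction()
    if s_high == 0 or c_high == 0:
        raise ValueError("no nuclei above the high threshold; ratio undefined")
    c_ratio = control.low_fraction() / c_high
    if c_ratio == 0:
        raise ValueError("control low/high ratio is zero")
    return (sample.low_fraction() / s_high) / c_ratio


def suggest_thresholds(
    intensities: Sequence[float], n_grid: int = 512
) -> Optional[Tuple[float, float]]:
    """Suggest low/high thresholds at the deepest valley of a Gaussian
    kernel-density estimate of the intensity histogram. Purely advisory:
    returns None when the KDE has no interior minimum."""
    from scipy.stats import gaussian_kde

    x = np.asarray(intensities, dtype=float)
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    dens = kde(grid)
    interior = (dens[1:-1] < dens[:-2]) & (dens[1:-1] < dens[2:])
    idx = np.flatnonzero(interior) + 1
    if idx.size == 0:
        return None
    valley = grid[idx[np.argmin(dens[idx])]]
    return float(valley), float(valley)
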