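"""Axial orientation distributions and their statistics.

Fiber orientations are *axial* quantities: a fiber pointing at angle
``theta`` is indistinguishable from one at ``theta + 180``.  All angles in
this module therefore live on the half-open interval [-90, +90) degrees and
means are computed with the angle-doubling construction of circular
statistics (double the angles, average on the circle, halve the result).

The central container is :class:`OrientationDistribution`, a 180-bin
frequency histogram with one-degree bins centred at integer degrees
-90 .. +89.  The module implements the operations that make such histograms
comparable and combinable across replicate micrographs:

* :func:`circular_mean_orientation` -- axial mean of a histogram;
* :func:`normalize_distribution` -- re-express angles relative to the mean
  fiber orientation, wrapping out-of-range values back by +/-180 degrees;
* :func:`average_distributions` -- per-bin average over replicates;
* :func:`orientation_index` -- scalar alignment index S in [-1, 1]
  (0 = isotropic, 1 = perfectly aligned with the mean axis);
* :func:`compare_distributions` -- two-sided Mann-Whitney U test between
  two normalized distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "N_BINS",
    "BIN_ANGLES",
    "OrientationDistribution",
    "MeanOrientation",
    "ComparisonResult",
    "wrap_axial",
    "circular_mean_orientation",
    "normalize_distribution",
    "average_distributions",
    "orientation_index",
    "compare_distributions",
    "total_variation",
    "read_histogram_csv",
    "write_histogram_csv",
]

N_BINS = 180
#: Bin centres in degrees, -90 .. +89.
BIN_ANGLES = np.arange(-90.0, 90.0)

#: Resultant lengths below this are treated as isotropic (no defined mean).
DEGENERATE_RESULTANT = 1e-6


def wrap_axial(angles):
    """Wrap angles (degrees) into the axial half-open range [-90, +90)."""
    return (np.asarray(angles, dtype=float) + 90.0) % 180.0 - 90.0


@dataclass
class OrientationDistribution:
    """A 180-bin axial orientation frequency histogram.

    Parameters
    ----------
    frequencies:
        Length-180 non-negative array, one value per 1-degree bin centred at
        integer degrees -90 .. +89.  When ``normalized`` is true the values
        must sum to 1 (within 1e-9).
    total_count:
        Number of underlying orientation samples, if known.
    normalized:
        Whether ``frequencies`` sum to one (relative frequencies) rather
        than being raw counts.
    relative_to_mean:
        True once the bin angles denote alpha, the angle relative to the
        mean fiber orientation, rather than absolute image orientation.
    mean_orientation:
        The absolute mean orientation (degrees) that was subtracted, when
        ``relative_to_mean`` is set.
    degenerate_mean:
        Flag set when the source histogram was isotropic and the mean was
        conventionally taken as 0.
    """

    frequencies: np.ndarray
    total_count: int | None = None
    normalized: bool = True
    relative_to_mean: bool = False
    mean_orientation: float | None = None
    degenerate_mean: bool = False

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (N_BINS,):
            raise ValueError(
                f"expected {N_BINS} bins, got array of shape {f.shape}"
            )
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("frequencies must be finite and non-negative")
        if self.normalized and abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                "normalized distribution must sum to 1 within 1e-9 "
                f"(got {f.sum()!r})"
            )
        self.frequencies = f

    @property
    def angles(self) -> np.ndarray:
        """Bin-centre angles in degrees."""
        return BIN_ANGLES

    def mode_angle(self) -> float:
        """Angle (degrees) of the most frequent bin."""
        return float(BIN_ANGLES[int(np.argmax(self.frequencies))])


class MeanOrientation(NamedTuple):
    """Axial mean with the doubled-angle resultant length and a degeneracy flag."""

    degrees: float
    resultant_length: float
    degenerate: bool

    def __float__(self) -> float:  # allows use directly as a number
        return self.degrees


@dataclass
class ComparisonResult:
    """Outcome of a two-sided Mann-Whitney U comparison."""

    U: float
    p_value: float
    n1: int
    n2: int
    mode: str = "bins"


def circular_mean_orientation(dist: OrientationDistribution) -> MeanOrientation:
    """Axial (doubled-angle) mean orientation of a histogram, in degrees.

    The bin angles are doubled, averaged on the circle with the bin
    frequencies as weights, and the resultant direction halved:

        theta_bar = 1/2 * atan2(sum f sin 2theta, sum f cos 2theta)

    mapped into [-90, +90).  If the doubled-angle resultant length is below
    1e-6 the distribution is isotropic for this purpose; the mean is then
    conventionally 0 and the result is flagged degenerate.
    """
    f = np.asarray(dist.frequencies, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("cannot take the mean of an empty (all-zero) distribution")
    w = f / total
    doubled = np.deg2rad(2.0 * BIN_ANGLES)
    c = float(np.sum(w * np.cos(doubled)))
    s = float(np.sum(w * np.sin(doubled)))
    r = float(np.hypot(c, s))
    if r < DEGENERATE_RESULTANT:
        return MeanOrientation(0.0, r, True)
    mean = float(wrap_axial(np.rad2deg(0.5 * np.arctan2(s, c))))
    return MeanOrientation(mean, r, False)


def normalize_distribution(dist: OrientationDistribution) -> OrientationDistribution:
    """Re-express a histogram relative to its mean fiber orientation.

    The axial mean is computed, rounded to the nearest whole degree, and
    subtracted from every bin angle; angles shifted outside [-90, +90) are
    wrapped back by +/-180 degrees.  Operationally this is an exact circular
    shift of the frequency array, so mass is conserved bin-for-bin.  The
    axial mean of the result is the sub-degree rounding residual, i.e. zero
    within half a bin.

    Isotropic inputs (degenerate mean) are passed through with shift 0 and a
    warning; the output carries ``degenerate_mean=True``.
    """
    f = np.asarray(dist.frequencies, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("cannot normalize an empty (all-zero) distribution")
    w = f / total

    mean = circular_mean_orientation(dist)
    if mean.degenerate:
        warnings.warn(
            "isotropic distribution: mean orientation undefined, "
            "normalizing with shift 0",
            stacklevel=2,
        )
        shift = 0
    else:
        shift = int(np.floor(mean.degrees + 0.5))  # round half-up

    # new[i] <- old[(i + shift) mod 180]:  bin at angle theta moves to
    # alpha = theta - shift (wrapped).
    shifted = np.roll(w, -shift)
    return OrientationDistribution(
        shifted,
        total_count=dist.total_count,
        normalized=True,
        relative_to_mean=True,
        mean_orientation=0.0 if mean.degenerate else mean.degrees,
        degenerate_mean=mean.degenerate,
    )


def average_distributions(
    dists: Sequence[OrientationDistribution],
) -> OrientationDistribution:
    """Per-bin arithmetic mean of normalized (mean-centred) distributions.

    All inputs must be normalized and relative to their own mean; the result
    again sums to one.  This is how replicate micrographs are combined into
    one distribution per experimental group.
    """
    if len(dists) == 0:
        raise ValueError("need at least one distribution to average")
    for d in dists:
        if not (d.normalized and d.relative_to_mean):
            raise ValueError(
                "average_distributions requires normalized, mean-centred "
                "distributions; raw histograms must be normalized first"
            )
    stacked = np.stack([d.frequencies for d in dists])
    counts = [d.total_count for d in dists]
    total = sum(counts) if all(c is not None for c in counts) else None
    return OrientationDistribution(
        stacked.mean(axis=0),
        total_count=total,
        normalized=True,
        relative_to_mean=True,
    )


def orientation_index(dist: OrientationDistribution) -> float:
    """Orientation index S of a normalized, mean-centred distribution.

        S = sum_bins f(alpha) * cos(2 alpha)

    with alpha in degrees converted to radians for the cosine.  S is 0 for a
    perfectly random (uniform) distribution and 1 for a perfectly aligned
    one (all mass at alpha = 0); negative values indicate mass concentrated
    perpendicular to the mean axis.
    """
    if not dist.normalized or abs(dist.frequencies.sum() - 1.0) > 1e-6:
        raise ValueError("orientation_index requires a normalized distribution")
    if not dist.relative_to_mean:
        raise ValueError(
            "orientation_index expects a mean-centred distribution; "
            "apply normalize_distribution first"
        )
    alpha = np.deg2rad(BIN_ANGLES)
    return float(np.sum(dist.frequencies * np.cos(2.0 * alpha)))


def _tie_corrected_variance(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))


def compare_distributions(
    a: OrientationDistribution,
    b: OrientationDistribution,
    mode: str = "bins",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two normalized distributions.

    ``mode="bins"`` (default) treats the 180 per-bin frequencies of each
    distribution as the two independent samples and applies the asymptotic
    normal approximation with tie correction.  ``mode="angles"`` instead
    reconstructs frequency-weighted absolute angles |alpha| as observations
    (requires ``total_count`` on both inputs) and tests those.

    Returns the exact U statistic (for the first sample), the two-sided
    p-value, and the sample sizes used.  Fully tied inputs (identical
    constant samples) have zero variance under the null; p is then 1.
    """
    for d in (a, b):
        if not d.normalized:
            raise ValueError("compare_distributions requires normalized inputs")

    if mode == "bins":
        x = np.asarray(a.frequencies, dtype=float)
        y = np.asarray(b.frequencies, dtype=float)
    elif mode == "angles":
        if a.total_count is None or b.total_count is None:
            raise ValueError('mode="angles" requires total_count on both inputs')
        cx = np.rint(a.frequencies * a.total_count).astype(int)
        cy = np.rint(b.frequencies * b.total_count).astype(int)
        x = np.repeat(np.abs(BIN_ANGLES), cx)
        y = np.repeat(np.abs(BIN_ANGLES), cy)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n1, n2 = len(x), len(y)
    if _tie_corrected_variance(np.concatenate([x, y]), n1, n2) <= 0:
        # all pooled observations tied: U is forced to its null mean
        return ComparisonResult(U=n1 * n2 / 2.0, p_value=1.0, n1=n1, n2=n2, mode=mode)

    res = _stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return ComparisonResult(
        U=float(res.statistic),
        p_value=float(res.pvalue),
        n1=n1,
        n2=n2,
        mode=mode,
    )


def total_variation(
    a: OrientationDistribution, b: OrientationDistribution
) -> float:
    """Total-variation distance between two normalized distributions."""
    return 0.5 * float(np.abs(a.frequencies - b.frequencies).sum())


# ---------------------------------------------------------------------------
# CSV exchange format: two columns "angle_deg,frequency", 180 rows.

def write_histogram_csv(dist: OrientationDistribution, path) -> None:
    """Write a distribution to the 180-row ``angle_deg,frequency`` CSV."""
    pd.DataFrame(
        {"angle_deg": BIN_ANGLES.astype(int), "frequency": dist.frequencies}
    ).to_csv(path, index=False)


def read_histogram_csv(path, relative_to_mean: bool = False) -> OrientationDistribution:
    """Read the ``angle_deg,frequency`` CSV written by :func:`write_histogram_csv`."""
    df = pd.read_csv(path)
    for col in ("angle_deg", "frequency"):
        if col not in df.columns:
            raise ValueError(f"histogram CSV missing column {col!r}")
    if len(df) != N_BINS or not np.array_equal(
        df["angle_deg"].to_numpy(), BIN_ANGLES.astype(int)
    ):
        raise ValueError("histogram CSV must have 180 rows with angles -90..89")
    f = df["frequency"].to_numpy(dtype=float)
    s = f.sum()
    normalized = abs(s - 1.0) <= 1e-9
    return OrientationDistribution(
        f,
        total_count=None,
        normalized=normalized,
        relative_to_mean=relative_to_mean,
    )
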