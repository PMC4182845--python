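"""Threshold selection on the saturation histogram.

Four methods are compared for separating bare soil (high saturation)
from mulch (low saturation):

* **OT** — Otsu's method: exhaustive search for the split maximizing the
  between-class variance σ_b² (equivalently minimizing the within-class
  variance σ_w², since σ_b² + σ_w² is the total variance at any split).
* **RC** — Ridler–Calvard (isodata): fixed-point iteration
  ``t ← (m1 + m2) / 2`` on the class means; converges to a real-valued
  threshold off the 1/255 grid.
* **LE** — local-entropy thresholding: second-order method on the
  gray-level co-occurrence matrix of the quantized plane; the split
  maximizes the summed Shannon entropies of the background-background
  and foreground-foreground quadrants.  A first-order variant (sum of
  the two renormalized one-dimensional class entropies) is available
  behind ``variant="first_order"`` for sensitivity analysis.
* **MT** — manual thresholding: a user-supplied value, wrapped verbatim.

Gray levels are worked in bin-index units (0..255); reported thresholds
are on the [0, 1] scale (``t = t_bin / 255`` for grid-valued methods).
All entropies use log base 2 (bits), with 0·log 0 ≡ 0.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateHistogramError,
    DegeneratePlaneError,
    InputError,
)
from .imaging import N_LEVELS, GrayHistogram, SaturationPlane

#: RC iteration stops when successive thresholds differ by less than half
#: a bin on the [0, 1] scale; matches the sub-bin precision of reported
#: RC thresholds that fall off the 1/255 grid.
RC_TOLERANCE = 1.0 / 510.0
RC_MAX_ITERATIONS = 200


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ThresholdResult:
    """A selected threshold.

    ``t`` is always on [0, 1].  ``t_bin`` is the integer bin index for
    grid-valued methods (OT, LE) and ``None`` for real-valued ones (RC)
    and for MT.  ``objective`` holds the achieved criterion value
    (σ_b² for OT, summed quadrant entropy for LE).
    """

    method: str  # one of {"OT", "RC", "LE", "MT"}
    t: float
    t_bin: int | None = None
    iterations: int | None = None
    objective: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise InputError(f"threshold {self.t} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class ClassStatistics:
    """Two-class statistics of a histogram split at bin ``t_bin``.

    Background = bins ≤ t_bin, foreground = bins > t_bin.  Means are in
    bin-index units; a class with zero mass has NaN mean and is flagged.
    """

    omega0: float
    omega1: float
    m1: float
    m2: float
    sigma_b2: float
    sigma_w2: float
    empty_class: bool


@dataclasses.dataclass(frozen=True)
class CooccurrenceMatrix:
    """Ordered gray-level pair counts at one-step axial adjacency.

    Entry (i, j) counts pairs where a pixel of level i has a right or
    below neighbor of level j (no wraparound).
    """

    counts: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise InputError("co-occurrence matrix is empty")
        return self.counts / total


@dataclasses.dataclass(frozen=True)
class EntropyValue:
    """Shannon entropy of a gray-level distribution, in bits."""

    H: float
    L: int = N_LEVELS


# ---------------------------------------------------------------------------
# Class statistics and Otsu
# ---------------------------------------------------------------------------

def _moments(hist: GrayHistogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative mass and first moment over bins, plus bin indices."""
    p = hist.probabilities
    k = np.arange(N_LEVELS, dtype=np.float64)
    return p, k, np.cumsum(p)


def class_statistics(hist: GrayHistogram, t_bin: int) -> ClassStatistics:
    """Per-class probabilities, means and variances at a candidate split."""
    if not 0 <= t_bin <= N_LEVELS - 1:
        raise InputError(f"t_bin {t_bin} outside 0..{N_LEVELS - 1}")
    if hist.n_pixels == 0:
        raise InputError("empty histogram")
    p, k, _ = _moments(hist)
    lo = slice(0, t_bin + 1)
    hi = slice(t_bin + 1, N_LEVELS)
    omega0 = float(p[lo].sum())
    omega1 = float(p[hi].sum())
    mu_total = float((p * k).sum())
    var_total = float((p * (k - mu_total) ** 2).sum())
    empty = omega0 == 0.0 or omega1 == 0.0
    m1 = float((p[lo] * k[lo]).sum() / omega0) if omega0 > 0 else math.nan
    m2 = float((p[hi] * k[hi]).sum() / omega1) if omega1 > 0 else math.nan
    if empty:
        sigma_b2 = 0.0
    else:
        sigma_b2 = omega0 * omega1 * (m1 - m2) ** 2
    sigma_w2 = var_total - sigma_b2
    return ClassStatistics(omega0, omega1, m1, m2, sigma_b2, max(sigma_w2, 0.0), empty)


def _between_class_variance_curve(hist: GrayHistogram) -> np.ndarray:
    """σ_b² at every candidate split t_bin = 0..255, vectorized."""
    p, k, w0 = _moments(hist)
    mu = np.cumsum(p * k)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sb2 = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    sb2[~np.isfinite(sb2)] = 0.0
    return sb2


def _check_two_levels(hist: GrayHistogram) -> None:
    if hist.n_pixels == 0:
        raise InputError("empty histogram")
    if int((hist.counts > 0).sum()) < 2:
        raise DegenerateHistogramError(
            "histogram has mass in fewer than two bins; no two-class split exists"
        )


def otsu_threshold(hist: GrayHistogram) -> ThresholdResult:
    """Otsu's threshold: the split maximizing the between-class variance.

    When several splits attain the maximal σ_b² (a plateau, typical for
    spiky histograms), the floor of the mean of the maximizing bin
    indices is returned, mirroring the common plateau-averaging default.
    """
    _check_two_levels(hist)
    sb2 = _between_class_variance_curve(hist)
    best = sb2.max()
    plateau = np.flatnonzero(sb2 == best)
    t_bin = int(math.floor(plateau.mean()))
    return ThresholdResult(
        method="OT", t=t_bin / (N_LEVELS - 1), t_bin=t_bin, objective=float(best)
    )


# ---------------------------------------------------------------------------
# Ridler–Calvard (isodata)
# ---------------------------------------------------------------------------

def ridler_calvard_threshold(hist: GrayHistogram) -> ThresholdResult:
    """Isodata fixed-point threshold ``t = (m1 + m2) / 2``.

    Starts from the overall histogram mean and iterates the class-mean
    average until successive thresholds differ by less than half a bin.
    The converged threshold is real-valued (not snapped to the grid).
    """
    _check_two_levels(hist)
    p, k, _ = _moments(hist)
    pk = p * k
    t = float(pk.sum())  # overall mean, bin units; strictly inside the support
    tol_bins = RC_TOLERANCE * (N_LEVELS - 1)
    for iteration in range(1, RC_MAX_ITERATIONS + 1):
        lo = k <= t
        w0 = p[lo].sum()
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:  # mean fell outside the occupied range
            raise ConvergenceError("isodata iteration produced an empty class")
        m1 = pk[lo].sum() / w0
        m2 = pk[~lo].sum() / w1
        t_new = 0.5 * (m1 + m2)
        if abs(t_new - t) < tol_bins:
            return ThresholdResult(
                method="RC", t=t_new / (N_LEVELS - 1), iterations=iteration
            )
        t = t_new
    raise ConvergenceError(
        f"isodata did not converge within {RC_MAX_ITERATIONS} iterations"
    )


# ---------------------------------------------------------------------------
# Local entropy
# ---------------------------------------------------------------------------

def cooccurrence_matrix(plane: SaturationPlane) -> CooccurrenceMatrix:
    """Build the 256×256 co-occurrence matrix of the quantized plane.

    Ordered pairs (pixel, right neighbor) and (pixel, below neighbor),
    no wraparound.
    """
    q = plane.quantized()
    pairs_i = np.concatenate([q[:, :-1].ravel(), q[:-1, :].ravel()])
    pairs_j = np.concatenate([q[:, 1:].ravel(), q[1:, :].ravel()])
    flat = np.bincount(pairs_i * N_LEVELS + pairs_j, minlength=N_LEVELS * N_LEVELS)
    return CooccurrenceMatrix(flat.reshape(N_LEVELS, N_LEVELS).astype(np.int64))


def _plogp(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _quadrant_entropy_curve(P: np.ndarray) -> np.ndarray:
    """Summed BB + FF quadrant entropies at every split t = 0..255.

    For a quadrant with total mass Ps and raw cell entropy term
    E = Σ p log2 p, the entropy after renormalizing cells to a
    distribution is ``log2(Ps) − E / Ps``; an empty quadrant
    contributes 0.
    """
    cs = P.cumsum(axis=0).cumsum(axis=1)
    es = _plogp(P).cumsum(axis=0).cumsum(axis=1)
    t = np.arange(N_LEVELS)
    p_bb = cs[t, t]
    e_bb = es[t, t]
    p_ff = cs[-1, -1] - cs[t, -1] - cs[-1, t] + cs[t, t]
    e_ff = es[-1, -1] - es[t, -1] - es[-1, t] + es[t, t]

    def _H(mass: np.ndarray, e: np.ndarray) -> np.ndarray:
        out = np.zeros(N_LEVELS)
        nz = mass > 0
        out[nz] = np.log2(mass[nz]) - e[nz] / mass[nz]
        return out

    return _H(p_bb, e_bb) + _H(p_ff, e_ff)


def _first_order_entropy_curve(hist: GrayHistogram) -> np.ndarray:
    """Sum of renormalized background and foreground entropies (Kapur-style)."""
    p = hist.probabilities
    mass = np.cumsum(p)
    e = np.cumsum(_plogp(p))
    curve = np.zeros(N_LEVELS)
    for side_mass, side_e in ((mass, e), (1.0 - mass, e[-1] - e)):
        nz = side_mass > 1e-300
        curve[nz] += np.log2(side_mass[nz]) - side_e[nz] / side_mass[nz]
    return curve


def local_entropy_threshold(
    plane: SaturationPlane, variant: str = "cooccurrence"
) -> ThresholdResult:
    """Entropy-maximizing threshold on the quantized saturation plane.

    The default ``"cooccurrence"`` variant maximizes the sum of the
    background-background and foreground-foreground quadrant entropies
    of the co-occurrence matrix (a local, second-order criterion); the
    ``"first_order"`` variant maximizes the sum of the two renormalized
    histogram class entropies.  The first bin attaining the maximum is
    returned.
    """
    q = plane.quantized()
    if np.unique(q).size < 2:
        raise DegeneratePlaneError("constant plane; no two-class split exists")
    if variant == "cooccurrence":
        P = cooccurrence_matrix(plane).probabilities
        curve = _quadrant_entropy_curve(P)
    elif variant == "first_order":
        counts = np.bincount(q.ravel(), minlength=N_LEVELS)
        curve = _first_order_entropy_curve(GrayHistogram(counts))
    else:
        raise InputError(f"unknown LE variant {variant!r}")
    t_bin = int(np.argmax(curve))
    return ThresholdResult(
        method="LE",
        t=t_bin / (N_LEVELS - 1),
        t_bin=t_bin,
        objective=float(curve[t_bin]),
    )


# ---------------------------------------------------------------------------
# Manual threshold and entropy
# ---------------------------------------------------------------------------

def manual_threshold(t: float) -> ThresholdResult:
    """Wrap a user-chosen threshold (partly subjective, histogram-guided)."""
    if not 0.0 <= t <= 1.0:
        raise InputError(f"manual threshold {t} outside [0, 1]")
    return ThresholdResult(method="MT", t=float(t))


def shannon_entropy(hist: GrayHistogram) -> EntropyValue:
    """Shannon entropy H = −Σ p_i log2 p_i of the histogram, in bits."""
    p = hist.probabilities
    return EntropyValue(H=float(-_plogp(p).sum()), L=N_LEVELS)
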