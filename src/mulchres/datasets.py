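"""Packaged study data and the synthetic field-image generator.

Two data sources back the package:

* the embedded per-image area table of the mulch-deterioration study
  (24 photographs: 4 mulch materials × 6 blocks, with the thresholds
  and percent-bare-soil areas of every method plus the expert-traced
  reference area), shipped verbatim as a CSV fixture; and
* a generator of synthetic two-class scenes with known ground-truth
  soil fraction, standing in for the original field photographs, which
  are not distributable.

The generator emulates the one property the method exploits — a bimodal
saturation histogram: soil pixels are chromatic (high S), intact black
mulch is nearly achromatic (low S).  Ground-truth masks are blobby
(thresholded smoothed noise) because mulch tears are irregular and blob
boundaries exercise the 8-connected cleanup realistically.  Default
class means (soil 0.5, mulch 0.15, spread 0.05) put the histogram
valley near the 0.2–0.35 threshold range observed on the real images;
the default scene is 120×240 px, a 1/100-linear-scale desk version of
the 1200×2400 field frames, which keeps the m·n/100 cleanup rule
proportionally meaningful.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .exceptions import InputError
from .imaging import RGBImage, hsv_to_rgb
from .segmentation import BinaryMask

#: per-material target soil fractions of the default simulated campaign;
#: chosen to mimic the deterioration ordering measured on the real plots
#: (biodegradable films ≈ half gone, polyethylene < 20%, paper ≈ 40%)
DEFAULT_DESIGN: dict[int, float] = {1: 0.51, 2: 0.53, 3: 0.18, 4: 0.44}

#: between-block spread of the soil fraction within one material
BLOCK_FRACTION_SD = 0.04

N_BLOCKS = 6


# ---------------------------------------------------------------------------
# The embedded study table
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Table1Row:
    """One photograph's thresholds and percent areas, as published.

    Mulches 1–2 are biodegradable plastic, 3 is polyethylene, 4 is
    paper.  Thresholds are on [0, 1]; areas are percent bare soil after
    small-object removal.  ``a_r`` is the expert-traced reference area.
    """

    image_id: int
    mulch: int
    block: int
    t_ot: float
    t_rc: float
    t_mt: float
    t_le: float
    a_ot: float
    a_rc: float
    a_mt: float
    a_le: float
    a_r: float


def table1_frame() -> pd.DataFrame:
    """The study's per-image table as a DataFrame, verbatim as published.

    The table is intentionally unedited: it includes one image where
    the isodata threshold exceeds the Otsu threshold (image 11) and one
    near-fully-covered plot with a 0.0000 entropy-method area (image
    17).
    """
    path = resources.files("mulchres").joinpath("data/table1.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_table1() -> list[Table1Row]:
    """The embedded table as typed rows (24 of them, 6 per mulch)."""
    return [Table1Row(**row) for row in table1_frame().to_dict(orient="records")]


# ---------------------------------------------------------------------------
# Synthetic scenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SyntheticScene:
    """A generated field image with known ground truth."""

    image: RGBImage
    truth_mask: BinaryMask
    soil_fraction: float
    mu_soil: float
    mu_mulch: float
    sigma: float
    seed: int
    mulch: int | None = None
    block: int | None = None

    @property
    def truth_area_pct(self) -> float:
        m, n = self.truth_mask.shape
        return 100.0 * self.truth_mask.n_soil / (m * n)


def _blob_mask(
    rng: np.random.Generator, dims: tuple[int, int], soil_fraction: float,
    blob_sigma: float,
) -> np.ndarray:
    """Blobby boolean mask whose True count is round(fraction · m·n)."""
    m, n = dims
    k = int(round(soil_fraction * m * n))
    if k <= 0:
        return np.zeros(dims, dtype=bool)
    if k >= m * n:
        return np.ones(dims, dtype=bool)
    field = ndimage.gaussian_filter(rng.standard_normal(dims), blob_sigma)
    mask = np.zeros(m * n, dtype=bool)
    mask[np.argpartition(field.ravel(), -k)[-k:]] = True
    return mask.reshape(dims)


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, size: int
) -> np.ndarray:
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def make_scene(
    soil_fraction: float,
    mu_soil: float = 0.5,
    mu_mulch: float = 0.15,
    sigma: float = 0.05,
    dims: tuple[int, int] = (120, 240),
    seed: int = 0,
    blob_sigma: float = 10.0,
    mulch: int | None = None,
    block: int | None = None,
) -> SyntheticScene:
    """Generate one two-class scene with known soil fraction.

    The ground-truth mask thresholds smoothed Gaussian noise at the
    quantile giving exactly ``round(soil_fraction · m·n)`` soil pixels.
    Per-pixel saturation is drawn from a normal truncated to [0, 1]
    with mean ``mu_soil`` on soil and ``mu_mulch`` on mulch and common
    spread ``sigma``.  The RGB image is composed so its HSV saturation
    equals the drawn plane: hue is a fixed earthy constant, value is
    moderately bright on soil and low on mulch.  Deterministic for a
    fixed seed.
    """
    if not 0.0 <= soil_fraction <= 1.0:
        raise InputError("soil_fraction must be in [0, 1]")
    if not 0.0 <= mu_mulch < mu_soil <= 1.0:
        raise InputError("need 0 <= mu_mulch < mu_soil <= 1")
    if sigma <= 0:
        raise InputError("sigma must be positive")
    if min(dims) < 64:
        raise InputError("scene must be at least 64x64 pixels")
    rng = np.random.default_rng(seed)
    truth = _blob_mask(rng, dims, soil_fraction, blob_sigma)
    saturation = np.empty(dims, dtype=float)
    saturation[truth] = _truncated_normal(rng, mu_soil, sigma, int(truth.sum()))
    saturation[~truth] = _truncated_normal(rng, mu_mulch, sigma, int((~truth).sum()))
    hue = np.full(dims, 1.0 / 12.0)  # earthy orange-brown
    value = np.where(truth, 0.55, 0.2)
    image = hsv_to_rgb(hue, saturation, value)
    return SyntheticScene(
        image=image,
        truth_mask=BinaryMask(truth),
        soil_fraction=float(soil_fraction),
        mu_soil=mu_soil,
        mu_mulch=mu_mulch,
        sigma=sigma,
        seed=int(seed),
        mulch=mulch,
        block=block,
    )


def scene_batch(
    design: dict[int, float] | None = None,
    seed: int = 0,
    n_blocks: int = N_BLOCKS,
    block_fraction_sd: float = BLOCK_FRACTION_SD,
    **scene_kwargs,
) -> list[SyntheticScene]:
    """Generate a simulated campaign: materials × blocks scenes.

    ``design`` maps material label → target soil fraction (defaults to
    :data:`DEFAULT_DESIGN`).  Block-to-block variation within a
    material is modeled by jittering the fraction with a truncated
    normal of spread ``block_fraction_sd``.  Per-scene seeds are
    spawned deterministically from the master seed, so two calls with
    the same seed yield identical scenes.
    """
    design = DEFAULT_DESIGN if design is None else design
    master = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    scenes: list[SyntheticScene] = []
    for material, fraction in sorted(design.items()):
        for block in range(1, n_blocks + 1):
            f = fraction + block_fraction_sd * jitter_rng.standard_normal()
            f = float(np.clip(f, 0.02, 0.98))
            child = master.spawn(1)[0]
            scene_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
            scenes.append(
                make_scene(
                    soil_fraction=f,
                    seed=scene_seed,
                    mulch=material,
                    block=block,
                    **scene_kwargs,
                )
            )
    return scenes
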