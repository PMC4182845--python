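"""Binarization, small-object cleanup and percent-bare-soil computation.

The binary mask uses the polarity forced by the data: soil is the
foreground (white, ``True``) and is *more* saturated than black mulch,
so a pixel is soil iff its saturation strictly exceeds the threshold.
Noise regions smaller than one-hundredth of the image pixel count are
removed from the mask and from its complement (hole filling), using
8-connected component labeling, before the percent area is computed.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from skimage import morphology

from .exceptions import InputError, MulchresError
from .imaging import (
    RGBImage,
    SaturationPlane,
    extract_saturation,
    rgb_to_hsv,
    saturation_histogram,
)
from .thresholding import (
    ThresholdResult,
    local_entropy_threshold,
    manual_threshold,
    otsu_threshold,
    ridler_calvard_threshold,
)

logger = logging.getLogger(__name__)

#: canonical two-letter method codes, keyed by CLI spelling
METHOD_CODES = {
    "otsu": "OT",
    "rc": "RC",
    "le": "LE",
    "manual": "MT",
    "OT": "OT",
    "RC": "RC",
    "LE": "LE",
    "MT": "MT",
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the segmentation pipeline.

    ``cleanup_divisor`` sets the small-object bound floor(m·n / divisor);
    ``connectivity`` is 4 or 8 (pixel neighbors edge-wise only, or edge-
    and corner-wise); ``le_variant`` selects the local-entropy objective.
    """

    bins: int = 256
    cleanup_divisor: int = 100
    connectivity: int = 8
    le_variant: str = "cooccurrence"

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")
        if self.cleanup_divisor < 1:
            raise InputError("cleanup divisor must be >= 1")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a config file, either plain ``key=value`` lines or YAML."""
    with open(path) as fh:
        text = fh.read()
    stripped = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in stripped if ln and not ln.startswith("#")]
    if lines and all("=" in ln for ln in lines):
        raw: dict = {}
        for ln in lines:
            key, _, value = ln.partition("=")
            raw[key.strip()] = yaml.safe_load(value.strip())
    else:
        raw = yaml.safe_load(text) or {}
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """Boolean raster B(x, y): True (white) = bare soil, False = mulch."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != np.bool_:
            raise InputError("mask must be a 2-D boolean array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_soil(self) -> int:
        return int(self.pixels.sum())


@dataclasses.dataclass(frozen=True)
class AreaRecord:
    """Percent bare soil measured on one image with one method."""

    image_id: str
    method: str
    t: float
    area_pct: float
    area_pct_precleanup: float
    mulch: int | None = None
    block: int | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def binarize(plane: SaturationPlane, t: ThresholdResult | float) -> BinaryMask:
    """Threshold the plane: a pixel is soil iff S > t (strict)."""
    tv = t.t if isinstance(t, ThresholdResult) else float(t)
    if not 0.0 <= tv <= 1.0:
        raise InputError(f"threshold {tv} outside [0, 1]")
    return BinaryMask(plane.values > tv)


def remove_small_objects(
    mask: BinaryMask, divisor: int = 100, connectivity: int = 8
) -> BinaryMask:
    """Delete noise components smaller than floor(m·n / divisor).

    Two passes of connected-component deletion ("smaller than" is
    strict): first small True components are set to False, then small
    False components of the result's complement are set back to True
    (hole filling).  Components are labeled with 8-connectivity by
    default.
    """
    m, n = mask.shape
    min_size = (m * n) // divisor
    if min_size <= 1:
        return mask
    conn = 2 if connectivity == 8 else 1
    # max_size removes components of size <= its value; the bound is a
    # strict "smaller than", so components of exactly min_size survive
    cleaned = morphology.remove_small_objects(
        mask.pixels, max_size=min_size - 1, connectivity=conn
    )
    filled = ~morphology.remove_small_objects(
        ~cleaned, max_size=min_size - 1, connectivity=conn
    )
    return BinaryMask(filled)


def soil_area_percent(mask: BinaryMask) -> float:
    """Percent white pixels: 100 · #True / (m·n)."""
    m, n = mask.shape
    return 100.0 * mask.n_soil / (m * n)


def select_threshold(
    plane: SaturationPlane,
    method: str,
    manual_t: float | None = None,
    config: PipelineConfig | None = None,
) -> ThresholdResult:
    """Dispatch to the requested thresholding method for one plane."""
    cfg = config or PipelineConfig()
    code = METHOD_CODES.get(method)
    if code is None:
        raise InputError(f"unknown method {method!r}")
    if (code == "MT") != (manual_t is not None):
        raise InputError("manual_t must be given exactly when method is manual")
    if code == "OT":
        return otsu_threshold(saturation_histogram(plane))
    if code == "RC":
        return ridler_calvard_threshold(saturation_histogram(plane))
    if code == "LE":
        return local_entropy_threshold(plane, variant=cfg.le_variant)
    return manual_threshold(manual_t)


def process_image(
    image: RGBImage,
    method: str,
    manual_t: float | None = None,
    image_id: str = "",
    mulch: int | None = None,
    block: int | None = None,
    config: PipelineConfig | None = None,
) -> AreaRecord:
    """Run the full pipeline on one photograph.

    RGB → HSV → saturation plane → histogram → threshold selection →
    binarization → small-object removal → percent bare soil.  Both the
    pre- and post-cleanup areas are recorded.
    """
    cfg = config or PipelineConfig()
    plane = extract_saturation(rgb_to_hsv(image))
    t = select_threshold(plane, method, manual_t=manual_t, config=cfg)
    raw_mask = binarize(plane, t)
    area_pre = soil_area_percent(raw_mask)
    cleaned = remove_small_objects(
        raw_mask, divisor=cfg.cleanup_divisor, connectivity=cfg.connectivity
    )
    return AreaRecord(
        image_id=image_id,
        method=METHOD_CODES[method],
        t=t.t,
        area_pct=soil_area_percent(cleaned),
        area_pct_precleanup=area_pre,
        mulch=mulch,
        block=block,
    )


def process_batch(
    items: Iterable[tuple[str, RGBImage]],
    method: str,
    manual_t: float | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[AreaRecord], dict[str, str]]:
    """Process many images; per-image failures are logged and skipped.

    Field batches contain degenerate frames (e.g. a fully covered plot
    with a constant saturation plane), so errors are collected per
    image rather than aborting the batch.  Returns the records and a
    mapping of failed image ids to error messages.
    """
    records: list[AreaRecord] = []
    failures: dict[str, str] = {}
    for image_id, image in items:
        try:
            records.append(
                process_image(
                    image, method, manual_t=manual_t, image_id=image_id, config=config
                )
            )
        except MulchresError as exc:
            logger.warning("image %s skipped: %s", image_id, exc)
            failures[image_id] = str(exc)
    return records, failures


def records_to_frame(records: Sequence[AreaRecord]) -> pd.DataFrame:
    """Tabulate records, rows sorted lexicographically by image id."""
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "mulch": r.mulch,
                "block": r.block,
                "method": r.method,
                "t": r.t,
                "area_pct_precleanup": r.area_pct_precleanup,
                "area_pct": r.area_pct,
            }
            for r in records
        ]
    )
    return df.sort_values("image_id", kind="stable").reset_index(drop=True)


def write_records_csv(records: Sequence[AreaRecord], path: str | os.PathLike) -> None:
    records_to_frame(records).to_csv(path, index=False)
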