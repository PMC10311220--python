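"""Two-channel colocalization: Mander's M1/M2, Pearson correlation, and
the threshold overlap score (TOS).

Quantifies the spatial overlap of an axonal marker (e.g. Tuj1) with a
somatodendritic marker (e.g. MAP2).  Images are background-subtracted
with a rolling-ball of configurable diameter, signal pixels are
thresholded per channel, and M1/M2 are computed as area ratios of
co-occurring signal pixels.  PCC is the product-moment correlation over
all pixels; TOS rescales the co-occurrence of the top-intensity pixel
sets against the independence expectation into [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage import filters as _skfilters
from skimage import morphology as _skmorph
from skimage import restoration as _skrestoration

__all__ = [
    "ImagePair",
    "ColocParams",
    "ColocResult",
    "subtract_background",
    "signal_masks",
    "manders",
    "pearson",
    "threshold_overlap_score",
    "colocalize",
]


@dataclass
class ImagePair:
    """Two aligned single-channel non-negative intensity grids."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    pixel_size: Optional[float] = None  # um / pixel

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.ndim != 2 or self.channel_b.ndim != 2:
            raise ValueError("channels must be 2-D intensity grids")
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channel shapes must match")
        for c in (self.channel_a, self.channel_b):
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError("intensities must be finite and non-negative")


@dataclass
class ColocParams:
    """Background, thresholding and top-fraction settings.

    ``ball_diameter`` is the rolling-ball diameter in pixels;
    ``top_fraction`` the fraction of brightest pixels sampled for TOS.
    ``mask_method`` selects per-channel signal thresholding for M1/M2:
    'otsu' (default) or 'fixed' with explicit thresholds (strict >).
    """

    ball_diameter: int = 25
    top_fraction: float = 0.10
    mask_method: str = "otsu"
    fixed_threshold_a: Optional[float] = None
    fixed_threshold_b: Optional[float] = None
    background_subtract: bool = True
    ball_method: str = "rolling_ball"

    def __post_init__(self) -> None:
        if self.ball_diameter < 3:
            raise ValueError("ball_diameter must be >= 3 pixels")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.mask_method not in ("otsu", "fixed"):
            raise ValueError("mask_method must be 'otsu' or 'fixed'")
        if self.ball_method not in ("rolling_ball", "opening"):
            raise ValueError("ball_method must be 'rolling_ball' or 'opening'")


@dataclass
class ColocResult:
    M1: float
    M2: float
    PCC: float
    TOS: float
    n_pixels_a: int
    n_pixels_b: int
    n_overlap: int


def subtract_background(
    image: np.ndarray, ball_diameter: int = 25, method: str = "rolling_ball"
) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the upper envelope of a ball of the given diameter
    rolled under the intensity surface (equivalently a grayscale opening
    with a ball-shaped structuring element); ``method='opening'`` uses a
    flat-disk grayscale opening instead.  The result is the residual,
    clipped at zero.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if ball_diameter < 3:
        raise ValueError("ball_diameter must be >= 3 pixels")
    radius = ball_diameter / 2.0
    if method == "rolling_ball":
        background = _skrestoration.rolling_ball(image, radius=radius)
    elif method == "opening":
        background = _skmorph.opening(image, _skmorph.disk(int(round(radius))))
    else:
        raise ValueError("method must be 'rolling_ball' or 'opening'")
    return np.clip(image - background, 0.0, None)


def signal_masks(pair: ImagePair, params: ColocParams | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Binary signal masks for the two channels.

    With ``mask_method='fixed'`` a pixel is signal iff its intensity is
    strictly above the channel's threshold.  With 'otsu' each channel is
    thresholded independently; a constant channel is an error since no
    two-class split exists.
    """
    params = params or ColocParams()
    masks = []
    for channel, fixed in (
        (pair.channel_a, params.fixed_threshold_a),
        (pair.channel_b, params.fixed_threshold_b),
    ):
        if params.mask_method == "fixed":
            if fixed is None:
                raise ValueError("fixed mask_method requires fixed_threshold_a and fixed_threshold_b")
            thr = fixed
        else:
            if np.ptp(channel) == 0:
                raise ValueError("otsu threshold undefined for a constant channel")
            thr = _skfilters.threshold_otsu(channel)
        masks.append(channel > thr)
    return masks[0], masks[1]


def manders(mask_a: np.ndarray, mask_b: np.ndarray) -> Tuple[float, float]:
    """Mander's area-overlap coefficients on binary masks.

    M1 = |A and B| / |A|, M2 = |A and B| / |B|.  An empty mask makes the
    corresponding coefficient NaN (undefined), never 0.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shapes must match")
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    n_ab = int((mask_a & mask_b).sum())
    m1 = n_ab / n_a if n_a else float("nan")
    m2 = n_ab / n_b if n_b else float("nan")
    return m1, m2


def pearson(pair: ImagePair) -> float:
    """Pearson correlation of the two channels over all pixels (NaN if constant)."""
    a = pair.channel_a.ravel()
    b = pair.channel_b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _top_mask(channel: np.ndarray, n_select: int) -> np.ndarray:
    flat = channel.ravel()
    # stable descending sort: ties broken by pixel order, so the
    # selected count is always exactly n_select and deterministic
    order = np.argsort(-flat, kind="stable")[:n_select]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order] = True
    return mask.reshape(channel.shape)


def threshold_overlap_score(pair: ImagePair, params: ColocParams | None = None) -> float:
    """Threshold overlap score of the two channels' brightest pixel sets.

    The top ``top_fraction`` of pixels is selected per channel (ties
    broken by pixel order).  With N total pixels, nA and nB selected and
    nAB co-occurring, e = nA*nB/N is the independence expectation and

        TOS = (nAB - e) / (min(nA, nB) - e)          if nAB >= e
        TOS = (nAB - e) / (e - max(0, nA + nB - N))  otherwise

    so TOS is 1 at maximal co-occurrence, 0 at independence and -1 at
    maximal exclusion.
    """
    params = params or ColocParams()
    n_total = pair.channel_a.size
    n_select = int(round(params.top_fraction * n_total))
    if n_select <= 0:
        raise ValueError("top_fraction selects zero pixels")
    top_a = _top_mask(pair.channel_a, n_select)
    top_b = _top_mask(pair.channel_b, n_select)
    n_a = int(top_a.sum())
    n_b = int(top_b.sum())
    n_ab = int((top_a & top_b).sum())
    expected = n_a * n_b / n_total
    if n_ab >= expected:
        denom = min(n_a, n_b) - expected
    else:
        denom = expected - max(0, n_a + n_b - n_total)
    if denom == 0:
        # attainable range collapses to a point; co-occurrence equals it
        return 0.0
    return float((n_ab - expected) / denom)


def colocalize(pair: ImagePair, params: ColocParams | None = None) -> ColocResult:
    """Full colocalization analysis of an image pair.

    Optionally background-subtracts both channels, derives per-channel
    signal masks, and reports Mander's M1/M2 together with PCC and TOS
    computed on the (subtracted) intensity images.
    """
    params = params or ColocParams()
    if params.background_subtract:
        a = subtract_background(pair.channel_a, params.ball_diameter, params.ball_method)
        b = subtract_background(pair.channel_b, params.ball_diameter, params.ball_method)
        pair = ImagePair(a, b, pair.pixel_size)
    mask_a, mask_b = signal_masks(pair, params)
    m1, m2 = manders(mask_a, mask_b)
    return ColocResult(
        M1=m1,
        M2=m2,
        PCC=pearson(pair),
        TOS=threshold_overlap_score(pair, params),
        n_pixels_a=int(mask_a.sum()),
        n_pixels_b=int(mask_b.sum()),
        n_overlap=int((mask_a & mask_b).sum()),
    )
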