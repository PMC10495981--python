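"""Per-frame T-cell localization with a scale-normalized LoG blob detector.

Bright, approximately Gaussian blobs of a known diameter d respond maximally
to a Laplacian-of-Gaussian filter at scale sigma = (d/2)/sqrt(2) (the 2D
scale-space optimum).  The response is negated and multiplied by sigma^2 so
bright blobs give positive, scale-comparable maxima; the detector then keeps
strict local maxima above a quality threshold.

The quality threshold is expressed on this normalized-response scale, which
is instrument-relative: thresholds quoted for other software's internal
quality units (e.g. the 40-120 band commonly used with the same detector in
TrackMate) do not transfer numerically and should be re-chosen relative to
the noise floor of the data at hand (see ``suggest_threshold``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

#: Quality band commonly used with this detector in TrackMate, on that
#: software's internal scale.  Documented for comparability only — the
#: values are NOT portable to the normalized response used here.
REFERENCE_QUALITY_BAND = (40.0, 120.0)


@dataclass(frozen=True)
class DetectionConfig:
    """Blob-detector settings.

    diameter_um : expected blob diameter (default 7 um, a lymphocyte).
    quality_threshold : minimum normalized LoG response at the maximum.
    subpixel : refine maxima by a local quadratic fit.
    """

    diameter_um: float = 7.0
    quality_threshold: float = 0.0
    subpixel: bool = False

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


@dataclass(frozen=True)
class Spot:
    """A detected blob: frame index, centroid in um, detector response."""

    frame: int
    x_um: float
    y_um: float
    quality: float
    radius_um: float


def log_response(image: np.ndarray, pixel_size_um: float, diameter_um: float) -> np.ndarray:
    """Negated, scale-normalized Laplacian-of-Gaussian response.

    ``response = -sigma_px^2 * LoG(image)`` at ``sigma = (d/2)/sqrt(2)``
    converted to pixels; bright blobs of diameter ``d`` yield positive
    maxima and the response is linear in image intensity.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if diameter_um < pixel_size_um:
        raise ValueError("blob diameter must be at least one pixel")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    sigma_px = (diameter_um / 2.0) / math.sqrt(2.0) / pixel_size_um
    raw = ndi.gaussian_laplace(image, sigma_px, mode="reflect")
    # the sampled LoG kernel has a small nonzero sum (discretization
    # residual); remove that DC component so a constant image maps to a
    # null response, preserving linearity and shift equivariance
    dc_gain = float(ndi.gaussian_laplace(np.ones((1, 1)), sigma_px, mode="reflect")[0, 0])
    raw -= dc_gain * ndi.gaussian_filter(image, sigma_px, mode="reflect")
    return -(sigma_px**2) * raw


def suggest_threshold(response: np.ndarray, k: float = 8.0) -> float:
    """Noise-floor-relative quality threshold.

    Returns ``k`` times a robust (MAD-based) estimate of the response
    standard deviation; blobs occupy a small image fraction so the MAD is
    dominated by the noise floor.
    """
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    return float(k * 1.4826 * mad)


def _quadratic_offset(fm, f0, fp):
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a concave maximum; keep integer position
        return 0.0
    off = 0.5 * (fm - fp) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    config: DetectionConfig,
    frame: int = 0,
) -> list[Spot]:
    """Detect blobs in a single frame.

    Spots are strict local maxima of the normalized LoG response within a
    window one blob radius wide on each side, with quality >= threshold.
    Maxima within one radius of the image border are discarded (reflect
    padding makes them unreliable).  Plateau ties keep the lexicographically
    smallest pixel index.  Coordinates are returned in micrometres with
    ``x`` along columns and ``y`` along rows.
    """
    resp = log_response(image, pixel_size_um, config.diameter_um)
    r_px = (config.diameter_um / 2.0) / pixel_size_um
    w = max(1, int(round(r_px)))
    maxf = ndi.maximum_filter(resp, size=2 * w + 1, mode="reflect")
    mask = (resp >= maxf) & (resp >= config.quality_threshold)

    border = int(math.ceil(r_px))
    mask[:border, :] = False
    mask[-border:, :] = False
    mask[:, :border] = False
    mask[:, -border:] = False

    candidates = np.argwhere(mask)  # row-major == lexicographic order
    kept: list[tuple[int, int]] = []
    for r, c in candidates:
        if any(max(abs(r - kr), abs(c - kc)) <= w for kr, kc in kept):
            continue  # plateau / shared window: first (lexicographic) wins
        kept.append((int(r), int(c)))

    spots = []
    for r, c in kept:
        rr, cc = float(r), float(c)
        if config.subpixel:
            rr += _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
            cc += _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
        spots.append(
            Spot(
                frame=frame,
                x_um=cc * pixel_size_um,
                y_um=rr * pixel_size_um,
                quality=float(resp[r, c]),
                radius_um=config.diameter_um / 2.0,
            )
        )
    return spots


def detect_stack(
    frames: np.ndarray,
    pixel_size_um: float,
    config: DetectionConfig,
) -> list[Spot]:
    """Run ``detect_spots`` over a (T, H, W) stack; frames indexed from 0."""
    spots: list[Spot] = []
    for t, frame_img in enumerate(frames):
        spots.extend(detect_spots(frame_img, pixel_size_um, config, frame=t))
    return spots
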