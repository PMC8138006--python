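"""Image preparation: bad-pixel repair, reference subtraction, flat-fielding, equalization.

The fixed stage order is

    repair_bad_pixels -> subtract_references -> flatfield_correct -> equalize_exposure

Repair runs first so that sensor defects cannot poison the reference-based
corrections.  Each stage is per-channel independent; the composed map is
idempotent on its own output (a processed block's references are rewritten
so a second pass is a no-op).

Correction conventions (the upstream literature defers the exact formulas to
instrument-specific references, so they are fixed explicitly here):

* the water reference is acquired with the shutter open and therefore
  already contains the dark level; subtracting it removes dark offset and
  stray/buffer background in one step;
* flat-fielding divides by the dark-subtracted calibration-fluid image,
  renormalized by its spatial mean so a uniform target keeps its mean level;
* "undetectable" pixels are those below dark mean + 2 x dark SD;
* outliers (spikes/dips) deviate from the local median by more than
  ``outlier_k`` local MADs (MAD scaled by 1.4826 to estimate sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, median_filter, minimum_filter

from .blocks import DataBlock, ReferenceImages, ValidationError

logger = logging.getLogger(__name__)

MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class CorrectionSettings:
    """Tunables of the repair stage.

    outlier_k : float
        Spike/dip threshold in local-MAD units (default 5).
    neighborhood : int
        Odd median window for detection and repair (default 3).
    clip_negative : bool
        Clip negatives to zero after reference subtraction.
    max_flag_fraction : float
        Abort if more than this fraction of a channel is flagged.
    """

    outlier_k: float = 5.0
    neighborhood: int = 3
    clip_negative: bool = True
    max_flag_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be odd and >= 3")


def _repair_stack(stack, flags, window):
    """Replace flagged pixels by the local median of non-flagged neighbours.

    Operates on a whole (n_channels, H, W) stack with channel-independent
    2-D windows.  Sparse flag sets (the usual case: defect rates ~1e-4) are
    repaired by gathering each flagged pixel's window directly, excluding
    other flagged pixels from the median; dense sets fall back to whole-image
    median filtering (two-pass, so clustered defects do not contaminate each
    other's repair value).
    """
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return stack
    if n_flagged > 0.005 * stack.size:
        med = median_filter(stack, size=(1, window, window), mode="reflect")
        masked = np.where(flags, med, stack)
        med2 = median_filter(masked, size=(1, window, window), mode="reflect")
        return np.where(flags, med2, stack)
    out = stack.copy()
    h, w = stack.shape[1:]
    cc, rr, qq = np.nonzero(flags)
    half = window // 2
    dr, dq = np.mgrid[-half : half + 1, -half : half + 1]
    dr, dq = dr.ravel(), dq.ravel()
    wr = np.clip(rr[:, None] + dr[None, :], 0, h - 1)
    wq = np.clip(qq[:, None] + dq[None, :], 0, w - 1)
    wc = np.broadcast_to(cc[:, None], wr.shape)
    vals = stack[wc, wr, wq].astype(float)
    vals[flags[wc, wr, wq]] = np.nan
    with np.errstate(invalid="ignore"):
        repaired = np.nanmedian(vals, axis=1)
    # a fully flagged window falls back to the channel median
    nanmask = ~np.isfinite(repaired)
    if nanmask.any():
        ch_med = np.median(stack, axis=(1, 2))
        repaired[nanmask] = ch_med[cc[nanmask]]
    out[cc, rr, qq] = repaired
    return out


def _detect_bad_pixels(stack, settings, saturation_level, undetectable_floor, dead_calib):
    """Per-pixel defect flags on an (n_channels, H, W) stack.

    Rules, per channel: at/above saturation; below the undetectable floor;
    dead according to the calibration image; or a spike/dip that both
    deviates from the local median by > k sigma and dominates every
    neighbour by at least half that deviation (the dominance condition
    distinguishes single-pixel defects from sharp structure such as cell
    boundaries, whose pixels have comparable neighbours).
    """
    flags = np.zeros(stack.shape, dtype=bool)
    if saturation_level is not None and np.isfinite(saturation_level):
        flags |= stack >= saturation_level
    if undetectable_floor is not None:
        flags |= stack < undetectable_floor[:, None, None]
    if dead_calib is not None:
        flags |= dead_calib
    k = settings.neighborhood
    stack32 = stack.astype(np.float32, copy=False)
    med = median_filter(stack32, size=(1, k, k), mode="reflect")
    resid = stack32 - med
    abs_resid = np.abs(resid)
    mad = median_filter(abs_resid, size=(1, k, k), mode="reflect")
    sigma = MAD_TO_SIGMA * mad
    # floor the scale estimate where the local MAD is uninformative (flat,
    # clipped, or noise-free neighbourhoods): a per-channel global residual
    # scale robust both to extreme spikes (unlike the SD) and to
    # clipped-to-zero regions (unlike the median; the 97.5th percentile of
    # |resid| equals 2.241 sigma for Gaussian noise), plus a small fraction
    # of the local signal level
    global_scale = np.maximum(
        MAD_TO_SIGMA * np.median(abs_resid, axis=(1, 2)),
        np.percentile(abs_resid, 97.5, axis=(1, 2)) / 2.241,
    )
    floor = np.maximum(global_scale[:, None, None], 1e-3 * np.abs(med))
    sigma = np.maximum(np.maximum(sigma, floor), 1e-12)
    footprint = np.ones((1, k, k), dtype=bool)
    footprint[0, k // 2, k // 2] = False
    nb_max = maximum_filter(stack32, footprint=footprint, mode="reflect")
    nb_min = minimum_filter(stack32, footprint=footprint, mode="reflect")
    spike = (resid > settings.outlier_k * sigma) & (stack32 - nb_max > 0.5 * resid)
    dip = (-resid > settings.outlier_k * sigma) & (nb_min - stack32 > -0.5 * resid)
    flags |= spike | dip
    return flags


def _detect_reference_spikes(stack, settings, saturation_level):
    """Defect flags for reference stacks (dark/water/calibration).

    References are spatially flat or smooth, so a single rule suffices:
    saturated pixels, plus residuals beyond k times the per-channel global
    robust scale.  (The local-MAD/dominance machinery exists to protect cell
    boundaries, which references do not have.)
    """
    flags = np.zeros(stack.shape, dtype=bool)
    if saturation_level is not None and np.isfinite(saturation_level):
        flags |= stack >= saturation_level
    k = settings.neighborhood
    stack32 = stack.astype(np.float32, copy=False)
    med = median_filter(stack32, size=(1, k, k), mode="reflect")
    resid = np.abs(stack32 - med)
    scale = np.maximum(
        np.maximum(
            MAD_TO_SIGMA * np.median(resid, axis=(1, 2)),
            np.percentile(resid, 97.5, axis=(1, 2)) / 2.241,
        ),
        1e-12,
    )
    flags |= resid > settings.outlier_k * scale[:, None, None]
    return flags


def repair_bad_pixels(
    block: DataBlock, settings: CorrectionSettings = CorrectionSettings()
):
    """Flag and repair dead/saturated/undetectable/outlier pixels.

    Returns ``(repaired_block, bad_pixel_map)`` with the map shaped like the
    channel stack.  Reference images are repaired with the same spike/dip
    rule (saturation only; the undetectable floor does not apply to darks).
    Raises if any channel has more than ``max_flag_fraction`` flagged.
    """
    out = block.copy()
    dark = block.references.dark
    floor = dark.mean(axis=(1, 2)) + 2.0 * dark.std(axis=(1, 2))
    flags_all = _detect_bad_pixels(
        block.channel_images,
        settings,
        block.saturation_level,
        floor,
        dead_calib=(block.references.calibration - dark) <= 0,
    )
    frac = flags_all.mean(axis=(1, 2))
    if np.any(frac > settings.max_flag_fraction):
        c = int(np.argmax(frac))
        raise ValidationError(
            f"channel {c + 1} unusable: {frac[c]:.1%} of pixels flagged "
            f"(limit {settings.max_flag_fraction:.0%})"
        )
    out.channel_images = _repair_stack(
        block.channel_images, flags_all, settings.neighborhood
    )
    if flags_all.any():
        logger.debug("repaired %d channel-stack pixels", int(flags_all.sum()))
    for name in ("dark", "water", "calibration"):
        stack = getattr(out.references, name)
        f = _detect_reference_spikes(stack, settings, block.saturation_level)
        setattr(
            out.references, name, _repair_stack(stack, f, settings.neighborhood)
        )
    return out, flags_all


def subtract_references(
    block: DataBlock, settings: CorrectionSettings = CorrectionSettings()
) -> DataBlock:
    """Subtract the water reference (dark-inclusive) from every channel.

    Removes dark offset and stray/buffer background in one step; negatives
    are clipped to zero when ``settings.clip_negative``.
    """
    if block.references.water.shape != block.channel_images.shape:
        raise ValidationError("water reference shape mismatch")
    out = block.copy()
    out.channel_images = block.channel_images - block.references.water
    if settings.clip_negative:
        np.clip(out.channel_images, 0.0, None, out=out.channel_images)
    out.references = ReferenceImages(
        dark=np.zeros_like(block.references.dark),
        water=np.zeros_like(block.references.water),
        calibration=block.references.calibration - block.references.dark,
    )
    return out


def flatfield_correct(block: DataBlock) -> DataBlock:
    """Flatten uneven illumination using the calibration-fluid image, per channel.

    ``flat = corrected * mean(calib - dark) / (calib - dark)`` pixel-wise.
    The mean renormalization preserves the spatial mean of a uniform target.
    Requires calib - dark strictly positive (non-positive pixels must have
    been repaired); fails naming the channel otherwise.
    """
    denom = block.references.calibration - block.references.dark
    for c in range(block.n_channels):
        if not np.all(denom[c] > 0):
            raise ValidationError(
                f"channel {c + 1}: calibration not strictly positive after dark "
                "subtraction; repair bad pixels first"
            )
    out = block.copy()
    gains = denom.mean(axis=(1, 2), keepdims=True) / denom
    out.channel_images = block.channel_images * gains
    # flat-fielded block: calibration becomes spatially uniform by construction
    out.references = ReferenceImages(
        dark=np.zeros_like(block.references.dark),
        water=np.zeros_like(block.references.water),
        calibration=np.broadcast_to(
            denom.mean(axis=(1, 2), keepdims=True), denom.shape
        ).copy(),
    )
    return out


def equalize_exposure(block: DataBlock) -> DataBlock:
    """Divide each channel by its exposure so intensities become counts/s."""
    exposures = block.channel_set.exposures
    if np.any(exposures <= 0):
        raise ValidationError("channel exposures must be positive")
    out = block.copy()
    out.channel_images = block.channel_images / exposures[:, None, None]
    from dataclasses import replace as dc_replace

    from .channels import ChannelSet

    out.channel_set = ChannelSet(
        tuple(dc_replace(c, exposure=1.0) for c in block.channel_set)
    )
    return out


def preprocess_block(
    block: DataBlock, settings: CorrectionSettings = CorrectionSettings()
):
    """Run the full fixed-order preparation; returns (block, bad_pixel_map).

    The output block's references and exposures are rewritten to the
    identity configuration (zero water/dark, uniform calibration, unit
    exposure, no finite saturation level), which makes the composed map
    idempotent on its own output.
    """
    repaired, bad_map = repair_bad_pixels(block, settings)
    corrected = subtract_references(repaired, settings)
    flat = flatfield_correct(corrected)
    equalized = equalize_exposure(flat)
    equalized.saturation_level = float("inf")
    return equalized, bad_map
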