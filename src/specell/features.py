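"""Per-cell spectral features: channel means, top-decile means, ratios, shape stats.

The cell's signature is built from its pixel intensities in each spectral
channel after preprocessing.  Two feature policies are supported:

* ``conservative`` — channel means, top-10%-pixel means, and channel
  intensity ratios; these stay interpretable in terms of fluorophore content
  (e.g. channel 2 ~ NAD(P)H, channels 15/32 ~ flavins, ch2/ch32 ~ redox
  ratio).
* ``extended`` — additionally per-channel pixel standard deviation,
  skewness and excess kurtosis, mathematically abstract but potentially
  more discriminative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import CellMask, DataBlock, validate_feature_table

logger = logging.getLogger(__name__)

KINDS = ("mean", "top_decile_mean", "sd", "skewness", "kurtosis", "ratio")
CONSERVATIVE_KINDS = ("mean", "top_decile_mean", "ratio")

#: channels with a dominant single fluorophore; default source of ratio pairs
INTERPRETABLE_CHANNELS = (2, 15, 32)


def mean_name(ch: int) -> str:
    return f"mean_ch{ch:02d}"


def top_decile_name(ch: int) -> str:
    return f"top10_ch{ch:02d}"


def ratio_name(a: int, b: int) -> str:
    return f"ratio_ch{a:02d}_ch{b:02d}"


def stat_name(kind: str, ch: int) -> str:
    return f"{kind}_ch{ch:02d}"


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named feature: a statistic of one channel, or a ratio of two means."""

    kind: str
    channel_a: int
    channel_b: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind '{self.kind}'")
        if self.kind == "ratio":
            if self.channel_b is None or self.channel_b == self.channel_a:
                raise ValueError("ratio requires two distinct channels")
        elif self.channel_b is not None:
            raise ValueError(f"{self.kind} takes a single channel")

    @property
    def name(self) -> str:
        if self.kind == "mean":
            return mean_name(self.channel_a)
        if self.kind == "top_decile_mean":
            return top_decile_name(self.channel_a)
        if self.kind == "ratio":
            return ratio_name(self.channel_a, self.channel_b)
        return stat_name(self.kind, self.channel_a)


@dataclass(frozen=True)
class FeatureSetPolicy:
    """Which feature kinds are admissible, and which ratio pairs to compute."""

    mode: str = "conservative"
    ratio_channels: tuple = INTERPRETABLE_CHANNELS
    extra_ratio_pairs: tuple = ()
    exhaustive_ratios: bool = False
    include_top_decile: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("conservative", "extended"):
            raise ValueError("mode must be 'conservative' or 'extended'")

    @property
    def kinds(self) -> tuple:
        return KINDS if self.mode == "extended" else CONSERVATIVE_KINDS

    def ratio_pairs(self, n_channels: int) -> list:
        if self.exhaustive_ratios:
            return [
                (a, b)
                for a in range(1, n_channels + 1)
                for b in range(1, n_channels + 1)
                if a != b
            ]
        pairs = [
            (a, b) for a in self.ratio_channels for b in self.ratio_channels if a != b
        ]
        pairs += [p for p in self.extra_ratio_pairs if p not in pairs]
        return pairs

    def descriptors(self, n_channels: int) -> list:
        """All admissible features in canonical column order."""
        out = [FeatureDescriptor("mean", c) for c in range(1, n_channels + 1)]
        if self.include_top_decile and "top_decile_mean" in self.kinds:
            out += [FeatureDescriptor("top_decile_mean", c) for c in range(1, n_channels + 1)]
        out += [FeatureDescriptor("ratio", a, b) for a, b in self.ratio_pairs(n_channels)]
        if self.mode == "extended":
            for kind in ("sd", "skewness", "kurtosis"):
                out += [FeatureDescriptor(kind, c) for c in range(1, n_channels + 1)]
        return out


def extract_cell_pixels(block: DataBlock, mask: CellMask, cell_id: int) -> np.ndarray:
    """Per-channel pixel vectors of one cell, (n_channels, n_pixels), registry order."""
    if cell_id not in mask.registry:
        raise KeyError(f"cell {cell_id} not present in mask of field {mask.field_id}")
    rows, cols = mask.registry[cell_id]
    return block.channel_images[:, rows, cols]


def top_decile_mean(values: np.ndarray) -> float:
    """Mean of the ceil(0.1 * n) largest pixels (at least one)."""
    n = values.size
    k = max(1, math.ceil(0.1 * n))
    return float(np.sort(values)[-k:].mean())


def compute_feature(pixels: np.ndarray, d: FeatureDescriptor) -> float:
    """Evaluate one feature on a cell's (n_channels, n_pixels) pixel matrix.

    Degenerate rules: sd/skewness/kurtosis of a constant (or too-short)
    vector are 0; a ratio with zero denominator is 0 with a warning.
    """
    if pixels.ndim != 2 or pixels.shape[1] == 0:
        raise ValueError("pixel matrix must be (n_channels, n_pixels) with n_pixels > 0")
    v = pixels[d.channel_a - 1]
    if d.kind == "mean":
        return float(v.mean())
    if d.kind == "top_decile_mean":
        return top_decile_mean(v)
    if d.kind == "ratio":
        num = float(v.mean())
        den = float(pixels[d.channel_b - 1].mean())
        if den == 0.0:
            logger.warning("zero denominator in %s; feature set to 0", d.name)
            return 0.0
        return num / den
    if v.size < 2 or np.ptp(v) == 0.0:
        return 0.0
    if d.kind == "sd":
        return float(v.std(ddof=1))
    if d.kind == "skewness":
        return float(stats.skew(v, bias=False)) if v.size >= 3 else 0.0
    if d.kind == "kurtosis":
        return float(stats.kurtosis(v, fisher=True, bias=False)) if v.size >= 4 else 0.0
    raise AssertionError(d.kind)


def build_feature_table(
    blocks,
    masks,
    policy: FeatureSetPolicy = FeatureSetPolicy(),
) -> pd.DataFrame:
    """One row per cell across all fields; columns per the policy, canonical order.

    Raises on any non-finite feature, naming the cell and feature.
    """
    if len(blocks) != len(masks):
        raise ValueError("blocks and masks must pair one-to-one")
    rows = []
    descriptors = None
    for block, mask in zip(blocks, masks):
        if descriptors is None:
            descriptors = policy.descriptors(block.n_channels)
        mask.validate_against(block)
        for cell_id in mask.cell_ids:
            pixels = extract_cell_pixels(block, mask, cell_id)
            row = {
                "patient_id": block.patient_id,
                "field_id": block.field_id,
                "cell_id": cell_id,
                "group_label": block.group_label,
            }
            for d in descriptors:
                value = compute_feature(pixels, d)
                if not np.isfinite(value):
                    raise ValueError(
                        f"non-finite feature {d.name} for cell {cell_id} "
                        f"in field {block.field_id}"
                    )
                row[d.name] = value
            rows.append(row)
    if not rows:
        raise ValueError("no cells found in any field")
    df = pd.DataFrame(rows)
    ordered = ["patient_id", "field_id", "cell_id", "group_label"] + [
        d.name for d in descriptors
    ]
    return validate_feature_table(df[ordered])
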