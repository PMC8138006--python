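"""In-memory containers: data blocks, reference images, cell masks, feature tables.

A *data block* is the per-field acquisition bundle: one image per spectral
channel of the same sample area, a brightfield image, and the per-channel
reference images (dark, water, calibration fluid of 30 uM NADH + 18 uM FAD)
used for background subtraction and flat-field correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import ChannelSet


class ValidationError(ValueError):
    """A domain invariant was violated on construction or read."""


@dataclass
class ReferenceImages:
    """Per-channel dark, water, and calibration-fluid reference stacks.

    All three stacks have shape (n_channels, H, W).  The calibration image
    must be strictly positive after dark subtraction in every channel
    (otherwise those pixels are sensor-dead and must be repaired before
    flat-fielding).
    """

    dark: np.ndarray
    water: np.ndarray
    calibration: np.ndarray

    def validate(self) -> None:
        shapes = {self.dark.shape, self.water.shape, self.calibration.shape}
        if len(shapes) != 1:
            raise ValidationError(f"reference stacks differ in shape: {shapes}")
        if self.dark.ndim != 3:
            raise ValidationError("reference stacks must be (n_channels, H, W)")

    @property
    def spatial_shape(self):
        return self.dark.shape[1:]


@dataclass
class DataBlock:
    """One field's multispectral acquisition: 34 channel images + brightfield + references."""

    channel_images: np.ndarray  # (n_channels, H, W) float64
    brightfield: np.ndarray  # (H, W)
    references: ReferenceImages
    channel_set: ChannelSet
    field_id: str
    patient_id: str
    group_label: int
    bit_depth: int = 16
    saturation_level: float = 65535.0

    def validate(self) -> None:
        n = len(self.channel_set)
        if self.channel_images.ndim != 3 or self.channel_images.shape[0] != n:
            raise ValidationError(
                f"block {self.field_id}: expected {n} channel images, "
                f"got array of shape {self.channel_images.shape}"
            )
        if self.brightfield.shape != self.spatial_shape:
            raise ValidationError(
                f"block {self.field_id}: brightfield shape {self.brightfield.shape} "
                f"!= channel shape {self.spatial_shape}"
            )
        self.references.validate()
        if self.references.spatial_shape != self.spatial_shape:
            raise ValidationError(
                f"block {self.field_id}: reference shape {self.references.spatial_shape} "
                f"!= channel shape {self.spatial_shape}"
            )
        if self.group_label not in (0, 1):
            raise ValidationError(f"block {self.field_id}: group_label must be 0 or 1")

    @property
    def n_channels(self) -> int:
        return self.channel_images.shape[0]

    @property
    def spatial_shape(self):
        return self.channel_images.shape[1:]

    def copy(self) -> "DataBlock":
        return DataBlock(
            channel_images=self.channel_images.copy(),
            brightfield=self.brightfield.copy(),
            references=ReferenceImages(
                self.references.dark.copy(),
                self.references.water.copy(),
                self.references.calibration.copy(),
            ),
            channel_set=self.channel_set,
            field_id=self.field_id,
            patient_id=self.patient_id,
            group_label=self.group_label,
            bit_depth=self.bit_depth,
            saturation_level=self.saturation_level,
        )


@dataclass
class CellMask:
    """Labelled segmentation image plus a registry tying cells to pixel coordinates.

    ``label_image`` uses 0 for background and k > 0 for cell k; labels need
    not be contiguous.  The registry preserves, per cell, the field id and
    the 0-based (row, column) coordinates of its pixels, the bookkeeping
    needed to trace every extracted feature back to its source pixels.
    """

    label_image: np.ndarray
    field_id: str
    registry: dict = field(default_factory=dict)  # cell_id -> (rows, cols)

    @classmethod
    def from_label_image(cls, label_image: np.ndarray, field_id: str) -> "CellMask":
        if not np.issubdtype(label_image.dtype, np.integer):
            raise ValidationError("label image must be integer-valued")
        labels = np.unique(label_image)
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValidationError(f"no cells in field {field_id}: mask has no positive labels")
        registry = {}
        for lab in labels:
            rows, cols = np.nonzero(label_image == lab)
            registry[int(lab)] = (rows, cols)
        return cls(label_image=label_image, field_id=field_id, registry=registry)

    @property
    def cell_ids(self):
        return sorted(self.registry)

    def pixel_count(self, cell_id: int) -> int:
        return len(self.registry[cell_id][0])

    def validate_against(self, block: DataBlock) -> None:
        if self.label_image.shape != block.spatial_shape:
            raise ValidationError(
                f"mask shape {self.label_image.shape} != block shape {block.spatial_shape}"
            )
        h, w = self.label_image.shape
        for cid, (rows, cols) in self.registry.items():
            if rows.size == 0:
                raise ValidationError(f"cell {cid} in field {self.field_id} has no pixels")
            if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
                raise ValidationError(f"cell {cid} registry coordinates out of bounds")


#: columns identifying a cell, always leading the feature columns
ID_COLUMNS = ["patient_id", "field_id", "cell_id", "group_label"]


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check FeatureTable invariants; return the table in canonical row order.

    Canonical order sorts by (patient_id, field_id, cell_id) so that two
    tables built from the same cells in any input order compare equal.
    """
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"feature table missing required column '{col}'")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"feature table contains missing values in {bad}")
    if not set(df["group_label"].unique()) <= {0, 1}:
        raise ValidationError("group_label must be binary 0/1")
    dup = df.duplicated(subset=["patient_id", "field_id", "cell_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate (patient_id, field_id, cell_id) rows: "
            f"{df.loc[dup, ['patient_id', 'field_id', 'cell_id']].values.tolist()}"
        )
    feature_cols = [c for c in df.columns if c not in ID_COLUMNS]
    values = df[feature_cols].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        rows, cols = np.nonzero(~np.isfinite(values))
        raise ValidationError(
            f"non-finite feature value: cell row {rows[0]}, feature '{feature_cols[cols[0]]}'"
        )
    out = df.sort_values(["patient_id", "field_id", "cell_id"], kind="mergesort")
    return out.reset_index(drop=True)[ID_COLUMNS + feature_cols]


def feature_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c not in ID_COLUMNS]
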