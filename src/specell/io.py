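"""Disk formats for data blocks, masks and feature tables.

Layout of a written block directory::

    <dir>/
      channels.tif        multi-page TIFF, page k = channel k+1
      brightfield.tif
      ref_dark.tif        multi-page, one page per channel
      ref_water.tif
      ref_calibration.tif
      metadata.json       every SpectralChannel field + block identity

Images are written losslessly: uint16 when the data are integral and fit the
stated bit depth, float32/float64 otherwise.  The JSON sidecar is canonical
(sorted keys, repr-roundtrip floats) so two writes of one block are
byte-identical.  Feature tables are CSV with '.' decimal, comma delimiter,
one header row, 12-significant-digit floats, rows in canonical order.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .blocks import (
    ID_COLUMNS,
    CellMask,
    DataBlock,
    ReferenceImages,
    ValidationError,
    validate_feature_table,
)
from .channels import ChannelSet, SpectralChannel

_CHANNELS = "channels.tif"
_BRIGHTFIELD = "brightfield.tif"
_REFS = {"dark": "ref_dark.tif", "water": "ref_water.tif", "calibration": "ref_calibration.tif"}
_METADATA = "metadata.json"


def _storage_dtype(arr: np.ndarray, bit_depth: int):
    if np.all(arr >= 0) and np.all(arr == np.round(arr)) and arr.max(initial=0) < 2**16:
        return np.uint16
    return np.float64


def _write_tiff(path: Path, arr: np.ndarray, bit_depth: int) -> None:
    tifffile.imwrite(path, arr.astype(_storage_dtype(arr, bit_depth)), photometric="minisblack")


def write_datablock(block: DataBlock, out_dir) -> list:
    """Write a validated block to ``out_dir``; returns the list of files written."""
    block.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    _write_tiff(out / _CHANNELS, block.channel_images, block.bit_depth)
    written.append(out / _CHANNELS)
    _write_tiff(out / _BRIGHTFIELD, block.brightfield, block.bit_depth)
    written.append(out / _BRIGHTFIELD)
    refs = block.references
    for name, fname in _REFS.items():
        _write_tiff(out / fname, getattr(refs, name), block.bit_depth)
        written.append(out / fname)
    meta = {
        "field_id": block.field_id,
        "patient_id": block.patient_id,
        "group_label": int(block.group_label),
        "bit_depth": int(block.bit_depth),
        "saturation_level": float(block.saturation_level),
        "n_channels": len(block.channel_set),
        "channels": [c.to_dict() for c in block.channel_set],
    }
    with open(out / _METADATA, "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
        fh.write("\n")
    written.append(out / _METADATA)
    return written


def read_datablock(block_dir, channel_set: ChannelSet | None = None) -> DataBlock:
    """Read a block directory written by :func:`write_datablock`.

    If ``channel_set`` is given, the sidecar's channel table must match its
    size; otherwise the sidecar's own channel table is used.
    """
    d = Path(block_dir)
    meta_path = d / _METADATA
    if not meta_path.exists():
        raise ValidationError(f"metadata sidecar missing in {d}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    sidecar_set = ChannelSet(tuple(SpectralChannel.from_dict(c) for c in meta["channels"]))
    if channel_set is not None and len(channel_set) != len(sidecar_set):
        raise ValidationError(
            f"metadata lists {len(sidecar_set)} channels but channel set expects "
            f"{len(channel_set)}"
        )
    cs = channel_set or sidecar_set

    for fname in [_CHANNELS, _BRIGHTFIELD, *_REFS.values()]:
        if not (d / fname).exists():
            raise ValidationError(f"missing image file {fname} in {d}")
    channels = np.asarray(tifffile.imread(d / _CHANNELS), dtype=np.float64)
    if channels.ndim == 2:
        channels = channels[None]
    if channels.shape[0] != len(cs):
        missing = set(range(1, len(cs) + 1)) - set(range(1, channels.shape[0] + 1))
        raise ValidationError(
            f"channel stack has {channels.shape[0]} pages, expected {len(cs)}; "
            f"absent channel indices: {sorted(missing)}"
        )
    brightfield = np.asarray(tifffile.imread(d / _BRIGHTFIELD), dtype=np.float64)
    refs = {}
    for name, fname in _REFS.items():
        arr = np.asarray(tifffile.imread(d / fname), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        refs[name] = arr
    block = DataBlock(
        channel_images=channels,
        brightfield=brightfield,
        references=ReferenceImages(**refs),
        channel_set=cs,
        field_id=meta["field_id"],
        patient_id=meta["patient_id"],
        group_label=int(meta["group_label"]),
        bit_depth=int(meta["bit_depth"]),
        saturation_level=float(meta["saturation_level"]),
    )
    block.validate()
    return block


def write_mask(mask: CellMask, path) -> None:
    tifffile.imwrite(Path(path), mask.label_image.astype(np.int32), photometric="minisblack")


def read_mask(path, block: DataBlock) -> CellMask:
    """Read a label-image mask and build its registry against ``block``.

    The mask must match the block's spatial shape and contain at least one
    cell (each imaged field contributes roughly 2-4 segmented cells).
    """
    label_image = np.asarray(tifffile.imread(Path(path)))
    if label_image.shape != block.spatial_shape:
        raise ValidationError(
            f"mask shape {label_image.shape} != block shape {block.spatial_shape}"
        )
    mask = CellMask.from_label_image(label_image.astype(np.int64), block.field_id)
    mask.validate_against(block)
    return mask


def write_feature_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a feature table as canonical CSV.

    Rows are sorted by (patient_id, field_id, cell_id), floats printed at 12
    significant digits; provenance (pipeline version, config hash) goes into
    a leading ``#`` comment line so the payload stays plain CSV.
    """
    df = validate_feature_table(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#")
    return validate_feature_table(df)


def validate_block_dir(block_dir) -> DataBlock:
    """Read + validate a block directory; raises ValidationError on any defect."""
    return read_datablock(block_dir)
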