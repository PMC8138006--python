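"""Synthetic multispectral cohorts with known ground truth.

No patient image data are publicly deposited for this kind of study, so the
pipeline is developed and validated against simulated cohorts that possess
the statistical structure the analysis assumes:

* linear spectral mixing of fluorophore endmembers, with channel 2 dominated
  by NAD(P)H and channels 15/32 by flavins (the interpretable channels);
* a group effect placed on the NAD(P)H:flavins log-abundance ratio — the
  cellular redox ratio is the one biologically anchored group-difference
  mechanism available — while nuisance fluorophores, overall brightness and
  illumination are group-independent;
* hierarchical variation: patient-level and cell-level Gaussian random
  effects on the log-ratio;
* acquisition physics: smooth multiplicative vignetting, Poisson shot noise,
  dark offset, Gaussian read noise, hot (saturated) and dead pixels, and
  per-channel reference images (dark / water / calibration fluid) generated
  consistently with the channel images.

Because the per-cell true log-ratio is Gaussian within each group with a
designed mean shift ``effect`` and total SD ``sqrt(between_sd^2 +
within_sd^2)``, the Bayes-optimal AUC of the true log-ratio is available in
closed form, ``Phi(effect / sqrt(2) / total_sd)``, and serves as the oracle
for end-to-end parameter-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .blocks import CellMask, DataBlock, ReferenceImages
from .channels import ChannelSet, default_channel_set
from .features import mean_name, ratio_name

NADPH = "NAD(P)H"
FLAVINS = "flavins"

#: channels whose intensity is dominated by a single fluorophore
NADPH_CHANNEL = 2
FLAVIN_CHANNELS = (15, 32)


@dataclass(frozen=True)
class EndmemberSpectra:
    """Per-channel emission response per unit abundance for each fluorophore.

    ``response`` has shape (n_channels, n_fluorophores); column order follows
    ``fluorophores``.  Invariants: the NAD(P)H column peaks at channel 2, the
    flavins column has its two largest entries at channels 15 and 32, and
    every fluorophore responds in at least one channel.
    """

    fluorophores: tuple
    response: np.ndarray
    channel_set: ChannelSet

    def __post_init__(self) -> None:
        n_ch, n_f = self.response.shape
        if n_ch != len(self.channel_set) or n_f != len(self.fluorophores):
            raise ValueError("response matrix shape does not match fluorophores/channels")
        if np.any(self.response < 0):
            raise ValueError("endmember responses must be non-negative")
        if np.any(self.response.sum(axis=0) <= 0):
            raise ValueError("every fluorophore needs at least one non-zero channel")
        nad = self.response[:, self.fluorophores.index(NADPH)]
        if int(np.argmax(nad)) + 1 != NADPH_CHANNEL:
            raise ValueError(f"NAD(P)H response must peak at channel {NADPH_CHANNEL}")
        fla = self.response[:, self.fluorophores.index(FLAVINS)]
        top2 = set(np.argsort(fla)[-2:] + 1)
        if top2 != set(FLAVIN_CHANNELS):
            raise ValueError(f"flavins response must peak at channels {FLAVIN_CHANNELS}")

    def column(self, name: str) -> np.ndarray:
        return self.response[:, self.fluorophores.index(name)]


def make_endmembers(channel_set: ChannelSet, seed: int = 0) -> EndmemberSpectra:
    """Build smooth endmember spectra honouring the channel-dominance structure.

    NAD(P)H: single emission bump peaking at channel 2 (UV-excited blue
    emission).  Flavins: double bump peaking at channels 15 and 32 (the two
    flavin-dominated channels).  A broad "lipofuscin-like" nuisance
    fluorophore spans mid channels.  Small seeded multiplicative jitter makes
    cohorts non-identical across seeds without breaking the invariants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE0D]))
    n = len(channel_set)
    ch = np.arange(1, n + 1, dtype=float)

    def bump(center, width, height=1.0):
        return height * np.exp(-0.5 * ((ch - center) / width) ** 2)

    nadph = bump(NADPH_CHANNEL, 3.5)
    flavins = bump(FLAVIN_CHANNELS[0], 2.5, 1.0) + bump(FLAVIN_CHANNELS[1], 2.5, 0.92)
    nuisance = bump(22, 9.0, 0.6)
    resp = np.stack([nadph, flavins, nuisance], axis=1)
    # 3% lognormal jitter, then re-impose the dominance peaks exactly
    resp = resp * np.exp(rng.normal(0.0, 0.03, size=resp.shape))
    resp[NADPH_CHANNEL - 1, 0] = resp[:, 0].max() * 1.05
    third = np.partition(resp[:, 1], -3)[-3]
    resp[FLAVIN_CHANNELS[0] - 1, 1] = third * 1.30
    resp[FLAVIN_CHANNELS[1] - 1, 1] = third * 1.20
    resp /= resp.max(axis=0, keepdims=True)
    return EndmemberSpectra(
        fluorophores=(NADPH, FLAVINS, "lipofuscin-like"),
        response=resp,
        channel_set=channel_set,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and acquisition parameters of a simulated cohort.

    The defaults describe the reference simulation: two patient groups, 2-4
    cells per imaged field, 256x256 detector (desk-scale stand-in for the
    instrument's 1200x1200), ~12% illumination CV, 16-bit depth, and a group
    effect on the NAD(P)H:flavins log-ratio sized to a Bayes AUC of 0.9.
    """

    n_patients_per_group: int = 5
    fields_per_patient: int = 2
    cells_per_field: int = 3
    cells_per_group: tuple | None = None  # exact totals, e.g. (41, 84); overrides fields
    image_shape: tuple = (256, 256)
    #: group-2 minus group-1 shift of the mean NAD(P)H:flavins log-abundance ratio
    effect: float = 0.6408
    between_patient_sd: float = 0.25
    within_patient_sd: float = 0.25
    brightness_sd: float = 0.30  # lognormal per-cell overall brightness (nuisance)
    texture_sd: float = 0.30  # lognormal intra-cell pixel texture
    base_brightness: float = 1200.0  # counts/s at unit endmember response
    vignette_strength: float = 0.5
    dark_offset: float = 100.0
    read_noise: float = 2.0
    water_background: float = 20.0  # constant stray/buffer background, counts
    calibration_level: float = 8000.0  # counts/s of the NADH+FAD fluid at mean illumination
    reference_averages: int = 25
    hot_pixel_rate: float = 1e-4
    dead_pixel_rate: float = 1e-4
    shot_noise: bool = True
    quantize: bool = True
    bit_depth: int = 16
    saturation_level: float = 65535.0
    cell_radius_range: tuple = (0.030, 0.055)  # semi-axes, fraction of min(H, W)
    placement_retries: int = 200
    measurement_noise_sd: float = 0.02  # channel-mean noise in the feature-level path
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hot_pixel_rate", "dead_pixel_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("between_patient_sd", "within_patient_sd", "brightness_sd", "texture_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_sd(self) -> float:
        return math.hypot(self.between_patient_sd, self.within_patient_sd)


def bayes_auc(cfg: CohortConfig) -> float:
    """Closed-form Bayes-optimal AUC of the true log-ratio under ``cfg``."""
    return float(norm.cdf(cfg.effect / (math.sqrt(2.0) * cfg.total_sd)))


def effect_for_auc(target_auc: float, between_sd: float = 0.25, within_sd: float = 0.25) -> float:
    """Invert :func:`bayes_auc`: the log-ratio shift giving a designed AUC."""
    total = math.hypot(between_sd, within_sd)
    return float(norm.ppf(target_auc) * math.sqrt(2.0) * total)


def noise_free(cfg: CohortConfig) -> CohortConfig:
    """Variant of ``cfg`` with every stochastic acquisition artefact disabled."""
    return replace(
        cfg,
        shot_noise=False,
        read_noise=0.0,
        hot_pixel_rate=0.0,
        dead_pixel_rate=0.0,
        quantize=False,
    )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cells: pd.DataFrame  # per-cell abundances, log-ratio, labels
    illumination: np.ndarray | None = None
    clean_signal: np.ndarray | None = None  # (n_channels, H, W), pre-noise counts
    hot_mask: np.ndarray | None = None
    dead_mask: np.ndarray | None = None


def _illumination_field(shape, strength, rng) -> np.ndarray:
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    cx, cy = rng.uniform(-0.15, 0.15, size=2)
    tilt_x, tilt_y = rng.uniform(-0.03, 0.03, size=2)
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    f = 1.0 - strength * r2 / 2.0 + tilt_x * x + tilt_y * y
    f = np.clip(f, 0.1, None)
    return f / f.mean()


def _place_cells(shape, n_cells, radius_range, retries, rng):
    """Non-overlapping ellipses; returns a label image (labels 1..n_cells)."""
    h, w = shape
    label = np.zeros(shape, dtype=np.int64)
    rmin, rmax = (r * min(h, w) for r in radius_range)
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(1, n_cells + 1):
        for attempt in range(retries):
            a, b = rng.uniform(rmin, rmax, size=2)
            theta = rng.uniform(0, np.pi)
            margin = max(a, b) + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not inside.any():
                continue
            if (label[inside] != 0).any():
                continue
            label[inside] = k
            break
        else:
            raise RuntimeError(
                f"could not place cell {k} without overlap after {retries} retries"
            )
    return label


def _sample_cell_abundances(cfg, group_label, patient_effect, rng):
    """One cell's fluorophore abundances from the hierarchical model."""
    r = (
        cfg.effect * (group_label - 0.5)
        + patient_effect
        + rng.normal(0.0, cfg.within_patient_sd)
    )
    t = math.log(cfg.base_brightness) + rng.normal(0.0, cfg.brightness_sd)
    a_n = math.exp(t + r / 2.0)
    a_f = math.exp(t - r / 2.0)
    a_x = math.exp(t + rng.normal(-0.7, 0.25))
    return {NADPH: a_n, FLAVINS: a_f, "lipofuscin-like": a_x, "log_ratio": r}


def generate_datablock(
    cfg: CohortConfig,
    spectra: EndmemberSpectra,
    patient_id: str,
    group_label: int,
    field_id: str,
    n_cells: int | None = None,
    patient_effect: float = 0.0,
    rng: np.random.Generator | None = None,
    uniform_target_level: float | None = None,
):
    """Render one field: (DataBlock, CellMask | None, GroundTruth).

    Clean pixel signal is ``illumination(x, y) * texture(x, y) *
    sum_f abundance_f * response[channel, f] * exposure`` inside cells, zero
    outside; the observation adds a constant stray background, Poisson shot
    noise, the dark offset and Gaussian read noise, then stamps hot pixels to
    the saturation level and dead pixels to zero.

    With ``uniform_target_level`` set, the field is a uniformly fluorescent
    target of that emission level (counts/s) instead of cells — the
    configuration used to verify flat-field correction; the mask is None.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cs = spectra.channel_set
    n_ch = len(cs)
    h, w = cfg.image_shape
    exposures = cs.exposures

    illum = _illumination_field((h, w), cfg.vignette_strength, rng)
    clean = np.zeros((n_ch, h, w), dtype=np.float64)
    cell_rows = []

    if uniform_target_level is not None:
        clean[:] = illum[None] * uniform_target_level * exposures[:, None, None]
        label = None
    else:
        n_cells = cfg.cells_per_field if n_cells is None else n_cells
        label = _place_cells((h, w), n_cells, cfg.cell_radius_range, cfg.placement_retries, rng)
        for k in range(1, n_cells + 1):
            ab = _sample_cell_abundances(cfg, group_label, patient_effect, rng)
            spectrum = sum(
                ab[f] * spectra.column(f) for f in spectra.fluorophores
            )  # (n_ch,) counts/s
            inside = label == k
            texture = np.exp(
                rng.normal(-cfg.texture_sd**2 / 2.0, cfg.texture_sd, size=int(inside.sum()))
            )
            weight = illum[inside] * texture  # (n_px,)
            clean[:, inside] += spectrum[:, None] * weight[None, :] * exposures[:, None]
            cell_rows.append(
                {
                    "patient_id": patient_id,
                    "field_id": field_id,
                    "cell_id": k,
                    "group_label": int(group_label),
                    **{f"abundance_{f}": ab[f] for f in spectra.fluorophores},
                    "log_ratio": ab["log_ratio"],
                }
            )

    expected = clean + cfg.water_background
    if cfg.shot_noise:
        observed = rng.poisson(expected).astype(np.float64)
    else:
        observed = expected.copy()
    observed += cfg.dark_offset
    if cfg.read_noise > 0:
        observed += rng.normal(0.0, cfg.read_noise, size=observed.shape)

    hot = rng.random(observed.shape) < cfg.hot_pixel_rate
    dead = (~hot) & (rng.random(observed.shape) < cfg.dead_pixel_rate)
    observed[hot] = cfg.saturation_level
    observed[dead] = 0.0
    if cfg.quantize:
        observed = np.clip(np.round(observed), 0, cfg.saturation_level)

    ref_noise = cfg.read_noise / math.sqrt(cfg.reference_averages)

    def _reference(level_map):
        img = np.broadcast_to(level_map, (n_ch, h, w)).astype(np.float64).copy()
        if cfg.shot_noise:
            shot_sd = np.sqrt(np.maximum(img - cfg.dark_offset, 0.0) / cfg.reference_averages)
            img = img + rng.normal(0.0, 1.0, size=img.shape) * shot_sd
        if ref_noise > 0:
            img = img + rng.normal(0.0, ref_noise, size=img.shape)
        if cfg.quantize:
            img = np.clip(np.round(img), 0, cfg.saturation_level)
        return img

    dark_ref = _reference(np.full((n_ch, h, w), cfg.dark_offset))
    water_ref = _reference(np.full((n_ch, h, w), cfg.dark_offset + cfg.water_background))
    calib_clean = (
        cfg.dark_offset
        + illum[None] * cfg.calibration_level * exposures[:, None, None]
    )
    calib_ref = _reference(calib_clean)

    brightfield = 1000.0 * np.ones((h, w))
    if label is not None:
        brightfield[label > 0] = 600.0

    block = DataBlock(
        channel_images=observed,
        brightfield=brightfield,
        references=ReferenceImages(dark=dark_ref, water=water_ref, calibration=calib_ref),
        channel_set=cs,
        field_id=field_id,
        patient_id=patient_id,
        group_label=int(group_label),
        bit_depth=cfg.bit_depth,
        saturation_level=cfg.saturation_level,
    )
    block.validate()
    mask = CellMask.from_label_image(label, field_id) if label is not None else None
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        illumination=illum,
        clean_signal=clean,
        hot_mask=hot,
        dead_mask=dead,
    )
    return block, mask, truth


def _allocate_cells(cfg: CohortConfig, group: int) -> list:
    """Per-patient cell counts for one group, honouring exact group totals."""
    p = cfg.n_patients_per_group
    if cfg.cells_per_group is not None:
        total = cfg.cells_per_group[group]
        base, extra = divmod(total, p)
        return [base + (1 if i < extra else 0) for i in range(p)]
    return [cfg.fields_per_patient * cfg.cells_per_field] * p


def iter_cohort(cfg: CohortConfig, spectra: EndmemberSpectra, out_dir=None):
    """Yield ``(block, mask, truth)`` per field of a two-group cohort.

    Streaming form of :func:`generate_cohort`: one field's data block is in
    memory at a time, which keeps full-size cohorts within desk-scale RAM.
    When ``out_dir`` is given, every block and mask is also written to disk
    through the I/O layer (one directory per field), so downstream stages
    can consume files rather than memory.
    """
    from . import io as dbio

    for group in (0, 1):
        counts = _allocate_cells(cfg, group)
        for p_idx, n_cells_patient in enumerate(counts):
            patient_id = f"G{group + 1}P{p_idx + 1:02d}"
            p_rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), group, p_idx, 0xC0])
            )
            patient_effect = p_rng.normal(0.0, cfg.between_patient_sd)
            remaining = n_cells_patient
            f_idx = 0
            while remaining > 0:
                n_cells = min(cfg.cells_per_field, remaining)
                remaining -= n_cells
                field_id = f"{patient_id}F{f_idx + 1:02d}"
                f_idx += 1
                f_rng = np.random.default_rng(
                    np.random.SeedSequence([int(cfg.seed), group, p_idx, f_idx, 0xF1])
                )
                block, mask, truth = generate_datablock(
                    cfg,
                    spectra,
                    patient_id=patient_id,
                    group_label=group,
                    field_id=field_id,
                    n_cells=n_cells,
                    patient_effect=patient_effect,
                    rng=f_rng,
                )
                if out_dir is not None:
                    block_dir = f"{out_dir}/{field_id}"
                    dbio.write_datablock(block, block_dir)
                    dbio.write_mask(mask, f"{block_dir}/mask.tif")
                yield block, mask, truth


def generate_cohort(cfg: CohortConfig, spectra: EndmemberSpectra, out_dir=None):
    """Simulate a two-group cohort; returns ``(blocks, masks, truth)``.

    Materializes :func:`iter_cohort`; ``truth.cells`` is the per-cell table
    of true abundances.  For full-size cohorts prefer the iterator, which
    holds one block at a time.
    """
    blocks, masks, truth_frames = [], [], []
    for block, mask, truth in iter_cohort(cfg, spectra, out_dir=out_dir):
        blocks.append(block)
        masks.append(mask)
        truth_frames.append(truth.cells)
    truth = GroundTruth(cells=pd.concat(truth_frames, ignore_index=True))
    return blocks, masks, truth


def generate_feature_cohort(cfg: CohortConfig, spectra: EndmemberSpectra):
    """Fast feature-level cohort: channel means computed analytically.

    Samples the same hierarchical abundance model as the image path but maps
    abundances straight to per-cell mean channel intensities (``response @
    abundances`` times lognormal measurement noise), skipping pixel
    rendering.  Returns ``(feature_table, truth)``; the feature table holds
    all per-channel means plus the interpretable-channel ratios, in the same
    naming scheme as the image-derived tables.  Intended for simulation
    studies that need hundreds of cohorts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xFEA]))
    n_ch = len(spectra.channel_set)
    rows, truth_rows = [], []
    for group in (0, 1):
        counts = _allocate_cells(cfg, group)
        for p_idx, n_cells_patient in enumerate(counts):
            patient_id = f"G{group + 1}P{p_idx + 1:02d}"
            patient_effect = rng.normal(0.0, cfg.between_patient_sd)
            for c_idx in range(n_cells_patient):
                ab = _sample_cell_abundances(cfg, group, patient_effect, rng)
                means = sum(ab[f] * spectra.column(f) for f in spectra.fluorophores)
                if cfg.measurement_noise_sd > 0:
                    means = means * np.exp(
                        rng.normal(0.0, cfg.measurement_noise_sd, size=n_ch)
                    )
                row = {
                    "patient_id": patient_id,
                    "field_id": f"{patient_id}F01",
                    "cell_id": c_idx + 1,
                    "group_label": int(group),
                }
                row.update({mean_name(c + 1): means[c] for c in range(n_ch)})
                pairs = [(a, b) for a in (2, 15, 32) for b in (2, 15, 32) if a != b]
                for a, b in pairs:
                    row[ratio_name(a, b)] = means[a - 1] / means[b - 1]
                rows.append(row)
                truth_rows.append(
                    {
                        "patient_id": patient_id,
                        "field_id": row["field_id"],
                        "cell_id": c_idx + 1,
                        "group_label": int(group),
                        "log_ratio": ab["log_ratio"],
                    }
                )
    from .blocks import validate_feature_table

    table = validate_feature_table(pd.DataFrame(rows))
    truth = GroundTruth(cells=pd.DataFrame(truth_rows))
    return table, truth


def default_spectra(seed: int = 0, n_channels: int = 34) -> EndmemberSpectra:
    """Convenience: endmembers over the default channel grid."""
    return make_endmembers(default_channel_set(n_channels), seed=seed)
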