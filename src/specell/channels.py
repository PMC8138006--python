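"""Spectral channel definitions for the multispectral acquisition geometry.

A channel is one (excitation band, emission band) pair of the imaging system.
The instrument modelled here acquires 34 such channels spanning excitation
340-510 nm and emission 420-650 nm, each with its own exposure time (up to
5 s) and frame averaging (nominally 3).

The instrument's exact per-channel wavelength table is not publicly
distributed, so :func:`default_channel_set` builds a grid over the published
excitation/emission ranges that satisfies every per-channel invariant.  Real
channel tables can be dropped in through a YAML config with the same fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

EXCITATION_RANGE = (340.0, 510.0)
EMISSION_RANGE = (420.0, 650.0)
N_CHANNELS_DEFAULT = 34


@dataclass(frozen=True)
class SpectralChannel:
    """One excitation/emission band of the multispectral system.

    Parameters
    ----------
    index : int
        1-based channel number.
    excitation_center : float
        Center of the excitation band, nm.  Must lie in [340, 510].
    excitation_halfwidth : float
        Half-width of the (narrowband) excitation filter, nm.
    emission_low, emission_high : float
        Emission collection band, nm.  Both in [420, 650], low < high, and
        the band must sit above the excitation center (Stokes shift).
    exposure : float
        Acquisition time in seconds, 0 < exposure <= 5.
    n_averages : int
        Number of averaged frames, >= 1.
    """

    index: int
    excitation_center: float
    emission_low: float
    emission_high: float
    excitation_halfwidth: float = 5.0
    exposure: float = 1.0
    n_averages: int = 3

    def __post_init__(self) -> None:
        lo, hi = EXCITATION_RANGE
        if not lo <= self.excitation_center <= hi:
            raise ValueError(
                f"channel {self.index}: excitation_center {self.excitation_center} nm "
                f"outside [{lo}, {hi}]"
            )
        elo, ehi = EMISSION_RANGE
        if not (elo <= self.emission_low < self.emission_high <= ehi):
            raise ValueError(
                f"channel {self.index}: emission band "
                f"[{self.emission_low}, {self.emission_high}] invalid or outside [{elo}, {ehi}]"
            )
        if self.emission_low <= self.excitation_center:
            raise ValueError(
                f"channel {self.index}: emission_low {self.emission_low} nm must exceed "
                f"excitation_center {self.excitation_center} nm"
            )
        if not 0 < self.exposure <= 5:
            raise ValueError(f"channel {self.index}: exposure {self.exposure} s outside (0, 5]")
        if self.n_averages < 1:
            raise ValueError(f"channel {self.index}: n_averages must be >= 1")

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "excitation_center": float(self.excitation_center),
            "excitation_halfwidth": float(self.excitation_halfwidth),
            "emission_low": float(self.emission_low),
            "emission_high": float(self.emission_high),
            "exposure": float(self.exposure),
            "n_averages": int(self.n_averages),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralChannel":
        return cls(
            index=int(d["index"]),
            excitation_center=float(d["excitation_center"]),
            emission_low=float(d["emission_low"]),
            emission_high=float(d["emission_high"]),
            excitation_halfwidth=float(d.get("excitation_halfwidth", 5.0)),
            exposure=float(d.get("exposure", 1.0)),
            n_averages=int(d.get("n_averages", 3)),
        )


@dataclass(frozen=True)
class ChannelSet:
    """Ordered collection of spectral channels with unique contiguous indices."""

    channels: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        indices = [c.index for c in self.channels]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("channel indices must be unique and contiguous from 1")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, i: int) -> SpectralChannel:
        return self.channels[i]

    @property
    def exposures(self):
        import numpy as np

        return np.array([c.exposure for c in self.channels], dtype=float)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"channels": [c.to_dict() for c in self.channels]}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ChannelSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(tuple(SpectralChannel.from_dict(d) for d in data["channels"]))


def default_channel_set(
    n_channels: int = N_CHANNELS_DEFAULT,
    exposures=None,
) -> ChannelSet:
    """Build the default 34-channel grid over the system's spectral ranges.

    Excitation centers step linearly over 340-510 nm; each channel collects a
    40 nm emission band that starts 30 nm above its excitation center,
    clipped into 420-650 nm.  Exposures default to a 1/2/5 s cycle so that
    exposure equalization is exercised on realistic heterogeneous metadata.
    """
    channels = []
    exc_lo, exc_hi = EXCITATION_RANGE
    em_lo_min, em_hi_max = EMISSION_RANGE
    cycle = (1.0, 2.0, 5.0)
    for i in range(n_channels):
        frac = i / max(n_channels - 1, 1)
        exc = exc_lo + frac * (exc_hi - exc_lo)
        lo = max(exc + 30.0, em_lo_min)
        hi = min(lo + 40.0, em_hi_max)
        if hi <= lo:  # pushed against the top of the emission range
            lo = em_hi_max - 40.0
            hi = em_hi_max
        exposure = exposures[i] if exposures is not None else cycle[i % len(cycle)]
        channels.append(
            SpectralChannel(
                index=i + 1,
                excitation_center=round(exc, 2),
                emission_low=round(lo, 2),
                emission_high=round(hi, 2),
                exposure=exposure,
            )
        )
    return ChannelSet(tuple(channels))
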