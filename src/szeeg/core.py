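"""Shared domain types: frequency bands, channels, recordings, errors.

The analysis operates on 16-channel resting-state EEG sampled at 128 Hz,
decomposed into the five canonical rhythms (Delta through Gamma) that
partition the 0.5-45 Hz analysis range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid analysis or simulation configuration."""


class InputError(ValueError):
    """Malformed or unusable input data."""


class FeatureError(ValueError):
    """A feature value is undefined for the given window (e.g. zero power)."""


#: 10-20 montage used throughout, in canonical order.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "F7", "F8", "C3", "C4", "Cz", "T3",
    "T4", "T5", "T6", "P3", "P4", "Pz", "O1", "O2",
)

GROUPS = ("HC", "SCZ")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigurationError(
                f"band {self.name}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: The five canonical bands; they partition [0.5, 45) Hz exactly.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Delta", 0.5, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 13.0),
    BandDefinition("Beta", 13.0, 30.0),
    BandDefinition("Gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class SpectralBounds:
    """Overall analysis band [f_n, f_m] in Hz (broadband filter edges)."""

    f_n: float = 0.5
    f_m: float = 45.0

    def __post_init__(self) -> None:
        if not 0 < self.f_n < self.f_m:
            raise ConfigurationError(
                f"need 0 < f_n < f_m, got [{self.f_n}, {self.f_m}]"
            )


DEFAULT_BOUNDS = SpectralBounds()


@dataclass
class Recording:
    """One subject's multichannel EEG.

    data is (n_channels, n_samples), amplitudes in arbitrary
    microvolt-scale units.
    """

    subject_id: str
    group: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.group not in GROUPS:
            raise InputError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InputError(
                f"data must be (n_channels, n_samples) = ({len(self.channels)}, *), "
                f"got shape {self.data.shape}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise InputError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise InputError(f"non-finite values in recording {self.subject_id}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(self.subject_id, self.group, self.fs, self.channels, data)


def validate_bands(bands, fs: float) -> None:
    """Check band edges against the Nyquist frequency."""
    for b in bands:
        if b.f_hi > fs / 2:
            raise ConfigurationError(
                f"band {b.name} upper edge {b.f_hi} Hz exceeds Nyquist {fs / 2} Hz"
            )
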