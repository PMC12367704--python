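"""Two-group synthetic EEG cohort generator.

Each channel is a sum over the five canonical bands of band-limited filtered
noise whose amplitude encodes the group's band-power shift, plus three kinds
of planted group effects:

* band-power shifts — per-band multiplicative amplitude factors applied to
  the SCZ group (relative band power moves accordingly);
* regularity gains — a per-band fraction of the band variance is replaced by
  a fixed-frequency sinusoid at the band center in the SCZ group, which
  lowers fuzzy entropy there;
* coupling edges — a shared band-limited source injected into one channel
  and, with an integer-sample delay approximating the requested phase lag at
  the band center, into a second channel; the injected variance fraction is
  the group's coupling strength, which raises the phase lag index of that
  pair in that band.

Band-limited noise is produced with the same zero-phase Butterworth filters
used by the analysis, so generation and analysis agree on what "a band" is.
Amplitudes are arbitrary units; every downstream feature is scale-invariant
or ratio-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    DEFAULT_BANDS,
    DEFAULT_CHANNELS,
    ConfigurationError,
    Recording,
)
from .preprocess import design_bandpass, write_recording, zero_phase_filter

#: Baseline per-band RMS amplitudes (arbitrary units), a coarse 1/f-like
#: resting-EEG profile with the usual alpha prominence.
BASE_BAND_AMPLITUDE: dict[str, float] = {
    "Delta": 20.0, "Theta": 10.0, "Alpha": 15.0, "Beta": 5.0, "Gamma": 2.0,
}

#: Seconds of padding generated on each side and trimmed after filtering.
_PAD_S = 2.0


@dataclass(frozen=True)
class CouplingEdge:
    """A planted phase-coupled channel pair in one band."""

    ch_i: str
    ch_j: str
    band: str
    coupling_hc: float
    coupling_scz: float
    phase_lag: float  # radians at the band center frequency

    def __post_init__(self) -> None:
        for c in (self.coupling_hc, self.coupling_scz):
            if not 0 <= c < 1:
                raise ConfigurationError(f"coupling strength {c} outside [0, 1)")
        lag = self.phase_lag % (2 * np.pi)
        if min(lag, abs(lag - np.pi), abs(lag - 2 * np.pi)) < 1e-9:
            raise ConfigurationError(
                "phase lag of 0 or pi yields coupling invisible to the "
                "phase lag index"
            )

    def coupling(self, group: str) -> float:
        return self.coupling_scz if group == "SCZ" else self.coupling_hc


def default_coupling_edges() -> tuple[CouplingEdge, ...]:
    """Ten planted edges: Theta/Beta/Gamma coupling up in SCZ, Alpha down."""
    lag = np.pi / 2
    up = [("F3", "C3", "Theta"), ("F4", "C4", "Theta"),
          ("F3", "P3", "Beta"), ("F4", "P4", "Beta"), ("C4", "P4", "Beta"),
          ("F7", "C3", "Gamma"), ("F8", "C4", "Gamma")]
    down = [("F3", "O1", "Alpha"), ("F4", "O2", "Alpha"), ("P4", "O2", "Alpha")]
    return tuple(
        [CouplingEdge(i, j, b, 0.0, 0.6, lag) for i, j, b in up]
        + [CouplingEdge(i, j, b, 0.6, 0.0, lag) for i, j, b in down]
    )


def _neutral_shift() -> dict[str, float]:
    return {b: 1.0 for b in BAND_NAMES}


def _default_shift() -> dict[str, float]:
    return {"Delta": 1.3, "Theta": 1.3, "Alpha": 0.7, "Beta": 1.3, "Gamma": 0.7}


def _default_gain() -> dict[str, float]:
    return {"Delta": 0.0, "Theta": 0.5, "Alpha": 0.5, "Beta": 0.5, "Gamma": 0.5}


@dataclass
class EffectSpec:
    """Planted group differences (all defaults follow the SCZ literature
    directions: delta/theta/beta power up, alpha/gamma down; complexity
    reduced outside delta; theta/beta/gamma coupling up, alpha down)."""

    band_power_shift: dict[str, float] = field(default_factory=_default_shift)
    regularity_gain: dict[str, float] = field(default_factory=_default_gain)
    coupling_edges: tuple[CouplingEdge, ...] = field(
        default_factory=default_coupling_edges
    )
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for b, f in self.band_power_shift.items():
            if f <= 0:
                raise ConfigurationError(f"band_power_shift[{b}]={f} must be > 0")
        for b, g in self.regularity_gain.items():
            if not 0 <= g < 1:
                raise ConfigurationError(
                    f"regularity_gain[{b}]={g} outside [0, 1)"
                )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @classmethod
    def neutral(cls) -> "EffectSpec":
        """No group differences: both groups draw from one distribution."""
        return cls(
            band_power_shift=_neutral_shift(),
            regularity_gain={b: 0.0 for b in BAND_NAMES},
            coupling_edges=(),
        )


@dataclass
class CohortConfig:
    """Study-design parameters of a simulated two-group cohort."""

    n_hc: int = 39
    n_scz: int = 45
    fs: float = 128.0
    duration_s: float = 60.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0
    effects: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.n_hc < 1 or self.n_scz < 1:
            raise ConfigurationError("need at least one subject per group")
        if self.fs <= 2 * 45.0:
            raise ConfigurationError(f"fs={self.fs} must exceed 90 Hz (2 x 45)")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "duration_s x fs must be an integer number of samples"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel labels must be unique")
        for e in self.effects.coupling_edges:
            for ch in (e.ch_i, e.ch_j):
                if ch not in self.channels:
                    raise ConfigurationError(
                        f"coupling edge references unknown channel {ch!r}"
                    )
            if e.band not in BAND_NAMES:
                raise ConfigurationError(
                    f"coupling edge references unknown band {e.band!r}"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _unit_band_noise(rng: np.random.Generator, sos, shape) -> np.ndarray:
    """Band-limited noise with unit variance per row."""
    x = zero_phase_filter(rng.standard_normal(shape), sos)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_recording(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> Recording:
    """Draw one subject's recording under the group's effect parameters."""
    eff = config.effects
    n_ch = len(config.channels)
    n_pad = int(round(_PAD_S * config.fs))
    n_tot = config.n_samples + 2 * n_pad
    ch_index = {c: k for k, c in enumerate(config.channels)}
    t = np.arange(n_tot) / config.fs

    data = np.zeros((n_ch, n_tot))
    for band in DEFAULT_BANDS:
        shift = eff.band_power_shift.get(band.name, 1.0) if group == "SCZ" else 1.0
        amp = BASE_BAND_AMPLITUDE[band.name] * shift
        sos = design_bandpass(band.f_lo, band.f_hi, config.fs)
        noise = _unit_band_noise(rng, sos, (n_ch, n_tot))
        gain = eff.regularity_gain.get(band.name, 0.0) if group == "SCZ" else 0.0
        if gain > 0:
            # Replace a variance fraction with a deterministic oscillation.
            # The tone sits in the lower quarter of the band: a tone at the
            # band center beats against the surviving band noise and raises
            # rather than lowers short-range irregularity at moderate gains.
            f_tone = band.f_lo + 0.25 * band.width
            phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
            osc = np.sqrt(2.0) * np.sin(2 * np.pi * f_tone * t + phases)
            band_sig = np.sqrt(1 - gain) * noise + np.sqrt(gain) * osc
        else:
            band_sig = noise
        data += amp * band_sig

        # planted phase-coupled pairs in this band
        for edge in eff.coupling_edges:
            if edge.band != band.name:
                continue
            c = edge.coupling(group)
            if c == 0:
                continue
            delay = max(
                1, int(round(edge.phase_lag / (2 * np.pi * band.center) * config.fs))
            )
            shared = _unit_band_noise(rng, sos, (1, n_tot))[0]
            w = amp * np.sqrt(c / (1 - c))
            data[ch_index[edge.ch_i]] += w * shared
            data[ch_index[edge.ch_j]] += w * np.roll(shared, delay)

    if eff.noise_sd > 0:
        data += eff.noise_sd * rng.standard_normal((n_ch, n_tot))
    data = data[:, n_pad : n_pad + config.n_samples]
    return Recording(subject_id, group, config.fs, config.channels, data)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Per-subject generators are spawned deterministically from the master
    seed, so any subject can be regenerated independently.  Returns the
    recordings and a manifest (subject_id, group, subseed).
    """
    groups = ["HC"] * config.n_hc + ["SCZ"] * config.n_scz
    ids = [f"HC{i + 1:03d}" for i in range(config.n_hc)] + [
        f"SCZ{i + 1:03d}" for i in range(config.n_scz)
    ]
    subseeds = np.random.SeedSequence(config.seed).generate_state(
        len(ids), dtype=np.uint64
    )
    recordings, rows = [], []
    for sid, grp, sub in zip(ids, groups, subseeds):
        rng = np.random.default_rng(int(sub))
        recordings.append(simulate_recording(config, grp, rng, sid))
        rows.append({"subject_id": sid, "group": grp, "subseed": int(sub)})
    manifest = pd.DataFrame(rows)
    manifest.attrs["config"] = config
    return recordings, manifest


def write_cohort(
    recordings: list[Recording], manifest: pd.DataFrame, out_dir
) -> Path:
    """Write one CSV matrix per subject plus manifest.csv; returns out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(out_dir / f"{rec.subject_id}.csv", rec)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def strong_effects() -> EffectSpec:
    """Alias for the default planted-effect specification."""
    return EffectSpec()


def null_config(**kwargs) -> CohortConfig:
    """A cohort configuration with no group differences."""
    return replace(CohortConfig(**kwargs), effects=EffectSpec.neutral())
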