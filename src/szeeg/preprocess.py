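"""Filtering, re-referencing, band decomposition and window segmentation.

Processing order is fixed: broadband bandpass -> average reference -> per-band
decomposition -> non-overlapping segmentation.  All filters are 4th-order
Butterworth applied forward-backward (zero net phase), which keeps the
instantaneous phases used by the connectivity features undistorted.
Decomposition happens before windowing so that window edges carry no
per-window filter transients.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import (
    DEFAULT_BANDS,
    DEFAULT_BOUNDS,
    BandDefinition,
    ConfigurationError,
    InputError,
    Recording,
    SpectralBounds,
    validate_bands,
)

FILTER_ORDER = 4


def design_bandpass(f_lo: float, f_hi: float, fs: float):
    """Second-order sections for a Butterworth bandpass [f_lo, f_hi] Hz."""
    if f_hi >= fs / 2:
        raise ConfigurationError(
            f"bandpass upper edge {f_hi} Hz must be below Nyquist {fs / 2} Hz"
        )
    return butter(FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def zero_phase_filter(data: np.ndarray, sos) -> np.ndarray:
    """Forward-backward filtering along the last axis."""
    try:
        return sosfiltfilt(sos, data, axis=-1)
    except ValueError as exc:  # padlen exceeds signal length
        raise InputError(f"signal too short for zero-phase filtering: {exc}") from exc


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every time point."""
    return data - data.mean(axis=0, keepdims=True)


def bandpass_and_reference(
    rec: Recording, bounds: SpectralBounds = DEFAULT_BOUNDS
) -> Recording:
    """Broadband-filter a recording to [f_n, f_m] and re-reference to average.

    After this step the across-channel sum is zero at every sample.
    """
    if rec.fs <= 2 * bounds.f_m:
        raise ConfigurationError(
            f"fs={rec.fs} Hz too low for upper bound {bounds.f_m} Hz"
        )
    sos = design_bandpass(bounds.f_n, bounds.f_m, rec.fs)
    return rec.copy_with(average_reference(zero_phase_filter(rec.data, sos)))


def band_decompose(
    rec: Recording, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, Recording]:
    """Filter a recording into each band; returns {band name: Recording}."""
    validate_bands(bands, rec.fs)
    out = {}
    for band in bands:
        sos = design_bandpass(band.f_lo, band.f_hi, rec.fs)
        out[band.name] = rec.copy_with(zero_phase_filter(rec.data, sos))
    return out


@dataclass
class EpochTensor:
    """Band-decomposed, windowed signal segments for one recording.

    broadband_epochs: (n_windows, n_channels, n_samples) of the 0.5-45 Hz
    signal; band_epochs: (n_bands, n_windows, n_channels, n_samples) ordered
    Delta -> Gamma.  Windows are contiguous from sample 0, non-overlapping;
    the trailing remainder is dropped.
    """

    subject_id: str
    group: str
    fs: float
    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    window_length_s: float
    broadband_epochs: np.ndarray = field(repr=False)
    band_epochs: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return self.broadband_epochs.shape[0]


def _to_windows(data: np.ndarray, n_win: int, w: int) -> np.ndarray:
    """(channels, samples) -> (windows, channels, window samples)."""
    return (
        data[:, : n_win * w].reshape(data.shape[0], n_win, w).transpose(1, 0, 2)
    )


def segment_windows(
    broadband: Recording,
    band_signals: dict[str, Recording],
    window_length_s: float,
) -> EpochTensor:
    """Cut broadband and band signals into non-overlapping windows."""
    w_float = window_length_s * broadband.fs
    w = int(round(w_float))
    if abs(w_float - w) > 1e-9 or w <= 0:
        raise ConfigurationError(
            f"window_length_s={window_length_s} x fs={broadband.fs} "
            "is not an integer number of samples"
        )
    n_win = broadband.n_samples // w
    if n_win == 0:
        raise InputError(
            f"recording of {broadband.n_samples} samples shorter than one "
            f"{w}-sample window"
        )
    band_names = tuple(band_signals)
    band_epochs = np.stack(
        [_to_windows(band_signals[b].data, n_win, w) for b in band_names]
    )
    return EpochTensor(
        subject_id=broadband.subject_id,
        group=broadband.group,
        fs=broadband.fs,
        channels=broadband.channels,
        band_names=band_names,
        window_length_s=window_length_s,
        broadband_epochs=_to_windows(broadband.data, n_win, w),
        band_epochs=band_epochs,
    )


def preprocess_recording(
    rec: Recording,
    window_length_s: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    bounds: SpectralBounds = DEFAULT_BOUNDS,
) -> EpochTensor:
    """Full chain: broadband filter + average reference -> bands -> windows."""
    broad = bandpass_and_reference(rec, bounds)
    return segment_windows(broad, band_decompose(broad, bands), window_length_s)


# ---------------------------------------------------------------------------
# I/O: plain-text matrices (samples x channels) and cohort manifests.


def _sniff_delimiter(first_line: str) -> str | None:
    return "," if "," in first_line else None


def read_recording(
    path,
    fs: float,
    subject_id: str | None = None,
    group: str = "HC",
    channels: tuple[str, ...] | None = None,
    format: str = "text-matrix",
) -> Recording:
    """Read one subject's EEG from a text matrix (samples x channels).

    A header row of channel labels is auto-detected; otherwise ``channels``
    must be supplied.  ``format='edf'`` requires the optional mne dependency.
    """
    path = Path(path)
    if format == "edf":
        try:
            import mne  # noqa: F401
        except ImportError as exc:
            raise InputError(
                "EDF input requires the optional 'mne' package; "
                "use the text-matrix format instead"
            ) from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            subject_id or path.stem, group, raw.info["sfreq"],
            tuple(raw.ch_names), raw.get_data(),
        )
    if format != "text-matrix":
        raise InputError(f"unsupported format {format!r}")
    if not path.exists():
        raise InputError(f"{path}: no such file")
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    delim = _sniff_delimiter(first)
    tokens = [t for t in first.replace(",", " ").split() if t]
    has_header = any(not _is_number(t) for t in tokens)
    text = rest if has_header else first + rest
    try:
        mat = np.loadtxt(io.StringIO(text), delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric entry ({exc})") from exc
    if has_header:
        file_channels = tuple(tokens)
    elif channels is not None:
        file_channels = tuple(channels)
    else:
        raise InputError(f"{path}: no header row and no channel list supplied")
    if mat.shape[1] != len(file_channels):
        raise InputError(
            f"{path}: expected {len(file_channels)} channel columns, "
            f"found {mat.shape[1]}"
        )
    if channels is not None and tuple(channels) != file_channels:
        raise InputError(
            f"{path}: header channels {file_channels} do not match "
            f"expected {tuple(channels)}"
        )
    return Recording(subject_id or path.stem, group, fs, file_channels, mat.T)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_recording(path, rec: Recording, fmt: str = "%.8g") -> None:
    """Write a recording as a CSV text matrix (samples x channels, header)."""
    pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
        path, index=False, float_format=fmt
    )


def load_cohort(
    manifest_path, data_dir=None, fs: float = 128.0,
    channels: tuple[str, ...] | None = None,
) -> list[Recording]:
    """Load all recordings listed in a cohort manifest CSV.

    The manifest needs columns subject_id and group; each subject's data are
    read from ``<data_dir>/<subject_id>.csv``.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "group"):
        if col not in manifest.columns:
            raise InputError(f"{manifest_path}: manifest lacks column {col!r}")
    return [
        read_recording(
            data_dir / f"{row.subject_id}.csv", fs=fs,
            subject_id=str(row.subject_id), group=str(row.group),
            channels=channels,
        )
        for row in manifest.itertuples()
    ]
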