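"""The three per-window feature families and the canonical feature table.

* Relative power (RP): fraction of a window's periodogram mass inside a band,
  rescaled by (total analysis bandwidth / band bandwidth), so a flat spectrum
  scores 1 in every band.  Computed on the broadband (0.5-45 Hz) window.
* Fuzzy entropy (FuzEn): irregularity of a band-filtered window, comparing
  mean-centered m- and (m+1)-subsequences under a Gaussian-like fuzzy
  membership of their Chebyshev distance; lower = more regular.
* Phase lag index (PLI): absolute mean signum of the instantaneous-phase
  difference (Hilbert analytic signal) between two band-filtered windows;
  0 = no coupling or pure zero-lag coupling, 1 = a fixed nonzero lag.

With 16 channels and 5 bands the canonical table has 80 RP + 80 FuzEn +
600 PLI = 760 columns, ordered family-major (RP, FuzEn, PLI), band-major
within family (Delta..Gamma), channel / channel-pair order within band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ._fuzen import fuzen_value
from .core import (
    BAND_NAMES,
    DEFAULT_BANDS,
    DEFAULT_BOUNDS,
    DEFAULT_CHANNELS,
    BandDefinition,
    FeatureError,
    InputError,
    SpectralBounds,
)
from .preprocess import EpochTensor, preprocess_recording

logger = logging.getLogger(__name__)

FAMILIES = ("RP", "FuzEn", "PLI")
META_COLUMNS = ("subject_id", "group", "window_index")

#: Fraction of samples dropped at each window edge before the PLI sign
#: average (finite-window Hilbert edge distortion).
DEFAULT_EDGE_TRIM = 0.05

_EDGE_EPS = 1e-9  # tolerance for assigning DFT bins to band edges


@dataclass(frozen=True)
class FuzEnParams:
    """Fuzzy-entropy parameters: embedding dimension m and tolerance
    r = k x (per-window, per-channel standard deviation)."""

    m: int = 2
    k: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InputError(f"embedding dimension m={self.m} must be >= 1")
        if not 0 < self.k < 1:
            raise InputError(f"tolerance coefficient k={self.k} outside (0, 1)")


@dataclass(frozen=True)
class FeatureKey:
    """Canonical identity of one feature column."""

    family: str  # RP | FuzEn | PLI
    band: str
    site: tuple[str, ...]  # one channel, or an ordered channel pair

    @property
    def name(self) -> str:
        return f"{self.family}_{self.band}_{'-'.join(self.site)}"


def feature_keys(
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    band_names: tuple[str, ...] = BAND_NAMES,
    families: tuple[str, ...] = FAMILIES,
) -> list[FeatureKey]:
    """All feature keys in canonical column order."""
    bad = set(families) - set(FAMILIES)
    if bad:
        raise InputError(f"unknown feature families {sorted(bad)}")
    n = len(channels)
    pairs = [
        (channels[i], channels[j]) for i in range(n) for j in range(i + 1, n)
    ]
    keys: list[FeatureKey] = []
    for family in FAMILIES:
        if family not in families:
            continue
        for band in band_names:
            sites = pairs if family == "PLI" else [(c,) for c in channels]
            keys.extend(FeatureKey(family, band, tuple(s)) for s in sites)
    return keys


def parse_feature_name(name: str) -> FeatureKey:
    family, band, site = name.split("_", 2)
    return FeatureKey(family, band, tuple(site.split("-")))


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table, in stored (canonical) order."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Spectral features


def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram on the DFT grid k*fs/N.

    Normalized so the bins sum to the mean square of the signal (discrete
    Parseval identity); the normalization cancels in relative power.
    Accepts (..., N) arrays; the spectrum is along the last axis.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise InputError(f"need at least 2 samples for a spectrum, got {n}")
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite values in signal")
    pxx = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n**2
    pxx[..., 1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not duplicated in the two-sided spectrum
        pxx[..., -1] /= 2.0
    return np.fft.rfftfreq(n, 1.0 / fs), pxx


def band_bin_mask(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Half-open bin assignment [f_lo, f_hi) on the DFT grid."""
    return (freqs >= f_lo - _EDGE_EPS) & (freqs < f_hi - _EDGE_EPS)


def relative_power(
    freqs: np.ndarray,
    pxx: np.ndarray,
    band: BandDefinition,
    bounds: SpectralBounds = DEFAULT_BOUNDS,
) -> float | np.ndarray:
    """Band-power fraction rescaled by (f_m - f_n)/(f_h - f_l).

    The rescaling makes RP bandwidth-corrected: a flat spectrum gives 1 in
    every band, and the bandwidth-weighted sum over a band partition is
    exactly 1.  Bins are assigned half-open, so shared edges are never
    counted twice.
    """
    if band.f_lo < bounds.f_n - _EDGE_EPS or band.f_hi > bounds.f_m + _EDGE_EPS:
        raise InputError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] outside analysis "
            f"bounds [{bounds.f_n}, {bounds.f_m}]"
        )
    total = pxx[..., band_bin_mask(freqs, bounds.f_n, bounds.f_m)].sum(axis=-1)
    if np.any(total <= 0):
        raise FeatureError("zero total power in the analysis band")
    num = pxx[..., band_bin_mask(freqs, band.f_lo, band.f_hi)].sum(axis=-1)
    return num / total * (bounds.f_m - bounds.f_n) / band.width


# ---------------------------------------------------------------------------
# Fuzzy entropy


def fuzzy_entropy(x: np.ndarray, params: FuzEnParams = FuzEnParams()) -> float:
    """FuzEn of a 1-D window with tolerance r = k x std(x).

    Tying r to the window's own standard deviation makes the value invariant
    to positive rescaling of the signal.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise InputError("fuzzy_entropy expects a 1-D signal")
    if x.size <= params.m + 1:
        raise InputError(
            f"need more than m+1={params.m + 1} samples, got {x.size}"
        )
    sd = float(x.std())
    if sd == 0:
        raise FeatureError("constant signal: FuzEn undefined (r = 0)")
    return fuzen_value(x, params.m, params.k * sd)


# ---------------------------------------------------------------------------
# Phase lag index


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to [-pi, pi)."""
    return np.mod(dphi + np.pi, 2 * np.pi) - np.pi


def _trim_count(n: int, edge_trim: float) -> int:
    if not 0 <= edge_trim < 0.5:
        raise InputError(f"edge_trim={edge_trim} outside [0, 0.5)")
    k = int(round(edge_trim * n))
    if n - 2 * k < 1:
        raise InputError("window too short after edge trimming")
    return k


def pli(
    x_k: np.ndarray, x_l: np.ndarray, edge_trim: float = DEFAULT_EDGE_TRIM
) -> float:
    """Phase lag index between two equal-length band-filtered windows.

    |mean over t of sign(phi_k(t) - phi_l(t))| with phases from the Hilbert
    analytic signal of the whole window and ``edge_trim`` of samples excluded
    at each end.  sign(0) contributes exactly 0, so identical signals give
    PLI = 0 exactly.
    """
    x_k = np.asarray(x_k, dtype=np.float64)
    x_l = np.asarray(x_l, dtype=np.float64)
    if x_k.shape != x_l.shape or x_k.ndim != 1:
        raise InputError(
            f"signals must be equal-length 1-D, got {x_k.shape} vs {x_l.shape}"
        )
    k = _trim_count(x_k.size, edge_trim)
    sl = slice(k, x_k.size - k)
    dphi = np.angle(hilbert(x_k)) - np.angle(hilbert(x_l))
    return float(np.abs(np.mean(np.sign(_wrap_phase(dphi))[sl])))


def pli_matrix(
    window: np.ndarray, edge_trim: float = DEFAULT_EDGE_TRIM
) -> np.ndarray:
    """Symmetric zero-diagonal PLI matrix for one (n_channels, n_samples)
    band-filtered window."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise InputError("pli_matrix expects (n_channels, n_samples)")
    n_ch, n = window.shape
    k = _trim_count(n, edge_trim)
    ph = np.angle(hilbert(window, axis=-1))[:, k : n - k]
    signs = np.sign(_wrap_phase(ph[:, None, :] - ph[None, :, :]))
    mat = np.abs(signs.mean(axis=-1))
    np.fill_diagonal(mat, 0.0)
    return mat


# ---------------------------------------------------------------------------
# Feature-table assembly


def build_feature_table(
    epochs: list[EpochTensor],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    bounds: SpectralBounds = DEFAULT_BOUNDS,
    fuzen_params: FuzEnParams = FuzEnParams(),
    edge_trim: float = DEFAULT_EDGE_TRIM,
    families: tuple[str, ...] = FAMILIES,
) -> pd.DataFrame:
    """One row per (subject, window); feature columns in canonical order.

    RP comes from the broadband window's periodogram, FuzEn and PLI from the
    band-filtered windows.  A window with a degenerate channel (constant
    signal or zero total power) is dropped whole and logged, never imputed;
    dropped rows are listed in ``table.attrs['dropped']``.
    """
    if not epochs:
        raise InputError("no epochs supplied")
    ref = epochs[0]
    band_by_name = {b.name: b for b in bands}
    for ep in epochs:
        if ep.channels != ref.channels or ep.band_names != ref.band_names:
            raise InputError("epochs disagree on channels or bands")
        if ep.band_epochs.shape[-1] != ref.band_epochs.shape[-1]:
            raise InputError("epochs disagree on window length")
    missing = set(ref.band_names) - set(band_by_name)
    if missing:
        raise InputError(f"no BandDefinition for bands {sorted(missing)}")

    keys = feature_keys(ref.channels, ref.band_names, families)
    columns = [key.name for key in keys]
    n_ch = len(ref.channels)
    iu = np.triu_indices(n_ch, 1)
    do_rp = "RP" in families
    do_fuzen = "FuzEn" in families
    do_pli = "PLI" in families

    meta_rows: list[dict] = []
    value_rows: list[np.ndarray] = []
    dropped: list[dict] = []
    for ep in epochs:
        freqs = np.fft.rfftfreq(ep.broadband_epochs.shape[-1], 1.0 / ep.fs)
        band_masks = [
            band_bin_mask(freqs, band_by_name[b].f_lo, band_by_name[b].f_hi)
            for b in ep.band_names
        ]
        total_mask = band_bin_mask(freqs, bounds.f_n, bounds.f_m)
        for w in range(ep.n_windows):
            try:
                parts = []
                if do_rp:
                    _, pxx = power_spectrum(ep.broadband_epochs[w], ep.fs)
                    total = pxx[:, total_mask].sum(axis=1)
                    if np.any(total <= 0):
                        raise FeatureError("zero total power")
                    parts.extend(
                        pxx[:, mask].sum(axis=1) / total
                        * (bounds.f_m - bounds.f_n) / band_by_name[b].width
                        for b, mask in zip(ep.band_names, band_masks)
                    )
                if do_fuzen:
                    for bi in range(len(ep.band_names)):
                        sig = ep.band_epochs[bi, w]
                        parts.append(
                            np.array(
                                [fuzzy_entropy(sig[c], fuzen_params)
                                 for c in range(n_ch)]
                            )
                        )
                if do_pli:
                    for bi in range(len(ep.band_names)):
                        mat = pli_matrix(ep.band_epochs[bi, w], edge_trim)
                        parts.append(mat[iu])
            except FeatureError as exc:
                logger.warning(
                    "dropping %s window %d: %s", ep.subject_id, w, exc
                )
                dropped.append(
                    {"subject_id": ep.subject_id, "window_index": w,
                     "reason": str(exc)}
                )
                continue
            meta_rows.append(
                {"subject_id": ep.subject_id, "group": ep.group,
                 "window_index": w}
            )
            value_rows.append(np.concatenate(parts))

    values = (
        np.vstack(value_rows) if value_rows else np.empty((0, len(columns)))
    )
    table = pd.concat(
        [pd.DataFrame(meta_rows, columns=list(META_COLUMNS)),
         pd.DataFrame(values, columns=columns)],
        axis=1,
    )
    table.attrs["dropped"] = dropped
    return table


def extract_features(
    recordings,
    window_length_s: float = 4.0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    bounds: SpectralBounds = DEFAULT_BOUNDS,
    fuzen_params: FuzEnParams = FuzEnParams(),
    edge_trim: float = DEFAULT_EDGE_TRIM,
    families: tuple[str, ...] = FAMILIES,
) -> pd.DataFrame:
    """Preprocess recordings and assemble their feature table."""
    epochs = [
        preprocess_recording(rec, window_length_s, bands, bounds)
        for rec in recordings
    ]
    return build_feature_table(
        epochs, bands, bounds, fuzen_params, edge_trim, families
    )
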