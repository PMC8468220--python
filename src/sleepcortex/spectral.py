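"""Sleep-EEG spectral quantification.

The analysis chain implemented here: re-reference scalp channels to the
averaged mastoids, zero-phase band-pass (0.33-30 Hz), cut the recording into
4-s windows aligned to the 20-s scoring epochs, estimate a per-window FFT
periodogram at 0.25 Hz resolution (0.50-30.00 Hz, 119 bins), average the
windows of a sleep state (NREM = N2+N3, or REM) into a state spectrum,
normalize to percentage power over the whole topography (19 channels x
0.50-24.75 Hz, 98 bins, summing to 100), and aggregate into the five standard
frequency bands and six scalp clusters.  The three subject-level sleep-EEG
indexes are the NREM sigma and REM delta/beta cluster percentages.

Power scaling convention: the full positive-frequency periodogram of a
(mean-removed) window sums to the window's mean-squared value (Parseval).
Only ratios of bin powers matter downstream, so any fixed scaling would do;
this one makes an on-bin sinusoid of amplitude A carry A^2/2 in its bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.fft as sp_fft
from scipy.signal import butter, sosfiltfilt, sosfreqz

from .errors import (
    DegenerateInputError,
    FormatError,
    InsufficientDataError,
    SpecError,
)
from .hypnogram import Hypnogram

#: The 19 scalp sites of the 10-20 system, in canonical order.
SCALP_CHANNELS = (
    "Fp1", "Fp2", "F7", "F8", "F3", "F4", "Fz",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "T3", "T4", "T5", "T6", "O1", "O2",
)
MASTOIDS = ("A1", "A2")

#: Modern 10-10 labels accepted as aliases of the classical temporal sites.
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: Scalp clusters used to aggregate channel-level band power.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "frontopolar": ("Fp1", "Fp2", "F7", "F8"),
    "frontal": ("F3", "F4", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "Pz"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "occipital": ("O1", "O2"),
}
CLUSTER_NAMES = tuple(CLUSTERS)

#: Frequency bands as closed bin-center intervals [lo, hi] in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.50, 4.75),
    "theta": (5.00, 7.75),
    "alpha": (8.00, 11.75),
    "sigma": (12.00, 15.75),
    "beta": (16.00, 24.75),
}
BAND_NAMES = tuple(BANDS)

BIN_STEP = 0.25
WINDOW_SECONDS = 4.0
FULL_RANGE = (0.50, 30.00)  # retained periodogram slice
NORM_RANGE = (0.50, 24.75)  # percentage-normalization denominator range

FULL_FREQS = np.round(np.arange(FULL_RANGE[0], FULL_RANGE[1] + BIN_STEP / 2, BIN_STEP), 2)
NORM_FREQS = FULL_FREQS[FULL_FREQS <= NORM_RANGE[1] + 1e-9]
N_FULL_BINS = FULL_FREQS.size   # 119
N_NORM_BINS = NORM_FREQS.size   # 98

INDEX_NAMES = ("NREM_sigma", "REM_delta", "REM_beta")


def band_bin_mask(band: str, freqs: np.ndarray = NORM_FREQS) -> np.ndarray:
    lo, hi = BANDS[band]
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def canonical_channel(label: str) -> Optional[str]:
    """Map a raw channel label to its canonical 10-20 name, or None."""
    s = label.strip()
    for prefix in ("EEG ", "eeg "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    s = s.split("-")[0].strip()  # strip reference suffix like "C3-A2"
    lookup = {c.upper(): c for c in SCALP_CHANNELS + MASTOIDS}
    lookup.update({k.upper(): v for k, v in CHANNEL_ALIASES.items()})
    return lookup.get(s.upper())


@dataclass
class PsgRecording:
    """A multichannel PSG segment in microvolts.

    ``data`` is channels x samples, row order given by ``labels``; sample 0 is
    aligned with epoch 0 of the companion hypnogram.
    """

    labels: tuple[str, ...]
    sfreq: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise FormatError("data must be (n_channels, n_samples) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("duplicate channel labels")
        n_win_samples = self.sfreq * WINDOW_SECONDS
        if abs(n_win_samples - round(n_win_samples)) > 1e-9:
            raise FormatError(
                f"sampling rate {self.sfreq} Hz does not give an integer number "
                f"of samples per {WINDOW_SECONDS:.0f}-s window"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def scalp_order(self) -> "PsgRecording":
        """Return a copy restricted to the 19 scalp channels in canonical order."""
        missing = [c for c in SCALP_CHANNELS if c not in self.labels]
        if missing:
            raise FormatError(f"missing required scalp channels: {missing}")
        idx = [self.channel_index(c) for c in SCALP_CHANNELS]
        return PsgRecording(SCALP_CHANNELS, self.sfreq, self.data[idx])


@dataclass
class StageSpectrum:
    """Per-channel absolute power spectrum for one sleep state (uV^2/bin)."""

    state: str  # "NREM" or "REM"
    power: np.ndarray  # (19, 119)
    n_windows: int
    freqs: np.ndarray = field(default_factory=lambda: FULL_FREQS.copy())


@dataclass
class RelativePowerTable:
    """Topography-normalized percentage power (19 channels x 98 bins)."""

    state: str
    values: np.ndarray  # (19, 98), grand sum 100
    freqs: np.ndarray = field(default_factory=lambda: NORM_FREQS.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(SCALP_CHANNELS), columns=self.freqs)


@dataclass
class BandClusterTable:
    """Band x channel and band x cluster percentage power for one state."""

    state: str
    channel_band: pd.DataFrame  # 19 channels x 5 bands
    cluster_band: pd.DataFrame  # 6 clusters x 5 bands


@dataclass
class SleepEegIndexSet:
    """The three per-cluster sleep-EEG indexes of one subject (percent)."""

    nrem_sigma: pd.Series  # over 6 clusters
    rem_delta: pd.Series
    rem_beta: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row layout: columns are (index_name, cluster)."""
        data = {}
        for name, series in zip(INDEX_NAMES, (self.nrem_sigma, self.rem_delta, self.rem_beta)):
            for cluster in CLUSTER_NAMES:
                data[(name, cluster)] = series[cluster]
        frame = pd.DataFrame([data])
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame


def reference_to_linked_mastoids(rec: PsgRecording) -> PsgRecording:
    """Re-reference every scalp channel to the averaged mastoids (A1+A2)/2.

    The mastoid channels are dropped from the output.  Raises if a mastoid is
    missing, in which case the caller may skip re-referencing (data already
    referenced at acquisition).
    """
    missing = [m for m in MASTOIDS if m not in rec.labels]
    if missing:
        raise FormatError(f"mastoid channel(s) {missing} missing; cannot re-reference")
    ref = 0.5 * (rec.data[rec.channel_index("A1")] + rec.data[rec.channel_index("A2")])
    keep = [i for i, lab in enumerate(rec.labels) if lab not in MASTOIDS]
    labels = tuple(rec.labels[i] for i in keep)
    return PsgRecording(labels, rec.sfreq, rec.data[keep] - ref)


def _butter_sos(lo: float, hi: float, sfreq: float, order: int) -> np.ndarray:
    nyq = sfreq / 2.0
    if not (0 < lo < hi):
        raise SpecError("require 0 < lo < hi")
    if hi >= nyq:
        raise SpecError(f"high cut {hi} Hz must be below Nyquist ({nyq} Hz)")
    return butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


_GAIN_CACHE: dict[tuple, np.ndarray] = {}


def _zero_phase_gain(
    n: int, sfreq: float, lo: float, hi: float, order: int
) -> np.ndarray:
    """Squared-magnitude Butterworth response on the length-n rfft grid."""
    key = (n, sfreq, lo, hi, order)
    if key not in _GAIN_CACHE:
        if len(_GAIN_CACHE) > 8:
            _GAIN_CACHE.clear()
        sos = _butter_sos(lo, hi, sfreq, order)
        freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
        _, h = sosfreqz(sos, worN=2 * np.pi * freqs / sfreq)
        _GAIN_CACHE[key] = np.abs(h) ** 2
    return _GAIN_CACHE[key]


def bandpass(
    rec: PsgRecording,
    lo: float = 0.33,
    hi: float = 30.0,
    order: int = 6,
    method: str = "fft",
) -> PsgRecording:
    """Zero-phase band-pass filter of every channel.

    ``method="fft"`` (default) multiplies the full-record spectrum by the
    squared magnitude response of the digital order-``order`` Butterworth
    band-pass (exactly zero-phase; the response ``filtfilt`` approximates).
    ``method="filtfilt"`` applies the same Butterworth forward and backward
    with :func:`scipy.signal.sosfiltfilt`.  With the defaults the stopband
    attenuation exceeds 20 dB below ``lo/2`` and above ``2*hi`` and passband
    droop stays under 1 dB on [2*lo, 0.8*hi] (requires ``hi`` at or below
    about half of Nyquist).
    """
    sos = _butter_sos(lo, hi, rec.sfreq, order)
    if method == "filtfilt":
        out = sosfiltfilt(sos, rec.data, axis=1)
    elif method == "fft":
        n = rec.n_samples
        gain = _zero_phase_gain(n, rec.sfreq, lo, hi, order).astype(
            rec.data.dtype, copy=False
        )
        spec = sp_fft.rfft(rec.data, axis=1)
        out = sp_fft.irfft(spec * gain, n=n, axis=1).astype(rec.data.dtype, copy=False)
    else:
        raise SpecError(f"unknown filter method {method!r}")
    return PsgRecording(rec.labels, rec.sfreq, out)


def _window_view(rec: PsgRecording) -> np.ndarray:
    """Non-overlapping 4-s windows as a zero-copy view (n_win, n_ch, wlen)."""
    wlen = int(round(rec.sfreq * WINDOW_SECONDS))
    n_win = rec.n_samples // wlen
    v = rec.data[:, : n_win * wlen].reshape(rec.data.shape[0], n_win, wlen)
    return np.swapaxes(v, 0, 1)


def eligible_window_indices(
    rec: PsgRecording,
    hyp: Hypnogram,
    states: Iterable[str],
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Indexes of artifact-free 4-s windows whose parent epoch is in ``states``.

    Windows are aligned to epoch starts (a 20-s epoch holds exactly five);
    only epochs within the lights-off..lights-on interval are eligible.
    """
    wps = hyp.epoch_duration / WINDOW_SECONDS
    if abs(wps - round(wps)) > 1e-9:
        raise SpecError("epoch_duration must be a multiple of the 4-s window")
    wps = int(round(wps))
    wlen = int(round(rec.sfreq * WINDOW_SECONDS))
    n_win_total = rec.n_samples // wlen
    states = set(states)
    idx = []
    for ep in range(hyp.lights_off, hyp.lights_on):
        if hyp.stages[ep] not in states:
            continue
        for w in range(ep * wps, (ep + 1) * wps):
            if w >= n_win_total:
                break
            if mask is not None and w < len(mask) and mask[w]:
                continue
            idx.append(w)
    return np.asarray(idx, dtype=np.intp)


def select_windows(
    rec: PsgRecording,
    hyp: Hypnogram,
    states: Iterable[str],
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Extract the eligible 4-s windows as an array (n_win, n_ch, wlen).

    Raises :class:`InsufficientDataError` when no window qualifies.
    """
    idx = eligible_window_indices(rec, hyp, states, mask)
    if idx.size == 0:
        raise InsufficientDataError(
            f"no artifact-free windows in states {sorted(set(states))}"
        )
    return _window_view(rec)[idx]


def _taper_vector(taper: str, wlen: int) -> np.ndarray:
    if taper == "rect":
        return np.ones(wlen)
    if taper == "hann":
        return np.hanning(wlen)
    raise SpecError(f"unknown taper {taper!r}")


def periodogram_4s(
    window: np.ndarray,
    sfreq: float,
    taper: str = "rect",
    full: bool = False,
) -> np.ndarray:
    """FFT periodogram of 4-s window(s) at 0.25 Hz resolution.

    ``window`` is (..., wlen) with ``wlen == 4*sfreq``.  The window mean is
    removed, an optional taper applied (normalized so white-noise power is
    unbiased), and power scaled so the sum over all positive-frequency bins
    equals the mean square of the mean-removed window.  By default the
    0.50-30.00 Hz slice (119 bins) is returned; ``full=True`` returns all
    positive-frequency bins.
    """
    window = np.asarray(window)
    if window.dtype not in (np.float32, np.float64):
        window = window.astype(np.float64)
    wlen = int(round(sfreq * WINDOW_SECONDS))
    if window.shape[-1] != wlen:
        raise SpecError(
            f"window length {window.shape[-1]} != {wlen} (= {WINDOW_SECONDS:.0f} s at {sfreq} Hz)"
        )
    x = window - window.mean(axis=-1, keepdims=True)
    t = _taper_vector(taper, wlen).astype(window.dtype)
    t = t / np.sqrt(np.mean(t**2))  # unit mean-square taper: preserves power scale
    spec = sp_fft.rfft(x * t, axis=-1)
    p = (np.abs(spec).astype(np.float64) ** 2) / wlen**2
    if wlen % 2 == 0:  # fold negative frequencies; DC (and Nyquist if present) unique
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    if full:
        return p
    k_lo = int(round(FULL_RANGE[0] * WINDOW_SECONDS))
    k_hi = int(round(FULL_RANGE[1] * WINDOW_SECONDS))
    if k_hi >= p.shape[-1]:
        raise SpecError(
            f"sampling rate {sfreq} Hz too low for the {FULL_RANGE[1]} Hz bin"
        )
    return p[..., k_lo : k_hi + 1]


def stage_spectrum(
    windows: np.ndarray,
    sfreq: float,
    state: str,
    taper: str = "rect",
) -> StageSpectrum:
    """Average per-window periodograms into the state spectrum.

    ``windows`` is (n_win, n_ch, wlen) as produced by :func:`select_windows`.
    """
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[0] == 0:
        raise InsufficientDataError("need at least one window (n_win, n_ch, wlen)")
    p = periodogram_4s(windows, sfreq, taper=taper)
    return StageSpectrum(state=state, power=p.mean(axis=0), n_windows=windows.shape[0])


def relative_power(s: StageSpectrum) -> RelativePowerTable:
    """Percentage power per bin, normalized over the whole topography.

    Each cell is 100 * power / (sum over 19 channels x 0.50-24.75 Hz bins);
    bins above 24.75 Hz are discarded.
    """
    sub = s.power[:, :N_NORM_BINS]
    total = float(sub.sum())
    if total <= 0:
        raise DegenerateInputError("zero total power in the normalization range")
    return RelativePowerTable(state=s.state, values=100.0 * sub / total)


def band_cluster_power(rp: RelativePowerTable) -> BandClusterTable:
    """Sum percentage power into bands per channel, then clusters per band."""
    ch_vals = np.column_stack(
        [rp.values[:, band_bin_mask(b, rp.freqs)].sum(axis=1) for b in BAND_NAMES]
    )
    ch_pos = {c: i for i, c in enumerate(SCALP_CHANNELS)}
    cl_vals = np.vstack(
        [ch_vals[[ch_pos[c] for c in CLUSTERS[cl]]].sum(axis=0) for cl in CLUSTER_NAMES]
    )
    ch = pd.DataFrame(ch_vals, index=list(SCALP_CHANNELS), columns=list(BAND_NAMES))
    cl = pd.DataFrame(cl_vals, index=list(CLUSTER_NAMES), columns=list(BAND_NAMES))
    return BandClusterTable(state=rp.state, channel_band=ch, cluster_band=cl)


def sleep_indexes(nrem: BandClusterTable, rem: BandClusterTable) -> SleepEegIndexSet:
    """Extract the NREM sigma and REM delta/beta cluster percentages."""
    if nrem.state != "NREM" or rem.state != "REM":
        raise SpecError(
            f"expected (NREM, REM) tables, got ({nrem.state!r}, {rem.state!r})"
        )
    return SleepEegIndexSet(
        nrem_sigma=nrem.cluster_band["sigma"].copy(),
        rem_delta=rem.cluster_band["delta"].copy(),
        rem_beta=rem.cluster_band["beta"].copy(),
    )


STATE_STAGES = {"NREM": ("N2", "N3"), "REM": ("REM",)}


def state_band_cluster(
    rec: PsgRecording,
    hyp: Hypnogram,
    state: str,
    mask: Optional[np.ndarray] = None,
    taper: str = "rect",
) -> BandClusterTable:
    """Windows -> periodograms -> normalized band/cluster table for one state."""
    windows = select_windows(rec, hyp, STATE_STAGES[state], mask)
    spec = stage_spectrum(windows, rec.sfreq, state, taper=taper)
    return band_cluster_power(relative_power(spec))


def compute_sleep_indexes(
    rec: PsgRecording,
    hyp: Hypnogram,
    mask: Optional[np.ndarray] = None,
    taper: str = "rect",
    rereference: bool = True,
    filter_method: str = "fft",
) -> SleepEegIndexSet:
    """Full single-subject spectral path from raw recording to the index set.

    Re-references to averaged mastoids (if present and ``rereference``),
    band-passes 0.33-30 Hz, and computes the NREM and REM band/cluster tables.
    """
    if rereference and all(m in rec.labels for m in MASTOIDS):
        rec = reference_to_linked_mastoids(rec)
    rec = rec.scalp_order()
    rec = bandpass(rec, method=filter_method)
    nrem = state_band_cluster(rec, hyp, "NREM", mask, taper)
    rem = state_band_cluster(rec, hyp, "REM", mask, taper)
    return sleep_indexes(nrem, rem)


def read_artifact_mask(path: str | Path) -> np.ndarray:
    """Read a per-4-s-window artifact mask TSV (columns window, rejected)."""
    df = pd.read_csv(path, sep="\t")
    if not {"window", "rejected"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'window' and 'rejected'")
    if not np.array_equal(df["window"].to_numpy(), np.arange(len(df))):
        raise FormatError(f"{path}: window indexes must be contiguous from 0")
    return df["rejected"].astype(int).to_numpy().astype(bool)


def write_artifact_mask(mask: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"window": np.arange(len(mask)), "rejected": np.asarray(mask).astype(int)}
    ).to_csv(path, sep="\t", index=False)
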