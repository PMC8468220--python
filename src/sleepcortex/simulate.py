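"""Synthetic polysomnography, hypnograms and cohorts with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_hypnogram` -- a first-order Markov chain over AASM stages
  whose stationary composition matches target stage percentages, with
  per-stage switch rates controlling fragmentation (consolidated wake bouts,
  short N1, spindle-rich fragmented N2, near-absent N3 for the default
  AD-like profile).
* :func:`simulate_psg` -- multichannel 1/f^gamma Gaussian background plus
  state-gated oscillatory bursts (raised-cosine envelopes, 0.5-1.5 s) such
  as 13 Hz sigma bursts during N2 at frontal/central/parietal sites and
  1-4 Hz delta bursts during REM at frontopolar/temporal sites; optional
  artifact windows with high-amplitude transients, flagged in the mask.
* :func:`simulate_cohort` -- per-subject sleep-EEG indexes and regional
  thickness drawn from a joint Gaussian with planted Pearson correlations
  (zero elsewhere), plus age/sex covariates.

:func:`simulate_linked_study` couples the two levels: a latent per-subject
gain drives the sigma-burst power of the signal generator and the thickness
of a chosen region, planting a correlation that the full signal pipeline
must recover.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.fft as sp_fft

from .errors import SpecError
from .hypnogram import Hypnogram, STAGES, SLEEP_STAGES
from .spectral import (
    BAND_NAMES,
    CLUSTERS,
    CLUSTER_NAMES,
    INDEX_NAMES,
    MASTOIDS,
    NORM_FREQS,
    PsgRecording,
    SCALP_CHANNELS,
    WINDOW_SECONDS,
    band_bin_mask,
)
from .thickness import ALL_REGIONS, DESIKAN_REGIONS, HEMISPHERES, ThicknessTable

# --------------------------------------------------------------------------
# Hypnogram generator
# --------------------------------------------------------------------------

#: Per-stage switch rates (probability per epoch of leaving via a re-draw).
#: Calibrated once so that (a) at 1350 epochs the realized stage mix tracks
#: its targets to within ~3 percentage points on average and (b) an AD-like
#: in-bed profile yields on the order of 20 intra-sleep awakenings with
#: consolidated (several-minute) wake bouts.
STAGE_SWITCH_RATES: dict[str, float] = {
    "W": 0.09,
    "N1": 0.50,
    "N2": 0.30,
    "N3": 0.30,
    "REM": 0.20,
}

#: AD-like stage targets as percent of the in-bed record, derived from an
#: N2-dominant, N3-poor, low-efficiency profile (stage %TST x SEI 71.4%).
AD_STAGE_TARGETS: dict[str, float] = {
    "N1": 5.0,
    "N2": 53.1,
    "N3": 0.4,
    "REM": 13.0,
}


def simulate_hypnogram(
    targets: Mapping[str, float],
    n_epochs: int,
    fragmentation: float = 1.0,
    seed: int | np.random.Generator = 0,
    epoch_duration: float = 20.0,
) -> Hypnogram:
    """Markov-chain hypnogram with stationary stage mix ``targets``.

    ``targets`` maps sleep stages (and optionally ``"W"``) to percentages of
    the record; an unspecified remainder is wake.  ``fragmentation`` scales
    all per-stage switch rates (0 freezes the initial stage).  The chain
    jumps from stage *i* with probability ``fragmentation * rate[i]`` to a
    stage drawn from the jump law ``q proportional to target * rate``, which
    leaves the target mix stationary while giving each stage its own dwell
    time.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_epochs < 1:
        raise SpecError("n_epochs must be positive")
    tgt = {s: 0.0 for s in STAGES}
    for k, v in targets.items():
        if k not in STAGES:
            raise SpecError(f"unknown stage {k!r} in targets")
        if v < 0:
            raise SpecError(f"negative target for {k}")
        tgt[k] = float(v)
    sleep_sum = sum(tgt[s] for s in SLEEP_STAGES)
    if sleep_sum - 1e-9 > 100.0:
        raise SpecError(f"sleep-stage targets sum to {sleep_sum} > 100")
    if "W" not in targets:
        tgt["W"] = 100.0 - sleep_sum
    elif abs(sum(tgt.values()) - 100.0) > 1e-6:
        raise SpecError("targets (including W) must sum to 100")
    if fragmentation < 0:
        raise SpecError("fragmentation must be nonnegative")

    pi = np.array([tgt[s] for s in STAGES]) / 100.0
    if pi.sum() <= 0:
        raise SpecError("all-zero targets")
    rates = np.array([fragmentation * STAGE_SWITCH_RATES[s] for s in STAGES])
    rates = np.clip(rates, 0.0, 1.0)
    jump_w = pi * rates
    if jump_w.sum() > 0:
        q = jump_w / jump_w.sum()
    else:  # fragmentation == 0: never leaves the initial state
        q = pi / pi.sum()

    if pi[0] > 0:  # nights start awake
        state = 0
    else:
        state = int(rng.choice(len(STAGES), p=q))
    out = []
    for _ in range(n_epochs):
        out.append(STAGES[state])
        if rng.random() < rates[state]:
            state = int(rng.choice(len(STAGES), p=q))
    return Hypnogram(stages=tuple(out), epoch_duration=epoch_duration)


# --------------------------------------------------------------------------
# PSG signal generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillatoryComponent:
    """A state-gated band-limited burst generator.

    Bursts (raised-cosine envelope, 0.5-1.5 s) of a sinusoid with frequency
    jittered within ``bandwidth`` around ``freq`` are added, synchronously,
    to every channel in ``channels`` during epochs scored as ``state``.
    ``duty_cycle`` fixes the fraction of each such epoch spent inside bursts
    (burst count per epoch is deterministic, placement and phase random).
    """

    state: str
    channels: tuple[str, ...]
    freq: float
    bandwidth: float
    amplitude: float  # peak, in uV
    duty_cycle: float

    def __post_init__(self) -> None:
        if self.state not in STAGES:
            raise SpecError(f"unknown state {self.state!r}")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise SpecError("duty_cycle must lie in [0, 1]")
        if self.amplitude < 0:
            raise SpecError("amplitude must be nonnegative")


def ad_components(sigma_amplitude: float = 9.0, delta_amplitude: float = 25.0) -> tuple:
    """Default oscillatory components of the AD-like signal profile."""
    return (
        OscillatoryComponent(
            state="N2",
            channels=CLUSTERS["frontal"] + CLUSTERS["central"] + CLUSTERS["parietal"],
            freq=13.0,
            bandwidth=1.0,
            amplitude=sigma_amplitude,
            duty_cycle=0.25,
        ),
        OscillatoryComponent(
            state="REM",
            channels=CLUSTERS["frontopolar"] + CLUSTERS["temporal"],
            freq=2.0,
            bandwidth=2.0,
            amplitude=delta_amplitude,
            duty_cycle=0.5,
        ),
    )


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the synthetic multichannel PSG signal."""

    sampling_rate: float = 128.0
    gamma: float = 1.0
    background_rms: float = 15.0  # uV, per scalp channel
    noise_floor: float = 0.02  # white floor relative to S(f)=1/(f+knee)^gamma at 1
    knee_hz: float = 0.5  # low-frequency knee of the 1/f^gamma model
    highcut_hz: float = 35.0  # background synthesized up to here (analysis uses <=30)
    components: tuple[OscillatoryComponent, ...] = field(default_factory=ad_components)
    artifact_rate: float = 0.0
    mastoid_rms: float = 2.0  # uV

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        for comp in self.components:
            if comp.freq + comp.bandwidth / 2 >= nyq:
                raise SpecError(
                    f"component at {comp.freq} Hz reaches Nyquist ({nyq} Hz)"
                )
        if not 0.0 <= self.artifact_rate < 1.0:
            raise SpecError("artifact_rate must lie in [0, 1)")
        n = self.sampling_rate * WINDOW_SECONDS
        if abs(n - round(n)) > 1e-9:
            raise SpecError("sampling_rate must give integer samples per 4-s window")


def background_psd_shape(spec: SignalSpec, freqs: np.ndarray) -> np.ndarray:
    """Relative PSD of the background model: (f+knee)^-gamma + floor."""
    f = np.asarray(freqs, dtype=float)
    return (f + spec.knee_hz) ** (-spec.gamma) + spec.noise_floor


def background_band_shares(spec: SignalSpec) -> pd.Series:
    """Analytic band shares of the background over the normalization bins."""
    s = background_psd_shape(spec, NORM_FREQS)
    total = s.sum()
    return pd.Series(
        {b: s[band_bin_mask(b)].sum() / total for b in BAND_NAMES}, name="share"
    )


def background_cluster_band_shares(spec: SignalSpec) -> pd.DataFrame:
    """Expected cluster x band percentage table for a pure-background signal.

    Channels are i.i.d., so a cluster's share is its channel count over 19.
    """
    band = background_band_shares(spec)
    rows = {c: len(CLUSTERS[c]) / len(SCALP_CHANNELS) * band * 100.0 for c in CLUSTER_NAMES}
    return pd.DataFrame(rows).T[list(BAND_NAMES)]


def _synth_background(
    rng: np.random.Generator, spec: SignalSpec, n_ch: int, n_samples: int
) -> np.ndarray:
    """1/f^gamma Gaussian noise, float32, channels x samples.

    The background is synthesized up to ``highcut_hz`` only: the analysis
    band tops out at 30 Hz, so spectral content above the high-cut would be
    removed by the band-pass anyway and carries no information.
    """
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / spec.sampling_rate)
    nf_cut = min(nf, int(np.searchsorted(freqs, spec.highcut_hz, side="right")))
    shape = background_psd_shape(spec, freqs[:nf_cut]).astype(np.float32)
    shape[0] = 0.0  # zero mean
    z = rng.standard_normal((n_ch, 2 * nf_cut), dtype=np.float32).view(np.complex64)
    coef = np.zeros((n_ch, nf), dtype=np.complex64)
    coef[:, :nf_cut] = z * np.sqrt(shape)
    x = sp_fft.irfft(coef, n=n_samples, axis=1)
    # rescale to the requested per-channel RMS (expected, common factor)
    expected_ms = 4.0 * float(shape.sum()) / n_samples**2
    x *= np.float32(spec.background_rms / np.sqrt(expected_ms))
    return x


def _add_bursts(
    data: np.ndarray,
    hyp: Hypnogram,
    comp: OscillatoryComponent,
    sfreq: float,
    rng: np.random.Generator,
    ch_index: Mapping[str, int],
) -> None:
    """Add one component's bursts in place (synchronous across its channels)."""
    if comp.amplitude == 0 or comp.duty_cycle == 0:
        return
    ep_len = int(round(hyp.epoch_duration * sfreq))
    rows = [ch_index[c] for c in comp.channels]
    mean_burst = 1.0  # s; individual lengths drawn U(0.5, 1.5)
    n_bursts = max(1, int(round(comp.duty_cycle * hyp.epoch_duration / mean_burst)))
    for ep, stage in enumerate(hyp.stages):
        if stage != comp.state:
            continue
        ep_start = ep * ep_len
        if ep_start >= data.shape[1]:
            break
        slot = hyp.epoch_duration / n_bursts
        for b in range(n_bursts):
            dur = rng.uniform(0.5, 1.5)
            # keep total burst time per epoch at duty_cycle on average
            dur *= comp.duty_cycle * hyp.epoch_duration / (n_bursts * mean_burst)
            dur = min(dur, slot)
            offset = rng.uniform(0, slot - dur)
            start = ep_start + int(round((b * slot + offset) * sfreq))
            nsamp = int(round(dur * sfreq))
            if nsamp < 2:
                continue
            stop = min(start + nsamp, data.shape[1])
            nsamp = stop - start
            t = np.arange(nsamp) / sfreq
            f = rng.uniform(comp.freq - comp.bandwidth / 2, comp.freq + comp.bandwidth / 2)
            phase = rng.uniform(0, 2 * np.pi)
            env = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nsamp) / nsamp)
            burst = (comp.amplitude * env * np.sin(2 * np.pi * f * t + phase)).astype(
                data.dtype
            )
            data[rows, start:stop] += burst


def simulate_psg(
    hyp: Hypnogram,
    spec: SignalSpec = SignalSpec(),
    seed: int | np.random.Generator = 0,
) -> tuple[PsgRecording, np.ndarray]:
    """Synthesize a PSG recording (19 scalp + A1/A2) and its artifact mask.

    Returns ``(recording, mask)`` where ``mask`` is boolean per 4-s window
    (True = rejected).  Pure function of the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sfreq = spec.sampling_rate
    n_samples = int(round(hyp.n_epochs * hyp.epoch_duration * sfreq))
    labels = SCALP_CHANNELS + MASTOIDS
    data = np.empty((len(labels), n_samples), dtype=np.float32)
    data[: len(SCALP_CHANNELS)] = _synth_background(
        rng, spec, len(SCALP_CHANNELS), n_samples
    )
    data[len(SCALP_CHANNELS) :] = spec.mastoid_rms * rng.standard_normal(
        (len(MASTOIDS), n_samples), dtype=np.float32
    )
    ch_index = {c: i for i, c in enumerate(labels)}
    for comp in spec.components:
        _add_bursts(data, hyp, comp, sfreq, rng, ch_index)

    wlen = int(round(WINDOW_SECONDS * sfreq))
    n_win = n_samples // wlen
    mask = rng.random(n_win) < spec.artifact_rate
    if mask.any():
        t = np.arange(wlen) / sfreq
        transient = (
            400.0 * np.hanning(wlen) * np.sin(2 * np.pi * 1.5 * t)
        ).astype(np.float32)
        for w in np.nonzero(mask)[0]:
            data[: len(SCALP_CHANNELS), w * wlen : (w + 1) * wlen] += transient
    return PsgRecording(labels, sfreq, data), mask


# --------------------------------------------------------------------------
# Cohort generator (latent-Gaussian level)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedLink:
    """A planted Pearson correlation between an index cell and a region."""

    region: str
    hemisphere: str
    index_name: str
    cluster: str
    r: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise SpecError(f"|r| > 1 in planted link {self}")
        if self.index_name not in INDEX_NAMES:
            raise SpecError(f"unknown index {self.index_name!r}")
        if self.cluster not in CLUSTER_NAMES:
            raise SpecError(f"unknown cluster {self.cluster!r}")


def _default_index_means() -> pd.Series:
    """Plausible index means (percent of topography-normalized power).

    REM delta dominates (EEG slowing), sigma and beta are small; within an
    index, cluster magnitude roughly follows cluster size.
    """
    base = {"NREM_sigma": 0.45, "REM_delta": 2.8, "REM_beta": 0.25}
    vals = {}
    for name in INDEX_NAMES:
        for cluster in CLUSTER_NAMES:
            vals[(name, cluster)] = base[name] * len(CLUSTERS[cluster])
    return pd.Series(vals)


def _default_thickness_means() -> pd.Series:
    """Plausible mean regional thickness (mm) for an AD cohort."""
    special = {
        "entorhinal": 3.0,
        "temporal pole": 3.4,
        "insula": 2.9,
        "pericalcarine": 1.5,
        "cuneus": 1.8,
        "lingual": 1.9,
        "postcentral": 1.9,
        "precuneus": 2.2,
    }
    vals = {}
    for hemi in HEMISPHERES:
        for region in DESIKAN_REGIONS:
            vals[(hemi, region)] = special.get(region, 2.4)
        vals[(hemi, "mean")] = 2.3
    return pd.Series(vals)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the latent-Gaussian cohort generator."""

    n_subjects: int = 23
    planted_links: tuple[PlantedLink, ...] = ()
    index_sd_frac: float = 0.30  # per-cell SD as a fraction of its mean
    thickness_sd: float = 0.25  # mm
    age_mean: float = 73.2
    age_sd: float = 6.2
    female_fraction: float = 12 / 23

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise SpecError("n_subjects must be at least 5")
        if not 0 <= self.female_fraction <= 1:
            raise SpecError("female_fraction must lie in [0, 1]")


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, ThicknessTable, pd.DataFrame, dict]:
    """Draw per-subject indexes, thickness and covariates with planted links.

    Index cells and regions are jointly Gaussian with unit-diagonal
    covariance equal to the planted correlations for linked pairs and zero
    elsewhere; means and SDs are plausible fixed defaults.  The hemispheric
    ``mean`` pseudo-region is a latent variable of its own (not the average
    of the sampled regions), so links to it can be planted directly.
    Returns ``(indexes, thickness, covariates, truth)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    index_cells = [(i, c) for i in INDEX_NAMES for c in CLUSTER_NAMES]
    thick_cells = [(h, r) for h in HEMISPHERES for r in ALL_REGIONS]
    dims = index_cells + thick_cells
    pos = {cell: k for k, cell in enumerate(dims)}
    corr = np.eye(len(dims))
    for link in spec.planted_links:
        i = pos[(link.index_name, link.cluster)]
        j = pos[(link.hemisphere, link.region)]
        if corr[i, j] != 0:
            raise SpecError(f"duplicate planted link for {dims[i]} x {dims[j]}")
        corr[i, j] = corr[j, i] = link.r
    # eigen factorization admits |r| = 1 (positive semi-definite) exactly
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise SpecError(
            "planted links are mutually inconsistent (correlation matrix not "
            f"positive definite): {[vars(l) for l in spec.planted_links]}"
        )
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((spec.n_subjects, len(dims))) @ factor.T
    subjects = [f"S{k + 1:02d}" for k in range(spec.n_subjects)]

    idx_means = _default_index_means()
    idx_block = z[:, : len(index_cells)]
    idx_vals = {}
    for k, cell in enumerate(index_cells):
        mu = idx_means[cell]
        idx_vals[cell] = np.maximum(mu + spec.index_sd_frac * mu * idx_block[:, k], 0.0)
    indexes = pd.DataFrame(idx_vals, index=subjects)
    indexes.columns = pd.MultiIndex.from_tuples(index_cells)

    th_means = _default_thickness_means()
    th_block = z[:, len(index_cells) :]
    long_rows = []
    for k, (hemi, region) in enumerate(thick_cells):
        mm = np.maximum(th_means[(hemi, region)] + spec.thickness_sd * th_block[:, k], 0.3)
        for s, v in zip(subjects, mm):
            long_rows.append((s, hemi, region, float(v)))
    thickness = ThicknessTable(
        data=pd.DataFrame(
            long_rows, columns=["subject", "hemisphere", "region", "thickness_mm"]
        )
        .pivot(index="subject", columns=["hemisphere", "region"], values="thickness_mm")
        .reindex(index=subjects, columns=pd.MultiIndex.from_tuples(thick_cells))
    )

    n_f = int(round(spec.female_fraction * spec.n_subjects))
    sexes = np.array(["F"] * n_f + ["M"] * (spec.n_subjects - n_f))
    rng.shuffle(sexes)
    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, spec.n_subjects), 40.0, None)
    covariates = pd.DataFrame(
        {"age": np.round(ages, 1), "sex": sexes, "sex_code": (sexes == "F").astype(float)},
        index=subjects,
    )
    truth = {
        "planted_links": [vars(l) for l in spec.planted_links],
        "n_subjects": spec.n_subjects,
    }
    return indexes, thickness, covariates, truth


# --------------------------------------------------------------------------
# Signal-level coupled study
# --------------------------------------------------------------------------


def simulate_linked_study(
    n_subjects: int = 23,
    minutes: float = 30.0,
    link_region: str = "precuneus",
    link_hemisphere: str = "R",
    link_r: float = 0.55,
    gain_spread: float = 0.5,
    seed: int | np.random.Generator = 0,
    signal_spec: SignalSpec = SignalSpec(),
    stage_targets: Optional[Mapping[str, float]] = None,
) -> dict:
    """Generate a full synthetic study with signal-level index coupling.

    A per-subject latent gain ``g = 1 + gain_spread * z`` (``z`` standard
    normal, floored at 0.05) multiplies the *power* of the N2 sigma bursts
    (amplitude scales with sqrt(g)), so each subject's parietal/central/
    frontal NREM sigma percentage tracks ``z`` nearly linearly.  The linked
    region's thickness is ``mean + sd * (r*z + sqrt(1-r^2)*noise)``; all
    other regions are independent.  Returns per-subject recordings,
    hypnograms, masks, the thickness table, covariates and the ground truth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if abs(link_r) > 1:
        raise SpecError("|link_r| must be at most 1")
    targets = dict(stage_targets) if stage_targets is not None else dict(AD_STAGE_TARGETS)
    n_epochs = int(round(minutes * 60.0 / 20.0))
    z = rng.standard_normal(n_subjects)
    gains = np.maximum(1.0 + gain_spread * z, 0.05)

    base_sigma = None
    for comp in signal_spec.components:
        if comp.state == "N2":
            base_sigma = comp.amplitude
    recordings, hypnograms, masks = [], [], []
    for i in range(n_subjects):
        hyp = simulate_hypnogram(targets, n_epochs, seed=rng)
        comps = tuple(
            replace(c, amplitude=c.amplitude * float(np.sqrt(gains[i])))
            if c.state == "N2"
            else c
            for c in signal_spec.components
        )
        spec_i = replace(signal_spec, components=comps)
        rec, mask = simulate_psg(hyp, spec_i, seed=rng)
        recordings.append(rec)
        hypnograms.append(hyp)
        masks.append(mask)

    th_means = _default_thickness_means()
    subjects = [f"S{k + 1:02d}" for k in range(n_subjects)]
    sd = 0.25
    long_rows = []
    link_region_canon = link_region
    eps = rng.standard_normal(n_subjects)
    for hemi in HEMISPHERES:
        for region in ALL_REGIONS:
            if hemi == link_hemisphere and region == link_region_canon:
                latent = link_r * z + np.sqrt(1 - link_r**2) * eps
            else:
                latent = rng.standard_normal(n_subjects)
            mm = np.maximum(th_means[(hemi, region)] + sd * latent, 0.3)
            long_rows.extend(
                (s, hemi, region, float(v)) for s, v in zip(subjects, mm)
            )
    thickness = ThicknessTable(
        data=pd.DataFrame(
            long_rows, columns=["subject", "hemisphere", "region", "thickness_mm"]
        )
        .pivot(index="subject", columns=["hemisphere", "region"], values="thickness_mm")
        .reindex(
            index=subjects,
            columns=pd.MultiIndex.from_tuples(
                [(h, r) for h in HEMISPHERES for r in ALL_REGIONS]
            ),
        )
    )
    n_f = int(round(12 / 23 * n_subjects))
    sexes = np.array(["F"] * n_f + ["M"] * (n_subjects - n_f))
    rng.shuffle(sexes)
    ages = np.clip(rng.normal(73.2, 6.2, n_subjects), 40.0, None)
    covariates = pd.DataFrame(
        {"age": np.round(ages, 1), "sex": sexes, "sex_code": (sexes == "F").astype(float)},
        index=subjects,
    )
    return {
        "subjects": subjects,
        "recordings": recordings,
        "hypnograms": hypnograms,
        "masks": masks,
        "thickness": thickness,
        "covariates": covariates,
        "truth": {
            "latent": z,
            "gains": gains,
            "link": {
                "region": link_region_canon,
                "hemisphere": link_hemisphere,
                "index_name": "NREM_sigma",
                "cluster": "parietal",
                "r": link_r,
            },
            "base_sigma_amplitude": base_sigma,
        },
    }
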