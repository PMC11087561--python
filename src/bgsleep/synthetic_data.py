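"""Synthetic stage-annotated recordings, cohorts and connectome studies.

Every downstream module is testable without any data download: the
generator emulates the signal structure the features assume —
delta-dominant NREM, theta-elevated REM, alpha/beta-tinged wake over a
1/f background — plus subject-level spectral variability, per-channel
signal quality differences, optional cortico-subcortical coherence via
a shared band-limited source, and an optional ECG-like artifact train.

Oscillations are synthesised as band-shaped noise (spectral shaping of
white noise in the frequency domain) rather than pure sines, so the
entropy and fractal features carry class information as well as the
band powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import build_feature_matrix
from .labels import Hypnogram
from .signal_io import EpochSet, RawRecording, epoch_align

__all__ = [
    "StageProfile",
    "CohortSpec",
    "SubjectRecord",
    "DEFAULT_PROFILE",
    "simulate_hypnogram",
    "simulate_recording",
    "simulate_cohort",
    "simulate_feature_cohort",
    "simulate_connectome_study",
]

_STAGE_ORDER = ("W", "N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class StageProfile:
    """Stage-dependent spectral structure of the simulated signal.

    ``band_gains`` multiplies the 1/f background within each analysis
    band, per stage; a gain of 1 leaves the background unchanged.
    ``subject_sigma`` is the s.d. of a per-subject log-normal multiplier
    on each band gain (spectral variability between patients); it may be
    a single value or a per-band mapping. The defaults make the
    theta/alpha/beta bands far more variable between subjects than
    delta, so wake and REM generalize worse across subjects than NREM —
    the pattern seen in patient cohorts.
    ``coherence_level`` in [0, 1) sets the amplitude of a shared
    theta-band source injected into paired cortical channels.
    ``ecg_amplitude`` adds a periodic spike train at ~1.1 Hz (off by
    default, mirroring externalized-recording conditions).
    ``amplitude_uv`` sets the RMS of the gain-free background in
    microvolts.
    """

    band_gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "W":   {"delta": 0.8, "theta": 0.9, "alpha": 2.0, "low_beta": 1.6,
                    "high_beta": 1.25, "low_gamma": 1.0, "high_gamma": 1.0},
            "N1":  {"delta": 1.3, "theta": 1.6, "alpha": 1.0, "low_beta": 0.8,
                    "high_beta": 0.7, "low_gamma": 0.8, "high_gamma": 0.8},
            "N2":  {"delta": 3.5, "theta": 1.2, "alpha": 0.7, "low_beta": 0.6,
                    "high_beta": 0.6, "low_gamma": 0.6, "high_gamma": 0.6},
            "N3":  {"delta": 7.0, "theta": 1.0, "alpha": 0.5, "low_beta": 0.4,
                    "high_beta": 0.4, "low_gamma": 0.5, "high_gamma": 0.5},
            "REM": {"delta": 0.75, "theta": 2.1, "alpha": 0.9, "low_beta": 0.75,
                    "high_beta": 0.75, "low_gamma": 1.0, "high_gamma": 1.0},
        }
    )
    band_edges: dict[str, tuple[float, float]] | None = None
    amplitude_uv: float = 10.0
    one_over_f_exponent: float = 1.5
    noise_level: float = 0.15
    subject_sigma: float | dict[str, float] = field(
        default_factory=lambda: {
            "delta": 0.08, "theta": 0.42, "alpha": 0.55, "low_beta": 0.50,
            "high_beta": 0.50, "low_gamma": 0.30, "high_gamma": 0.30,
        }
    )
    coherence_level: float = 0.6
    ecg_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for stage, gains in self.band_gains.items():
            if any(g <= 0 for g in gains.values()):
                raise ValueError(f"gains must be > 0 (stage {stage})")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


DEFAULT_PROFILE = StageProfile()

_BAND_EDGES = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "low_beta": (13.0, 20.0), "high_beta": (20.0, 30.0),
    "low_gamma": (30.0, 45.0), "high_gamma": (55.0, 90.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator settings.

    The sleep-structure targets are the share of each sleep stage among
    sleep epochs (percent), with ``efficiency_pct`` the share of sleep
    among in-bed epochs; defaults follow a movement-disorder cohort
    (N1/N2/N3/REM = 9.8/62.2/10.1/17.8%, efficiency 72.8%).
    """

    n_subjects: int = 8
    nights_per_subject: int = 1
    epochs_per_night: int = 600
    structure_pct: dict[str, float] = field(
        default_factory=lambda: {"N1": 9.8, "N2": 62.2, "N3": 10.1, "REM": 17.8}
    )
    efficiency_pct: float = 72.8
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.epochs_per_night <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.efficiency_pct <= 100:
            raise ValueError("efficiency_pct must be in [0, 100]")

    def stage_targets(self) -> dict[str, float]:
        """Target proportions of all in-bed epochs, per five-class stage."""
        eff = self.efficiency_pct / 100.0
        total = sum(self.structure_pct.values())
        out = {"W": 1.0 - eff}
        for s in ("N1", "N2", "N3", "REM"):
            share = self.structure_pct.get(s, 0.0) / total if total > 0 else 0.0
            out[s] = eff * share
        return out


#: mean bout length (epochs) per stage for the semi-Markov hypnogram
_MEAN_DWELL = {"W": 4.0, "N1": 2.0, "N2": 12.0, "N3": 9.0, "REM": 9.0}


def simulate_hypnogram(spec: CohortSpec, seed: int | None = None) -> Hypnogram:
    """Semi-Markov stage sequence with geometric bout durations.

    Each stage receives an epoch budget equal to its target proportion;
    bouts of geometric length (stage-specific means) are drawn until
    the budget is spent, then all bouts are shuffled into a night.
    Realized stage proportions therefore match the targets up to bout
    rounding at any night length. Lights-out is epoch 0, lights-on the
    final epoch.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.epochs_per_night
    targets = spec.stage_targets()
    active = [s for s in _STAGE_ORDER if targets[s] > 0]
    if len(active) == 1:
        return Hypnogram(stages=np.array([active[0]] * n, dtype=object))

    # largest-remainder allocation so the budgets sum to exactly n epochs
    raw = np.array([targets[s] * n for s in active])
    budgets = np.floor(raw).astype(int)
    short = n - budgets.sum()
    for i in np.argsort(-(raw - np.floor(raw)))[:short]:
        budgets[i] += 1

    bouts: list[tuple[str, int]] = []
    for s, budget in zip(active, budgets):
        budget = int(budget)
        while budget > 0:
            dwell = min(int(rng.geometric(1.0 / _MEAN_DWELL[s])), budget)
            bouts.append((s, dwell))
            budget -= dwell
    order = rng.permutation(len(bouts))
    stages: list[str] = []
    for i in order:
        s, dwell = bouts[i]
        stages.extend([s] * dwell)
    return Hypnogram(stages=np.array(stages[:n], dtype=object))


def _epoch_spectrum_shape(
    freqs: np.ndarray,
    gains: dict[str, float],
    exponent: float,
    noise: float,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    shape = 1.0 / np.power(np.maximum(freqs, 0.5) + 1.0, exponent)
    gain = np.ones_like(freqs)
    for band, (lo, hi) in (band_edges or _BAND_EDGES).items():
        gain[(freqs >= lo) & (freqs < hi)] = gains.get(band, 1.0)
    return shape * gain + noise * shape.mean()


def _shaped_noise(
    rng: np.random.Generator, n_epochs: int, n_samples: int, amp: np.ndarray
) -> np.ndarray:
    nf = amp.size
    z = rng.standard_normal((n_epochs, nf)) + 1j * rng.standard_normal((n_epochs, nf))
    z[:, 0] = 0.0
    return np.fft.irfft(z * amp, n=n_samples, axis=1) * np.sqrt(n_samples)


def _ecg_template(rate: float, n_samples: int, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_samples) / rate
    period = 1.0 / 1.1
    phase = rng.uniform(0, period)
    x = np.zeros(n_samples)
    spike_t = np.arange(phase, t[-1], period)
    idx = np.round(spike_t * rate).astype(int)
    width = max(int(0.02 * rate), 1)
    for i in idx:
        j = np.arange(max(i - 2 * width, 0), min(i + 2 * width, n_samples))
        x[j] += amplitude * np.exp(-0.5 * ((j - i) / width) ** 2)
    return x


def simulate_recording(
    hypnogram: Hypnogram,
    profile: StageProfile = DEFAULT_PROFILE,
    n_channels: int = 1,
    rate: float = 200.0,
    seed: int = 0,
    channel_quality: list[float] | None = None,
    paired_cortical: bool = False,
) -> RawRecording | tuple[RawRecording, RawRecording]:
    """Generate a multichannel recording whose epochs follow the hypnogram.

    Each epoch's spectrum follows its stage's band gains on a 1/f
    background. ``channel_quality`` (default 1.0, 0.6, 0.35, ...)
    attenuates the stage-dependent modulation per channel, so deeper
    channels decode better — mirroring contact-to-target geometry. With
    ``paired_cortical`` a second, cortical recording is returned that
    shares a theta-band source with the first basal-ganglia channel at
    the profile's coherence level.
    """
    rng = np.random.default_rng(seed)
    n_ep = len(hypnogram)
    n_samp = int(round(hypnogram.epoch_length * rate))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)

    # normalise so the gain-free background has RMS amplitude_uv
    ref = _epoch_spectrum_shape(
        freqs, {}, profile.one_over_f_exponent, profile.noise_level,
        profile.band_edges,
    )
    uv_scale = profile.amplitude_uv * np.sqrt(n_samp / (4.0 * ref[1:].sum()))

    if channel_quality is None:
        channel_quality = [1.0 / (1.6 ** i) for i in range(n_channels)]
    if len(channel_quality) != n_channels:
        raise ValueError("one quality value per channel required")

    # per-subject (per-call) spectral variability on each band gain
    sigma = profile.subject_sigma
    subj_mult = {
        b: float(np.exp(rng.normal(0.0, sigma[b] if isinstance(sigma, dict) else sigma)))
        for b in (profile.band_edges or _BAND_EDGES)
    }

    stages_arr = np.asarray(hypnogram.stages, dtype=object)
    data = np.empty((n_channels, n_ep, n_samp))
    for c, q in enumerate(channel_quality):
        for stage in np.unique(stages_arr):
            rows = np.flatnonzero(stages_arr == stage)
            gains = profile.band_gains.get(str(stage), {})
            eff_gains = {
                b: 1.0 + q * (g * subj_mult[b] - 1.0) for b, g in gains.items()
            }
            amp = uv_scale * np.sqrt(
                _epoch_spectrum_shape(
                    freqs, eff_gains, profile.one_over_f_exponent,
                    profile.noise_level, profile.band_edges,
                )
            )
            data[c, rows] = _shaped_noise(rng, rows.size, n_samp, amp)
    if profile.ecg_amplitude > 0:
        for c in range(n_channels):
            for e in range(n_ep):
                data[c, e] += _ecg_template(
                    rate, n_samp, profile.ecg_amplitude, rng
                )
    bg = RawRecording(
        samples=data.reshape(n_channels, n_ep * n_samp),
        rate=rate,
        channel_labels=[f"ch{c + 1}" for c in range(n_channels)],
    )
    if not paired_cortical:
        return bg

    # cortical channel: own background + shared theta-band source
    ctx = np.empty((n_ep, n_samp))
    theta_amp = np.zeros_like(freqs)
    theta_amp[(freqs >= 4.0) & (freqs < 8.0)] = 1.0
    for stage in np.unique(stages_arr):
        rows = np.flatnonzero(stages_arr == stage)
        gains = profile.band_gains.get(str(stage), {})
        amp = uv_scale * np.sqrt(
            _epoch_spectrum_shape(
                freqs, gains, profile.one_over_f_exponent,
                profile.noise_level, profile.band_edges,
            )
        )
        ctx[rows] = _shaped_noise(rng, rows.size, n_samp, amp)
    c = profile.coherence_level
    if c > 0:
        theta_ref = uv_scale * np.sqrt(
            _epoch_spectrum_shape(freqs, {}, profile.one_over_f_exponent, 0.0)
        ) * theta_amp
        shared = _shaped_noise(rng, n_ep, n_samp, theta_ref)
        scale = np.sqrt(c / (1.0 - c))
        ctx += scale * shared
        flat = bg.samples.reshape(n_channels, n_ep, n_samp)
        flat[0] += scale * shared
    ctx_rec = RawRecording(
        samples=ctx.reshape(1, n_ep * n_samp), rate=rate,
        channel_labels=["ecog1"],
    )
    return bg, ctx_rec


@dataclass
class SubjectRecord:
    """One simulated subject-night: labels, signals and cohort metadata."""

    subject: str
    hypnogram: Hypnogram
    recording: RawRecording
    disease: str
    target: str


_DISEASES = ("PD", "DYS")
_TARGETS = ("STN", "GPi")


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    profile: StageProfile = DEFAULT_PROFILE,
) -> list[SubjectRecord]:
    """Simulate a cohort of subject-nights with disease/target metadata.

    Subjects cycle through the disease x target groups so grouped
    decoding contexts are satisfiable on small cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(2 * spec.n_subjects)
    out = []
    for i in range(spec.n_subjects):
        h = simulate_hypnogram(spec, seed=int(seeds[2 * i]))
        rec = simulate_recording(
            h, profile, n_channels=spec.n_channels, seed=int(seeds[2 * i + 1])
        )
        out.append(
            SubjectRecord(
                subject=f"S{i + 1:02d}",
                hypnogram=h,
                recording=rec,
                disease=_DISEASES[i % 2],
                target=_TARGETS[(i // 2) % 2],
            )
        )
    return out


def simulate_feature_cohort(
    spec: CohortSpec = CohortSpec(),
    profile: StageProfile = DEFAULT_PROFILE,
    scheme: str = "three_class",
) -> pd.DataFrame:
    """Cohort straight to a decoding-ready feature matrix.

    Runs the standard pipeline (epoch alignment, per-channel feature
    extraction) over a simulated cohort and stacks the per-channel
    matrices, with stage labels mapped to the requested scheme.
    """
    from .labels import map_stages

    frames = []
    for rec in simulate_cohort(spec, profile):
        h = map_stages(rec.hypnogram, scheme) if scheme != "five_class" else rec.hypnogram
        for c, label in enumerate(rec.recording.channel_labels):
            single = RawRecording(
                samples=rec.recording.samples[c : c + 1],
                rate=rec.recording.rate,
                channel_labels=[label],
            )
            es = epoch_align(single, h)
            frames.append(
                build_feature_matrix(
                    es, mode="single_site", subject=rec.subject,
                    channel=label, disease=rec.disease, target=rec.target,
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_connectome_study(
    n_subjects: int = 16,
    channels_per_subject: int = 4,
    n_parcels: int = 166,
    n_informative: int = 1,
    accuracy_noise: float = 0.0,
    link_sigma_mm: float = 12.0,
    contact_spacing_mm: float = 6.0,
    isolation_quantile: float = 0.9,
    seed: int = 0,
):
    """Toy connectome study with a known accuracy-connectivity link.

    Builds a synthetic normative connectome and designates
    ``n_informative`` spatially isolated, centrally located parcels
    (isolation controlled by ``isolation_quantile``). Each subject's
    lead clusters near the designated region — as DBS leads cluster
    around the target nucleus — with bipolar channel midpoints spaced
    ``contact_spacing_mm`` along a random trajectory. Decoding accuracy
    is a monotone (affine) function of each channel's connectivity to
    the Gaussian network (width ``link_sigma_mm``) around the
    designated parcels, after removing the channel's mean connectivity
    level, plus optional Gaussian noise.

    Returns a dict with ``coordinates`` (DataFrame subject/channel/x/y/z),
    ``profiles`` (n_channels x n_parcels), ``accuracies``,
    ``informative_parcels`` and the ``connectome`` object.
    """
    from .network_mapping import SyntheticConnectome, channel_connectivity, seed_volume

    if n_parcels < 10:
        raise ValueError("need at least 10 parcels")
    rng = np.random.default_rng(seed)
    conn = SyntheticConnectome(n_parcels=n_parcels, seed=int(rng.integers(2**31)))
    # designated parcels are spatially isolated (no near-duplicate parcel
    # shares their profile) and mutually far apart, so the noiseless map
    # recovers them exactly
    centers = conn.parcel_centers
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn_dist = d.min(axis=1)
    central = np.linalg.norm(centers, axis=1) <= 30.0
    candidates = np.flatnonzero(
        central & (nn_dist >= np.quantile(nn_dist, isolation_quantile))
    )
    if candidates.size == 0:
        candidates = np.flatnonzero(nn_dist >= np.quantile(nn_dist, isolation_quantile))
    informative = [int(candidates[np.argmax(nn_dist[candidates])])]
    while len(informative) < n_informative:
        rest = np.setdiff1d(candidates, informative)
        gap = d[np.ix_(rest, informative)].min(axis=1)
        informative.append(int(rest[np.argmax(gap)]))
    informative = np.asarray(informative)

    # leads cluster around the designated parcel, as DBS leads cluster
    # around the target nucleus; bipolar channel midpoints are spaced
    # along the lead trajectory
    anchor = centers[informative[0]]
    rows = []
    profiles = []
    for s in range(n_subjects):
        entry = anchor + rng.normal(0.0, 8.0, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        for c in range(channels_per_subject):
            xyz = entry + direction * contact_spacing_mm * c
            rows.append(
                {"subject": f"S{s + 1:02d}", "channel": f"ch{c + 1}",
                 "x": xyz[0], "y": xyz[1], "z": xyz[2]}
            )
            sv = seed_volume(xyz, radius=5.0, grid=2.0)
            profiles.append(channel_connectivity(sv, conn))
    profiles = np.vstack(profiles)
    # accuracy tracks connectivity to the network around the designated
    # parcel(s): Gaussian parcel weights centred on each designated
    # parcel, peaking there, after removing each channel's common
    # connectivity level
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    w = np.zeros(n_parcels)
    for j in informative:
        dj = np.linalg.norm(centers - centers[j], axis=1)
        w += np.exp(-0.5 * (dj / link_sigma_mm) ** 2)
    link = centered @ (w / w.sum())
    accuracies = 0.6 + 0.35 * (link - link.min()) / np.ptp(link)
    accuracies = accuracies + accuracy_noise * rng.standard_normal(len(accuracies))
    return {
        "coordinates": pd.DataFrame(rows),
        "profiles": profiles,
        "accuracies": accuracies,
        "informative_parcels": np.sort(informative),
        "connectome": conn,
    }
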