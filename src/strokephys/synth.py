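"""Seeded synthetic-data generators with known ground truth.

Every downstream analysis stage (evoked-FP scoring, paired-pulse ratio, CSD,
MUA, reaching kinematics, platform metrics, behavioral scores) can be
exercised on data whose injected parameters are known exactly, so recovery
can be scored without re-deriving anything.  The generators are
phenomenological, not biophysical: they reproduce the *shape* of the real
signals (laminar evoked lobes, bell-shaped reach submovements, force pulses)
and the *directions* of the group effects (stroke damps the early negative
FP, enhances the late positive one, deepens paired-pulse depression;
rehabilitation normalizes), with magnitudes chosen once as realistic values.

Determinism contract: identical (config, seed) yields bit-identical output.
Each generator call derives all randomness from a single explicit seed via
``numpy.random.SeedSequence``; there is no hidden global state.  Per-subject
parameter draws use a stream separate from the noise stream, so changing a
deterministic setting (e.g. an amplitude scale) never perturbs the other
draws.

Evoked waveform family
----------------------
FP lobes are raised-cosine (Hann) bumps with *compact support*: the negative
lobe (half-width 6 ms, latency drawn on the sample grid in 18-25 ms) and the
positive lobe (half-width 10 ms, latency 42-48 ms) never overlap each other,
and at the shortest paired-pulse interval (50 ms) the first response ends
before the second response's scoring window begins.  Only the extremum
amplitude and latency are contractual; the compact support makes noiseless
recovery exact, which Gaussian tails would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .behavior import BehaviorCounts, PlatformTrial
from .ephys import LaminarRecording, VALID_ISIS
from .kinematics import ReachTrajectory

__all__ = [
    "CONDITIONS",
    "CONDITION_SCALES",
    "BEHAVIOR_PRESETS",
    "CohortConfig",
    "ReachConfig",
    "PlatformConfig",
    "EvokedTruth",
    "SubjectEphys",
    "ReachTruth",
    "PlatformTruth",
    "gen_evoked_lfp",
    "gen_reach_trajectory",
    "gen_platform_trial",
    "gen_behavior_counts",
    "depth_profile",
    "render_reach_frames",
]

CONDITIONS = ("sham", "stroke5d", "stroke30d", "robot_bont")

# (neg_amp_scale, pos_amp_scale, ppd_ratio): direction-only condition effects.
# Stroke damps the early negative (transcallosal excitatory) component --
# strongly at 5 days, partially recovered at 30 days -- enhances the late
# positive (inhibitory) component most at 30 days, and deepens paired-pulse
# depression; robotic rehabilitation plus contralateral silencing normalizes
# all three toward sham.
CONDITION_SCALES: dict[str, tuple[float, float, float]] = {
    "sham": (1.0, 1.0, 0.8),
    "stroke5d": (0.25, 1.25, 0.6),
    "stroke30d": (0.6, 1.6, 0.5),
    "robot_bont": (0.85, 1.15, 0.7),
}

# Behavioral condition presets used by the pipeline: foot-fault probability
# of the impaired limb, probability that a cylinder wall contact uses the
# impaired limb, probability of an incorrect grasp, mean platform attempts
# before a successful pull, and reach submovement count (more submovements =
# more fragmented movement).
BEHAVIOR_PRESETS: dict[str, dict[str, float]] = {
    "sham": dict(p_fault=0.05, p_impaired_use=0.50, p_incorrect=0.20,
                 platform_attempts=2.0, n_submovements=2),
    "stroke5d": dict(p_fault=0.35, p_impaired_use=0.25, p_incorrect=0.60,
                     platform_attempts=8.0, n_submovements=5),
    "stroke30d": dict(p_fault=0.25, p_impaired_use=0.30, p_incorrect=0.50,
                      platform_attempts=6.0, n_submovements=4),
    "robot_bont": dict(p_fault=0.10, p_impaired_use=0.45, p_incorrect=0.30,
                       platform_attempts=3.0, n_submovements=3),
}

_NEG_HALF_WIDTH_MS = 6.0
_POS_HALF_WIDTH_MS = 10.0
_NEG_LATENCY_RANGE = (18.0, 25.0)
_POS_LATENCY_RANGE = (42.0, 48.0)
_N_CHANNELS = 16
_CHANNEL_SPACING_UM = 100.0


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Synthetic evoked-LFP cohort.

    ``neg_amp_scale``, ``pos_amp_scale`` and ``ppd_ratio`` default to the
    condition presets in :data:`CONDITION_SCALES`.  ``noise_sd`` is the SD of
    the low-frequency background noise in mV; ``subject_cv`` is the
    between-subject coefficient of variation of the injected amplitudes.
    The stimulation protocol defaults match the experimental one: 15
    repetitions spaced 5 s.  LFP-band content only needs 1 kHz sampling;
    spike bursts for MUA analysis are embedded when ``sample_rate`` is at
    least 20 kHz.
    """

    condition: str = "sham"
    n_subjects: int = 1
    seed: int = 0
    neg_amp_scale: float | None = None
    pos_amp_scale: float | None = None
    ppd_ratio: float | None = None
    noise_sd: float = 0.05          # mV
    n_trials: int = 15
    trial_spacing: float = 5.0      # s
    sample_rate: float = 1000.0     # Hz
    subject_cv: float = 0.1
    base_neg_amp: float = 0.8       # mV at the peak (deep) channel, sham scale
    base_pos_amp: float = 0.6       # mV
    include_spikes: bool = True
    spike_rate_max: float = 800.0   # Hz at the burst peak, peak channel

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        scales = CONDITION_SCALES[self.condition]
        if self.neg_amp_scale is None:
            self.neg_amp_scale = scales[0]
        if self.pos_amp_scale is None:
            self.pos_amp_scale = scales[1]
        if self.ppd_ratio is None:
            self.ppd_ratio = scales[2]
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.ppd_ratio <= 1:
            raise ValueError("ppd_ratio must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_trials < 1 or self.trial_spacing <= 0 or self.sample_rate <= 0:
            raise ValueError("n_trials, trial_spacing and sample_rate must be positive")


@dataclass
class ReachConfig:
    """Synthetic skilled-reaching trajectory.

    The tangential speed is a sum of ``n_submovements`` temporally separated
    bell-shaped (raised-cosine) profiles; the path is an out-and-back loop in
    the sagittal plane with outbound extent ``path_extent``.  The speed
    profile is scaled so the integrated distance equals the loop arc length;
    ``peak_speed`` sets the relative bell heights and the realized maximum
    speed is reported in the ground truth.
    """

    n_submovements: int = 3
    total_duration: float = 1.0     # s
    peak_speed: float = 150.0       # mm/s (nominal)
    path_extent: float = 12.0       # mm
    noise_sd_xy: float = 0.0        # mm
    frame_rate: float = 120.0       # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_submovements < 1:
            raise ValueError("n_submovements must be >= 1")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.path_extent <= 0 or self.peak_speed <= 0:
            raise ValueError("path_extent and peak_speed must be positive")
        if self.noise_sd_xy < 0:
            raise ValueError("noise_sd_xy must be >= 0")


@dataclass
class PlatformConfig:
    """Synthetic robotic-platform trial.

    ``n_attempts`` subthreshold force pulses (no handle movement) are
    followed by one suprathreshold pull producing a monotone retraction of
    ``extension`` mm back to the start position.
    """

    n_attempts: int = 3
    attempt_peak_force: float = 0.12    # N, must stay below the friction threshold
    pull_force: float = 0.5             # N
    friction_threshold: float = 0.2     # N (static friction)
    extension: float = 10.0             # mm
    sample_rate: float = 100.0          # Hz
    seed: int = 0
    attempt_spacing: float = 1.0        # s
    retraction_duration: float = 0.8    # s
    force_noise_sd: float = 0.002       # N

    def __post_init__(self) -> None:
        if self.n_attempts < 0:
            raise ValueError("n_attempts must be >= 0")
        if not self.attempt_peak_force < self.friction_threshold <= self.pull_force:
            raise ValueError(
                "config requires attempt_peak_force < friction_threshold <= pull_force "
                f"(got {self.attempt_peak_force} / {self.friction_threshold} / {self.pull_force})"
            )
        if self.extension <= 0 or self.sample_rate <= 0:
            raise ValueError("extension and sample_rate must be positive")


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class EvokedTruth:
    """Injected parameters of one synthetic subject's evoked responses."""

    neg_amp: np.ndarray             # mV per channel (first response)
    pos_amp: np.ndarray             # mV per channel
    neg_latency_ms: float
    pos_latency_ms: float
    ppd_ratio: float                # realized (with subject jitter)
    depth_profile: np.ndarray
    peak_channel: int
    noise_sd: float
    spike_rate_max: float | None    # None when no spikes were embedded


@dataclass
class SubjectEphys:
    """One synthetic subject: recordings keyed by ISI (None = single pulse)."""

    subject: int
    condition: str
    recordings: dict[int | None, LaminarRecording]
    truth: EvokedTruth


@dataclass
class ReachTruth:
    arc_len: float                  # mm, continuous loop length
    area: float                     # mm^2, enclosed by the noiseless loop
    n_submovements: int
    peak_speed: float               # mm/s, realized
    mean_speed: float               # mm/s = arc_len / duration


@dataclass
class PlatformTruth:
    t_target: float                 # s, time at which the retraction completes
    n_attempts: int


# ---------------------------------------------------------------------------
# evoked LFP generator
# ---------------------------------------------------------------------------

def depth_profile(n_channels: int = _N_CHANNELS) -> np.ndarray:
    """Smooth unimodal amplitude profile across depth, peaking in deep layers.

    Maximum 1 at the peak channel (three quarters down the probe, mimicking
    the strongest layer-V responses) with a floor of 0.25 superficially.
    """
    i = np.arange(n_channels)
    peak = int(round(0.75 * n_channels))
    return 0.25 + 0.75 * np.exp(-((i - peak) ** 2) / (2 * 3.5**2))


def _hann_lobe(n_samples_half: int) -> np.ndarray:
    """Raised-cosine bump of unit peak on 2*n+1 samples (compact support)."""
    k = np.arange(-n_samples_half, n_samples_half + 1)
    return 0.5 * (1.0 + np.cos(np.pi * k / n_samples_half))


def _grid_latency(rng: np.random.Generator, lo: float, hi: float, sr: float) -> tuple[int, float]:
    """Draw a latency uniformly in [lo, hi] ms, snapped to the sample grid."""
    lat_ms = rng.uniform(lo, hi)
    lat_samp = int(round(lat_ms * 1e-3 * sr))
    return lat_samp, lat_samp / sr * 1e3


def _lowband_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float,
                   sr: float) -> np.ndarray:
    """Low-frequency background noise, per-channel SD exactly ``sd`` mV.

    White Gaussian noise low-passed at 100 Hz (LFP background is dominated by
    slow components) and rescaled per channel.
    """
    noise = rng.standard_normal(shape)
    if sr > 250.0:
        sos = signal.butter(2, 100.0, btype="low", fs=sr, output="sos")
        noise = signal.sosfiltfilt(sos, noise, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * sd


def _spike_waveform(sr: float) -> np.ndarray:
    """Biphasic ~1 ms transient (derivative-of-Gaussian), unit peak."""
    sigma = 0.2e-3
    t = np.arange(-0.6e-3, 0.6e-3 + 0.5 / sr, 1.0 / sr)
    w = -t / sigma * np.exp(0.5 - t**2 / (2 * sigma**2))
    return w / np.abs(w).max()


def _sample_lobe_times(rng: np.random.Generator, n: int, half_width_s: float) -> np.ndarray:
    """Times (s, relative to lobe center) drawn from the Hann-lobe density."""
    grid = np.linspace(-half_width_s, half_width_s, 513)
    cdf = np.cumsum(0.5 * (1 + np.cos(np.pi * grid / half_width_s)))
    cdf /= cdf[-1]
    return np.interp(rng.uniform(0, 1, size=n), cdf, grid)


def gen_evoked_lfp(
    config: CohortConfig,
    isi_list: Sequence[int | None] = (None,),
) -> list[SubjectEphys]:
    """Generate laminar evoked recordings for a synthetic cohort.

    One 16-channel recording per subject per entry of ``isi_list`` (``None``
    for single-pulse stimulation, otherwise a paired-pulse inter-stimulus
    interval of 50, 100 or 200 ms).  Each stimulus evokes on every channel a
    negative lobe (latency 18-25 ms on the sample grid, amplitude = depth
    profile x ``base_neg_amp`` x ``neg_amp_scale`` x subject factor) and a
    positive lobe (latency 42-48 ms, scaled analogously); for paired pulses
    the second response is multiplied by the subject's realized
    ``ppd_ratio``.  High-band spike bursts rate-modulated by the negative
    lobe are embedded when the sample rate supports them (>= 20 kHz).  Each
    subject's injected parameters are returned alongside the recordings.
    """
    for isi in isi_list:
        if isi is not None and isi not in VALID_ISIS:
            raise ValueError(
                f"unknown ISI {isi!r}: expected None (single pulse) or one of {VALID_ISIS}"
            )
    sr = config.sample_rate
    max_isi_s = max((isi or 0) for isi in isi_list) * 1e-3
    if config.trial_spacing < 0.5 + max_isi_s:
        raise ValueError("trial_spacing too short for the requested ISIs")

    profile = depth_profile(_N_CHANNELS)
    depths = (np.arange(_N_CHANNELS) + 1) * _CHANNEL_SPACING_UM
    spikes_active = config.include_spikes and sr >= 20000.0
    wave = _spike_waveform(sr) if spikes_active else None

    hw_n = int(round(_NEG_HALF_WIDTH_MS * 1e-3 * sr))
    hw_p = int(round(_POS_HALF_WIDTH_MS * 1e-3 * sr))
    lobe_n = _hann_lobe(hw_n)
    lobe_p = _hann_lobe(hw_p)

    subjects = []
    root = np.random.SeedSequence(config.seed)
    for subj, subj_ss in enumerate(root.spawn(config.n_subjects)):
        param_ss, noise_ss, spike_ss = subj_ss.spawn(3)
        prng = np.random.default_rng(param_ss)
        # fixed-order parameter draws: independent of any config scaling
        z_neg, z_pos, z_ppd = prng.standard_normal(3)
        lat_n_samp, lat_n_ms = _grid_latency(prng, *_NEG_LATENCY_RANGE, sr)
        lat_p_samp, lat_p_ms = _grid_latency(prng, *_POS_LATENCY_RANGE, sr)

        f_neg = float(np.exp(config.subject_cv * z_neg))
        f_pos = float(np.exp(config.subject_cv * z_pos))
        ppd_jit = 0.05 if config.subject_cv > 0 else 0.0
        ppd_subj = float(np.clip(config.ppd_ratio + ppd_jit * z_ppd, 0.05, 1.0))

        neg_amp = config.base_neg_amp * config.neg_amp_scale * f_neg * profile
        pos_amp = config.base_pos_amp * config.pos_amp_scale * f_pos * profile

        truth = EvokedTruth(
            neg_amp=neg_amp,
            pos_amp=pos_amp,
            neg_latency_ms=lat_n_ms,
            pos_latency_ms=lat_p_ms,
            ppd_ratio=ppd_subj,
            depth_profile=profile.copy(),
            peak_channel=int(np.argmax(profile)),
            noise_sd=config.noise_sd,
            spike_rate_max=config.spike_rate_max if spikes_active else None,
        )

        nrng = np.random.default_rng(noise_ss)
        srng = np.random.default_rng(spike_ss)
        recordings: dict[int | None, LaminarRecording] = {}
        for isi in isi_list:
            duration = 1.0 + config.n_trials * config.trial_spacing
            n_samp = int(round(duration * sr))
            data = np.zeros((_N_CHANNELS, n_samp))
            stim_times = 1.0 + np.arange(config.n_trials) * config.trial_spacing
            stim_samples = np.round(stim_times * sr).astype(int)

            if isi is None:
                pulses = [(0, 1.0)]
            else:
                pulses = [(0, 1.0), (int(round(isi * 1e-3 * sr)), ppd_subj)]
            for s0 in stim_samples:
                for off, scale in pulses:
                    c_n = s0 + off + lat_n_samp
                    c_p = s0 + off + lat_p_samp
                    data[:, c_n - hw_n:c_n + hw_n + 1] -= np.outer(neg_amp * scale, lobe_n)
                    data[:, c_p - hw_p:c_p + hw_p + 1] += np.outer(pos_amp * scale, lobe_p)
                    if spikes_active:
                        _embed_bursts(data, srng, wave, s0 + off + lat_n_samp, hw_n, sr,
                                      config.spike_rate_max * scale, profile)

            if config.noise_sd > 0:
                data += _lowband_noise(nrng, data.shape, config.noise_sd, sr)

            recordings[isi] = LaminarRecording(
                voltages=data,
                sample_rate=sr,
                channel_depths=depths,
                stim_times=stim_times,
                condition=config.condition,
                isi_ms=isi,
            )
        subjects.append(SubjectEphys(subject=subj, condition=config.condition,
                                     recordings=recordings, truth=truth))
    return subjects


def _embed_bursts(
    data: np.ndarray,
    rng: np.random.Generator,
    wave: np.ndarray,
    center_samp: int,
    hw_samp: int,
    sr: float,
    rate_max: float,
    profile: np.ndarray,
) -> None:
    """Add Poisson spike bursts rate-modulated by the negative lobe.

    The instantaneous rate on channel c is ``rate_max * profile[c]`` times
    the unit Hann lobe centred on the negative-component latency, so the
    expected spike count per burst is ``rate_max * profile[c] * half_width``.
    Spike amplitude 0.1 mV x depth profile, +/-30% jitter.
    """
    half_width_s = hw_samp / sr
    wl = wave.size
    n_samp = data.shape[1]
    for ch in range(data.shape[0]):
        lam = rate_max * profile[ch] * half_width_s
        n_spikes = rng.poisson(lam)
        if n_spikes == 0:
            continue
        times = _sample_lobe_times(rng, n_spikes, half_width_s)
        amps = 0.1 * profile[ch] * rng.uniform(0.7, 1.3, size=n_spikes)
        for t_rel, a in zip(times, amps):
            i0 = center_samp + int(round(t_rel * sr)) - wl // 2
            if i0 < 0 or i0 + wl > n_samp:
                continue
            data[ch, i0:i0 + wl] += a * wave


# ---------------------------------------------------------------------------
# reaching trajectory generator
# ---------------------------------------------------------------------------

def _loop_geometry(extent: float, n_fine: int = 4001):
    """Circular out-and-back loop in the sagittal plane, finely sampled.

    Outbound along the upper semicircle, back along the lower one.  Constant
    curvature is deliberate: the tangential speed reconstructed from sampled
    positions by central differences is then a monotone transform of the
    injected speed (the chord-shortening factor is the same everywhere), so
    the injected submovement count is recoverable exactly from noiseless
    frames.  Real reach loops are thinner; only the scalar ground-truth
    metrics, not the silhouette, are contractual.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 2 * n_fine - 1)
    x = 0.5 * extent * (1.0 - np.cos(theta))
    y = 0.5 * extent * np.sin(theta)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return x, y, s, float(s[-1]), area


def _bell_speed_and_distance(t: np.ndarray, centers: np.ndarray, heights: np.ndarray,
                             half_width: float):
    """Sum of Hann speed bells and its exact running integral."""
    v = np.zeros_like(t)
    dist = np.zeros_like(t)
    for c, h in zip(centers, heights):
        tau = np.clip(t - c, -half_width, half_width)
        inside = np.abs(t - c) < half_width
        v[inside] += h * 0.5 * (1.0 + np.cos(np.pi * (t[inside] - c) / half_width))
        dist += h * (0.5 * (tau + half_width)
                     + half_width / (2 * np.pi) * np.sin(np.pi * tau / half_width))
    return v, dist


def gen_reach_trajectory(config: ReachConfig) -> tuple[ReachTrajectory, ReachTruth]:
    """Generate an out-and-back reach whose speed is a sum of separated bells.

    Submovement bells are centred at ``(k + 1/2) * D / n`` with half-width
    ``0.35 * D / n``, leaving speed-zero gaps between them so the injected
    submovement count is recoverable exactly on noiseless data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_submovements
    d = config.total_duration
    centers = (np.arange(n) + 0.5) * d / n
    half_width = 0.35 * d / n
    rel_heights = config.peak_speed * rng.uniform(0.8, 1.0, size=n)

    x_f, y_f, s_f, loop_len, area = _loop_geometry(config.path_extent)
    raw_total = float(rel_heights.sum() * half_width)   # integral of the raw bells
    heights = rel_heights * (loop_len / raw_total)

    n_frames = int(round(d * config.frame_rate)) + 1
    t = np.arange(n_frames) / config.frame_rate
    v, dist = _bell_speed_and_distance(t, centers, heights, half_width)
    dist = np.clip(dist, 0.0, loop_len)
    x = np.interp(dist, s_f, x_f)
    y = np.interp(dist, s_f, y_f)
    if config.noise_sd_xy > 0:
        x = x + rng.normal(0.0, config.noise_sd_xy, size=n_frames)
        y = y + rng.normal(0.0, config.noise_sd_xy, size=n_frames)

    traj = ReachTrajectory(t=t, x=x, y=y, frame_rate=config.frame_rate)
    truth = ReachTruth(
        arc_len=loop_len,
        area=area,
        n_submovements=n,
        peak_speed=float(v.max()),
        mean_speed=loop_len / d,
    )
    return traj, truth


def render_reach_frames(
    x_px: np.ndarray,
    y_px: np.ndarray,
    shape: tuple[int, int] = (64, 96),
    radius: float = 4.0,
    supersample: int = 4,
) -> np.ndarray:
    """Render a green disc (the painted paw) onto gray frames.

    ``x_px`` runs along image columns and ``y_px`` upward; anti-aliased by
    coverage supersampling so the thresholded centroid is sub-pixel
    accurate.  Returns uint8 RGB frames ``(n, H, W, 3)``.
    """
    h, w = shape
    n = len(x_px)
    bg = np.array([60, 60, 60], dtype=float)
    fg = np.array([30, 220, 30], dtype=float)
    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    for i in range(n):
        cx = float(x_px[i])
        cy = float(h - 1 - y_px[i])  # row coordinate
        frame = np.tile(bg, (h, w, 1))
        r0 = max(0, int(np.floor(cy - radius - 1)))
        r1 = min(h, int(np.ceil(cy + radius + 2)))
        c0 = max(0, int(np.floor(cx - radius - 1)))
        c1 = min(w, int(np.ceil(cx + radius + 2)))
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        rr = rows[:, None, None, None] + sub[None, None, :, None]
        cc = cols[None, :, None, None] + sub[None, None, None, :]
        inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        cov = inside.mean(axis=(2, 3))
        frame[r0:r1, c0:c1] = bg + cov[..., None] * (fg - bg)
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------------
# platform trial generator
# ---------------------------------------------------------------------------

def gen_platform_trial(config: PlatformConfig) -> tuple[PlatformTrial, PlatformTruth]:
    """Generate a force/position trace: failed attempts, then one pull.

    ``n_attempts`` raised-cosine force pulses (peaks below the friction
    threshold, handle stationary at full extension) spaced
    ``attempt_spacing`` s apart, followed by a suprathreshold pull during
    which the position retracts monotonically (smoothstep) from
    ``extension`` to exactly 0.  Ground-truth t-target is the time the
    retraction completes.
    """
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    pull_start = 0.5 + config.n_attempts * config.attempt_spacing
    t_complete = pull_start + config.retraction_duration
    duration = t_complete + 0.5
    n_samp = int(round(duration * sr)) + 1
    t = np.arange(n_samp) / sr
    force = np.zeros(n_samp)
    position = np.full(n_samp, config.extension)

    bump_hw = 0.1  # s
    for k in range(config.n_attempts):
        c = 0.5 + k * config.attempt_spacing + bump_hw
        peak = config.attempt_peak_force * rng.uniform(0.85, 1.0)
        inside = np.abs(t - c) < bump_hw
        force[inside] += peak * 0.5 * (1 + np.cos(np.pi * (t[inside] - c) / bump_hw))

    # suprathreshold pull: force plateau over the retraction, smoothstep position
    u = np.clip((t - pull_start) / config.retraction_duration, 0.0, 1.0)
    ramp = np.clip((t - pull_start) / 0.1, 0.0, 1.0) * np.clip((t_complete - t) / 0.1, 0.0, 1.0)
    force += config.pull_force * ramp
    position -= config.extension * (3 * u**2 - 2 * u**3)

    if config.force_noise_sd > 0:
        force += rng.normal(0.0, config.force_noise_sd, size=n_samp)

    trial = PlatformTrial(t=t, force=force, position=position,
                          friction_threshold=config.friction_threshold,
                          target_extension=config.extension)
    return trial, PlatformTruth(t_target=t_complete, n_attempts=config.n_attempts)


# ---------------------------------------------------------------------------
# behavioral counts generator
# ---------------------------------------------------------------------------

def gen_behavior_counts(
    p_fault_per_limb: Mapping[str, float],
    p_impaired_use: float,
    n_events: int,
    seed: int = 0,
    p_incorrect_reach: float = 0.3,
) -> tuple[BehaviorCounts, dict[str, float]]:
    """Binomially sampled behavioral tallies with their ground-truth rates.

    ``n_events`` is used as the number of steps per limb (Gridwalk), of wall
    contacts (cylinder) and of reaching attempts.  Returns the counts and a
    dict of the injected probabilities.
    """
    for name, p in [*p_fault_per_limb.items(), ("p_impaired_use", p_impaired_use),
                    ("p_incorrect_reach", p_incorrect_reach)]:
        if not 0 <= p <= 1:
            raise ValueError(f"probability {name} = {p} outside [0, 1]")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    faults = {limb: int(rng.binomial(n_events, p)) for limb, p in p_fault_per_limb.items()}
    correct = {limb: n_events - faults[limb] for limb in faults}
    n_imp = int(rng.binomial(n_events, p_impaired_use))
    n_incorrect = int(rng.binomial(n_events, p_incorrect_reach))
    counts = BehaviorCounts(
        correct_steps=correct,
        foot_faults=faults,
        n_impaired=n_imp,
        n_unimpaired=n_events - n_imp,
        n_correct=n_events - n_incorrect,
        n_incorrect=n_incorrect,
        n_attempts_total=n_events,
    )
    truth = {f"p_fault_{limb}": p for limb, p in p_fault_per_limb.items()}
    truth.update(p_impaired_use=p_impaired_use, p_incorrect_reach=p_incorrect_reach,
                 n_events=n_events)
    return counts, truth
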