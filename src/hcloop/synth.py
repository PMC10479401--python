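"""Seeded synthetic-data generators emulating each class of recording.

Every generator is a deterministic function of its configuration block and a
seed.  The defaults are matched to the study conditions the analyses assume:
PSP amplitudes of a few mV with dual-exponential kinetics sampled at 50 us,
ITDP potentiation folds of 1.75 (EC_L2/3 sensory pathway) and 1.40 (EC_L5
hippocampal pathway), 20-Hz head tracking in a 37 x 29 cm arena with a
cohort novelty index near 0.60 for control-like attraction bias, Barnes-maze
logs with configurable error counts and latencies, axon-fluorescence images
with an EC_L5 : EC_L2/3 band-intensity ratio of 2.5, and multinomial rabies
input counts with CA1 at 11.9 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .behavior import ARENA_CM, BarnesLog, ObjectSpec, TrackingSession
from .ephys import ITDPExperiment, StimulusEvent, Sweep

__all__ = [
    "SynthConfig",
    "SweepSet",
    "default_objects",
    "gen_sweep_set",
    "gen_itdp_experiment",
    "gen_trajectory_session",
    "gen_barnes_log",
    "gen_axon_image",
    "gen_axon_stack",
    "gen_input_counts",
    "INPUT_REGION_PROPORTIONS",
    "CONTROL_BIAS",
    "UNBIASED_BIAS",
    "SILENCED_BIAS",
]


# Rabies input-region proportions for the synthetic generator.  The three
# largest shares follow the reported cohort means (MEC deep layers 26.7 %,
# pre/post-subiculum 22.5 %, CA1 11.9 %); the remaining regions split the
# rest in plausible, order-of-magnitude shares.
INPUT_REGION_PROPORTIONS: dict[str, float] = {
    "MEC_L5/6": 0.267,
    "pre-postSub": 0.225,
    "CA1": 0.119,
    "paraSub": 0.080,
    "MEC_L3": 0.070,
    "cPre-postSub": 0.060,
    "LEC_L2": 0.050,
    "Sub": 0.040,
    "MEC_L2": 0.030,
    "AD_thalamus": 0.025,
    "M_septum": 0.015,
    "RSC": 0.012,
    "PIR/EPd": 0.007,
}

# Object-attraction biases (novel, familiar).  The novelty index of the
# biased random walk tracks the novel share of the attraction mass, slightly
# compressed toward 0.5 by incidental symmetric exploration while roaming.
# The control-like and silenced-like shares (0.61 and 0.33) were calibrated
# once against the generator so the cohort-mean indices land at the target
# values 0.60 and 0.35.
UNBIASED_BIAS = (1.0, 1.0)
CONTROL_BIAS = (1.22, 0.78)
SILENCED_BIAS = (0.66, 1.34)


@dataclass(frozen=True)
class SynthConfig:
    """Parameter blocks for all generators, plus the master seed."""

    seed: int = 0

    # --- sweeps / PSPs ---
    sweep_duration: float = 0.5          # s
    sampling_interval: float = 50e-6     # s
    stim_onset: float = 0.15             # s
    psp_amplitude: float = 5.0           # mV at saturating intensity
    rise_ms: float = 2.0
    decay_ms: float = 20.0
    noise_sd: float = 0.5                # mV per-sample Gaussian noise
    amplitude_jitter_sd: float = 0.0     # mV sweep-to-sweep amplitude SD
    intensity_half_max: float = 20.0     # % LED at half-maximal amplitude
    rest_potential: float = -70.0        # mV
    spike_threshold_depol: float = 20.0  # mV above rest for AP insertion
    spike_peak: float = 30.0             # mV absolute AP peak

    # --- ITDP ---
    itdp_baseline_mv: float = 4.0
    itdp_n_pre: int = 12
    itdp_n_post: int = 12

    # --- behavior ---
    frame_rate: float = 20.0
    session_duration: float = 600.0      # s (10-minute trial)
    roam_weight: float = 2.0
    roam_mean_s: float = 6.0
    dwell_mean_s: float = 2.5
    approach_speed: float = 8.0          # cm/s
    walk_speed_sd: float = 4.0           # cm/s roaming velocity noise

    # --- Barnes maze ---
    barnes_errors: int = 3
    barnes_latency: float = 45.0
    barnes_cap: float = 180.0

    # --- axon images ---
    image_shape: tuple[int, int] = (240, 160)   # rows (depth) x cols
    pixel_um: float = 5.0
    band_intensity: float = 100.0        # a.u., EC_L5 band
    band_ratio: float = 2.5              # EC_L5 / EC_L2/3 intensity
    image_noise_sd: float = 4.0
    n_slices: int = 6

    # --- rabies input counts ---
    input_proportions: dict = field(
        default_factory=lambda: dict(INPUT_REGION_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.amplitude_jitter_sd < 0 or self.image_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ValueError("kernel time constants must be > 0")
        total = sum(self.input_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"input proportions must sum to 1 (got {total})")


def _rng(cfg: SynthConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


def _psp_kernel(cfg: SynthConfig, n_samples: int, onset_idx: int) -> np.ndarray:
    """Unit-peak dual-exponential kernel aligned to the stimulus onset."""
    t = np.arange(n_samples - onset_idx) * cfg.sampling_interval
    tau_r = cfg.rise_ms * 1e-3
    tau_d = cfg.decay_ms * 1e-3
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k /= k.max()  # unit peak on the sampled grid, so round-trips are exact
    out = np.zeros(n_samples)
    out[onset_idx:] = k
    return out


@dataclass
class SweepSet:
    """Generated sweeps plus their noise-free ground-truth amplitudes."""

    sweeps: list
    true_amplitudes: np.ndarray


def _make_sweep(
    cfg: SynthConfig,
    amplitude: float,
    rng: np.random.Generator,
    kernel: np.ndarray,
    stim: StimulusEvent,
) -> Sweep:
    n = kernel.size
    signal = cfg.rest_potential + amplitude * kernel
    if amplitude >= cfg.spike_threshold_depol:
        # stereotyped AP riding on the noiseless depolarization peak
        peak_idx = int(np.argmax(kernel))
        half = max(int(round(0.75e-3 / cfg.sampling_interval)), 1)
        i0, i1 = max(peak_idx - half, 0), min(peak_idx + half + 1, n)
        ap = np.interp(np.arange(i0, i1), [i0, peak_idx, i1 - 1],
                       [signal[i0], cfg.spike_peak, signal[i1 - 1]])
        signal = signal.copy()
        signal[i0:i1] = ap
    samples = signal + rng.normal(0.0, cfg.noise_sd, size=n)
    return Sweep(samples=samples, stimulus=stim,
                 sampling_interval=cfg.sampling_interval,
                 clamp_mode="current", holding=cfg.rest_potential)


def saturating_amplitude(cfg: SynthConfig, intensity: float) -> float:
    """Mean PSP amplitude as a saturating function of LED intensity (%)."""
    return cfg.psp_amplitude * intensity / (intensity + cfg.intensity_half_max)


def gen_sweep_set(
    cfg: SynthConfig,
    n: int,
    intensity: float = 100.0,
    seed: int | None = None,
) -> SweepSet:
    """Generate ``n`` light-evoked PSP sweeps at one LED intensity.

    Each sweep is rest potential + dual-exponential PSP whose noise-free
    amplitude follows a saturating intensity curve with optional
    sweep-to-sweep jitter, plus white Gaussian noise; an AP is inserted
    whenever the noiseless depolarization crosses the spike threshold.
    """
    if n < 1:
        raise ValueError("need n >= 1 sweeps")
    rng = _rng(cfg, seed)
    n_samples = int(round(cfg.sweep_duration / cfg.sampling_interval))
    onset_idx = int(round(cfg.stim_onset / cfg.sampling_interval))
    kernel = _psp_kernel(cfg, n_samples, onset_idx)
    stim = StimulusEvent(onset=cfg.stim_onset, duration=0.002,
                         modality="optical", intensity=intensity)
    mean_amp = saturating_amplitude(cfg, intensity)
    amps = mean_amp + rng.normal(0.0, cfg.amplitude_jitter_sd, size=n)
    amps = np.clip(amps, 0.0, None)
    sweeps = [_make_sweep(cfg, float(a), rng, kernel, stim) for a in amps]
    return SweepSet(sweeps=sweeps, true_amplitudes=amps)


def gen_itdp_experiment(
    cfg: SynthConfig,
    fold: float,
    layer: str = "EC_L2/3",
    pathway: str = "sensory",
    seed: int | None = None,
) -> ITDPExperiment:
    """Generate an ITDP experiment with a known potentiation fold.

    Pre-induction sweeps have the configured baseline amplitude; post
    sweeps have ``baseline * fold``.  With the default spike threshold the
    experiment stays sub-threshold; a lower ``spike_threshold_depol`` plus
    amplitude jitter emulates the post-induction spiking seen in the EC_L2/3
    sensory pathway.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if cfg.itdp_n_pre < 10 or cfg.itdp_n_post < 10:
        raise ValueError("ITDP epochs need >= 10 sweeps each")
    rng = _rng(cfg, seed)
    n_samples = int(round(cfg.sweep_duration / cfg.sampling_interval))
    onset_idx = int(round(cfg.stim_onset / cfg.sampling_interval))
    kernel = _psp_kernel(cfg, n_samples, onset_idx)
    modality = "electrical" if pathway == "sensory" else "optical"
    stim = StimulusEvent(onset=cfg.stim_onset,
                         duration=0.0001 if modality == "electrical" else 0.002,
                         modality=modality, intensity=100.0)

    def epoch(n: int, amp: float) -> list:
        amps = np.clip(amp + rng.normal(0.0, cfg.amplitude_jitter_sd, size=n), 0, None)
        return [_make_sweep(cfg, float(a), rng, kernel, stim) for a in amps]

    pre = epoch(cfg.itdp_n_pre, cfg.itdp_baseline_mv)
    post = epoch(cfg.itdp_n_post, cfg.itdp_baseline_mv * fold)
    return ITDPExperiment(pre_sweeps=pre, post_sweeps=post, pathway=pathway)


# ---------------------------------------------------------------------------
# behavior


def default_objects(novel: str = "right") -> list[ObjectSpec]:
    """Two objects 7 cm from the side walls on the arena midline."""
    r = 3.0
    left = ObjectSpec(id="left", x=7.0, y=ARENA_CM[1] / 2, radius=r,
                      status="novel" if novel == "left" else "familiar")
    right = ObjectSpec(id="right", x=ARENA_CM[0] - 7.0, y=ARENA_CM[1] / 2, radius=r,
                       status="novel" if novel == "right" else "familiar")
    return [left, right]


def gen_trajectory_session(
    cfg: SynthConfig,
    objects: list[ObjectSpec] | None = None,
    biases: tuple[float, ...] | None = None,
    duration: float | None = None,
    seed: int | None = None,
) -> TrackingSession:
    """Bounded biased random walk emulating an open-field trial.

    The animal alternates between roaming epochs (Ornstein-Uhlenbeck-like
    velocity noise, reflected at the walls) and object-directed epochs in
    which it approaches an object, hovers at its edge for an exponential
    dwell with the head toward the center, then resumes roaming.  Epoch
    targets are drawn with probability proportional to the per-object
    attraction ``biases`` (and ``cfg.roam_weight`` for roaming), so the
    novelty index tracks the novel object's share of attraction mass.
    """
    if duration is None:
        duration = cfg.session_duration
    if duration <= 0:
        raise ValueError("duration must be > 0")
    objects = objects if objects is not None else default_objects()
    for obj in objects:
        if not obj.inside_arena(ARENA_CM):
            raise ValueError(f"object {obj.id!r} outside the arena")
    if biases is None:
        biases = tuple(1.0 for _ in objects)
    if len(biases) != len(objects) or any(b < 0 for b in biases):
        raise ValueError("need one non-negative bias per object")

    rng = _rng(cfg, seed)
    dt = 1.0 / cfg.frame_rate
    n_frames = int(round(duration * cfg.frame_rate))
    lx, ly = ARENA_CM

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    hs = np.empty(n_frames)
    px, py = lx / 2, ly / 2
    vx, vy = 0.0, 0.0
    heading = 0.0
    weights = np.asarray(list(biases) + [cfg.roam_weight], dtype=float)
    weights = weights / weights.sum()

    k = 0
    while k < n_frames:
        choice = rng.choice(len(weights), p=weights)
        if choice == len(objects):  # roam
            n_ep = max(int(rng.exponential(cfg.roam_mean_s) / dt), 1)
            for _ in range(min(n_ep, n_frames - k)):
                vx = 0.85 * vx + rng.normal(0.0, cfg.walk_speed_sd)
                vy = 0.85 * vy + rng.normal(0.0, cfg.walk_speed_sd)
                px += vx * dt
                py += vy * dt
                if px < 0.5 or px > lx - 0.5:
                    vx = -vx
                    px = min(max(px, 0.5), lx - 0.5)
                if py < 0.5 or py > ly - 0.5:
                    vy = -vy
                    py = min(max(py, 0.5), ly - 0.5)
                if abs(vx) > 1e-9 or abs(vy) > 1e-9:
                    heading = math.degrees(math.atan2(vy, vx))
                xs[k], ys[k], hs[k] = px, py, heading
                k += 1
                if k >= n_frames:
                    break
        else:
            obj = objects[choice]
            # approach until just outside the object edge
            while k < n_frames:
                dx, dy = obj.x - px, obj.y - py
                dist_edge = math.hypot(dx, dy) - obj.radius
                if dist_edge <= 0.8:
                    break
                ux, uy = dx / math.hypot(dx, dy), dy / math.hypot(dx, dy)
                px += (cfg.approach_speed * ux + rng.normal(0, 1.0)) * dt
                py += (cfg.approach_speed * uy + rng.normal(0, 1.0)) * dt
                heading = math.degrees(math.atan2(dy, dx))
                xs[k], ys[k], hs[k] = px, py, heading
                k += 1
            # dwell at the edge, sniffing toward the center
            n_dwell = max(int(rng.exponential(cfg.dwell_mean_s) / dt), 1)
            for _ in range(min(n_dwell, n_frames - k)):
                dx, dy = obj.x - px, obj.y - py
                d = math.hypot(dx, dy)
                # keep the head hovering ~1 cm outside the edge
                target_d = obj.radius + 1.0
                if d > 1e-9:
                    px = obj.x - dx / d * target_d + rng.normal(0, 0.15)
                    py = obj.y - dy / d * target_d + rng.normal(0, 0.15)
                heading = math.degrees(math.atan2(obj.y - py, obj.x - px)) \
                    + rng.normal(0, 8.0)
                xs[k], ys[k], hs[k] = px, py, heading
                k += 1
            vx, vy = 0.0, 0.0

    np.clip(xs, 0.0, lx, out=xs)
    np.clip(ys, 0.0, ly, out=ys)
    t = np.arange(n_frames) * dt
    return TrackingSession(t=t, x=xs, y=ys, heading=hs % 360.0,
                           frame_rate=cfg.frame_rate)


def gen_barnes_log(
    cfg: SynthConfig,
    errors: int | None = None,
    latency: float | None = None,
    enter: bool = True,
    escape_hole: int = 0,
    seed: int | None = None,
) -> BarnesLog:
    """Emit a Barnes-maze event log with a known score.

    Exactly ``errors`` non-entry hole visits are placed at random times
    before the entry event at ``latency`` (or before the trial cap when the
    animal never enters).
    """
    errors = cfg.barnes_errors if errors is None else errors
    latency = cfg.barnes_latency if latency is None else latency
    if errors < 0:
        raise ValueError("error count must be >= 0")
    if enter and latency > cfg.barnes_cap:
        raise ValueError("entry latency exceeds the trial cap")
    rng = _rng(cfg, seed)
    horizon = latency if enter else cfg.barnes_cap
    times = np.sort(rng.uniform(0.5, max(horizon - 0.5, 0.6), size=errors))
    times = np.unique(times)
    while times.size < errors:  # guard against duplicate draws
        extra = rng.uniform(0.5, max(horizon - 0.5, 0.6), size=errors - times.size)
        times = np.unique(np.concatenate([times, extra]))
    holes = rng.integers(0, 20, size=errors)
    events = [(float(t), int(h), False) for t, h in zip(times, holes)]
    if enter:
        events.append((float(latency), escape_hole, True))
    return BarnesLog(events=events, escape_hole=escape_hole,
                     trial_cap=cfg.barnes_cap)


# ---------------------------------------------------------------------------
# anatomy


def gen_axon_image(cfg: SynthConfig, seed: int | None = None):
    """One synthetic fluorescence slice: two axon bands + ROIs + profile.

    Returns ``(image, rois, profile)`` where ``rois`` maps layer labels to
    equal-area rectangular polygons inside the bands and ``profile`` is the
    pia-anchored ``(depth_um, intensity)`` line profile (column-averaged).
    The EC_L2/3 band (nearer the pia) is ``band_ratio`` times dimmer than
    the EC_L5 band.
    """
    rng = _rng(cfg, seed)
    n_rows, n_cols = cfg.image_shape
    if cfg.band_ratio <= 0:
        raise ValueError("band_ratio must be > 0")
    l23 = (40, 90)   # row extent of the superficial band
    l5 = (140, 190)  # row extent of the deep band (equal height)
    if l5[1] >= n_rows:
        raise ValueError("band geometry exceeds the image")
    image = np.zeros((n_rows, n_cols), dtype=float)
    image[l23[0]:l23[1], :] = cfg.band_intensity / cfg.band_ratio
    image[l5[0]:l5[1], :] = cfg.band_intensity
    if cfg.image_noise_sd > 0:
        image = image + rng.normal(0.0, cfg.image_noise_sd, size=image.shape)

    def rect(r0, r1):
        # equal-area rectangles inset from the band and image borders
        return np.array([
            [2.5, r0 + 2.5], [n_cols - 3.5, r0 + 2.5],
            [n_cols - 3.5, r1 - 3.5], [2.5, r1 - 3.5],
        ])

    rois = {"EC_L2/3": rect(*l23), "EC_L5": rect(*l5)}
    depth = np.arange(n_rows) * cfg.pixel_um
    profile = image.mean(axis=1)
    return image, rois, (depth, profile)


def gen_axon_stack(cfg: SynthConfig, seed: int | None = None) -> list:
    """A stack of ``cfg.n_slices`` slices with independent noise."""
    base = cfg.seed if seed is None else seed
    return [gen_axon_image(cfg, seed=base + 1000 * i) for i in range(cfg.n_slices)]


def gen_input_counts(cfg: SynthConfig, n_cells: int, seed: int | None = None) -> dict:
    """Multinomial presynaptic cell counts across input regions."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    regions = list(cfg.input_proportions)
    p = np.asarray([cfg.input_proportions[r] for r in regions], dtype=float)
    rng = _rng(cfg, seed)
    draws = rng.multinomial(n_cells, p)
    return {r: int(c) for r, c in zip(regions, draws)}
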