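"""Feature extraction from patch-clamp sweeps.

Implements the quantification conventions used throughout the slice
experiments: baseline-subtracted peak amplitudes (maximum for PSPs and
IPSCs, minimum for EPSCs, baseline averaged over the 100 ms before stimulus
onset), threshold-crossing spike detection, the 500-ms sustained-photocurrent
screen for functional opsin expression, LED input-output curves,
input-timing-dependent plasticity (ITDP) potentiation and spike probability
from the last ten sweeps of each epoch, per-cell excitation/inhibition
ratios, monosynaptic classification under TTX/4-AP, and connection
probability summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "StimulusEvent",
    "Sweep",
    "PeakMeasurement",
    "ITDPExperiment",
    "ITDPResult",
    "ConnectivityTable",
    "measure_peak_amplitude",
    "detect_spikes",
    "detect_sustained_photocurrent",
    "input_output_curve",
    "compute_itdp",
    "ei_ratio",
    "classify_monosynaptic",
    "summarize_connectivity",
]

#: default spike threshold (mV, absolute) and refractory period (s)
SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_S = 0.002


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: light pulse or electrical shock.

    ``onset``/``duration`` in seconds from sweep start; ``intensity`` as a
    percentage of maximum drive (LED power or stimulator current).
    """

    onset: float
    duration: float
    modality: str = "optical"  # optical | electrical
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if not 0 <= self.intensity <= 100:
            raise ValueError("intensity must be in [0, 100] %")
        if self.modality not in ("optical", "electrical"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class Sweep:
    """A single recorded sweep.

    ``samples`` are mV in current clamp and nA in voltage clamp, at a fixed
    ``sampling_interval`` (default 50 us).  ``holding`` is the holding
    potential in mV (-70 current clamp; -80 or +10 voltage clamp).
    """

    samples: np.ndarray
    stimulus: StimulusEvent
    sampling_interval: float = 50e-6
    clamp_mode: str = "current"  # current | voltage
    holding: float = -70.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.clamp_mode not in ("current", "voltage"):
            raise ValueError(f"unknown clamp_mode {self.clamp_mode!r}")
        if self.samples.size * self.sampling_interval <= self.stimulus.onset:
            raise ValueError("sweep must contain samples after stimulus onset")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval

    @property
    def duration(self) -> float:
        return self.samples.size * self.sampling_interval


@dataclass(frozen=True)
class PeakMeasurement:
    """Baseline-referenced peak of one sweep (amplitude is signed)."""

    baseline: float
    peak_value: float
    amplitude: float
    polarity: str
    peak_time: float


@dataclass
class ITDPExperiment:
    """Pre/post-induction sweep series for one pathway of one cell.

    Sweeps are acquired every 15 s; the induction (electrical sensory pulse
    followed 20 ms later by the optical hippocampal pulse, 90 repeats at
    1 Hz) is metadata only and sits between the two epochs.
    """

    pre_sweeps: list
    post_sweeps: list
    pathway: str = "sensory"  # sensory | hippocampal
    inter_sweep_interval: float = 15.0
    pairing_delay: float = 0.020
    pairing_repeats: int = 90
    pairing_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if len(self.pre_sweeps) < 10 or len(self.post_sweeps) < 10:
            raise ValueError(
                "ITDP estimators need >= 10 pre- and >= 10 post-induction sweeps"
            )


@dataclass(frozen=True)
class ITDPResult:
    """Potentiation fold and spike probabilities for one experiment."""

    potentiation_fold: float
    spike_probability_pre: float
    spike_probability_post: float
    baseline_amplitude: float
    n_subthreshold_post: int
    fold_defined: bool = True


@dataclass(frozen=True)
class ConnectivityTable:
    """Counts of responsive/spiking/monosynaptic cells per layer.

    ``counts[layer][category] = (count, n_tested)``; each category carries
    its own tested denominator because different cells enter each assay.
    """

    counts: dict  # layer -> {category -> (count, n_tested)}

    def __post_init__(self) -> None:
        for layer, cats in self.counts.items():
            for cat, (c, n) in cats.items():
                if n < 0 or c < 0 or c > n:
                    raise ValueError(
                        f"{layer}/{cat}: count {c} outside [0, tested={n}]"
                    )


def _window_slice(sweep: Sweep, start: float, stop: float) -> slice:
    i0 = int(round(start / sweep.sampling_interval))
    i1 = int(round(stop / sweep.sampling_interval))
    return slice(max(i0, 0), min(i1, sweep.samples.size))


def measure_peak_amplitude(
    sweep: Sweep,
    polarity: str = "max",
    baseline_window: float = 0.100,
    search_window: float = 0.100,
    smooth: float = 0.0,
) -> PeakMeasurement:
    """Baseline-subtracted peak amplitude of a stimulus-evoked response.

    The baseline is the mean over ``baseline_window`` seconds immediately
    before stimulus onset; the peak is the maximum (``polarity="max"``, for
    PSPs and IPSCs) or minimum (``"min"``, for EPSCs) within
    ``search_window`` seconds after onset.  ``smooth`` > 0 applies a boxcar
    of that width (seconds) before the extremum search, which suppresses the
    upward bias that point-wise noise adds to a raw extremum; it is off by
    default so that noise-free sweeps measure exactly.
    """
    if polarity not in ("max", "min"):
        raise ValueError("polarity must be 'max' or 'min'")
    onset = sweep.stimulus.onset
    if onset - baseline_window < -1e-12:
        raise ValueError(
            f"baseline window of {baseline_window} s extends before sweep start "
            f"(onset {onset} s)"
        )
    y = sweep.samples
    if smooth > 0:
        width = max(int(round(smooth / sweep.sampling_interval)), 1)
        y = uniform_filter1d(y, size=width, mode="nearest")

    base = float(np.mean(y[_window_slice(sweep, onset - baseline_window, onset)]))
    win = _window_slice(sweep, onset, onset + search_window)
    seg = y[win]
    if seg.size == 0:
        raise ValueError("search window contains no samples")
    idx = int(np.argmax(seg) if polarity == "max" else np.argmin(seg))
    peak = float(seg[idx])
    t_peak = (win.start + idx) * sweep.sampling_interval
    return PeakMeasurement(
        baseline=base,
        peak_value=peak,
        amplitude=peak - base,
        polarity=polarity,
        peak_time=t_peak,
    )


def detect_spikes(
    sweep: Sweep,
    threshold: float = SPIKE_THRESHOLD_MV,
    refractory: float = SPIKE_REFRACTORY_S,
) -> tuple[int, np.ndarray]:
    """Count action potentials as upward threshold crossings.

    Crossings closer than ``refractory`` seconds to the previous accepted
    spike are folded into it.  Only meaningful in current clamp.
    """
    if sweep.clamp_mode != "current":
        raise ValueError("spike detection requires a current-clamp sweep")
    y = sweep.samples
    above = y >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    times = []
    last = -math.inf
    for i in crossings:
        t = i * sweep.sampling_interval
        if t - last >= refractory:
            times.append(t)
            last = t
    times = np.asarray(times)
    return len(times), times


def detect_sustained_photocurrent(
    sweep: Sweep,
    pulse: StimulusEvent | None = None,
    threshold: float = 20.0,
    plateau_fraction: float = 0.5,
) -> bool:
    """Screen for functional opsin expression with a long light pulse.

    True iff the mean current over the final ``plateau_fraction`` of the
    pulse deviates from baseline by more than ``threshold`` (pA for sweeps
    in pA).  A brief synaptic transient decays before the plateau window and
    does not pass; a sustained somatic photocurrent does.
    """
    pulse = pulse or sweep.stimulus
    if pulse.duration < 0.100:
        raise ValueError("photocurrent screen needs a pulse of >= 100 ms")
    if pulse.onset + pulse.duration > sweep.duration + 1e-12:
        raise ValueError("light pulse extends beyond the sweep")
    base_start = max(pulse.onset - 0.100, 0.0)
    base = float(np.mean(sweep.samples[_window_slice(sweep, base_start, pulse.onset)]))
    t0 = pulse.onset + (1.0 - plateau_fraction) * pulse.duration
    plateau = sweep.samples[_window_slice(sweep, t0, pulse.onset + pulse.duration)]
    return bool(abs(float(np.mean(plateau)) - base) > threshold)


def input_output_curve(
    sweeps: list,
    polarity: str = "max",
    **peak_kwargs,
) -> pd.DataFrame:
    """Mean +/- SEM response amplitude per stimulus intensity.

    Sweeps are grouped by ``stimulus.intensity``; rows are sorted by
    ascending intensity.  SEM is 0 for singleton groups.
    """
    if not sweeps:
        raise ValueError("input_output_curve needs at least one sweep")
    rows = []
    for sw in sweeps:
        m = measure_peak_amplitude(sw, polarity=polarity, **peak_kwargs)
        rows.append({"intensity": sw.stimulus.intensity, "amplitude": m.amplitude})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("intensity")["amplitude"]
        .agg(n="size", mean_amplitude="mean", sem_amplitude=lambda a: a.sem(ddof=1))
        .reset_index()
        .sort_values("intensity", ignore_index=True)
    )
    out["sem_amplitude"] = out["sem_amplitude"].fillna(0.0)
    return out


def _sweep_spikes(sweep: Sweep, threshold: float, refractory: float) -> bool:
    n, _ = detect_spikes(sweep, threshold=threshold, refractory=refractory)
    return n > 0


def compute_itdp(
    exp: ITDPExperiment,
    spike_threshold: float = SPIKE_THRESHOLD_MV,
    refractory: float = SPIKE_REFRACTORY_S,
    smooth: float = 0.002,
    n_points: int = 10,
    **peak_kwargs,
) -> ITDPResult:
    """Potentiation fold and spike probabilities for one pathway.

    The pre-induction steady state is the mean amplitude of the last
    ``n_points`` pre-induction sweeps; potentiation is the mean of the
    sub-threshold amplitudes among the last ``n_points`` post-induction
    sweeps normalised to it.  Spike probability is the spiking fraction of
    the same last-``n_points`` window of each epoch.  If every late post
    sweep spikes the fold is undefined and flagged.
    """
    pre = exp.pre_sweeps[-n_points:]
    post = exp.post_sweeps[-n_points:]

    pre_spiking = [_sweep_spikes(s, spike_threshold, refractory) for s in pre]
    post_spiking = [_sweep_spikes(s, spike_threshold, refractory) for s in post]

    pre_amp = [
        measure_peak_amplitude(s, polarity="max", smooth=smooth, **peak_kwargs).amplitude
        for s, spk in zip(pre, pre_spiking)
        if not spk
    ]
    if not pre_amp:
        raise ValueError("all late pre-induction sweeps spike; no baseline amplitude")
    denom = float(np.mean(pre_amp))
    if denom == 0:
        raise ValueError("pre-induction steady-state amplitude is zero")

    post_amp = [
        measure_peak_amplitude(s, polarity="max", smooth=smooth, **peak_kwargs).amplitude
        for s, spk in zip(post, post_spiking)
        if not spk
    ]
    if post_amp:
        fold = float(np.mean(post_amp)) / denom
        defined = True
    else:
        fold = math.nan
        defined = False

    return ITDPResult(
        potentiation_fold=fold,
        spike_probability_pre=sum(pre_spiking) / len(pre),
        spike_probability_post=sum(post_spiking) / len(post),
        baseline_amplitude=denom,
        n_subthreshold_post=len(post_amp),
        fold_defined=defined,
    )


def ei_ratio(epsc_amplitude: float, ipsc_amplitude: float) -> float:
    """Per-cell excitation/inhibition ratio |EPSC| / |IPSC|.

    Cohort-level E/I is the mean of per-cell ratios, not the ratio of
    cohort-mean amplitudes.
    """
    if ipsc_amplitude == 0:
        raise ZeroDivisionError("IPSC amplitude is zero; E/I undefined")
    return abs(epsc_amplitude) / abs(ipsc_amplitude)


def classify_monosynaptic(
    response: PeakMeasurement,
    noise_sd: float,
    k: float = 3.0,
) -> bool:
    """Monosynaptic iff the TTX/4-AP response exceeds ``k`` noise SDs.

    Under TTX + 4-AP, polysynaptic transmission is abolished; a response
    that persists above the noise floor (strict ``|amplitude| > k * sd``)
    marks a direct connection.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return bool(abs(response.amplitude) > k * noise_sd)


def summarize_connectivity(table: ConnectivityTable) -> pd.DataFrame:
    """Percentages (2 decimals) of each response category per layer."""
    rows = []
    for layer, cats in table.counts.items():
        for cat, (c, n) in cats.items():
            if n == 0:
                raise ValueError(f"{layer}/{cat}: cannot summarize 0 tested cells")
            rows.append(
                {
                    "layer": layer,
                    "category": cat,
                    "count": c,
                    "n_tested": n,
                    "percent": round(100.0 * c / n, 2),
                }
            )
    return pd.DataFrame(rows)
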