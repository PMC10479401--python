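"""Rate-based model of the EC_L2/3 <-> hippocampus feedback loop.

Two sensory channels project with weights ``w`` onto a read-out neuron in
entorhinal cortex layer 2/3 whose rate is ``ro = w . s``.  The hippocampal
rate ``h`` sits at a baseline and, when the full loop is intact, additionally
receives the read-out through a fixed feedback weight.  Each pairing of a
sensory channel with the hippocampal feedback potentiates that channel's
weight by a Hebbian increment ``alpha * h * s`` (the feedback weight itself
does not undergo plasticity).

Three regimes are supported:

* severed loop ("slice" condition): ``h`` stays at baseline, so the paired
  weight grows linearly and reaches 1.5-fold after 100 pairings with the
  default learning rate;
* intact loop: the read-out feeds back onto ``h``, potentiation compounds,
  and the same 100 pairings yield a ~2.29-fold weight boost;
* silenced hippocampus: ``h = 0`` and no potentiation occurs.

``closed_form_final_weight`` provides an analytic oracle for all three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoopParams",
    "CircuitState",
    "SimulationTrace",
    "constant_schedule",
    "update_step",
    "simulate_pairings",
    "closed_form_final_weight",
]


@dataclass(frozen=True)
class LoopParams:
    """Parameters of the feedback-loop plasticity model.

    Parameters
    ----------
    alpha
        Hebbian learning rate (unitless).
    n_pairings
        Number of sensory/feedback pairing steps.
    w_init
        Initial weight per sensory channel.
    h_init
        Baseline hippocampal rate.
    feedback_weight
        Fixed synaptic weight of the read-out -> hippocampus projection
        (only effective when ``loop_intact``).
    loop_intact
        If True the full cortico-hippocampal loop operates (in vivo
        condition); if False the read-out -> hippocampus axons are severed
        (acute-slice condition).
    hc_silenced
        If True the hippocampal rate is clamped to zero (optogenetic
        silencing), abolishing plasticity.
    seed
        Reserved for stochastic extensions; the model itself is
        deterministic.
    """

    alpha: float = 0.005
    n_pairings: int = 100
    w_init: tuple[float, ...] = (1.0, 1.0)
    h_init: float = 1.0
    feedback_weight: float = 1.0
    loop_intact: bool = False
    hc_silenced: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_pairings < 0:
            raise ValueError("n_pairings must be >= 0")
        if self.feedback_weight < 0:
            raise ValueError("feedback_weight must be >= 0")
        if any(w < 0 for w in self.w_init):
            raise ValueError("initial weights must be >= 0")


@dataclass
class CircuitState:
    """Instantaneous model state: weights, hippocampal rate, read-out rate."""

    w: np.ndarray
    h: float
    ro: float


@dataclass
class SimulationTrace:
    """Per-step history of a pairing simulation (includes the initial state)."""

    w: np.ndarray          # (n_pairings + 1, n_channels)
    h: np.ndarray          # (n_pairings + 1,)
    ro: np.ndarray         # (n_pairings + 1,)
    fold_change: np.ndarray  # final weight / initial weight per channel

    def to_frame(self):
        """Trace as a tidy DataFrame with one row per step."""
        import pandas as pd

        n_ch = self.w.shape[1]
        data = {"step": np.arange(self.w.shape[0])}
        for i in range(n_ch):
            data[f"w{i + 1}"] = self.w[:, i]
        data["h"] = self.h
        data["ro"] = self.ro
        return pd.DataFrame(data)


def constant_schedule(n_pairings: int, s: tuple[int, ...] = (1, 0)) -> np.ndarray:
    """Stimulus schedule repeating the same binary pattern every step."""
    sched = np.tile(np.asarray(s, dtype=float), (n_pairings, 1))
    return sched


def _validate_stimulus(s: np.ndarray, n_channels: int) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (n_channels,):
        raise ValueError(
            f"stimulus has {s.shape} entries, expected ({n_channels},)"
        )
    if not np.all(np.isin(s, (0.0, 1.0))):
        raise ValueError("stimulus entries must be binary (0 or 1)")
    return s


def _hippocampal_rate(ro: float, params: LoopParams) -> float:
    if params.hc_silenced:
        return 0.0
    if params.loop_intact:
        return params.h_init + params.feedback_weight * ro
    return params.h_init


def update_step(state: CircuitState, s, params: LoopParams) -> CircuitState:
    """One pairing step: read-out, hippocampal rate, then weight update.

    The read-out is computed from the incoming weights, the hippocampal rate
    from that read-out (baseline only if the loop is severed, zero if
    silenced), and the weights are then incremented by ``alpha * h * s``.
    Channels with ``s == 0`` are untouched.
    """
    s = _validate_stimulus(s, state.w.shape[0])
    ro = float(state.w @ s)
    h = _hippocampal_rate(ro, params)
    w_new = state.w + params.alpha * h * s
    return CircuitState(w=w_new, h=h, ro=ro)


def simulate_pairings(params: LoopParams, schedule=None) -> SimulationTrace:
    """Run ``n_pairings`` update steps and record the full trajectory.

    ``schedule`` is an (n_pairings, n_channels) binary array; by default
    channel 1 is paired on every step and all other channels stay off, the
    protocol used for both the slice-like and the intact-loop condition.
    """
    n_ch = len(params.w_init)
    if schedule is None:
        schedule = constant_schedule(params.n_pairings, (1,) + (0,) * (n_ch - 1))
    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 2 or schedule.shape != (params.n_pairings, n_ch):
        raise ValueError(
            f"schedule shape {schedule.shape} does not match "
            f"(n_pairings={params.n_pairings}, n_channels={n_ch})"
        )

    w0 = np.asarray(params.w_init, dtype=float)
    h0 = 0.0 if params.hc_silenced else params.h_init
    state = CircuitState(w=w0.copy(), h=h0, ro=0.0)
    w_hist = np.empty((params.n_pairings + 1, n_ch))
    h_hist = np.empty(params.n_pairings + 1)
    ro_hist = np.empty(params.n_pairings + 1)
    w_hist[0] = state.w
    h_hist[0] = state.h
    ro_hist[0] = state.ro

    for k in range(params.n_pairings):
        state = update_step(state, schedule[k], params)
        w_hist[k + 1] = state.w
        h_hist[k + 1] = state.h
        ro_hist[k + 1] = state.ro

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(w0 > 0, w_hist[-1] / w0, np.nan)
    return SimulationTrace(w=w_hist, h=h_hist, ro=ro_hist, fold_change=fold)


def closed_form_final_weight(params: LoopParams) -> float:
    """Analytic final weight of the paired channel under constant s1 = 1.

    Silenced: ``w0`` (no update).  Severed loop: ``w0 + N * alpha * h_init``
    (linear growth).  Intact loop with feedback weight ``g > 0``: the update
    ``w <- w (1 + alpha g) + alpha h_init`` is affine, giving

        w_N = (w0 + h_init / g) * (1 + alpha g)^N  -  h_init / g.

    With the defaults this is ``2 * 1.005^100 - 1 ~= 2.2933``.
    """
    w0 = float(params.w_init[0])
    n = params.n_pairings
    if params.hc_silenced:
        return w0
    if not params.loop_intact:
        return w0 + n * params.alpha * params.h_init
    g = params.feedback_weight
    if g == 0:
        # intact loop but no feedback drive: degenerates to the severed case
        return w0 + n * params.alpha * params.h_init
    r = 1.0 + params.alpha * g
    c = params.h_init / g
    return (w0 + c) * r**n - c
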