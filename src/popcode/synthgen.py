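"""Synthetic calcium-imaging sessions with planted ground truth.

Emulates the statistical structure the downstream analyses assume: sparse
binary event rasters (~80 neurons, 10^4-10^5 frames at 20 Hz), an epoch
structure of interleaved social bouts (or home-cage/maze blocks with
Markov-chain arm occupancy), per-neuron multiplicative modulation gains
(positive and negative), optional slow drift of baseline rates, and
optional cross-context remapping of the social ensemble.

Events are independent Bernoulli draws per neuron per frame with rate

    rate[i, t] = baseline_rate * social_gain * context_gain * arm_gain * drift

(each gain applied only on the frames where its condition holds, clipped at
0.95 to avoid saturation).  Traces are built by convolving events with an
instant-rise, single-exponential-decay kernel plus white noise, giving the
event detector a realistic GCaMP-like target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import CalciumTraces, EventRaster, SessionAnnotation

__all__ = [
    "Bout",
    "EpochPlan",
    "SessionSpec",
    "TruthConfig",
    "GroundTruth",
    "SyntheticSession",
    "make_social_epoch_plan",
    "make_maze_epoch_plan",
    "default_social_spec",
    "default_maze_spec",
    "draw_ground_truth",
    "generate_session",
    "generate_maze_session",
    "MAZE_ARMS",
]

RATE_CLIP = 0.95

#: Arm vocabularies per maze.  The elevated zero maze distinguishes travel
#: direction (clockwise / counter-clockwise) in addition to open vs closed
#: quadrants; the elevated plus maze has open vs closed arms; the T-maze is
#: fully enclosed with long vs short arms.
MAZE_ARMS: dict[str, tuple[str, ...]] = {
    "EZM": ("open_CW", "open_CCW", "closed_CW", "closed_CCW"),
    "EPM": ("open", "closed"),
    "TM": ("long", "short"),
}


@dataclass(frozen=True)
class Bout:
    """A labelled behavioural interval, frames relative to epoch start."""

    behavior_label: str
    start: int
    end: int  # half-open


@dataclass(frozen=True)
class EpochPlan:
    epoch_id: str
    context_id: str
    duration_frames: int
    bout_plan: tuple[Bout, ...] = ()
    maze: str | None = None  # EZM / EPM / TM for maze epochs

    def __post_init__(self):
        if self.duration_frames <= 0:
            raise ValueError(f"epoch {self.epoch_id}: duration must be > 0")
        prev_end = None
        for b in sorted(self.bout_plan, key=lambda b: b.start):
            if not (0 <= b.start < b.end <= self.duration_frames):
                raise ValueError(
                    f"epoch {self.epoch_id}: bout {b} outside [0, {self.duration_frames})"
                )
            if prev_end is not None and b.start < prev_end:
                raise ValueError(f"epoch {self.epoch_id}: overlapping bouts")
            prev_end = b.end


@dataclass
class SessionSpec:
    """Generator configuration for one synthetic session."""

    n_neurons: int = 80
    frame_rate: float = 20.0
    epoch_plan: tuple[EpochPlan, ...] = ()
    baseline_rate: float = 0.01  # per-frame event probability
    noise_sd: float = 0.05  # dF/F units
    transient_tau: float = 0.5  # seconds, decay constant
    transient_amp_range: tuple[float, float] = (4.0, 8.0)  # multiples of noise_sd
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must lie in (0, 1)")
        if self.transient_amp_range[0] > self.transient_amp_range[1]:
            raise ValueError("transient_amp_range must be (lo, hi) with lo <= hi")
        ids = [e.epoch_id for e in self.epoch_plan]
        if len(ids) != len(set(ids)):
            raise ValueError("epoch ids must be unique")

    @property
    def n_frames(self) -> int:
        return sum(e.duration_frames for e in self.epoch_plan)


@dataclass
class TruthConfig:
    """How to draw planted per-neuron modulation gains.

    ``social_frac_pos`` / ``social_frac_neg`` neurons get the multiplicative
    social gains below; likewise for context gains (applied in every context
    other than the first).  With ``remap`` on, the social ensemble is redrawn
    independently per context; off, the same neurons carry the same social
    gain everywhere.  ``independent_context`` draws the context ensemble
    independently of the social one (orthogonal plant); off, the context
    ensemble reuses the social neurons with matching gain sign (correlated
    plant).  Drift, when positive, is a per-neuron geometric ramp of the
    baseline rate.
    """

    social_frac_pos: float = 0.1
    social_frac_neg: float = 0.1
    social_gain_pos: float = 2.0
    social_gain_neg: float = 0.5
    context_frac_pos: float = 0.1
    context_frac_neg: float = 0.1
    context_gain_pos: float = 2.0
    context_gain_neg: float = 0.5
    arm_gains: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    # arm label -> (frac_modulated, gain_pos, gain_neg); half the drawn
    # neurons get gain_pos, half gain_neg; each label draws independently
    arm_groups: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    # substring -> (frac, gain_pos, gain_neg): ONE shared ensemble applied to
    # every arm label containing the substring (e.g. "open" plants the same
    # anxiety ensemble in the EZM and EPM open arms)
    remap: bool = False
    independent_context: bool = True
    drift_rate: float = 0.0  # per-frame log-multiplier sd 0 => off

    def __post_init__(self):
        for g in (
            self.social_gain_pos,
            self.social_gain_neg,
            self.context_gain_pos,
            self.context_gain_neg,
        ):
            if g <= 0:
                raise ValueError("gains must be > 0")


@dataclass
class GroundTruth:
    """Planted per-neuron gains and remapping flags for one session."""

    social_gain: dict[str, np.ndarray]  # context_id -> (n_neurons,)
    context_gain: dict[str, np.ndarray]  # context_id -> (n_neurons,)
    arm_gain: dict[str, np.ndarray]  # arm_label -> (n_neurons,)
    remap: bool
    drift: np.ndarray  # (n_neurons,) per-frame geometric ramp (1.0 => none)

    def social_labels(self, context_id: str) -> np.ndarray:
        """+1 / -1 / 0 planted social modulation per neuron."""
        g = self.social_gain[context_id]
        return np.sign(np.log(g)).astype(int)

    def context_labels(self, context_id: str) -> np.ndarray:
        g = self.context_gain[context_id]
        return np.sign(np.log(g)).astype(int)


@dataclass
class SyntheticSession:
    traces: CalciumTraces
    raster: EventRaster
    annotation: SessionAnnotation
    truth: GroundTruth
    spec: SessionSpec | None = None
    true_onsets: list[np.ndarray] | None = None  # per-neuron event frames

    def __post_init__(self):
        if self.traces.values.shape != self.raster.values.shape:
            raise ValueError("traces and raster must share shape")
        self.annotation.check_length(self.raster.n_frames)


# --------------------------------------------------------------------------
# epoch-plan builders
# --------------------------------------------------------------------------

def make_social_epoch_plan(
    contexts: Sequence[str] = ("ctx1", "ctx1", "ctx2", "ctx2"),
    pre_frames: int = 6000,
    n_bouts: int = 10,
    bout_frames: int = 600,
    gap_frames: int = 300,
    baseline_frames: int = 6000,
) -> tuple[EpochPlan, ...]:
    """Four social epochs (A-D) with interleaved bouts.

    Each epoch starts with ``pre_frames`` alone frames (the window preceding
    introduction of the conspecific), then alternates social bouts with
    conspecific-present gaps.  Extra baseline blocks precede the first and
    third epoch, mirroring the recordings taken before each pair of
    interactions.  Pass ``contexts`` with a single repeated id for a
    static-context day, or two ids for a dynamic day (A&B vs C&D).
    """
    if len(contexts) != 4:
        raise ValueError("expected one context per epoch A-D")
    plans: list[EpochPlan] = []
    epoch_ids = ("A", "B", "C", "D")
    for k, (eid, ctx) in enumerate(zip(epoch_ids, contexts)):
        if baseline_frames > 0 and k in (0, 2):
            plans.append(
                EpochPlan(f"base{1 + k // 2}", ctx, baseline_frames, ())
            )
        bouts: list[Bout] = []
        t = pre_frames
        for b in range(n_bouts):
            bouts.append(Bout("social", t, t + bout_frames))
            t += bout_frames
            if b < n_bouts - 1:
                bouts.append(Bout("present", t, t + gap_frames))
                t += gap_frames
        plans.append(EpochPlan(eid, ctx, t, tuple(bouts)))
    return tuple(plans)


def make_maze_epoch_plan(
    hc_frames: int = 12000,
    maze_frames: int = 12000,
    mazes: Sequence[str] = ("EZM", "EPM", "TM"),
) -> tuple[EpochPlan, ...]:
    """Home-cage / maze block layout: HC before and after each maze."""
    plans: list[EpochPlan] = []
    hc = 0
    for m in mazes:
        if m not in MAZE_ARMS:
            raise ValueError(f"unknown maze {m!r}; expected one of {sorted(MAZE_ARMS)}")
        hc += 1
        plans.append(EpochPlan(f"HC{hc}", "HC", hc_frames, ()))
        plans.append(EpochPlan(m, m, maze_frames, (), maze=m))
        hc += 1
        plans.append(EpochPlan(f"HC{hc}", "HC", hc_frames, ()))
    return tuple(plans)


_SOCIAL_PLAN_KEYS = ("pre_frames", "n_bouts", "bout_frames", "gap_frames", "baseline_frames")
_MAZE_PLAN_KEYS = ("hc_frames", "maze_frames", "mazes")


def default_social_spec(seed: int = 0, dynamic: bool = True, **kwargs) -> SessionSpec:
    """Paper-scale social session: 80 neurons, 20 Hz, four epochs with
    5-minute social interaction per epoch.  Plan-shaping keywords
    (``pre_frames``, ``n_bouts``, ...) are forwarded to
    :func:`make_social_epoch_plan`; the rest go to :class:`SessionSpec`."""
    contexts = ("ctx1", "ctx1", "ctx2", "ctx2") if dynamic else ("ctx1",) * 4
    plan_kw = {k: kwargs.pop(k) for k in _SOCIAL_PLAN_KEYS if k in kwargs}
    plan = make_social_epoch_plan(contexts=contexts, **plan_kw)
    return SessionSpec(epoch_plan=plan, seed=seed, **kwargs)


def default_maze_spec(seed: int = 0, **kwargs) -> SessionSpec:
    plan_kw = {k: kwargs.pop(k) for k in _MAZE_PLAN_KEYS if k in kwargs}
    return SessionSpec(epoch_plan=make_maze_epoch_plan(**plan_kw), seed=seed, **kwargs)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def _draw_signed_gains(
    n: int, frac_pos: float, frac_neg: float, gain_pos: float, gain_neg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    gains = np.ones(n)
    n_pos = int(round(frac_pos * n))
    n_neg = int(round(frac_neg * n))
    idx = rng.permutation(n)[: n_pos + n_neg]
    gains[idx[:n_pos]] = gain_pos
    gains[idx[n_pos:]] = gain_neg
    return gains


def draw_ground_truth(
    config: TruthConfig,
    n_neurons: int,
    contexts: Sequence[str],
    arms: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw planted gains for one session.

    Context gains are 1 in the first (reference) context and take the
    configured values in every other context; social gains are shared across
    contexts unless ``remap`` is set, in which case they are redrawn per
    context.
    """
    rng = np.random.default_rng(rng)
    contexts = list(dict.fromkeys(contexts))
    base_social = _draw_signed_gains(
        n_neurons, config.social_frac_pos, config.social_frac_neg,
        config.social_gain_pos, config.social_gain_neg, rng,
    )
    social = {}
    for ctx in contexts:
        if config.remap:
            social[ctx] = _draw_signed_gains(
                n_neurons, config.social_frac_pos, config.social_frac_neg,
                config.social_gain_pos, config.social_gain_neg, rng,
            )
        else:
            social[ctx] = base_social.copy()
    context_gain = {contexts[0]: np.ones(n_neurons)}
    for ctx in contexts[1:]:
        if config.independent_context:
            context_gain[ctx] = _draw_signed_gains(
                n_neurons, config.context_frac_pos, config.context_frac_neg,
                config.context_gain_pos, config.context_gain_neg, rng,
            )
        else:
            # correlated plant: context ensemble = social ensemble, with the
            # context modulation sign (first-context-minus-later convention)
            # matching the social modulation sign: socially up-modulated
            # neurons are *less* active in later contexts and vice versa
            g = np.ones(n_neurons)
            g[base_social > 1] = config.context_gain_neg
            g[base_social < 1] = config.context_gain_pos
            context_gain[ctx] = g
    group_gain = {
        key: _draw_signed_gains(n_neurons, frac / 2, frac / 2, gp, gn, rng)
        for key, (frac, gp, gn) in config.arm_groups.items()
    }
    arm_gain = {}
    for arm in arms:
        g = np.ones(n_neurons)
        if arm in config.arm_gains:
            frac, gp, gn = config.arm_gains[arm]
            g = g * _draw_signed_gains(n_neurons, frac / 2, frac / 2, gp, gn, rng)
        for key, shared in group_gain.items():
            if key in arm:
                g = g * shared
        arm_gain[arm] = g
    if config.drift_rate > 0:
        drift = np.exp(rng.normal(0.0, config.drift_rate, size=n_neurons))
    else:
        drift = np.ones(n_neurons)
    return GroundTruth(social, context_gain, arm_gain, config.remap, drift)


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

def _build_annotation(
    spec: SessionSpec, rng: np.random.Generator, arm_dwell_frames: float,
    arm_transition: Mapping[str, Mapping[str, float]] | None,
) -> SessionAnnotation:
    rows_epoch, rows_ctx, rows_beh, rows_arm = [], [], [], []
    for ep in spec.epoch_plan:
        n = ep.duration_frames
        beh = np.full(n, "alone", dtype=object)
        for b in ep.bout_plan:
            beh[b.start : b.end] = b.behavior_label
        arm = np.full(n, "", dtype=object)
        if ep.maze is not None:
            arm[:] = _markov_arms(
                MAZE_ARMS[ep.maze], n, arm_dwell_frames, arm_transition, rng
            )
            beh[:] = "explore"
        rows_epoch.append(np.full(n, ep.epoch_id, dtype=object))
        rows_ctx.append(np.full(n, ep.context_id, dtype=object))
        rows_beh.append(beh)
        rows_arm.append(arm)
    frame = pd.DataFrame(
        {
            "epoch_id": np.concatenate(rows_epoch),
            "context_id": np.concatenate(rows_ctx),
            "behavior_label": np.concatenate(rows_beh),
            "arm_label": np.concatenate(rows_arm),
        }
    )
    return SessionAnnotation(frame)


def _markov_arms(
    arms: Sequence[str], n_frames: int, dwell_frames: float,
    transition: Mapping[str, Mapping[str, float]] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov chain over arm labels with geometric dwell times."""
    k = len(arms)
    stay = 1.0 - 1.0 / max(dwell_frames, 1.0)
    if transition is None:
        P = np.full((k, k), (1.0 - stay) / (k - 1)) if k > 1 else np.ones((1, 1))
        np.fill_diagonal(P, stay if k > 1 else 1.0)
    else:
        P = np.array([[transition[a].get(b, 0.0) for b in arms] for a in arms])
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("arm transition rows must sum to 1")
    state = rng.integers(k)
    out = np.empty(n_frames, dtype=object)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_frames)
    for t in range(n_frames):
        out[t] = arms[state]
        state = int(np.searchsorted(cum[state], u[t]))
    return out


def _effective_rates(
    spec: SessionSpec, annotation: SessionAnnotation, truth: GroundTruth
) -> np.ndarray:
    """Per-neuron per-frame Bernoulli rates after all gains, clipped."""
    n, T = spec.n_neurons, annotation.n_frames
    rates = np.full((n, T), spec.baseline_rate)
    beh = annotation.frame["behavior_label"].to_numpy()
    ctx = annotation.frame["context_id"].to_numpy()
    arm = annotation.frame["arm_label"].to_numpy()
    social = beh == "social"
    for c in annotation.context_ids:
        in_ctx = ctx == c
        if c in truth.context_gain:
            rates[:, in_ctx] *= truth.context_gain[c][:, None]
        sg = truth.social_gain.get(c)
        if sg is not None:
            m = in_ctx & social
            if m.any():
                rates[:, m] *= sg[:, None]
    for a, g in truth.arm_gain.items():
        m = arm == a
        if m.any():
            rates[:, m] *= g[:, None]
    if not np.allclose(truth.drift, 1.0):
        t = np.arange(T)
        rates *= np.power(truth.drift[:, None], t[None, :] / T)
    if (rates > RATE_CLIP).any():
        warnings.warn(
            f"effective event rates exceeded {RATE_CLIP}; clipping", RuntimeWarning
        )
        rates = np.clip(rates, 0.0, RATE_CLIP)
    return rates


def _events_to_traces(
    events: np.ndarray, spec: SessionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Convolve events with an instant-rise exponential-decay kernel."""
    tau_frames = spec.transient_tau * spec.frame_rate
    kernel = np.exp(-np.arange(int(np.ceil(5 * tau_frames)) + 1) / tau_frames)
    lo, hi = spec.transient_amp_range
    amps = rng.uniform(lo, hi, size=events.shape) * spec.noise_sd * events
    traces = fftconvolve(amps, kernel[None, :], axes=1)[:, : events.shape[1]]
    traces += rng.normal(0.0, spec.noise_sd, size=events.shape)
    return traces


def generate_session(
    spec: SessionSpec,
    truth_params: TruthConfig | GroundTruth | None = None,
    *,
    arm_dwell_frames: float = 40.0,
    arm_transition: Mapping[str, Mapping[str, float]] | None = None,
) -> SyntheticSession:
    """Generate one synthetic session (events, traces, annotation, truth).

    Identical ``spec.seed`` gives a bit-identical session.
    """
    if not spec.epoch_plan:
        raise ValueError("epoch_plan is empty")
    if not any(ep.bout_plan or ep.maze for ep in spec.epoch_plan):
        raise ValueError("no epoch carries a bout plan or maze; nothing to analyse")
    rng = np.random.default_rng(spec.seed)
    ann_rng, truth_rng, ev_rng, tr_rng = rng.spawn(4)
    annotation = _build_annotation(spec, ann_rng, arm_dwell_frames, arm_transition)
    arms = annotation.arm_labels()
    if truth_params is None:
        truth_params = TruthConfig()
    if isinstance(truth_params, GroundTruth):
        truth = truth_params
    else:
        truth = draw_ground_truth(
            truth_params, spec.n_neurons, annotation.context_ids, arms, truth_rng
        )
    rates = _effective_rates(spec, annotation, truth)
    events = (ev_rng.random(rates.shape) < rates).astype(np.uint8)
    traces = _events_to_traces(events, spec, tr_rng)
    onsets = [np.flatnonzero(events[i]) for i in range(spec.n_neurons)]
    return SyntheticSession(
        traces=CalciumTraces(traces, spec.frame_rate),
        raster=EventRaster(events, spec.frame_rate),
        annotation=annotation,
        truth=truth,
        spec=spec,
        true_onsets=onsets,
    )


def generate_maze_session(
    spec: SessionSpec,
    truth_params: TruthConfig | GroundTruth | None = None,
    **kwargs,
) -> SyntheticSession:
    """Generate a home-cage / maze session with Markov-chain arm occupancy."""
    if not any(ep.maze for ep in spec.epoch_plan):
        raise ValueError("maze session requires at least one maze epoch")
    for ep in spec.epoch_plan:
        if ep.maze is not None and ep.maze not in MAZE_ARMS:
            raise ValueError(f"unknown maze {ep.maze!r}")
    return generate_session(spec, truth_params, **kwargs)
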