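"""Synthetic coupled-dyad generator.

Each subject is a two-state (move/freeze) chain stepped frame by frame with
time-varying switch hazards.  The CS onset raises the freeze-onset hazard
sharply and then lets it relax toward a lower asymptote, which produces the
characteristic cohort dynamic: freezing probability rises within a few
seconds of CS onset and then declines slowly.  Bouts are kept at least
``min_bout_frames`` long by a refractory rule — the freeze-offset hazard is
suppressed until a bout has reached the minimum length, and onsets too close
to the session end to complete a minimal bout are suppressed — rather than by
post-hoc merging, which would distort the coupling dynamics under study.

Dyadic coupling is hazard-multiplicative, with ``gamma = 0`` neutral:

* **follow** (``gamma_follow``): while the dyad is incongruent, each mouse's
  hazard of switching *toward* its partner's state is multiplied by
  ``1 + gamma_follow``.
* **retroact** (``gamma_retroact_freeze`` / ``gamma_retroact_move``): for
  ``retroact_memory_s`` seconds after a mouse breaks a congruent state and
  while the partner has not followed, the breaker's hazard of reversing its
  own switch is multiplied by ``1 + gamma``; the ``freeze`` variant applies
  to breaks of joint freezing, the ``move`` variant to breaks of joint
  moving.

``buffering_shift`` emulates fear buffering/equalization by shrinking the two
partners' individual freeze-onset rate multipliers toward their common mean.
A playback mode replays a fixed ethogram as one member (the robot-ball
control): the scripted member never couples to the subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ethogram import BinaryTrace, Ethogram, SessionLayout, ethogram_from_trace
from .synchrony import Dyad

__all__ = [
    "SimConfig",
    "simulate_dyad",
    "simulate_cohort",
    "playback_partner",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the standard session.

    Hazards are per-frame switch probabilities.  Defaults were chosen once so
    that a default cohort's mean CS freezing falls in the 30–70% band and its
    mean freezing-probability trace peaks within ~5 s of CS onset.
    """

    layout: SessionLayout = field(default_factory=SessionLayout)
    pre_cs_on: float = 0.005
    pre_cs_off: float = 0.30
    cs_on_peak: float = 0.35
    cs_on_floor: float = 0.02
    cs_on_decay_s: float = 20.0
    cs_off: float = 0.06
    gamma_follow: float = 0.0
    gamma_retroact_freeze: float = 0.0
    gamma_retroact_move: float = 0.0
    retroact_memory_s: float = 1.0
    buffering_shift: float = 0.0
    freeze_rate_sigma: float = 0.4
    min_bout_frames: int = 4

    def __post_init__(self) -> None:
        for name in ("pre_cs_on", "pre_cs_off", "cs_on_peak", "cs_on_floor", "cs_off"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"hazard {name}={v} outside [0, 1]")
        for name in ("gamma_follow", "gamma_retroact_freeze", "gamma_retroact_move"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.retroact_memory_s * self.layout.fps < 1:
            raise ValueError("retroact memory must span at least one frame")
        if not (0.0 <= self.buffering_shift <= 1.0):
            raise ValueError("buffering_shift must lie in [0, 1]")
        if self.min_bout_frames < 1:
            raise ValueError("min_bout_frames must be >= 1")

    @property
    def memory_frames(self) -> int:
        return int(round(self.retroact_memory_s * self.layout.fps))

    def onset_hazard(self) -> np.ndarray:
        """Per-frame baseline freeze-onset hazard over the whole session."""
        lay = self.layout
        h = np.full(lay.n_frames, self.pre_cs_on, dtype=float)
        t = np.arange(lay.cs_frames, dtype=float)
        decay = self.cs_on_decay_s * lay.fps
        h[lay.pre_cs_frames :] = self.cs_on_floor + (
            self.cs_on_peak - self.cs_on_floor
        ) * np.exp(-t / decay)
        return h

    def offset_hazard(self) -> np.ndarray:
        """Per-frame baseline freeze-offset hazard over the whole session."""
        lay = self.layout
        h = np.full(lay.n_frames, self.pre_cs_off, dtype=float)
        h[lay.pre_cs_frames :] = self.cs_off
        return h


def _onset_multipliers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject lognormal onset-rate multipliers, shrunk by buffering.

    Drawn first from the dyad's stream, so two configs that differ only in
    coupling or buffering simulate the *same* pair of individuals.
    """
    log_m = config.freeze_rate_sigma * rng.standard_normal(2)
    log_m = (1.0 - config.buffering_shift) * log_m + config.buffering_shift * log_m.mean()
    return np.exp(log_m)


def _simulate_traces(
    config: SimConfig,
    rng: np.random.Generator,
    scripted_b: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step the coupled two-chain model; returns full-session 0/1 traces."""
    n = config.layout.n_frames
    on = config.onset_hazard()
    off = config.offset_hazard()
    mult = _onset_multipliers(config, rng)
    u = rng.random((n, 2))  # drawn up front: playback consumes the same stream
    memory = config.memory_frames
    min_bout = config.min_bout_frames
    g_follow = 1.0 + config.gamma_follow
    g_rf = 1.0 + config.gamma_retroact_freeze
    g_rm = 1.0 + config.gamma_retroact_move

    state = [0, 0]  # 1 = freezing; both start moving
    if scripted_b is not None:
        if scripted_b.size != n:
            raise ValueError("scripted partner trace must cover the full session")
        state[1] = int(scripted_b[0])
    frames_in_state = [1, 1]
    breaker: tuple[int, int, int] | None = None  # (mouse, broken_state, age)
    out = np.zeros((n, 2), dtype=np.uint8)
    out[0] = state

    for t in range(1, n):
        new = [state[0], state[1]]
        for i in (0, 1):
            if i == 1 and scripted_b is not None:
                new[1] = int(scripted_b[t])
                continue
            partner = state[1 - i]
            if state[i] == 0:  # moving: candidate freeze onset
                if n - t < min_bout:
                    continue  # a bout started now could not reach minimum length
                h = on[t] * mult[i]
                if partner == 1:
                    h *= g_follow
                if breaker is not None and breaker[0] == i and breaker[1] == 0:
                    h *= g_rf  # broke joint freezing; boosted to reverse
            else:  # freezing: candidate offset
                if frames_in_state[i] < min_bout:
                    continue  # refractory: bout must reach minimum length
                h = off[t]
                if partner == 0:
                    h *= g_follow
                if breaker is not None and breaker[0] == i and breaker[1] == 3:
                    h *= g_rm  # broke joint moving; boosted to reverse
            if u[t, i] < min(h, 1.0):
                new[i] = 1 - state[i]

        was_congruent = state[0] == state[1]
        switched = (new[0] != state[0], new[1] != state[1])
        if was_congruent:
            if switched[0] != switched[1]:  # exactly one mouse broke the state
                broken = 0 if state[0] == 1 else 3
                breaker = (0 if switched[0] else 1, broken, 0)
            else:
                breaker = None
        else:
            if new[0] == new[1] or any(switched):
                breaker = None  # congruency restored, or the episode changed shape
            elif breaker is not None:
                mouse, broken, age = breaker
                breaker = (mouse, broken, age + 1) if age + 1 <= memory else None

        for i in (0, 1):
            frames_in_state[i] = frames_in_state[i] + 1 if new[i] == state[i] else 1
        state = new
        out[t] = state

    return out[:, 0], out[:, 1]


def simulate_dyad(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    subject_ids: tuple[str, str] = ("sim_a", "sim_b"),
) -> tuple[Ethogram, Ethogram]:
    """Simulate one coupled dyad; returns the two validated ethograms.

    A fixed seed gives bit-identical bout tables across runs.
    """
    rng = np.random.default_rng(seed)
    a, b = _simulate_traces(config, rng)
    lay = config.layout
    return (
        ethogram_from_trace(subject_ids[0], lay, BinaryTrace(0, a)),
        ethogram_from_trace(subject_ids[1], lay, BinaryTrace(0, b)),
    )


def playback_partner(
    pattern: Ethogram,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    subject_id: str = "subject",
) -> Dyad:
    """One live subject tested against a scripted playback partner.

    The playback member replays ``pattern`` exactly (no coupling into it);
    the live subject may couple to it through its gamma parameters.  With all
    gammas zero this emulates the inert (clean-ball) control.
    """
    if pattern.layout != config.layout:
        raise ValueError("playback pattern layout does not match config layout")
    from .ethogram import bouts_to_trace

    scripted = bouts_to_trace(pattern, (0, pattern.layout.n_frames)).values
    rng = np.random.default_rng(seed)
    a, _ = _simulate_traces(config, rng, scripted_b=scripted)
    subject = ethogram_from_trace(subject_id, config.layout, BinaryTrace(0, a))
    return Dyad(
        dyad_id=f"playback:{subject_id}+{pattern.subject_id}",
        ethogram_a=subject,
        ethogram_b=pattern,
        treatment="playback",
    )


def simulate_cohort(
    config: SimConfig,
    n_dyads: int,
    seed: int,
    *,
    param_spread: dict[str, tuple[float, float]] | None = None,
    group: str = "sim",
    sex_composition: str = "MM",
    id_prefix: str = "d",
) -> tuple[list[Dyad], pd.DataFrame]:
    """Simulate a cohort of dyads with optional dyad-level parameter spread.

    ``param_spread`` maps SimConfig field names to (low, high) bounds; each
    dyad draws its own value uniformly, which induces across-dyad
    heterogeneity (e.g. a follow-count vs synchrony correlation when
    ``gamma_follow`` is spread).  Per-dyad seeds are derived deterministically
    from ``seed``, so results do not depend on iteration order.

    Returns the dyads and a subject metadata table in the ethogram-I/O
    dialect (``subject_id,dyad_id,sex,group,configuration``).
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    if sex_composition == "MM":
        sexes = ("M", "M")
    elif sex_composition == "FF":
        sexes = ("F", "F")
    elif sex_composition == "MF":
        sexes = ("M", "F")
    else:
        raise ValueError(f"unknown sex composition {sex_composition!r}")

    dyads: list[Dyad] = []
    meta_rows = []
    for k in range(n_dyads):
        ss = np.random.SeedSequence(seed, spawn_key=(k,))
        rng = np.random.default_rng(ss)
        cfg = config
        if param_spread:
            draws = {
                name: float(rng.uniform(lo, hi))
                for name, (lo, hi) in sorted(param_spread.items())
            }
            cfg = dataclasses.replace(config, **draws)
        dyad_id = f"{id_prefix}{k:03d}"
        ids = (f"{dyad_id}a", f"{dyad_id}b")
        eth_a, eth_b = simulate_dyad(cfg, rng, subject_ids=ids)
        dyads.append(
            Dyad(
                dyad_id=dyad_id,
                ethogram_a=eth_a,
                ethogram_b=eth_b,
                sex_composition=sex_composition,
                sex_a=sexes[0],
                sex_b=sexes[1],
            )
        )
        for sid, sex in zip(ids, sexes):
            meta_rows.append((sid, dyad_id, sex, group, "PAIR"))
    meta = pd.DataFrame(
        meta_rows, columns=["subject_id", "dyad_id", "sex", "group", "configuration"]
    )
    return dyads, meta
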