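"""Dyad-state decomposition and two-step behavioral-motif counting.

A dyad occupies one of four joint states at every frame:

====  =====================
code  meaning
====  =====================
0     both freeze (congruent)
1     A freezes, B moves (incongruent)
2     A moves, B freezes (incongruent)
3     both move (congruent)
====  =====================

Frame-to-frame transitions form a 16-cell matrix (4 self-loops included).
Motif counting operates on the run-length-collapsed sequence, so frames spent
inside a state never interrupt a motif:

* **follow** — the dyad crosses between the two congruent states, either via a
  single incongruent state (one mouse switches, the partner copies) or
  directly within one frame; events ending in state 0 are *follow-to-freeze*,
  ending in state 3 *follow-to-move*.
* **retroact** — the dyad leaves a congruent state via an incongruent one and
  returns to the same congruent state (the mouse that broke the state reverses
  itself): 0→{1,2}→0 is *retroact-to-freeze*, 3→{1,2}→3 *retroact-to-move*.

The default ("strict") reading counts only two-step excursions through a
single incongruent state; a "lenient" mode accepts any excursion through
incongruent states, for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ethogram import BinaryTrace

__all__ = [
    "CONGRUENT_STATES",
    "INCONGRUENT_STATES",
    "DyadStateSequence",
    "BehaviorCounts",
    "dyad_state_sequence",
    "traces_from_states",
    "transition_counts",
    "count_follow",
    "count_retroact",
    "behavior_counts",
]

logger = logging.getLogger(__name__)

CONGRUENT_STATES = (0, 3)
INCONGRUENT_STATES = (1, 2)


@dataclass(eq=False)
class DyadStateSequence:
    """Per-frame joint states plus their run-length-collapsed form."""

    states: np.ndarray
    collapsed: np.ndarray

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class BehaviorCounts:
    """Follow / retroact motif counts for one dyad."""

    follow_to_freeze: int
    follow_to_move: int
    retroact_to_freeze: int
    retroact_to_move: int

    def __post_init__(self) -> None:
        for f in (
            self.follow_to_freeze,
            self.follow_to_move,
            self.retroact_to_freeze,
            self.retroact_to_move,
        ):
            if f < 0:
                raise ValueError("behavior counts must be non-negative")

    @property
    def follow_total(self) -> int:
        return self.follow_to_freeze + self.follow_to_move


def _as_values(trace) -> np.ndarray:
    if isinstance(trace, BinaryTrace):
        return trace.values
    return np.asarray(trace, dtype=np.uint8)


def collapse_runs(states: np.ndarray) -> np.ndarray:
    """Merge consecutive duplicate states into a single entry."""
    s = np.asarray(states)
    if s.size == 0:
        return s.copy()
    keep = np.r_[True, s[1:] != s[:-1]]
    return s[keep]


def dyad_state_sequence(trace_a, trace_b) -> DyadStateSequence:
    """Map a pair of freezing traces to the joint 4-state sequence.

    ``state = 0`` for (freeze, freeze), ``1`` for (freeze, move), ``2`` for
    (move, freeze), ``3`` for (move, move).
    """
    a = _as_values(trace_a)
    b = _as_values(trace_b)
    if a.size != b.size:
        raise ValueError(f"trace lengths differ: {a.size} vs {b.size}")
    states = (2 * (1 - a.astype(np.int8)) + (1 - b.astype(np.int8))).astype(np.int8)
    return DyadStateSequence(states=states, collapsed=collapse_runs(states))


def traces_from_states(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the state encoding back to the (a, b) freezing indicator pair."""
    s = np.asarray(states, dtype=np.int8)
    a = (1 - (s >> 1)).astype(np.uint8)
    b = (1 - (s & 1)).astype(np.uint8)
    return a, b


def transition_counts(seq: DyadStateSequence | np.ndarray) -> np.ndarray:
    """4×4 matrix of frame-to-frame transition counts, self-loops included.

    Counted on the un-collapsed sequence, so the matrix total equals
    ``len(sequence) - 1``.
    """
    s = seq.states if isinstance(seq, DyadStateSequence) else np.asarray(seq)
    if s.size == 0:
        raise ValueError("empty state sequence")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (s[:-1], s[1:]), 1)
    return counts


def _congruent_excursions(collapsed: np.ndarray):
    """Yield (i, j) index pairs of consecutive congruent-state visits."""
    idx = np.flatnonzero(np.isin(collapsed, CONGRUENT_STATES))
    for i, j in zip(idx[:-1], idx[1:]):
        yield int(i), int(j)


def count_follow(
    seq: DyadStateSequence | np.ndarray, mode: str = "strict"
) -> tuple[int, int, int]:
    """Count follow motifs; returns (follow_to_freeze, follow_to_move, total).

    strict: congruent → one incongruent state → the other congruent state,
    plus direct congruent↔congruent adjacencies (both mice switch within one
    frame; logged, since at 4 fps such events indicate coarse sampling).
    lenient: any excursion through incongruent states that ends in the other
    congruent state.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown motif mode {mode!r}")
    c = seq.collapsed if isinstance(seq, DyadStateSequence) else collapse_runs(np.asarray(seq))
    f2f = f2m = 0
    n_direct = 0
    for i, j in _congruent_excursions(c):
        if c[j] == c[i]:
            continue  # same congruent state: retroact territory
        if j == i + 1:
            n_direct += 1  # direct 0<->3 switch counts as a follow
        elif mode == "strict" and j != i + 2:
            continue  # excursion through >1 incongruent state: strict skips
        if c[j] == 0:
            f2f += 1
        else:
            f2m += 1
    if n_direct:
        logger.info(
            "counted %d direct congruent-to-congruent switches as follow events "
            "(both mice switched within one frame)",
            n_direct,
        )
    return f2f, f2m, f2f + f2m


def count_retroact(
    seq: DyadStateSequence | np.ndarray, mode: str = "strict"
) -> tuple[int, int]:
    """Count retroact motifs; returns (retroact_to_freeze, retroact_to_move).

    strict: two-step loops 0→{1,2}→0 and 3→{1,2}→3 on the collapsed sequence
    (overlapping loops each counted).  lenient: any incongruent excursion that
    returns to the same congruent state.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown motif mode {mode!r}")
    c = seq.collapsed if isinstance(seq, DyadStateSequence) else collapse_runs(np.asarray(seq))
    r2f = r2m = 0
    for i, j in _congruent_excursions(c):
        if c[j] != c[i] or j == i + 1:
            continue
        if mode == "strict" and j != i + 2:
            continue
        if c[i] == 0:
            r2f += 1
        else:
            r2m += 1
    return r2f, r2m


def behavior_counts(
    seq: DyadStateSequence | np.ndarray, mode: str = "strict"
) -> BehaviorCounts:
    """Bundle follow and retroact counts for one dyad."""
    f2f, f2m, _ = count_follow(seq, mode=mode)
    r2f, r2m = count_retroact(seq, mode=mode)
    return BehaviorCounts(
        follow_to_freeze=f2f,
        follow_to_move=f2m,
        retroact_to_freeze=r2f,
        retroact_to_move=r2m,
    )


def motif_events(seq: DyadStateSequence | np.ndarray, mode: str = "strict"):
    """List motif events with the actor mouse that broke/fixed the state.

    Each event is a dict with the collapsed-sequence index, kind
    (``follow_to_freeze`` …), the incongruent state traversed (None for
    direct switches) and the actor: for a via-state excursion the breaker is
    implied uniquely by the incongruent state (state 1 = B moved or B froze
    alone, depending on origin).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown motif mode {mode!r}")
    c = seq.collapsed if isinstance(seq, DyadStateSequence) else collapse_runs(np.asarray(seq))
    events = []
    for i, j in _congruent_excursions(c):
        direct = j == i + 1
        if mode == "strict" and not direct and j != i + 2:
            continue
        via = None if direct else int(c[i + 1])
        if c[j] == c[i]:
            if direct:
                continue
            kind = "retroact_to_freeze" if c[i] == 0 else "retroact_to_move"
            # the breaker acted and reversed itself
            actor = _breaker(int(c[i]), via)
        else:
            kind = "follow_to_freeze" if c[j] == 0 else "follow_to_move"
            actor = None if direct else _follower(int(c[i]), via)
        events.append({"index": int(i), "kind": kind, "via_state": via, "actor": actor})
    return events


def _breaker(origin: int, via: int | None) -> str | None:
    """Which mouse broke congruent state ``origin`` given the via state."""
    if via is None:
        return None
    # from 0 (both freeze): state 1 = (A freeze, B move) -> B moved; state 2 -> A moved
    # from 3 (both move): state 1 = (A freeze, B move) -> A froze; state 2 -> B froze
    if origin == 0:
        return "B" if via == 1 else "A"
    return "A" if via == 1 else "B"


def _follower(origin: int, via: int | None) -> str | None:
    """Which mouse completed a follow motif (the one that copied)."""
    b = _breaker(origin, via)
    if b is None:
        return None
    return "A" if b == "B" else "B"
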