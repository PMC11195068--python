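"""Chance-corrected freezing synchrony for dyads.

For a dyad tested during the CS segment, let ``p_a`` and ``p_b`` be each
subject's freezing fraction, ``O`` the fraction of frames on which both
freeze (observed overlap) and ``E = p_a * p_b`` the overlap expected if the
two freezing processes were independent.  Raw synchrony is the standardized
excess overlap

    S_raw = (O - E) / sd_null,

where ``sd_null`` is the spread of the overlap under a null that preserves
each subject's freezing statistics.  Two nulls are provided: the default
circular-shift surrogate (rotate one trace by a random nonzero offset, which
preserves bout structure and autocorrelation) and a closed-form binomial null
``sqrt(E (1 - E) / n)`` that treats frames as independent.

Because both members of a dyad share CS-locked freezing dynamics, even
independent mice show a small positive S_raw.  This non-social component is
estimated from *virtual dyads* — all pairings of subjects from a group that
were never actually tested together — and subtracted:

    S = S_raw - mean(S_raw over the group's virtual dyads).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .ethogram import BinaryTrace, Ethogram, bouts_to_trace

__all__ = [
    "Dyad",
    "SynchronyResult",
    "NullConfig",
    "DegenerateTraceError",
    "observed_overlap",
    "chance_overlap",
    "rotation_overlaps",
    "null_overlap_spread",
    "raw_synchrony",
    "group_raw_synchrony",
    "enumerate_virtual_dyads",
    "corrected_synchrony",
    "apply_nonsocial_correction",
    "freezing_probability_trace",
]

logger = logging.getLogger(__name__)


class DegenerateTraceError(ValueError):
    """A subject froze on 0% or 100% of window frames; synchrony undefined."""


@dataclass(frozen=True)
class Dyad:
    """A pair of subjects analyzed together (really or virtually)."""

    dyad_id: str
    ethogram_a: Ethogram
    ethogram_b: Ethogram
    sex_composition: str = "MM"  # MM, FF or MF
    familiarity: str = "familiar"
    treatment: str = "control"
    is_virtual: bool = False
    sex_a: str | None = None
    sex_b: str | None = None

    def __post_init__(self) -> None:
        if self.ethogram_a.subject_id == self.ethogram_b.subject_id:
            raise ValueError(f"dyad {self.dyad_id!r}: members must differ")
        if self.ethogram_a.layout != self.ethogram_b.layout:
            raise ValueError(f"dyad {self.dyad_id!r}: members share one layout")
        if self.sex_composition not in ("MM", "FF", "MF"):
            raise ValueError(f"unknown sex composition {self.sex_composition!r}")

    def traces(self, window: tuple[int, int] | None = None) -> tuple[BinaryTrace, BinaryTrace]:
        """Binary traces of both members over ``window`` (default CS segment)."""
        w = window if window is not None else self.ethogram_a.layout.cs_window
        return bouts_to_trace(self.ethogram_a, w), bouts_to_trace(self.ethogram_b, w)

    def member_sexes(self) -> tuple[str, str]:
        if self.sex_a and self.sex_b:
            return self.sex_a, self.sex_b
        if self.sex_composition == "MM":
            return "M", "M"
        if self.sex_composition == "FF":
            return "F", "F"
        raise ValueError(
            f"dyad {self.dyad_id!r}: MF dyads need explicit sex_a/sex_b labels"
        )


@dataclass(frozen=True)
class SynchronyResult:
    """Overlap statistics and synchrony scores for one dyad."""

    dyad_id: str
    p_a: float
    p_b: float
    observed: float
    chance: float
    null_sd: float
    raw: float
    corrected: float | None = None
    is_virtual: bool = False


@dataclass(frozen=True)
class NullConfig:
    """Null model configuration for the synchrony denominator."""

    method: str = "circular_shift"
    n_surrogates: int | str = 1000
    seed: int = 17
    window: str = "cs"

    def __post_init__(self) -> None:
        if self.method not in ("circular_shift", "binomial"):
            raise ValueError(f"unknown null method {self.method!r}")
        if self.method == "circular_shift" and self.n_surrogates != "all":
            if int(self.n_surrogates) < 100:
                raise ValueError("circular_shift needs n_surrogates >= 100 (or 'all')")


def _values(trace) -> np.ndarray:
    if isinstance(trace, BinaryTrace):
        return trace.values
    return np.asarray(trace, dtype=np.uint8)


def _check_equal_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise ValueError(f"trace lengths differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty traces")


def observed_overlap(trace_a, trace_b) -> float:
    """Fraction of frames on which both subjects freeze."""
    a, b = _values(trace_a), _values(trace_b)
    _check_equal_length(a, b)
    return float((a & b).sum() / a.size)


def chance_overlap(trace_a, trace_b) -> float:
    """Overlap expected under independence: ``p_a * p_b``."""
    a, b = _values(trace_a), _values(trace_b)
    _check_equal_length(a, b)
    return float(a.mean() * b.mean())


def rotation_overlaps(trace_a, trace_b) -> np.ndarray:
    """Overlap fraction of ``a`` against every circular rotation of ``b``.

    Entry ``k`` is ``observed_overlap(a, roll(b, -k))``, computed exactly via
    FFT circular cross-correlation on the 0/1 traces; entry 0 is the observed
    overlap itself.
    """
    a, b = _values(trace_a).astype(float), _values(trace_b).astype(float)
    _check_equal_length(a, b)
    n = a.size
    cc = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n)
    return np.rint(cc) / n


def null_overlap_spread(
    trace_a,
    trace_b,
    method: str = "circular_shift",
    n_surrogates: int | str = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Spread of the freezing overlap under the chosen null model.

    ``circular_shift`` — standard deviation of the overlap over random
    nonzero rotations of trace b (``n_surrogates`` draws with replacement, or
    ``"all"`` for exhaustive enumeration of the n-1 rotations).
    ``binomial`` — closed form ``sqrt(E (1 - E) / n)``.

    Raises :class:`DegenerateTraceError` when either subject freezes on 0% or
    100% of frames (the standardized score is then undefined).
    """
    a, b = _values(trace_a), _values(trace_b)
    _check_equal_length(a, b)
    p_a, p_b = float(a.mean()), float(b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise DegenerateTraceError(
            f"degenerate trace (p_a={p_a}, p_b={p_b}): null spread undefined"
        )
    n = a.size
    if method == "binomial":
        e = p_a * p_b
        return float(np.sqrt(e * (1.0 - e) / n))
    if method != "circular_shift":
        raise ValueError(f"unknown null method {method!r}")
    overlaps = rotation_overlaps(a, b)[1:]  # exclude the unrotated alignment
    if n_surrogates == "all":
        sample = overlaps
    else:
        n_surrogates = int(n_surrogates)
        if n_surrogates < 100:
            raise ValueError("circular_shift needs n_surrogates >= 100 (or 'all')")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        sample = overlaps[rng.integers(0, overlaps.size, size=n_surrogates)]
    return float(sample.std())


def _dyad_rng(seed: int, dyad_id: str) -> np.random.Generator:
    """Per-dyad RNG derived from a pipeline seed and the dyad id.

    Deterministic and independent of iteration order.
    """
    key = zlib.crc32(dyad_id.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def raw_synchrony(
    dyad: Dyad,
    null: NullConfig | None = None,
    window: tuple[int, int] | None = None,
) -> SynchronyResult:
    """Raw (uncorrected) synchrony of one dyad over the analysis window.

    Raises :class:`DegenerateTraceError` for dyads with a member freezing 0%
    or 100% of the window.
    """
    null = null or NullConfig()
    ta, tb = dyad.traces(window)
    a, b = ta.values, tb.values
    p_a, p_b = float(a.mean()), float(b.mean())
    o = observed_overlap(a, b)
    e = chance_overlap(a, b)
    sd = null_overlap_spread(
        a,
        b,
        method=null.method,
        n_surrogates=null.n_surrogates,
        rng=_dyad_rng(null.seed, dyad.dyad_id),
    )
    return SynchronyResult(
        dyad_id=dyad.dyad_id,
        p_a=p_a,
        p_b=p_b,
        observed=o,
        chance=e,
        null_sd=sd,
        raw=(o - e) / sd,
        is_virtual=dyad.is_virtual,
    )


def group_raw_synchrony(
    dyads,
    null: NullConfig | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[list[SynchronyResult], list[str]]:
    """Raw synchrony for a collection of dyads, excluding degenerate ones.

    Returns (results, excluded dyad ids); each exclusion is logged.
    """
    results: list[SynchronyResult] = []
    excluded: list[str] = []
    for d in dyads:
        try:
            results.append(raw_synchrony(d, null=null, window=window))
        except DegenerateTraceError as exc:
            logger.warning("dyad %s excluded from synchrony: %s", d.dyad_id, exc)
            excluded.append(d.dyad_id)
    return results, excluded


def enumerate_virtual_dyads(group_dyads) -> list[Dyad]:
    """All conceivable pairings of a group's subjects minus the real pairs.

    Same-sex groups pair every two subjects (``C(2k, 2) - k`` virtual dyads
    for ``k`` real dyads); opposite-sex groups pair every male with every
    female except real partners.  Virtual dyads inherit the group's labels.
    """
    group_dyads = list(group_dyads)
    if len(group_dyads) < 2:
        raise ValueError("virtual-dyad enumeration needs at least 2 real dyads")
    subjects: dict[str, Ethogram] = {}
    sexes: dict[str, str] = {}
    real_pairs = set()
    for d in group_dyads:
        sa, sb = d.member_sexes()
        for eth, sex in ((d.ethogram_a, sa), (d.ethogram_b, sb)):
            if eth.subject_id in subjects:
                raise ValueError(f"duplicate subject id {eth.subject_id!r} in group")
            subjects[eth.subject_id] = eth
            sexes[eth.subject_id] = sex
        real_pairs.add(frozenset((d.ethogram_a.subject_id, d.ethogram_b.subject_id)))
    template = group_dyads[0]

    ids = sorted(subjects)
    if template.sex_composition == "MF":
        males = [s for s in ids if sexes[s] == "M"]
        females = [s for s in ids if sexes[s] == "F"]
        candidates = itertools.product(males, females)
    else:
        candidates = itertools.combinations(ids, 2)

    virtual = []
    for s1, s2 in candidates:
        if frozenset((s1, s2)) in real_pairs:
            continue
        virtual.append(
            Dyad(
                dyad_id=f"virtual:{s1}+{s2}",
                ethogram_a=subjects[s1],
                ethogram_b=subjects[s2],
                sex_composition=template.sex_composition,
                familiarity=template.familiarity,
                treatment=template.treatment,
                is_virtual=True,
                sex_a=sexes[s1],
                sex_b=sexes[s2],
            )
        )
    return virtual


def apply_nonsocial_correction(
    results, component: float
) -> list[SynchronyResult]:
    """Subtract a group's non-social synchrony component from raw scores."""
    return [dataclasses.replace(r, corrected=r.raw - component) for r in results]


def corrected_synchrony(
    real_results, virtual_results
) -> tuple[list[SynchronyResult], float]:
    """Corrected synchrony: raw minus the group's virtual-dyad mean.

    Returns the corrected real-dyad results and the subtracted non-social
    component (the mean raw synchrony over the group's virtual dyads).
    """
    virtual_results = list(virtual_results)
    if not virtual_results:
        raise ValueError("no virtual results: cannot estimate non-social component")
    component = float(np.mean([r.raw for r in virtual_results]))
    return apply_nonsocial_correction(real_results, component), component


def freezing_probability_trace(
    traces, window_s: float = 1.0, fps: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Cohort freezing-probability dynamics with a sliding-window smoother.

    Each subject's 0/1 trace is smoothed with a centered moving average of
    ``window_s`` seconds (edges normalized by actual window coverage); the
    across-subject mean and SD per frame are returned.
    """
    arrays = [_values(t).astype(float) for t in traces]
    if not arrays:
        raise ValueError("empty trace collection")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("traces must share one length")
    w = int(round(window_s * fps))
    if w < 1:
        raise ValueError("window_s * fps must be >= 1 frame")
    kernel = np.ones(w)
    coverage = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = np.vstack([np.convolve(a, kernel, mode="same") / coverage for a in arrays])
    return smoothed.mean(axis=0), smoothed.std(axis=0)
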