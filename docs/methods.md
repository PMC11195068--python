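# Methods

## Problem and data model

Two fear-conditioned mice tested side by side tend to freeze at the same
times.  `dyadsync` quantifies that coordination from frame-indexed freezing
annotations: one row per freezing bout (subject, first frame, last frame),
recorded at 4 frames/s over a session with a 60 s tone-free baseline and a
120 s conditioned-stimulus (CS) tone.  All analysis operates on the CS
segment — 480 frames at the default layout — and a freezing bout must span
at least 1 s (4 frames), which is the annotation criterion the input data
are assumed to follow.

Internally, coordinates are 0-based frames and intervals half-open
`[start, end)`.  Annotator tables that record the *last* frame of a bout
(the common convention) are converted on ingest (`end = last + 1`); a
`bout_end_convention` flag and a `frame_origin` flag cover the alternative
conventions, since annotation tools differ and the convention is rarely
stated in the data themselves.  Adjacent bouts with no gap are rejected
rather than merged: under the 1 s bout criterion they indicate an
annotation error, and silently merging would hide it.  Sub-second gaps
between bouts are legal (the criterion constrains bout length, not gap
length).

## Synchrony score

For a dyad with CS freezing fractions `p_a`, `p_b`, observed both-freezing
fraction `O` and independence expectation `E = p_a p_b`, the raw synchrony
is the standardized excess overlap

    S_raw = (O − E) / sd_null.

Two null models supply the denominator:

* **circular shift** (default): the overlap of trace *a* against random
  nonzero circular rotations of trace *b*; `sd_null` is the standard
  deviation over `n_surrogates = 1000` rotations (or all `n − 1` rotations
  exhaustively).  Rotation preserves each subject's bout-length and
  autocorrelation structure, which is the relevant null for strongly
  autocorrelated freezing traces; an independence null that ignores
  autocorrelation understates the spread and inflates |S|.  All rotation
  overlaps are computed exactly with an FFT circular cross-correlation
  (integer counts recovered by rounding); a useful identity, used in the
  tests, is that the mean overlap over *all* n rotations equals `E`
  exactly.
* **binomial**: `sqrt(E (1 − E) / n)`, the closed form for frame-wise
  independent traces; retained for speed and for closed-form test cases.

Dyads in which a subject froze on 0% or 100% of CS frames have no defined
standardized score; they are excluded with a logged warning rather than
scored 0.

**Non-social correction.**  Because every mouse's freezing is driven by the
same CS, even mice that never met show a small positive `S_raw` (a shared
rise-then-decline dynamic aligns their bouts).  The non-social component is
estimated as the mean `S_raw` over *virtual dyads* — all pairings of the
group's subjects except the real ones (`C(2k, 2) − k` pairs for `k`
same-sex dyads; all male×female non-partner pairs for mixed groups, since a
virtual dyad must be a conceivable dyad of that group) — and subtracted:

    S = S_raw − mean(S_raw | virtual).

The subtraction recenters the virtual population to exactly 0 by
construction and is reported per group.  The correction is applied per
experimental group.

Randomness is controlled by a single pipeline seed fanned out per dyad via
`SeedSequence(seed, spawn_key=(crc32(dyad_id),))`, so results are identical
regardless of iteration order.

## Dyad states and motif counts

Each CS frame maps to a joint state: 0 = both freeze, 1 = A freezes/B
moves, 2 = A moves/B freezes, 3 = both move; states 0 and 3 are congruent,
1 and 2 incongruent.  Frame-to-frame transitions fill a 16-cell matrix
(4 self-loops), whose total is `frames − 1`.

Motifs are counted on the run-length-collapsed sequence, so dwell frames
never interrupt a motif:

* **follow** — congruent → one incongruent state → the *other* congruent
  state (one mouse switches, the partner copies), or a direct
  congruent↔congruent adjacency (both switch within one frame; counted,
  but logged, because at 4 fps it indicates sampling too coarse to resolve
  the order).  Events ending in state 0 are follow-to-freeze, in state 3
  follow-to-move.  On sequences without direct 0↔3 or 1↔2 adjacencies the
  two subtype counts can differ by at most 1 (the congruent-state visit
  sequence alternates only at follow events); the test suite proves this
  exhaustively for all constrained collapsed sequences up to length 10 and
  checks it on 10,000 random ones.
* **retroact** — congruent → one incongruent state → the *same* congruent
  state (the breaker reverses itself): 0→{1,2}→0 is retroact-to-freeze,
  3→{1,2}→3 retroact-to-move.  Overlapping loops each count.

The strict two-step reading skips excursions that visit both incongruent
states (e.g. collapsed 0,1,2,3); a `lenient` mode accepts any
incongruent excursion, for sensitivity analysis.  Direct 1↔2 adjacencies
terminate motifs in strict mode.  The actor mouse of each motif is implied
uniquely by the incongruent state traversed and is available from
`motif_events`, though the headline counts do not use it.

## Group statistics

Freezing levels are percent of CS frames frozen.  Equalization compares
per-dyad absolute freezing differences between PAIR and SINGLE
configurations (paired Wilcoxon).  Before correlating partners' freezing
levels in same-sex groups, members are assigned to the "animal 1"/
"animal 2" columns by the alternating scheme: sort dyads by mean freezing
descending, then alternate whether the within-dyad high freezer goes to
column 1 or 2, which balances the columns in both means and high/low
counts (difference ≤ 1 by construction; within-dyad ties resolve by
subject id and are logged).  Opposite-sex groups correlate male vs female
directly.  Top/bottom splits by synchrony take `floor(0.40 N)` dyads per
tail (floor guarantees disjoint subsets for every N; boundary ties break
by dyad id with a warning).  Correlations are Pearson by default with a
Spearman option.  Two-group comparisons follow a normality-gated rule —
Shapiro–Wilk, then t-test or Wilcoxon/Mann–Whitney — and report both
two- and one-tailed p-values, since published analyses of this assay use
one-tailed tests in places.

## Synthetic dyads

The generator steps two move/freeze chains frame by frame.

Baseline hazards (per frame, defaults in parentheses): pre-CS onset
0.005 and offset 0.30 (mice mostly move before the tone); at CS onset the
onset hazard jumps to 0.35 and relaxes exponentially with a 20 s time
constant toward a 0.02 floor, with offset 0.06.  This produces the
assay's canonical cohort dynamic — freezing probability rising within a
few seconds of CS onset, then declining slowly — and a cohort mean CS
freezing near 50% (the 30–70% band): at the defaults, 49% mean freezing
with the 1 s-smoothed cohort trace at 90% of its peak within ~2 s
(seed 0, 40 dyads).  These values are design choices, not fits to any
recorded data.  Dwell distributions are geometric with a refractory
floor: offsets are suppressed until a bout reaches the 4-frame minimum,
and onsets too close to the session end to complete a minimal bout are
suppressed, so every simulated ethogram satisfies the input invariants
without post-hoc merging (merging would distort the coupling dynamics
under test).

Individual variation: each subject draws a lognormal onset-rate
multiplier (σ = 0.4).  `buffering_shift ∈ [0, 1]` shrinks the two
partners' log-multipliers toward their mean, emulating fear
buffering/equalization; multipliers are drawn before the dynamics from
the dyad's own stream, so configurations differing only in coupling or
buffering simulate the same individuals (used by the equalization tests).

Coupling is hazard-multiplicative with γ = 0 neutral (multiplier
`1 + γ`), which keeps probabilities bounded after clipping at 1:

* `gamma_follow` boosts each mouse's hazard of switching toward its
  partner's state while the dyad is incongruent.
* `gamma_retroact_freeze` / `gamma_retroact_move` boost the breaker's
  reversal hazard for ~1 s (`retroact_memory_s`) after it broke a
  congruent state, while the partner has not followed.

A playback mode replays a fixed ethogram as one member with no coupling
into it, emulating a programmed robot-ball partner; the live subject may
still couple to it (γ = 0 for an inert control, γ > 0 for a socially
salient one).

**What the generator does and does not emulate.**  It reproduces
CS-locked onset dynamics, minimum bout lengths, individual variation and
the two coupling motifs, so passing tests show that the estimator recovers
synchrony and strategy structure *of this generative form*.  It does not
model within-session habituation beyond the hazard decay, bout-duration
distributions measured from real animals (none are published), sex
differences, or sensory detail; agreement on synthetic cohorts therefore
validates the statistical machinery, not any biological claim about real
dyads.

**Known limitation — retroact/follow competing risks.**  Raising a
retroact γ shortens incongruent episodes, which removes some chance
opportunities for the partner to complete a follow; across an extreme
grid (γ up to 4, i.e. 5× reversal hazard) mean follow counts decline by
roughly a third rather than staying literally flat.  The dissociation is
directional: retroact-to-freeze counts rise monotonically with their γ
while follow counts never co-increase.  Any coupled two-chain generator
shares this property.

## Numerical and tie-break choices

* Overlap fractions are exact rationals realized in double precision;
  FFT cross-correlations are rounded to the nearest integer count before
  division, so they match brute-force enumeration to 1e-12.
* The null SD uses the population convention (ddof 0), matching the
  exhaustive-rotation population it estimates.
* The sliding-window smoother renormalizes by actual window coverage at
  the edges; an even window leans one frame toward the past.
* Cohort trace SD is the population SD across subjects.
* Within-dyad freezing ties, split-boundary ties, direct 0↔3 events and
  degenerate-dyad exclusions are all logged with the dyad id.

## Problem sizes used by the test and acceptance runs

Null calibration uses 200 uncoupled dyads with the full virtual
enumeration (79,600 virtual pairs); coupling-recovery grids use
{0, 0.5, 1, 2, 4} with 100 dyads per point; motif-counting identities use
10,000 random sequences; exhaustive rotation checks use traces up to 64
frames.  These sizes make the stochastic checks stable at fixed seeds
while the whole suite runs in about a minute on one core.
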