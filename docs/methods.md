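# Methods

## Task model

A conditioning trial is a deterministic, loop-free MDP.  The standard variant
has eight states: pre-CS (`s0`), CS onset (`s1`, the single behavioural choice
point), lever approached (`s2`), exploring (`s3`), magazine engaged (`s4`),
US delivered while at the lever (`s5`) or away (`s6`), and food available at
the cup (`s7`), ending with `eat` (reward 1; all other transitions reward 0).
Three paths lead from trial start to `eat`: sign (s1→s2→s5→s7), explore
(s1→s3→s6→s7) and goal (s1→s4→s7).  The goal path is one step shorter — an
animal engaged with the magazine is already at the cup when the pellet drops —
which is the structural source of the model-based system's goal preference:
with a fully learned model, A(s1, goM) = 0 while A(s1, goL) = γ²(γ − 1)·max Q
< 0 for any γ ∈ (0, 1).

Published sources give the state-action-feature table and several textual
anchors but no explicit transition table; the wiring above is the unique one
consistent with those constraints.  State labels are internal — analyses
depend only on path identity.

The split-CS variant divides the 8-s CS period into two decision points
(first/last 4 s).  At CS onset only `goL`/`goM` are available (exploration
removed); at the mid-CS states the agent may stay with its stimulus or switch
to the other.  Being at the magazine when the US drops again skips the
retrieval step, so with a learned model the two CS-onset actions tie while the
mid-CS advantage favours the magazine — the mechanism behind the within-CS
shift toward goal-tracking.  The exact node count of the original variant is
not published; this is the minimal graph with both cross-transitions, isolated
behind its own builder so an alternative wiring is a one-function change.

## Feature function variants

The `eat` action is focused on the food (`food` variant, the original
convention) or on the magazine (`magazine` variant).  Under the food variant
the terminal error is identically r − V(F) = 0; under the magazine variant it
is 1 − V(M), which both yields a non-trivial consumption-time error (the
dopamine-proxy analyses need it) and updates the magazine value on every
trial, including sign-tracking trials.

That second consequence matters more than it first appears.  Under the food
variant the lever and magazine receive exactly two structurally identical TD
updates per trial on their respective paths, so apart from the ITI decay of
V(M) they are symmetric, and a pure-FMF agent drifts into sign-tracking under
*both* ITI conditions (whichever feature wins the early race keeps its value;
the magazine additionally decays).  Only the magazine variant — where V(M) is
pulled toward 1 by α(1 − V(M)) every trial and pushed down by u·V(M) — makes
short-ITI goal-tracking emerge in FMF-dominant agents (equilibrium magazine
value roughly α/(α + u) scaled, i.e. high at u = 0.01 and low at u = 0.1).
All experiment presets therefore use the magazine variant; the food variant
remains the standard-task default and is the setting in which the exact
terminal-error identity is checked.

## Learners

FMF values start at 0 for E, L, M (the convention consistent with the
explicitly zero-initialized T and R) and V(F) is pinned at 1.  Errors are
computed and logged on every transition, including ones whose update is a
no-op.  The max in the TD target runs over all actions of the successor state.
The episode ends at `eat` with zero continuation value in both learners, so
Q(s7, eat) → R(s7, eat) exactly.

The world model updates only the observed triple (no row renormalization):
in this deterministic task visited transitions converge to 1 and impossible
ones stay absent, but transiently T is biased by the agent's own choices,
which is a deliberate property (it lets a dominant FMF system distort the
MB system's advantages, but not vice versa).  Q is recomputed by synchronous
value iteration after every model update (tolerance 1e-9, cap 10,000
iterations — unreachable for γ < 1; the task graph is acyclic so iteration
converges in graph-depth steps, and the solver warm-starts from the previous
solution).  An independently coded asynchronous fixed-point oracle agrees to
1e-9 in the tests.

## Agent

Decisions use estimates held before the transition (learn-after-act); both
learners update from every transition regardless of ω, which only weights the
behavioural mixture.  ω is fixed per subject.  α and γ are shared between
systems.  Softmax selection uses max-subtraction for overflow safety.  The ITI
revision is applied exactly once per completed trial; there is no reset of any
kind between sessions.

One derived correction to a commonly assumed closed form: on a forced sign
path with no ITI decay, V(L) receives *two* updates per trial (toward γ·V(L)
at approach, toward γ·V(F) at engagement), so its fixed point is
αγ / (1 − (1 + α(γ − 1))(1 − α)) ≈ γ/(2 − γ) ≈ 0.67 — not γ.  The tests
assert the cycle fixed point derived by hand against brute-force iteration.

## Parameters

| parameter | meaning | default | note |
|---|---|---|---|
| α | shared learning rate | 0.03 | reference value from prior optimizations |
| γ | discount per MDP step | 0.8 | drives the MB goal preference |
| τ | softmax temperature | 0.15 | larger → more random choice |
| u_ITI | per-trial down-revision of V(M), V(E) | 0.01 short / 0.1 long | the only channel through which ITI duration acts |
| ω | FMF weight, fixed per subject | experiment-specific | 1 = pure FMF, 0 = pure MB |

Population ω is drawn once per subject from beta(2, 1) by default — the
simplest density increasing toward 1, matching the reported prevalence of
sign-trackers; the published histogram does not fix the parameters, so all
β-dependent conclusions are directional, never numeric.  A uniform(0, 1)
alternative and degenerate fixed-ω populations are presets.  20 subjects per
population and per single-system condition (the original count for the mixed
population; the single-system agent count is not published).  The
extended-training preset runs 30 sessions, enough for the short-ITI lever
value to overtake the magazine.  The early/late phase split is sessions 1–3
versus the remainder.

## Randomness and pairing

All randomness flows from one integer master seed through a SeedSequence
tree: one child for ω sampling, one per subject.  Paired-condition runs reuse
both the ω vector and the per-subject streams in the short and long arms, so
condition contrasts are within-subject by construction and a pure-MB
population produces literally identical choice sequences in both arms.

## What the simulations do and do not show

The generator *is* the study system: there is no empirical data path.  The
simulations reproduce the qualitative machinery — ITI-driven switching between
phenotypes, its restriction to FMF-dominant agents, the ordering and
early/late evolution of CS- and consumption-time prediction errors, and the
within-CS shift toward the magazine in the split task.  They do not model
response latencies, repeated interactions within a trial (outside the split
variant's single extra decision), composite behavioural indices built from
those quantities, within-ITI events, or any refit of parameters to empirical
data.  Population-level test statistics depend on the unpublished ω sample
and are therefore meaningful only directionally.

## Analyses

Scores are computed from both softmax probabilities and realized choice
frequencies; the probability-based score is always defined (softmax outputs
are strictly positive), the frequency-based score is guarded and emits NaN
with a warning if a subject neither sign- nor goal-tracked.  The US-tagged
error is the food-appearance transition under the food variant and the eat
transition under the magazine variant; both are always logged.  The
repeated-measures ANOVA (statsmodels AnovaRM) uses two within factors
(condition × session) without sphericity correction; Welch and paired t tests
and Wilcoxon signed-rank tests come from scipy; identical paired samples
short-circuit to statistic 0, p = 1 rather than raising.  Reported p-values
are uncorrected.  Degenerate-input behaviour (empty late windows, unbalanced
designs, mixed-variant logs, mismatched subject sets) raises structural
errors rather than silently proceeding.

## Numerical choices

Value-iteration tolerance 1e-9; trial CSVs are written with `%.17g` and read
with round-trip float parsing so re-analysis of a stored log reproduces the
original analyses bit-for-bit; action sampling inverts the cumulative softmax
with a single uniform draw per decision.
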