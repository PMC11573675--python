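# Methods

This note documents the generative task model, the three successor
agents, the fitting and comparison machinery, and the numerical choices
behind them. Everything below is computed by the package itself; no
number here comes from anywhere else.

## Task model

A session has two phases. Each phase's stimuli are compound images whose
two features evolve as *simultaneous* traversals of two graph factors,
one step per observation:

* a **cycle** factor advances deterministically through its states in a
  fixed order (the order of images contributed by a cycle never changes
  across a phase);
* a **path** factor takes a reflecting random walk — interior states
  move left or right with probability 1/2, boundary states move inward
  with probability 1.

The prior phase (48 trials of 12 observations) combines a 4-cycle with a
6-path (`prior4cycle` condition) or a 4-path with a 6-cycle
(`prior6cycle`). The transfer phase (36 trials of 12 observations) is
identical for both conditions: a 4-cycle and a 6-cycle over ten entirely
new feature labels. Because the factors are bipartite, the 24 compound
states split under joint stepping into two disconnected components of 12
(the parity `(a + b) mod 2` is invariant). Sequences stay inside one
component, the *experienced* component; the other is held out.

After every sequence come two binary-choice probes: an **experience
probe** cued by a compound from the just-shown sequence, and an
**inference probe** cued by a held-out compound. The correct option is
the next compound under the generative dynamics (for a path factor, the
transition realized in that sequence); the lure differs from the correct
option only on one designated factor, so each probe tests knowledge of
exactly one factor (size 4 or 6). Probed-size assignment of compounds is
a seeded balanced bijection (six compounds per size per component),
fixed per subject; probed sizes alternate across trials so each size is
probed equally often per probe type.

Design choices where the design space was genuinely open:

* **Lures.** For a probed cycle the lure feature is the cue's
  predecessor (pinned down by the published example `D'8' -> A'9'` vs
  `C'9'`). For a probed path the lure is a seeded uniform draw over
  positions at distance >= 2 from the cue's path position, so it can
  never be a plausible one-step successor. No parity constraint is
  imposed: on the 4-path, interior cues have no non-adjacent
  same-parity position at all.
* **Sequence starts.** Prior-phase sequences restart at a uniformly
  drawn experienced-component state each trial; the transfer sequence
  always starts at the same state and therefore repeats identically.
* **Transitions across trial boundaries.** One 12-image sequence shows
  11 within-trial transitions. In transfer the repeated sequence's
  deterministic successor of its last state *is* the next trial's first
  state, so consecutive presentations form an unbroken walk and the
  cross-trial pair counts as a genuine transition (12 distinct
  transitions total, exactly half the full set of 24). A prior-phase
  restart is a teleport and is never treated (or learned) as a
  transition.

## The three agents

All agents learn a successor matrix `M` by temporal-difference updates
with learning rate α (separate `alpha_prior` / `alpha_transfer` in the
2α variants) and fixed discount γ = 0.9, and answer probes through a
softmax over option values with temperature τ (separate `tau_exp` /
`tau_inf` in the 2τ variants):

    P(correct) = σ((v_correct − v_lure) / τ).

The SR convention is *self-inclusive with identity initialization*: row
`s` moves toward `e_s + γ · M[s']`, so diagonals are nonzero even for
never-experienced states and every entry stays in `[0, 1/(1−γ)]`.

* **M1 (successor compound).** States are whole compounds; one 24×24
  matrix per phase. Value of an option is `M[cue, option]`. Held-out
  compounds keep identity rows, so both options of an inference probe
  are worth exactly 0 and M1 answers those probes at exactly 50% for
  any parameters.
* **M2 (successor features).** Each compound is the two-hot vector of
  its features; one 10×10 matrix per phase, with no carry-over between
  phases. Both current-feature rows move toward
  `φ(s) + γ · mean(M[j1], M[j2])` over the successor's features. The
  *mean* (not the sum) keeps the `1/(1−γ)` bound; this is the one place
  the published equations could not be checked directly and is flagged
  here as a convention. Option values sum the four cue-feature ×
  option-feature entries, so two options sharing a feature differ only
  through the probed factor.
* **M3 (successor features + transfer).** Learns exactly like M2, and
  additionally searches for the feature bijection π maximizing the
  similarity `⟨P M_prior Pᵀ, M_transfer⟩` (Frobenius inner product;
  equivalent to minimal Frobenius distance since permutations preserve
  norms). Transfer-phase probes are answered from the mixture
  `ω · (P M_prior Pᵀ) + (1−ω) · M_transfer`. The mapping is recomputed
  before each trial's probes from the current transfer matrix (the
  matrix does not change between the two probes of a trial, so one
  search per trial is exact); recomputing per trial is what produces a
  transfer advantage from the very first trials. The search is
  unconstrained over all 10-feature bijections — the mechanism is
  purely data-driven, with no oracle knowledge of which features belong
  to which factor. Prior-phase probes use the prior matrix only, so ω
  and the mapping act exclusively in transfer.

The mapping search is best-improvement pairwise-swap hill climbing from
an identity start plus seeded random restarts (default 5 during replay,
20 for standalone calls; O(n) swap deltas). Restart permutations are
derived from the protocol seed and trial index, so the generative run
and the likelihood replay search from identical starting points — the
number of restarts is part of the model's definition, and likelihoods
must replay with the same setting used to generate.

A consequence of online TD worth stating: with α = 1 on the
deterministic 12-state transfer loop, information propagates one step
backwards per update, so after L laps each SR entry equals the
discounted-occupancy series truncated at ⌈L/12⌉ terms. The default
36-lap session yields `M(s,s) = Σ_{j≤3} γ^{12j} ≈ 1.3847` exactly; full
convergence to `(I − γT)⁻¹` within 1e−6 needs on the order of 150 laps
(error contracts by γ per lap). The oracle test asserts both facts.

## Model space, likelihood, fitting

The model space crosses {M1, M2, M3} × {1α, 2α} × {1τ, 2τ} — twelve
variants; M3 adds ω, so free-parameter counts run from 2 to 5.

The likelihood deterministically replays the subject's observation
stream with the same kernels the generative agents use and scores each
observed choice by the probability the agent would have sampled it from;
probabilities are clipped to `[1e−9, 1−1e−9]` inside logs. Unanswered
probes are skipped, never imputed.

Fitting is bounded maximum likelihood (α ∈ [1e−4, 1], τ ∈ [1e−3, 20],
ω ∈ [0, 1]) by Nelder–Mead in a sigmoid-transformed unconstrained
space. The mapping step makes the M3 likelihood piecewise smooth and
multimodal in the learning rates, so simplex starts are not drawn
blindly: a deterministic coarse grid over the parameter box is scored
first — cheaply, because the replay depends only on the learning rates
while τ and ω enter analytically through the stored value components —
and the best grid points seed the simplex runs (random seeded starts
top up if more starts are requested than the grid provides). A fit
where no start converges is returned flagged, not raised.

## Model comparison

WAIC requires posterior draws but the models are fitted by MLE, so a
**Laplace approximation** bridges the two: a Gaussian at the MLE with
covariance from the finite-difference Hessian of the negative
log-likelihood (statsmodels `approx_hess`), draws truncated to the
parameter box, each draw replayed to produce pointwise log-likelihoods.
Non-positive-definite curvature (common at bounds) falls back to a
diagonal-jittered Hessian and is flagged. WAIC uses
`−2(lppd − p_waic)` with population variance in `p_waic` (replicating
the draw set leaves the value unchanged). AIC is reported alongside as
a deterministic alternative, and reports label which metric each number
uses. Best model per subject is the lowest criterion value, exact ties
going to fewer parameters.

Posterior simulations rerun the generative agents at each subject's MLE
(default 10 repetitions) and summarize accuracy per condition ×
probed size × probe type, plus the across-condition difference per
probed size — the data feature whose disordinal pattern (positive for
4-cycle probes and negative for 6-cycle probes when conditions are
labelled 4-cycle-prior minus 6-cycle-prior) separates the transfer
model from its ablations.

## Descriptive statistics

Group summaries always average within subject first. Learning curves
use four equal trial bins per phase (12 prior / 9 transfer trials per
bin). Temporal trends are per-subject two-parameter logistic fits of
correctness on trial number, reported with the probability-scale
per-trial change at the subject's mean accuracy; all-identical outcomes
make the slope unidentified (the intercept diverges), so such cells
report slope 0 with a flag, and fitted slopes are clipped to ±10 with a
flag. The interaction contrast resamples subjects (not trials) within
condition, 10,000 bootstrap draws by default, percentile CIs. The
paper-style multilevel Bayesian GLMs are intentionally replaced by
these descriptive estimates; the quantities they summarize (trends,
interaction) are reproduced, their posterior machinery is not.

## Synthetic cohorts

`simulate_cohort` draws one parameter vector per subject index and
reuses it in both conditions (matched-parameters contract of a-priori
simulation designs). Default cohort conditions used throughout the
tests: α ~ U(0.1, 0.5) per phase, τ ~ U(0.1, 0.5) per probe type, and
for M3 ω ~ U(0.4, 0.9) — moderate learning, softmax noise that keeps
accuracies in the 0.6–0.9 band of the task, and substantial but
heterogeneous reuse. `simulate_profile_subjects` generates
schema-identical tables with fixed per-cell Bernoulli accuracies; these
carry no sequential structure and exist to give the statistics stages
known ground truth.

What the synthetic cohorts do *not* emulate: attention lapses,
within-session parameter drift, reaction times, and any explicit
strategy use. Passing tests therefore certify the pipeline's internal
consistency (simulation ↔ likelihood ↔ recovery ↔ signatures), not that
these models describe any particular empirical dataset.

## Problem sizes and numerical choices

The test suite runs cohorts of 50 subjects per condition for the
headline signature, 20 subjects per generating class for model
recovery, and a 60-subject seeded grid for parameter recovery, with 3
or fewer simplex starts and a few hundred function evaluations per
start — sizes chosen so the full suite runs on a single CPU in well
under half an hour while every qualitative effect remains unambiguous.
Replay kernels are numba-compiled; the first call in a fresh
environment pays a one-time JIT cost. All randomness flows through
`numpy.random.SeedSequence` trees rooted at explicit seeds; rerunning
any stage with the same configuration is bit-reproducible.

## Known limitations

* The exact published forms of the update equations, the fitted
  optimizer settings, and the original WAIC-from-MLE procedure were not
  available; the conventions above (self-inclusive SR, mean-bootstrap
  feature updates, Laplace-WAIC, simplex fitting) are this package's
  own, each chosen to satisfy the published qualitative constraints
  (nonzero diagonals for unseen compounds, nonzero cross-factor blocks,
  first-trial transfer advantage).
* The mapping requires equal feature counts across phases;
  eigendecomposition-based size-mismatched generalization is out of
  scope.
* ω recovery is noisier than τ recovery: ω is identified only through
  transfer-phase probes and interacts with the discrete mapping, so
  individual estimates scatter even when rank correlations are high.
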