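# Methods

`shiftpower` measures the statistical power of two families of
diversification methods — state-dependent likelihood models (BiSSE) and
character-independent stepwise-AIC birth–death search — to detect a
single speciation-rate shift placed at a known node of a simulated,
dated, ultrametric phylogeny. Everything below is the package's own
account of what it computes and why.

## 1. Tree simulation

### Constant-rate birth–death, conditioned on crown age

`simulate_bd_tree(age, rates, seed)` runs a forward Gillespie birth–death
process started from **two lineages at the crown** for exactly `age`
time units. Every lineage waits an Exp(λ+µ) time, then speciates with
probability λ/(λ+µ) or goes extinct. Extinct lineages are pruned and
unary nodes suppressed. A run is rejected unless **both crown lineages
leave extant descendants**; this guarantees that the reconstructed tree's
crown age equals the requested age exactly (conditioning only on "≥ 2
survivors" would let the reconstructed crown slide rootward). The
rejection budget is 10,000 attempts per call; exceeding it raises an
explicit infeasibility error naming the (λ, µ, age) combination.

Node ages are the primary coordinates (tips pinned at exactly 0), so
simulated and grafted trees are ultrametric to machine precision, not
merely within tolerance.

Distributional check: for a pure-birth (Yule) process the expected tip
count of an age-conditioned crown is `2 e^(λt)` (each crown lineage's
progeny is geometric with mean `e^(λt)`, and conditioning is vacuous when
µ = 0); the test suite verifies the simulated mean over 10,000 runs to
within three standard errors.

### Composite single-shift trees (prune and graft)

A composite tree with one speciation-rate shift is built by:

1. simulating a *basetree* at rate λ0 with crown age `B_age`;
2. choosing uniformly at random one internal non-root clade whose
   **crown age** matches the target subtree age `S_age` within ±2.5%
   (candidates whose parent sits below `S_age` are skipped, since the
   graft could not fit);
3. simulating an independent *subtree* at rate λ1 > λ0 with crown age
   `S_age` and grafting it in place of the pruned clade. The subtree's
   stem length is set to `age(parent) − S_age`, so the composite is
   exactly ultrametric and the grafted crown sits at its own simulated
   age — the ±2.5% matching slack never leaks into the composite.

The grafted crown node is labelled `SHIFT` in emitted Newick; tips are
relabelled `b1..bn` (basetree) and `s1..sm` (subtree), and the binary
character used by the state-dependent analyses is defined as descent
from the graft node (state 1 = subtree). Crown-age (rather than
stem-age) matching is a deliberate choice: grafting equates the
subtree's crown with the pruned clade's crown, so the crown is the
quantity that must match.

### The two factorial designs

The generator's defaults are the study conditions, not tuning knobs.

**Design 1 (rate asymmetry).** λ0 = 0.2, µ0 = µ1 = 0.05; speciation
asymmetry λ1/λ0 ∈ {1.5, 2.5, 3.5, 4.5, 5.5}; relative subtree age
100·S_age/B_age ∈ {20, 40, 60}%; overall size classes
{50, 100, 150, 200, 300, 500} ± 10 tips. Per replicate, `B_age` is drawn
uniformly from [5, 35], the basetree and subtree are simulated, and the
attempt is accepted iff a matching clade exists and the composite tip
count lands in the size window. A cheap analytic screen
(expected tips `2e^{(λ−µ)t}` within 4× of the target) skips hopeless
draws before any simulation.

**Design 2 (tip ratio).** Asymmetry fixed at 2×; basetree:subtree
tip-ratio targets 9:1, 1:9, 1:19 at sizes {50, 100, 200, 400, 800} ± 10;
acceptance additionally requires each part within ±25% of its
ratio-implied target. λ0 is drawn from {0.2, 0.26, 0.28}, relative
subtree age uniformly from [30, 70]%, `B_age` uniformly from [5, 35];
the tip-count acceptance then acts as an automated calibration search
over these axes. One special case: (100 ± 10, 1:9) is geometrically
unattainable and is remapped to 1:8 with a logged notice. Replicates
within a cell therefore vary in (λ0, rel. age, B_age) rather than
sharing one pilot-calibrated triple; spot checks with several fixed
feasible triples produced indistinguishable detection power, so the
simpler scheme was kept.

Per-replicate seeds derive deterministically from
`(base seed, cell index, replicate index)`, so grids are byte-identical
across runs and reduced-replicate runs are prefixes of full runs.

### What the generator does and does not emulate

It produces complete, error-free, perfectly dated trees with exactly one
instantaneous speciation-rate shift and state assignment that matches
descent perfectly. Real data add topology and dating error, incomplete
and non-random sampling, multiple or gradual rate changes, and
character states that are imperfect proxies of the causal trait. Power
measured here is therefore an upper bound on what the corresponding
analyses achieve in practice.

## 2. Likelihood engines

### Birth–death (reconstructed process)

For a dated tree with n tips the constant-rate likelihood is written in
propagator form. With r = λ − µ and

    E(t)   = µ (1 − e^{−rt}) / (λ − µ e^{−rt})          (extinction prob.)
    φ(t)   = e^{−rt} · ( r / (λ − µ e^{−rt}) )²          (branch propagator)

the log-likelihood is

    ln L = (n−1) ln λ + Σ_branches [ ln φ(t_parent) − ln φ(t_child) ]
           − [ ln λ + 2 ln(1 − E(T)) ]       (survival conditioning)

The critical case λ = µ uses the limits E → λt/(1+λt),
φ → (1+λt)^{−2}; `expm1` keeps the expressions stable near r = 0. In
the Yule limit (µ = 0) this reduces to `(n−2) ln λ − λ·(total branch
time)`, which the tests pin against hand-derived constants. µ > λ is a
legitimate evaluation; λ ≤ 0 is rejected.

### Two-state Markov character (Mk2)

Felsenstein pruning with the closed-form 2×2 transition matrix
(stationary frequencies q10/q, q01/q and relaxation rate q = q01+q10).
Per-node rescaling guards underflow. Impossible data (e.g. both states
under q = 0) return a large negative sentinel (−10^10) rather than −∞ so
model-selection machinery can treat them as "always worse".

### State-dependent speciation/extinction (BiSSE)

Along every branch the system

    E0' = µ0 − (λ0+µ0+q01) E0 + q01 E1 + λ0 E0²
    D0' =    − (λ0+µ0+q01) D0 + q01 D1 + 2 λ0 E0 D0     (and 0 ↔ 1)

is integrated tipward→rootward with an embedded Cash–Karp 4(5)
Runge–Kutta pair (numba-compiled; default tolerances rel 1e-8, abs
1e-10). At nodes, `D_s = λ_s · D_left,s · D_right,s`; the D pair is
renormalized at every node with the log-scale accumulated. At the root,
states are weighted by their relative D values ("observed" weighting),
and survival conditioning divides by `Σ_s w_s λ_s (1 − E_s(T))²`. Both
conventions are switchable via `LikelihoodOptions` (the oracle tests
exercise equal weights and unconditioned evaluation).

Two independent oracles validate the engine: (i) with
λ0 = λ1, µ0 = µ1 the joint likelihood factorizes exactly into
`bd_loglik + mk2_loglik` under matched conventions, which the suite
checks to 1e-6 over random trees and parameter draws; (ii) a plain
scipy `solve_ivp` re-integration of the same equations agrees to ~1e-7
at unequal rates. Halving–tightening the integrator tolerances from
1e-6 to 1e-9 moves 500-tip log-likelihoods by < 1e-4.

## 3. Model fitting and likelihood-ratio detection

The six-parameter model (λ0, λ1, µ0, µ1, q01, q10) is constrained into
eight patterns by tying rate pairs equal — from the full model (k = 6)
to the all-equal null (k = 3). Each pattern is fitted by maximizing the
log-likelihood over log-scale parameters bounded in [1e-6, 20]:
Nelder–Mead from a moment-based start (λ from the crown-Yule estimate
`ln(n/2)/T`, µ = 0.1 λ, q = 0.01), polished with L-BFGS-B, with three
restarts jittered multiplicatively (σ = 0.5 on the log scale). A fit
that never achieves a finite likelihood is flagged non-converged and
excluded from model selection — it is never silently counted as a
non-detection.

Detection declares a speciation-rate shift iff a likelihood-ratio test
between an unequal-λ and an equal-λ model gives P < 0.05:

* **approach 1** — minimum-AIC member of {I, III, IV, VI} versus
  minimum-AIC member of {II, V, VII, VIII} (AIC ties break toward fewer
  parameters, then the lower model number);
* **approach 2** — model III (free λ, tied µ, free q) versus V;
* **approach 3** — model VI versus VIII.

The χ² degrees of freedom are the difference in free-parameter counts,
floored at one: the AIC-chosen pair of approach 1 need not be nested,
and the floor keeps the test defined in that case. A non-positive
statistic yields P = 1.

**Behavioral note.** In small trees whose character is heavily biased
toward the fast state (e.g. 5 of 50 tips in state 0), the equal-λ model
with free extinction and transition rates can reach nearly the full
model's likelihood by re-explaining the fast clade's proliferation as
lower extinction. Approach 1 then rarely rejects, while approach 2 —
which denies the equal-λ side that freedom — retains substantial power.
This is a property of honestly maximized likelihoods in that regime,
not an optimizer artifact: the compensating optimum was verified
against the independent integrator and is robust to 1–10 restarts.
Users comparing approaches on small, strongly tip-biased data should
expect exactly this divergence.

## 4. Stepwise-AIC birth–death search

The tree is partitioned into pieces, each with its own (λ, µ); a shift
placed at a node applies from its stem edge downward. The total
log-likelihood is the sum of per-piece propagator-form likelihoods
(§2): each internal node contributes ln λ of its piece, each branch
segment contributes its φ-ratio under the piece's own rates, and
survival conditioning is applied once, at the root piece. With equal
rates everywhere the sum telescopes exactly to the single-piece value —
the split-consistency oracle, checked to 1e-8.

Because the decomposition is separable, each stepwise candidate (every
internal non-root node not already a shift point) requires refitting
only the two affected pieces: 2-parameter Nelder–Mead over
(ln λ, logit of µ/λ), started from the parent piece's rates so a split
can never lose likelihood — making the accepted-model log-likelihood
trace provably non-decreasing. Terminal edges are not candidates: a
single-edge piece has no branching events and its rates are
unidentifiable without external richness information.

Model size is k = 2·(pieces) + (pieces − 1) locations; the small-sample
correction uses AICc = AIC + 2k(k+1)/(n−k−1) with n = the number of
internal nodes. A new shift is accepted iff AICc improves by more than
a threshold that **grows with tree size**: the package's default equals
`χ²₂(1 − 0.05/B) − 6` where B is the number of candidate edges — the
AICc drop at which a Bonferroni-corrected 2-df likelihood-ratio test at
family-wise level 0.05 would reject, net of the 6-point AIC penalty the
three extra parameters already pay. This mirrors the stepwise-AIC
convention that the required improvement scales with the number of
branches tried, while giving the rule an explicit error-rate
interpretation; it is deliberately conservative relative to historical
defaults of stepwise-AIC shift searches, and a `fixed_threshold`
override is available. On ~100-tip constant-rate trees the default
keeps the false-shift rate well under 20%.

Detection requires both a multi-rate selected model **and** the shift
located exactly at the graft node (stem placement counts as the node).

## 5. Power and error statistics

* power = detected / analyzed replicates per cell;
* estimated asymmetry = median over replicates of fitted λ1/λ0
  (full-model fit for the likelihood detectors; the two-piece rates for
  the stepwise detector, with undetected replicates contributing ratio
  1, making the stepwise median conservative);
* asymmetry error = (estimated − true)/true (0 = none, sign = direction);
* rate error = median of estimated/true λ (1 = none), separately for λ0
  and λ1.

Aggregation is a pure function of the per-replicate log, so
re-summarizing a saved log reproduces the summary bit-for-bit, and
replicate seeds are bound to replicates (not workers), so results are
identical for any degree of parallelism.

## 6. Problem sizes

The full factorial designs (4,500 + 1,500 trees at 50–100 replicates
per cell) are supported through `GridSpec`/`run_experiment` and the CLI.
The package's own test suite and the acceptance script run desk-scale
versions chosen as 20 replicates per examined cell — enough to place a
power estimate within a ±0.2 binomial band — and single seeded
instances for directional checks (e.g. parameter recovery on ten
500-tip trees).

## 7. Known limitations

* Single instantaneous shift only; no time-varying rates, mass
  extinctions, multiple shifts, or incomplete sampling.
* The approach-1/approach-2 divergence described in §3 means headline
  "power of the likelihood method" figures are sensitive to the model
  pool offered to AIC in small, tip-biased regimes.
* The stepwise threshold convention is the package's own calibrated
  rule; other implementations of stepwise shift searches use laxer
  data-driven thresholds and will report more (true and false) shifts.
* Extinction-rate estimates are not assessed; they are known to be
  poorly identified from extant-only trees and are treated as nuisance
  parameters throughout.
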