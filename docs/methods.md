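# Methods

## Game model and simulator

The simulator plays the pairwise Iterated Prisoner's Dilemma with per-round
payoffs R=3, S=0, T=4, P=1 (so T > R > P > S and 2R > T + S: defection is
tempting each round, but sustained mutual cooperation beats alternating
exploitation).  Two matching treatments are emulated:

- **FP (fixed partners):** the same perfect matching every round.  The
  default pairing is adjacent positions in the cohort list, so a cohort
  ordered in intended pairs keeps those pairs — this is what lets tests
  plant, say, "AllC pairs" deliberately.
- **SP (shuffled partners):** an independent uniform perfect matching each
  round, rejection-sampled so that no player keeps the previous round's
  opponent.  Nothing stronger is enforced — repeats two or more rounds
  apart are allowed, the weakest reading of "the opponent changes each
  round".  SP therefore needs at least 4 players.

Agents are stochastic **memory-one strategies**: an opening cooperation
probability `p_init` plus four conditional probabilities
`(p_cc, p_cd, p_dc, p_dd)` indexed by the previous round's (own, opponent)
actions.  The archetype registry holds AllC (1,1,1,1,1), AllD (0,0,0,0,0),
TFT (1,1,0,1,0), GTFT (1,1,1/3,1,1/3), WSLS (1,1,0,0,1), Grim (1,1,0,0,0)
and Random (.5,.5,.5,.5,.5), written (p_init, p_cc, p_cd, p_dc, p_dd).

**Execution noise** ε flips the *intended* action with probability ε,
independently per decision; the co-player observes the executed action, and
the player's own memory also carries the executed action.  A strategy with
noise ε therefore exhibits conditional cooperation ε + (1 − 2ε)p, not p —
the quantity an estimator can actually recover from play.  In SP the context
a player carries into a round refers to the *previous* partner, mirroring
what participants in shuffled treatments actually see.

Default study conditions: 100 rounds (agents are memory-one, so the unknown
horizon is irrelevant to them, but the length matches the experiments the
cohort sizes come from), 92 players in FP and 96 in SP, noise 0.05.  The
default mixed cohort draws archetypes with weights AllC .15, AllD .15,
TFT .20, GTFT .10, WSLS .15, Grim .10, Random .15 — conditional reciprocators
deliberately in the majority, with unconditional and noise players present,
which is the qualitative mix long IPD experiments report.

What the generator does *not* emulate: learning or strategy switching within
a game, memory beyond one round, session structure, and any dependence of
behavior on accumulated payoffs.  Recovery results on synthetic cohorts
therefore certify the inference chain (encoding → clustering → HMM →
archetype call), not the adequacy of the memory-one model for human data.

## Encoding

Context (CC, CD, DC, DD; own action first) plus current action maps to
symbol `2*context_index + (0 for C, 1 for D)`.  Round 1 has no context and
yields no symbol.  Windowed analyses keep cross-window contexts: the first
symbol of rounds 26–50 uses round 25's actions, because participants saw the
previous round regardless of how the analyst cuts the data; hence window 1
has 24 symbols and later windows 25.  A conditional-cooperation probability
for a context a player never experienced is carried as NaN, never imputed.

## Clustering

Both levels use scikit-learn K-means (10 seeded restarts, best inertia).
Features are raw counts — with a fixed round count, counts and frequencies
are proportional; a `normalize` switch divides by sequence length for
variable-length imports.  Contexts counts feed level 1 (K_max 8), cooperative
-response counts feed level 2 (K_max 6, clusters smaller than 4 pass through
unsplit).  Contextual clusters are lettered A, B, C… by decreasing mean CC
count, so A is always the most mutually cooperative group.

**Elbow selection:** inertias for k = 1..K_max are made non-increasing
(running minimum), both axes are min-max normalized, and k* is the interior
point with the largest vertical distance below the chord joining the curve's
endpoints, ties toward smaller k.  A flat curve — identical players — yields
k* = 1 and no silhouette.  The candidate range is additionally capped at the
number of distinct feature rows.

**Silhouette:** mean over points of (b − a)/max(a, b) with Euclidean
distances (scikit-learn's implementation; singletons contribute 0).  It is
reported, not optimized.

## Left-to-right HMM

Per behavioral sub-cluster, all members' symbol sequences are pooled as
independent sequences and fitted by multi-sequence Baum–Welch under two
structural constraints held exactly at every iteration: π = (1, 0, …, 0) and
an upper-triangular transition matrix (skips forward allowed; a `chain`
option restricts to self-loop + successor).  Both survive EM automatically —
expected-count updates cannot resurrect a structural zero — and π is simply
not re-estimated.  Emissions are initialized from flat Dirichlet draws,
transitions uniform over the allowed entries; 5 seeded restarts, relative
tolerance 1e−4, at most 500 iterations; the best restart by final
log-likelihood is returned together with its per-iteration history.  States
a run never visits keep their current rows rather than dividing by zero.

The forward pass uses the standard scaling recursion; likelihood evaluation
is vectorized across equal-length sequences.

**State-count selection.**  The number of states S is grown from 1: the
S-state fit is kept only while it improves the log-likelihood by at least a
relative δ = 0.01 over the kept model (the comparison is inclusive, so a
zero gain on an already perfect fit stops growth).  An alternative `bic`
criterion minimizes −2·loglik + p·log(N) with p = S(S+1)/2 − S free
transitions plus 7S free emissions (π fixed).  Both are pragmatic small-model
criteria chosen here because the rendered machines are meant to be readable;
neither reproduces any particular published selection procedure.  S_max
defaults to 4.

**Display pruning.**  For rendering, emissions ≤ 0.05 and transitions ≤ 0.01
are hidden (thresholds inclusive); the pruned copy is display-only and not
renormalized.  DOT output labels each state with its surviving
(context)action emissions, bolds the initial state, and draws surviving
transitions including self-loops.

## Pipeline, reports and archetype calls

Per sub-cluster the report pools members' context counts and cooperative
responses; conditional cooperation is the ratio with binomial standard error
sqrt(p(1−p)/n) per context.  The nearest archetype is chosen by L1 distance
on (p_cc, p_cd, p_dc, p_dd), NaN entries excluded from both sides, ties
broken by registry order.  Sub-clusters partition contextual clusters, which
partition the cohort; everything is deterministic given the config seed.

The Dryad-style importer is a column-mapping adapter: it renames a deposited
long-format table's columns onto the native schema, translates action labels
and recomputes payoffs if absent, making no assumption about session sizing
or re-pairing rules beyond the schema itself.

## Validation design and problem sizes

The test-suite benchmarks run at sizes chosen to keep the full suite around
a minute while leaving no property under-sampled: forward-algorithm oracle
on 100 random models (S ≤ 3, length ≤ 6) against brute-force path
enumeration (tolerance 1e−10), with hmmlearn as an independent cross-check
of the forward scores; 2-state parameter recovery from 50 sequences × 100
symbols (elementwise 0.05); planted-partition recovery on cohorts of AllC,
AllD and Random pairs (30 each, noise 0.05, 5 seeds) — three groups chosen
to be *well separated* in context space, which is what contextual clustering
can legitimately be asked to recover (a TFT-vs-AllD pair, by contrast,
collapses into the mutual-defection context cloud under noise and is not
separable from AllD pairs by any context-based method); and end-to-end
archetype recovery on pure single-archetype FP cohorts (30 players each),
scored against the planted strategy's *executed* conditional cooperation
ε + (1 − 2ε)p, since that is what was planted and what a consistent
estimator should converge to.

## Known limitations

- The elbow rule always returns an interior k for a non-flat inertia curve,
  so noisy but structureless cohorts are still split; downstream estimates
  from very small sub-clusters (1–3 players) carry large binomial errors on
  rarely experienced contexts.
- Conditional-cooperation estimates for contexts observed a handful of times
  are reported as-is with their standard errors; no shrinkage is applied.
- The HMM alphabet size is parametric in the code but only the 8-symbol
  memory-one alphabet is exercised; memory-two (64-symbol) analyses would
  need new validation.
- Archetype calls name the *nearest* textbook strategy; a large reported L1
  distance means "none of the archetypes fits well", not a confident match.
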