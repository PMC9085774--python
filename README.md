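# ipdinfer

Strategy inference for **long Iterated Prisoner's Dilemma (IPD) experiments**.

Behavioral experiments on cooperation collect thousands of cooperate/defect
decisions but rarely say *which strategies* people actually used.  `ipdinfer`
implements an unsupervised inference chain for long pairwise IPD treatments —
fixed partners (FP) or shuffled partners (SP) — and a synthetic cohort
simulator of noisy memory-one strategies so the whole chain can be validated
against planted ground truth.  It is aimed at experimental economists and
evolutionary game theorists working with long-format game tables.

## The method

Play uses payoffs R=3 (mutual cooperation), S=0/T=4 (sucker/temptation),
P=1 (mutual defection), satisfying T > R > P > S and 2R > T + S.

1. **Conditional-action encoding.** The previous round's (own, opponent)
   action pair — the *context*, one of CC, CD, DC, DD — combined with the
   current action gives one of 8 symbols: (CC)C=0, (CC)D=1, (CD)C=2, (CD)D=3,
   (DC)C=4, (DC)D=5, (DD)C=6, (DD)D=7.  A 100-round game becomes a 99-symbol
   sequence per player (round 1 has no context).
2. **Contextual clustering.** K-means on each player's four context counts
   (n_CC, n_CD, n_DC, n_DD); k chosen at the knee of the inertia curve
   (largest vertical distance below the chord between its endpoints), quality
   reported as the mean silhouette coefficient (b − a)/max(a, b).
3. **Behavioral sub-clustering.** Within each contextual cluster, K-means on
   the cooperative-response counts (c_CC … c_DD) separates players who faced
   the same situations but answered them differently.
4. **Left-to-right HMM per sub-cluster.** Pooled symbol sequences are fitted
   by a multinomial hidden Markov model with π = e₁ and an upper-triangular
   transition matrix (no returns to earlier states), trained by constrained
   Baum–Welch; the state count is chosen by a relative log-likelihood gain
   rule (or BIC).  For display, emissions ≤ 0.05 and transitions ≤ 0.01 are
   hidden and the model is rendered as GraphViz DOT.
5. **Archetype calls.** Each sub-cluster's conditional-cooperation vector
   (p(C|CC), p(C|CD), p(C|DC), p(C|DD)) is matched to the nearest memory-one
   archetype (AllC, AllD, TFT, GTFT, WSLS, Grim, Random) by L1 distance.
6. **Windowed analysis.** The same chain re-run on round windows 1–25, 26–50,
   51–75, 76–100 exposes the early learning phase versus settled behavior.

## Worked example

```sh
python examples/full_pipeline.py
```

runs the full chain on a simulated 60-player FP treatment (mixed archetypes,
5% execution noise) and prints:

```
contextual clusters: 3 (silhouette 0.4491)
treatment cluster  n  n_subclusters  silhouette
       FP       A 24              3    0.460115
       FP       B 15              2    0.698546
       FP       C 21              2    0.816602

per sub-cluster: conditional cooperation (CC, CD, DC, DD), call, HMM size
  A.2 (n=4): [0.96, 0.92, 1.00, 1.00] -> AllC (L1=0.12, majority planted: AllC, S=4)
  B.0 (n=14): [0.79, 0.14, 0.20, 0.85] -> WSLS (L1=0.70, majority planted: WSLS, S=4)
  C.1 (n=4): [0.97, 0.00, 0.09, 0.04] -> Grim (L1=0.16, majority planted: Grim, S=3)
  ...
```

Cluster A collects the mutually cooperative players, C the defect-dominated
ones, B sits in between; each sub-cluster's four numbers are its pooled
cooperation probabilities after contexts CC/CD/DC/DD, and the call names the
closest textbook strategy (B.0's lose-shift signature — cooperate after CC
and DD, defect after CD and DC — is WSLS).  Other examples:
`simulate_cohort.py`, `encode_profiles.py`, `cluster_players.py`,
`fit_hmm.py`.

A thin CLI wraps the same stages:

```sh
ipdinfer simulate --mode FP --players 92 --rounds 100 --noise 0.05 --seed 1 --out games.csv
ipdinfer analyze --games games.csv --out bundle/ --seed 1
ipdinfer windows --games games.csv --out windows/ --window-size 25
ipdinfer report --bundle bundle/
```

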