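# Methods

This note documents the models and procedures implemented in `specfdr`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Spectra, libraries and preprocessing

A spectrum is a precursor m/z plus a peak list (mass in Da, raw intensity);
all library processing assumes positive mode and singly protonated ions
([M+H]+, proton mass 1.00727646688 Da). Library inclusion requires positive
ion mode, a compound mass strictly below 1000 Da, and at least five peaks
with relative intensity above 2% of the base peak; when a structure-derived
monoisotopic mass is present, the precursor must agree with it to 10 p.p.m.
Spectra of one compound recorded at different collision energies are merged
by pooling peaks and clustering within the matching tolerance; each cluster
keeps the mass and intensity of its most intense member. Maximum (rather
than summed) intensities preserve the relative-intensity profile that the
informative-peak filter evaluates; a sum rule would inflate peaks measured
at many collision energies.

Mass matching throughout uses max(10 p.p.m. relative, 2 mDa absolute) — the
permissive combination, because below ~200 Da the p.p.m. window alone falls
under realistic instrument accuracy. Decoy generation uses a plain 5 p.p.m.
separation rule between decoy peaks.

## Fragmentation trees and noise filtering

A fragmentation tree assigns molecular formulas (alphabet C, H, N, O, P, S,
F, Cl, Br, I) to a subset of peaks; edges carry neutral losses, and child
formula + loss = parent formula along every edge. Trees are exchanged in a
small DOT dialect (node label `FORMULA\nmass`, edge label = loss formula,
optional `intensity` attribute; unknown attributes ignored). Noise
filtering keeps exactly the peaks matching a tree-node mass, with their
original intensities; spectra left empty or precursor-only are dropped.

Computing trees from spectra is a hard global optimization and out of scope
here; trees are consumed as input. For fixtures only, a greedy annotator
attaches each peak (descending mass) to the first existing node from which
a single loss out of a 14-loss alphabet (H2, CH2, NH3, H2O, C2H2, HCN, CO,
CH2O, CH4O, C2H4, C2H2O, CO2, CH2O2, C3H6) reproduces the peak mass. All
alphabet losses differ pairwise by far more than the matching tolerance, so
the greedy assignment is mass-unambiguous.

## Scoring

Spectrum–spectrum similarity is a normalized dot product over an optimal
one-to-one peak matching. Variants differ in peak weight w and matching:
`cosine` (w = I), `massbank` (w = m²·I^0.5, emphasizing heavy
structure-specific fragments), `gnps` (w = I^0.5 with *shifted* matching: a
pair may also be displaced by the precursor-mass difference, so fragments
sharing a neutral loss from their precursor align — the "modified cosine").
The exact weight conventions are documented stand-ins for the production
scores of the public platforms, which are not specified to formula level in
the open literature; they are swappable via the `variant` parameter.

The matching is an exact maximum-weight bipartite matching
(`scipy.optimize.linear_sum_assignment`) over tolerance-compatible
candidate pairs; greedy matching would be peak-order-dependent, and
exactness is what makes the brute-force enumeration oracle in the test
suite meaningful. Weights are L2-normalized over the full peak list, so
self-similarity is exactly 1. Library search returns the best-scoring
reference per query, subject to a minimum matched-peak count, with ties
broken toward the lexicographically smaller identifier.

## Decoy libraries

All three constructions conserve, per entry, the target's precursor mass
and intensity multiset, so target and decoy libraries are indistinguishable
in per-spectrum summary statistics and any precursor window admits equally
many target and decoy references. Drawn masses above the precursor or
within 5 p.p.m. of an already drawn mass are rejected. Intensities are
assigned to drawn masses by mass rank (smallest decoy mass gets the
intensity of the smallest target mass), preserving the intensity-vs-rank
profile. The naive method applies the same hygiene rules as the
spectrum-based one to keep the constructions comparable.

The spectrum-based candidate set is persistent and growing: each decoy ion
recruits five uniformly drawn fragments from the library spectra containing
that ion (all, if fewer than five); candidates are drawn without
replacement; when the set runs dry the remaining slots fall back to naive
draws (logged).

For the tree-based method, n (edges requiring re-grafting if node v became
root) is computed operationally: propagate formulas outward from v once,
counting edges whose child formula goes invalid and not descending below
them. The new root is sampled with probability ∝ 1/(n+1). Invalid subtrees
are re-attached to a uniformly drawn valid node, re-propagating inside the
subtree, with at most 100 attempts per subtree before its peaks are dropped
(logged; this keeps generation total). Distinct re-rooted paths can sum to
the same total formula; such mass collisions are dropped and logged rather
than silently merged, so intensity-multiset conservation is auditable.

## FDR estimation

Separated target–decoy: target and decoy hit lists are merged and sorted by
score, decoys first at ties (conservative). At each target-hit threshold t,
FDR(t) = PIT·D(t)/T(t); q-values are the running minimum of FDR over
thresholds at or below each hit's score. PIT = 1 recovers the classical
separated estimator. The decoy p-value of a score is the fraction of decoy
hits strictly above it (an add-one variant is available for users who
cannot work with p = 0).

Empirical Bayes: scores s ∈ (0, 1] follow
π₀·Gamma(s; a, b) + (1−π₀)·g(1−s; θ), with g one of Gamma, Gumbel or
Weibull ("mirrored": applied to 1 − s so its mass sits at high scores;
the mirroring point is 1 because cosine-family scores are bounded by 1).
EM alternates responsibilities with exact *weighted maximum-likelihood*
M-steps per component (Gamma via the digamma equation, Gumbel and Weibull
via their profile equations, each solved by bracketed root finding); an
update is rejected if it would lower the expected complete-data
log-likelihood, so the observed log-likelihood is non-decreasing (a
generalized EM). Initialization is deterministic: moments on the lower /
upper score halves, π₀ = 0.5; convergence at |Δ log L| < 1e−6 or 500
iterations. With the family unspecified, all three are fitted and the
maximum-likelihood one kept. PEP(s) = π₀f₀/(π₀f₀+(1−π₀)f₁) (set to 1 where
the total density vanishes); FDR(t) is the mean PEP above t; PIT = π₀,
which for normalized densities equals the area under the scaled
false-component curve. The fit is refused below 50 scores, where the
mixture is not identifiable; the target–decoy route remains available.

Known analytic quirk: far above all data (s → 1) the mirrored Gumbel's
doubly exponential tail can dip under the Gamma tail, so PEP may tick
upward where both densities are ≈ 0; this is outside the decision-relevant
range and left as is.

## Synthetic benchmark

The generator builds a world in which ground truth is known and the decoy
premise can hold. Compounds get random CHNOS formulas (C10–C30, mass
150–950 Da). Each fragmentation tree has a **uniform random unrooted
topology** (random Prüfer sequence) rooted at a uniformly chosen node, with
edge losses drawn from the 14-loss alphabet under validity, ≥ 55 Da and
pairwise-separation constraints. The uniform-topology choice is
deliberate: trees grown outward from the root would give re-rooted decoy
trees systematically deeper loss paths than target trees, making the decoy
score distribution stochastically smaller than the false-target one — a
fixture artifact, not a property of the method. With root-exchangeable
topology, re-rooting preserves the tree distribution, which is precisely
the "decoys mimic targets" premise under test.

Library spectra take the tree-node ion masses (fragment jitter ±3 p.p.m.,
log-uniform intensities over 1.2 decades, so every fragment clears the 2%
filter) plus 0–3 low-intensity noise peaks. Queries are perturbed copies:
10% peak dropout, ±5 p.p.m. mass jitter, lognormal intensity noise
(σ = 0.3), 0–5 noise peaks. Query composition: 50% true replicates, an
isomer fraction (default 10%) of compounds absent from the library whose
spectra copy a library entry with 30% of peaks shifted by a random
small-loss mass (same precursor), and unrelated null compounds for the
rest. Benchmark searches use the shifted `gnps` score with
min-matched-peaks 3 and no precursor window — synthetic precursor masses
are continuous, so a window would leave null queries without eligible
references; with real libraries a ±10 p.p.m. window is the norm.

What the benchmark emulates: shared fragmentation chemistry (the common
loss alphabet is why unrelated compounds reach non-trivial modified-cosine
scores), near-miss isomers, instrument noise. What it does not: real
fragmentation energetics, adducts/isotopes, intensity structure of real
spectra, precursor-mass collisions. Passing calibration here shows the
estimators are correct under the stated model, not that any particular
real-data FDR is exact.

## Evaluation harness and problem sizes

True q-values come from labeled correctness (ratio of false hits above
threshold, monotonized); the calibration report tabulates estimated vs true
q, the KS statistic of false-hit decoy p-values against uniformity, and the
maximum absolute deviation inside the true-q band [0.05, 0.3]. The standard
study sizes are 200 compounds with 200 queries (null-model checks) and 500
queries (calibration), ten decoy replicates where replication matters;
these sizes put ≥ 100 false hits behind each KS test and ≥ 20 hits in the
calibration band while keeping a full run in minutes on one CPU.

## Known limitations

* **Top-of-list granularity.** Estimated FDR has steps of PIT·1/T(t); at
  the top of the hit list a single decoy hit moves q by ≥ 0.05. The
  1/(n+1) re-rooting law always gives the original root weight 1, so a
  noticeable fraction of tree decoys equal their noise-filtered targets and
  occasionally tie with top target hits — between decoy replicates, q at
  the first ~10 ranks can therefore swing by more than 0.05. Averaging
  q-values over several decoy libraries smooths the curve but not this
  granularity.
* **Isomer blind spot.** False hits from near-identical isomers score above
  anything a decoy library can produce, so decoy-based estimates
  under-state the FDR in exactly the regions where such hits accumulate;
  with the default 10% isomer queries the estimated q undershoots the true
  q by up to ~0.05–0.1 inside the [0.05, 0.3] band (the naive decoy is
  several times worse). The empirical-Bayes route is partially robust
  (isomer scores load on its false component) but inherits its parametric
  assumptions.
* The MassBank/GNPS score formulas are documented conventions, not
  byte-level reproductions; the toy tree annotator is fixture plumbing, not
  a fragmentation-tree solver; mix-max and target-decoy competition
  estimators are not implemented.
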