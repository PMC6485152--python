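# Methods

## Model and assumptions

All measures assume a single-rooted **tree** taxonomy (one parent per node;
no DAG-shaped ontologies such as the full UMLS graph). Levels are 1-based
from the root because the path IC is defined as exactly that number. For
ICD-10-style inputs the hierarchy can be derived lexically: virtual root →
chapter (first letter) → category (three characters) → subcategory (five
characters, e.g. `M06.9`) → expansion code (full string, e.g. `I00.x01`).
This five-level reading contains no block layer (A00–A09 style groupings);
users who want block layers can supply an explicit child–parent edge list,
which is the general input format. Codes lacking deeper characters attach
at their natural depth, so mixed-granularity inputs are legal.

Although the source formulas are usually called similarities, every one of
them returns 0 for maximal resemblance, so the package uniformly calls
them **distances**. Two deliberate formula-level choices:

- **CS #3 exponent sign.** The two-parameter form is implemented as
  `1 − exp(−α·Δ)·tanh(β·IC(c))` with Δ = IC(a)+IC(b)−2·IC(c) ≥ 0. The
  decaying exponent keeps the value inside [0, 1] and makes the distance
  grow as the concepts separate from their LCA; a growing exponent would
  invert the ranking behaviour and leave the unit interval. Note that
  `li(a, a) = 1 − tanh(β·IC(a)) > 0`: identity is not at distance zero
  under this formula. Also, `li(root, root) = 1` only under ontology IC
  (where IC(root)=0); under path IC the root has IC 1 by definition, so
  the identity value there is `1 − tanh(β)`.
- **CS #4's IC(l).** "The deepest level" has one IC value under path IC
  (the total level count L) but not under ontology IC; IC(l) is therefore
  taken as the maximum IC over all nodes, which reduces to L for path IC
  and is well defined for both.

The ontology IC uses the natural logarithm. The base cancels inside CS #2
(a ratio of ICs — asserted in the tests) and only rescales the exponents
of CS #3, so nothing downstream depends on the choice.

**SS #8 normalization.** The raw matching total grows with set size, so it
is divided by the number of matched edges min(|A|,|B|). This keeps the
result in [0, 1] and comparable both across sizes and with the other SS
measures. Unequal sizes are solved natively as a rectangular assignment
(no dummy padding); surplus codes of the larger set are deliberately
ignored — that asymmetry of attention is precisely what makes the
bipartite measure robust to redundant codes. Ties among equally optimal
matchings are unconstrained: only the total is contractual.

Degenerate inputs are errors, not defaults: empty sets, the virtual root
inside a code set, k = 0 prototypes, and sub-2-point separation curves all
raise, because silent defaults would corrupt parameter sweeps. One
exception: `cs_wu(root, root)` under ontology IC is 0/0 and returns 0
(identity takes precedence) with a warning to exclude the root from sets.

## Prototypes and the HLOS experiment

Prototype ranking is **ascending by summed distance**: the code with the
smallest total distance to all diagnosis occurrences of the stratum is the
most central, hence the most prototypical. The score sums over the
**multiset** of occurrences by default, so common diagnoses dominate
centrality; a `distinct=True` switch gives the set reading. Self-pairs are
included (they contribute 0 under CS #2 and a small constant under CS #3,
never changing ascending ranks under CS #2). Ties are broken
lexicographically by code, making prototypes deterministic and
patient-order invariant.

The four strata cross age 18–50 vs ≥ 51 years with HLOS 1–18 vs 19–50
days. The classifier compares a patient's code set against the top-k sets
of the short and long prototypes of the patient's *age* stratum and
predicts the nearer one's class; the positive class is short HLOS
(≤ 18 days) throughout, and exact distance ties resolve to "short" with a
logged warning so that runs are reproducible (the bias direction is
documented rather than hidden). Precision is reported as 0 (flagged) when
no positives are predicted. Train/test splitting is the caller's choice;
`split_cohort` provides a seeded split stratified by age stratum × HLOS
class.

Prototype separation between two strata at size k is the all-pairs mean
distance between their top-k code sets, and the area under the
separation-vs-k curve (trapezoidal) summarizes a CS method's separation
ability across sizes.

MDS is **classical (Torgerson)**: double-center −½·D², eigendecompose,
scale the top eigenvectors by √eigenvalue. It is deterministic up to sign
and rotation, so tests compare embedded distances, never raw coordinates.
Negative eigenvalues (non-Euclidean input) are clipped to zero.

## Synthetic data

No clinical data ships with the package; the generator produces the study
conditions instead. Defaults, chosen once:

- **Taxonomy**: a full 5-level tree with branching (6, 4, 4, 3) → 288
  leaves across 6 chapters. Five levels mirror the ICD-10-style depth; six
  chapters leave one disjoint core branch per stratum plus two shared
  background branches.
- **Cohort**: stratum sizes 283 / 82 / 257 / 83 (young-short, young-long,
  old-short, old-long — the predefined four-way stratification's cell
  counts); codes per patient from a truncated Poisson, mean 4, min 1
  (patient diagnosis sets in this setting average about 4 distinct codes);
  ages uniform within the stratum band (capped at 90 for the open-ended
  elderly band), HLOS uniform within the band.
- **Mixture**: each patient draws a `core_fraction` share (default 0.7) of
  codes from their stratum's core pool and the rest from the shared
  background. `core_fraction=1` gives fully disjoint strata,
  `core_fraction=0` exchangeable ones.

The two-pool mixture is the simplest structure that reproduces the
qualitative phenomena the experiments probe: recoverable prototypes and
near-perfect classification when cores are disjoint, chance-level
behaviour when strata are exchangeable, and — in the dedicated dilution
fixture, where small cores also circulate in everyone's background pool —
converging prototype supports at large k that erode the bipartite
measure's discrimination while the averaging measures stay stable. It does
*not* emulate real EMR features: diagnosis frequencies are uniform within
a pool (no power-law prevalence), codes are independent given the stratum
(no comorbidity correlation structure), and there are no care trajectories
or visit sequences. Passing tests therefore demonstrate correctness of the
measures and the *existence* of the qualitative set-size effects, not
clinical performance on real cohorts.

All randomness flows through one `numpy` generator seeded per call; no
global state. CSV floats are written with 12 significant digits so
identical seeded runs produce byte-identical outputs.

## Problem sizes in the shipped experiments

The recovery experiment uses the default 705-patient cohort (70/30 split,
seeds 1–5, all ten ⟨IC,CS,SS⟩ combinations, prototype sizes 20 and 40).
The dilution fixture uses 600 patients (150 per stratum), 12-code cores,
`core_fraction` 0.5, and prototype sizes 5–100. The Hungarian matcher is
cross-checked against exhaustive enumeration on all matrix shapes up to
6×6 (108 random instances), and the ordering properties on 1000 random
set pairs. These sizes were picked so the whole suite recomputes every
claim from scratch in well under a minute per experiment.

## Known limitations

- Tree taxonomies only; no multi-parent ontologies.
- `li` violates the identity axiom (distance 0 at a = b) by construction;
  code deduplication before SS computation, not the CS formula, is what
  keeps SS identities at 0 for the matching-based measure.
- The exchangeable-cohort check tests *independence* of predictions from
  truth (accuracy within a 3σ binomial band of the independence
  expectation); it is not a formal hypothesis test with controlled size
  across all ten combinations.
- The bipartite crossover point depends on the fixture's pool sizes and is
  not a portable constant; only its existence is asserted.
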