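# Methods

## Response model

The reduced reparameterized unified model (RRUM) gives the probability of a
correct response as

P(X_j = 1 | α) = π\*_j · ∏_{k: q_jk=1} (r\*_jk)^(1−α_k),

with π\*_j ∈ (0,1) the success probability of an examinee mastering every
attribute item *j* requires, and r\*_jk ∈ (0,1) the multiplicative penalty
for each required-but-unmastered attribute (the ratio of the non-master's to
the master's success probability on that attribute). The model is
non-compensatory: every missing required attribute discounts the success
probability, and mastery of unrequired attributes is irrelevant. A residual
continuous-ability term sometimes named alongside the full reparameterized
unified model is not part of the reduced model's response function and is
not implemented. Likewise the per-attribute factors whose product defines
π\*_j are never needed individually; only π\*_j is stored and simulated.

The candidate space is all 2^K mastery profiles, ordered lexicographically
with attribute 1 as the most significant bit. Every module indexes profiles
in this order.

## Posterior machinery

The examinee's posterior over the 2^K profiles starts uniform and is
updated after every response by multiplying in the item's Bernoulli
likelihood. Likelihoods accumulate as log-sums; the normalized mass is a
max-shifted softmax, so long response strings cannot underflow (at the
default test length of 10 this is insurance, not necessity). With the
uniform prior, MAP classification coincides with maximum likelihood. MAP
ties — common early in a session, when profiles agreeing on all attributes
measured so far have identical likelihoods — are broken uniformly at random
from the session's generator. Breaking ties by lowest index instead would
systematically favour profiles with few mastered attributes.

## Item information and attribute discrimination

All KL quantities use the natural logarithm (values in nats); a fixed
change of base would rescale every index and every ADI bound jointly and
change no selection decision. Per item, the (2^K × 2^K) matrix of pairwise
divergences D_j(α_u ‖ α_v) between response distributions is precomputed
once at pool construction (≈6 MB for a 775-item, K=5 pool) and reused by
PWKL, MPWKL and the ADI computations; PWKL for all 775 items then costs one
(775×32)·(32,) product per step.

The attribute discrimination index of item *j* for attribute *k* averages
D_j over the 2^(K−1) profile pairs that differ only in attribute *k* — in
both directions, since KL is asymmetric — with uniform weights 1/2^(K−1),
and the item's per-attribute ADI is the mean of the two directions. Items
with q_jk = 0 have ADI exactly zero for *k*: their response distribution
does not depend on α_k. Only the uniform ("A") weighting is implemented;
weighting pairs by an assumed population distribution over knowledge states
is a documented extension point, deliberately not built, because the
uniform variant is a property of the item alone.

## Selection and balancing

At each step the engine computes the configured information index
(PWKL at the current MAP estimate, or MPWKL over the full posterior) for
all unadministered items. Under a coverage constraint, the index is
multiplied by the attribute-balance index (ABI): the product over the
item's measured attributes of the remaining per-attribute deficit —
(B_k − b_k)/B_k for item counts, (ADI_k − adi_k)/ADI_k for accumulated
discrimination — with each factor floored at zero. Flooring per factor
rather than flooring the final product avoids two overshot attributes
multiplying into a spuriously positive index; the literal product-level
floor is available behind `SelectionConfig(clamp="product")` for
sensitivity checks. While any unadministered item has ABI > 0, the argmax
runs over information × ABI restricted to those items; once every
candidate's ABI is zero (all constraints met, in practice) selection falls
back to the bare information index, so a constrained session becomes
indistinguishable from an unconstrained one after its constraints are
satisfied. Argmax ties are broken uniformly at random.

Each session administers a fixed number of items (default L = 10). The
first item is drawn uniformly at random from the pool and its attribute
coverage counts toward the constraint accumulators like any other item.

## Study design and the synthetic data generator

The generator reproduces the study conditions exactly as stated:

* **Pools** — J = 775 items, K = 5. π\* ~ U(0.75, 0.95) in all pools;
  r\* ~ U(0.15, 0.50) (LD), U(0.05, 0.40) (HD), U(0.05, 0.50) (HyD),
  independently per measured attribute. The Q-matrix replicates each of the
  31 nonzero attribute patterns 25 times, so every attribute is measured by
  exactly 400 items. This balanced design is the construction consistent
  with the HD pool's published per-attribute item counts; the unequal
  LD/HyD counts reported elsewhere imply an unstated, different Q design
  and are not reproduced — all three pools here share the balanced Q and
  differ only in parameter ranges.
* **Populations** — N = 3,200. The uniform population is stratified
  exactly: 100 examinees per profile, order shuffled. The correlated
  populations threshold a multivariate normal with unit variances and
  common correlation ρ ∈ {0.5, 0.8}: attribute k is mastered iff
  z_k > Φ^{-1}(1 − p_k), p = (0.45, 0.50, 0.55, 0.60, 0.65), the standard
  construction whose marginals match p by design. Note the model-implied
  attribute-count distribution of these correlated populations (e.g. an
  all-masters cell of ≈1,024/3,200 at ρ = 0.8) differs substantially from
  some published frequency tables for nominally identical settings; the
  tests here assert the model-implied values (frozen from a 2×10^6-draw
  Monte-Carlo oracle).
* **Factorial sweep** — 3 pools × 3 populations × 3 constraint levels
  (uncontrolled; count-based with B_k = 2; ADI-based with bound 1.0 nats)
  × 2 information indices = 54 cells. Within a pool × population block the
  same pool, population and per-examinee session seeds are shared by the
  six method cells, so method comparisons are paired; blocks and examinee
  sessions derive independent child seeds from the master seed, making
  every result bit-reproducible.

What the generator does *not* emulate: calibrated (estimated rather than
known) item parameters, model misfit, attribute hierarchies, slipping
structure beyond the RRUM, or examinee behaviour such as rapid guessing.
Passing tests therefore demonstrate properties of the method under its own
model, not robustness on real response data.

## Evaluation criteria

PCCR is the fraction of examinees whose whole pattern is recovered; ACCR_k
the per-attribute analogue (so PCCR ≤ min_k ACCR_k identically). E-ACCR is
the coefficient of variation of the K ACCR values in percent,
100·SD/mean, using the sample (n−1) SD — the convention that matches
published triples digit-for-digit. The exposure index is
χ² = Σ_{j=1}^{J} (exp_j − L/J)² / (L/J) with exp_j the fraction of
examinees who saw item j; it is zero iff exposure is uniform at L/J and
≈765 if the same L = 10 items of a 775-item pool are given to everyone.
(Published renderings of this formula garble the summation limit and the
target rate; the form above is the one consistent with "J is the number of
items" and with the observed magnitudes.) The qualification rate scores
every condition — including uncontrolled ones — against the same yardstick
of at least B_k = 2 items measuring each attribute; for ADI-constrained
runs the rate of meeting the ADI bound itself is reported as a secondary
column (it is 1.0 whenever the constraint is feasible, by construction of
the fallback rule).

## Numerical choices

* Profile order: lexicographic, attribute 1 most significant; shared by all
  modules, so posterior vectors, D tensors and population arrays index
  identically.
* Tie detection in argmax operations uses relative tolerance 1e−12; exact
  ties occur structurally (uniform posterior; profiles indistinguishable on
  the items seen so far), near-ties from rounding are treated the same way.
* D-matrix diagonals are exactly zero and tiny negative rounding residues
  are clipped to zero, preserving KL non-negativity bit-for-bit.
* Item-bank CSVs carry 12 significant digits, enough to round-trip every
  reported quantity; readers reject all-zero Q rows and out-of-range
  parameters with the offending row number.

## Relation to published results

Single-run tables have been published for this exact design (same pools,
populations, constraints, L = 10, N = 3,200) reporting, e.g.,
whole-pattern recovery of 0.378 for unconstrained PWKL in the
HD-uniform cell, 0.705/0.675 for the count-/ADI-constrained variants, and
uncontrolled qualification rates as low as 0.26. This package does not
reproduce those values, and the acceptance tests that assert them fail by
design rather than being weakened. The discrepancy is a property of the
published numbers, not of sampling noise:

* Implemented exactly as defined, posterior-weighted selection attains
  PCCR ≈ 0.75 (LD) to 0.87 (HD) in *every* constraint mode at these
  settings — consistent with the magnitudes reported in the PWKL/MPWKL
  source literature for comparable pools — because the posterior weights
  direct items at whatever attributes remain uncertain, making explicit
  coverage forcing nearly redundant for accuracy.
* A non-adaptive benchmark (10 random items per examinee) yields PCCR
  0.29–0.35 here; the published "uncontrolled PWKL" values sit barely above
  that floor, and they *decrease* when pool discrimination increases — a
  pattern a correctly targeted adaptive rule cannot produce on average.
  Replacing the posterior weights with uniform weights (plain KL at the
  running MAP estimate — the predecessor method PWKL was designed to
  improve upon) reproduces the published signature qualitatively: low
  uncontrolled accuracy, large cross-attribute ACCR spread, the
  LD-over-HD inversion, and a large gain from coverage constraints.
* Consequently this implementation also reverses the published ordering:
  unconstrained selection matches or exceeds the constrained variants on
  PCCR, while the constraints still deliver what they actually promise —
  guaranteed coverage (qualification rate 1.0 for the count-based rule)
  and, for the ADI rule, more even per-attribute accuracy.

The count-based constraint guarantees b_k ≥ 2 whenever feasible, and does
so in every simulated session; the ADI constraint guarantees accumulated
discrimination, which high-ADI items can satisfy with fewer than two items
per attribute, so its item-count qualification rate is below 1.0 by
construction under posterior-weighted selection.

## Limitations

* Fixed-length tests only; no variable-length stopping rule.
* No exposure control (Sympson–Hetter and relatives) and no content
  constraints beyond attribute coverage.
* RRUM only, with known item parameters; no calibration error, no other
  cognitive diagnosis models, no attribute hierarchies.
* The balanced Q-matrix is one defensible construction; pools whose
  attribute coverage is unbalanced may interact differently with the
  balancing rules.
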