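# cdcat — attribute-coverage balancing for short cognitive diagnostic CAT

`cdcat` simulates **cognitive diagnostic computerized adaptive testing**
(CD-CAT): adaptive item delivery whose target of inference is a binary
attribute-mastery profile α ∈ {0,1}^K rather than a continuous trait. It is
aimed at psychometricians studying how short fixed-length adaptive tests
(here: 10 items over K = 5 attributes) should be forced to *cover* every
attribute, and what that coverage costs or buys in classification accuracy.

## The model and the selection rules

Responses follow the **reduced reparameterized unified model (RRUM)**, a
non-compensatory cognitive diagnosis model. Item *j* carries a Q-matrix row
*q_j* (which attributes it requires), a baseline success probability π\*_j,
and penalty ratios r\*_jk ∈ (0,1):

    P(X_j = 1 | α) = π*_j · ∏_{k: q_jk = 1} (r*_jk)^(1 − α_k)

Items are chosen by posterior-weighted Kullback–Leibler information. With
π(α_c | X) the posterior over the 2^K candidate profiles and α̂ the current
MAP estimate,

    PWKL_j(α̂)  = Σ_c D_j(α̂ ‖ α_c) · π(α_c | X)
    MPWKL_j    = Σ_d Σ_c D_j(α_d ‖ α_c) · π(α_d | X) · π(α_c | X)

where D_j(α_u ‖ α_v) is the two-outcome KL divergence between the item's
response distributions under the two profiles (natural log).

Attribute coverage is balanced by multiplying the information index with an
**attribute-balance index** (ABI) in [0,1]:

* **count-based** (the MGDI method): ABI_j = ∏_k ((B_k − b_k)/B_k)^{q_jk},
  with B_k the minimum number of items that must measure attribute k
  (default 2) and b_k the number already administered;
* **ADI-based**: the item-count deficit is replaced by an information
  deficit, ∏_k ((ADI_k − adi_k)/ADI_k)^{q_jk}, where the **attribute
  discrimination index** of an item for attribute k averages the KL
  divergences over the 2^(K−1) profile pairs differing only in attribute k
  (both directions, uniform weights), and ADI_k is a lower bound on the ADI
  a test must accumulate per attribute (default 1.0 nats).

Met constraints zero an item's ABI; once every candidate item's ABI is zero,
selection falls back to the bare information index.

The built-in study design crosses three 775-item pools (LD / HD / HyD,
differing in the r\* range), three populations of 3,200 examinees (uniform
over all 32 profiles; thresholded multivariate normal with inter-attribute
correlation 0.5 or 0.8), three constraint levels and the two information
indices — the evaluation reports PCCR (whole-pattern accuracy), per-attribute
ACCR, E-ACCR (percent coefficient of variation of the ACCRs), an item
exposure χ² index, and the examinee qualification rate.

## Worked example

Simulate one condition — high-discrimination pool, uniform population,
ADI-based balancing, 10-item tests:

```bash
cdcat simulate --pool HD --population Unif --constraint adi_based \
       -n 320 -l 10 --seed 7
```

prints (one row per condition):

```
pool population constraint information  n_examinees  test_length   pccr  accr_1   accr_2   accr_3  accr_4   accr_5  accr_mean  accr_sd   e_accr  exposure_chi2  qualification_rate  qualification_rate_adi
  HD       Unif  adi_based        PWKL          320           10 0.8125  0.9375 0.965625 0.971875    0.95 0.946875   0.954375  0.01408 1.475295      289.98252                0.85                     1.0
```

Reading the row: 81.25% of the 320 simulated examinees had their whole
5-attribute mastery pattern recovered exactly (`pccr`); each single
attribute was classified correctly for 94–97% of examinees (`accr_*`), with
a coefficient of variation of 1.48% across attributes (`e_accr`); every
examinee accumulated at least 1.0 nats of attribute discrimination on every
attribute (`qualification_rate_adi = 1.0`), while 85% also happened to see
two or more items per attribute (`qualification_rate`). Larger
`exposure_chi2` means item usage concentrated further above the uniform
rate L/J.

The same machinery is scriptable from Python:

```python
import numpy as np, cdcat

bank = cdcat.generate_item_pool(cdcat.POOL_SPECS["HD"], np.random.default_rng(1))
pop  = cdcat.generate_population_uniform(3200, 5, np.random.default_rng(2))
cfg  = cdcat.SelectionConfig(information="PWKL", constraint="count_based")
result = cdcat.run_condition(bank, pop, cfg, seed=3)
print(result.pccr, result.accr_mean)
```

`cdcat study` sweeps the full 54-condition factorial design and writes tidy
CSVs (`results.csv`, pool and population summaries); `cdcat summarize-pool`
prints parameter and per-attribute ADI summaries of a generated or loaded
item bank. Item banks, populations and results round-trip through a plain
CSV dialect documented in `cdcat.cli_io`.

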