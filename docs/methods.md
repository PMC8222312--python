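# Methods

## Data model

The analysis input is a species × site matrix of non-negative real
abundances (rows = species, columns = sites). Sites play the role of
resource states: the overlap analysis treats a species' spatial
distribution of abundance as its resource-utilization vector.
Abundances may be non-integer (e.g., catches averaged over sampling
sessions); all statistics accept real values. Missing cells are not
allowed — trap surveys yield true zeros — and negative or non-finite
values are rejected at construction with the offending species and site
named.

Species with zero total abundance carry no information for either
statistic; analysis entry points drop them with a logged warning (or
raise, where the caller asked for strictness). Analyses require at
least two usable species.

## Statistics

*Pianka overlap.* For utilization proportions `p_ij` (row-normalized
abundances), `O_jk = Σ p_ij p_ik / sqrt(Σ p_ij² Σ p_ik²)`. The index is
invariant to positive rescaling of any species row and to any common
permutation of sites; both invariances are property-tested. The
matrix-wide summary is the mean over all unordered pairs, and the
reported "variance" is the **population** variance of the enumerated
pairwise values — the pairs are a complete enumeration, not a sample, so
no degrees-of-freedom correction applies. Pairwise values are computed
in double precision via one Gram-matrix product; at the package's scales
(≤ tens of species, ≤ ~100 sites) compensated summation is unnecessary.

*C-score.* On the binary matrix (presence = abundance strictly above a
threshold, default 0), `C_jk = (R_j − SS)(R_k − SS)` with `R` the row
totals and `SS` the pair's shared-site count; the matrix-wide C-score is
the pairwise mean, and the variance again uses the population
convention.

## Null models

### RA1–RA4 (utilization randomizations)

All four operate row-wise on the utilization matrix and return rows
summing to 1:

| algorithm | entries | zero structure | conserves |
|-----------|---------|----------------|-----------|
| RA1 | replaced by uniform(0,1) | destroyed | row normalization only |
| RA2 | non-zeros replaced by uniform(0,1) | retained | guild (zero) structure |
| RA3 | whole row permuted | reshuffled | niche breadth (value multiset) |
| RA4 | non-zeros permuted among non-zero positions | retained | breadth and zeros |

Replacement draws are uniform(0,1) before renormalization — random
equiprobable specialization, with every site a priori equally usable.
RA2 raises an error on a row with no positive entries (it cannot be
renormalized); RA4 returns rows with ≤ 1 positive entry unchanged.

A caution recorded during validation: the intuition that the more
constrained RA4 null yields higher mean overlap than RA3 holds when the
zero structure is shared across species (all rows confined to the same
few sites), but **not** for generic sparse matrices with uncoordinated
supports, where RA4 can sit below RA3. The test suite asserts the
inequality only in the shared-support regime where its mechanism
operates.

### FF (fixed–fixed swap chain)

The co-occurrence null holds both row totals (species incidences) and
column totals (site richnesses) fixed. One attempted swap draws 2
distinct rows and 2 distinct columns uniformly; if the 2×2 submatrix is
a checkerboard it is flipped, otherwise the state is unchanged (and the
attempt still counts). Because proposals are symmetric, the chain's
stationary distribution is uniform over the fixed-marginal class, and
the sampled C-score distribution is validated against exhaustive
enumeration of every marginal class with ≤ 12 cells (total variation
< 0.05 at 10,000 samples).

Chain schedule: burn-in of `10·n_rows·n_cols` attempted swaps, then one
recorded statistic every `n_rows·n_cols` attempts — a standard
decorrelation heuristic; both are configurable. A matrix with no
checkerboard unit anywhere cannot move; this is detected up front and a
point-mass warning is issued. The inner loop is numba-compiled (a
pure-NumPy fallback with identical semantics is used if numba is
absent; its random stream differs).

### Tail probabilities and limits

With `k` simulated values at or beyond the observed statistic out of
`N`, tails are reported as the add-one Monte-Carlo estimate
`(1 + k)/(N + 1)`; ties count toward both tails, so
`p_lower + p_upper ≥ 1` always and each tail lies in (0, 1]. The raw
proportion `k/N` is available via `p_value_method="raw"`; at N = 10,000
the two differ by < 1e-4. Null-distribution limits are the 5th/95th
(one-tailed) and 2.5th/97.5th (two-tailed) percentiles computed as
nearest order statistics, so every reported limit is an element of the
simulated vector.

### Seeding

Every run records its integer seed. The study driver derives one
independent seed per run from the master seed via `SeedSequence.spawn`,
so a full study is bit-reproducible and insensitive to the order in
which individual runs would be re-executed.

## Study workflow

Analysis units are the pooled ecosystem matrices (column-wise
concatenation of their sectors, species aligned by id and zero-filled,
site ids required to be unique) followed by each sector. Pooling
sectors into ecosystem-level matrices is this package's explicit
convention for broad-scale analyses. Each unit gets an RA3 and an RA2
overlap null and an FF C-score null; verdicts are a pure function of the
stored tail probabilities and the significance level (default 0.05,
one-tailed in each direction, both tails always reported, no
multiple-testing correction across units). Histograms bin the simulated
vector by the Freedman–Diaconis rule and mark the observed value and
both pairs of limits.

## Synthetic communities

`generate_community` draws from a latent site-suitability model:

* base suitability `exp(z)` with `z ~ N(0,1)` i.i.d. per cell
  (log-normal heterogeneity);
* **aggregated** mode mixes in a shared site-quality gradient on the log
  scale, `log s = (1−w)·z + w·q` with `q ~ N(0,1)` per site, so `w`
  (strength) is the species' common response to site quality;
* **segregated** mode alternates species between two contiguous site
  blocks; each off-block site is structurally unsuitable with
  probability `w`, and suitability at the remaining off-block sites is
  damped by `1−w`. Two blocks — rather than many small ones — keep each
  species' attainable incidence comparable to the unstructured case, so
  increasing strength produces genuine checkerboard segregation of
  *presences* instead of merely shrinking row totals (which would cap
  `C_jk = (R_j−SS)(R_k−SS)` and make the expected C-score non-monotone
  in strength). At `w = 1` species occupy disjoint blocks exactly.

Suitability below its `occupancy` quantile is set to zero (structural
zeros; zeros already created by segregation count toward the target),
the rest is scaled to a target mean abundance, and counts are drawn from
a gamma-Poisson mixture with heterogeneity `abundance_dispersion`
(negative-binomial-like, matching the zero-heavy, clumped catches of
pitfall data). A species whose realized row is all zero is redrawn up
to a bounded number of times, then an error is raised (occupancy too
extreme). The three modes consume the random stream in the same order,
so `strength = 0` reproduces the unstructured community bit for bit.

Defaults — 10 species, 15 sites, occupancy 0.45, mean abundance 3.0
individuals/site, dispersion 1.0 — give ~55–60% zero cells, similar to
the bundled survey's sector tables.

`generate_from_table1` builds sector matrices whose per-species
incidences and abundance totals match the bundled summary exactly:
occupied sites are drawn uniformly, one individual is placed at each,
and the remainder is allocated multinomially. These surrogates carry
the published marginals but **random** within-sector placement; they
exercise the full workflow at realistic size and sparsity but cannot
reproduce the original survey's observed overlap or C-score values,
which depend on the unpublished site-level co-occurrence pattern.

What the generator does *not* emulate: spatial autocorrelation among
sites, temporal (per-session) structure, trap-level variation below the
site, or environmental covariates. Passing the recovery tests therefore
shows the estimators and nulls behave correctly under controlled
aggregation/segregation with realistic sparsity — not that any
particular field system will show such structure.

## Validation scales

The test suite validates: pairwise formulas against independent
scalar-loop oracles (1,000 random inputs, 1e-12); conservation laws of
every randomization over 1,000 draws; the FF sampler against exhaustive
enumeration of all fixed-marginal classes with ≤ 12 cells (10,000
samples each, thinning 3·cells); statistical power on 50 replicates of
strength-0.8 structured communities and type-I calibration on 200
unstructured replicates (2,000 null iterations per replicate); and
bit-reproducibility of the full eight-unit study at 10,000 iterations.
These sizes are the package's validation choices; production analyses
default to 10,000 iterations per run.

## Known limitations

* The FF chain mixes by local swaps; for matrices far larger or far
  sparser than the validated regime the default burn-in/thinning may
  need increasing (both are exposed).
* The add-one p-value is mildly conservative; with highly discrete
  C-score nulls (tiny matrices) both tails can be large simultaneously.
* Ecosystem-level pooling assumes sectors are commensurable samples of
  one community; species totals are conserved but any between-sector
  habitat signal is folded into the pooled matrix by construction.
* Pairwise verdicts are reported per unit without correction for
  testing multiple units.
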