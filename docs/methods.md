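# Methods

`microtrace` asks whether an animal species — and an individual animal —
can be recognised from the composition of its fecal microbiota, and
which bacterial families carry that signal.  The input is a
family-by-sample table of 16S read counts plus metadata tying each
sample to a species, an individual, a site (zoo) and a day index inside
a short consecutive-day sampling series.  The package implements the
full analysis chain and a synthetic-data generator that plants known
structure, so every stage can be validated without sequencing data.

## The clustering pipeline

Counts are filtered (families with fewer than 10 reads in total across
the dataset are dropped) and converted to per-sample relative
abundances.  Two branches then build a distance matrix:

* **Single clustering.**  Every sample is one item; the distance between
  two samples is the Euclidean distance between their family-proportion
  vectors.
* **Time-series clustering.**  All samples of one sampling series form
  one item.  The distance between two series is classic dynamic time
  warping (DTW): with local cost `c(t, u)` the Euclidean distance
  between day profile `t` of one series and day profile `u` of the
  other, the cumulative cost follows
  `D(t, u) = c(t, u) + min(D(t-1, u), D(t, u-1), D(t-1, u-1))`,
  `D(1, 1) = c(1, 1)`, and the distance is `D(n, m)` — no warping
  window, no path-length normalisation (both available as options for
  sensitivity analysis).  DTW lets a day of one series align with
  several days of another, which absorbs missing days: carnivores do not
  reliably defecate daily, so series lengths differ.

Either distance matrix is converted to a **shared-nearest-neighbor
Jaccard similarity**: each item's `k` nearest items (ties broken by item
index; self included) form a neighbor set, and
`J(i, j) = |N(i) ∩ N(j)| / |N(i) ∪ N(j)|`.  The default
`k = round(sqrt(N))`, clipped to `[2, N-1]`, is the common SNN
heuristic; it is exposed as a parameter because no principled value
exists at these sample sizes.

Two clusterers consume the similarity matrix:

* **Ward's linkage** on the dissimilarity `1 − J`, via the
  Lance–Williams recurrence applied to squared dissimilarities (the
  "Ward on a precomputed dissimilarity" convention; for genuinely
  Euclidean input the merge height equals `sqrt(2·ΔESS)`).  The number
  of clusters is chosen automatically as the cut with the largest
  merge-height gap, subject to a minimum cluster count: 2 when species
  are sought (two species are expected), otherwise 3 (solutions with
  two or fewer clusters are discarded in individual mode).
* **Greedy modularity community detection** on the weighted Jaccard
  graph (all positive off-diagonal similarities are edges).  Starting
  from singletons, the merge with the largest modularity gain
  `ΔQ = 2(w(A,B)/m − a_A a_B)` is applied repeatedly (connected pairs
  only, ties toward the lowest community indices), and the partition
  with the highest `Q = Σ_c (e_c − a_c²)` seen along the merge path is
  returned.  Modularity is computed on edge weights, generalising the
  edge-count formulation to the weighted graph the pipeline produces.
  Greedy modularity maximisation is a heuristic — the exact problem is
  NP-hard — and the suite demonstrates both its exactness on small
  structured graphs (verified against exhaustive partition enumeration)
  and its bounded suboptimality on unstructured random graphs.

Agreement between the two clusterers, and of each against the true
labels, is scored with **normalized mutual information**
`NMI = I(a;b) / sqrt(H(a)·H(b))` (natural logs, contingency-table
estimate).  Degenerate cases follow fixed conventions: two
single-cluster labelings score 1, a single-cluster labeling against a
non-trivial one scores 0.  The normaliser (`sqrt`, `max` or
`arithmetic`) is recorded in every report header because published NMI
values can shift slightly between variants.

The full protocol runs both branches on the total dataset (species
labels, minimum 2 clusters) and on each species-specific slice
(individual labels, minimum 3 clusters); slices are re-filtered and
re-normalised after subsetting.

## Feature attribution

Families that discriminate the classes are found by L1-penalised
(multinomial where more than two classes) logistic regression on
z-standardised proportions.  The penalty is chosen on a geometric grid
(`C` from 1e-3 to 1e2, 21 points) by 5-fold cross-validated deviance
with the **one-standard-error rule**: the strongest penalty within one
standard error of the best mean held-out score.  Folds are stratified
and — whenever the classes span several individuals — group-aware,
holding out whole individuals: longitudinal samples of one animal are
strongly dependent, and sample-level folds leak identity into the
held-out score, which makes the plain CV-minimum rule retain spurious
features even for permuted labels (measured during development: 6–13 of
30 families in 3 of 10 permutation runs; the 1-SE rule selects none,
while keeping perfect recovery of the planted species families and
selected sets of the same size on real labels).  The selected set is
exactly the families with a nonzero coefficient at the chosen strength;
constant columns are dropped with a log note.

Descriptive calls complement the model: a family is a **core** taxon of
a series if its proportion exceeds the presence threshold (default 0,
i.e. any nonzero count) on every sampled day, and **persistent** if it
is present on at least two consecutive calendar days (`day_index`
differing by 1 — a family seen on days 1 and 3 only is not persistent
even if day 2 was unsampled).  With that calendar reading, core does
not imply persistent for a series whose sampled days contain no
adjacent pair; such series are essentially absent under realistic
missingness, and the containment `core ⊆ persistent` is asserted for
series with at least one adjacent-day pair.  Abundance is reported per
family and series as mean ± sample standard deviation (n−1) of the
daily percentages; single-day series report sd 0 with a flag.

## The synthetic world

The generator emulates a two-species zoo study: by default 2 species ×
7 series, 6 + 5 individuals (so 1 + 2 individuals contribute a second
series), up to 8 consecutive days, 30 bacterial families, and
multinomial sequencing depth drawn log-uniformly between 5,836 and
230,928 reads — the depth range typical of the MiSeq feature tables
this pipeline targets.  For family `f`, day `t`, individual `i` of
species `s` the latent log-abundance is

    λ = β_f + σ_species·1[f ∈ core(s)] + u_{i,f}·1[f ∈ signature(i)]
        + v_{z,f} + ε_{t,f}

with `β_f ~ N(0,1)` drawn once per dataset, `u_{i,f} ~ N(0, σ_individual)`
shared by both series of an individual, `v_{z,f} ~ N(0, σ_site)` (0 by
default — site labels were deliberately uninformative) and `ε` an AR(1)
process with lag-1 correlation `ρ_day = 0.3` and marginal sd `σ_day`.
Day profiles are the softmax of λ over the families present that day; a
sporadic subset (20% of families) is masked to zero on days where an
independent Bernoulli(0.4) fails.  The carnivore-like species misses
each day with probability 0.15 (a series always keeps at least one
day); the herbivore-like species never misses.  The logistic-normal
construction was chosen over a Dirichlet because it gives independent
control of the species, individual and day variance components — the
three contrasts the clustering has to separate.

Family roles partition into four categories: species-core (4 per
species), sporadic, individual-signature and background.  Each
individual draws 3 signature families from a signature-eligible subpool
(half of the non-core, non-sporadic families, overlaps between
individuals allowed — discrimination comes from the per-individual `u`
values, not from disjoint identities); the reserved other half stays
background, so false-selection rates have a non-trivial reference set.

Default effect sizes are `σ_species = 2.0`, `σ_individual = 1.0`,
`σ_day = 0.5` on the log scale.  No quantitative within- vs
between-individual variance estimates exist for this setting; the
defaults are chosen so the planted structure reproduces the qualitative
pattern the pipeline is meant to detect — species trivially separable
from whole series, individuals separable but noisy — and they are
plainly labelled synthetic.  All randomness flows from a single seed
through one `numpy` generator in a fixed draw order; effects are scaled
standard normals, so paired seeds stay coupled when one σ is varied.

What a green test does establish: the algorithms are implemented
correctly (exact oracle equivalence for DTW, Ward and small-graph
modularity), and the pipeline recovers structure of the planted kind at
the planted strength.  What it does not establish: performance on real
sequencing data, whose zero-inflation, taxonomic correlation structure,
compositional biases and sequencing error the generator deliberately
does not model.

## Numerical choices and edge cases

* Relative-abundance rows must sum to 1 within 1e-9; distance matrices
  must be symmetric within 1e-12 (then symmetrised exactly).
* kNN distance ties break by ascending item index; Ward merge ties by
  the lowest (cluster-a, cluster-b) id pair; community merge ties by
  the lowest community indices.  Outputs are therefore deterministic
  for a fixed input order, but not invariant to permuting the input:
  Jaccard values are discrete and exact ties are common.
* A sample with zero total counts is rejected at normalisation (filter
  output may legitimately contain one); an all-zero similarity graph
  yields singleton communities with a warning; a single-sample series
  has no persistent taxa (warning) and reports sd 0.
* LASSO coefficients with magnitude below 1e-8 are treated as exact
  zeros; `saga` runs with tol 1e-5 and up to 30,000 iterations, which
  converges on all default-world fits.

## Known limitations

* Ward and the pairwise DTW matrix are O(N³) and O(N²·L²) respectively
  — ample for studies of ~100 samples, not for thousands.
* The SNN construction discards the magnitudes of distances beyond the
  neighbor ranks; with very small N (< 5 series) the Jaccard graph is
  close to complete and both clusterers degenerate.
* Greedy modularity can split or merge weakly separated communities
  (a highly variable carnivore-like species tends to acquire an extra
  cluster); no Louvain/Leiden refinement is attempted.
* The generator plants family-level effects only; it does not simulate
  read-level error, taxonomic misassignment or chimeras.
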