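# microtrace

Can you tell *which animal* a fecal sample came from by its microbiota
alone?  `microtrace` implements a clustering pipeline for longitudinal
fecal-microbiota profiles that assigns samples to species and to
individual animals, targeted at zoo settings where a per-individual
microbial fingerprint would enable cheap, non-invasive health
monitoring.  It is aimed at microbial-ecology practitioners holding a
16S family-level feature table with day-by-day samples per animal (for
example a herbivore and a carnivore species, each individual sampled on
up to eight consecutive days).

Two analysis branches are compared:

* **single clustering** — every sample is clustered on its own, using
  Euclidean distances between relative-abundance profiles;
* **time-series clustering** — all samples of one individual's series
  form a single item, compared by dynamic time warping (DTW),

      D(t,u) = c(t,u) + min(D(t−1,u), D(t,u−1), D(t−1,u−1)),

  with local cost `c(t,u)` the Euclidean distance between day profiles,
  so that unequal series lengths (carnivores skip days) are absorbed by
  the warping.

Either distance feeds a shared-nearest-neighbor Jaccard similarity
`J(i,j) = |N(i) ∩ N(j)| / |N(i) ∪ N(j)|` over kNN sets, which is then
clustered two ways: Ward's linkage (minimal increase in the error sum
of squares, automatic cut at the largest dendrogram height gap, with a
minimum of 2 clusters in species mode and 3 in individual mode) and
greedy-modularity community detection (maximising `Q = Σ_c e_c − a_c²`
on the weighted graph).  Agreement is scored with normalized mutual
information, `NMI = I(a;b)/√(H(a)H(b))`, between the two clusterers and
against the true species/individual labels.  Finally an L1-penalised
logistic regression on the true labels (penalty chosen by group-aware
cross-validation with the one-standard-error rule) names the bacterial
families that drive each separation, alongside descriptive core
(present every sampled day) and persistent (present on two consecutive
days) taxon calls with mean ± sd percentages.

A synthetic-data generator plants species-core, individual-signature,
sporadic and background families in a logistic-normal/multinomial model
of the eight-day, two-species design, providing ground truth for every
stage; see `docs/methods.md` for the model and its limits.

## Worked example

Simulate a study and run the full protocol (both branches, all slices,
LASSO attribution):

```sh
microtrace protocol --simulate 1 --seed 1 --outdir out/
```

which prints the per-slice report (also written to
`out/report.tsv` / `out/report.json`):

```
slice   approach label_mode  n_items  nmi_com_ward  nmi_ward_true  nmi_com_true  n_clusters_ward  n_clusters_com
total     single    species      106      0.819272       0.629347      0.718547                6               4
  sp1     single individual       50      0.830303       0.110769      0.113663                3               3
  sp2     single individual       56      0.871149       0.082193      0.118369                3               3
total timeseries    species       14      1.000000       1.000000      1.000000                2               2
  sp1 timeseries individual        7      0.625067       0.886695      0.443799                6               2
  sp2 timeseries individual        7      0.000000       0.660277      0.000000                4               1
```

Read it row by row: clustering the 106 samples individually recovers
the two species only imperfectly (Ward vs truth NMI 0.63, six clusters
instead of two), and individuals within a species barely at all
(NMI ≈ 0.1).  Clustering the 14 whole time series via DTW instead
assigns every series to its correct species (NMI 1.0, exactly 2
clusters) and lifts individual assignment to NMI 0.89/0.66 — the
central point: consecutive-day series carry an individual fingerprint
that single samples do not.  `out/lasso_species.tsv` lists the selected
families; on this seed the selection contains all eight planted
species-core families (`F01`–`F08`), and `out/taxon_summary.tsv` gives
per-series mean ± sd percentages with core/persistent flags.

Other entry points: `microtrace simulate` (emit counts/metadata/truth
TSVs), `microtrace single` / `microtrace timeseries` (one branch, one
slice), `microtrace attribute` (LASSO only) — or the library functions
(`microtrace.run_full_protocol`, `microtrace.dtw_distance`, ...).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete protocol from scratch on the default synthetic
world with the given seed — generation, both clustering branches on the
total and per-species slices, NMI evaluation and LASSO attribution —
writing the protocol bundle next to the JSON output.  The scientific
acceptance checks themselves live in `tests/test_acceptance.py`: exact
oracle equivalence of DTW (exhaustive warping-path enumeration), Ward
(from-scratch ESS recomputation) and community detection (exhaustive
partition enumeration on small graphs), analytic NMI values,
planted-truth recovery of species and of discriminating families, and
the single-vs-time-series dominance pattern.
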