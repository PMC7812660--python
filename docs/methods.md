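# Methods

This note documents the models and numerical conventions behind
`porelist`: what each procedure assumes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Data model and recoding rules

An occurrence record is one observation of basidiomes of one species
on one substrate unit, annotated with provenance (source dataset I /
IIa–IId / IIIa–IIIb, year, optional plot), stand descriptors
(site-type group, tree-composition class, age class — or a pooled
special habitat such as park or wooded meadow), and substrate
descriptors (host taxon, woody fraction, decay stage I–V).

Fixed recoding rules:

* **Decay**: stages I–II → `early`, III → `medium`, IV–V → `late`;
  free-text "extremely decayed" annotations map to `late`. Missing
  decay is propagated, never imputed.
* **Woody fraction**: dead items strictly below 10 cm diameter at the
  basidiome location are fine woody debris (FWD) regardless of
  posture; the 10 cm boundary itself goes to the coarse classes
  (snags/stumps if standing or a stump, otherwise coarse fallen).
* **Banded counts**: export tables censor record counts strictly above
  a threshold (default 100) as `>100`; a count equal to the threshold
  prints exactly. Percentages and classifications always use raw
  counts, never banded ones.
* **Habitat keys**: either the stand triple
  `site_type_group|tree_class|age_class` or a pooled special habitat;
  having both, or an incomplete triple, is an error.
  Early-successional (post clear-cut) stands carry a flag so the
  assemblage analysis, which targets stands older than 20 years, can
  exclude them.

Checklist reconciliation is ledger-driven: each entry records one
action (merge into a target, exclusion as unsupported or
misidentified, addition, split) so every change between checklist
snapshots is traceable. Strict mode rejects entries referencing
unknown names and re-additions; lenient mode treats such entries as
already applied, which makes re-application idempotent.

## Richness estimation

Chao1 extrapolates unseen richness from the rare tail:
`S_obs + f1^2/(2 f2)` (classic) with the bias-corrected fallback
`S_obs + f1(f1-1)/2` when no doubletons exist, and the bias-corrected
variant `S_obs + f1(f1-1)/(2(f2+1))` available throughout. The classic
form is the default because it is the conventional checklist-report
statistic; raw estimates are returned unrounded and rounded only in
reports (half-up). The estimator is a lower bound under heterogeneous
detectability, which regional record compilations certainly have.

Turnover between an old and a new accepted list is
`100 (|losses| + |gains|) / (2 S_ref)` with `S_ref` the old pool size
— the average of the loss and gain rates. The report keeps the raw
loss/gain name lists so any alternative denominator can be recomputed.
The regional-extinction rule flags species whose last record is more
than `horizon` years old (default 50, strict inequality: a gap of
exactly 50 years does not flag).

## Substrate-association classification

The regular/specialist rules are absolute-and-relative hybrids.
Numerical conventions chosen here:

* the three regular clauses are an OR; the a → b → c precedence is
  only used to *report* which clause fired first;
* "total records" in the 40-record threshold means the species' total
  across all datasets (configurable in principle, fixed in this
  implementation);
* a zero category total skips clause (c) rather than erroring;
* thresholds are inclusive exactly as written: ≥5%, >1, ≥5%, >2, ≥90%,
  totals 3–9 inclusive. A species with 8 of 9 records on a category
  (88.9%) fails both specialist clauses; this gap is faithful to the
  rules, not smoothed over.

Because clause (b) depends on absolute counts, the classification is
scale-dependent only through that clause: multiplying all counts
tenfold can change outcomes for species under 40 records but never for
species at or above it (tested).

Host-range classes (1–2 / 3–7 / ≥8 host taxa) are reported only for
species with strictly more than 10 records. The clustering input
restricts the host × species presence/absence matrix to *regular*
pairs — cell 1 iff the records of the species on the host reach 5% of
the species' records or 5% of the host's records — because raw
presence/absence over-weights atypical substrates.

## Community-analysis engine

**Bray-Curtis** is Σ|x−y| ∕ Σ(x+y) over non-negative sample rows
(scipy's kernel behind a validation wrapper); all-zero samples are a
hard error naming the sample.

**NMDS** is Kruskal's non-metric scaling, implemented in-package:
stress-1 = √(Σ(d−d̂)² ∕ Σd²), with disparities d̂ the weighted
least-squares monotone fit (pool-adjacent-violators) of configuration
distances against the rank order of the input dissimilarities. Ties in
the input follow the primary approach (tied dissimilarities may be
fitted unequally; stable sort). Each start is refined by Guttman
transforms with the stress tracked explicitly — an iteration that
would increase stress-1 is rejected and the start stops, so the
recorded stress is non-increasing within a start. Defaults: k = 2,
20 random uniform starts plus one classical (metric eigendecomposition)
start, 300 iterations, tolerance 1e-7 on stress improvement. The
metric start usually dominates but can be disabled to match a strictly
random-start protocol. The final configuration is centred, rotated to
principal axes (axis 1 carries maximal variance) with a deterministic
sign convention. Non-convergence within the iteration budget is
reported in the `converged` flag, not raised.

**MRPP** uses δ = Σ w_g · (mean within-group dissimilarity), with
weights w_g = n_g∕N by default (the common implementation default;
(n_g−1)- and equal-weight variants are selectable, since published
analyses rarely state the choice). The null relabels samples: when the
number of distinct label assignments is ≤ 10,000 the enumeration is
exhaustive and p is the exact proportion of relabelings with
δ ≤ δ_obs (the observed labelling counts itself); otherwise B seeded
Monte-Carlo permutations with the add-one estimator
p = (1+count)∕(B+1), which cannot report p = 0. A = 1 − δ_obs∕E[δ].
Every group must have at least two members; callers (and the pipeline)
drop singleton groups before testing. Bonferroni correction is
min(1, m·p).

**UPGMA** merges the closest pair repeatedly with size-weighted
average linkage; distance ties break toward the lowest cluster
indices, making the tree deterministic. Merge heights are the merge
distances; halving into branch lengths is a Newick-export option
(`to_newick(halve_heights=True)`), since an ultrametric merge height
is the sum of the two child branch lengths. Agreement with an
independent average-linkage implementation is tested on random inputs,
and ultrametric inputs are fixed points.

**Habitat matrices** recode record counts to 0/1/2 (absent / one /
more than one record) — a compromise between raw counts (dominated by
uneven effort and detectability) and presence/absence (over-weights
singletons). Species recorded from a single habitat type are dropped
before ordination and testing. Set-overlap counts report, per habitat
combination, the species present in every member type and the subset
found in no other type; Euler-diagram *layout* is out of scope.

## Synthetic-data generator

The generator emulates the statistical structure of a regional
polypore record compilation:

* **Abundances**: log-series with shape θ (default 0.995 at the
  default pool size S = 200), chosen so that roughly 5–10% of species
  end up as singletons at the default survey effort — the regime in
  which Chao estimation is actually used.
* **Habitat structure**: per-species affinities over site-type groups
  (a few preferred groups each) and host preferences concentrated in
  one of three phylogenetic host blocks (conifers, soft deciduous
  trees, hardwoods), combined with per-tree-class host availability
  typical of hemiboreal stands.
* **Survey protocol**: per plot, candidate draws arrive in seeded
  order with probability ∝ abundance × site affinity × host match;
  the per-species cap (10) truncates in that order — mirroring a
  "first ten records described" protocol — and the plot stops at 150
  records. Plot effort is Poisson (mean 200 candidate draws).
* **Casual stream**: ~600 expected records (about 10% of the default
  total, as in mixed compilations) drawn ∝ abundance × detectability,
  with detectability uniform on (0.05, 1]; casual records carry a
  plot habitat or a pooled special habitat but no plot id.
* **Specialists**: a configurable fraction (default 0.2) of species is
  constructed as strict single-host specialists (all host preference
  on one taxon) or single-habitat specialists, recorded in a
  machine-readable truth table. When a strict specialist is drawn in
  the casual stream outside its host's availability table, the host is
  taken from the species' own preference — collectors find the species
  where its host occurs.
* Decay-stage and woody-fraction assignment are Dirichlet profiles per
  species, independent of habitat given the species — a stated
  simplification.

What the generator does **not** emulate: spatial autocorrelation
between plots, temporal dynamics, climate covariates, observer
differences, or misidentification. Passing recovery tests therefore
demonstrate that the machinery extracts the structure it was given at
realistic effort and noise, not that real compilations are free of the
biases the generator omits.

Known artifact worth naming: in host-block recovery, the sparse
low-availability host (juniper, 1–2% availability) sometimes splits
off as a singleton cluster before the three blocks separate — exactly
the behaviour sparse hosts show in real presence/absence clustering.
The recovery criterion is therefore the mean Rand index over 20 seeded
surveys (≥ 0.9) rather than a per-seed bound.

## Pipeline and reproducibility

The pipeline runs records → checklist → substrate → assemblage from a
single validated config (unknown keys rejected; every stochastic stage
requires an explicit seed). All outputs are plain text (CSV, JSON,
Newick); the manifest lists each file with a SHA-256 hash, and
identical config + seed reproduces every byte. Table-style exports
band counts above 100 and give percentage breakdowns only for species
with ≥ 25 systematic records; integer percentages use
largest-remainder apportionment so each block sums to exactly 100
(plain rounding can drift by several points with many categories).

Problem sizes used in the shipped configuration and tests — 200-species
pool, 60 plots, ~8,000 records, 999 Monte-Carlo permutations, 10–20
ordination starts, 500-replicate calibration — are the package's
default study conditions; all scale up linearly through the config.

## Limitations

* Chao1 is a lower bound; with strong detectability heterogeneity the
  true pool can exceed it substantially.
* The turnover denominator (2·S_ref) is one convention among several;
  raw loss/gain lists are retained for recomputation.
* MRPP weighting follows the common default; published analyses using
  other weights will give different A values (the variants are
  exposed).
* NMDS stress values are comparable only between runs with the same
  dissimilarity and dimensionality; no significance test for stress is
  provided.
* Records lacking substrate annotations are kept in species totals but
  excluded from substrate tables; if annotation missingness correlates
  with substrate, association shares are biased accordingly.
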