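# Methods

This note records what each stage of the pipeline computes, the choices
made where the design was genuinely open, and what the packaged data and
synthetic generators can and cannot support.

## Curation

Alignments are pre-aligned, equal-length sequences over {A, C, G, T, -, N}
with a population label per sample. All site coordinates on the public
surface are 1-based and inclusive.

*Hypervariable sites* are removed by explicit 1-based position
(`remove_sites`); the package provides a data-driven way to find them
(the homoplasy screen, below) but never removes sites on its own.

*Repeat-motif collapsing* (`collapse_repeat_motif`) recodes a
microsatellite-like tract so each complete motif copy occupies a single
column: a slippage event that adds or removes k copies then counts as k
single-column gap differences rather than k·len(motif) substitutions.
The operation is idempotent; an already-collapsed tract is recognized and
returned unchanged.

*Haplotype collapsing* pools identical sequences into a haplotype ×
population count table. Gaps are a fifth character state for identity and
contribute one step per differing column. A sequence containing N merges
into another haplotype only when it is otherwise identical, the partner
is strictly more resolved, and the partner is unique; ambiguous partial
sequences stay separate. This avoids inflating the haplotype count from
partial reads without guessing among equally compatible resolutions; all
such merges are flagged in the table's `merge_log`.

## Diversity indices

* `Hd = n/(n−1)·(1 − Σ p_i²)` (unbiased). This small-sample correction is
  fixed, not optional: it is the estimator that reproduces the published
  per-locality values from integer counts.
* `Π` is the mean number of pairwise differences over all C(n,2) sequence
  pairs, computed from haplotype counts and a step-count distance matrix.
* `π = Π / L`, stored as a fraction, printed as a percentage.
* `S` counts columns with ≥ 2 observed states; gaps count as a state, N
  is treated as missing.

Internal values are full precision. Reporting (`diversity_table`) rounds
half away from zero, 3 decimals for Hd/Π and 2 for π%.

## Structure

AMOVA follows the sums-of-squared-deviations formulation: for any set of
sequences, SSD = (1/n)·Σ_{i<j} δ_ij with δ the squared inter-haplotype
distance — δ_ij = 1 for distinct haplotypes (F_ST) or the mutational step
count (φ_ST). Two-level (pairwise) and three-level
(groups / populations-within-groups / populations) decompositions use the
standard unbiased coefficients (n_c, n′, n″, n‴ from the sample-size
configuration). Negative variance components are reported as computed;
they are the estimator's expected behaviour near panmixia and are never
clamped. When every group holds exactly one population the middle level
is empty and F_CT reduces algebraically to the pairwise F_ST (tested).

Permutation p-values use the (b+1)/(B+1) estimator. Schemes: individuals
among populations (pairwise indices, F_ST, F_SC within groups) and whole
populations among groups (F_CT).

Hudson's Snn: for each sequence, the fraction of its nearest neighbours
(ties at the minimal distance share weight equally, self excluded)
belonging to its own population, averaged over sequences; significance by
label permutation. Nearest-neighbour sets do not depend on the labels, so
they are computed once. If all sequences are identical Snn is undefined
and the test returns NaN with p = 1 and a diagnostic note.

Nei's net divergence `d_A = d_XY − (d_X + d_Y)/2` uses frequency-weighted
(n², not n(n−1)) within-population diversities, matching the
between-population term, so two identical populations give d_A = 0
exactly. An optional bootstrap over individuals supplies a standard
deviation.

Correspondence analysis operates on the presence/absence matrix
(localities × haplotypes) via SVD of the standardized residuals of the
correspondence matrix, with principal normalization for both rows and
columns; axes are ordered by inertia and signs are arbitrary.

## Median-joining networks

The construction iterates a minimum spanning network — the union of all
minimum spanning trees, characterized as the edges whose weight is within
ε of the minimax (bottleneck) path weight between their endpoints — with
insertion of median vectors: per-column majority consensus of every
triple (u, v, w) in which v links to both u and w. New medians are added
until closure; afterwards unsampled nodes that never reach degree 3 in
the spanning network over the remaining node set are pruned as obsolete.
ε defaults to 0 (the conventional software default) and is exposed.
Columns where all three states differ yield no majority and no candidate.

Determinism: all ties break lexicographically on (weight, sequence), so
the network is invariant to haplotype input order.

The *loop census* is the cycle rank E − V + components. The *homoplasy
screen* rebuilds the network with each polymorphic column removed and
reports Δloops per site; a hypervariable site that mutated in parallel on
several backgrounds produces derived twins of existing haplotypes, the
twins replicate the edges among their parents, and removing the column
collapses those reticulations (k affected classes on a connected subtree
yield k − 1 loops, so four affected haplotype pairs give three).

## Microsatellites

Per locus: Ho = fraction heterozygous, unbiased
`He = 2n/(2n−1)·(1 − Σ p_i²)`, nA = distinct alleles; missing genotypes
are excluded from n with a warning.

The allelic-richness comparison is an unpaired pooled-reallocation test
on per-locus allele counts: pool the 2k values, reallocate into equal
halves, and report the upper-tail probability that group A's mean is at
least the observed one (with equal halves, sum and mean orderings
coincide). All C(2k, k) splits are enumerated when that number is at most
200,000; otherwise 10,000 (configurable) Monte Carlo reallocations are
used with the (b+1)/(B+1) estimator. For the packaged panels this means
the five-locus inter-hemisphere comparison is exact (252 splits) and the
twelve-locus intra-Pacific one is randomized. The two loci with a
homozygote excess in the Chilean panel (DlrFCB6, GT51) are excluded from
inter-hemisphere comparisons via the `usable` locus lists, not
hard-coded; the within-hemisphere comparison keeps the full shared panel,
which is also the configuration that reproduces the published
intra-Pacific p-value.

## Demographic model and ABC

The simulator is a haploid (maternal-lineage) structured coalescent with
two demes, South and North, in generations, with no migration. Backward
in time: North has size Ne_n until t1; between t1 and t2 it has the
founder size Nf (scenario 1, founder effect) or keeps Ne_n (scenario 2,
vicariance); at t2 North merges into South; South and the merged
ancestral population have size Ne throughout. Prior sizes are used
directly as haploid effective sizes — mtDNA is effectively haploid, and
no ploidy conversion is applied. Ne_n is an independent draw from the Ne
prior (the post-growth northern size is not pinned to the ancestral one;
this symmetric reading is a design choice). Mutations are infinite-sites
at rate u per site per generation over L = 345 sites; at the diversity
levels involved (≪ 1 difference per site) finite-site saturation is
negligible.

Priors: Ne ~ U(1,000, 100,000); Nf ~ U(10, 1,000) (scenario 1 only);
t2 ~ U(10,000, 35,000); t1 ~ U(2,000, 15,000) with t2 > t1 enforced by
joint redraw; u log-uniform on (1.5e−8, 1.5e−7) — the prior's shape
across the stated decade is not dictated by the ranges alone, and
log-uniform treats it scale-free. Times are generations internally; any
conversion to years is the caller's (no generation time is assumed).

Summary statistics (fixed order): per deme h, S, Hd, Π; cross-deme
identity-F_ST, mean between-deme pairwise differences, and
shared/private haplotype counts. Rejection ABC standardizes every
statistic by its reference-table standard deviation (zero-variance
statistics are dropped with a warning, which makes the procedure
invariant to affine rescaling of any statistic), ranks rows by Euclidean
distance, and reports: model posterior = per-scenario fraction among the
k closest rows (the "direct approach"); parameter posterior = median and
2.5/97.5 percentiles of the k closest same-scenario rows. No regression
adjustment is applied.

Problem sizes: the package's reference-table default in tests and
examples is 60,000 simulations with 50 + 50 sampled lineages and k = 500
(k = 200 in the quick example), a desk-scale setting at which the
self-consistency oracles hold: pseudo-observed data generated under the
founder scenario (Ne = 20,000, Nf = 50, t1 = 5,000, t2 = 20,000,
u = 5e−8 — all inside the priors) is assigned to it in ≥ 80% of
replicates, and 95% rejection intervals cover the generating parameters
in ≥ 17/20 replicates. Larger tables sharpen both.

## Synthetic data

`make_haplotype_dataset` realizes per-population haplotype spectra either
exactly (deterministic counts — required wherever published numbers are
pinned from integer counts) or multinomially, over haplotype sequences
generated on a star or a random homoplasy-free tree (one unique site per
mutation, so distances are additive and networks are loop-free). Ground
truth records the sample partition, realized counts, distance matrix and
analytic Hd/Π.

`inject_homoplasy` makes one column hypervariable by placing a shared
derived state on part of the samples of each of the n most frequent
haplotype classes, creating derived twins; see the network section for
the loop arithmetic. `make_msat_panel` draws diploid genotypes under
Hardy–Weinberg from specified allele frequencies. `make_pseudo_observed`
wraps one coalescent draw plus summarization with a truth record. All
generators are deterministic given their seed.

What the generators do **not** emulate: sequencing error, alignment
uncertainty, recombination (absent in mtDNA), selection, migration after
the split, and linkage among microsatellite loci. Passing tests therefore
validate the estimators and the inference machinery, not robustness to
those real-data complications.

## The packaged study tables and their caveats

The haplotype × locality count table (10 localities, 15 haplotypes,
1,012 sequences) is transcribed from the published study. The rows for
CL, NWA, FI, UK, IB, NEA, GIB and MED and the NZ spectrum were validated
by back-computing the published Hd (and, where distances are pinned, Π)
to 3 decimals. The three Tasmanian private-haplotype counts and parts of
the haplotype-to-column assignment are reconstructions; those localities
are flagged `APPROXIMATE` and no pinned value relies on them. Two
published Hd values (FI 0.365, GIB 0.436) sit one unit of the third
decimal below the half-away rounding of the recomputed values
(0.366, 0.437), most likely truncation in the original software; the
package reproduces the five confirmed rows exactly and documents these
two.

Haplotype sequences in the fixture are synthetic realizations of the
mutation tree implied by the validated pairwise-difference values; they
reproduce the validated step counts but are not the GenBank sequences.
Quantities that need the real sequences (the subspecies-level
F_ST = 0.439 / φ_ST = 0.464, Snn = 0.830, the AMOVA table cells,
d_A = 0.00158) are therefore not pinned; the pipeline's outputs on the
reconstruction land close (e.g. d_A ≈ 0.0016, F_CT ≈ 0.39–0.46 depending
on the distance model) and the corresponding estimators are instead
guaranteed by exact oracles: AMOVA/pairwise-F_ST equivalence, brute-force
Snn enumeration, brute-force variance decomposition, the Steiner-optimum
check for networks, and coalescent agreement with E[Π] = 2NuL and with an
independent simulator. In the correspondence analysis of the
reconstructed presence/absence matrix the first axis carries the
hemispheric contrast, but the two North Atlantic localities whose
haplotype sets are subsets of the southern core (NWA, FI) sit near zero
rather than strictly on the northern side; the packaged test asserts the
sign separation for the localities whose profiles are validated.

On the microsatellite side, the published per-locus table is packaged
as-is. The intra-Pacific richness comparison uses all 12 loci shared
between the southwestern-Pacific and Chilean panels: the homozygote-excess
exclusion applies to cross-hemisphere comparisons, and this full-panel
configuration is the one that reproduces the published p ≈ 0.166 (exact
enumeration gives 0.1645; a 10,000-draw randomization scatters around
that within ±0.011 at 3 SE). Restricting to the 10 "usable" loci instead
gives p = 0.129 (`intrapacific_shared_loci(usable_only=True)`).

## Numerical conventions

* Reporting rounds half away from zero; internal values are never rounded.
* Permutation and randomization p-values are (b+1)/(B+1), hence in (0, 1].
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); every simulation, permutation test and
  generator is reproducible given its seed.
* Degenerate inputs: empty populations are skipped with a warning;
  n < 2 raises for Hd and pairwise indices; an all-identical sample makes
  Snn undefined (NaN, p = 1); a single sampled lineage yields S = 0.

## Known limitations

* AMOVA p-values permute at the individual level via count tables;
  individual-level covariates are out of scope.
* The median-joining implementation targets mtDNA-scale data (tens of
  haplotypes); it recomputes the spanning network per iteration and is
  not tuned for thousands of haplotypes.
* No regression-adjusted ABC, no isolation-by-distance tests, no
  migration in the demographic scenarios, no HWE/null-allele screening —
  all deliberately outside the pipeline's scope.
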