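# haplogeo

Haplotype-based phylogeography for structured populations: the complete
analysis chain of a global mtDNA + microsatellite study, built around the
long-finned pilot whale (*Globicephala melas*), a matrilineal odontocete
with an antitropical distribution split into a Southern Hemisphere
subspecies (*G. m. edwardii*) and a North Atlantic / Mediterranean one
(*G. m. melas*).

The package is for population geneticists who want a scriptable, tested
version of the classic control-region workflow — the kind of analysis
usually spread across Arlequin, DnaSP, Network and DIYABC — as one
importable library:

* **curation** (`haplogeo.alignment`) — labelled alignments, removal of
  hypervariable sites, collapsing of repeat-motif length variation
  (each motif copy = one mutational step), pooling identical sequences
  into a haplotype × locality count table;
* **diversity** (`haplogeo.diversity`) — h, segregating sites S, unbiased
  haplotype diversity `Hd = n/(n−1)·(1 − Σ p_i²)`, mean pairwise
  differences Π and nucleotide diversity π = Π/L;
* **structure** (`haplogeo.structure`) — AMOVA in the
  Excoffier–Smouse–Quattro sums-of-squared-deviations form, pairwise
  F_ST (haplotype identity) and φ_ST (mutational distance), hierarchical
  variance components with permutation p-values, Hudson's Snn
  nearest-neighbour test, Nei's net divergence
  `d_A = d_XY − (d_X + d_Y)/2`, and correspondence analysis of haplotype
  presence/absence;
* **networks** (`haplogeo.network`) — median-joining haplotype networks
  (Bandelt–Forster–Röhl), loop census, and a per-site homoplasy screen;
* **microsatellites** (`haplogeo.msat`) — Ho, unbiased He, allelic
  richness, and an upper-tail pooled-reallocation randomization test for
  richness differences between panels;
* **demographic inference** (`haplogeo.coalescent`, `haplogeo.abc`) — a
  haploid two-deme coalescent simulator for a founder-effect scenario and
  a vicariance scenario, and rejection ABC (direct-approach model choice
  over the k closest simulations, plain rejection parameter posteriors);
* **synthetic data** (`haplogeo.synthetic`) — generators with recorded
  ground truth for every input class; `haplogeo.datasets` packages the
  published pilot-whale count tables.

## Worked example

```python
>>> import haplogeo as hg
>>> from haplogeo import datasets as ds
>>> table = ds.haplotype_table()          # 1012 sequences, 15 haplotypes
>>> hg.haplotype_diversity(table.counts["CL"])   # Chile: counts 31/45/12/2
0.6199750312109863
>>> round(float(hg.pairwise_fst(table, "GIB", "MED")), 3)  # Gibraltar vs Mediterranean
0.174
```

Running `python examples/05_microsatellites.py` prints:

```
Chile: mean alleles per usable locus = 7.5

SW Pacific vs North Atlantic (5 shared loci):
  allele counts [10, 9, 9, 10, 7] vs [9, 5, 6, 6, 7]
  upper-tail p = 0.028 (enumeration, 252 splits)

SW Pacific vs Chile (12 shared loci):
  upper-tail p = 0.171 (randomization, 10000 draws)
```

The Chilean mtDNA sample has Hd ≈ 0.62 with π ≈ 0.23% — low diversity,
typical of matrilineal odontocetes. The richness test pools the per-locus
allele counts of two panels and asks how often a random equal split gives
the first group a mean at least as large as observed: southern pilot
whales carry significantly more microsatellite alleles than northern ones
(p = 7/252 ≈ 0.028), while the two South Pacific panels do not differ
(p ≈ 0.17). Together with the hemispheric F_ST/φ_ST structure and a net
divergence d_A ≈ 0.0016 (below the 0.004–0.04 subspecies band), this is
the pattern expected if the Northern Hemisphere population was founded
from the south around the Last Glacial Maximum — the scenario the ABC
module tests explicitly (`examples/06_abc.py`).

Each script in `examples/` is a short narrative of one capability:
curation, the diversity table, structure statistics, networks and the
homoplasy screen, microsatellites, and ABC model choice.

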