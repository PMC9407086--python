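# ylineage

Y-chromosome STR/SNP population and forensic analysis for male-lineage
studies: forensic haplotype statistics under the common commercial Y-STR
panels, AMOVA-based R<sub>ST</sub> genetic distances with MDS and
neighbor-joining trees, hierarchical Y-SNP haplogroup calling with
frequency aggregation and PCA, weighted median-joining haplotype
networks, and a forward-time male-lineage simulator that generates
realistic STR+SNP populations for end-to-end validation.

The package is aimed at forensic and population geneticists who work
with Y-STR genotype tables (one row per male, one column per locus,
alleles named by repeat count with microvariants such as `38.2`) and
Y-SNP marker panels that place each male in the paternal haplogroup
hierarchy.

## The statistics at the core

For a population sample of *n* males with haplotype frequency spectrum
*s<sub>k</sub>* (the number of distinct haplotypes observed exactly *k*
times, *H* = Σ<sub>k</sub> *s<sub>k</sub>* distinct haplotypes):

- match probability  MP = Σ<sub>k</sub> s<sub>k</sub>·(k/n)²
- haplotype diversity  HD = n/(n−1)·(1 − MP)
- discrimination capacity  DC = H/n
- fraction of unique haplotypes  FUH = s₁/n

Per-locus gene diversity uses the same unbiased form,
GD = n/(n−1)·(1 − Σ p<sub>i</sub>²), over allele frequencies
p<sub>i</sub> (multi-copy loci such as DYS385a/b are scored on the
sorted allele pair).

Between-population differentiation is R<sub>ST</sub>, the microsatellite
analogue of F<sub>ST</sub>: an AMOVA on repeat counts with squared
difference distances, partitioning variance into among- and
within-population components.  The distance matrix feeds classical +
non-metric MDS (Kruskal stress-1) and a Saitou–Nei neighbor-joining
tree.

Haplotype networks use the median-joining construction under a weighted
Manhattan metric, with integer locus weights (1–5) assigned from
mutation rates — the slower the locus, the higher the weight — and the
ancestral haplotype chosen as the frequency-weighted medoid.

## Worked example

The package bundles the published haplotype frequency spectra of two
Shanghai Han population samples (Pudong, n = 689; Chongming Island,
n = 530) typed on the 38-locus Yfiler Platinum system and re-scored
under four panels:

```python
>>> from ylineage import forensic_parameters
>>> from ylineage.datasets import shanghai_spectrum
>>> forensic_parameters(shanghai_spectrum("Pudong", "yfiler")).rounded(5)
{'n': 689, 'H': 619, 'FUH': 0.83164, 'HD': 0.99957, 'MP': 0.00189, 'DC': 0.8984}
```

Of the 689 Pudong males, 619 distinct 17-locus haplotypes were seen and
83.2 % of men carried a haplotype observed exactly once; two random men
match with probability 0.19 %.  Under the full 38-locus panel the same
sample gives `FUH 0.97097, HD 0.99996` — near-complete individual
resolution, which is why the larger panels are preferred for casework.

Clade frequencies aggregate over the haplogroup tree:

```python
>>> from ylineage import clade_frequency
>>> from ylineage.datasets import shanghai_haplogroup_vector
>>> clade_frequency(shanghai_haplogroup_vector("Chongming"), "N")
13.59
```

i.e. 13.59 % of Chongming males fall in haplogroup N-M231 (N 9.06 % +
N1a1 4.53 %), roughly double the Pudong value (7.26 %) — the kind of
founder-effect signal the island setting produces.

A full synthetic study runs from the shell:

```bash
ylineage simulate --seed 7 --out-prefix sim       # divergent pair, STR+SNP tables
ylineage forensic --panel yfiler_plus --str sim.str.tsv
ylineage distance --str sim.str.tsv --out rst.tsv
ylineage haplogroup --snp sim.snp.tsv --out-prefix hg
ylineage network --str sim.str.tsv --snp sim.snp.tsv --haplogroup O1a --out-prefix net
```

or end-to-end with `ylineage run --config run.yaml` (see
`ylineage.pipeline.RunConfig` for the keys).

## Documentation

`docs/methods.md` describes the models, estimators, simulator
assumptions, numerical choices and known limitations.
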