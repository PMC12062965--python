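# tecapture

Toolkit for studying **protein-domain capture from transposable elements
(TEs) and viruses**, and for asking how such captures become embedded in host
genomes and protein-interaction networks. It grew out of the analysis of a
nematode F-box gene family that acquired a Tc1/Mariner transposase
helix-turn-helix (HTH) domain, but every pipeline is generic.

It is aimed at molecular-evolution and structural-bioinformatics researchers
who have (or can simulate) three kinds of input:

1. **A protein domain-annotation table** (InterPro-style accessions with
   amino-acid coordinates) plus two curated accession lists — domains that
   define eukaryotic *multicopy* gene families (F-box, ankyrin, BTB/POZ, ...)
   and domains diagnostic of *TEs/viruses* (transposase HTH, integrase,
   reverse transcriptase, ...).
2. **A genome annotation**: gene models (GFF3), a gene→PFAM map, and TE
   copies (GFF3/BED with EDTA-style classification strings).
3. **A structural interaction screen**: two-chain predicted complexes (PDB)
   with pTM/ipTM confidences and a labeled interactor/noninteractor
   benchmark.

## The three analyses

**Domain co-occurrence screen** (`tecapture.domain_screen`). Finds proteins
carrying ≥ 1 multicopy and ≥ 1 TE/viral domain, groups them by
(multicopy, TE) accession pair, tallies each group's taxonomic spread, and
quantifies two signatures of genuine capture events: the N-terminal bias of
the TE-derived domain (exact two-sided binomial sign test on leftmost-domain
relative midpoints, ties excluded) and the association between host family
size and the number of distinct captured domains (Spearman's ρ).

**TE-proximity enrichment** (`tecapture.te_enrichment`). For each PFAM
family *f* the statistic is

&nbsp;&nbsp;&nbsp;&nbsp;T(f) = Σ_{g ∈ f} min(10, #{classified TE copies overlapping gene g ± 500 bp}),

compared against B = 1000 nulls in which every TE copy is independently
replaced across scaffolds (scaffold chosen ∝ legal start positions, start
uniform; copy number, lengths and classifications preserved). Empirical tail
p-values use the add-one rule p = (1 + #{T* ≥ T}) / (1 + B), are
Benjamini–Hochberg corrected across families, and reported as signed
−log₁₀ q scores. Both enrichment and depletion sides are computed, with
optional stratification by TE class (DNA / LTR / RC-Helitron / LINE).

**Interaction-screen triage** (`tecapture.interaction_screen`). ROC analysis
of pTM/ipTM against the benchmark (AUC = Mann–Whitney U /(n₊n₋), ties ½);
threshold selection at the Kolmogorov–Smirnov supremum
D = max_t [ECDF₋(t) − ECDF₊(t)]; high-confidence calls require both metrics
to pass. Interface geometry then excludes van-der-Waals-clashed atom pairs
(inter-chain d < r₁ + r₂, Bondi radii), computes per-bait-residue minimum
distances to the prey, and summarizes the median distance per bait domain —
revealing which domain (e.g. HTH vs F-box vs FTH) is the preferred contact
platform.

A fourth module, `tecapture.synthetic_data`, generates seeded synthetic
inputs with planted truth records for all three pipelines, and
`tecapture.pipeline`/the `tecapture` CLI orchestrate multi-stage runs with a
checksum manifest.

## Worked example

Simulate a domain table with 60 planted F-box × Mariner-HTH fusion proteins
(N-terminal TE domain) and a genome with λ = 5 extra TE copies planted per
focal-family gene window, then run the two screens:

```python
from pathlib import Path
from tecapture import synthetic_data as sd, domain_screen as ds, te_enrichment as te

cfg = sd.SimConfig(seed=11, enrichment_plant=sd.EnrichmentPlant(extra_te_rate=5.0))
paths, truth = sd.gen_domain_table(cfg, Path("demo"))
sets = ds.load_domain_sets(paths["sets"])
records = ds.load_domain_table(paths["domains"], sets)
cooc = ds.screen_cooccurrence(records)
groups = ds.group_by_domain_pair(cooc, ds.load_taxonomy(paths["taxonomy"]))
count, total, pct = ds.clade_fraction(groups[0], "phylum", "Nematoda")
bias = ds.positional_bias(cooc, records)

gpaths, _ = sd.gen_genome_with_tes(cfg, Path("demo"))
genes, _ = te.load_gene_models(gpaths["genes"], gpaths["pfam_map"])
tes = te.load_te_annotations(gpaths["tes"])
lengths = te.load_scaffold_lengths(gpaths["scaffolds"])
res = te.run_enrichment(genes, tes, lengths, te.EnrichmentParams(replicates=200, seed=11))
```

Output:

```
screen hits: 60 (60 single, 0 multiple)
largest pair group: ('IPR001810', 'IPR041426') with 60 members
Nematoda fraction: 60/60 (100.0%)
TE-domain N-terminal fraction: 1.00 (binomial p = 1.73e-18)
top family: PF00646  observed=100  null=11.3+/-3.5  p_enrich=0.004975  q=0.0995  score=1.00
```

Reading: all 60 planted fusion proteins are recovered; the largest
co-occurrence group is the planted (F-box, Tc1/Mariner HTH) pair, confined to
Nematoda; the TE domain sits N-terminal in every carrier (sign test
p ≈ 2 × 10⁻¹⁸); and the focal family PF00646 shows ~9× the TE count expected
under the shuffle null (its p is at the add-one floor 1/201; q is the
BH-corrected value across the 20 families tested).

The same stages are available from the shell
(`tecapture simulate|screen|enrich|interact|run`); see `tecapture --help`.

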