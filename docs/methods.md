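# Methods

## Domain co-occurrence screen

A protein is a screen hit when it carries at least one domain from the
curated multicopy set and at least one from the curated TE/viral set;
categories are derived purely from set membership, and the two sets must be
disjoint. Coordinates are 1-based inclusive amino-acid positions (the
InterPro convention) and are stored unchanged.

Counting conventions, chosen once and used everywhere:

* **Single vs multiple TE domains** is decided on *distinct accessions*:
  several copies of the same captured domain do not make a protein
  "multiple". This keeps a tandem duplication of one capture event from
  masquerading as several captures.
* **Pair groups**: a protein carrying *m* multicopy and *t* TE/viral
  accessions contributes to all *m × t* pairs, since each pair is a distinct
  candidate fusion architecture.
* **Taxonomy**: clade counts are tallied at every rank present in the
  lineage table; taxa without a lineage (or without the rank) are binned as
  `unclassified` and kept in denominators, so per-rank counts always sum to
  the group size. Reported percentages are rounded half-up to one decimal,
  matching how such fractions are conventionally printed.
* **N-terminal bias**: per protein the *leftmost* domain of each category is
  reduced to its relative midpoint (start+end)/2 ÷ length, and a protein is
  a success when the TE midpoint is strictly smaller. Exact ties are
  excluded and the success count is tested with an exact two-sided binomial
  test against 0.5. Midpoints (rather than starts or span fractions) are
  used because they are insensitive to the systematically different lengths
  of TE-derived and host domains; the choice matters little when domains do
  not interleave. The statistic is antisymmetric under coordinate mirroring,
  which the tests exploit.
* **Family-size association**: Spearman's ρ between a multicopy accession's
  carrier count and its number of distinct TE/viral partners. Rank
  correlation is preferred because family sizes are heavy-tailed. A constant
  variable makes the correlation undefined; the function returns NaN with a
  warning instead of failing, so callers can summarize many strata.

## TE-proximity enrichment

Internal coordinates are 0-based half-open; GFF3 is converted at the
boundary. Only *classified* TE copies participate (empty or `Unknown`
classifications are dropped and the removed count is logged), mirroring
standard practice for EDTA-style annotations.

**Statistic.** Per gene, the window is the gene body extended `flank`
(default 500) bp on each side, clipped at zero. Every classified copy
overlapping the window by ≥ 1 bp is at edge distance zero, so "the `cap`
nearest copies" reduces to `min(cap, overlap count)` with `cap` = 10 by
default. Per-gene counts are summed per PFAM family; a gene with several
PFAMs contributes to each. A copy overlapping several gene windows counts
for each gene.

**Null.** Position randomization with copy number, lengths, and
classifications fixed: each copy independently lands on a scaffold with
probability proportional to its number of legal start positions
(length − TE length + 1), then uniformly among them. Shuffled copies may
overlap each other and genes — no exclusion zones are imposed. This
preserves the genome-wide TE density while destroying any gene association,
which is exactly the hypothesis under test. Resampling copies with
replacement was considered and rejected: it changes the copy-number marginal
that the observed statistic is conditioned on.

**Inference.** Add-one empirical tails, p = (1 + #{T* ≥ T})/(1 + B) per
side, so p = 0 is impossible at finite B (floor 1/(B+1); 1/1001 at the
default B = 1000). The enrichment-side p-values are corrected across
families by Benjamini–Hochberg (Bonferroni available) and reported as
scores −log₁₀ q, signed positive when the enrichment side is the smaller
tail. Replicate b uses seed `master_seed XOR b`, so any replicate is
individually reproducible and replicates are independent of their order.
Optional stratification reruns the entire procedure per TE class prefix
(`DNA`, `LTR`, `RC`, `LINE`, ...).

The production counter uses per-scaffold sorted edge arrays
(count = #starts < window_end − #ends ≤ window_start), which the tests pin
against the O(genes × TEs) brute-force definition.

## Interaction-screen triage

**ROC.** Classifier "score ≥ t ⇒ interactor" over the unique observed
scores; AUC via the rank statistic (equals the trapezoidal integral of the
curve and the Mann–Whitney U statistic with ties counted ½). **Threshold**:
the one-sided Kolmogorov–Smirnov scan D(t) = ECDF₋(t⁻) − ECDF₊(t⁻) over
candidate thresholds, taking the *smallest* t attaining max D (the most
inclusive rule at equal separation). The one-sided difference is used
because the scores are oriented (interactors score higher); if max D ≤ 0
the metric is flagged non-separable and the threshold is +∞ so nothing
passes. **High confidence** requires pTM *and* ipTM to pass (an
`any_metric` switch gives the disjunction).

**Geometry.** Clashes are evaluated over *inter-chain* atom pairs only —
intra-chain geometry is the structure predictor's responsibility — with the
strict rule d < r₁ + r₂ on Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, P 1.80 Å; overridable via a radii table). Both atoms of a clashing
pair are excluded. Per-bait-residue minima are all-atom (hydrogens included
when present), taken over non-excluded atoms; a residue with no eligible
partner carries an explicit no-contact sentinel, never a fake 0 Å. Domain
summaries take the median of each domain's residue minima (sentinels
excluded; a domain with no usable residue is dropped with a warning) and
prefer the argmin domain, reporting `ambiguous` on exact ties. All geometry
is invariant under rigid motions to well below 10⁻⁶ Å, which the tests
verify.

## Synthetic data

Generators are pure functions of their `SimConfig` (seed included) and write
a JSON truth record next to each dataset.

* **Domain tables**: planted carriers hold the configured accession pair
  with the TE-domain relative midpoint ~ U(0.05, 0.30) in `nterm` mode
  (multicopy at U(0.45, 0.90)), mirrored for `cterm`, both U(0.05, 0.95) in
  `uniform` mode. Defaults (60 carriers of the F-box × Mariner-HTH pair
  among 500 proteins, nematode taxa) echo the flagship biological case.
  Background proteins carry uncurated domains, and one in five carries a
  single curated domain so the screen has true negatives.
* **Genomes**: genes are packed without overlap (windows separated by
  ≥ 2×flank), one PFAM per gene with the non-focal families assigned by
  shuffled round-robin so every declared family is realized. Background
  copies are placed by the *same* length-proportional rule as the shuffle
  null, making the observed statistic exchangeable with its null at
  λ = 0 — the basis of the calibration tests. Planted enrichment adds
  Poisson(λ) copies inside each focal gene's window.
* **Benchmarks**: pTM/ipTM drawn from truncated normals on [0, 1]
  (positives μ = 0.8, negatives μ = 0.3, σ = 0.12 by default; 255 positive
  and 490 negative pairs, the size of the curated interactor library the
  triage is designed around). The distribution family is a modelling
  convenience, not a claim about predictor score distributions.
* **Complexes**: the bait is a straight Cα trace (3.8 Å spacing) of three
  20-residue domains (HTH, F-box, FTH); the prey runs parallel to the
  planted domain at the configured offset (must exceed the 3.4 Å C–C
  contact distance; small seeded jitter σ = 0.05 Å), so planted-domain
  residues sit at ≈ the offset while other domains are several-fold
  farther. Clash injection adds one prey atom 1.5 Å above a bait atom in
  the farthest domain; its nearest neighbours are 4.08 Å away, so exactly
  one pair clashes.

What the generators deliberately do **not** emulate: real sequence content,
domain-architecture diversity, genomic TE clustering/nesting, correlated
pTM/ipTM errors, or side-chain geometry. Passing tests therefore certify the
*procedures* (counting rules, null construction, calibration, threshold
logic, geometry) — not performance on any real proteome or genome.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to make the
statistical checks sharp: 100 random 1,000-protein fixtures for the
brute-force screen oracle; 200 null families at B = 200 replicates for
calibration (99% binomial envelope around 0.05); 20 seeds at λ = 5 on 20
focal genes for planted recovery; 50 random benchmarks for the AUC/U
identity and 100 label permutations for the chance band; 100 random
≤ 200-atom complexes for the geometry oracle. Full-genome scans simply scale
the same code paths.

Ties are broken deterministically everywhere (lexicographic clade order,
smallest KS threshold, `ambiguous` on exact median ties); percentages round
half-up to one decimal; empirical p-values can never be 0 or exceed 1.

## Known limitations

* The co-occurrence screen trusts the input annotation; it cannot detect
  captures that annotation pipelines missed, and protein isoforms sharing
  an accession are counted as distinct proteins.
* The enrichment null randomizes TEs only; gene positions are taken as
  fixed, so clustered gene families in genuinely TE-poor regions can appear
  depleted without any causal link.
* The KS threshold is a point estimate from the benchmark; no uncertainty
  is propagated into the high-confidence calls.
* Clash filtering with fixed radii ignores element charge states and
  covalent context; it is a triage filter, not an energy model.
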