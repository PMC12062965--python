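"""Screen protein domain-annotation tables for TE/viral domain capture.

Mobile genetic elements (transposons, endogenous viruses) occasionally donate
protein-coding domains to host genes. A hallmark of such capture events is the
co-occurrence, within one protein, of a domain characteristic of TEs or viruses
(transposase helix-turn-helix folds, integrases, reverse transcriptases, ...)
with a host domain that defines a large multicopy gene family (F-box, ankyrin
repeats, BTB/POZ, ...). This module cross-references a flat domain-annotation
table (one row per located domain, InterPro-style accessions) against two
curated accession sets and reports the co-occurrence proteins, their grouping
by domain pair, taxonomic spread, positional bias of the TE-derived domain, and
the association between host family size and the diversity of captured domains.
"""

from __future__ import annotations

import decimal
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

CATEGORY_MULTICOPY = "multicopy"
CATEGORY_TE_VIRAL = "te_viral"
CATEGORY_OTHER = "other"

_DOMAIN_TABLE_COLUMNS = ["protein_id", "taxon_id", "length", "accession", "start", "end"]

UNCLASSIFIED_CLADE = "unclassified"


@dataclass(frozen=True)
class DomainAnnotation:
    """A located domain on a protein; 1-based inclusive amino-acid coordinates."""

    accession: str
    start: int
    end: int
    category: str = CATEGORY_OTHER

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid domain coordinates {self.accession}: [{self.start}, {self.end}]"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ProteinRecord:
    protein_id: str
    taxon_id: str
    length: int
    domains: list[DomainAnnotation] = field(default_factory=list)

    def domains_of(self, category: str) -> list[DomainAnnotation]:
        return [d for d in self.domains if d.category == category]


@dataclass
class DomainSet:
    """A curated accession list: either the multicopy or the TE/viral side."""

    label: str
    accessions: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"domain set {self.label!r} is empty")


@dataclass
class TaxonomyMap:
    """Per-taxon lineages as ordered (rank, clade) pairs, long-format friendly."""

    lineages: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for taxon, lineage in self.lineages.items():
            ranks = [r for r, _ in lineage]
            if len(ranks) != len(set(ranks)):
                raise ValueError(f"duplicate rank in lineage of taxon {taxon!r}")

    @property
    def ranks(self) -> list[str]:
        seen: dict[str, None] = {}
        for lineage in self.lineages.values():
            for rank, _ in lineage:
                seen.setdefault(rank, None)
        return list(seen)

    def clade_of(self, taxon_id: str, rank: str) -> str:
        for r, clade in self.lineages.get(taxon_id, []):
            if r == rank:
                return clade
        return UNCLASSIFIED_CLADE


@dataclass
class CooccurrenceRecord:
    """A protein carrying at least one domain of each curated category."""

    protein_id: str
    multicopy_hits: list[DomainAnnotation]
    te_hits: list[DomainAnnotation]
    taxon_id: str = ""

    def __post_init__(self) -> None:
        if not self.multicopy_hits or not self.te_hits:
            raise ValueError("both hit lists must be non-empty")


@dataclass
class CooccurrenceGroup:
    """All proteins sharing one (multicopy, TE/viral) accession pair."""

    pair: tuple[str, str]
    members: set[str]
    clade_counts: dict[str, Counter]  # rank -> clade -> member count


@dataclass
class PositionalBiasResult:
    n_proteins: int
    fraction_te_nterminal: float
    binomial_p: float
    relative_positions: list[tuple[float, float]]


def percent_half_up(count: int, total: int, ndigits: int = 1) -> float:
    """100*count/total, rounded half-up (the convention of printed percentages)."""
    if total == 0:
        raise ZeroDivisionError("zero denominator")
    q = decimal.Decimal(count) * 100 / decimal.Decimal(total)
    exp = decimal.Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# loaders


def load_domain_sets(path) -> tuple[DomainSet, DomainSet]:
    """Load the curated accession lists (TSV: accession, category[, description]).

    Returns (multicopy, te_viral). Overlapping accessions are an error: an
    accession cannot be both a host multicopy domain and a TE/viral domain.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("accession", "category"):
        if col not in df.columns:
            raise ValueError(f"domain set table missing column {col!r}")
    if "description" not in df.columns:
        df["description"] = ""
    sets = {}
    for label in (CATEGORY_MULTICOPY, CATEGORY_TE_VIRAL):
        sub = df[df["category"] == label]
        sets[label] = DomainSet(
            label=label,
            accessions=set(sub["accession"]),
            descriptions=dict(zip(sub["accession"], sub["description"].fillna(""))),
        )
    bad = set(df["category"]) - {CATEGORY_MULTICOPY, CATEGORY_TE_VIRAL}
    if bad:
        raise ValueError(f"unknown domain-set categories: {sorted(bad)}")
    overlap = sets[CATEGORY_MULTICOPY].accessions & sets[CATEGORY_TE_VIRAL].accessions
    if overlap:
        raise ValueError(f"accessions in both sets: {sorted(overlap)}")
    return sets[CATEGORY_MULTICOPY], sets[CATEGORY_TE_VIRAL]


def load_taxonomy(path) -> TaxonomyMap:
    """Load a long-format lineage table (TSV: taxon_id, rank, clade_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("taxon_id", "rank", "clade_name"):
        if col not in df.columns:
            raise ValueError(f"taxonomy table missing column {col!r}")
    lineages: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for row in df.itertuples(index=False):
        lineages[row.taxon_id].append((row.rank, row.clade_name))
    return TaxonomyMap(lineages=dict(lineages))


def categorize(accession: str, domain_sets: tuple[DomainSet, DomainSet]) -> str:
    multicopy, te_viral = domain_sets
    if accession in multicopy.accessions:
        return CATEGORY_MULTICOPY
    if accession in te_viral.accessions:
        return CATEGORY_TE_VIRAL
    return CATEGORY_OTHER


def load_domain_table(
    path, domain_sets: tuple[DomainSet, DomainSet]
) -> list[ProteinRecord]:
    """Read the per-domain annotation table into one record per protein.

    The table has one row per located domain (protein_id, taxon_id, length,
    accession, start, end). Domains are categorized purely by membership in the
    supplied curated sets. Row numbers in error messages count the header as
    line 1.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "taxon_id": str})
    missing = [c for c in _DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table missing columns: {missing}")
    dup = df.duplicated(subset=["protein_id", "accession", "start", "end"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(f"duplicate domain rows at lines {lines}")
    bad = df.index[(df["start"] > df["end"]) | (df["start"] < 1)]
    if len(bad):
        raise ValueError(f"start > end (or start < 1) at line {int(bad[0]) + 2}")
    bad = df.index[df["end"] > df["length"]]
    if len(bad):
        raise ValueError(f"domain end beyond protein length at line {int(bad[0]) + 2}")

    records: dict[str, ProteinRecord] = {}
    for row in df.itertuples(index=True):
        rec = records.get(row.protein_id)
        if rec is None:
            rec = ProteinRecord(
                protein_id=row.protein_id,
                taxon_id=row.taxon_id,
                length=int(row.length),
            )
            records[row.protein_id] = rec
        elif rec.length != int(row.length) or rec.taxon_id != row.taxon_id:
            raise ValueError(
                f"inconsistent length/taxon for protein {row.protein_id!r} "
                f"at line {row.Index + 2}"
            )
        rec.domains.append(
            DomainAnnotation(
                accession=row.accession,
                start=int(row.start),
                end=int(row.end),
                category=categorize(row.accession, domain_sets),
            )
        )
    return list(records.values())


# ---------------------------------------------------------------------------
# screening


def screen_cooccurrence(records: Iterable[ProteinRecord]) -> list[CooccurrenceRecord]:
    """Proteins with >=1 multicopy-category and >=1 TE/viral-category domain."""
    out = []
    for rec in records:
        mc = rec.domains_of(CATEGORY_MULTICOPY)
        te = rec.domains_of(CATEGORY_TE_VIRAL)
        if mc and te:
            out.append(
                CooccurrenceRecord(
                    protein_id=rec.protein_id,
                    multicopy_hits=mc,
                    te_hits=te,
                    taxon_id=rec.taxon_id,
                )
            )
    return out


def partition_by_te_count(
    cooc: Sequence[CooccurrenceRecord],
) -> tuple[list[CooccurrenceRecord], list[CooccurrenceRecord]]:
    """Split screen hits into single- vs multiple-TE/viral-domain proteins.

    Counting is by distinct TE/viral accession: several copies of the same
    captured domain still count as a single TE/viral domain.
    """
    single, multiple = [], []
    for rec in cooc:
        n = len({d.accession for d in rec.te_hits})
        (single if n == 1 else multiple).append(rec)
    return single, multiple


def group_by_domain_pair(
    cooc: Sequence[CooccurrenceRecord], taxonomy: TaxonomyMap
) -> list[CooccurrenceGroup]:
    """Group screen hits by (multicopy accession, TE/viral accession) pair.

    A protein carrying several domains of each category contributes to every
    pair it realizes. Clade counts are tallied at every rank present in the
    taxonomy; taxa without a lineage (or without the rank) are binned as
    "unclassified" so per-rank totals stay equal to the member count. Groups
    are returned sorted by member count descending, then by pair.
    """
    members: dict[tuple[str, str], set[str]] = defaultdict(set)
    taxon_of: dict[str, str] = {}
    for rec in cooc:
        taxon_of[rec.protein_id] = rec.taxon_id
        for m in {d.accession for d in rec.multicopy_hits}:
            for t in {d.accession for d in rec.te_hits}:
                members[(m, t)].add(rec.protein_id)

    ranks = taxonomy.ranks
    groups = []
    for pair, prot_ids in members.items():
        clade_counts: dict[str, Counter] = {rank: Counter() for rank in ranks}
        for pid in prot_ids:
            for rank in ranks:
                clade_counts[rank][taxonomy.clade_of(taxon_of[pid], rank)] += 1
        groups.append(CooccurrenceGroup(pair=pair, members=prot_ids, clade_counts=clade_counts))
    groups.sort(key=lambda g: (-len(g.members), g.pair))
    return groups


def clade_fraction(
    group: CooccurrenceGroup, rank: str, clade: str
) -> tuple[int, int, float]:
    """(count, total, percent) of group members falling in `clade` at `rank`."""
    count = group.clade_counts.get(rank, Counter()).get(clade, 0)
    total = len(group.members)
    return count, total, percent_half_up(count, total)


def summarize_taxonomic_spread(
    group: CooccurrenceGroup, rank: str, top_n: int
) -> list[tuple[str, int]]:
    """Top clades of a group at one rank, count-descending, ties lexicographic."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts = group.clade_counts.get(rank, Counter())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def positional_bias(
    cooc: Sequence[CooccurrenceRecord],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
) -> PositionalBiasResult:
    """Test whether the TE/viral domain sits N-terminal of the multicopy domain.

    Per protein we take the leftmost domain of each category and its relative
    midpoint (start+end)/2 divided by the protein length. A protein is a
    "success" when the TE/viral midpoint is strictly left of the multicopy
    midpoint; exact ties are excluded from the sign test. The p-value is the
    exact two-sided binomial test of the success count against 0.5.
    """
    if not isinstance(records, Mapping):
        records = {r.protein_id: r for r in records}
    positions: list[tuple[float, float]] = []
    n_success = 0
    n_informative = 0
    for rec in cooc:
        length = records[rec.protein_id].length
        te = min(rec.te_hits, key=lambda d: (d.start, d.end))
        mc = min(rec.multicopy_hits, key=lambda d: (d.start, d.end))
        te_rel = te.midpoint / length
        mc_rel = mc.midpoint / length
        positions.append((te_rel, mc_rel))
        if te_rel < mc_rel:
            n_success += 1
            n_informative += 1
        elif te_rel > mc_rel:
            n_informative += 1
    if n_informative == 0:
        raise ValueError("no informative proteins for positional bias")
    p = stats.binomtest(n_success, n_informative, 0.5, alternative="two-sided").pvalue
    return PositionalBiasResult(
        n_proteins=len(positions),
        fraction_te_nterminal=n_success / n_informative,
        binomial_p=float(p),
        relative_positions=positions,
    )


def family_size_association(
    records: Iterable[ProteinRecord], groups: Sequence[CooccurrenceGroup]
) -> tuple[float, float]:
    """Spearman rho between multicopy family size and captured-domain diversity.

    Family size of a multicopy accession = number of proteins carrying it;
    captured diversity = number of distinct TE/viral accessions it co-occurs
    with (zero if the accession never appears in a screen group). When either
    variable is constant the correlation is undefined: returns (nan, nan) with
    a warning.
    """
    family_size: Counter = Counter()
    for rec in records:
        for acc in {d.accession for d in rec.domains_of(CATEGORY_MULTICOPY)}:
            family_size[acc] += 1
    if len(family_size) < 3:
        raise ValueError("need >=3 observed multicopy accessions")
    partners: dict[str, set[str]] = defaultdict(set)
    for g in groups:
        partners[g.pair[0]].add(g.pair[1])
    sizes = []
    diversity = []
    for acc, n in sorted(family_size.items()):
        sizes.append(n)
        diversity.append(len(partners.get(acc, ())))
    if len(set(sizes)) == 1 or len(set(diversity)) == 1:
        warnings.warn("undefined correlation: a variable is constant", stacklevel=2)
        return math.nan, math.nan
    rho, p = stats.spearmanr(sizes, diversity)
    return float(rho), float(p)


def class_fraction(counts: Mapping[str, int], focal: str) -> float:
    """Percent of the focal class in a count partition, half-up to 1 decimal."""
    if focal not in counts:
        raise KeyError(f"focal class {focal!r} not in counts")
    total = sum(counts.values())
    return percent_half_up(counts[focal], total)
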