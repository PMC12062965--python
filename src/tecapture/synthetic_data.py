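"""Seeded synthetic inputs with the statistical structure the pipelines assume.

Each generator is a pure function of its configuration (seed included): the
same config yields byte-identical files. Alongside every dataset a JSON truth
record is written with the planted signal, so recovery can be scored without
re-deriving it. The generators emulate, at desk scale, the three input kinds
of the analysis: a protein domain-annotation table with planted co-occurring
(multicopy, TE/viral) pairs; a genome with background-uniform TE copies plus
optional enrichment planted near the genes of a focal PFAM family; benchmark
confidence-score sets drawn from truncated-normal positive/negative models;
and toy two-chain C-alpha-trace complexes with the prey placed at a controlled
distance from a chosen bait domain, with optional injected steric clashes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .interaction_screen import Atom, ComplexModel, BAIT, PREY, write_complex


@dataclass
class PlantedPair:
    multicopy_accession: str = "IPR001810"  # F-box
    te_accession: str = "IPR041426"  # Tc1/Mariner HTH
    n_carriers: int = 60
    te_position_mode: str = "nterm"  # nterm | cterm | uniform


@dataclass
class EnrichmentPlant:
    focal_pfam: str = "PF00646"  # F-box
    extra_te_rate: float = 0.0  # Poisson rate of planted copies per focal gene window


@dataclass
class ScoreModel:
    pos_mean: float = 0.8
    neg_mean: float = 0.3
    sd: float = 0.12


@dataclass
class ContactPlant:
    domain_label: str = "HTH"
    prey_offset_aa: float = 4.0  # Angstrom
    inject_clash: bool = False


@dataclass
class SimConfig:
    seed: int = 0
    # domain table
    n_proteins: int = 500
    planted_pairs: list[PlantedPair] = field(default_factory=lambda: [PlantedPair()])
    # genome
    n_genes: int = 200
    n_tes: int = 400
    n_scaffolds: int = 3
    scaffold_length: int = 1_000_000
    n_pfams: int = 20
    n_focal_genes: int = 20
    gene_length: int = 1500
    te_length_range: tuple[int, int] = (100, 2000)
    unknown_te_rate: float = 0.05
    flank: int = 500
    enrichment_plant: EnrichmentPlant = field(default_factory=EnrichmentPlant)
    # benchmark: library sizes follow the curated 255/490 interactor library
    n_pos: int = 255
    n_neg: int = 490
    score_model: ScoreModel = field(default_factory=ScoreModel)
    # complex
    residues_per_domain: int = 20
    prey_residues: int = 20
    contact_plant: ContactPlant = field(default_factory=ContactPlant)


_TE_CLASSES = ["DNA/TcMar", "DNA/hAT", "LTR/Gypsy", "RC/Helitron", "LINE/L1"]
_OTHER_ACCESSIONS = [f"IPR9{i:05d}" for i in range(40)]

_DOMAIN_SET_ROWS = [
    ("IPR001810", "multicopy", "F-box domain"),
    ("IPR011333", "multicopy", "BTB/POZ domain"),
    ("IPR036770", "multicopy", "Ankyrin repeat"),
    ("IPR041426", "te_viral", "Tc1/Mariner transposase HTH (Mos1-type)"),
    ("IPR041588", "te_viral", "Integrase zinc-binding domain"),
    ("IPR000477", "te_viral", "Reverse transcriptase"),
]

_TAXA = [  # taxon_id, kingdom, phylum
    ("tax_cele", "Metazoa", "Nematoda"),
    ("tax_cbri", "Metazoa", "Nematoda"),
    ("tax_crem", "Metazoa", "Nematoda"),
    ("tax_hsap", "Metazoa", "Chordata"),
    ("tax_drer", "Metazoa", "Chordata"),
    ("tax_atha", "Viridiplantae", "Streptophyta"),
    ("tax_dmel", "Metazoa", "Arthropoda"),
]


def _write_truth(out_dir: Path, name: str, truth: dict) -> Path:
    path = out_dir / name
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# domain tables


def gen_domain_table(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], dict]:
    """Synthesize domains.tsv, sets.tsv, taxonomy.tsv and a truth record.

    Background proteins carry 1-4 uncurated domains; a further slice carries a
    single curated domain of only one category (so the co-occurrence filter has
    something to reject). Planted carriers hold a configured (multicopy,
    TE/viral) pair with the TE-domain relative midpoint drawn per position
    mode: nterm ~ U(0.05, 0.30) with the multicopy domain at U(0.45, 0.90);
    cterm mirrors this; uniform draws both at U(0.05, 0.95).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    n_planted = sum(p.n_carriers for p in cfg.planted_pairs)
    if n_planted > cfg.n_proteins:
        raise ValueError("planted carriers exceed n_proteins")

    taxon_ids = [t[0] for t in _TAXA]
    nem_taxa = [t[0] for t in _TAXA if t[2] == "Nematoda"]
    rows: list[tuple] = []
    truth_carriers: list[dict] = []
    pid = 0

    def new_protein(taxon: str, length: int) -> str:
        nonlocal pid
        pid += 1
        return f"P{pid:06d}", taxon, length

    def place(length: int, rel_lo: float, rel_hi: float, width: int) -> tuple[int, int]:
        mid = rng.uniform(rel_lo, rel_hi) * length
        half = width / 2
        start = int(max(1, round(mid - half)))
        end = int(min(length, round(mid + half)))
        return start, max(end, start)

    for pair in cfg.planted_pairs:
        for _ in range(pair.n_carriers):
            name, taxon, length = new_protein(
                str(rng.choice(nem_taxa)), int(rng.integers(300, 1000))
            )
            if pair.te_position_mode == "nterm":
                te_lo, te_hi, mc_lo, mc_hi = 0.05, 0.30, 0.45, 0.90
            elif pair.te_position_mode == "cterm":
                te_lo, te_hi, mc_lo, mc_hi = 0.70, 0.95, 0.10, 0.55
            elif pair.te_position_mode == "uniform":
                te_lo, te_hi, mc_lo, mc_hi = 0.05, 0.95, 0.05, 0.95
            else:
                raise ValueError(f"unknown position mode {pair.te_position_mode!r}")
            te_start, te_end = place(length, te_lo, te_hi, 60)
            mc_start, mc_end = place(length, mc_lo, mc_hi, 50)
            rows.append((name, taxon, length, pair.te_accession, te_start, te_end))
            rows.append((name, taxon, length, pair.multicopy_accession, mc_start, mc_end))
            truth_carriers.append(
                {
                    "protein_id": name,
                    "pair": [pair.multicopy_accession, pair.te_accession],
                    "mode": pair.te_position_mode,
                }
            )

    n_background = cfg.n_proteins - n_planted
    single_category = [r[0] for r in _DOMAIN_SET_ROWS]
    for i in range(n_background):
        name, taxon, length = new_protein(
            str(rng.choice(taxon_ids)), int(rng.integers(200, 1200))
        )
        if i % 5 == 0:  # single-category curated carrier, never a pair
            acc = str(rng.choice(single_category))
            start, end = place(length, 0.05, 0.95, 50)
            rows.append((name, taxon, length, acc, start, end))
        n_dom = int(rng.integers(1, 5))
        accs = rng.choice(_OTHER_ACCESSIONS, size=n_dom, replace=False)
        for acc in accs:
            start, end = place(length, 0.05, 0.95, 40)
            rows.append((name, taxon, length, str(acc), start, end))

    paths = {
        "domains": out_dir / "domains.tsv",
        "sets": out_dir / "sets.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
    }
    _write_tsv(
        paths["domains"],
        ["protein_id", "taxon_id", "length", "accession", "start", "end"],
        rows,
    )
    _write_tsv(paths["sets"], ["accession", "category", "description"], _DOMAIN_SET_ROWS)
    tax_rows = []
    for taxon, kingdom, phylum in _TAXA:
        tax_rows.append((taxon, "kingdom", kingdom))
        tax_rows.append((taxon, "phylum", phylum))
    _write_tsv(paths["taxonomy"], ["taxon_id", "rank", "clade_name"], tax_rows)
    truth = {
        "seed": cfg.seed,
        "n_proteins": cfg.n_proteins,
        "carriers": truth_carriers,
    }
    paths["truth"] = _write_truth(out_dir, "domains.truth.json", truth)
    return paths, truth


# ---------------------------------------------------------------------------
# genomes


def gen_genome_with_tes(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], dict]:
    """Synthesize genes.gff3, tes.gff3, scaffolds.tsv, pfam_map.tsv + truth.

    Genes are placed non-overlapping, uniformly across scaffolds; each gene
    carries one PFAM accession, with exactly ``n_focal_genes`` assigned to the
    focal family. Background TE copies are placed by the same
    length-proportional uniform rule the shuffle null uses, so under a zero
    planting rate the observed statistic is exchangeable with its null. With
    ``extra_te_rate`` lambda > 0, Poisson(lambda) additional copies are planted
    inside each focal gene's +/- flank window.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    scaffolds = {f"scaf{i + 1}": cfg.scaffold_length for i in range(cfg.n_scaffolds)}
    names = sorted(scaffolds)

    # non-overlapping gene placement by rejection sampling
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[tuple[str, str, int, int]] = []  # gene_id, scaffold, start, end
    for i in range(cfg.n_genes):
        for _attempt in range(1000):
            scaf = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, scaffolds[scaf] - cfg.gene_length))
            end = start + cfg.gene_length
            pad_lo, pad_hi = start - 2 * cfg.flank, end + 2 * cfg.flank
            if all(e <= pad_lo or s >= pad_hi for s, e in placed[scaf]):
                placed[scaf].append((start, end))
                genes.append((f"g{i + 1:04d}", scaf, start, end))
                break
        else:
            raise RuntimeError("gene packing infeasible after 1000 attempts")

    plant = cfg.enrichment_plant
    pfams = [plant.focal_pfam] + [f"PF{90000 + k}" for k in range(1, cfg.n_pfams)]
    if cfg.n_focal_genes > cfg.n_genes:
        raise ValueError("n_focal_genes exceeds n_genes")
    focal_idx = set(
        int(i) for i in rng.choice(cfg.n_genes, size=cfg.n_focal_genes, replace=False)
    )
    pfam_map: list[tuple[str, str]] = []
    focal_genes: list[str] = []
    # shuffled round-robin over the non-focal families so every declared
    # family is realized by at least one gene
    n_other = cfg.n_genes - cfg.n_focal_genes
    other_assign = [pfams[1 + k % (cfg.n_pfams - 1)] for k in range(n_other)]
    rng.shuffle(other_assign)
    j = 0
    for i, (gene_id, *_rest) in enumerate(genes):
        if i in focal_idx:
            pfam_map.append((gene_id, plant.focal_pfam))
            focal_genes.append(gene_id)
        else:
            pfam_map.append((gene_id, other_assign[j]))
            j += 1

    # background TEs: length-proportional scaffold choice, uniform start
    L = np.asarray([scaffolds[n] for n in names], dtype=np.int64)
    te_rows: list[tuple[str, int, int, str]] = []
    lo, hi = cfg.te_length_range
    for _ in range(cfg.n_tes):
        te_len = int(rng.integers(lo, hi + 1))
        w = np.maximum(L - te_len + 1, 0)
        scaf = int((np.cumsum(w) <= rng.random() * w.sum()).sum())
        start = int(rng.integers(0, w[scaf]))
        cls = (
            "Unknown"
            if rng.random() < cfg.unknown_te_rate
            else _TE_CLASSES[int(rng.integers(len(_TE_CLASSES)))]
        )
        te_rows.append((names[scaf], start, start + te_len, cls))

    # planted enrichment inside focal gene windows
    n_planted = 0
    if plant.extra_te_rate > 0:
        for gene_id, scaf, gstart, gend in genes:
            if gene_id not in focal_genes:
                continue
            for _ in range(int(rng.poisson(plant.extra_te_rate))):
                te_len = int(rng.integers(100, 1000))
                ws = max(0, gstart - cfg.flank)
                we = min(scaffolds[scaf], gend + cfg.flank)
                start = int(rng.integers(ws, max(ws + 1, we - te_len)))
                cls = _TE_CLASSES[int(rng.integers(len(_TE_CLASSES)))]
                te_rows.append((scaf, start, start + te_len, cls))
                n_planted += 1

    paths = {
        "genes": out_dir / "genes.gff3",
        "tes": out_dir / "tes.gff3",
        "scaffolds": out_dir / "scaffolds.tsv",
        "pfam_map": out_dir / "pfam_map.tsv",
    }
    with open(paths["genes"], "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, scaf, start, end in genes:
            fh.write(
                f"{scaf}\ttecapture\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )
    with open(paths["tes"], "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for k, (scaf, start, end, cls) in enumerate(te_rows, start=1):
            fh.write(
                f"{scaf}\ttecapture\tdispersed_repeat\t{start + 1}\t{end}\t.\t.\t.\t"
                f"ID=te{k:05d};classification={cls}\n"
            )
    with open(paths["scaffolds"], "w", newline="\n") as fh:
        for n in names:
            fh.write(f"{n}\t{scaffolds[n]}\n")
    _write_tsv(paths["pfam_map"], ["gene_id", "pfam_id"], pfam_map)
    truth = {
        "seed": cfg.seed,
        "focal_pfam": plant.focal_pfam,
        "extra_te_rate": plant.extra_te_rate,
        "focal_genes": sorted(focal_genes),
        "n_planted_tes": n_planted,
    }
    paths["truth"] = _write_truth(out_dir, "genome.truth.json", truth)
    return paths, truth


# ---------------------------------------------------------------------------
# benchmark scores


def gen_benchmark_scores(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], dict]:
    """Benchmark TSV with pTM/ipTM drawn from truncated normals on [0, 1]."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    m = cfg.score_model
    if m.sd <= 0:
        raise ValueError("score sd must be positive")

    def draw(mean: float, size: int) -> np.ndarray:
        a, b = (0.0 - mean) / m.sd, (1.0 - mean) / m.sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=m.sd, size=size, random_state=rng)

    rows = []
    for i in range(cfg.n_pos):
        rows.append(
            (f"pos{i + 1:04d}", "interactor",
             f"{draw(m.pos_mean, 1)[0]:.6f}", f"{draw(m.pos_mean, 1)[0]:.6f}")
        )
    for i in range(cfg.n_neg):
        rows.append(
            (f"neg{i + 1:04d}", "noninteractor",
             f"{draw(m.neg_mean, 1)[0]:.6f}", f"{draw(m.neg_mean, 1)[0]:.6f}")
        )
    paths = {"benchmark": out_dir / "benchmark.tsv"}
    _write_tsv(paths["benchmark"], ["pair_id", "label", "ptm", "iptm"], rows)
    truth = {
        "seed": cfg.seed,
        "n_pos": cfg.n_pos,
        "n_neg": cfg.n_neg,
        "score_model": asdict(m),
    }
    paths["truth"] = _write_truth(out_dir, "benchmark.truth.json", truth)
    return paths, truth


# ---------------------------------------------------------------------------
# toy complexes


def build_complex(cfg: SimConfig) -> tuple[ComplexModel, list[tuple[int, int, str]], dict]:
    """Construct the toy two-chain model in memory (see gen_complex)."""
    rng = np.random.default_rng(cfg.seed)
    plant = cfg.contact_plant
    n = cfg.residues_per_domain
    domain_map = [
        (1, n, "HTH"),
        (n + 1, 2 * n, "F-box"),
        (2 * n + 1, 3 * n, "FTH"),
    ]
    labels = [label for _s, _e, label in domain_map]
    if plant.domain_label not in labels:
        raise ValueError(f"unknown planted domain {plant.domain_label!r}")
    if plant.prey_offset_aa <= 3.4:  # C+C Bondi contact distance
        raise ValueError("prey offset must exceed the C-C van der Waals contact")

    spacing = 3.8  # C-alpha virtual bond length, Angstrom
    atoms: list[Atom] = []
    for i in range(3 * n):
        atoms.append(
            Atom(
                chain=BAIT, residue_index=i + 1, residue_name="GLY",
                atom_name="CA", element="C",
                position=(round(i * spacing, 3), 0.0, 0.0),
            )
        )
    dstart, dend, _ = domain_map[labels.index(plant.domain_label)]
    n_prey = min(cfg.prey_residues, dend - dstart + 1)
    x0 = (dstart - 1) * spacing
    jitter = rng.normal(0.0, 0.05, size=(n_prey, 2))
    for j in range(n_prey):
        atoms.append(
            Atom(
                chain=PREY, residue_index=j + 1, residue_name="ALA",
                atom_name="CA", element="C",
                position=(
                    round(x0 + j * spacing + jitter[j, 0], 3),
                    round(plant.prey_offset_aa, 3),
                    round(jitter[j, 1], 3),
                ),
            )
        )
    clash_pair = None
    if plant.inject_clash:
        # one extra prey atom hovering 1.5 A over a bait atom in the farthest
        # domain: clashes with exactly that atom (neighbours are 4.08 A away)
        far = [lab for lab in labels if lab != plant.domain_label][-1]
        fs, fe, _ = domain_map[labels.index(far)]
        target = fe  # last residue of the far domain
        tx = (target - 1) * spacing
        atoms.append(
            Atom(
                chain=PREY, residue_index=n_prey + 1, residue_name="ALA",
                atom_name="CA", element="C",
                position=(round(tx, 3), 0.0, 1.5),
            )
        )
        clash_pair = [
            [BAIT, target, "CA"],
            [PREY, n_prey + 1, "CA"],
        ]
    model = ComplexModel(
        bait_id="bait1", prey_id="prey1", atoms=atoms, ptm=0.9, iptm=0.85
    )
    truth = {
        "seed": cfg.seed,
        "planted_domain": plant.domain_label,
        "prey_offset": plant.prey_offset_aa,
        "clash_pair": clash_pair,
    }
    return model, domain_map, truth


def gen_complex(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], dict]:
    """Write a toy two-chain PDB + domain map + confidence row + truth record.

    The bait is a straight C-alpha trace of three equal-length labeled domain
    segments (HTH, F-box, FTH). The prey chain runs parallel to the planted
    domain at the configured offset (small seeded jitter), so every planted-
    domain residue has a prey atom at about that distance while the other
    domains sit several-fold farther. Optionally one extra prey atom is
    injected inside a bait atom's van der Waals envelope to exercise the
    clash filter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, domain_map, truth = build_complex(cfg)
    paths = {
        "pdb": out_dir / "complex.pdb",
        "domain_map": out_dir / "domain_map.tsv",
        "confidence": out_dir / "confidence.tsv",
    }
    write_complex(model, paths["pdb"])
    _write_tsv(
        paths["domain_map"],
        ["bait", "domain_label", "start_res", "end_res"],
        [(model.bait_id, label, s, e) for s, e, label in domain_map],
    )
    _write_tsv(
        paths["confidence"],
        ["bait", "prey", "ptm", "iptm"],
        [(model.bait_id, model.prey_id, model.ptm, model.iptm)],
    )
    paths["truth"] = _write_truth(out_dir, "complex.truth.json", truth)
    return paths, truth
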