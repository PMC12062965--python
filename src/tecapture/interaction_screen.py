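"""Triage of a proteome-wide two-chain complex-prediction screen.

Structure predictors emit, for every bait-prey pair, a model with global
(pTM) and interface (ipTM) confidence scores. This module post-processes such
a screen: (i) benchmark-driven ROC analysis of the confidence metrics against
a curated library of true interactors and noninteractors; (ii) score-threshold
selection by the Kolmogorov-Smirnov statistic between the two labeled score
distributions; (iii) high-confidence interactor calling; (iv) removal of
physically implausible interface atoms (two atoms closer than the sum of their
van der Waals radii are "clashed" and ignored); (v) per-bait-residue minimum
distance profiles to the prey; and (vi) per-domain median-distance summaries
that reveal which bait domain (e.g. a captured HTH vs the substrate-binding
FTH) forms the preferred contact surface.
"""

from __future__ import annotations

import logging
import math
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

BAIT = "bait"
PREY = "prey"

#: Bondi van der Waals radii (Angstrom) for the elements of standard residues.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

NO_CONTACT = None  # sentinel for residues with no eligible contact partner

AtomId = tuple[str, int, str]  # (chain, residue_index, atom_name)


@dataclass(frozen=True)
class Atom:
    chain: str  # BAIT or PREY
    residue_index: int  # sequential within chain, from 1
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]

    @property
    def atom_id(self) -> AtomId:
        return (self.chain, self.residue_index, self.atom_name)


@dataclass
class ComplexModel:
    bait_id: str
    prey_id: str
    atoms: list[Atom]
    ptm: float
    iptm: float

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]


@dataclass(frozen=True)
class BenchmarkPair:
    pair_id: str
    label: str  # "interactor" | "noninteractor"
    ptm: float
    iptm: float


@dataclass
class VdwRadiusTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("van der Waals radii must be positive")

    def radius(self, atom: Atom) -> float:
        try:
            return self.radii[atom.element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.atom_id})"
            ) from None


@dataclass
class RocResult:
    metric: str
    points: list[tuple[float, float, float]]  # (threshold, tpr, fpr)
    auc: float


@dataclass
class ThresholdSelection:
    metric: str
    threshold: float
    ks_statistic: float
    separable: bool = True


@dataclass
class DistanceProfile:
    bait_id: str
    prey_id: str
    min_distance_per_residue: dict[int, float | None]
    excluded_atoms: set[AtomId]


@dataclass
class DomainContactSummary:
    per_domain_median: dict[str, float]
    preferred_domain: str


# ---------------------------------------------------------------------------
# I/O


def load_benchmark(path) -> list[BenchmarkPair]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "label": str})
    for col in ("pair_id", "label", "ptm", "iptm"):
        if col not in df.columns:
            raise ValueError(f"benchmark table missing column {col!r}")
    bad = set(df["label"]) - {"interactor", "noninteractor"}
    if bad:
        raise ValueError(f"unknown benchmark labels: {sorted(bad)}")
    return [
        BenchmarkPair(r.pair_id, r.label, float(r.ptm), float(r.iptm))
        for r in df.itertuples(index=False)
    ]


def load_confidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "prey": str})
    for col in ("bait", "prey", "ptm", "iptm"):
        if col not in df.columns:
            raise ValueError(f"confidence table missing column {col!r}")
    return df


def load_radii(path) -> VdwRadiusTable:
    df = pd.read_csv(path, sep="\t", dtype={"element": str})
    return VdwRadiusTable(
        radii={r.element.upper(): float(r.radius) for r in df.itertuples(index=False)}
    )


def load_domain_map(path) -> dict[str, list[tuple[int, int, str]]]:
    """Domain map TSV (bait, domain_label, start_res, end_res) -> per-bait ranges."""
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "domain_label": str})
    out: dict[str, list[tuple[int, int, str]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.bait, []).append((int(r.start_res), int(r.end_res), r.domain_label))
    return out


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element of atom {atom_name!r}")
    if stripped[0] in "HD":
        return "H"
    return stripped[0]


def load_complex(
    pdb_path,
    confidence_row: Mapping[str, float | str],
    bait_chain: str = "A",
    prey_chain: str = "B",
) -> ComplexModel:
    """Read a two-chain PDB model; confidence_row supplies bait, prey, ptm, iptm.

    Chains are mapped to bait/prey by chain id (default A = bait, B = prey);
    residue indices are renumbered sequentially within each chain from 1.
    Elements come from the PDB element column when present, else are inferred
    from the atom name.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("complex", str(pdb_path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if len(chains) != 2:
        raise ValueError(f"{pdb_path}: expected exactly 2 chains, found {len(chains)}")
    if bait_chain not in chains or prey_chain not in chains:
        raise ValueError(
            f"{pdb_path}: chains {sorted(chains)} do not match convention "
            f"bait={bait_chain!r}, prey={prey_chain!r}"
        )
    atoms: list[Atom] = []
    for role, chain_id in ((BAIT, bait_chain), (PREY, prey_chain)):
        for idx, residue in enumerate(chains[chain_id].get_residues(), start=1):
            for atom in residue.get_atoms():
                element = (atom.element or "").strip() or _infer_element(atom.get_name())
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(
                    Atom(
                        chain=role,
                        residue_index=idx,
                        residue_name=residue.get_resname(),
                        atom_name=atom.get_name(),
                        element=element,
                        position=(x, y, z),
                    )
                )
    return ComplexModel(
        bait_id=str(confidence_row["bait"]),
        prey_id=str(confidence_row["prey"]),
        atoms=atoms,
        ptm=float(confidence_row["ptm"]),
        iptm=float(confidence_row["iptm"]),
    )


def write_complex(model: ComplexModel, path, bait_chain: str = "A", prey_chain: str = "B") -> None:
    """Write a two-chain model as PDB (coordinates at PDB's 3-decimal precision)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("complex")
    builder.init_model(0)
    for role, chain_id in ((BAIT, bait_chain), (PREY, prey_chain)):
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        current = None
        for atom in model.chain_atoms(role):
            if atom.residue_index != current:
                builder.init_residue(atom.residue_name, " ", atom.residue_index, " ")
                current = atom.residue_index
            builder.init_atom(
                atom.atom_name,
                np.asarray(atom.position, dtype=float),
                0.0,
                1.0,
                " ",
                atom.atom_name.center(4),
                element=atom.element,
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# benchmark analysis


def _scores_by_label(
    benchmark: Sequence[BenchmarkPair], metric: str
) -> tuple[np.ndarray, np.ndarray]:
    if metric not in ("ptm", "iptm"):
        raise ValueError(f"unknown metric {metric!r}")
    pos = np.asarray([getattr(b, metric) for b in benchmark if b.label == "interactor"])
    neg = np.asarray([getattr(b, metric) for b in benchmark if b.label == "noninteractor"])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("benchmark must contain both labels")
    return pos, neg


def roc_analysis(benchmark: Sequence[BenchmarkPair], metric: str) -> RocResult:
    """ROC of "score >= t => interactor" over the unique observed scores.

    The AUC equals both the trapezoidal integral of the curve and the
    Mann-Whitney U statistic divided by n_pos*n_neg (ties counted 1/2).
    """
    pos, neg = _scores_by_label(benchmark, metric)
    thresholds = np.unique(np.concatenate([pos, neg]))
    points = [
        (float(t), float((pos >= t).mean()), float((neg >= t).mean()))
        for t in thresholds
    ]
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    auc = float(roc_auc_score(labels, np.concatenate([pos, neg])))
    return RocResult(metric=metric, points=points, auc=auc)


def select_threshold_ks(
    benchmark: Sequence[BenchmarkPair], metric: str
) -> ThresholdSelection:
    """Score threshold at the Kolmogorov-Smirnov supremum.

    Over candidate thresholds t (the unique observed scores), the one-sided
    separation D(t) = ECDF_neg(t-) - ECDF_pos(t-), i.e. the fraction of
    noninteractors strictly below t minus that of interactors. The threshold
    is the smallest t attaining max D. If max D <= 0 the scores do not
    separate the labels: the selection is flagged non-separable and the
    threshold is +inf (nothing passes).
    """
    pos, neg = _scores_by_label(benchmark, metric)
    best_d = -math.inf
    best_t = math.inf
    for t in np.unique(np.concatenate([pos, neg])):
        d = float((neg < t).mean() - (pos < t).mean())
        if d > best_d:
            best_d, best_t = d, float(t)
    if best_d <= 0:
        return ThresholdSelection(metric=metric, threshold=math.inf,
                                  ks_statistic=max(best_d, 0.0), separable=False)
    return ThresholdSelection(metric=metric, threshold=best_t, ks_statistic=best_d)


def classify_high_confidence(
    models: Iterable[ComplexModel],
    t_ptm: float,
    t_iptm: float,
    any_metric: bool = False,
) -> set[tuple[str, str]]:
    """Pairs passing the selected thresholds (conjunction by default)."""
    out = set()
    for m in models:
        ok_ptm = m.ptm >= t_ptm
        ok_iptm = m.iptm >= t_iptm
        if (ok_ptm or ok_iptm) if any_metric else (ok_ptm and ok_iptm):
            out.add((m.bait_id, m.prey_id))
    return out


# ---------------------------------------------------------------------------
# geometry


def clash_filter(
    model: ComplexModel, radii: VdwRadiusTable | None = None
) -> set[AtomId]:
    """Atoms in any inter-chain van der Waals clash (strictly d < r1 + r2).

    Only bait-prey pairs are evaluated; intra-chain geometry is the
    predictor's responsibility. Both atoms of a clashing pair are excluded.
    """
    radii = radii or VdwRadiusTable()
    bait = model.chain_atoms(BAIT)
    prey = model.chain_atoms(PREY)
    if not bait or not prey:
        return set()
    bp = np.asarray([a.position for a in bait])
    pp = np.asarray([a.position for a in prey])
    br = np.asarray([radii.radius(a) for a in bait])
    pr = np.asarray([radii.radius(a) for a in prey])
    d = cdist(bp, pp)
    clash = d < (br[:, None] + pr[None, :])
    excluded: set[AtomId] = set()
    bi, pi = np.nonzero(clash)
    for i in bi:
        excluded.add(bait[int(i)].atom_id)
    for j in pi:
        excluded.add(prey[int(j)].atom_id)
    return excluded


def min_distance_profile(
    model: ComplexModel, excluded: set[AtomId] | None = None
) -> DistanceProfile:
    """Per-bait-residue minimum distance to any non-excluded prey atom.

    Residues whose atoms are all excluded (or when no prey atom survives the
    clash filter) carry the no-contact sentinel rather than a fake 0 A.
    """
    excluded = excluded or set()
    bait = [a for a in model.chain_atoms(BAIT) if a.atom_id not in excluded]
    prey = [a for a in model.chain_atoms(PREY) if a.atom_id not in excluded]
    residues = sorted({a.residue_index for a in model.chain_atoms(BAIT)})
    minima: dict[int, float | None] = {r: NO_CONTACT for r in residues}
    if not prey:
        logger.warning(
            "%s-%s: all prey atoms excluded; profile is all no-contact",
            model.bait_id, model.prey_id,
        )
    elif bait:
        pp = np.asarray([a.position for a in prey])
        bp = np.asarray([a.position for a in bait])
        d = cdist(bp, pp).min(axis=1)
        for atom, dist in zip(bait, d):
            cur = minima[atom.residue_index]
            if cur is NO_CONTACT or dist < cur:
                minima[atom.residue_index] = float(dist)
    return DistanceProfile(
        bait_id=model.bait_id,
        prey_id=model.prey_id,
        min_distance_per_residue=minima,
        excluded_atoms=set(excluded),
    )


def domain_contact_summary(
    profile: DistanceProfile,
    domain_map: Sequence[tuple[int, int, str]],
) -> DomainContactSummary:
    """Median per-domain contact distance and the closest (preferred) domain.

    ``domain_map`` lists (start_res, end_res, label) ranges, 1-based inclusive;
    unmapped residues fall into "other". Residues with no contact partner are
    excluded from medians; a domain with no usable residue is dropped from the
    argmin with a warning. Exactly tied minima give "ambiguous".
    """
    def label_of(residue: int) -> str:
        for start, end, label in domain_map:
            if start <= residue <= end:
                return label
        return "other"

    per_domain: dict[str, list[float]] = {}
    for residue, dist in profile.min_distance_per_residue.items():
        per_domain.setdefault(label_of(residue), [])
        if dist is not NO_CONTACT:
            per_domain[label_of(residue)].append(dist)
    medians: dict[str, float] = {}
    for label, values in per_domain.items():
        if values:
            medians[label] = float(statistics.median(values))
        else:
            logger.warning("domain %s has no contact distances; excluded", label)
    if not medians:
        return DomainContactSummary(per_domain_median={}, preferred_domain="ambiguous")
    best = min(medians.values())
    winners = [label for label, v in medians.items() if v == best]
    preferred = winners[0] if len(winners) == 1 else "ambiguous"
    return DomainContactSummary(per_domain_median=medians, preferred_domain=preferred)


# ---------------------------------------------------------------------------
# report


@dataclass
class ScreenReport:
    thresholds: dict[str, ThresholdSelection]
    pairs: pd.DataFrame  # bait, prey, ptm, iptm, high_confidence, preferred_domain
    baits: pd.DataFrame  # bait, n_high_confidence, modal_preferred_domain


def screen_report(
    models: Sequence[ComplexModel],
    benchmark: Sequence[BenchmarkPair],
    domain_maps: Mapping[str, Sequence[tuple[int, int, str]]],
    radii: VdwRadiusTable | None = None,
    any_metric: bool = False,
) -> ScreenReport:
    """End-to-end triage: thresholds, high-confidence calls, contact domains.

    Per bait the report gives the number of high-confidence interactors, each
    interactor's preferred contact domain (post clash filtering), and the
    modal preferred domain across its interactors.
    """
    sel_ptm = select_threshold_ks(benchmark, "ptm")
    sel_iptm = select_threshold_ks(benchmark, "iptm")
    passing = classify_high_confidence(
        models, sel_ptm.threshold, sel_iptm.threshold, any_metric=any_metric
    )
    rows = []
    for m in models:
        hc = (m.bait_id, m.prey_id) in passing
        preferred = ""
        if hc:
            excluded = clash_filter(m, radii)
            profile = min_distance_profile(m, excluded)
            summary = domain_contact_summary(
                profile, domain_maps.get(m.bait_id, [])
            )
            preferred = summary.preferred_domain
        rows.append(
            {
                "bait": m.bait_id,
                "prey": m.prey_id,
                "ptm": m.ptm,
                "iptm": m.iptm,
                "high_confidence": hc,
                "preferred_domain": preferred,
            }
        )
    pairs = pd.DataFrame(rows)
    bait_rows = []
    for bait in sorted({m.bait_id for m in models}):
        sub = pairs[(pairs["bait"] == bait) & pairs["high_confidence"]]
        if len(sub):
            counts = Counter(sub["preferred_domain"])
            top = counts.most_common()
            modal = (
                top[0][0]
                if len(top) == 1 or top[0][1] > top[1][1]
                else "ambiguous"
            )
        else:
            modal = ""
        bait_rows.append(
            {
                "bait": bait,
                "n_high_confidence": int(len(sub)),
                "modal_preferred_domain": modal,
            }
        )
    return ScreenReport(
        thresholds={"ptm": sel_ptm, "iptm": sel_iptm},
        pairs=pairs,
        baits=pd.DataFrame(bait_rows),
    )
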