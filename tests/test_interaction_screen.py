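"""Unit and property tests of the interaction-screen triage."""

import math

import numpy as np
import pytest

from tecapture.interaction_screen import (
    BAIT,
    PREY,
    Atom,
    BenchmarkPair,
    ComplexModel,
    VdwRadiusTable,
    clash_filter,
    classify_high_confidence,
    domain_contact_summary,
    load_complex,
    min_distance_profile,
    roc_analysis,
    screen_report,
    select_threshold_ks,
    write_complex,
)


def _atom(chain, resi, pos, element="C", name="CA"):
    return Atom(chain, resi, "GLY", name, element, tuple(float(v) for v in pos))


def _model(bait_pos, prey_pos, ptm=0.9, iptm=0.9, bait_id="b", prey_id="p"):
    atoms = [_atom(BAIT, i + 1, p) for i, p in enumerate(bait_pos)]
    atoms += [_atom(PREY, i + 1, p) for i, p in enumerate(prey_pos)]
    return ComplexModel(bait_id, prey_id, atoms, ptm, iptm)


def _benchmark(pos_scores, neg_scores):
    pairs = [BenchmarkPair(f"p{i}", "interactor", s, s) for i, s in enumerate(pos_scores)]
    pairs += [BenchmarkPair(f"n{i}", "noninteractor", s, s) for i, s in enumerate(neg_scores)]
    return pairs


def brute_force_auc(pos, neg):
    """Mann-Whitney U / (n_pos * n_neg), ties counted one half."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPdbIo:
    def test_minimal_two_atom_complex(self, tmp_path):
        model = _model([(0, 0, 0)], [(5, 0, 0)])
        path = tmp_path / "m.pdb"
        write_complex(model, path)
        loaded = load_complex(
            path, {"bait": "b", "prey": "p", "ptm": 0.5, "iptm": 0.4}
        )
        assert len(loaded.atoms) == 2
        assert {a.chain for a in loaded.atoms} == {BAIT, PREY}
        assert loaded.ptm == 0.5

    def test_three_chain_file_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        lines = []
        for i, chain in enumerate("ABC"):
            lines.append(
                f"ATOM  {i + 1:>5}  CA  GLY {chain}   1    "
                f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(ValueError, match="2 chains"):
            load_complex(path, {"bait": "b", "prey": "p", "ptm": 0, "iptm": 0})

    def test_coordinates_round_trip_at_pdb_precision(self, tmp_path):
        rng = np.random.default_rng(8)
        bait = [tuple(round(v, 3) for v in rng.uniform(-50, 50, 3)) for _ in range(30)]
        prey = [tuple(round(v, 3) for v in rng.uniform(-50, 50, 3)) for _ in range(20)]
        model = _model(bait, prey)
        path = tmp_path / "m.pdb"
        write_complex(model, path)
        loaded = load_complex(path, {"bait": "b", "prey": "p", "ptm": 1, "iptm": 1})
        np.testing.assert_allclose(
            np.array([a.position for a in loaded.atoms]),
            np.array([a.position for a in model.atoms]),
            atol=5e-4,
        )
        # second round trip is bit-identical
        path2 = tmp_path / "m2.pdb"
        write_complex(loaded, path2)
        assert path.read_text() == path2.read_text()


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_analysis(_benchmark([0.9, 0.8], [0.1, 0.2]), "iptm")
        assert roc.auc == 1.0

    def test_all_identical_scores_give_auc_half(self):
        roc = roc_analysis(_benchmark([0.5, 0.5], [0.5, 0.5, 0.5]), "ptm")
        assert roc.auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_bruteforce_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        pos = list(np.round(rng.uniform(0, 1, 18), 2))  # rounding forces ties
        neg = list(np.round(rng.uniform(0, 1, 12), 2))
        roc = roc_analysis(_benchmark(pos, neg), "iptm")
        assert roc.auc == pytest.approx(brute_force_auc(pos, neg))

    def test_auc_of_negated_metric_is_complement(self):
        rng = np.random.default_rng(40)
        pos = list(np.round(rng.uniform(0, 1, 15), 2))
        neg = list(np.round(rng.uniform(0, 1, 15), 2))
        auc = roc_analysis(_benchmark(pos, neg), "ptm").auc
        auc_neg = roc_analysis(
            _benchmark([-s for s in pos], [-s for s in neg]), "ptm"
        ).auc
        assert auc + auc_neg == pytest.approx(1.0)

    def test_points_tpr_fpr_monotone_along_thresholds(self):
        rng = np.random.default_rng(2)
        roc = roc_analysis(
            _benchmark(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)), "ptm"
        )
        tprs = [p[1] for p in roc.points]
        fprs = [p[2] for p in roc.points]
        assert all(a >= b for a, b in zip(tprs, tprs[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(
                [BenchmarkPair("p", "interactor", 0.5, 0.5)], "ptm"
            )


class TestKsThreshold:
    def test_disjoint_supports_give_full_separation(self):
        sel = select_threshold_ks(_benchmark([0.8, 0.9], [0.1, 0.2]), "iptm")
        assert sel.threshold == pytest.approx(0.8)
        assert sel.ks_statistic == 1.0
        assert sel.separable

    def test_identical_distributions_flagged_non_separable(self):
        sel = select_threshold_ks(_benchmark([0.5, 0.7], [0.5, 0.7]), "ptm")
        assert not sel.separable
        assert sel.threshold == math.inf
        assert sel.ks_statistic == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.round(rng.normal(0.7, 0.2, 25).clip(0, 1), 2)
        neg = np.round(rng.normal(0.4, 0.2, 30).clip(0, 1), 2)
        sel = select_threshold_ks(_benchmark(pos, neg), "ptm")
        best_d, best_t = -np.inf, None
        for t in sorted(set(pos) | set(neg)):
            d = np.mean(neg < t) - np.mean(pos < t)
            if d > best_d:
                best_d, best_t = d, t
        assert sel.ks_statistic == pytest.approx(best_d)
        assert sel.threshold == pytest.approx(best_t)


class TestClassify:
    def test_conjunction_rule(self):
        hi = _model([(0, 0, 0)], [(9, 0, 0)], ptm=0.8, iptm=0.7, prey_id="x")
        lo = _model([(0, 0, 0)], [(9, 0, 0)], ptm=0.8, iptm=0.2, prey_id="y")
        passing = classify_high_confidence([hi, lo], 0.5, 0.5)
        assert passing == {("b", "x")}
        assert classify_high_confidence([lo], 0.5, 0.5, any_metric=True) == {("b", "y")}

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(6)
        models = [
            _model([(0, 0, 0)], [(9, 0, 0)],
                   ptm=float(rng.uniform()), iptm=float(rng.uniform()),
                   prey_id=f"p{i}")
            for i in range(40)
        ]
        passing = classify_high_confidence(models, 0.6, 0.4)
        expected = {(m.bait_id, m.prey_id) for m in models if m.ptm >= 0.6 and m.iptm >= 0.4}
        assert passing == expected


def _random_complex(rng, n_bait=30, n_prey=30, spread=12.0):
    bait = rng.uniform(0, spread, (n_bait, 3))
    prey = rng.uniform(0, spread, (n_prey, 3))
    atoms = [_atom(BAIT, i // 3 + 1, p, name=f"A{i % 3}") for i, p in enumerate(bait)]
    atoms += [_atom(PREY, i // 3 + 1, p, name=f"A{i % 3}") for i, p in enumerate(prey)]
    return ComplexModel("b", "p", atoms, 0.9, 0.9)


def brute_force_clashes(model, radii):
    excluded = set()
    for a in model.chain_atoms(BAIT):
        for b in model.chain_atoms(PREY):
            d = math.dist(a.position, b.position)
            if d < radii.radius(a) + radii.radius(b):
                excluded.add(a.atom_id)
                excluded.add(b.atom_id)
    return excluded


def brute_force_profile(model, excluded):
    minima = {}
    for residue in sorted({a.residue_index for a in model.chain_atoms(BAIT)}):
        best = None
        for a in model.chain_atoms(BAIT):
            if a.residue_index != residue or a.atom_id in excluded:
                continue
            for b in model.chain_atoms(PREY):
                if b.atom_id in excluded:
                    continue
                d = math.dist(a.position, b.position)
                if best is None or d < best:
                    best = d
        minima[residue] = best
    return minima


class TestClashFilter:
    def test_two_carbons_inside_contact_distance_both_excluded(self):
        model = _model([(0, 0, 0)], [(3.0, 0, 0)])
        assert clash_filter(model) == {(BAIT, 1, "CA"), (PREY, 1, "CA")}

    def test_two_carbons_outside_contact_distance_retained(self):
        model = _model([(0, 0, 0)], [(3.5, 0, 0)])
        assert clash_filter(model) == set()

    def test_strict_inequality_at_exact_contact(self):
        model = _model([(0, 0, 0)], [(3.4, 0, 0)])
        assert clash_filter(model) == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_and_chain_swap_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_complex(rng, 48, 51, spread=10.0)
        radii = VdwRadiusTable()
        excluded = clash_filter(model, radii)
        assert excluded == brute_force_clashes(model, radii)
        swapped = ComplexModel(
            "b", "p",
            [Atom(PREY if a.chain == BAIT else BAIT, a.residue_index,
                  a.residue_name, a.atom_name, a.element, a.position)
             for a in model.atoms],
            0.9, 0.9,
        )
        assert {(c, r, n) for c, r, n in clash_filter(swapped, radii)} == {
            (PREY if c == BAIT else BAIT, r, n) for c, r, n in excluded
        }

    def test_unknown_element_names_the_atom(self):
        model = _model([(0, 0, 0)], [(1, 0, 0)], )
        model.atoms[0] = _atom(BAIT, 1, (0, 0, 0), element="Xx")
        with pytest.raises(KeyError, match="Xx"):
            clash_filter(model)


class TestDistanceProfile:
    def test_minimum_over_prey_atoms(self):
        model = _model([(0, 0, 0)], [(5, 0, 0), (0, 3, 0)])
        profile = min_distance_profile(model, set())
        assert profile.min_distance_per_residue == {1: pytest.approx(3.0)}

    def test_excluded_nearest_atom_falls_back_to_next(self):
        model = _model([(0, 0, 0)], [(5, 0, 0), (0, 3, 0)])
        profile = min_distance_profile(model, {(PREY, 1, "CA")})
        # prey atom 1 is at distance 5; atom 2 (excluded is the 3.0 one)
        excluded = {(PREY, 2, "CA")}
        profile = min_distance_profile(model, excluded)
        assert profile.min_distance_per_residue == {1: pytest.approx(5.0)}

    def test_all_prey_excluded_gives_no_contact_sentinel(self):
        model = _model([(0, 0, 0)], [(1, 0, 0)])
        profile = min_distance_profile(model, {(PREY, 1, "CA")})
        assert profile.min_distance_per_residue == {1: None}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed + 10)
        model = _random_complex(rng, 60, 45)
        excluded = clash_filter(model)
        profile = min_distance_profile(model, excluded)
        brute = brute_force_profile(model, excluded)
        for residue, expected in brute.items():
            got = profile.min_distance_per_residue[residue]
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    def test_removing_non_minimal_prey_atom_preserves_minima(self):
        rng = np.random.default_rng(3)
        model = _random_complex(rng, 30, 30)
        profile = min_distance_profile(model, set())
        dists = {
            b.atom_id: min(
                math.dist(a.position, b.position) for a in model.chain_atoms(BAIT)
            )
            for b in model.chain_atoms(PREY)
        }
        farthest = max(dists, key=dists.get)
        pruned = ComplexModel(
            "b", "p", [a for a in model.atoms if a.atom_id != (PREY,) + farthest[1:]
                       or a.chain == BAIT],
            0.9, 0.9,
        )
        pruned = ComplexModel(
            "b", "p",
            [a for a in model.atoms if not (a.chain == PREY and a.atom_id == farthest)],
            0.9, 0.9,
        )
        profile2 = min_distance_profile(pruned, set())
        for residue, v in profile.min_distance_per_residue.items():
            assert profile2.min_distance_per_residue[residue] >= v - 1e-12


class TestRigidMotionInvariance:
    def test_clash_and_profile_invariant_under_rotation_translation(self):
        rng = np.random.default_rng(77)
        model = _random_complex(rng, 45, 45)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-30, 30, 3)
        moved = ComplexModel(
            "b", "p",
            [Atom(a.chain, a.residue_index, a.residue_name, a.atom_name, a.element,
                  tuple(q @ np.asarray(a.position) + shift))
             for a in model.atoms],
            0.9, 0.9,
        )
        assert clash_filter(moved) == clash_filter(model)
        p1 = min_distance_profile(model, clash_filter(model))
        p2 = min_distance_profile(moved, clash_filter(moved))
        for residue, v in p1.min_distance_per_residue.items():
            w = p2.min_distance_per_residue[residue]
            if v is None:
                assert w is None
            else:
                assert abs(v - w) < 1e-6


class TestDomainSummary:
    def _profile(self, minima):
        from tecapture.interaction_screen import DistanceProfile
        return DistanceProfile("b", "p", minima, set())

    def test_closest_domain_preferred(self):
        minima = {r: 4.0 for r in range(1, 11)} | {r: 20.0 for r in range(11, 21)}
        summary = domain_contact_summary(
            self._profile(minima), [(1, 10, "HTH"), (11, 20, "F-box")]
        )
        assert summary.per_domain_median == {"HTH": 4.0, "F-box": 20.0}
        assert summary.preferred_domain == "HTH"

    def test_equal_medians_are_ambiguous(self):
        minima = {1: 5.0, 2: 5.0}
        summary = domain_contact_summary(
            self._profile(minima), [(1, 1, "HTH"), (2, 2, "FTH")]
        )
        assert summary.preferred_domain == "ambiguous"

    def test_unmapped_residues_fall_into_other(self):
        summary = domain_contact_summary(
            self._profile({1: 3.0, 2: 9.0}), [(1, 1, "HTH")]
        )
        assert summary.per_domain_median["other"] == 9.0

    def test_no_contact_residues_excluded_from_median(self):
        minima = {1: 2.0, 2: None, 3: 8.0}
        summary = domain_contact_summary(self._profile(minima), [(1, 3, "HTH")])
        assert summary.per_domain_median["HTH"] == 5.0

    @pytest.mark.parametrize("n", [3, 4, 7, 8])
    def test_median_equals_sorted_middle_bruteforce(self, n):
        rng = np.random.default_rng(n)
        values = list(np.round(rng.uniform(1, 30, n), 3))
        summary = domain_contact_summary(
            self._profile({i + 1: v for i, v in enumerate(values)}),
            [(1, n, "HTH")],
        )
        s = sorted(values)
        expected = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert summary.per_domain_median["HTH"] == pytest.approx(expected)


class TestScreenReport:
    def test_planted_contacts_recovered_and_baits_distinguished(self):
        from tecapture.synthetic_data import ContactPlant, SimConfig, build_complex

        benchmark = _benchmark([0.8, 0.85, 0.9], [0.1, 0.2, 0.3])
        models, maps = [], {}
        for seed, (bait, domain) in enumerate(
            [("bait_hth", "HTH"), ("bait_fth", "FTH")]
        ):
            model, dmap, _ = build_complex(
                SimConfig(seed=seed, contact_plant=ContactPlant(domain, 4.0))
            )
            model.bait_id = bait
            models.append(model)
            maps[bait] = dmap
        report = screen_report(models, benchmark, maps)
        baits = dict(zip(report.baits["bait"], report.baits["modal_preferred_domain"]))
        assert baits == {"bait_hth": "HTH", "bait_fth": "FTH"}

    def test_no_high_confidence_interactors_is_not_a_failure(self):
        benchmark = _benchmark([0.9, 0.95], [0.1, 0.2])
        model = _model([(0, 0, 0)], [(9, 0, 0)], ptm=0.1, iptm=0.1)
        report = screen_report([model], benchmark, {"b": [(1, 1, "HTH")]})
        assert report.baits.loc[0, "n_high_confidence"] == 0
        assert not report.pairs.loc[0, "high_confidence"]
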