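import collections

import numpy as np
import pytest

from specfdr import (
    FragmentationTree,
    MolecularFormula,
    Peak,
    Spectrum,
    build_decoy_library,
    naive_decoy,
    noise_filter,
    reroot_choices,
    spectrum_based_decoy,
    toy_tree_annotator,
    tree_based_decoy,
)

SEP = 5e-6  # 5 ppm relative separation


def min_rel_gap(masses):
    ms = sorted(masses)
    return min(
        (b - a) / max(a, b) for a, b in zip(ms, ms[1:])
    ) if len(ms) > 1 else np.inf


class TestNaiveDecoy:
    def test_peak_count_and_intensity_multiset_conserved(self, pool_library, rng):
        target = pool_library.entries[3]
        d = naive_decoy(target, pool_library, rng)
        assert len(d) == len(target)
        assert sorted(d.intensities) == sorted(target.intensities)
        assert d.precursor_mass == target.precursor_mass

    def test_no_mass_above_precursor(self, pool_library, rng):
        target = pool_library.entries[0]  # smallest precursor: forces rejections
        d = naive_decoy(target, pool_library, rng)
        assert max(d.masses) <= target.precursor_mass

    def test_masses_separated_by_5ppm(self, pool_library, rng):
        d = naive_decoy(pool_library.entries[4], pool_library, rng)
        assert min_rel_gap(d.masses) > SEP

    def test_seed_determinism(self, pool_library):
        t = pool_library.entries[2]
        d1 = naive_decoy(t, pool_library, np.random.default_rng(7))
        d2 = naive_decoy(t, pool_library, np.random.default_rng(7))
        d3 = naive_decoy(t, pool_library, np.random.default_rng(8))
        assert d1.peaks == d2.peaks
        assert d1.peaks != d3.peaks


class TestSpectrumBasedDecoy:
    def test_first_ion_is_target_precursor(self, pool_library, rng):
        target = pool_library.entries[5]
        d = spectrum_based_decoy(target, pool_library, rng)
        assert any(m == pytest.approx(target.precursor_mass) for m in d.masses)

    def test_discard_rules_hold(self, pool_library, rng):
        for t in pool_library.entries:
            d = spectrum_based_decoy(t, pool_library, rng)
            assert max(d.masses) <= t.precursor_mass + 1e-9
            assert min_rel_gap(d.masses) > SEP
            assert len(d) == len(t)
            assert sorted(d.intensities) == sorted(t.intensities)

    def test_seed_determinism(self, pool_library):
        t = pool_library.entries[1]
        d1 = spectrum_based_decoy(t, pool_library, np.random.default_rng(3))
        d2 = spectrum_based_decoy(t, pool_library, np.random.default_rng(3))
        assert d1.peaks == d2.peaks


class TestTreeBasedDecoy:
    def test_root_formula_is_precursor_and_all_valid(self, star_tree, rng):
        prec = star_tree.node(star_tree.root)
        target = Spectrum(
            "STAR", prec.mass,
            peaks=tuple(Peak(star_tree.node(i).mass, 10.0) for i in star_tree.node_ids()),
        )
        d, status = tree_based_decoy(target, star_tree, rng)
        assert status == "ok"
        assert d.precursor_mass == target.precursor_mass
        # root keeps the precursor-ion formula -> precursor ion mass present
        assert any(m == pytest.approx(prec.mass, abs=1e-6) for m in d.masses)
        assert len(d) == len(star_tree)

    def test_identity_rerooting_reproduces_filtered_target(self, glucose_spectrum):
        """If the original root is drawn again, the decoy is the noise-filtered
        target (theoretical node masses, original intensities)."""
        tree = toy_tree_annotator(glucose_spectrum, MolecularFormula("C6H12O6"))
        filtered = noise_filter(glucose_spectrum, tree)
        # find a seed that re-selects the original root
        for seed in range(50):
            rng = np.random.default_rng(seed)
            choices = reroot_choices(tree)
            weights = np.array([w for _, _, w in choices])
            idx = rng.choice(len(choices), p=weights / weights.sum())
            if choices[idx][0] == tree.root:
                d, _ = tree_based_decoy(glucose_spectrum, tree, np.random.default_rng(seed))
                assert sorted(d.intensities) == sorted(filtered.intensities)
                for dm, fm in zip(sorted(d.masses), sorted(filtered.masses)):
                    assert dm == pytest.approx(fm, abs=0.002)
                return
        pytest.fail("no seed re-selected the original root in 50 tries")

    def test_star_tree_uniform_root_choice(self, star_tree):
        """All re-rootings of a star tree are valid, so n = 0 for every node and
        the 1/(n+1) law reduces to the uniform distribution; empirical root
        frequencies over 10,000 draws must sit within 3 binomial sigma."""
        choices = reroot_choices(star_tree)
        assert all(n == 0 for _, n, _ in choices)
        k = len(choices)
        rng = np.random.default_rng(99)
        weights = np.array([w for _, _, w in choices])
        counts = collections.Counter(
            int(rng.choice(k, p=weights / weights.sum())) for _ in range(10_000)
        )
        p = 1.0 / k
        sigma = np.sqrt(10_000 * p * (1 - p))
        for i in range(k):
            assert abs(counts[i] - 10_000 * p) < 3 * sigma

    def test_regraft_count_matches_enumeration(self):
        """n (edges to re-graft) agrees with direct per-edge checking on a
        hand-built tree where one re-rooting must trigger a re-graft."""
        # root C3H8O3; children via H2O and CO2: C3H6O2 and C2H8O
        t = FragmentationTree.from_root(MolecularFormula("C3H8O3"), "X")
        t.add_child(t.root, MolecularFormula("H2O"), 5.0)
        t.add_child(t.root, MolecularFormula("CO2"), 7.0)
        by_node = {v: n for v, n, _ in reroot_choices(t)}
        assert by_node[0] == 0  # original root
        # re-root at the H2O child: root gets C3H8O3, edge back to old root
        # subtracts H2O -> C3H6O2 (valid), then CO2 -> C2H6 (valid): n=0
        assert by_node[1] == 0
        # re-root at the CO2 child: old root via CO2 -> C2H8O (valid),
        # then H2O -> C2H6 (valid): n=0 as well; weights all 1
        assert by_node[2] == 0
        weights = [w for _, _, w in reroot_choices(t)]
        assert weights == [1.0, 1.0, 1.0]

    def test_regraft_triggered_for_impossible_subtraction(self):
        """Re-rooting at a node that cannot afford a loss flags that edge."""
        # root C6H6O6 -(C2H2)-> C4H4O6 -(CO2)-> C3H4O4
        t = FragmentationTree.from_root(MolecularFormula("C6H6O6"), "Y")
        a = t.add_child(t.root, MolecularFormula("C2H2"), 5.0)
        t.add_child(a, MolecularFormula("CO2"), 3.0)
        by_node = {v: n for v, n, _ in reroot_choices(t)}
        assert by_node[0] == 0
        # leaf as root: C6H6O6 -(CO2)-> C5H6O4 -(C2H2)-> C3H4O4: all valid
        assert by_node[2] == 0

    def test_intensity_multiset_conserved(self, small_bundle, rng):
        sid = small_bundle.target.entries[0].identifier
        tree = small_bundle.trees[sid]
        target = small_bundle.target[sid]
        d, status = tree_based_decoy(target, tree, rng)
        if status == "ok":
            expect = sorted(
                tree.node(i).peak_intensity for i in tree.node_ids()
            )
            assert sorted(d.intensities) == pytest.approx(expect)


class TestDecoyLibraryBuilder:
    @pytest.mark.parametrize("method", ["naive", "spectrum_based"])
    def test_entrywise_mirroring(self, pool_library, method):
        lib = build_decoy_library(pool_library, method=method, seed=1)
        assert len(lib) == len(pool_library)
        for t, d in zip(pool_library.entries, lib.entries):
            assert len(d) == len(t)
            assert d.precursor_mass == t.precursor_mass
            assert sorted(d.intensities) == sorted(t.intensities)

    def test_precursor_histogram_exact_equality(self, small_bundle):
        lib = build_decoy_library(
            small_bundle.target, small_bundle.trees, method="tree_based", seed=2
        )
        used = set(lib.used_target_ids)
        t_prec = sorted(
            s.precursor_mass for s in small_bundle.target if s.identifier in used
        )
        d_prec = sorted(d.precursor_mass for d in lib.entries)
        assert t_prec == d_prec

    def test_seeds_reproduce_and_differ(self, pool_library):
        l1 = build_decoy_library(pool_library, method="naive", seed=1)
        l2 = build_decoy_library(pool_library, method="naive", seed=1)
        l3 = build_decoy_library(pool_library, method="naive", seed=2)
        assert [s.peaks for s in l1] == [s.peaks for s in l2]
        assert [s.peaks for s in l1] != [s.peaks for s in l3]

    def test_tree_method_skips_targets_without_trees(self, small_bundle):
        trees = dict(small_bundle.trees)
        dropped = small_bundle.target.entries[0].identifier
        del trees[dropped]
        lib = build_decoy_library(small_bundle.target, trees, method="tree_based", seed=1)
        assert dropped not in lib.used_target_ids
        assert lib.report[dropped] == "skipped-no-tree"
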