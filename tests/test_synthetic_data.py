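import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from scoper.saxs_core import compute_profile, fit_scale
from scoper.synthetic_data import (SyntheticSpec, decoy_positions, make_conformers,
                                   make_planted_structures, make_pseudo_rna,
                                   simulate_experiment)


class TestPseudoRna:
    def test_one_phosphorus_per_residue(self, default_spec):
        rna = make_pseudo_rna(default_spec)
        p_atoms = [a for a in rna.atoms if a.element == "P"]
        assert len(p_atoms) == default_spec.n_residues

    def test_backbone_spacing_is_regular(self, default_spec):
        rna = make_pseudo_rna(default_spec)
        p = np.array([a.coord for a in rna.atoms if a.name == "P"])
        d = np.linalg.norm(np.diff(p, axis=0), axis=1)
        # every residue advances by the same rise along the (bent) helical
        # path; the P-P chord varies only with the side of the axis bend
        np.testing.assert_allclose(d, d.mean(), rtol=0.05)
        assert d.mean() >= default_spec.rise

    def test_seed_determinism_and_decorrelation(self, default_spec):
        a = make_pseudo_rna(default_spec)
        b = make_pseudo_rna(default_spec)
        np.testing.assert_array_equal(a.coords(), b.coords())
        from dataclasses import replace
        c = make_pseudo_rna(replace(default_spec, seed=99))
        assert not np.allclose(a.coords(), c.coords())

    def test_no_coincident_atoms(self, default_spec):
        # bonded neighbors sit at ~1.3-1.5 Å with independent jitter; what
        # matters downstream (Debye sums, probe generation) is that no two
        # atoms overlap
        from scipy.spatial.distance import pdist
        rna = make_pseudo_rna(default_spec)
        assert pdist(rna.coords()).min() > 0.7

    def test_zero_residues_rejected(self, default_spec):
        from dataclasses import replace
        with pytest.raises(ValueError):
            make_pseudo_rna(replace(default_spec, n_residues=0))


class TestPlantedSites:
    def test_ion_coordination_shells(self, planted_system):
        coords = planted_system.rna.coords()
        is_on = np.array([a.element in ("O", "N") for a in planted_system.rna.atoms])
        for pos in planted_system.ion_positions:
            d = np.linalg.norm(coords[is_on] - pos, axis=1)
            assert ((d >= 1.8) & (d <= 2.4)).sum() >= 4

    def test_waters_lack_shells(self, planted_system):
        coords = planted_system.rna.coords()
        is_on = np.array([a.element in ("O", "N") for a in planted_system.rna.atoms])
        for pos in planted_system.water_positions:
            d = np.linalg.norm(coords[is_on] - pos, axis=1)
            assert (d <= 2.4).sum() <= 2

    def test_sets_are_disjoint(self, planted_system):
        for w in planted_system.water_positions:
            d = np.linalg.norm(planted_system.ion_positions - w, axis=1)
            assert d.min() > 3.0

    def test_no_clashes(self, planted_system):
        coords = planted_system.rna.coords()
        for pos in planted_system.ion_positions:
            assert np.linalg.norm(coords - pos, axis=1).min() >= 1.8
        for pos in planted_system.water_positions:
            assert np.linalg.norm(coords - pos, axis=1).min() >= 2.5

    def test_rule_is_linearly_recoverable(self):
        """O/N count within 2.4 Å alone separates ions from waters (AUROC > 0.95):
        the planted signature bounds what any classifier can learn."""
        counts, labels = [], []
        for s in make_planted_structures(6, SyntheticSpec(n_planted_ions=6,
                                                          n_waters=8), seed=5):
            rna_coords = np.array([a.coord for a in s.atoms
                                   if a.residue_name not in ("MG", "HOH")])
            on = np.array([a.element in ("O", "N") for a in s.atoms
                           if a.residue_name not in ("MG", "HOH")])
            for a in s.atoms:
                if a.residue_name == "MG":
                    labels.append(1)
                elif a.residue_name == "HOH":
                    labels.append(0)
                else:
                    continue
                d = np.linalg.norm(rna_coords[on] - a.coord, axis=1)
                counts.append((d <= 2.4).sum())
        assert roc_auc_score(labels, counts) > 0.95

    def test_truth_structure_contains_records(self, planted_system):
        truth = planted_system.truth_structure(include_waters=True)
        n_mg = sum(a.residue_name == "MG" for a in truth.atoms)
        n_w = sum(a.residue_name == "HOH" for a in truth.atoms)
        assert n_mg == len(planted_system.ion_positions)
        assert n_w == len(planted_system.water_positions)


class TestSimulatedExperiment:
    def test_seed_determinism(self, rna, q_grid):
        a = simulate_experiment(rna, q_grid, seed=4)
        b = simulate_experiment(rna, q_grid, seed=4)
        np.testing.assert_array_equal(a.I, b.I)

    def test_noise_to_zero_limit(self, rna, rna_fractions, q_grid):
        exp = simulate_experiment(rna, q_grid, noise_fraction=1e-9, seed=0,
                                  surface_fractions=rna_fractions)
        calc = compute_profile(rna, q_grid, surface_fractions=rna_fractions)
        res = fit_scale(exp, calc)
        assert res.chi2 == pytest.approx(1.0, abs=0.5)
        assert res.params.c == pytest.approx(1.0, abs=1e-6)

    def test_sigma_is_fractional(self, rna, rna_fractions, q_grid):
        exp = simulate_experiment(rna, q_grid, noise_fraction=0.02, seed=0,
                                  surface_fractions=rna_fractions)
        calc = compute_profile(rna, q_grid, surface_fractions=rna_fractions)
        np.testing.assert_allclose(exp.sigma, 0.02 * calc.I, rtol=1e-12)


class TestConformers:
    def test_zeroth_conformer_is_input(self, rna):
        confs = make_conformers(rna, 4, 1.5, seed=0)
        np.testing.assert_array_equal(confs[0].coords(), rna.coords())

    def test_zero_perturbation_is_identity(self, rna):
        confs = make_conformers(rna, 3, 0.0, seed=0)
        for c in confs:
            np.testing.assert_allclose(c.coords(), rna.coords(), atol=1e-9)

    def test_rmsd_matches_requested_perturbation(self, rna):
        target = 1.5
        confs = make_conformers(rna, 40, target, seed=2)
        base = rna.coords()
        rmsds = [np.sqrt(np.mean(np.sum((c.coords() - base) ** 2, axis=1)))
                 for c in confs[1:]]
        assert np.mean(rmsds) == pytest.approx(target, rel=0.30)

    def test_local_backbone_distances_preserved(self, rna):
        confs = make_conformers(rna, 10, 1.5, seed=3)
        base_p = np.array([a.coord for a in rna.atoms if a.name == "P"])
        d0 = np.linalg.norm(np.diff(base_p, axis=0), axis=1)
        for c in confs[1:]:
            p = np.array([a.coord for a in c.atoms if a.name == "P"])
            d = np.linalg.norm(np.diff(p, axis=0), axis=1)
            assert np.max(np.abs(d / d0 - 1.0)) < 0.05

    def test_seed_determinism(self, rna):
        a = make_conformers(rna, 5, 2.0, seed=9)
        b = make_conformers(rna, 5, 2.0, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords(), y.coords())


def test_decoys_respect_resolution_separation(planted_system):
    decoys = decoy_positions(planted_system, 6, seed=1)
    assert decoys.shape == (6, 3)
    for d in decoys:
        sep = np.linalg.norm(planted_system.ion_positions - d, axis=1)
        assert sep.min() >= 2 * np.pi / 0.4 - 1e-9


def test_recovery_benchmark_certifies_unique_optimum():
    """No candidate subset lacking a planted ion can mimic the truth profile
    within the detection scale (checked over all wrong subsets of size <= 4)."""
    from itertools import combinations

    import numpy as np

    from scoper.saxs_core import (ScatteringProfile, decompose, fit_scale,
                                  solvent_accessible_fraction)
    from scoper.synthetic_data import recovery_benchmark

    system, decoys = recovery_benchmark(20240901)
    assert len(system.ion_positions) == 3 and len(decoys) == 7
    frac = solvent_accessible_fraction(system.rna)
    cands = np.vstack([system.ion_positions, decoys])
    partials = decompose(system.rna, cands, surface_fractions=frac)
    I_full = partials.assemble(range(3))
    exp = ScatteringProfile(partials.q, I_full, 0.005 * I_full)
    for size in range(5):
        for keep in combinations(range(10), size):
            if {0, 1, 2} <= set(keep):
                continue
            assert fit_scale(exp, partials.assemble_profile(keep)).chi2 >= 0.3


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(noise_fraction=0.0)
    with pytest.raises(ValueError):
        SyntheticSpec(n_residues=-1)
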