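import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import naive_debye, random_structure
from scoper.saxs_core import (NoGuinierRegionError, ProfileError,
                              ScatteringProfile, compute_profile, decompose,
                              default_q_grid, dimensionless_kratky,
                              effective_form_factors, fit_profile, fit_scale,
                              guinier_rg, pr_from_structure,
                              solvent_accessible_fraction, vacuum_form_factor,
                              write_fit)
from scoper.structure_io import Atom, Structure
from scoper.synthetic_data import simulate_experiment

Q0 = np.zeros(1)


@pytest.mark.parametrize("element,electrons", [
    ("C", 6), ("N", 7), ("O", 8), ("P", 15), ("S", 16),
    ("MG", 10), ("NA", 10), ("CL", 18), ("K", 18), ("H", 1)])
def test_vacuum_form_factor_at_zero_equals_electron_count(element, electrons):
    assert vacuum_form_factor(element, Q0)[0] == pytest.approx(electrons, abs=0.01)


def test_single_ion_intensity_at_low_q(q_grid):
    ion = Structure([Atom(element="MG", coord=[0, 0, 0], name="MG", residue_name="MG")])
    prof = compute_profile(ion, q_grid, c2=0.0)
    F = effective_form_factors(ion, q_grid, 1.0, 0.0, np.ones(1))
    np.testing.assert_allclose(prof.I, F[0] ** 2, rtol=1e-12)
    assert prof.I[0] > 0


def test_two_identical_atoms_closed_form(q_grid):
    d = 7.3
    s = Structure([Atom(element="C", coord=[0, 0, 0], name="C"),
                   Atom(element="C", coord=[0, 0, d], name="C")])
    frac = np.ones(2)
    prof = compute_profile(s, q_grid, surface_fractions=frac)
    f = effective_form_factors(s, q_grid, 1.0, 1.0, frac)[0]
    expected = 2 * f ** 2 * (1 + np.sinc(q_grid * d / np.pi))
    np.testing.assert_allclose(prof.I, expected, rtol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_debye_matches_double_loop_oracle(seed, q_grid):
    rng = np.random.default_rng(seed)
    s = random_structure(rng, int(rng.integers(10, 60)))
    frac = solvent_accessible_fraction(s)
    prof = compute_profile(s, q_grid, c1=1.02, c2=0.7, surface_fractions=frac)
    F = effective_form_factors(s, q_grid, 1.02, 0.7, frac)
    oracle = naive_debye(s.coords(), F, q_grid)
    np.testing.assert_allclose(prof.I, oracle, rtol=1e-10)


def test_debye_rigid_motion_and_permutation_invariance(q_grid):
    rng = np.random.default_rng(3)
    s = random_structure(rng, 25)
    frac = solvent_accessible_fraction(s)
    ref = compute_profile(s, q_grid, surface_fractions=frac).I
    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = s.rotated(R).translated([5.0, -3.0, 11.0])
    np.testing.assert_allclose(
        compute_profile(moved, q_grid, surface_fractions=frac).I, ref, rtol=1e-9)
    perm = rng.permutation(len(s))
    np.testing.assert_allclose(
        compute_profile(s.subset(perm), q_grid, surface_fractions=frac[perm]).I,
        ref, rtol=1e-9)


def test_isolated_atom_fully_accessible():
    s = Structure([Atom(element="C", coord=[0, 0, 0], name="C")])
    assert solvent_accessible_fraction(s)[0] == 1.0


def test_caged_atom_is_buried():
    # tight icosahedral-ish cage of 12 atoms occludes the center
    from scoper.surface_probes import fibonacci_sphere
    pts = 3.0 * fibonacci_sphere(12)
    atoms = [Atom(element="C", coord=[0, 0, 0], name="C")]
    atoms += [Atom(element="C", coord=p, name="C") for p in pts]
    frac = solvent_accessible_fraction(Structure(atoms))
    assert frac[0] < 0.05
    assert np.all((frac >= 0) & (frac <= 1))


def test_fit_scale_identity_and_pure_scaling(q_grid, rna, rna_fractions):
    calc = compute_profile(rna, q_grid, surface_fractions=rna_fractions)
    exp = ScatteringProfile(q_grid, calc.I, 0.01 * calc.I)
    res = fit_scale(exp, calc)
    assert res.params.c == pytest.approx(1.0, rel=1e-12)
    assert res.chi2 == pytest.approx(0.0, abs=1e-18)
    exp2 = ScatteringProfile(q_grid, 2.0 * calc.I, 0.01 * calc.I)
    res2 = fit_scale(exp2, calc)
    assert res2.params.c == pytest.approx(2.0, rel=1e-12)
    assert res2.chi2 == pytest.approx(0.0, abs=1e-18)


@pytest.mark.parametrize("seed", range(4))
def test_closed_form_scale_matches_brute_force_scan(seed, q_grid):
    rng = np.random.default_rng(seed)
    I_calc = rng.uniform(0.5, 10.0, q_grid.size)
    I_exp = rng.uniform(0.5, 10.0, q_grid.size)
    sigma = rng.uniform(0.05, 0.2, q_grid.size)
    exp = ScatteringProfile(q_grid, I_exp, sigma)
    calc = ScatteringProfile(q_grid, I_calc)
    c_star = fit_scale(exp, calc).params.c
    grid = np.linspace(0.2 * c_star, 3.0 * c_star, 200001)
    chi2 = np.mean(((I_exp[None, :] - grid[:, None] * I_calc[None, :])
                    / sigma[None, :]) ** 2, axis=1)
    c_scan = grid[np.argmin(chi2)]
    assert c_star == pytest.approx(c_scan, rel=1e-4)


@pytest.mark.parametrize("seed", range(3))
def test_self_fit_chi2_is_calibrated(seed, rna, rna_fractions, q_grid):
    """Fitting the truth against its own 1%-noise simulation gives chi2 ~ 1."""
    exp = simulate_experiment(rna, q_grid, noise_fraction=0.01, seed=seed,
                              surface_fractions=rna_fractions)
    res = fit_profile(exp, rna)
    assert 0.6 <= res.chi2 <= 1.5


def test_free_fit_never_worse_than_fixed(rna, rna_fractions, q_grid):
    exp = simulate_experiment(rna, q_grid, noise_fraction=0.02, seed=5,
                              surface_fractions=rna_fractions)
    fixed = fit_profile(exp, rna, fix_c1_c2=True)
    free = fit_profile(exp, rna, fix_c1_c2=False, n_c1=5, n_c2=9)
    assert free.chi2 <= fixed.chi2 + 1e-12


def test_fit_requires_errors(q_grid, rna):
    exp = ScatteringProfile(q_grid, np.ones_like(q_grid))
    with pytest.raises(ProfileError):
        fit_profile(exp, rna)


@pytest.fixture(scope="module")
def decompose_setup(rna, rna_fractions, q_grid):
    rng = np.random.default_rng(11)
    coords = rna.coords()
    cands = []
    while len(cands) < 6:
        pos = coords[rng.integers(len(coords))] + rng.normal(0, 4, 3)
        if np.linalg.norm(coords - pos, axis=1).min() > 2.0:
            cands.append(pos)
    cands = np.array(cands)
    partials = decompose(rna, cands, q_grid, surface_fractions=rna_fractions)
    return rna, rna_fractions, cands, partials


class TestDecompose:
    @pytest.fixture()
    def setup(self, decompose_setup):
        return decompose_setup

    def test_empty_subset_is_rna_profile(self, setup, q_grid):
        rna, frac, _, partials = setup
        direct = compute_profile(rna, q_grid, surface_fractions=frac)
        np.testing.assert_allclose(partials.assemble([]), direct.I, rtol=1e-10)

    def test_single_candidate_is_rna_plus_A(self, setup):
        *_, partials = setup
        np.testing.assert_allclose(partials.assemble([2]),
                                   partials.I_rna + partials.A[2], rtol=1e-14)

    @pytest.mark.parametrize("subset", [(0,), (1, 4), (0, 2, 5), (0, 1, 2, 3, 4, 5)])
    def test_assembly_matches_direct_debye(self, setup, subset, q_grid):
        rna, frac, cands, partials = setup
        st = rna.copy()
        for k in subset:
            st.atoms.append(Atom(element="MG", coord=cands[k], name="MG",
                                 residue_name="MG", residue_id=1000 + k,
                                 is_hetero=True))
        full_frac = np.concatenate([frac, np.ones(len(subset))])
        direct = compute_profile(st, q_grid, surface_fractions=full_frac)
        np.testing.assert_allclose(partials.assemble(subset), direct.I, rtol=1e-10)


def test_guinier_recovers_gaussian_rg():
    rg_true = 18.15
    q = default_q_grid()
    profile = ScatteringProfile(q, 5.0 * np.exp(-(q * rg_true) ** 2 / 3.0))
    rg, i0 = guinier_rg(profile)
    assert rg == pytest.approx(rg_true, abs=0.01)
    assert i0 == pytest.approx(5.0, rel=1e-6)


def test_guinier_sphere_within_one_percent():
    R = 25.0
    q = np.linspace(0.005, 0.2, 200)
    x = q * R
    amp = 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
    profile = ScatteringProfile(q, amp ** 2)
    # qRg < 0.8 window: avoids the curvature bias of the sphere's ln I vs q^2
    rg, _ = guinier_rg(profile, qrg_max=0.8)
    assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.01)


def test_guinier_scale_invariant_and_flat_profile_rejected():
    q = default_q_grid()
    prof = ScatteringProfile(q, np.exp(-(q * 12.0) ** 2 / 3.0))
    rg1, _ = guinier_rg(prof)
    rg2, _ = guinier_rg(ScatteringProfile(q, 1e6 * prof.I))
    assert rg1 == pytest.approx(rg2, rel=1e-12)
    with pytest.raises(NoGuinierRegionError):
        guinier_rg(ScatteringProfile(q, np.ones_like(q)))


def test_dimensionless_kratky_gaussian_peak():
    rg = 18.15
    q = default_q_grid()
    profile = ScatteringProfile(q, np.exp(-(q * rg) ** 2 / 3.0))
    x, y = dimensionless_kratky(profile, rg, 1.0)
    peak = np.argmax(y)
    grid_step = (q[1] - q[0]) * rg
    assert x[peak] == pytest.approx(np.sqrt(3.0), abs=grid_step)
    assert y[peak] == pytest.approx(3.0 / np.e, abs=0.01)
    assert y[0] < y[peak]
    # joint scaling of I and I0 leaves the curve unchanged
    x2, y2 = dimensionless_kratky(ScatteringProfile(q, 7.0 * profile.I), rg, 7.0)
    np.testing.assert_allclose(y2, y, rtol=1e-12)


def test_pr_two_atoms_single_spike():
    s = Structure([Atom(element="C", coord=[0, 0, 0], name="C"),
                   Atom(element="C", coord=[0, 0, 10.0], name="C")])
    r, p, d_max = pr_from_structure(s, n_bins=50)
    assert d_max == pytest.approx(10.0)
    assert np.count_nonzero(p) == 1
    assert r[np.argmax(p)] == pytest.approx(10.0, abs=10.0 / 50)


def test_pr_properties_on_random_structure():
    rng = np.random.default_rng(7)
    s = random_structure(rng, 40)
    r, p, d_max = pr_from_structure(s, n_bins=64)
    widths = np.diff(np.linspace(0, d_max, 65))
    assert (p * widths).sum() == pytest.approx(1.0, rel=1e-9)
    coords = s.coords()
    brute = max(np.linalg.norm(coords[i] - coords[j])
                for i in range(len(s)) for j in range(i + 1, len(s)))
    assert d_max == pytest.approx(brute, rel=1e-12)
    with pytest.raises(Exception):
        pr_from_structure(Structure([s.atoms[0]]))


def test_profile_load_save_round_trip(tmp_path, q_grid):
    rng = np.random.default_rng(0)
    prof = ScatteringProfile(q_grid, rng.uniform(1, 2, q_grid.size),
                             rng.uniform(0.01, 0.02, q_grid.size))
    path = tmp_path / "exp.dat"
    prof.save(path)
    again = ScatteringProfile.load(path)
    np.testing.assert_allclose(again.q, prof.q)
    np.testing.assert_allclose(again.I, prof.I)
    np.testing.assert_allclose(again.sigma, prof.sigma)


def test_fit_file_has_header_and_four_columns(tmp_path, rna, rna_fractions, q_grid):
    exp = simulate_experiment(rna, q_grid, noise_fraction=0.01, seed=0,
                              surface_fractions=rna_fractions)
    res = fit_profile(exp, rna)
    path = tmp_path / "out.fit"
    write_fit(path, exp, res)
    header = path.read_text().splitlines()[0]
    assert "chi2=" in header and "c1=" in header
    data = np.loadtxt(path)
    assert data.shape == (q_grid.size, 4)


def test_profile_validation():
    with pytest.raises(ProfileError):
        ScatteringProfile(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
    with pytest.raises(ProfileError):
        ScatteringProfile(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                          np.array([0.0, 0.1]))
    with pytest.raises(Exception):
        compute_profile(Structure([]))
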