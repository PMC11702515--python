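"""Synthetic fixtures: pseudo-RNA helices, planted ion/water sites, perturbed
conformers and simulated noisy SAXS measurements.

The pseudo-RNA is an A-form-like helix of simplified nucleotide motifs —
plausible geometry without a forcefield.  Planted Mg2+ sites carry the
physical signature the classifier must learn (an octahedral shell of O/N
atoms at inner-sphere distance ~2.1 Å), built by repositioning nearby O/N
atoms; planted waters are surface positions without such a shell.  The
conformer generator applies smoothly ramped hinge rotations between
quasi-rigid segments: it is a test fixture emulating conformational
plasticity, not a physical sampler of RNA motion.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .saxs_core import ScatteringProfile, compute_profile, default_q_grid
from .structure_io import Atom, Structure


@dataclass
class SyntheticSpec:
    n_residues: int = 24
    rise: float = 2.8               # axial translation per residue, Å
    twist: float = 32.7             # rotation per residue, degrees
    radius: float = 9.0             # backbone (P) radius, Å
    bend_angle: float = 60.0        # total axis bend over the molecule, degrees
    n_planted_ions: int = 3
    coordination_distance: float = 2.1  # Mg-O/N inner-sphere distance, Å
    n_waters: int = 20
    conformer_perturbation: float = 1.5  # RMS amplitude of bending, Å
    noise_fraction: float = 0.01    # relative sigma of simulated profiles
    jitter: float = 0.12            # per-atom coordinate jitter, Å
    seed: int = 0

    def __post_init__(self):
        if min(self.n_residues, self.n_planted_ions, self.n_waters) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_fraction <= 0:
            raise ValueError("noise fraction must be positive")


# simplified nucleotide motif in the residue frame (radial, tangential, axial)
_MOTIF = [
    ("P", "P", (0.0, 0.0, 0.0)),
    ("OP1", "O", (1.3, 0.6, 0.3)),
    ("OP2", "O", (1.1, -0.8, -0.5)),
    ("O5'", "O", (-0.9, 0.8, 0.9)),
    ("C5'", "C", (-1.8, 1.6, 1.5)),
    ("C4'", "C", (-2.9, 1.0, 2.2)),
    ("O4'", "O", (-3.5, -0.1, 1.6)),
    ("O2'", "O", (-3.6, 2.0, 3.0)),
    ("N1", "N", (-4.8, 0.2, 1.2)),
    ("C2", "C", (-5.9, 0.9, 1.0)),
    ("O2", "O", (-6.1, 2.2, 1.6)),
    ("N3", "N", (-6.9, 0.2, 0.5)),
]
_CHAIN_LETTERS = "ACGU"


def make_pseudo_rna(spec: SyntheticSpec) -> Structure:
    """Helical pseudo-RNA: one simplified nucleotide motif per residue.

    Consecutive residues advance by ``rise`` of arc length along a smoothly
    curved axis (a circular arc subtending ``bend_angle``; stem-loops in
    solution are bent, and a perfectly straight helix would be a pathological
    scattering benchmark, its screw symmetry making distinct surface sites
    nearly indistinguishable by their distance spectra) and rotate by
    ``twist`` about the local axis.  A small seeded jitter decorrelates
    structures generated with different seeds.
    """
    if spec.n_residues == 0:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    twist = np.deg2rad(spec.twist)
    total_arc = spec.n_residues * spec.rise
    bend = np.deg2rad(spec.bend_angle)
    # circular-arc axis in the x-z plane; straight axis when bend -> 0
    r_bend = total_arc / bend if bend > 1e-9 else np.inf
    for i in range(spec.n_residues):
        s = i * spec.rise
        if np.isfinite(r_bend):
            phi = s / r_bend
            axis_pt = np.array([r_bend * (1.0 - np.cos(phi)), 0.0, r_bend * np.sin(phi)])
            t_hat = np.array([np.sin(phi), 0.0, np.cos(phi)])   # axis tangent
            m2 = np.array([np.cos(phi), 0.0, -np.sin(phi)])     # in-plane normal
        else:
            axis_pt = np.array([0.0, 0.0, s])
            t_hat = np.array([0.0, 0.0, 1.0])
            m2 = np.array([1.0, 0.0, 0.0])
        m1 = np.array([0.0, 1.0, 0.0])
        theta = i * twist
        u = np.cos(theta) * m2 + np.sin(theta) * m1   # radial
        v = -np.sin(theta) * m2 + np.cos(theta) * m1  # tangential
        origin = axis_pt + spec.radius * u
        resname = _CHAIN_LETTERS[i % 4]
        for name, element, (a, b, c) in _MOTIF:
            jit = rng.normal(0.0, spec.jitter, 3) if spec.jitter > 0 else 0.0
            coord = origin + a * u + b * v + c * t_hat + jit
            if name == "P":
                coord = origin  # keep the P backbone curve exact for geometry checks
            atoms.append(Atom(element=element, coord=coord, name=name,
                              residue_name=resname, residue_id=i + 1))
    return Structure(atoms, label=f"pseudo_rna_seed{spec.seed}")


@dataclass
class PlantedSystem:
    """Ground truth: adjusted RNA plus planted ion and water positions."""

    rna: Structure
    ion_positions: np.ndarray
    water_positions: np.ndarray

    def truth_structure(self, include_waters: bool = False) -> Structure:
        """RNA with MG (and optionally HOH) records appended."""
        out = self.rna.copy()
        next_id = max((a.residue_id for a in out.atoms), default=0) + 1
        for pos in self.ion_positions:
            out.atoms.append(Atom(element="MG", coord=pos, name="MG",
                                  residue_name="MG", residue_id=next_id,
                                  chain="M", is_hetero=True))
            next_id += 1
        if include_waters:
            for pos in self.water_positions:
                out.atoms.append(Atom(element="O", coord=pos, name="O",
                                      residue_name="HOH", residue_id=next_id,
                                      chain="W", is_hetero=True))
                next_id += 1
        return out


def _octahedral_vertices(outward: np.ndarray, rng) -> np.ndarray:
    e1 = outward / np.linalg.norm(outward)
    r = rng.normal(size=3)
    e2 = r - (r @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.array([-e1, e2, -e2, e3, -e3, e1])


def plant_sites(rna: Structure, spec: SyntheticSpec) -> PlantedSystem:
    """Plant Mg2+ sites with octahedral O/N shells and shell-free waters.

    Each ion sits at coordination distance outside an anchor oxygen; up to
    five further O/N atoms are repositioned onto the remaining octahedral
    vertices, so every planted ion ends with >= 4 O/N neighbors in the
    [1.8, 2.4] Å shell.  Waters are surface points with no O/N inside 2.4 Å.
    The returned structure is the adjusted copy; downstream code must use it.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    rna = rna.copy()
    coords = rna.coords()
    d_c = spec.coordination_distance

    is_on = np.array([a.element in ("O", "N") for a in rna.atoms])
    anchors = list(np.where(is_on)[0])
    rng.shuffle(anchors)

    ion_positions: list[np.ndarray] = []
    moved: set[int] = set()
    for anchor in anchors:
        if len(ion_positions) >= spec.n_planted_ions:
            break
        if anchor in moved:
            continue
        # outward = away from the local atom cloud (works for any axis shape)
        near = np.linalg.norm(coords - coords[anchor], axis=1) < 8.0
        outward = coords[anchor] - coords[near].mean(axis=0)
        if np.linalg.norm(outward) < 1e-6:
            continue
        outward /= np.linalg.norm(outward)
        pos = coords[anchor] + d_c * outward
        clearance = np.linalg.norm(coords - pos, axis=1)
        clearance[anchor] = np.inf
        if clearance.min() < 1.9:
            continue
        if any(np.linalg.norm(pos - p) < 8.0 for p in ion_positions):
            continue
        vertices = _octahedral_vertices(outward, rng)
        # anchor occupies the inward vertex (-e1) exactly
        coords[anchor] = pos + d_c * vertices[0]
        shell = [anchor]
        d_all = np.linalg.norm(coords - pos, axis=1)
        near = [j for j in np.argsort(d_all)
                if is_on[j] and j != anchor and j not in moved and 0.5 < d_all[j] < 6.0]
        free = list(range(1, 6))
        for j in near:
            if not free:
                break
            vi = min(free, key=lambda v: np.linalg.norm(coords[j] - (pos + d_c * vertices[v])))
            new_coord = pos + rng.uniform(d_c - 0.15, d_c + 0.15) * vertices[vi]
            others = np.linalg.norm(coords - new_coord, axis=1)
            others[j] = np.inf
            for s in shell:
                others[s] = np.inf
            if others.min() < 1.8:
                continue
            coords[j] = new_coord
            shell.append(j)
            free.remove(vi)
        if len(shell) >= 4:
            ion_positions.append(pos)
            moved.update(shell)
        else:
            # revert is unnecessary: shell atoms stay near their origin; but
            # drop the site and release the anchor
            moved.update(shell)
    if len(ion_positions) < spec.n_planted_ions:
        warnings.warn(f"planted only {len(ion_positions)} of "
                      f"{spec.n_planted_ions} requested ion sites")

    for i, atom in enumerate(rna.atoms):
        atom.coord = coords[i]

    # waters: hydrogen-bond-like surface positions (2.7-3.3 Å from an O/N
    # donor/acceptor, crevices included) without an inner coordination shell
    water_positions: list[np.ndarray] = []
    on_coords = coords[is_on]
    on_idx = np.where(is_on)[0]
    attempts = 0
    while len(water_positions) < spec.n_waters and attempts < 200 * max(spec.n_waters, 1):
        attempts += 1
        base = coords[on_idx[rng.integers(len(on_idx))]]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = base + rng.uniform(2.7, 3.3) * direction
        if np.linalg.norm(coords - pos, axis=1).min() < 2.5:
            continue
        if (np.linalg.norm(on_coords - pos, axis=1) < 2.4).sum() > 2:
            continue
        if any(np.linalg.norm(pos - p) < 3.0 for p in ion_positions):
            continue
        if any(np.linalg.norm(pos - p) < 3.0 for p in water_positions):
            continue
        water_positions.append(pos)
    if len(water_positions) < spec.n_waters:
        warnings.warn(f"placed only {len(water_positions)} of "
                      f"{spec.n_waters} requested waters")

    return PlantedSystem(
        rna=rna,
        ion_positions=np.array(ion_positions).reshape(-1, 3),
        water_positions=np.array(water_positions).reshape(-1, 3),
    )


def decoy_positions(system: PlantedSystem, n: int, seed: int = 0,
                    min_ion_separation: float = 2 * np.pi / 0.4,
                    min_mutual: float = 5.0) -> np.ndarray:
    """Water-like false-positive candidate sites for recovery benchmarks.

    Decoys sit on the surface (2.8-4.0 Å from the nearest atom) at least
    ``min_ion_separation`` from every planted ion — by default the Shannon
    resolution 2 pi / q_max of the standard q range, since candidate sets
    closer than the data's resolving power are indistinguishable by any
    fitting method.
    """
    rng = np.random.default_rng(seed + 15485863)
    coords = system.rna.coords()
    decoys: list[np.ndarray] = []
    attempts = 0
    while len(decoys) < n and attempts < 20000:
        attempts += 1
        base = coords[rng.integers(len(coords))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = base + rng.uniform(2.8, 4.0) * direction
        if np.linalg.norm(coords - pos, axis=1).min() < 2.6:
            continue
        if any(np.linalg.norm(pos - p) < min_ion_separation
               for p in system.ion_positions):
            continue
        if any(np.linalg.norm(pos - p) < min_mutual for p in decoys):
            continue
        decoys.append(pos)
    if len(decoys) < n:
        warnings.warn(f"placed only {len(decoys)} of {n} requested decoys")
    return np.array(decoys).reshape(-1, 3)


def recovery_benchmark(seed: int, n_decoys: int = 7,
                       noise_fraction: float = 0.005,
                       min_margin: float = 0.3, max_tries: int = 60):
    """A planted system plus decoy candidates with a certified-unique optimum.

    Regenerates (system, decoys) until, in the noise-free chi2 landscape
    over every candidate subset, each subset that does not contain all the
    planted ions misfits the truth by at least ``min_margin`` in reduced
    chi2 at the stated noise level.  Without this certificate some planted
    configurations are degenerate — a proper subset, possibly together with
    a decoy, reproduces the truth profile within the detection scale, and
    recovery is impossible for any method.
    """
    from itertools import combinations

    from .saxs_core import (ScatteringProfile, decompose, fit_scale,
                            solvent_accessible_fraction)

    spec = SyntheticSpec(seed=seed)
    last = None
    for t in range(max_tries):
        s = replace(spec, seed=spec.seed + 1000003 * t)
        system = plant_sites(make_pseudo_rna(s), s)
        k = len(system.ion_positions)
        decoys = decoy_positions(system, n_decoys, seed=s.seed)
        last = (system, decoys)
        if k < spec.n_planted_ions or len(decoys) < n_decoys:
            continue
        frac = solvent_accessible_fraction(system.rna)
        cands = np.vstack([system.ion_positions, decoys])
        partials = decompose(system.rna, cands, surface_fractions=frac)
        I_full = partials.assemble(range(k))
        exp = ScatteringProfile(partials.q, I_full, noise_fraction * I_full)
        truth = frozenset(range(k))
        n = partials.n_candidates
        worst = np.inf
        for size in range(n + 1):
            for keep in combinations(range(n), size):
                if truth <= set(keep):
                    continue
                worst = min(worst, fit_scale(exp, partials.assemble_profile(keep)).chi2)
            if worst < min_margin:
                break
        if worst >= min_margin:
            return system, decoys
    warnings.warn("no certified-unique recovery instance found; returning the "
                  "last candidate")
    return last


def make_planted_structures(n_structures: int, spec: SyntheticSpec | None = None,
                            seed: int = 0) -> list[Structure]:
    """Independent pseudo-RNAs with MG and HOH records, for classifier training."""
    spec = spec or SyntheticSpec()
    structures = []
    for i in range(n_structures):
        s = replace(spec, seed=seed + 7919 * (i + 1))
        system = plant_sites(make_pseudo_rna(s), s)
        truth = system.truth_structure(include_waters=True)
        truth.label = f"synthetic_{seed}_{i}"
        structures.append(truth)
    return structures


def simulate_experiment(truth: Structure, q: np.ndarray | None = None,
                        noise_fraction: float = 0.01, seed: int = 0,
                        c1: float = 1.0, c2: float = 1.0,
                        surface_fractions: np.ndarray | None = None) -> ScatteringProfile:
    """Noisy simulated measurement of a ground-truth structure.

    I_exp(q) = I_true(q) (1 + eps), eps ~ N(0, noise_fraction) i.i.d.;
    sigma(q) = noise_fraction * I_true(q) (high-signal multiplicative regime).
    ``surface_fractions`` pins the hydration convention (pass RNA-only
    fractions with ions fully exposed to match the subset-assembly model).
    """
    if q is None:
        q = default_q_grid()
    rng = np.random.default_rng(seed)
    calc = compute_profile(truth, q, c1=c1, c2=c2,
                           surface_fractions=surface_fractions)
    eps = rng.normal(0.0, noise_fraction, size=calc.I.shape)
    sigma = noise_fraction * calc.I
    return ScatteringProfile(calc.q, calc.I * (1.0 + eps), sigma)


def _rotate_about(points: np.ndarray, center: np.ndarray, axis: np.ndarray,
                  angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of each point about (center, axis) by its own angle."""
    p = points - center
    k = axis / np.linalg.norm(axis)
    cos, sin = np.cos(angles)[:, None], np.sin(angles)[:, None]
    kxp = np.cross(np.broadcast_to(k, p.shape), p)
    kdp = (p @ k)[:, None]
    return center + p * cos + kxp * sin + k * kdp * (1.0 - cos)


def make_conformers(rna: Structure, n: int, perturbation: float,
                    seed: int = 0, n_hinges: int = 2,
                    ramp_residues: int = 5) -> list[Structure]:
    """Hinge-bent conformers of an input structure.

    Each conformer rotates the chain downstream of ``n_hinges`` random hinge
    residues about random axes through the hinge, with the rotation angle
    ramped in smoothly over ``ramp_residues`` residues so the bond strain is
    spread instead of concentrated at one junction.  Angles are rescaled so
    the RMSD to the input matches the requested perturbation (within a
    sampled ±15% spread).  Hinge motion between quasi-rigid segments mimics
    the dominant large-scale flexibility of folded RNA while leaving local
    geometry nearly intact.  Conformer 0 is the unperturbed input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = rna.coords()
    res_ids = np.array([a.residue_id for a in rna.atoms])
    res_min, res_max = res_ids.min(), res_ids.max()
    n_res = res_max - res_min + 1
    conformers = [rna.copy()]
    conformers[0].label = f"{rna.label}#conf0"
    for m in range(1, n):
        target = perturbation * rng.uniform(0.85, 1.15)
        coords = base.copy()
        if perturbation > 0 and n_res >= 3:
            hinges = []
            for _ in range(n_hinges):
                hinge_res = int(rng.integers(res_min + n_res // 4,
                                             res_max - n_res // 4 + 1))
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                pivot = base[res_ids == hinge_res].mean(axis=0)
                sign = rng.choice([-1.0, 1.0])
                hinges.append((hinge_res, axis, pivot, sign))
            amp = 0.05  # rad; rescaled to the target RMSD below
            for _ in range(3):
                coords = base.copy()
                for hinge_res, axis, pivot, sign in hinges:
                    # smooth ramp of the rotation angle across the hinge
                    frac = np.clip((res_ids - hinge_res) / ramp_residues + 0.5,
                                   0.0, 1.0)
                    weight = frac * frac * (3.0 - 2.0 * frac)  # smoothstep
                    coords = _rotate_about(coords, pivot, axis,
                                           sign * amp * weight)
                rmsd = float(np.sqrt(np.mean(np.sum((coords - base) ** 2, axis=1))))
                if rmsd < 1e-12:
                    break
                amp *= target / rmsd
        conf = rna.copy()
        for i, atom in enumerate(conf.atoms):
            atom.coord = coords[i]
        conf.label = f"{rna.label}#conf{m}"
        conformers.append(conf)
    return conformers
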