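"""Surface probe generation and probe-centered neighborhood graphs.

Probes are candidate Mg2+ centers sampled on a dot-approximated molecular
surface (a water-sized sphere rolled over van der Waals spheres); each probe's
atomic neighborhood within 8 Å becomes a small graph that the ion classifier
consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

# van der Waals radii, Å
_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
          "H": 1.20, "MG": 1.60, "NA": 2.27, "K": 2.75, "CL": 1.75}
DEFAULT_PROBE_RADIUS = 1.5  # water-sized rolling probe (surface/SASA work)
MG_PROBE_RADIUS = 0.65      # Mg2+ ionic radius: candidate sites must reach
                            # inner-sphere contact (~2.1 Å from O), which a
                            # water-sized probe geometrically cannot
NEIGHBORHOOD_RADIUS = 8.0
ATOM_EDGE_CUTOFF = 4.0
DEDUP_GRID = 1.0
CLASH_TOL = 0.1

ELEMENT_CLASSES = ["C", "N", "O", "P", "other"]
ATOM_CATEGORIES = ["phosphate_O", "ribose_O", "base_O", "base_N", "other"]
RESIDUE_CLASSES = ["A", "C", "G", "U", "other"]
N_NODE_FEATURES = 1 + len(ELEMENT_CLASSES) + len(ATOM_CATEGORIES) + len(RESIDUE_CLASSES)

_PHOSPHATE_O = {"OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'", "O3'", "O5*", "O3*"}
_RIBOSE_O = {"O2'", "O4'", "O2*", "O4*"}
_BASE_O = {"O2", "O4", "O6"}
_BASE_N = {"N1", "N2", "N3", "N4", "N6", "N7", "N9"}
_RES_MAP = {"A": "A", "ADE": "A", "RA": "A", "C": "C", "CYT": "C", "RC": "C",
            "G": "G", "GUA": "G", "RG": "G", "U": "U", "URA": "U", "RU": "U"}


class NeighborhoodError(ValueError):
    """Raised for empty or degenerate probe neighborhoods."""


def atomic_radius(element: str) -> float:
    return _RADII.get(element, 1.70)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class Probe:
    position: np.ndarray
    parent_atom_index: int


def generate_probes(rna: Structure, dot_density: int = 64,
                    probe_radius: float = DEFAULT_PROBE_RADIUS,
                    tol: float = CLASH_TOL) -> list[Probe]:
    """Candidate probe centers on the solvent-expanded surface.

    For each atom, dots are placed on the sphere of radius r_atom + r_probe;
    dots within (r_other + r_probe - tol) of any other atom are occluded.
    Survivors are deduplicated on a 1 Å grid (ties keep the lowest parent
    atom index).
    """
    coords = rna.coords()
    radii = np.array([atomic_radius(a.element) for a in rna.atoms])
    dots = fibonacci_sphere(dot_density)
    tree = cKDTree(coords)
    max_reach = radii.max() + 2 * probe_radius

    seen: dict[tuple, Probe] = {}
    for i, (xyz, r) in enumerate(zip(coords, radii)):
        pts = xyz + (r + probe_radius) * dots
        neighbors = np.array([j for j in tree.query_ball_point(xyz, r + max_reach)
                              if j != i], dtype=int)
        if neighbors.size:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            keep = ~((d < radii[neighbors][None, :] + probe_radius - tol).any(axis=1))
        else:
            keep = np.ones(len(pts), dtype=bool)
        for pt in pts[keep]:
            cell = tuple(np.floor(pt / DEDUP_GRID).astype(int))
            if cell not in seen:  # atoms visited in index order -> lowest parent wins
                seen[cell] = Probe(position=pt, parent_atom_index=i)
    probes = list(seen.values())
    if not probes:
        warnings.warn("structure surface fully occluded: no probes generated")
    return probes


def _atom_category(atom) -> str:
    if atom.element == "O":
        if atom.name in _PHOSPHATE_O:
            return "phosphate_O"
        if atom.name in _RIBOSE_O:
            return "ribose_O"
        if atom.name in _BASE_O:
            return "base_O"
    if atom.element == "N" and atom.name in _BASE_N:
        return "base_N"
    return "other"


def atom_features(atom) -> np.ndarray:
    """Chemistry one-hots for a single atom node (is_probe flag = 0)."""
    f = np.zeros(N_NODE_FEATURES)
    el = atom.element if atom.element in ELEMENT_CLASSES else "other"
    f[1 + ELEMENT_CLASSES.index(el)] = 1.0
    f[1 + len(ELEMENT_CLASSES) + ATOM_CATEGORIES.index(_atom_category(atom))] = 1.0
    res = _RES_MAP.get(atom.residue_name, "other")
    f[1 + len(ELEMENT_CLASSES) + len(ATOM_CATEGORIES) + RESIDUE_CLASSES.index(res)] = 1.0
    return f


@dataclass
class NeighborhoodGraph:
    """Probe-centered atom graph.

    Node 0 is the probe (is_probe flag set, zeroed chemistry features); the
    probe connects to every atom node, and atom-atom edges exist for pairs
    within the local cutoff.  Edges are stored once per unordered pair.
    """

    node_features: np.ndarray  # (n_nodes, N_NODE_FEATURES)
    edges: np.ndarray          # (n_edges, 2) int
    edge_distances: np.ndarray  # (n_edges,)
    label: int | None = None   # 1 = ion, 0 = water
    source: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def extract_neighborhood(rna: Structure, position, radius: float = NEIGHBORHOOD_RADIUS,
                         atom_edge_cutoff: float = ATOM_EDGE_CUTOFF,
                         label: int | None = None) -> NeighborhoodGraph:
    """Graph of all atoms within ``radius`` of a probe position."""
    position = np.asarray(position, dtype=float)
    if position.shape != (3,) or not np.all(np.isfinite(position)):
        raise NeighborhoodError("probe position must be a finite 3-vector")
    coords = rna.coords()
    d = np.linalg.norm(coords - position, axis=1)
    idx = np.where(d <= radius)[0]
    if idx.size == 0:
        raise NeighborhoodError("no atoms within the neighborhood radius")
    if np.any(d[idx] < 1e-6):
        raise NeighborhoodError("probe coincides with an atom")

    n = idx.size + 1
    feats = np.zeros((n, N_NODE_FEATURES))
    feats[0, 0] = 1.0  # probe flag; chemistry features stay zero
    for row, j in enumerate(idx, start=1):
        feats[row] = atom_features(rna.atoms[j])

    probe_edges = np.column_stack([np.zeros(idx.size, dtype=int),
                                   np.arange(1, n)])
    probe_dists = d[idx]
    sub = coords[idx]
    if idx.size > 1:
        iu, ju = np.triu_indices(idx.size, 1)
        dd = np.linalg.norm(sub[iu] - sub[ju], axis=1)
        keep = dd <= atom_edge_cutoff
        atom_edges = np.column_stack([iu[keep] + 1, ju[keep] + 1])
        atom_dists = dd[keep]
    else:
        atom_edges = np.zeros((0, 2), dtype=int)
        atom_dists = np.zeros(0)
    return NeighborhoodGraph(
        node_features=feats,
        edges=np.concatenate([probe_edges, atom_edges]).astype(int),
        edge_distances=np.concatenate([probe_dists, atom_dists]),
        label=label,
        source=rna.label,
    )


@dataclass
class GraphDataset:
    """A labeled set of neighborhood graphs with their source-structure ids."""

    graphs: list[NeighborhoodGraph] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=int)

    @property
    def groups(self) -> np.ndarray:
        """Source-structure identifiers for leakage-free fold splitting."""
        sources = [g.source for g in self.graphs]
        uniq = {s: i for i, s in enumerate(dict.fromkeys(sources))}
        return np.array([uniq[s] for s in sources], dtype=int)

    def save(self, path) -> None:
        """Single .npz archive of concatenated arrays + JSON metadata."""
        node_feats = np.concatenate([g.node_features for g in self.graphs])
        node_counts = np.array([g.n_nodes for g in self.graphs])
        edge_arr = np.concatenate([g.edges for g in self.graphs])
        edge_counts = np.array([len(g.edges) for g in self.graphs])
        edge_d = np.concatenate([g.edge_distances for g in self.graphs])
        meta = json.dumps({"sources": [g.source for g in self.graphs],
                           "n_node_features": N_NODE_FEATURES})
        np.savez(path, node_features=node_feats, node_counts=node_counts,
                 edges=edge_arr, edge_counts=edge_counts, edge_distances=edge_d,
                 labels=self.labels, meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "GraphDataset":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        graphs = []
        n_off = e_off = 0
        for count, e_count, label, source in zip(z["node_counts"], z["edge_counts"],
                                                 z["labels"], meta["sources"]):
            graphs.append(NeighborhoodGraph(
                node_features=z["node_features"][n_off:n_off + count],
                edges=z["edges"][e_off:e_off + e_count],
                edge_distances=z["edge_distances"][e_off:e_off + e_count],
                label=int(label), source=source))
            n_off += count
            e_off += e_count
        return cls(graphs)


def build_training_set(structures: list[Structure],
                       negatives_per_positive: float = 1.0,
                       radius: float = NEIGHBORHOOD_RADIUS,
                       seed: int = 0) -> GraphDataset:
    """Labeled graphs from structures containing Mg2+ (positives) and water
    oxygens (negatives).

    Neighborhoods are extracted over the RNA atoms only, so no graph contains
    its own center (or any Mg/water atom): label leakage is impossible by
    construction.  Structures lacking both site types are skipped.
    """
    from .structure_io import split_components

    rng = np.random.default_rng(seed)
    dataset = GraphDataset()
    for si, structure in enumerate(structures):
        rna, ions, waters = split_components(structure)
        if len(ions) == 0 and len(waters) == 0:
            warnings.warn(f"structure {structure.label or si}: no MG or HOH records, skipped")
            continue
        source = structure.label or f"structure_{si}"
        rna.label = source
        n_pos = 0
        for ion in ions.atoms:
            try:
                dataset.graphs.append(
                    extract_neighborhood(rna, ion.coord, radius, label=1))
                n_pos += 1
            except NeighborhoodError:
                continue
        water_oxygens = [w for w in waters.atoms if w.element == "O"]
        n_neg_target = int(round(negatives_per_positive * max(n_pos, 1))) \
            if n_pos else len(water_oxygens)
        if len(ions) and not water_oxygens:
            warnings.warn(f"structure {source}: positives but no waters for negatives")
        order = rng.permutation(len(water_oxygens))
        n_neg = 0
        for wi in order:
            if n_neg >= n_neg_target:
                break
            try:
                dataset.graphs.append(
                    extract_neighborhood(rna, water_oxygens[wi].coord, radius, label=0))
                n_neg += 1
            except NeighborhoodError:
                continue
    return dataset
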