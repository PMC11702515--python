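"""Pipeline orchestration: conformer scoring, ion prediction, SAXS-based ion
selection and multi-state fitting.

Stages: (1) every conformer is scored against the experimental profile with
fixed c1/c2; (2) for the top-M conformers, surface probes are generated and
classified; (3) a branch-and-bound selects the ion subset minimizing chi2 per
conformer; (4) if no single decorated conformer fits within the acceptance
threshold, a multi-state model is fitted over the candidate states.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ionnet as ionnet_mod
from .ion_selection import SelectionConfig, select_ions
from .multistate import enumerate_multistate
from .saxs_core import (ScatteringProfile, decompose, fit_profile,
                        solvent_accessible_fraction, write_fit)
from .structure_io import Structure, write_pdb_with_ions
from .surface_probes import generate_probes

log = logging.getLogger("scoper")


@dataclass
class PipelineConfig:
    conformer_source: str | None = None   # PDB file or directory of PDBs
    profile_path: str | None = None
    model_path: str | None = None
    ionnet_threshold: float = 0.5
    merge_radius: float = 3.5
    top_m: int = 20                       # conformers carried into ion prediction
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    max_states: int = 5
    multistate_beam: int = 50
    accept_chi2: float = 1.5              # "fits within the noise" convention
    fit_c1_c2: bool = False
    c2_zero_convention: bool = False
    output_dir: str | None = None
    seed: int = 0
    probe_dot_density: int = 64
    probe_radius: float = 0.65   # Mg2+-sized probe for candidate generation


@dataclass
class ConformerResult:
    index: int
    label: str
    chi2_plain: float
    chi2_with_ions: float | None = None
    ion_positions: np.ndarray | None = None
    n_ions: int = 0
    error: str | None = None


@dataclass
class PipelineReport:
    chi2_initial: float
    chi2_best_conformer: float
    chi2_best_with_ions: float
    best_conformer_index: int
    best_ion_positions: np.ndarray
    conformers: list[ConformerResult]
    multistate: dict | None = None
    n_atoms: int = 0
    timings: dict = field(default_factory=dict)

    @property
    def n_selected_ions(self) -> int:
        return len(self.best_ion_positions)

    def to_dict(self) -> dict:
        return {
            "chi2_initial": self.chi2_initial,
            "chi2_best_conformer": self.chi2_best_conformer,
            "chi2_best_with_ions": self.chi2_best_with_ions,
            "best_conformer_index": self.best_conformer_index,
            "n_selected_ions": self.n_selected_ions,
            "best_ion_positions": np.asarray(self.best_ion_positions).tolist(),
            "n_atoms": self.n_atoms,
            "conformers": [
                {"index": c.index, "label": c.label, "chi2_plain": c.chi2_plain,
                 "chi2_with_ions": c.chi2_with_ions, "n_ions": c.n_ions,
                 "error": c.error}
                for c in self.conformers
            ],
            "multistate": self.multistate,
            "timings": self.timings,
        }


def load_conformers(source) -> list[Structure]:
    """Conformers from a multi-model PDB file or a directory of PDB files."""
    from .structure_io import read_pdb_models

    path = Path(source)
    if path.is_dir():
        structures = []
        for f in sorted(path.glob("*.pdb")):
            structures.extend(read_pdb_models(f))
        if not structures:
            raise FileNotFoundError(f"no PDB files under {source}")
        return structures
    return read_pdb_models(path)


def run_pipeline(config: PipelineConfig,
                 conformers: list[Structure] | None = None,
                 profile: ScatteringProfile | None = None,
                 model: "ionnet_mod.IonNetModel | None" = None) -> PipelineReport:
    """Run all pipeline stages; in-memory arguments override config paths."""
    t0 = time.time()
    if conformers is None:
        conformers = load_conformers(config.conformer_source)
    if profile is None:
        profile = ScatteringProfile.load(config.profile_path)
    if model is None and config.model_path is not None:
        model = ionnet_mod.IonNetModel.load(config.model_path)
    if not conformers:
        raise ValueError("at least one conformer required")

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: score all conformers (fixed c1/c2 unless explicitly opted in)
    if config.fit_c1_c2:
        log.warning("fitting c1/c2 freely: risk of overfitting the data")
    results: list[ConformerResult] = []
    fits = []
    for i, conf in enumerate(conformers):
        try:
            res = fit_profile(profile, conf, fix_c1_c2=not config.fit_c1_c2,
                              c2_zero_convention=config.c2_zero_convention)
            results.append(ConformerResult(i, conf.label or f"conf{i}", res.chi2))
            fits.append(res)
        except Exception as exc:  # stagewise: record and continue
            results.append(ConformerResult(i, conf.label or f"conf{i}", np.inf,
                                           error=f"stage1: {exc}"))
            fits.append(None)
    t1 = time.time()
    order = sorted((r.index for r in results if r.error is None),
                   key=lambda i: results[i].chi2_plain)
    if not order:
        raise RuntimeError("all conformers failed profile fitting")
    chi2_initial = results[0].chi2_plain if results[0].error is None \
        else results[order[0]].chi2_plain
    chi2_best_conformer = results[order[0]].chi2_plain

    # stages 2-3: ion prediction and subset selection for the top-M conformers
    top = order[:max(1, config.top_m)]
    best_with_ions = (chi2_best_conformer, order[0], np.zeros((0, 3)))
    for i in top:
        conf = conformers[i]
        try:
            if model is not None:
                probes = generate_probes(conf, dot_density=config.probe_dot_density,
                                         probe_radius=config.probe_radius)
                preds = ionnet_mod.predict(model, conf, probes)
                sites = ionnet_mod.threshold_and_cluster(
                    preds, config.ionnet_threshold, config.merge_radius)
                candidates = np.array([s.position for s in sites]).reshape(-1, 3)
            else:
                candidates = np.zeros((0, 3))
            if candidates.shape[0] == 0:
                results[i].chi2_with_ions = results[i].chi2_plain
                continue
            frac = solvent_accessible_fraction(conf)
            c2 = 0.0 if config.c2_zero_convention else 1.0
            partials = decompose(conf, candidates, profile.q, c2=c2,
                                 surface_fractions=frac)
            sel = select_ions(profile, partials, config.selection)
            chosen = partials.candidates[list(sel.best.ion_indices)]
            results[i].chi2_with_ions = sel.best.chi2
            results[i].ion_positions = chosen
            results[i].n_ions = len(chosen)
            if sel.best.chi2 < best_with_ions[0]:
                best_with_ions = (sel.best.chi2, i, chosen)
        except Exception as exc:
            results[i].error = f"stage2/3: {exc}"
    t2 = time.time()
    chi2_best_with_ions, best_idx, best_ions = best_with_ions

    # stage 4: multi-state fitting when no single state fits within the noise
    multistate_report = None
    if chi2_best_with_ions > config.accept_chi2 and len(conformers) > 1:
        state_profiles, state_ids = [], []
        for i in top:
            if fits[i] is None:
                continue
            # bare conformer state: unscaled computed profile on the exp grid
            bare = ScatteringProfile(profile.q, fits[i].fitted_profile.I
                                     / max(fits[i].params.c, 1e-300))
            state_profiles.append(bare)
            state_ids.append(f"conf{i}")
            if results[i].ion_positions is not None and results[i].n_ions > 0:
                frac = solvent_accessible_fraction(conformers[i])
                c2 = 0.0 if config.c2_zero_convention else 1.0
                partials = decompose(conformers[i], results[i].ion_positions,
                                     profile.q, c2=c2, surface_fractions=frac)
                decorated = partials.assemble_profile(range(results[i].n_ions))
                state_profiles.append(decorated)
                state_ids.append(f"conf{i}+mg")
        try:
            per_n, recommended = enumerate_multistate(
                profile, state_profiles, max_states=config.max_states,
                beam=config.multistate_beam)
            multistate_report = {
                "per_n": [{"n_states": m.n_states,
                           "states": [state_ids[s] for s in m.state_ids],
                           "weights": m.weights.tolist(), "chi2": m.chi2}
                          for m in per_n],
                "recommended_n": recommended.n_states,
                "recommended_chi2": recommended.chi2,
            }
        except Exception as exc:
            multistate_report = {"error": str(exc)}
    t3 = time.time()

    report = PipelineReport(
        chi2_initial=chi2_initial,
        chi2_best_conformer=chi2_best_conformer,
        chi2_best_with_ions=chi2_best_with_ions,
        best_conformer_index=best_idx,
        best_ion_positions=best_ions,
        conformers=results,
        multistate=multistate_report,
        n_atoms=len(conformers[0]),
        timings={"stage1_s": t1 - t0, "stage23_s": t2 - t1, "stage4_s": t3 - t2},
    )

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        write_pdb_with_ions(conformers[best_idx], best_ions,
                            out_dir / f"best_conf{best_idx}_with_ions.pdb")
        if fits[best_idx] is not None:
            write_fit(out_dir / f"best_conf{best_idx}.fit", profile, fits[best_idx])
    return report


def ion_count_vs_size(reports: list[PipelineReport]) -> float:
    """Pearson correlation between RNA atom count and selected ion count."""
    if len(reports) < 3:
        raise ValueError("need at least 3 reports")
    x = np.array([r.n_atoms for r in reports], dtype=float)
    y = np.array([r.n_selected_ions for r in reports], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(x, y)[0, 1])
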