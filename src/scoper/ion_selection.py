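"""Branch-and-bound selection of the Mg2+ subset that best fits a SAXS profile.

Subsets are grown one ion at a time: every retained subset of size n-1 is
extended by each unused candidate (branch), scored by O(1) assembly from
precomputed sub-profiles plus a closed-form scale fit, and only the K best
per size survive (bound).  Growth stops when adding an ion no longer lowers
chi2 by more than a small epsilon, or at the optional size cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .saxs_core import (FitResult, PartialProfiles, ProfileError,
                        ScatteringProfile, fit_scale)


@dataclass
class SelectionConfig:
    """Beam width K, optional subset-size cap, and the stop threshold.

    ``improvement_epsilon`` guards against noise-chasing: adding the best of
    m spurious candidates to an already-correct model reduces the reduced
    chi2 by roughly max of m half-chi2(1) draws / S ~ 2 ln(m) / S, which is
    ~0.05 for a typical candidate set (m ~ 10) on a 100-point profile.  The
    default stops there; epsilon = 0 recovers a strict-decrease rule.
    """

    K: int = 50
    max_ions: int | None = None
    improvement_epsilon: float = 0.05

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("beam width K must be >= 1")
        if self.improvement_epsilon < 0:
            raise ValueError("improvement_epsilon must be >= 0")


@dataclass(order=True)
class SubsetState:
    chi2: float
    ion_indices: tuple = field(compare=False)
    scale: float = field(default=1.0, compare=False)


def _score_subset(exp: ScatteringProfile, partials: PartialProfiles, indices) -> SubsetState:
    profile = partials.assemble_profile(indices)
    res: FitResult = fit_scale(exp, profile)
    return SubsetState(chi2=res.chi2, ion_indices=tuple(sorted(indices)),
                       scale=res.params.c)


@dataclass
class SelectionResult:
    per_size: list[SubsetState]   # best subset for sizes 0, 1, ... (retained path)
    best: SubsetState

    def chi2_curve(self):
        return chi2_decrease_curve(self.per_size)


def select_ions(exp: ScatteringProfile, partials: PartialProfiles,
                config: SelectionConfig | None = None) -> SelectionResult:
    """Minimize chi2 over subsets of candidate ion positions.

    The experimental grid must match the decomposition grid.  With an
    exhaustive beam (K >= 2^n) and epsilon = 0 the search is exact.
    """
    config = config or SelectionConfig()
    if exp.sigma is None:
        raise ProfileError("experimental profile must carry errors")
    if not (exp.q.shape == partials.q.shape and np.allclose(exp.q, partials.q)):
        raise ProfileError("decomposition grid must match the experimental grid")

    n = partials.n_candidates
    empty = _score_subset(exp, partials, ())
    per_size = [empty]
    if n == 0:
        return SelectionResult(per_size=per_size, best=empty)

    max_size = n if config.max_ions is None else min(config.max_ions, n)
    beam = [empty]
    for size in range(1, max_size + 1):
        candidates: dict[tuple, SubsetState] = {}
        for state in beam:
            used = set(state.ion_indices)
            for k in range(n):
                if k in used:
                    continue
                key = tuple(sorted(state.ion_indices + (k,)))
                if key in candidates:
                    continue
                candidates[key] = _score_subset(exp, partials, key)
        if not candidates:
            break
        ranked = sorted(candidates.values(), key=lambda s: (s.chi2, s.ion_indices))
        beam = ranked[:config.K]
        best_here = beam[0]
        if per_size[-1].chi2 - best_here.chi2 <= config.improvement_epsilon:
            break  # the larger model is rejected, not just the iteration
        per_size.append(best_here)
    best = min(per_size, key=lambda s: (s.chi2, s.ion_indices))
    return SelectionResult(per_size=per_size, best=best)


def chi2_decrease_curve(per_size_bests: list[SubsetState]):
    """(n_ions, chi2) pairs along the retained path, clipped to the monotone
    non-increasing prefix implied by the stopping rule."""
    if not per_size_bests:
        raise ValueError("empty per-size list")
    return [(len(s.ion_indices), s.chi2) for s in per_size_bests]


def exhaustive_select(exp: ScatteringProfile, partials: PartialProfiles,
                      max_ions: int | None = None) -> SelectionResult:
    """Brute-force enumeration of every subset (oracle for small candidate sets)."""
    from itertools import combinations

    n = partials.n_candidates
    max_size = n if max_ions is None else min(max_ions, n)
    per_size = [_score_subset(exp, partials, ())]
    for size in range(1, max_size + 1):
        states = [_score_subset(exp, partials, c)
                  for c in combinations(range(n), size)]
        per_size.append(min(states, key=lambda s: (s.chi2, s.ion_indices)))
    best = min(per_size, key=lambda s: (s.chi2, s.ion_indices))
    return SelectionResult(per_size=per_size, best=best)
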