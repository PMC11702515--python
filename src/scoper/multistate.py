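"""Multi-state (weighted conformer ensemble) fitting of SAXS profiles.

When no single conformation fits the measurement within the noise, the
profile is modeled as I(q) = c * sum_k w_k I_k(q) with non-negative weights
summing to one.  Weights are found by non-negative least squares on
sigma-weighted residuals; state subsets are enumerated with the same
branch-and-bound strategy as ion selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .saxs_core import ProfileError, ScatteringProfile


@dataclass
class MultiStateModel:
    state_ids: tuple
    weights: np.ndarray
    chi2: float
    scale: float = 1.0

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.state_ids):
            raise ValueError("one weight per state required")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def _check_grids(exp: ScatteringProfile, state_profiles) -> np.ndarray:
    if exp.sigma is None:
        raise ProfileError("experimental profile must carry errors")
    if not state_profiles:
        raise ProfileError("at least one state profile required")
    I = np.empty((len(state_profiles), exp.S))
    for k, prof in enumerate(state_profiles):
        if prof.q.shape != exp.q.shape or not np.allclose(prof.q, exp.q):
            raise ProfileError("state profiles must share the experimental grid")
        I[k] = prof.I
    return I


def fit_weights(exp: ScatteringProfile, state_profiles: list[ScatteringProfile],
                state_ids=None, weight_floor: float = 0.0) -> MultiStateModel:
    """NNLS weight fit of a fixed set of state profiles.

    The unnormalized NNLS solution u_k is split into weights w_k = u_k / sum u
    and an overall scale c = sum u.  States fitted below ``weight_floor`` are
    pruned and the remainder refit (guards against phantom states).
    """
    I = _check_grids(exp, state_profiles)
    if not np.any(I):
        raise ProfileError("all state profiles are zero")
    if state_ids is None:
        state_ids = tuple(range(len(state_profiles)))
    state_ids = tuple(state_ids)

    active = list(range(len(state_profiles)))
    while True:
        A = (I[active] / exp.sigma[None, :]).T
        b = exp.I / exp.sigma
        u, _ = nnls(A, b)
        total = u.sum()
        if total <= 0:
            raise ProfileError("NNLS found no positive combination of states")
        w = u / total
        if weight_floor > 0 and len(active) > 1 and w.min() < weight_floor:
            drop = int(np.argmin(w))
            active.pop(drop)
            continue
        break
    model_I = total * (w @ I[active])
    chi2 = float(np.mean(((exp.I - model_I) / exp.sigma) ** 2))
    return MultiStateModel(state_ids=tuple(state_ids[i] for i in active),
                           weights=w, chi2=chi2, scale=float(total))


def enumerate_multistate(exp: ScatteringProfile,
                         state_profiles: list[ScatteringProfile],
                         max_states: int = 5, beam: int = 50,
                         weight_floor: float = 0.0,
                         improvement_fraction: float = 0.05):
    """Best multi-state model per state count via beam-limited enumeration.

    Returns (per_n, recommended): per_n[n-1] is the best model using exactly n
    candidate states; recommended is the smallest n whose chi2 is within
    ``improvement_fraction`` of the best overall.
    """
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    _check_grids(exp, state_profiles)
    n = len(state_profiles)
    max_states = min(max_states, n)

    def score(ids: tuple) -> MultiStateModel:
        return fit_weights(exp, [state_profiles[i] for i in ids], state_ids=ids,
                           weight_floor=weight_floor)

    # beam entries carry the offered subset (the enumeration key) separately
    # from the fitted model, whose state list may be smaller after pruning
    per_n: list[MultiStateModel] = []
    current = sorted(((( i,), score((i,))) for i in range(n)),
                     key=lambda km: (km[1].chi2, km[0]))
    per_n.append(current[0][1])
    current = current[:beam]
    for _size in range(2, max_states + 1):
        candidates: dict[tuple, MultiStateModel] = {}
        for key, _model in current:
            for k in range(n):
                if k in key:
                    continue
                new_key = tuple(sorted(key + (k,)))
                if new_key not in candidates:
                    candidates[new_key] = score(new_key)
        if not candidates:
            break
        ranked = sorted(candidates.items(), key=lambda km: (km[1].chi2, km[0]))
        per_n.append(ranked[0][1])
        current = ranked[:beam]

    best_chi2 = min(m.chi2 for m in per_n)
    recommended = next(m for m in per_n
                       if m.chi2 <= best_chi2 * (1.0 + improvement_fraction))
    return per_n, recommended


def exhaustive_multistate(exp: ScatteringProfile,
                          state_profiles: list[ScatteringProfile],
                          max_states: int) -> list[MultiStateModel]:
    """Brute-force oracle over all state subsets of size <= max_states."""
    n = len(state_profiles)
    per_n = []
    for size in range(1, min(max_states, n) + 1):
        models = [fit_weights(exp, [state_profiles[i] for i in ids], state_ids=ids)
                  for ids in combinations(range(n), size)]
        per_n.append(min(models, key=lambda m: (m.chi2, m.state_ids)))
    return per_n
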