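"""Energy-landscape topography of a fitted model.

A *stable state* is a binary community state whose energy is strictly
lower than that of every single-flip neighbour; its *basin* is the set of
states from which steepest single-flip descent reaches it.  Continuous
(chemical) components have no single-flip move, so they are clamped at
fixed levels and folded into the effective fields of the binary
subsystem before enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maxent import MaxEntParams, energy, enumerate_states

__all__ = [
    "LandscapeSummary",
    "clamp_continuous",
    "find_minima",
    "descend",
    "landscape_over_gradient",
]

_EXACT_N_MAX = 20


@dataclass
class LandscapeSummary:
    """Local minima, their energies and the basin partition at one env.

    ``minima`` is ordered by increasing energy.  ``basin_of`` maps every
    enumerated state index (bit pattern, component i = bit i) to an index
    into ``minima``; on a perfectly flat landscape there are no strict
    minima and ``flat`` is set.
    """

    env: tuple[float, float]
    minima: list[tuple[np.ndarray, float]]
    basin_of: Optional[np.ndarray] = None
    flat: bool = False
    component_names: Optional[list[str]] = None

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    def basin_sizes(self) -> np.ndarray:
        if self.basin_of is None:
            return np.array([], dtype=int)
        return np.bincount(self.basin_of, minlength=len(self.minima))

    def to_frame(self) -> pd.DataFrame:
        """Minima table: bitstring, energy, basin size."""
        sizes = self.basin_sizes()
        rows = []
        for k, (state, e) in enumerate(self.minima):
            bits = "".join(str(int(b)) for b in state)
            rows.append({"state": bits, "energy": e,
                         "basin_size": int(sizes[k]) if sizes.size else 0})
        return pd.DataFrame(rows)


def clamp_continuous(params: MaxEntParams, kinds: Sequence[str],
                     clamp_values: np.ndarray
                     ) -> tuple[MaxEntParams, np.ndarray]:
    """Fold clamped continuous components into the binary subsystem.

    With continuous components fixed at ``clamp_values``, the energy of
    the binary part keeps the same J among binary components and gains
    ``sum_c J_ic * value_c`` on each h_i (plus a constant that shifts all
    energies equally and is dropped).  Returns the reduced parameters and
    the indices of the binary components.
    """
    kinds = list(kinds)
    binary_idx = np.array([i for i, k in enumerate(kinds) if k == "binary"])
    cont_idx = np.array([i for i, k in enumerate(kinds) if k != "binary"])
    if cont_idx.size == 0:
        return params, binary_idx
    vals = np.asarray(clamp_values, dtype=float)
    if vals.size != cont_idx.size:
        raise ValueError("one clamp value per continuous component required")
    h_eff = params.h[binary_idx] + params.J[np.ix_(binary_idx,
                                                   cont_idx)] @ vals
    names = ([params.component_names[i] for i in binary_idx]
             if params.component_names else None)
    reduced = MaxEntParams(h_eff,
                           params.J[np.ix_(binary_idx, binary_idx)],
                           params.g_a[binary_idx], params.g_s[binary_idx],
                           names)
    return reduced, binary_idx


def _neighbor_energies(energies: np.ndarray, n: int) -> np.ndarray:
    """(2^n, n) matrix: energy after flipping bit b of each state."""
    idx = np.arange(energies.size, dtype=np.int64)
    return energies[idx[:, None] ^ (1 << np.arange(n))]


def find_minima(params: MaxEntParams, env: Sequence[float],
                compute_basins: bool = True) -> LandscapeSummary:
    """All strict local minima of the energy over the binary hypercube.

    Exhaustive for N <= 20 (basins computed up to N <= 16 by default);
    a state qualifies only if strictly lower than all N single-flip
    neighbours, so plateaus are never silently merged — a fully flat
    landscape reports zero minima with the ``flat`` flag.
    """
    n = params.n_components
    if n > _EXACT_N_MAX:
        raise ValueError(
            f"exact enumeration limited to N <= {_EXACT_N_MAX}; use "
            "multi-start descend() for larger systems")
    states = enumerate_states(n)
    e = np.asarray(energy(states, env, params))
    neigh = _neighbor_energies(e, n)
    is_min = (e[:, None] < neigh).all(axis=1)
    order = np.argsort(e[is_min], kind="stable")
    min_idx = np.flatnonzero(is_min)[order]
    minima = [(states[i].copy(), float(e[i])) for i in min_idx]
    flat = len(minima) == 0
    basin_of = None
    if compute_basins and not flat:
        nxt = _descent_pointers(e, neigh, n)
        reach = nxt.copy()
        # path doubling until every pointer is a fixed point
        while True:
            nxt2 = reach[reach]
            if np.array_equal(nxt2, reach):
                break
            reach = nxt2
        min_rank = np.full(e.size, -1, dtype=np.int64)
        min_rank[min_idx] = np.arange(len(min_idx))
        basin_of = min_rank[reach]
    return LandscapeSummary(env=(float(env[0]), float(env[1])),
                            minima=minima, basin_of=basin_of, flat=flat,
                            component_names=params.component_names)


def _descent_pointers(e: np.ndarray, neigh: np.ndarray, n: int
                      ) -> np.ndarray:
    """Steepest-descent successor of every state (itself at a minimum).

    Ties among equally low neighbours break toward the lowest component
    index; moves happen only on a strict energy decrease.
    """
    idx = np.arange(e.size, dtype=np.int64)
    best_bit = np.argmin(neigh, axis=1)           # first minimum = lowest bit
    best_e = neigh[idx, best_bit]
    nxt = np.where(best_e < e, idx ^ (1 << best_bit), idx)
    return nxt


def _state_to_index(state: np.ndarray) -> int:
    bits = np.asarray(state).astype(np.int64)
    return int((bits << np.arange(bits.size)).sum())


def descend(state: np.ndarray, params: MaxEntParams,
            env: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Steepest single-flip descent from ``state`` to its local minimum.

    Moves to the lowest-energy neighbour while strictly lower (ties break
    on the lowest component index); returns (final state, flat flag) — the
    flag is set when the start state had no strictly lower neighbour yet
    is not a strict minimum (a plateau / flat landscape).
    """
    s = np.asarray(state, dtype=float).copy()
    n = params.n_components
    e = float(energy(s, env, params))
    while True:
        flips = np.tile(s, (n, 1))
        flips[np.arange(n), np.arange(n)] = 1.0 - flips[np.arange(n),
                                                        np.arange(n)]
        ne = np.asarray(energy(flips, env, params))
        b = int(np.argmin(ne))
        if ne[b] < e:
            s = flips[b]
            e = float(ne[b])
        else:
            flat = bool((ne == e).any())
            return s, flat


def landscape_over_gradient(params: MaxEntParams,
                            eps_a_values: Sequence[float] = (0.0, 1.0),
                            eps_s_grid: Optional[Sequence[float]] = None,
                            compute_basins: bool = True
                            ) -> tuple[list[LandscapeSummary], pd.DataFrame]:
    """Stable states tracked across the treatment x growth-stage gradient.

    Returns the per-gridpoint summaries and a tidy surface table
    (eps_a, eps_s, minimum rank by energy, state bitstring, energy, basin
    size) suitable for plotting the landscape against the gradient.
    """
    if eps_s_grid is None:
        eps_s_grid = np.linspace(0.0, 1.0, 21)
    summaries: list[LandscapeSummary] = []
    rows = []
    for ea in eps_a_values:
        for es in eps_s_grid:
            summ = find_minima(params, (ea, es),
                               compute_basins=compute_basins)
            summaries.append(summ)
            sizes = summ.basin_sizes()
            if summ.flat:
                rows.append({"eps_a": ea, "eps_s": es, "rank": -1,
                             "state": "", "energy": np.nan,
                             "basin_size": 0, "flat": True})
            for k, (state, e) in enumerate(summ.minima):
                rows.append({
                    "eps_a": ea, "eps_s": es, "rank": k,
                    "state": "".join(str(int(b)) for b in state),
                    "energy": e,
                    "basin_size": int(sizes[k]) if sizes.size else 0,
                    "flat": False})
    return summaries, pd.DataFrame(rows)
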