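"""Brute-force LP oracle: vertex enumeration of the flux polytope.

Independent of the package's solver path: enumerates candidate vertices of
{v : S v = 0, lb <= v <= ub} by fixing subsets of fluxes at their bounds
and solving the resulting square linear systems, then takes the best
feasible vertex under the objective.  Because the box bounds make the
polytope bounded, the LP optimum is attained at a vertex, so for models
small enough to enumerate (<= ~15 reactions) this is an exact oracle.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> list[np.ndarray]:
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    k = n - rank
    vertices: list[np.ndarray] = []
    seen: set[tuple] = set()
    for subset in combinations(range(n), k):
        E = np.zeros((k, n))
        for row, j in enumerate(subset):
            E[row, j] = 1.0
        A = np.vstack([S, E]) if m else E
        if np.linalg.matrix_rank(A) < n:
            continue
        for pattern in product((0, 1), repeat=k):
            b = np.concatenate(
                [np.zeros(m),
                 [lb[j] if p == 0 else ub[j] for j, p in zip(subset, pattern)]]
            )
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b), initial=0.0) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            key = tuple(np.round(v, 7))
            if key not in seen:
                seen.add(key)
                vertices.append(np.clip(v, lb, ub))
    return vertices


def oracle_optimum(model, objective=None, sense: str = "max") -> float | None:
    """Exact LP optimum by vertex enumeration; None if infeasible."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    lb, ub = model.bounds_arrays()
    obj = objective if objective is not None else model.objective
    if isinstance(obj, str):
        obj = {obj: 1.0}
    c = np.array([obj.get(rid, 0.0) for rid in rxn_ids])
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    values = [float(c @ v) for v in vertices]
    return max(values) if sense == "max" else min(values)
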