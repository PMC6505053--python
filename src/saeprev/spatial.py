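"""Global spatial autocorrelation (Moran's I) over an area adjacency graph.

Used as the justification check for omitting a spatially structured random
effect from the hierarchical model: if area values show no significant
autocorrelation beyond the exchangeable intercepts, the simpler model
stands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = ["MoranResult", "morans_i", "adjacency_matrix"]


def adjacency_matrix(edges: pd.DataFrame | list[tuple[str, str]],
                     areas: list[str]) -> np.ndarray:
    """Symmetric binary 0/1 adjacency from an undirected edge list."""
    if isinstance(edges, pd.DataFrame):
        edges = list(zip(edges.iloc[:, 0], edges.iloc[:, 1]))
    pos = {a: i for i, a in enumerate(areas)}
    A = np.zeros((len(areas), len(areas)))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on area {a!r}")
        if a not in pos or b not in pos:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown area")
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1.0
    return A


class MoranResult(dict):
    """Mapping with keys I, expected_I, p_value, n_permutations."""

    __getattr__ = dict.__getitem__


def _moran_stat(z: np.ndarray, A: np.ndarray, W: float) -> float:
    n = z.size
    d = z - z.mean()
    return float(n / W * (d @ A @ d) / (d @ d))


def morans_i(values, adjacency: np.ndarray, n_permutations: int = 999,
             seed: int = 0, exact: bool = False) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    I = (n/W) * sum_ij a_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2,
    W = sum_ij a_ij. The p-value is the two-sided tail probability of |I -
    E[I]| under random relabeling of areas (the observed labeling counts as
    one permutation); E[I] = -1/(n-1) under no autocorrelation. With
    ``exact=True`` all n! relabelings are enumerated instead (small n only)
    and the p-value is the exact tail fraction.
    """
    z = np.asarray(values, dtype=float)
    A = np.asarray(adjacency, dtype=float)
    n = z.size
    if A.shape != (n, n):
        raise ValueError("adjacency shape does not match number of areas")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have no self-loops")
    W = A.sum()
    if W <= 0:
        raise ValueError("adjacency needs at least one edge")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I is undefined for constant values")

    I_obs = _moran_stat(z, A, W)
    e_I = -1.0 / (n - 1)
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 areas")
        from itertools import permutations

        stats = [_moran_stat(z[list(perm)], A, W)
                 for perm in permutations(range(n))]
        hits = sum(abs(s - e_I) >= abs(I_obs - e_I) - 1e-12 for s in stats)
        return MoranResult(I=I_obs, expected_I=e_I,
                           p_value=hits / len(stats),
                           n_permutations=len(stats))
    rng = substream(seed, "moran")
    extreme = 1  # the observed arrangement
    for _ in range(n_permutations):
        I_perm = _moran_stat(rng.permutation(z), A, W)
        if abs(I_perm - e_I) >= abs(I_obs - e_I) - 1e-12:
            extreme += 1
    return MoranResult(I=I_obs, expected_I=e_I,
                       p_value=extreme / (n_permutations + 1),
                       n_permutations=n_permutations)
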