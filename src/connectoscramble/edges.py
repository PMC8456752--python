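"""Edge indexing over the 116-node parcellation.

The package-wide convention for vectorizing a symmetric connectivity matrix
is the strict upper triangle in row-major order, 0-based: edge 0 is (0,1),
edge 1 is (0,2), ..., edge V-2 is (0,V-1), edge V-1 is (1,2), and so on.
For V=116 nodes this gives E = V(V-1)/2 = 6670 unique edges, the unique
values of each band of a wavelet correlation matrix.
"""

from __future__ import annotations

import numpy as np

N_NODES = 116
N_EDGES = N_NODES * (N_NODES - 1) // 2  # 6670


def edge_index(i: int, j: int, n_nodes: int = N_NODES) -> int:
    """Row-major upper-triangle index of the unordered pair (i, j)."""
    if i == j:
        raise ValueError("diagonal entries are not edges")
    if not (0 <= i < n_nodes and 0 <= j < n_nodes):
        raise ValueError(f"node out of range for V={n_nodes}: ({i}, {j})")
    if i > j:
        i, j = j, i
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def edge_pair(e: int, n_nodes: int = N_NODES) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: unordered pair (i, j), i < j."""
    if not 0 <= e < n_nodes * (n_nodes - 1) // 2:
        raise ValueError(f"edge index out of range: {e}")
    i = int(
        np.floor(
            (2 * n_nodes - 1 - np.sqrt((2 * n_nodes - 1) ** 2 - 8 * e)) / 2
        )
    )
    j = e - i * (2 * n_nodes - i - 1) // 2 + i + 1
    return i, j


def triu_rows_cols(n_nodes: int = N_NODES) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) arrays of all edges in package edge order."""
    return np.triu_indices(n_nodes, k=1)


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle of a (..., V, V) stack in edge order."""
    v = matrix.shape[-1]
    r, c = np.triu_indices(v, k=1)
    return matrix[..., r, c]


def unvectorize(values: np.ndarray, n_nodes: int = N_NODES,
                diagonal: float = 0.0) -> np.ndarray:
    """Write an edge vector (..., E) back into a symmetric (..., V, V) matrix."""
    e = n_nodes * (n_nodes - 1) // 2
    if values.shape[-1] != e:
        raise ValueError(f"expected {e} edge values, got {values.shape[-1]}")
    r, c = np.triu_indices(n_nodes, k=1)
    out = np.zeros(values.shape[:-1] + (n_nodes, n_nodes), dtype=values.dtype)
    out[..., r, c] = values
    out[..., c, r] = values
    idx = np.arange(n_nodes)
    out[..., idx, idx] = diagonal
    return out


def inner_edges(nodes, n_nodes: int = N_NODES) -> np.ndarray:
    """Edges with both endpoints in ``nodes``: n(n-1)/2 for n nodes.

    Returns a sorted array of edge indices in the package edge order.
    """
    nodes = sorted(set(int(v) for v in nodes))
    _check_nodes(nodes, n_nodes)
    out = [edge_index(a, b, n_nodes)
           for k, a in enumerate(nodes) for b in nodes[k + 1:]]
    return np.array(sorted(out), dtype=np.int64)


def connecting_edges(nodes, n_nodes: int = N_NODES) -> np.ndarray:
    """Edges with at least one endpoint in ``nodes``: n(V-1) - n(n-1)/2.

    Inner edges are included (they touch two member nodes).
    """
    nodes = set(int(v) for v in nodes)
    _check_nodes(nodes, n_nodes)
    r, c = np.triu_indices(n_nodes, k=1)
    member = np.isin(r, list(nodes)) | np.isin(c, list(nodes))
    return np.flatnonzero(member).astype(np.int64)


def edge_fraction(edge_set, n_edges: int = N_EDGES) -> float:
    """Percentage of all unique edges in ``edge_set``, rounded to 2 decimals."""
    edge_set = np.asarray(edge_set)
    if edge_set.size and (edge_set.min() < 0 or edge_set.max() >= n_edges):
        raise ValueError("edge set contains indices outside the edge range")
    return round(100.0 * len(np.unique(edge_set)) / n_edges, 2)


def _check_nodes(nodes, n_nodes: int) -> None:
    for v in nodes:
        if not 0 <= v < n_nodes:
            raise ValueError(f"node index {v} outside [0, {n_nodes})")
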