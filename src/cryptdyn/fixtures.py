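"""Seeded toy models and brute-force oracles.

Small randomly generated factor graphs let every assembly and solver
property be exercised without the full five-gene state space, against
independent references: the Cartesian-product adjacency built by explicit
vertex-pair enumeration (checks the Kronecker sum) and a dense
matrix-exponential solve (checks both solver routes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import ParameterError

#: default per-year rate range spanning the magnitudes of the real model
DEFAULT_RATE_RANGE = (1e-6, 1e-1)


@dataclass(frozen=True)
class ToyModel:
    """A list of random upper-triangular factor rate matrices."""

    seed: int
    factors: tuple[np.ndarray, ...]

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.dims))


def make_toy(
    seed: int,
    n_genes: int = 2,
    states_per_gene: int | tuple[int, ...] = 3,
    rate_range: tuple[float, float] = DEFAULT_RATE_RANGE,
    generator: bool = True,
) -> ToyModel:
    """Deterministically generate random upper-triangular factor graphs.

    Rates are drawn uniformly from ``rate_range`` on every
    strictly-upper-triangular entry.  With ``generator=True`` diagonals
    compensate the outgoing rates (zero row sums); otherwise diagonals are
    left at zero (pure adjacency).
    """
    if not 1 <= n_genes <= 4:
        raise ParameterError(f"n_genes must be in 1..4, got {n_genes}")
    dims = (
        (states_per_gene,) * n_genes
        if isinstance(states_per_gene, int)
        else tuple(states_per_gene)
    )
    if len(dims) != n_genes or any(not 2 <= d <= 4 for d in dims):
        raise ParameterError(f"states per gene must be in 2..4, got {dims}")
    lo, hi = rate_range
    if not 0 <= lo <= hi:
        raise ParameterError(f"invalid rate range {rate_range}")
    rng = np.random.default_rng(seed)
    factors = []
    for d in dims:
        mat = np.triu(rng.uniform(lo, hi, size=(d, d)), k=1)
        if generator:
            np.fill_diagonal(mat, -mat.sum(axis=1))
        factors.append(mat)
    return ToyModel(seed=seed, factors=tuple(factors))


def brute_force_product(model: ToyModel) -> np.ndarray:
    """Adjacency of the Cartesian graph product by explicit enumeration.

    Vertices are tuples of factor vertices; an edge connects tuples that
    differ in exactly one coordinate, with the factor's edge weight;
    diagonal entries add across factors.  Equals the Kronecker sum of the
    factors — used as its equality oracle.
    """
    if model.total_dim > 256:
        raise ParameterError(f"brute-force oracle limited to dim <= 256, got {model.total_dim}")
    dims = model.dims
    vertices = list(itertools.product(*(range(d) for d in dims)))
    flat = {v: i for i, v in enumerate(vertices)}
    out = np.zeros((model.total_dim, model.total_dim))
    for u in vertices:
        for k, fac in enumerate(model.factors):
            # diagonal: sum of factor diagonals
            out[flat[u], flat[u]] += fac[u[k], u[k]]
            for j in range(dims[k]):
                if j == u[k]:
                    continue
                w = fac[u[k], j]
                if w != 0.0:
                    v = u[:k] + (j,) + u[k + 1:]
                    out[flat[u], flat[v]] += w
    return out


def dense_reference_solve(model: ToyModel, x0: np.ndarray, t: float) -> np.ndarray:
    """Dense matrix-exponential reference solution on the product space."""
    if model.total_dim > 256:
        raise ParameterError("reference solve limited to dim <= 256")
    M = brute_force_product(model)
    return expm(t * M.T) @ np.asarray(x0, dtype=float)
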