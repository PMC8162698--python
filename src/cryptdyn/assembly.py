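"""Genotype state space and Kronecker assembly of the system matrix.

A genotype is a tuple of per-gene mutation statuses, one per modelled gene
in the fixed order MMR, CTNNB1, APC, KRAS, TP53.  The independent part of
the dynamics is the Kronecker sum of the per-gene rate matrices — the
adjacency matrix of the Cartesian product of the gene mutation graphs,
encoding one-gene-at-a-time transitions.  Mutational dependencies are
added as separate Kronecker-product matrices, each the product of a small
per-gene factor with 0/1 selector diagonals restricting the effect to the
triggering genotypes:

* ``B`` — point-mutation rate of APC raised by a factor beta after
  mismatch-repair deficiency;
* ``C`` — positive association of MLH1 and CTNNB1 alterations: a fraction
  ``r_effLOH`` of the MLH1 LOH flux is redirected into simultaneous
  MLH1+CTNNB1 LOH events;
* ``D`` — LOH rates of MMR, CTNNB1 and TP53 raised by a factor delta after
  APC inactivation;
* ``E`` — mutual enhancement of ``C`` and ``D`` (the redirection applied
  to the delta-boosted flux in APC-inactivated crypts);
* ``F`` — KRAS mutation rate raised by a factor zeta after
  mismatch-repair deficiency.

All matrices are upper triangular under the flat genotype index (mutations
are irreversible) and every dependency matrix has zero row sums: it reroutes
or accelerates flux but neither creates nor destroys crypts.  Fitness terms
live only on the diagonal of the independent component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError
from .genes import (
    GeneSpec,
    GlobalParams,
    MutationGraph,
    N_MUT,
    build_gene_graph,
    loh_rate,
    point_mutation_rate,
)

def _find_mmr(idx: "GenotypeIndex") -> GeneSpec | None:
    """The mismatch-repair gene of the index, if one is modelled."""
    for g in idx.genes:
        if g.role.startswith("mmr"):
            return g
    return None


@dataclass(frozen=True)
class GenotypeIndex:
    """Bijection between genotype tuples and flat matrix indices.

    Row-major with the first gene most significant, matching the order of
    the Kronecker factors: advancing any single gene in its canonical state
    order strictly increases the flat index.
    """

    genes: tuple[GeneSpec, ...]

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(g.n_states for g in self.genes)

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.dims))

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise ConfigurationError(f"no gene named {name!r} in index")

    def gene_position(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise ConfigurationError(f"no gene named {name!r} in index")

    def to_flat(self, genotype: tuple[str, ...]) -> int:
        if len(genotype) != len(self.genes):
            raise ConfigurationError(
                f"genotype has {len(genotype)} entries, expected {len(self.genes)}"
            )
        idx = 0
        for g, state in zip(self.genes, genotype):
            idx = idx * g.n_states + g.state_index(state)
        return idx

    def to_tuple(self, flat: int) -> tuple[str, ...]:
        states = []
        for g in reversed(self.genes):
            flat, r = divmod(flat, g.n_states)
            states.append(g.states[r])
        return tuple(reversed(states))

    def genotypes(self):
        """Iterate all genotype tuples in flat-index order."""
        return itertools.product(*(g.states for g in self.genes))

    def label(self, flat: int, sep: str = "|") -> str:
        return sep.join(
            f"{g.name}:{s}" for g, s in zip(self.genes, self.to_tuple(flat))
        )

    def state_mask(self, admissible: dict[str, set[str] | frozenset[str] | tuple[str, ...]]) -> np.ndarray:
        """Boolean mask over flat indices for genotypes whose per-gene state
        lies in the given admissible set (genes not listed: unrestricted)."""
        mask = np.ones(1, dtype=bool)
        for g in self.genes:
            if g.name in admissible:
                allowed = set(admissible[g.name])
                unknown = allowed - set(g.states)
                if unknown:
                    raise ConfigurationError(
                        f"{g.name}: admissible states {sorted(unknown)} not in state set"
                    )
                gene_mask = np.array([s in allowed for s in g.states])
            else:
                gene_mask = np.ones(g.n_states, dtype=bool)
            mask = np.kron(mask, gene_mask) if mask.size else gene_mask
        return mask


def kronecker_sum(matrices: list) -> sp.csr_matrix:
    """Kronecker sum ``A1 (+) A2 (+) ... (+) An = sum_i I x..x Ai x..x I``.

    This is the adjacency matrix of the Cartesian product of the factor
    graphs; its dimension is the product of the factor dimensions.
    """
    if not matrices:
        raise ValueError("kronecker_sum requires at least one matrix")
    mats = [sp.csr_matrix(np.asarray(m) if not sp.issparse(m) else m) for m in matrices]
    for m in mats:
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"kronecker_sum factor is not square: {m.shape}")
    total = None
    n = len(mats)
    for i, mi in enumerate(mats):
        term = sp.identity(1, format="csr")
        for j in range(n):
            factor = mi if j == i else sp.identity(mats[j].shape[0], format="csr")
            term = sp.kron(term, factor, format="csr")
        total = term if total is None else total + term
    return total.tocsr()


def _kron_chain(factors: list) -> sp.csr_matrix:
    out = sp.identity(1, format="csr")
    for f in factors:
        f = f if sp.issparse(f) else sp.csr_matrix(np.asarray(f))
        out = sp.kron(out, f, format="csr")
    return out.tocsr()


def _selector(gene: GeneSpec, states: tuple[str, ...]) -> sp.csr_matrix:
    """0/1 diagonal selecting the given states of a gene."""
    d = np.array([1.0 if s in states else 0.0 for s in gene.states])
    return sp.diags(d, format="csr")


def _zero_rowsum_edges(gene: GeneSpec, edges: list[tuple[str, str, float]]) -> sp.csr_matrix:
    """Small factor matrix with the given directed edges and a compensating
    diagonal so every row sums to zero."""
    n = gene.n_states
    mat = np.zeros((n, n))
    for src, dst, w in edges:
        mat[gene.state_index(src), gene.state_index(dst)] += w
    np.fill_diagonal(mat, np.diag(mat) - mat.sum(axis=1))
    return sp.csr_matrix(mat)


@dataclass(frozen=True)
class DependencyParams:
    """Strengths of the modelled mutational dependencies.

    ``beta``: fold-increase of the APC point-mutation rate under MMR
    deficiency; ``delta``: fold-increase of LOH rates after APC
    inactivation; ``zeta``: fold-increase of the KRAS mutation rate under
    MMR deficiency; ``r_eff_loh``: fraction of the MLH1 LOH flux redirected
    into simultaneous CTNNB1 LOH (the MLH1-CTNNB1 association).
    """

    beta: float = 1e3
    delta: float = 1e2
    zeta: float = 1e2
    r_eff_loh: float = 0.9

    def __post_init__(self) -> None:
        for name in ("beta", "delta", "zeta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v!r}")
        if not 0.0 <= self.r_eff_loh <= 1.0:
            raise ConfigurationError(f"r_eff_loh must lie in [0, 1], got {self.r_eff_loh!r}")


def build_A(graphs: list[MutationGraph], idx: GenotypeIndex) -> sp.csr_matrix:
    """Independent component: Kronecker sum of the per-gene rate matrices."""
    if tuple(g.gene.name for g in graphs) != idx.gene_names:
        raise ConfigurationError(
            f"graph order {[g.gene.name for g in graphs]} does not match index {idx.gene_names}"
        )
    return kronecker_sum([g.rate_matrix for g in graphs])


def _mmr_deficient_selector(gene: GeneSpec) -> sp.csr_matrix:
    return _selector(gene, tuple(s for s in ("mm", "ml", "ll") if s in gene.states))


def _gated_product(
    idx: GenotypeIndex,
    factors: dict[str, sp.csr_matrix],
) -> sp.csr_matrix:
    """Kronecker product with the given per-gene factors, identity elsewhere."""
    return _kron_chain([
        factors.get(g.name, sp.identity(g.n_states)) for g in idx.genes
    ])


def build_B(idx: GenotypeIndex, params: DependencyParams, g: GlobalParams) -> sp.csr_matrix:
    """APC point-mutation edges scaled by beta, gated on MMR deficiency."""
    mmr = _find_mmr(idx)
    if mmr is None:
        return sp.csr_matrix((idx.total_dim, idx.total_dim))
    apc = idx.gene("APC")
    edges = [
        (src, dst, params.beta * point_mutation_rate(apc, N_MUT[src], g))
        for src, dst in (("0", "m"), ("m", "mm"), ("l", "ml"))
    ]
    return _gated_product(idx, {
        mmr.name: _mmr_deficient_selector(mmr),
        "APC": _zero_rowsum_edges(apc, edges),
    })


def _mlh1_ctnnb1_pair_edges(
    mmr: GeneSpec, ctnnb1: GeneSpec, weight: float
) -> list[tuple[tuple[str, str], tuple[str, str], float]]:
    """The eight-edge redirection pattern on MMR x CTNNB1 state pairs.

    For each MLH1 LOH-gaining transition (m->ml, l->ll) with CTNNB1 in a
    state that can still gain an LOH (0 or m), a weight ``-w`` is placed on
    the plain transition and ``+w`` on the simultaneous transition whose
    CTNNB1 state also advances by one LOH — redirecting, not creating, flux.
    """
    if "ll" not in mmr.states:
        raise ConfigurationError(
            f"{mmr.name} lacks state 'll'; the MLH1-CTNNB1 association needs the full LOH ladder"
        )
    edges = []
    for mmr_src, mmr_dst in (("m", "ml"), ("l", "ll")):
        for ct_src, ct_dst in (("0", "l"), ("m", "ml")):
            edges.append(((mmr_src, ct_src), (mmr_dst, ct_src), -weight))
            edges.append(((mmr_src, ct_src), (mmr_dst, ct_dst), +weight))
    return edges


def _pair_matrix(
    mmr: GeneSpec,
    ctnnb1: GeneSpec,
    edges: list[tuple[tuple[str, str], tuple[str, str], float]],
) -> sp.csr_matrix:
    n = mmr.n_states * ctnnb1.n_states
    mat = sp.lil_matrix((n, n))
    for (s_mmr, s_ct), (d_mmr, d_ct), w in edges:
        src = mmr.state_index(s_mmr) * ctnnb1.n_states + ctnnb1.state_index(s_ct)
        dst = mmr.state_index(d_mmr) * ctnnb1.n_states + ctnnb1.state_index(d_ct)
        mat[src, dst] += w
    return mat.tocsr()


def _pair_product(
    idx: GenotypeIndex, pair: sp.csr_matrix, factors: dict[str, sp.csr_matrix]
) -> sp.csr_matrix:
    """Kronecker product with a combined factor over the leading MMR x
    CTNNB1 block (possible because those genes lead the canonical order)."""
    if idx.gene_names[:2] != (idx.genes[0].name, "CTNNB1"):
        raise ConfigurationError("MMR and CTNNB1 must be the two leading genes")
    rest = [factors.get(g.name, sp.identity(g.n_states)) for g in idx.genes[2:]]
    return _kron_chain([pair, *rest])


def build_C(
    idx: GenotypeIndex, params: DependencyParams, g: GlobalParams, mmr_gene: str = "MLH1"
) -> sp.csr_matrix:
    """MLH1-CTNNB1 positive association (zero unless the MMR gene is MLH1)."""
    mmr = _find_mmr(idx)
    if mmr is None or mmr.name != mmr_gene or mmr_gene != "MLH1":
        return sp.csr_matrix((idx.total_dim, idx.total_dim))
    ctnnb1 = idx.gene("CTNNB1")
    w = params.r_eff_loh * loh_rate(mmr, 1, g)  # p_LOH(MLH1)/2
    pair = _pair_matrix(mmr, ctnnb1, _mlh1_ctnnb1_pair_edges(mmr, ctnnb1, w))
    return _pair_product(idx, pair, {})


def _loh_edge_list(gene: GeneSpec, scale: float, g: GlobalParams) -> list[tuple[str, str, float]]:
    edges = []
    for src, dst in (("0", "l"), ("m", "ml"), ("l", "ll")):
        if src in gene.states and dst in gene.states and gene.n_bp is not None:
            edges.append((src, dst, scale * loh_rate(gene, N_MUT[src], g)))
    return edges


def build_D(idx: GenotypeIndex, params: DependencyParams, g: GlobalParams) -> sp.csr_matrix:
    """LOH rates of MMR, CTNNB1 and TP53 scaled by delta in APC-inactivated
    crypts; one Kronecker term per affected gene, summed."""
    apc_pos = idx.gene_position("APC")
    apc_sel = _selector(idx.genes[apc_pos], ("mm", "ml"))
    total = sp.csr_matrix((idx.total_dim, idx.total_dim))
    for name in ("MMR", "CTNNB1", "TP53"):
        if name == "MMR":
            target = next((gn for gn in idx.genes if gn.role.startswith("mmr")), None)
            if target is None:
                continue
        else:
            target = idx.gene(name)
        edges = _loh_edge_list(target, params.delta, g)
        if not edges:
            continue
        d_target = _zero_rowsum_edges(target, edges)
        factors = []
        for i, gn in enumerate(idx.genes):
            if gn.name == target.name:
                factors.append(d_target)
            elif i == apc_pos:
                factors.append(apc_sel)
            else:
                factors.append(sp.identity(gn.n_states))
        total = total + _kron_chain(factors)
    return total


def build_E(
    idx: GenotypeIndex, params: DependencyParams, g: GlobalParams, mmr_gene: str = "MLH1"
) -> sp.csr_matrix:
    """Mutual enhancement of the MLH1-CTNNB1 association and the
    APC-triggered LOH boost: the same eight-edge redirection with magnitude
    ``delta * r_effLOH * p_LOH(MLH1)/2``, gated on APC inactivation."""
    mmr = _find_mmr(idx)
    if mmr is None or mmr.name != mmr_gene or mmr_gene != "MLH1":
        return sp.csr_matrix((idx.total_dim, idx.total_dim))
    ctnnb1 = idx.gene("CTNNB1")
    w = params.delta * params.r_eff_loh * loh_rate(mmr, 1, g)
    pair = _pair_matrix(mmr, ctnnb1, _mlh1_ctnnb1_pair_edges(mmr, ctnnb1, w))
    return _pair_product(idx, pair, {"APC": _selector(idx.gene("APC"), ("mm", "ml"))})


def build_F(idx: GenotypeIndex, params: DependencyParams, g: GlobalParams) -> sp.csr_matrix:
    """KRAS activation edge scaled by zeta, gated on MMR deficiency."""
    mmr = _find_mmr(idx)
    if mmr is None:
        return sp.csr_matrix((idx.total_dim, idx.total_dim))
    kras = idx.gene("KRAS")
    f_kras = _zero_rowsum_edges(
        kras, [("0", "m", params.zeta * point_mutation_rate(kras, 0, g))]
    )
    return _gated_product(idx, {
        mmr.name: _mmr_deficient_selector(mmr),
        "KRAS": f_kras,
    })


@dataclass
class SystemMatrix:
    """The assembled genotype-level rate matrices and their sum ``M``."""

    index: GenotypeIndex
    A: sp.csr_matrix
    B: sp.csr_matrix
    C: sp.csr_matrix
    D: sp.csr_matrix
    E: sp.csr_matrix
    F: sp.csr_matrix

    @property
    def M(self) -> sp.csr_matrix:
        return (self.A + self.B + self.C + self.D + self.E + self.F).tocsr()

    def component(self, name: str) -> sp.csr_matrix:
        if name == "M":
            return self.M
        if name in "ABCDEF":
            return getattr(self, name)
        raise ConfigurationError(f"unknown component {name!r}; expected one of A-F or M")


def assemble(
    genes: list[GeneSpec],
    g: GlobalParams,
    params: DependencyParams | None = None,
    active: frozenset[str] | set[str] = frozenset("BCDEF"),
    mmr_gene: str = "MLH1",
) -> SystemMatrix:
    """Build the full system matrix from gene specifications.

    ``active`` names the dependency components to include; inactive ones
    are stored as zero matrices so the decomposition is always complete.
    """
    params = params or DependencyParams()
    idx = GenotypeIndex(genes=tuple(genes))
    graphs = [build_gene_graph(gn, g) for gn in genes]
    zero = sp.csr_matrix((idx.total_dim, idx.total_dim))
    A = build_A(graphs, idx)
    B = build_B(idx, params, g) if "B" in active else zero
    C = build_C(idx, params, g, mmr_gene) if "C" in active else zero
    D = build_D(idx, params, g) if "D" in active else zero
    E = build_E(idx, params, g, mmr_gene) if "E" in active else zero
    F = build_F(idx, params, g) if "F" in active else zero
    return SystemMatrix(index=idx, A=A, B=B, C=C, D=D, E=E, F=F)
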