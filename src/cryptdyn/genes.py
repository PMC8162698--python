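"""Driver genes, their mutation-status state sets and per-year event rates.

Each modelled gene carries a small set of mutation statuses describing how
many of its two alleles have been hit and by which mechanism:

``0`` (wild-type), ``m`` (one allele point-mutated), ``l`` (one allele lost
by LOH), ``mm``, ``ml``, ``ll`` (both alleles hit).  Which subset of these
states a gene uses depends on its functional role:

* mismatch-repair genes (MLH1, MSH2) in a hereditary (Lynch) context start
  from a monoallelic germline hit, so the wild-type state is absent;
* classical tumour suppressors (APC, TP53) and the biallelically acting
  oncogene CTNNB1 need two hits for inactivation but lose the ``ll`` state,
  because homozygous deletion of these genes kills the cell before a crypt
  can fix it;
* the oncogene KRAS is activated by a single point mutation and has just
  the two states ``0`` and ``m``.

Transitions between statuses happen at per-year, per-crypt rates combining
the replication point-mutation load, the gene's hotspot and total length,
and a gene-specific fixation affinity (the tendency of a single mutant cell
to take over, i.e. monoclonally convert, its crypt).  A gene's rate matrix
is a continuous-time generator over its states, optionally carrying a
fitness self-loop (clonal expansion or disadvantage) on the functionally
altered states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ConfigurationError, ParameterError

# Canonical ordering of mutation statuses.  Every transition moves from an
# earlier to a later state, so all gene rate matrices are upper triangular.
STATE_ORDER: tuple[str, ...] = ("0", "m", "l", "mm", "ml", "ll")

#: number of already-hit alleles per mutation status
N_MUT: dict[str, int] = {"0": 0, "m": 1, "l": 1, "mm": 2, "ml": 2, "ll": 2}

#: states per functional role (Lynch context for MMR: no wild-type state)
ROLE_STATES: dict[str, tuple[str, ...]] = {
    "mmr": ("m", "l", "mm", "ml", "ll"),
    "mmr_sporadic": ("0", "m", "l", "mm", "ml", "ll"),
    "tumor_suppressor": ("0", "m", "l", "mm", "ml"),
    "biallelic_oncogene": ("0", "m", "l", "mm", "ml"),
    "oncogene": ("0", "m"),
}

#: functionally altered states per role (where the fitness term attaches)
ROLE_ALTERED: dict[str, tuple[str, ...]] = {
    "mmr": ("mm", "ml", "ll"),
    "mmr_sporadic": ("mm", "ml", "ll"),
    "tumor_suppressor": ("mm", "ml"),
    "biallelic_oncogene": ("mm", "ml"),
    "oncogene": ("m",),
}

DAYS_PER_YEAR = 365.0


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v) or v <= 0:
            raise ParameterError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass
class GlobalParams:
    """Organism- and genome-level constants shared by all genes.

    Parameters
    ----------
    n_pt
        Point mutations accumulated per cell division (one division/day).
    n_cells
        Dividing cells per colonic crypt.
    n_bp_genome
        Genome length in base pairs.
    n_crypts
        Number of crypts in the colon.
    alpha
        Per-base-pair LOH proportionality constant; ``None`` until
        calibrated with :func:`calibrate_alpha`.
    """

    n_pt: float = 1.2
    n_cells: float = 1.5e3
    n_bp_genome: float = 3.2e9
    n_crypts: float = 9.95e6
    days_per_year: float = DAYS_PER_YEAR
    alpha: float | None = None

    def __post_init__(self) -> None:
        _check_positive(
            n_pt=self.n_pt,
            n_cells=self.n_cells,
            n_bp_genome=self.n_bp_genome,
            n_crypts=self.n_crypts,
            days_per_year=self.days_per_year,
        )
        if self.alpha is not None and (not math.isfinite(self.alpha) or self.alpha < 0):
            raise ParameterError(f"alpha must be nonnegative and finite, got {self.alpha!r}")


@dataclass(frozen=True)
class GeneSpec:
    """One gene's identity, role, state set and rate parameters.

    ``n_hs`` is the hotspot length in bp (positions where a point mutation
    yields the driver phenotype), ``n_bp`` the total gene length in bp used
    for LOH susceptibility (``None`` for genes without an LOH channel),
    ``f`` the fixation affinity and ``b_altered`` the per-year fitness term
    attached to the functionally altered states.
    """

    name: str
    role: str
    n_hs: float
    n_bp: float | None = None
    f: float = 1.0
    b_altered: float = 0.0
    states: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.role not in ROLE_STATES:
            raise ConfigurationError(
                f"unknown role {self.role!r}; expected one of {sorted(ROLE_STATES)}"
            )
        if not self.states:
            object.__setattr__(self, "states", ROLE_STATES[self.role])
        order = [STATE_ORDER.index(s) for s in self.states]
        if order != sorted(order):
            raise ConfigurationError(f"states of {self.name} not in canonical order: {self.states}")
        _check_positive(n_hs=self.n_hs, f=self.f)
        if self.n_bp is not None:
            _check_positive(n_bp=self.n_bp)
            if self.n_hs > self.n_bp:
                raise ConfigurationError(
                    f"{self.name}: hotspot length {self.n_hs} exceeds gene length {self.n_bp}"
                )
        if not math.isfinite(self.b_altered):
            raise ParameterError(f"{self.name}: non-finite fitness term")

    @property
    def altered_states(self) -> tuple[str, ...]:
        """States in which the gene is functionally altered (deficient,
        inactivated or activated, depending on the role)."""
        return tuple(s for s in ROLE_ALTERED[self.role] if s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ConfigurationError(f"{self.name} has no state {state!r}") from None

    def with_overrides(self, **kwargs) -> "GeneSpec":
        if "role" in kwargs and "states" not in kwargs:
            kwargs["states"] = ()  # re-derive states from the new role
        return replace(self, **kwargs)


def point_mutation_rate(gene: GeneSpec, n_mut: int, g: GlobalParams) -> float:
    """Per-year rate of a crypt fixing a driver point mutation in *gene*.

    The rate is the daily point-mutation load of the crypt's dividing cells,
    restricted to the gene's hotspot positions, scaled by the fixation
    affinity, with an allele-availability factor ``1 - n_mut/2``: a gene
    with one allele already hit has half the target, with both hit none.
    """
    if n_mut not in (0, 1, 2):
        raise ParameterError(f"n_mut must be 0, 1 or 2, got {n_mut!r}")
    return (
        g.days_per_year
        * g.n_pt
        * g.n_cells
        * (gene.n_hs / g.n_bp_genome)
        * gene.f
        * (1.0 - n_mut / 2.0)
    )


def loh_rate(gene: GeneSpec, n_mut: int, g: GlobalParams) -> float:
    """Per-year rate of a crypt fixing a loss-of-heterozygosity event.

    Any LOH event overlapping the gene inactivates it, so the rate is
    proportional to the full gene length via the calibrated per-bp constant
    ``alpha`` (see :func:`calibrate_alpha`), with the same allele and
    fixation factors as the point-mutation rate.
    """
    if n_mut not in (0, 1, 2):
        raise ParameterError(f"n_mut must be 0, 1 or 2, got {n_mut!r}")
    if g.alpha is None:
        raise CalibrationError("alpha is unset; call calibrate_alpha first")
    if gene.n_bp is None:
        raise ConfigurationError(f"{gene.name} has no gene length; no LOH channel")
    return (
        g.days_per_year
        * g.n_cells
        * (1.0 - n_mut / 2.0)
        * g.alpha
        * gene.n_bp
        * gene.f
    )


def calibrate_alpha(g: GlobalParams, mlh1: GeneSpec) -> float:
    """Fix the per-bp LOH constant so that MLH1 inactivation by LOH is
    exactly twice as likely as by point mutation.

    Solving ``p_LOH(MLH1) = 2 p_pt(MLH1)`` for alpha gives

    ``alpha = 2 n_hs(MLH1) n_pt / (n_bp(MLH1) n_bp_genome)``,

    which is gene-independent and is applied to all genes thereafter.
    """
    if mlh1.n_bp is None or mlh1.n_bp == 0:
        raise ParameterError("MLH1 gene length required for calibration")
    return 2.0 * mlh1.n_hs * g.n_pt / (mlh1.n_bp * g.n_bp_genome)


@dataclass(frozen=True)
class MutationGraph:
    """A single gene's rate matrix over its mutation statuses.

    Off-diagonal entries are per-year transition rates from earlier to
    later states (upper triangular under the canonical order).  Diagonal
    entries follow the generator convention: fitness term of the state
    minus the total outgoing rate, so with all fitness terms zero every
    row sums to zero and crypt mass is conserved.
    """

    gene: GeneSpec
    rate_matrix: np.ndarray

    @property
    def states(self) -> tuple[str, ...]:
        return self.gene.states

    def rate(self, src: str, dst: str) -> float:
        return float(self.rate_matrix[self.gene.state_index(src), self.gene.state_index(dst)])


#: allowed transitions (src, dst, mechanism); mechanism selects the rate law
_TRANSITIONS: tuple[tuple[str, str, str], ...] = (
    ("0", "m", "pt"),
    ("0", "l", "loh"),
    ("m", "mm", "pt"),
    ("m", "ml", "loh"),
    ("l", "ml", "pt"),
    ("l", "ll", "loh"),
)


def gene_edges(gene: GeneSpec, g: GlobalParams) -> list[tuple[str, str, str, float]]:
    """List the gene's transitions as ``(src, dst, mechanism, rate)``.

    Only transitions whose endpoints are both in the gene's state set are
    produced; genes without a length (KRAS) have no LOH transitions.
    """
    edges = []
    for src, dst, mech in _TRANSITIONS:
        if src not in gene.states or dst not in gene.states:
            continue
        if mech == "loh":
            if gene.n_bp is None:
                continue
            rate = loh_rate(gene, N_MUT[src], g)
        else:
            rate = point_mutation_rate(gene, N_MUT[src], g)
        edges.append((src, dst, mech, rate))
    return edges


def build_gene_graph(gene: GeneSpec, g: GlobalParams) -> MutationGraph:
    """Assemble the gene's generator-plus-fitness rate matrix."""
    n = gene.n_states
    mat = np.zeros((n, n))
    for src, dst, _mech, rate in gene_edges(gene, g):
        mat[gene.state_index(src), gene.state_index(dst)] += rate
    altered = set(gene.altered_states)
    for i, s in enumerate(gene.states):
        out = mat[i].sum() - mat[i, i]
        b = gene.b_altered if s in altered else 0.0
        mat[i, i] = b - out
    return MutationGraph(gene=gene, rate_matrix=mat)


def default_gene_specs() -> dict[str, GeneSpec]:
    """Published hotspot counts, gene lengths, fixation affinities and
    fitness terms for the five modelled driver genes (plus MSH2 as an
    alternative mismatch-repair gene)."""
    return {
        "MLH1": GeneSpec("MLH1", "mmr", n_hs=2270, n_bp=57_500, f=2.3e-6, b_altered=-0.01),
        "MSH2": GeneSpec("MSH2", "mmr", n_hs=2800, n_bp=80_000, f=2.3e-6, b_altered=-0.01),
        "CTNNB1": GeneSpec(
            "CTNNB1", "biallelic_oncogene", n_hs=5, n_bp=41_000, f=1.2e-3, b_altered=0.0
        ),
        "APC": GeneSpec(
            "APC", "tumor_suppressor", n_hs=2400, n_bp=139_000, f=8.3e-7, b_altered=0.10
        ),
        "KRAS": GeneSpec("KRAS", "oncogene", n_hs=7, n_bp=None, f=2.5e-8, b_altered=0.01),
        "TP53": GeneSpec(
            "TP53", "tumor_suppressor", n_hs=1180, n_bp=19_200, f=1.2e-5, b_altered=0.0
        ),
    }


def default_global_params(calibrate: bool = True) -> GlobalParams:
    """Default genome/crypt constants, with alpha calibrated against MLH1."""
    g = GlobalParams()
    if calibrate:
        g.alpha = calibrate_alpha(g, default_gene_specs()["MLH1"])
    return g
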