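"""Scenario presets: Lynch syndrome, Lynch-like, sporadic MSI, MSS, FAP.

A scenario fixes which genes are modelled (in particular whether a
mismatch-repair gene is included and whether it starts from a germline
hit), the initial genotype of all crypts, and which dependency components
are active:

* ``lynch-mlh1`` / ``lynch-msh2`` — hereditary monoallelic MMR variant;
  every crypt starts with one MMR allele point-mutated (``m``).  The
  ``-loh`` variant starts from a germline LOH (``l``) instead, covering
  the minority of carriers whose first hit is a deletion.
* ``lynch-like`` / ``sporadic-msi`` — same genotype space as Lynch but
  with a wild-type MMR state; all crypts start fully wild-type.
* ``mss`` / ``sporadic-apc`` — microsatellite-stable carcinogenesis: the
  MMR factor is dropped entirely (250 genotypes) and only the
  APC-triggered LOH boost remains active.
* ``fap`` — germline APC point mutation; the APC hotspot count is reduced
  to the classical germline mutation cluster region (600 bp).

The MLH1-CTNNB1 association components (C, E) are active only when the
modelled MMR gene is MLH1; for MSH2 they are structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import DependencyParams, GenotypeIndex, SystemMatrix, assemble
from .errors import ConfigurationError
from .genes import (
    GeneSpec,
    GlobalParams,
    calibrate_alpha,
    default_gene_specs,
)

#: canonical gene order for the five-gene model
CANONICAL_ORDER = ("MMR", "CTNNB1", "APC", "KRAS", "TP53")

PRESET_NAMES = (
    "lynch-mlh1",
    "lynch-mlh1-loh",
    "lynch-msh2",
    "lynch-like",
    "sporadic-msi",
    "mss",
    "fap",
    "sporadic-apc",
)


@dataclass
class ScenarioConfig:
    """A fully resolved model configuration.

    ``germline`` maps gene name to the mutation status every crypt carries
    at birth; genes not listed start wild-type (or, for a Lynch-context MMR
    gene, cannot be omitted since wild-type is absent from its state set).
    """

    scenario: str
    genes: tuple[GeneSpec, ...]
    global_params: GlobalParams
    dependency_params: DependencyParams = field(default_factory=DependencyParams)
    active_dependencies: frozenset[str] = frozenset("BCDEF")
    germline: dict[str, str] = field(default_factory=dict)
    mmr_gene: str | None = None

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise ConfigurationError(f"no gene named {name!r} in scenario {self.scenario!r}")

    def with_overrides(
        self,
        global_params: dict | None = None,
        dependency_params: dict | None = None,
        gene_overrides: dict[str, dict] | None = None,
    ) -> "ScenarioConfig":
        """New config with numeric parameters replaced, alpha re-calibrated."""
        g = replace(self.global_params, **(global_params or {}))
        dep = replace(self.dependency_params, **(dependency_params or {}))
        genes = tuple(
            gn.with_overrides(**gene_overrides[gn.name])
            if gene_overrides and gn.name in gene_overrides
            else gn
            for gn in self.genes
        )
        if global_params is None or "alpha" not in global_params:
            # alpha is pinned to MLH1 (scenario's own spec if present)
            mlh1 = next(
                (gn for gn in genes if gn.name == "MLH1"), default_gene_specs()["MLH1"]
            )
            g.alpha = calibrate_alpha(g, mlh1)
        return replace(
            self, genes=genes, global_params=g, dependency_params=dep
        )


def preset(name: str, b_zero: bool = False) -> ScenarioConfig:
    """Construct a named scenario with published default parameters.

    ``b_zero`` zeroes all fitness terms (useful for conservation checks).
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown scenario {name!r}; expected one of {PRESET_NAMES}")
    specs = default_gene_specs()
    g = GlobalParams()
    g.alpha = calibrate_alpha(g, specs["MLH1"])
    dep = DependencyParams()

    mmr_gene: str | None = "MLH1"
    germline: dict[str, str] = {}
    active = set("BCDEF")

    if name in ("lynch-mlh1", "lynch-mlh1-loh", "lynch-msh2"):
        mmr_name = "MSH2" if name == "lynch-msh2" else "MLH1"
        mmr_gene = mmr_name
        mmr = specs[mmr_name]  # Lynch context: no wild-type MMR state
        germline[mmr_name] = "l" if name.endswith("-loh") else "m"
    elif name in ("lynch-like", "sporadic-msi"):
        mmr = specs["MLH1"].with_overrides(role="mmr_sporadic")
    elif name in ("mss", "sporadic-apc"):
        mmr = None
        mmr_gene = None
        active = {"D"}  # only the APC-triggered LOH boost applies without MMR
    elif name == "fap":
        mmr = specs["MLH1"].with_overrides(role="mmr_sporadic")
        germline["APC"] = "m"
        specs["APC"] = specs["APC"].with_overrides(n_hs=600)
    else:  # pragma: no cover
        raise AssertionError(name)

    order = [mmr] if mmr is not None else []
    order += [specs["CTNNB1"], specs["APC"], specs["KRAS"], specs["TP53"]]
    if b_zero:
        order = [gn.with_overrides(b_altered=0.0) for gn in order]
    return ScenarioConfig(
        scenario=name,
        genes=tuple(order),
        global_params=g,
        dependency_params=dep,
        active_dependencies=frozenset(active),
        germline=germline,
        mmr_gene=mmr_gene,
    )


def initial_state(config: ScenarioConfig, idx: GenotypeIndex) -> np.ndarray:
    """All crypts concentrated on the scenario's germline genotype."""
    genotype = []
    for gene in idx.genes:
        state = config.germline.get(gene.name)
        if state is None:
            if "0" not in gene.states:
                raise ConfigurationError(
                    f"{gene.name} has no wild-type state; a germline status is required"
                )
            state = "0"
        if state not in gene.states:
            raise ConfigurationError(
                f"germline state {state!r} not in state set of {gene.name}"
            )
        genotype.append(state)
    x0 = np.zeros(idx.total_dim)
    x0[idx.to_flat(tuple(genotype))] = config.global_params.n_crypts
    return x0


def build_system_matrix(config: ScenarioConfig) -> SystemMatrix:
    """Assemble A..F and their sum for a scenario configuration."""
    return assemble(
        list(config.genes),
        config.global_params,
        config.dependency_params,
        active=config.active_dependencies,
        mmr_gene=config.mmr_gene or "",
    )


def simulate(config: ScenarioConfig, ages: np.ndarray | None = None):
    """Build the system matrix, form the initial vector and solve.

    Returns a :class:`~cryptdyn.solver.Trajectory` over the default
    0..70-year grid unless ``ages`` is given.
    """
    from .solver import solve  # local import to keep module layering acyclic

    system = build_system_matrix(config)
    x0 = initial_state(config, system.index)
    return solve(system, x0, ages)
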