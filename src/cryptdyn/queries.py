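"""Aggregation of trajectories into named genotype classes.

The clinically meaningful readouts of the model are sums of crypt counts
over genotype classes: mismatch-repair-deficient crypt foci (the earliest
detectable precursor lesions), early/late adenomatous states and the
cancerous state of the three-strikes reading of colorectal carcinogenesis,
and the split of each adenoma-carcinoma stage into MMR-deficient versus
MMR-proficient crypts, which estimates how often MMR deficiency came first
among the competing pathways.

"Intact" is interpreted functionally by default: a tumour suppressor is
intact unless both alleles are hit, KRAS is intact only in its wild-type
state.  A strict interpretation (intact = exactly wild-type) is available
via ``strict=True`` where relevant.  Wnt alteration is by default the
union of APC inactivation and CTNNB1 activation; ``wnt="and"`` requires
both, ``wnt="apc"``/``wnt="ctnnb1"`` isolate one driver's share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, QueryError
from .solver import Trajectory

#: biallelically hit states (gene functionally altered for two-hit genes)
BIALLELIC = ("mm", "ml")
#: MMR-deficient statuses
MMR_DEFICIENT = ("mm", "ml", "ll")


@dataclass(frozen=True)
class NamedStateQuery:
    """A genotype-class predicate as per-gene admissible state sets.

    ``clauses`` is a tuple of alternatives (logical OR); each clause maps
    gene name to the admissible states of that gene (logical AND over
    genes, genes not listed unrestricted).
    """

    name: str
    clauses: tuple[dict[str, tuple[str, ...]], ...]

    def mask(self, traj: Trajectory) -> np.ndarray:
        idx = traj.index
        mask = np.zeros(idx.total_dim, dtype=bool)
        for clause in self.clauses:
            missing = set(clause) - set(idx.gene_names)
            if missing:
                raise QueryError(f"query {self.name!r} references unknown genes {sorted(missing)}")
            mask |= idx.state_mask(clause)
        return mask


def _mmr_name(traj: Trajectory) -> str | None:
    for g in traj.index.genes:
        if g.role.startswith("mmr"):
            return g.name
    return None


def _present(traj: Trajectory, gene: str, states: tuple[str, ...]) -> tuple[str, ...]:
    gene_states = traj.index.gene(gene).states
    return tuple(s for s in states if s in gene_states)


def _wnt_clauses(wnt: str) -> list[dict[str, tuple[str, ...]]]:
    apc = {"APC": BIALLELIC}
    ctnnb1 = {"CTNNB1": BIALLELIC}
    if wnt == "or":
        return [apc, ctnnb1]
    if wnt == "and":
        return [{**apc, **ctnnb1}]
    if wnt == "apc":
        return [apc]
    if wnt == "ctnnb1":
        return [ctnnb1]
    raise QueryError(f"unknown Wnt interpretation {wnt!r}")


def builtin_query(
    name: str, traj: Trajectory, strict: bool = False, wnt: str = "or"
) -> NamedStateQuery:
    """Construct one of the named genotype classes for a trajectory.

    ``mmr_deficient_foci``: MMR biallelically inactivated, all other genes
    wild-type.  ``state1``/``state2``/``state3``: Wnt-altered crypts with
    progressively KRAS activated and TP53 inactivated (early adenomatous,
    late adenomatous, cancerous).  ``apc_inactivated``: both APC alleles
    hit regardless of the other genes.
    """
    kras_intact = ("0",)
    tp53_intact = ("0",) if strict else ("0", "m", "l")
    wnt_clauses = _wnt_clauses(wnt)

    if name == "mmr_deficient_foci":
        mmr = _mmr_name(traj)
        if mmr is None:
            raise QueryError("no mismatch-repair gene in this model")
        clause = {mmr: MMR_DEFICIENT}
        for g in traj.index.genes:
            if g.name != mmr:
                clause[g.name] = ("0",)
        return NamedStateQuery(name, (clause,))
    if name == "state1":
        return NamedStateQuery(
            name,
            tuple({**c, "KRAS": kras_intact, "TP53": tp53_intact} for c in wnt_clauses),
        )
    if name == "state2":
        return NamedStateQuery(
            name,
            tuple({**c, "KRAS": ("m",), "TP53": tp53_intact} for c in wnt_clauses),
        )
    if name == "state3":
        return NamedStateQuery(
            name,
            tuple({**c, "KRAS": ("m",), "TP53": BIALLELIC} for c in wnt_clauses),
        )
    if name == "apc_inactivated":
        return NamedStateQuery(name, ({"APC": BIALLELIC},))
    raise QueryError(f"unknown state label {name!r}")


BUILTIN_QUERIES = ("mmr_deficient_foci", "state1", "state2", "state3", "apc_inactivated")


def aggregate(traj: Trajectory, q: NamedStateQuery | str, **kwargs) -> pd.Series:
    """Per-age crypt count in the query's genotype class."""
    if isinstance(q, str):
        q = builtin_query(q, traj, **kwargs)
    counts = traj.states[:, q.mask(traj)].sum(axis=1)
    return pd.Series(counts, index=pd.Index(traj.ages, name="age"), name=q.name)


#: Vogelstein-track stages; ``exclusive=True`` keeps a crypt in the latest
#: stage it has reached, so the stages partition the APC-inactivated pool
STAGES = ("apc_inactivated", "apc_kras", "apc_kras_tp53")


def _stage_clause(stage: str, exclusive: bool) -> dict[str, tuple[str, ...]]:
    clause: dict[str, tuple[str, ...]] = {"APC": BIALLELIC}
    if stage == "apc_inactivated":
        if exclusive:
            clause["KRAS"] = ("0",)
            clause["TP53"] = ("0", "m", "l")
    elif stage == "apc_kras":
        clause["KRAS"] = ("m",)
        if exclusive:
            clause["TP53"] = ("0", "m", "l")
    elif stage == "apc_kras_tp53":
        clause["KRAS"] = ("m",)
        clause["TP53"] = BIALLELIC
    else:
        raise QueryError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return clause


def pathway_proportions(
    traj: Trajectory,
    stages: tuple[str, ...] = STAGES,
    exclusive: bool = True,
) -> pd.DataFrame:
    """MMR-deficient vs MMR-proficient fractions per adenoma-carcinoma stage.

    For each stage and age, crypts in the stage are split by MMR status
    (deficient: both MMR alleles hit; proficient: at most one).  Fractions
    sum to one; ages at which the stage holds no crypts are reported as NA
    rather than propagating 0/0.

    Returns a tidy frame with columns ``age``, ``stage``, ``mmr_deficient``,
    ``mmr_proficient``, ``total``.
    """
    mmr = _mmr_name(traj)
    if mmr is None:
        raise QueryError("pathway proportions need a mismatch-repair gene in the model")
    deficient_states = _present(traj, mmr, MMR_DEFICIENT)
    rows = []
    for stage in stages:
        clause = _stage_clause(stage, exclusive)
        total = aggregate(traj, NamedStateQuery(stage, (clause,))).to_numpy()
        deficient = aggregate(
            traj, NamedStateQuery(stage, ({**clause, mmr: deficient_states},))
        ).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, deficient / total, np.nan)
        for age, tot, fr in zip(traj.ages, total, frac):
            rows.append({
                "age": age,
                "stage": stage,
                # NaN marks "undefined" (empty stage), never a failed division
                "mmr_deficient": fr,
                "mmr_proficient": 1.0 - fr if tot > 0 else np.nan,
                "total": tot,
            })
    return pd.DataFrame(rows)


def compare_runs(
    traj_a: Trajectory, traj_b: Trajectory, q: NamedStateQuery | str, **kwargs
) -> pd.Series:
    """Elementwise ratio of the query aggregate in two runs (A over B).

    Ages where both aggregates vanish are undefined and reported as NA.
    """
    if traj_a.ages.shape != traj_b.ages.shape or not np.allclose(traj_a.ages, traj_b.ages):
        raise AlignmentError("trajectories are on different age grids")
    a = aggregate(traj_a, q, **kwargs).to_numpy()
    b = aggregate(traj_b, q, **kwargs).to_numpy()
    ratio: list[object] = []
    for x, y in zip(a, b):
        if y == 0:
            ratio.append(pd.NA if x == 0 else np.inf)
        else:
            ratio.append(x / y)
    name = q if isinstance(q, str) else q.name
    return pd.Series(ratio, index=pd.Index(traj_a.ages, name="age"), name=f"ratio_{name}")
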