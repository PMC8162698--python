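"""Configuration files, matrix/trajectory export and run manifests.

Configuration is one human-editable YAML file.  The minimal form names a
preset and optional numeric overrides::

    scenario: lynch-mlh1
    global_params: {n_pt: 1.2}
    dependency_params: {beta: 1.0e3}
    genes:
      APC: {n_hs: 600}

A fully resolved configuration (as written to manifests) additionally
lists every gene with all of its parameters and round-trips exactly.

Matrices are exported in MatrixMarket coordinate format with a sidecar
TSV mapping flat genotype index to a label such as
``MLH1:mm|CTNNB1:0|APC:0|KRAS:0|TP53:0`` (wild-type rendered ``0``).
Every output directory receives a JSON manifest with the resolved
parameters, so a run can be reproduced bit-identically from it.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import scipy.io
import yaml

from . import __version__
from .assembly import DependencyParams, SystemMatrix
from .errors import ConfigurationError
from .genes import GeneSpec, GlobalParams
from .scenarios import PRESET_NAMES, ScenarioConfig, preset
from .solver import Trajectory


def scenario_to_dict(config: ScenarioConfig) -> dict:
    """Fully resolved, YAML/JSON-serializable form of a configuration."""
    return {
        "scenario": config.scenario,
        "mmr_gene": config.mmr_gene,
        "germline": dict(config.germline),
        "active_dependencies": sorted(config.active_dependencies),
        "global_params": {
            f.name: getattr(config.global_params, f.name)
            for f in dataclasses.fields(GlobalParams)
        },
        "dependency_params": dataclasses.asdict(config.dependency_params),
        "genes": [
            {
                "name": g.name,
                "role": g.role,
                "n_hs": g.n_hs,
                "n_bp": g.n_bp,
                "f": g.f,
                "b_altered": g.b_altered,
                "states": list(g.states),
            }
            for g in config.genes
        ],
    }


def scenario_from_dict(data: dict) -> ScenarioConfig:
    """Build a configuration from a preset name plus overrides, or from a
    fully resolved dictionary."""
    if "scenario" not in data:
        raise ConfigurationError("config must name a 'scenario'")
    name = data["scenario"]
    genes = data.get("genes")
    if isinstance(genes, list):  # fully resolved form
        specs = tuple(
            GeneSpec(
                name=g["name"],
                role=g["role"],
                n_hs=g["n_hs"],
                n_bp=g.get("n_bp"),
                f=g.get("f", 1.0),
                b_altered=g.get("b_altered", 0.0),
                states=tuple(g["states"]) if "states" in g else (),
            )
            for g in genes
        )
        gp = GlobalParams(**data.get("global_params", {}))
        dep = DependencyParams(**data.get("dependency_params", {}))
        return ScenarioConfig(
            scenario=name,
            genes=specs,
            global_params=gp,
            dependency_params=dep,
            active_dependencies=frozenset(data.get("active_dependencies", "BCDEF")),
            germline=dict(data.get("germline", {})),
            mmr_gene=data.get("mmr_gene"),
        )
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown scenario {name!r}; expected one of {PRESET_NAMES}")
    config = preset(name)
    gene_overrides = genes if isinstance(genes, dict) else None
    try:
        return config.with_overrides(
            global_params=data.get("global_params"),
            dependency_params=data.get("dependency_params"),
            gene_overrides=gene_overrides,
        )
    except TypeError as exc:
        raise ConfigurationError(f"invalid override in config: {exc}") from exc


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return scenario_from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=False)


def genotype_labels(index) -> list[str]:
    return [index.label(i) for i in range(index.total_dim)]


def export_labels(index, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tgenotype\n")
        for i, lab in enumerate(genotype_labels(index)):
            fh.write(f"{i}\t{lab}\n")


def export_matrix(system: SystemMatrix, outdir: str | Path, components=("M",)) -> list[Path]:
    """Write the requested components in MatrixMarket coordinate format,
    plus the genotype-label sidecar TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for comp in components:
        mat = system.component(comp)
        path = outdir / f"{comp}.mtx"
        scipy.io.mmwrite(str(path), mat.tocoo())
        written.append(path)
    labels = outdir / "genotypes.tsv"
    export_labels(system.index, labels)
    written.append(labels)
    return written


def export_trajectory(traj: Trajectory, path: str | Path, wide: bool = False) -> None:
    """Tidy TSV (age, genotype, count) or wide matrix with labeled columns."""
    frame = traj.to_frame(tidy=not wide)
    frame.to_csv(path, sep="\t", index=wide, float_format="%.17g")


def write_manifest(
    outdir: str | Path, config: ScenarioConfig, outputs: list[str | Path], **extra
) -> Path:
    manifest = {
        "scenario": config.scenario,
        "software": {"name": "cryptdyn", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": scenario_to_dict(config),
        "outputs": [str(Path(p)) for p in outputs],
        **extra,
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")
    return path


def config_from_manifest(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        manifest = json.load(fh)
    return scenario_from_dict(manifest["config"])
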