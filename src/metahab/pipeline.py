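"""End-to-end orchestration: rarefy -> diversity -> weight regression ->
core taxa -> Rao partition -> assembly processes -> source tracking.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage;
the master seed is split deterministically into per-stage sub-seeds so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import DEFAULT_RAREFACTION_DEPTH, rarefy, spawn_seeds
from . import assembly, coretaxa, diversity, io, rao, sourcetrack, weightreg

logger = logging.getLogger(__name__)

STAGES = ("rarefy", "diversity", "weightreg", "core", "partition", "processes", "sourcetrack")


@dataclass
class PipelineConfig:
    table: str
    metadata: str
    output_dir: str
    tree: str | None = None
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    permutations: int = 1000
    mantel_permutations: int = 10000
    n_null: int = 999
    prevalence_threshold: float = 0.8
    abundance_threshold: float = 0.01
    distance_mode: str = "taxonomic"
    correction: str = "equivalent_numbers"
    sink_depth: int = 1000
    gibbs: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index", double_precision=12))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json(double_precision=12))
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns (and writes) the aggregated report.

    Any stage error aborts the run with the stage name and cause; outputs of
    completed stages are retained in the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = io.read_otu_table(config.table)
    meta = io.read_metadata(config.metadata)
    tree = io.read_newick(config.tree) if config.tree else None
    if "processes" in config.stages and tree is None:
        raise StageError("processes", ValueError("missing input: tree (newick path)"))

    seeds = dict(zip(STAGES, spawn_seeds(config.seed, len(STAGES))))
    cfg_dict = _jsonable(asdict(config))
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
        }
    }

    def stage(name):
        return name in config.stages

    def run_stage(name, fn):
        t0 = time.monotonic()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s finished in %.1fs", name, time.monotonic() - t0)
        return result

    dm = None
    if stage("rarefy"):
        def _rarefy():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                rt = rarefy(table, config.rarefaction_depth, seed=seeds["rarefy"])
            io.write_otu_table(rt, out / "rarefied.tsv")
            return rt

        table = run_stage("rarefy", _rarefy)
        meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
        report["rarefy"] = {
            "depth": config.rarefaction_depth,
            "samples_retained": table.n_samples,
        }

    if stage("diversity"):
        def _diversity():
            alpha = diversity.alpha_diversity(table)
            local_dm = diversity.bray_curtis(table)
            ord_res = diversity.pcoa(local_dm)
            perm = diversity.permanova(
                local_dm, meta["habitat"], permutations=config.permutations,
                seed=seeds["diversity"],
            )
            ano = diversity.anosim(
                local_dm, meta["habitat"], permutations=config.permutations,
                seed=seeds["diversity"],
            )
            alpha.to_csv(out / "alpha.tsv", sep="\t")
            pd.DataFrame(
                local_dm.data, index=local_dm.ids, columns=local_dm.ids
            ).to_csv(out / "bc_distance.tsv", sep="\t")
            ord_res.axes.to_csv(out / "pcoa_axes.tsv", sep="\t")
            return local_dm, {
                "alpha_chao1_mean": float(alpha.mean()),
                "permanova": _jsonable(perm),
                "anosim": _jsonable(ano),
                "pcoa_proportion_explained": ord_res.proportion_explained[:3].tolist(),
            }

        dm, report["diversity"] = run_stage("diversity", _diversity)

    if stage("weightreg"):
        def _weightreg():
            local_dm = dm if dm is not None else diversity.bray_curtis(table)
            fits = weightreg.habitat_regressions(
                table, meta, local_dm,
                permutations=config.permutations, seed=seeds["weightreg"],
            )
            block = {k: _jsonable(v) for k, v in fits.items()}
            (out / "regression.json").write_text(json.dumps(block, indent=2, sort_keys=True))
            return block

        report["weightreg"] = run_stage("weightreg", _weightreg)

    if stage("core"):
        def _core():
            habitats = list(dict.fromkeys(meta["habitat"]))
            sets = []
            block = {}
            for h in habitats:
                cs = coretaxa.find_core(
                    table, meta, h,
                    prevalence_threshold=config.prevalence_threshold,
                    abundance_threshold=config.abundance_threshold,
                )
                sets.append(cs)
                block[h] = {
                    "core_otu_ids": sorted(cs.core_otu_ids),
                    "core_abundance_fraction": cs.core_abundance_fraction,
                }
                pd.Series(sorted(cs.core_otu_ids)).to_csv(
                    out / f"core_{h}.tsv", sep="\t", index=False, header=["otu_id"]
                )
            if len(sets) >= 2:
                venn = coretaxa.core_overlap(sets)
                block["venn"] = {"&".join(k): sorted(v) for k, v in sorted(venn.items())}
                (out / "venn.json").write_text(
                    json.dumps(block["venn"], indent=2, sort_keys=True)
                )
            return block

        report["core"] = run_stage("core", _core)

    if stage("partition"):
        def _partition():
            part = rao.partition_diversity(
                table, meta,
                distance_mode=config.distance_mode,
                correction=config.correction, tree=tree,
            )
            block = _jsonable(part)
            (out / "partition.json").write_text(json.dumps(block, indent=2, sort_keys=True))
            return block

        report["partition"] = run_stage("partition", _partition)

    if stage("processes"):
        def _processes():
            profiles = assembly.assembly_profile(
                table, meta, tree, n_null=config.n_null, seed=seeds["processes"]
            )
            block = {g: _jsonable(p) for g, p in profiles.items()}
            (out / "profile.json").write_text(json.dumps(block, indent=2, sort_keys=True))
            return block

        report["processes"] = run_stage("processes", _processes)

    if stage("sourcetrack"):
        def _sourcetrack():
            res = sourcetrack.leave_one_habitat_out(
                table, meta, sink_depth=config.sink_depth,
                seed=seeds["sourcetrack"], **config.gibbs,
            )
            block = {}
            for h, frame in res.items():
                frame.to_csv(out / f"sources_{h}.tsv", sep="\t")
                block[h] = _jsonable(frame.loc["mean"])
            (out / "sources.json").write_text(json.dumps(block, indent=2, sort_keys=True))
            return block

        report["sourcetrack"] = run_stage("sourcetrack", _sourcetrack)

    text = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(text)
    return report
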