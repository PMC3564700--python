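"""End-to-end experiment drivers: perturbation robustness and the
simulation benchmark, with serialisable run configuration and manifests.

Both experiments stream one replicate/family at a time, derive every random
number from one master seed through named substreams, and write a JSON
manifest (tool version, config, config hash, outputs) from which a rerun
reproduces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from . import __version__
from .evolve import (
    BenchmarkResult,
    EvolveConfig,
    benchmark_rcm,
    rose_like_config,
    score_trees,
)
from .perturb import PAPER_RATES, perturb_dataset
from .phylo import nj_tree, read_trees, robustness_curve, write_tree
from .rcm import distance_matrix
from .sequences import read_fasta, write_fasta

__all__ = [
    "RunConfig",
    "run_robustness_experiment",
    "run_benchmark_experiment",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run parameters: a plain dict plus helpers.

    Fully serialisable; the config hash identifies a run, and re-running
    from a saved config reproduces byte-identical outputs.
    """

    params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset handles JSON too
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(data)

    def get(self, key, default=None):
        return self.params.get(key, default)

    def updated(self, **kw) -> "RunConfig":
        merged = dict(self.params)
        merged.update({k: v for k, v in kw.items() if v is not None})
        return RunConfig(merged)

    def canonical_json(self) -> str:
        return json.dumps(self.params, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _substream_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=tuple(key)).generate_state(1)[0])


def _prepare_outdir(outdir: Union[str, Path], force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def _write_manifest(outdir: Path, config: RunConfig, outputs: dict, seeds: dict) -> Path:
    manifest = {
        "tool": "rcmphylo",
        "version": __version__,
        "config": config.params,
        "config_hash": config.config_hash,
        "resolved_seed_tree": seeds,
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# Robustness experiment


def run_robustness_experiment(config: Union[RunConfig, dict]) -> Path:
    """Original tree + per-rate perturbation replicates -> consensus -> RF.

    Config keys: ``input`` (FASTA path, >= 4 sequences), ``rates`` (default:
    the seven standard levels), ``replicates`` (default 1000), ``seed``,
    ``out`` (output directory), ``force``.  Writes ``report.tsv`` (one row
    per rate), ``replicate_rf.tsv`` (per-replicate RF distances, the
    histogram source), one consensus Newick per rate, the original tree,
    and ``manifest.json``.  Returns the manifest path.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(dict(config))
    fasta = cfg.get("input")
    if fasta is None:
        raise ValueError("robustness config requires 'input' (FASTA path)")
    rates = [float(r) for r in cfg.get("rates", PAPER_RATES)]
    n_reps = int(cfg.get("replicates", 1000))
    seed = int(cfg.get("seed", 0))
    outdir = _prepare_outdir(cfg.get("out", "robustness_out"), bool(cfg.get("force", False)))

    seqs = read_fasta(fasta, ambiguous=cfg.get("ambiguous", "reject"))
    if len(seqs) < 4:
        raise ValueError(f"robustness experiment needs >= 4 sequences, got {len(seqs)}")

    stage = "original tree"
    try:
        original = nj_tree(distance_matrix(seqs))
        write_tree(original, outdir / "original.nwk")
        trees_by_rate: dict[float, list] = {}
        seeds: dict[str, int] = {"master": seed}
        for ri, rate in enumerate(rates):
            rate_seed = _substream_seed(seed, ri)
            seeds[f"rate_{rate:g}"] = rate_seed
            rep_trees = []
            stage = f"rate {rate:g} perturbation setup"
            for rep_idx, dataset in enumerate(perturb_dataset(seqs, rate, n_reps, rate_seed)):
                stage = f"rate {rate:g} replicate {rep_idx}"
                rep_seqs = [r.sequence for r in dataset]
                rep_trees.append(nj_tree(distance_matrix(rep_seqs)))
            trees_by_rate[rate] = rep_trees
            log.info("rate %g: %d replicate trees built", rate, len(rep_trees))
        stage = "consensus"
        curve = robustness_curve(original, trees_by_rate)
    except Exception as err:
        raise RuntimeError(f"robustness experiment failed at stage: {stage}") from err

    report_lines = ["rate\tn_replicates\trf_consensus\tmean_replicate_rf\tmax_replicate_rf"]
    rf_lines = ["rate\treplicate\trf"]
    outputs: dict[str, str] = {"original_tree": "original.nwk"}
    for rate, point in curve.items():
        cons_name = f"consensus_rate_{rate:g}.nwk"
        write_tree(point.consensus, outdir / cons_name)
        outputs[f"consensus_{rate:g}"] = cons_name
        max_rf = max(point.replicate_rf) if point.replicate_rf else 0
        report_lines.append(
            f"{rate:g}\t{len(point.replicate_rf)}\t{point.rf_consensus}"
            f"\t{point.mean_replicate_rf:.6f}\t{max_rf}"
        )
        for rep_idx, rf in enumerate(point.replicate_rf):
            rf_lines.append(f"{rate:g}\t{rep_idx}\t{rf}")
        log.info("rate %g: consensus RF %d", rate, point.rf_consensus)
    (outdir / "report.tsv").write_text("\n".join(report_lines) + "\n")
    (outdir / "replicate_rf.tsv").write_text("\n".join(rf_lines) + "\n")
    outputs["report"] = "report.tsv"
    outputs["replicate_rf"] = "replicate_rf.tsv"
    return _write_manifest(outdir, cfg, outputs, seeds)


# ---------------------------------------------------------------------------
# Benchmark experiment


def _summary_tsv(results: Sequence[BenchmarkResult]) -> str:
    lines = ["method\tmodel\tn_families\tmean_rf\tsd_rf\tmean_rf_normalized\tsd_rf_normalized"]
    for r in results:
        method, model, n, mr, sr, mn, sn = r.row()
        lines.append(f"{method}\t{model}\t{n}\t{mr:.6f}\t{sr:.6f}\t{mn:.6f}\t{sn:.6f}")
    return "\n".join(lines) + "\n"


def run_benchmark_experiment(config: Union[RunConfig, dict]) -> Path:
    """Simulation benchmark: families -> RCM+NJ trees -> RF to the truth.

    Config keys: ``models`` (list, default ["K2P", "F84"]), ``families``
    (per model, default 200), ``length`` (default 500), ``seed``, ``out``,
    ``force``, ``write_families`` (write per-family FASTA/Newick/alignment),
    ``external`` (mapping method name -> Newick file with one tree per
    family, scored identically and tabulated alongside RCM — requires
    ``write_families`` so the true trees are the same ones on disk).
    Writes ``summary.tsv`` and ``manifest.json``; returns the manifest path.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(dict(config))
    models = [str(m).upper() for m in cfg.get("models", ["K2P", "F84"])]
    n_families = int(cfg.get("families", 200))
    length = int(cfg.get("length", 500))
    seed = int(cfg.get("seed", 0))
    write_families = bool(cfg.get("write_families", False))
    external = dict(cfg.get("external", {}))
    outdir = _prepare_outdir(cfg.get("out", "benchmark_out"), bool(cfg.get("force", False)))

    results: list[BenchmarkResult] = []
    seeds: dict[str, int] = {"master": seed}
    outputs: dict[str, str] = {}
    for mi, model in enumerate(models):
        model_seed = _substream_seed(seed, mi)
        seeds[model] = model_seed
        ecfg = rose_like_config(model, root_length_mean=length)
        res, families = benchmark_rcm(
            ecfg, n_families, seed=model_seed, keep_families=True
        )
        results.append(res)
        log.info(
            "%s: mean RF %.4f (normalized %.4f) over %d families",
            model, res.mean_raw, res.mean_normalized, res.n_families,
        )
        if write_families:
            for f, fam in enumerate(families):
                fam_dir = outdir / model.lower() / f"family_{f:04d}"
                fam_dir.mkdir(parents=True, exist_ok=True)
                write_fasta(fam.leaves, fam_dir / "leaves.fasta")
                write_tree(fam.tree, fam_dir / "true_tree.nwk")
                aln = "".join(
                    f">{label}\n{row}\n" for label, row in fam.alignment.items()
                )
                (fam_dir / "true_alignment.fasta").write_text(aln)
            outputs[f"families_{model}"] = f"{model.lower()}/"
        for name, tree_file in external.items():
            try:
                est = read_trees(tree_file)
                true_trees = [fam.tree for fam in families]
                results.append(score_trees(str(name), model, est, true_trees))
            except Exception as err:  # error isolation: RCM rows still stand
                log.error("external trees %s (%s): %s", name, tree_file, err)

    summary = _summary_tsv(results)
    (outdir / "summary.tsv").write_text(summary)
    outputs["summary"] = "summary.tsv"
    return _write_manifest(outdir, cfg, outputs, seeds)
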