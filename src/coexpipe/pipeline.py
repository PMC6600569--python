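"""End-to-end orchestration of the co-expression analysis chain.

One declarative config drives the full chain: simulate (or load) counts
-> RPKM -> exact-test DEG calling and Venn partition -> trend profiles
-> HRR network -> MCL modules -> module enrichment.  Every stage writes
a plain-text artifact into the output directory and the run finishes
with a manifest recording the package version, the fully resolved
parameters (no silent defaults) and per-stage row counts.  Reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, coexnet, diffexp, mcl, quantify, syndata, trends
from .enrich import enrich_modules

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("coexpipe")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage.  Outputs written by
    earlier stages are left in place."""


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # input route A: existing tables
    counts_tsv: str | None = None
    annotation_tsv: str | None = None
    library_sizes: list[int] | None = None
    # input route B: simulation block (dict mirroring SimulationConfig)
    simulation: dict | None = None
    annotation_sim: dict = field(
        default_factory=lambda: {
            "n_terms": 50,
            "background_rate": 0.05,
            "enriched_rate": 0.8,
        }
    )
    # stage parameters
    pseudocount: float = 1.0
    deg_thresholds: tuple[float, float, float] = (2.0, 0.05, 2.0)
    gcn_thresholds: tuple[float, float, float] = (0.0, 0.05, 1.5)
    flat_threshold: float = 1.0
    trend_permutations: int = 1000
    hrr_cutoff: int = 30
    mcl_inflation: float = 1.6
    mcl_min_module_size: int = 15
    enrich_min_mapped: int = 2
    enrich_alpha: float = 0.05
    enrich_background: str = "annotation"  # or "network"

    def __post_init__(self) -> None:
        if self.counts_tsv is None and self.simulation is None:
            raise ValueError(
                "config must provide either counts_tsv or a simulation block"
            )
        if self.enrich_background not in ("annotation", "network"):
            raise ValueError("enrich_background must be 'annotation' or 'network'")
        self.deg_thresholds = tuple(self.deg_thresholds)
        self.gcn_thresholds = tuple(self.gcn_thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["deg_thresholds"] = list(self.deg_thresholds)
        out["gcn_thresholds"] = list(self.gcn_thresholds)
        return out


def _simulation_config(block: dict, seed: int) -> syndata.SimulationConfig:
    block = dict(block)
    modules = [
        syndata.ModuleSpec(**m) if isinstance(m, dict) else m
        for m in block.pop("modules", [])
    ]
    de_genes = [
        syndata.DeSpec(**d) if isinstance(d, dict) else d
        for d in block.pop("de_genes", [])
    ]
    block.setdefault("seed", seed)
    return syndata.SimulationConfig(modules=modules, de_genes=de_genes, **block)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": config.resolved(),
        "stages": {},
    }

    def stage(name: str):
        def deco(fn):
            log.info("stage %s", name)
            try:
                rows, path = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - surfaced with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"rows": rows, "file": path}
            return None

        return deco

    state: dict = {}

    @stage("counts")
    def _counts():
        if config.simulation is not None:
            sim = _simulation_config(config.simulation, config.seed)
            counts, truth = syndata.simulate_counts(sim)
            truth.to_json(out / "ground_truth.json")
            state["truth"] = truth
            ann = syndata.simulate_annotation(
                truth,
                genes=counts.gene_ids,
                seed=config.seed + 1,
                **config.annotation_sim,
            )
            syndata.write_annotation_tsv(ann, out / "annotation.tsv")
            state["annotation"] = ann
        else:
            counts = quantify.CountMatrix.from_tsv(
                config.counts_tsv, library_sizes=config.library_sizes
            )
            if config.annotation_tsv:
                state["annotation"] = syndata.read_annotation_tsv(
                    config.annotation_tsv
                )
        counts.to_tsv(out / "counts.tsv")
        state["counts"] = counts
        return counts.n_genes, "counts.tsv"

    @stage("rpkm")
    def _rpkm():
        expr = quantify.compute_rpkm(state["counts"])
        expr.to_tsv(out / "rpkm.tsv")
        state["expr"] = expr
        return len(expr.gene_ids), "rpkm.tsv"

    @stage("diffexp")
    def _diffexp():
        table = diffexp.call_degs(
            state["expr"],
            state["counts"],
            diffexp.ThresholdSet(*config.deg_thresholds),
            pseudocount=config.pseudocount,
        )
        table.to_csv(out / "deg_table.tsv", sep="\t", index=False)
        state["deg_table"] = table
        sets = diffexp.deg_sets(table)
        if len(sets) == 3:
            venn = diffexp.venn_partition(sets)
            venn.to_json(out / "venn.json")
            state["venn"] = venn
        return len(table), "deg_table.tsv"

    @stage("trends")
    def _trends():
        expr = state["expr"]
        table = state["deg_table"]
        degs = sorted(set(table.loc[table["passes"], "gene_id"]))
        idx = [expr.gene_ids.index(g) for g in degs]
        sub = expr.rpkm[idx, :]
        assignments = trends.classify_profiles(
            sub, degs, config.flat_threshold, config.pseudocount
        )
        assignments.to_csv(out / "trends.tsv", sep="\t", index=False)
        if len(degs):
            _, p = trends.profile_significance(
                sub,
                config.flat_threshold,
                config.trend_permutations,
                seed=config.seed + 2,
                pseudocount=config.pseudocount,
            )
        else:
            p = None
        trends.write_summary(assignments, out / "trends_summary.json", p)
        state["trend_assignments"] = assignments
        return len(assignments), "trends.tsv"

    @stage("network")
    def _network():
        expr = state["expr"]
        counts = state["counts"]
        gcn_table = diffexp.call_degs(
            expr,
            counts,
            diffexp.ThresholdSet(*config.gcn_thresholds),
            pseudocount=config.pseudocount,
        )
        eligible = sorted(set(gcn_table.loc[gcn_table["passes"], "gene_id"]))
        if len(eligible) < 3:
            raise ValueError(
                f"only {len(eligible)} genes pass the network filter; need >= 3"
            )
        idx = [expr.gene_ids.index(g) for g in eligible]
        profiles = np.log2(expr.rpkm[idx, :] + config.pseudocount)
        corr, _ = pearson_warned(profiles, eligible)
        hrr = coexnet.hrr_matrix(corr)
        net = coexnet.build_network(hrr, eligible, config.hrr_cutoff, corr)
        coexnet.write_edge_list(net, out / "network_edges.tsv")
        coexnet.write_sif(net, out / "network.sif")
        coexnet.network_stats(net).to_json(out / "network_stats.json")
        state["network"] = net
        return net.number_of_edges(), "network_edges.tsv"

    @stage("modules")
    def _modules():
        params = mcl.MclParams(
            inflation=config.mcl_inflation,
            min_module_size=config.mcl_min_module_size,
        )
        partition = mcl.mcl_cluster(state["network"], params)
        partition.to_tsv(out / "clusters.tsv")
        summary = partition.summary()
        (out / "clusters_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        comparison = state["deg_table"]["comparison"].iloc[0]
        comp = mcl.module_composition(partition, state["deg_table"], comparison)
        comp.to_csv(out / "module_composition.tsv", sep="\t", index=False)
        state["partition"] = partition
        state["module_summary"] = summary
        return summary["n_clusters"], "clusters.tsv"

    @stage("enrichment")
    def _enrichment():
        if "annotation" not in state:
            return 0, None
        annotation = state["annotation"]
        partition = state["partition"]
        if config.enrich_background == "network":
            background = sorted(partition.assignment)
            annotation = syndata.AnnotationMap(
                gene_terms={
                    g: t
                    for g, t in annotation.gene_terms.items()
                    if g in set(background)
                },
                term_universe=annotation.term_universe,
                background=background,
            )
        modules = {
            cid: genes
            for cid, genes in partition.clusters.items()
            if partition.is_module(cid)
        }
        if not modules:
            return 0, None
        result = enrich_modules(
            modules,
            annotation,
            min_mapped=config.enrich_min_mapped,
            alpha=config.enrich_alpha,
        )
        result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        state["enrichment"] = result
        return len(result), "enrichment.tsv"

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    state["manifest"] = manifest
    return manifest


def pearson_warned(profiles: np.ndarray, gene_ids: list[str]):
    """Pearson matrix with the short-profile warning demoted to a log line."""
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        corr, flagged = coexnet.pearson_matrix(profiles, gene_ids)
    for w in caught:
        log.info("%s", w.message)
    return corr, flagged
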