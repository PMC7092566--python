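"""Config-driven orchestration of the full analysis.

A YAML config (see :func:`load_config`) either points at real input files
(counts, sample table, annotation, GMT) or enables the synthetic-data
stage; the enabled analysis stages then run in dependency order:

    simulate -> de -> cluster -> zscore -> jaccard -> discriminate
             -> scan -> enrich

Every output file is TSV/GMT/JSON; the run summary records a sha256
checksum per output, so identical config + seed reproduces identical
checksums. One global seed is fanned out to per-stage seeds by fixed
offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, contrast, de, enrichment, io, positional, sample_scores
from .simulate import Hotspot, SimulationDesign, simulate_annotation, simulate_counts, simulate_gene_sets

logger = logging.getLogger("caniuc")

STAGE_ORDER = ["simulate", "de", "cluster", "zscore", "jaccard", "discriminate", "scan", "enrich"]

SEED_OFFSETS = {"simulate": 0, "cluster": 1, "jaccard": 2, "gene_sets": 3}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    lfc: float = 1.0
    q: float = 0.01
    z: float = 2.5
    unchanged_band: float = 0.5
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.q <= 1 or not 0 < self.alpha <= 1:
            raise ValueError("q and alpha thresholds must lie in (0, 1]")
        if self.lfc < 0 or self.z < 0 or self.unchanged_band < 0:
            raise ValueError("lfc, z and unchanged_band thresholds must be >= 0")


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    design: SimulationDesign | None = None
    inputs: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    cluster_k: int = 2
    cluster_resamples: int = 1000
    cluster_subsample_frac: float = 0.8
    cluster_n_features: int = 2000
    jaccard_method: str = "permutation"
    jaccard_n_perm: int = 10_000
    enrich_top: int = 10

    def validate(self) -> None:
        self.thresholds.validate()
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        if self.stages.get("simulate"):
            if self.design is None:
                self.design = SimulationDesign(seed=self.seed + SEED_OFFSETS["simulate"])
        else:
            for key in ("counts", "samples"):
                path = self.inputs.get(key)
                if not path:
                    raise ValueError(f"simulation disabled but inputs.{key} not given")
                if not Path(path).exists():
                    raise FileNotFoundError(f"inputs.{key}: {path}")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file. A seed is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an integer 'seed'")
    cfg = RunConfig(seed=int(raw["seed"]))
    cfg.stages.update(raw.get("stages", {}))
    sim = raw.get("simulate", {})
    if isinstance(sim, dict) and sim:
        sim = dict(sim)
        if "hotspots" in sim:
            sim["hotspots"] = [Hotspot(**h) for h in sim["hotspots"]]
        valid = {f.name for f in fields(SimulationDesign)}
        unknown = set(sim) - valid
        if unknown:
            raise ValueError(f"unknown simulate parameters: {sorted(unknown)}")
        sim.setdefault("seed", cfg.seed + SEED_OFFSETS["simulate"])
        cfg.design = SimulationDesign(**sim)
    cfg.inputs = raw.get("inputs", {}) or {}
    thr = raw.get("thresholds", {}) or {}
    cfg.thresholds = Thresholds(**thr)
    for key in ("k", "resamples", "subsample_frac", "n_features"):
        if key in raw.get("cluster", {}):
            setattr(cfg, f"cluster_{key}", raw["cluster"][key])
    for key in ("method", "n_perm"):
        if key in raw.get("jaccard", {}):
            setattr(cfg, f"jaccard_{key}", raw["jaccard"][key])
    if "top" in raw.get("enrich", {}):
        cfg.enrich_top = raw["enrich"]["top"]
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages; return (and write) the run summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}

    def _record(stage: str, name: str, path: Path) -> None:
        summary["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        summary["stages"][stage]["outputs"].append(name)

    def _run(stage: str, fn) -> None:
        if not config.stages.get(stage, False):
            return
        t0 = time.time()
        summary["stages"][stage] = {"outputs": []}
        try:
            fn(stage)
        except Exception as exc:
            (outdir / f"{stage}.partial").write_text(str(exc) + "\n")
            raise StageError(stage, exc) from exc
        summary["stages"][stage]["seconds"] = round(time.time() - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, summary["stages"][stage]["seconds"])

    # ----- simulate ------------------------------------------------------
    def _simulate(stage: str) -> None:
        design = config.design
        counts, samples, truth = simulate_counts(design)
        records = simulate_annotation(design, truth)
        gene_sets = simulate_gene_sets(truth, seed=config.seed + SEED_OFFSETS["gene_sets"])
        io.write_table(counts, outdir / "counts.tsv")
        io.write_table(samples, outdir / "samples.tsv")
        io.write_annotation(records, outdir / "annotation.tsv")
        io.write_table(truth.genes, outdir / "truth.tsv")
        io.write_gmt(gene_sets, outdir / "sets.gmt")
        lengths = pd.DataFrame(design.chrom_lengths().items())
        lengths.to_csv(outdir / "chrom_lengths.tsv", sep="\t", header=False, index=False)
        state.update(
            counts=counts, samples=samples, truth=truth, annotation=records,
            gene_sets=gene_sets, chrom_lengths=design.chrom_lengths(),
        )
        for name in ("counts.tsv", "samples.tsv", "annotation.tsv", "truth.tsv",
                     "sets.gmt", "chrom_lengths.tsv"):
            _record(stage, name, outdir / name)

    _run("simulate", _simulate)

    # ----- ingest when not simulating ------------------------------------
    if "counts" not in state:
        if not config.inputs.get("counts"):
            raise StageError("de", FileNotFoundError(
                "no count matrix available: enable the simulate stage or set inputs.counts"
            ))
        state["counts"] = io.read_counts(config.inputs["counts"])
        state["samples"] = io.read_samples(config.inputs["samples"])
        if config.inputs.get("annotation"):
            state["annotation"] = io.read_annotation(
                config.inputs["annotation"],
                config.inputs.get("annotation_dialect", "tsv4col"),
            )
        if config.inputs.get("gmt"):
            state["gene_sets"] = io.read_gmt(config.inputs["gmt"])
        if config.inputs.get("chrom_lengths"):
            state["chrom_lengths"] = io.read_chrom_lengths(config.inputs["chrom_lengths"])

    counts, samples = state["counts"], state["samples"]
    thr = config.thresholds

    # ----- differential expression (all tumors vs normals) ---------------
    def _de(stage: str) -> None:
        result = de.nb_wald_test(counts, samples, "tumor", "normal", thr.lfc, thr.q)
        state["de_tumor"] = result
        io.write_table(result, outdir / "de_tumor_vs_normal.tsv")
        _record(stage, "de_tumor_vs_normal.tsv", outdir / "de_tumor_vs_normal.tsv")

    _run("de", _de)

    # shared VST matrix for clustering / z-scores
    def _vst() -> pd.DataFrame:
        if "vst" not in state:
            state["vst"] = de.vst(counts)
        return state["vst"]

    # ----- consensus clustering of tumors --------------------------------
    def _cluster(stage: str) -> None:
        tumor_ids = samples.loc[samples["tissue"] == "tumor", "sample_id"].tolist()
        expr = _vst()[tumor_ids]
        result = clustering.consensus_cluster(
            expr,
            k=config.cluster_k,
            n_resamples=config.cluster_resamples,
            subsample_frac=config.cluster_subsample_frac,
            seed=config.seed + SEED_OFFSETS["cluster"],
            n_features=config.cluster_n_features,
        )
        state["consensus"] = result
        io.write_table(
            result.consensus_matrix.reset_index(names="sample_id"),
            outdir / "consensus_matrix.tsv",
        )
        assignments = pd.DataFrame(
            {
                "sample_id": result.assignments.index,
                "cluster": result.assignments.to_numpy(),
                "item_consensus": result.item_consensus.to_numpy(),
            }
        )
        io.write_table(assignments, outdir / "cluster_assignments.tsv")
        emb = clustering.pca_embed(expr, n_dims=2)
        io.write_table(
            emb.coordinates.reset_index(names="sample_id"), outdir / "pca_tumors.tsv"
        )
        for name in ("consensus_matrix.tsv", "cluster_assignments.tsv", "pca_tumors.tsv"):
            _record(stage, name, outdir / name)

    _run("cluster", _cluster)

    # ----- per-sample z-scores --------------------------------------------
    def _zscore(stage: str) -> None:
        sig = sample_scores.per_sample_zscores(_vst(), samples, thr.z)
        state["zscores"] = sig
        io.write_table(sig.z.reset_index(names="gene_id"), outdir / "zscores.tsv")
        with open(outdir / "significant_sets.tsv", "w") as fh:
            for sample in sig.z.columns:
                up = ",".join(sorted(sig.up_sets[sample]))
                down = ",".join(sorted(sig.down_sets[sample]))
                fh.write(f"{sample}\t{up}\t{down}\n")
        for name in ("zscores.tsv", "significant_sets.tsv"):
            _record(stage, name, outdir / name)

    _run("zscore", _zscore)

    # ----- Jaccard coherence ----------------------------------------------
    def _jaccard(stage: str) -> None:
        if "zscores" not in state:
            raise FileNotFoundError(
                "jaccard stage needs per-sample z-score sets: enable the zscore stage"
            )
        comp = sample_scores.compare_group_similarity(
            state["zscores"],
            samples,
            method=config.jaccard_method,
            n_perm=config.jaccard_n_perm,
            seed=config.seed + SEED_OFFSETS["jaccard"],
        )
        state["jaccard"] = comp
        io.write_table(comp.scores, outdir / "jaccard_pairs.tsv")
        payload = {
            "method": comp.method,
            "set_kind": comp.set_kind,
            "p_within_mut_vs_between": comp.p_within_mut_vs_between,
            "p_within_wt_vs_between": comp.p_within_wt_vs_between,
        }
        (outdir / "jaccard_comparison.json").write_text(json.dumps(payload, indent=2) + "\n")
        for name in ("jaccard_pairs.tsv", "jaccard_comparison.json"):
            _record(stage, name, outdir / name)

    _run("jaccard", _jaccard)

    # ----- per-cluster DE + discriminating genes --------------------------
    def _discriminate(stage: str) -> None:
        de_mut, de_wt = contrast.per_cluster_de(counts, samples, thr.lfc, thr.q)
        state["de_mut"], state["de_wt"] = de_mut, de_wt
        classification = contrast.classify_genes(de_mut, de_wt, thr.unchanged_band)
        state["classification"] = classification
        io.write_table(de_mut, outdir / "de_mut_vs_normal.tsv")
        io.write_table(de_wt, outdir / "de_wt_vs_normal.tsv")
        io.write_table(classification, outdir / "gene_classification.tsv")
        for name in ("de_mut_vs_normal.tsv", "de_wt_vs_normal.tsv", "gene_classification.tsv"):
            _record(stage, name, outdir / name)

    _run("discriminate", _discriminate)

    # ----- positional scan -------------------------------------------------
    def _scan(stage: str) -> None:
        if "annotation" not in state:
            raise FileNotFoundError(
                "scan stage needs a transcript annotation: set inputs.annotation "
                "or enable the simulate stage"
            )
        if "chrom_lengths" not in state:
            raise FileNotFoundError("scan stage needs chromosome lengths")
        de_tables = {}
        if "de_mut" in state:
            de_tables["mut"], de_tables["wt"] = state["de_mut"], state["de_wt"]
        elif "de_tumor" in state:
            de_tables["tumor"] = state["de_tumor"]
        else:
            raise FileNotFoundError(
                "scan stage needs a DE table: enable the de or discriminate stage"
            )
        pos = positional.assign_positions(state["annotation"])
        all_regions = []
        for label, table in de_tables.items():
            for direction in ("up", "down"):
                windows = positional.scan(
                    pos, table, state["chrom_lengths"], direction, thr.alpha
                )
                name = f"windows_{label}_{direction}.tsv"
                io.write_table(windows, outdir / name)
                _record(stage, name, outdir / name)
                regions = positional.merge_regions(windows, pos, table)
                regions.insert(0, "group", label)
                all_regions.append(regions)
        non_empty = [r for r in all_regions if not r.empty]
        if non_empty:
            merged = pd.concat(non_empty, ignore_index=True)
        else:
            merged = all_regions[0]
        state["regions"] = merged
        io.write_table(merged, outdir / "regions.tsv")
        # BED export: name=group_direction, score=-log10 p
        with open(outdir / "regions.bed", "w") as fh:
            for row in merged.itertuples(index=False):
                score = -np.log10(max(row.p_region, 1e-300))
                fh.write(
                    f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                    f"{row.group}_{row.direction}\t{score:.4g}\n"
                )
        for name in ("regions.tsv", "regions.bed"):
            _record(stage, name, outdir / name)

    _run("scan", _scan)

    # ----- gene-set over-representation ------------------------------------
    def _enrich(stage: str) -> None:
        if "gene_sets" not in state:
            raise FileNotFoundError(
                "enrich stage needs a GMT collection: set inputs.gmt or enable simulate"
            )
        if "de_tumor" in state:
            table = state["de_tumor"]
        elif "de_mut" in state:
            table = state["de_mut"]
        else:
            raise FileNotFoundError("enrich stage needs a DE table: enable the de stage")
        universe = set(table["gene_id"])
        query = set(table.loc[table["call"] != "ns", "gene_id"])
        rows = enrichment.overrepresentation(query, state["gene_sets"], universe)
        state["enrichment"] = rows
        io.write_table(rows, outdir / "enrichment.tsv")
        top = enrichment.top_k(rows, config.enrich_top)
        io.write_table(top, outdir / "enrichment_top.tsv")
        for name in ("enrichment.tsv", "enrichment_top.tsv"):
            _record(stage, name, outdir / name)

    _run("enrich", _enrich)

    summary_path = outdir / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
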