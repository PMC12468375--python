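"""End-to-end orchestration of the repurposing pipeline.

Wires the stages together over a file-based workspace: simulate -> de ->
signature -> aggregate -> enrich -> structsim -> synergy -> report. Each
stage reads the plain-text artifacts of its upstream stages and writes its
own, so stages can be re-run independently; a JSON manifest records the
config snapshot and SHA-256 hashes of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .consensus import (
    aggregate_across_datasets,
    aggregate_within_dataset,
    rank_pathways,
    retain_threshold,
    truncate_top_k,
)
from .de import extract_signature, moderated_t, quantile_normalize
from .enrichment import GeneSetCollection, hypergeom_ora, significant_terms, targets_to_query
from .structsim import cluster_drugs
from .synergy import classify_and_rank, score_surface
from .synthetic import (
    PlantedExpressionTruth,
    PlantedSynergyTruth,
    PlantedToolTruth,
    gen_dose_response,
    gen_expression,
    gen_fingerprints,
    gen_tool_outputs,
    write_truth,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "de", "signature", "aggregate", "enrich", "structsim", "synergy", "report"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_MISSING_DEPENDENCY = 3


class ValidationError(ValueError):
    """Bad configuration or malformed input (CLI exit code 2)."""


class MissingDependencyError(FileNotFoundError):
    """An upstream artifact is absent (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with the study-condition defaults."""

    outdir: str = "reprank_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["MGUS", "sMM", "MM"])
    # consensus
    w1: float = 0.7
    w2: float = 0.3
    top_k: int = 50
    threshold: float = 0.75
    absent_policy: str = "ignore"
    # enrichment
    alpha: float = 0.05
    # de / signature
    signature_size: int = 150
    rank_first: bool = False
    # structural similarity
    n_bits: int = 512
    soergel_cut: float = 0.15
    screen_threshold: float = 0.80
    # synergy
    synergy_thresholds: tuple[float, float] = (5.0, 10.0)
    # synthetic-data conditions
    n_genes: int = 1000
    n_planted_per_direction: int = 100
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_cases: int = 20
    n_controls: int = 20
    n_tools: int = 3
    n_datasets: int = 4
    rank_advantage: float = 0.9
    n_drugs: int = 200
    n_true_reversers: int = 20
    fp_n_drugs: int = 30
    fp_n_clusters: int = 3
    fp_within_tanimoto: float = 0.95
    dr_noise_sd: float = 2.0
    dr_deltas: tuple[float, ...] = (0.0, 7.0, 12.0)

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            logger.warning("w1 + w2 = %.3f != 1", self.w1 + self.w2)
        for name, value, lo, hi in [
            ("threshold", self.threshold, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("soergel_cut", self.soergel_cut, 0, 2),
            ("screen_threshold", self.screen_threshold, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise ValidationError(f"{name}={value} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingDependencyError(f"stage '{stage}' needs missing artifact: {path}")
    return path


def _dataset_ids(config: PipelineConfig) -> list[str]:
    return [f"DS{i + 1}" for i in range(config.n_datasets)]


# -- stage implementations ----------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    """Generate every synthetic input, with truth sidecars."""
    rng = np.random.default_rng([config.seed, 99])
    written: list[Path] = []
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]

    # expression per stage x dataset, one planted truth per stage
    for si, stage in enumerate(config.stages):
        chosen = rng.choice(config.n_genes, size=2 * config.n_planted_per_direction, replace=False)
        truth = PlantedExpressionTruth(
            de_genes_up={genes[i] for i in chosen[: config.n_planted_per_direction]},
            de_genes_down={genes[i] for i in chosen[config.n_planted_per_direction:]},
            effect_size=config.effect_size,
            noise_sd=config.noise_sd,
        )
        for di, dataset_id in enumerate(_dataset_ids(config)):
            ds = gen_expression(
                config.n_genes, config.n_cases, config.n_controls, truth,
                seed=config.seed + 1000 * si + di, stage=stage, dataset_id=dataset_id,
            )
            matrix_path = out / "expression" / f"{stage}_{dataset_id}.tsv"
            samples_path = out / "expression" / f"{stage}_{dataset_id}.samples.tsv"
            io.write_expression(ds, matrix_path, samples_path, seed=config.seed)
            written += [matrix_path, samples_path, write_truth(truth, matrix_path)]

    # tool outputs over one drug universe, per stage
    drugs = [f"drug{i:03d}" for i in range(config.n_drugs)]
    tool_truth = PlantedToolTruth(
        true_reversers=set(drugs[: config.n_true_reversers]),
        n_tools=config.n_tools, n_datasets=config.n_datasets,
        top_k=config.top_k, rank_advantage=config.rank_advantage,
    )
    for si, stage in enumerate(config.stages):
        per_dataset = gen_tool_outputs(drugs, tool_truth, seed=config.seed + 77 * si, stage=stage)
        path = out / "tools" / f"{stage}_tool_outputs.csv"
        io.write_tool_outputs(per_dataset, path, seed=config.seed)
        written += [path, write_truth(tool_truth, path)]

    # fingerprint library with planted clusters
    library, clusters = gen_fingerprints(
        config.fp_n_drugs, config.n_bits, config.fp_n_clusters,
        config.fp_within_tanimoto, seed=config.seed,
    )
    fp_path = out / "fingerprints" / "library.csv"
    io.write_fingerprints(library, fp_path, seed=config.seed)
    truth_path = fp_path.with_suffix(".csv.truth.json")
    truth_path.write_text(json.dumps({"kind": "fingerprints", "clusters": clusters}, indent=2) + "\n")
    written += [fp_path, truth_path]

    # dose-response surfaces: every model x planted delta
    surfaces, truths = [], []
    for mi, model in enumerate(("zip", "loewe", "hsa", "bliss")):
        for di, delta in enumerate(config.dr_deltas):
            truth = PlantedSynergyTruth(
                model=model, delta=float(delta),
                hill_params_a=(0.0, 90.0, 1.0, 1.2), hill_params_b=(0.0, 80.0, 2.0, 0.9),
            )
            doses = np.array([0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
            surf = gen_dose_response(
                truth, doses, doses, noise_sd=config.dr_noise_sd,
                seed=config.seed + 100 * mi + di,
                drug_row=f"{model}_d{delta:g}_A", drug_col=f"{model}_d{delta:g}_B",
            )
            surfaces.append(surf)
            truths.append(truth.as_json())
    dr_path = out / "dose_response" / "surfaces.csv"
    io.write_dose_response(surfaces, dr_path, seed=config.seed)
    dr_truth = dr_path.with_suffix(".csv.truth.json")
    dr_truth.write_text(json.dumps({"kind": "dose_response_suite", "surfaces": truths}, indent=2) + "\n")
    written += [dr_path, dr_truth]

    # gene sets: planted terms enriched for the DE genes of each stage + decoys
    sets: dict[str, tuple[str, list[str]]] = {}
    for si, stage in enumerate(config.stages):
        truth_file = out / "expression" / f"{stage}_DS1.tsv.truth.json"
        planted = json.loads(truth_file.read_text())
        de_genes = planted["de_genes_up"] + planted["de_genes_down"]
        members = list(rng.choice(de_genes, size=min(30, len(de_genes)), replace=False))
        sets[f"SET_{stage}_PLANTED"] = (f"planted {stage} process", members)
    for k in range(20):
        members = [genes[i] for i in rng.choice(config.n_genes, size=30, replace=False)]
        sets[f"SET_DECOY{k:02d}"] = ("random decoy process", members)
    gmt_path = out / "genesets" / "sets.gmt"
    io.write_gmt(sets, gmt_path)
    written.append(gmt_path)

    # synthetic drug-target map over the measured genes
    rows = []
    for drug in drugs:
        for gene_idx in rng.choice(config.n_genes, size=3, replace=False):
            rows.append((drug, genes[gene_idx], "synthetic"))
    targets_path = out / "targets" / "drug_targets.csv"
    io.write_table(pd.DataFrame(rows, columns=["drug", "target", "source"]), targets_path,
                   seed=config.seed)
    written.append(targets_path)
    return written


def stage_de(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    for stage in config.stages:
        for dataset_id in _dataset_ids(config):
            matrix = _require(out / "expression" / f"{stage}_{dataset_id}.tsv", "de")
            samples = _require(out / "expression" / f"{stage}_{dataset_id}.samples.tsv", "de")
            ds = io.read_expression(matrix, samples, stage=stage, dataset_id=dataset_id)
            ds.matrix = quantile_normalize(ds.matrix)
            de = moderated_t(ds)
            path = out / "de" / f"{stage}_{dataset_id}_de.csv"
            written.append(io.write_table(de.reset_index(), path, seed=config.seed))
    return written


def stage_signature(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    for stage in config.stages:
        for dataset_id in _dataset_ids(config):
            de_path = _require(out / "de" / f"{stage}_{dataset_id}_de.csv", "signature")
            de = io.read_table(de_path, index_col=0)
            sig = extract_signature(
                de, stage=stage, dataset_id=dataset_id,
                n_per_direction=config.signature_size, alpha=config.alpha,
                rank_first=config.rank_first,
            )
            path = out / "signatures" / f"{stage}_{dataset_id}_signature.tsv"
            written.append(io.write_signature(sig, path, seed=config.seed))
    return written


def stage_aggregate(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    for stage in config.stages:
        tool_path = _require(out / "tools" / f"{stage}_tool_outputs.csv", "aggregate")
        per_dataset_lists = io.read_tool_outputs(tool_path).get(stage, {})
        if not per_dataset_lists:
            raise ValidationError(f"{tool_path} holds no lists for stage {stage}")
        within = []
        for dataset_id in sorted(per_dataset_lists):
            lists = [truncate_top_k(l, config.top_k) for l in per_dataset_lists[dataset_id]]
            table = aggregate_within_dataset(lists, config.w1, config.w2, config.absent_policy)
            within.append(table)
            path = out / "consensus" / f"{stage}_{dataset_id}_within.csv"
            written.append(io.write_table(table, path, seed=config.seed))
        cross = aggregate_across_datasets(within, stage=stage, w1=config.w1, w2=config.w2,
                                          absent_policy=config.absent_policy)
        cross_path = out / "consensus" / f"{stage}_cross.csv"
        written.append(io.write_table(cross, cross_path, seed=config.seed))
        shortlist = retain_threshold(cross, config.threshold, stage=stage)
        short_path = out / "consensus" / f"{stage}_shortlist.csv"
        written.append(io.write_table(shortlist.retained, short_path, seed=config.seed))
    return written


def stage_enrich(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    gmt_path = _require(out / "genesets" / "sets.gmt", "enrich")
    sets = io.read_gmt(gmt_path)
    universe = frozenset(f"GENE{i:04d}" for i in range(config.n_genes))
    collection = GeneSetCollection(sets=dict(sets), universe=universe)

    for stage in config.stages:
        per_dataset = []
        for dataset_id in _dataset_ids(config):
            sig_path = _require(out / "signatures" / f"{stage}_{dataset_id}_signature.tsv", "enrich")
            sig = io.read_signature(sig_path, stage=stage, dataset_id=dataset_id)
            rows = hypergeom_ora(set(sig.up) | set(sig.down), collection)
            per_dataset.append(rows)
            path = out / "enrichment" / f"{stage}_{dataset_id}_ora.csv"
            written.append(io.write_table(rows, path, seed=config.seed))
        ranked = rank_pathways(per_dataset, stage=stage, w1=config.w1, w2=config.w2)
        written.append(io.write_table(ranked, out / "enrichment" / f"{stage}_pathways_cross.csv",
                                      seed=config.seed))

        # drug-target ORA for the stage shortlist
        short_path = _require(out / "consensus" / f"{stage}_shortlist.csv", "enrich")
        shortlist = retain_threshold(io.read_table(short_path), config.threshold, stage=stage)
        targets = io.read_drug_targets(_require(out / "targets" / "drug_targets.csv", "enrich"))
        query, report = targets_to_query(shortlist, targets)
        if query:
            target_rows = significant_terms(hypergeom_ora(query, collection), config.alpha)
        else:
            target_rows = pd.DataFrame(columns=["term_id", "adj_p"])
        path = out / "enrichment" / f"{stage}_targets_ora.csv"
        written.append(io.write_table(target_rows, path, seed=config.seed))
        (out / "enrichment" / f"{stage}_targets_report.json").write_text(
            json.dumps(report, indent=2) + "\n"
        )
    return written


def stage_structsim(config: PipelineConfig, out: Path) -> list[Path]:
    fp_path = _require(out / "fingerprints" / "library.csv", "structsim")
    library = io.read_fingerprints(fp_path)
    assignment = cluster_drugs(library, cut=config.soergel_cut)
    df = pd.DataFrame(sorted(assignment.labels.items()), columns=["drug_id", "cluster"])
    path = out / "structsim" / "clusters.csv"
    return [io.write_table(df, path, seed=config.seed)]


def stage_synergy(config: PipelineConfig, out: Path) -> list[Path]:
    dr_path = _require(out / "dose_response" / "surfaces.csv", "synergy")
    surfaces = io.read_dose_response(dr_path)
    summaries = [score_surface(s) for s in surfaces]
    table = pd.DataFrame([s.as_dict() for s in summaries])
    written = [io.write_table(table, out / "synergy" / "summaries.csv", seed=config.seed)]
    ranked = classify_and_rank(summaries, thresholds=config.synergy_thresholds)
    for model, top in ranked["top"].items():
        written.append(io.write_table(top, out / "synergy" / f"top_{model}.csv", seed=config.seed))
    written.append(io.write_table(ranked["union"], out / "synergy" / "union.csv", seed=config.seed))
    inter = pd.DataFrame({"pair_id": ranked["intersection"]})
    written.append(io.write_table(inter, out / "synergy" / "intersection.csv", seed=config.seed))
    return written


def stage_report(config: PipelineConfig, out: Path) -> list[Path]:
    """Summarise every stage's outputs and score recovery against truth."""
    lines = [f"reprank v{__version__} run report (seed={config.seed})"]

    for stage in config.stages:
        short_path = out / "consensus" / f"{stage}_shortlist.csv"
        if short_path.exists():
            shortlist = io.read_table(short_path)
            lines.append(f"[{stage}] shortlist: {len(shortlist)} drugs at score >= {config.threshold}")
            truth_path = out / "tools" / f"{stage}_tool_outputs.csv.truth.json"
            if truth_path.exists():
                truth = json.loads(truth_path.read_text())
                planted = {d.casefold() for d in truth["true_reversers"]}
                hits = sum(1 for d in shortlist["item_id"] if str(d).casefold() in planted)
                lines.append(f"[{stage}]   planted reversers recovered in shortlist: {hits}/{len(planted)}")
        ora_path = out / "enrichment" / f"{stage}_pathways_cross.csv"
        if ora_path.exists():
            ranked = io.read_table(ora_path)
            lines.append(f"[{stage}] consensus pathways: {len(ranked)} "
                         f"(top: {ranked['item_id'].iloc[0]} score={ranked['score'].iloc[0]:.3f})")

    cluster_path = out / "structsim" / "clusters.csv"
    if cluster_path.exists():
        clusters = io.read_table(cluster_path)
        n_found = clusters["cluster"].nunique()
        lines.append(f"[structsim] clusters at Soergel <= {config.soergel_cut}: {n_found}")
        truth_path = out / "fingerprints" / "library.csv.truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())["clusters"]
            lines.append(f"[structsim]   planted clusters: {len(set(truth.values()))}")

    synergy_path = out / "synergy" / "summaries.csv"
    if synergy_path.exists():
        table = io.read_table(synergy_path)
        for model in ("zip", "loewe", "hsa", "bliss"):
            n_mod = int((table[f"{model}_class"] == "moderate").sum())
            n_str = int((table[f"{model}_class"] == "strong").sum())
            lines.append(f"[synergy] {model}: {n_mod} moderate, {n_str} strong of {len(table)} pairs")

    if len(lines) == 1:
        lines.append("no stage outputs found")
    text = "\n".join(lines) + "\n"
    print(text, end="")
    path = out / "report.txt"
    path.write_text(text)
    return [path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "signature": stage_signature,
    "aggregate": stage_aggregate,
    "enrich": stage_enrich,
    "structsim": stage_structsim,
    "synergy": stage_synergy,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    requested = stages or STAGE_ORDER
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in requested]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"reprank v{__version__}",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
    }
    for name in ordered:
        t0 = time.perf_counter()
        written = _STAGE_FUNCS[name](config, out)
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(elapsed, 3), "n_outputs": len(written)}
        for path in written:
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
        logger.info("stage %-9s done in %.2fs (%d outputs)", name, elapsed, len(written))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
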