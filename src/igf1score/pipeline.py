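"""End-to-end pipeline: simulate/load -> DE -> signature -> score -> associate.

Each run writes its intermediate artifacts into the output directory and
finishes with a manifest (config hash, package version, per-file SHA-256
checksums, timestamps). Deterministic stages re-run on identical inputs
reproduce identical checksums; a failed stage leaves a manifest flagged
incomplete with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cohort as _cohort
from . import io as _io
from .config import PipelineConfig, save_config
from .de import build_signature, estimate_dispersions, wald_de
from .preprocess import FilterRule, estimate_size_factors, filter_genes
from .score import compute_igf1_score
from .simulate import simulate_cohort, simulate_reference

log = logging.getLogger("igf1score")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    complete: bool = False
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    error: str | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json).hexdigest(),
        version=__version__,
        started=time.time(),
    )
    manifest_path = outdir / "manifest.json"
    save_config(config, outdir / "config.yaml")

    def record(name: str, *paths: Path) -> None:
        manifest.stages.append(name)
        for p in paths:
            manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)

    stage = "setup"
    try:
        sim = dataclasses.replace(config.simulation, seed=config.seed)

        stage = "inputs"
        log.info("stage %s: seed=%d", stage, config.seed)
        if config.counts_ref is not None:
            counts_ref = _io.read_counts(config.counts_ref)
            groups = pd.read_csv(config.groups_ref, sep="\t", comment="#", index_col=0).iloc[:, 0]
            groups = groups.reindex(counts_ref.columns)
        else:
            counts_ref, groups, truth = simulate_reference(sim)
        if config.counts_cohort is not None:
            counts_cohort = _io.read_counts(config.counts_cohort)
            meta = _io.read_metadata(config.metadata_cohort)
        else:
            counts_cohort, meta, cohort_truth = simulate_cohort(sim, truth)
        p_ref = outdir / "reference_counts.tsv"
        p_coh = outdir / "cohort_counts.tsv"
        p_meta = outdir / "cohort_metadata.tsv"
        _io.write_counts(counts_ref, p_ref, comment=f"seed={config.seed}")
        _io.write_counts(counts_cohort, p_coh, comment=f"seed={config.seed}")
        _io.write_metadata(meta, p_meta)
        record("inputs", p_ref, p_coh, p_meta)

        stage = "preprocess"
        rule = FilterRule(config.min_count, config.min_fraction)
        log.info("stage %s: min_count=%d min_fraction=%.4f", stage, rule.min_count, rule.min_fraction)
        filtered = filter_genes(counts_ref, rule)
        sf = estimate_size_factors(filtered)
        p_sf = outdir / "reference_size_factors.tsv"
        _io.write_size_factors(sf, p_sf)
        record("preprocess", p_sf)

        stage = "de"
        log.info("stage %s: NB Wald, pseudocount=%.3g", stage, config.pseudocount)
        disp = estimate_dispersions(filtered, groups, sf)
        res = wald_de(filtered, groups, sf, disp, config.pseudocount)
        p_de = outdir / "de_results.tsv"
        res.to_csv(p_de, sep="\t", index=False)
        record("de", p_de)

        stage = "signature"
        log.info("stage %s: alpha=%.3g", stage, config.alpha)
        sig = build_signature(res, config.alpha)
        p_sig_json = outdir / "signature.json"
        p_sig_gmt = outdir / "signature.gmt"
        _io.write_signature(sig, p_sig_json)
        _io.write_signature(sig, p_sig_gmt)
        record("signature", p_sig_json, p_sig_gmt)

        stage = "score"
        log.info("stage %s: min_overlap=%.2f", stage, config.min_overlap)
        sv = compute_igf1_score(counts_cohort, sig, rule, config.pseudocount, config.min_overlap)
        p_scores = outdir / "scores.tsv"
        scores_df = sv.scores.to_frame()
        scores_df["n_genes_used"] = sv.n_genes_used
        scores_df.to_csv(p_scores, sep="\t", index_label="sample")
        record("score", p_scores)

        stage = "associate"
        log.info("stage %s: stratify_on=%s", stage, config.stratify_on)
        meta_scored = meta.copy()
        meta_scored["igf1_score"] = sv.scores
        strata = _cohort.median_split(meta_scored[config.stratify_on])
        report = _cohort.summarize_cohort(meta_scored, strata)
        p_rep_tsv = outdir / "association_report.tsv"
        p_rep_json = outdir / "association_report.json"
        report.table.to_csv(p_rep_tsv, sep="\t", index=False)
        payload = report.to_json_dict()
        if config.pattern_column in meta_scored:
            payload["score_by_group"] = _cohort.score_by_group(
                sv.scores, meta_scored[config.pattern_column]
            )
        p_rep_json.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        record("associate", p_rep_tsv, p_rep_json)

        manifest.complete = True
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        manifest.error = f"stage {stage!r} failed: {exc}"
        log.error(manifest.error)
        manifest.finished = time.time()
        manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
        raise
    manifest.finished = time.time()
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest
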