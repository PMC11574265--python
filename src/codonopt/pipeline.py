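"""Orchestration of the per-stage analysis with a serializable run config.

A run computes, per stage: proportional codon usage, demand/supply, CAI and
etAI weights, per-transcript scores, and the Watson-Crick vs wobble
dwell-time comparison; across stages: codon-usage CVs and a Fisher z
comparison of the per-stage etAI–decoding-rate correlations; and, when a
time-course is supplied, half-lives, the CSC table and class-content tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import abundance, decay, optimality, stats
from .genetic_code import AnticodonRepertoire, build_decoding_map, default_repertoire, read_cds_fasta

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(Exception):
    """Invalid or inconsistent run configuration."""


class DataError(Exception):
    """Input files that fail to parse or validate."""


@dataclass
class StageInput:
    label: str
    trna_counts_column: str
    expression_samples: list[str] = field(default_factory=list)
    dwell_times: str | None = None


@dataclass
class RunConfig:
    """Fully serializable configuration of one analysis run."""

    cds_fasta: str
    trna_counts: str
    expression: str
    stages: list[StageInput]
    timecourse: str | None = None
    repertoire: str | None = None
    top_fraction: float = 0.05
    t0_min_tpm: float = 10.0
    alpha: float = 0.05
    csc_mode: str = "frequency"
    etai_zero_floor: str | float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            stages = [StageInput(**s) for s in raw.pop("stages", [])]
            cfg = cls(stages=stages, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config fields: {exc}") from exc
        if not cfg.stages:
            raise ConfigError("config must declare at least one stage")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_stage_analysis(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis described by ``config`` into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": {}}
    checksums: dict[str, str] = {}

    for name in ("cds_fasta", "trna_counts", "expression", "timecourse", "repertoire"):
        path = getattr(config, name)
        if path is None:
            continue
        if not Path(path).exists():
            raise DataError(f"{name} file not found: {path}")
        checksums[name] = _checksum(path)

    rep = (AnticodonRepertoire.from_tsv(config.repertoire)
           if config.repertoire else default_repertoire())
    try:
        dmap = build_decoding_map(rep)
        cds_set = read_cds_fasta(config.cds_fasta)
        counts = abundance.read_trna_counts_tsv(config.trna_counts)
        expr = abundance.ExpressionTable.from_tsv(config.expression)
    except (ValueError, OSError) as exc:
        raise DataError(str(exc)) from exc

    n_valid = sum(c.valid for c in cds_set)
    if n_valid == 0:
        raise DataError("no valid CDS records in input FASTA")
    summary["n_cds"] = len(cds_set)
    summary["n_valid_cds"] = n_valid
    dmap.to_tsv(out / "decoding_map.tsv")

    usage_by_stage: dict[str, dict[str, float]] = {}
    etai_rate_corr: dict[str, tuple[float, int]] = {}

    for stage in config.stages:
        label = stage.label
        sdir = out / label
        sdir.mkdir(exist_ok=True)
        if stage.trna_counts_column not in counts.columns:
            raise DataError(f"tRNA counts column {stage.trna_counts_column!r} missing")
        try:
            profile = abundance.trna_proportions(
                counts[stage.trna_counts_column].to_dict(),
                include=rep.labels, label=label,
            )
            tpm = expr.mean_tpm(stage.expression_samples or None)
            usage = abundance.weighted_codon_usage(cds_set, tpm, stage=label)
            ds = abundance.demand_supply(usage, profile, dmap)
            cai_w = optimality.cai_weights(cds_set, tpm, config.top_fraction,
                                           reference_label=label)
            etai_w = optimality.etai_weights(profile, dmap,
                                             zero_floor=config.etai_zero_floor)
        except ValueError as exc:
            raise DataError(f"stage {label}: {exc}") from exc

        usage.to_series().rename_axis("codon").reset_index(name="usage").to_csv(
            sdir / "codon_usage.tsv", sep="\t", index=False)
        ds.to_csv(sdir / "demand_supply.tsv", sep="\t", index=False)
        cai_w.to_tsv(sdir / "cai_weights.tsv")
        etai_w.to_tsv(sdir / "etai_weights.tsv")
        usage_by_stage[label] = dict(usage.usage)
        stage_summary: dict[str, Any] = {"n_expressed": len(tpm)}

        if stage.dwell_times:
            try:
                dts = optimality.DwellTimeTable.from_tsv(stage.dwell_times, label=label)
                rates = optimality.decoding_rates(dts)
                scores = optimality.score_transcripts(cds_set, cai_w, etai_w, rates)
                pairs, w_stat, w_p = optimality.wobble_vs_wc_dt(dts, dmap)
            except (ValueError, OSError) as exc:
                raise DataError(f"stage {label}: {exc}") from exc
            scores.to_csv(sdir / "transcript_scores.tsv", sep="\t", index=False)
            pairs.to_csv(sdir / "wobble_pairs_dt.tsv", sep="\t", index=False)
            r, _ = sps.pearsonr(scores["etai"], scores["decoding_rate"])
            etai_rate_corr[label] = (float(r), len(scores))
            stage_summary.update({
                "wobble_vs_wc_p": w_p,
                "etai_decoding_rate_r": float(r),
            })
        summary["stages"][label] = stage_summary

    if len(usage_by_stage) >= 2:
        cv = abundance.cross_stage_cv(usage_by_stage)
        pd.DataFrame(sorted(cv.items()), columns=["codon", "cv_percent"]).to_csv(
            out / "codon_usage_cv.tsv", sep="\t", index=False)
        finite = [v for v in cv.values() if np.isfinite(v)]
        summary["usage_cv_percent_range"] = [min(finite), max(finite)] if finite else None

    if len(etai_rate_corr) >= 2:
        (l1, (r1, n1)), (l2, (r2, n2)) = list(etai_rate_corr.items())[:2]
        cmp = stats.fisher_z_compare(r1, n1, r2, n2)
        summary["etai_rate_correlation_comparison"] = {
            "stage1": l1, "stage2": l2, "r1": r1, "r2": r2,
            "z": cmp.z_stat, "p": cmp.p_two_sided,
        }

    if config.timecourse:
        try:
            courses = decay.read_timecourse_tsv(config.timecourse)
            results = decay.fit_half_lives(courses, config.t0_min_tpm, config.alpha)
            freqs = decay.transcript_codon_frequencies(cds_set, mode=config.csc_mode)
            csc = decay.compute_csc(freqs, results, alpha=config.alpha)
        except ValueError as exc:
            raise DataError(f"time-course: {exc}") from exc
        decay.half_lives_to_frame(results).to_csv(out / "half_lives.tsv",
                                                  sep="\t", index=False)
        csc.to_tsv(out / "csc.tsv")
        n_classes = csc.table["codon_class"].value_counts().to_dict()
        summary["half_life"] = {
            "n_fit": len(results),
            "n_retained": sum(r.status == decay.STATUS_RETAINED for r in results),
        }
        summary["csc_classes"] = {k: int(v) for k, v in n_classes.items()}

    config.to_yaml(out / "config.yaml")
    with open(out / "run_log.json", "w") as fh:
        json.dump({"input_checksums": checksums}, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("analysis complete: %s", out)
    return out
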