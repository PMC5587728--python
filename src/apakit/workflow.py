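"""Pipeline orchestration: alignments in, atlases and statistics out.

Runs the stages in order — PASS calling per sample, atlas construction
(clustering, annotation, filtering, signal classes), expression and
regulation calls, APA significance and trend statistics, and motif
analyses — writing plain TSV/BED/JSON outputs so every stage is
independently inspectable, with a machine-readable summary and manifest.
Identical inputs and seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from . import apa, atlas, motif, pass_reads, quantify

logger = logging.getLogger("apakit")

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Invalid run configuration; carries the full error list."""

    def __init__(self, errors: Sequence[str]):
        super().__init__("; ".join(errors))
        self.errors = list(errors)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class SampleSpec:
    path: str
    sample_id: str
    condition: str


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Thresholds default to the standard analysis settings: 24-nt cluster
    window, >= 2 reads and > 5% relative abundance for PAS retention,
    fold change > 2 with > 50 reads for regulation calls, BH FDR < 0.05
    for APA significance, and a -100..+100 motif scan window.
    """

    genome: str
    annotation: str
    samples: list[SampleSpec]
    out_dir: str
    pfm: str | None = None
    seed: int = 0
    ctrl_condition: str = "ctrl"
    window: int = 24
    min_reads: int = 2
    min_frac: float = 0.05
    extension: int = 4000
    min_mapq: int = 10
    min_tail: int = 2
    tail_mode: str = "five_prime_t"
    fc_cutoff: float = 2.0
    min_total: int = 50
    fdr: float = 0.05
    pseudocount: float = 1.0
    depth_equalize: bool = True
    scan_upstream: int = 100
    scan_downstream: int = 100
    variant_hexamers: tuple[str, ...] = atlas.DEFAULT_VARIANT_HEXAMERS

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_cutoff))


def validate_config(config) -> RunConfig:
    """Normalise a mapping or RunConfig, collecting all validation errors."""
    if isinstance(config, Mapping):
        data = dict(config)
        samples = [
            s if isinstance(s, SampleSpec) else SampleSpec(**s)
            for s in data.pop("samples", [])
        ]
        if "variant_hexamers" in data:
            data["variant_hexamers"] = tuple(data["variant_hexamers"])
        try:
            config = RunConfig(samples=samples, **data)
        except TypeError as exc:
            raise ConfigError([str(exc)]) from exc
    errors = []
    for path_field in ("genome", "annotation"):
        p = getattr(config, path_field)
        if not p or not Path(p).exists():
            errors.append(f"{path_field} path does not exist: {p!r}")
    if config.pfm is not None and not Path(config.pfm).exists():
        errors.append(f"pfm path does not exist: {config.pfm!r}")
    if not config.samples:
        errors.append("at least one sample is required")
    for spec in config.samples:
        if not Path(spec.path).exists():
            errors.append(f"sample SAM does not exist: {spec.path!r}")
    if config.window < 0:
        errors.append(f"window must be >= 0, got {config.window}")
    if config.min_reads < 1:
        errors.append("min_reads must be >= 1")
    if not 0 <= config.min_frac <= 1:
        errors.append(f"min_frac must be in [0, 1], got {config.min_frac}")
    if config.fc_cutoff <= 0:
        errors.append("fc_cutoff must be positive")
    if not 0 < config.fdr < 1:
        errors.append(f"fdr must be in (0, 1), got {config.fdr}")
    if config.extension < 0:
        errors.append("extension must be >= 0")
    if config.tail_mode not in ("five_prime_t", "three_prime_a"):
        errors.append(f"unknown tail_mode {config.tail_mode!r}")
    if errors:
        raise ConfigError(errors)
    return config


def load_config(path) -> RunConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    base = Path(path).parent
    for key in ("genome", "annotation", "pfm", "out_dir"):
        if data.get(key):
            data[key] = str((base / data[key]).resolve()) if not Path(
                data[key]
            ).is_absolute() else data[key]
    for sample in data.get("samples", []):
        if not Path(sample["path"]).is_absolute():
            sample["path"] = str((base / sample["path"]).resolve())
    return validate_config(data)


def read_annotation(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {
        "gene_id",
        "contig",
        "strand",
        "gene_start",
        "gene_end",
        "last_exon_start",
        "last_exon_end",
        "biotype",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    return frame


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary."""
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"seed": config.seed, "samples": {}}

    def emit(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        _write_tsv(frame, path, index=index)
        written.append(path)

    # --- stage: PASS calling -------------------------------------------
    stage = "callpas"
    try:
        genome = pyfaidx.Fasta(str(config.genome))
        results = []
        for spec in config.samples:
            result = pass_reads.call_pass_reads(
                spec.path,
                genome,
                spec.sample_id,
                min_mapq=config.min_mapq,
                min_tail=config.min_tail,
                tail_mode=config.tail_mode,
            )
            logger.info(
                "%s: %d records, %d PASS events, rejections=%s",
                spec.sample_id,
                result.n_records,
                result.n_events,
                dict(result.rejections),
            )
            summary["samples"][spec.sample_id] = {
                "condition": spec.condition,
                "records": result.n_records,
                "pass_events": result.n_events,
                "rejections": dict(result.rejections),
            }
            results.append(result)
        merged = pass_reads.merge_tallies([r.tally for r in results])
        emit(pass_reads.tally_to_frame(merged), "cleavage_counts.tsv")
        emit(
            pd.concat([r.rejection_frame for r in results], ignore_index=True),
            "rejections.tsv",
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- stage: atlas ---------------------------------------------------
    stage = "atlas"
    try:
        annotation = read_annotation(config.annotation)
        clusters = atlas.cluster_cleavage_sites(merged, window=config.window)
        clusters = atlas.annotate_pas_location(
            clusters, annotation, extension=config.extension
        )
        retained = atlas.filter_pas_clusters(
            clusters, min_reads=config.min_reads, min_frac=config.min_frac
        )
        atlas.attach_signal_classes(
            retained, genome, variant_hexamers=config.variant_hexamers
        )
        logger.info("atlas: %d clusters, %d retained", len(clusters), len(retained))
        sample_ids = [s.sample_id for s in config.samples]
        atlas_frame = atlas.clusters_to_frame(retained, sample_ids)
        emit(atlas_frame, "pas_atlas.tsv")
        (out / "pas_atlas.bed").write_text(atlas.clusters_to_bed(retained))
        written.append(out / "pas_atlas.bed")
        summary["n_clusters"] = len(clusters)
        summary["n_retained_pas"] = len(retained)
        summary["n_genes_with_pas"] = int(
            atlas_frame["gene_id"].dropna().nunique()
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    if not retained:
        raise StageError("atlas", RuntimeError("no PAS clusters retained"))

    # --- stage: quantify -------------------------------------------------
    stage = "quantify"
    try:
        counts, meta = atlas.frame_to_counts(atlas_frame)
        meta = meta.copy()
        meta["biotype"] = meta["gene_id"].map(
            annotation.set_index("gene_id")["biotype"]
        )
        table = quantify.CountTable(counts, meta)
        gene_rpm = quantify.gene_level_expression(table)
        emit(table.rpm, "pas_rpm.tsv", index=True)
        emit(gene_rpm, "gene_rpm.tsv", index=True)

        ctrl_samples = [
            s.sample_id for s in config.samples if s.condition == config.ctrl_condition
        ]
        kd_samples = [
            s.sample_id for s in config.samples if s.condition != config.ctrl_condition
        ]
        if not ctrl_samples or not kd_samples:
            raise ValueError(
                f"need control ({config.ctrl_condition!r}) and knockdown samples"
            )
        ctrl = ctrl_samples[0]
        summary["comparisons"] = {}
        fc_columns = {}
        calls_frames = []
        for kd in kd_samples:
            log2fc = quantify.transcript_fold_change(
                table, kd, ctrl, pseudocount=config.pseudocount
            )
            totals = table.counts[kd] + table.counts[ctrl]
            regulation = quantify.call_regulated_transcripts(
                log2fc, totals, fc_cutoff=config.fc_cutoff, min_total=config.min_total
            )
            fc_columns[kd] = log2fc
            frame = regulation.calls.copy()
            frame.insert(0, "comparison", f"{kd}_vs_{ctrl}")
            calls_frames.append(frame)
            gene_fc = quantify.gene_fold_change(
                table, kd, ctrl, pseudocount=config.pseudocount
            )
            strata = quantify.expression_strata(gene_rpm[ctrl])
            ks_expr = quantify.stratified_ks(gene_fc, strata, ("low", "high"))
            biotype = meta.drop_duplicates("gene_id").set_index("gene_id")["biotype"]
            ks_bio = quantify.stratified_ks(
                gene_fc, biotype.reindex(gene_fc.index), ("mRNA", "lncRNA")
            )
            summary["comparisons"][f"{kd}_vs_{ctrl}"] = {
                "n_down": regulation.n_down,
                "n_up": regulation.n_up,
                "down_up_ratio": None
                if not np.isfinite(regulation.down_up_ratio)
                else regulation.down_up_ratio,
                "down_up_ratio_infinite": regulation.ratio_infinite,
                "ks_low_vs_high_p": ks_expr.pvalue,
                "ks_mrna_vs_lncrna_p": ks_bio.pvalue,
            }
        emit(pd.concat(calls_frames), "transcript_calls.tsv", index=True)
        if len(fc_columns) >= 2:
            matrix = pd.DataFrame(fc_columns)
            regulated_any = pd.concat(
                [f["call"] != "unchanged" for f in calls_frames], axis=1
            ).any(axis=1)
            matrix = matrix[regulated_any.reindex(matrix.index, fill_value=False)]
            if len(matrix) >= 2:
                link, labels = quantify.cluster_samples(matrix)
                emit(
                    pd.DataFrame(
                        link, columns=["node_a", "node_b", "distance", "n_members"]
                    ),
                    "sample_linkage.tsv",
                )
                summary["sample_linkage_labels"] = labels
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: apa -------------------------------------------------------
    stage = "apa"
    try:
        summary["apa"] = {}
        utr_frames = []
        ur_frames = []
        for kd in kd_samples:
            utr = apa.run_saap_utr(
                table,
                ctrl,
                kd,
                fdr_threshold=config.fdr,
                pseudocount=config.pseudocount,
                depth_equalize=config.depth_equalize,
                seed=config.seed,
                clusters=retained,
            )
            trend = apa.gaap_utr_trend(utr, fdr_threshold=config.fdr)
            ur, ur_trend = apa.run_ur_group_test(
                table,
                ctrl,
                kd,
                fdr_threshold=config.fdr,
                pseudocount=config.pseudocount,
                depth_equalize=config.depth_equalize,
                seed=config.seed,
                clusters=retained,
            )
            utr = utr.copy()
            utr.insert(0, "comparison", f"{kd}_vs_{ctrl}")
            ur = ur.copy()
            ur.insert(0, "comparison", f"{kd}_vs_{ctrl}")
            utr_frames.append(utr)
            ur_frames.append(ur)
            summary["apa"][f"{kd}_vs_{ctrl}"] = {
                "n_tested_utr": int(utr["testable"].sum()),
                "n_shortened": trend.n_negative,
                "n_lengthened": trend.n_positive,
                "utr_trend_log2": trend.trend,
                "n_ur_activated": ur_trend.n_positive,
                "n_ur_suppressed": ur_trend.n_negative,
                "ur_trend_log2": ur_trend.trend,
            }
        emit(pd.concat(utr_frames, ignore_index=True), "apa_utr.tsv")
        emit(pd.concat(ur_frames, ignore_index=True), "apa_ur.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: motif -----------------------------------------------------
    stage = "motif"
    try:
        pfm = motif.Pfm.from_tsv(config.pfm) if config.pfm else motif.example_pfm()
        flanks = {
            cluster_id: motif.extract_flank(
                genome,
                row["contig"],
                int(row["position"]),
                row["strand"],
                upstream=config.scan_upstream,
                downstream=config.scan_downstream,
            )
            for cluster_id, row in meta.iterrows()
        }
        full = {
            cid: f
            for cid, f in flanks.items()
            if len(f) == config.scan_upstream + config.scan_downstream + 1
        }
        scores = pd.Series(
            {
                cid: motif.mean_upstream_score(f, pfm, upstream=config.scan_upstream)
                for cid, f in full.items()
            },
            name="mean_upstream_score",
        )
        emit(scores.to_frame(), "motif_scores.tsv", index=True)
        profile = motif.build_meta_profile(
            list(full.values()), pfm, upstream=config.scan_upstream
        )
        emit(
            pd.DataFrame(
                {
                    "offset": profile.offsets,
                    "mean_score": profile.raw,
                    "smoothed": profile.smoothed,
                }
            ),
            "motif_meta_profile.tsv",
        )
        kd = kd_samples[0]
        log2fc = fc_columns[kd].reindex(scores.index)
        if len(scores) >= 20:
            ks = motif.percentile_group_ks(
                scores.to_numpy(), log2fc.to_numpy(), cut="90th"
            )
            summary["motif_score_ks"] = {
                "comparison": f"{kd}_vs_{ctrl}",
                "statistic": ks.statistic,
                "p_value": ks.pvalue,
            }
        calls = calls_frames[0]
        down_ids = calls.index[calls["call"] == "down"]
        other_ids = calls.index[calls["call"] != "down"]
        region = (-100, -41)
        if len(down_ids) >= 1 and len(other_ids) >= 1:
            group = [
                f[region[0] + config.scan_upstream : region[1] + config.scan_upstream + 1]
                for cid, f in full.items()
                if cid in set(down_ids)
            ]
            background = [
                f[region[0] + config.scan_upstream : region[1] + config.scan_upstream + 1]
                for cid, f in full.items()
                if cid in set(other_ids)
            ]
            if group and background:
                enrich = motif.kmer_enrichment(
                    group, background, k=4, region_id="-100..-41"
                )
                emit(enrich, "kmer_enrichment.tsv")
            sig_groups = {
                "down": [
                    meta.at[cid, "signal_class"]
                    for cid in down_ids
                    if pd.notna(meta.at[cid, "signal_class"])
                ],
                "other": [
                    meta.at[cid, "signal_class"]
                    for cid in other_ids
                    if pd.notna(meta.at[cid, "signal_class"])
                ],
            }
            if all(sig_groups.values()):
                comp = motif.signal_composition_test(sig_groups, ("down", "other"))
                emit(
                    comp.counts.reset_index(names="group"), "signal_composition.tsv"
                )
                summary["signal_composition_p"] = comp.pvalue
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    summary_path = out / "summary.json"
    with open(summary_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=float)
    written.append(summary_path)
    manifest = {p.name: _sha256(p) for p in written}
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    summary["manifest"] = manifest
    return summary
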