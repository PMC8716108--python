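"""End-to-end orchestration: simulate/load → call TTSs → quantify → motif →
statistics, with a machine-readable run summary.

Every tunable keeps the published default where one exists (search window
200 nt, ratio filter 1.1, difference filter 5, TTE cut-offs 0.3/0.6, TQRR
cut-offs 0.6/1.0); the effective configuration is serialized verbatim into
the summary so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import stats_summary, synthetic_data, terminator_motif
from .formats_io import (
    EndCoverageTrack,
    read_bedgraph,
    read_fasta,
    read_gff3,
    write_tts_table,
)
from .termination_metrics import annotate_metrics, metrics_to_frame
from .tts_caller import call_tts

logger = logging.getLogger("termtte")

__all__ = ["StageError", "RunConfig", "run_full", "validate_inputs"]

_DEFAULTS: dict[str, Any] = {
    "max_downstream": 200,
    "ratio_min": 1.1,
    "diff_min": 5,
    "min_reads": 10,
    "combine": "mean",
    "wt_condition": "WT",
    "dep_condition": "dep",
    "which_contexts": "primary",
    "seed": 0,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(dict):
    """A strict flat config: unknown keys are rejected at construction."""

    _KNOWN = set(_DEFAULTS) | {
        "genome", "gff", "coverage", "sim", "outdir", "log_level",
    }

    def __init__(self, mapping: Mapping[str, Any] | None = None, **kw: Any):
        merged = {**_DEFAULTS, **(dict(mapping) if mapping else {}), **kw}
        unknown = set(merged) - self._KNOWN
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        super().__init__(merged)


def _load_inputs(config: RunConfig):
    """Either simulate (config['sim']) or read FASTA/GFF3/bedGraph inputs.

    ``config['coverage']`` maps a condition label to
    ``{replicate: {'+': path, '-': path}}``.
    """
    if "sim" in config:
        sim_kw = dict(config["sim"])
        sim_kw.setdefault("seed", config["seed"])
        cfg = synthetic_data.SimConfig(**sim_kw)
        ds = synthetic_data.simulate_dataset(cfg)
        return ds.genome, ds.tus, {
            cond: ds.tracks_for(cond) for cond in synthetic_data.CONDITIONS
        }, ds.truths
    genomes = read_fasta(config["genome"])
    if len(genomes) != 1:
        raise ValueError("exactly one replicon expected in the genome FASTA")
    genome = genomes[0]
    tus = read_gff3(config["gff"], genomes)
    tracks: dict[str, list[EndCoverageTrack]] = {}
    for cond, reps in config["coverage"].items():
        tracks[cond] = []
        for rep, by_strand in reps.items():
            for strand, path in by_strand.items():
                tracks[cond].append(read_bedgraph(
                    path, cond, int(rep), strand,
                    genome_length=len(genome)))
    return genome, tus, tracks, None


def validate_inputs(config: RunConfig) -> dict:
    """Pre-flight consistency checks; returns a report, never raises."""
    failures: list[str] = []
    if "sim" in config:
        return {"failures": failures}
    try:
        genomes = read_fasta(config["genome"])
        chroms = {g.chrom_id for g in genomes}
    except Exception as exc:  # noqa: BLE001 - report, don't raise
        return {"failures": [f"genome unreadable: {exc}"]}
    try:
        read_gff3(config["gff"], genomes)
    except Exception as exc:  # noqa: BLE001
        failures.append(f"annotation problem: {exc}")
    coverage = config.get("coverage", {})
    for cond, reps in coverage.items():
        if len(reps) < 2:
            failures.append(
                f"condition {cond!r} has {len(reps)} replicate(s); "
                "replicate consensus needs >= 2")
        for rep, by_strand in reps.items():
            missing = {"+", "-"} - set(by_strand)
            if missing:
                failures.append(
                    f"{cond} rep {rep}: missing strand file(s) "
                    f"{sorted(missing)}")
            for strand, path in by_strand.items():
                try:
                    t = read_bedgraph(path, cond, int(rep), strand)
                except Exception as exc:  # noqa: BLE001
                    failures.append(f"{path}: unreadable ({exc})")
                    continue
                if t.chrom is not None and t.chrom not in chroms:
                    failures.append(
                        f"{path}: chromosome {t.chrom!r} not in genome "
                        f"FASTA ({sorted(chroms)})")
    return {"failures": failures}


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_full(config: RunConfig | Mapping[str, Any]) -> dict:
    """Execute every stage in order and write the standard outputs.

    Writes ``tts.tsv``, ``metrics.tsv``, ``contexts.tsv``, ``motif.json``,
    ``summary.json`` (and ``recovery.json`` for simulated inputs) into
    ``config['outdir']``; returns the summary dict.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)

    genome, tus, tracks, truths = _stage("load")(_load_inputs)(config)
    wt = config["wt_condition"]
    dep = config["dep_condition"] if config["dep_condition"] in tracks else None
    logger.info("loaded %d TUs, conditions: %s", len(tus), sorted(tracks))

    @_stage("call-tts")
    def _call():
        return call_tts(
            genome_length=len(genome), tus=tus, wt_tracks=tracks[wt],
            tracks_by_condition=tracks,
            max_downstream=config["max_downstream"],
            ratio_min=config["ratio_min"], diff_min=config["diff_min"],
            min_reads=config["min_reads"], combine=config["combine"],
        )

    records = _call()
    n_primary = sum(r.is_primary for r in records)
    logger.info("called %d TTSs (%d primary)", len(records), n_primary)
    write_tts_table(records, outdir / "tts.tsv")

    @_stage("quantify")
    def _quantify():
        return annotate_metrics(records, wt_condition=wt, dep_condition=dep)

    metrics = _quantify()

    @_stage("motif")
    def _motif():
        contexts = terminator_motif.annotate_contexts(
            genome, records, which=config["which_contexts"])
        matrix = terminator_motif.build_motif_matrix(
            [c for c in contexts if not c.clipped])
        return contexts, matrix

    contexts, matrix = _motif()
    by_key = {(c.tu_id, c.pos): c for c in contexts}
    for m in metrics:
        c = by_key.get((m.tu_id, m.pos))
        if c is not None:
            m.u4_count, m.u4_group = c.u4_count, c.u4_group

    metrics_to_frame(metrics).to_csv(outdir / "metrics.tsv", sep="\t",
                                     index=False)
    pd.DataFrame([vars(c) for c in contexts]).to_csv(
        outdir / "contexts.tsv", sep="\t", index=False)
    with open(outdir / "motif.json", "w") as fh:
        json.dump(matrix.to_dict(), fh, indent=1, sort_keys=True)

    @_stage("stats")
    def _stats():
        primary = [m for m in metrics if m.is_primary]
        evaluable = [m for m in primary
                     if m.tte_wt is not None and m.u4_count is not None]
        out: dict[str, Any] = {
            "n_tts": len(records),
            "n_primary": n_primary,
            "n_tte_unevaluable": sum(m.tte_wt is None for m in primary),
            "tte_group_counts": {
                g: sum(m.tte_group == g for m in primary)
                for g in ("high", "medium", "low")
            },
            "u4_group_counts": {
                g: sum(m.u4_group == g for m in primary)
                for g in ("0", "1", "2", ">2")
            },
        }
        if len(evaluable) >= 3:
            try:
                rho, p = stats_summary.spearman(
                    [m.u4_count for m in evaluable],
                    [m.tte_wt for m in evaluable])
                out["spearman_u4_tte"] = {
                    "rho": rho, "p": p,
                    "p_text": stats_summary.format_pvalue(p)}
            except ValueError:
                out["spearman_u4_tte"] = None
        out["tte_by_u4_group"] = [
            dataclasses.asdict(g)
            for g in stats_summary.group_summaries(primary, "u4_group",
                                                   "tte_wt")]
        if dep is not None:
            with_tqrr = [m for m in primary if m.tqrr is not None]
            out["n_tqrr_unevaluable"] = sum(m.tqrr is None for m in primary)
            out["dependency_class_counts"] = {
                g: sum(m.dependency_class == g for m in primary)
                for g in ("highly", "moderately", "non")
            }
            out["tqrr_by_u4_group"] = [
                dataclasses.asdict(g)
                for g in stats_summary.group_summaries(primary, "u4_group",
                                                       "tqrr")]
            if with_tqrr:
                overall, by_group = stats_summary.dependency_fractions(primary)
                out["fraction_tqrr_lt1"] = overall
                out["fraction_tqrr_lt1_by_u4_group"] = by_group
        return out

    # outdir is machine-specific and would break byte-level reproducibility
    summary = {
        "config": {k: v for k, v in sorted(config.items()) if k != "outdir"},
        "stats": _stats(),
    }

    if truths is not None:
        recovery = synthetic_data.recovery_report(metrics, truths)
        summary["recovery"] = recovery
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=1, sort_keys=True)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
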