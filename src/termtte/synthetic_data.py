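"""Synthetic Term-seq data with planted terminators, for recovery testing.

The generator emits a genome, a gene annotation, per-strand 3'-end coverage
tracks for two conditions × two replicates, and a truth table of the planted
parameters.  The statistical structure mirrors what the termination analysis
assumes about real data:

* each TU ends in a terminator window (-31..-1 of the planted TTS) written
  into the genome with an exact number of maximal U-runs (T-runs on the
  coding strand) of length 4-7;
* 3'-end counts form an upstream plateau at level λ, a peak at the TTS
  (-1 site, factor ``1 + c·e``), and a readthrough tail at ``λ·(1-e)``, where
  ``e`` is the planted termination efficacy; counts are Poisson
  (optionally negative-binomial) with a uniform background ε everywhere;
* planted efficacy increases with the U4-tract count (defaults follow the
  published group medians: 30 %, 43.3 %, 52.1 %, 55.5 % for 0/1/2/≥3 tracts);
* in the depletion condition the efficacy drops to ``e·(1-δ)`` with δ
  increasing with U4 count, so factor dependency (TQRR < 1) is planted.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    EndCoverageTrack,
    GenomeSequence,
    TranscriptionUnitAnnotation,
    write_bedgraph,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_genome",
    "simulate_coverage",
    "simulate_dataset",
    "write_dataset",
    "recovery_report",
]

CONDITIONS = ("WT", "dep")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults are the conditions the termination analysis was designed for:
    two replicates, Poisson counts, planted efficacies at the published
    per-group medians and depletion losses that increase with U4 count.
    """

    n_tus: int = 200
    genome_gc: float = 0.33          # M. maripaludis-like AT-rich genome
    tu_length_range: tuple[int, int] = (200, 400)
    utr_offset_range: tuple[int, int] = (20, 150)  # TTS distance after stop
    u4_weights: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.19, 1: 0.40, 2: 0.26, 3: 0.15})
    depth_lambda: float = 200.0      # mean 3'-end count at the plateau
    lambda_spread: float = 0.5       # λ_tu uniform in λ·[1-s, 1+s]
    peak_factor: float = 3.0         # -1 site mean = λ·(1 + c·e)
    background_eps: float = 1.0
    tte_base: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.300, 1: 0.433, 2: 0.521, 3: 0.555})
    tte_jitter_sd: float = 0.05
    dependency_delta: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.20, 1: 0.35, 2: 0.50, 3: 0.55})
    delta_jitter_sd: float = 0.05
    replicates: int = 2
    plateau_len: int = 60            # upstream plateau, nt (rel -plateau..-2)
    tail_len: int = 30               # readthrough tail, nt (rel +1..+tail)
    intergenic_gap: int = 60
    noise: str = "poisson"           # poisson | nb | off
    nb_dispersion: float = 10.0      # NB size parameter (larger → Poisson)
    chrom_id: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.genome_gc < 1:
            raise ValueError("genome_gc must be in (0, 1)")
        if self.noise not in {"poisson", "nb", "off"}:
            raise ValueError(f"unknown noise model {self.noise!r}")
        for u4, e in self.tte_base.items():
            if not 0 <= e < 1:
                raise ValueError(f"planted TTE for u4={u4} outside [0, 1)")
        lo, hi = self.utr_offset_range
        if not 1 <= lo <= hi <= 200:
            raise ValueError("utr_offset_range must lie within [1, 200]")


@dataclass
class SimTruth:
    """Planted per-TU parameters, the oracle for recovery tests."""

    tu_id: str
    strand: str
    planted_tts_pos: int
    u4_count_planted: int
    tte_wt_true: float
    tte_dep_true: float
    lambda_tu: float


@dataclass
class SimDataset:
    config: SimConfig
    genome: GenomeSequence
    tus: list[TranscriptionUnitAnnotation]
    tracks: dict[tuple[str, int, str], EndCoverageTrack]  # (cond, rep, strand)
    truths: list[SimTruth]

    def tracks_for(self, condition: str,
                   strand: str | None = None) -> list[EndCoverageTrack]:
        return [t for (c, _r, s), t in sorted(self.tracks.items())
                if c == condition and (strand is None or s == strand)]


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *key]))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _terminator_window(rng: np.random.Generator, u4: int,
                       width: int = 31) -> str:
    """A ``width``-nt RNA-sense window (written as DNA, T for U) containing
    exactly ``u4`` maximal T-runs of length 4-7.

    Filler positions are drawn from {A, C, G} so no accidental run can form
    or merge two planted runs; runs are separated by at least one filler.
    """
    while True:
        run_lens = rng.integers(4, 8, size=u4)
        if run_lens.sum() + max(u4 - 1, 0) <= width:
            break
    fill_total = width - int(run_lens.sum())
    # u4+1 gaps: internal ones get 1 guaranteed separator each
    gaps = np.zeros(u4 + 1, dtype=int)
    if u4 >= 1:
        gaps[1:u4] = 1
    remaining = fill_total - int(gaps.sum())
    if remaining > 0:
        extra = rng.multinomial(remaining, np.full(u4 + 1, 1 / (u4 + 1)))
        gaps += extra
    parts = []
    for i in range(u4 + 1):
        parts.append("".join(rng.choice(np.array(list("ACG")), size=gaps[i])))
        if i < u4:
            parts.append("T" * int(run_lens[i]))
    return "".join(parts)


_RC = str.maketrans("ACGT", "TGCA")


def simulate_genome(cfg: SimConfig) -> tuple[GenomeSequence,
                                             list[TranscriptionUnitAnnotation],
                                             list[SimTruth]]:
    """Lay out TUs on alternating strands with planted terminator windows.

    ``SimTruth`` entries come back with efficacies already drawn; only the
    coverage itself is left to :func:`simulate_coverage`.
    """
    layout_rng = _rng(cfg, 1)
    param_rng = _rng(cfg, 2)
    u4_levels = sorted(cfg.u4_weights)
    weights = np.array([cfg.u4_weights[u] for u in u4_levels], float)
    weights = weights / weights.sum()

    tus: list[TranscriptionUnitAnnotation] = []
    truths: list[SimTruth] = []
    plants: list[tuple[int, str]] = []  # (genomic start of window, +strand seq)
    cursor = 1 + cfg.intergenic_gap
    for i in range(cfg.n_tus):
        strand = "+" if i % 2 == 0 else "-"
        gene_len = int(layout_rng.integers(*cfg.tu_length_range,
                                           endpoint=True))
        offset = int(layout_rng.integers(*cfg.utr_offset_range,
                                         endpoint=True))
        u4 = int(layout_rng.choice(u4_levels, p=weights))
        window = _terminator_window(layout_rng, u4)
        if strand == "+":
            span_start = cursor
            stop3 = span_start + gene_len - 1
            tts = stop3 + offset
            plants.append((tts - 30, window))
            cursor = tts + cfg.tail_len + cfg.intergenic_gap + 1
        else:
            tts = cursor + cfg.tail_len
            stop3 = tts + offset
            span_start, stop3_end = stop3, stop3 + gene_len - 1
            # - strand: RNA-sense window maps to revcomp on the stored strand
            plants.append((tts, window[::-1].translate(_RC)))
            cursor = stop3_end + cfg.intergenic_gap + 1
        if strand == "+":
            span = (span_start, stop3)
        else:
            span = (span_start, stop3 + gene_len - 1)
        tu_id = f"TU{i + 1:04d}"
        tus.append(TranscriptionUnitAnnotation(
            tu_id=tu_id, chrom=cfg.chrom_id, strand=strand,
            span_start=span[0], span_end=span[1], stop3=stop3,
            biotype="coding"))

        e = float(np.clip(
            cfg.tte_base[min(u4, max(cfg.tte_base))]
            + param_rng.normal(0, cfg.tte_jitter_sd), 0.02, 0.95))
        delta = float(np.clip(
            cfg.dependency_delta[min(u4, max(cfg.dependency_delta))]
            + param_rng.normal(0, cfg.delta_jitter_sd), 0.0, 0.95))
        lam = float(cfg.depth_lambda
                    * param_rng.uniform(1 - cfg.lambda_spread,
                                        1 + cfg.lambda_spread))
        truths.append(SimTruth(
            tu_id=tu_id, strand=strand, planted_tts_pos=tts,
            u4_count_planted=u4, tte_wt_true=e,
            tte_dep_true=e * (1 - delta), lambda_tu=lam))

    genome_len = cursor + cfg.intergenic_gap
    seq = _random_dna(_rng(cfg, 3), genome_len, cfg.genome_gc)
    for start, window in plants:
        seq[start - 1:start + 30] = list(window)
    genome = GenomeSequence(cfg.chrom_id, "".join(seq))
    return genome, tus, truths


def _mean_profile(cfg: SimConfig, truth: SimTruth, genome_len: int,
                  condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Genomic positions and Poisson means of one TU's 3'-end profile."""
    e = truth.tte_wt_true if condition == "WT" else truth.tte_dep_true
    lam = truth.lambda_tu
    rels = np.concatenate([np.arange(-cfg.plateau_len, 0),      # -plateau..-1
                           np.arange(1, cfg.tail_len + 1)])     # +1..+tail
    means = np.where(rels <= -2, lam,
                     np.where(rels == -1, lam * (1 + cfg.peak_factor * e),
                              lam * (1 - e)))
    steps = np.where(rels < 0, rels + 1, rels)
    sign = 1 if truth.strand == "+" else -1
    pos = truth.planted_tts_pos + sign * steps
    keep = (pos >= 1) & (pos <= genome_len)
    return pos[keep], means[keep]


def simulate_coverage(cfg: SimConfig, genome_len: int,
                      truths: Sequence[SimTruth],
                      ) -> dict[tuple[str, int, str], EndCoverageTrack]:
    """Draw the per-track counts: 2 conditions × replicates × 2 strands."""
    tracks: dict[tuple[str, int, str], EndCoverageTrack] = {}
    for ci, cond in enumerate(CONDITIONS):
        for rep in range(1, cfg.replicates + 1):
            for si, strand in enumerate("+-"):
                mean = np.full(genome_len, float(cfg.background_eps))
                for truth in truths:
                    if truth.strand != strand:
                        continue
                    pos, mu = _mean_profile(cfg, truth, genome_len, cond)
                    mean[pos - 1] += mu
                rng = _rng(cfg, 10, ci, rep, si)
                if cfg.noise == "off":
                    counts = np.rint(mean)
                elif cfg.noise == "poisson":
                    counts = rng.poisson(mean)
                else:  # negative binomial with size r: p = r/(r+mu)
                    r = cfg.nb_dispersion
                    counts = rng.negative_binomial(r, r / (r + mean))
                nz = np.nonzero(counts)[0]
                tracks[(cond, rep, strand)] = EndCoverageTrack(
                    condition=cond, replicate=rep, strand=strand,
                    counts={int(i + 1): float(counts[i]) for i in nz},
                    chrom=cfg.chrom_id)
    return tracks


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Genome + annotation + coverage + truth, fully determined by the seed."""
    genome, tus, truths = simulate_genome(cfg)
    tracks = simulate_coverage(cfg, len(genome), truths)
    return SimDataset(config=cfg, genome=genome, tus=tus, tracks=tracks,
                      truths=truths)


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gff3, per-track bedGraphs and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta([ds.genome], paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    write_gff3(ds.tus, [ds.genome], paths["annotation"])
    for (cond, rep, strand), track in sorted(ds.tracks.items()):
        name = f"{cond}_rep{rep}_{'plus' if strand == '+' else 'minus'}.bedgraph"
        write_bedgraph(track, outdir / name, chrom=ds.genome.chrom_id)
        paths[name] = outdir / name
    truth_df = pd.DataFrame([dataclasses.asdict(t) for t in ds.truths])
    paths["truth"] = outdir / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_report(metrics: Sequence, truths: Sequence[SimTruth],
                    ) -> dict:
    """Compare pipeline output against the planted truth.

    ``metrics`` are :class:`~termtte.termination_metrics.TerminationMetrics`
    for called TTSs (primary records are matched positionally against the
    planted sites).  Reports exact-position recall/precision, per-U4-group
    TTE bias and RMSE, TQRR bias, and the monotonicity of median TTE and
    TQRR across U4 groups.
    """
    truth_by_id = {t.tu_id: t for t in truths}
    primaries = [m for m in metrics if m.is_primary]
    unknown = {m.tu_id for m in primaries} - set(truth_by_id)
    if unknown:
        raise KeyError(f"called TUs absent from truth table: {sorted(unknown)}")
    matched = [m for m in primaries
               if m.pos == truth_by_id[m.tu_id].planted_tts_pos]
    recall = len(matched) / len(truths) if truths else 0.0
    precision = len(matched) / len(primaries) if primaries else 0.0

    by_group: dict[str, dict] = {}
    med_tte, med_tqrr = {}, {}
    for label, sel in [("0", [0]), ("1", [1]), ("2", [2]),
                       (">2", list(range(3, 100)))]:
        sub = [m for m in matched
               if truth_by_id[m.tu_id].u4_count_planted in sel]
        errs = [m.tte_wt - truth_by_id[m.tu_id].tte_wt_true
                for m in sub if m.tte_wt is not None]
        tqrr_errs = []
        for m in sub:
            t = truth_by_id[m.tu_id]
            if m.tqrr is not None and t.tte_dep_true < 1:
                true_tqrr = (1 - t.tte_wt_true) / (1 - t.tte_dep_true)
                tqrr_errs.append(m.tqrr - true_tqrr)
        ttes = [m.tte_wt for m in sub if m.tte_wt is not None]
        tqrrs = [m.tqrr for m in sub if m.tqrr is not None]
        by_group[label] = {
            "n": len(sub),
            "tte_bias": float(np.mean(errs)) if errs else None,
            "tte_rmse": float(np.sqrt(np.mean(np.square(errs))))
            if errs else None,
            "tqrr_bias": float(np.mean(tqrr_errs)) if tqrr_errs else None,
        }
        if ttes:
            med_tte[label] = float(np.median(ttes))
        if tqrrs:
            med_tqrr[label] = float(np.median(tqrrs))

    order = ["0", "1", "2", ">2"]
    tte_series = [med_tte[g] for g in order if g in med_tte]
    tqrr_series = [med_tqrr[g] for g in order if g in med_tqrr]
    return {
        "n_true": len(truths),
        "n_called_primary": len(primaries),
        "recall": recall,
        "precision": precision,
        "by_u4_group": by_group,
        "median_tte_by_group": med_tte,
        "median_tqrr_by_group": med_tqrr,
        "tte_monotone_nondecreasing": all(
            a <= b for a, b in zip(tte_series, tte_series[1:])),
        "tqrr_monotone_nonincreasing": all(
            a >= b for a, b in zip(tqrr_series, tqrr_series[1:])),
    }
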