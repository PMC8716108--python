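"""Transcription termination site (TTS) calling from 3'-end coverage.

A candidate TTS is a position whose 3'-end read count drops sharply to the
next nucleotide in transcription direction: the read ratio of the -1 site
(the TTS nucleotide) to the +1 site must exceed ``ratio_min`` (default 1.1)
and the count difference must exceed ``diff_min`` (default 5).  Search is
restricted to the 200 nt immediately downstream of each coding gene's stop
codon, which enriches authentic termination sites over RNA processing or
degradation 3' ends.  Sites must pass in both replicates of the reference
(wild-type) condition; the site with the highest -1 signal in a TU is its
primary TTS, all others are secondary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats_io import (
    EndCoverageTrack,
    FormatError,
    TranscriptionUnitAnnotation,
    rel_to_genomic,
)

__all__ = [
    "TTSCandidate",
    "TTSRecord",
    "search_window",
    "find_candidates",
    "replicate_consensus",
    "assign_primary",
    "utr3_length",
    "call_tts",
    "call_tts_ncrna",
]


@dataclass
class TTSCandidate:
    """A position passing the drop filters in at least one replicate."""

    tu_id: str
    chrom: str
    strand: str
    pos: int
    reads_m1: dict[int, float] = field(default_factory=dict)  # replicate → -1
    reads_p1: dict[int, float] = field(default_factory=dict)  # replicate → +1
    passes: dict[int, bool] = field(default_factory=dict)


@dataclass
class TTSRecord:
    """A called TTS with quadruplet counts and primary/secondary status.

    ``quadruplet`` maps a condition label to replicate-combined counts at the
    relative positions (-2, -1, +1, +2).
    """

    tu_id: str
    chrom: str
    strand: str
    pos: int
    is_primary: bool
    utr3_len: int
    quadruplet: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)
    reads_m1: dict[int, float] = field(default_factory=dict)
    overlaps_cds: bool = False


def search_window(tu: TranscriptionUnitAnnotation, genome_length: int,
                  max_downstream: int = 200) -> tuple[int, int]:
    """The ``max_downstream`` nt immediately 3' of the stop codon.

    Returns a 1-based inclusive genomic interval, clipped at the genome end.
    """
    if tu.stop3 is None:
        raise ValueError(f"{tu.tu_id}: no stop codon anchor (ncRNA TU?)")
    if tu.strand == "+":
        lo, hi = tu.stop3 + 1, min(tu.stop3 + max_downstream, genome_length)
    else:
        lo, hi = max(tu.stop3 - max_downstream, 1), tu.stop3 - 1
    if lo > hi:
        raise FormatError(
            f"{tu.tu_id}: search window downstream of stop codon at "
            f"{tu.stop3} falls entirely outside the genome"
        )
    return lo, hi


def _passes_filters(r_m1: float, r_p1: float, ratio_min: float,
                    diff_min: float) -> bool:
    # A nonzero -1 count over a zero +1 count passes the ratio criterion:
    # the intended inequality is "-1 exceeds +1 by > (ratio_min-1)*100 %".
    ratio_ok = r_m1 > 0 and (r_p1 == 0 or r_m1 / r_p1 > ratio_min)
    return ratio_ok and (r_m1 - r_p1) > diff_min


def find_candidates(track: EndCoverageTrack, window: tuple[int, int],
                    strand: str, tu_id: str = "", chrom: str = "",
                    ratio_min: float = 1.1,
                    diff_min: float = 5) -> list[TTSCandidate]:
    """Scan every position of ``window`` with the ratio and difference filters."""
    lo, hi = window
    out = []
    for pos in range(lo, hi + 1):
        nxt = pos + 1 if strand == "+" else pos - 1
        r_m1, r_p1 = track[pos], track[nxt]
        if _passes_filters(r_m1, r_p1, ratio_min, diff_min):
            out.append(TTSCandidate(
                tu_id=tu_id, chrom=chrom, strand=strand, pos=pos,
                reads_m1={track.replicate: r_m1},
                reads_p1={track.replicate: r_p1},
                passes={track.replicate: True},
            ))
    return out


def replicate_consensus(
        per_replicate: Sequence[list[TTSCandidate]]) -> list[TTSCandidate]:
    """Keep positions that pass the filters in every replicate.

    Candidate lists must come from the same TU/window with identical
    parameters; replicate counts are merged onto the surviving candidates.
    """
    if not per_replicate:
        return []
    common = set.intersection(*[{c.pos for c in cands}
                                for cands in per_replicate])
    by_pos: dict[int, TTSCandidate] = {}
    for cands in per_replicate:
        for c in cands:
            if c.pos not in common:
                continue
            if c.pos not in by_pos:
                by_pos[c.pos] = TTSCandidate(
                    tu_id=c.tu_id, chrom=c.chrom, strand=c.strand, pos=c.pos)
            merged = by_pos[c.pos]
            merged.reads_m1.update(c.reads_m1)
            merged.reads_p1.update(c.reads_p1)
            merged.passes.update(c.passes)
    return [by_pos[p] for p in sorted(common)]


def _combine(values: Sequence[float], mode: str) -> float:
    if mode == "mean":
        return sum(values) / len(values)
    if mode == "pooled":
        return float(sum(values))
    raise ValueError(f"unknown combine mode {mode!r}")


def quadruplet_counts(tracks: Sequence[EndCoverageTrack], pos: int,
                      strand: str,
                      combine: str = "mean") -> tuple[float, float, float, float]:
    """Replicate-combined counts at relative positions (-2, -1, +1, +2)."""
    quad = []
    for rel in (-2, -1, 1, 2):
        g = rel_to_genomic(pos, rel, strand)
        quad.append(_combine([t[g] for t in tracks], combine))
    return tuple(quad)


def utr3_length(stop3: int, tts_pos: int, strand: str) -> int:
    """3'UTR length: nt from the first position after the stop codon through
    the TTS nucleotide inclusive (a TTS immediately after the stop codon → 1).
    """
    d = tts_pos - stop3 if strand == "+" else stop3 - tts_pos
    if d < 1:
        raise ValueError(
            f"TTS at {tts_pos} is not downstream of stop codon 3' end {stop3}"
        )
    return d


def assign_primary(tu: TranscriptionUnitAnnotation,
                   sites: list[TTSCandidate],
                   tracks_by_condition: Mapping[str, Sequence[EndCoverageTrack]],
                   combine: str = "mean") -> list[TTSRecord]:
    """Mark the site with the highest replicate-mean -1 count as primary.

    Ties break toward the site most proximal to the stop codon.  Quadruplet
    counts for every supplied condition are attached replicate-combined.
    """
    if not sites:
        return []

    def mean_m1(c: TTSCandidate) -> float:
        return sum(c.reads_m1.values()) / len(c.reads_m1)

    def stop_distance(c: TTSCandidate) -> int:
        return utr3_length(tu.stop3, c.pos, tu.strand)

    primary = min(sites, key=lambda c: (-mean_m1(c), stop_distance(c)))
    records = []
    for c in sorted(sites, key=stop_distance):
        records.append(TTSRecord(
            tu_id=c.tu_id, chrom=c.chrom, strand=c.strand, pos=c.pos,
            is_primary=c is primary,
            utr3_len=stop_distance(c),
            quadruplet={
                cond: quadruplet_counts(tracks, c.pos, tu.strand, combine)
                for cond, tracks in tracks_by_condition.items()
            },
            reads_m1=dict(c.reads_m1),
        ))
    return records


def _call_in_window(tu: TranscriptionUnitAnnotation, window: tuple[int, int],
                    wt_tracks: Sequence[EndCoverageTrack],
                    tracks_by_condition: Mapping[str, Sequence[EndCoverageTrack]],
                    ratio_min: float, diff_min: float, min_reads: float,
                    combine: str) -> list[TTSRecord]:
    per_rep = [
        find_candidates(t, window, tu.strand, tu.tu_id, tu.chrom,
                        ratio_min, diff_min)
        for t in wt_tracks
    ]
    consensus = replicate_consensus(per_rep)
    # "high coverage" surrogate: minimum -1 count per replicate
    consensus = [c for c in consensus
                 if all(v >= min_reads for v in c.reads_m1.values())]
    return assign_primary(tu, consensus, tracks_by_condition, combine)


def call_tts(genome_length: int,
             tus: Iterable[TranscriptionUnitAnnotation],
             wt_tracks: Sequence[EndCoverageTrack],
             tracks_by_condition: Mapping[str, Sequence[EndCoverageTrack]],
             max_downstream: int = 200, ratio_min: float = 1.1,
             diff_min: float = 5, min_reads: float = 10,
             combine: str = "mean",
             cds_index: Sequence[TranscriptionUnitAnnotation] | None = None,
             ) -> list[TTSRecord]:
    """Full caller for coding TUs: window → filters → consensus → primary.

    ``wt_tracks`` are the reference-condition replicate tracks used for
    candidate detection (one per replicate, same strand handling as the TU);
    ``tracks_by_condition`` supplies every condition whose quadruplet counts
    should be attached.  Tracks must be pre-selected per strand by the caller
    (see :func:`termtte.pipeline.run_full`).
    """
    records: list[TTSRecord] = []
    for tu in tus:
        if tu.biotype != "coding":
            continue
        try:
            window = search_window(tu, genome_length, max_downstream)
        except FormatError:
            continue
        strand_wt = [t for t in wt_tracks if t.strand == tu.strand]
        strand_cond = {
            cond: [t for t in tracks if t.strand == tu.strand]
            for cond, tracks in tracks_by_condition.items()
        }
        recs = _call_in_window(tu, window, strand_wt, strand_cond,
                               ratio_min, diff_min, min_reads, combine)
        if cds_index is not None:
            for r in recs:
                r.overlaps_cds = any(
                    o.biotype == "coding" and o.tu_id != tu.tu_id
                    and o.span_start <= r.pos <= o.span_end
                    for o in cds_index
                )
        records.extend(recs)
    return records


def call_tts_ncrna(tus: Iterable[TranscriptionUnitAnnotation],
                   windows: Mapping[str, tuple[int, int]],
                   wt_tracks: Sequence[EndCoverageTrack],
                   tracks_by_condition: Mapping[str, Sequence[EndCoverageTrack]],
                   ratio_min: float = 1.1, diff_min: float = 5,
                   min_reads: float = 10,
                   combine: str = "mean") -> list[TTSRecord]:
    """ncRNA mode: identical filters/consensus, explicit per-TU windows.

    ncRNAs have no stop codon, so the user supplies each search interval;
    ``utr3_len`` is reported relative to the window's 5' edge.
    """
    records: list[TTSRecord] = []
    for tu in tus:
        if tu.tu_id not in windows:
            raise KeyError(f"no search window supplied for ncRNA {tu.tu_id!r}")
        lo, hi = windows[tu.tu_id]
        if lo > hi:  # zero-length window → no calls
            continue
        # anchor utr3_len at the window edge just 5' of it
        anchor = lo - 1 if tu.strand == "+" else hi + 1
        pseudo = TranscriptionUnitAnnotation(
            tu_id=tu.tu_id, chrom=tu.chrom, strand=tu.strand,
            span_start=min(tu.span_start, lo), span_end=max(tu.span_end, hi),
            stop3=anchor, biotype="coding")
        strand_wt = [t for t in wt_tracks if t.strand == tu.strand]
        strand_cond = {
            cond: [t for t in tracks if t.strand == tu.strand]
            for cond, tracks in tracks_by_condition.items()
        }
        records.extend(_call_in_window(
            pseudo, (lo, hi), strand_wt, strand_cond,
            ratio_min, diff_min, min_reads, combine))
    return records
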