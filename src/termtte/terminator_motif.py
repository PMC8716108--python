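"""Terminator U4-tract counting and TTS-flanking motif matrices.

Archaeal intrinsic terminators are U-rich tracts without a required upstream
hairpin.  The signal counted here is the U4-tract: a maximal run of at least
four consecutive uridines in the RNA-sense window from -31 to -1 relative to
the TTS (31 nt, TTS nucleotide included).  A run of five or seven Us is one
tract, not several — the maximal-run convention; N breaks a run.

Motif matrices cover the -30..+5 logo window (35 nt) and report per-position
base counts plus information content in bits (2 minus the Shannon entropy of
the position's base frequencies, no small-sample correction).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import FormatError, GenomeSequence, extract_rna_window

__all__ = [
    "TerminatorContext",
    "MotifMatrix",
    "count_u4_tracts",
    "classify_u4_group",
    "annotate_contexts",
    "build_motif_matrix",
    "pwm_log_odds",
    "U4_WINDOW",
    "LOGO_WINDOW",
]

U4_WINDOW = (-31, -1)   # terminator scan window, TTS-inclusive, 31 nt
LOGO_WINDOW = (-30, 5)  # logo window, 35 nt

_BASES = "ACGU"
_U4_RE = re.compile(r"U{4,}")


@dataclass
class TerminatorContext:
    """The terminator-window sequences and U4-tract annotation of one TTS."""

    tu_id: str
    pos: int
    strand: str
    is_primary: bool
    window_seq: str | None   # -31..-1, None when clipped at a genome end
    logo_seq: str | None     # -30..+5, None when clipped
    u4_count: int | None
    u4_group: str | None
    clipped: bool = False


@dataclass
class MotifMatrix:
    """Per-position base counts and information content over -30..+5."""

    positions: list[int]                   # zero-free relative labels
    freq: dict[str, list[int]]             # base → counts per position
    info_bits: list[float]
    n_sequences: int

    def to_dict(self) -> dict:
        return {
            "positions": self.positions,
            "freq": self.freq,
            "info_bits": self.info_bits,
            "n_sequences": self.n_sequences,
        }


def count_u4_tracts(seq: str) -> int:
    """Number of maximal runs of ≥ 4 consecutive U in an RNA-sense string."""
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-ACGUN symbols in sequence: {sorted(bad)}")
    return len(_U4_RE.findall(seq))


def classify_u4_group(count: int) -> str:
    """Four-way grouping by U4-tract number: '0', '1', '2', '>2' (≥ 3)."""
    if count < 0:
        raise ValueError("negative U4-tract count")
    return str(count) if count <= 2 else ">2"


def annotate_contexts(genome: GenomeSequence, tts_records: Iterable,
                      which: str = "primary") -> list[TerminatorContext]:
    """Extract terminator and logo windows for called TTSs and count U4-tracts.

    ``which`` selects ``"primary"`` TTSs (the default, matching the published
    terminator analysis) or ``"all"``.  Windows running off a genome end are
    flagged clipped and excluded from motif matrices.
    """
    if which not in {"primary", "all"}:
        raise ValueError(f"which must be 'primary' or 'all', got {which!r}")
    contexts = []
    for rec in tts_records:
        if which == "primary" and not rec.is_primary:
            continue
        try:
            window_seq = extract_rna_window(genome, rec.strand, rec.pos,
                                            *U4_WINDOW)
        except FormatError:
            window_seq = None
        try:
            logo_seq = extract_rna_window(genome, rec.strand, rec.pos,
                                          *LOGO_WINDOW)
        except FormatError:
            logo_seq = None
        clipped = window_seq is None or logo_seq is None
        u4 = count_u4_tracts(window_seq) if window_seq is not None else None
        contexts.append(TerminatorContext(
            tu_id=rec.tu_id, pos=rec.pos, strand=rec.strand,
            is_primary=rec.is_primary,
            window_seq=window_seq, logo_seq=logo_seq,
            u4_count=u4,
            u4_group=classify_u4_group(u4) if u4 is not None else None,
            clipped=clipped,
        ))
    return contexts


def _column_info(counts: dict[str, int]) -> float:
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = -sum((c / total) * math.log2(c / total)
             for c in counts.values() if c > 0)
    return 2.0 - h


def build_motif_matrix(contexts: Sequence[TerminatorContext]) -> MotifMatrix:
    """Base-count and information matrix over the -30..+5 logo window.

    Only full-length (unclipped) logo sequences contribute.  N bases are
    excluded from their column, so column totals may fall below the sequence
    count at N-containing positions.
    """
    seqs = [c.logo_seq for c in contexts
            if c.logo_seq is not None and len(c.logo_seq) == 35]
    if not seqs:
        raise ValueError("no full-length logo sequences to build a matrix from")
    positions = [r for r in range(LOGO_WINDOW[0], LOGO_WINDOW[1] + 1) if r != 0]
    freq = {b: [0] * len(positions) for b in _BASES}
    info = []
    for i in range(len(positions)):
        col = {b: 0 for b in _BASES}
        for s in seqs:
            if s[i] in col:
                col[s[i]] += 1
        for b in _BASES:
            freq[b][i] = col[b]
        info.append(_column_info(col))
    return MotifMatrix(positions=positions, freq=freq, info_bits=info,
                       n_sequences=len(seqs))


def pwm_log_odds(matrix: MotifMatrix, seq: str,
                 pseudocount: float = 0.5) -> float:
    """Optional extension: log2-odds score of a 35-nt sequence against the
    matrix, relative to a uniform background (0.25 per base).

    This is a plain PWM match score; it is not part of the core statistics.
    """
    if len(seq) != len(matrix.positions):
        raise ValueError(
            f"sequence length {len(seq)} != matrix width {len(matrix.positions)}"
        )
    score = 0.0
    for i, base in enumerate(seq):
        if base not in _BASES:  # N contributes nothing
            continue
        total = sum(matrix.freq[b][i] for b in _BASES) + 4 * pseudocount
        p = (matrix.freq[base][i] + pseudocount) / total
        score += math.log2(p / 0.25)
    return score
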