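"""I/O for the standard formats the pipeline touches, and the coordinate
conventions used throughout.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere in memory and in TSV
  output.  bedGraph input/output uses the standard 0-based half-open dialect.
* Relative coordinates around a termination site (TTS) are zero-free, as is
  customary for Term-seq work: ``-1`` is the TTS nucleotide itself, ``-2`` the
  nucleotide immediately 5' of it, ``+1`` immediately 3'; there is no
  position 0.  All windows (terminator scan ``-31..-1``, logo ``-30..+5``)
  are stated in these coordinates.
* "Downstream" means increasing genomic coordinate on the ``+`` strand and
  decreasing coordinate on the ``-`` strand.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TranscriptionUnitAnnotation",
    "EndCoverageTrack",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "rel_to_genomic",
    "extract_rna_window",
    "write_tts_table",
    "read_tts_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A malformed input file or an out-of-bounds coordinate request."""


@dataclass(frozen=True)
class GenomeSequence:
    """One replicon: an uppercase DNA sequence (plus strand as stored)."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.chrom_id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"sequence of {self.chrom_id!r} contains non-ACGTN symbols: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` on the stored (+) strand."""
        if not 1 <= pos <= len(self.sequence):
            raise FormatError(
                f"position {pos} outside {self.chrom_id!r} (length {len(self)})"
            )
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class TranscriptionUnitAnnotation:
    """A gene/TU with strand, span and the stop-codon 3' anchor.

    ``stop3`` is the genomic coordinate of the 3'-most nucleotide of the stop
    codon in transcription direction: the maximal CDS end on ``+``, the
    minimal CDS start on ``-``.  ncRNA TUs carry ``stop3 = None``.
    """

    tu_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    stop3: int | None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span_start > self.span_end:
            raise ValueError(
                f"{self.tu_id}: span_start {self.span_start} > span_end "
                f"{self.span_end}"
            )
        if self.biotype == "coding":
            if self.stop3 is None:
                raise ValueError(f"{self.tu_id}: coding TU without stop3")
            if not self.span_start <= self.stop3 <= self.span_end:
                raise ValueError(
                    f"{self.tu_id}: stop3 {self.stop3} outside span "
                    f"[{self.span_start}, {self.span_end}]"
                )


@dataclass
class EndCoverageTrack:
    """Strand-specific per-base transcript 3'-end read counts for one sample.

    Positions absent from ``counts`` read as 0; lookups never fail.
    """

    condition: str
    replicate: int
    strand: str
    counts: dict[int, float] = field(default_factory=dict)
    chrom: str | None = None

    def __getitem__(self, pos: int) -> float:
        return self.counts.get(pos, 0)

    def total(self) -> float:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are uppercased and U is converted to T."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA header id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.append(GenomeSequence(rec.id, seq))
    return out


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.chrom_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_NCRNA_TYPES = {"ncRNA", "ncRNA_gene", "tRNA", "rRNA", "sRNA"}


def read_gff3(path: str | Path,
              genome: list[GenomeSequence]) -> list[TranscriptionUnitAnnotation]:
    """Read gene/CDS features into TU annotations.

    For each coding gene ``stop3`` is the maximal CDS end on ``+`` and the
    minimal CDS start on ``-``.  Gene records without any CDS child are
    treated (with a warning) as ncRNA TUs.
    """
    path = Path(path)
    lengths = {g.chrom_id: len(g) for g in genome}
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    tus: list[TranscriptionUnitAnnotation] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in {"gene"} | _NCRNA_TYPES:
            continue
        if feat.seqid not in lengths:
            raise FormatError(
                f"{path}: seqid {feat.seqid!r} absent from the genome FASTA"
            )
        if feat.end > lengths[feat.seqid]:
            raise FormatError(
                f"{path}: feature {feat.id} extends past end of {feat.seqid!r}"
            )
        cds = list(db.children(feat, featuretype="CDS"))
        if feat.featuretype == "gene" and cds:
            stop3 = (max(c.end for c in cds) if feat.strand == "+"
                     else min(c.start for c in cds))
            biotype = "coding"
        else:
            if feat.featuretype == "gene":
                warnings.warn(
                    f"gene {feat.id} has no CDS; treating as ncRNA",
                    stacklevel=2,
                )
            stop3, biotype = None, "ncRNA"
        tus.append(TranscriptionUnitAnnotation(
            tu_id=feat.id, chrom=feat.seqid, strand=feat.strand,
            span_start=feat.start, span_end=feat.end,
            stop3=stop3, biotype=biotype,
        ))
    return tus


def write_gff3(tus: Iterable[TranscriptionUnitAnnotation],
               genome: list[GenomeSequence], path: str | Path) -> None:
    """Write TU annotations as GFF3 gene (+CDS for coding) features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome:
            fh.write(f"##sequence-region {g.chrom_id} 1 {len(g)}\n")
        for tu in tus:
            ftype = "gene" if tu.biotype == "coding" else "ncRNA"
            fh.write(
                f"{tu.chrom}\ttermtte\t{ftype}\t{tu.span_start}\t{tu.span_end}"
                f"\t.\t{tu.strand}\t.\tID={tu.tu_id}\n"
            )
            if tu.biotype == "coding":
                fh.write(
                    f"{tu.chrom}\ttermtte\tCDS\t{tu.span_start}\t{tu.span_end}"
                    f"\t.\t{tu.strand}\t0\tID={tu.tu_id}.cds;Parent={tu.tu_id}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, condition: str, replicate: int,
                  strand: str, genome_length: int | None = None,
                  chrom: str | None = None) -> EndCoverageTrack:
    """Read a bedGraph (0-based half-open) into a per-base 1-based track.

    Overlapping intervals, negative counts, and coordinates beyond the genome
    (when ``genome_length`` is given) are errors.
    """
    path = Path(path)
    counts: dict[int, float] = {}
    track_chrom = chrom
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            c, start, end, value = fields
            start, end = int(start), int(end)
            value = float(value)
            if track_chrom is None:
                track_chrom = c
            elif c != track_chrom:
                raise FormatError(
                    f"{path}:{lineno}: multiple chromosomes not supported "
                    f"({c!r} vs {track_chrom!r})"
                )
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative count {value}")
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            if genome_length is not None and end > genome_length:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} beyond genome "
                    f"length {genome_length}"
                )
            for pos in range(start + 1, end + 1):  # 0-based half-open → 1-based
                if pos in counts:
                    raise FormatError(
                        f"{path}:{lineno}: overlapping interval at position {pos}"
                    )
                if value != 0:
                    counts[pos] = value
    return EndCoverageTrack(condition=condition, replicate=replicate,
                            strand=strand, counts=counts, chrom=track_chrom)


def write_bedgraph(track: EndCoverageTrack, path: str | Path,
                   chrom: str | None = None) -> None:
    """Write a track as bedGraph, merging runs of equal adjacent counts."""
    chrom = chrom or track.chrom or "chr"
    positions = sorted(p for p, v in track.counts.items() if v != 0)
    with open(path, "w") as fh:
        i = 0
        while i < len(positions):
            j = i
            value = track.counts[positions[i]]
            while (j + 1 < len(positions)
                   and positions[j + 1] == positions[j] + 1
                   and track.counts[positions[j + 1]] == value):
                j += 1
            fmt = f"{value:g}"
            fh.write(f"{chrom}\t{positions[i] - 1}\t{positions[j]}\t{fmt}\n")
            i = j + 1


# ---------------------------------------------------------------------------
# Relative-coordinate windows
# ---------------------------------------------------------------------------

def rel_to_genomic(tts_pos: int, rel: int, strand: str) -> int:
    """Map a zero-free relative coordinate to a genomic position.

    ``-1`` maps to the TTS nucleotide itself; negative offsets run 5' of it
    and positive offsets 3' of it, in transcription direction.
    """
    if rel == 0:
        raise ValueError("relative coordinates have no position 0")
    step = rel + 1 if rel < 0 else rel
    return tts_pos + step if strand == "+" else tts_pos - step


def extract_rna_window(genome: GenomeSequence, strand: str, tts_pos: int,
                       rel_start: int, rel_end: int) -> str:
    """Extract the RNA-sense sequence over ``rel_start..rel_end`` around a TTS.

    The returned string reads 5'→3' in transcription direction (reverse
    complement on the ``-`` strand) with T replaced by U.  A window running
    off either genome end raises :class:`FormatError`.
    """
    if rel_start >= rel_end:
        raise ValueError("rel_start must be < rel_end")
    rels = [r for r in range(rel_start, rel_end + 1) if r != 0]
    bases = []
    for r in rels:
        g = rel_to_genomic(tts_pos, r, strand)
        b = genome.base(g)  # raises FormatError when out of bounds
        if strand == "-":
            b = b.translate(_COMPLEMENT)
        bases.append(b)
    return "".join(bases).replace("T", "U")


# ---------------------------------------------------------------------------
# TTS tables
# ---------------------------------------------------------------------------

_TTS_FIXED_COLS = ["tu_id", "chrom", "strand", "pos", "is_primary", "utr3_len"]
_QUAD_LABELS = ("m2", "m1", "p1", "p2")


def write_tts_table(records, path: str | Path) -> None:
    """Write called-TTS records (optionally with metrics) as a TSV.

    Quadruplet counts appear as ``<condition>_{m2,m1,p1,p2}`` columns; the
    table round-trips losslessly through :func:`read_tts_table`.
    """
    rows = []
    conditions: list[str] = []
    for rec in records:
        row = {
            "tu_id": rec.tu_id, "chrom": rec.chrom, "strand": rec.strand,
            "pos": rec.pos, "is_primary": rec.is_primary,
            "utr3_len": rec.utr3_len,
        }
        for cond, quad in rec.quadruplet.items():
            if cond not in conditions:
                conditions.append(cond)
            for label, v in zip(_QUAD_LABELS, quad):
                row[f"{cond}_{label}"] = v
        rows.append(row)
    cols = _TTS_FIXED_COLS + [f"{c}_{l}" for c in conditions
                              for l in _QUAD_LABELS]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_tts_table(path: str | Path):
    """Read a TSV written by :func:`write_tts_table` back into records."""
    from .tts_caller import TTSRecord  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t")
    conditions = sorted({c.rsplit("_", 1)[0] for c in df.columns
                         if c.endswith("_m2")})
    records = []
    for _, row in df.iterrows():
        quad = {
            cond: tuple(float(row[f"{cond}_{l}"]) for l in _QUAD_LABELS)
            for cond in conditions
            if not pd.isna(row[f"{cond}_m2"])
        }
        records.append(TTSRecord(
            tu_id=row.tu_id, chrom=row.chrom, strand=row.strand,
            pos=int(row.pos), is_primary=bool(row.is_primary),
            utr3_len=int(row.utr3_len), quadruplet=quad,
        ))
    return records
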