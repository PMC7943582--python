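"""Genome and transcript-annotation data model.

Parses GTF transcript structure, derives 5'UTR / CDS / 3'UTR intervals in a
strand-aware way, extracts transcript-sense sequences, and assigns genomic
peaks to annotation feature classes (the classification behind "fraction of
peaks in 3'UTRs" style summaries).

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

Interval = tuple[int, int]

# Feature labels, in assignment precedence order (highest first). A peak
# overlapping several classes takes the highest-precedence class among the
# same-strand transcripts it touches.
FEATURE_THREE_UTR = "three_utr"
FEATURE_FIVE_UTR = "five_utr"
FEATURE_CDS = "cds_exon"
FEATURE_NONCODING = "noncoding_exon"
FEATURE_INTRON = "intron"
FEATURE_INTERGENIC = "intergenic"

FEATURE_PRECEDENCE = (
    FEATURE_THREE_UTR,
    FEATURE_FIVE_UTR,
    FEATURE_CDS,
    FEATURE_NONCODING,
    FEATURE_INTRON,
    FEATURE_INTERGENIC,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome name -> length (bases)."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length < 0:
                raise AnnotationError(f"negative length for chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect(intervals: Sequence[Interval], lo: int, hi: int) -> list[Interval]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


@dataclass
class Transcript:
    """One transcript: sorted non-overlapping exons, optional CDS span,
    and the 5'UTR / CDS / 3'UTR interval lists derived from them.

    ``three_utr`` lies 3' of the CDS in transcript orientation: genomically
    right of the CDS on '+', left of it on '-'.  Non-coding transcripts
    (no ``cds_span``) have all three derived lists empty.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_span: Interval | None = None
    five_utr: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: invalid exon ({s}, {e})"
                )
        self._derive_regions()

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def _derive_regions(self) -> None:
        self.five_utr, self.cds, self.three_utr = [], [], []
        if self.cds_span is None:
            return
        cs, ce = self.cds_span
        exon_lo, exon_hi = self.span
        # the span may cross introns, but its endpoints must be exonic
        if (
            cs < exon_lo or ce > exon_hi
            or not any(s <= cs < e for s, e in self.exons)
            or not any(s < ce <= e for s, e in self.exons)
        ):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS span ({cs}, {ce}) "
                "endpoints not within exons"
            )
        left = _intersect(self.exons, exon_lo, cs)
        right = _intersect(self.exons, ce, exon_hi)
        self.cds = _intersect(self.exons, cs, ce)
        if self.strand == "+":
            self.five_utr, self.three_utr = left, right
        else:
            self.five_utr, self.three_utr = right, left

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def three_utr_length(self) -> int:
        return sum(e - s for s, e in self.three_utr)


class TranscriptomeIndex:
    """Interval-indexed transcript collection.

    ``query(chrom, start, end)`` returns every transcript whose span
    intersects the query interval (both strands; callers filter by strand).
    """

    def __init__(self, transcripts: Sequence[Transcript], build: GenomeBuild):
        self.transcripts = list(transcripts)
        self.build = build
        self.by_id = {t.transcript_id: t for t in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise AnnotationError("duplicate transcript_id in annotation")
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            if t.chrom not in build:
                raise AnnotationError(
                    f"transcript {t.transcript_id}: unknown chromosome {t.chrom!r}"
                )
            if t.end > build.length(t.chrom):
                raise AnnotationError(
                    f"transcript {t.transcript_id}: exon beyond end of {t.chrom}"
                )
            self._trees.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t.transcript_id
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def query(self, chrom: str, start: int, end: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.by_id[iv.data] for iv in tree.overlap(start, end)]

    def coding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.is_coding]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path: str | Path, build: GenomeBuild) -> TranscriptomeIndex:
    """Load exon/CDS records from a GTF file into a TranscriptomeIndex.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Raises :class:`AnnotationError` naming the offending line for malformed
    records, and naming the transcript for out-of-bounds exons.
    """
    exons: dict[str, dict] = {}
    cds: dict[str, list[Interval]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno} "
                    f"({len(fields)} fields, expected 9)"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # -> 0-based half-open
            except ValueError:
                raise AnnotationError(
                    f"{gtf_path}: non-integer coordinates on line {lineno}"
                ) from None
            if strand not in {"+", "-"} or end <= start:
                raise AnnotationError(f"{gtf_path}: invalid record on line {lineno}")
            attrs = _parse_gtf_attributes(attr)
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno} lacks transcript_id/gene_id"
                ) from None
            if feature == "exon":
                rec = exons.setdefault(
                    tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "ivs": []}
                )
                rec["ivs"].append((start, end))
            else:
                cds.setdefault(tid, []).append((start, end))

    transcripts = []
    for tid, rec in exons.items():
        cds_span = None
        if tid in cds:
            ivs = cds[tid]
            cds_span = (min(s for s, _ in ivs), max(e for _, e in ivs))
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["ivs"],
                cds_span=cds_span,
            )
        )
    return TranscriptomeIndex(transcripts, build)


def write_gtf(index: TranscriptomeIndex, path: str | Path) -> None:
    """Write exon and CDS records (1-based inclusive) for round-tripping."""
    with open(path, "w") as fh:
        for t in sorted(index.transcripts, key=lambda t: (t.chrom, t.start)):
            common = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tqclip\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{common}\n"
                )
            for s, e in t.cds:
                fh.write(
                    f"{t.chrom}\tqclip\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t{common}\n"
                )


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(
    intervals: Sequence[Interval],
    strand: str,
    chrom_seq: str,
) -> str:
    """Concatenate interval sequences and return the transcript-sense string.

    ``chrom_seq`` is the full chromosome sequence (a plain string or any
    sliceable sequence, e.g. a pyfaidx record). For '-' strand the
    concatenation is reverse-complemented so the result reads 5'->3'.
    """
    n = len(chrom_seq)
    parts = []
    for s, e in sorted(intervals):
        if s < 0 or e > n:
            raise AnnotationError(f"interval ({s}, {e}) beyond chromosome end {n}")
        parts.append(str(chrom_seq[s:e]))
    seq = "".join(parts).upper()
    return reverse_complement(seq) if strand == "-" else seq


def transcript_sequence(t: Transcript, chrom_seq: str, region: str = "exons") -> str:
    ivs = {"exons": t.exons, "five_utr": t.five_utr, "cds": t.cds,
           "three_utr": t.three_utr}[region]
    return extract_sequence(ivs, t.strand, chrom_seq)


# ---------------------------------------------------------------------------
# Peak feature assignment
# ---------------------------------------------------------------------------

def _overlaps_any(intervals: Sequence[Interval], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def assign_peak_feature(
    peak: Interval, chrom: str, strand: str, index: TranscriptomeIndex
) -> str:
    """Classify a stranded peak interval into one annotation feature class.

    Considers only transcripts on the peak's own strand; overlap by >= 1 base
    qualifies; precedence three_utr > five_utr > cds_exon > noncoding_exon >
    intron > intergenic resolves multi-class overlap.
    """
    start, end = peak
    present: set[str] = set()
    for t in index.query(chrom, start, end):
        if t.strand != strand:
            continue
        if t.is_coding:
            if _overlaps_any(t.three_utr, start, end):
                present.add(FEATURE_THREE_UTR)
            if _overlaps_any(t.five_utr, start, end):
                present.add(FEATURE_FIVE_UTR)
            if _overlaps_any(t.cds, start, end):
                present.add(FEATURE_CDS)
        else:
            if _overlaps_any(t.exons, start, end):
                present.add(FEATURE_NONCODING)
        span_s, span_e = t.span
        exonic = _intersect(t.exons, start, end)
        exonic_len = sum(e2 - s2 for s2, e2 in exonic)
        overlap_len = min(end, span_e) - max(start, span_s)
        if overlap_len > exonic_len:  # some overlapped bases are intronic
            present.add(FEATURE_INTRON)
    for label in FEATURE_PRECEDENCE:
        if label in present:
            return label
    return FEATURE_INTERGENIC


def feature_fraction_summary(labels: Iterable[str]) -> pd.DataFrame:
    """Tabulate label counts and percentages (sums to 100)."""
    ser = pd.Series(list(labels), dtype="object")
    counts = ser.value_counts()
    df = pd.DataFrame({
        "label": counts.index,
        "count": counts.values,
    })
    df["percent"] = 100.0 * df["count"] / df["count"].sum()
    return df.reset_index(drop=True)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an uncompressed FASTA into a name -> sequence dict (via pyfaidx)."""
    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
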