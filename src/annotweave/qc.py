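"""Structural quality metrics for an annotation against a genome.

Four metrics summarize how plausible a set of transcript models is:

* monoexonic fraction — share of single-exon transcripts,
* intron canonicity — share of distinct introns whose donor/acceptor
  dinucleotides are (GT,AG), (GC,AG) or (AT,AC),
* 5' completion — share of distinct TSS lying inside an open-chromatin
  (e.g. ATAC-seq) peak,
* 3' completion — share of distinct TTS with a polyadenylation-signal
  hexamer (AATAAA/ATTAAA) nearby, either within 50 bp (distance mode)
  or within the last 30 bp of the transcript (span mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    AnnotationSet,
    GenomeSequence,
    ParseError,
    ValidationError,
    reverse_complement,
)

__all__ = [
    "PeakSet",
    "PolyASiteSet",
    "QCReport",
    "read_bed",
    "splice_dinucleotides",
    "is_canonical",
    "canonicity_fraction",
    "scan_polya",
    "tts_completion",
    "tss_completion",
    "monoexonic_fraction",
    "qc_report",
]

log = logging.getLogger(__name__)

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
POLYA_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass
class PeakSet:
    """Strandless peak intervals per chromosome, 1-based inclusive."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def contains(self, chrom: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals.get(chrom, ()))


@dataclass
class PolyASiteSet:
    """Sorted hexamer-motif start positions per (chromosome, strand)."""

    positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    motif_length: int = 6

    def __len__(self) -> int:
        return sum(len(v) for v in self.positions.values())


@dataclass
class QCReport:
    metrics: dict[str, float]
    counts: dict[str, tuple[int, int]]  # metric -> (numerator, denominator)


def read_bed(path: str | Path) -> PeakSet:
    """Read BED intervals (0-based half-open), converting to 1-based inclusive."""
    path = Path(path)
    peaks = PeakSet()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name} line {lineno}: fewer than 3 BED columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from None
            if end0 <= start0:
                raise ParseError(f"{path.name} line {lineno}: empty or inverted interval")
            peaks.intervals.setdefault(fields[0], []).append((start0 + 1, end0))
    for v in peaks.intervals.values():
        v.sort()
    return peaks


def splice_dinucleotides(
    intron: tuple[int, int], chrom: str, strand: str, genome: GenomeSequence
) -> tuple[str, str]:
    """Donor and acceptor dinucleotides of an intron.

    On '+', the donor is the first two intronic bases and the acceptor
    the last two; on '-', the reverse complements of the last and first
    two forward-strand bases respectively. Introns shorter than 4 bp are
    rejected (the two dinucleotides would overlap).
    """
    start, end = intron
    if end - start + 1 < 4:
        raise ValidationError(f"intron {chrom}:{start}-{end} shorter than 4 bp")
    first = genome.fetch(chrom, start, start + 1)
    last = genome.fetch(chrom, end - 1, end)
    if strand == "+":
        return first, last
    return reverse_complement(last), reverse_complement(first)


def is_canonical(donor: str, acceptor: str) -> bool:
    return (donor, acceptor) in CANONICAL_PAIRS


def distinct_introns(annotation: AnnotationSet) -> set[tuple[str, str, int, int]]:
    out = set()
    for t in annotation.spliced():
        for s, e in t.introns():
            out.add((t.chromosome, t.strand, s, e))
    return out


def canonicity_fraction(
    annotation: AnnotationSet, genome: GenomeSequence
) -> tuple[float, tuple[int, int]]:
    """Fraction of distinct introns with canonical splice sites."""
    introns = distinct_introns(annotation)
    if not introns:
        return 0.0, (0, 0)
    canonical = 0
    for chrom, strand, s, e in introns:
        donor, acceptor = splice_dinucleotides((s, e), chrom, strand, genome)
        if is_canonical(donor, acceptor):
            canonical += 1
    return canonical / len(introns), (canonical, len(introns))


def scan_polya(genome: GenomeSequence) -> PolyASiteSet:
    """Locate every AATAAA/ATTAAA occurrence on both strands.

    Forward-strand sites are motif occurrences as-is; reverse-strand
    sites are occurrences of the reverse-complemented motifs on the
    forward sequence. Positions are 1-based motif starts (forward
    coordinates), sorted.
    """
    sites = PolyASiteSet()
    targets = {"+": POLYA_HEXAMERS, "-": tuple(reverse_complement(m) for m in POLYA_HEXAMERS)}
    for chrom in genome.chromosomes():
        seq = genome.sequence(chrom)
        for strand, motifs in targets.items():
            found: list[int] = []
            for motif in motifs:
                i = seq.find(motif)
                while i != -1:
                    found.append(i + 1)
                    i = seq.find(motif, i + 1)
            if found:
                sites.positions[(chrom, strand)] = sorted(set(found))
    return sites


def _distinct_tss(annotation: AnnotationSet) -> set[tuple[str, str, int]]:
    return {(t.chromosome, t.strand, t.tss) for t in annotation}


def _distinct_tts(annotation: AnnotationSet) -> set[tuple[str, str, int]]:
    return {(t.chromosome, t.strand, t.tts) for t in annotation}


def tts_completion(
    annotation: AnnotationSet,
    polya: PolyASiteSet,
    window_bp: int = 50,
) -> tuple[float, tuple[int, int]]:
    """Fraction of distinct TTS with a same-strand polyA site within < window_bp.

    Distance is the minimum absolute difference between the TTS position
    and any base of a motif occurrence on the same chromosome and strand
    (0 when the TTS falls inside the hexamer).
    """
    tts = _distinct_tts(annotation)
    if not tts:
        return 0.0, (0, 0)
    k = polya.motif_length - 1
    hit = 0
    for chrom, strand, pos in tts:
        for p in polya.positions.get((chrom, strand), ()):
            if p - window_bp < pos < p + k + window_bp:
                hit += 1
                break
    return hit / len(tts), (hit, len(tts))


def tts_span_completion(
    annotation: AnnotationSet,
    polya: PolyASiteSet,
    span_bp: int = 30,
) -> tuple[float, tuple[int, int]]:
    """Alternative 3' metric: last span_bp transcript bases contain a motif start."""
    tts = _distinct_tts(annotation)
    if not tts:
        return 0.0, (0, 0)
    hit = 0
    for chrom, strand, pos in tts:
        if strand == "+":
            lo, hi = pos - span_bp + 1, pos
        else:
            lo, hi = pos, pos + span_bp - 1
        if any(lo <= p <= hi for p in polya.positions.get((chrom, strand), ())):
            hit += 1
    return hit / len(tts), (hit, len(tts))


def tss_completion(
    annotation: AnnotationSet, peaks: PeakSet
) -> tuple[float, tuple[int, int]]:
    """Fraction of distinct TSS lying within at least one peak interval."""
    tss = _distinct_tss(annotation)
    if not tss:
        return 0.0, (0, 0)
    if len(peaks) == 0:
        log.warning("empty peak set: 5' completion is 0 by definition")
        return 0.0, (0, len(tss))
    hit = sum(1 for chrom, _strand, pos in tss if peaks.contains(chrom, pos))
    return hit / len(tss), (hit, len(tss))


def monoexonic_fraction(annotation: AnnotationSet) -> tuple[float, tuple[int, int]]:
    if len(annotation) == 0:
        raise ValidationError("empty annotation")
    mono = sum(1 for t in annotation if t.is_monoexonic)
    return mono / len(annotation), (mono, len(annotation))


def qc_report(
    annotation: AnnotationSet,
    genome: GenomeSequence | None = None,
    peaks: PeakSet | None = None,
    polya: PolyASiteSet | None = None,
    polya_window_bp: int = 50,
) -> QCReport:
    """All QC metrics that the provided inputs allow."""
    metrics: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}

    value, backing = monoexonic_fraction(annotation)
    metrics["monoexonic_fraction"] = value
    counts["monoexonic_fraction"] = backing

    if genome is not None:
        value, backing = canonicity_fraction(annotation, genome)
        metrics["canonical_intron_fraction"] = value
        counts["canonical_intron_fraction"] = backing
        if polya is None:
            polya = scan_polya(genome)
    if peaks is not None:
        value, backing = tss_completion(annotation, peaks)
        metrics["tss_completion"] = value
        counts["tss_completion"] = backing
    if polya is not None:
        value, backing = tts_completion(annotation, polya, polya_window_bp)
        metrics["tts_completion"] = value
        counts["tts_completion"] = backing
    return QCReport(metrics=metrics, counts=counts)
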