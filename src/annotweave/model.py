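"""Core data model for genomes and transcript annotations.

All internal coordinates are 1-based inclusive, the GTF convention.
BED and PSL inputs (0-based half-open) are converted at the reading
boundary, never inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

__all__ = [
    "AnnotweaveError",
    "ValidationError",
    "ParseError",
    "ConfigError",
    "GenomeSequence",
    "IntronChain",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "reverse_complement",
]


class AnnotweaveError(Exception):
    """Base class for all package errors."""


class ValidationError(AnnotweaveError):
    """An object violates a structural invariant."""


class ParseError(AnnotweaveError):
    """An input file could not be parsed."""


class ConfigError(AnnotweaveError):
    """Invalid configuration of a pipeline stage."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase A/C/G/T/N string.

    Lookups use 1-based inclusive coordinates; positions outside
    ``[1, length]`` raise :class:`ValidationError`.
    """

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - self._ALPHABET
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains characters outside "
                    f"A/C/G/T/N: {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based inclusive, forward strand)."""
        seq = self._seq(chrom)
        if not (1 <= start <= end <= len(seq)):
            raise ValidationError(
                f"{chrom}:{start}-{end} outside [1, {len(seq)}]"
            )
        return seq[start - 1 : end]

    def sequence(self, chrom: str) -> str:
        return self._seq(chrom)


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron intervals of a spliced transcript.

    Introns are 1-based inclusive: first intronic base to last intronic
    base. A monoexonic transcript has an empty chain. The triple
    (chromosome, strand, introns) is the hashable identity used to decide
    whether two transcripts may be collapsed.
    """

    chromosome: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.introns)

    @property
    def is_empty(self) -> bool:
        return not self.introns


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``exons`` are 1-based inclusive intervals, sorted, non-overlapping,
    separated by at least one intronic base. ``tpm`` maps the sample
    (input transcriptome) name to the TPM reported for this model in that
    sample; ``sources`` is the set of input transcriptomes the model was
    seen in, and drives the consistency filter.
    """

    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    attributes: dict[str, str] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)
    sources: frozenset[str] = frozenset()
    origin: str = "novel"  # {"reference", "novel"}

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise ValidationError(
                    f"{self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start <= prev_end + 1:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are adjacent "
                    f"(... {prev_end}] [{start} ...)"
                )
            prev_end = end
        if self.origin not in ("reference", "novel"):
            raise ValidationError(f"bad origin {self.origin!r}")
        for sample, value in self.tpm.items():
            if value < 0:
                raise ValidationError(
                    f"{self.transcript_id}: negative TPM {value} in {sample!r}"
                )

    # -- structure ---------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    def intron_chain(self) -> IntronChain:
        return IntronChain(self.chromosome, self.strand, self.introns())

    @property
    def detection_count(self) -> int:
        return len(self.sources)

    @property
    def tss(self) -> int:
        """5'-most genomic position on the transcript strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """3'-most genomic position on the transcript strand."""
        return self.end if self.strand == "+" else self.start

    @property
    def gene_id(self) -> str:
        return self.attributes.get("gene_id", "")

    def overlaps(self, other: "TranscriptModel") -> bool:
        """Genomic extent overlap of >= 1 bp on the same chromosome."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def exonic_overlap_bp(self, other: "TranscriptModel") -> int:
        """Summed exon-by-exon overlap in bp (ignores strand)."""
        if self.chromosome != other.chromosome:
            return 0
        total = 0
        for s1, e1 in self.exons:
            for s2, e2 in other.exons:
                total += max(0, min(e1, e2) - max(s1, s2) + 1)
        return total

    def copy(self, **changes) -> "TranscriptModel":
        if "attributes" not in changes:
            changes["attributes"] = dict(self.attributes)
        if "tpm" not in changes:
            changes["tpm"] = dict(self.tpm)
        return replace(self, **changes)


def intron_chain(transcript: TranscriptModel) -> IntronChain:
    """The 1-based inclusive gaps between consecutive exons."""
    return transcript.intron_chain()


@dataclass
class GeneModel:
    """A gene locus: transcripts sharing same-strand exonic overlap."""

    gene_id: str
    transcript_ids: list[str]
    chromosome: str
    strand: str
    start: int
    end: int
    coding_status: str = "uncharacterized"  # {mRNA, lncRNA, uncharacterized}
    novelty: str = ""  # {known, enriched, unknown}
    ref_gene_ids: list[str] = field(default_factory=list)


class AnnotationSet:
    """A collection of transcripts with a gene index and provenance label.

    Provenance is ``"reference"``, ``"sample:<name>"`` or ``"merged"``.
    Transcript ids are unique; each transcript belongs to exactly one
    gene (via its ``gene_id`` attribute).
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        provenance: str = "merged",
    ):
        self.provenance = provenance
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            self.add(t)
        self.genes: dict[str, GeneModel] = {}

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.transcript_id in self.transcripts:
            raise ValidationError(
                f"duplicate transcript id {transcript.transcript_id!r}"
            )
        self.transcripts[transcript.transcript_id] = transcript

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def by_chromosome(self) -> dict[str, list[TranscriptModel]]:
        index: dict[str, list[TranscriptModel]] = {}
        for t in self:
            index.setdefault(t.chromosome, []).append(t)
        return index

    def spliced(self) -> list[TranscriptModel]:
        return [t for t in self if not t.is_monoexonic]

    def monoexonic(self) -> list[TranscriptModel]:
        return [t for t in self if t.is_monoexonic]

    def rebuild_gene_index(self) -> None:
        """Group transcripts into GeneModels by their gene_id attribute."""
        self.genes = {}
        for t in sorted(self, key=lambda t: (t.chromosome, t.start, t.transcript_id)):
            gid = t.gene_id or t.transcript_id
            gene = self.genes.get(gid)
            if gene is None:
                self.genes[gid] = GeneModel(
                    gene_id=gid,
                    transcript_ids=[t.transcript_id],
                    chromosome=t.chromosome,
                    strand=t.strand,
                    start=t.start,
                    end=t.end,
                )
            else:
                if gene.chromosome != t.chromosome or gene.strand != t.strand:
                    raise ValidationError(
                        f"gene {gid!r} mixes chromosomes or strands"
                    )
                gene.transcript_ids.append(t.transcript_id)
                gene.start = min(gene.start, t.start)
                gene.end = max(gene.end, t.end)

    def structural_key(self) -> set:
        """Hashable summary of exon structures, used for set equality."""
        return {
            (t.chromosome, t.strand, t.exons) for t in self
        }
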