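"""Positional classes, novelty labels and unified biotypes.

Spliced transcripts are compared to a reference annotation and given
exactly one of five positional classes, in priority order:

* ``Exact`` — a reference transcript has the identical intron chain,
* ``Extension`` — the transcript extends a reference transcript: same
  strand, overlapping, identical chain on the overlap, and at least one
  extra intron 5'-ward and/or 3'-ward,
* ``Inclusion`` — a reference transcript is an Extension of it,
* ``Overlapping`` — same-strand overlap not qualifying above,
* ``Intergenic_or_Antisense`` — none of the above.

Monoexonic transcripts are handled separately (class ``Monoexonic``).

A transcript is *known* when its exon-intron structure exactly matches a
reference transcript; a gene is known/unknown when all its transcripts
are, and *enriched* otherwise. Reference and FEELnc biotypes are
combined into one unified biotype with mRNA winning conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .merge import is_extension
from .model import AnnotationSet, TranscriptModel, ValidationError

__all__ = [
    "PositionalClass",
    "LncPositionClass",
    "positional_class",
    "transcript_novelty",
    "gene_novelty",
    "feelnc_eligible",
    "unified_transcript_biotype",
    "gene_coding_status",
    "classify_lnc_position",
    "catalog_match",
    "classification_table",
]


class PositionalClass(str, Enum):
    EXACT = "Exact"
    EXTENSION = "Extension"
    INCLUSION = "Inclusion"
    OVERLAPPING = "Overlapping"
    INTERGENIC_OR_ANTISENSE = "Intergenic_or_Antisense"
    MONOEXONIC = "Monoexonic"


_MRNA_LABELS = {"mRNA", "protein_coding"}
_LNC_LABELS = {"lncRNA", "lincRNA", "long_noncoding"}


def _same_strand_candidates(t: TranscriptModel, reference: AnnotationSet):
    for r in reference:
        if r.chromosome == t.chromosome:
            yield r


def positional_class(
    transcript: TranscriptModel, reference: AnnotationSet
) -> PositionalClass:
    """First positional class in priority order whose predicate holds."""
    if transcript.is_monoexonic:
        raise ValidationError(
            "positional_class is defined for spliced transcripts; "
            "monoexonic transcripts are classified separately"
        )
    chain = transcript.intron_chain()
    overlapping = False
    for r in _same_strand_candidates(transcript, reference):
        if r.strand != transcript.strand:
            continue
        if not r.is_monoexonic and r.intron_chain() == chain:
            return PositionalClass.EXACT
    for r in _same_strand_candidates(transcript, reference):
        if r.strand != transcript.strand or r.is_monoexonic:
            continue
        if is_extension(transcript, r):
            return PositionalClass.EXTENSION
    for r in _same_strand_candidates(transcript, reference):
        if r.strand != transcript.strand or r.is_monoexonic:
            continue
        if is_extension(r, transcript):
            return PositionalClass.INCLUSION
    for r in _same_strand_candidates(transcript, reference):
        if r.strand == transcript.strand and transcript.overlaps(r):
            overlapping = True
            break
    if overlapping:
        return PositionalClass.OVERLAPPING
    return PositionalClass.INTERGENIC_OR_ANTISENSE


def transcript_novelty(
    transcript: TranscriptModel, reference: AnnotationSet
) -> str:
    """``known`` iff the exon-intron structure exactly matches a reference model.

    Spliced: identical intron chain on the same strand. Monoexonic:
    identical (chromosome, strand, start, end) with a reference
    monoexonic transcript — the strictest reading of exact structural
    correspondence.
    """
    if transcript.is_monoexonic:
        key = (transcript.chromosome, transcript.strand, transcript.start, transcript.end)
        for r in reference.monoexonic():
            if (r.chromosome, r.strand, r.start, r.end) == key:
                return "known"
        return "unknown"
    chain = transcript.intron_chain()
    for r in reference.spliced():
        if r.intron_chain() == chain:
            return "known"
    return "unknown"


def gene_novelty(transcript_novelties: list[str]) -> str:
    """known if all transcripts known, unknown if all unknown, else enriched."""
    if not transcript_novelties:
        raise ValidationError("gene has no transcripts")
    kinds = set(transcript_novelties)
    if kinds == {"known"}:
        return "known"
    if kinds == {"unknown"}:
        return "unknown"
    return "enriched"


def feelnc_eligible(
    transcript: TranscriptModel, reference_mrnas: list[TranscriptModel]
) -> bool:
    """Eligibility for coding-potential classification of lncRNA candidates.

    The transcript must be longer than 200 bp of spliced length, have no
    same-strand exonic overlap with any reference mRNA transcript, and
    have either strictly more than two exons, or exactly two exons both
    longer than 25 bp.
    """
    if transcript.exonic_length <= 200:
        return False
    n = len(transcript.exons)
    if n < 2:
        return False
    if n == 2 and not all(e - s + 1 > 25 for s, e in transcript.exons):
        return False
    for r in reference_mrnas:
        if r.strand == transcript.strand and transcript.exonic_overlap_bp(r) >= 1:
            return False
    return True


def unified_transcript_biotype(transcript: TranscriptModel) -> str:
    """Combine reference and FEELnc biotypes; mRNA wins conflicts.

    Labels are read from the ``transcript_biotype`` (reference) and
    ``feelnc_biotype`` attributes. Either source saying
    protein_coding/mRNA gives ``mRNA``; otherwise either saying lncRNA
    gives ``lncRNA``; otherwise FEELnc's TUCp/noORF pass through; with no
    label at all the transcript is ``uncharacterized``.
    """
    ref = transcript.attributes.get("transcript_biotype", "")
    feelnc = transcript.attributes.get("feelnc_biotype", "")
    if ref in _MRNA_LABELS or feelnc in _MRNA_LABELS:
        return "mRNA"
    if ref in _LNC_LABELS or feelnc in _LNC_LABELS:
        return "lncRNA"
    if feelnc in ("TUCp", "noORF"):
        return feelnc
    return "uncharacterized"


def gene_coding_status(member_biotypes: list[str]) -> str:
    """mRNA if any member is mRNA, else lncRNA if any is lncRNA, else uncharacterized."""
    if not member_biotypes:
        raise ValidationError("gene has no transcripts")
    if "mRNA" in member_biotypes:
        return "mRNA"
    if "lncRNA" in member_biotypes:
        return "lncRNA"
    return "uncharacterized"


@dataclass(frozen=True)
class LncPositionClass:
    """Position of a lncRNA relative to its closest coding transcript."""

    scope: str  # {"genic", "intergenic", "unclassified"}
    sublocation: str = ""  # genic: {"exonic", "intronic"}
    direction: str = ""  # intergenic: {"upstream", "downstream"}
    orientation: str = ""  # {"sense", "antisense"}
    derived: str = ""  # intergenic antisense: {"divergent", "convergent"}
    mrna_id: str = ""

    @property
    def label(self) -> str:
        if self.scope == "unclassified":
            return "unclassified"
        if self.scope == "genic":
            return f"genic_{self.sublocation}_{self.orientation}"
        parts = f"intergenic_{self.direction}_{self.orientation}"
        return f"{parts}_{self.derived}" if self.derived else parts


def classify_lnc_position(
    lnc: TranscriptModel,
    mrnas: list[TranscriptModel],
    window_bp: int = 100_000,
) -> LncPositionClass:
    """Classify a lncRNA by position relative to its closest mRNA.

    Overlapping an mRNA extent makes it genic (exonic when there is
    >=1 bp exon-exon overlap, else intronic), with sense/antisense
    orientation by strand. Otherwise the nearest mRNA within
    ``window_bp`` defines upstream/downstream relative to the mRNA's
    orientation; antisense upstream is additionally labelled divergent
    and antisense downstream convergent.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    same_chrom = [m for m in mrnas if m.chromosome == lnc.chromosome]

    overlapping = [m for m in same_chrom if lnc.start <= m.end and m.start <= lnc.end]
    if overlapping:
        m = max(
            overlapping,
            key=lambda m: (
                min(m.end, lnc.end) - max(m.start, lnc.start),
                m.transcript_id,
            ),
        )
        sub = "exonic" if lnc.exonic_overlap_bp(m) >= 1 else "intronic"
        orient = "sense" if m.strand == lnc.strand else "antisense"
        return LncPositionClass("genic", sublocation=sub, orientation=orient, mrna_id=m.transcript_id)

    def distance(m):
        if m.end < lnc.start:
            return lnc.start - m.end
        return m.start - lnc.end

    in_window = [m for m in same_chrom if distance(m) < window_bp]
    if not in_window:
        return LncPositionClass("unclassified")
    m = min(in_window, key=lambda m: (distance(m), m.transcript_id))
    # direction relative to the mRNA's own orientation: the lncRNA is
    # upstream when it lies 5'-ward of the mRNA's TSS
    lnc_before = lnc.end < m.start
    if m.strand == "+":
        direction = "upstream" if lnc_before else "downstream"
    else:
        direction = "downstream" if lnc_before else "upstream"
    orient = "sense" if m.strand == lnc.strand else "antisense"
    derived = ""
    if orient == "antisense":
        derived = "divergent" if direction == "upstream" else "convergent"
    return LncPositionClass(
        "intergenic", direction=direction, orientation=orient, derived=derived, mrna_id=m.transcript_id
    )


def catalog_match(transcript: TranscriptModel, catalog: AnnotationSet) -> bool:
    """Is the transcript found in an external catalog annotation?

    Monoexonic: stranded overlap with a monoexonic catalog transcript.
    Spliced: shares at least one identical intron (chromosome, strand,
    start, end) with a catalog transcript.
    """
    if transcript.is_monoexonic:
        for c in catalog.monoexonic():
            if (
                c.chromosome == transcript.chromosome
                and c.strand == transcript.strand
                and transcript.start <= c.end
                and c.start <= transcript.end
            ):
                return True
        return False
    introns = set(transcript.introns())
    for c in catalog.spliced():
        if c.chromosome != transcript.chromosome or c.strand != transcript.strand:
            continue
        if introns & set(c.introns()):
            return True
    return False


def classification_table(
    annotation: AnnotationSet,
    reference: AnnotationSet,
    catalog: AnnotationSet | None = None,
    lnc_window_bp: int = 100_000,
):
    """Per-transcript classification as a pandas DataFrame.

    Columns: transcript_id, gene_id, positional_class, novelty,
    unified_biotype, gene_status, lnc_position, catalog_match.
    """
    import pandas as pd

    annotation.rebuild_gene_index()
    biotypes = {t.transcript_id: unified_transcript_biotype(t) for t in annotation}
    novelties = {t.transcript_id: transcript_novelty(t, reference) for t in annotation}
    gene_status = {}
    gene_nov = {}
    for gid, gene in annotation.genes.items():
        members = gene.transcript_ids
        gene_status[gid] = gene_coding_status([biotypes[tid] for tid in members])
        gene_nov[gid] = gene_novelty([novelties[tid] for tid in members])

    mrnas = [t for t in annotation if biotypes[t.transcript_id] == "mRNA"]
    rows = []
    for t in sorted(annotation, key=lambda t: (t.chromosome, t.start, t.transcript_id)):
        if t.is_monoexonic:
            pos = PositionalClass.MONOEXONIC
        else:
            pos = positional_class(t, reference)
        lnc_label = ""
        if biotypes[t.transcript_id] == "lncRNA":
            lnc_label = classify_lnc_position(t, mrnas, lnc_window_bp).label
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "positional_class": pos.value,
                "novelty": novelties[t.transcript_id],
                "gene_novelty": gene_nov[t.gene_id],
                "unified_biotype": biotypes[t.transcript_id],
                "gene_status": gene_status[t.gene_id],
                "lnc_position": lnc_label,
                "catalog_match": (
                    catalog_match(t, catalog) if catalog is not None else ""
                ),
            }
        )
    return pd.DataFrame(rows)
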