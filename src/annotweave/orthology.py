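"""Projection-based orthology from PSL alignments, plus synteny triplets.

A query transcript projected onto a target genome yields one or more
PSL alignments. Each is scored as

    score = matches + repMatches - misMatches - qNumInsert - tNumInsert

and the best alignment per query is the highest score, ties going to
the alignment with more blocks, then to file order. The best hit is
assigned to the target transcript with the longest same-strand exonic
overlap; target genes accumulate per source gene. Against a truth set
of 1-to-1 gene orthologs, sensitivity and precision are reported as
percentages rounded half-up to one decimal.

lncRNA orthology uses synteny: triplets of consecutive genes
(coding, lnc, coding), matched across species through the orthology of
the flanking coding genes (unordered by default, robust to inversions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .model import AnnotationSet, ParseError, ValidationError

__all__ = [
    "PslAlignment",
    "TripletRecord",
    "OrthologyEvaluation",
    "read_psl",
    "score_alignment",
    "best_hit",
    "best_hits_by_query",
    "map_to_targets",
    "evaluate_orthology",
    "extract_triplets",
    "match_triplets",
    "percentage",
]


@dataclass
class PslAlignment:
    """One 21-column PSL record (coordinates kept 0-based half-open as in PSL)."""

    query_id: str
    target_chrom: str
    strand: str
    matches: int
    mis_matches: int
    rep_matches: int
    q_num_insert: int
    t_num_insert: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]
    t_starts: tuple[int, ...]
    order: int = 0  # position in input file, for the final tie-break

    def __post_init__(self) -> None:
        if not (len(self.block_sizes) == len(self.q_starts) == len(self.t_starts)):
            raise ValidationError(f"{self.query_id}: inconsistent block lists")
        if any(size <= 0 for size in self.block_sizes):
            raise ValidationError(f"{self.query_id}: non-positive block size")

    @property
    def block_count(self) -> int:
        return len(self.block_sizes)

    def target_blocks(self) -> list[tuple[int, int]]:
        """Target-side block intervals converted to 1-based inclusive."""
        return [(ts + 1, ts + size) for size, ts in zip(self.block_sizes, self.t_starts)]


def _int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")


def read_psl(path: str | Path) -> list[PslAlignment]:
    """Parse a UCSC 21-column PSL file (headerless or with psLayout header)."""
    path = Path(path)
    alignments: list[PslAlignment] = []
    order = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", "#")) or line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) != 21:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 21 PSL columns, got {len(fields)}"
                )
            try:
                block_count = int(fields[17])
                aln = PslAlignment(
                    query_id=fields[9],
                    target_chrom=fields[13],
                    strand=fields[8],
                    matches=int(fields[0]),
                    mis_matches=int(fields[1]),
                    rep_matches=int(fields[2]),
                    q_num_insert=int(fields[4]),
                    t_num_insert=int(fields[6]),
                    block_sizes=_int_list(fields[18]),
                    q_starts=_int_list(fields[19]),
                    t_starts=_int_list(fields[20]),
                    order=order,
                )
            except ValueError:
                raise ParseError(f"{path.name} line {lineno}: non-integer PSL field") from None
            if aln.block_count != block_count:
                raise ParseError(
                    f"{path.name} line {lineno}: blockCount {block_count} does not "
                    f"match {aln.block_count} block sizes"
                )
            alignments.append(aln)
            order += 1
    return alignments


def score_alignment(psl: PslAlignment) -> int:
    """matches + repMatches - misMatches - qNumInsert - tNumInsert."""
    return (
        psl.matches
        + psl.rep_matches
        - psl.mis_matches
        - psl.q_num_insert
        - psl.t_num_insert
    )


def best_hit(alignments: list[PslAlignment]) -> PslAlignment:
    """Highest score; ties to more blocks; ties to first in file order."""
    if not alignments:
        raise ValidationError("best_hit on empty alignment list")
    return min(alignments, key=lambda a: (-score_alignment(a), -a.block_count, a.order))


def best_hits_by_query(alignments: list[PslAlignment]) -> dict[str, PslAlignment]:
    grouped: dict[str, list[PslAlignment]] = {}
    for aln in alignments:
        grouped.setdefault(aln.query_id, []).append(aln)
    return {query: best_hit(group) for query, group in grouped.items()}


def _strand_char(psl_strand: str) -> str:
    # pslMap output may carry two strand chars (query+target); the
    # target-side orientation is the last character
    return psl_strand[-1]


def map_to_targets(
    best_hits: dict[str, PslAlignment],
    target: AnnotationSet,
    query_genes: dict[str, str] | None = None,
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Assign each best hit to the target transcript with longest overlap.

    Overlap is bp of same-strand exon-by-block intersection summed over
    all blocks and exons; ties go to the lexicographically smallest
    target transcript id. Returns (query transcript -> target
    transcript) and, when ``query_genes`` maps query transcripts to
    source genes, (source gene -> set of hit target genes).
    """
    by_chrom: dict[str, list] = {}
    for t in target:
        by_chrom.setdefault(t.chromosome, []).append(t)

    transcript_hits: dict[str, str] = {}
    gene_hits: dict[str, set[str]] = {}
    for query, aln in sorted(best_hits.items()):
        strand = _strand_char(aln.strand)
        blocks = aln.target_blocks()
        best_overlap = 0
        best_t = None
        for t in by_chrom.get(aln.target_chrom, ()):
            if t.strand != strand:
                continue
            overlap = 0
            for bs, be in blocks:
                for es, ee in t.exons:
                    overlap += max(0, min(be, ee) - max(bs, es) + 1)
            if overlap > best_overlap or (
                overlap == best_overlap
                and overlap > 0
                and (best_t is None or t.transcript_id < best_t.transcript_id)
            ):
                best_overlap = overlap
                best_t = t
        if best_t is None:
            continue
        transcript_hits[query] = best_t.transcript_id
        if query_genes is not None:
            source_gene = query_genes.get(query)
            if source_gene is not None:
                gene_hits.setdefault(source_gene, set()).add(best_t.gene_id)
    return transcript_hits, gene_hits


def percentage(numerator: int, denominator: int) -> float:
    """Half-up percentage rounded to one decimal (the reporting convention)."""
    if denominator == 0:
        raise ValidationError("percentage of an empty set is undefined")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class OrthologyEvaluation:
    eligible: int
    recovered: int
    truth_eligible: int
    truth_recovered: int

    @property
    def sensitivity(self) -> float:
        return percentage(self.recovered, self.eligible)

    @property
    def precision(self) -> float:
        return percentage(self.truth_recovered, self.truth_eligible)


def evaluate_orthology(
    predicted: dict[str, set[str]],
    truth: dict[str, str],
    colocalization: dict[str, set[str]],
) -> OrthologyEvaluation:
    """Sensitivity/precision of projected orthology against 1-to-1 truth pairs.

    ``predicted`` maps each source (novel-annotation) gene to the target
    genes its projection hit; ``truth`` maps source *reference* genes to
    their known 1-to-1 target ortholog; ``colocalization`` maps source
    genes to the reference genes they overlap.

    Sensitivity: over source genes colocalizing with a truth-bearing
    reference gene, the share whose hit list contains the known
    ortholog. Precision: over truth target genes, the share hit by the
    projection of a source gene colocalizing with their reference
    partner.
    """
    eligible = 0
    recovered = 0
    for source_gene, ref_genes in sorted(colocalization.items()):
        expected = {truth[g] for g in ref_genes if g in truth}
        if not expected:
            continue
        eligible += 1
        if expected & predicted.get(source_gene, set()):
            recovered += 1
    if eligible == 0:
        raise ValidationError("no source gene colocalizes with a truth-bearing gene")

    by_ref: dict[str, list[str]] = {}
    for source_gene, ref_genes in colocalization.items():
        for g in ref_genes:
            by_ref.setdefault(g, []).append(source_gene)

    truth_eligible = 0
    truth_recovered = 0
    for ref_gene, target_gene in sorted(truth.items()):
        truth_eligible += 1
        hit = any(
            target_gene in predicted.get(source_gene, set())
            for source_gene in by_ref.get(ref_gene, ())
        )
        if hit:
            truth_recovered += 1
    return OrthologyEvaluation(eligible, recovered, truth_eligible, truth_recovered)


@dataclass(frozen=True)
class TripletRecord:
    """Three consecutive genes (coding, lnc, coding), any strands."""

    chromosome: str
    upstream_coding: str
    lnc: str
    downstream_coding: str

    @property
    def flanking(self) -> frozenset:
        return frozenset((self.upstream_coding, self.downstream_coding))


def extract_triplets(annotation: AnnotationSet) -> list[TripletRecord]:
    """All (coding, lnc, coding) triplets of consecutive genes.

    Genes are ordered by (chromosome, start) irrespective of strand; any
    gene of another status between the three breaks adjacency.
    """
    if not annotation.genes:
        annotation.rebuild_gene_index()
    genes = sorted(
        annotation.genes.values(), key=lambda g: (g.chromosome, g.start, g.gene_id)
    )
    triplets = []
    for i in range(1, len(genes) - 1):
        prev, mid, nxt = genes[i - 1], genes[i], genes[i + 1]
        if prev.chromosome != mid.chromosome or nxt.chromosome != mid.chromosome:
            continue
        if (
            mid.coding_status == "lncRNA"
            and prev.coding_status == "mRNA"
            and nxt.coding_status == "mRNA"
        ):
            triplets.append(
                TripletRecord(mid.chromosome, prev.gene_id, mid.gene_id, nxt.gene_id)
            )
    return triplets


def match_triplets(
    source_triplets: list[TripletRecord],
    target_triplets: list[TripletRecord],
    coding_orthologs: dict[str, str],
    ordered: bool = False,
) -> list[tuple[str, str]]:
    """Pair source and target lncRNAs through orthologous flanking genes.

    A source lnc L pairs with target lnc L' when L's flanking coding
    genes map, via ``coding_orthologs``, onto L''s flanking pair —
    compared as unordered pairs by default (robust to inversions), or as
    ordered pairs with ``ordered=True``. Each (L, L') pair is reported
    once, in sorted order.
    """
    if ordered:
        target_index: dict = {}
        for t in target_triplets:
            target_index.setdefault((t.upstream_coding, t.downstream_coding), set()).add(t.lnc)
    else:
        target_index = {}
        for t in target_triplets:
            target_index.setdefault(t.flanking, set()).add(t.lnc)

    pairs = set()
    for s in source_triplets:
        a = coding_orthologs.get(s.upstream_coding)
        b = coding_orthologs.get(s.downstream_coding)
        if a is None or b is None:
            continue
        key = (a, b) if ordered else frozenset((a, b))
        for lnc in target_index.get(key, ()):
            pairs.add((s.lnc, lnc))
    return sorted(pairs)
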