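"""Readers and writers for GTF and FASTA.

GTF handling is deliberately line-level: the contracts here (parse
errors carrying line numbers, duplicate-exon detection, a count of
dropped unstranded models) need per-line control. Only ``exon``
feature rows contribute structure; other feature rows are ignored.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .model import (
    AnnotationSet,
    GenomeSequence,
    ParseError,
    TranscriptModel,
    ValidationError,
)

__all__ = ["read_gtf", "write_gtf", "read_fasta"]

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: attributes that are structural rather than free-form, handled explicitly
_RESERVED = ("gene_id", "transcript_id")


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if not attrs:
        raise ParseError(f"line {lineno}: unparsable attribute column: {text!r}")
    return attrs


def read_gtf(
    path: str | Path,
    tpm_attribute: str = "TPM",
    sample: str | None = None,
    provenance: str | None = None,
    drop_unstranded: bool = True,
) -> AnnotationSet:
    """Read a GTF2.2 file into an :class:`AnnotationSet`.

    Exon rows are grouped by ``transcript_id``; the TPM attribute (the
    StringTie dialect key ``"TPM"`` by default) is parsed as a float and
    stored under ``sample`` (default: the file stem). Unstranded ('.')
    transcripts are dropped with a counted warning unless
    ``drop_unstranded`` is false, in which case they are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sample = sample if sample is not None else path.stem

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    unstranded: set[str] = set()

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if end < start:
                raise ParseError(
                    f"{path.name} line {lineno}: exon end {end} < start {start}"
                )
            attrs = _parse_attributes(attr_s, lineno)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(
                    f"{path.name} line {lineno}: exon without transcript_id"
                )
            if "gene_id" not in attrs:
                raise ParseError(
                    f"{path.name} line {lineno}: exon without gene_id"
                )
            if strand == ".":
                if not drop_unstranded:
                    raise ValidationError(
                        f"{path.name} line {lineno}: unstranded transcript {tid!r}"
                    )
                unstranded.add(tid)
                continue
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path.name} line {lineno}: bad strand {strand!r}"
                )
            info = meta.setdefault(tid, {"chromosome": chrom, "strand": strand, "attrs": {}})
            if info["chromosome"] != chrom or info["strand"] != strand:
                raise ValidationError(
                    f"{path.name} line {lineno}: transcript {tid!r} spans "
                    "multiple chromosomes or strands (trans-splicing is not supported)"
                )
            bucket = exons.setdefault(tid, [])
            if (start, end) in bucket:
                raise ValidationError(
                    f"{path.name} line {lineno}: duplicate exon "
                    f"({start},{end}) for transcript {tid!r}"
                )
            bucket.append((start, end))
            info["attrs"].update(attrs)

    if unstranded:
        log.warning(
            "%s: dropped %d unstranded transcript(s)", path.name, len(unstranded)
        )

    transcripts = []
    for tid, intervals in exons.items():
        info = meta[tid]
        attrs = info["attrs"]
        tpm: dict[str, float] = {}
        if tpm_attribute in attrs:
            try:
                tpm[sample] = float(attrs[tpm_attribute])
            except ValueError:
                raise ParseError(
                    f"{path.name}: transcript {tid!r}: unparsable "
                    f"{tpm_attribute} value {attrs[tpm_attribute]!r}"
                ) from None
        # provenance attributes written by write_gtf survive a round trip
        origin = "reference" if provenance == "reference" else attrs.pop("origin", "novel")
        if origin not in ("reference", "novel"):
            origin = "novel"
        if "detected_in" in attrs:
            try:
                count = int(attrs.pop("detected_in"))
            except ValueError:
                raise ParseError(
                    f"{path.name}: transcript {tid!r}: bad detected_in value"
                ) from None
            sources = frozenset(f"{sample}:{i}" for i in range(count))
        elif origin == "reference":
            sources = frozenset()
        else:
            sources = frozenset({sample})
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                chromosome=info["chromosome"],
                strand=info["strand"],
                exons=tuple(sorted(intervals)),
                attributes={k: v for k, v in attrs.items() if k != tpm_attribute},
                tpm=tpm,
                sources=sources,
                origin=origin,
            )
        )

    result = AnnotationSet(transcripts, provenance=provenance or f"sample:{sample}")
    result.unstranded_dropped = len(unstranded)
    return result


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "annotweave") -> None:
    """Write exon rows sorted by (chromosome, start, transcript id).

    Round trip: ``read_gtf(write_gtf(A))`` reproduces A's structures and
    attributes.
    """
    path = Path(path)
    rows = []
    for t in annotation:
        for start, end in t.exons:
            rows.append((t.chromosome, start, t.transcript_id, end, t))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w", newline="\n") as handle:
        handle.write("##provenance: %s\n" % annotation.provenance)
        for chrom, start, tid, end, t in rows:
            attrs = {"gene_id": t.gene_id or tid, "transcript_id": tid}
            for key, value in sorted(t.attributes.items()):
                if key not in attrs:
                    attrs[key] = value
            if t.origin == "reference":
                attrs["origin"] = "reference"
            elif t.sources:
                attrs["detected_in"] = str(t.detection_count)
            if t.tpm:
                attrs["TPM"] = "%g" % max(t.tpm.values())
            attr_s = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            handle.write(
                f"{chrom}\t{source}\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attr_s}\n"
            )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read FASTA into a :class:`GenomeSequence`.

    Sequence names are the first whitespace-delimited header token;
    sequences are uppercased and validated against A/C/G/T/N.
    """
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as handle:
        for name in genome.chromosomes():
            handle.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
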