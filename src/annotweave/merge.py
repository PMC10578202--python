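"""Merge per-sample transcriptomes with a reference annotation.

The merge is conservative: spliced transcripts are collapsed only when
they share exactly the same intron chain, so the only possible
modification to a model is extending its first or last exonic position.
Transcripts strictly included in others are discarded. At the gene
level, transcripts sharing at least one same-strand exonic position are
clustered into one gene.

Reference models can never be removed: they are reported into the
output unchanged, except that a reference transcript extended at an
extremity by a chain-identical novel model is replaced by the longer
isoform, which keeps the reference transcript id and biotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import AnnotationSet, TranscriptModel, ValidationError

__all__ = [
    "MergeConfig",
    "collapse_spliced",
    "collapse_monoexonic",
    "is_extension",
    "remove_contained",
    "integrate_reference",
    "assign_gene_ids",
    "assign_reference_ids",
    "merge_annotations",
]

log = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    keep_reference: bool = True
    monoexonic_collapse: bool = True
    gene_prefix: str = "TAGG"
    transcript_prefix: str = "TAGT"

    def __post_init__(self) -> None:
        if not self.gene_prefix or not self.transcript_prefix:
            raise ValidationError("id prefixes must be non-empty")
        if self.gene_prefix == self.transcript_prefix:
            raise ValidationError("gene and transcript prefixes must differ")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _merge_group(members: list[TranscriptModel], exons: tuple[tuple[int, int], ...]) -> TranscriptModel:
    """One transcript from collapse members: merged provenance and TPM maxima."""
    members = sorted(members, key=lambda t: t.transcript_id)
    rep = members[0]
    tpm: dict[str, float] = {}
    sources: set[str] = set()
    attributes: dict[str, str] = {}
    for t in members:
        sources |= t.sources
        for sample, value in t.tpm.items():
            tpm[sample] = max(tpm.get(sample, 0.0), value)
        for key, value in t.attributes.items():
            attributes.setdefault(key, value)
    merged_ids = ",".join(t.transcript_id for t in members[1:])
    if merged_ids:
        attributes["merged_with"] = merged_ids
    return TranscriptModel(
        transcript_id=rep.transcript_id,
        chromosome=rep.chromosome,
        strand=rep.strand,
        exons=exons,
        attributes=attributes,
        tpm=tpm,
        sources=frozenset(sources),
        origin="reference" if any(t.origin == "reference" for t in members) else "novel",
    )


def collapse_spliced(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse spliced transcripts sharing (chromosome, strand, intron chain).

    The collapsed model keeps the internal exons unchanged and takes the
    min first-exon start and max last-exon end over the members. Note
    transcripts with an identical non-empty chain necessarily overlap
    (they all span the chain), so grouping by chain identity suffices.
    """
    for t in transcripts:
        if t.is_monoexonic:
            raise ValidationError(
                f"collapse_spliced got monoexonic transcript {t.transcript_id!r}"
            )
    groups: dict = {}
    for t in transcripts:
        groups.setdefault(t.intron_chain(), []).append(t)
    out = []
    for chain, members in groups.items():
        start = min(t.start for t in members)
        end = max(t.end for t in members)
        introns = chain.introns
        exons = [(start, introns[0][0] - 1)]
        for i in range(len(introns) - 1):
            exons.append((introns[i][1] + 1, introns[i + 1][0] - 1))
        exons.append((introns[-1][1] + 1, end))
        out.append(_merge_group(members, tuple(exons)))
    out.sort(key=lambda t: (t.chromosome, t.start, t.transcript_id))
    return out


def collapse_monoexonic(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse monoexonic transcripts by stranded transitive interval union."""
    for t in transcripts:
        if not t.is_monoexonic:
            raise ValidationError(
                f"collapse_monoexonic got spliced transcript {t.transcript_id!r}"
            )
    out = []
    by_key: dict = {}
    for t in transcripts:
        by_key.setdefault((t.chromosome, t.strand), []).append(t)
    for members in by_key.values():
        members.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        # sweep: overlapping (transitively) runs become one union interval
        run: list[TranscriptModel] = []
        run_end = -1
        for t in members:
            if run and t.start > run_end:
                out.append(_merge_group(run, ((run[0].start, run_end),)))
                run = []
            if not run:
                run = [t]
                run_end = t.end
            else:
                run.append(t)
                run_end = max(run_end, t.end)
        if run:
            start = min(t.start for t in run)
            out.append(_merge_group(run, ((start, run_end),)))
    out.sort(key=lambda t: (t.chromosome, t.start, t.transcript_id))
    return out


def _subchain_index(container: tuple, sub: tuple) -> int | None:
    """Index at which ``sub`` occurs as a contiguous slice of ``container``."""
    n, m = len(container), len(sub)
    for i in range(n - m + 1):
        if container[i : i + m] == sub:
            return i
    return None


def is_extension(candidate: TranscriptModel, base: TranscriptModel) -> bool:
    """True iff ``candidate`` extends ``base`` by extra introns.

    Requires: same strand, >= 1 bp genomic overlap, base's intron chain a
    contiguous sub-chain of candidate's (identical chain on the
    overlapping portion), and candidate having at least one more intron
    5'-ward and/or 3'-ward of base's chain.
    """
    if candidate.is_monoexonic or base.is_monoexonic:
        raise ValidationError("is_extension requires two spliced transcripts")
    if candidate.chromosome != base.chromosome or candidate.strand != base.strand:
        return False
    if not candidate.overlaps(base):
        return False
    ci, bi = candidate.introns(), base.introns()
    if len(ci) <= len(bi):
        return False
    return _subchain_index(ci, bi) is not None


def remove_contained(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Discard transcripts strictly included in others.

    A spliced transcript T is removed if some U is an extension of T and
    T's extent lies within U's. A monoexonic T is removed if its interval
    lies within a single exon of a same-strand U. Removed ids are
    recorded in the survivor's ``contains`` attribute.
    """
    by_key: dict = {}
    for t in transcripts:
        by_key.setdefault((t.chromosome, t.strand), []).append(t)

    removed: dict[str, str] = {}  # removed id -> container id
    for members in by_key.values():
        for t in members:
            for u in members:
                if u.transcript_id == t.transcript_id:
                    continue
                if t.is_monoexonic:
                    if any(s <= t.start and t.end <= e for s, e in u.exons):
                        removed[t.transcript_id] = u.transcript_id
                        break
                else:
                    if (
                        not u.is_monoexonic
                        and u.start <= t.start
                        and t.end <= u.end
                        and is_extension(u, t)
                    ):
                        removed[t.transcript_id] = u.transcript_id
                        break

    out = []
    contains: dict[str, list[str]] = {}
    for tid, container in removed.items():
        contains.setdefault(container, []).append(tid)
    for t in transcripts:
        if t.transcript_id in removed:
            continue
        if t.transcript_id in contains:
            t = t.copy()
            t.attributes["contains"] = ",".join(sorted(contains[t.transcript_id]))
        out.append(t)
    return out


def integrate_reference(
    novel: list[TranscriptModel],
    reference: AnnotationSet,
    config: MergeConfig | None = None,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Fold the filtered, collapsed novel set into the reference.

    Every reference transcript appears in the output exactly once: either
    verbatim, or — when a novel transcript has the same intron chain with
    longer terminal exon(s) — replaced by the longer isoform carrying the
    reference transcript id and biotype. Novel transcripts strictly
    included in reference models are discarded. Returns the merged list
    and a per-transcript action report.
    """
    config = config or MergeConfig()
    report: dict[str, str] = {}
    ref_ids = {t.transcript_id for t in reference}
    for t in novel:
        if t.transcript_id in ref_ids:
            raise ValidationError(
                f"novel transcript id collides with reference: {t.transcript_id!r}"
            )

    spliced_ref: dict = {}
    for r in reference.spliced():
        spliced_ref.setdefault(r.intron_chain(), []).append(r)
    mono_ref: dict = {}
    for r in reference.monoexonic():
        mono_ref.setdefault((r.chromosome, r.strand), []).append(r)

    out: list[TranscriptModel] = []
    consumed_ref: set[str] = set()
    used_novel: set[str] = set()

    for t in novel:
        if t.is_monoexonic:
            continue
        matches = spliced_ref.get(t.intron_chain())
        if not matches:
            continue
        r = min(matches, key=lambda r: r.transcript_id)
        used_novel.add(t.transcript_id)
        consumed_ref.add(r.transcript_id)
        if t.start < r.start or t.end > r.end:
            start = min(t.start, r.start)
            end = max(t.end, r.end)
            exons = list(r.exons)
            exons[0] = (start, exons[0][1])
            exons[-1] = (exons[-1][0], end)
            merged = r.copy(exons=tuple(exons), tpm={**t.tpm}, sources=t.sources)
            merged.attributes["extended_by"] = t.transcript_id
            out.append(merged)
            report[r.transcript_id] = "replaced"
            report[t.transcript_id] = "merged_into_reference"
        else:
            # novel model adds nothing: reference kept verbatim, but it
            # inherits the novel model's expression/provenance evidence
            kept = r.copy(tpm={**t.tpm}, sources=t.sources)
            out.append(kept)
            report[r.transcript_id] = "kept"
            report[t.transcript_id] = "contained_in_reference"

    # monoexonic novel vs monoexonic reference: containment-based analog
    for t in novel:
        if not t.is_monoexonic or t.transcript_id in used_novel:
            continue
        candidates = [
            r
            for r in mono_ref.get((t.chromosome, t.strand), [])
            if r.transcript_id not in consumed_ref
            and t.start <= r.end
            and r.start <= t.end
        ]
        if not candidates:
            continue
        r = max(
            candidates,
            key=lambda r: (min(r.end, t.end) - max(r.start, t.start), r.transcript_id),
        )
        if t.start <= r.start and t.end >= r.end and (t.start < r.start or t.end > r.end):
            used_novel.add(t.transcript_id)
            consumed_ref.add(r.transcript_id)
            merged = r.copy(exons=((t.start, t.end),), tpm={**t.tpm}, sources=t.sources)
            merged.attributes["extended_by"] = t.transcript_id
            out.append(merged)
            report[r.transcript_id] = "replaced"
            report[t.transcript_id] = "merged_into_reference"
        elif r.start <= t.start and t.end <= r.end:
            used_novel.add(t.transcript_id)
            consumed_ref.add(r.transcript_id)
            out.append(r.copy(tpm={**t.tpm}, sources=t.sources))
            report[r.transcript_id] = "kept"
            report[t.transcript_id] = "contained_in_reference"

    for r in reference:
        if r.transcript_id not in consumed_ref:
            out.append(r.copy())
            report.setdefault(r.transcript_id, "kept")

    # surviving novel transcripts, minus those strictly included in a
    # reference model ("strictly included transcripts are discarded")
    ref_list = list(reference)
    survivors = []
    for t in novel:
        if t.transcript_id in used_novel:
            continue
        container = None
        for r in ref_list:
            if r.chromosome != t.chromosome or r.strand != t.strand:
                continue
            if t.is_monoexonic:
                if any(s <= t.start and t.end <= e for s, e in r.exons):
                    container = r
                    break
            elif not r.is_monoexonic and r.start <= t.start and t.end <= r.end and is_extension(r, t):
                container = r
                break
        if container is not None:
            report[t.transcript_id] = "contained_in_reference"
        else:
            survivors.append(t.copy())
            report[t.transcript_id] = "novel"
    out.extend(survivors)

    n_replaced = sum(1 for r in reference if report.get(r.transcript_id) == "replaced")
    assert len(reference) == (len(reference) - n_replaced) + n_replaced
    return out, report


def _exonic_overlap_components(transcripts: list[TranscriptModel]) -> list[list[int]]:
    """Connected components under same-strand >=1 bp exonic overlap."""
    uf = _UnionFind(len(transcripts))
    by_key: dict = {}
    for i, t in enumerate(transcripts):
        by_key.setdefault((t.chromosome, t.strand), []).append(i)
    for indices in by_key.values():
        events = []  # (start, end, transcript index) per exon
        for i in indices:
            for s, e in transcripts[i].exons:
                events.append((s, e, i))
        events.sort()
        active: list[tuple[int, int]] = []  # (end, index)
        for s, e, i in events:
            active = [(ae, ai) for ae, ai in active if ae >= s]
            for _ae, ai in active:
                uf.union(i, ai)
            active.append((e, i))
    comps: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        comps.setdefault(uf.find(i), []).append(i)
    return list(comps.values())


def assign_gene_ids(
    transcripts: list[TranscriptModel],
    config: MergeConfig | None = None,
    reference: AnnotationSet | None = None,
) -> list[TranscriptModel]:
    """Cluster transcripts into genes by same-strand exonic overlap.

    Components containing reference transcripts keep the lexicographically
    first reference gene id; purely novel components get deterministic
    ``TAGG%06d`` ids in (chromosome, start) order. Every transcript also
    receives a ``ref_gene_id`` attribute listing all reference genes with
    same-strand exonic overlap, when a reference is given.
    """
    config = config or MergeConfig()
    comps = _exonic_overlap_components(transcripts)
    comps.sort(key=lambda c: min((transcripts[i].chromosome, transcripts[i].start) for i in c))

    out = [t.copy() for t in transcripts]
    counter = 0
    for comp in comps:
        ref_gids = sorted(
            {
                out[i].attributes["gene_id"]
                for i in comp
                if out[i].origin == "reference" and out[i].attributes.get("gene_id")
            }
        )
        if ref_gids:
            gid = ref_gids[0]
        else:
            counter += 1
            gid = f"{config.gene_prefix}{counter:06d}"
        for i in comp:
            out[i].attributes["gene_id"] = gid

    if reference is not None:
        ref_transcripts = list(reference)
        for t in out:
            overlapping = sorted(
                {
                    r.attributes.get("gene_id", "")
                    for r in ref_transcripts
                    if r.strand == t.strand and t.exonic_overlap_bp(r) >= 1
                }
                - {""}
            )
            if overlapping:
                t.attributes["ref_gene_id"] = ",".join(overlapping)
    return out


def assign_reference_ids(
    annotation: AnnotationSet, reference: AnnotationSet
) -> AnnotationSet:
    """Inherit reference transcript ids and biotypes on exact structure match.

    Spliced transcripts inherit on intron-chain identity; monoexonic
    transcripts only on identical (chromosome, strand, start, end). Ties
    (duplicate reference chains) go to the lexicographically smallest
    reference transcript id.
    """
    spliced_ref: dict = {}
    for r in reference.spliced():
        key = r.intron_chain()
        if key not in spliced_ref or r.transcript_id < spliced_ref[key].transcript_id:
            spliced_ref[key] = r
    mono_ref: dict = {}
    for r in reference.monoexonic():
        key = (r.chromosome, r.strand, r.start, r.end)
        if key not in mono_ref or r.transcript_id < mono_ref[key].transcript_id:
            mono_ref[key] = r

    out = AnnotationSet(provenance=annotation.provenance)
    for t in annotation:
        match = (
            spliced_ref.get(t.intron_chain())
            if not t.is_monoexonic
            else mono_ref.get((t.chromosome, t.strand, t.start, t.end))
        )
        t = t.copy()
        if match is not None:
            t.attributes["ref_transcript_id"] = match.transcript_id
            if "transcript_biotype" in match.attributes:
                t.attributes["transcript_biotype"] = match.attributes["transcript_biotype"]
        out.add(t)
    return out


def merge_annotations(
    assemblies: list[AnnotationSet],
    reference: AnnotationSet,
    config: MergeConfig | None = None,
) -> tuple[AnnotationSet, dict[str, str]]:
    """Full merge: collapse across samples, drop contained, fold in reference.

    Returns the merged annotation (gene ids assigned, reference ids
    inherited) and the per-transcript action report. Novel transcripts
    are renamed ``TAGT%06d`` in (chromosome, start) order.
    """
    config = config or MergeConfig()
    pooled: list[TranscriptModel] = []
    ref_ids = {t.transcript_id for t in reference}
    seen: dict[str, int] = {}
    for annot in assemblies:
        for t in annot:
            tid = t.transcript_id
            if tid in seen or tid in ref_ids:
                # same id in two sample files, or an input that already
                # carries reference ids (re-merging a merged annotation)
                seen[tid] = seen.get(tid, 0) + 1
                t = t.copy(transcript_id=f"{tid}.in{seen[tid]}")
            else:
                seen[tid] = 0
            pooled.append(t)

    spliced = collapse_spliced([t for t in pooled if not t.is_monoexonic]) if pooled else []
    monos = [t for t in pooled if t.is_monoexonic]
    if config.monoexonic_collapse:
        monos = collapse_monoexonic(monos)
    collapsed = remove_contained(spliced + monos)
    merged, report = integrate_reference(collapsed, reference, config)

    # deterministic novel ids in genomic order
    novels = sorted(
        (t for t in merged if t.origin == "novel"),
        key=lambda t: (t.chromosome, t.start, t.end, t.transcript_id),
    )
    renames = {
        t.transcript_id: f"{config.transcript_prefix}{i:06d}"
        for i, t in enumerate(novels, start=1)
    }
    final = []
    for t in merged:
        if t.transcript_id in renames:
            new = t.copy(transcript_id=renames[t.transcript_id])
            new.attributes["assembled_id"] = t.transcript_id
            report[new.transcript_id] = report.pop(t.transcript_id, "novel")
            final.append(new)
        else:
            final.append(t)

    final = assign_gene_ids(final, config, reference=reference)
    result = AnnotationSet(final, provenance="merged")
    result = assign_reference_ids(result, reference)
    result.rebuild_gene_index()
    return result, report
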