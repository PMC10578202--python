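"""Noise filters for novel transcripts.

Two filters protect the merged annotation from assembly noise; both act
on novel transcripts only, reference models are never removed:

* consistency: a novel transcript detected in fewer than
  ``min_transcriptomes`` input transcriptomes (2 by default) is dropped,
* expression: a novel transcript whose highest TPM across all
  transcriptomes does not reach ``min_tpm`` (0.1 by default) is dropped.

Comparisons are inclusive: a transcript survives iff its detection count
is >= min_transcriptomes and its maximum TPM is >= min_tpm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import AnnotationSet, ValidationError

__all__ = ["FilterConfig", "consistency_filter", "expression_filter", "apply_filters"]

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_transcriptomes: int = 2
    min_tpm: float = 0.1

    def __post_init__(self) -> None:
        if self.min_transcriptomes < 1:
            raise ValidationError("min_transcriptomes must be >= 1")
        if self.min_tpm < 0:
            raise ValidationError("min_tpm must be >= 0")


def _subset(annotation: AnnotationSet, keep) -> AnnotationSet:
    out = AnnotationSet(provenance=annotation.provenance)
    for t in annotation:
        if keep(t):
            out.add(t.copy())
    out.rebuild_gene_index()
    return out


def consistency_filter(
    annotation: AnnotationSet, config: FilterConfig | None = None
) -> AnnotationSet:
    """Drop novel transcripts seen in fewer than min_transcriptomes samples."""
    config = config or FilterConfig()
    removed = []

    def keep(t):
        if t.origin == "reference":
            return True
        if not t.sources and not t.tpm:
            raise ValidationError(
                f"novel transcript {t.transcript_id!r} has no detection record"
            )
        if t.detection_count < config.min_transcriptomes:
            removed.append(t.transcript_id)
            return False
        return True

    out = _subset(annotation, keep)
    if removed:
        log.info("consistency filter removed %d transcript(s)", len(removed))
    out.removed_by_filter = removed
    return out


def expression_filter(
    annotation: AnnotationSet, config: FilterConfig | None = None
) -> AnnotationSet:
    """Drop novel transcripts whose max TPM across samples is below min_tpm."""
    config = config or FilterConfig()
    removed = []

    def keep(t):
        if t.origin == "reference":
            return True
        for sample, value in t.tpm.items():
            if value < 0:
                raise ValidationError(
                    f"{t.transcript_id!r}: negative TPM in {sample!r}"
                )
        top = max(t.tpm.values(), default=0.0)
        if top < config.min_tpm:
            removed.append(t.transcript_id)
            return False
        return True

    out = _subset(annotation, keep)
    if removed:
        log.info("expression filter removed %d transcript(s)", len(removed))
    out.removed_by_filter = removed
    return out


def apply_filters(
    annotation: AnnotationSet, config: FilterConfig | None = None
) -> AnnotationSet:
    """Both filters; the two commute, order is immaterial."""
    return expression_filter(consistency_filter(annotation, config), config)
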