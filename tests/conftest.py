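"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import settings

from annotweave.model import AnnotationSet, TranscriptModel

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from annotweave.simulate import FixtureSpec, SyntheticDataset


def make_transcript(
    tid: str,
    exons,
    chrom: str = "chr1",
    strand: str = "+",
    gene: str | None = None,
    origin: str = "novel",
    sources=(),
    tpm=None,
    **attrs,
) -> TranscriptModel:
    attributes = {"gene_id": gene or f"g_{tid}"}
    attributes.update(attrs)
    return TranscriptModel(
        transcript_id=tid,
        chromosome=chrom,
        strand=strand,
        exons=tuple(exons),
        attributes=attributes,
        tpm=dict(tpm or {}),
        sources=frozenset(sources),
        origin=origin,
    )


def make_annotation(*transcripts, provenance: str = "merged") -> AnnotationSet:
    return AnnotationSet(transcripts, provenance=provenance)


@pytest.fixture(scope="session")
def dataset() -> SyntheticDataset:
    """One seeded synthetic dataset shared by read-only tests."""
    ds = SyntheticDataset(FixtureSpec(seed=11))
    ds.assemblies()  # finalize genome bytes before anyone reads them
    return ds


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The same dataset emitted to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    ds = SyntheticDataset(FixtureSpec(seed=11))
    paths = ds.write(outdir)
    return ds, paths
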