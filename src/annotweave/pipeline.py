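"""End-to-end orchestration: merge -> filter -> classify -> qc -> express."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classification_table
from .filters import FilterConfig, apply_filters
from .io import read_fasta, read_gtf, write_gtf
from .merge import merge_annotations
from .qc import qc_report, read_bed

__all__ = ["run_pipeline"]


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(
    reference_path: str | Path,
    assembly_paths: list,
    outdir: str | Path,
    genome_path: str | Path | None = None,
    peaks_path: str | Path | None = None,
    matrix_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    min_transcriptomes: int = 2,
    min_tpm: float = 0.1,
    tpm_attribute: str = "TPM",
) -> dict[str, Path]:
    """Run the in-scope stages in order; outputs are deterministic.

    Returns a mapping of stage name to output path. A run manifest with
    the package version, configuration and input checksums is written
    alongside (the only file carrying environment-dependent content).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    reference = read_gtf(reference_path, tpm_attribute, provenance="reference")
    assemblies = [read_gtf(p, tpm_attribute) for p in assembly_paths]

    merged, report = merge_annotations(assemblies, reference)
    filtered = apply_filters(
        merged, FilterConfig(min_transcriptomes=min_transcriptomes, min_tpm=min_tpm)
    )
    outputs["annotation"] = outdir / "novel_annotation.gtf"
    write_gtf(filtered, outputs["annotation"])
    outputs["merge_report"] = outdir / "merge_report.tsv"
    pd.Series(report, name="action").rename_axis("transcript_id").sort_index().to_csv(
        outputs["merge_report"], sep="\t"
    )

    table = classification_table(filtered, reference)
    outputs["classes"] = outdir / "classes.tsv"
    table.to_csv(outputs["classes"], sep="\t", index=False)

    genome = read_fasta(genome_path) if genome_path else None
    peaks = read_bed(peaks_path) if peaks_path else None
    qc = qc_report(filtered, genome=genome, peaks=peaks)
    outputs["qc"] = outdir / "qc.tsv"
    pd.DataFrame(
        [
            {
                "metric": name,
                "value": value,
                "numerator": qc.counts[name][0],
                "denominator": qc.counts[name][1],
            }
            for name, value in qc.metrics.items()
        ]
    ).to_csv(outputs["qc"], sep="\t", index=False)

    if matrix_path and metadata_path:
        from .expression import (
            ExpressionMatrix,
            cluster_samples,
            sample_similarity,
            tissue_specific_genes,
        )

        matrix = ExpressionMatrix.from_tsv(matrix_path, metadata_path)
        specific = tissue_specific_genes(matrix)
        outputs["tissue_specific"] = outdir / "tissue_specific.tsv"
        specific.to_csv(outputs["tissue_specific"], sep="\t")
        similarity = sample_similarity(matrix)
        outputs["similarity"] = outdir / "similarity.tsv"
        similarity.to_csv(outputs["similarity"], sep="\t")
        merges = cluster_samples(similarity)
        outputs["dendrogram"] = outdir / "dendrogram.tsv"
        with open(outputs["dendrogram"], "w") as handle:
            handle.write("step\tcluster_a\tcluster_b\theight\n")
            for i, (a, b, height) in enumerate(merges, start=1):
                handle.write(
                    f"{i}\t{','.join(sorted(a))}\t{','.join(sorted(b))}\t{height:.6f}\n"
                )

    manifest = {
        "version": __version__,
        "config": {
            "min_transcriptomes": min_transcriptomes,
            "min_tpm": min_tpm,
            "tpm_attribute": tpm_attribute,
        },
        "inputs": {
            str(p): _checksum(p)
            for p in [reference_path, *assembly_paths]
            + [p for p in (genome_path, peaks_path, matrix_path, metadata_path) if p]
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outputs
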