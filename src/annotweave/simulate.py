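"""Deterministic synthetic data with recorded ground truth.

Generates toy genomes, reference annotations, noisy per-sample
transcript assemblies, expression matrices, open-chromatin peaks and
PSL projections, so the whole toolkit is testable without downloads.

What the data emulates
----------------------
A multi-tissue annotation project: a reference annotation of
non-overlapping single-transcript gene loci with interleaved
coding/lncRNA biotypes (so synteny triplets exist); per-sample
StringTie-like assemblies containing jittered reference models, a known
number K of novel isoforms seen consistently (>= 2 samples, TPM >= 0.1),
terminal-exon extensions, and assembly noise seen in one sample only or
below the TPM floor; a 7-tissue x 3-stage x 4-replicate expression
design with planted tissue-specific genes; and a second species plus
PSL alignments with decoys for orthology.

The genome is random sequence with splice-site dinucleotides,
polyadenylation hexamers and ATAC-like peaks *planted* at recorded
positions; accidental polyA hexamers are scrubbed so the planted QC
fractions are exact. Every draw derives from the master seed through
stable per-artifact labels, so changing one fixture never perturbs
another and every emitted file is byte-identical across runs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_fasta, write_gtf
from .model import (
    AnnotationSet,
    GenomeSequence,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)
from .qc import POLYA_HEXAMERS

__all__ = ["FixtureSpec", "GroundTruth", "SyntheticDataset", "generate"]


@dataclass
class FixtureSpec:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    n_genes: int = 60
    exons_per_transcript: tuple[int, int] = (2, 5)
    fraction_monoexonic: float = 0.1
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (80, 250)
    intergenic_gap: tuple[int, int] = (800, 1600)
    canonical_fraction: float = 0.95
    p_polya: float = 0.8
    p_peak: float = 0.7
    n_samples: int = 6
    p_detect: float = 0.8
    terminal_jitter: int = 30
    n_novel: int = 8
    n_extensions: int = 3
    extension_bp: int = 60
    n_noise: int = 10
    tpm_log_mean: float = 1.0
    tpm_log_sigma: float = 1.0
    n_tissues: int = 7
    n_stages: int = 3
    n_replicates: int = 4
    n_tissue_specific: int = 7
    specificity_ratio: float = 50.0
    expression_noise_sigma: float = 0.5
    n_decoys: int = 2

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValidationError("counts must be positive")
        if not (0 <= self.canonical_fraction <= 1):
            raise ValidationError("canonical_fraction must be in [0, 1]")

    def rng(self, label: str) -> np.random.Generator:
        """Child generator derived from the master seed by a stable label."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


@dataclass
class GroundTruth:
    """Planted quantities, recorded while generating."""

    novel_ids: list[str] = field(default_factory=list)
    extension_ref_ids: list[str] = field(default_factory=list)
    noise_ids: list[str] = field(default_factory=list)
    reference_transcripts: int = 0
    monoexonic_fraction: float = 0.0
    canonical_fraction: float = 0.0
    tss_completion: float = 0.0
    tts_completion: float = 0.0
    tissue_specific: dict[str, str] = field(default_factory=dict)
    triplet_count: int = 0
    orthology_pairs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


_NONCANONICAL = ("CC", "GG")  # planted donor/acceptor for non-canonical introns


def _scrub_polya(seq: bytearray) -> None:
    """Remove accidental polyA hexamers (both strands) from a sequence.

    The motifs contain only A/T, so writing a C in the middle of an
    occurrence can never create a new occurrence.
    """
    motifs = [m.encode() for m in POLYA_HEXAMERS] + [
        reverse_complement(m).encode() for m in POLYA_HEXAMERS
    ]
    changed = True
    while changed:
        changed = False
        for motif in motifs:
            i = seq.find(motif)
            while i != -1:
                seq[i + 3] = ord("C")
                changed = True
                i = seq.find(motif, i + 1)


def _plant(seq: bytearray, pos: int, bases: str) -> None:
    """Overwrite bases at a 1-based position."""
    seq[pos - 1 : pos - 1 + len(bases)] = bases.encode()


def _plant_splice_sites(
    seq: bytearray, intron: tuple[int, int], strand: str, canonical: bool
) -> None:
    donor, acceptor = ("GT", "AG") if canonical else _NONCANONICAL
    s, e = intron
    if strand == "+":
        _plant(seq, s, donor)
        _plant(seq, e - 1, acceptor)
    else:
        _plant(seq, e - 1, reverse_complement(donor))
        _plant(seq, s, reverse_complement(acceptor))


class SyntheticDataset:
    """Lazy builder for one seeded synthetic dataset."""

    def __init__(self, spec: FixtureSpec | None = None, **kwargs):
        self.spec = spec or FixtureSpec(**kwargs)
        self.truth = GroundTruth()
        self._layout: list[dict] | None = None
        self._genome: GenomeSequence | None = None
        self._reference: AnnotationSet | None = None
        self._sequences: dict[str, bytearray] = {}

    # -- gene layout -------------------------------------------------------

    def _build_layout(self) -> list[dict]:
        if self._layout is not None:
            return self._layout
        spec = self.spec
        rng = spec.rng("layout")
        chroms = list(spec.chromosome_lengths)
        genes: list[dict] = []
        chrom_i = 0
        cursor = 1000
        biotype_cycle = ("protein_coding", "lncRNA", "protein_coding")
        for g in range(spec.n_genes):
            mono = rng.random() < spec.fraction_monoexonic
            n_exons = 1 if mono else int(rng.integers(*spec.exons_per_transcript, endpoint=True))
            exon_lens = rng.integers(*spec.exon_length, endpoint=True, size=n_exons)
            intron_lens = rng.integers(*spec.intron_length, endpoint=True, size=max(0, n_exons - 1))
            span = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(*spec.intergenic_gap, endpoint=True))
            while cursor + span + gap > spec.chromosome_lengths[chroms[chrom_i]] - 1000:
                chrom_i += 1
                cursor = 1000
                if chrom_i >= len(chroms):
                    raise ValidationError(
                        "chromosomes too small for the requested gene count"
                    )
            exons = []
            pos = cursor
            for i, length in enumerate(exon_lens):
                exons.append((pos, pos + int(length) - 1))
                pos += int(length)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                {
                    "gene_id": f"REFG{g + 1:04d}",
                    "transcript_id": f"REFT{g + 1:04d}",
                    "chromosome": chroms[chrom_i],
                    "strand": strand,
                    "exons": tuple(exons),
                    "biotype": biotype_cycle[g % 3],
                }
            )
            cursor = pos + gap
        self._layout = genes
        return genes

    # -- genome ------------------------------------------------------------

    def genome(self) -> GenomeSequence:
        if self._genome is not None:
            return self._genome
        spec = self.spec
        layout = self._build_layout()
        rng = spec.rng("genome")
        seqs: dict[str, bytearray] = {}
        for chrom, length in spec.chromosome_lengths.items():
            raw = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
            seqs[chrom] = bytearray(raw.tobytes())
        for seq in seqs.values():
            _scrub_polya(seq)

        # plant splice dinucleotides: an exact share of distinct introns canonical
        introns = []
        for gene in layout:
            t = TranscriptModel(
                gene["transcript_id"], gene["chromosome"], gene["strand"], gene["exons"]
            )
            for iv in t.introns():
                introns.append((gene["chromosome"], gene["strand"], iv))
        n_canonical = round(spec.canonical_fraction * len(introns))
        order = spec.rng("canonicity").permutation(len(introns))
        canonical_flags = {order[i]: i < n_canonical for i in range(len(introns))}
        for i, (chrom, strand, iv) in enumerate(introns):
            _plant_splice_sites(seqs[chrom], iv, strand, canonical_flags[i])
        self.truth.canonical_fraction = (
            n_canonical / len(introns) if introns else 0.0
        )

        # plant polyA hexamers near a designated share of TTSs
        polya_rng = spec.rng("polya")
        n_polya = 0
        for gene in layout:
            gene["has_polya"] = polya_rng.random() < spec.p_polya
            if not gene["has_polya"]:
                continue
            n_polya += 1
            seq = seqs[gene["chromosome"]]
            if gene["strand"] == "+":
                tts = gene["exons"][-1][1]
                _plant(seq, tts - 25, "AATAAA")
            else:
                tts = gene["exons"][0][0]
                _plant(seq, tts + 20, reverse_complement("AATAAA"))
        self.truth.tts_completion = n_polya / len(layout)

        # introns planted after the scrub cannot recreate A/T-only
        # hexamers (GT/AG/CC/GG all contain G or C), and planted hexamers
        # sit inside terminal exons, so both plantings are independent
        self._sequences = seqs
        self._genome = GenomeSequence({c: s.decode() for c, s in seqs.items()})
        self.truth.monoexonic_fraction = sum(
            1 for g in layout if len(g["exons"]) == 1
        ) / len(layout)
        return self._genome

    # -- reference annotation ---------------------------------------------

    def reference(self) -> AnnotationSet:
        if self._reference is not None:
            return self._reference
        layout = self._build_layout()
        transcripts = []
        for gene in layout:
            transcripts.append(
                TranscriptModel(
                    transcript_id=gene["transcript_id"],
                    chromosome=gene["chromosome"],
                    strand=gene["strand"],
                    exons=gene["exons"],
                    attributes={
                        "gene_id": gene["gene_id"],
                        "transcript_biotype": gene["biotype"],
                    },
                    origin="reference",
                )
            )
        ref = AnnotationSet(transcripts, provenance="reference")
        ref.rebuild_gene_index()
        for gene in ref.genes.values():
            biotype = ref.transcripts[gene.transcript_ids[0]].attributes["transcript_biotype"]
            gene.coding_status = "mRNA" if biotype == "protein_coding" else "lncRNA"
        self.truth.reference_transcripts = len(ref)
        # planted triplets: consecutive coding/lnc/coding runs per chromosome
        count = 0
        by_chrom: dict[str, list] = {}
        for gene in layout:
            by_chrom.setdefault(gene["chromosome"], []).append(gene)
        for genes in by_chrom.values():
            for i in range(1, len(genes) - 1):
                if (
                    genes[i]["biotype"] == "lncRNA"
                    and genes[i - 1]["biotype"] == "protein_coding"
                    and genes[i + 1]["biotype"] == "protein_coding"
                ):
                    count += 1
        self.truth.triplet_count = count
        self._reference = ref
        return ref

    # -- peaks -------------------------------------------------------------

    def peaks(self):
        """ATAC-like peaks covering a designated share of TSSs (1-based)."""
        from .qc import PeakSet

        layout = self._build_layout()
        rng = self.spec.rng("peaks")
        peaks = PeakSet()
        n = 0
        for gene in layout:
            if rng.random() < self.spec.p_peak:
                n += 1
                tss = gene["exons"][0][0] if gene["strand"] == "+" else gene["exons"][-1][1]
                peaks.intervals.setdefault(gene["chromosome"], []).append(
                    (tss - 50, tss + 50)
                )
        for v in peaks.intervals.values():
            v.sort()
        self.truth.tss_completion = n / len(layout)
        return peaks

    # -- per-sample assemblies ----------------------------------------------

    def assemblies(self) -> dict[str, AnnotationSet]:
        """Per-sample transcript sets emulating StringTie outputs."""
        spec = self.spec
        self.genome()  # ensures layout + splice planting done first
        layout = self._build_layout()
        samples = [f"sample{i + 1:02d}" for i in range(spec.n_samples)]
        rng = spec.rng("assemblies")

        per_sample: dict[str, list[TranscriptModel]] = {s: [] for s in samples}

        def tpm_draw(minimum: float = 0.0) -> float:
            value = float(rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sigma))
            return round(max(value, minimum), 4)

        # jittered copies of reference transcripts (chain-preserving shrink)
        for gene in layout:
            for sample in samples:
                if rng.random() >= spec.p_detect:
                    continue
                exons = list(gene["exons"])
                first, last = exons[0], exons[-1]
                shrink5 = int(rng.integers(0, spec.terminal_jitter + 1))
                shrink3 = int(rng.integers(0, spec.terminal_jitter + 1))
                exons[0] = (first[0] + min(shrink5, first[1] - first[0] - 10), first[1])
                exons[-1] = (exons[-1][0], last[1] - min(shrink3, last[1] - exons[-1][0] - 10))
                per_sample[sample].append(
                    TranscriptModel(
                        transcript_id=f"{sample}.{gene['transcript_id']}",
                        chromosome=gene["chromosome"],
                        strand=gene["strand"],
                        exons=tuple(exons),
                        attributes={"gene_id": f"{sample}.{gene['gene_id']}"},
                        tpm={sample: tpm_draw()},
                        sources=frozenset({sample}),
                    )
                )

        # planted novel isoforms: shift the first intron's donor inward,
        # giving a chain that neither matches nor is contained in the
        # reference chain; present in >= 2 samples at TPM >= 0.1
        spliced_genes = [g for g in layout if len(g["exons"]) >= 2]
        if spec.n_novel > len(spliced_genes):
            raise ValidationError("n_novel exceeds the number of spliced genes")
        pick = rng.choice(len(spliced_genes), size=spec.n_novel, replace=False)
        for k, gi in enumerate(sorted(pick)):
            gene = spliced_genes[gi]
            exons = list(gene["exons"])
            shift = 12
            exons[0] = (exons[0][0], exons[0][1] + shift)
            new_intron = (exons[0][1] + 1, exons[1][0] - 1)
            _plant_splice_sites(
                self._sequences[gene["chromosome"]], new_intron, gene["strand"], True
            )
            tid = f"NOVEL{k + 1:03d}"
            self.truth.novel_ids.append(tid)
            n_in = int(rng.integers(2, spec.n_samples + 1))
            chosen = rng.choice(spec.n_samples, size=n_in, replace=False)
            for si in sorted(chosen):
                sample = samples[si]
                per_sample[sample].append(
                    TranscriptModel(
                        transcript_id=f"{sample}.{tid}",
                        chromosome=gene["chromosome"],
                        strand=gene["strand"],
                        exons=tuple(exons),
                        attributes={"gene_id": f"{sample}.{gene['gene_id']}"},
                        tpm={sample: tpm_draw(minimum=0.5)},
                        sources=frozenset({sample}),
                    )
                )
        # genome bytes changed (new donor sites): refresh the view
        self._genome = GenomeSequence(
            {c: s.decode() for c, s in self._sequences.items()}
        )

        # planted terminal extensions of reference transcripts
        ext_candidates = spliced_genes
        pick = rng.choice(len(ext_candidates), size=min(spec.n_extensions, len(ext_candidates)), replace=False)
        for k, gi in enumerate(sorted(pick)):
            gene = ext_candidates[gi]
            exons = list(gene["exons"])
            exons[-1] = (exons[-1][0], exons[-1][1] + spec.extension_bp)
            self.truth.extension_ref_ids.append(gene["transcript_id"])
            n_in = int(rng.integers(2, spec.n_samples + 1))
            chosen = rng.choice(spec.n_samples, size=n_in, replace=False)
            for si in sorted(chosen):
                sample = samples[si]
                per_sample[sample].append(
                    TranscriptModel(
                        transcript_id=f"{sample}.EXT{k + 1:03d}",
                        chromosome=gene["chromosome"],
                        strand=gene["strand"],
                        exons=tuple(exons),
                        attributes={"gene_id": f"{sample}.{gene['gene_id']}"},
                        tpm={sample: tpm_draw(minimum=0.5)},
                        sources=frozenset({sample}),
                    )
                )

        # noise: intergenic transcripts failing one filter each
        gaps = self._intergenic_gaps()
        if spec.n_noise > len(gaps):
            raise ValidationError("n_noise exceeds the number of intergenic gaps")
        pick = rng.choice(len(gaps), size=spec.n_noise, replace=False)
        for k, gi in enumerate(sorted(pick)):
            chrom, lo, hi = gaps[gi]
            start = lo + (hi - lo - 200) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            tid = f"NOISE{k + 1:03d}"
            self.truth.noise_ids.append(tid)
            low_tpm = k % 2 == 1  # alternate failure mode
            if low_tpm:
                chosen = rng.choice(spec.n_samples, size=2, replace=False)
                tpm_value = 0.05
            else:
                chosen = rng.choice(spec.n_samples, size=1)
                tpm_value = round(tpm_draw(minimum=0.5), 4)
            for si in sorted(chosen):
                sample = samples[si]
                per_sample[sample].append(
                    TranscriptModel(
                        transcript_id=f"{sample}.{tid}",
                        chromosome=chrom,
                        strand=strand,
                        exons=((start, start + 199),),
                        attributes={"gene_id": f"{sample}.{tid}"},
                        tpm={sample: tpm_value},
                        sources=frozenset({sample}),
                    )
                )

        return {
            s: AnnotationSet(ts, provenance=f"sample:{s}")
            for s, ts in per_sample.items()
        }

    def _intergenic_gaps(self) -> list[tuple[str, int, int]]:
        layout = self._build_layout()
        gaps = []
        by_chrom: dict[str, list] = {}
        for gene in layout:
            by_chrom.setdefault(gene["chromosome"], []).append(gene)
        for chrom, genes in by_chrom.items():
            for a, b in zip(genes, genes[1:]):
                lo = a["exons"][-1][1] + 150
                hi = b["exons"][0][0] - 150
                if hi - lo >= 300:
                    gaps.append((chrom, lo, hi))
        return gaps

    # -- expression ----------------------------------------------------------

    def expression(self):
        """84-sample TPM matrix over reference genes with planted specificity."""
        from .expression import ExpressionMatrix

        spec = self.spec
        ref = self.reference()
        rng = spec.rng("expression")
        tissues = [f"tissue{i + 1}" for i in range(spec.n_tissues)]
        stages = [f"stage{i + 1}" for i in range(spec.n_stages)]
        samples = []
        meta = []
        for tissue in tissues:
            for stage in stages:
                for rep in range(1, spec.n_replicates + 1):
                    name = f"{tissue}_{stage}_rep{rep}"
                    samples.append(name)
                    meta.append({"sample": name, "tissue": tissue, "stage": stage, "replicate": rep})
        genes = sorted(ref.genes)
        base = rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sigma, size=len(genes))

        specific = {}
        pick = rng.choice(len(genes), size=min(spec.n_tissue_specific, len(genes)), replace=False)
        for i, gi in enumerate(sorted(pick)):
            specific[genes[gi]] = tissues[i % len(tissues)]
        self.truth.tissue_specific = dict(specific)

        values = np.empty((len(genes), len(samples)))
        for gi, gene in enumerate(genes):
            for si, record in enumerate(meta):
                level = base[gi]
                if gene in specific and record["tissue"] == specific[gene]:
                    level *= spec.specificity_ratio
                noise = rng.lognormal(0.0, spec.expression_noise_sigma)
                values[gi, si] = round(level * noise, 4)
        matrix = pd.DataFrame(values, index=pd.Index(genes, name="feature"), columns=samples)
        metadata = pd.DataFrame(meta).set_index("sample")
        return ExpressionMatrix(values=matrix, metadata=metadata)

    # -- orthology ------------------------------------------------------------

    def target_species(self) -> AnnotationSet:
        """A second species' annotation with a 1-to-1 gene correspondence."""
        other = SyntheticDataset(
            FixtureSpec(
                seed=(self.spec.seed + 104729) % 2**31,  # independent layout, same scale
                chromosome_lengths=dict(self.spec.chromosome_lengths),
                n_genes=self.spec.n_genes,
                fraction_monoexonic=self.spec.fraction_monoexonic,
            )
        )
        target = other.reference()
        renamed = AnnotationSet(provenance="reference")
        for t in target:
            t = t.copy(
                transcript_id=t.transcript_id.replace("REFT", "TGTT"),
            )
            t.attributes["gene_id"] = t.attributes["gene_id"].replace("REFG", "TGTG")
            renamed.add(t)
        renamed.rebuild_gene_index()
        for gene in renamed.genes.values():
            biotype = renamed.transcripts[gene.transcript_ids[0]].attributes["transcript_biotype"]
            gene.coding_status = "mRNA" if biotype == "protein_coding" else "lncRNA"
        self.truth.orthology_pairs = {
            f"REFG{i + 1:04d}": f"TGTG{i + 1:04d}" for i in range(self.spec.n_genes)
        }
        return renamed

    def psl_alignments(self, target: AnnotationSet):
        """One true high-scoring alignment per source transcript plus decoys."""
        from .orthology import PslAlignment, score_alignment

        spec = self.spec
        ref = self.reference()
        rng = spec.rng("psl")
        target_transcripts = {t.transcript_id: t for t in target}
        alignments: list[PslAlignment] = []
        order = 0
        source = sorted(ref, key=lambda t: t.transcript_id)
        for t in source:
            pair_target = target_transcripts[
                self.truth.orthology_pairs[t.gene_id].replace("TGTG", "TGTT")
            ]
            sizes = tuple(e - s + 1 for s, e in pair_target.exons)
            q_starts = tuple(int(x) for x in np.cumsum((0,) + sizes[:-1]))
            t_starts = tuple(s - 1 for s, _e in pair_target.exons)
            true = PslAlignment(
                query_id=t.transcript_id,
                target_chrom=pair_target.chromosome,
                strand=pair_target.strand,
                matches=int(sum(sizes)),
                mis_matches=0,
                rep_matches=0,
                q_num_insert=0,
                t_num_insert=len(sizes) - 1,
                block_sizes=sizes,
                q_starts=q_starts,
                t_starts=t_starts,
                order=order,
            )
            alignments.append(true)
            order += 1
            for _ in range(spec.n_decoys):
                decoy_t = target_transcripts[
                    f"TGTT{int(rng.integers(1, spec.n_genes + 1)):04d}"
                ]
                d_sizes = tuple(
                    max(20, (e - s + 1) // 3) for s, e in decoy_t.exons
                )
                decoy = PslAlignment(
                    query_id=t.transcript_id,
                    target_chrom=decoy_t.chromosome,
                    strand=decoy_t.strand,
                    matches=int(sum(d_sizes) // 2),
                    mis_matches=int(sum(d_sizes) - sum(d_sizes) // 2),
                    rep_matches=0,
                    q_num_insert=1,
                    t_num_insert=len(d_sizes) - 1,
                    block_sizes=d_sizes,
                    q_starts=tuple(int(x) for x in np.cumsum((0,) + d_sizes[:-1])),
                    t_starts=tuple(s - 1 for s, _e in decoy_t.exons),
                    order=order,
                )
                order += 1
                assert score_alignment(decoy) < score_alignment(true)
                alignments.append(decoy)
        return alignments

    # -- emission --------------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every fixture file; byte-identical for a fixed seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        assemblies = self.assemblies()  # also finalizes the genome bytes
        genome = self.genome()
        paths["genome"] = outdir / "genome.fa"
        write_fasta(genome, paths["genome"])

        ref = self.reference()
        paths["reference"] = outdir / "reference.gtf"
        write_gtf(ref, paths["reference"])

        for sample, annot in assemblies.items():
            p = outdir / f"{sample}.gtf"
            write_gtf(annot, p)
            paths[sample] = p

        peaks = self.peaks()
        paths["peaks"] = outdir / "peaks.bed"
        with open(paths["peaks"], "w", newline="\n") as handle:
            for chrom in sorted(peaks.intervals):
                for s, e in peaks.intervals[chrom]:
                    handle.write(f"{chrom}\t{s - 1}\t{e}\n")

        matrix = self.expression()
        paths["matrix"] = outdir / "tpm.tsv"
        matrix.values.to_csv(paths["matrix"], sep="\t")
        paths["metadata"] = outdir / "metadata.tsv"
        matrix.metadata.to_csv(paths["metadata"], sep="\t")

        target = self.target_species()
        paths["target"] = outdir / "target.gtf"
        write_gtf(target, paths["target"])
        alignments = self.psl_alignments(target)
        paths["psl"] = outdir / "hits.psl"
        with open(paths["psl"], "w", newline="\n") as handle:
            for a in alignments:
                q_size = sum(a.block_sizes) + a.q_num_insert
                t_end = a.t_starts[-1] + a.block_sizes[-1]
                fields = [
                    a.matches, a.mis_matches, a.rep_matches, 0,
                    a.q_num_insert, 0, a.t_num_insert, 0, a.strand,
                    a.query_id, q_size, 0, q_size,
                    a.target_chrom, 10 ** 6, a.t_starts[0], t_end,
                    a.block_count,
                    ",".join(map(str, a.block_sizes)) + ",",
                    ",".join(map(str, a.q_starts)) + ",",
                    ",".join(map(str, a.t_starts)) + ",",
                ]
                handle.write("\t".join(map(str, fields)) + "\n")

        paths["truth_pairs"] = outdir / "truth_pairs.tsv"
        with open(paths["truth_pairs"], "w", newline="\n") as handle:
            handle.write("source_gene\ttarget_gene\n")
            for s, t in sorted(self.truth.orthology_pairs.items()):
                handle.write(f"{s}\t{t}\n")

        paths["ground_truth"] = outdir / "ground_truth.json"
        self.truth.to_json(paths["ground_truth"])
        return paths


def generate(spec: FixtureSpec | None = None, **kwargs) -> SyntheticDataset:
    return SyntheticDataset(spec, **kwargs)
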