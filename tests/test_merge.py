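"""Merge engine: collapse, containment, reference integration, gene clustering.

Brute-force oracles: pairwise chain comparison for collapse, exhaustive
containment scans, and networkx connected components for gene clustering.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from annotweave.filters import apply_filters
from annotweave.merge import (
    MergeConfig,
    assign_gene_ids,
    assign_reference_ids,
    collapse_monoexonic,
    collapse_spliced,
    integrate_reference,
    is_extension,
    merge_annotations,
    remove_contained,
)
from annotweave.model import AnnotationSet, ValidationError
from annotweave.simulate import FixtureSpec, SyntheticDataset

from conftest import make_annotation, make_transcript


def random_transcripts(rng, n, chroms=("chr1", "chr2"), spliced_only=False):
    """Small random stranded transcripts for oracle comparisons."""
    out = []
    for i in range(n):
        n_exons = int(rng.integers(2 if spliced_only else 1, 4))
        pos = int(rng.integers(1, 2000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(10, 80))
        out.append(
            make_transcript(
                f"t{i:03d}",
                exons,
                chrom=str(rng.choice(chroms)),
                strand=str(rng.choice(["+", "-"])),
                sources={f"s{int(rng.integers(0, 4))}"},
                tpm={f"s{int(rng.integers(0, 4))}": float(rng.uniform(0.2, 9))},
            )
        )
    return out


class TestCollapseSpliced:
    def test_idempotent_on_identical_pair(self):
        a = make_transcript("a", [(100, 200), (300, 400)])
        b = make_transcript("b", [(100, 200), (300, 400)])
        (merged,) = collapse_spliced([a, b])
        assert merged.exons == ((100, 200), (300, 400))

    def test_terminal_extension_union(self):
        a = make_transcript("a", [(100, 200), (300, 400)], sources={"s1"}, tpm={"s1": 1.0})
        b = make_transcript("b", [(150, 200), (300, 450)], sources={"s2"}, tpm={"s2": 2.0})
        (merged,) = collapse_spliced([a, b])
        assert merged.exons == ((100, 200), (300, 450))
        assert merged.detection_count == 2
        assert merged.tpm == {"s1": 1.0, "s2": 2.0}

    def test_per_sample_tpm_maxima(self):
        a = make_transcript("a", [(1, 10), (30, 40)], sources={"s1"}, tpm={"s1": 1.0})
        b = make_transcript("b", [(1, 10), (30, 40)], sources={"s1"}, tpm={"s1": 5.0})
        (merged,) = collapse_spliced([a, b])
        assert merged.tpm == {"s1": 5.0}
        assert merged.detection_count == 1

    def test_different_chromosomes_kept_apart(self):
        a = make_transcript("a", [(100, 200), (300, 400)], chrom="chr1")
        b = make_transcript("b", [(100, 200), (300, 400)], chrom="chr2")
        assert len(collapse_spliced([a, b])) == 2

    def test_monoexonic_input_rejected(self):
        with pytest.raises(ValidationError):
            collapse_spliced([make_transcript("m", [(1, 50)])])

    def test_agrees_with_pairwise_brute_force(self):
        """Collapse result matches grouping by (chrom, strand, chain) computed
        by exhaustive pairwise comparison."""
        rng = np.random.default_rng(42)
        ts = random_transcripts(rng, 60, spliced_only=True)
        result = collapse_spliced(ts)
        # oracle: union-find over pairwise same-chain relation
        g = nx.Graph()
        g.add_nodes_from(range(len(ts)))
        for i, j in itertools.combinations(range(len(ts)), 2):
            if ts[i].intron_chain() == ts[j].intron_chain():
                g.add_edge(i, j)
        components = list(nx.connected_components(g))
        assert len(result) == len(components)
        for comp in components:
            members = [ts[i] for i in comp]
            start = min(t.start for t in members)
            end = max(t.end for t in members)
            chain = members[0].intron_chain()
            match = [
                r for r in result
                if r.intron_chain() == chain and (r.start, r.end) == (start, end)
            ]
            assert len(match) == 1


class TestCollapseMonoexonic:
    def test_overlap_union(self):
        a = make_transcript("a", [(100, 200)])
        b = make_transcript("b", [(150, 250)])
        (merged,) = collapse_monoexonic([a, b])
        assert merged.exons == ((100, 250),)

    def test_strand_separation(self):
        a = make_transcript("a", [(100, 200)], strand="+")
        b = make_transcript("b", [(150, 250)], strand="-")
        assert len(collapse_monoexonic([a, b])) == 2

    def test_transitive_chain_union(self):
        ts = [
            make_transcript("a", [(1, 10)]),
            make_transcript("b", [(5, 15)]),
            make_transcript("c", [(12, 20)]),
        ]
        (merged,) = collapse_monoexonic(ts)
        assert merged.exons == ((1, 20),)

    def test_agrees_with_union_find_oracle(self):
        rng = np.random.default_rng(7)
        ts = []
        for i in range(50):
            start = int(rng.integers(1, 500))
            ts.append(
                make_transcript(
                    f"m{i}", [(start, start + int(rng.integers(10, 80)))],
                    strand=str(rng.choice(["+", "-"])),
                )
            )
        result = collapse_monoexonic(ts)
        g = nx.Graph()
        g.add_nodes_from(range(len(ts)))
        for i, j in itertools.combinations(range(len(ts)), 2):
            a, b = ts[i], ts[j]
            if (
                a.chromosome == b.chromosome
                and a.strand == b.strand
                and a.start <= b.end
                and b.start <= a.end
            ):
                g.add_edge(i, j)
        comps = list(nx.connected_components(g))
        assert len(result) == len(comps)
        expected = {
            (
                ts[next(iter(c))].strand,
                min(ts[i].start for i in c),
                max(ts[i].end for i in c),
            )
            for c in comps
        }
        assert {(t.strand, t.start, t.end) for t in result} == expected


class TestIsExtension:
    def test_extra_flank_intron(self):
        cand = make_transcript("c", [(1, 10), (21, 30), (41, 50)])  # introns (11,20),(31,40)
        base = make_transcript("b", [(25, 30), (41, 55)])  # intron (31,40)
        assert is_extension(cand, base)
        assert not is_extension(base, cand)

    def test_identical_chains_are_not_extensions(self):
        a = make_transcript("a", [(1, 10), (21, 30)])
        b = make_transcript("b", [(5, 10), (21, 35)])
        assert not is_extension(a, b) and not is_extension(b, a)

    def test_chain_mismatch(self):
        cand = make_transcript("c", [(1, 30), (46, 60)])  # intron (31,45)
        base = make_transcript("b", [(1, 30), (41, 60)])  # intron (31,40)
        assert not is_extension(cand, base)

    def test_agrees_with_subchain_brute_force(self):
        rng = np.random.default_rng(3)
        ts = random_transcripts(rng, 40, chroms=("chr1",), spliced_only=True)

        def oracle(c, b):
            if c.strand != b.strand or not c.overlaps(b):
                return False
            ci, bi = c.introns(), b.introns()
            if len(ci) <= len(bi):
                return False
            return any(
                ci[k : k + len(bi)] == bi for k in range(len(ci) - len(bi) + 1)
            )

        for a, b in itertools.permutations(ts, 2):
            assert is_extension(a, b) == oracle(a, b)


class TestRemoveContained:
    def test_monoexonic_inside_exon_removed(self):
        u = make_transcript("u", [(300, 400), (500, 600)])
        t = make_transcript("t", [(310, 380)])
        survivors = remove_contained([u, t])
        assert [s.transcript_id for s in survivors] == ["u"]
        assert survivors[0].attributes["contains"] == "t"

    def test_subchain_prefix_removed(self):
        u = make_transcript("u", [(1, 10), (21, 30), (41, 50)])
        t = make_transcript("t", [(5, 10), (21, 28)])  # u minus its last exon
        survivors = remove_contained([u, t])
        assert [s.transcript_id for s in survivors] == ["u"]

    def test_monoexonic_spanning_intron_kept(self):
        u = make_transcript("u", [(100, 200), (300, 400)])
        t = make_transcript("t", [(150, 350)])
        assert len(remove_contained([u, t])) == 2

    def test_incompatible_chain_not_discarded_despite_extent(self):
        u = make_transcript("u", [(1, 30), (41, 100)])  # intron (31,40)
        t = make_transcript("t", [(5, 30), (46, 90)])  # intron (31,45)
        assert len(remove_contained([u, t])) == 2


class TestIntegrateReference:
    def _ref(self):
        return make_annotation(
            make_transcript("R1", [(100, 200), (300, 400)], gene="G1", origin="reference"),
            make_transcript("R2", [(1000, 1100)], gene="G2", origin="reference"),
            provenance="reference",
        )

    def test_untouched_reference_reported_verbatim(self):
        merged, report = integrate_reference([], self._ref())
        assert {t.transcript_id for t in merged} == {"R1", "R2"}
        assert all(report[tid] == "kept" for tid in ("R1", "R2"))

    def test_terminal_extension_replaces_reference_keeping_id(self):
        novel = [make_transcript("n1", [(100, 200), (300, 460)], sources={"s1", "s2"})]
        merged, report = integrate_reference(novel, self._ref())
        ids = {t.transcript_id for t in merged}
        assert ids == {"R1", "R2"}
        replaced = next(t for t in merged if t.transcript_id == "R1")
        assert replaced.exons == ((100, 200), (300, 460))
        assert report["R1"] == "replaced"

    def test_novel_with_extra_intron_kept_as_second_isoform(self):
        novel = [make_transcript("n1", [(20, 40), (60, 200), (300, 400)], sources={"s1"})]
        merged, _ = integrate_reference(novel, self._ref())
        assert {t.transcript_id for t in merged} == {"R1", "R2", "n1"}

    def test_novel_contained_in_reference_discarded(self):
        novel = [make_transcript("n1", [(320, 390)])]  # inside R1's second exon
        merged, report = integrate_reference(novel, self._ref())
        assert {t.transcript_id for t in merged} == {"R1", "R2"}
        assert report["n1"] == "contained_in_reference"

    def test_id_collision_rejected(self):
        with pytest.raises(ValidationError):
            integrate_reference([make_transcript("R1", [(1, 10), (30, 40)])], self._ref())

    def test_reference_conservation_count_identity(self, dataset):
        ref = dataset.reference()
        merged, report = merge_annotations(list(dataset.assemblies().values()), ref)
        for r in ref:
            assert r.transcript_id in merged.transcripts
        actions = {report[r.transcript_id] for r in ref}
        assert actions <= {"kept", "replaced"}


class TestAssignGeneIds:
    def test_same_strand_exonic_overlap_one_gene(self):
        a = make_transcript("a", [(100, 200)])
        b = make_transcript("b", [(150, 250)])
        out = assign_gene_ids([a, b])
        assert out[0].gene_id == out[1].gene_id

    def test_transitive_chaining(self):
        a = make_transcript("a", [(100, 200)])
        b = make_transcript("b", [(180, 320)])
        c = make_transcript("c", [(300, 400)])
        out = assign_gene_ids([a, b, c])
        assert len({t.gene_id for t in out}) == 1

    def test_opposite_strands_two_genes(self):
        a = make_transcript("a", [(100, 200)], strand="+")
        b = make_transcript("b", [(150, 250)], strand="-")
        out = assign_gene_ids([a, b])
        assert out[0].gene_id != out[1].gene_id

    def test_intronic_overlap_does_not_join(self):
        # b lies inside a's intron: extent overlap but no exonic overlap
        a = make_transcript("a", [(100, 200), (500, 600)])
        b = make_transcript("b", [(250, 450)])
        out = assign_gene_ids([a, b])
        assert out[0].gene_id != out[1].gene_id

    def test_reference_gene_id_inherited(self):
        r = make_transcript("r", [(100, 200)], gene="GENE7", origin="reference")
        n = make_transcript("n", [(150, 260)])
        out = assign_gene_ids([r, n])
        assert all(t.gene_id == "GENE7" for t in out)

    def test_agrees_with_networkx_union_find_on_200_random(self):
        rng = np.random.default_rng(19)
        ts = random_transcripts(rng, 200)
        out = assign_gene_ids(ts)
        g = nx.Graph()
        g.add_nodes_from(range(len(ts)))
        for i, j in itertools.combinations(range(len(ts)), 2):
            a, b = ts[i], ts[j]
            if (
                a.chromosome == b.chromosome
                and a.strand == b.strand
                and a.exonic_overlap_bp(b) >= 1
            ):
                g.add_edge(i, j)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got: dict[str, set[int]] = {}
        for i, t in enumerate(out):
            got.setdefault(t.gene_id, set()).add(i)
        assert {frozenset(v) for v in got.values()} == expected


class TestAssignReferenceIds:
    def test_chain_identity_inherits_id_and_biotype(self):
        ref = make_annotation(
            make_transcript(
                "R1", [(100, 200), (300, 400)], origin="reference",
                transcript_biotype="protein_coding",
            ),
            provenance="reference",
        )
        annot = make_annotation(make_transcript("n", [(90, 200), (300, 420)]))
        out = assign_reference_ids(annot, ref)
        t = out.transcripts["n"]
        assert t.attributes["ref_transcript_id"] == "R1"
        assert t.attributes["transcript_biotype"] == "protein_coding"

    def test_duplicate_reference_chains_smallest_id_wins(self):
        ref = make_annotation(
            make_transcript("RB", [(100, 200), (300, 400)], origin="reference"),
            make_transcript("RA", [(110, 200), (300, 390)], origin="reference"),
            provenance="reference",
        )
        annot = make_annotation(make_transcript("n", [(100, 200), (300, 400)]))
        out = assign_reference_ids(annot, ref)
        assert out.transcripts["n"].attributes["ref_transcript_id"] == "RA"

    def test_monoexonic_requires_exact_coordinates(self):
        ref = make_annotation(
            make_transcript("R1", [(100, 200)], origin="reference"),
            provenance="reference",
        )
        near = make_annotation(make_transcript("n", [(101, 200)]))
        exact = make_annotation(make_transcript("n", [(100, 200)]))
        assert "ref_transcript_id" not in assign_reference_ids(near, ref).transcripts["n"].attributes
        assert (
            assign_reference_ids(exact, ref).transcripts["n"].attributes["ref_transcript_id"]
            == "R1"
        )


class TestMergePipeline:
    def test_idempotence(self, dataset):
        """Merging the merged output with the reference again changes nothing."""
        ref = dataset.reference()
        merged, _ = merge_annotations(list(dataset.assemblies().values()), ref)
        again, _ = merge_annotations([merged], ref)
        assert again.structural_key() == merged.structural_key()

    def test_no_duplicate_spliced_chains_among_novel_output(self, dataset):
        merged, _ = merge_annotations(list(dataset.assemblies().values()), dataset.reference())
        chains = [t.intron_chain() for t in merged.spliced() if t.origin == "novel"]
        assert len(chains) == len(set(chains))

    def test_reference_only_input_reproduces_reference(self, dataset):
        ref = dataset.reference()
        merged, _ = merge_annotations([], ref)
        assert merged.structural_key() == ref.structural_key()

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_recovery_across_seeds(self, seed):
        """Exactly K planted novel isoforms survive merge + filters, and every
        reference transcript is conserved, under one-sample/low-TPM noise."""
        ds = SyntheticDataset(FixtureSpec(seed=seed, n_genes=30, n_novel=5, n_noise=6))
        assemblies = ds.assemblies()
        ref = ds.reference()
        merged, _ = merge_annotations(list(assemblies.values()), ref)
        filtered = apply_filters(merged)
        novel = [t for t in filtered if t.origin == "novel"]
        assert len(novel) == len(ds.truth.novel_ids) == 5
        assert all(r.transcript_id in filtered.transcripts for r in ref)
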