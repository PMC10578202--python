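"""Positional classes, novelty, biotypes, lncRNA position, catalog overlap.

The five-class labelling is checked against a brute-force oracle that
evaluates all predicates independently and applies the priority order.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from annotweave.classify import (
    PositionalClass,
    catalog_match,
    classify_lnc_position,
    feelnc_eligible,
    gene_coding_status,
    gene_novelty,
    positional_class,
    transcript_novelty,
    unified_transcript_biotype,
)
from annotweave.merge import is_extension
from annotweave.model import ValidationError

from conftest import make_annotation, make_transcript
from test_merge import random_transcripts


REF = make_annotation(
    # spliced reference: introns (211,299) and (411,499)
    make_transcript("R1", [(100, 210), (300, 410), (500, 600)], gene="G1", origin="reference"),
    # a second, merely overlapping reference model on the same strand
    make_transcript("R2", [(80, 150), (700, 800)], gene="G2", origin="reference"),
    # monoexonic reference
    make_transcript("R3", [(2000, 2300)], gene="G3", origin="reference"),
    provenance="reference",
)


class TestPositionalClass:
    def test_exact(self):
        t = make_transcript("t", [(150, 210), (300, 410), (500, 550)])
        assert positional_class(t, REF) == PositionalClass.EXACT

    def test_extension_wins_over_overlapping(self):
        # adds a 5' intron to R1's chain while another reference transcript
        # (R2) merely overlaps: Extension takes priority
        t = make_transcript("t", [(40, 60), (90, 210), (300, 410), (500, 550)])
        assert positional_class(t, REF) == PositionalClass.EXTENSION

    def test_inclusion(self):
        t = make_transcript("t", [(320, 410), (500, 560)])  # sub-chain of R1
        assert positional_class(t, REF) == PositionalClass.INCLUSION

    def test_overlapping(self):
        t = make_transcript("t", [(550, 620), (660, 680)])
        assert positional_class(t, REF) == PositionalClass.OVERLAPPING

    def test_intergenic_or_antisense(self):
        away = make_transcript("t", [(5000, 5100), (5200, 5300)])
        anti = make_transcript("t", [(150, 210), (300, 410)], strand="-")
        assert positional_class(away, REF) == PositionalClass.INTERGENIC_OR_ANTISENSE
        assert positional_class(anti, REF) == PositionalClass.INTERGENIC_OR_ANTISENSE

    def test_monoexonic_rejected(self):
        with pytest.raises(ValidationError):
            positional_class(make_transcript("t", [(1, 300)]), REF)

    def test_agrees_with_all_predicates_brute_force(self):
        """Priority-first class equals an oracle evaluating every predicate
        independently, over random transcript pairs covering all classes."""
        rng = np.random.default_rng(23)
        pool = random_transcripts(rng, 60, chroms=("chr1",), spliced_only=True)
        reference = make_annotation(
            *[t.copy(transcript_id=f"R{i}", origin="reference")
              for i, t in enumerate(pool[:30])],
            provenance="reference",
        )
        ref_spliced = list(reference.spliced())

        def oracle(t):
            exact = any(
                r.intron_chain() == t.intron_chain() for r in ref_spliced
            )
            extension = any(is_extension(t, r) for r in ref_spliced)
            inclusion = any(is_extension(r, t) for r in ref_spliced)
            overlap = any(
                r.strand == t.strand and t.overlaps(r) for r in reference
            )
            for flag, cls in [
                (exact, PositionalClass.EXACT),
                (extension, PositionalClass.EXTENSION),
                (inclusion, PositionalClass.INCLUSION),
                (overlap, PositionalClass.OVERLAPPING),
            ]:
                if flag:
                    return cls
            return PositionalClass.INTERGENIC_OR_ANTISENSE

        seen = set()
        for t in pool[30:]:
            got = positional_class(t, reference)
            assert got == oracle(t)
            seen.add(got)
        # exact/extension/inclusion conflicts need constructed cases too
        constructed = [
            make_transcript("c1", [(150, 210), (300, 410), (500, 550)]),
            make_transcript("c2", [(40, 60), (90, 210), (300, 410), (500, 550)]),
            make_transcript("c3", [(320, 410), (500, 560)]),
        ]
        for t in constructed:
            assert positional_class(t, REF) == oracle_against_REF(t)


def oracle_against_REF(t):
    ref_spliced = list(REF.spliced())
    if any(r.intron_chain() == t.intron_chain() for r in ref_spliced):
        return PositionalClass.EXACT
    if any(is_extension(t, r) for r in ref_spliced):
        return PositionalClass.EXTENSION
    if any(is_extension(r, t) for r in ref_spliced):
        return PositionalClass.INCLUSION
    if any(r.strand == t.strand and t.overlaps(r) for r in REF):
        return PositionalClass.OVERLAPPING
    return PositionalClass.INTERGENIC_OR_ANTISENSE


class TestNovelty:
    def test_exact_class_implies_known(self):
        t = make_transcript("t", [(150, 210), (300, 410), (500, 550)])
        assert positional_class(t, REF) == PositionalClass.EXACT
        assert transcript_novelty(t, REF) == "known"

    def test_extension_class_is_unknown(self):
        t = make_transcript("t", [(40, 60), (90, 210), (300, 410), (500, 550)])
        assert transcript_novelty(t, REF) == "unknown"

    def test_monoexonic_one_bp_shift_is_unknown(self):
        """Coordinate-identity oracle checked over all +/-1 bp shifts."""
        for ds, de in itertools.product((-1, 0, 1), repeat=2):
            t = make_transcript("t", [(2000 + ds, 2300 + de)])
            expected = "known" if (ds, de) == (0, 0) else "unknown"
            assert transcript_novelty(t, REF) == expected

    def test_intergenic_implies_unknown(self):
        t = make_transcript("t", [(9000, 9100), (9200, 9300)])
        assert transcript_novelty(t, REF) == "unknown"

    @pytest.mark.parametrize(
        "members,expected",
        [
            (["known", "known"], "known"),
            (["known", "unknown"], "enriched"),
            (["unknown", "unknown", "unknown"], "unknown"),
        ],
    )
    def test_gene_novelty_rules(self, members, expected):
        assert gene_novelty(members) == expected
        # permutation invariance
        for perm in itertools.permutations(members):
            assert gene_novelty(list(perm)) == expected

    def test_empty_gene_rejected(self):
        with pytest.raises(ValidationError):
            gene_novelty([])


class TestFeelncEligibility:
    MRNAS = [make_transcript("m", [(100, 210), (300, 400)], origin="reference")]

    def test_short_transcript_rejected(self):
        t = make_transcript("t", [(5000, 5074), (5100, 5174)])  # 150 bp
        assert not feelnc_eligible(t, self.MRNAS)

    def test_two_exons_both_must_exceed_25bp(self):
        bad = make_transcript("t", [(5000, 5029), (5100, 5119)])  # 30 and 20 bp
        good = make_transcript("t", [(5000, 5129), (5200, 5329)])  # 130 + 130
        assert not feelnc_eligible(bad, self.MRNAS)
        assert feelnc_eligible(good, self.MRNAS)

    def test_three_exons_no_mrna_overlap_eligible(self):
        t = make_transcript("t", [(5000, 5099), (5200, 5299), (5400, 5500)])
        assert feelnc_eligible(t, self.MRNAS)

    def test_same_strand_mrna_exonic_overlap_disqualifies(self):
        t = make_transcript("t", [(150, 250), (300, 410), (500, 600)])
        assert not feelnc_eligible(t, self.MRNAS)
        opposite = t.copy(strand="-")
        assert feelnc_eligible(opposite, self.MRNAS)


class TestUnifiedBiotype:
    @pytest.mark.parametrize(
        "ref,feelnc,expected",
        [
            ("protein_coding", "lncRNA", "mRNA"),
            ("", "lncRNA", "lncRNA"),
            ("lncRNA", "", "lncRNA"),
            ("", "TUCp", "TUCp"),
            ("", "noORF", "noORF"),
            ("", "", "uncharacterized"),
            ("lncRNA", "mRNA", "mRNA"),
        ],
    )
    def test_priority_rules(self, ref, feelnc, expected):
        attrs = {}
        if ref:
            attrs["transcript_biotype"] = ref
        if feelnc:
            attrs["feelnc_biotype"] = feelnc
        t = make_transcript("t", [(1, 300)], **attrs)
        assert unified_transcript_biotype(t) == expected

    def test_reference_protein_coding_never_becomes_lncRNA(self):
        for feelnc in ("lncRNA", "TUCp", "noORF", ""):
            attrs = {"transcript_biotype": "protein_coding"}
            if feelnc:
                attrs["feelnc_biotype"] = feelnc
            t = make_transcript("t", [(1, 300)], **attrs)
            assert unified_transcript_biotype(t) == "mRNA"

    @pytest.mark.parametrize(
        "members,expected",
        [
            (["mRNA", "lncRNA"], "mRNA"),
            (["lncRNA", "TUCp"], "lncRNA"),
            (["noORF"], "uncharacterized"),
            (["TUCp", "uncharacterized"], "uncharacterized"),
        ],
    )
    def test_gene_coding_status(self, members, expected):
        assert gene_coding_status(members) == expected


class TestLncPosition:
    MRNA_PLUS = make_transcript("m+", [(10_000, 10_200), (12_000, 12_300)], strand="+")

    def test_genic_intronic_antisense(self):
        lnc = make_transcript("l", [(10_500, 10_700)], strand="-")
        cls = classify_lnc_position(lnc, [self.MRNA_PLUS])
        assert cls.label == "genic_intronic_antisense"

    def test_genic_exonic_sense(self):
        lnc = make_transcript("l", [(10_100, 10_400)], strand="+")
        assert classify_lnc_position(lnc, [self.MRNA_PLUS]).label == "genic_exonic_sense"

    def test_upstream_antisense_is_divergent(self):
        lnc = make_transcript("l", [(5_000, 5_400)], strand="-")
        cls = classify_lnc_position(lnc, [self.MRNA_PLUS])
        assert cls.direction == "upstream" and cls.derived == "divergent"

    def test_downstream_antisense_is_convergent(self):
        lnc = make_transcript("l", [(13_000, 13_400)], strand="-")
        cls = classify_lnc_position(lnc, [self.MRNA_PLUS])
        assert cls.direction == "downstream" and cls.derived == "convergent"

    def test_direction_follows_mrna_orientation(self):
        # same genomic side, minus-strand mRNA: now downstream
        mrna = self.MRNA_PLUS.copy(strand="-")
        lnc = make_transcript("l", [(5_000, 5_400)], strand="-")
        cls = classify_lnc_position(lnc, [mrna])
        assert cls.direction == "downstream" and cls.orientation == "sense"

    def test_out_of_window_unclassified(self):
        lnc = make_transcript("l", [(500_000, 500_400)], strand="-")
        assert classify_lnc_position(lnc, [self.MRNA_PLUS]).label == "unclassified"


class TestCatalogMatch:
    CATALOG = make_annotation(
        make_transcript("c1", [(100, 200), (300, 400), (500, 600)]),
        make_transcript("c2", [(5_000, 5_400)]),
        provenance="merged",
    )

    def test_one_shared_intron_suffices(self):
        # shares intron (401,499) only
        t = make_transcript("t", [(350, 400), (500, 550), (700, 800)])
        assert catalog_match(t, self.CATALOG)

    def test_monoexonic_stranded_overlap(self):
        t = make_transcript("t", [(5_300, 5_500)])
        assert catalog_match(t, self.CATALOG)
        assert not catalog_match(t.copy(strand="-"), self.CATALOG)

    def test_overlap_without_shared_intron_is_no_match(self):
        t = make_transcript("t", [(100, 250), (340, 400)])  # intron (251,339)
        assert not catalog_match(t, self.CATALOG)
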