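import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapklnc.annotation import AnnotationSet, TranscriptModel
from mapklnc.discovery import (
    coding_potential,
    discover,
    exclude_known,
    fickett_score,
    filter_structure,
    longest_orf,
    merge_isoforms,
)


def t(tid, exons, strand="+", gene=None, chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or tid, chrom=chrom, strand=strand,
        exons=tuple(exons),
    )


class TestExcludeKnown:
    reference = AnnotationSet([t("ref", [(1000, 2000)], gene="gene1")])

    def test_contained_transcript_excluded(self):
        asm = AnnotationSet([t("x", [(1200, 1400)])])
        assert len(exclude_known(asm, self.reference)) == 0

    def test_one_bp_overlap_excluded(self):
        asm = AnnotationSet([t("x", [(2000, 2500)])])
        assert len(exclude_known(asm, self.reference)) == 0

    def test_adjacent_transcript_kept(self):
        asm = AnnotationSet([t("x", [(2001, 2500)])])
        assert len(exclude_known(asm, self.reference)) == 1

    def test_stranded_mode_keeps_antisense(self):
        antisense = AnnotationSet([t("x", [(1200, 1400)], strand="-")])
        # default strand-agnostic mode excludes regardless of strand
        assert len(exclude_known(antisense, self.reference)) == 0
        # stranded mode keeps the antisense overlap (reference is +)
        assert len(exclude_known(antisense, self.reference, stranded=True)) == 1
        # but same-strand overlap is still excluded
        sense = AnnotationSet([t("x", [(1200, 1400)], strand="+")])
        assert len(exclude_known(sense, self.reference, stranded=True)) == 0
        # unknown strand matches either
        unknown = AnnotationSet([t("x", [(1200, 1400)], strand=".")])
        assert len(exclude_known(unknown, self.reference, stranded=True)) == 0

    def test_exon_mode_ignores_intronic_overlap(self):
        ref = AnnotationSet([t("ref", [(1000, 1100), (1900, 2000)], gene="g")])
        asm = AnnotationSet([t("x", [(1300, 1500)])])  # inside the ref intron
        assert len(exclude_known(asm, ref, overlap="exon")) == 1
        assert len(exclude_known(asm, ref, overlap="span")) == 0

    def test_idempotent(self, annotation_bundle):
        once = exclude_known(annotation_bundle.assembled, annotation_bundle.reference)
        twice = exclude_known(once, annotation_bundle.reference)
        assert set(once.transcript_ids) == set(twice.transcript_ids)

    def test_matches_brute_force_interval_oracle(self, annotation_bundle):
        asm, ref = annotation_bundle.assembled, annotation_bundle.reference
        gene_hulls = [
            (chrom, s, e)
            for intervals in ref.gene_index().values()
            for chrom, s, e in intervals
        ]

        def overlaps_any(tr):
            s, e = tr.span
            return any(
                tr.chrom == chrom and s <= he and hs <= e
                for chrom, hs, he in gene_hulls
            )

        expected = {tr.transcript_id for tr in asm if not overlaps_any(tr)}
        assert set(exclude_known(asm, ref).transcript_ids) == expected


class TestFilterStructure:
    @pytest.mark.parametrize(
        "exons,kept",
        [
            ([(1, 5000)], False),                       # mono-exonic, long
            ([(1, 100), (151, 250)], False),            # exactly 200 nt
            ([(1, 100), (151, 251)], True),             # 201 nt, intron 50
            ([(1, 150), (161, 311)], False),            # intron exactly 10
            ([(1, 150), (162, 312)], True),             # intron 11
        ],
        ids=["mono-exonic", "len-200-boundary", "len-201", "intron-10-boundary",
             "intron-11"],
    )
    def test_strict_boundaries(self, exons, kept):
        result = filter_structure(AnnotationSet([t("x", exons)]))
        assert (len(result) == 1) == kept

    def test_monotone_in_min_len(self, annotation_bundle):
        asm = annotation_bundle.assembled
        previous = None
        for min_len in (100, 200, 400, 1000):
            ids = set(filter_structure(asm, min_len=min_len).transcript_ids)
            if previous is not None:
                assert ids <= previous
            previous = ids


class TestMergeIsoforms:
    def test_identical_transcripts_one_locus(self):
        exons = [(1, 100), (201, 400)]
        merged, mapping = merge_isoforms(
            AnnotationSet([t("a", exons), t("b", exons)])
        )
        assert len(merged) == 1
        locus = next(iter(merged))
        assert locus.exons == ((1, 100), (201, 400))
        assert mapping["a"] == mapping["b"]

    def test_shared_exon_links_disjoint_third_separate(self):
        merged, mapping = merge_isoforms(
            AnnotationSet(
                [
                    t("a", [(1, 100), (201, 300)]),
                    t("b", [(250, 300), (401, 500)]),
                    t("c", [(10_000, 10_100), (10_201, 10_300)]),
                ]
            )
        )
        assert len(merged) == 2
        assert mapping["a"] == mapping["b"] != mapping["c"]

    def test_span_overlap_without_exon_overlap_not_linked(self):
        # b sits entirely inside a's intron
        merged, _ = merge_isoforms(
            AnnotationSet(
                [
                    t("a", [(1, 100), (901, 1000)]),
                    t("b", [(200, 300), (401, 500)]),
                ]
            )
        )
        assert len(merged) == 2

    def test_opposite_strands_not_linked(self):
        merged, _ = merge_isoforms(
            AnnotationSet(
                [
                    t("a", [(1, 100), (201, 300)], strand="+"),
                    t("b", [(50, 150), (201, 300)], strand="-"),
                ]
            )
        )
        assert len(merged) == 2

    def test_partition_matches_connected_components_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            transcripts = []
            for i in range(20):
                start = int(rng.integers(1, 5000))
                e1 = start + int(rng.integers(50, 300))
                s2 = e1 + int(rng.integers(20, 200))
                e2 = s2 + int(rng.integers(50, 300))
                transcripts.append(
                    t(f"t{i}", [(start, e1), (s2, e2)],
                      strand="+" if rng.random() < 0.5 else "-")
                )
            annot = AnnotationSet(transcripts)
            _, mapping = merge_isoforms(annot)

            # brute-force connected components of the exon-overlap graph
            def linked(a, b):
                if a.strand != b.strand and "." not in (a.strand, b.strand):
                    return False
                return any(
                    s1 <= e2 and s2 <= e1
                    for s1, e1 in a.exons
                    for s2, e2 in b.exons
                )

            parent = {tr.transcript_id: tr.transcript_id for tr in transcripts}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for a in transcripts:
                for b in transcripts:
                    if a.transcript_id < b.transcript_id and linked(a, b):
                        parent[find(a.transcript_id)] = find(b.transcript_id)
            oracle_groups = {}
            for tr in transcripts:
                oracle_groups.setdefault(find(tr.transcript_id), set()).add(
                    tr.transcript_id
                )
            impl_groups = {}
            for tid, locus in mapping.items():
                impl_groups.setdefault(locus, set()).add(tid)
            assert sorted(oracle_groups.values(), key=sorted) == sorted(
                impl_groups.values(), key=sorted
            )

    def test_idempotent_on_merged_output(self):
        annot = AnnotationSet(
            [t("a", [(1, 100), (201, 300)]), t("b", [(50, 150), (251, 400)])]
        )
        merged, _ = merge_isoforms(annot)
        again, _ = merge_isoforms(merged)
        assert {m.exons for m in merged} == {m.exons for m in again}


def brute_force_orf(seq):
    """Independent six-frame scanner: longest complete ATG->stop ORF."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    best = 0
    for s in (seq, rc):
        for offset in range(3):
            codons = [s[i:i + 3] for i in range(offset, len(s) - 2, 3)]
            for i, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                for j in range(i, len(codons)):
                    if "N" in codons[j]:
                        break
                    if codons[j] in ("TAA", "TAG", "TGA"):
                        best = max(best, 3 * (j - i + 1))
                        break
    return best


class TestCodingPotential:
    def test_no_atg_anywhere_is_ncrna(self):
        seq = "CCGGCCGG" * 50
        report = coding_potential("x", seq)
        assert report.orf_length == 0
        assert report.class_label == "ncRNA"

    def test_full_length_orf_with_motif_is_coding(self):
        # 900 nt: ATG + 298 GCA codons + TAA = one ORF spanning the sequence
        seq = "ATG" + "GCA" * 298 + "TAA"
        assert len(seq) == 900
        report = coding_potential("x", seq, motifs=["AAA"])  # poly-Ala motif
        assert report.orf_length == 900
        assert report.orf_coverage == pytest.approx(1.0)
        assert report.motif_hit
        assert report.class_label == "coding"

    def test_orf_without_motif_is_tucp(self):
        seq = "ATG" + "GCA" * 298 + "TAA"
        report = coding_potential("x", seq, motifs=["WWWW"])
        assert report.class_label == "TUCP"

    def test_motif_without_orf_is_tucp(self):
        seq = "CCGGCCGG" * 50  # no ATG; translated frames contain PAGR repeats
        report = coding_potential("x", seq, motifs=["PAGR"])
        assert report.motif_hit
        assert report.class_label == "TUCP"

    def test_n_breaks_orf(self):
        clean = "ATG" + "GCA" * 120 + "TAA"
        broken = "ATG" + "GCA" * 60 + "NNN" + "GCA" * 59 + "TAA"
        assert longest_orf(clean) == len(clean)
        assert longest_orf(broken) < longest_orf(clean)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            coding_potential("x", "")

    def test_orf_scan_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=1000)])
            assert longest_orf(seq) == brute_force_orf(seq)

    @given(st.text(alphabet="ACGTN", min_size=30, max_size=300))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_report_invariants_for_arbitrary_sequences(self, seq):
        report = coding_potential("x", seq)
        assert 0 <= report.orf_length <= len(seq)
        assert report.orf_coverage == pytest.approx(report.orf_length / len(seq))
        assert 0.0 < report.fickett_score < 1.4
        assert report.class_label in {"coding", "ncRNA", "TUCP"}

    def test_fickett_score_discriminates_composition(self):
        # strongly periodic codon-like sequence vs a homopolymer-ish one
        coding_like = "ATGGCC" * 100
        assert fickett_score(coding_like) > fickett_score("ATATATAT" * 75)

    def test_every_transcript_gets_exactly_one_class(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        labels = set()
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, size=600)])
            labels.add(coding_potential("x", seq, motifs=["MKL"]).class_label)
        assert labels <= {"coding", "ncRNA", "TUCP"}


class TestCascade:
    def test_recovers_exactly_planted_lncrnas(self, annotation_bundle):
        rows, lnc_ids = discover(
            annotation_bundle.assembled,
            annotation_bundle.reference,
            annotation_bundle.sequences,
        )
        assert sorted(lnc_ids) == sorted(
            annotation_bundle.truth.planted_novel_lncrna_ids
        )
        assert all(r["class_label"] == "ncRNA" for r in rows)
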