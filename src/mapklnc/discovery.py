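"""Candidate lncRNA discovery from assembled vs. reference annotations.

The cascade takes transcripts assembled from RNA-seq, removes everything
overlapping known genes, discards structurally implausible models
(mono-exonic, short, or without a real intron), merges isoforms into loci,
and classifies the survivors by coding potential into protein-coding,
non-coding RNA (ncRNA) or transcript of unknown coding potential (TUCP).

Coding potential uses two transparent evidence channels:

* an open-reading-frame channel: longest complete ATG→stop ORF over all six
  frames, combined with the Fickett TESTCODE statistic;
* a protein-motif channel: exact amino-acid motif matches in the six
  translated frames (a lightweight stand-in for a profile-domain search).

A transcript is *coding* when both channels fire, *ncRNA* when neither
does, and *TUCP* when they disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .annotation import AnnotationSet, TranscriptModel

__all__ = [
    "CodingPotentialReport",
    "exclude_known",
    "filter_structure",
    "merge_isoforms",
    "longest_orf",
    "fickett_score",
    "coding_potential",
    "discover",
]

# ---------------------------------------------------------------------------
# Novelty exclusion


def _reference_trees(
    reference: AnnotationSet, overlap: str
) -> Dict[str, IntervalTree]:
    """Interval trees per chromosome; data payload is the feature strand."""
    trees: Dict[str, IntervalTree] = {}
    if overlap == "span":
        gene_strands: Dict[str, set] = {}
        for t in reference:
            gene_strands.setdefault(t.gene_id, set()).add(t.strand)
        for gene, intervals in reference.gene_index().items():
            strands = gene_strands[gene]
            strand = next(iter(strands)) if len(strands) == 1 else "."
            for chrom, start, end in intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, strand)
    elif overlap == "exon":
        for t in reference:
            tree = trees.setdefault(t.chrom, IntervalTree())
            for start, end in t.exons:
                tree.addi(start, end + 1, t.strand)
    else:
        raise ValueError(f"overlap must be 'span' or 'exon', got {overlap!r}")
    return trees


def _strands_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def exclude_known(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    overlap: str = "span",
    stranded: bool = False,
) -> AnnotationSet:
    """Drop assembled transcripts overlapping any reference gene by >= 1 bp.

    ``overlap="span"`` (default) tests the transcript span against reference
    gene hulls — the most-excluding reading; ``overlap="exon"`` tests against
    reference exons only. ``stranded=True`` only counts overlaps on the same
    strand (unknown strand matches either).
    """
    trees = _reference_trees(reference, overlap)
    survivors = []
    for t in assembled:
        start, end = t.span
        hits = trees[t.chrom].overlap(start, end + 1) if t.chrom in trees else set()
        if stranded:
            hits = {h for h in hits if _strands_compatible(t.strand, h.data)}
        if not hits:
            survivors.append(t)
    return AnnotationSet(survivors)


# ---------------------------------------------------------------------------
# Structural filter


def filter_structure(
    candidates: AnnotationSet, min_len: int = 200, min_intron: int = 10
) -> AnnotationSet:
    """Keep multi-exonic transcripts > ``min_len`` nt with >= 1 intron > ``min_intron``.

    All three inequalities are strict: a 200-nt two-exon transcript fails,
    as does one whose longest intron is exactly 10 bp.
    """
    kept = [
        t
        for t in candidates
        if t.n_exons >= 2
        and t.length > min_len
        and any(l > min_intron for l in t.intron_lengths)
    ]
    return AnnotationSet(kept)


# ---------------------------------------------------------------------------
# Isoform merging


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.chrom != b.chrom or not _strands_compatible(a.strand, b.strand):
        return False
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _coalesce(intervals: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Union of 1-based inclusive intervals, adjacent-or-overlapping merged."""
    merged: List[List[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def merge_isoforms(
    candidates: AnnotationSet,
) -> Tuple[AnnotationSet, Dict[str, str]]:
    """Group transcripts into loci by single-linkage on same-strand exonic overlap.

    Returns the merged locus models (exon set = coalesced union of member
    exons) and the member→locus mapping. Locus ids are assigned in genomic
    order (chrom, hull start).
    """
    members = sorted(candidates, key=lambda t: (t.chrom, t.span, t.transcript_id))
    uf = _UnionFind(len(members))
    # single-linkage: brute-force pairwise test after sorting by start lets us
    # stop the inner loop once spans no longer overlap
    for i, a in enumerate(members):
        for j in range(i + 1, len(members)):
            b = members[j]
            if b.chrom != a.chrom or b.span[0] > a.span[1]:
                break
            if _exonic_overlap(a, b):
                uf.union(i, j)
    groups: Dict[int, List[TranscriptModel]] = {}
    for i, t in enumerate(members):
        groups.setdefault(uf.find(i), []).append(t)
    ordered = sorted(
        groups.values(), key=lambda g: (g[0].chrom, min(t.span[0] for t in g))
    )
    merged_models = []
    mapping: Dict[str, str] = {}
    for k, group in enumerate(ordered, start=1):
        locus_id = f"LOC{k:05d}"
        strands = {t.strand for t in group} - {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        exons = _coalesce(e for t in group for e in t.exons)
        merged_models.append(
            TranscriptModel(
                transcript_id=locus_id,
                gene_id=locus_id,
                chrom=group[0].chrom,
                strand=strand,
                exons=exons,
            )
        )
        for t in group:
            mapping[t.transcript_id] = locus_id
    return AnnotationSet(merged_models), mapping


# ---------------------------------------------------------------------------
# Coding potential

_STOPS = {"TAA", "TAG", "TGA"}

# Fickett (1982) TESTCODE lookup tables: probability that a window with the
# given position asymmetry / base content is coding, plus channel weights.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


@dataclass(frozen=True)
class CodingPotentialReport:
    transcript_id: str
    orf_length: int
    orf_coverage: float
    fickett_score: float
    motif_hit: bool
    class_label: str  # coding | ncRNA | TUCP


def _lookup(value: float, para: List[float], prob: List[float]) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Combines, for each base, a position-asymmetry value (max over the three
    codon positions of the base count, divided by min + 1) and a content
    value (base fraction), each mapped through the published coding
    probabilities and weighted. Scores >= 0.95 indicate coding-like
    composition. Bases other than ACGT are ignored.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    score = 0.0
    for base in "ACGT":
        counts = [
            sum(1 for i in range(phase, len(seq), 3) if seq[i] == base)
            for phase in range(3)
        ]
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / len(seq)
        score += _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def _frames(seq: str) -> List[str]:
    rc = str(Seq(seq).reverse_complement())
    return [seq[i:] for i in range(3)] + [rc[i:] for i in range(3)]


def longest_orf(seq: str) -> int:
    """Length (nt, stop codon included) of the longest complete ATG→stop ORF
    over all six frames. Codons containing N are walls: they can neither
    start nor extend an ORF. Incomplete ORFs (no in-frame stop) count zero.
    """
    seq = seq.upper()
    best = 0
    for frame in _frames(seq):
        start: Optional[int] = None
        for i in range(0, len(frame) - 2, 3):
            codon = frame[i : i + 3]
            if "N" in codon:
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def _translate_frames(seq: str) -> List[str]:
    proteins = []
    for frame in _frames(seq):
        frame = frame[: len(frame) - len(frame) % 3]
        proteins.append(str(Seq(frame).translate()))
    return proteins


def coding_potential(
    transcript_id: str,
    seq: str,
    motifs: Sequence[str] = (),
    min_orf: int = 300,
    min_coverage: float = 0.5,
    min_fickett: float = 0.95,
) -> CodingPotentialReport:
    """Classify one transcript sequence as coding, ncRNA or TUCP.

    The ORF rule fires when the longest complete ORF is >= ``min_orf`` nt,
    or covers >= ``min_coverage`` of the transcript with a Fickett score
    >= ``min_fickett``. The motif rule fires when any supplied amino-acid
    motif occurs in any translated frame.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{transcript_id}: empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"{transcript_id}: sequence not over ACGTN")
    orf_len = longest_orf(seq)
    coverage = orf_len / len(seq)
    fickett = fickett_score(seq)
    orf_rule = orf_len >= min_orf or (coverage >= min_coverage and fickett >= min_fickett)
    motif_hit = False
    if motifs:
        proteins = _translate_frames(seq)
        motif_hit = any(m in p for m in motifs for p in proteins)
    if orf_rule and motif_hit:
        label = "coding"
    elif orf_rule or motif_hit:
        label = "TUCP"
    else:
        label = "ncRNA"
    return CodingPotentialReport(
        transcript_id=transcript_id,
        orf_length=orf_len,
        orf_coverage=coverage,
        fickett_score=fickett,
        motif_hit=motif_hit,
        class_label=label,
    )


# ---------------------------------------------------------------------------
# Full cascade


def discover(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    sequences: Mapping[str, str],
    motifs: Sequence[str] = (),
    min_len: int = 200,
    min_intron: int = 10,
    overlap: str = "span",
    stranded: bool = False,
):
    """Run the full discovery cascade; returns (candidate rows, ncRNA ids).

    Candidate rows are dicts (one per surviving member transcript) with the
    locus assignment, structural statistics and coding-potential report.
    The returned id list contains the transcripts classified as ncRNA —
    the novel lncRNA candidates.
    """
    novel = exclude_known(assembled, reference, overlap=overlap, stranded=stranded)
    structural = filter_structure(novel, min_len=min_len, min_intron=min_intron)
    _, locus_of = merge_isoforms(structural)
    rows = []
    lncrna_ids = []
    for t in sorted(structural, key=lambda t: (t.chrom, t.span, t.transcript_id)):
        report = coding_potential(t.transcript_id, sequences[t.transcript_id], motifs)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "locus_id": locus_of[t.transcript_id],
                "length": t.length,
                "n_exons": t.n_exons,
                "max_intron": max(t.intron_lengths),
                "class_label": report.class_label,
                "orf_length": report.orf_length,
                "orf_coverage": round(report.orf_coverage, 6),
                "fickett_score": round(report.fickett_score, 6),
                "motif_hit": report.motif_hit,
            }
        )
        if report.class_label == "ncRNA":
            lncrna_ids.append(t.transcript_id)
    return rows, lncrna_ids
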