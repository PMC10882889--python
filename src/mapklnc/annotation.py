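"""Transcript models and annotation sets on a genome.

Coordinates follow the GTF convention (1-based, inclusive) at every public
surface; interval arithmetic converts to 0-based half-open internally and
converts back before anything is returned or written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "AnnotationSet",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on a genome.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; transcript ids are unique within an :class:`AnnotationSet`.
    chrom : str
        Chromosome name.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unknown).
    exons : tuple of (start, end)
        1-based inclusive genomic coordinates, sorted by start, non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in exons:
            if end < start:
                raise ValueError(
                    f"{self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span (first exon start, last exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Summed exon length in nt."""
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based inclusive; may be empty."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def intron_lengths(self) -> Tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.introns)


class AnnotationSet:
    """A collection of transcripts with a gene-level interval index.

    The gene index maps each gene id to the union hull of its transcripts'
    spans per chromosome, which is what span-level overlap queries use.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: Dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self._transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._transcripts)

    def gene_index(self) -> Dict[str, List[Tuple[str, int, int]]]:
        """Per gene: list of (chrom, hull_start, hull_end), 1-based inclusive."""
        index: Dict[str, Dict[str, Tuple[int, int]]] = {}
        for t in self:
            s, e = t.span
            per_chrom = index.setdefault(t.gene_id, {})
            if t.chrom in per_chrom:
                cs, ce = per_chrom[t.chrom]
                per_chrom[t.chrom] = (min(cs, s), max(ce, e))
            else:
                per_chrom[t.chrom] = (s, e)
        return {
            g: [(c, s, e) for c, (s, e) in chroms.items()]
            for g, chroms in index.items()
        }


def _format_attributes(gene_id: str, transcript_id: str) -> str:
    return f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'


def write_gtf(annot: AnnotationSet, path) -> None:
    """Write exon features in GTF (tab-separated, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(annot, key=lambda t: (t.chrom, t.span, t.transcript_id)):
            for start, end in t.exons:
                fields = [
                    t.chrom,
                    "mapklnc",
                    "exon",
                    str(start),
                    str(end),
                    ".",
                    t.strand,
                    ".",
                    _format_attributes(t.gene_id, t.transcript_id),
                ]
                fh.write("\t".join(fields) + "\n")


def _parse_attributes(raw: str) -> Dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`."""
    exons: Dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, raw_attrs = fields[:9]
            attrs = _parse_attributes(raw_attrs)
            tid = attrs["transcript_id"]
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                },
            )
            rec["exons"].append((int(start), int(end)))
    return AnnotationSet(
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        for tid, rec in exons.items()
    )


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
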