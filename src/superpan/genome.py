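"""Gene models and annotated genomes.

Coordinates are 0-based, half-open everywhere inside the package; the GFF3
reader/writer in :mod:`superpan.io` converts to/from the 1-based closed
convention of the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model on one chromosome.

    ``exons`` are 0-based half-open intervals sorted by start regardless of
    strand; for the minus strand the first coding exon is the last interval.
    All exons are coding here (no UTRs are modelled), so the CDS is the
    concatenation of exon sequences, reverse-complemented on '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    def cds_sequence(self, genome_seq: str) -> str:
        parts = [genome_seq[s:e] for s, e in self.exons]
        cds = "".join(parts)
        return cds if self.strand == "+" else revcomp(cds)

    def shifted(self, offset: int) -> "GeneModel":
        return replace(
            self,
            start=self.start + offset,
            end=self.end + offset,
            exons=tuple((s + offset, e + offset) for s, e in self.exons),
        )


@dataclass
class AnnotatedGenome:
    """One accession: a single-chromosome sequence plus its gene models."""

    name: str
    seq: str
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))

    def intergenic_intervals(self) -> list[tuple[int, int]]:
        """Maximal intervals not covered by any gene body, in order."""
        out: list[tuple[int, int]] = []
        pos = 0
        for g in self.sorted_genes():
            if g.start > pos:
                out.append((pos, g.start))
            pos = max(pos, g.end)
        if pos < self.length:
            out.append((pos, self.length))
        return out
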