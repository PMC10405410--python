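"""Gene annotation: the universe RNA-side contacts are assigned to.

Genes carry one of six annotated RNA classes (rRNA, metazoan srpRNA, snRNA,
snoRNA, lncRNA, mRNA).  A seventh class, unkRNA, is not an annotation input:
it is the *output* of sliding-window detection of transcribed regions that
overlap no annotated gene (see :mod:`charlink.contact_statistics`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from intervaltree import IntervalTree

from .genome import GenomeModel
from .linker import reverse_complement

RNA_CLASSES = ("rRNA", "msrpRNA", "snRNA", "snoRNA", "lncRNA", "mRNA")

#: gene_id used for contacts whose RNA side maps outside any annotated gene
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GeneRecord:
    """One gene: 1-based inclusive span on a named chromosome."""

    gene_id: str
    rna_class: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: invalid span {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown RNA class {self.rna_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the transcript."""
        return self.start if self.strand == "+" else self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class Annotation:
    """Indexed collection of :class:`GeneRecord`."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        self.by_id: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
        self.by_class: dict[str, list[GeneRecord]] = {c: [] for c in RNA_CLASSES}
        for g in self.genes:
            self.by_class[g.rna_class].append(g)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            # interval tree uses half-open 0-based [start-1, end)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start - 1, g.end, g
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[GeneRecord]:
        """Genes overlapping the 0-based half-open interval [start0, end0)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start0, end0)]

    def transcript_seq(self, gene_id: str, genome: GenomeModel) -> str:
        """Unspliced transcript sequence (reverse-complemented for '-' genes)."""
        g = self.by_id[gene_id]
        s = genome.fetch(g.chrom, g.start - 1, g.end)
        return reverse_complement(s) if g.strand == "-" else s

    # -- GFF3 -------------------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id};biotype={g.rna_class}"
                fh.write(
                    f"{g.chrom}\tcharlink\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "Annotation":
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
        genes = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            genes.append(
                GeneRecord(
                    gene_id=feat.attributes["ID"][0],
                    rna_class=feat.attributes["biotype"][0],
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
        return cls(genes)
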