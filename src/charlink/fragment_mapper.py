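"""Exact unique placement of RNA/DNA fragments and contact joining.

The mapper is an exact-match substring index: a fragment is placed only when
its full sequence occurs exactly once across both strands of the reference
set ("single best placement"); fragments occurring at two or more positions
are discarded as multimappers and fragments with no occurrence as unmapped.
A :class:`Mapper` protocol lets deployments swap in an external aligner while
the rest of the pipeline stays unchanged.

RNA fragments are searched against the transcriptome (one unspliced
transcript per gene) and the genome; transcriptome coordinates win when both
agree on the genomic locus, genome-only hits are attributed to the
overlapping gene if any (else ``unassigned``, feeding unkRNA detection), and
disagreeing hits drop the fragment as ambiguous.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol

import numpy as np
import pandas as pd

from .annotation import UNASSIGNED, Annotation
from .genome import GenomeModel
from .linker import reverse_complement

_SEPARATOR = "#"


@dataclass(frozen=True)
class Alignment:
    """One placement: 0-based half-open on a named reference."""

    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    n_best: int = 1

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("empty alignment interval")
        if self.n_best < 1:
            raise ValueError("n_best must be >= 1")


class Mapper(Protocol):
    """Adapter contract for pluggable aligners."""

    def map_unique(self, fragment: str) -> tuple[Alignment | None, str]:
        ...


class SubstringIndex:
    """Seed-and-verify exact substring index over a set of references.

    Every k-mer of the concatenated references is hashed; a query of length
    >= k is located by looking up its first k-mer and verifying the full
    sequence at each candidate.  Queries containing N never match.
    """

    def __init__(self, references: Mapping[str, str], k: int = 18):
        names = list(references)
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names")
        self.k = k
        self.names = names
        parts: list[str] = []
        starts: list[int] = []
        off = 0
        for n in names:
            seq = references[n].upper()
            starts.append(off)
            parts.append(seq)
            parts.append(_SEPARATOR)
            off += len(seq) + 1
        self._concat = "".join(parts)
        self._starts = starts
        self._ref_lens = [len(references[n]) for n in names]
        self._kmap: dict[str, object] = {}
        concat = self._concat
        kmap = self._kmap
        bad = np.zeros(len(concat) + 1, dtype=np.int32)
        for ch in set(concat) - set("ACGT"):
            i = concat.find(ch)
            while i >= 0:
                bad[i + 1] = 1
                i = concat.find(ch, i + 1)
        badcum = np.cumsum(bad)
        for i in range(len(concat) - k + 1):
            if badcum[i + k] - badcum[i]:
                continue
            kmer = concat[i:i + k]
            prev = kmap.get(kmer)
            if prev is None:
                kmap[kmer] = i
            elif isinstance(prev, int):
                kmap[kmer] = [prev, i]
            else:
                prev.append(i)

    def occurrences(self, query: str, limit: int = 0) -> list[int]:
        """Concatenated-coordinate start positions of exact full-length
        occurrences of ``query`` (forward sense only)."""
        if len(query) < self.k or "N" in query:
            return []
        cand = self._kmap.get(query[: self.k])
        if cand is None:
            return []
        if isinstance(cand, int):
            cand = (cand,)
        concat = self._concat
        out = []
        for pos in cand:
            if concat.startswith(query, pos):
                out.append(pos)
                if limit and len(out) >= limit:
                    break
        return out

    def to_ref(self, concat_pos: int) -> tuple[str, int]:
        """Translate a concatenated position to (ref_name, offset)."""
        i = bisect_right(self._starts, concat_pos) - 1
        return self.names[i], concat_pos - self._starts[i]


def build_index(references: Mapping[str, str], k: int = 18) -> SubstringIndex:
    """Construct a :class:`SubstringIndex` (the desk-scale aligner)."""
    return SubstringIndex(references, k=k)


def transcriptome(annotation: Annotation, genome: GenomeModel) -> dict[str, str]:
    """One unspliced transcript sequence per gene, keyed by gene_id."""
    return {
        g.gene_id: annotation.transcript_seq(g.gene_id, genome)
        for g in annotation
    }


def map_unique(
    fragment: str, index: SubstringIndex, max_n_fraction: float = 0.10
) -> tuple[Alignment | None, str]:
    """Place a fragment if and only if it has a single exact occurrence
    across both strands (a hit on each strand counts as two placements).

    Returns ``(alignment, reason)`` with reason in ``{mapped, unmapped,
    multimapper, n_rich}``.
    """
    if fragment.count("N") > max_n_fraction * len(fragment):
        return None, "n_rich"
    fwd = index.occurrences(fragment)
    rev = index.occurrences(reverse_complement(fragment))
    n = len(fwd) + len(rev)
    if n == 0:
        return None, "unmapped"
    if n > 1:
        return None, "multimapper"
    if fwd:
        pos, strand = fwd[0], "+"
    else:
        pos, strand = rev[0], "-"
    name, off = index.to_ref(pos)
    return Alignment(ref_name=name, ref_start=off, ref_end=off + len(fragment),
                     strand=strand, n_best=1), "mapped"


@dataclass(frozen=True)
class RnaAssignment:
    """Reconciled RNA-side placement: gene (or unassigned) + genomic locus."""

    gene_id: str
    rna_class: str
    chrom: str
    pos: int  # 1-based leftmost genomic coordinate
    strand: str


def _lift_tx(tx_hit: Alignment, annotation: Annotation) -> tuple[str, int, str]:
    """Genomic (chrom, 0-based leftmost, strand) of a transcript placement."""
    if tx_hit.ref_name not in annotation:
        raise KeyError(f"transcript {tx_hit.ref_name!r} absent from annotation")
    g = annotation[tx_hit.ref_name]
    length = tx_hit.ref_end - tx_hit.ref_start
    if g.strand == "+":
        left0 = (g.start - 1) + tx_hit.ref_start
        strand = tx_hit.strand
    else:
        left0 = g.end - tx_hit.ref_end
        strand = "-" if tx_hit.strand == "+" else "+"
    return g.chrom, left0, strand


def reconcile_rna_hit(
    tx_hit: Alignment | None,
    genome_hit: Alignment | None,
    annotation: Annotation,
) -> RnaAssignment | None:
    """Combine transcriptome and genome placements of one RNA fragment.

    Transcriptome coordinates win when both placements name the same genomic
    locus; a genome-only hit is attributed to the overlapping annotated gene
    if any, else ``unassigned``; disagreeing placements return ``None``
    (fragment dropped as ambiguous).
    """
    if tx_hit is None and genome_hit is None:
        raise ValueError("at least one hit must be present")
    if tx_hit is not None:
        chrom, left0, strand = _lift_tx(tx_hit, annotation)
        if genome_hit is not None and (
            genome_hit.ref_name != chrom or genome_hit.ref_start != left0
        ):
            return None
        g = annotation[tx_hit.ref_name]
        return RnaAssignment(gene_id=g.gene_id, rna_class=g.rna_class,
                             chrom=chrom, pos=left0 + 1, strand=strand)
    hits = annotation.overlapping(
        genome_hit.ref_name, genome_hit.ref_start, genome_hit.ref_end
    )
    if hits:
        g = min(hits, key=lambda x: x.gene_id)  # deterministic tie-break
        return RnaAssignment(gene_id=g.gene_id, rna_class=g.rna_class,
                             chrom=genome_hit.ref_name,
                             pos=genome_hit.ref_start + 1,
                             strand=genome_hit.strand)
    return RnaAssignment(gene_id=UNASSIGNED, rna_class="unkRNA",
                         chrom=genome_hit.ref_name,
                         pos=genome_hit.ref_start + 1,
                         strand=genome_hit.strand)


@dataclass
class JoinStats:
    valid: int = 0
    rna_only: int = 0
    dna_only: int = 0


CONTACT_COLUMNS = [
    "read_id", "rna_gene_id", "rna_class", "rna_chrom", "rna_pos",
    "dna_chrom", "dna_pos", "replicate",
]


def join_contacts(
    rna_assignments: Mapping[str, RnaAssignment] | Iterable[tuple[str, RnaAssignment]],
    dna_alignments: Mapping[str, Alignment] | Iterable[tuple[str, Alignment]],
    replicate_id: str = "rep1",
) -> tuple[pd.DataFrame, JoinStats]:
    """Match RNA and DNA placements by read id into one contact per read.

    Duplicate read ids within one input are an upstream bug and raise.
    The result is canonically sorted by read id, so the join is symmetric in
    input order.
    """
    rna = _as_unique_dict(rna_assignments, "rna")
    dna = _as_unique_dict(dna_alignments, "dna")
    stats = JoinStats()
    rows = []
    for rid in sorted(set(rna) | set(dna)):
        a = rna.get(rid)
        d = dna.get(rid)
        if a is None:
            stats.dna_only += 1
            continue
        if d is None:
            stats.rna_only += 1
            continue
        stats.valid += 1
        rows.append((rid, a.gene_id, a.rna_class, a.chrom, a.pos,
                     d.ref_name, d.ref_start + 1, replicate_id))
    df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return df, stats


def _as_unique_dict(items, label):
    if isinstance(items, Mapping):
        return dict(items)
    out = {}
    for rid, val in items:
        if rid in out:
            raise ValueError(f"duplicate read_id {rid!r} in {label} set")
        out[rid] = val
    return out


@dataclass
class MapStats:
    """Fragment-level outcome counts for a mapping run."""

    fragments_in: int = 0
    valid: int = 0
    rna_unmapped: int = 0
    rna_multimapper: int = 0
    rna_ambiguous: int = 0
    dna_unmapped: int = 0
    dna_multimapper: int = 0


def build_contacts(
    fragment_pairs,
    genome: GenomeModel,
    annotation: Annotation,
    genome_index: SubstringIndex | None = None,
    tx_index: SubstringIndex | None = None,
    replicate_id: str = "rep1",
    k: int = 18,
) -> tuple[pd.DataFrame, MapStats]:
    """Map a stream of :class:`~charlink.bridge_parser.FragmentPair` and join
    both sides into a contact table (streaming; one pass, no id joining step
    needed because both sides arrive together)."""
    if genome_index is None:
        genome_index = build_index(genome.sequences, k=k)
    if tx_index is None:
        tx_index = build_index(transcriptome(annotation, genome), k=k)
    stats = MapStats()
    read_ids, gene_ids, classes, rchroms, rpos, dchroms, dpos = (
        [], [], [], [], [], [], [])
    for pair in fragment_pairs:
        stats.fragments_in += 1
        tx_hit, tx_reason = map_unique(pair.rna_seq, tx_index)
        if tx_reason == "multimapper":
            stats.rna_multimapper += 1
            continue
        gen_hit, gen_reason = map_unique(pair.rna_seq, genome_index)
        if tx_hit is None:
            if gen_reason == "multimapper":
                stats.rna_multimapper += 1
                continue
            if gen_hit is None:
                stats.rna_unmapped += 1
                continue
        assignment = reconcile_rna_hit(tx_hit, gen_hit, annotation)
        if assignment is None:
            stats.rna_ambiguous += 1
            continue
        dna_hit, dna_reason = map_unique(pair.dna_seq, genome_index)
        if dna_hit is None:
            if dna_reason == "multimapper":
                stats.dna_multimapper += 1
            else:
                stats.dna_unmapped += 1
            continue
        stats.valid += 1
        read_ids.append(pair.read_id)
        gene_ids.append(assignment.gene_id)
        classes.append(assignment.rna_class)
        rchroms.append(assignment.chrom)
        rpos.append(assignment.pos)
        dchroms.append(dna_hit.ref_name)
        dpos.append(dna_hit.ref_start + 1)
    df = pd.DataFrame({
        "read_id": read_ids,
        "rna_gene_id": gene_ids,
        "rna_class": pd.Categorical(classes),
        "rna_chrom": pd.Categorical(rchroms, categories=genome.names),
        "rna_pos": np.asarray(rpos, dtype=np.int64),
        "dna_chrom": pd.Categorical(dchroms, categories=genome.names),
        "dna_pos": np.asarray(dpos, dtype=np.int64),
        "replicate": replicate_id,
    })
    return df, stats


def write_contacts(df: pd.DataFrame, path) -> None:
    """Contact table TSV (1-based positions, stated in the header)."""
    with open(path, "w") as fh:
        fh.write("#coordinates: 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_contacts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
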