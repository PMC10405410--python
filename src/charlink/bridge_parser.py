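"""Detect the linker tag in paired reads and split chimeras into RNA/DNA sides.

A valid ChAR-seq read pair carries the linker tag (or its reverse complement)
on exactly one mate.  The sequence 5' of the linker is the cDNA of the RNA
side; the sequence 3' of it is the genomic DNA side.  The untagged mate reads
the distal end of the same molecule and, depending on the tagged mate's
orientation, extends the DNA side (forward) or the RNA side (reverse).
Ambiguous reads (tag on both mates, or more than one tag occurrence) are
counted and excluded, never silently kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .linker import DEFAULT_LINKER, LinkerSpec, reverse_complement


class _AmbiguousTag:
    """Sentinel for reads with conflicting or repeated tag occurrences."""

    def __repr__(self) -> str:  # pragma: no cover
        return "AMBIGUOUS_TAG"


AMBIGUOUS_TAG = _AmbiguousTag()


@dataclass(frozen=True)
class TagHit:
    """Location and orientation of the linker tag inside one read."""

    position: int  # 0-based offset of the tag start in the read
    orientation: str  # "forward" (tag) or "reverse" (tag_rc)
    mate: int = 0


@dataclass(frozen=True)
class FragmentPair:
    """RNA-side and DNA-side fragments recovered from one read pair.

    Both sequences are stored in the orientation of the forward-sense
    chimeric molecule: reverse-orientation reads are reverse-complemented
    before splitting, so the RNA side is in transcript (cDNA) sense and the
    DNA side on the genome forward strand of the sequenced molecule.
    """

    read_id: str
    rna_seq: str
    dna_seq: str
    orientation: str
    provenance: str = "tagged_only"


def find_tag(read_seq: str, linker: LinkerSpec = DEFAULT_LINKER):
    """Exact search for the tag, then its reverse complement.

    Returns a :class:`TagHit`, ``None`` when neither occurs, or
    :data:`AMBIGUOUS_TAG` when both orientations occur or one occurs twice.
    """
    tag, tag_rc = linker.tag, linker.tag_rc
    i_f = read_seq.find(tag)
    i_r = read_seq.find(tag_rc)
    if i_f >= 0 and i_r >= 0:
        return AMBIGUOUS_TAG
    if i_f >= 0:
        if read_seq.find(tag, i_f + 1) >= 0:
            return AMBIGUOUS_TAG
        return TagHit(position=i_f, orientation="forward")
    if i_r >= 0:
        if read_seq.find(tag_rc, i_r + 1) >= 0:
            return AMBIGUOUS_TAG
        return TagHit(position=i_r, orientation="reverse")
    return None


def split_read(
    read_seq: str, hit: TagHit, linker: LinkerSpec = DEFAULT_LINKER
) -> tuple[str, str]:
    """Split a tagged read into (rna_part, dna_part).

    The full linker (both arms, derived from :class:`LinkerSpec`) is excised:
    the RNA part ends where the linker's upstream arm begins and the DNA part
    starts after the downstream arm.  Reverse-orientation reads are
    reverse-complemented first and then treated as forward.  Arms running off
    a read end simply truncate the corresponding side (possibly to empty);
    the length filter deals with those.
    """
    up = len(linker.upstream_arm)
    down = len(linker.downstream_arm)
    tlen = len(linker.tag)
    if hit.orientation == "reverse":
        read_seq = reverse_complement(read_seq)
        pos = len(read_seq) - hit.position - tlen
    else:
        pos = hit.position
    rna = read_seq[: pos - up] if pos >= up else ""
    dna = read_seq[pos + tlen + down:]
    return rna, dna


def _merge_prefix(known_prefix: str, candidate: str) -> str:
    """Extend a fragment whose proximal prefix is known; conservative."""
    if candidate.startswith(known_prefix):
        return candidate
    if known_prefix.startswith(candidate):
        return known_prefix
    return known_prefix


def _merge_suffix(known_suffix: str, candidate: str) -> str:
    if candidate.endswith(known_suffix):
        return candidate
    if known_suffix.endswith(candidate):
        return known_suffix
    return known_suffix


def resolve_pair(
    mate1: tuple[str, str],
    mate2: tuple[str, str] | None,
    linker: LinkerSpec = DEFAULT_LINKER,
) -> tuple[FragmentPair | None, str]:
    """Combine a read pair into a :class:`FragmentPair`.

    Returns ``(pair, outcome)`` with outcome one of ``valid``, ``no_tag``,
    ``ambiguous``.  Mates with different ids raise ``ValueError``.  The
    untagged mate extends the DNA side when the tagged mate is forward and
    the RNA side when it is reverse; if its sequence is inconsistent with the
    tagged mate's fragments the pair falls back to the tagged mate alone.
    """
    id1, seq1 = mate1
    if mate2 is not None:
        id2, seq2 = mate2
        if id1 != id2:
            raise ValueError(f"read id mismatch: {id1!r} vs {id2!r}")
    else:
        seq2 = None

    h1 = find_tag(seq1, linker)
    h2 = find_tag(seq2, linker) if seq2 is not None else None
    if h1 is AMBIGUOUS_TAG or h2 is AMBIGUOUS_TAG:
        return None, "ambiguous"
    if h1 is not None and h2 is not None:
        return None, "ambiguous"
    if h1 is None and h2 is None:
        return None, "no_tag"

    if h1 is not None:
        hit, tagged, untagged = h1, seq1, seq2
    else:
        hit, tagged, untagged = h2, seq2, seq1

    rna, dna = split_read(tagged, hit, linker)
    provenance = "tagged_only"
    if untagged:
        if hit.orientation == "forward":
            merged = _merge_prefix(dna, reverse_complement(untagged))
            if merged != dna:
                provenance = "mate_extended_dna"
            dna = merged
        else:
            merged = _merge_suffix(rna, untagged)
            if merged != rna:
                provenance = "mate_extended_rna"
            rna = merged
    return (
        FragmentPair(
            read_id=id1,
            rna_seq=rna,
            dna_seq=dna,
            orientation=hit.orientation,
            provenance=provenance,
        ),
        "valid",
    )


def length_filter(pair: FragmentPair, min_len: int = 18) -> FragmentPair | None:
    """Keep the pair only when both sides are at least ``min_len`` long.

    Fragments of 17 bp or less are not usable, so the whole pair is
    discarded (never one side alone); the default keeps >= 18 bp.
    """
    if len(pair.rna_seq) >= min_len and len(pair.dna_seq) >= min_len:
        return pair
    return None


@dataclass
class ParseStats:
    """Per-read outcome bookkeeping; ``pairs_in`` always equals
    ``valid + no_tag + ambiguous + length_filtered``."""

    pairs_in: int = 0
    valid: int = 0
    no_tag: int = 0
    ambiguous: int = 0
    length_filtered: int = 0

    def conserved(self) -> bool:
        return self.pairs_in == (
            self.valid + self.no_tag + self.ambiguous + self.length_filtered
        )


def parse_pairs(
    pairs: Iterable[tuple[str, str, str]],
    linker: LinkerSpec = DEFAULT_LINKER,
    min_len: int = 18,
    stats: ParseStats | None = None,
) -> Iterator[FragmentPair]:
    """Stream ``(read_id, mate1_seq, mate2_seq)`` triples into valid
    :class:`FragmentPair` objects, updating ``stats`` if given."""
    if stats is None:
        stats = ParseStats()
    for rid, s1, s2 in pairs:
        stats.pairs_in += 1
        pair, outcome = resolve_pair((rid, s1), (rid, s2) if s2 is not None
                                     else None, linker)
        if outcome != "valid":
            setattr(stats, outcome, getattr(stats, outcome) + 1)
            continue
        kept = length_filter(pair, min_len)
        if kept is None:
            stats.length_filtered += 1
            continue
        stats.valid += 1
        yield kept


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def read_fastq_pairs(
    fq1: str | Path, fq2: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Iterate paired FASTQ files (gzip allowed) as id/seq/seq triples."""
    import pysam

    with pysam.FastxFile(str(fq1)) as f1, pysam.FastxFile(str(fq2)) as f2:
        for r1, r2 in zip(f1, f2):
            if r1.name != r2.name:
                raise ValueError(
                    f"read id mismatch between mates: {r1.name!r} vs {r2.name!r}"
                )
            yield r1.name, r1.sequence.upper(), r2.sequence.upper()


def parse_fastq(
    fq1: str | Path,
    fq2: str | Path,
    out_rna: str | Path,
    out_dna: str | Path,
    audit: str | Path | None = None,
    linker: LinkerSpec = DEFAULT_LINKER,
    min_len: int = 18,
) -> ParseStats:
    """File-level front end: split paired FASTQ into rna.fq / dna.fq streams
    sharing read ids, plus an optional per-read outcome audit TSV."""
    stats = ParseStats()
    audit_fh = open(audit, "w") if audit is not None else None
    try:
        if audit_fh:
            audit_fh.write("read_id\toutcome\trna_len\tdna_len\n")
        with open(out_rna, "w") as fr, open(out_dna, "w") as fd:
            for rid, s1, s2 in read_fastq_pairs(fq1, fq2):
                stats.pairs_in += 1
                pair, outcome = resolve_pair((rid, s1), (rid, s2), linker)
                if outcome == "valid":
                    kept = length_filter(pair, min_len)
                    if kept is None:
                        outcome = "length_filtered"
                        stats.length_filtered += 1
                    else:
                        stats.valid += 1
                        fr.write(f"@{rid}\n{kept.rna_seq}\n+\n"
                                 f"{'I' * len(kept.rna_seq)}\n")
                        fd.write(f"@{rid}\n{kept.dna_seq}\n+\n"
                                 f"{'I' * len(kept.dna_seq)}\n")
                else:
                    setattr(stats, outcome, getattr(stats, outcome) + 1)
                if audit_fh:
                    rl = len(pair.rna_seq) if pair else 0
                    dl = len(pair.dna_seq) if pair else 0
                    audit_fh.write(f"{rid}\t{outcome}\t{rl}\t{dl}\n")
    finally:
        if audit_fh:
            audit_fh.close()
    return stats
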