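"""The ChAR-seq bridge linker and small sequence utilities.

The linker is a short double-stranded oligo that is ligated between an RNA
molecule (via its single-stranded 5' arm) and an adjacent DpnII-cut genomic
DNA fragment.  Computationally only its *top strand* matters: it carries a
13-mer tag whose position and orientation inside a sequenced chimera separate
the cDNA (RNA side) from the genomic DNA side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Top strand of the bridge linker.  Chemistry annotations of the physical
#: oligo (5' adenylation, 3' spacer, biotin) are not sequence and are omitted;
#: the three N positions are randomized per molecule during synthesis.
TOP_STRAND = "AANNNAAACCGGCGTCCAAGGATCTTTAATTAAGTCGCAG"

#: Bottom strand (the biotinylated one; terminal biotin-dT modeled as plain T).
BOTTOM_STRAND = "GATCTGCGACTTAATTAAAGATCCTTGGACGCCGGTT"

#: The tag: the substring of the top strand used to recognize the junction.
TAG = "ACCGGCGTCCAAG"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LinkerSpec:
    """Sequence description of the bridge linker.

    The tag arms are *derived* from ``top_strand`` by locating ``tag`` inside
    it, so a custom linker only has to supply consistent sequences.
    """

    top_strand: str = TOP_STRAND
    bottom_strand: str = BOTTOM_STRAND
    tag: str = TAG

    def __post_init__(self) -> None:
        if self.tag not in self.top_strand:
            raise ValueError("linker tag must be a substring of the top strand")

    @property
    def tag_rc(self) -> str:
        return reverse_complement(self.tag)

    @property
    def tag_offset(self) -> int:
        """0-based offset of the tag inside the top strand."""
        return self.top_strand.find(self.tag)

    @property
    def upstream_arm(self) -> str:
        """Linker sequence 5' of the tag (contains the randomized N block)."""
        return self.top_strand[: self.tag_offset]

    @property
    def downstream_arm(self) -> str:
        """Linker sequence 3' of the tag."""
        return self.top_strand[self.tag_offset + len(self.tag):]

    def realized_top(self, rng) -> str:
        """Top strand with every N replaced by a random base drawn from *rng*."""
        out = []
        for c in self.top_strand:
            out.append("ACGT"[rng.integers(4)] if c == "N" else c)
        return "".join(out)


DEFAULT_LINKER = LinkerSpec()
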