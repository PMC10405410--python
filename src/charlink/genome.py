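"""Reference genome container with concatenated ("dot-plot") coordinates.

A :class:`GenomeModel` holds named sequences in a canonical order: the
assembled macro-chromosomes first (in the order given), then every remaining
entry (linkage groups, unassembled scaffolds) in lexicographic name order.
Contact maps are drawn against a single concatenated axis, so each entry also
carries the global offset of its first base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class GenomeModel:
    """Ordered named sequences plus concatenated-coordinate bookkeeping."""

    names: list[str]
    sequences: dict[str, str]
    assembled_names: list[str]
    lengths: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in genome")
        missing = [n for n in self.names if n not in self.sequences]
        if missing:
            raise ValueError(f"sequences missing for entries: {missing}")
        unknown = [n for n in self.assembled_names if n not in self.sequences]
        if unknown:
            raise ValueError(f"assembled names not in genome: {unknown}")
        scaffolds = sorted(n for n in self.names if n not in self.assembled_names)
        self.names = list(self.assembled_names) + scaffolds
        for name in self.names:
            bad = set(self.sequences[name].upper()) - _VALID
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)}")
        self.lengths = {n: len(self.sequences[n]) for n in self.names}
        self.offsets = {}
        off = 0
        for n in self.names:
            self.offsets[n] = off
            off += self.lengths[n]

    # -- basic queries ----------------------------------------------------

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @property
    def scaffold_names(self) -> list[str]:
        return [n for n in self.names if n not in self.assembled_names]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)`` (0-based half-open)."""
        return self.sequences[chrom][start:end]

    # -- concatenated coordinates ----------------------------------------

    def concat_position(self, chrom: str, pos: int) -> int:
        """Global 1-based position of 1-based ``pos`` on ``chrom``."""
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self.lengths[chrom]:
            raise ValueError(
                f"position {pos} outside {chrom} (length {self.lengths[chrom]})"
            )
        return self.offsets[chrom] + pos

    def invert_concat(self, global_pos: int) -> tuple[str, int]:
        """Inverse of :meth:`concat_position`."""
        if not 1 <= global_pos <= self.total_length:
            raise ValueError(f"global position {global_pos} outside genome")
        starts = self._offset_array()
        i = int(np.searchsorted(starts, global_pos - 1, side="right")) - 1
        name = self.names[i]
        return name, global_pos - self.offsets[name]

    def _offset_array(self) -> np.ndarray:
        return np.array([self.offsets[n] for n in self.names], dtype=np.int64)

    # -- FASTA I/O --------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[n]), id=n, description="")
            for n in self.names
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls, path: str | Path, assembled_names: Sequence[str] | None = None
    ) -> "GenomeModel":
        """Load a FASTA file; entries whose name starts with ``chr`` are taken
        as assembled chromosomes unless ``assembled_names`` is given."""
        seqs: dict[str, str] = {}
        order: list[str] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
            order.append(rec.id)
        if assembled_names is None:
            assembled_names = [n for n in order if n.startswith("chr")]
        return cls(names=order, sequences=seqs, assembled_names=list(assembled_names))
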