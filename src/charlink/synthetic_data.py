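"""Synthetic ChAR-seq study generator with recorded ground truth.

Everything the pipeline consumes can be generated here: a multi-chromosome
genome with unassembled scaffolds, a six-class gene annotation, planted
RNA-DNA contacts with per-lncRNA cis/trans propensities, chimeric
cDNA-linker-DNA bridge read pairs in both tag orientations, ChIP-style
coverage reads with planted enrichment/depletion, and tissue x gene TPM
tables with planted group differences.  Each emitter is byte-deterministic
for a fixed seed, and every emitted read pair traces back to exactly one row
of the truth table, which is what makes parameter-recovery testing possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import RNA_CLASSES, Annotation, GeneRecord
from .genome import GenomeModel
from .linker import DEFAULT_LINKER, LinkerSpec, reverse_complement

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Liver contact composition over annotated classes.  The raw percentages are
#: the published rounded shares (70 / 14 / 13 / 2 / 1 / 0.04), normalized so
#: the mixture sums to exactly 1 over the six annotated classes.
_RAW_LIVER = {
    "rRNA": 0.70,
    "lncRNA": 0.14,
    "mRNA": 0.13,
    "snRNA": 0.02,
    "msrpRNA": 0.01,
    "snoRNA": 0.0004,
}
LIVER_PROFILE: dict[str, float] = {
    k: v / sum(_RAW_LIVER.values()) for k, v in _RAW_LIVER.items()
}

#: Fraction of contacts emitted from unannotated (intergenic) transcribed
#: loci; feeds the unkRNA detector.  Separate from the class mixture, which
#: always describes the annotated part only.
DEFAULT_INTERGENIC_FRACTION = 0.10

#: Default split of lncRNAs between planted regulatory modes.
DEFAULT_CIS_FRACTION = 0.875

DEFAULT_GENE_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "rRNA": (1500, 4000),
    "msrpRNA": (250, 350),
    "snRNA": (100, 300),
    "snoRNA": (70, 200),
    "lncRNA": (200, 1500),
    "mRNA": (400, 2500),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(
    seed: int,
    n_assembled: int = 6,
    assembled_lengths: int | Sequence[int] = 100_000,
    n_scaffolds: int = 4,
    scaffold_length_range: tuple[int, int] = (5_000, 10_000),
) -> GenomeModel:
    """Uniform-random genome shaped like a reptile assembly: ``n_assembled``
    macro-chromosomes (chr1..chrN) followed by short unassembled scaffolds.

    Uniform sequence means GATC tetramers occur at the background rate of
    ~1/256, so DpnII-anchored DNA fragments exist everywhere.
    """
    rng = np.random.default_rng(seed)
    if isinstance(assembled_lengths, int):
        assembled_lengths = [assembled_lengths] * n_assembled
    if len(assembled_lengths) != n_assembled:
        raise ValueError("assembled_lengths must match n_assembled")
    lo, hi = scaffold_length_range
    lengths = list(assembled_lengths) + [
        int(rng.integers(lo, hi + 1)) for _ in range(n_scaffolds)
    ]
    for L in lengths:
        if L < 1_000:
            raise ValueError(f"sequence length {L} below the 1 kb minimum")
    names = [f"chr{i + 1}" for i in range(n_assembled)] + [
        f"scaffold_{j + 1:03d}" for j in range(n_scaffolds)
    ]
    seqs = {name: _random_seq(rng, L) for name, L in zip(names, lengths)}
    return GenomeModel(
        names=names, sequences=seqs, assembled_names=names[:n_assembled]
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def make_annotation(
    genome: GenomeModel,
    seed: int,
    class_counts: Mapping[str, int],
    length_ranges: Mapping[str, tuple[int, int]] | None = None,
    chromosomes: Sequence[str] | None = None,
) -> Annotation:
    """Place non-overlapping genes of the requested classes on the genome.

    Placement samples uniformly over the remaining free gaps of each
    chromosome (chromosome chosen proportionally to its free capacity), so it
    only fails when a gene genuinely no longer fits; the error names the
    fullest chromosome.  Genes are placed on the assembled chromosomes by
    default, mirroring an analysis restricted to macro-chromosomes.
    """
    rng = np.random.default_rng(seed)
    ranges = dict(DEFAULT_GENE_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    chroms = list(chromosomes) if chromosomes else list(genome.assembled_names)
    # free gaps per chromosome as half-open 0-based [start, end)
    gaps: dict[str, list[tuple[int, int]]] = {
        c: [(0, genome.lengths[c])] for c in chroms
    }
    genes: list[GeneRecord] = []
    for cls in RNA_CLASSES:  # fixed class order keeps the draw deterministic
        count = int(class_counts.get(cls, 0))
        if count < 0:
            raise ValueError(f"negative count for class {cls}")
        lo, hi = ranges[cls]
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            placed = _place(rng, gaps, length)
            if placed is None:
                worst = max(chroms, key=lambda c: _capacity(gaps[c], length))
                raise ValueError(
                    f"cannot place {cls} gene of {length} bp; no free gap left "
                    f"(largest remaining capacity on {worst})"
                )
            chrom, start0 = placed
            genes.append(
                GeneRecord(
                    gene_id=f"{cls}_{i + 1:05d}",
                    rna_class=cls,
                    chrom=chrom,
                    start=start0 + 1,
                    end=start0 + length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return Annotation(genes)


def _capacity(gap_list: list[tuple[int, int]], length: int) -> int:
    return sum(max(0, (e - s) - length + 1) for s, e in gap_list)


def _place(
    rng: np.random.Generator,
    gaps: dict[str, list[tuple[int, int]]],
    length: int,
) -> tuple[str, int] | None:
    weights = []
    chroms = list(gaps)
    for c in chroms:
        weights.append(_capacity(gaps[c], length))
    total = sum(weights)
    if total == 0:
        return None
    chrom = chroms[
        int(rng.choice(len(chroms), p=np.asarray(weights, float) / total))
    ]
    gap_list = gaps[chrom]
    caps = np.array([max(0, (e - s) - length + 1) for s, e in gap_list], float)
    gi = int(rng.choice(len(gap_list), p=caps / caps.sum()))
    s, e = gap_list[gi]
    start0 = s + int(rng.integers(0, (e - s) - length + 1))
    # split the gap around the placed gene
    new = []
    if start0 > s:
        new.append((s, start0))
    if start0 + length < e:
        new.append((start0 + length, e))
    gap_list[gi:gi + 1] = new
    return chrom, start0


# ---------------------------------------------------------------------------
# contact planting
# ---------------------------------------------------------------------------

@dataclass
class ContactTruth:
    """Planted contacts plus the parameters that generated them.

    ``table`` columns: read_id, gene_id (or "intergenic"), rna_class
    ("intergenic" for unannotated loci), rna_strand, rna_chrom, rna_pos,
    dna_chrom, dna_pos, orientation.  Positions are 1-based leftmost
    coordinates of the future RNA/DNA fragments on the forward strand.
    """

    table: pd.DataFrame
    lncrna_classes: dict[str, str]
    window: int = 10_000

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#coordinates: 1-based inclusive\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _check_mixture(mix: Mapping[str, float]) -> None:
    bad = set(mix) - set(RNA_CLASSES)
    if bad:
        raise ValueError(f"unknown RNA classes in mixture: {sorted(bad)}")
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mixture sums to {total!r}, not 1")


def plant_contacts(
    annotation: Annotation,
    genome: GenomeModel,
    seed: int,
    class_mixture: Mapping[str, float] | None = None,
    intergenic_fraction: float | None = None,
    lncrna_class_assignment: Mapping[str, str] | None = None,
    n_contacts: int = 0,
    per_gene_counts: Mapping[str, int] | None = None,
    p_cis: float = 0.9,
    p_trans: float = 0.9,
    p_mrna_proximal: float = 0.5,
    cis_fraction: float = DEFAULT_CIS_FRACTION,
    dpnII_anchor: bool = True,
    orientation_mix: float = 0.5,
    window: int = 10_000,
    n_intergenic_loci: int = 30,
    min_fragment_room: int = 20,
) -> ContactTruth:
    """Draw planted RNA-DNA contacts with known per-gene ground truth.

    Each lncRNA carries a planted regulatory mode: ``cis_proximal`` genes put
    each contact within ``window`` of their span with probability ``p_cis``
    (else uniformly genome-wide); ``trans_acting`` genes put each contact on
    a different chromosome with probability ``p_trans`` (else uniformly on
    their own chromosome).  mRNAs behave like nascent transcripts
    (``p_mrna_proximal`` of contacts near the locus); the small structural
    RNA classes contact chromatin uniformly genome-wide.  DNA positions are
    snapped to the nearest GATC (DpnII site) inside their intended region
    when ``dpnII_anchor`` is on.

    ``per_gene_counts`` bypasses the mixture and plants an exact number of
    contacts per listed gene (still in a deterministic shuffled order).
    """
    rng = np.random.default_rng(seed)
    if class_mixture is None:
        class_mixture = LIVER_PROFILE
    _check_mixture(class_mixture)
    if intergenic_fraction is None:
        intergenic_fraction = DEFAULT_INTERGENIC_FRACTION
    if not 0 <= intergenic_fraction < 1:
        raise ValueError("intergenic_fraction must be in [0, 1)")

    # planted lncRNA modes ------------------------------------------------
    lnc_ids = [g.gene_id for g in annotation.by_class["lncRNA"]]
    if lncrna_class_assignment is None:
        draws = rng.random(len(lnc_ids))
        lncrna_classes = {
            gid: ("cis_proximal" if d < cis_fraction else "trans_acting")
            for gid, d in zip(lnc_ids, draws)
        }
    else:
        lncrna_classes = dict(lncrna_class_assignment)
        bad = [v for v in lncrna_classes.values()
               if v not in ("cis_proximal", "trans_acting")]
        if bad:
            raise ValueError(f"unknown planted class {bad[0]!r}")

    # choose the RNA source of every contact ------------------------------
    genes = list(annotation.genes)
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    if per_gene_counts is not None:
        src = np.concatenate([
            np.full(int(c), gene_index[gid], dtype=np.int64)
            for gid, c in per_gene_counts.items()
        ]) if per_gene_counts else np.empty(0, dtype=np.int64)
        rng.shuffle(src)
        intergenic_mask = np.zeros(len(src), dtype=bool)
    else:
        cats = list(RNA_CLASSES) + ["intergenic"]
        probs = np.array(
            [class_mixture.get(c, 0.0) * (1 - intergenic_fraction)
             for c in RNA_CLASSES] + [intergenic_fraction]
        )
        probs = probs / probs.sum()
        cat_draw = rng.choice(len(cats), size=n_contacts, p=probs)
        intergenic_mask = cat_draw == len(RNA_CLASSES)
        src = np.full(n_contacts, -1, dtype=np.int64)
        for ci, cls in enumerate(RNA_CLASSES):
            m = cat_draw == ci
            k = int(m.sum())
            if k == 0:
                continue
            pool = annotation.by_class[cls]
            if not pool:
                raise ValueError(
                    f"mixture requests class {cls} but annotation has no "
                    f"{cls} genes"
                )
            pool_idx = np.array([gene_index[g.gene_id] for g in pool])
            src[m] = pool_idx[rng.integers(0, len(pool_idx), size=k)]

    n = len(src)
    if n == 0:
        empty = pd.DataFrame(
            columns=["read_id", "gene_id", "rna_class", "rna_strand",
                     "rna_chrom", "rna_pos", "dna_chrom", "dna_pos",
                     "orientation"]
        )
        return ContactTruth(table=empty, lncrna_classes=lncrna_classes,
                            window=window)

    # per-gene arrays ------------------------------------------------------
    name_to_code = {c: i for i, c in enumerate(genome.names)}
    chrom_lengths = np.array([genome.lengths[c] for c in genome.names],
                             dtype=np.int64)
    chrom_offsets = np.array([genome.offsets[c] for c in genome.names],
                             dtype=np.int64)
    total_len = genome.total_length

    g_chrom = np.array([name_to_code[g.chrom] for g in genes], dtype=np.int64)
    g_start = np.array([g.start for g in genes], dtype=np.int64)
    g_end = np.array([g.end for g in genes], dtype=np.int64)
    g_strand = np.array([g.strand == "-" for g in genes])
    g_class = np.array([RNA_CLASSES.index(g.rna_class) for g in genes],
                       dtype=np.int64)
    g_mode = np.zeros(len(genes), dtype=np.int64)  # 1 cis, 2 trans
    for gid, mode in lncrna_classes.items():
        g_mode[gene_index[gid]] = 1 if mode == "cis_proximal" else 2

    # intergenic source loci ----------------------------------------------
    inter_chrom = np.empty(0, np.int64)
    inter_start = np.empty(0, np.int64)
    if intergenic_mask.any():
        loci = _intergenic_loci(rng, annotation, genome, n_intergenic_loci,
                                span=2_000, room=min_fragment_room,
                                margin=300)
        li = rng.integers(0, len(loci), size=int(intergenic_mask.sum()))
        inter_chrom = np.array([name_to_code[c] for c, _ in loci])[li]
        inter_start = np.array([s for _, s in loci])[li]

    # RNA-side anchors (1-based leftmost of the future RNA fragment) ------
    rna_chrom = np.empty(n, np.int64)
    rna_pos = np.empty(n, np.int64)
    rna_strand = np.full(n, "+", dtype="U1")
    genic = ~intergenic_mask
    gi = src[genic]
    span_room = g_end[gi] - g_start[gi] + 1 - (min_fragment_room - 1)
    rna_pos[genic] = g_start[gi] + (rng.random(gi.size) * span_room).astype(
        np.int64)
    rna_chrom[genic] = g_chrom[gi]
    rs = np.full(n, False)
    rs[genic] = g_strand[gi]
    rna_strand[rs] = "-"
    if intergenic_mask.any():
        k = int(intergenic_mask.sum())
        rna_chrom[intergenic_mask] = inter_chrom
        rna_pos[intergenic_mask] = inter_start + (
            rng.random(k) * (2_000 - min_fragment_room + 1)).astype(np.int64)

    # DNA-side positions ---------------------------------------------------
    dna_chrom = np.empty(n, np.int64)
    dna_pos = np.empty(n, np.int64)

    def _uniform_global(m: np.ndarray) -> None:
        k = int(m.sum())
        if not k:
            return
        glob = rng.integers(0, total_len, size=k)
        ci = np.searchsorted(chrom_offsets, glob, side="right") - 1
        dna_chrom[m] = ci
        dna_pos[m] = glob - chrom_offsets[ci] + 1

    mode = np.zeros(n, np.int64)
    mode[genic] = g_mode[gi]
    cls_of = np.full(n, -1, np.int64)
    cls_of[genic] = g_class[gi]
    u = rng.random(n)

    is_lnc_cis = mode == 1
    is_lnc_trans = mode == 2
    is_mrna = cls_of == RNA_CLASSES.index("mRNA")

    near = (is_lnc_cis & (u < p_cis)) | (is_mrna & (u < p_mrna_proximal))
    far_cis = is_lnc_trans & (u >= p_trans)
    trans = is_lnc_trans & (u < p_trans)
    elsewhere = ~(near | far_cis | trans)

    # near: uniform inside (start - window, end + window), clipped to chrom
    if near.any():
        gi_n = src[near]
        lo = np.maximum(1, g_start[gi_n] - window + 1)
        hi = np.minimum(chrom_lengths[g_chrom[gi_n]] - (min_fragment_room - 1),
                        g_end[gi_n] + window - 1)
        dna_chrom[near] = g_chrom[gi_n]
        dna_pos[near] = lo + (rng.random(gi_n.size) * (hi - lo + 1)).astype(
            np.int64)

    # far_cis: uniform on the gene's own chromosome
    if far_cis.any():
        gi_f = src[far_cis]
        c = g_chrom[gi_f]
        dna_chrom[far_cis] = c
        dna_pos[far_cis] = 1 + (rng.random(gi_f.size)
                                * chrom_lengths[c]).astype(np.int64)

    # trans: uniform on the complement of the gene's own chromosome
    if trans.any():
        gi_t = src[trans]
        c = g_chrom[gi_t]
        own_len = chrom_lengths[c]
        own_off = chrom_offsets[c]
        glob = (rng.random(gi_t.size) * (total_len - own_len)).astype(np.int64)
        glob = np.where(glob >= own_off, glob + own_len, glob)
        ci = np.searchsorted(chrom_offsets, glob, side="right") - 1
        dna_chrom[trans] = ci
        dna_pos[trans] = glob - chrom_offsets[ci] + 1

    _uniform_global(elsewhere)

    # snap to DpnII sites inside the intended region ----------------------
    if dpnII_anchor:
        lo_bound = np.ones(n, np.int64)
        hi_bound = chrom_lengths[dna_chrom] - (min_fragment_room - 1)
        if near.any():
            gi_n = src[near]
            lo_bound[near] = np.maximum(1, g_start[gi_n] - window + 1)
            hi_bound[near] = np.minimum(hi_bound[near],
                                        g_end[gi_n] + window - 1)
        dna_pos = _snap_to_gatc(genome, dna_chrom, dna_pos, lo_bound,
                                hi_bound)
    dna_pos = np.minimum(dna_pos,
                         chrom_lengths[dna_chrom] - (min_fragment_room - 1))
    dna_pos = np.maximum(dna_pos, 1)

    gene_ids = np.array([g.gene_id for g in genes] + ["intergenic"])
    class_names = np.array(list(RNA_CLASSES) + ["intergenic"])
    src_disp = np.where(intergenic_mask, len(genes), src)
    cls_disp = np.where(intergenic_mask, len(RNA_CLASSES), cls_of)
    orientation = np.where(rng.random(n) < orientation_mix,
                           "reverse", "forward")

    chrom_cat = pd.CategoricalDtype(categories=genome.names)
    table = pd.DataFrame(
        {
            "read_id": [f"r{i:07d}" for i in range(n)],
            "gene_id": gene_ids[src_disp],
            "rna_class": pd.Categorical.from_codes(
                cls_disp, categories=list(class_names)),
            "rna_strand": rna_strand,
            "rna_chrom": pd.Categorical.from_codes(rna_chrom,
                                                   dtype=chrom_cat),
            "rna_pos": rna_pos,
            "dna_chrom": pd.Categorical.from_codes(dna_chrom,
                                                   dtype=chrom_cat),
            "dna_pos": dna_pos,
            "orientation": orientation,
        }
    )
    return ContactTruth(table=table, lncrna_classes=lncrna_classes,
                        window=window)


def _intergenic_loci(
    rng: np.random.Generator,
    annotation: Annotation,
    genome: GenomeModel,
    n_loci: int,
    span: int,
    room: int,
    margin: int = 300,
) -> list[tuple[str, int]]:
    """Random loci of ``span`` bp on assembled chromosomes overlapping no
    annotated gene (start is 1-based).  ``margin`` keeps a buffer past the
    locus end so RNA fragments anchored near it cannot reach into a gene."""
    loci: list[tuple[str, int]] = []
    chroms = genome.assembled_names
    lens = np.array([genome.lengths[c] for c in chroms], float)
    for _ in range(n_loci):
        for _attempt in range(1_000):
            c = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
            start = int(rng.integers(1, genome.lengths[c] - span - room - margin))
            if not annotation.overlapping(c, start - 1,
                                          start - 1 + span + margin):
                loci.append((c, start))
                break
        else:
            raise ValueError("could not find intergenic space for a locus")
    return loci


def _snap_to_gatc(
    genome: GenomeModel,
    chrom_codes: np.ndarray,
    pos: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Snap each 1-based position to the nearest downstream GATC start within
    [lo, hi]; fall back to the nearest upstream site in the window, and leave
    the position untouched when the window holds no site."""
    out = pos.copy()
    for code, name in enumerate(genome.names):
        m = chrom_codes == code
        if not m.any():
            continue
        sites = _gatc_positions(genome, name)  # 1-based starts, sorted
        if sites.size == 0:
            continue
        p = pos[m]
        i = np.searchsorted(sites, p, side="left")
        down = np.where(i < sites.size, sites[np.minimum(i, sites.size - 1)],
                        np.iinfo(np.int64).max)
        up = np.where(i > 0, sites[np.maximum(i - 1, 0)], np.iinfo(np.int64).min)
        snapped = np.where(down <= hi[m], down, np.where(up >= lo[m], up, p))
        out[m] = snapped
    return out


_GATC_CACHE: dict[int, dict[str, np.ndarray]] = {}


def _gatc_positions(genome: GenomeModel, chrom: str) -> np.ndarray:
    cache = _GATC_CACHE.setdefault(id(genome), {})
    if chrom not in cache:
        seq = genome.sequences[chrom]
        hits = []
        i = seq.find("GATC")
        while i >= 0:
            hits.append(i + 1)
            i = seq.find("GATC", i + 1)
        cache[chrom] = np.array(hits, dtype=np.int64)
    return cache[chrom]


# ---------------------------------------------------------------------------
# bridge reads
# ---------------------------------------------------------------------------

def iter_bridge_reads(
    truth: ContactTruth,
    genome: GenomeModel,
    seed: int,
    annotation: Annotation | None = None,
    linker: LinkerSpec = DEFAULT_LINKER,
    read_length: int = 150,
    rna_frag_range: tuple[int, int] = (20, 110),
    dna_frag_range: tuple[int, int] = (20, 110),
    error_rate: float = 0.0,
    orientation_mix: float | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, mate1, mate2)`` for every truth contact.

    The chimeric molecule is cDNA (RNA side, transcript sense) + linker top
    strand (N block randomized per molecule) + genomic DNA (forward strand).
    Mate 1 reads the molecule from the RNA end (forward orientation) or from
    the DNA end of the opposite strand (reverse orientation, carrying the
    reverse-complement tag); mate 2 reads the distal fragment of the same
    molecule from the other end, so the tag lies on exactly one mate.

    ``orientation_mix=None`` honours the orientation recorded in the truth
    table; a float redraws orientations locally (a parser stress-test knob
    that leaves the truth table untouched).
    """
    if read_length < len(linker.tag):
        raise ValueError("read_length shorter than the linker tag")
    for name, (lo, hi) in (("rna_frag_range", rna_frag_range),
                           ("dna_frag_range", dna_frag_range)):
        if not (1 <= lo <= hi <= 300):
            raise ValueError(f"{name} must lie within [1, 300]")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    t = truth.table
    n = len(t)
    if n == 0:
        return

    rna_len = rng.integers(rna_frag_range[0], rna_frag_range[1] + 1, size=n)
    dna_len = rng.integers(dna_frag_range[0], dna_frag_range[1] + 1, size=n)
    n_blocks = _BASES[rng.integers(0, 4, size=(n, 3))]
    if orientation_mix is None:
        reverse = (t["orientation"].to_numpy() == "reverse")
    else:
        reverse = rng.random(n) < orientation_mix

    # right clamp for the RNA fragment: gene end (or chromosome end)
    rna_limit = np.empty(n, np.int64)
    gene_ids = t["gene_id"].to_numpy()
    rna_chroms = t["rna_chrom"].to_numpy()
    if annotation is not None:
        for i in range(n):
            gid = gene_ids[i]
            rna_limit[i] = (annotation[gid].end if gid in annotation
                            else genome.lengths[rna_chroms[i]])
    else:
        rna_limit[:] = [genome.lengths[c] for c in rna_chroms]

    rna_pos = t["rna_pos"].to_numpy()
    dna_pos = t["dna_pos"].to_numpy()
    dna_chroms = t["dna_chrom"].to_numpy()
    rna_strands = t["rna_strand"].to_numpy()
    read_ids = t["read_id"].to_numpy()
    up, tag, down = linker.upstream_arm, linker.tag, linker.downstream_arm
    seqs = genome.sequences

    for i in range(n):
        rl = min(int(rna_len[i]), int(rna_limit[i] - rna_pos[i] + 1))
        dl = min(int(dna_len[i]),
                 genome.lengths[dna_chroms[i]] - int(dna_pos[i]) + 1)
        r0 = int(rna_pos[i]) - 1
        d0 = int(dna_pos[i]) - 1
        rna = seqs[rna_chroms[i]][r0:r0 + rl]
        if rna_strands[i] == "-":
            rna = reverse_complement(rna)
        dna = seqs[dna_chroms[i]][d0:d0 + dl]
        nb = n_blocks[i].tobytes().decode()
        mol = rna + up[:2] + nb + up[5:] + tag + down + dna
        if reverse[i]:
            mate1 = reverse_complement(mol)[:read_length]
            mate2 = rna[:read_length]
        else:
            mate1 = mol[:read_length]
            mate2 = reverse_complement(dna)[:read_length]
        if error_rate > 0:
            mate1 = _mutate(mate1, rng, error_rate)
            mate2 = _mutate(mate2, rng, error_rate)
        yield str(read_ids[i]), mate1, mate2


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def emit_bridge_reads(
    truth: ContactTruth,
    genome: GenomeModel,
    seed: int,
    fq1: str | Path,
    fq2: str | Path,
    **kwargs,
) -> int:
    """Write the bridge read pairs of :func:`iter_bridge_reads` as paired
    FASTQ (constant quality, byte-deterministic per seed).  Returns the
    number of pairs written."""
    n = 0
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for rid, m1, m2 in iter_bridge_reads(truth, genome, seed, **kwargs):
            f1.write(f"@{rid}\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}\n{m2}\n+\n{'I' * len(m2)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# ChIP-style coverage reads
# ---------------------------------------------------------------------------

def emit_coverage_track(
    genome: GenomeModel,
    seed: int,
    contact_sites_enriched: Sequence[tuple[str, int]] = (),
    contact_sites_depleted: Sequence[tuple[str, int]] = (),
    effect_size: float = 1.0,
    n_reads: int = 100_000,
    read_length: int = 100,
    halfwidth: int = 200,
    bin_size: int = 50,
    bed: str | Path | None = None,
    bedgraph: str | Path | None = None,
):
    """Simulate a ChIP coverage library: uniform background read starts with
    the local start intensity multiplied by ``effect_size`` in +-``halfwidth``
    bp around each enriched site (divided for depleted sites).

    Returns ``(reads, track)`` where ``reads`` is a DataFrame with 0-based
    half-open ``chrom/start/end`` intervals and ``track`` the binned RPKM
    :class:`~charlink.chromatin_association.CoverageTrack`.  Sites are given
    as ``(chrom, pos)`` with 1-based positions.
    """
    from .chromatin_association import rpkm_track  # local: avoid cycle

    if effect_size < 1:
        raise ValueError("effect_size must be >= 1 (fold-change)")
    rng = np.random.default_rng(seed)
    weights = {c: np.ones(genome.lengths[c], dtype=np.float64)
               for c in genome.names}
    for sites, factor in ((contact_sites_enriched, effect_size),
                          (contact_sites_depleted, 1.0 / effect_size)):
        for chrom, pos in sites:
            if chrom not in genome or not 1 <= pos <= genome.lengths[chrom]:
                raise ValueError(f"site outside genome: {chrom}:{pos}")
            lo = max(0, pos - 1 - halfwidth)
            hi = min(genome.lengths[chrom], pos - 1 + halfwidth + 1)
            weights[chrom][lo:hi] *= factor
    flat = np.concatenate([weights[c] for c in genome.names])
    if n_reads > 0:
        starts_global = rng.choice(len(flat), size=n_reads, p=flat / flat.sum())
        starts_global.sort()
        offsets = np.array([genome.offsets[c] for c in genome.names])
        ci = np.searchsorted(offsets, starts_global, side="right") - 1
        chrom_names = np.array(genome.names)
        lens = np.array([genome.lengths[c] for c in genome.names])
        start0 = starts_global - offsets[ci]
        end0 = np.minimum(start0 + read_length, lens[ci])
        reads = pd.DataFrame({
            "chrom": chrom_names[ci], "start": start0, "end": end0,
        })
    else:
        reads = pd.DataFrame({"chrom": [], "start": [], "end": []})
    track = rpkm_track(reads, genome, bin_size=bin_size)
    if bed is not None:
        with open(bed, "w") as fh:
            for row in reads.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t+\n")
    if bedgraph is not None:
        track.to_bedgraph(bedgraph)
    return reads, track


# ---------------------------------------------------------------------------
# TPM expression matrix
# ---------------------------------------------------------------------------

def emit_tpm_matrix(
    gene_ids: Sequence[str],
    seed: int,
    n_embryonic: int = 47,
    n_adult: int = 28,
    group_assignment: Mapping[str, str] | None = None,
    group_fold: float = 1.0,
    gene_log_sigma: float = 1.0,
    noise_log_sigma: float = 0.8,
    base_log_mean: float = 2.0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Gene x tissue TPM matrix with log-normal expression.

    Each gene gets a baseline mean ``exp(N(base_log_mean, gene_log_sigma))``;
    tissue values multiply log-normal noise onto it.  Genes assigned to the
    "high" group get their mean multiplied by ``group_fold``.  Columns are
    named ``embryonic_NN`` / ``adult_NN`` (defaults mirror a 47 embryonic +
    28 adult tissue panel).
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    if group_fold <= 0:
        raise ValueError("group_fold must be positive")
    rng = np.random.default_rng(seed)
    n_t = n_embryonic + n_adult
    base = np.exp(rng.normal(base_log_mean, gene_log_sigma, size=len(gene_ids)))
    if group_assignment:
        fold = np.array([
            group_fold if group_assignment.get(g) == "high" else 1.0
            for g in gene_ids
        ])
        base = base * fold
    noise = np.exp(rng.normal(0.0, noise_log_sigma,
                              size=(len(gene_ids), n_t)))
    tpm = base[:, None] * noise
    cols = [f"embryonic_{i + 1:02d}" for i in range(n_embryonic)] + [
        f"adult_{i + 1:02d}" for i in range(n_adult)]
    df = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                      columns=cols)
    if path is not None:
        df.to_csv(path, sep="\t")
    return df
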