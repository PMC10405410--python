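"""Per-gene and per-class contact statistics.

Implements the Contact Distribution Index (CDI: contacts on the
most-contacted chromosome over total contacts), the three-way partition of a
gene's contacts into cis-proximal (< 10 kb around the locus), cis-distal
(further away on the same chromosome) and trans (other chromosomes), the
>50% cis/trans classification of lncRNAs, distance-from-locus histograms,
concatenated dot-plot coordinates, and sliding-window detection of
transcribed regions that overlap no annotated gene (unkRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import UNASSIGNED, Annotation, GeneRecord
from .genome import GenomeModel

DEFAULT_WINDOW = 10_000
DISTANCE_CAPS = (20_000, 40_000, 100_000, 200_000, 300_000)


@dataclass
class GeneContactProfile:
    """Contact summary for one gene."""

    gene_id: str
    rna_class: str
    total_contacts: int
    per_chrom: dict[str, int]
    cdi: float
    f_cis_proximal: float | None = None
    f_cis_distal: float | None = None
    f_trans: float | None = None
    classification: str = "unclassified"


def compute_cdi(per_chrom: Mapping[str, int] | pd.Series) -> float:
    """Contacts on the most-contacted chromosome divided by all contacts.

    1.0 means every contact is on a single chromosome; 1/n means an even
    spread over n chromosomes.  Undefined (raises) for zero contacts.
    """
    values = np.asarray(list(per_chrom.values())
                        if isinstance(per_chrom, Mapping) else per_chrom,
                        dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("CDI undefined for a gene with zero contacts")
    return float(values.max() / total)


def tally(
    contacts: pd.DataFrame, annotation: Annotation
) -> tuple[list[GeneContactProfile], list[str]]:
    """Per-gene totals and per-chromosome DNA-side counts.

    Returns ``(profiles, not_detected)`` where ``not_detected`` lists
    annotated genes with zero contacts.  Contacts naming a gene absent from
    the annotation raise; ``unassigned`` contacts are skipped here (they feed
    :func:`detect_unk_regions`).
    """
    assigned = contacts[contacts["rna_gene_id"] != UNASSIGNED]
    unknown = set(assigned["rna_gene_id"].unique()) - set(annotation.by_id)
    if unknown:
        raise ValueError(f"contacts name unknown genes: {sorted(unknown)[:5]}")
    counts = (
        assigned.groupby(["rna_gene_id", "dna_chrom"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    profiles = []
    for gid, row in counts.iterrows():
        per_chrom = {c: int(v) for c, v in row.items() if v > 0}
        total = int(row.sum())
        profiles.append(
            GeneContactProfile(
                gene_id=gid,
                rna_class=annotation[gid].rna_class,
                total_contacts=total,
                per_chrom=per_chrom,
                cdi=compute_cdi(per_chrom),
            )
        )
    detected = {p.gene_id for p in profiles}
    not_detected = [g.gene_id for g in annotation if g.gene_id not in detected]
    return profiles, not_detected


def partition(
    gene: GeneRecord,
    dna_chroms: Sequence[str] | np.ndarray,
    dna_positions: Sequence[int] | np.ndarray,
    window: int = DEFAULT_WINDOW,
) -> tuple[float, float, float]:
    """Fractions of a gene's contacts that are cis-proximal, cis-distal and
    trans.

    A contact is cis-proximal when it is on the gene's chromosome and its
    start is strictly closer than ``window`` to the gene span (distance 0
    inside the span; exactly ``window`` away counts as cis-distal).
    """
    chroms = np.asarray(dna_chroms)
    pos = np.asarray(dna_positions, dtype=np.int64)
    n = len(pos)
    if n == 0:
        raise ValueError(f"{gene.gene_id}: no contacts, fractions undefined")
    same = chroms == gene.chrom
    dist = np.maximum.reduce([
        gene.start - pos, pos - gene.end, np.zeros(n, dtype=np.int64)
    ])
    proximal = same & (dist < window)
    f_prox = proximal.sum() / n
    f_distal = (same & ~proximal).sum() / n
    f_trans = (~same).sum() / n
    return float(f_prox), float(f_distal), float(f_trans)


def classify(
    f_cis_proximal: float,
    f_cis_distal: float,
    f_trans: float,
    threshold: float = 0.5,
) -> str:
    """Three-way call: ``cis_proximal`` when the cis-proximal fraction
    strictly exceeds ``threshold``, ``trans_acting`` when the trans fraction
    does, else ``unclassified`` (exactly 50% is unclassified)."""
    if f_cis_proximal > threshold:
        return "cis_proximal"
    if f_trans > threshold:
        return "trans_acting"
    return "unclassified"


def classify_same_chrom(f_trans: float, threshold: float = 0.5) -> str:
    """Two-way call on the same-chromosome fraction (cis = cis-proximal +
    cis-distal); the alternative reading of "cis-acting"."""
    if 1 - f_trans > threshold:
        return "cis_acting"
    if f_trans > threshold:
        return "trans_acting"
    return "unclassified"


def gene_profiles(
    contacts: pd.DataFrame,
    annotation: Annotation,
    genome: GenomeModel | None = None,
    window: int = DEFAULT_WINDOW,
    assembled_only: bool = True,
) -> pd.DataFrame:
    """Vectorized per-gene profile table: totals, CDI, partition fractions
    and both classification schemes.

    With ``assembled_only`` (the default) genes on unassembled scaffolds are
    excluded from partitioning/classification, mirroring an analysis
    restricted to the macro-chromosomes; it requires ``genome``.
    """
    assigned = contacts[contacts["rna_gene_id"] != UNASSIGNED]
    if assembled_only:
        if genome is None:
            raise ValueError("assembled_only requires the genome model")
        keep_chroms = set(genome.assembled_names)
        ok_ids = {
            g.gene_id for g in annotation if g.chrom in keep_chroms
        }
        assigned = assigned[assigned["rna_gene_id"].isin(ok_ids)]
    if len(assigned) == 0:
        return pd.DataFrame(
            columns=["gene_id", "rna_class", "total_contacts", "cdi",
                     "f_cis_proximal", "f_cis_distal", "f_trans",
                     "classification", "classification_same_chrom"]
        )
    df = assigned.copy()
    gid = df["rna_gene_id"]
    df["g_chrom"] = gid.map({g.gene_id: g.chrom for g in annotation})
    df["g_start"] = gid.map({g.gene_id: g.start for g in annotation})
    df["g_end"] = gid.map({g.gene_id: g.end for g in annotation})
    pos = df["dna_pos"].to_numpy()
    dist = np.maximum(
        np.maximum(df["g_start"].to_numpy() - pos,
                   pos - df["g_end"].to_numpy()),
        0,
    )
    same = (df["dna_chrom"].astype(str) == df["g_chrom"]).to_numpy()
    df["cat"] = np.where(
        same & (dist < window), "cis_proximal",
        np.where(same, "cis_distal", "trans"),
    )
    frac = (
        df.groupby("rna_gene_id", observed=True)["cat"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["cis_proximal", "cis_distal", "trans"],
                 fill_value=0.0)
    )
    per_chrom = (
        df.groupby(["rna_gene_id", "dna_chrom"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    total = per_chrom.sum(axis=1)
    cdi = per_chrom.max(axis=1) / total
    out = pd.DataFrame({
        "gene_id": frac.index,
        "rna_class": [annotation[g].rna_class for g in frac.index],
        "total_contacts": total.reindex(frac.index).astype(int).to_numpy(),
        "cdi": cdi.reindex(frac.index).to_numpy(),
        "f_cis_proximal": frac["cis_proximal"].to_numpy(),
        "f_cis_distal": frac["cis_distal"].to_numpy(),
        "f_trans": frac["trans"].to_numpy(),
    }).reset_index(drop=True)
    out["classification"] = [
        classify(a, b, c) for a, b, c in zip(
            out["f_cis_proximal"], out["f_cis_distal"], out["f_trans"])
    ]
    out["classification_same_chrom"] = [
        classify_same_chrom(t) for t in out["f_trans"]
    ]
    return out


def class_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-RNA-class aggregation of a :func:`gene_profiles` table: gene
    counts, contact totals and shares, and median CDI."""
    grp = profiles.groupby("rna_class", observed=True)
    out = pd.DataFrame({
        "n_genes": grp.size(),
        "total_contacts": grp["total_contacts"].sum(),
        "median_contacts": grp["total_contacts"].median(),
        "median_cdi": grp["cdi"].median(),
    })
    out["contact_share_pct"] = (
        100 * out["total_contacts"] / out["total_contacts"].sum()
    )
    return out.reset_index()


def classification_split(profiles: pd.DataFrame,
                         rna_class: str = "lncRNA") -> dict[str, float]:
    """Percentage of classified genes of one class per category."""
    sub = profiles[profiles["rna_class"] == rna_class]
    n = len(sub)
    if n == 0:
        return {"n": 0}
    counts = sub["classification"].value_counts()
    return {
        "n": n,
        "pct_cis_proximal": 100 * counts.get("cis_proximal", 0) / n,
        "pct_trans_acting": 100 * counts.get("trans_acting", 0) / n,
        "pct_unclassified": 100 * counts.get("unclassified", 0) / n,
    }


def detection_summary(
    profiles: pd.DataFrame | Iterable[GeneContactProfile],
    annotation: Annotation,
    rna_class: str = "lncRNA",
) -> tuple[int, int, float]:
    """(detected, annotated, percent) genes of a class with >= 1 contact."""
    if isinstance(profiles, pd.DataFrame):
        detected = set(
            profiles.loc[profiles["rna_class"] == rna_class, "gene_id"]
        )
    else:
        detected = {p.gene_id for p in profiles if p.rna_class == rna_class}
    annotated = len(annotation.by_class[rna_class])
    if annotated == 0:
        raise ValueError(f"no {rna_class} genes annotated")
    return len(detected), annotated, 100.0 * len(detected) / annotated


def distance_profile(
    gene: GeneRecord,
    contact_positions: Sequence[int] | np.ndarray,
    caps: Sequence[int] = DISTANCE_CAPS,
    bin_size: int = 1_000,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Histograms of |gene midpoint - contact start| for same-chromosome
    contacts, restricted to each cap around the locus.

    Returns ``{cap: (counts, bin_edges)}``; empty input yields all-zero
    histograms.
    """
    pos = np.asarray(contact_positions, dtype=np.int64)
    dist = np.abs(pos - gene.midpoint)
    out = {}
    for cap in caps:
        within = dist[dist <= cap]
        edges = np.arange(0, cap + bin_size, bin_size)
        counts, edges = np.histogram(within, bins=edges)
        out[cap] = (counts, edges)
    return out


def distances_from_locus(
    gene: GeneRecord, contact_positions: Sequence[int] | np.ndarray
) -> np.ndarray:
    """|midpoint(gene) - contact start| for same-chromosome contacts."""
    return np.abs(np.asarray(contact_positions, dtype=np.int64)
                  - gene.midpoint)


def concat_position(chrom: str, pos: int, genome: GenomeModel) -> int:
    """Global dot-plot coordinate of a chromosome position (both 1-based)."""
    return genome.concat_position(chrom, pos)


def invert_concat_position(global_pos: int,
                           genome: GenomeModel) -> tuple[str, int]:
    """Inverse of :func:`concat_position`."""
    return genome.invert_concat(global_pos)


@dataclass(frozen=True)
class UnkRegion:
    """A window of unannotated transcription: RNA-side contact pileup that
    overlaps no annotated gene."""

    chrom: str
    window_start: int  # 1-based
    window_end: int  # inclusive
    n_contacts: int


def detect_unk_regions(
    contacts: pd.DataFrame,
    annotation: Annotation,
    genome: GenomeModel,
    window: int = DEFAULT_WINDOW,
    min_contacts: int = 500,
    step: int | None = None,
) -> list[UnkRegion]:
    """Tile the genome into windows and report tiles that hold at least
    ``min_contacts`` RNA-side positions of unassigned contacts while
    overlapping no annotated gene.

    RNA-side (not DNA-side) positions define transcribed regions.  The
    default step equals the window (non-overlapping tiles).
    """
    if step is None:
        step = window
    unk = contacts[contacts["rna_gene_id"] == UNASSIGNED]
    regions: list[UnkRegion] = []
    for chrom in genome.names:
        sub = unk[unk["rna_chrom"].astype(str) == chrom]
        pos = np.sort(sub["rna_pos"].to_numpy())
        L = genome.lengths[chrom]
        for start0 in range(0, L, step):
            end0 = min(start0 + window, L)
            n = int(np.searchsorted(pos, end0, side="right")
                    - np.searchsorted(pos, start0 + 1, side="left"))
            if n < min_contacts:
                continue
            if annotation.overlapping(chrom, start0, end0):
                continue
            regions.append(UnkRegion(chrom=chrom, window_start=start0 + 1,
                                     window_end=end0, n_contacts=n))
    return regions


def unk_regions_to_bed(regions: Iterable[UnkRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.window_start - 1}\t{r.window_end}\t"
                     f"unkRNA\t{r.n_contacts}\t.\n")
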