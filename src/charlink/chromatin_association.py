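"""Epigenetic-mark association: binned RPKM coverage, contact-site sampling,
rank-sum tests and FDR control.

For each lncRNA with enough DNA-side contacts, the coverage of a mark (e.g.
H4K16ac) at its contact positions is compared against one shared sample of
random genomic background positions with a two-sided Mann-Whitney U test;
p-values are Benjamini-Hochberg adjusted across the tested set and the
direction (higher/lower coverage) is called from the sample medians when the
adjusted q falls below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel

DEFAULT_BIN = 50


@dataclass
class CoverageTrack:
    """Binned RPKM coverage: per-chromosome arrays of constant-width bins.

    Each read contributes to exactly one bin (the one holding its 5' start),
    so the RPKM values integrate back to the total read count:
    sum(value * bin_kb * total_reads/1e6) == total_reads up to rounding at
    chromosome-final partial bins.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    total_reads: int

    def bin_of(self, pos0: int) -> int:
        return pos0 // self.bin_size

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                for i, v in enumerate(arr):
                    if v == 0:
                        continue
                    fh.write(f"{chrom}\t{i * self.bin_size}\t"
                             f"{(i + 1) * self.bin_size}\t{v:.10g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome: GenomeModel,
                      bin_size: int = DEFAULT_BIN,
                      total_reads: int = 0) -> "CoverageTrack":
        values = {
            c: np.zeros(-(-genome.lengths[c] // bin_size))
            for c in genome.names
        }
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "#")):
                    continue
                chrom, start, _end, val = line.split("\t")
                values[chrom][int(start) // bin_size] = float(val)
        return cls(bin_size=bin_size, values=values, total_reads=total_reads)


def rpkm_track(
    read_intervals: pd.DataFrame | Iterable[tuple[str, int, int]],
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN,
) -> CoverageTrack:
    """Bin read starts and convert counts to RPKM.

    ``read_intervals`` are 0-based half-open (chrom, start, end); each read
    is assigned to the bin containing its 5' start.  RPKM = count /
    (bin_length_kb * total_reads_in_millions); an empty library yields an
    all-zero track with a warning.
    """
    if not isinstance(read_intervals, pd.DataFrame):
        read_intervals = pd.DataFrame(
            read_intervals, columns=["chrom", "start", "end"]
        )
    total = len(read_intervals)
    values = {}
    for chrom in genome.names:
        n_bins = -(-genome.lengths[chrom] // bin_size)
        sub = read_intervals[read_intervals["chrom"] == chrom]
        counts = np.bincount(
            sub["start"].to_numpy(dtype=np.int64) // bin_size,
            minlength=n_bins,
        ).astype(float)
        if counts.size > n_bins:
            raise ValueError(f"read start beyond chromosome {chrom}")
        values[chrom] = counts
    if total == 0:
        warnings.warn("zero mapped reads: RPKM track is all zero")
        return CoverageTrack(bin_size=bin_size, values=values, total_reads=0)
    denom = (bin_size / 1_000) * (total / 1_000_000)
    for chrom in values:
        values[chrom] /= denom
    return CoverageTrack(bin_size=bin_size, values=values, total_reads=total)


def coverage_at(
    track: CoverageTrack,
    positions: Iterable[tuple[str, int]] | tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """RPKM value of the bin containing each 0-based position (duplicates
    kept: three contacts in a bin contribute that value three times)."""
    if isinstance(positions, tuple) and len(positions) == 2 and not isinstance(
        positions[0], str
    ):
        chroms, pos = positions
        pairs = zip(np.asarray(chroms), np.asarray(pos, dtype=np.int64))
    else:
        pairs = positions
    out = []
    for chrom, p in pairs:
        arr = track.values.get(str(chrom))
        if arr is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        b = int(p) // track.bin_size
        if not 0 <= b < arr.size or p < 0:
            raise ValueError(f"position {p} outside {chrom}")
        out.append(arr[b])
    return np.asarray(out)


def sample_background(
    genome: GenomeModel,
    n: int = 100_000,
    seed: int = 0,
    restrict_to_assembled: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random 0-based positions over the genome (optionally only the
    assembled chromosomes); deterministic per seed.  Returns parallel arrays
    ``(chroms, positions)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = (genome.assembled_names if restrict_to_assembled
             else genome.names)
    lens = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    glob = rng.integers(0, offsets[-1], size=n)
    ci = np.searchsorted(offsets, glob, side="right") - 1
    return np.array(names, dtype=object)[ci], glob - offsets[ci]


def rank_sum_test(
    sample_a: Sequence[float] | np.ndarray,
    sample_b: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have <= 20
    observations and the data are tie-free, and the tie-corrected normal
    approximation (with continuity correction) otherwise.  Returns
    ``(U_of_sample_a, p_two_sided)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) \
        else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving with
    the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AssociationResult:
    """Coverage comparison of one lncRNA's contact sites vs background."""

    lncrna_id: str
    n_contacts: int
    contact_rpkm: np.ndarray
    background_rpkm: np.ndarray
    u_statistic: float
    p_raw: float
    q_bh: float = float("nan")
    direction: str = "none"

    @property
    def median_contact(self) -> float:
        return float(np.median(self.contact_rpkm))

    @property
    def median_background(self) -> float:
        return float(np.median(self.background_rpkm))


def associate(
    track: CoverageTrack,
    contacts: pd.DataFrame,
    lncrna_ids: Sequence[str],
    genome: GenomeModel,
    n_background: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_contacts: int = 100,
    restrict_to_assembled: bool = False,
    background: np.ndarray | None = None,
) -> list[AssociationResult]:
    """Test each lncRNA's contact-site coverage against one shared random
    background sample.

    lncRNAs with fewer than ``min_contacts`` DNA-side contacts are skipped
    with a warning (never silently tested).  BH adjustment runs across the
    set actually tested here (one track = one correction family); direction
    is called from medians only when q < alpha.
    """
    if background is None:
        bg_pos = sample_background(genome, n=n_background, seed=seed,
                                   restrict_to_assembled=restrict_to_assembled)
        background = coverage_at(track, bg_pos)
    results: list[AssociationResult] = []
    for lid in lncrna_ids:
        sub = contacts[contacts["rna_gene_id"] == lid]
        if len(sub) < min_contacts:
            warnings.warn(
                f"{lid}: only {len(sub)} contacts (< {min_contacts}); skipped"
            )
            continue
        sample = coverage_at(
            track,
            (sub["dna_chrom"].to_numpy(), sub["dna_pos"].to_numpy() - 1),
        )
        u, p = rank_sum_test(sample, background)
        results.append(
            AssociationResult(
                lncrna_id=lid, n_contacts=len(sub), contact_rpkm=sample,
                background_rpkm=background, u_statistic=u, p_raw=p,
            )
        )
    if not results:
        return results
    q = bh_adjust([r.p_raw for r in results])
    for r, qv in zip(results, q):
        r.q_bh = float(qv)
        if qv < alpha:
            if r.median_contact > r.median_background:
                r.direction = "higher"
            elif r.median_contact < r.median_background:
                r.direction = "lower"
            else:  # tie on medians: fall back to mean shift
                r.direction = ("higher" if r.contact_rpkm.mean()
                               > r.background_rpkm.mean() else "lower")
    return results


def association_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "lncrna_id": r.lncrna_id,
            "n_contacts": r.n_contacts,
            "median_contact_rpkm": r.median_contact,
            "median_background_rpkm": r.median_background,
            "u_statistic": r.u_statistic,
            "p_raw": r.p_raw,
            "q_bh": r.q_bh,
            "direction": r.direction,
        }
        for r in results
    ])
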