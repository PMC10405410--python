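"""Promoter-contact target calling and target-set expression comparison.

A gene is a putative target of a trans-acting lncRNA when at least one of the
lncRNA's DNA-side contacts falls within +-5 kb of the gene's transcription
start site (TSS: span start for '+' genes, span end for '-'); the lncRNA
itself is never its own target.  Expression of two target sets is compared
with the Mann-Whitney U test on TPM values from a gene x tissue matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation
from .chromatin_association import bh_adjust, rank_sum_test

DEFAULT_PROMOTER_WINDOW = 5_000


@dataclass(frozen=True)
class TargetCall:
    lncrna_id: str
    target_gene_id: str
    target_class: str
    contact_count_at_promoter: int


def _target_class(rna_class: str) -> str:
    return "protein_coding" if rna_class == "mRNA" else rna_class


def call_targets(
    contacts: pd.DataFrame,
    lncrna_id: str,
    annotation: Annotation,
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[TargetCall]:
    """Genes with >= 1 of the lncRNA's DNA-side contacts within TSS +-
    ``window`` (inclusive at both ends).  Idempotent and order-independent;
    results are sorted by gene id."""
    if lncrna_id not in annotation:
        raise KeyError(f"unknown lncRNA {lncrna_id!r}")
    sub = contacts[contacts["rna_gene_id"] == lncrna_id]
    chroms = sub["dna_chrom"].astype(str).to_numpy()
    pos = sub["dna_pos"].to_numpy(dtype=np.int64)
    calls = []
    for g in annotation:
        if g.gene_id == lncrna_id:
            continue
        m = (chroms == g.chrom) & (np.abs(pos - g.tss) <= window)
        n = int(m.sum())
        if n:
            calls.append(
                TargetCall(
                    lncrna_id=lncrna_id,
                    target_gene_id=g.gene_id,
                    target_class=_target_class(g.rna_class),
                    contact_count_at_promoter=n,
                )
            )
    return sorted(calls, key=lambda c: c.target_gene_id)


def targets_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


@dataclass
class ComparisonResult:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_raw: float
    q_bh: float


def compare_target_expression(
    tpm_matrix: pd.DataFrame,
    set_a_genes: Sequence[str],
    set_b_genes: Sequence[str],
    mode: str = "per_gene_median",
    min_tissues: int = 2,
) -> ComparisonResult:
    """Rank-sum comparison of the expression of two target-gene sets.

    The default comparison unit is each gene's median TPM across tissues,
    which keeps the test calibrated (TPM values of one gene across tissues
    are correlated, so pooling them as independent observations is
    anticonservative); ``mode="pooled"`` pools all gene x tissue values
    instead.  Genes absent from the matrix raise with their names; fewer
    than ``min_tissues`` tissue columns refuses (n too small for a
    tissue-pooled expression summary).
    """
    if tpm_matrix.shape[1] < min_tissues:
        raise ValueError(
            f"matrix has {tpm_matrix.shape[1]} tissue column(s); "
            f"need at least {min_tissues} (n too small)"
        )
    if mode not in ("per_gene_median", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = []
    for label, genes in (("a", set_a_genes), ("b", set_b_genes)):
        genes = list(genes)
        if not genes:
            raise ValueError(f"target set {label} is empty")
        missing = [g for g in genes if g not in tpm_matrix.index]
        if len(missing) == len(genes):
            raise ValueError(
                f"no genes of set {label} in the matrix; missing: "
                f"{missing[:5]}"
            )
        present = [g for g in genes if g in tpm_matrix.index]
        values = tpm_matrix.loc[present]
        if mode == "per_gene_median":
            samples.append(values.median(axis=1).to_numpy())
        else:
            samples.append(values.to_numpy().ravel())
    a, b = samples
    u, p = rank_sum_test(a, b)
    return ComparisonResult(
        n_a=a.size, n_b=b.size,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        u_statistic=u, p_raw=p, q_bh=p,
    )


def compare_target_sets(
    tpm_matrix: pd.DataFrame,
    comparisons: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    mode: str = "per_gene_median",
) -> pd.DataFrame:
    """Run several named set-vs-set comparisons and BH-adjust across them."""
    rows = {}
    for name, (a, b) in comparisons.items():
        rows[name] = compare_target_expression(tpm_matrix, a, b, mode=mode)
    q = bh_adjust([r.p_raw for r in rows.values()])
    out = []
    for (name, r), qv in zip(rows.items(), q):
        r.q_bh = float(qv)
        out.append({"comparison": name, **r.__dict__})
    return pd.DataFrame(out)
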