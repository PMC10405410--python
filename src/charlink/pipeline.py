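"""Stage orchestration and canonical simulation experiments.

Two kinds of entry points live here.  The ``*_experiment`` functions encode
the package's reference study conditions (genome shape, annotation size,
planted mixtures) and run the relevant slice of the pipeline at desk scale;
they are what the test suite and the reproduction script call.
:func:`run_pipeline` is the file-level orchestrator behind ``charlink run``:
simulate -> parse -> map -> stats -> classify -> chip-assoc -> targets, with
every stage writing its plain-text table into the output directory and a
deterministic JSON report at the end.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import (
    bridge_parser,
    chromatin_association as chip,
    contact_statistics as cstats,
    expression_targets,
    fragment_mapper,
    synthetic_data as synth,
)
from .annotation import Annotation
from .genome import GenomeModel


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), int(stage)])
               .generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# canonical experiments (study conditions used by tests and the
# reproduction script)
# ---------------------------------------------------------------------------

def classification_experiment(
    seed: int,
    n_cis: int = 1_040,
    n_trans: int = 148,
    contacts_per_gene: int = 200,
    p_cis: float = 0.9,
    p_trans: float = 0.9,
) -> dict[str, Any]:
    """Plant cis/trans lncRNA contacts and recover the classification split.

    The default population mirrors the reference lncRNA set analysed on the
    macro-chromosomes: 1,188 lncRNAs of which 1,040 are planted cis-proximal
    and 148 trans-acting, >= 200 contacts each.
    """
    n_lnc = n_cis + n_trans
    genome = synth.make_genome(stage_seed(seed, 0), n_assembled=6,
                               assembled_lengths=500_000, n_scaffolds=4)
    annotation = synth.make_annotation(
        genome, stage_seed(seed, 1), class_counts={"lncRNA": n_lnc},
    )
    lnc_ids = [g.gene_id for g in annotation.by_class["lncRNA"]]
    assignment = {
        gid: ("cis_proximal" if i < n_cis else "trans_acting")
        for i, gid in enumerate(lnc_ids)
    }
    truth = synth.plant_contacts(
        annotation, genome, stage_seed(seed, 2),
        lncrna_class_assignment=assignment,
        per_gene_counts={gid: contacts_per_gene for gid in lnc_ids},
        p_cis=p_cis, p_trans=p_trans,
    )
    contacts = truth_as_contacts(truth)
    profiles = cstats.gene_profiles(contacts, annotation, genome)
    split = cstats.classification_split(profiles, "lncRNA")
    planted = pd.Series(assignment)
    called = profiles.set_index("gene_id")["classification"].reindex(
        planted.index)
    accuracy = float((called == planted).mean())
    return {
        "n_lncrnas": n_lnc,
        "pct_cis_proximal": split["pct_cis_proximal"],
        "pct_trans_acting": split["pct_trans_acting"],
        "pct_unclassified": split["pct_unclassified"],
        "planted_accuracy": accuracy,
        "profiles": profiles,
    }


def detection_experiment(
    seed: int,
    n_annotated: int = 3_176,
    n_detected: int = 2_282,
    contacts_per_detected: int = 3,
) -> dict[str, Any]:
    """Plant contacts for a subset of annotated lncRNAs and report the
    detected percentage (genes with >= 1 contact)."""
    genome = synth.make_genome(stage_seed(seed, 0), n_assembled=6,
                               assembled_lengths=1_000_000, n_scaffolds=4)
    annotation = synth.make_annotation(
        genome, stage_seed(seed, 1), class_counts={"lncRNA": n_annotated},
    )
    lnc_ids = [g.gene_id for g in annotation.by_class["lncRNA"]]
    rng = np.random.default_rng(stage_seed(seed, 2))
    subset = list(rng.choice(lnc_ids, size=n_detected, replace=False))
    truth = synth.plant_contacts(
        annotation, genome, stage_seed(seed, 3),
        per_gene_counts={gid: contacts_per_detected for gid in subset},
    )
    contacts = truth_as_contacts(truth)
    profiles = cstats.gene_profiles(contacts, annotation, genome)
    detected, annotated, pct = cstats.detection_summary(
        profiles, annotation, "lncRNA")
    return {"n_detected": detected, "n_annotated": annotated,
            "pct_detected": pct}


def composition_experiment(
    seed: int,
    n_contacts: int = 1_000_000,
    error_rate: float = 0.0,
    class_counts: Mapping[str, int] | None = None,
) -> dict[str, Any]:
    """Full reads -> parse -> map -> tally run under the default liver
    mixture; reports per-class contact shares among gene-assigned valid
    contacts together with the planted truth shares."""
    if class_counts is None:
        class_counts = {"rRNA": 3, "msrpRNA": 3, "snRNA": 70, "snoRNA": 33,
                        "lncRNA": 300, "mRNA": 400}
    genome = synth.make_genome(stage_seed(seed, 0), n_assembled=6,
                               assembled_lengths=200_000, n_scaffolds=4)
    annotation = synth.make_annotation(
        genome, stage_seed(seed, 1), class_counts=class_counts,
        length_ranges={"lncRNA": (200, 1_000), "mRNA": (300, 1_200),
                       "rRNA": (1_200, 2_500)},
    )
    truth = synth.plant_contacts(
        annotation, genome, stage_seed(seed, 2), n_contacts=n_contacts,
    )
    reads = synth.iter_bridge_reads(
        truth, genome, stage_seed(seed, 3), annotation=annotation,
        error_rate=error_rate,
    )
    stats = bridge_parser.ParseStats()
    fragments = bridge_parser.parse_pairs(reads, stats=stats)
    contacts, map_stats = fragment_mapper.build_contacts(
        fragments, genome, annotation)
    from .annotation import RNA_CLASSES

    assigned = contacts[contacts["rna_gene_id"] != "unassigned"]
    shares = {
        str(k): float(v) for k, v in
        (100 * assigned["rna_class"].value_counts(normalize=True)).items()
        if str(k) in RNA_CLASSES
    }
    t = truth.table
    t_assigned = t[t["gene_id"] != "intergenic"]
    truth_shares = {
        str(k): float(v) for k, v in
        (100 * t_assigned["rna_class"].value_counts(normalize=True)).items()
        if str(k) in RNA_CLASSES
    }
    return {
        "n_truth": len(t),
        "n_valid": len(contacts),
        "n_assigned": len(assigned),
        "shares_pct": shares,
        "truth_shares_pct": truth_shares,
        "parse_stats": stats,
        "map_stats": map_stats,
        "contacts": contacts,
        "truth": truth,
        "genome": genome,
        "annotation": annotation,
    }


def association_experiment(
    seed: int,
    effect: str = "enriched",
    effect_size: float = 8.0,
    n_lncrnas: int = 6,
    contacts_per_gene: int = 250,
    n_chip_reads: int = 120_000,
    n_background: int = 4_000,
    halfwidth: int = 100,
    alpha: float = 0.05,
):
    """Plant a coverage effect at one trans-acting lncRNA's contact sites
    and run the association test over all lncRNAs.

    ``effect`` is ``enriched``, ``depleted`` or ``null`` (no planted effect;
    ``effect_size`` ignored).  The genome is kept large relative to the
    planted effect windows (narrow ``halfwidth``) so that the uniform random
    background stays representative of the other lncRNAs' trans contacts.
    Returns ``(results, target_id)``.
    """
    genome = synth.make_genome(stage_seed(seed, 0), n_assembled=6,
                               assembled_lengths=200_000, n_scaffolds=2)
    annotation = synth.make_annotation(
        genome, stage_seed(seed, 1),
        class_counts={"lncRNA": n_lncrnas, "mRNA": 20},
    )
    lnc = [g.gene_id for g in annotation.by_class["lncRNA"]]
    truth = synth.plant_contacts(
        annotation, genome, stage_seed(seed, 2),
        per_gene_counts={gid: contacts_per_gene for gid in lnc},
        lncrna_class_assignment={gid: "trans_acting" for gid in lnc},
    )
    contacts = truth_as_contacts(truth)
    target = lnc[0]
    sites = [
        (str(r.dna_chrom), int(r.dna_pos))
        for r in contacts[contacts["rna_gene_id"] == target].itertuples()
    ]
    kwargs = dict(n_reads=n_chip_reads, halfwidth=halfwidth)
    if effect == "enriched":
        kwargs.update(contact_sites_enriched=sites, effect_size=effect_size)
    elif effect == "depleted":
        kwargs.update(contact_sites_depleted=sites, effect_size=effect_size)
    elif effect != "null":
        raise ValueError(f"unknown effect {effect!r}")
    _reads, track = synth.emit_coverage_track(genome, stage_seed(seed, 3),
                                              **kwargs)
    results = chip.associate(track, contacts, lnc, genome,
                             n_background=n_background,
                             seed=stage_seed(seed, 4), alpha=alpha,
                             min_contacts=100)
    return results, target


def truth_as_contacts(truth: synth.ContactTruth,
                      replicate_id: str = "rep1") -> pd.DataFrame:
    """View a truth table as a contact table (the planted contacts as the
    pipeline would recover them at zero error)."""
    t = truth.table
    return pd.DataFrame({
        "read_id": t["read_id"],
        "rna_gene_id": t["gene_id"].where(t["gene_id"] != "intergenic",
                                          "unassigned"),
        "rna_class": t["rna_class"],
        "rna_chrom": t["rna_chrom"],
        "rna_pos": t["rna_pos"],
        "dna_chrom": t["dna_chrom"],
        "dna_pos": t["dna_pos"],
        "replicate": replicate_id,
    })


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full run; every threshold is echoed into the
    report for provenance."""

    seed: int = 0
    outdir: str = "charlink_out"
    genome: dict = field(default_factory=lambda: {
        "n_assembled": 6, "assembled_lengths": 100_000, "n_scaffolds": 4,
    })
    annotation: dict = field(default_factory=lambda: {
        "class_counts": {"rRNA": 3, "msrpRNA": 3, "snRNA": 20, "snoRNA": 10,
                         "lncRNA": 60, "mRNA": 80},
    })
    contacts: dict = field(default_factory=lambda: {"n_contacts": 20_000})
    reads: dict = field(default_factory=dict)
    chip: dict = field(default_factory=lambda: {
        "n_reads": 50_000, "effect_size": 6.0, "n_enriched_lncrnas": 1,
    })
    expression: dict = field(default_factory=lambda: {"group_fold": 4.0})
    thresholds: dict = field(default_factory=lambda: {
        "min_fragment_len": 18, "cis_window": 10_000, "unk_window": 10_000,
        "unk_min_contacts": 50, "alpha": 0.05, "n_background": 5_000,
        "assoc_min_contacts": 100,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the toggled stages end to end and write the summary report.

    Every number in the report is read back from a TSV written by a stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    th = config.thresholds

    # -- simulate ---------------------------------------------------------
    genome = synth.make_genome(stage_seed(seed, 0), **config.genome)
    genome.to_fasta(out / "genome.fa")
    annotation = synth.make_annotation(genome, stage_seed(seed, 1),
                                       **config.annotation)
    annotation.to_gff3(out / "annotation.gff3")
    truth = synth.plant_contacts(annotation, genome, stage_seed(seed, 2),
                                 **config.contacts)
    truth.to_tsv(out / "truth.tsv")
    n_pairs = synth.emit_bridge_reads(
        truth, genome, stage_seed(seed, 3), out / "reads_1.fq",
        out / "reads_2.fq", annotation=annotation, **config.reads)

    # -- parse ------------------------------------------------------------
    parse_stats = bridge_parser.parse_fastq(
        out / "reads_1.fq", out / "reads_2.fq", out / "rna.fq",
        out / "dna.fq", audit=out / "parse_audit.tsv",
        min_len=th["min_fragment_len"])

    # -- map + join -------------------------------------------------------
    fragments = (
        bridge_parser.FragmentPair(r1.name, r1.sequence, r2.sequence,
                                   "forward")
        for r1, r2 in _paired_fastx(out / "rna.fq", out / "dna.fq")
    )
    contacts, map_stats = fragment_mapper.build_contacts(
        fragments, genome, annotation)
    fragment_mapper.write_contacts(contacts, out / "contacts.tsv")

    # -- stats + classify -------------------------------------------------
    profiles = cstats.gene_profiles(contacts, annotation, genome,
                                    window=th["cis_window"])
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    summary = cstats.class_summary(profiles)
    summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    split = cstats.classification_split(profiles, "lncRNA")
    unk = cstats.detect_unk_regions(
        contacts, annotation, genome, window=th["unk_window"],
        min_contacts=th["unk_min_contacts"])
    cstats.unk_regions_to_bed(unk, out / "unk_regions.bed")

    # -- chip association -------------------------------------------------
    lnc_profiles = profiles[profiles["rna_class"] == "lncRNA"]
    top = lnc_profiles.sort_values(
        ["total_contacts", "gene_id"], ascending=[False, True]
    )["gene_id"].head(8).tolist()
    n_enriched = int(config.chip.get("n_enriched_lncrnas", 1))
    enriched_ids = top[:n_enriched]
    sites = [
        (str(r.dna_chrom), int(r.dna_pos))
        for lid in enriched_ids
        for r in contacts[contacts["rna_gene_id"] == lid].itertuples()
    ]
    chip_reads, track = synth.emit_coverage_track(
        genome, stage_seed(seed, 4), contact_sites_enriched=sites,
        effect_size=float(config.chip.get("effect_size", 6.0)),
        n_reads=int(config.chip.get("n_reads", 50_000)),
        bed=out / "chip_reads.bed", bedgraph=out / "chip.bedgraph")
    results = chip.associate(
        track, contacts, top, genome,
        n_background=th["n_background"], seed=stage_seed(seed, 5),
        alpha=th["alpha"], min_contacts=th["assoc_min_contacts"])
    assoc = chip.association_frame(results)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)

    # -- targets + expression --------------------------------------------
    trans_ids = lnc_profiles[
        lnc_profiles["classification"] == "trans_acting"]["gene_id"].tolist()
    target_rows = []
    for lid in trans_ids[:5]:
        target_rows.extend(expression_targets.call_targets(
            contacts, lid, annotation))
    targets = expression_targets.targets_frame(target_rows)
    targets.to_csv(out / "targets.tsv", sep="\t", index=False)
    gene_ids = [g.gene_id for g in annotation]
    target_set = sorted({c.target_gene_id for c in target_rows})
    rng = np.random.default_rng(stage_seed(seed, 6))
    assign = {g: ("high" if g in set(target_set) else "low")
              for g in gene_ids}
    tpm = synth.emit_tpm_matrix(
        gene_ids, stage_seed(seed, 7), group_assignment=assign,
        group_fold=float(config.expression.get("group_fold", 4.0)),
        path=out / "tpm.tsv")
    expr_report: dict[str, Any] = {}
    other = [g for g in gene_ids if g not in set(target_set)]
    if target_set and other:
        cmp_res = expression_targets.compare_target_expression(
            tpm, target_set, other)
        pd.DataFrame([cmp_res.__dict__]).to_csv(
            out / "expression_comparison.tsv", sep="\t", index=False)
        expr_report = {"p_raw": cmp_res.p_raw,
                       "median_target": cmp_res.median_a,
                       "median_other": cmp_res.median_b}

    # -- report -----------------------------------------------------------
    summary_read = pd.read_csv(out / "class_summary.tsv", sep="\t")
    report = {
        "config": {
            "seed": seed,
            "thresholds": dict(th),
            "genome": dict(config.genome),
            "annotation": {"class_counts":
                           dict(config.annotation["class_counts"])},
            "contacts": dict(config.contacts),
        },
        "reads": {"pairs": n_pairs, **parse_stats.__dict__},
        "mapping": map_stats.__dict__,
        "class_composition": summary_read.to_dict(orient="records"),
        "lncrna_classification": split,
        "unk_regions": len(unk),
        "association": assoc.to_dict(orient="records"),
        "expression": expr_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_safe)
        fh.write("\n")
    return report


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _paired_fastx(path1, path2):
    import pysam

    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        yield from zip(f1, f2)
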