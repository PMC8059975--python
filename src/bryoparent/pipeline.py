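"""End-to-end reproducible runs: simulate -> demultiplex -> trim ->
genotype -> assign -> tabulate -> statistics.

A :class:`RunConfig` carries every knob of a run (panel, design,
sequencing, processing thresholds); a single seed fans out to per-stage
child streams so reruns are byte-identical and stages individually
rerunnable. ``run_pipeline`` returns a manifest of per-stage record counts
and artifact hashes, and can optionally skip writing intermediates for
large in-memory evaluations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotyping import AmpliconIndex, genotype_pool
from .io import ensure_dir, write_tsv
from .util import sha256_file
from .panel import ParentPanel
from .parentage import (
    CLASS_RESOLVED,
    RESOLVED,
    UnknownRegistry,
    assignments_frame,
    match_pool,
    tabulate_crosses,
)
from .preprocess import SampleSheet, demultiplex, trim_batch
from .stats import anova, chisq_genotype_success, ks_fit, stats_report, treatment_count_test
from .synth import (
    DispersalKernel,
    MesocosmDesign,
    QualityModel,
    make_sample_sheet,
    simulate_crosses,
    simulate_panel,
    simulate_pool_reads,
    simulate_traits,
    truth_frame,
)
from .util import child_seed

_STAGE_POOL = 7


@dataclass
class RunConfig:
    """Everything needed to reproduce one synthetic mesocosm run."""

    seed: int = 0
    # panel
    n_males: int = 6
    n_females: int = 9
    n_loci: int = 5
    locus_length: int = 300
    snps_per_locus: int = 3
    force_ambiguous_female_pair: bool = False
    # design
    n_mesocosms_per_treatment: int = 8
    n_sporophytes: int | float = 100
    treatment_effect: float = 839 / 228
    disc_radius: float = 5.25
    pot_radius: float = 18.0
    kernel_family: str = "lognormal"
    kernel_mu: float = 2.3
    kernel_sigma: float = 0.4
    # sequencing
    depth_per_locus: int = 100
    read_length: int = 250
    paired: bool = True
    substitution_error: float = 0.005
    index_error_rate: float = 0.001
    quality_q_start: float = 38.0
    quality_q_end: float = 32.0
    # processing thresholds
    trim_window: int = 10
    trim_min_q: int = 30
    trim_min_len: int = 50
    max_index_mismatch: int = 1
    min_identity: float = 0.9
    min_minor_frac: float = 0.2
    min_site_depth: int = 10
    min_depth: int = 25
    max_hap_mismatch: int = 0
    min_overlap: int = 3

    def validate(self) -> None:
        if not 0 <= self.substitution_error < 0.25:
            raise ValueError("substitution_error outside [0, 0.25)")
        if self.min_depth < 1 or self.trim_window < 1:
            raise ValueError("thresholds out of range")
        if self.max_index_mismatch < 0 or self.max_hap_mismatch < 0:
            raise ValueError("mismatch tolerances must be >= 0")

    # TOML round trip -----------------------------------------------------

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# bryoparent run configuration\n")
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, bool):
                    fh.write(f"{f.name} = {str(v).lower()}\n")
                elif isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                else:
                    fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def study_mimic_config(seed: int = 0, **overrides) -> RunConfig:
    """The default experiment-like configuration: 9 females, 6 males,
    5 loci x 3 diagnostic SNPs, 2 x 8 mesocosms, paired 2x250 bp reads."""
    return RunConfig(seed=seed, **overrides)


def _build_design(cfg: RunConfig, panel: ParentPanel) -> MesocosmDesign:
    return MesocosmDesign(
        female_ids=panel.females(),
        male_ids=panel.males(),
        dispersal=DispersalKernel(cfg.kernel_family, cfg.kernel_mu, cfg.kernel_sigma),
        n_sporophytes=cfg.n_sporophytes,
        treatment_effect=cfg.treatment_effect,
        n_mesocosms_per_treatment=cfg.n_mesocosms_per_treatment,
        disc_radius=cfg.disc_radius,
        pot_radius=cfg.pot_radius,
    )


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    write_artifacts: bool = True,
    design: MesocosmDesign | None = None,
) -> dict:
    """Execute every stage and return the run manifest.

    The manifest records the package version, seed, per-stage record
    counts, assignment-status tallies, headline statistics and (when
    artifacts are written) the sha256 of every output file.
    """
    config.validate()
    stage = "panel"
    try:
        panel = simulate_panel(
            config.n_males, config.n_females, config.n_loci, config.locus_length,
            config.snps_per_locus, config.force_ambiguous_female_pair,
            seed=child_seed(config.seed, 11),
        )
        stage = "crosses"
        if design is None:
            design = _build_design(config, panel)
        truth = simulate_crosses(panel, design, seed=child_seed(config.seed, 12))
        stage = "sample_sheet"
        sheet_frame = make_sample_sheet(truth, seed=child_seed(config.seed, 13))
        sheet = SampleSheet(sheet_frame)
        index_of = {
            r.sample_id: (r.i5_index, r.i7_index) for r in sheet_frame.itertuples()
        }

        stage = "reads"
        quality = QualityModel(config.quality_q_start, config.quality_q_end)
        batches, sidecars = [], []
        for t in truth:
            b, sc = simulate_pool_reads(
                panel, t,
                depth_per_locus=config.depth_per_locus,
                read_length=config.read_length,
                substitution_error=config.substitution_error,
                quality=quality,
                index_pair=index_of[t.sporophyte_id],
                index_error_rate=config.index_error_rate,
                seed=child_seed(config.seed, _STAGE_POOL, int(t.sporophyte_id[1:])),
                paired=config.paired,
            )
            batches.append(b)
            sidecars.append(sc)
        from .io import ReadBatch

        reads = ReadBatch.concat(batches)
        sidecar = pd.concat(sidecars, ignore_index=True) if sidecars else pd.DataFrame()

        stage = "demultiplex"
        bins, demux_report = demultiplex(reads, sheet, max_mismatch=config.max_index_mismatch)

        stage = "trim"
        trimmed: dict[str, object] = {}
        n_dropped = 0
        for t in truth:
            kept, dropped = trim_batch(
                bins[t.sporophyte_id],
                window=config.trim_window,
                min_mean_q=config.trim_min_q,
                min_len=config.trim_min_len,
            )
            trimmed[t.sporophyte_id] = kept
            n_dropped += dropped

        stage = "genotyping"
        index = AmpliconIndex(panel.loci)
        registry = UnknownRegistry()
        assignments = []
        haplotype_rows = []
        for t in truth:
            pools = genotype_pool(
                trimmed[t.sporophyte_id], panel.loci,
                min_identity=config.min_identity,
                min_minor_frac=config.min_minor_frac,
                min_site_depth=config.min_site_depth,
                min_depth=config.min_depth,
                index=index,
            )
            pairs = {locus_id: pair for locus_id, (pair, _) in pools.items()}
            stage = "parentage"
            assignments.append(
                match_pool(
                    t.sporophyte_id, pairs, panel,
                    max_mismatch=config.max_hap_mismatch,
                    min_overlap=config.min_overlap,
                    unknown_registry=registry,
                )
            )
            for locus_id, pair in pairs.items():
                for label, hap in (("hapA", pair.hap_a), ("hapB", pair.hap_b)):
                    haplotype_rows.append(
                        {"id": f"{t.sporophyte_id}|{locus_id}|{label}", "seq": hap}
                    )
            stage = "genotyping"

        stage = "tabulate"
        table = tabulate_crosses(assignments, sheet_frame)

        stage = "stats"
        stat_results = []
        stats_notes = []
        tf = truth_frame(truth)
        resolved_counts = table.counts
        try:
            if len(resolved_counts) and resolved_counts["count"].sum() >= 2:
                stat_results.append(
                    chisq_genotype_success(table, "father", genotypes=panel.males())
                )
                mother_levels = sorted(
                    {m for m in resolved_counts["mother"]}
                )
                if len(mother_levels) >= 2:
                    stat_results.append(chisq_genotype_success(table, "mother",
                                                               genotypes=mother_levels))
                per_mes = _per_mesocosm_counts(tf, config)
                stat_results.append(treatment_count_test(per_mes))
                if len(tf) >= 5:
                    stat_results.append(ks_fit(tf["distance_cm"], "lognormal",
                                               seed=child_seed(config.seed, 31)))
            else:
                stats_notes.append("insufficient data for statistics")
        except ValueError as exc:
            stats_notes.append(f"statistics skipped: {exc}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    status_tally: dict[str, int] = {}
    for a in assignments:
        status_tally[a.status] = status_tally.get(a.status, 0) + 1

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": {
            "parents": len(panel.parents),
            "loci": len(panel.loci),
            "sporophytes": len(truth),
            "reads": reads.n,
            "reads_demultiplexed": int(
                demux_report.loc[demux_report["sample_id"] != "undetermined", "n_reads"].sum()
            ),
            "reads_undetermined": int(
                demux_report.loc[demux_report["sample_id"] == "undetermined", "n_reads"].iloc[0]
            ),
            "reads_dropped_by_trimming": n_dropped,
            "assignments": len(assignments),
            "cross_table_total": int(table.counts["count"].sum()) if len(table.counts) else 0,
        },
        "assignment_status": status_tally,
        "stats_notes": stats_notes,
        "statistics": [
            {"test": r.test, "statistic": r.statistic, "df": str(r.df), "p": r.p_value}
            for r in stat_results
        ],
    }

    if write_artifacts and out_dir is not None:
        out = ensure_dir(out_dir)
        panel.write(out / "panel")
        write_tsv(tf, out / "truth.tsv")
        sheet.to_tsv(out / "sample_sheet.tsv")
        if reads.n:
            r1 = reads.subset(reads.mate != 2) if reads.mate is not None else reads
            r1.to_fastq(out / "reads_R1.fastq")
            if reads.mate is not None and (reads.mate == 2).any():
                reads.subset(reads.mate == 2).to_fastq(out / "reads_R2.fastq")
        write_tsv(sidecar, out / "read_truth_sidecar.tsv")
        write_tsv(demux_report, out / "demux_report.tsv")
        write_tsv(assignments_frame(assignments), out / "assignments.tsv")
        table.to_tsv(out / "cross_table.tsv")
        write_tsv(stats_report(stat_results), out / "stats.tsv")
        with open(out / "haplotypes.fasta", "w") as fh:
            for row in haplotype_rows:
                fh.write(f">{row['id']}\n{row['seq']}\n")
        config.to_toml(out / "run_config.toml")
        manifest["artifacts"] = {
            p.name: sha256_file(p) for p in sorted(out.rglob("*")) if p.is_file()
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    manifest["_objects"] = {
        "panel": panel,
        "truth": truth,
        "sheet": sheet_frame,
        "assignments": assignments,
        "cross_table": table,
        "stat_results": stat_results,
    }
    return manifest


def _per_mesocosm_counts(tf: pd.DataFrame, config: RunConfig):
    counts = tf.groupby(["mesocosm_id", "treatment"]).size().reset_index(name="count")
    # mesocosms with zero sporophytes still count as zeros
    rows = []
    for arm, prefix in (("arthropod", "A"), ("control", "C")):
        for i in range(config.n_mesocosms_per_treatment):
            mid = f"{prefix}{i + 1}"
            hit = counts[counts["mesocosm_id"] == mid]
            rows.append((arm, int(hit["count"].iloc[0]) if len(hit) else 0))
    return rows


def compare_to_truth(manifest: dict) -> dict:
    """Score a run against its own simulator truth.

    Counts sporophytes resolved to exactly the true (mother, father) —
    treating a class-resolved mother as correct iff the true mother is a
    member of the class — and, crucially, sporophytes resolved to a WRONG
    parent, which the method is designed never to produce (errors may only
    demote a call to ambiguous/unknown).
    """
    panel: ParentPanel = manifest["_objects"]["panel"]
    truth = manifest["_objects"]["truth"]
    assignments = manifest["_objects"]["assignments"]
    truth_by_id = {t.sporophyte_id: t for t in truth}
    n_correct = n_wrong = n_unresolved = 0
    for a in assignments:
        t = truth_by_id[a.sporophyte_id]
        if a.status == RESOLVED:
            ok = a.mother == t.mother_id and a.father == t.father_id
        elif a.status == CLASS_RESOLVED:
            ok = _class_match(a.mother, t.mother_id, panel) and _class_match(
                a.father, t.father_id, panel
            )
        else:
            n_unresolved += 1
            continue
        if ok:
            n_correct += 1
        else:
            n_wrong += 1
    return {
        "n_sporophytes": len(assignments),
        "n_correct": n_correct,
        "n_wrong_parent": n_wrong,
        "n_unresolved": n_unresolved,
        "fraction_correct": n_correct / len(assignments) if assignments else float("nan"),
    }


def _class_match(called: str, true_parent: str, panel: ParentPanel) -> bool:
    if called == true_parent:
        return True
    return panel.ambiguity_class_of(true_parent) == called
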