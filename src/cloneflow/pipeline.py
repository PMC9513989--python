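"""End-to-end orchestration: simulate -> profile -> ccf -> cluster -> evolve -> sc -> cnv.

One :class:`RunConfig` (YAML-loadable) drives the whole pipeline; a single
seed fans out to per-stage child seeds so any stage is reproducible in
isolation, and identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ccf as ccf_mod
from .clustering import assign_clusters, select_k
from .evolution import build_tree, classify_timing, fishplot_table
from .io_formats import count_matrices, variants_to_frame, write_cell_counts, write_cnv_segments, write_variant_vcf
from .profiles import build_category_table, burden_per_mb, spectrum_table, vaf_concordance
from .single_cell import CellGenotypeMatrix, CloneAssigner, mutated_cell_fraction
from .cnv import fraction_from_ratio
from .synthetic import SimulationConfig, simulate_cohort
from .io_formats import RegionIndex

logger = logging.getLogger("cloneflow")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Run configuration for the full pipeline.

    All thresholds carry the defaults used throughout the package; unknown
    keys in a YAML file are rejected rather than silently ignored.
    """

    outdir: str = "cloneflow_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    depth_min: int = 5
    vaf_min: float = 0.05
    eps: float = 0.05
    present_thresh: float = 0.10
    absent_thresh: float = 0.02
    min_cluster_size: int = 3
    k_min: int = 1
    k_max: int = 8
    restarts: int = 10
    callable_genome_mb: float = 2800.0

    def __post_init__(self) -> None:
        if not 0 <= self.absent_thresh < self.present_thresh <= 1:
            raise ValueError("need 0 <= absent_thresh < present_thresh <= 1")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.depth_min < 0 or not 0 <= self.vaf_min <= 1 or self.eps < 0:
            raise ValueError("threshold out of domain")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated cohort and write all outputs.

    Returns the run report: per-stage output files with row counts, the
    selected number of clonal groups, the tree edge list and timing
    classes.  On a stage failure the report records the failing stage and
    downstream stages are skipped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "outputs": {}, "failed_stage": None}
    child = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("simulate", "cluster"), np.random.SeedSequence(config.seed).spawn(2)
        )
    }

    def emit(stage: str, name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=True)
        report["outputs"][name] = {"stage": stage, "rows": int(len(df))}
        return path

    # --- simulate ---------------------------------------------------------
    try:
        sim = SimulationConfig(**{**config.simulation, "seed": child["simulate"]})
        truth, records, single_cells, cnvs = simulate_cohort(sim)
        manifest = sim.sample_manifest()
        sample_ids = [m.sample_id for m in manifest]
        write_variant_vcf(outdir / "variants.vcf", records, manifest)
        report["outputs"]["variants.vcf"] = {"stage": "simulate", "rows": len(records)}
        emit("simulate", "truth_prevalence.tsv", truth.prevalence)
        emit(
            "simulate",
            "truth_clones.tsv",
            pd.DataFrame(
                {"variant_id": truth.mutation_ids, "clone": truth.clone_of_mutation}
            ).set_index("variant_id"),
        )
        for stage_name, (alt, tot, labels) in single_cells.items():
            write_cell_counts(outdir / f"cells_{stage_name}.tsv", alt, tot)
            report["outputs"][f"cells_{stage_name}.tsv"] = {
                "stage": "simulate",
                "rows": int(alt.size),
            }
        write_cnv_segments(outdir / "cnv_segments.tsv", cnvs)
        report["outputs"]["cnv_segments.tsv"] = {"stage": "simulate", "rows": len(cnvs)}
    except Exception as exc:  # noqa: BLE001 - report, do not crash downstream
        report["failed_stage"] = "simulate"
        report["error"] = str(exc)
        return report

    # --- profile ----------------------------------------------------------
    try:
        region_index = RegionIndex({})  # no annotation in simulation: all intergenic
        cat = build_category_table(records, region_index, sample_ids)
        emit("profile", "category_table.tsv", cat)
        emit("profile", "spectrum.tsv", spectrum_table(records, sample_ids))
        emit(
            "profile",
            "burden_per_mb.tsv",
            burden_per_mb(cat, config.callable_genome_mb).to_frame("per_mb"),
        )
        conc_rows = []
        for st in sim.stages:
            r, p, n = vaf_concordance(records, sim.sample_id(st, "PB"), sim.sample_id(st, "BM"))
            conc_rows.append({"stage": st, "r": r, "p": p, "n": n})
        emit("profile", "pb_bm_concordance.tsv", pd.DataFrame(conc_rows).set_index("stage"))
    except Exception as exc:
        report["failed_stage"] = "profile"
        report["error"] = str(exc)
        return report

    # --- ccf + cluster + evolve (BM compartment) --------------------------
    try:
        bm_ids = [sim.sample_id(st, "BM") for st in sim.stages]
        alt, tot = count_matrices(records, bm_ids)
        estimates = []
        for vid in alt.index:
            for sid in bm_ids:
                d = int(tot.at[vid, sid])
                if d == 0:
                    continue
                estimates.append(
                    ccf_mod.ccf_from_vaf(
                        alt.at[vid, sid] / d, sim.purity, 2, 1, variant_id=vid, sample_id=sid
                    )
                )
        emit(
            "ccf",
            "ccf_estimates.tsv",
            pd.DataFrame([dataclasses.asdict(e) for e in estimates]).set_index("variant_id"),
        )
    except Exception as exc:
        report["failed_stage"] = "ccf"
        report["error"] = str(exc)
        return report

    try:
        fit = select_k(
            alt,
            tot,
            k_range=range(config.k_min, config.k_max + 1),
            seed=child["cluster"],
            restarts=config.restarts,
            min_cluster_size=config.min_cluster_size,
        )
        report["selected_k"] = int(fit.n_components_)
        clusters = assign_clusters(fit, bm_ids, purity={s: sim.purity for s in bm_ids})
        emit(
            "cluster",
            "clusters.tsv",
            pd.DataFrame({"variant_id": alt.index, "cluster": fit.labels_}).set_index("variant_id"),
        )
        prev = pd.DataFrame(
            {c.cluster_id: c.prevalence for c in clusters}
        ).T.rename(columns=dict(zip(bm_ids, sim.stages)))
        emit("cluster", "cluster_prevalence.tsv", prev)
    except Exception as exc:
        report["failed_stage"] = "cluster"
        report["error"] = str(exc)
        return report

    try:
        tree = build_tree(prev, eps=config.eps)
        report["tree"] = {str(k): int(v) for k, v in tree.parent.items()}
        report["tree_consistent"] = tree.is_consistent
        timing = classify_timing(prev, config.present_thresh, config.absent_thresh)
        report["timing"] = {str(k): v for k, v in timing.items()}
        emit("evolve", "fishplot.tsv", fishplot_table(tree).set_index("stage"))
    except Exception as exc:
        report["failed_stage"] = "evolve"
        report["error"] = str(exc)
        return report

    # --- single cells -----------------------------------------------------
    try:
        profiles = pd.DataFrame(
            {c: truth.genotype(c) for c in range(sim.n_clones)}, index=truth.mutation_ids
        ).T
        assigner = CloneAssigner(ado_rate=sim.ado_rate, fp_rate=sim.fp_rate).fit(profiles)
        sc_rows = []
        for stage_name, (a, t, labels) in single_cells.items():
            matrix = CellGenotypeMatrix.from_counts(a, t, config.depth_min, config.vaf_min)
            assigned = assigner.predict(matrix)
            for cell, clone in assigned.items():
                sc_rows.append({"stage": stage_name, "cell_id": cell, "clone": clone})
        emit("sc", "cell_assignments.tsv", pd.DataFrame(sc_rows).set_index("cell_id"))
    except Exception as exc:
        report["failed_stage"] = "sc"
        report["error"] = str(exc)
        return report

    # --- cnv --------------------------------------------------------------
    try:
        est = [fraction_from_ratio(s) for s in cnvs]
        emit(
            "cnv",
            "cnv_fractions.tsv",
            pd.DataFrame(
                [
                    {
                        "chrom": e.segment.chrom,
                        "start": e.segment.start,
                        "end": e.segment.end,
                        "stage": e.segment.stage,
                        "copy_number": e.segment.copy_number,
                        "fraction": e.fraction,
                        "clipped": e.clipped,
                    }
                    for e in est
                ]
            ).set_index("chrom"),
        )
    except Exception as exc:
        report["failed_stage"] = "cnv"
        report["error"] = str(exc)
        return report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
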