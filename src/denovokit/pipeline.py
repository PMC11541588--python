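"""End-to-end orchestration: simulate -> filter -> phase -> regress -> spectra.

``RunConfig`` gathers every stage's parameters (all thresholds default to the
standard trio-filter settings), round-trips losslessly through YAML, and
rejects unknown keys.  ``run_pipeline`` executes the stages in fixed order
and returns a consolidated report whose every number is reproducible from
the stored config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dnmfilter, pae, phasing, sigkit
from .dnmfilter import FilterThresholds
from .simdata import (
    SimConfig,
    build_context_index,
    default_signature_catalog,
    simulate_cohort,
    simulate_discovery_calls,
    simulate_fragments,
    simulate_genome,
    simulate_validation_readouts,
    write_fasta,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("denovokit")


@dataclass
class RunConfig:
    """Fully resolved configuration for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    phasing_min_support: int = 1
    phasing_window: int = 500
    pae_link: str = "identity"
    decompose_add_tol: float = 0.01
    decompose_prune_tol: float = 0.01
    extract_k_range: tuple[int, int] = (1, 2)
    extract_replicates: int = 8
    mask_bed: str | None = None
    outdir: str | None = None
    report_format: str = "json"  # json | tsv

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["children_range"] = list(self.sim.children_range)
        d["sim"]["children_dist"] = list(self.sim.children_dist)
        d["sim"]["age_at_first_child_dist"] = list(self.sim.age_at_first_child_dist)
        d["sim"]["interbirth_gap_dist"] = list(self.sim.interbirth_gap_dist)
        d["extract_k_range"] = list(self.extract_k_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return validate_config(yaml.safe_load(fh) or {})


def _coerce_dataclass(cls, payload: dict, prefix: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    for k in sorted(unknown):
        errors.append(f"unknown key {prefix}{k}")
    kwargs = {}
    for name, f in fields.items():
        if name in payload:
            v = payload[name]
            if name in ("children_range", "children_dist", "age_at_first_child_dist", "interbirth_gap_dist"):
                v = tuple(v)
            kwargs[name] = v
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{prefix[:-1]}: {exc}")
        return cls()


def validate_config(payload: dict | None = None) -> RunConfig:
    """Build a RunConfig from a (possibly empty) mapping.

    Defaults are injected for every missing key; unknown keys and out-of-range
    values are rejected with an aggregated, human-readable error.
    """
    payload = dict(payload or {})
    errors: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for k in sorted(set(payload) - top_fields):
        errors.append(f"unknown key {k}")

    sim = _coerce_dataclass(SimConfig, payload.get("sim") or {}, "sim.", errors)
    thr = _coerce_dataclass(FilterThresholds, payload.get("thresholds") or {}, "thresholds.", errors)

    cfg = RunConfig(sim=sim, thresholds=thr)
    for name in (
        "phasing_min_support", "phasing_window", "pae_link", "decompose_add_tol",
        "decompose_prune_tol", "extract_replicates", "mask_bed", "outdir", "report_format",
    ):
        if name in payload:
            setattr(cfg, name, payload[name])
    if "extract_k_range" in payload:
        cfg.extract_k_range = tuple(payload["extract_k_range"])

    try:
        sim.validate()
    except ValueError as exc:
        errors.append(str(exc))
    for name in ("min_depth", "min_gq", "min_strand_reads", "min_val_depth"):
        if getattr(thr, name) < 0:
            errors.append(f"thresholds.{name} must be >= 0")
    for name in ("max_parent_frac", "min_proband_aaf", "max_parent_aaf"):
        v = getattr(thr, name)
        if not 0 <= v <= 1:
            errors.append(f"thresholds.{name} must lie in [0, 1]")
    if cfg.report_format not in ("json", "tsv"):
        errors.append("report_format must be 'json' or 'tsv'")
    if cfg.pae_link not in ("identity", "log"):
        errors.append("pae_link must be 'identity' or 'log'")
    if cfg.phasing_min_support < 1:
        errors.append("phasing_min_support must be >= 1")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _write_tables(outdir: Path, tables: dict[str, pd.DataFrame]) -> None:
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full synthetic-cohort analysis and return the run report.

    Stage order: genome + cohort simulation, discovery calls, caller merge,
    optional region mask, discovery filter cascade, recurrence removal,
    validation, cohort summary + mutation rate, phasing, PAE regression
    (cohort and per family), 96-channel spectra (cohort / per-child / age
    quartiles), signature extraction and decomposition against the built-in
    generating catalog.  A stage failure raises with the stage name; partial
    outputs written so far are retained.
    """
    config = config or RunConfig()
    sim = config.sim
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": sim.seed}
    tables: dict[str, pd.DataFrame] = {}

    stage = "simulate"
    try:
        genome = simulate_genome(
            sim.genome_length, sim.gc_content, sim.cpg_island_fraction, seed=sim.seed
        )
        index = build_context_index(genome)
        cohort = simulate_cohort(sim, genome, context_index=index)
        log.info("simulated %d families / %d children / %d true DNMs",
                 sim.n_families, len(cohort.pedigrees), len(cohort.truth))
        candidates, artifacts = simulate_discovery_calls(cohort, genome)
        readouts = simulate_validation_readouts(cohort)
        tables["pedigree"] = cohort.pedigrees
        tables["truth"] = cohort.truth
        tables["candidates"] = candidates[
            [c for c in candidates.columns if c not in ("record_class", "aux_frac", "mosaic_parent")]
        ]
        tables["readouts"] = readouts
        if outdir:
            write_fasta(genome, outdir / "genome.fa")

        stage = "merge_callers"
        calls_a = candidates[candidates["callers"].str.contains("A")].drop(columns=["callers"])
        calls_b = candidates[candidates["callers"].str.contains("B")].drop(columns=["callers"])
        merged, overlap = dnmfilter.merge_callers(calls_a, calls_b)
        report["caller_overlap"] = overlap

        stage = "region_mask"
        trace = dnmfilter.FilterTrace()
        if config.mask_bed:
            mask = dnmfilter.read_bed(config.mask_bed)
            merged, trace = dnmfilter.apply_region_mask(merged, mask, trace)
        else:
            trace.add("region_mask", len(merged), 0)

        stage = "discovery_filters"
        survivors, trace = dnmfilter.apply_discovery_filters(merged, config.thresholds, trace)
        stage = "recurrence"
        unique, rec_stats = dnmfilter.remove_recurrent(survivors, trace)
        report["recurrence"] = rec_stats

        stage = "validation"
        validated, unvalidated, vtrace = dnmfilter.apply_validation_filters(
            unique, readouts, config.thresholds
        )
        trace.stages.extend(vtrace.stages)
        report["filter_trace"] = trace.to_dict()
        tables["validated"] = validated
        tables["filter_trace"] = trace.to_frame()
        report["n_validated"] = len(validated)
        report["n_unvalidated_no_bait"] = len(unvalidated)

        stage = "cohort_summary"
        summary = dnmfilter.cohort_summary(validated, cohort.pedigrees)
        tables["per_child_counts"] = summary["per_child"]
        report["cohort_summary"] = {
            k: v for k, v in summary.items() if not isinstance(v, pd.DataFrame)
        }
        report["mutation_rate"] = dnmfilter.mutation_rate(
            summary["total_validated"], summary["n_probands"], sim.callable_diploid_bp
        )

        stage = "phasing"
        val_truth = validated.merge(
            cohort.truth[["child_id", "chrom", "pos", "alt", "parent_of_origin"]],
            on=["child_id", "chrom", "pos", "alt"],
            how="left",
        )
        phaseable = val_truth[val_truth["parent_of_origin"].notna()]
        sites, frags = simulate_fragments(phaseable, sim)
        calls = phasing.phase_cohort(
            val_truth, sites, frags,
            min_support=config.phasing_min_support, window=config.phasing_window,
        )
        phase_summary = phasing.summarize_phasing(calls, cohort.pedigrees)
        tables["phase_calls"] = calls
        tables["phase_per_family"] = phase_summary["per_family"]
        report["phasing"] = {
            k: v for k, v in phase_summary.items() if not isinstance(v, pd.DataFrame)
        }

        stage = "pae"
        per_child = summary["per_child"]
        cohort_fit = pae.fit_pae(
            per_child["n_validated"].to_numpy(), per_child["paternal_age"].to_numpy(),
            link=config.pae_link,
        )
        family_fits, skipped = pae.fit_family_slopes(per_child, link=config.pae_link)
        ranked = pae.rank_families(family_fits)
        tables["pae_family_fits"] = ranked
        report["pae"] = {"cohort": cohort_fit.to_dict(), "skipped_families": skipped}

        stage = "spectrum"
        spec = sigkit.build_matrix(validated, genome, grouping="cohort")
        spec_child = sigkit.build_matrix(validated, genome, grouping="per_child")
        quart, bounds = sigkit.stratify_by_age_quartile(validated, cohort.pedigrees, genome)
        tables["spectrum_cohort"] = spec.counts.reset_index()
        tables["spectrum_per_child"] = spec_child.counts.reset_index()
        tables["spectrum_age_quartiles"] = quart.counts.reset_index()
        report["spectrum"] = {
            "total": int(spec.totals.sum()),
            "n_unclassifiable": spec.n_unclassifiable,
            "cpg_ct_fraction": float(spec.cpg_ct_counts.sum() / max(spec.totals.sum(), 1)),
            "age_quartile_bounds": [round(b, 2) for b in bounds],
            "q1_cpg_ct_fraction": float(quart.counts.loc[list(sigkit.CPG_CHANNELS), "Q1"].sum()
                                        / max(quart.counts["Q1"].sum(), 1)),
            "q4_cpg_ct_fraction": float(quart.counts.loc[list(sigkit.CPG_CHANNELS), "Q4"].sum()
                                        / max(quart.counts["Q4"].sum(), 1)),
        }

        stage = "signatures"
        extraction = sigkit.extract_signature(
            spec_child.counts,
            k_range=range(config.extract_k_range[0], config.extract_k_range[1] + 1),
            n_replicates=config.extract_replicates,
            seed=sim.seed,
        )
        catalog = default_signature_catalog()
        decomp = sigkit.decompose(
            extraction.primary(), catalog,
            add_tol=config.decompose_add_tol, prune_tol=config.decompose_prune_tol,
        )
        ranking = sigkit.best_match(extraction.primary(), catalog)
        tables["extracted_signatures"] = extraction.signatures.reset_index()
        report["extraction"] = {
            "selected_k": extraction.selected_k,
            "stats": extraction.stats.reset_index().to_dict(orient="records"),
        }
        report["decomposition"] = decomp.to_dict()
        report["best_match"] = ranking.to_dict(orient="records")
    except Exception as exc:
        if outdir:
            _write_tables(outdir, tables)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir:
        _write_tables(outdir, tables)
        config.to_yaml(outdir / "config.yaml")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        if config.report_format == "tsv":
            trace.to_frame().to_csv(outdir / "filter_trace.tsv", sep="\t", index=False)
    return report


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
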