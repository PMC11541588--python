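"""Dual-caller merge, trio filter cascade, recurrence removal and validation.

Candidate de novo SNVs from two callers are merged by (child, chrom, pos,
alt), passed through a fixed-order discovery filter cascade (parental allele
fraction, strand support, trio depth, trio genotype quality, parental alt
reads), stripped of cohort-recurrent sites, and finally validated against
deep-resequencing readouts.  Every stage reports a telescoping trace so the
counts always reconcile.  Cohort summary statistics and the per-generation
mutation rate round the module off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "FilterTrace",
    "merge_callers",
    "caller_intersection",
    "read_bed",
    "apply_region_mask",
    "apply_discovery_filters",
    "remove_recurrent",
    "apply_validation_filters",
    "cohort_summary",
    "mutation_rate",
]

_KEY = ["child_id", "chrom", "pos", "alt"]

CANDIDATE_METRICS = [
    "child_depth", "father_depth", "mother_depth",
    "child_alt", "father_alt", "mother_alt",
    "child_alt_fwd", "child_alt_rev",
    "child_gq", "father_gq", "mother_gq",
]


@dataclass
class FilterThresholds:
    """Cascade thresholds; defaults are the standard trio-filter settings.

    Inclusive thresholds (min_depth, min_gq) keep the boundary value;
    strict ones (max_parent_frac, min_proband_aaf, min_val_depth) follow a
    strict inequality, e.g. a proband AAF of exactly 0.3 is removed.
    """

    max_parent_frac: float = 0.10  # discovery: parental alt fraction above this removes
    min_strand_reads: int = 2  # alt reads required on each strand
    min_depth: int = 12  # trio depth, inclusive
    min_gq: int = 20  # trio GQ, inclusive
    max_parent_alt: int = 0  # any parental alt read removes
    min_proband_aaf: float = 0.3  # validation: strictly greater passes
    min_val_depth: int = 10  # validation proband depth, strictly greater passes
    max_parent_aaf: float = 0.10  # validation parental AAF, strictly greater removes
    val_depth_is_total: bool = True  # switch: total vs alt-supporting validation depth


@dataclass
class FilterTrace:
    """Per-stage input/removed/output counts plus each variant's first failing stage."""

    stages: list[dict] = field(default_factory=list)
    first_fail: pd.Series | None = None

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_removed": n_removed, "n_out": n_in - n_removed}
        )

    def validate(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev["n_out"] != cur["n_in"]:
                raise AssertionError(f"trace does not telescope at stage {cur['stage']}")
        for s in self.stages:
            if s["n_in"] - s["n_removed"] != s["n_out"]:
                raise AssertionError(f"stage {s['stage']} counts inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_dict(self) -> dict:
        return {"stages": list(self.stages)}


def merge_callers(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Union two callers' candidate tables, preserving provenance.

    Records agree when they share (child, chrom, pos, alt); a shared key with
    conflicting reference alleles raises, naming the site.  Returns the merged
    table plus ``{"n_a", "n_b", "n_intersection", "n_union"}`` — the identity
    ``n_union = n_a + n_b - n_intersection`` holds exactly.
    """
    a = calls_a.copy()
    b = calls_b.copy()
    a_keys = set(map(tuple, a[_KEY].itertuples(index=False, name=None)))
    b_keys = set(map(tuple, b[_KEY].itertuples(index=False, name=None)))
    shared = a_keys & b_keys

    if shared:
        ref_a = a.set_index(_KEY)["ref"]
        ref_b = b.set_index(_KEY)["ref"]
        for key in shared:
            ra, rb = ref_a.loc[key], ref_b.loc[key]
            ra = ra if isinstance(ra, str) else ra.iloc[0]
            rb = rb if isinstance(rb, str) else rb.iloc[0]
            if ra != rb:
                child, chrom, pos, alt = key
                raise ValueError(
                    f"conflicting ref alleles at {child} {chrom}:{pos} (alt {alt}): {ra!r} vs {rb!r}"
                )

    a["callers"] = ["A,B" if k in shared else "A" for k in map(tuple, a[_KEY].itertuples(index=False, name=None))]
    b_only = b[[k not in shared for k in map(tuple, b[_KEY].itertuples(index=False, name=None))]].copy()
    b_only["callers"] = "B"
    merged = pd.concat([a, b_only], ignore_index=True)
    stats = {
        "n_a": len(a_keys),
        "n_b": len(b_keys),
        "n_intersection": len(shared),
        "n_union": len(a_keys | b_keys),
    }
    return merged, stats


def caller_intersection(n_a: int, n_b: int, n_union: int) -> int:
    """Intersection size by inclusion–exclusion from the two list sizes and their union."""
    n = n_a + n_b - n_union
    if n < 0 or n > min(n_a, n_b):
        raise ValueError(f"inconsistent sizes: |A|={n_a}, |B|={n_b}, |A∪B|={n_union}")
    return n


def read_bed(path) -> pd.DataFrame:
    """Read a 0-based half-open BED mask; malformed lines raise with their number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"malformed BED line {i}: end < start")
            rows.append({"chrom": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def apply_region_mask(
    variants: pd.DataFrame, mask: pd.DataFrame, trace: FilterTrace | None = None
) -> tuple[pd.DataFrame, FilterTrace]:
    """Drop variants whose 0-based position (pos - 1) falls in a mask interval."""
    from intervaltree import IntervalTree

    trace = trace or FilterTrace()
    trees: dict[str, IntervalTree] = {}
    for r in mask.itertuples(index=False):
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    if trees:
        hit = np.array(
            [bool(trees[c][p - 1]) if c in trees else False
             for c, p in zip(variants["chrom"], variants["pos"].astype(int))]
        )
    else:
        hit = np.zeros(len(variants), dtype=bool)
    out = variants[~hit].reset_index(drop=True)
    trace.add("region_mask", len(variants), int(hit.sum()))
    return out, trace


_DISCOVERY_STAGES = [
    (
        "parental_alt_fraction",
        lambda v, t: (v["father_alt"] / v["father_depth"].clip(lower=1) > t.max_parent_frac)
        | (v["mother_alt"] / v["mother_depth"].clip(lower=1) > t.max_parent_frac),
    ),
    (
        "strand_support",
        lambda v, t: (v["child_alt_fwd"] < t.min_strand_reads) | (v["child_alt_rev"] < t.min_strand_reads),
    ),
    (
        "trio_depth",
        lambda v, t: (v["child_depth"] < t.min_depth)
        | (v["father_depth"] < t.min_depth)
        | (v["mother_depth"] < t.min_depth),
    ),
    (
        "trio_gq",
        lambda v, t: (v["child_gq"] < t.min_gq) | (v["father_gq"] < t.min_gq) | (v["mother_gq"] < t.min_gq),
    ),
    (
        "parental_alt_reads",
        lambda v, t: (v["father_alt"] > t.max_parent_alt) | (v["mother_alt"] > t.max_parent_alt),
    ),
]


def apply_discovery_filters(
    variants: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    trace: FilterTrace | None = None,
) -> tuple[pd.DataFrame, FilterTrace]:
    """Fixed-order discovery cascade over trio read metrics.

    Stage order: parental alt fraction, strand support, trio depth, trio GQ,
    parental alt reads.  The stages are independent predicates, so the
    survivor set does not depend on the order — only the per-stage removal
    attribution does.
    """
    t = thresholds or FilterThresholds()
    missing = [c for c in CANDIDATE_METRICS if c not in variants.columns]
    if missing:
        raise ValueError(f"variants table lacks required metrics: {missing}")
    for col in CANDIDATE_METRICS:
        bad = variants[col].isna()
        if bad.any():
            r = variants[bad].iloc[0]
            raise ValueError(f"missing {col} for variant {r['child_id']} {r['chrom']}:{r['pos']}")

    trace = trace or FilterTrace()
    first_fail = pd.Series("pass", index=variants.index, dtype=object)
    alive = variants
    for name, pred in _DISCOVERY_STAGES:
        fails = pred(alive, t)
        first_fail.loc[alive.index[fails]] = name
        trace.add(name, len(alive), int(fails.sum()))
        alive = alive[~fails]
    trace.first_fail = first_fail
    trace.validate()
    return alive.reset_index(drop=True), trace


def remove_recurrent(
    variants: pd.DataFrame, trace: FilterTrace | None = None
) -> tuple[pd.DataFrame, dict]:
    """Remove every occurrence of any site seen in two or more children.

    Reports ``distinct_sites_removed`` (unique (chrom, pos, alt) keys) and
    ``occurrences_removed`` (rows) separately; idempotent by construction.
    """
    site = list(zip(variants["chrom"], variants["pos"].astype(int), variants["alt"]))
    counts = (
        pd.DataFrame({"site": site, "child_id": variants["child_id"]})
        .groupby("site")["child_id"]
        .nunique()
    )
    recurrent = set(counts.index[counts >= 2])
    is_rec = np.array([s in recurrent for s in site])
    out = variants[~is_rec].reset_index(drop=True)
    stats = {
        "distinct_sites_removed": len(recurrent),
        "occurrences_removed": int(is_rec.sum()),
    }
    if trace is not None:
        trace.add("recurrent_sites", len(variants), int(is_rec.sum()))
    return out, stats


def apply_validation_filters(
    candidates: pd.DataFrame,
    readouts: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterTrace]:
    """Retain candidates confirmed by deep resequencing.

    Keep iff father and mother AAF <= max_parent_aaf, proband AAF strictly
    above min_proband_aaf, and proband depth strictly above min_val_depth.
    Candidates without a readout (no designed bait) go to an explicit third
    bin — returned separately, never silently dropped.  Returns
    (validated, unvalidated, trace).
    """
    t = thresholds or FilterThresholds()
    trace = FilterTrace()
    merged = candidates.merge(
        readouts[["child_id", "chrom", "pos", "alt", "proband_depth", "proband_aaf", "father_aaf", "mother_aaf"]],
        on=["child_id", "chrom", "pos", "alt"],
        how="left",
        validate="one_to_one",
    )
    has_readout = merged["proband_aaf"].notna()
    unvalidated = merged[~has_readout].reset_index(drop=True)
    trace.add("bait_designed", len(merged), int((~has_readout).sum()))
    v = merged[has_readout]

    fail = (v["father_aaf"] > t.max_parent_aaf) | (v["mother_aaf"] > t.max_parent_aaf)
    trace.add("val_parental_aaf", len(v), int(fail.sum()))
    v = v[~fail]

    if t.val_depth_is_total:
        depth = v["proband_depth"]
    else:
        depth = (v["proband_depth"] * v["proband_aaf"]).round()
    fail = ~((v["proband_aaf"] > t.min_proband_aaf) & (depth > t.min_val_depth))
    trace.add("val_proband_aaf_depth", len(v), int(fail.sum()))
    v = v[~fail]
    trace.validate()
    return v.reset_index(drop=True), unvalidated, trace


def cohort_summary(validated: pd.DataFrame, pedigrees: pd.DataFrame) -> dict:
    """Per-child counts, per-family totals, and cohort means/SD/range.

    Children absent from the validated table count as zero; a validated child
    missing from the pedigree is an error.  With a single proband the SD is
    undefined and reported as 0 with ``sd_defined = False``.
    """
    ped_children = pedigrees[["family_id", "child_id", "paternal_age"]].drop_duplicates()
    unknown = set(validated["child_id"]) - set(ped_children["child_id"])
    if unknown:
        raise ValueError(f"validated calls for children absent from pedigree: {sorted(unknown)[:5]}")
    per_child = (
        validated.groupby("child_id").size().reindex(ped_children["child_id"], fill_value=0).rename("n_validated")
    )
    per_child = ped_children.set_index("child_id").join(per_child).reset_index()
    per_family = per_child.groupby("family_id")["n_validated"].sum().rename("n_validated").reset_index()

    n_pro, n_fam = len(per_child), len(per_family)
    total = int(per_child["n_validated"].sum())
    sd_defined = n_pro > 1
    return {
        "per_child": per_child,
        "per_family": per_family,
        "total_validated": total,
        "n_probands": n_pro,
        "n_families": n_fam,
        "mean_per_proband": total / n_pro,
        "sd_per_proband": float(per_child["n_validated"].std(ddof=1)) if sd_defined else 0.0,
        "sd_defined": sd_defined,
        "range_per_proband": (int(per_child["n_validated"].min()), int(per_child["n_validated"].max())),
        "mean_per_family": total / n_fam,
        "sd_per_family": float(per_family["n_validated"].std(ddof=1)) if n_fam > 1 else 0.0,
        "range_per_family": (int(per_family["n_validated"].min()), int(per_family["n_validated"].max())),
    }


def mutation_rate(
    total_validated: int,
    n_probands: int,
    callable_diploid_bp: float,
    ci_method: str = "normal",
) -> dict:
    """Per-base-pair per-generation germline mutation rate with a binomial 95% CI.

    rate = total / (n_probands * callable_diploid_bp); the CI treats the total
    as binomial out of that many opportunities (``ci_method``: 'normal' or
    'exact' Clopper–Pearson via the beta distribution).
    """
    if n_probands <= 0 or callable_diploid_bp <= 0:
        raise ValueError("n_probands and callable_diploid_bp must be positive")
    if total_validated < 0:
        raise ValueError("total_validated must be non-negative")
    nobs = n_probands * callable_diploid_bp
    rate = total_validated / nobs
    if ci_method == "normal":
        se = np.sqrt(max(rate * (1 - rate), 0.0) / nobs)
        lo, hi = max(rate - 1.96 * se, 0.0), rate + 1.96 * se
    elif ci_method == "exact":
        from scipy.stats import beta as beta_dist

        lo = beta_dist.ppf(0.025, total_validated, nobs - total_validated + 1) if total_validated > 0 else 0.0
        hi = beta_dist.ppf(0.975, total_validated + 1, nobs - total_validated)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {"rate": rate, "ci_low": float(lo), "ci_high": float(hi), "method": ci_method}
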