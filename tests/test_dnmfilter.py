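"""Caller merge, filter cascade, recurrence removal, validation, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from denovokit import dnmfilter
from denovokit.dnmfilter import (
    FilterThresholds,
    FilterTrace,
    apply_discovery_filters,
    apply_region_mask,
    apply_validation_filters,
    caller_intersection,
    cohort_summary,
    merge_callers,
    mutation_rate,
    remove_recurrent,
)
from conftest import random_variant_table


def _mini(rows):
    base = {
        "chrom": "chr1", "ref": "C", "family_id": "F01",
        "child_depth": 30, "father_depth": 30, "mother_depth": 30,
        "child_alt": 15, "father_alt": 0, "mother_alt": 0,
        "child_alt_fwd": 8, "child_alt_rev": 7,
        "child_gq": 90, "father_gq": 90, "mother_gq": 90,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestMergeCallers:
    def test_union_and_intersection_counts(self):
        a = _mini([{"child_id": "c1", "pos": p, "alt": "T"} for p in (10, 20, 30)])
        b = _mini([{"child_id": "c1", "pos": p, "alt": "T"} for p in (30, 40)])
        merged, stats = merge_callers(a, b)
        assert stats == {"n_a": 3, "n_b": 2, "n_intersection": 1, "n_union": 4}
        assert len(merged) == 4
        assert set(merged.loc[merged["pos"] == 30, "callers"]) == {"A,B"}

    def test_subset_caller_b(self):
        a = _mini([{"child_id": "c1", "pos": p, "alt": "T"} for p in (1, 2, 3)])
        b = a.iloc[:2].copy()
        _, stats = merge_callers(a, b)
        assert stats["n_union"] == stats["n_a"] == 3

    def test_conflicting_ref_raises_with_site(self):
        a = _mini([{"child_id": "c1", "pos": 10, "alt": "T"}])
        b = _mini([{"child_id": "c1", "pos": 10, "alt": "T", "ref": "G"}])
        with pytest.raises(ValueError, match="chr1:10"):
            merge_callers(a, b)

    def test_inclusion_exclusion_printed_sizes(self):
        # the dual-caller list sizes reported for the real cohort
        assert caller_intersection(11403, 2729, 11590) == 2542
        with pytest.raises(ValueError):
            caller_intersection(5, 5, 100)


class TestRegionMask:
    mask = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})

    def test_one_based_position_inside_halfopen_interval_removed(self):
        v = _mini([{"child_id": "c1", "pos": 11, "alt": "T"}])  # 0-based 10 in [10,20)
        out, _ = apply_region_mask(v, self.mask)
        assert len(out) == 0

    def test_halfopen_upper_boundary_kept(self):
        v = _mini([{"child_id": "c1", "pos": 21, "alt": "T"}])  # 0-based 20 not in [10,20)
        out, _ = apply_region_mask(v, self.mask)
        assert len(out) == 1

    def test_empty_mask_is_identity(self):
        v = _mini([{"child_id": "c1", "pos": 11, "alt": "T"}])
        out, _ = apply_region_mask(v, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out) == 1

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t20\nchr1\toops\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            dnmfilter.read_bed(p)


def brute_force_survivors(v, t):
    """Joint one-pass predicate evaluation, independent of the staged cascade."""
    keep = (
        (v["father_alt"] / v["father_depth"].clip(lower=1) <= t.max_parent_frac)
        & (v["mother_alt"] / v["mother_depth"].clip(lower=1) <= t.max_parent_frac)
        & (v["child_alt_fwd"] >= t.min_strand_reads)
        & (v["child_alt_rev"] >= t.min_strand_reads)
        & (v["child_depth"] >= t.min_depth)
        & (v["father_depth"] >= t.min_depth)
        & (v["mother_depth"] >= t.min_depth)
        & (v["child_gq"] >= t.min_gq)
        & (v["father_gq"] >= t.min_gq)
        & (v["mother_gq"] >= t.min_gq)
        & (v["father_alt"] <= t.max_parent_alt)
        & (v["mother_alt"] <= t.max_parent_alt)
    )
    return v[keep]


class TestDiscoveryFilters:
    def test_low_fraction_parent_read_removed_at_zero_support_stage(self):
        v = _mini([{"child_id": "c1", "pos": 5, "alt": "T", "father_alt": 1, "father_depth": 100}])
        out, trace = apply_discovery_filters(v)
        assert len(out) == 0
        assert trace.first_fail.iloc[0] == "parental_alt_reads"  # passes the 10% stage first

    def test_exact_thresholds_are_inclusive(self):
        v = _mini([{
            "child_id": "c1", "pos": 5, "alt": "T",
            "child_alt_fwd": 2, "child_alt_rev": 2, "child_alt": 4,
            "child_depth": 12, "father_depth": 12, "mother_depth": 12,
            "child_gq": 20, "father_gq": 20, "mother_gq": 20,
        }])
        out, _ = apply_discovery_filters(v)
        assert len(out) == 1

    def test_missing_metric_names_variant_and_field(self):
        v = _mini([{"child_id": "c1", "pos": 5, "alt": "T"}])
        v.loc[0, "child_gq"] = np.nan
        with pytest.raises(ValueError, match="child_gq"):
            apply_discovery_filters(v)

    def test_cascade_equals_joint_predicates_on_random_table(self):
        v = random_variant_table(1000, seed=3)
        t = FilterThresholds()
        out, trace = apply_discovery_filters(v, t)
        oracle = brute_force_survivors(v, t)
        assert len(out) == len(oracle)
        assert out.reset_index(drop=True).equals(oracle.reset_index(drop=True))
        # telescoping: removals plus survivors account for every input row
        assert sum(s["n_removed"] for s in trace.stages) + len(out) == len(v)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 120))
    def test_survivors_invariant_under_threshold_consistency(self, seed, n):
        v = random_variant_table(n, seed=seed)
        t = FilterThresholds()
        out, trace = apply_discovery_filters(v, t)
        trace.validate()
        assert set(out.index.tolist()) <= set(range(n))
        oracle = brute_force_survivors(v, t)
        assert len(out) == len(oracle)


class TestRemoveRecurrent:
    def test_site_in_three_children_fully_removed(self):
        v = _mini([{"child_id": c, "pos": 10, "alt": "T"} for c in ("c1", "c2", "c3")]
                  + [{"child_id": "c1", "pos": 99, "alt": "G"}])
        out, stats = remove_recurrent(v)
        assert stats == {"distinct_sites_removed": 1, "occurrences_removed": 3}
        assert list(out["pos"]) == [99]

    def test_unique_sites_untouched_and_idempotent(self):
        v = _mini([{"child_id": "c1", "pos": p, "alt": "T"} for p in (1, 2, 3)])
        out, stats = remove_recurrent(v)
        assert stats["occurrences_removed"] == 0
        again, stats2 = remove_recurrent(out)
        assert again.equals(out) and stats2["occurrences_removed"] == 0


class TestValidationFilters:
    readout_cols = ["child_id", "chrom", "pos", "alt", "proband_depth", "proband_aaf", "father_aaf", "mother_aaf"]

    def _readout(self, rows):
        return pd.DataFrame(rows, columns=self.readout_cols)

    def test_proband_aaf_boundary_is_strict(self):
        cand = _mini([{"child_id": "c1", "pos": 5, "alt": "T"}])
        reads = self._readout([("c1", "chr1", 5, "T", 300, 0.30, 0.0, 0.0)])
        validated, unval, _ = apply_validation_filters(cand, reads)
        assert len(validated) == 0 and len(unval) == 0

    def test_clear_het_with_clean_parents_validated(self):
        cand = _mini([{"child_id": "c1", "pos": 5, "alt": "T"}])
        reads = self._readout([("c1", "chr1", 5, "T", 300, 0.45, 0.0, 0.0)])
        validated, _, trace = apply_validation_filters(cand, reads)
        assert len(validated) == 1
        trace.validate()

    def test_parental_aaf_above_ten_percent_excluded(self):
        cand = _mini([{"child_id": "c1", "pos": 5, "alt": "T"}])
        reads = self._readout([("c1", "chr1", 5, "T", 300, 0.5, 0.12, 0.0)])
        validated, _, _ = apply_validation_filters(cand, reads)
        assert len(validated) == 0

    def test_candidate_without_readout_goes_to_no_bait_bin(self):
        cand = _mini([{"child_id": "c1", "pos": p, "alt": "T"} for p in (5, 6)])
        reads = self._readout([("c1", "chr1", 5, "T", 300, 0.5, 0.0, 0.0)])
        validated, unval, trace = apply_validation_filters(cand, reads)
        assert len(validated) == 1 and len(unval) == 1
        assert trace.stages[0]["stage"] == "bait_designed" and trace.stages[0]["n_removed"] == 1


class TestCohortSummary:
    def _cohort(self, total, n_children=48, n_families=13):
        children = [f"c{i}" for i in range(n_children)]
        ped = pd.DataFrame(
            {
                "family_id": [f"F{i % n_families:02d}" for i in range(n_children)],
                "child_id": children,
                "paternal_age": np.linspace(18, 40, n_children),
            }
        )
        counts = np.full(n_children, total // n_children)
        counts[: total % n_children] += 1
        validated = pd.DataFrame({"child_id": np.repeat(children, counts)})
        return validated, ped

    def test_printed_cohort_totals_reproduce_reported_means(self):
        validated, ped = self._cohort(2479)
        s = cohort_summary(validated, ped)
        assert round(s["mean_per_proband"], 1) == 51.6
        assert round(s["mean_per_family"], 1) == 190.7

    def test_single_child_sd_flagged(self):
        validated = pd.DataFrame({"child_id": ["c0"] * 5})
        ped = pd.DataFrame({"family_id": ["F01"], "child_id": ["c0"], "paternal_age": [30.0]})
        s = cohort_summary(validated, ped)
        assert s["mean_per_proband"] == 5 and s["sd_per_proband"] == 0.0 and not s["sd_defined"]

    def test_unknown_child_rejected(self):
        validated = pd.DataFrame({"child_id": ["ghost"]})
        ped = pd.DataFrame({"family_id": ["F01"], "child_id": ["c0"], "paternal_age": [30.0]})
        with pytest.raises(ValueError, match="ghost"):
            cohort_summary(validated, ped)


class TestMutationRate:
    def test_simple_arithmetic(self):
        r = mutation_rate(100, 10, 1e9)
        assert r["rate"] == pytest.approx(1e-8)

    def test_zero_counts_zero_rate(self):
        r = mutation_rate(0, 10, 1e9)
        assert r["rate"] == 0.0 and r["ci_low"] == 0.0

    def test_cohort_scale_rate(self):
        r = mutation_rate(2479, 48, 5.0e9)
        assert r["rate"] == pytest.approx(1.033e-8, rel=1e-3)
        assert r["ci_low"] < r["rate"] < r["ci_high"]

    def test_exact_ci_brackets_normal_ci(self):
        a = mutation_rate(2479, 48, 5.0e9, ci_method="normal")
        b = mutation_rate(2479, 48, 5.0e9, ci_method="exact")
        assert b["ci_low"] == pytest.approx(a["ci_low"], rel=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(10, 0, 1e9)


def test_trace_validation_catches_non_telescoping():
    t = FilterTrace()
    t.add("s1", 10, 3)
    t.stages.append({"stage": "s2", "n_in": 9, "n_removed": 1, "n_out": 8})
    with pytest.raises(AssertionError):
        t.validate()


def test_trio_vcf_roundtrip(tmp_path):
    """Candidate metrics survive a write/read cycle through a trio VCF."""
    import denovokit as dk
    from denovokit.vcf_io import read_trio_vcf, write_trio_vcf

    cfg = dk.SimConfig(n_families=2, genome_length=30_000, seed=1)
    genome = dk.simulate_genome(30_000, seed=1)
    co = dk.simulate_cohort(cfg, genome)
    cand, _ = dk.simulate_discovery_calls(co, genome)
    one = cand[cand["child_id"] == cand["child_id"].iloc[0]].copy()
    path = tmp_path / "trio.vcf"
    write_trio_vcf(one, path)
    back = read_trio_vcf(path, family_id=one["family_id"].iloc[0])
    assert back["child_id"].iloc[0] == one["child_id"].iloc[0]
    cols = ["chrom", "pos", "ref", "alt"] + dnmfilter.CANDIDATE_METRICS
    a = one.sort_values(["chrom", "pos"]).reset_index(drop=True)[cols]
    b = back[cols]
    pd.testing.assert_frame_equal(
        a.astype({"pos": int}), b.astype({"pos": int}), check_dtype=False
    )
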