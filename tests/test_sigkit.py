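"""96-channel spectra, cosine, greedy NNLS decomposition, NMF extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import nnls

from denovokit.sigkit import (
    CHANNELS_96,
    CPG_CHANNELS,
    Spectrum,
    best_match,
    build_matrix,
    classify_substitution,
    collapse_strand,
    cosine,
    decompose,
    extract_signature,
    read_catalog,
    stratify_by_age_quartile,
    write_catalog,
)

_COMP = str.maketrans("ACGT", "TGCA")


def brute_channel(tri: str, ref: str, alt: str) -> str:
    """Independent brute-force classifier: table-driven reverse complement."""
    assert tri[1] == ref
    if ref in "AG":
        tri = tri.translate(_COMP)[::-1]
        alt = alt.translate(_COMP)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


class TestChannels:
    def test_96_distinct_labels_pyrimidine_refs(self):
        assert len(CHANNELS_96) == len(set(CHANNELS_96)) == 96
        assert all(lbl[2] in "CT" for lbl in CHANNELS_96)
        assert len(CPG_CHANNELS) == 4

    def test_direct_pyrimidine_context(self):
        genome = {"chr1": "AAACGAA"}
        assert classify_substitution("chr1", 4, "C", "T", genome) == "A[C>T]G"

    def test_purine_ref_strand_collapsed(self):
        genome = {"chr1": "AACGTAA"}  # context CGT around the G at pos 4
        assert classify_substitution("chr1", 4, "G", "A", genome) == "A[C>T]G"

    def test_reference_mismatch_names_site(self):
        genome = {"chr1": "AAACGAA"}
        with pytest.raises(ValueError, match="chr1:4"):
            classify_substitution("chr1", 4, "T", "A", genome)

    def test_n_context_unclassifiable(self):
        genome = {"chr1": "AANCGAA"}
        assert classify_substitution("chr1", 4, "C", "T", genome) is None

    def test_matches_brute_force_on_random_sites(self, genome50k):
        rng = np.random.default_rng(17)
        seq = genome50k["chr1"]
        n_checked = 0
        while n_checked < 500:
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            got = classify_substitution("chr1", pos, ref, alt, genome50k)
            assert got == brute_channel(seq[pos - 2 : pos + 1], ref, alt)
            n_checked += 1

    def test_strand_invariance(self, genome50k):
        # classifying the reverse-complemented site yields the same channel
        rng = np.random.default_rng(23)
        seq = genome50k["chr1"]
        for _ in range(200):
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = classify_substitution("chr1", pos, ref, alt, genome50k)
            rc_genome = {"chr1": seq.translate(_COMP)[::-1]}
            rc_pos = len(seq) - pos + 1
            rev = classify_substitution(
                "chr1", rc_pos, ref.translate(_COMP), alt.translate(_COMP), rc_genome
            )
            assert fwd == rev


class TestSpectrum:
    def _dnms(self, genome, n, seed=0):
        rng = np.random.default_rng(seed)
        seq = genome["chr1"]
        rows = []
        for i in range(n):
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(
                {"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
                 "child_id": f"c{i % 6}", "family_id": f"F{i % 3}"}
            )
        return pd.DataFrame(rows)

    def test_single_snv_column_sum_one(self, genome50k):
        spec = build_matrix(self._dnms(genome50k, 1), genome50k)
        assert spec.totals.sum() == 1

    def test_grouping_totals_conserved(self, genome50k):
        d = self._dnms(genome50k, 300, seed=4)
        cohort = build_matrix(d, genome50k).counts["cohort"]
        per_child = build_matrix(d, genome50k, grouping="per_child").counts
        assert per_child.shape[1] == 6
        assert (per_child.sum(axis=1) == cohort).all()

    def test_counts_match_generating_mixture(self, genome50k, ctx_index):
        from denovokit.simdata import SimConfig, _mixture_for_age, default_signature_catalog, simulate_cohort

        cfg = SimConfig(n_families=10, genome_length=50_000, seed=19, cpg_age_shift=0.0)
        co = simulate_cohort(cfg, genome50k, context_index=ctx_index)
        spec = build_matrix(co.truth, genome50k)
        mix = _mixture_for_age(cfg, default_signature_catalog(), 30.0)
        obs = spec.counts["cohort"].to_numpy()
        exp = mix * obs.sum()
        keep = exp > 1e-12
        p = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum()).pvalue
        assert p > 0.001

    def test_quartile_boundaries_partition_children(self, genome50k):
        d = self._dnms(genome50k, 200, seed=6)
        ped = pd.DataFrame(
            {"family_id": "F0", "child_id": [f"c{i}" for i in range(6)],
             "paternal_age": [18.0, 21.0, 26.0, 30.0, 35.0, 39.0]}
        )
        spec, (lo, hi) = stratify_by_age_quartile(d, ped, genome50k)
        assert list(spec.counts.columns) == ["Q1", "Q4"]
        assert lo < hi
        q1_children = {f"c{i}" for i, a in enumerate(ped["paternal_age"]) if a < lo}
        expected_q1 = d[d["child_id"].isin(q1_children)]
        assert spec.counts["Q1"].sum() == len(expected_q1)

    def test_degenerate_ages_rejected(self, genome50k):
        d = self._dnms(genome50k, 10)
        ped = pd.DataFrame({"family_id": "F0", "child_id": [f"c{i}" for i in range(6)], "paternal_age": 30.0})
        with pytest.raises(ValueError, match="degenerate"):
            stratify_by_age_quartile(d, ped, genome50k)


class TestCosine:
    def test_self_similarity_one(self):
        v = np.random.default_rng(0).random(96)
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_support_zero(self):
        u = np.zeros(96); u[:10] = 1
        v = np.zeros(96); v[10:20] = 1
        assert cosine(u, v) == 0.0

    def test_hand_computed_value(self):
        u = np.zeros(96); u[:3] = [1, 2, 2]
        v = np.zeros(96); v[:3] = [2, 1, 2]
        assert cosine(u, v) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(96), np.ones(96))


class TestDecompose:
    def test_exact_two_signature_mixture_recovered(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        t = 0.85 * cat["FIX1"].to_numpy() + 0.15 * cat["FIX2"].to_numpy()
        res = decompose(t, cat)
        assert sorted(res.signatures) == ["FIX1", "FIX2"]
        w = dict(zip(res.signatures, res.weights))
        assert w["FIX1"] == pytest.approx(0.85, abs=1e-6)
        assert w["FIX2"] == pytest.approx(0.15, abs=1e-6)
        assert res.cosine >= 1 - 1e-9

    def test_single_catalog_signature(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        res = decompose(cat["FIX3"].to_numpy(), cat)
        assert res.signatures == ["FIX3"] and res.weights[0] == pytest.approx(1.0)

    def test_greedy_trace_monotone(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = rng.dirichlet(np.ones(5))
            t = cat.to_numpy() @ w
            res = decompose(t, cat)
            cosines = [c for _, c in res.trace]
            assert all(b >= a - 1e-12 for a, b in zip(cosines, cosines[1:]))
            assert res.cosine >= max(cosine(t, cat[n]) for n in cat.columns) - 1e-12

    def test_weights_normalised_and_nonnegative(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        t = np.random.default_rng(9).random(96)
        res = decompose(t, cat)
        assert np.all(res.weights >= 0)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnormalised_catalog_warned_and_renormalised(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        scaled = cat * 3.0
        with pytest.warns(UserWarning, match="renormalising"):
            res = decompose(cat["FIX1"].to_numpy(), scaled)
        assert res.signatures == ["FIX1"]

    def test_final_residual_beats_any_subset(self, fixture_catalogs):
        # NNLS residual of the selection is <= that of each strict subset
        cat, _ = fixture_catalogs
        t = 0.5 * cat["FIX1"].to_numpy() + 0.3 * cat["FIX2"].to_numpy() + 0.2 * cat["FIX4"].to_numpy()
        res = decompose(t, cat)
        mat = cat[res.signatures].to_numpy()
        _, full_res = nnls(mat, t / t.sum())
        for r in range(1, len(res.signatures)):
            for sub in itertools.combinations(range(len(res.signatures)), r):
                _, sub_res = nnls(mat[:, list(sub)], t / t.sum())
                assert full_res <= sub_res + 1e-12


class TestBestMatch:
    def test_target_itself_ranks_first(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        ranking = best_match(cat["FIX2"].to_numpy(), cat)
        assert ranking.loc[0, "signature"] == "FIX2"
        assert ranking.loc[0, "cosine"] == pytest.approx(1.0)

    def test_ranking_matches_exhaustive_comparison(self):
        from denovokit.simdata import make_reference_catalogs

        cat, _ = make_reference_catalogs(12, seed=3)
        t = np.random.default_rng(1).random(96)
        ranking = best_match(t, cat)
        oracle = sorted(
            ((n, cosine(t, cat[n].to_numpy())) for n in cat.columns),
            key=lambda x: (-x[1], x[0]),
        )
        assert list(ranking["signature"]) == [n for n, _ in oracle]


class TestCollapseStrand:
    def test_symmetric_strands_modes_agree(self):
        half = pd.Series(np.random.default_rng(2).dirichlet(np.ones(96)) / 2, index=list(CHANNELS_96))
        cat = pd.DataFrame({"S1": np.concatenate([half, half])})
        cat.index = [f"T:{c}" for c in CHANNELS_96] + [f"U:{c}" for c in CHANNELS_96]
        drop = collapse_strand(cat, mode="drop")
        summed = collapse_strand(cat, mode="sum")
        assert np.allclose(drop.to_numpy(), summed.to_numpy(), atol=1e-12)

    def test_columns_sum_to_one(self, fixture_catalogs):
        _, cat192 = fixture_catalogs
        for mode in ("drop", "sum"):
            out = collapse_strand(cat192, mode=mode)
            assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)
            assert out.attrs["strand_collapse_mode"] == mode

    def test_sum_mode_equals_mean_of_strands(self, fixture_catalogs):
        _, cat192 = fixture_catalogs
        t = cat192.iloc[:96].to_numpy()
        u = cat192.iloc[96:].to_numpy()
        expect = (t + u) / (t + u).sum(axis=0, keepdims=True)
        out = collapse_strand(cat192, mode="sum")
        assert np.allclose(out.to_numpy(), expect, atol=1e-12)

    def test_unpaired_rows_rejected(self, fixture_catalogs):
        _, cat192 = fixture_catalogs
        with pytest.raises(ValueError, match="unpaired|missing"):
            collapse_strand(cat192.iloc[:-1])


class TestCatalogIO:
    def test_roundtrip(self, tmp_path, fixture_catalogs):
        cat, _ = fixture_catalogs
        p = tmp_path / "cat.tsv"
        write_catalog(cat, p)
        back = read_catalog(p)
        assert np.allclose(back.to_numpy(), cat.to_numpy(), atol=1e-9)

    def test_permuted_rows_rejected_by_default(self, tmp_path, fixture_catalogs):
        cat, _ = fixture_catalogs
        p = tmp_path / "perm.tsv"
        write_catalog(cat.iloc[::-1], p)
        with pytest.raises(ValueError, match="canonical"):
            read_catalog(p)
        with pytest.warns(UserWarning, match="reindexing"):
            back = read_catalog(p, strict_order=False)
        assert list(back.index) == list(CHANNELS_96)

    def test_incomplete_channel_set_rejected(self, tmp_path, fixture_catalogs):
        cat, _ = fixture_catalogs
        p = tmp_path / "short.tsv"
        write_catalog(cat.iloc[:-1], p)
        with pytest.raises(ValueError, match="96"):
            read_catalog(p)


class TestExtraction:
    def test_k1_is_normalised_pooled_spectrum(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        rng = np.random.default_rng(8)
        M = pd.DataFrame(
            rng.poisson(100 * cat.to_numpy()[:, :3] + 1.0), index=list(CHANNELS_96)
        )
        res = extract_signature(M, k_range=(1,), n_replicates=3, seed=0)
        pooled = M.sum(axis=1) / M.to_numpy().sum()
        assert np.allclose(res.signatures.iloc[:, 0].to_numpy(), pooled.to_numpy(), atol=1e-12)

    def test_two_component_recovery(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        S = cat[["FIX1", "FIX2"]].to_numpy()
        rng = np.random.default_rng(42)
        cols = [rng.multinomial(500, S @ rng.dirichlet([1.0, 1.0])) for _ in range(20)]
        M = pd.DataFrame(np.stack(cols, axis=1), index=list(CHANNELS_96))
        res = extract_signature(M, k_range=(1, 2, 3), n_replicates=10, seed=3)
        assert res.selected_k == 2
        for j in range(2):
            sig = res.signatures.iloc[:, j].to_numpy()
            assert max(cosine(sig, S[:, 0]), cosine(sig, S[:, 1])) >= 0.95

    def test_deterministic_for_fixed_seed(self, fixture_catalogs):
        cat, _ = fixture_catalogs
        rng = np.random.default_rng(4)
        M = pd.DataFrame(rng.poisson(60 * cat.to_numpy() + 0.5), index=list(CHANNELS_96))
        a = extract_signature(M, k_range=(1, 2), n_replicates=5, seed=11)
        b = extract_signature(M, k_range=(1, 2), n_replicates=5, seed=11)
        assert a.selected_k == b.selected_k
        assert np.array_equal(a.signatures.to_numpy(), b.signatures.to_numpy())

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            extract_signature(np.zeros((96, 3)), k_range=(1,))
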