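"""QC filters, normalization, HVG selection and comparison statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from tastools.io import CountMatrix, TastoolsError
from tastools.metrics import (GeneComparisonRecord, MvpGeneSelector,
                              compare_annotation_bias,
                              composition_correlation, detection_stats,
                              filter_cells_mito, filter_matrix,
                              find_variable_genes_mvp, holm_adjust,
                              kl_divergence_binned, kl_divergence_profiles,
                              normalize_log_cpm, pseudobulk, qc_proportions)
from tastools.synth import generate_platform_pair

from conftest import random_count_matrix


def dense_matrix(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(genes, cells, sp.csr_matrix(arr))


class TestFilterMatrix:
    def test_gene_prevalence_boundary(self):
        # one gene seen in 4 cells, another in 5; min_cells=5 keeps only
        # the second (min_genes=0 so no cell is dropped)
        arr = np.zeros((2, 6), dtype=int)
        arr[0, :4] = 1
        arr[1, :5] = 1
        out = filter_matrix(dense_matrix(arr), min_cells=5, min_genes=0)
        assert out.gene_ids == ["g1"]

    def test_genes_per_cell_boundary(self):
        # cells with 499 and 500 detected genes at min_genes=500
        arr = np.zeros((500, 2), dtype=int)
        arr[:499, 0] = 1
        arr[:, 1] = 1
        out = filter_matrix(dense_matrix(arr), min_cells=1, min_genes=500)
        assert out.barcode_ids == ["c1"]

    def test_all_pass_identity(self, toy_matrix):
        out = filter_matrix(toy_matrix, min_cells=1, min_genes=1)
        assert out.equals(toy_matrix)

    def test_empty_result_reports_survivors(self):
        with pytest.raises(TastoolsError, match="survived"):
            filter_matrix(dense_matrix([[1, 0], [0, 1]]), min_cells=5,
                          min_genes=1)


class TestQc:
    def test_mito_fraction_arithmetic(self):
        m = dense_matrix([[25], [75]], genes=["mt-Co1", "Actb"])
        rec = qc_proportions(m)[0]
        assert rec.mito_fraction == pytest.approx(0.25)
        assert rec.total_reads == 100

    def test_no_matching_genes_gives_zero(self):
        m = dense_matrix([[10]], genes=["Actb"])
        rec = qc_proportions(m)[0]
        assert rec.mito_fraction == 0.0
        assert rec.rrna_fraction == 0.0

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(0)
        m = random_count_matrix(rng, 40, 25)
        genes = [f"mt-{g}" if i < 5 else g
                 for i, g in enumerate(m.gene_ids)]
        m = CountMatrix(genes, m.barcode_ids, m.counts)
        records = qc_proportions(m)
        dense = m.to_dense()
        for j, rec in enumerate(records):
            total = dense[:, j].sum()
            expect = dense[:5, j].sum() / total if total else 0.0
            assert rec.mito_fraction == pytest.approx(expect)

    def test_mito_filter_boundary(self):
        m = dense_matrix([[25, 26, 0], [75, 74, 10]],
                         genes=["mt-Co1", "Actb"])
        records = qc_proportions(m)
        out = filter_cells_mito(records, m, threshold=0.25)
        # exactly 0.25 is retained (strict "over"), 0.26 removed
        assert out.barcode_ids == ["c0", "c2"]
        assert filter_cells_mito(records, m, 1.0).equals(m)


class TestNormalize:
    def test_formula_example(self):
        m = dense_matrix([[10], [990]])
        out = normalize_log_cpm(m)
        # 10 of 1000 reads at scale 1e6 -> ln(1 + 10,000)
        assert out.iloc[0, 0] == pytest.approx(np.log(1 + 10_000), abs=1e-10)

    def test_zero_count_maps_to_zero(self):
        out = normalize_log_cpm(dense_matrix([[0], [5]]))
        assert out.iloc[0, 0] == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        m = random_count_matrix(rng, 30, 20, density=0.9)
        out = normalize_log_cpm(m)
        dense = m.to_dense().astype(float)
        totals = dense.sum(axis=0)
        expect = np.log(1 + dense / totals[None, :] * 1e6)
        assert np.max(np.abs(out.to_numpy() - expect)) < 1e-12

    def test_preserves_per_cell_rank_order(self):
        rng = np.random.default_rng(2)
        m = random_count_matrix(rng, 30, 10, density=0.8)
        out = normalize_log_cpm(m).to_numpy()
        dense = m.to_dense()
        for j in range(10):
            assert np.array_equal(np.argsort(dense[:, j], kind="stable"),
                                  np.argsort(out[:, j], kind="stable"))

    def test_zero_total_cell_errors(self):
        with pytest.raises(TastoolsError, match="zero-total"):
            normalize_log_cpm(dense_matrix([[1, 0]]))


def mvp_oracle(norm, mean_cutoff, dispersion_cutoff, n_bins):
    """Plain-loop recomputation of the mvp recipe."""
    delogged = np.expm1(norm.to_numpy(dtype=float))
    selected = []
    stats = {}
    for i, g in enumerate(norm.index):
        vals = delogged[i]
        mu, var = vals.mean(), vals.var(ddof=1)
        disp = np.log(var / mu) if mu > 0 and var > 0 else -np.inf
        stats[g] = (mu, disp)
    finite = {g: v for g, v in stats.items() if np.isfinite(v[1])}
    mus = [v[0] for v in finite.values()]
    lo, hi = min(mus), max(mus)
    width = (hi - lo) or 1.0
    bins = {}
    for g, (mu, disp) in finite.items():
        b = min(int((mu - lo) / width * n_bins), n_bins - 1)
        bins.setdefault(b, []).append(g)
    z = {}
    for b, members in bins.items():
        ds = np.array([finite[g][1] for g in members])
        sd = ds.std(ddof=1) if len(ds) > 1 else 0.0
        for g in members:
            z[g] = (finite[g][1] - ds.mean()) / sd if sd > 0 else 0.0
    for g, (mu, disp) in finite.items():
        if mu >= mean_cutoff[0] and z[g] >= dispersion_cutoff[0]:
            selected.append(g)
    return set(selected)


class TestMvp:
    def test_constant_gene_excluded(self):
        arr = np.vstack([np.full(30, 5),
                         np.random.default_rng(0).integers(1, 50, (25, 30))])
        norm = normalize_log_cpm(dense_matrix(arr))
        sel = MvpGeneSelector(n_bins=5).fit(norm)
        assert "g0" not in sel.selected_genes_ or \
            sel.stats_.loc["g0", "dispersion_z"] >= 0.5
        # a gene constant across cells after normalization has zero
        # variance only when totals are equal; check the flag pathway
        flat = pd.DataFrame(np.vstack([np.full(30, 2.0),
                                       norm.to_numpy()[1:]]),
                            index=norm.index, columns=norm.columns)
        sel2 = MvpGeneSelector(n_bins=5).fit(flat)
        assert not sel2.stats_.loc["g0", "finite_dispersion"]
        assert "g0" not in sel2.selected_genes_

    def test_planted_overdispersed_gene_selected(self):
        rng = np.random.default_rng(3)
        # background genes span a range of means so every bin is populated
        base = rng.poisson(rng.uniform(5, 45, 60)[:, None], size=(60, 100))
        # mean inside the bulk but wildly overdispersed
        spiky = np.where(rng.random(100) < 0.5, 35, 5)
        arr = np.vstack([base, spiky[None, :]])
        norm = normalize_log_cpm(dense_matrix(arr))
        sel = find_variable_genes_mvp(norm)
        assert "g60" in sel

    def test_matches_step_by_step_recomputation(self):
        rng = np.random.default_rng(4)
        m = random_count_matrix(rng, 200, 100, density=0.4)
        norm = normalize_log_cpm(m)
        got = find_variable_genes_mvp(norm)
        oracle = mvp_oracle(norm, (0.1, None), (0.5, None), 20)
        assert got == oracle


class TestDetectionStats:
    def test_delta_threshold_classes(self):
        a = dense_matrix([[1] * 6 + [0] * 14,   # pct 0.30
                          [1] * 2 + [0] * 18])  # pct 0.10
        b = dense_matrix([[1] * 3 + [0] * 17,   # pct 0.15
                          [1] * 2 + [0] * 18])  # pct 0.10
        recs = {r.gene_id: r for r in detection_stats(a, b)}
        assert recs["g0"].delta == pytest.approx(0.15)
        assert recs["g0"].detection_class == "a_favored"
        assert recs["g1"].detection_class == "common"

    def test_exclusive_detection_overrides_threshold(self):
        a = dense_matrix([[1] + [0] * 19])   # pct 0.05
        b = dense_matrix([[0] * 20])         # absent
        rec = detection_stats(a, b)[0]
        assert rec.detection_class == "a_favored"

    def test_identical_matrices_all_common(self, toy_matrix):
        recs = detection_stats(toy_matrix, toy_matrix)
        assert all(r.detection_class == "common" for r in recs)
        assert all(r.delta == 0 for r in recs)

    def test_symmetry_negates_deltas_and_swaps_classes(self):
        a, b, _, _ = generate_platform_pair(n_genes=100, n_cells=200, seed=0)
        fwd = {r.gene_id: r for r in detection_stats(a, b)}
        rev = {r.gene_id: r for r in detection_stats(b, a)}
        swap = {"a_favored": "b_favored", "b_favored": "a_favored",
                "common": "common"}
        for g, r in fwd.items():
            assert rev[g].delta == pytest.approx(-r.delta)
            assert rev[g].detection_class == swap[r.detection_class]


class TestAnnotationBias:
    def test_holm_worked_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_identical_distributions_large_p(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.4, 0.6, 40)
        recs = ([GeneComparisonRecord(f"a{i}", 1, 0, 1, "a_favored",
                                      vals[i], 1000) for i in range(20)]
                + [GeneComparisonRecord(f"c{i}", 1, 1, 0, "common",
                                        vals[20 + i], 1000)
                   for i in range(20)])
        out = compare_annotation_bias(recs)
        gc_test = out["tests"].query("variable == 'gc_fraction'")
        assert gc_test["p_value"].iloc[0] > 0.2

    def test_planted_length_shift(self):
        rng = np.random.default_rng(6)
        base = rng.integers(1000, 3000, 30)
        recs = ([GeneComparisonRecord(f"a{i}", 1, 0, 1, "a_favored", 0.5,
                                      base[i] + 10_000) for i in range(30)]
                + [GeneComparisonRecord(f"c{i}", 1, 1, 0, "common", 0.5,
                                        base[i]) for i in range(30)])
        out = compare_annotation_bias(recs)
        s = out["summaries"]
        assert (s["a_favored"]["transcript_length"]["median"]
                - s["common"]["transcript_length"]["median"]) == 10_000
        lt = out["tests"].query("variable == 'transcript_length'")
        assert lt["p_holm"].iloc[0] < 1e-6


class TestPseudobulk:
    def test_rescaling_arithmetic(self):
        m = dense_matrix([[3], [1]])
        prof = pseudobulk(m, {"c0": "x"})["x"]
        assert prof.values == pytest.approx([7.5e6, 2.5e6])

    def test_totals_equal_target(self):
        rng = np.random.default_rng(7)
        m = random_count_matrix(rng, 50, 40)
        labels = {b: ("A" if j % 2 else "B")
                  for j, b in enumerate(m.barcode_ids)}
        profs = pseudobulk(m, labels)
        dense = m.to_dense()
        for lab, prof in profs.items():
            assert prof.values.sum() == pytest.approx(1e7, rel=1e-6)
            cols = [j for j, b in enumerate(m.barcode_ids)
                    if labels[b] == lab]
            raw = dense[:, cols].sum(axis=1)
            # proportional to the brute-force group sums
            assert prof.values == pytest.approx(raw / raw.sum() * 1e7)

    def test_unlabeled_cell_errors(self):
        m = dense_matrix([[1, 2]])
        with pytest.raises(TastoolsError, match="unlabeled"):
            pseudobulk(m, {"c0": "x"})


class TestKlDivergence:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(8)
        m = random_count_matrix(rng, 60, 30)
        prof = pseudobulk(m, {b: "x" for b in m.barcode_ids})["x"]
        assert kl_divergence_profiles(prof, prof) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_two_bin_hand_computation(self):
        expect = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_divergence_binned([0.5, 0.5], [0.9, 0.1]) == pytest.approx(
            expect, abs=1e-12)
        assert expect == pytest.approx(0.5108, abs=1e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12))
    def test_nonnegativity(self, p, q):
        n = min(len(p), len(q))
        assert kl_divergence_binned(p[:n], q[:n], epsilon=1e-9) >= -1e-12

    def test_asymmetric(self):
        p, q = [0.5, 0.5], [0.9, 0.1]
        assert kl_divergence_binned(p, q) != pytest.approx(
            kl_divergence_binned(q, p))


class TestCompositionCorrelation:
    def test_identical_vectors(self):
        r = composition_correlation([0.1, 0.3, 0.6], [0.1, 0.3, 0.6])
        assert r.pearson_r == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_relation(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        b = 2 * a - 0.05
        r = composition_correlation(a, b)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.slope == pytest.approx(0.5)  # regression of a on b

    def test_hand_computed_pearson(self):
        a, b = np.array([0.1, 0.3, 0.6]), np.array([0.2, 0.3, 0.5])
        expect = (np.sum((a - a.mean()) * (b - b.mean()))
                  / np.sqrt(np.sum((a - a.mean()) ** 2)
                            * np.sum((b - b.mean()) ** 2)))
        assert composition_correlation(a, b).pearson_r == pytest.approx(
            expect, abs=1e-12)

    def test_label_mismatch_raises(self):
        with pytest.raises(TastoolsError, match="label mismatch"):
            composition_correlation({"a": 0.5, "b": 0.5},
                                    {"a": 0.5, "c": 0.5})

    def test_zero_variance_raises(self):
        with pytest.raises(TastoolsError, match="zero-variance"):
            composition_correlation([0.5, 0.5, 0.5], [0.2, 0.3, 0.5])
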