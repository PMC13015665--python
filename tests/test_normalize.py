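import numpy as np
import pandas as pd
import pytest

from cftme.io import SingleCellMatrix
from cftme.normalize import (
    NormalizationConfig,
    filter_expressed,
    log2_cpm,
    pca_embed,
    pseudobulk,
    select_variable_genes,
    tmm_factors,
)
from conftest import make_norm


def brute_force_tmm(counts: np.ndarray, m_trim=0.30, a_trim=0.05):
    """Independent TMM oracle: explicit sort-based double trim and weighted
    mean, assuming no ties in M or A (generic fixtures)."""
    lib = counts.sum(axis=0)
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = []
    for j in range(counts.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        keep_genes = (counts[:, j] > 0) & (counts[:, ref] > 0)
        o = counts[keep_genes, j] / lib[j]
        r = counts[keep_genes, ref] / lib[ref]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        var = (lib[j] - counts[keep_genes, j]) / (lib[j] * counts[keep_genes, j]) + (
            lib[ref] - counts[keep_genes, ref]
        ) / (lib[ref] * counts[keep_genes, ref])
        n = m.size
        drop_m = int(np.floor(n * m_trim))
        drop_a = int(np.floor(n * a_trim))
        order_m = np.argsort(m)
        order_a = np.argsort(a)
        ok_m = np.zeros(n, bool)
        ok_m[order_m[drop_m : n - drop_m]] = True
        ok_a = np.zeros(n, bool)
        ok_a[order_a[drop_a : n - drop_a]] = True
        sel = ok_m & ok_a
        logf.append(np.sum(m[sel] / var[sel]) / np.sum(1.0 / var[sel]))
    logf = np.array(logf) - np.mean(logf)
    return 2.0**logf


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 3, 40])
        counts = pd.DataFrame(np.tile(col[:, None], 4), columns=list("abcd"))
        factors = tmm_factors(counts)
        assert np.all(factors.to_numpy() == 1.0)

    def test_uniform_scaling_cancels(self):
        # identical composition, one sample sequenced 10x deeper: depth
        # cancels in the M ratios, so every factor stays 1
        rng = np.random.default_rng(0)
        col = rng.integers(1, 300, size=60)
        counts = np.tile(col[:, None], 4)
        counts[:, 2] *= 10
        factors = tmm_factors(pd.DataFrame(counts))
        np.testing.assert_allclose(factors.to_numpy(), 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        # 4 samples x 50 genes with a strongly shifted gene block in sample 3
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 400, size=(50, 4))
        counts[:12, 3] *= 6
        factors = tmm_factors(pd.DataFrame(counts))
        oracle = brute_force_tmm(counts.astype(float))
        np.testing.assert_allclose(factors.to_numpy(), oracle, atol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 500, size=(200, 8)))
        counts = filter_expressed(counts)
        factors = tmm_factors(counts)
        assert np.exp(np.log(factors).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_no_shared_positive_genes_is_error(self):
        counts = pd.DataFrame({"a": [5, 0, 9], "b": [0, 7, 0]})
        with pytest.raises(ValueError, match="no positive genes"):
            tmm_factors(counts)

    def test_explicit_reference_sample(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 100, size=(80, 3)), columns=list("xyz"))
        factors = tmm_factors(counts, NormalizationConfig(reference_sample="y"))
        assert np.exp(np.log(factors).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Cross-check against Bioconductor edgeR on a small fixture."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        counts = rng.integers(5, 800, size=(120, 5)).astype(float)
        counts[:30, 1] *= 4
        np.savetxt(tmp_path / "counts.tsv", counts, delimiter="\t", fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            'x <- as.matrix(read.table("%s"))\n'
            "suppressMessages(library(edgeR))\n"
            "f <- calcNormFactors(x, method='TMM')\n"
            'cat(sprintf("%%.12f\\n", f))\n' % (tmp_path / "counts.tsv")
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=120)
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
        expected = np.array([float(v) for v in proc.stdout.split()])
        factors = tmm_factors(pd.DataFrame(counts))
        np.testing.assert_allclose(factors.to_numpy(), expected, atol=1e-6)


class TestLog2CPM:
    def _counts_with_lib(self, entries, total=1_000_000):
        filler = total - sum(entries)
        return pd.DataFrame({"s": list(entries) + [filler]})

    def test_zero_count_value(self):
        counts = self._counts_with_lib([0])
        norm = log2_cpm(counts)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(-1.0, abs=1e-12)  # log2(0.5)

    def test_known_arithmetic(self):
        counts = self._counts_with_lib([999])
        norm = log2_cpm(counts)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(np.log2(999.5), abs=1e-12)

    def test_monotone_in_counts(self):
        counts = pd.DataFrame({"s": [1, 2, 3, 1000]})
        values = log2_cpm(counts).logcpm["s"].to_numpy()
        assert np.all(np.diff(values[:3]) > 0)

    def test_scale_invariance(self):
        # doubling counts+pseudocount jointly with the effective library
        # leaves every entry unchanged
        c1 = pd.DataFrame({"s": [10, 90]})
        c2 = pd.DataFrame({"s": [20, 180]})
        n1 = log2_cpm(c1, config=NormalizationConfig(pseudocount=0.5)).logcpm
        n2 = log2_cpm(c2, config=NormalizationConfig(pseudocount=1.0)).logcpm
        np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy(), atol=1e-12)

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError, match="effective library"):
            log2_cpm(counts)

    def test_detection_mask_recovers_nonzero_counts(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 4, size=(50, 6)))
        counts = filter_expressed(counts)
        norm = log2_cpm(counts, tmm_factors(counts))
        pd.testing.assert_frame_equal(norm.detection_mask(), counts > 0)


def _sc_fixture(layout, n_genes=7):
    rng = np.random.default_rng(1)
    cells, samples, clusters = [], [], []
    for (s, c), n in layout.items():
        for _ in range(n):
            cells.append(rng.integers(0, 5, size=n_genes))
            samples.append(s)
            clusters.append(c)
    return SingleCellMatrix(
        counts=np.array(cells),
        genes=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(len(cells))],
        sample_labels=np.array(samples, dtype=object),
        cluster_labels=np.array(clusters, dtype=object),
    )


class TestPseudobulk:
    def test_sums_cells_within_sample_cluster(self):
        sc = SingleCellMatrix(
            counts=np.array([[1, 2], [3, 4]]),
            genes=["g1", "g2"],
            cell_ids=["c1", "c2"],
            sample_labels=np.array(["s", "s"], dtype=object),
            cluster_labels=np.array(["k", "k"], dtype=object),
        )
        res = pseudobulk(sc)
        assert list(res.counts["s|k"]) == [4, 6]

    def test_mass_conservation(self):
        layout = {(f"S{i}", f"K{j}"): 12 for i in range(3) for j in range(2)}
        sc = _sc_fixture(layout)
        res = pseudobulk(sc)
        assert res.counts.to_numpy().sum() == sc.counts.sum()

    def test_deficient_cluster_excluded(self):
        # cluster K2 has 5 cells in 4 of 5 samples -> deficient in >3 samples
        layout = {(f"S{i}", "K1"): 15 for i in range(5)}
        layout.update({(f"S{i}", "K2"): (5 if i < 4 else 15) for i in range(5)})
        res = pseudobulk(_sc_fixture(layout))
        assert res.excluded_clusters == ["K2"]

    def test_boundary_cluster_retained(self):
        # 9 cells in exactly 3 samples: the rule requires more than 3
        layout = {(f"S{i}", "K1"): (9 if i < 3 else 20) for i in range(5)}
        res = pseudobulk(_sc_fixture(layout))
        assert res.excluded_clusters == []
        assert not res.cluster_report["excluded"].any()


class TestVariableGenesAndPCA:
    def test_single_varying_gene(self):
        values = np.ones((5, 4))
        values[2] = [0, 1, 2, 3]
        norm = make_norm(values)
        assert select_variable_genes(norm, 1) == ["g2"]

    def test_n_equal_gene_count_returns_all(self, toy_norm):
        got = select_variable_genes(toy_norm, len(toy_norm.genes))
        assert sorted(got) == sorted(toy_norm.genes)

    def test_matches_variance_sort_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(100, 12)) * rng.uniform(0.1, 3.0, size=(100, 1))
        norm = make_norm(values)
        got = select_variable_genes(norm, 20)
        var = values.var(axis=1, ddof=1)
        expected = [f"g{i}" for i in np.argsort(-var)[:20]]
        assert set(got) == set(expected)

    def test_invalid_n_rejected(self, toy_norm):
        with pytest.raises(ValueError):
            select_variable_genes(toy_norm, 0)

    def test_perfectly_correlated_genes_give_single_component(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        norm = make_norm(np.vstack([base, 2 * base]))
        _, evr = pca_embed(norm, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_explained_variance_fractions_valid(self, toy_norm):
        _, evr = pca_embed(toy_norm, n_components=4)
        assert evr.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(10, 6))
        norm = make_norm(values)
        emb, evr = pca_embed(norm, n_components=3)
        x = values.T - values.T.mean(axis=0)
        cov = x.T @ x / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(-w)
        for k in range(3):
            expected = x @ v[:, order[k]]
            got = emb.iloc[:, k].to_numpy()
            agree = min(np.abs(got - expected).max(), np.abs(got + expected).max())
            assert agree < 1e-8
            assert evr[k] == pytest.approx(w[order[k]] * (x.shape[0] - 1) / (x**2).sum(), abs=1e-10)

    def test_pairwise_distances_preserved_full_rank(self, toy_norm):
        emb, _ = pca_embed(toy_norm, n_components=len(toy_norm.samples) - 1)
        x = toy_norm.logcpm.to_numpy().T
        x = x - x.mean(axis=0)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb.to_numpy()), pdist(x), atol=1e-8)

    def test_constant_input_is_error(self):
        norm = make_norm(np.ones((4, 3)))
        with pytest.raises(ValueError, match="constant"):
            pca_embed(norm, n_components=1)
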