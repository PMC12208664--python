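"""Tests for the measurement-side indices (GI/SI, GLORI-GI, TMM, LFC, PC1)."""

import numpy as np
import pandas as pd
import pytest

from m6adyn import (
    CountTable,
    ParameterError,
    glori_gene_index,
    m6a_gene_index,
    m6a_sample_index,
    nuc_cyt_lfc,
    pc1_loadings,
    tmm_factors,
)


def table(data: dict, lib=None) -> CountTable:
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    sizes = None
    if lib is not None:
        sizes = pd.Series(lib, index=df.columns, dtype=float)
    return CountTable(counts=df, library_sizes=sizes)


class TestGeneIndex:
    def test_definitional_ratio(self):
        # IP 200 of lib 1000 vs input 100 of lib 1000 -> GI = 2
        ip = table({"s1": [200, 800]}, lib=[1000])
        inp = table({"s1": [100, 900]}, lib=[1000])
        gi = m6a_gene_index(ip, inp).gi
        assert gi.loc["g0", "s1"] == pytest.approx(2.0)

    def test_proportional_tables_give_unit_index(self, rng):
        counts = rng.integers(50, 500, size=(30, 1))
        ip = table({"s1": 3 * counts[:, 0]})
        inp = table({"s1": counts[:, 0]})
        gi = m6a_gene_index(ip, inp).gi
        assert np.allclose(gi["s1"], 1.0)

    def test_depth_invariance(self, rng):
        counts = rng.integers(50, 500, size=(30, 1))
        ip = table({"s1": counts[:, 0] * 2})
        inp = table({"s1": counts[:, 0]})
        gi1 = m6a_gene_index(ip, inp).gi
        ip_deeper = table({"s1": counts[:, 0] * 20})
        gi2 = m6a_gene_index(ip_deeper, inp).gi
        pd.testing.assert_frame_equal(gi1, gi2)

    def test_low_input_reported_missing(self):
        ip = table({"s1": [50, 500]})
        inp = table({"s1": [5, 500]})  # g0 below the 20-read floor
        gi = m6a_gene_index(ip, inp).gi
        assert np.isnan(gi.loc["g0", "s1"])
        assert np.isfinite(gi.loc["g1", "s1"])

    def test_unpaired_samples_rejected(self):
        ip = table({"s1": [10], "s2": [10]})
        inp = table({"s1": [10]})
        with pytest.raises(ParameterError):
            m6a_gene_index(ip, inp)


class TestSampleIndex:
    def test_unit_indices_give_unit_si(self):
        ip = table({"s1": [100, 300, 600]}, lib=[1000])
        inp = table({"s1": [100, 300, 600]}, lib=[1000])
        si = m6a_sample_index(ip, inp)
        assert si["s1"] == pytest.approx(1.0)

    def test_linearity_in_gi(self):
        inp = table({"s1": [100, 300, 600]}, lib=[1000])
        ip = table({"s1": [100, 300, 600]}, lib=[1000])
        ip2 = table({"s1": [200, 600, 1200]}, lib=[1000])  # every GI doubled
        si, si2 = m6a_sample_index(ip, inp), m6a_sample_index(ip2, inp)
        assert si2["s1"] == pytest.approx(2 * si["s1"])


class TestGloriIndex:
    def test_worked_example(self):
        # coverage/score filters keep (25,0.5) and (30,0.3); 100 adenosines
        sites = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4"],
                "gene_id": ["g"] * 4,
                "coverage": [25, 30, 19, 50],
                "score": [0.5, 0.3, 0.9, 0.05],
                "in_drach": [True] * 4,
                "adenosine_count": [100] * 4,
            }
        )
        gi = glori_gene_index(sites)
        assert gi["g"] == pytest.approx(0.008)

    def test_score_threshold_is_strict(self):
        sites = pd.DataFrame(
            {
                "site_id": ["s1"], "gene_id": ["g"], "coverage": [100],
                "score": [0.1], "in_drach": [True], "adenosine_count": [10],
            }
        )
        assert glori_gene_index(sites)["g"] == 0.0

    def test_non_drach_sites_ignored(self):
        sites = pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "gene_id": ["g", "g"],
                "coverage": [100, 100],
                "score": [0.5, 0.9],
                "in_drach": [True, False],
                "adenosine_count": [10, 10],
            }
        )
        assert glori_gene_index(sites)["g"] == pytest.approx(0.05)

    def test_zero_adenosine_count_missing(self):
        sites = pd.DataFrame(
            {
                "site_id": ["s1"], "gene_id": ["g"], "coverage": [100],
                "score": [0.5], "in_drach": [True], "adenosine_count": [0],
            }
        )
        assert np.isnan(glori_gene_index(sites)["g"])

    def test_monotone_in_site_scores(self, rng):
        def make(score):
            return pd.DataFrame(
                {
                    "site_id": ["s1", "s2"], "gene_id": ["g", "g"],
                    "coverage": [50, 50], "score": [score, 0.4],
                    "in_drach": [True, True], "adenosine_count": [100, 100],
                }
            )

        lo = glori_gene_index(make(0.2))["g"]
        hi = glori_gene_index(make(0.6))["g"]
        assert hi > lo


class TestTMM:
    @staticmethod
    def toy_matrix():
        rng = np.random.default_rng(42)
        base = rng.gamma(2, 50, 200).round().astype(int) + 1
        counts = pd.DataFrame(
            {"s1": base, "s2": base * 2, "s3": rng.poisson(base).astype(int)}
        )
        s4 = base.copy()
        s4[:10] = s4[:10] * 10  # 5% of genes 10-fold up
        counts["s4"] = s4
        counts.index = [f"g{i}" for i in range(200)]
        return counts

    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_matches_reference_implementation(self):
        # frozen edgeR::calcNormFactors output for this exact matrix
        expected = [0.9998387607, 0.9998387607, 1.0004838740, 0.9998387607]
        got = tmm_factors(self.toy_matrix())
        assert np.allclose(got, expected, atol=1e-9)

    def test_pure_depth_difference_normalizes_away(self):
        counts = self.toy_matrix()[["s1", "s2"]]
        f = tmm_factors(counts)
        lib = counts.sum(axis=0) * f
        norm = counts / lib
        pd.testing.assert_frame_equal(
            norm["s1"].rename(None).to_frame(), norm["s2"].rename(None).to_frame()
        )

    def test_trimming_removes_outlier_genes(self):
        # s4 has 5% of genes 10-fold up; trimmed factor stays ~1
        f = tmm_factors(self.toy_matrix())
        assert abs(f["s4"] - 1.0) < 0.01

    def test_geometric_mean_is_one(self):
        f = tmm_factors(self.toy_matrix())
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ParameterError):
            tmm_factors(pd.DataFrame({"a": [1, 2]}))


class TestNucCytLFC:
    def test_fourfold_ratio_without_pseudocount(self):
        nuc = table({"n1": [200, 300]}, lib=[1000])
        cyt = table({"c1": [50, 450]}, lib=[1000])
        lfc = nuc_cyt_lfc(nuc, cyt, normalization="library_size", pseudocount=0.0)
        assert lfc.loc["g0"].iloc[0] == pytest.approx(2.0)

    def test_equal_counts_zero_lfc(self):
        nuc = table({"n1": [100, 200]})
        cyt = table({"c1": [100, 200]})
        lfc = nuc_cyt_lfc(nuc, cyt, normalization="library_size")
        assert np.allclose(lfc.iloc[:, 0], 0.0)

    def test_pseudocount_keeps_dropouts_finite(self):
        nuc = table({"n1": [0, 1000]})
        cyt = table({"c1": [500, 500]})
        lfc = nuc_cyt_lfc(nuc, cyt, normalization="library_size")
        assert np.isfinite(lfc.iloc[0, 0])


class TestPC1:
    @staticmethod
    def mirror_matrix(n_genes=20, n_samples=5):
        # half the genes rise geometrically across samples, half fall
        # (log2 makes the profiles exactly linear, so PC1 is exact)
        base = 2.0 ** np.linspace(0, 1, n_samples)
        up = np.tile(base, (n_genes // 2, 1))
        down = np.tile(base[::-1], (n_genes // 2, 1))
        X = np.vstack([up, down])
        return pd.DataFrame(
            X, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"t{j}" for j in range(n_samples)],
        )

    def test_mirror_matrix_splits_by_sign(self):
        res = pc1_loadings(self.mirror_matrix())
        assert res.explained_variance_ratio > 0.999
        assert (res.loadings.iloc[:10] > 0).all()
        assert (res.loadings.iloc[10:] < 0).all()
        assert np.linalg.norm(res.loadings) == pytest.approx(1.0)

    def test_sign_fixed_by_sample_order(self):
        res = pc1_loadings(self.mirror_matrix())
        # rising genes get positive loadings because the sample profile
        # is aligned with the declared (positional) order
        order = np.arange(5, dtype=float)
        assert np.corrcoef(res.sample_profile, order)[0, 1] > 0

    def test_gene_permutation_equivariance(self):
        mat = self.mirror_matrix()
        res = pc1_loadings(mat)
        perm = mat.sample(frac=1.0, random_state=3)
        res_p = pc1_loadings(perm)
        pd.testing.assert_series_equal(res.loadings.loc[perm.index], res_p.loadings)

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ParameterError):
            pc1_loadings(mat)

    def test_missing_entries_rejected(self):
        mat = self.mirror_matrix()
        mat.iloc[0, 0] = np.nan
        with pytest.raises(ParameterError):
            pc1_loadings(mat)
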