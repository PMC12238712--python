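import numpy as np
import pandas as pd
import pytest

from odontofa import FAMD, encode_mixed


def ca_indicator_eigenvalues(labels_by_var: dict[str, list]) -> np.ndarray:
    """Independent MCA oracle: correspondence analysis of the indicator matrix.

    Classic CA route (profile matrix, marginal weights), coded without
    reference to the package's standardized-column encoding.  Under the
    indicator-matrix convention with total inertia sum(K_j - 1), the
    mixed-data decomposition's eigenvalues equal J times the CA
    eigenvalues.
    """
    blocks = [pd.get_dummies(pd.Series(v)).to_numpy(float) for v in labels_by_var.values()]
    Z = np.hstack(blocks)
    J = len(labels_by_var)
    n = Z.shape[0]
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    sv = np.linalg.svd(S, compute_uv=False)
    eig = sv**2
    return J * eig[eig > 1e-12]


class TestLimits:
    def test_all_quantitative_equals_correlation_pca(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        eig = FAMD(X).fit().eigenvalues
        pca_eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X.to_numpy().T)))[::-1]
        assert eig == pytest.approx(pca_eig, abs=1e-8)

    def test_all_categorical_equals_mca(self, rng):
        data = {
            "g": list(rng.choice(list("ABC"), 60)),
            "h": list(rng.choice(["x", "y"], 60)),
            "k": list(rng.choice(["u", "v", "w", "q"], 60)),
        }
        eig = FAMD(pd.DataFrame(data)).fit().eigenvalues
        mca = ca_indicator_eigenvalues(data)
        assert eig == pytest.approx(np.sort(mca)[::-1], abs=1e-8)

    def test_single_quantitative_variable_inertia_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        res = FAMD(X).fit()
        assert res.total_inertia == pytest.approx(1.0, abs=1e-10)

    def test_single_balanced_binary_inertia_one(self):
        X = pd.DataFrame({"g": ["a", "b"] * 10})
        res = FAMD(X).fit()
        assert res.total_inertia == pytest.approx(1.0, abs=1e-10)


class TestEncoding:
    def test_hand_encoded_toy_table(self):
        # 4 individuals, 1 quantitative + 1 binary categorical
        df = pd.DataFrame({"q": [1.0, 2.0, 3.0, 4.0], "g": ["a", "a", "b", "b"]})
        enc = encode_mixed(df)
        q = np.array([1.0, 2.0, 3.0, 4.0])
        zq = (q - 2.5) / q.std(ddof=0)
        # category column: indicator / sqrt(p) - sqrt(p), p = 0.5
        p = 0.5
        za = np.array([1, 1, 0, 0]) / np.sqrt(p) - np.sqrt(p)
        zb = np.array([0, 0, 1, 1]) / np.sqrt(p) - np.sqrt(p)
        expected = np.column_stack([zq, za, zb])
        assert enc.X == pytest.approx(expected)
        assert enc.columns == ["q", "g=a", "g=b"]
        assert enc.total_inertia == pytest.approx(2.0)

    def test_quantitative_columns_standardized(self, rng):
        df = pd.DataFrame({"q": rng.normal(3, 2, 30), "r": rng.normal(size=30)})
        enc = encode_mixed(df)
        assert enc.X.mean(axis=0) == pytest.approx(np.zeros(2), abs=1e-10)
        assert enc.X.std(axis=0, ddof=0) == pytest.approx(np.ones(2), abs=1e-10)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            encode_mixed(pd.DataFrame({"q": [1.0, np.nan]}))

    def test_single_level_categorical_rejected(self):
        with pytest.raises(ValueError, match="'g'"):
            encode_mixed(pd.DataFrame({"g": ["a", "a", "a"], "q": [1.0, 2.0, 3.0]}))

    def test_zero_variance_quantitative_rejected(self):
        with pytest.raises(ValueError, match="'q'"):
            encode_mixed(pd.DataFrame({"q": [1.0, 1.0, 1.0], "g": ["a", "b", "a"]}))


def toy_mixed_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "q1": [2.0, 4.0, 6.0, 3.0, 5.0, 1.0],
            "q2": [1.0, 0.5, 0.2, 0.9, 0.1, 0.6],
            "g": ["a", "b", "a", "b", "a", "b"],
        }
    )


def dense_svd_oracle(df: pd.DataFrame):
    """Independently coded decomposition of the same 6x3 mixed table."""
    n = len(df)
    cols = []
    for c in ("q1", "q2"):
        x = df[c].to_numpy()
        cols.append((x - x.mean()) / x.std(ddof=0))
    for lv in ("a", "b"):
        ind = (df["g"] == lv).to_numpy(float)
        p = ind.mean()
        cols.append(ind / np.sqrt(p) - np.sqrt(p))
    M = np.column_stack(cols) / np.sqrt(n)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return M, U, s, Vt


class TestDecomposition:
    def test_toy_mixed_table_matches_dense_svd_oracle(self):
        df = toy_mixed_table()
        res = FAMD(df).fit()
        M, U, s, Vt = dense_svd_oracle(df)
        keep = s**2 > 1e-12
        assert res.eigenvalues == pytest.approx(s[keep] ** 2, abs=1e-10)
        # coordinates compared up to the sign convention
        F = np.sqrt(len(df)) * U[:, keep] * s[keep]
        got = res.row_coordinates.to_numpy()
        for l in range(got.shape[1]):
            assert got[:, l] == pytest.approx(F[:, l], abs=1e-8) or got[:, l] == pytest.approx(
                -F[:, l], abs=1e-8
            )
        ctr = 100 * Vt[keep, :].T ** 2
        assert res.column_contributions_pct.to_numpy() == pytest.approx(ctr, abs=1e-8)

    def test_contributions_sum_to_100(self, rng):
        df = pd.DataFrame(
            {
                "q": rng.normal(size=30),
                "g": rng.choice(["a", "b", "c"], 30),
                "h": rng.choice(["x", "y"], 30),
            }
        )
        res = FAMD(df).fit()
        sums = res.column_contributions_pct.sum(axis=0)
        assert sums.to_numpy() == pytest.approx(np.full(res.n_components, 100.0), abs=1e-6)
        var_sums = res.variable_contributions_pct.sum(axis=0)
        assert var_sums.to_numpy() == pytest.approx(np.full(res.n_components, 100.0), abs=1e-6)

    def test_row_coordinate_variance_equals_eigenvalue(self, rng):
        df = pd.DataFrame({"q": rng.normal(size=50), "r": rng.normal(size=50)})
        res = FAMD(df).fit()
        var = res.row_coordinates.to_numpy().var(axis=0, ddof=0)
        assert var == pytest.approx(res.eigenvalues, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        df = pd.DataFrame({"q": rng.normal(size=15), "g": rng.choice(["a", "b"], 15)})
        model = FAMD(df)
        res = model.fit()
        assert np.abs(res.reconstruct() - model.encoded.X).max() < 1e-8

    def test_row_permutation_permutes_coordinates(self, rng):
        df = toy_mixed_table()
        perm = rng.permutation(len(df))
        res1 = FAMD(df).fit()
        res2 = FAMD(df.iloc[perm].reset_index(drop=True)).fit()
        got = res2.row_coordinates.to_numpy()
        want = res1.row_coordinates.to_numpy()[perm]
        # per-dimension sign is a convention, not an invariant
        for l in range(got.shape[1]):
            assert got[:, l] == pytest.approx(want[:, l], abs=1e-8) or got[:, l] == pytest.approx(
                -want[:, l], abs=1e-8
            )

    def test_column_permutation_preserves_eigenvalues(self):
        df = toy_mixed_table()
        res1 = FAMD(df).fit()
        res2 = FAMD(df[["g", "q2", "q1"]]).fit()
        assert res2.eigenvalues == pytest.approx(res1.eigenvalues, abs=1e-10)

    def test_ndim_beyond_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            FAMD(toy_mixed_table()).fit(10)


class TestReporting:
    def test_screeplot_percentages(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        res = FAMD(df).fit()
        scree = res.screeplot_data()
        assert scree["percent_variance"].sum() == pytest.approx(100.0)
        assert scree["cumulative_percent"].is_monotonic_increasing
        assert scree["cumulative_percent"].iloc[-1] == pytest.approx(100.0)
        expected = 100 * res.eigenvalues / res.eigenvalues.sum()
        assert scree["percent_variance"].to_numpy() == pytest.approx(expected)

    def test_single_dimension_is_all_variance(self, rng):
        x = rng.normal(size=25)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = FAMD(df).fit(1)
        assert res.screeplot_data()["percent_variance"].iloc[0] == pytest.approx(100.0)

    def test_dimension_defining_variable_ranks_first(self, rng):
        z = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "driver": z,
                "echo": z + rng.normal(0, 0.05, 200),
                "noise1": rng.normal(size=200),
                "noise2": rng.normal(size=200),
            }
        )
        res = FAMD(df).fit(2)
        top = res.top_contributors(1, k=2)
        assert set(top.index) == {"driver", "echo"}

    def test_top_contributors_matches_oracle_ranking(self):
        df = toy_mixed_table()
        res = FAMD(df).fit()
        top = res.top_contributors(1, k=3, by="column")
        ctr = res.column_contributions_pct["dim1"]
        assert list(top["contribution_pct"]) == sorted(ctr, reverse=True)[:3]

    def test_out_of_range_dim_rejected(self):
        res = FAMD(toy_mixed_table()).fit(2)
        with pytest.raises(ValueError):
            res.top_contributors(5)

    def test_four_factor_cohort_scree_elbow(self, default_cohort):
        """Four latent factors drive the covariates: the 4 leading eigenvalues
        stand above the noise bulk."""
        from odontofa import impute_famd

        imp = impute_famd(default_cohort.covariates, ncp=5, schema=default_cohort.schema)
        res = FAMD.from_completed(imp).fit(10)
        eig = res.eigenvalues
        bulk_top = eig[4]
        assert np.all(eig[:4] > bulk_top)
        assert eig[0] > 1.5 * np.median(eig[eig > 1e-10])
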