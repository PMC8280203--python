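import numpy as np
import pandas as pd
import pytest

from scmirna import metrics as mx
from scmirna import simulate as sim


class TestCoefficientOfVariation:
    def test_equimolar_perfection_is_zero(self):
        s = pd.Series([100.0, 100.0, 100.0], index=list("abc"))
        assert mx.coefficient_of_variation(s) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert mx.coefficient_of_variation(s) == pytest.approx(0.5)  # sd 1 / mean 2

    def test_zeros_included_via_reindex(self):
        s = pd.Series([2.0, 2.0], index=["a", "b"])
        cv_all = mx.coefficient_of_variation(s, all_feature_ids=["a", "b", "c", "d"])
        assert cv_all > 0.5  # two dropouts double the spread
        assert mx.coefficient_of_variation(
            s, all_feature_ids=["a", "b", "c"], detected_only=True
        ) == pytest.approx(0.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            mx.coefficient_of_variation(pd.Series([0.0, 0.0]))

    def test_bias_noise_increases_cv(self, refs_small, arch):
        # same seeds elsewhere, larger per-feature lognormal noise -> larger CV
        from scmirna import preprocess as pp
        from scmirna import quantify as qt

        cvs = []
        for sigma in (0.0, 1.0):
            cfg = sim.LibrarySimConfig(
                n_reads=8000, frac_dimer=0, frac_other_rna=0, frac_junk=0,
                bias_beta_g=0, bias_sigma=sigma, pcr_mean_reads_per_molecule=1,
                seq_error_rate=0, low_quality_tail_frac=0, seed=31, bias_seed=7,
            )
            lib = sim.simulate_library(refs_small, arch, cfg)
            kept, _ = pp.preprocess_reads(lib.reads, pp.TrimConfig(), umi_len=8)
            hits = qt.map_to_reference(kept, refs_small)
            m = qt.count_features({"s": hits}, refs_small.feature_ids)
            rpmm = qt.rpmm_normalize(m.layer("raw"))
            cvs.append(
                mx.coefficient_of_variation(rpmm["s"], all_feature_ids=refs_small.feature_ids)
            )
        assert cvs[1] > cvs[0]


class TestReproducibilityDistances:
    def test_identical_columns_zero_distance(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["f1", "f2"])
        d = mx.reproducibility_distances(m, {"a": "P", "b": "P"})
        assert d.distance.iloc[0] == pytest.approx(0.0)
        assert d.kind.iloc[0] == "within"

    def test_hand_arithmetic(self):
        # log2(0+1)=0, log2(3+1)=2 -> distance sqrt(2^2 + 2^2)
        m = pd.DataFrame({"a": [0.0, 3.0], "b": [3.0, 0.0]}, index=["f1", "f2"])
        d = mx.reproducibility_distances(m, {"a": "P", "b": "Q"}, pseudocount=1.0)
        assert d.distance.iloc[0] == pytest.approx(np.sqrt(8))
        assert d.kind.iloc[0] == "between"

    def test_nonredundant_pairs(self):
        m = pd.DataFrame(
            np.arange(12.0).reshape(3, 4),
            index=list("fgh"),
            columns=list("abcd"),
        )
        d = mx.reproducibility_distances(m, dict.fromkeys("abcd", "P"))
        assert len(d) == 6  # 4 choose 2

    def test_unknown_group_rejected(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["f"])
        with pytest.raises(ValueError, match="without a group"):
            mx.reproducibility_distances(m, {"a": "P"})

    def test_triangle_inequality_spot_check(self, rng):
        m = pd.DataFrame(
            rng.poisson(20, size=(30, 3)).astype(float),
            index=[f"f{i}" for i in range(30)],
            columns=list("abc"),
        )
        d = mx.reproducibility_distances(m, dict.fromkeys("abc", "P"))
        dist = {(r.sample_a, r.sample_b): r.distance for r in d.itertuples()}
        ab, ac, bc = dist[("a", "b")], dist[("a", "c")], dist[("b", "c")]
        assert ab <= ac + bc + 1e-9
        assert ac <= ab + bc + 1e-9
        assert bc <= ab + ac + 1e-9


class TestGcontentAssociation:
    def test_monotone_rates_give_rho_one(self, refs_small):
        g = refs_small.g_content_series()
        rho, p = mx.gcontent_detection_association(refs_small, g * 0.9 + 0.05)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_reversed_monotone_minus_one(self, refs_small):
        g = refs_small.g_content_series()
        rho, _ = mx.gcontent_detection_association(refs_small, 1.0 - g)
        assert rho == pytest.approx(-1.0)

    def test_constant_rates_undefined(self, refs_small):
        rates = pd.Series(1.0, index=refs_small.feature_ids)
        rho, p = mx.gcontent_detection_association(refs_small, rates)
        assert np.isnan(rho)


class TestCellQc:
    def test_negative_control_filtering(self):
        totals = pd.Series({"cell1": 60, "neg1": 7, "neg2": 14})
        assert mx.filter_cells(totals, 50) == ["cell1"]

    def test_zero_threshold_keeps_all(self):
        totals = pd.Series({"a": 0, "b": 3})
        assert set(mx.filter_cells(totals, 0)) == {"a", "b"}

    def test_all_below_warns_empty(self):
        with pytest.warns(UserWarning):
            assert mx.filter_cells(pd.Series({"a": 1}), 50) == []

    def test_monotone_in_threshold(self):
        totals = pd.Series({"a": 10, "b": 49, "c": 50, "d": 400})
        kept = [len(mx.filter_cells(totals, t)) for t in (0, 10, 50, 100, 1000)]
        assert kept == sorted(kept, reverse=True)


class TestLognormalize:
    def test_zero_stays_zero(self):
        raw = pd.DataFrame({"s": [0, 5]}, index=["a", "b"])
        out = mx.lognormalize(raw)
        assert out.loc["a", "s"] == 0.0

    def test_closed_form_single_feature(self):
        raw = pd.DataFrame({"s": [5]}, index=["a"])
        out = mx.lognormalize(raw, scale=1e4)
        assert out.loc["a", "s"] == pytest.approx(np.log(10001), rel=1e-9)

    def test_conservation_of_scale(self):
        raw = pd.DataFrame({"s": [3, 7, 10]}, index=list("abc"))
        out = mx.lognormalize(raw, scale=1e4)
        assert (np.exp(out["s"]) - 1).sum() == pytest.approx(1e4)


class TestVariableFeatures:
    @staticmethod
    def _homogeneous(rng, n_feat=120, n_samp=24):
        lam = rng.uniform(5, 200, size=n_feat)
        X = rng.poisson(lam[:, None], size=(n_feat, n_samp)).astype(float)
        return pd.DataFrame(
            X, index=[f"f{i}" for i in range(n_feat)],
            columns=[f"s{j}" for j in range(n_samp)],
        )

    def test_bimodal_spike_ranks_first(self, rng):
        raw = self._homogeneous(rng)
        half = raw.shape[1] // 2
        raw.loc["f0"] = np.r_[np.full(half, 10.0), np.full(raw.shape[1] - half, 100.0)]
        assert mx.variable_features(raw, n=5)[0] == "f0"

    def test_zero_variance_ranks_last(self, rng):
        raw = self._homogeneous(rng)
        raw.loc["f1"] = 50.0
        ranked = mx.variable_features(raw, n=raw.shape[0])
        assert ranked[-1] == "f1" or ranked.index("f1") > len(ranked) - 5

    def test_requesting_all_returns_all_deterministically(self, rng):
        raw = self._homogeneous(rng, n_feat=40)
        a = mx.variable_features(raw, n=40)
        b = mx.variable_features(raw, n=40)
        assert a == b
        assert set(a) == set(raw.index)


class TestEmbedAndCluster:
    @staticmethod
    def _two_groups(seed=0, n_per=6, n_feat=60):
        rng = np.random.default_rng(seed)
        base_a = rng.uniform(1, 4, n_feat)
        base_b = base_a.copy()
        base_b[: n_feat // 2] += 4.0  # strong group shift
        cols, data = [], []
        for g, base in (("A", base_a), ("B", base_b)):
            for i in range(n_per):
                cols.append(f"{g}{i}")
                data.append(base + rng.normal(0, 0.15, n_feat))
        X = pd.DataFrame(
            np.array(data).T, index=[f"f{i}" for i in range(n_feat)], columns=cols
        )
        truth = pd.Series([c[0] for c in cols], index=cols)
        return X, truth

    def test_two_groups_recovered(self):
        X, truth = self._two_groups()
        cfg = mx.ClusterConfig(n_pcs=4, snn_k=5, umap_neighbors=4, seed=0,
                               louvain_resolution=1.0)
        emb, labels = mx.embed_and_cluster(X, cfg)
        assert emb.shape == (12, 2)
        assert mx.adjusted_mutual_information(labels, truth) == pytest.approx(1.0)

    def test_identical_samples_one_cluster(self):
        X = pd.DataFrame(
            np.tile(np.arange(30.0)[:, None], (1, 8)),
            index=[f"f{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(8)],
        )
        cfg = mx.ClusterConfig(n_pcs=2, snn_k=4, umap_neighbors=3, seed=1,
                               louvain_resolution=1.0)
        _emb, labels = mx.embed_and_cluster(X, cfg)
        assert labels.nunique() == 1

    def test_deterministic_given_seed(self):
        X, _ = self._two_groups(seed=3)
        cfg = mx.ClusterConfig(n_pcs=3, snn_k=4, umap_neighbors=4, seed=7,
                               louvain_resolution=1.0)
        emb1, lab1 = mx.embed_and_cluster(X, cfg)
        emb2, lab2 = mx.embed_and_cluster(X, cfg)
        pd.testing.assert_frame_equal(emb1, emb2)
        assert list(lab1) == list(lab2)

    def test_feature_order_invariant_labels(self):
        X, _ = self._two_groups(seed=5)
        cfg = mx.ClusterConfig(n_pcs=3, snn_k=4, umap_neighbors=4, seed=2,
                               louvain_resolution=1.0)
        _e1, lab1 = mx.embed_and_cluster(X, cfg)
        _e2, lab2 = mx.embed_and_cluster(X.iloc[::-1], cfg)
        assert mx.adjusted_mutual_information(lab1, lab2) == pytest.approx(1.0)

    def test_too_few_samples_raises(self):
        X = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            mx.embed_and_cluster(X, mx.ClusterConfig(n_pcs=15))


class TestAmi:
    def test_identical_labelings(self):
        assert mx.adjusted_mutual_information(list("AABB"), list("XXYY")) == pytest.approx(1.0)

    def test_constant_labeling_zero(self):
        assert mx.adjusted_mutual_information(list("AABB"), list("XXXX")) == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mx.adjusted_mutual_information([1, 2], [1])

    def test_against_direct_formula(self):
        # fixed 3x3 contingency; AMI computed from the definition:
        # (MI - E[MI]) / (mean(H_a, H_b) - E[MI]) with the hypergeometric
        # expected MI
        import math
        from scipy.special import gammaln

        a = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2]
        b = [0, 0, 1, 1, 1, 2, 0, 2, 2, 1, 0, 2]
        n = len(a)
        from collections import Counter

        na = Counter(a)
        nb = Counter(b)
        nij = Counter(zip(a, b))
        mi = sum(
            (c / n) * math.log((c / n) / ((na[i] / n) * (nb[j] / n)))
            for (i, j), c in nij.items()
        )
        ha = -sum((c / n) * math.log(c / n) for c in na.values())
        hb = -sum((c / n) * math.log(c / n) for c in nb.values())
        emi = 0.0
        for ai in na.values():
            for bj in nb.values():
                lo, hi = max(1, ai + bj - n), min(ai, bj)
                for k in range(lo, hi + 1):
                    p = math.exp(
                        gammaln(ai + 1) + gammaln(bj + 1)
                        + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                        - gammaln(n + 1) - gammaln(k + 1)
                        - gammaln(ai - k + 1) - gammaln(bj - k + 1)
                        - gammaln(n - ai - bj + k + 1)
                    )
                    emi += p * (k / n) * math.log(n * k / (ai * bj))
        expected = (mi - emi) / ((ha + hb) / 2 - emi)
        assert mx.adjusted_mutual_information(a, b) == pytest.approx(expected, abs=1e-9)
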