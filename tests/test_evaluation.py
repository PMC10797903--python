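"""AUPR, R^2, Fisher enrichment, and the NCA two-stage baseline."""

import numpy as np
import pandas as pd
import pytest

import primegrn as pg
from primegrn.erv import RankedEdgeList
from conftest import oracle_aupr, oracle_fisher_one_sided


def ranked_from_pairs(pairs, scores=None):
    scores = scores if scores is not None else list(range(len(pairs), 0, -1))
    t = pd.DataFrame({
        "regulator": [p[0] for p in pairs],
        "gene": [p[1] for p in pairs],
        "erv": scores,
        "sign": 1,
    })
    t["rank"] = np.arange(1, len(t) + 1)
    return RankedEdgeList(t)


class TestAupr:
    def test_perfect_ranking(self):
        pairs = [("t", f"g{i}") for i in range(6)]
        gold = pg.EdgeSet(edges=set(pairs[:2]))
        uni = pg.EdgeSet(edges=set(pairs))
        res = pg.aupr(ranked_from_pairs(pairs), gold, uni)
        assert res.aupr == 1.0

    def test_true_false_true_is_five_sixths(self):
        pairs = [("t", "g0"), ("t", "g1"), ("t", "g2")]
        gold = pg.EdgeSet(edges={("t", "g0"), ("t", "g2")})
        uni = pg.EdgeSet(edges=set(pairs))
        res = pg.aupr(ranked_from_pairs(pairs), gold, uni)
        assert res.aupr == pytest.approx(5 / 6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        pairs = [("t", f"g{i}") for i in range(30)]
        gold_idx = rng.choice(30, 7, replace=False)
        gold = pg.EdgeSet(edges={pairs[i] for i in gold_idx})
        uni = pg.EdgeSet(edges=set(pairs))
        res = pg.aupr(ranked_from_pairs(pairs), gold, uni)
        labels = [p in gold.edges for p in pairs]
        assert res.aupr == pytest.approx(oracle_aupr(labels, 7))

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(1)
        pairs = [("t", f"g{i}") for i in range(50)]
        scores = rng.normal(size=50)
        order = np.argsort(-scores)
        gold = pg.EdgeSet(edges={pairs[i] for i in rng.choice(50, 10, replace=False)})
        uni = pg.EdgeSet(edges=set(pairs))
        ranked = ranked_from_pairs([pairs[i] for i in order],
                                   scores=sorted(scores, reverse=True))
        res = pg.aupr(ranked, gold, uni)
        y = np.array([p in gold.edges for p in pairs])
        assert res.aupr == pytest.approx(average_precision_score(y, scores))

    def test_random_ranking_converges_to_density(self):
        # exact permutation-null expectation of average precision:
        # E[AP] = (1/P) sum_r (1/r) * (P/n) * (1 + (r-1)(P-1)/(n-1)),
        # which approaches the positive density P/n for large n
        rng = np.random.default_rng(2)
        n, n_pos = 400, 40
        ranks = np.arange(1, n + 1)
        null_mean = float(np.sum(
            (1 / ranks) * (n_pos / n) * (1 + (ranks - 1) * (n_pos - 1) / (n - 1))
        ) / n_pos)
        pairs = [("t", f"g{i}") for i in range(n)]
        gold = pg.EdgeSet(edges=set(pairs[:n_pos]))
        uni = pg.EdgeSet(edges=set(pairs))
        auprs = []
        for _ in range(1000):
            perm = rng.permutation(n)
            auprs.append(pg.aupr(ranked_from_pairs([pairs[i] for i in perm]),
                                 gold, uni).aupr)
        assert np.mean(auprs) == pytest.approx(null_mean, rel=0.03)
        assert null_mean == pytest.approx(n_pos / n, rel=0.25)

    def test_unranked_candidates_appended(self):
        pairs = [("t", "g0")]
        gold = pg.EdgeSet(edges={("t", "g0"), ("t", "g1")})
        uni = pg.EdgeSet(edges={("t", "g0"), ("t", "g1"), ("t", "g2")})
        res = pg.aupr(ranked_from_pairs(pairs), gold, uni)
        assert res.n_candidates == 3
        # g0 at rank 1 (hit), g1 appended at rank 2 (hit), g2 rank 3
        assert res.aupr == pytest.approx((1 / 1 + 2 / 2) / 2)

    def test_empty_gold_rejected(self):
        uni = pg.EdgeSet(edges={("t", "g0")})
        with pytest.raises(ValueError, match="gold"):
            pg.aupr(ranked_from_pairs([("t", "g0")]), pg.EdgeSet(edges=set()), uni)

    def test_gold_outside_universe_rejected(self):
        uni = pg.EdgeSet(edges={("t", "g0")})
        gold = pg.EdgeSet(edges={("t", "gX")})
        with pytest.raises(ValueError, match="universe"):
            pg.aupr(ranked_from_pairs([("t", "g0")]), gold, uni)


class TestRSquared:
    def test_perfect_prediction(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        assert pg.r_squared(x, x) == 1.0

    def test_mean_predictor_scores_zero(self):
        x = np.random.default_rng(1).normal(size=(10, 4))
        assert pg.r_squared(x, np.full_like(x, x.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        x = np.random.default_rng(2).normal(size=(10, 4))
        assert pg.r_squared(x, x + 10) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pg.r_squared(np.ones((3, 3)), np.ones((3, 3)))

    def test_per_gene_variant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 3))
        xh = x.copy()
        xh[:, 0] = x[:, 0].mean()
        out = pg.r_squared(x, xh, per_gene=True)
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0) and out[2] == pytest.approx(1.0)


class TestFisherEnrichment:
    def _erv_pair(self, a_vals, b_vals, genes, tfs):
        from primegrn.erv import ERVMatrix
        return (ERVMatrix(a_vals, genes, tfs, "tf"),
                ERVMatrix(b_vals, genes, tfs, "tf"))

    def test_cross_product_odds_ratio(self):
        # engineered to give the 2x2 table [[10,2],[3,15]] -> OR 25
        genes = [f"g{i}" for i in range(30)]
        ann = {}
        a = np.zeros((30, 1))
        b = np.zeros((30, 1))
        i = 0
        for n, (cls, annot) in [(10, ("A", "A")), (2, ("A", "B")),
                                (3, ("B", "A")), (15, ("B", "B"))]:
            for _ in range(n):
                if cls == "A":
                    a[i, 0], b[i, 0] = 0.5, 0.2
                else:
                    a[i, 0], b[i, 0] = 0.2, 0.5
                ann[genes[i]] = annot
                i += 1
        ea, eb = self._erv_pair(a, b, genes, ["t"])
        res = pg.fisher_context_enrichment(ea, eb, ann)
        np.testing.assert_array_equal(res.table, [[10, 2], [3, 15]])
        assert res.odds_ratio == pytest.approx(25.0)

    def test_p_matches_hypergeometric_oracle(self):
        # all 2x2 tables with margins <= 12
        from scipy import stats
        for a in range(1, 6):
            for b in range(1, 6):
                for c in range(1, 6):
                    for d in range(1, 6):
                        table = [[a, b], [c, d]]
                        p_scipy = stats.fisher_exact(table, alternative="greater")[1]
                        assert p_scipy == pytest.approx(
                            oracle_fisher_one_sided(table), abs=1e-12)

    def test_ties_dropped_and_counted(self):
        genes = ["g0", "g1", "g2"]
        a = np.array([[0.5], [0.5], [0.3]])
        b = np.array([[0.5], [0.2], [0.6]])
        ann = {"g0": "A", "g1": "A", "g2": "B"}
        ea, eb = self._erv_pair(a, b, genes, ["t"])
        res = pg.fisher_context_enrichment(ea, eb, ann)
        assert res.n_ties_dropped == 1
        assert res.table.sum() == 2

    def test_degenerate_margin_rejected(self):
        genes = ["g0", "g1"]
        a = np.array([[0.5], [0.4]])
        b = np.array([[0.1], [0.1]])
        ann = {"g0": "A", "g1": "A"}  # nothing annotated B -> zero margin
        ea, eb = self._erv_pair(a, b, genes, ["t"])
        with pytest.raises(ValueError, match="margin"):
            pg.fisher_context_enrichment(ea, eb, ann)


class TestNCA:
    def test_identity_prior_returns_data(self):
        y = np.random.default_rng(0).normal(size=(8, 3))
        p = pg.PriorMatrix(["g0", "g1", "g2"], ["t0", "t1", "t2"], np.eye(3))
        fit = pg.nca_estimate_tfa(y, p)
        np.testing.assert_allclose(fit.tfa, y, atol=1e-10)

    def test_exact_two_stage_recovery(self):
        rng = np.random.default_rng(1)
        s, k, n = 200, 10, 100
        p_vals = (rng.random((n, k)) < 0.3).astype(float)
        p_vals[np.arange(k), np.arange(k)] = 1.0
        prior = pg.PriorMatrix([f"g{i}" for i in range(n)],
                               [f"t{i}" for i in range(k)], p_vals)
        phi_true = rng.normal(size=(s, k))
        y = phi_true @ prior.values.T  # Y = phi P^T, noise-free
        stage1 = pg.nca_estimate_tfa(y, prior)
        np.testing.assert_allclose(stage1.tfa, phi_true, atol=1e-8)
        stage2 = pg.nca_estimate_grn(y, stage1)
        np.testing.assert_allclose(stage2.grn, prior.values.T, atol=1e-8)

    def test_residual_orthogonal_to_prior_rowspace(self):
        rng = np.random.default_rng(2)
        prior = pg.PriorMatrix(["g0", "g1", "g2", "g3"], ["t0", "t1"],
                               np.array([[1.0, 0], [1, 1], [0, 1], [1, 0]]))
        y = rng.normal(size=(30, 4))
        fit = pg.nca_estimate_tfa(y, prior)
        resid = y - fit.tfa @ prior.values.T
        # normal equations: residual orthogonal to the prior columns
        np.testing.assert_allclose(resid @ prior.values, 0.0, atol=1e-10)

    def test_orthonormal_tfa_gives_projection_grn(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        y = rng.normal(size=(20, 6))
        fit = pg.NCAFit(tfa=q, tfs=[f"t{i}" for i in range(4)],
                        genes=[f"g{i}" for i in range(6)])
        out = pg.nca_estimate_grn(y, fit)
        np.testing.assert_allclose(out.grn, q.T @ y, atol=1e-10)

    def test_duplicated_samples_leave_grn_unchanged(self):
        rng = np.random.default_rng(4)
        phi = rng.normal(size=(15, 3))
        y = rng.normal(size=(15, 5))
        base = pg.nca_estimate_grn(
            y, pg.NCAFit(tfa=phi, tfs=list("abc"), genes=[f"g{i}" for i in range(5)]))
        doubled = pg.nca_estimate_grn(
            np.vstack([y, y]),
            pg.NCAFit(tfa=np.vstack([phi, phi]), tfs=list("abc"),
                      genes=[f"g{i}" for i in range(5)]))
        np.testing.assert_allclose(base.grn, doubled.grn, atol=1e-10)

    def test_rank_deficient_prior_needs_fallback(self):
        # two identical TF columns -> rank deficient
        prior = pg.PriorMatrix(["g0", "g1"], ["t0", "t1"],
                               np.array([[1.0, 1.0], [1.0, 1.0]]))
        y = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            pg.nca_estimate_tfa(y, prior)
        fit = pg.nca_estimate_tfa(y, prior, ridge_fallback=True)
        assert np.isfinite(fit.tfa).all()

    def test_zero_activity_tf_row_zeroed(self):
        phi = np.zeros((10, 2))
        phi[:, 0] = np.random.default_rng(5).normal(size=10)
        y = np.random.default_rng(6).normal(size=(10, 3))
        out = pg.nca_estimate_grn(
            y, pg.NCAFit(tfa=phi, tfs=["a", "b"], genes=["g0", "g1", "g2"]))
        np.testing.assert_array_equal(out.grn[1], 0.0)

    def test_recovers_tfa_up_to_scale_on_generative_data(self):
        # linear noise-free generative benchmark: per-TF correlation > 0.99
        # activator-only regulons: reporter-gene averages preserve each TF's
        # direction, so the binary-prior projection recovers TFA up to scale
        spec = pg.SyntheticSpec(n_genes=200, n_tfs=8, samples_per_context=300,
                                out_degree=10, noise_sd=0.0, fn_rate=0.0,
                                fp_rate=0.0, positive_weights=True, seed=8)
        ds = pg.make_benchmark(spec)
        fit = pg.nca_estimate_tfa(ds.expression.values, ds.prior)
        for k in range(spec.n_tfs):
            r = np.corrcoef(fit.tfa[:, k], ds.tfa[:, k])[0, 1]
            assert abs(r) > 0.99


class TestWeightRankingBaseline:
    def test_weight_ranking_uses_magnitude(self):
        from conftest import make_small_trained
        m, x, _ = make_small_trained(0, architecture="shallow")
        ranked = pg.rank_edges_by_weight(m)
        vals = ranked.table["erv"].to_numpy()
        assert (vals[:-1] >= vals[1:]).all()
        assert (vals >= 0).all()
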