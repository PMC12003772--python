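import itertools

import numpy as np
import pandas as pd
import pytest

import grnformer as gf
from grnformer.benchmark import auprc_from_scores, epr_from_scores
from grnformer.networks import NetworkMatrix


def _net_from_scores(scores, genes):
    """Wrap a dense pairwise score matrix (targets on rows) as a network."""
    return NetworkMatrix(scores=np.asarray(scores, dtype=float),
                         row_genes=list(genes), col_genes=list(genes))


# ---------------------------------------------------------------------------
# independent oracles: exhaustive threshold enumeration
# ---------------------------------------------------------------------------

def epr_oracle(scores, labels, K):
    """Enumerate the confusion table at the top-K cutoff directly (assumes
    strictly distinct scores so no tie-break is involved)."""
    order = np.argsort(-np.asarray(scores))
    predicted = np.zeros(len(scores), dtype=bool)
    predicted[order[:K]] = True
    labels = np.asarray(labels, dtype=bool)
    tp = np.sum(predicted & labels)
    fp = np.sum(predicted & ~labels)
    fn = np.sum(~predicted & labels)
    tn = np.sum(~predicted & ~labels)
    if fp == 0 or fn == 0:
        return float("inf")
    return (tp * tn) / (fp * fn)


def auprc_oracle(scores, labels):
    """Exhaustive sweep over every achievable cutoff, trapezoid by hand."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    P = labels.sum()
    prevalence = P / len(labels)
    pts = []
    for cut in sorted(set(scores), reverse=True):
        predicted = scores >= cut
        tp = np.sum(predicted & labels)
        pts.append((tp / P, tp / predicted.sum()))
    recalls = [0.0] + [r for r, _ in pts]
    precs = [pts[0][1]] + [p for _, p in pts]
    area = 0.0
    for i in range(1, len(recalls)):
        y0 = max(precs[i - 1] - prevalence, 0.0)
        y1 = max(precs[i] - prevalence, 0.0)
        area += 0.5 * (y0 + y1) * (recalls[i] - recalls[i - 1])
    return area


class TestEPR:
    def test_perfect_ranking_is_infinite(self):
        genes = list("abcd")
        truth = gf.GroundTruthNetwork(
            edges={("a", "b"), ("c", "d")}, universe=tuple(genes)
        )
        scores = np.full((4, 4), 0.1)
        # targets on rows: edge s->t sits at [t, s]
        scores[1, 0] = 0.9
        scores[3, 2] = 0.8
        assert gf.epr(_net_from_scores(scores, genes), truth) == float("inf")

    def test_hand_enumerated_two_by_two_table(self):
        # 4 candidate pairs, 2 true, top-2 holds exactly 1 true:
        # TP=1 FP=1 FN=1 TN=1 -> EPR = 1
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, False, True, False])
        assert epr_from_scores(scores, labels, K=2) == 1.0

    def test_random_scores_average_to_one(self):
        """Independent uniform scores vs a random truth give mean EPR ~ 1."""
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            labels = rng.random(380) < 0.05
            if not labels.any() or labels.all():
                continue
            scores = rng.random(380)
            vals.append(epr_from_scores(scores, labels))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * se

    def test_matches_exhaustive_oracle_on_small_universes(self):
        rng = np.random.default_rng(1)
        for n in (3, 4, 5, 6):
            n_pairs = n * (n - 1)
            for trial in range(20):
                scores = rng.permutation(n_pairs) / n_pairs  # distinct scores
                labels = rng.random(n_pairs) < 0.3
                if not labels.any() or labels.all():
                    continue
                K = int(labels.sum())
                assert epr_from_scores(scores, labels, K) == pytest.approx(
                    epr_oracle(scores, labels, K)
                )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.random(100) < 0.1
        a = epr_from_scores(scores, labels, seed=5)
        b = epr_from_scores(np.exp(3 * scores), labels, seed=5)
        assert a == b

    def test_orientation_swap_regression(self):
        genes = list("abcde")
        rng = np.random.default_rng(3)
        scores = rng.random((5, 5))
        truth = gf.GroundTruthNetwork(
            edges={("a", "c"), ("b", "d"), ("e", "a")}, universe=tuple(genes)
        )
        flipped = gf.GroundTruthNetwork(
            edges={(t, s) for s, t in truth.edges}, universe=tuple(genes)
        )
        net = _net_from_scores(scores, genes)
        assert gf.epr(net, truth, seed=1) == gf.epr(gf.orient(net), flipped,
                                                    seed=1)

    def test_empty_truth_rejected(self):
        net = _net_from_scores(np.ones((3, 3)), list("abc"))
        truth = gf.GroundTruthNetwork(edges=set(), universe=("a", "b", "c"))
        with pytest.raises(ValueError):
            gf.epr(net, truth)


class TestAUPRC:
    def test_perfect_ranking_equals_one_minus_prevalence(self):
        rng = np.random.default_rng(0)
        labels = rng.random(200) < 0.1
        scores = labels + 0.1 * rng.random(200)
        prevalence = labels.mean()
        assert auprc_from_scores(scores, labels) == pytest.approx(
            1 - prevalence, abs=1e-12
        )

    def test_anti_ranking_clips_to_zero(self):
        labels = np.array([True] * 5 + [False] * 95)
        scores = np.linspace(0, 1, 100)  # positives get the lowest scores
        assert auprc_from_scores(scores, labels) == 0.0

    def test_random_scores_near_zero(self):
        rng = np.random.default_rng(1)
        labels = rng.random(5000) < 0.05
        scores = rng.random(5000)
        assert auprc_from_scores(scores, labels) < 0.02

    def test_matches_exhaustive_oracle_on_small_universes(self):
        rng = np.random.default_rng(2)
        for n in (3, 4, 5, 6):
            n_pairs = n * (n - 1)
            for trial in range(20):
                scores = rng.random(n_pairs)
                labels = rng.random(n_pairs) < 0.4
                if not labels.any():
                    continue
                assert auprc_from_scores(scores, labels) == pytest.approx(
                    auprc_oracle(scores, labels), abs=1e-12
                )

    def test_bounded_by_one_minus_prevalence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.random(60) < 0.3
            if not labels.any():
                continue
            scores = rng.random(60)
            assert auprc_from_scores(scores, labels) <= 1 - labels.mean() + 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.random(80)
        labels = rng.random(80) < 0.2
        assert auprc_from_scores(scores, labels) == pytest.approx(
            auprc_from_scores(scores**3 + 1, labels), abs=1e-12
        )


class TestPrerank:
    def _net(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        np.fill_diagonal(m, 0.0)
        return _net_from_scores(m, [f"g{i}" for i in range(n)])

    def test_top_ranked_set_maximally_enriched(self):
        net = self._net()
        from grnformer.benchmark import _node_ranking

        top = list(_node_ranking(net, "target-hub").index[:8])
        res = gf.prerank_enrichment(net, {"top": top}, n_perm=200, seed=0)
        # the set of top-ranked genes attains the maximal ES of 1 and the
        # smallest p the sign-conditioned permutation null can produce
        assert res[0].es == pytest.approx(1.0, abs=1e-9)
        assert res[0].p < 0.02

    def test_null_pvalues_uniform(self):
        """Random set vs random ranking: p-values over seeded draws are
        uniform (KS test)."""
        from scipy import stats

        ps = []
        for seed in range(60):
            net = self._net(seed=seed, n=30)
            rng = np.random.default_rng(1000 + seed)
            members = list(rng.choice(net.gene_ids, size=8, replace=False))
            res = gf.prerank_enrichment(net, {"s": members}, n_perm=200,
                                        seed=seed)
            ps.append(res[0].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_eigenvector_mode_ranks_star_hub_first(self):
        """On a symmetric star graph the dominant eigenvector concentrates on
        the hub."""
        n = 9
        m = np.zeros((n, n))
        m[0, 1:] = 1.0
        m[1:, 0] = 1.0
        net = _net_from_scores(m, [f"g{i}" for i in range(n)])
        from grnformer.benchmark import _node_ranking

        ranking = _node_ranking(net, "eigenvector")
        assert ranking.index[0] == "g0"

    def test_empty_intersection_reported_not_fatal(self):
        net = self._net()
        res = gf.prerank_enrichment(net, {"none": ["zz1", "zz2"]}, n_perm=100,
                                    seed=0)
        assert np.isnan(res[0].es) and res[0].n_hits == 0

    def test_matches_gseapy_es_on_toy_ranking(self):
        """Cross-check the weighted-KS statistic against gseapy's prerank."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        vals = np.sort(rng.random(50))[::-1] + 0.01
        rnk = pd.DataFrame({"gene": genes, "score": vals}).set_index("gene")
        members = [genes[i] for i in [1, 3, 5, 8, 13, 21, 34]]
        out = gseapy.prerank(
            rnk=rnk, gene_sets={"s": members}, permutation_num=10,
            min_size=2, max_size=50, seed=0, outdir=None, weight=1.0,
            threads=1, no_plot=True,
        )
        es_gseapy = float(out.res2d["ES"].iloc[0])
        from grnformer.benchmark import _es_stat

        hit = np.isin(genes, members)
        assert np.isclose(_es_stat(vals, hit), es_gseapy, atol=1e-6)


class TestTruthConstruction:
    def test_all_ones_pmatrix_empty_network(self):
        pm = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        assert gf.truth_from_pvalues(pm).n_edges == 0

    def test_single_significant_entry(self):
        pm = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        pm.iloc[0, 1] = 0.01
        truth = gf.truth_from_pvalues(pm)
        assert truth.edges == {("a", "b")}

    def test_cutoff_one_gives_complete_digraph(self):
        pm = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"),
                          columns=list("abc"))
        truth = gf.truth_from_pvalues(pm, cutoff=1.0)
        assert truth.n_edges == 6  # complete minus self-loops

    def test_out_of_range_pvalues_rejected(self):
        pm = pd.DataFrame([[1.5]], index=["a"], columns=["b"])
        with pytest.raises(ValueError):
            gf.truth_from_pvalues(pm)

    def test_edgelist_loader_dedup_and_count(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("a\tb\na\tb\nc\td\nbroken\n\ne\tf\n")
        with pytest.warns(UserWarning, match="malformed"):
            truth = gf.load_truth_edgelist(p)
        assert truth.edges == {("a", "b"), ("c", "d"), ("e", "f")}

    def test_gmt_reader(self, tmp_path):
        from grnformer.benchmark import load_gene_sets_gmt

        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\t-\tg4\n")
        sets = load_gene_sets_gmt(p)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4"]}

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            truth = gf.load_truth_edgelist(p)
        assert truth.n_edges == 0
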