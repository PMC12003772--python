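import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

import grnformer as gf
from grnformer.losses import DownsampleConfig, hierarchical_ce_batch, log_nb
from grnformer.model import ZINBParams


# ---------------------------------------------------------------------------
# brute-force PMF oracle: numerically normalized ZINB mass function
# ---------------------------------------------------------------------------

def zinb_pmf_oracle(x, mu, theta, rho, support=5000):
    """Normalize pi*delta0 + (1-pi)*NB over x = 0..support numerically,
    using scipy's nbinom (independent of the package's log-gamma path)."""
    pi = 1.0 / (1.0 + np.exp(-rho))
    xs = np.arange(support + 1)
    nb = stats.nbinom.pmf(xs, theta, theta / (theta + mu))
    pmf = (1 - pi) * nb
    pmf[0] += pi
    pmf = pmf / pmf.sum()
    return pmf[x]


class TestDownsample:
    def test_r_zero_is_identity(self):
        x = np.arange(50)
        out = gf.downsample(x, DownsampleConfig(r=0.0), np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_zero_vector_stays_zero(self):
        x = np.zeros(100, dtype=int)
        out = gf.downsample(x, DownsampleConfig(), np.random.default_rng(0))
        assert np.all(out == 0)

    def test_dominance_and_integrality(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(20, size=(50, 40))
        out = gf.downsample(x, DownsampleConfig(), rng)
        assert np.all(out <= x) and np.all(out >= 0)
        assert np.issubdtype(out.dtype, np.integer)

    def test_mask_zero_positions_are_exactly_zero(self):
        # with r*s -> 1-eps the mask empties almost everything; seeded check
        cfg = DownsampleConfig(r=1.0, s=0.9)
        rng = np.random.default_rng(0)
        x = np.full(10_000, 5)
        out = gf.downsample(x, cfg, rng)
        assert np.mean(out == 0) > 0.89  # mask alone zeroes ~90%

    def test_retained_fraction_analytic_bracket(self):
        """At r=0.6, s=0.55 the mean retained fraction over many cells lies in
        [(1-0.33)^2, 1-0.33]: thinning removes at most rs in expectation
        before truncation, and masking removes rs of the remainder."""
        rng = np.random.default_rng(42)
        x = rng.poisson(1.0, size=(10_000, 1000))  # depth ~1000 per cell
        out = gf.downsample(x, DownsampleConfig(r=0.6, s=0.55), rng)
        frac = out.sum() / x.sum()
        assert (1 - 0.33) ** 2 <= frac <= 1 - 0.33

    def test_rs_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            DownsampleConfig(r=1.0, s=1.0)


class TestZINBNLL:
    def test_matches_bruteforce_pmf_grid(self):
        """NLL equals -log of the numerically normalized PMF within 1e-6 on
        a grid of (x, mu, theta, rho)."""
        xs = np.arange(0, 21)
        for mu in [0.1, 1.0, 5.0, 40.0]:
            for theta in [0.3, 1.0, 10.0]:
                for rho in [-3.0, 0.0, 2.0]:
                    params = ZINBParams(
                        mu=np.full(len(xs), mu),
                        theta=np.full(len(xs), theta),
                        rho=np.full(len(xs), rho),
                    )
                    nll = np.asarray(gf.zinb_nll(xs.astype(float), params,
                                                 reduce="none"))
                    oracle = -np.log(zinb_pmf_oracle(xs, mu, theta, rho))
                    assert np.allclose(nll, oracle, atol=1e-6), (mu, theta, rho)

    def test_certain_zero_limit(self):
        """x=0 with rho -> +inf makes the zero certain: NLL -> 0."""
        params = ZINBParams(mu=np.array([5.0]), theta=np.array([1.0]),
                            rho=np.array([40.0]))
        assert float(gf.zinb_nll(np.array([0.0]), params)) < 1e-8

    def test_poisson_limit(self):
        """rho -> -inf and theta huge reduce ZINB to Poisson."""
        x = np.array([3.0])
        params = ZINBParams(mu=np.array([2.0]), theta=np.array([1e6]),
                            rho=np.array([-40.0]))
        want = -stats.poisson.logpmf(3, 2.0)
        assert abs(float(gf.zinb_nll(x, params)) - want) < 1e-3

    def test_nb_mode_equals_zinb_when_pi_zero(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(4, size=30).astype(float)
        params = ZINBParams(
            mu=rng.gamma(2, 2, size=30), theta=rng.gamma(2, 2, size=30),
            rho=np.full(30, -40.0),
        )
        assert np.isclose(
            float(gf.zinb_nll(x, params)), float(gf.nb_nll(x, params)), atol=1e-10
        )

    def test_nb_matches_scipy_oracle(self):
        x = np.arange(0, 15).astype(float)
        mu, theta = 3.0, 2.0
        nll = np.asarray(
            gf.nb_nll(x, ZINBParams(mu=np.full(15, mu), theta=np.full(15, theta),
                                    rho=np.zeros(15)), reduce="none")
        )
        want = -stats.nbinom.logpmf(np.arange(15), theta, theta / (theta + mu))
        assert np.allclose(nll, want, atol=1e-6)

    def test_mse_of_identical_is_zero(self):
        x = np.array([0.0, 1.0, 7.0])
        assert float(gf.mse_loss(np.log2(1 + x), x)) == 0.0


class TestHierarchicalCE:
    def test_leaf_label_equals_softmax_ce(self, small_ontology):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=small_ontology.n_leaves)
        leaf = small_ontology.leaves[2]
        got = float(gf.hierarchical_ce(logits, leaf, small_ontology))
        want = -(logits[2] - logsumexp(logits))
        assert np.isclose(got, want, atol=1e-12)

    def test_single_descendant_internal_label(self):
        onto = gf.OntologyDAG(
            nodes=["root", "a", "leafA", "leafB"],
            parent_edges=[("a", "root"), ("leafA", "a"), ("leafB", "root")],
        )
        logits = np.array([0.7, -0.2])
        iA = onto.leaf_position("leafA")
        got = float(gf.hierarchical_ce(logits, "a", onto))
        want = -(logits[iA] - logsumexp(logits))
        assert np.isclose(got, want, atol=1e-12)

    def test_three_leaf_marginalization_oracle(self):
        """Internal label over leaves {1,2} with logits (1,2,0): the loss is
        -log of the summed softmax mass of those leaves."""
        onto = gf.OntologyDAG(
            nodes=["root", "mid", "l0", "l1", "l2"],
            parent_edges=[("l0", "root"), ("mid", "root"),
                          ("l1", "mid"), ("l2", "mid")],
        )
        logits_by_leaf = {"l0": 0.0, "l1": 1.0, "l2": 2.0}
        logits = np.array([logits_by_leaf[x] for x in onto.leaves])
        got = float(gf.hierarchical_ce(logits, "mid", onto))
        # brute-force marginalization oracle
        probs = np.exp(logits) / np.exp(logits).sum()
        mass = sum(
            probs[onto.leaf_position(x)] for x in onto.leaf_descendants("mid")
        )
        assert np.isclose(got, -np.log(mass), atol=1e-12)
        # closed form from the collapsed-logit construction:
        # collapsed logits (LSE(1,2), 0) -> CE = log(1 + e^(0 - LSE(1,2)))
        want = np.log(1 + np.exp(0.0 - logsumexp([1.0, 2.0])))
        assert np.isclose(got, want, atol=1e-12)

    def test_lse_preserving_perturbation_invariance(self, small_ontology):
        rng = np.random.default_rng(3)
        onto = small_ontology
        internal = [n for n in onto.nodes
                    if not onto.is_leaf(n) and 1 < len(onto.leaf_descendants(n)) < onto.n_leaves]
        node = internal[0]
        logits = rng.normal(size=onto.n_leaves)
        base = float(gf.hierarchical_ce(logits, node, onto))
        desc = onto.leaf_descendant_indices(node)
        # redistribute mass inside the descendant block, keeping its LSE
        target_lse = logsumexp(logits[desc])
        new_block = rng.normal(size=len(desc))
        new_block += target_lse - logsumexp(new_block)
        pert = logits.copy()
        pert[desc] = new_block
        assert abs(float(gf.hierarchical_ce(pert, node, onto)) - base) < 1e-8

    def test_unknown_label_contributes_zero(self, small_ontology):
        logits = np.ones(small_ontology.n_leaves)
        assert gf.hierarchical_ce(logits, None, small_ontology) == 0.0
        assert gf.hierarchical_ce(logits, "unknown", small_ontology) == 0.0
        batch = hierarchical_ce_batch(
            np.ones((2, small_ontology.n_leaves)),
            ["unknown", small_ontology.leaves[0]],
            small_ontology,
        )
        # the known leaf alone defines the mean
        want = float(gf.hierarchical_ce(logits, small_ontology.leaves[0],
                                        small_ontology))
        assert np.isclose(float(batch), want)

    def test_label_not_in_ontology_raises(self, small_ontology):
        with pytest.raises(KeyError):
            gf.hierarchical_ce(np.ones(small_ontology.n_leaves), "bogus",
                               small_ontology)


class TestContrastiveLoss:
    def test_identical_embeddings_give_zero(self):
        E = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        assert abs(float(gf.contrastive_loss(E))) < 1e-12

    def test_two_orthogonal_vectors_give_half(self):
        """Ordered pairs incl. self: (1-cos) values are (0,1,1,0)/4 = 0.5."""
        E = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.isclose(float(gf.contrastive_loss(E)), 0.5)

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            E = rng.normal(size=(5, 8))
            v = float(gf.contrastive_loss(E))
            assert 0.0 <= v <= 2.0

    def test_zero_norm_vector_rejected(self):
        E = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            gf.contrastive_loss(E)

    def test_repel_sign_flag(self):
        E = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert np.isclose(float(gf.contrastive_loss(E, sign="repel")), 2.0)
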