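"""Pretraining loss primitives.

Count downsampling (the corruption used by the denoising objective), the
zero-inflated negative binomial negative log-likelihood and its NB / MSE
variants, the hierarchical classification cross-entropy over ontology leaves,
and the contrastive disentanglement term.

All likelihoods are computed in log space via log-gamma.  With pi = sigmoid(rho)
the ZINB likelihood of a count x is

    L(x) = pi * [x == 0] + (1 - pi) * NB(x | mu, theta),

so  log L(0) = logaddexp(rho, log NB(0)) - softplus(rho)  and
    log L(x>0) = log NB(x) - softplus(rho),

which is exact and overflow-safe for any rho.  As rho -> -inf the ZINB NLL
reduces to the NB NLL, and as additionally theta -> inf the NB reduces to the
Poisson — both limits are exercised by the test suite against brute-force
PMF oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import gammaln

from .vocab import OntologyDAG

__all__ = [
    "DownsampleConfig",
    "downsample",
    "log_nb",
    "zinb_nll",
    "nb_nll",
    "mse_loss",
    "hierarchical_ce",
    "contrastive_loss",
]


@dataclass
class DownsampleConfig:
    """Zero-inflated-Poisson downsampling: fraction r of counts to drop,
    scaled by the tuning constant s (0.55 by default, slightly above the
    even split of 0.5 for numerical reasons)."""

    r: float = 0.6
    s: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("dropout fraction r must be in [0, 1]")
        if self.r * self.s >= 1.0:
            raise ValueError("r * s must be < 1")


def downsample(
    x: np.ndarray, cfg: DownsampleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt a count vector/matrix by ZIP thinning.

    Elementwise: draw p ~ Poisson(x * r * s), a mask pi = I(U >= r * s), and
    return max((x - p) * pi, 0).  Roughly half the removed counts come from
    the Poisson thinning and half from complete dropout of the masked genes.
    Output is integer with 0 <= out <= x.
    """
    x = np.asarray(x)
    if x.size and x.min() < 0:
        raise ValueError("counts must be nonnegative")
    rs = cfg.r * cfg.s
    if rs == 0.0:
        return x.copy()
    p = rng.poisson(x * rs)
    mask = rng.random(x.shape) >= rs
    return np.maximum((x - p) * mask, 0).astype(x.dtype)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def log_nb(x, mu, theta):
    """Log PMF of NB with mean mu and inverse-dispersion theta."""
    log_theta_mu = anp.log(theta + mu)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (anp.log(theta) - log_theta_mu)
        + x * (anp.log(mu) - log_theta_mu)
    )


def _softplus(z):
    return anp.logaddexp(0.0, z)


def zinb_nll(x, params, reduce: str = "mean"):
    """Mean negative log-likelihood of counts under ZINB(mu, theta, sigmoid(rho)).

    ``params`` is any object with ``mu``, ``theta``, ``rho`` attributes of
    shapes broadcastable to ``x``.
    """
    x = anp.asarray(x, dtype=float) if not hasattr(x, "_value") else x
    mu, theta, rho = params.mu, params.theta, params.rho
    lnb = log_nb(x, mu, theta)
    lnb0 = log_nb(0.0, mu, theta)
    sp = _softplus(rho)
    ll = anp.where(x == 0, anp.logaddexp(rho, lnb0) - sp, lnb - sp)
    out = -ll
    if reduce == "mean":
        out = anp.mean(out)
        val = out._value if hasattr(out, "_value") else out
        if not np.isfinite(val):
            _locate_nonfinite(x, params)
    return out


def _locate_nonfinite(x, params):
    mu = np.asarray(getattr(params.mu, "_value", params.mu))
    theta = np.asarray(getattr(params.theta, "_value", params.theta))
    rho = np.asarray(getattr(params.rho, "_value", params.rho))
    xv = np.asarray(getattr(x, "_value", x))
    with np.errstate(all="ignore"):
        per = -np.where(
            xv == 0,
            np.logaddexp(rho, log_nb(0.0, mu, theta)) - np.logaddexp(0, rho),
            log_nb(xv, mu, theta) - np.logaddexp(0, rho),
        )
    bad = np.argwhere(~np.isfinite(per))
    raise FloatingPointError(
        f"non-finite ZINB NLL at entries (cell, gene) = {bad[:5].tolist()}"
    )


def nb_nll(x, params, reduce: str = "mean"):
    """NB negative log-likelihood: the ZINB with the zero-inflation term
    dropped (pi = 0)."""
    x = anp.asarray(x, dtype=float) if not hasattr(x, "_value") else x
    out = -log_nb(x, params.mu, params.theta)
    return anp.mean(out) if reduce == "mean" else out


def mse_loss(pred_log, x, reduce: str = "mean"):
    """MSE between a single decoded value and log2(1 + x)."""
    x = anp.asarray(x, dtype=float) if not hasattr(x, "_value") else x
    out = (pred_log - anp.log2(1.0 + x)) ** 2
    return anp.mean(out) if reduce == "mean" else out


# ---------------------------------------------------------------------------
# hierarchical classification loss
# ---------------------------------------------------------------------------

def hierarchical_ce(logits, label: str | None, onto: OntologyDAG):
    """Softmax cross-entropy over ontology leaves, tolerant of coarse labels.

    For a leaf label this is the ordinary softmax CE against that leaf.  For
    an internal label, the block of descendant-leaf logits is collapsed into a
    single log-sum-exp logit and the CE is taken against that collapsed
    position; algebraically the loss is

        LSE(all leaf logits) - LSE(descendant leaf logits),

    so it depends on the descendant block only through its LSE.  A None /
    "unknown" label contributes 0.
    """
    if label is None or label == "unknown":
        return 0.0
    desc = onto.leaf_descendant_indices(label)
    if len(desc) == 0:
        raise KeyError(f"label {label!r} has no leaf descendants")
    all_lse = _lse(logits)
    desc_lse = _lse(logits[desc]) if len(desc) < onto.n_leaves else all_lse
    return all_lse - desc_lse


def _lse(z):
    m = anp.max(z)
    return m + anp.log(anp.sum(anp.exp(z - m)))


def hierarchical_ce_batch(logits, labels, onto: OntologyDAG):
    """Mean hierarchical CE over a batch; unknown labels contribute 0 and do
    not count toward the denominator."""
    terms = []
    for i, lab in enumerate(labels):
        if lab is None or lab == "unknown":
            continue
        terms.append(hierarchical_ce(logits[i], lab, onto))
    if not terms:
        return 0.0
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


# ---------------------------------------------------------------------------
# contrastive disentanglement
# ---------------------------------------------------------------------------

def contrastive_loss(embeddings, sign: str = "as-printed"):
    """Average (1 - cos) over all ordered pairs of embeddings, self-pairs
    included; value lies in [0, 2].

    ``sign="repel"`` switches to (1 + cos)/ pairs, which actively pushes the
    embeddings apart; the default follows the printed formulation.
    """
    E = embeddings
    norms = anp.sqrt(anp.sum(E * E, axis=-1))
    nv = norms._value if hasattr(norms, "_value") else norms
    if np.any(np.asarray(nv) < 1e-12):
        raise ValueError("zero-norm embedding in contrastive loss")
    En = E / norms[:, None]
    C = anp.dot(En, En.T)
    m = np.shape(E)[0]
    if sign == "repel":
        return anp.sum(1.0 + C) / (m * m)
    return anp.sum(1.0 - C) / (m * m)
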