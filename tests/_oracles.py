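"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning machinery: likelihoods and
posteriors are computed by explicit enumeration over all internal-state
assignments, transition matrices by a truncated-series matrix exponential,
and gamma category means by adaptive quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from p53evo.evo_models import AA_INDEX


def expm_series(A: np.ndarray, n_terms: int = 30) -> np.ndarray:
    """Scaling-and-squaring truncated Taylor series for expm."""
    norm = np.abs(A).sum(axis=1).max()
    s = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1)
    B = A / (2**s)
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, n_terms + 1):
        term = term @ B / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def gamma_slice_means(alpha: float, k: int) -> np.ndarray:
    """Mean of each equal-probability slice of a mean-1 gamma, by quadrature."""
    scale = 1.0 / alpha
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=scale)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        hi_eff = gamma_dist.ppf(1 - 1e-14, a=alpha, scale=scale) if np.isinf(hi) else hi
        val, _ = quad(
            lambda x: x * gamma_dist.pdf(x, a=alpha, scale=scale),
            lo,
            hi_eff,
            limit=200,
        )
        means.append(val * k)
    return np.array(means)


def _tree_tables(tree):
    """Flatten a TimeTree into parent/length tables (postorder)."""
    nodes = list(tree.postorder())
    index = {nd: i for i, nd in enumerate(nodes)}
    parents = [index[nd.parent] if nd.parent is not None else -1 for nd in nodes]
    lengths = [nd.length if nd.length is not None else 0.0 for nd in nodes]
    return nodes, index, parents, lengths


def enumeration_likelihood_and_posteriors(tree, aln, model, branch_scale=1.0):
    """Site likelihoods and marginal node posteriors by full enumeration.

    Sums over every assignment of states to internal nodes, for every rate
    category, using the series expm.  Exponential in the number of internal
    nodes; fine for trees of <= 5 taxa.
    """
    from p53evo.evo_models import build_rate_matrix

    nodes, index, parents, lengths = _tree_tables(tree)
    Q = build_rate_matrix(model)
    pi = model.frequencies
    rates, weights = model.mixture()
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf]
    leaves = [i for i, nd in enumerate(nodes) if nd.is_leaf]
    root = index[tree.root]

    codes = {lb: [AA_INDEX.get(c, -1) for c in seq]
             for lb, seq in zip(aln.labels, aln.sequences)}
    n_sites = aln.n_sites

    pmats = []
    for r in rates:
        per_node = {}
        for i, nd in enumerate(nodes):
            if parents[i] >= 0:
                per_node[i] = expm_series(Q * (r * lengths[i] * branch_scale))
        pmats.append(per_node)

    site_liks = np.zeros(n_sites)
    post = np.zeros((len(internal), n_sites, 20))
    int_pos = {n: j for j, n in enumerate(internal)}

    for site in range(n_sites):
        obs = {i: codes[nodes[i].label][site] for i in leaves}
        for r_idx, w in enumerate(weights):
            P = pmats[r_idx]
            for assign in itertools.product(range(20), repeat=len(internal)):
                state = dict(zip(internal, assign))
                p = w * pi[state[root]]
                for i in leaves:
                    ob = obs[i]
                    if ob >= 0:
                        p *= P[i][state[parents[i]], ob]
                for i in internal:
                    if parents[i] >= 0:
                        p *= P[i][state[parents[i]], state[i]]
                site_liks[site] += p
                for i in internal:
                    post[int_pos[i], site, state[i]] += p
    post /= post.sum(axis=2, keepdims=True)
    node_ids = [nodes[i].node_id for i in internal]
    return site_liks, node_ids, post
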