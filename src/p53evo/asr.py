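"""Maximum-likelihood ancestral sequence reconstruction.

Likelihoods are computed by Felsenstein pruning over a rate mixture of
discretised-gamma categories plus an optional invariant class.  Marginal
ancestral posteriors at every internal node come from the standard two-pass
(inside/outside) algorithm; rate categories are mixed with their per-site
posterior weights.  Gaps and ``X`` are missing data (partial-likelihood
vectors of ones); there is no indel model.

Ancestral calls follow the ML / AltAll convention: the ML sequence takes the
posterior argmax at every site, while the AltAll sequence swaps in the
second-most-probable residue wherever the best posterior is below 0.90 and
the runner-up reaches at least 0.10, summarising reconstruction uncertainty
in a single alternative protein.

Model choice among the JTT family is ranked by small-sample-corrected AIC
(AICc) with Akaike weights, and BIC alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logsumexp

from .evo_models import (
    AA_INDEX,
    AMINO_ACIDS,
    KNOWN_MODEL_NAMES,
    SpectralRateMatrix,
    SubstitutionModel,
    build_rate_matrix,
    empirical_frequencies,
    model_from_name,
)
from .phylo import TimeTree, TreeNode

_LOG_ZERO_FLOOR = 1e-300


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A protein multiple sequence alignment.

    ``column_map`` optionally maps 1-based alignment columns to an external
    site numbering (e.g. human p53 positions 15-27 of the MDM2-binding
    motif).
    """

    labels: list[str]
    sequences: list[str]
    column_map: dict[int, int] | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError("alignment labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def codes(self) -> np.ndarray:
        """Integer residue codes, shape (n_taxa, n_sites); -1 = missing."""
        arr = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int8)
        for i, seq in enumerate(self.sequences):
            for j, ch in enumerate(seq):
                arr[i, j] = AA_INDEX.get(ch, -1)
        return arr

    def row(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in zip(self.labels, self.sequences):
                fh.write(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# Pruning engine


class _Engine:
    """Shared state for repeated likelihood evaluations on one dataset."""

    def __init__(self, tree: TimeTree, aln: Alignment, model: SubstitutionModel):
        tree_labels = set(tree.leaf_labels)
        aln_labels = set(aln.labels)
        if tree_labels != aln_labels:
            missing = sorted(tree_labels ^ aln_labels)
            raise AlignmentError(
                f"tree and alignment labels do not match; mismatched: {missing}"
            )
        self.tree = tree
        self.aln = aln
        self.model = model
        self.pi = model.frequencies
        self.Q = build_rate_matrix(model)
        self.spectral = SpectralRateMatrix.from_q(self.Q, self.pi)
        self.post_nodes = list(tree.postorder())
        self.n_sites = aln.n_sites
        codes = aln.codes()
        row_of = {lb: i for i, lb in enumerate(aln.labels)}
        # one-hot leaf partials; missing data = all-ones
        self.leaf_onehot: dict[TreeNode, np.ndarray] = {}
        eye = np.eye(20)
        for leaf in tree.leaves():
            c = codes[row_of[leaf.label]]
            oh = np.ones((self.n_sites, 20))
            obs = c >= 0
            oh[obs] = eye[c[obs]]
            self.leaf_onehot[leaf] = oh

    def _branch_lengths(self, branch_scale, branch_lengths):
        out: dict[TreeNode, float] = {}
        for nd in self.post_nodes:
            if nd.parent is None:
                continue
            if branch_lengths is not None:
                out[nd] = float(branch_lengths[nd])
            else:
                out[nd] = float(nd.length) * branch_scale
        return out

    def _pmats(self, rates, lengths) -> dict[TreeNode, np.ndarray]:
        """Per-branch stack of per-category transition matrices (C, 20, 20)."""
        pmats = {}
        eye = np.eye(20)
        for nd, t in lengths.items():
            stack = np.empty((len(rates), 20, 20))
            for c, r in enumerate(rates):
                stack[c] = eye if r * t == 0 else self.spectral.probs(r * t)
            pmats[nd] = stack
        return pmats

    def _up_messages(self, rates, pmats):
        """Upward pass.

        Returns ``(msg, logscale, partial_root, logscale_root)`` where
        ``msg[node]`` is the rescaled message (C, S, 20) a node sends to its
        parent and ``logscale[node]`` (C, S) its accumulated log scaling.
        """
        C = len(rates)
        msg: dict[TreeNode, np.ndarray] = {}
        logscale: dict[TreeNode, np.ndarray] = {}
        partial_root = None
        ls_root = None
        for nd in self.post_nodes:
            if nd.is_leaf:
                partial = np.broadcast_to(
                    self.leaf_onehot[nd], (C, self.n_sites, 20)
                ).copy()
                ls = np.zeros((C, self.n_sites))
            else:
                partial = np.ones((C, self.n_sites, 20))
                ls = np.zeros((C, self.n_sites))
                for ch in nd.children:
                    partial *= msg.pop(ch)
                    ls += logscale.pop(ch)
                m = partial.max(axis=2)
                np.maximum(m, _LOG_ZERO_FLOOR, out=m)
                partial /= m[:, :, None]
                ls += np.log(m)
            if nd.parent is None:
                partial_root, ls_root = partial, ls
            else:
                # message to parent: msg(s_parent) = sum_s P[s_parent, s] L(s)
                msg[nd] = np.einsum("csk,cjk->csj", partial, pmats[nd])
                logscale[nd] = ls
        return partial_root, ls_root

    def site_loglik_by_cat(self, branch_scale=1.0, branch_lengths=None):
        rates, weights = self.model.mixture()
        lengths = self._branch_lengths(branch_scale, branch_lengths)
        pmats = self._pmats(rates, lengths)
        partial_root, ls_root = self._up_messages(rates, pmats)
        lik = np.einsum("k,csk->cs", self.pi, partial_root)
        ll_cat = np.log(np.maximum(lik, _LOG_ZERO_FLOOR)) + ls_root
        return ll_cat, np.log(weights)

    def site_logliks(self, branch_scale=1.0, branch_lengths=None) -> np.ndarray:
        ll_cat, logw = self.site_loglik_by_cat(branch_scale, branch_lengths)
        return logsumexp(ll_cat + logw[:, None], axis=0)

    def marginal_posteriors(self, branch_scale=1.0, branch_lengths=None):
        """Marginal node posteriors; see module docstring for conventions."""
        rates, weights = self.model.mixture()
        lengths = self._branch_lengths(branch_scale, branch_lengths)
        pmats = self._pmats(rates, lengths)

        C, S = len(rates), self.n_sites
        # upward pass, keeping messages and (unscaled-shape) partials
        msg: dict[TreeNode, np.ndarray] = {}
        partials: dict[TreeNode, np.ndarray] = {}
        ls: dict[TreeNode, np.ndarray] = {}
        for nd in self.post_nodes:
            if nd.is_leaf:
                partial = np.broadcast_to(self.leaf_onehot[nd], (C, S, 20)).copy()
                scale = np.zeros((C, S))
            else:
                partial = np.ones((C, S, 20))
                scale = np.zeros((C, S))
                for ch in nd.children:
                    partial *= msg[ch]
                    scale += ls[ch]
                m = np.maximum(partial.max(axis=2), _LOG_ZERO_FLOOR)
                partial /= m[:, :, None]
                scale += np.log(m)
            partials[nd] = partial
            ls[nd] = scale
            if nd.parent is not None:
                msg[nd] = np.einsum("csk,cjk->csj", partial, pmats[nd])

        root = self.tree.root
        lik = np.einsum("k,csk->cs", self.pi, partials[root])
        ll_cat = np.log(np.maximum(lik, _LOG_ZERO_FLOOR)) + ls[root]
        logw = np.log(weights)
        site_ll = logsumexp(ll_cat + logw[:, None], axis=0)
        # per-site posterior weight of each rate category
        cat_post = np.exp(ll_cat + logw[:, None] - site_ll[None, :])

        internal = [nd for nd in self.tree.preorder() if not nd.is_leaf]
        node_index = {nd: i for i, nd in enumerate(internal)}
        post = np.zeros((len(internal), S, 20))

        # downward (outside) pass; G is renormalised freely per (cat, site)
        # because posteriors are normalised within each category below.
        G: dict[TreeNode, np.ndarray] = {root: np.broadcast_to(self.pi, (C, S, 20)).copy()}
        for nd in self.tree.preorder():
            if nd.is_leaf:
                continue
            g = G.pop(nd)
            joint = g * partials[nd]
            norm = joint.sum(axis=2, keepdims=True)
            joint /= np.maximum(norm, _LOG_ZERO_FLOOR)
            post[node_index[nd]] = np.einsum("cs,csk->sk", cat_post, joint)
            for ch in nd.children:
                if ch.is_leaf:
                    continue  # posteriors are only reported at internal nodes
                h = g.copy()
                for other in nd.children:
                    if other is not ch:
                        h *= msg[other]
                m = np.maximum(h.max(axis=2), _LOG_ZERO_FLOOR)
                h /= m[:, :, None]
                G[ch] = np.einsum("csj,cjk->csk", h, pmats[ch])
        return internal, post, site_ll


def log_likelihood(
    tree: TimeTree,
    aln: Alignment,
    model: SubstitutionModel,
    branch_scale: float = 1.0,
    branch_lengths: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood by Felsenstein pruning.

    ``branch_scale`` converts chronogram branch lengths (My) into expected
    substitutions per site per My; alternatively ``branch_lengths`` supplies
    per-branch lengths already on the substitution scale.
    """
    if branch_scale <= 0:
        raise ValueError("branch_scale must be positive")
    eng = _Engine(tree, aln, model)
    site_ll = eng.site_logliks(branch_scale, branch_lengths)
    return float(site_ll.sum()), site_ll


# ---------------------------------------------------------------------------
# Parameter fitting


@dataclass
class FitResult:
    model: SubstitutionModel
    branch_scale: float
    branch_lengths: dict | None
    log_likelihood: float
    trace: list[float]
    n_evaluations: int
    converged: bool


def _pack(model, branch_scale, optimize):
    x0, names = [], []
    if "alpha" in optimize and model.gamma_shape is not None:
        x0.append(np.log(model.gamma_shape))
        names.append("alpha")
    if "p_inv" in optimize and model.p_invariant is not None:
        p = min(max(model.p_invariant, 1e-4), 0.95)
        x0.append(np.log(p / (1 - p)))
        names.append("p_inv")
    if "branch_scale" in optimize:
        x0.append(np.log(branch_scale))
        names.append("branch_scale")
    return np.array(x0), names


def _unpack(x, names, model, branch_scale):
    kwargs = {}
    for xi, name in zip(x, names):
        if name == "alpha":
            kwargs["gamma_shape"] = float(np.clip(np.exp(xi), 1e-3, 1e3))
        elif name == "p_inv":
            kwargs["p_invariant"] = float(expit(np.clip(xi, -500, 500)) * 0.999)
        elif name == "branch_scale":
            branch_scale = float(np.clip(np.exp(xi), 1e-9, 1e6))
    return (model.with_params(**kwargs) if kwargs else model), branch_scale


def fit_model_parameters(
    tree: TimeTree,
    aln: Alignment,
    model: SubstitutionModel,
    optimize: Sequence[str] = ("alpha", "p_inv", "branch_scale"),
    branch_scale: float = 1.0,
    branch_mode: str = "scale",
    n_branch_sweeps: int = 2,
) -> FitResult:
    """Maximise the likelihood over rate-model and branch parameters.

    ``branch_mode="scale"`` (default) keeps the chronogram topology and
    branch lengths and fits a single global substitution-rate scalar;
    ``branch_mode="per_branch"`` additionally re-optimises every branch
    length on the substitution scale by coordinate-wise Brent sweeps
    starting from the scaled chronogram.
    """
    if aln.n_taxa < 2:
        raise AlignmentError("parameter fitting needs at least 2 sequences")
    if branch_mode not in ("scale", "per_branch"):
        raise ValueError("branch_mode must be 'scale' or 'per_branch'")
    codes = aln.codes()
    observed = codes >= 0
    variable = 0
    for j in range(aln.n_sites):
        col = codes[observed[:, j], j]
        if col.size and np.unique(col).size > 1:
            variable += 1
    if variable == 0 and ("alpha" in optimize or "p_inv" in optimize):
        warnings.warn(
            "no variable sites: rate-heterogeneity parameters are not "
            "identifiable; returning boundary estimates",
            stacklevel=2,
        )

    eng = _Engine(tree, aln, model)
    trace: list[float] = []
    n_eval = 0

    # Cheap 1-D line search on the global rate scalar first: chronogram
    # branch lengths are in My, so the likelihood-relevant scale can be many
    # orders of magnitude away from any generic start, and launching the
    # joint simplex from a bad scale risks the wrong basin of the
    # gamma/invariant ridge.
    if "branch_scale" in optimize:
        def scale_obj(log_s):
            nonlocal n_eval
            n_eval += 1
            return -float(eng.site_logliks(float(np.exp(log_s))).sum())

        res0 = minimize_scalar(
            scale_obj, bounds=(np.log(1e-8), np.log(1e3)), method="bounded",
            options={"xatol": 1e-3},
        )
        branch_scale = float(np.exp(res0.x))

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        mdl, bs = _unpack(x, names, model, branch_scale)
        eng.model = mdl
        ll = float(eng.site_logliks(bs).sum())
        trace.append(max(ll, trace[-1]) if trace else ll)
        return -ll

    x0, names = _pack(model, branch_scale, optimize)
    if names:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
        )
        best_model, best_scale = _unpack(res.x, names, model, branch_scale)
        converged = bool(res.success)
    else:
        best_model, best_scale, converged = model, branch_scale, True
    eng.model = best_model
    best_ll = float(eng.site_logliks(best_scale).sum())

    branch_lengths = None
    if branch_mode == "per_branch":
        branch_lengths = {
            nd: max(float(nd.length) * best_scale, 1e-9)
            for nd in eng.post_nodes
            if nd.parent is not None
        }
        for _ in range(n_branch_sweeps):
            before = best_ll
            for nd in list(branch_lengths):
                def br_obj(t):
                    branch_lengths[nd] = t
                    return -float(eng.site_logliks(1.0, branch_lengths).sum())

                res1 = minimize_scalar(
                    br_obj, bounds=(1e-9, 50.0), method="bounded",
                    options={"xatol": 1e-6},
                )
                branch_lengths[nd] = float(res1.x)
                best_ll = -float(res1.fun)
                trace.append(max(best_ll, trace[-1]) if trace else best_ll)
            if best_ll - before < 1e-4:
                break
    return FitResult(
        model=best_model,
        branch_scale=best_scale,
        branch_lengths=branch_lengths,
        log_likelihood=best_ll,
        trace=trace,
        n_evaluations=n_eval,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Marginal reconstruction and sequence calls


@dataclass
class AncestralPosterior:
    """Per-node, per-site posterior distributions over the 20 residues."""

    node_ids: list[int]
    probabilities: np.ndarray  # (n_nodes, n_sites, 20)
    site_logliks: np.ndarray
    primary_cutoff: float = 0.90
    secondary_min: float = 0.10
    column_map: dict[int, int] | None = None

    def __post_init__(self):
        sums = self.probabilities.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("posterior vectors must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.probabilities.shape[1]

    def _row(self, node_id: int) -> np.ndarray:
        return self.probabilities[self.node_ids.index(node_id)]

    def site_posterior(self, node_id: int, site: int) -> np.ndarray:
        """Posterior 20-vector at a 1-based alignment column."""
        return self._row(node_id)[site - 1]

    def ml_sequence(self, node_id: int) -> str:
        probs = self._row(node_id)
        return "".join(AMINO_ACIDS[i] for i in probs.argmax(axis=1))

    def altall_sequence(self, node_id: int) -> str:
        probs = self._row(node_id)
        ml, altall = _call_from_probs(probs, self.primary_cutoff, self.secondary_min)
        return altall

    def calls(self) -> dict[int, tuple[str, str]]:
        return call_sequences(self, self.primary_cutoff, self.secondary_min)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        calls = self.calls()
        for ni, node_id in enumerate(self.node_ids):
            ml, alt = calls[node_id]
            for s in range(self.n_sites):
                row = {"node": node_id, "site": s + 1}
                if self.column_map:
                    row["mapped_site"] = self.column_map.get(s + 1)
                for a, p in zip(AMINO_ACIDS, self.probabilities[ni, s]):
                    row[a] = p
                row["ml"] = ml[s]
                row["altall"] = alt[s]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _call_from_probs(probs: np.ndarray, primary_cutoff: float, secondary_min: float):
    order = np.argsort(-probs, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    p_best = probs[np.arange(len(probs)), best]
    p_second = probs[np.arange(len(probs)), second]
    ml = "".join(AMINO_ACIDS[i] for i in best)
    swap = (p_best < primary_cutoff) & (p_second >= secondary_min)
    alt = "".join(
        AMINO_ACIDS[second[i]] if swap[i] else AMINO_ACIDS[best[i]]
        for i in range(len(probs))
    )
    return ml, alt


def marginal_posteriors(
    tree: TimeTree,
    aln: Alignment,
    model: SubstitutionModel,
    branch_scale: float = 1.0,
    branch_lengths: dict | None = None,
    primary_cutoff: float = 0.90,
    secondary_min: float = 0.10,
) -> AncestralPosterior:
    """Marginal ancestral reconstruction at every internal node.

    For each internal node and site the posterior over the 20 residues is
    marginalised over all other nodes; rate categories are mixed with their
    per-site posterior weights.  Internal nodes without ids are numbered
    (postorder, starting above the leaf count) before reporting.
    """
    tree.assign_node_ids(start=len(tree.leaf_labels) + 1)
    eng = _Engine(tree, aln, model)
    internal, post, site_ll = eng.marginal_posteriors(branch_scale, branch_lengths)
    post = post / post.sum(axis=2, keepdims=True)
    return AncestralPosterior(
        node_ids=[nd.node_id for nd in internal],
        probabilities=post,
        site_logliks=site_ll,
        primary_cutoff=primary_cutoff,
        secondary_min=secondary_min,
        column_map=aln.column_map,
    )


def call_sequences(
    post: AncestralPosterior,
    primary_cutoff: float = 0.90,
    secondary_min: float = 0.10,
) -> dict[int, tuple[str, str]]:
    """Per-node (ML, AltAll) sequence pairs.

    AltAll swaps in the second-most-likely residue exactly where the best
    posterior is < ``primary_cutoff`` and the runner-up is >=
    ``secondary_min``; everywhere else it equals the ML call.
    """
    out = {}
    for ni, node_id in enumerate(post.node_ids):
        out[node_id] = _call_from_probs(
            post.probabilities[ni], primary_cutoff, secondary_min
        )
    return out


# ---------------------------------------------------------------------------
# Model selection


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(log_lik: float, k: int, n: int) -> float:
    return -2.0 * log_lik + k * np.log(n)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - np.nanmin(a)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(a)] = 0.0
    return w / np.nansum(w)


def model_selection_table(
    tree: TimeTree,
    aln: Alignment,
    candidates: Sequence[str] = KNOWN_MODEL_NAMES,
    alpha0: float = 1.0,
    p_inv0: float = 0.1,
    n_categories: int = 5,
) -> pd.DataFrame:
    """Fit each candidate JTT-family model and rank by AICc.

    The sample size ``n`` is the number of alignment columns; the parameter
    count is the model's free rate parameters plus one global branch-rate
    scalar.  Akaike weights are normalised over rows with a defined AICc.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    n = aln.n_sites
    rows = []
    emp = None
    for name in candidates:
        if name.endswith("+F") and emp is None:
            emp = empirical_frequencies(aln)
        mdl = model_from_name(
            name, alpha=alpha0, p_inv=p_inv0, n_categories=n_categories,
            empirical_frequencies_=emp if name.endswith("+F") else None,
        )
        fit = fit_model_parameters(tree, aln, mdl)
        k = mdl.n_free_parameters() + 1  # + branch_scale
        try:
            aicc_val = aicc(fit.log_likelihood, k, n)
        except ValueError:
            aicc_val = np.nan
        rows.append(
            {
                "model": name,
                "log_likelihood": fit.log_likelihood,
                "k": k,
                "n": n,
                "AICc": aicc_val,
                "BIC": bic(fit.log_likelihood, k, n),
                "alpha": fit.model.gamma_shape,
                "p_inv": fit.model.p_invariant,
                "branch_scale": fit.branch_scale,
            }
        )
    df = pd.DataFrame(rows)
    df["akaike_weight"] = akaike_weights(df["AICc"].to_numpy())
    df = df.sort_values("AICc").reset_index(drop=True)
    return df
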