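"""Amino-acid substitution models with gamma + invariant-sites rate mixtures.

The reconstruction pipeline works with time-reversible empirical models of
the GTR form: an instantaneous rate matrix ``Q`` is assembled from a
symmetric exchangeability matrix ``S`` and a vector of equilibrium
frequencies ``pi`` as ``q_ij = S_ij * pi_j`` (i != j), then normalised so
that the expected substitution rate at stationarity is one.  Among-site rate
heterogeneity follows the standard discretised-gamma treatment (equal-weight
categories, shape ``alpha``) with an optional extra invariant category of
weight ``p_invariant`` and rate zero.  The packaged empirical model is JTT
(Jones-Taylor-Thornton), optionally with alignment-derived frequencies (+F).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

#: Canonical residue order used throughout the package (alphabetical
#: one-letter codes).  All matrices, posterior vectors and sequence codes
#: index into this string; argmax ties are broken by this order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residue order used by the published JTT tables (PAML convention).
_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

GAP_CHARS = frozenset("-.")
MISSING_CHARS = frozenset("Xx?") | GAP_CHARS

KNOWN_MODEL_NAMES = ("JTT", "JTT+G", "JTT+I", "JTT+G+I", "JTT+G+I+F")


class DegenerateModelError(ValueError):
    """Raised when (S, pi) cannot be normalised into a rate matrix."""


class EmptyDataError(ValueError):
    """Raised when an alignment carries no countable residues."""


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible amino-acid substitution model.

    Parameters
    ----------
    name:
        Human-readable label, e.g. ``"JTT+G+I"``.
    exchangeabilities:
        Symmetric nonnegative 20x20 matrix ``S``; the diagonal is ignored.
    frequencies:
        Equilibrium frequencies ``pi`` (length 20, sums to 1).
    gamma_shape:
        Shape ``alpha`` of the discretised gamma rate distribution, or
        ``None`` for rate homogeneity (no +G component).
    n_categories:
        Number of discrete gamma categories (default 5).
    p_invariant:
        Proportion of invariant sites in [0, 1), or ``None`` for no +I
        component.
    use_empirical_freqs:
        Marker that ``frequencies`` were estimated from the data (+F).
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 5
    p_invariant: float | None = None
    use_empirical_freqs: bool = False
    gamma_method: str = "mean"

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20):
            raise ValueError(f"exchangeability matrix must be 20x20, got {S.shape}")
        if pi.shape != (20,):
            raise ValueError(f"frequency vector must have length 20, got {pi.shape}")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be nonnegative and sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.p_invariant is not None and not (0.0 <= self.p_invariant < 1.0):
            raise ValueError("p_invariant must lie in [0, 1)")
        if self.gamma_method not in ("mean", "median"):
            raise ValueError("gamma_method must be 'mean' or 'median'")
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi)

    # -- derived quantities -------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(rates, weights)`` of the full rate mixture.

        Gamma categories first (or the single rate 1 when ``gamma_shape`` is
        None), followed by the invariant category when ``p_invariant`` is set.
        """
        if self.gamma_shape is None:
            rates = np.array([1.0])
        else:
            rates = discretize_gamma(
                self.gamma_shape, self.n_categories, method=self.gamma_method
            )
        return make_rate_mixture(rates, self.p_invariant or 0.0)

    def n_free_parameters(self) -> int:
        """Free parameters contributed by the rate model itself.

        Counts alpha, p_invariant and (for +F) 19 free frequencies.  Branch
        rate/length parameters are counted by the caller, which knows how
        branch lengths were treated.
        """
        k = 0
        if self.gamma_shape is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        if self.use_empirical_freqs:
            k += 19
        return k

    def with_params(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Packaged JTT data


def _load_jtt_table() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("p53evo.data").joinpath("jtt_rates.txt").read_text()
    values = [
        float(tok)
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
        for tok in line.split()
    ]
    if len(values) != 210:
        raise RuntimeError("corrupt JTT data file")
    tri, freqs = values[:190], np.array(values[190:])
    S = np.zeros((20, 20))
    pos = 0
    # column-major lower triangle in PAML residue order
    for col in range(19):
        for row in range(col + 1, 20):
            S[row, col] = S[col, row] = tri[pos]
            pos += 1
    # permute into the package's alphabetical residue order
    perm = [_PAML_ORDER.index(a) for a in AMINO_ACIDS]
    S = S[np.ix_(perm, perm)]
    pi = freqs[perm]
    pi = pi / pi.sum()
    return S, pi


_JTT_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def jtt_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """The published JTT exchangeability matrix and frequencies (packaged)."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = _load_jtt_table()
    S, pi = _JTT_CACHE
    return S.copy(), pi.copy()


def jtt_model(
    gamma_shape: float | None = None,
    p_invariant: float | None = None,
    n_categories: int = 5,
    frequencies: np.ndarray | None = None,
    gamma_method: str = "mean",
) -> SubstitutionModel:
    """Build a JTT-family model (JTT, +G, +I, +G+I, optionally +F)."""
    S, pi = jtt_exchangeabilities()
    use_f = frequencies is not None
    if use_f:
        pi = np.asarray(frequencies, dtype=float)
    parts = ["JTT"]
    if gamma_shape is not None:
        parts.append("G")
    if p_invariant is not None:
        parts.append("I")
    if use_f:
        parts.append("F")
    return SubstitutionModel(
        name="+".join(parts),
        exchangeabilities=S,
        frequencies=pi,
        gamma_shape=gamma_shape,
        n_categories=n_categories,
        p_invariant=p_invariant,
        use_empirical_freqs=use_f,
        gamma_method=gamma_method,
    )


def model_from_name(
    name: str,
    alpha: float = 1.0,
    p_inv: float = 0.1,
    n_categories: int = 5,
    empirical_frequencies_: np.ndarray | None = None,
    gamma_method: str = "mean",
) -> SubstitutionModel:
    """Instantiate one of the named JTT-family models.

    ``alpha``/``p_inv`` are starting (or fixed) values for the components the
    name switches on; components the name omits are disabled.
    """
    key = name.upper().replace(" ", "")
    if key not in KNOWN_MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {KNOWN_MODEL_NAMES}")
    has_g = "+G" in key
    has_i = "+I" in key
    has_f = key.endswith("+F")
    if has_f and empirical_frequencies_ is None:
        raise ValueError("+F model requires empirical frequencies from an alignment")
    return jtt_model(
        gamma_shape=alpha if has_g else None,
        p_invariant=p_inv if has_i else None,
        n_categories=n_categories,
        frequencies=empirical_frequencies_ if has_f else None,
        gamma_method=gamma_method,
    )


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities


def build_rate_matrix(
    model: SubstitutionModel | None = None,
    exchangeabilities: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the normalised instantaneous rate matrix Q.

    ``q_ij = S_ij * pi_j`` off the diagonal, diagonal set so rows sum to
    zero, and the whole matrix scaled so the mean rate at stationarity,
    ``-sum_i pi_i q_ii``, equals 1.  Branch lengths therefore measure
    expected substitutions per site (before any rate-category multiplier).
    """
    if model is not None:
        S = model.exchangeabilities
        pi = model.frequencies
    else:
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0.0 or not np.isfinite(mean_rate):
        raise DegenerateModelError(
            "model has zero mean substitution rate; frequencies/exchangeabilities "
            "are degenerate"
        )
    return Q / mean_rate


@dataclass(frozen=True)
class SpectralRateMatrix:
    """Eigendecomposition of a reversible Q for cheap repeated P(t).

    For reversible Q, ``A = D^{1/2} Q D^{-1/2}`` (D = diag(pi)) is symmetric;
    with ``A = U diag(lam) U^T`` we get ``P(t) = D^{-1/2} U e^{lam t} U^T D^{1/2}``.
    """

    eigvals: np.ndarray
    left: np.ndarray   # D^{-1/2} U
    right: np.ndarray  # U^T D^{1/2}

    @classmethod
    def from_q(cls, Q: np.ndarray, pi: np.ndarray) -> "SpectralRateMatrix":
        mask = pi > 0
        s = np.sqrt(np.where(mask, pi, 1.0))
        A = (s[:, None] * Q) / s[None, :]
        A = 0.5 * (A + A.T)  # symmetrise against round-off
        lam, U = np.linalg.eigh(A)
        return cls(eigvals=lam, left=U / s[:, None], right=U.T * s[None, :])

    def probs(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probs(Q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """Row-stochastic transition matrix P(rate * t) = expm(Q * rate * t)."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if not np.isfinite(t):
        raise ValueError("branch length must be finite")
    n = Q.shape[0]
    if t == 0.0 or rate == 0.0:
        return np.eye(n)
    P = linalg.expm(Q * (rate * t))
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Rate heterogeneity


def discretize_gamma(alpha: float, k: int, method: str = "mean") -> np.ndarray:
    """Discretise a mean-1 gamma distribution into ``k`` equal-weight rates.

    ``method="mean"`` uses the mean of each equal-probability slice (exact
    via the regularised incomplete gamma function); ``method="median"`` uses
    slice medians rescaled to overall mean 1.  Rates are returned in
    nondecreasing order.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if k < 1:
        raise ValueError("number of categories must be >= 1")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    # X ~ Gamma(shape=alpha, rate=alpha) so E[X] = 1
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    if method == "mean":
        # integral of x f(x) over a slice of Gamma(alpha, rate alpha) is
        # P(alpha+1, alpha*b) evaluated at the slice bounds
        upper = np.where(np.isinf(bounds), np.inf, alpha * bounds)
        cum = gammainc(alpha + 1.0, upper[1:])
        cum_lo = gammainc(alpha + 1.0, upper[:-1])
        rates = k * (cum - cum_lo)
    elif method == "median":
        med_probs = (np.arange(k) + 0.5) / k
        rates = gamma_dist.ppf(med_probs, a=alpha, scale=1.0 / alpha)
        rates = rates / rates.mean()
    else:
        raise ValueError("method must be 'mean' or 'median'")
    rates = np.maximum(rates, 0.0)
    return np.sort(rates)


def make_rate_mixture(
    rates: Sequence[float], p_invariant: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Combine gamma rates with an invariant class into a mean-1 mixture.

    Returns ``(rates, weights)``.  The ``k`` variable categories keep weight
    ``(1 - p_invariant)/k`` each and are rescaled by ``1/(1 - p_invariant)``
    so that the mixture mean is exactly 1; the invariant category (appended
    last, only when ``p_invariant > 0``) has rate 0 and weight
    ``p_invariant``.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or rates.size < 1:
        raise ValueError("rates must be a nonempty 1-D sequence")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if not (0.0 <= p_invariant < 1.0):
        raise ValueError("p_invariant must lie in [0, 1)")
    k = rates.size
    mean = rates.mean()
    if mean <= 0:
        raise ValueError("mean of variable rates must be positive")
    scaled = rates / mean / (1.0 - p_invariant)
    if p_invariant == 0.0:
        return scaled, np.full(k, 1.0 / k)
    out_rates = np.concatenate([scaled, [0.0]])
    out_weights = np.concatenate([np.full(k, (1.0 - p_invariant) / k), [p_invariant]])
    return out_rates, out_weights


def empirical_frequencies(alignment) -> np.ndarray:
    """Residue frequencies over non-gap, non-ambiguous alignment cells (+F)."""
    counts = np.zeros(20)
    for seq in alignment.sequences:
        for ch in seq:
            idx = AA_INDEX.get(ch.upper())
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise EmptyDataError("alignment has no unambiguous residues to count")
    return counts / total
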