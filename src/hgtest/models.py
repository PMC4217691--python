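"""Time-reversible amino-acid substitution models with invariant sites and
discrete-gamma rate heterogeneity (LG+I+G, WAG+I+G, and PAML-format plug-ins).

The rate matrix follows the usual GTR-family construction
``Q_ij = s_ij * pi_j`` (i != j), rescaled to one expected substitution per
unit branch length, and exponentiated through the eigendecomposition of the
reversibly symmetrized matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma_dist

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

__all__ = [
    "AA_ALPHABET",
    "SubstitutionModel",
    "RateCategories",
    "build_rate_matrix",
    "discretize_gamma",
    "site_rate_distribution",
    "transition_matrix",
    "read_paml_matrix",
    "parse_model",
]


@dataclass(frozen=True)
class RateCategories:
    """Discrete site-rate distribution with unit mean: Σ w_k r_k = 1."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, float)
        w = np.asarray(self.weights, float)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)
        if r.shape != w.shape:
            raise ValueError("rates and weights must have equal length")
        if np.any(r < 0) or np.any(w < 0):
            raise ValueError("negative rate or weight")
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        if abs(float(w @ r) - 1.0) > 1e-10:
            raise ValueError("mean rate must be 1")


def discretize_gamma(alpha: float, n_cat: int) -> RateCategories:
    """Equal-weight discretization of Gamma(alpha, alpha); each category rate
    is the mean of its quantile slice, so the unit mean is preserved exactly.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if n_cat == 1:
        return RateCategories(np.ones(1), np.ones(1))
    probs = np.arange(1, n_cat) / n_cat
    bounds = _gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    # E[X; slice] for Gamma(a, rate a) via the shape a+1 CDF (mean is 1)
    cdf_up = _gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    cdf_up = np.concatenate([[0.0], cdf_up, [1.0]])
    rates = n_cat * np.diff(cdf_up)
    weights = np.full(n_cat, 1.0 / n_cat)
    rates = rates / float(weights @ rates)  # exact unit mean
    return RateCategories(rates, weights)


def site_rate_distribution(alpha: float | None, p_inv: float,
                           n_cat: int = 4) -> RateCategories:
    """Combined +I+G site-rate distribution: a zero-rate invariant category
    of weight ``p_inv`` plus ``n_cat`` gamma categories rescaled to keep the
    overall mean rate at 1."""
    if not 0.0 <= p_inv < 1.0:
        raise ValueError(f"p_inv must be in [0, 1), got {p_inv}")
    if alpha is None:
        g = RateCategories(np.ones(1), np.ones(1))
    else:
        g = discretize_gamma(alpha, n_cat)
    if p_inv == 0.0:
        return g
    rates = np.concatenate([[0.0], g.rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], g.weights * (1.0 - p_inv)])
    return RateCategories(rates, weights)


class SubstitutionModel:
    """Reversible substitution model over an arbitrary state alphabet.

    Parameters
    ----------
    states : str
        State alphabet (e.g. the 20 amino acids in PAML order).
    exchangeabilities : array (S, S)
        Symmetric non-negative matrix, diagonal ignored.
    frequencies : array (S,)
        Stationary frequencies, strictly positive, summing to 1.
    alpha : float or None
        Discrete-gamma shape; ``None`` disables rate heterogeneity.
    p_inv : float
        Proportion of invariant sites.
    n_cat : int
        Number of gamma categories (default 4).
    """

    def __init__(self, states: str, exchangeabilities, frequencies,
                 alpha: float | None = None, p_inv: float = 0.0,
                 n_cat: int = 4, name: str | None = None):
        s = np.asarray(exchangeabilities, float)
        pi = np.asarray(frequencies, float)
        n = len(states)
        if len(set(states)) != n:
            raise ValueError("duplicate state symbols")
        if s.shape != (n, n):
            raise ValueError(f"exchangeability matrix must be {n}x{n}")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(s < 0):
            raise ValueError("negative exchangeability")
        if pi.shape != (n,):
            raise ValueError(f"frequencies must have length {n}")
        if np.any(pi <= 0):
            raise ValueError("all frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"frequencies sum to {pi.sum()}, not 1")
        if alpha is not None and alpha <= 0:
            raise ValueError("alpha must be positive")
        self.states = states
        self.exchangeabilities = s
        self.frequencies = pi / pi.sum()
        self.alpha = alpha
        self.p_inv = float(p_inv)
        self.n_cat = int(n_cat)
        self.name = name

    @property
    def n_states(self) -> int:
        return len(self.states)

    def with_rates(self, alpha=None, p_inv=0.0, n_cat=4) -> "SubstitutionModel":
        return SubstitutionModel(self.states, self.exchangeabilities,
                                 self.frequencies, alpha, p_inv, n_cat, self.name)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    @cached_property
    def rate_categories(self) -> RateCategories:
        return site_rate_distribution(self.alpha, self.p_inv, self.n_cat)

    @cached_property
    def _eigen(self):
        """Eigendecomposition of the symmetrized rate matrix; returns
        (eigenvalues, left transform, right transform) with
        P(t) = right @ diag(exp(lam t)) @ left."""
        pi = self.frequencies
        sq = np.sqrt(pi)
        B = (sq[:, None] * self.rate_matrix) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
        lam, U = np.linalg.eigh(B)
        right = U / sq[:, None]
        left = U.T * sq[None, :]
        return lam, left, right

    def transition_matrices(self, lengths) -> np.ndarray:
        """P(t_k) for an array of effective lengths t_k; shape (K, S, S)."""
        t = np.atleast_1d(np.asarray(lengths, float))
        if np.any(t < 0):
            raise ValueError("negative branch length")
        lam, left, right = self._eigen
        expl = np.exp(lam[None, :] * t[:, None])  # (K, S)
        P = np.einsum("ia,ka,aj->kij", right, expl, left, optimize=True)
        np.clip(P, 0.0, None, out=P)
        return P


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Q_ij = s_ij pi_j (i != j), diagonal completing zero row sums, rescaled
    so the expected substitution rate -Σ pi_i Q_ii is exactly 1."""
    pi = model.frequencies
    Q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu


def transition_matrix(model: SubstitutionModel, branch_length: float,
                      rate: float = 1.0) -> np.ndarray:
    """P = exp(Q * t * r), a row-stochastic matrix."""
    if branch_length < 0:
        raise ValueError(f"negative branch length {branch_length}")
    if rate < 0:
        raise ValueError(f"negative rate {rate}")
    if rate == 0.0 or branch_length == 0.0:
        return np.eye(model.n_states)
    return model.transition_matrices([branch_length * rate])[0]


# ---------------------------------------------------------------------------
# PAML .dat empirical matrices and model-string parsing
# ---------------------------------------------------------------------------

def read_paml_matrix(source) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-format amino-acid rate file: 190 lower-triangle
    exchangeabilities followed by 20 stationary frequencies.  Lines starting
    with ``*`` or ``#`` are comments."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    values = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped[0] in "*#":
            continue
        values.extend(float(tok) for tok in stripped.split())
    if len(values) < 210:
        raise ValueError(f"expected >= 210 numbers (190 + 20), got {len(values)}")
    tri, freqs = values[:190], np.array(values[190:210])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    return S, freqs / freqs.sum()


def _empirical_model(name: str) -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("hgtest.data").joinpath(f"{name}.dat")
    with path.open() as fh:
        return read_paml_matrix(fh)


_MODEL_RE = re.compile(r"^(?P<base>[A-Za-z0-9_.]+)(?P<mods>(\+[A-Za-z]+\d*)*)$")


def parse_model(spec: str, alpha: float | None = None,
                p_inv: float | None = None) -> SubstitutionModel:
    """Build a model from a spec string such as ``LG+I+G4``, ``WAG+G`` or
    ``POISSON``.  ``alpha`` / ``p_inv`` override the defaults (1.0 and 0.1)
    used when +G / +I are requested without explicit values."""
    m = _MODEL_RE.match(spec.strip())
    if m is None:
        raise ValueError(f"cannot parse model spec {spec!r}")
    base = m.group("base").upper()
    if base in ("LG", "WAG"):
        S, pi = _empirical_model(base)
    elif base == "POISSON":
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        pi = np.full(20, 0.05)
    else:
        raise ValueError(f"unknown base model {base!r} (use LG, WAG or POISSON)")
    use_g, n_cat, use_i = False, 4, False
    for mod in re.findall(r"\+([A-Za-z]+\d*)", m.group("mods") or ""):
        mu = mod.upper()
        if mu == "I":
            use_i = True
        elif mu.startswith("G"):
            use_g = True
            if mu[1:]:
                n_cat = int(mu[1:])
        else:
            raise ValueError(f"unknown model modifier +{mod}")
    a = (alpha if alpha is not None else 1.0) if use_g else None
    p = (p_inv if p_inv is not None else 0.1) if use_i else 0.0
    return SubstitutionModel(AA_ALPHABET, S, pi, alpha=a, p_inv=p,
                             n_cat=n_cat, name=spec.strip().upper())


def two_state_model(freq0: float = 0.5, alpha: float | None = None,
                    p_inv: float = 0.0, n_cat: int = 4) -> SubstitutionModel:
    """Binary-alphabet model, handy for closed-form checks."""
    S = np.array([[0.0, 1.0], [1.0, 0.0]])
    pi = np.array([freq0, 1.0 - freq0])
    return SubstitutionModel("01", S, pi, alpha=alpha, p_inv=p_inv,
                             n_cat=n_cat, name="TWO-STATE")
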