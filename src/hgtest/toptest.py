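"""Frequentist topology tests on a site log-likelihood matrix.

Implements the RELL bootstrap (resampling estimated log-likelihoods), the
Kishino-Hasegawa paired test, and the approximately-unbiased (AU) test via
multiscale bootstrap: bootstrap proportions bp(r) at several replicate-size
scales r are inverse-normal transformed and fitted by weighted least squares
to  z(r) = d*sqrt(r) + c/sqrt(r),  giving  p_AU = 1 - Phi(d - c).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phylik import SiteLLMatrix

__all__ = [
    "TopologyTestResult",
    "rell_resample",
    "kh_test",
    "au_test",
    "topology_tests",
    "DEFAULT_SCALES",
    "DEFAULT_N_REP",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))
DEFAULT_N_REP = 10_000
_CHUNK = 2_000  # replicates per resampling block


@dataclass
class TopologyTestResult:
    tree_id: object
    delta_lnL: float
    bp: float | None = None
    p_kh: float | None = None
    p_au: float | None = None
    n_replicates: int | None = None
    scales: tuple | None = None
    seed: int | None = None
    flags: tuple = ()
    fit_deviance: float | None = None

    def __post_init__(self):
        for p in (self.p_kh, self.p_au, self.bp):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")

    def to_dict(self):
        return asdict(self)


def _check_matrix(m: SiteLLMatrix):
    if m.n_trees == 0 or m.n_sites == 0:
        raise ValueError("empty site log-likelihood matrix")


def rell_resample(m: SiteLLMatrix, n_rep: int, scale: float = 1.0,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Bootstrap totals (trees x n_rep): each replicate draws
    round(scale * n_sites) site indices with replacement and sums each
    tree's site log-likelihoods.  Seeded and reproducible."""
    _check_matrix(m)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = m.n_sites
    m_len = max(1, int(round(scale * n)))
    out = np.empty((m.n_trees, n_rep))
    for lo in range(0, n_rep, _CHUNK):
        hi = min(lo + _CHUNK, n_rep)
        idx = rng.integers(0, n, size=(hi - lo, m_len))
        out[:, lo:hi] = m.values[:, idx].sum(axis=2)
    return out


def _smooth(count: int, n: int) -> float:
    return (count + 1.0) / (n + 1.0)


def kh_test(m: SiteLLMatrix, n_rep: int = DEFAULT_N_REP, seed: int = 0,
            two_sided: bool = True) -> list[TopologyTestResult]:
    """Kishino-Hasegawa paired test of exactly two trees.

    The observed total-lnL difference is compared against centered RELL
    replicate differences; two-sided by default (one-sided tests the
    directional hypothesis that the named tree is worse).  Add-one smoothing
    keeps p >= 1/(n_rep + 1).
    """
    _check_matrix(m)
    if m.n_trees != 2:
        raise ValueError(f"KH test needs exactly 2 trees, got {m.n_trees}")
    if m.n_sites < 2:
        raise ValueError("KH test needs at least 2 sites")
    totals = m.totals()
    delta = totals[0] - totals[1]
    reps = rell_resample(m, n_rep, 1.0, seed)
    dstar = reps[0] - reps[1]
    centered = dstar - dstar.mean()
    if two_sided:
        p0 = p1 = _smooth(int(np.sum(np.abs(centered) >= abs(delta))), n_rep)
    else:
        # p for tree i = evidence that tree i is the worse one
        p0 = _smooth(int(np.sum(centered <= delta)), n_rep)
        p1 = _smooth(int(np.sum(centered >= delta)), n_rep)
    best = 0 if delta >= 0 else 1
    deltas = [max(0.0, -delta), max(0.0, delta)]
    return [
        TopologyTestResult(m.tree_ids[i], deltas[i], p_kh=(p0, p1)[i],
                           n_replicates=n_rep, seed=_as_seed(seed))
        for i in range(2)
    ]


def _as_seed(seed):
    return seed if isinstance(seed, int) else None


def _multiscale_fit(scales: np.ndarray, bps: np.ndarray, n_rep: int):
    """Weighted least-squares fit of z(r) = d sqrt(r) + c / sqrt(r) to
    inverse-normal transformed bootstrap proportions.

    Returns (d, c, p_au, deviance, flags).  Only scales with an informative
    bootstrap proportion (strictly between 0 and 1) enter the fit: a bp
    pinned at 0 or 1 carries no usable probit value, and fitting its clamped
    stand-in would flatten the z(r) curve and bias d - c toward 0.  When
    fewer than two informative scales remain the tree is (essentially)
    always or never best, and p is the corresponding smoothed extreme."""
    flags = []
    lo = 1.0 / (n_rep + 1.0)

    def wls(sc, bp):
        z = norm.ppf(1.0 - bp)
        w = n_rep * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
        X = np.column_stack([np.sqrt(sc), 1.0 / np.sqrt(sc)])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        resid = z - X @ coef
        return coef, float(w @ resid**2)

    informative = (bps > lo) & (bps < 1.0 - lo)
    if informative.sum() < 2:
        (d, c), deviance = wls(scales, np.clip(bps, lo, 1.0 - lo))
        flags.append("degenerate_fit")
        p = lo if bps.mean() < 0.5 else 1.0 - lo
        return float(d), float(c), p, deviance, flags
    if not informative.all():
        flags.append("uninformative_scales_dropped")
    (d, c), deviance = wls(scales[informative], bps[informative])
    p = float(1.0 - norm.cdf(d - c))
    p = min(max(p, lo), 1.0 - lo)
    return float(d), float(c), p, deviance, flags


def au_test(m: SiteLLMatrix, scales=DEFAULT_SCALES, n_rep: int = DEFAULT_N_REP,
            seed: int = 0) -> list[TopologyTestResult]:
    """Approximately-unbiased test for every tree in the matrix.

    Bootstrap proportions of each tree being best are measured at each
    replicate-size scale (ties broken toward the lowest tree index, flagged),
    then the multiscale model is fitted per tree.
    """
    _check_matrix(m)
    scales = np.asarray(sorted(scales), float)
    if m.n_trees < 2:
        return [TopologyTestResult(m.tree_ids[0], 0.0, bp=1.0, p_au=1.0,
                                   n_replicates=n_rep, scales=tuple(scales),
                                   seed=_as_seed(seed))]
    if len(scales) < 2 or scales.min() >= 1.0 or scales.max() <= 1.0:
        raise ValueError("need >= 2 scales spanning values below and above 1")
    rng = np.random.default_rng(seed)
    totals = m.totals()
    best_total = totals.max()
    T = m.n_trees
    bp = np.zeros((len(scales), T))
    tied = False
    for si, r in enumerate(scales):
        reps = rell_resample(m, n_rep, float(r), rng)
        winners = np.argmax(reps, axis=0)  # ties -> lowest index
        top = reps.max(axis=0)
        tied = tied or bool(np.any(np.sum(reps == top, axis=0) > 1))
        bp[si] = np.bincount(winners, minlength=T) / n_rep
    i_naive = int(np.argmin(np.abs(scales - 1.0)))
    results = []
    for t in range(T):
        d, c, p, dev, flags = _multiscale_fit(scales, bp[:, t], n_rep)
        if tied:
            flags = list(flags) + ["ties_broken_low_index"]
        results.append(TopologyTestResult(
            m.tree_ids[t], float(best_total - totals[t]), bp=float(bp[i_naive, t]),
            p_au=p, n_replicates=n_rep, scales=tuple(scales),
            seed=_as_seed(seed), flags=tuple(flags), fit_deviance=dev))
    return results


def topology_tests(m: SiteLLMatrix, scales=DEFAULT_SCALES,
                   n_rep: int = DEFAULT_N_REP, seed: int = 0,
                   two_sided_kh: bool = True) -> list[TopologyTestResult]:
    """Combined report: AU p-values for all trees plus a KH p-value of each
    tree against the best-scoring tree (the best tree gets p_kh = 1)."""
    _check_matrix(m)
    au = au_test(m, scales=scales, n_rep=n_rep, seed=seed)
    totals = m.totals()
    best = int(np.argmax(totals))
    for t, res in enumerate(au):
        if t == best:
            res.p_kh = 1.0
            continue
        pair = SiteLLMatrix([m.tree_ids[best], m.tree_ids[t]],
                            m.values[[best, t]])
        kh = kh_test(pair, n_rep=n_rep, seed=seed, two_sided=two_sided_kh)
        res.p_kh = kh[1].p_kh
    return au


def results_to_frame(results: list[TopologyTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.to_dict()
        d["flags"] = ";".join(r.flags)
        d.pop("scales", None)
        rows.append(d)
    return pd.DataFrame(rows)


def write_report(results: list[TopologyTestResult], tsv_path=None,
                 json_path=None):
    df = results_to_frame(results)
    if tsv_path is not None:
        df[["tree_id", "delta_lnL", "bp", "p_kh", "p_au", "flags"]].to_csv(
            tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        payload = [r.to_dict() for r in results]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
    return df


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
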