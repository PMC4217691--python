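"""Felsenstein-pruning likelihood engine for protein alignments.

Produces the per-site log-likelihoods consumed by the topology tests, plus
coordinate-wise branch-length optimization.  Gaps, ``X`` and ``?`` are
treated as missing data (partial likelihood 1 in every state).  All
likelihoods are natural logs.  Per-pattern log-scaling keeps partials in
range, and a site whose configuration has zero likelihood (conflicting
states across zero-length paths) yields -inf rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .models import AA_ALPHABET, SubstitutionModel
from .treeops import PhyloTree

__all__ = [
    "ProteinAlignment",
    "SiteLLMatrix",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "site_ll_matrix",
]

MISSING_CHARS = "-X?."
BRANCH_MAX = 10.0  # expected substitutions/site


class ProteinAlignment:
    """Aligned sequences over a state alphabet, with site-pattern compression.

    The canonical alphabet is the 20 amino acids; binary and 4-state toy
    alphabets are supported for oracle tests.  Missing data (gap, X, ?) is
    encoded as -1.
    """

    def __init__(self, taxa, codes: np.ndarray, alphabet: str = AA_ALPHABET):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2 or codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be a taxa x sites matrix")
        self.codes = codes
        self.alphabet = alphabet
        self._patterns = None

    @classmethod
    def from_records(cls, records, alphabet: str = AA_ALPHABET) -> "ProteinAlignment":
        """Build from (label, sequence) pairs; sequences must be equal length."""
        records = list(records)
        if not records:
            return cls([], np.zeros((0, 0), dtype=np.int16), alphabet)
        lengths = {len(seq) for _, seq in records}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        lut = np.full(128, -2, dtype=np.int16)
        for i, ch in enumerate(alphabet):
            lut[ord(ch)] = i
            lut[ord(ch.lower())] = i
        for ch in MISSING_CHARS:
            lut[ord(ch)] = -1
        taxa, rows = [], []
        for label, seq in records:
            taxa.append(label)
            arr = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
            if np.any(arr == -2):
                bad = sorted({seq[i] for i in np.nonzero(arr == -2)[0]})
                raise ValueError(f"record {label!r} contains invalid characters {bad}")
            rows.append(arr)
        return cls(taxa, np.vstack(rows), alphabet)

    @classmethod
    def from_fasta(cls, path, alphabet: str = AA_ALPHABET) -> "ProteinAlignment":
        from .prep import read_fasta
        return cls.from_records(read_fasta(path), alphabet)

    @classmethod
    def from_file(cls, path, alphabet: str = AA_ALPHABET) -> "ProteinAlignment":
        """Read FASTA or relaxed PHYLIP (format sniffed)."""
        from .prep import read_alignment_file
        return cls.from_records(read_alignment_file(path), alphabet)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, label: str) -> str:
        row = self.codes[self.taxa.index(label)]
        return "".join("-" if c < 0 else self.alphabet[c] for c in row)

    def records(self):
        return [(t, self.sequence(t)) for t in self.taxa]

    def patterns(self):
        """(pattern columns (taxa x n_pat), counts, site -> pattern index)."""
        if self._patterns is None:
            cols, idx, counts = np.unique(self.codes, axis=1,
                                          return_inverse=True, return_counts=True)
            self._patterns = (cols, counts.astype(float), idx.ravel())
        return self._patterns

    def subset_columns(self, keep) -> "ProteinAlignment":
        return ProteinAlignment(self.taxa, self.codes[:, keep], self.alphabet)


# ---------------------------------------------------------------------------
# Site log-likelihood matrix container + TSV I/O
# ---------------------------------------------------------------------------

@dataclass
class SiteLLMatrix:
    """Candidate trees x alignment sites matrix of natural-log site
    likelihoods, in uncompressed site order."""

    tree_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.tree_ids) != len(set(self.tree_ids)):
            raise ValueError("duplicate tree ids")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.tree_ids):
            raise ValueError("values must be trees x sites")

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_tsv(self, path):
        df = pd.DataFrame(self.values, index=self.tree_ids,
                          columns=[f"site_{i + 1}" for i in range(self.n_sites)])
        df.index.name = "tree_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SiteLLMatrix":
        with open(path) as fh:
            first = fh.readline()
        # puzzle-style .sitelh variant: a bare "n_trees n_sites" count line
        skip = 1 if len(first.split()) == 2 and first.split()[0].isdigit() else 0
        if skip:
            df = pd.read_csv(path, sep=r"\s+", skiprows=1, header=None, index_col=0)
        else:
            df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(float))


# ---------------------------------------------------------------------------
# Pruning calculator
# ---------------------------------------------------------------------------

class _TreeLikelihood:
    """One (alignment, tree, model) likelihood workspace.

    Holds pattern-compressed leaf partials, the per-category transition
    matrices of every edge, and up/down partial caches used for fast 1-D
    branch-length profiles.
    """

    def __init__(self, aln: ProteinAlignment, tree: PhyloTree,
                 model: SubstitutionModel):
        tree_taxa = tree.leaf_labels()
        if tree_taxa != frozenset(aln.taxa):
            diff = sorted(tree_taxa ^ frozenset(aln.taxa))
            raise ValueError(f"tree/alignment leaf sets differ by {diff}")
        self.model = model
        self.tree = tree
        cats = model.rate_categories
        self.rates = cats.rates
        self.logw = np.log(cats.weights)
        self.pi = model.frequencies
        self.n_cat = len(self.rates)
        S = model.n_states

        cols, self.counts, self.site_to_pat = aln.patterns()
        self.n_pat = cols.shape[1]
        row_of = {t: i for i, t in enumerate(aln.taxa)}

        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.leaf_partial = {}
        for n in self.nodes:
            if n.is_leaf:
                codes = cols[row_of[n.label]]
                part = np.ones((self.n_pat, S))
                obs = codes >= 0
                part[obs] = 0.0
                part[np.nonzero(obs)[0], codes[obs]] = 1.0
                self.leaf_partial[id(n)] = part
        self.pmats = {}
        for n in self.nodes[:-1]:  # all but root
            self._set_pmat(n)
        self._up = None
        self._down = None

    # -- transition matrices -------------------------------------------
    def _set_pmat(self, node):
        t = node.length if node.length is not None else 0.0
        self.pmats[id(node)] = self._pmat_for(t)

    def _pmat_for(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        return self.model.transition_matrices(self.rates * t)

    # -- passes ---------------------------------------------------------
    @staticmethod
    def _rescale(arr, scale):
        """In-place per-(category, pattern) max-rescaling; only done when a
        value is small enough to threaten underflow (or is exactly zero)."""
        mx = arr.max(axis=2)
        if mx.min() > 1e-100:
            return arr, scale
        nz = mx > 0
        safe = np.where(nz, mx, 1.0)
        arr = arr / safe[..., None]
        with np.errstate(divide="ignore"):
            scale = scale + np.where(nz, np.log(safe), -np.inf)
        return arr, scale

    def up_pass(self):
        """Post-order partials; returns (up, upscale, msg) keyed by node id."""
        up, upscale, msg = {}, {}, {}
        for n in self.nodes:
            if n.is_leaf:
                u = np.broadcast_to(self.leaf_partial[id(n)],
                                    (self.n_cat, self.n_pat, len(self.pi)))
                up[id(n)] = u
                upscale[id(n)] = np.zeros((self.n_cat, self.n_pat))
            else:
                prod = None
                scale = np.zeros((self.n_cat, self.n_pat))
                for c in n.children:
                    m = np.matmul(up[id(c)], self.pmats[id(c)].transpose(0, 2, 1))
                    msg[id(c)] = m
                    prod = m if prod is None else prod * m
                    scale = scale + upscale[id(c)]
                prod, scale = self._rescale(prod, scale)
                up[id(n)] = prod
                upscale[id(n)] = scale
        self._up = (up, upscale, msg)
        return self._up

    def down_pass(self):
        """Pre-order 'rest of tree' partials for every edge.  For the edge
        above node c, oth[c] is the partial of everything except c's subtree
        (root frequencies included), seen from c's parent."""
        if self._up is None:
            self.up_pass()
        up, upscale, msg = self._up
        oth, othscale = {}, {}
        out, outscale = {}, {}
        root = self.nodes[-1]
        out[id(root)] = np.broadcast_to(self.pi, (self.n_cat, self.n_pat, len(self.pi)))
        outscale[id(root)] = np.zeros((self.n_cat, self.n_pat))
        for n in reversed(self.nodes):  # pre-order
            if n.is_leaf:
                continue
            for c in n.children:
                o = out[id(n)].copy()
                s = outscale[id(n)].copy()
                for sib in n.children:
                    if sib is c:
                        continue
                    o = o * msg[id(sib)]
                    s = s + upscale[id(sib)]
                o, s = self._rescale(o, s)
                oth[id(c)], othscale[id(c)] = o, s
                if not c.is_leaf:
                    out[id(c)] = np.matmul(o, self.pmats[id(c)])
                    outscale[id(c)] = s
        self._down = (oth, othscale)
        return self._down

    # -- likelihood -----------------------------------------------------
    def pattern_log_likelihoods(self) -> np.ndarray:
        up, upscale, _ = self.up_pass()
        root = self.nodes[-1]
        val = up[id(root)] @ self.pi  # (n_cat, n_pat)
        with np.errstate(divide="ignore"):
            logval = np.log(val) + upscale[id(root)]
        return logsumexp(logval + self.logw[:, None], axis=0)

    def site_log_likelihoods(self) -> np.ndarray:
        return self.pattern_log_likelihoods()[self.site_to_pat]

    def total(self) -> float:
        pll = self.pattern_log_likelihoods()
        if np.any(np.isneginf(pll)):
            return -np.inf
        return float(self.counts @ pll)

    # -- branch-length optimization --------------------------------------
    def _edge_profile(self, node):
        """Returns f(t) -> total lnL as a function of this edge's length,
        using cached up/down partials (valid while other edges are fixed).

        The profile is evaluated through the spectral form
        f(t) = sum_s (A*B)_s exp(lambda_s r t) with A, B the inside/outside
        partials rotated into the eigenbasis, so each 1-D evaluation costs
        one small matrix-vector product."""
        up, upscale, _ = self._up
        oth, othscale = self._down
        lam, left, right = self.model._eigen
        A = np.matmul(oth[id(node)], right)        # (n_cat, n_pat, S)
        B = np.matmul(up[id(node)], left.T)
        C = A * B
        base = upscale[id(node)] + othscale[id(node)] + self.logw[:, None]
        counts = self.counts
        rates = self.rates

        def f(t: float) -> float:
            E = np.exp(np.outer(rates * t, lam))   # (n_cat, S)
            val = np.einsum("cps,cs->cp", C, E)
            np.clip(val, 0.0, None, out=val)       # cancellation round-off
            with np.errstate(divide="ignore"):
                ll = logsumexp(np.log(val) + base, axis=0)
            if np.any(np.isneginf(ll)):
                return -np.inf
            return float(counts @ ll)

        return f

    def _optimize_edge(self, node, xatol: float, maxiter: int = 30) -> float:
        """1-D bounded maximization of one edge; returns the profile lnL."""
        f = self._edge_profile(node)
        t0 = node.length if node.length is not None else 0.0
        res = minimize_scalar(lambda t: -f(t), bounds=(0.0, BRANCH_MAX),
                              method="bounded",
                              options={"xatol": xatol, "maxiter": maxiter})
        best = -res.fun
        at0 = f(t0)
        if best > at0:
            node.length = float(res.x)
            self._set_pmat(node)
            return best
        return at0

    def optimize(self, tol: float = 1e-6, max_rounds: int = 20,
                 xatol: float = 1e-5) -> float:
        """Cycle bounded 1-D optimizations over all edges until the total
        lnL improves by less than ``tol``; lnL is non-decreasing.

        Each round first tries a fast sweep that reuses the round-start
        partials for every edge; if that ever fails to improve the total
        (possible because later profiles are then slightly stale), the
        round is redone exactly, refreshing the partials per edge.
        """
        edges = self.nodes[:-1]
        lnl = self.total()
        if not np.isfinite(lnl):
            raise ValueError("non-finite log-likelihood at starting lengths")

        def exact_round():
            # Gauss-Seidel: refresh partials before each edge
            for node in edges:
                self.up_pass()
                self.down_pass()
                self._optimize_edge(node, xatol)
                self._up = self._down = None
            return self.total()

        rounds = 0
        while rounds < max_rounds:
            start = lnl
            saved = [(n, n.length) for n in edges]
            self.up_pass()
            self.down_pass()
            for node in edges:
                self._optimize_edge(node, xatol)
            self._up = self._down = None
            lnl = self.total()
            rounds += 1
            if lnl < start:  # stale sweep overshot: redo this round exactly
                for n, t in saved:
                    n.length = t
                    self._set_pmat(n)
                lnl = exact_round()
            if lnl - start < tol:
                # confirm convergence with one exact sweep; the fast sweep
                # can take vanishing steps away from a stationary point
                confirmed = exact_round()
                rounds += 1
                if confirmed - lnl < tol:
                    return confirmed
                lnl = confirmed
        return lnl


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def site_log_likelihoods(aln: ProteinAlignment, tree: PhyloTree,
                         model: SubstitutionModel) -> np.ndarray:
    """Per-site natural-log likelihoods in original site order."""
    return _TreeLikelihood(aln, tree, model).site_log_likelihoods()


def total_log_likelihood(aln: ProteinAlignment, tree: PhyloTree,
                         model: SubstitutionModel) -> float:
    """Total lnL, computed on compressed patterns weighted by counts."""
    return _TreeLikelihood(aln, tree, model).total()


def optimize_branch_lengths(aln: ProteinAlignment, tree: PhyloTree,
                            model: SubstitutionModel, tol: float = 1e-6,
                            max_rounds: int = 20, xatol: float = 1e-5,
                            ) -> tuple[PhyloTree, float]:
    """Coordinate-wise branch-length optimization (bounded 1-D method per
    branch); returns (tree copy with optimized lengths, final lnL)."""
    work = tree.copy().fill_lengths()
    calc = _TreeLikelihood(aln, work, model)
    lnl = calc.optimize(tol=tol, max_rounds=max_rounds, xatol=xatol)
    return work, lnl


def site_ll_matrix(aln: ProteinAlignment, trees, model: SubstitutionModel,
                   optimize: bool = True, tree_ids=None,
                   tol: float = 1e-6, max_rounds: int = 20) -> SiteLLMatrix:
    """Row per candidate tree of per-site log-likelihoods, with per-tree
    branch-length optimization when requested."""
    trees = list(trees)
    if tree_ids is None:
        tree_ids = [f"tree_{i + 1}" for i in range(len(trees))]
    if len(tree_ids) != len(set(tree_ids)):
        raise ValueError("duplicate tree ids")
    rows = []
    for t in trees:
        if optimize:
            t, _ = optimize_branch_lengths(aln, t, model, tol=tol,
                                           max_rounds=max_rounds)
        rows.append(site_log_likelihoods(aln, t, model))
    return SiteLLMatrix(list(tree_ids), np.vstack(rows))
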