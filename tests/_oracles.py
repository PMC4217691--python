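"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: likelihoods
by exhaustive enumeration over internal-node states, bipartition sets via
dendropy, and gamma category means by adaptive quadrature.
"""

import itertools

import numpy as np
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from hgtest.models import transition_matrix


def brute_force_site_lls(aln, tree, model):
    """Site log-likelihoods by summing over all internal-node state
    assignments, category by category."""
    cats = model.rate_categories
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    row = {t: i for i, t in enumerate(aln.taxa)}
    S = model.n_states
    out = np.zeros(aln.n_sites)
    for site in range(aln.n_sites):
        total = 0.0
        for rate, weight in zip(cats.rates, cats.weights):
            pmats = {id(n): transition_matrix(model, n.length or 0.0, rate)
                     for n in nodes if n.parent is not None}
            acc = 0.0
            for assign in itertools.product(range(S), repeat=len(internals)):
                amap = dict(zip((id(n) for n in internals), assign))
                pr = model.frequencies[amap[id(nodes[-1])]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    pa = amap[id(n.parent)]
                    if n.is_leaf:
                        code = aln.codes[row[n.label], site]
                        if code >= 0:
                            pr *= pmats[id(n)][pa, code]
                    else:
                        pr *= pmats[id(n)][pa, amap[id(n)]]
                acc += pr
            total += weight * acc
        out[site] = np.log(total) if total > 0 else -np.inf
    return out


def gamma_slice_means(alpha, n_cat):
    """Mean of each equal-probability slice of Gamma(alpha, alpha) by
    adaptive quadrature."""
    bounds = gamma_dist.ppf(np.arange(n_cat + 1) / n_cat, alpha,
                            scale=1.0 / alpha)
    bounds[-1] = np.inf
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(
            lambda x: x * gamma_dist.pdf(x, alpha, scale=1.0 / alpha),
            lo, hi, limit=200)
        means.append(val * n_cat)  # each slice has probability 1/n_cat
    return np.array(means)


def dendropy_rf(newick1, newick2):
    """Robinson-Foulds symmetric difference via dendropy."""
    import dendropy
    from dendropy.calculate import treecompare
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    t2 = dendropy.Tree.get(data=newick2, schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)
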