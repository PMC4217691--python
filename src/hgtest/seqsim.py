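"""Synthetic-data generator: protein alignments evolved along species trees,
optional prune-and-regraft transfer events, and stationary MCMC-style
log-likelihood trace pairs.

Every stage of the transfer-detection pipeline can be exercised offline:
``build_hgt_scenario`` plants a known gene transfer (or none), together with
the monophyly constraint that is true exactly when no transfer happened, so
detection power and type-I error are directly measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayescmp import MCMCTrace, DEFAULT_BURN_IN
from .models import SubstitutionModel, parse_model
from .phylik import ProteinAlignment
from .treeops import (MonophylyConstraint, Node, PhyloTree, is_compatible,
                      spr_transfer)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "random_species_tree",
    "random_transfer",
    "simulate_alignment",
    "build_hgt_scenario",
    "simulate_trace_pair",
]

BRANCH_MEAN = 0.15  # mean of the exponential branch-length prior


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def random_species_tree(n_taxa: int, seed, branch_mean: float = BRANCH_MEAN,
                        labels=None) -> PhyloTree:
    """Uniform random resolved unrooted topology (random stepwise addition)
    with i.i.d. exponential branch lengths."""
    rng = _rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    root = Node()
    for l in labels[:3]:
        root.add(Node(l))
    for label in labels[3:]:
        edges = [n for n in root.postorder() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(label))
        root = root  # tree modified in place
    tree = PhyloTree(root, canonicalize=False)
    for n in tree.edges():
        n.length = float(rng.exponential(branch_mean))
    return tree


def recipient_home_group(tree: PhyloTree, recipient: str) -> frozenset:
    """The recipient plus its smaller sister subtree: of the two minimal
    splits adjacent to the recipient's pendant edge, the one with fewer taxa
    (ties broken lexicographically).  This is a non-trivial clade of the
    species tree whose monophyly a transfer event destroys."""
    n = tree.n_leaves
    if n < 4:
        raise ValueError("home group undefined for fewer than 4 taxa")
    leaf = next(l for l in tree.leaves() if l.label == recipient)
    attach = leaf.parent
    all_leaves = tree.leaf_labels()
    # the components adjacent to the attachment node, minus the recipient
    sides = [c.leaf_labels() for c in attach.children if c is not leaf]
    if attach.parent is not None:
        sides.append(all_leaves - attach.leaf_labels())
    candidates = [frozenset({recipient}) | s for s in sides]
    candidates = [g for g in candidates if 2 <= len(g) <= n - 2]
    if not candidates:
        raise ValueError(f"no proper home group for {recipient!r}")
    return min(candidates, key=lambda g: (len(g), tuple(sorted(g))))


def _edge_distance(tree: PhyloTree, node_a: Node, node_b: Node) -> int:
    """Number of edges between two nodes of the rooted representation."""
    anc_a = []
    n = node_a
    while n is not None:
        anc_a.append(n)
        n = n.parent
    depth = {id(n): i for i, n in enumerate(anc_a)}
    n, steps = node_b, 0
    while id(n) not in depth:
        n = n.parent
        steps += 1
    return steps + depth[id(n)]


def random_transfer(tree: PhyloTree, seed, min_edge_distance: int = 2):
    """Pick a (donor_clade, recipient) pair such that the donor clade is
    disjoint from the recipient's home group and the recipient is moved
    across at least ``min_edge_distance`` edges (edges strictly between its
    attachment node and the regraft edge).
    Returns (donor_clade frozenset, recipient label)."""
    rng = _rng(seed)
    leaves = sorted(tree.leaf_labels())
    order = rng.permutation(len(leaves))
    nodes = [n for n in tree.postorder() if n.parent is not None]
    for li in order:
        recipient = leaves[li]
        home = recipient_home_group(tree, recipient)
        rnode = next(n for n in tree.leaves() if n.label == recipient)
        candidates = []
        for n in nodes:
            clade = n.leaf_labels()
            if recipient in clade or clade & home:
                continue
            # the path attach -> donor node ends with the regraft edge
            # itself, so edges crossed = path length - 1
            if _edge_distance(tree, rnode.parent, n) - 1 < min_edge_distance:
                continue
            candidates.append(clade)
        if candidates:
            pick = candidates[rng.integers(len(candidates))]
            return frozenset(pick), recipient
    raise ValueError("tree admits no transfer at the requested distance")


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       n_sites: int, seed) -> ProteinAlignment:
    """Evolve sites along the tree: per-site rate category, root state from
    the stationary frequencies, states propagated through each branch's
    transition matrix.  Deterministic given the seed."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    cats = model.rate_categories
    cat_of_site = rng.choice(len(cats.rates), size=n_sites, p=cats.weights)
    pi = model.frequencies
    S = model.n_states
    states = {id(tree.root): rng.choice(S, size=n_sites, p=pi)}
    for node in reversed(list(tree.postorder())):  # pre-order
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        t = node.length if node.length is not None else 0.0
        child = parent_states.copy()
        for ci, rate in enumerate(cats.rates):
            mask = cat_of_site == ci
            if not mask.any() or rate == 0.0 or t == 0.0:
                continue
            P = model.transition_matrices([t * rate])[0]
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(mask.sum()))
            rows = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[id(node)] = child
    taxa, rows = [], []
    for leaf in tree.leaves():
        taxa.append(leaf.label)
        rows.append(states[id(leaf)])
    order = np.argsort(taxa)
    return ProteinAlignment([taxa[i] for i in order],
                            np.vstack([rows[i] for i in order]).astype(np.int16),
                            model.states)


@dataclass
class ScenarioConfig:
    """One simulated gene: a species tree, a substitution model, and an
    optional single transfer event."""

    n_taxa: int = 6
    n_sites: int = 1000
    model: str = "LG+I+G4"
    alpha: float = 1.0
    p_inv: float = 0.1
    branch_mean: float = BRANCH_MEAN
    transfer: tuple | None = None  # (donor_clade, recipient) or "random"
    min_edge_distance: int = 2
    seed: int = 0

    def substitution_model(self) -> SubstitutionModel:
        return parse_model(self.model, alpha=self.alpha, p_inv=self.p_inv)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        """Load a scenario config file; keys mirror the dataclass fields.
        ``transfer`` may be "random", null, or a [donor_taxa, recipient]
        pair."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
        if isinstance(data.get("transfer"), (list, tuple)):
            donor, recipient = data["transfer"]
            data["transfer"] = (frozenset(donor), recipient)
        return cls(**data)


@dataclass
class Scenario:
    alignment: ProteinAlignment
    species_tree: PhyloTree
    gene_tree: PhyloTree
    constraint: MonophylyConstraint
    constraint_true: bool
    donor_clade: frozenset | None
    recipient: str | None
    config: ScenarioConfig

    def write(self, outdir):
        """FASTA + two Newick files + constraint file + truth JSON."""
        from .prep import write_fasta
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.alignment.records(), out / "alignment.fasta")
        (out / "species_tree.nwk").write_text(self.species_tree.to_newick() + "\n")
        (out / "gene_tree.nwk").write_text(self.gene_tree.to_newick() + "\n")
        self.constraint.to_file(out / "constraint.txt")
        truth = {
            "constraint_true": self.constraint_true,
            "recipient": self.recipient,
            "donor_clade": sorted(self.donor_clade) if self.donor_clade else None,
            "seed": self.config.seed,
            "n_taxa": self.config.n_taxa,
            "n_sites": self.config.n_sites,
            "model": self.config.model,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        return out


def build_hgt_scenario(cfg: ScenarioConfig,
                       species_tree: PhyloTree | None = None) -> Scenario:
    """Simulate one gene.  Without a transfer the gene tree is the species
    tree and the monophyly constraint (the recipient's home group) holds;
    with a transfer the recipient is regrafted onto the donor clade and the
    same constraint is false."""
    rng = np.random.default_rng(cfg.seed)
    tree_seed, transfer_seed, aln_seed = rng.integers(2**31, size=3)
    if species_tree is None:
        species_tree = random_species_tree(cfg.n_taxa, tree_seed,
                                           cfg.branch_mean)
    model = cfg.substitution_model()

    if cfg.transfer is None:
        # null scenario: constrain an arbitrary true clade (the home group
        # of the first taxon in label order)
        recipient_for_group = sorted(species_tree.leaf_labels())[0]
        group = recipient_home_group(species_tree, recipient_for_group)
        constraint = MonophylyConstraint([group])
        gene_tree = species_tree.copy()
        donor, recipient = None, None
        constraint_true = True
    else:
        if cfg.transfer == "random":
            donor, recipient = random_transfer(species_tree, transfer_seed,
                                               cfg.min_edge_distance)
        else:
            donor, recipient = frozenset(cfg.transfer[0]), cfg.transfer[1]
        home = recipient_home_group(species_tree, recipient)
        if donor & home:
            raise ValueError(
                "donor clade overlaps the recipient's home group; such a "
                "transfer cannot violate the monophyly constraint")
        constraint = MonophylyConstraint([home])
        gene_tree = spr_transfer(species_tree, donor, recipient)
        constraint_true = False
        assert not is_compatible(gene_tree, constraint)

    alignment = simulate_alignment(gene_tree, model, cfg.n_sites, aln_seed)
    return Scenario(alignment, species_tree, gene_tree, constraint,
                    constraint_true, donor, recipient, cfg)


def simulate_trace_pair(mean_a: float, mean_b: float, sd: float, n: int,
                        autocorr: float = 0.0, seed=0,
                        burn_in_fraction: float = DEFAULT_BURN_IN,
                        stride: int = 100) -> tuple[MCMCTrace, MCMCTrace]:
    """Paired stationary AR(1) Gaussian log-likelihood traces with the
    stated stationary means, a shared stationary SD and autocorrelation.
    ``n`` is the total number of samples per trace; the burn-in convention
    is attached as metadata.  Generations use the given thinning stride."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 <= autocorr < 1.0:
        raise ValueError("autocorrelation must be in [0, 1)")
    if n < 100:
        raise ValueError("need n >= 100 samples")
    rng = _rng(seed)
    innov_sd = sd * np.sqrt(1.0 - autocorr**2)
    gens = np.arange(n, dtype=np.int64) * stride

    def one(mean: float, label: str) -> MCMCTrace:
        x = np.empty(n)
        eps = rng.normal(0.0, 1.0, size=n)
        x[0] = mean + sd * eps[0]
        if autocorr == 0.0:
            x[1:] = mean + sd * eps[1:]
        else:
            from scipy.signal import lfilter
            dev = lfilter([1.0], [1.0, -autocorr], innov_sd * eps[1:],
                          zi=[autocorr * (x[0] - mean)])[0]
            x[1:] = mean + dev
        return MCMCTrace(gens, x, burn_in_fraction, label)

    return one(mean_a, "run_a"), one(mean_b, "run_b")
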