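"""Unrooted phylogenetic trees: Newick I/O, monophyly constraints, topology
search, and the prune-and-regraft move used to emulate a gene transfer.

Trees are stored in a rooted representation whose root carries a basal
trifurcation (the standard encoding of an unrooted binary tree).  All
topology comparisons go through non-trivial bipartitions ("splits"), so two
representations of the same unrooted tree always compare equal.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "MonophylyConstraint",
    "NewickError",
    "parse_newick",
    "write_newick",
    "is_compatible",
    "rf_distance",
    "spr_transfer",
    "enumerate_topologies",
    "nni_neighbors",
    "constrained_start_tree",
    "search_ml_tree",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.postorder() if n.is_leaf)

    def copy(self) -> "Node":
        n = Node(self.label, self.length)
        for c in self.children:
            n.add(c.copy())
        return n


class PhyloTree:
    """An (implicitly unrooted) tree with unique leaf labels and
    non-negative branch lengths (``None`` = unspecified)."""

    def __init__(self, root: Node, canonicalize: bool = True):
        self.root = root
        if canonicalize:
            self._suppress_root_bifurcation()
        self._validate()

    # -- construction / validation ------------------------------------
    def _suppress_root_bifurcation(self):
        """Collapse a degree-2 root so n>=3 trees carry a basal trifurcation."""
        root = self.root
        while len(root.children) == 2:
            internal = [c for c in root.children if not c.is_leaf]
            if not internal:
                break  # two-leaf tree: keep the bifurcating root
            keep = internal[0]
            other = root.children[0] if root.children[1] is keep else root.children[1]
            if keep.length is not None or other.length is not None:
                other.length = (keep.length or 0.0) + (other.length or 0.0)
            root.children = list(keep.children)
            for c in root.children:
                c.parent = root
            keep.children = []
            root.add(other)
        # a degree-1 root (rooted on a pendant edge) is also suppressed
        if len(root.children) == 1:
            only = root.children[0]
            if not only.is_leaf:
                only.parent = None
                only.length = None
                self.root = only
                self._suppress_root_bifurcation()

    def _validate(self):
        labels = [n.label for n in self.root.postorder() if n.is_leaf]
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise NewickError(f"duplicate leaf labels: {sorted(dup)}")
        if any(l is None for l in labels):
            raise NewickError("unlabelled leaf")
        for n in self.root.postorder():
            if n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length {n.length}")

    # -- basic accessors ----------------------------------------------
    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self):
        return self.root.postorder()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), canonicalize=False)

    def edges(self) -> list[Node]:
        """Every non-root node, i.e. one entry per edge (the edge above it)."""
        return [n for n in self.root.postorder() if n.parent is not None]

    def fill_lengths(self, default: float = 0.1):
        for n in self.edges():
            if n.length is None:
                n.length = default
        self.root.length = None
        return self

    # -- splits ---------------------------------------------------------
    def splits(self, nontrivial: bool = True) -> frozenset:
        """Normalized bipartitions: each split is the frozenset of leaf labels
        on the side *not* containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_labels()
        ref = min(all_leaves)
        out = set()
        for node in self.edges():
            side = node.leaf_labels()
            if ref in side:
                side = all_leaves - side
            if nontrivial and not (2 <= len(side) <= len(all_leaves) - 2):
                continue
            out.add(frozenset(side))
        return frozenset(out)

    def same_topology(self, other: "PhyloTree") -> bool:
        return (self.leaf_labels() == other.leaf_labels()
                and self.splits() == other.splits())

    # -- Newick ---------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self):
        return f"PhyloTree({self.to_newick()})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf():
        label = dnode.label
    n = Node(label, dnode.edge.length)
    for c in dnode.child_nodes():
        n.add(_from_dendropy(c))
    return n


def parse_newick(text: str) -> PhyloTree:
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise NewickError(f"malformed Newick: {exc}") from None
    root = _from_dendropy(dt.seed_node)
    root.length = None
    return PhyloTree(root)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(n: Node) -> str:
    if n.is_leaf:
        s = _quote_label(n.label)
    else:
        s = "(" + ",".join(_newick_node(c) for c in n.children) + ")"
    if n.length is not None:
        s += f":{n.length:.10g}"
    return s


def write_newick(tree: PhyloTree) -> str:
    return _newick_node(tree.root) + ";"


# ---------------------------------------------------------------------------
# Monophyly constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyConstraint:
    """A set of taxon groups each required to form a clade (one side of an
    unrooted bipartition).  Overlapping groups must be nested."""

    groups: tuple[frozenset, ...]

    def __init__(self, groups):
        gs = tuple(frozenset(g) for g in groups)
        for g in gs:
            if len(g) < 2:
                raise ValueError(f"constraint group {sorted(g)} has fewer than 2 taxa")
        for g1, g2 in itertools.combinations(gs, 2):
            if g1 & g2 and not (g1 <= g2 or g2 <= g1):
                raise ValueError(
                    f"overlapping constraint groups must be nested: "
                    f"{sorted(g1)} vs {sorted(g2)}")
        object.__setattr__(self, "groups", gs)

    @classmethod
    def from_file(cls, path) -> "MonophylyConstraint":
        groups = []
        with open(path) as fh:
            for line in fh:
                labels = line.split()
                if labels:
                    groups.append(frozenset(labels))
        return cls(groups)

    def to_file(self, path):
        with open(path, "w") as fh:
            for g in self.groups:
                fh.write(" ".join(sorted(g)) + "\n")

    def validate_against(self, leaf_labels: frozenset):
        for g in self.groups:
            unknown = g - leaf_labels
            if unknown:
                raise ValueError(f"constraint taxa not in tree: {sorted(unknown)}")


def is_compatible(tree: PhyloTree, constraint: MonophylyConstraint) -> bool:
    """True iff every constrained group is one side of some bipartition."""
    leaves = tree.leaf_labels()
    constraint.validate_against(leaves)
    splits = None
    ref = min(leaves)
    n = len(leaves)
    for g in constraint.groups:
        if len(g) >= n - 1:  # whole set or all-but-one: trivially a side
            continue
        side = g if ref not in g else leaves - g
        if splits is None:
            splits = tree.splits()
        if frozenset(side) not in splits:
            return False
    return True


# ---------------------------------------------------------------------------
# Robinson–Foulds distance
# ---------------------------------------------------------------------------

def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError("trees have different leaf sets: "
                         f"{sorted(t1.leaf_labels() ^ t2.leaf_labels())}")
    return len(t1.splits() ^ t2.splits())


# ---------------------------------------------------------------------------
# SPR transfer move
# ---------------------------------------------------------------------------

def _find_clade_edge(tree: PhyloTree, taxa: frozenset) -> Node:
    """Node whose edge separates ``taxa`` from the rest (clade side or its
    complement in the rooted representation)."""
    all_leaves = tree.leaf_labels()
    comp = all_leaves - taxa
    for node in tree.edges():
        under = node.leaf_labels()
        if under == taxa or under == comp:
            return node
    raise ValueError(f"taxon set {sorted(taxa)} is not a clade of the tree")


def _prune_leaf(tree: PhyloTree, label: str) -> float:
    """Remove a pendant leaf in place; returns its pendant edge length."""
    leaf = next(n for n in tree.leaves() if n.label == label)
    parent = leaf.parent
    parent.children.remove(leaf)
    length = leaf.length if leaf.length is not None else 0.0
    if parent.parent is None:
        tree._suppress_root_bifurcation()
    elif len(parent.children) == 1:
        only = parent.children[0]
        gp = parent.parent
        if only.length is not None or parent.length is not None:
            only.length = (only.length or 0.0) + (parent.length or 0.0)
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    return length


def spr_transfer(tree: PhyloTree, donor_clade, recipient: str) -> PhyloTree:
    """Prune the recipient's pendant edge and regraft it onto the edge
    subtending the donor clade, emulating a single gene transfer."""
    donor = frozenset(donor_clade)
    if recipient in donor:
        raise ValueError(f"recipient {recipient!r} is inside the donor clade")
    if recipient not in tree.leaf_labels():
        raise ValueError(f"unknown recipient {recipient!r}")
    _find_clade_edge(tree, donor)  # clade check on the input tree

    out = tree.copy()
    pendant = _prune_leaf(out, recipient)
    attach = _find_clade_edge(out, donor)
    parent = attach.parent
    mid = Node(None, None)
    if attach.length is not None:
        mid.length = attach.length / 2.0
        attach.length = attach.length / 2.0
    parent.children[parent.children.index(attach)] = mid
    mid.parent = parent
    mid.add(attach)
    mid.add(Node(recipient, pendant))
    return PhyloTree(out.root, canonicalize=False)


# ---------------------------------------------------------------------------
# Topology generation: exhaustive enumeration and NNI neighborhoods
# ---------------------------------------------------------------------------

def _insert_leaf_on_edge(root: Node, edge_index: int, label: str) -> Node:
    """Copy of the subtree with a new leaf grafted on the edge above the
    ``edge_index``-th non-root node (postorder)."""
    new_root = root.copy()
    edges = [n for n in new_root.postorder() if n.parent is not None]
    target = edges[edge_index]
    parent = target.parent
    mid = Node(None, None)
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add(target)
    mid.add(Node(label, None))
    return new_root


def enumerate_topologies(labels) -> list[PhyloTree]:
    """All (2n-5)!! unrooted binary topologies over ``labels`` (n >= 3),
    generated by stepwise addition.  Branch lengths are left unset."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    base = Node()
    for l in labels[:3]:
        base.add(Node(l, None))
    partial = [base]
    for label in labels[3:]:
        nxt = []
        for root in partial:
            n_edges = sum(1 for n in root.postorder() if n.parent is not None)
            for e in range(n_edges):
                nxt.append(_insert_leaf_on_edge(root, e, label))
        partial = nxt
    return [PhyloTree(r, canonicalize=False) for r in partial]


def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """The 2(n-3) nearest-neighbour-interchange rearrangements of an
    unrooted binary tree, each returned as a new tree."""
    nodes = list(tree.root.postorder())
    internal_edges = [i for i, n in enumerate(nodes)
                      if n.parent is not None and not n.is_leaf]
    out = []
    for i in internal_edges:
        for which in (0, 1):
            t = tree.copy()
            tnodes = list(t.root.postorder())
            c = tnodes[i]
            p = c.parent
            z = next(ch for ch in p.children if ch is not c)
            x = c.children[which]
            # swap subtree x (below c) with subtree z (sibling of c)
            p.children[p.children.index(z)] = x
            x.parent = p
            c.children[c.children.index(x)] = z
            z.parent = c
            out.append(PhyloTree(t.root, canonicalize=False))
    return out


def constrained_start_tree(labels, constraint: MonophylyConstraint | None) -> PhyloTree:
    """A deterministic resolved topology compatible with the constraint,
    built by nesting each constrained group as a caterpillar subtree."""
    labels = sorted(set(labels))
    groups = [] if constraint is None else \
        sorted(constraint.groups, key=lambda g: (-len(g), sorted(g)))

    def build(members: frozenset, candidates: list) -> list[Node]:
        sub = [g for g in candidates if g < members]
        top, rest = [], []
        for g in sub:
            if not any(g < h for h in sub):
                top.append(g)
            else:
                rest.append(g)
        items: list[Node] = []
        covered = frozenset().union(*top) if top else frozenset()
        for g in sorted(top, key=sorted):
            sub_items = build(g, [h for h in rest if h < g])
            items.append(_caterpillar(sub_items))
        for l in sorted(members - covered):
            items.append(Node(l, None))
        return items

    def _caterpillar(items: list[Node]) -> Node:
        node = items[0]
        for item in items[1:]:
            join = Node()
            join.add(node)
            join.add(item)
            node = join
        return node

    full = frozenset(labels)
    for g in groups:
        if not g <= full:
            raise ValueError(f"constraint taxa not in label set: {sorted(g - full)}")
    items = build(full, [g for g in groups if g != full])
    root = Node()
    if len(items) == 1:
        root = items[0]
    elif len(items) == 2:
        root.add(items[0])
        root.add(items[1])
    else:
        root.add(items[0])
        root.add(items[1])
        root.add(_caterpillar(items[2:]))
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# ML topology search
# ---------------------------------------------------------------------------

def count_unrooted_topologies(n: int) -> int:
    """(2n-5)!! for n >= 3."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def search_ml_tree(aln, model, constraint: MonophylyConstraint | None = None,
                   mode: str = "exhaustive", *, start_tree: PhyloTree | None = None,
                   init_length: float = 0.1, tol: float = 1e-5,
                   max_rounds: int = 15, max_steps: int = 50):
    """Maximum-likelihood topology under an optional monophyly constraint.

    ``exhaustive`` enumerates all unrooted topologies (n <= 8 only), filters
    by constraint compatibility and optimizes branch lengths on each;
    ``nni`` hill-climbs with constraint-respecting nearest-neighbour
    interchanges from a compatible starting tree.  Returns (tree, lnL).
    """
    from .phylik import optimize_branch_lengths  # local import: avoid cycle

    taxa = sorted(aln.taxa)
    if constraint is not None:
        constraint.validate_against(frozenset(taxa))

    def opt(tree, rounds, xatol):
        t = tree.copy().fill_lengths(init_length)
        return optimize_branch_lengths(aln, t, model, tol=tol,
                                       max_rounds=rounds, xatol=xatol)

    if mode == "exhaustive":
        if len(taxa) > 8:
            raise ValueError("exhaustive search supports at most 8 taxa; use mode='nni'")
        best_tree, best_lnl = None, -float("inf")
        for topo in enumerate_topologies(taxa):
            if constraint is not None and not is_compatible(topo, constraint):
                continue
            t, lnl = opt(topo, max_rounds, 1e-5)
            if lnl > best_lnl:
                best_tree, best_lnl = t, lnl
        if best_tree is None:
            raise ValueError("no topology compatible with the constraint")
        return best_tree, best_lnl

    if mode != "nni":
        raise ValueError(f"unknown search mode {mode!r}")

    current = start_tree.copy() if start_tree is not None \
        else constrained_start_tree(taxa, constraint)
    if constraint is not None and not is_compatible(current, constraint):
        raise ValueError("starting tree violates the constraint")
    current, cur_lnl = opt(current, max_rounds, 1e-5)
    for _ in range(max_steps):
        scored = []
        for nb in nni_neighbors(current):
            if constraint is not None and not is_compatible(nb, constraint):
                continue
            _, lnl = opt(nb, 2, 1e-2)  # coarse scoring pass
            scored.append((lnl, nb))
        scored.sort(key=lambda x: -x[0])
        # fully optimize the top coarse candidates; coarse scores
        # underestimate, so the current tree's lnL is not a fair cutoff
        accepted = False
        for _, nb in scored[:2]:
            cand, cand_lnl = opt(nb, max_rounds, 1e-5)
            if cand_lnl > cur_lnl + 1e-9:
                current, cur_lnl = cand, cand_lnl
                accepted = True
                break
        if not accepted:
            break
    return current, cur_lnl
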