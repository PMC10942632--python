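"""Rooted phylogenies, newick I/O, pruning, and cross-tree branch keying.

Evolutionary rate covariation compares branch-specific rates across gene
trees that all conform to one master species topology but may each be
missing taxa.  The central plumbing problem is deciding when a branch of
one pruned tree is "the same branch" as a branch of another: here every
branch is keyed by the descendant-leaf set of the *minimal* master-tree
branch whose descendants, restricted to the gene's species, equal the
branch's own descendant set.  With no missing taxa this reduces to the
identity keying; with missing taxa it attributes a merged path to its
leaf-most master branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable

import dendropy

__all__ = [
    "Phylogeny",
    "TreeSet",
    "PhyloError",
    "read_newick",
    "write_newick",
    "prune_to_species",
    "branch_keys",
    "read_tree_file",
    "read_tree_dir",
]


class PhyloError(ValueError):
    """Malformed or inconsistent tree input."""


BranchKey = frozenset  # frozenset of species labels; module-level alias


@dataclass
class Phylogeny:
    """A rooted tree stored as a parent-pointer table.

    ``parent[node]`` maps every non-root node id to its parent id;
    ``length[node]`` is the length of the branch *above* ``node`` (so there
    is exactly one branch per non-root node).  ``label`` maps leaf node ids
    to species labels.
    """

    parent: dict[int, int]
    length: dict[int, float]
    label: dict[int, str]
    root: int
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {}
        for child, par in self.parent.items():
            self._children.setdefault(par, []).append(child)

    # -- basic accessors -------------------------------------------------
    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self.label.values())

    @property
    def n_leaves(self) -> int:
        return len(self.label)

    @property
    def n_branches(self) -> int:
        return len(self.parent)

    def children(self, node: int) -> list[int]:
        return self._children.get(node, [])

    def is_leaf(self, node: int) -> bool:
        return node in self.label

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children(node))
        order.reverse()
        return order

    def descendant_leaves(self) -> dict[int, frozenset[str]]:
        """Descendant species set for every node, root included."""
        desc: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if self.is_leaf(node):
                desc[node] = frozenset([self.label[node]])
            else:
                acc: set[str] = set()
                for ch in self.children(node):
                    acc |= desc[ch]
                desc[node] = frozenset(acc)
        return desc

    def total_length(self) -> float:
        return sum(self.length.values())

    def validate(self) -> None:
        labels = list(self.label.values())
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise PhyloError(f"duplicate leaf labels: {dup}")
        for node, ln in self.length.items():
            if ln < 0:
                raise PhyloError(
                    f"negative branch length {ln} above node {node}"
                )
        # reachability from root == connected & acyclic for a parent map
        seen = set(self.postorder())
        if seen != set(self.parent) | {self.root}:
            raise PhyloError("tree is not connected")


@dataclass
class TreeSet:
    """A master species tree plus per-gene trees pruned from it."""

    master: Phylogeny
    gene_trees: dict[str, Phylogeny]

    def validate(self) -> None:
        master_leaves = self.master.leaves
        for gene, tree in self.gene_trees.items():
            extra = tree.leaves - master_leaves
            if extra:
                raise PhyloError(
                    f"gene {gene}: leaves {sorted(extra)} not in master tree"
                )
            # topology check is implicit in branch_keys; raise early here
            branch_keys(tree, self.master)


# ---------------------------------------------------------------------------
# newick I/O (dendropy behind the surface)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    parent: dict[int, int] = {}
    length: dict[int, float] = {}
    label: dict[int, str] = {}
    ids: dict[dendropy.Node, int] = {}
    for i, node in enumerate(dtree.preorder_node_iter()):
        ids[node] = i
        if node.parent_node is not None:
            parent[i] = ids[node.parent_node]
            ln = node.edge.length
            if ln is None:
                raise PhyloError(
                    f"missing branch length above node "
                    f"{node.taxon.label if node.taxon else i!r}"
                )
            length[i] = float(ln)
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise PhyloError("unlabeled leaf")
            label[i] = node.taxon.label
    tree = Phylogeny(parent=parent, length=length, label=label, root=0)
    tree.validate()
    return tree


def read_newick(text: str) -> Phylogeny:
    """Parse one newick string into a :class:`Phylogeny`.

    Branch lengths are required on every non-root edge; duplicate leaf
    labels and negative lengths are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny, precision: int = 10) -> str:
    """Serialize a tree to a single-line newick string."""

    def render(node: int) -> str:
        if tree.is_leaf(node):
            core = tree.label[node]
        else:
            parts = sorted(render(ch) for ch in tree.children(node))
            core = "(" + ",".join(parts) + ")"
        if node == tree.root:
            return core
        return f"{core}:{tree.length[node]:.{precision}g}"

    return render(tree.root) + ";"


def read_tree_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def read_tree_dir(path) -> TreeSet:
    """Load ``master.nwk`` plus one ``<id>.nwk`` per gene from a directory."""
    import pathlib

    p = pathlib.Path(path)
    master = read_tree_file(p / "master.nwk")
    genes: dict[str, Phylogeny] = {}
    for f in sorted(p.glob("*.nwk")):
        if f.stem == "master":
            continue
        genes[f.stem] = read_tree_file(f)
    return TreeSet(master=master, gene_trees=genes)


def write_tree_dir(trees: TreeSet, path) -> None:
    import pathlib

    p = pathlib.Path(path)
    p.mkdir(parents=True, exist_ok=True)
    (p / "master.nwk").write_text(write_newick(trees.master) + "\n")
    for gene, tree in trees.gene_trees.items():
        (p / f"{gene}.nwk").write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_to_species(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict a tree to a species subset, summing collapsed path lengths.

    Nodes left with a single child are suppressed and their branch lengths
    added to the child's, so the result's topology is the original
    restricted to ``keep``.
    """
    keep = set(keep)
    retained = keep & tree.leaves
    if len(retained) < 2:
        raise PhyloError(
            f"pruning would retain {len(retained)} species; need >= 2"
        )

    # count retained descendants per node, bottom-up
    desc = tree.descendant_leaves()
    keep_count = {node: len(desc[node] & retained) for node in desc}

    new_parent: dict[int, int] = {}
    new_length: dict[int, float] = {}
    new_label: dict[int, str] = {}

    def build(node: int) -> tuple[int, float]:
        """Return (new node id, pending length to add above it)."""
        if tree.is_leaf(node):
            new_label[node] = tree.label[node]
            return node, 0.0
        live = [ch for ch in tree.children(node) if keep_count[ch] > 0]
        if len(live) == 1:
            child, pend = build(live[0])
            return child, pend + tree.length[live[0]]
        for ch in live:
            sub, pend = build(ch)
            new_parent[sub] = node
            new_length[sub] = tree.length[ch] + pend
        return node, 0.0

    root_live = [ch for ch in tree.children(tree.root) if keep_count[ch] > 0]
    if len(root_live) == 1 and not tree.is_leaf(tree.root):
        # root becomes unary: descend until a real split, dropping the
        # rootward stub (there is no branch above the root to absorb it)
        node = tree.root
        while True:
            live = [ch for ch in tree.children(node) if keep_count[ch] > 0]
            if tree.is_leaf(node) or len(live) > 1:
                break
            node = live[0]
        new_root, _ = build(node)
    else:
        new_root, _ = build(tree.root)

    pruned = Phylogeny(
        parent=new_parent, length=new_length, label=new_label, root=new_root
    )
    pruned.validate()
    return pruned


# ---------------------------------------------------------------------------
# branch keying
# ---------------------------------------------------------------------------

def branch_keys(tree: Phylogeny, master: Phylogeny) -> dict[int, BranchKey]:
    """Key every branch of ``tree`` by a master-tree descendant set.

    A branch whose descendant set (on ``tree``) is ``D`` is keyed by the
    descendant set of the minimal master branch ``B`` with
    ``desc(B) & tree.leaves == D``.  Raises :class:`PhyloError` when no
    master branch matches, i.e. the topologies are inconsistent.
    """
    tree_leaves = tree.leaves
    if not tree_leaves <= master.leaves:
        raise PhyloError("tree has leaves outside the master tree")

    master_desc = master.descendant_leaves()
    # minimal master branch per restricted descendant set: since candidate
    # branches matching one D form a rootward path, minimal = smallest set
    best: dict[frozenset, frozenset] = {}
    for node, dset in master_desc.items():
        if node == master.root:
            continue
        restricted = frozenset(dset & tree_leaves)
        if not restricted:
            continue
        if restricted not in best or len(dset) < len(best[restricted]):
            best[restricted] = frozenset(dset)

    tree_desc = tree.descendant_leaves()
    keys: dict[int, BranchKey] = {}
    for node in tree.parent:  # every non-root node owns one branch
        dset = tree_desc[node]
        if dset not in best:
            raise PhyloError(
                f"no master branch matches descendant set {sorted(dset)}; "
                "tree topology inconsistent with master"
            )
        keys[node] = best[dset]
    if len(set(keys.values())) != len(keys):
        raise PhyloError("branch keying is not injective; topology mismatch")
    return keys


def key_to_str(key: BranchKey) -> str:
    return ";".join(sorted(key))


def key_from_str(text: str) -> BranchKey:
    return frozenset(text.split(";"))
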