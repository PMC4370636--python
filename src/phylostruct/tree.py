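"""Phylogeny container, newick I/O, pool-tree pruning, even-spacing node
dating, and patristic distances.

The tree is the backbone of every downstream diversity metric.  Community
megatrees come with topology and (at best) a handful of fossil-calibrated
node ages, so the module provides a pseudo-chronogram builder in the style
of branch-length adjustment ("bladj") tools: ages are fixed at the root and
at named calibration nodes, and every undated node is placed evenly (by node
count) between its nearest dated ancestor and its nearest dated
descendant-or-tip.  Tips sit at age zero, so the result is ultrametric
whenever the input topology admits it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "AgeTable",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_ages",
    "prune_to_taxa",
    "date_tree",
    "patristic_matrix",
    "NewickParseError",
    "DatingError",
]


class NewickParseError(ValueError):
    """Malformed newick input (position reported by the underlying reader)."""


class DatingError(ValueError):
    """Age constraints that cannot be satisfied on the given topology."""


class Phylogeny:
    """A rooted tree with named tips, optional internal labels, branch
    lengths (in My once dated) and optional node ages.

    Thin wrapper over a :class:`dendropy.Tree`; node ages live in
    ``node.age_my`` annotations managed by :func:`date_tree`.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ----------------------------------------------------
    def _validate(self) -> None:
        names = self.tip_names
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate tip names: {dups}")
        if any(not n for n in names):
            raise NewickParseError("empty tip name")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- ages -------------------------------------------------------------
    @property
    def is_dated(self) -> bool:
        return all(
            getattr(nd, "age_my", None) is not None for nd in self._tree
        )

    def node_ages(self) -> dict[str, float]:
        """Ages of all *named* nodes (tips and labelled internals)."""
        out: dict[str, float] = {}
        for nd in self._tree:
            name = nd.taxon.label if nd.taxon else nd.label
            age = getattr(nd, "age_my", None)
            if name and age is not None:
                out[name] = age
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips}, dated={self.is_dated})"


@dataclass(frozen=True)
class AgeTable:
    """Calibration ages (My) for named internal nodes."""

    ages: Mapping[str, float]

    def __post_init__(self):
        for name, age in self.ages.items():
            if age <= 0:
                raise ValueError(f"age for {name!r} must be > 0, got {age}")

    @classmethod
    def from_file(cls, path) -> "AgeTable":
        return read_ages(path)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick statement.

    Polytomies and internal labels are preserved; quoted labels are accepted
    on read.  Raises :class:`NewickParseError` with the offending position
    for unbalanced or malformed input.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    if not text.strip().endswith(";"):
        raise NewickParseError("newick statement must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry line/column
        raise NewickParseError(str(exc)) from exc
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize with unquoted labels; round-trips topology and lengths."""
    text = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_ages(path) -> AgeTable:
    """Read a two-column whitespace-delimited (name, age-in-My) file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["name", "age"], comment="#")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate names in ages file: {dups}")
    return AgeTable(dict(zip(df["name"].astype(str), df["age"].astype(float))))


def prune_to_taxa(tree: Phylogeny, names: Iterable[str]) -> Phylogeny:
    """Extract the subtree spanning *names*, collapsing unifurcations.

    Branch lengths of collapsed chains are summed, so patristic distances
    among retained tips are unchanged.
    """
    names = set(names)
    have = set(tree.tip_names)
    missing = sorted(names - have)
    if missing:
        raise KeyError(f"tip names not in tree: {missing}")
    if len(names) < 2:
        raise ValueError("need at least 2 tip names to prune to")
    t = tree.dendropy_tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(names))
    return Phylogeny(t)


def _named(nd: dendropy.Node) -> str | None:
    return nd.taxon.label if nd.taxon else nd.label


def date_tree(tree: Phylogeny, ages: AgeTable | Mapping[str, float] | None = None,
              root_age: float = 137.0) -> Phylogeny:
    """Build a pseudo-chronogram by even-spacing interpolation.

    The root is fixed at *root_age* (default 137 My, the age of the eudicot
    crown in the source calibration), every internal node named in *ages*
    keeps its given age, tips get age 0, and each undated internal node is
    placed so that node ages along the path from its nearest dated ancestor
    to its nearest dated descendant-or-tip are evenly spaced by node count.
    Branch lengths are rewritten as age differences.

    Ties between equally near dated descendants are broken toward the larger
    age (the most constraining), which keeps the procedure deterministic and
    the age sequence monotone along every root-to-tip path.
    """
    if ages is None:
        ages = {}
    age_map = dict(ages.ages) if isinstance(ages, AgeTable) else dict(ages)

    out = tree.copy()
    t = out.dendropy_tree
    root = t.seed_node

    tip_labels = set(tree.tip_names)
    for name in age_map:
        if name in tip_labels:
            raise DatingError(f"age constraint {name!r} refers to a tip")

    # fixed ages: tips 0, root root_age, calibrated internals from the table
    fixed: dict[int, float] = {}
    for nd in t:
        if nd.is_leaf():
            fixed[id(nd)] = 0.0
    name_hits = set()
    for nd in t.preorder_node_iter():
        name = _named(nd)
        if name in age_map and not nd.is_leaf():
            fixed[id(nd)] = float(age_map[name])
            name_hits.add(name)
    if id(root) in fixed and fixed[id(root)] > root_age:
        raise DatingError(
            f"root constraint {fixed[id(root)]} exceeds root_age {root_age}"
        )
    fixed[id(root)] = float(
        fixed.get(id(root), root_age) if _named(root) in age_map else root_age
    )

    max_constraint = max(age_map[n] for n in name_hits) if name_hits else 0.0
    if root_age < max_constraint:
        raise DatingError(
            f"root_age {root_age} is below the largest constraint {max_constraint}"
        )

    # ancestor/descendant consistency of the constraints themselves
    stack = [(root, fixed[id(root)])]
    while stack:
        nd, anc_age = stack.pop()
        a = fixed.get(id(nd))
        if a is not None:
            if a > anc_age + 1e-12:
                raise DatingError(
                    f"constrained age {a} at node {_named(nd)!r} exceeds its "
                    f"dated ancestor's age {anc_age}"
                )
            anc_age = a
        stack.extend((ch, anc_age) for ch in nd.child_nodes())

    # nearest dated descendant by node count; ties -> larger age
    def nearest_dated_below(nd) -> tuple[float, int]:
        """Return (age, n_undated_on_path) for the closest fixed descendant.

        n_undated counts undated nodes strictly between nd and the fixed
        node (nd itself excluded; it is the caller's undated node).
        """
        frontier = [(ch, 0) for ch in nd.child_nodes()]
        best: tuple[int, float] | None = None
        while frontier:
            nxt = []
            for node, depth in frontier:
                if id(node) in fixed:
                    if best is None or fixed[id(node)] > best[1]:
                        best = (depth, fixed[id(node)])
                else:
                    nxt.extend((ch, depth + 1) for ch in node.child_nodes())
            if best is not None:
                return best[1], best[0]
            frontier = nxt
        raise DatingError("internal node with no tip descendant")  # pragma: no cover

    # preorder assignment: parents are always dated before children
    assigned: dict[int, float] = {}
    for nd in t.preorder_node_iter():
        if id(nd) in fixed:
            assigned[id(nd)] = fixed[id(nd)]
            continue
        parent_age = assigned[id(nd.parent_node)]
        d_age, n_between = nearest_dated_below(nd)
        # nd plus n_between undated nodes before the fixed descendant
        step = (parent_age - d_age) / (n_between + 2)
        assigned[id(nd)] = parent_age - step

    for nd in t.preorder_node_iter():
        nd.age_my = assigned[id(nd)]
        if nd.parent_node is not None:
            length = assigned[id(nd.parent_node)] - assigned[id(nd)]
            if length < -1e-9:
                raise DatingError("negative branch length after dating")
            nd.edge.length = max(length, 0.0)
    return out


def patristic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Tip-by-tip matrix of path lengths (sum of branch lengths).

    For a dated ultrametric tree the entries are twice the age of the most
    recent common ancestor.  Raises if any branch length is unset.
    """
    t = tree.dendropy_tree
    tips = [lf for lf in t.leaf_node_iter()]
    labels = [lf.taxon.label for lf in tips]
    index = {id(lf): i for i, lf in enumerate(tips)}
    n = len(tips)
    D = np.zeros((n, n))

    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._tips = np.array([index[id(nd)]], dtype=np.intp)
            nd._dists = np.zeros(1)
            continue
        parts = []
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise ValueError("tree has unset branch lengths; date it first")
            parts.append((ch._tips, ch._dists + ch.edge.length))
            del ch._tips, ch._dists
        for a in range(len(parts)):
            ti, di = parts[a]
            for b in range(a + 1, len(parts)):
                tj, dj = parts[b]
                block = di[:, None] + dj[None, :]
                D[np.ix_(ti, tj)] = block
                D[np.ix_(tj, ti)] = block.T
        nd._tips = np.concatenate([p[0] for p in parts])
        nd._dists = np.concatenate([p[1] for p in parts])
    del t.seed_node._tips, t.seed_node._dists
    return pd.DataFrame(D, index=labels, columns=labels)
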