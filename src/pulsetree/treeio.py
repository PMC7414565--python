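"""Time-calibrated trees: reading, validation, branching times, and
backbone-and-patch assembly.

All ages are in Ma before present (present = 0, ages increase into the past);
branch lengths are in Myr.  Trees are rooted, strictly binary and ultrametric:
every root-to-tip path has the same length (the crown age).  Trees whose tip
depths disagree by less than ``ULTRAMETRIC_RTOL`` times the crown age are
snapped to exact ultrametricity by averaging tip depths; larger disagreement
is an error.

Assembly follows the backbone-and-patch recipe used to build composite
time trees: deep node ages are fixed from a table of dated clades, extra taxa
are grafted from topology-only fragments, and any node left without a
tabulated age subdivides the span down to its nearest dated descendant into
equal-length segments, one per required branching event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import (
    AssemblyError,
    NewickParseError,
    UltrametricityError,
    ValidationError,
)

ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages of an ultrametric tree, sorted descending.

    ``ages[0]`` is the crown age; there are ``n_tips - 1`` entries.
    These are the sufficient statistics for every lineage-homogeneous
    birth-death likelihood in :mod:`pulsetree.bdcore`.
    """

    ages: np.ndarray
    n_tips: int

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if ages.ndim != 1 or len(ages) != self.n_tips - 1:
            raise ValidationError(
                f"expected {self.n_tips - 1} branching times, got {len(ages)}"
            )
        if len(ages) == 0:
            raise ValidationError("a tree must have at least 2 tips")
        if np.any(np.diff(ages) > 0):
            raise ValidationError("branching times must be sorted descending")
        if ages[-1] <= 0:
            raise ValidationError("branching times must be strictly positive")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def to_tsv(self, path) -> None:
        """Single-column TSV of node ages (Ma), descending."""
        with open(path, "w") as fh:
            fh.write("age_ma\n")
            for a in self.ages:
                fh.write(f"{a:.10g}\n")


class TimeTree:
    """A rooted, binary, ultrametric time tree (branch lengths in Myr)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        self._validate_and_snap()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed newick: {exc}") from None
        return cls(tree)

    # -- validation --------------------------------------------------------

    def _validate_and_snap(self) -> None:
        t = self._tree
        leaves = t.leaf_node_iter()
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise ValidationError("every tip must be labelled")
            labels.append(lf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ValidationError("a TimeTree needs at least 2 tips")
        for nd in t.preorder_node_iter():
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise ValidationError(
                    f"tree is not strictly binary: node with {nch} children"
                )
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValidationError("branch lengths are mandatory")
                if nd.edge.length < 0:
                    raise ValidationError("negative branch length")

        depths = {}
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
        tip_depths = {lf: depths[lf] for lf in t.leaf_node_iter()}
        dvals = np.array(list(tip_depths.values()))
        crown = float(dvals.mean())
        if crown <= 0:
            raise ValidationError("crown age must be positive")
        spread = dvals.max() - dvals.min()
        if spread > ULTRAMETRIC_RTOL * crown:
            hi = max(tip_depths, key=tip_depths.get)
            lo = min(tip_depths, key=tip_depths.get)
            raise UltrametricityError(
                f"tree is not ultrametric: tip {hi.taxon.label!r} has depth "
                f"{tip_depths[hi]:.6g} but tip {lo.taxon.label!r} has depth "
                f"{tip_depths[lo]:.6g} (tolerance {ULTRAMETRIC_RTOL * crown:.3g})"
            )
        # snap: stretch terminal branches so every tip sits at the mean depth
        for lf, d in tip_depths.items():
            lf.edge.length += crown - d
        self._crown_age = crown
        self._tip_labels = labels

    # -- basic accessors ---------------------------------------------------

    @property
    def crown_age(self) -> float:
        return self._crown_age

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        )
        return s.strip()

    def node_ages(self) -> np.ndarray:
        """Ages of internal nodes (Ma), unsorted preorder."""
        t = self._tree
        depths = {}
        out = []
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
            if not nd.is_leaf():
                out.append(self._crown_age - depths[nd])
        return np.asarray(out)

    def mrca_age(self, tips: Iterable[str]) -> float:
        """Age of the most recent common ancestor of the given tip labels."""
        taxa = self._tree.taxon_namespace.get_taxa(labels=list(tips))
        node = self._tree.mrca(taxa=taxa)
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        return self._crown_age - d


def read_newick(text: str) -> TimeTree:
    """Parse a newick string into a validated :class:`TimeTree`."""
    return TimeTree.from_newick(text)


def write_newick(tree: TimeTree) -> str:
    return tree.to_newick()


def branching_times(tree: TimeTree) -> BranchingTimes:
    """Internal node ages, sorted descending (crown age first)."""
    ages = np.sort(tree.node_ages())[::-1]
    return BranchingTimes(ages=ages, n_tips=tree.n_tips)


# ---------------------------------------------------------------------------
# Backbone-and-patch assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneRow:
    """A dated clade: the MRCA of ``tips`` is fixed at ``age`` Ma."""

    tips: frozenset
    age: float
    source: str = ""


@dataclass
class BackboneTable:
    rows: list[BackboneRow]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackboneTable":
        rows = []
        lines = Path(path).read_text().splitlines()
        header = lines[0].rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for needed in ("clade_tips", "age_ma"):
            if needed not in idx:
                raise ValidationError(f"backbone TSV missing column {needed!r}")
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            tips = frozenset(x.strip() for x in parts[idx["clade_tips"]].split(";") if x.strip())
            age = float(parts[idx["age_ma"]])
            source = parts[idx["source"]] if "source" in idx and len(parts) > idx["source"] else ""
            rows.append(BackboneRow(tips=tips, age=age, source=source))
        return cls(rows)


@dataclass(frozen=True)
class GraftSpec:
    """Topology-only graft: ``topology`` is a newick fragment (no branch
    lengths) over the tips currently inside ``attachment_clade`` plus
    ``new_tips``; it replaces the local topology of that clade."""

    attachment_clade: frozenset
    new_tips: tuple
    topology: str

    @staticmethod
    def list_from_tsv(path: str | Path) -> list["GraftSpec"]:
        out = []
        lines = Path(path).read_text().splitlines()
        header = lines[0].rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            clade = frozenset(
                x.strip() for x in parts[idx["attachment_clade"]].split(";") if x.strip()
            )
            new = tuple(
                x.strip() for x in parts[idx["new_tips"]].split(";") if x.strip()
            )
            out.append(GraftSpec(clade, new, parts[idx["topology"]].strip()))
        return out


class _ANode:
    """Mutable node used during assembly."""

    __slots__ = ("children", "label", "age", "parent")

    def __init__(self, label=None):
        self.children: list[_ANode] = []
        self.label = label  # tip label, or None for internal
        self.age: float | None = None  # None = undated internal; tips get 0.0
        self.parent: _ANode | None = None

    def is_leaf(self):
        return self.label is not None

    def tips(self) -> frozenset:
        if self.is_leaf():
            return frozenset([self.label])
        out = set()
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.add(nd.label)
            else:
                stack.extend(nd.children)
        return frozenset(out)

    def add(self, child: "_ANode"):
        child.parent = self
        self.children.append(child)


def _check_nested(rows: Sequence[BackboneRow]) -> None:
    for i, a in enumerate(rows):
        for b in rows[i + 1:]:
            inter = a.tips & b.tips
            if inter and inter != a.tips and inter != b.tips:
                raise AssemblyError(
                    f"backbone clades overlap without nesting: "
                    f"{sorted(a.tips)[:3]}... vs {sorted(b.tips)[:3]}..."
                )
            if a.tips == b.tips and a.age != b.age:
                raise AssemblyError(
                    f"conflicting ages for the same clade: {a.age} ({a.source or 'row'}) "
                    f"vs {b.age} ({b.source or 'row'})"
                )
            if a.tips < b.tips and a.age >= b.age:
                raise AssemblyError(
                    f"nested clade age {a.age} is not younger than enclosing clade age {b.age}"
                )
            if b.tips < a.tips and b.age >= a.age:
                raise AssemblyError(
                    f"nested clade age {b.age} is not younger than enclosing clade age {a.age}"
                )


def _build_hierarchy(rows: Sequence[BackboneRow]) -> _ANode:
    all_tips = frozenset().union(*(r.tips for r in rows))
    root_rows = [r for r in rows if r.tips == all_tips]
    if not root_rows:
        raise AssemblyError("backbone table must contain a root row covering all tips")
    # sort enclosing-first so parents exist before children are inserted
    ordered = sorted(rows, key=lambda r: -len(r.tips))
    nodes: list[tuple[BackboneRow, _ANode]] = []
    root = _ANode()
    root.age = root_rows[0].age
    nodes.append((ordered[0], root))
    for row in ordered[1:]:
        if row.tips == all_tips:
            continue
        # smallest strictly-containing dated clade already built
        candidates = [(r, nd) for r, nd in nodes if row.tips < r.tips]
        _, parent = min(candidates, key=lambda p: len(p[0].tips))
        nd = _ANode()
        nd.age = row.age
        parent.add(nd)
        nodes.append((row, nd))
    # attach each tip to the smallest dated clade containing it
    for tip in sorted(all_tips):
        candidates = [(r, nd) for r, nd in nodes if tip in r.tips]
        _, parent = min(candidates, key=lambda p: len(p[0].tips))
        leaf = _ANode(label=tip)
        leaf.age = 0.0
        parent.add(leaf)
    return root


def _parse_fragment(topology: str) -> _ANode:
    try:
        frag = dendropy.Tree.get(
            data=topology if topology.endswith(";") else topology + ";",
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise AssemblyError(f"malformed graft topology: {exc}") from None

    def conv(dnode) -> _ANode:
        if dnode.is_leaf():
            nd = _ANode(label=dnode.taxon.label)
            nd.age = 0.0
            return nd
        nd = _ANode()
        for ch in dnode.child_nodes():
            nd.add(conv(ch))
        return nd

    return conv(frag.seed_node)


def _find_clade_node(root: _ANode, tips: frozenset) -> _ANode:
    """Smallest node whose tip set contains ``tips`` (its MRCA)."""
    nd = root
    while True:
        nxt = None
        for ch in nd.children:
            if not ch.is_leaf() and tips <= ch.tips():
                nxt = ch
                break
            if ch.is_leaf() and tips == frozenset([ch.label]):
                return ch
        if nxt is None:
            return nd
        nd = nxt


def _apply_patch(root: _ANode, patch: GraftSpec) -> None:
    host = _find_clade_node(root, patch.attachment_clade)
    existing = host.tips()
    frag = _parse_fragment(patch.topology)
    frag_tips = frag.tips()
    expected = existing | frozenset(patch.new_tips)
    if frag_tips != expected:
        raise AssemblyError(
            f"graft topology tips {sorted(frag_tips)} do not match attachment "
            f"clade tips plus new tips {sorted(expected)}"
        )
    all_existing = root.tips()
    if frozenset(patch.new_tips) & all_existing:
        raise AssemblyError("new tip labels must be unique in the final tree")

    # collect dated descendant clades of the host (including host itself),
    # keyed by their ORIGINAL tip sets
    dated: list[tuple[frozenset, float]] = []
    stack = [host]
    while stack:
        nd = stack.pop()
        if nd.is_leaf():
            continue
        if nd.age is not None:
            dated.append((nd.tips(), nd.age))
        stack.extend(nd.children)

    # restore ages on the fragment: for each dated clade, the matching
    # fragment node is the SMALLEST one whose intersection with the original
    # tips equals the clade (new tips may nest inside it)
    def assign(tips_orig: frozenset, age: float) -> None:
        best = None
        stack2 = [frag]
        while stack2:
            nd = stack2.pop()
            if nd.is_leaf():
                continue
            inter = nd.tips() & all_existing
            if inter == tips_orig:
                if best is None or len(nd.tips()) < len(best.tips()):
                    best = nd
            stack2.extend(nd.children)
        if best is None:
            raise AssemblyError(
                f"graft topology conflicts with dated clade {sorted(tips_orig)} "
                f"(age {age}, no longer a clade after grafting)"
            )
        if best.age is not None and best.age != age:
            raise AssemblyError(
                f"conflicting ages for clade {sorted(tips_orig)}: {best.age} vs {age}"
            )
        best.age = age

    for tips_orig, age in dated:
        assign(tips_orig, age)

    # splice the fragment in place of the host subtree
    if host.parent is None:
        root.children = frag.children
        for ch in root.children:
            ch.parent = root
        root.age = frag.age if frag.age is not None else root.age
    else:
        parent = host.parent
        i = parent.children.index(host)
        frag.parent = parent
        parent.children[i] = frag


def _assign_undated_ages(node: _ANode, upper: float) -> None:
    """Equal-segment rule: an undated node heading a chain of k undated
    nodes that ends at a dated age b splits (upper - b) into k+1 equal
    segments."""

    def chain(nd: _ANode) -> tuple[int, float]:
        # returns (number of undated nodes in the longest chain starting at
        # nd, dated age terminating that chain)
        best_k, best_b = -1, 0.0
        for ch in nd.children:
            if not ch.is_leaf() and ch.age is None:
                cand = chain(ch)  # undated nodes below, inclusive of ch
            else:
                cand = (0, ch.age if ch.age is not None else 0.0)
            if cand[0] > best_k or (cand[0] == best_k and cand[1] > best_b):
                best_k, best_b = cand
        return 1 + best_k, best_b

    if node.is_leaf():
        return
    if node.age is None:
        k, b = chain(node)
        node.age = upper - (upper - b) / (k + 1)
    else:
        if node.parent is not None and node.age >= upper:
            raise AssemblyError(
                f"dated node at {node.age} Ma is not younger than its parent at {upper} Ma"
            )
    for ch in node.children:
        _assign_undated_ages(ch, node.age)


def _to_newick(node: _ANode) -> str:
    def rec(nd: _ANode) -> str:
        if nd.is_leaf():
            return nd.label
        inner = ",".join(rec(ch) for ch in nd.children)
        return f"({inner})"

    def rec_bl(nd: _ANode) -> str:
        if nd.is_leaf():
            core = nd.label
        else:
            core = "(" + ",".join(rec_bl(ch) for ch in nd.children) + ")"
        if nd.parent is None:
            return core
        bl = nd.parent.age - nd.age
        return f"{core}:{bl:.10g}"

    return rec_bl(node) + ";"


def assemble_backbone_patch(
    backbone: BackboneTable, patches: Sequence[GraftSpec] = ()
) -> TimeTree:
    """Build an ultrametric tree whose dated nodes carry exactly the
    tabulated ages; undated nodes follow the equal-segment rule."""
    if not backbone.rows:
        raise AssemblyError("empty backbone table")
    _check_nested(backbone.rows)
    root = _build_hierarchy(backbone.rows)
    for patch in patches:
        _apply_patch(root, patch)
    # binary check
    stack = [root]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            if len(nd.children) != 2:
                raise AssemblyError(
                    f"node over tips {sorted(nd.tips())[:4]}... has "
                    f"{len(nd.children)} children; supply a graft topology to resolve it"
                )
            stack.extend(nd.children)
    _assign_undated_ages(root, np.inf)
    return read_newick(_to_newick(root))
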