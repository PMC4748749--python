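"""Time-calibrated trees with fossil tips and sampled ancestors.

An :class:`FBDTree` is a rooted binary tree whose node ages are measured
before the present (extant tips at age 0).  Fossil samples appear in one of
two roles:

* **fossil tip** — the fossil terminates its own lineage; it is a leaf with a
  positive-length pendant branch;
* **sampled ancestor** — the fossil lies on a lineage with later sampled
  descendants.  Following the zero-length-branch convention, it is stored as
  a leaf hanging from a bifurcation at exactly the fossil's age, so the
  pendant branch has length 0.  Such a bifurcation is an *attachment point*,
  not a true speciation event, and is skipped when branching times are
  collected.

Fossils record how they were sampled: ``"psi"`` for rate-sampled (Poisson)
fossils, or ``"horizon"`` with the 1-based index of the boundary age at which
the lineage was sampled.  Horizon flags are explicit — classification never
relies on an age happening to coincide with a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["FossilInfo", "FBDNode", "FBDTree"]


@dataclass
class FossilInfo:
    """Sampling metadata for a fossil node."""

    kind: str = "psi"                 # "psi" or "horizon"
    horizon: Optional[int] = None     # 1-based boundary index for kind="horizon"
    age_lower: Optional[float] = None  # stratigraphic bounds (uniform age prior)
    age_upper: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("psi", "horizon"):
            raise ValueError(f"unknown fossil kind {self.kind!r}")
        if self.kind == "horizon" and self.horizon is None:
            raise ValueError("horizon fossils need a boundary index")


class FBDNode:
    """A node of an :class:`FBDTree`."""

    __slots__ = ("parent", "children", "age", "label", "fossil",
                 "partial", "logscale", "index")

    def __init__(self, age=0.0, label=None, fossil=None, children=()):
        self.parent: Optional[FBDNode] = None
        self.children: list[FBDNode] = []
        self.age = float(age)
        self.label = label
        self.fossil: Optional[FossilInfo] = fossil
        self.partial = None    # per-site conditional likelihoods (cache)
        self.logscale = None
        self.index = None      # stable id assigned by FBDTree.reindex()
        for child in children:
            self.add_child(child)

    # -- structure edits -----------------------------------------------------

    def add_child(self, child: "FBDNode"):
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "FBDNode"):
        self.children.remove(child)
        child.parent = None

    # -- classification ------------------------------------------------------

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_fossil(self) -> bool:
        return self.fossil is not None

    @property
    def is_extant(self) -> bool:
        return self.is_tip and self.fossil is None

    @property
    def is_sampled_ancestor(self) -> bool:
        """True for a fossil leaf whose pendant branch has length zero."""
        return (self.fossil is not None and self.parent is not None
                and self.parent.age == self.age)

    @property
    def sa_child(self) -> Optional["FBDNode"]:
        """The zero-length fossil child if this node is an attachment point."""
        for child in self.children:
            if child.fossil is not None and child.age == self.age:
                return child
        return None

    @property
    def is_attachment(self) -> bool:
        """True for the bifurcation carrying a sampled ancestor."""
        return len(self.children) == 2 and self.sa_child is not None

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self):  # pragma: no cover
        kind = ("extant" if self.is_extant else
                "fossil" if self.is_fossil else "internal")
        return f"<FBDNode {self.label or id(self)} {kind} age={self.age:.4g}>"


class FBDTree:
    """A rooted FBD tree with optional origin (stem) age."""

    def __init__(self, root: FBDNode, origin_age: Optional[float] = None):
        self.root = root
        self.origin_age = origin_age
        self.validate()

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> list[FBDNode]:
        out = []
        stack = [self.root]
        push = stack.extend
        append = out.append
        while stack:
            node = stack.pop()
            append(node)
            if node.children:
                push(node.children)
        return out

    def postorder(self) -> list[FBDNode]:
        return self.preorder()[::-1]

    def nodes(self) -> list[FBDNode]:
        return self.preorder()

    def leaves(self) -> list[FBDNode]:
        return [n for n in self.preorder() if n.is_tip]

    def extant_tips(self) -> list[FBDNode]:
        return [n for n in self.preorder() if n.is_extant]

    def fossils(self) -> list[FBDNode]:
        return [n for n in self.preorder() if n.is_fossil]

    def true_branchings(self) -> list[FBDNode]:
        """Internal nodes that are real speciation events (root included)."""
        return [n for n in self.preorder()
                if n.children and not n.is_attachment]

    def reindex(self):
        for i, node in enumerate(self.preorder()):
            node.index = i

    # -- summaries -----------------------------------------------------------

    @property
    def crown_age(self) -> float:
        return self.root.age

    def n_sampled_ancestors(self) -> int:
        return sum(1 for f in self.fossils() if f.is_sampled_ancestor)

    def n_fossil_tips(self) -> int:
        return sum(1 for f in self.fossils() if not f.is_sampled_ancestor)

    # -- integrity -----------------------------------------------------------

    def validate(self):
        seen = set()
        for node in self.preorder():
            if id(node) in seen:
                raise ValueError("cycle detected in tree")
            seen.add(id(node))
            if len(node.children) not in (0, 2):
                raise ValueError("FBD trees are strictly binary")
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("broken parent link")
                if child.age > node.age:
                    raise ValueError(
                        f"child {child.label!r} older than its parent")
            if node.is_tip and node.fossil is None and node.age != 0.0:
                raise ValueError(
                    f"extant tip {node.label!r} must sit at age 0")
        if self.origin_age is not None and self.origin_age < self.root.age:
            raise ValueError("origin age must not precede the root age")

    # -- copying -------------------------------------------------------------

    def copy(self) -> "FBDTree":
        """Structural deep copy (likelihood caches are not copied)."""
        def clone(node: FBDNode) -> FBDNode:
            fossil = None
            if node.fossil is not None:
                fossil = FossilInfo(node.fossil.kind, node.fossil.horizon,
                                    node.fossil.age_lower, node.fossil.age_upper)
            out = FBDNode(age=node.age, label=node.label, fossil=fossil)
            for child in node.children:
                out.add_child(clone(child))
            return out
        return FBDTree(clone(self.root), origin_age=self.origin_age)

    def __repr__(self):  # pragma: no cover
        return (f"<FBDTree {len(self.extant_tips())} extant, "
                f"{len(self.fossils())} fossils, crown {self.crown_age:.4g}>")
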