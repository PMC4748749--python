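"""Readers and writers: Newick trees, FASTA/NEXUS alignments, fossil tables.

Sampled ancestors are serialised as zero-length pendant branches — a
bifurcation whose fossil child has branch length exactly 0 — which every
Newick consumer can read.  Ages are reconstructed from branch lengths by
anchoring the present at the maximum root-to-tip path length; tips within a
relative tolerance of the present are snapped to age 0 (extant), all other
tips are fossils, and a fossil with a zero-length pendant is flagged as a
sampled ancestor.
"""

from __future__ import annotations

from typing import Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqmodel import Alignment
from .tree import FBDNode, FBDTree, FossilInfo

__all__ = ["write_newick", "read_newick", "write_fossil_table",
           "read_fossil_table", "read_fasta", "write_fasta", "read_nexus",
           "write_nexus_trees", "write_trace"]

_PRESENT_RTOL = 1e-9


def write_newick(tree: FBDTree, precision: int = 12) -> str:
    """Serialise an FBD tree (branch lengths are durations, tips labelled)."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(node: FBDNode) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            body = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                body += node.label
        if node.parent is None:
            return body
        return body + ":" + fmt(node.parent.age - node.age)

    return rec(tree.root) + ";"


def read_newick(text: str, fossil_meta: Optional[dict] = None) -> FBDTree:
    """Parse a Newick string into an :class:`FBDTree`.

    Ages are branch-length depths anchored so the deepest tip sits at the
    present.  ``fossil_meta`` may map tip labels to
    :class:`~fbdsky.tree.FossilInfo` (e.g. from a fossil table); otherwise
    any tip with a positive age becomes a rate-sampled fossil.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    droot = dtree.seed_node
    depths = {}

    def depth(dnode, acc):
        depths[id(dnode)] = acc
        for ch in dnode.child_nodes():
            depth(ch, acc + (ch.edge.length or 0.0))

    depth(droot, 0.0)
    height = max(depths[id(n)] for n in dtree.leaf_node_iter())
    scale = max(height, 1.0)

    def convert(dnode, age) -> FBDNode:
        if abs(age) <= _PRESENT_RTOL * scale:
            age = 0.0
        label = dnode.taxon.label if dnode.taxon is not None else (
            dnode.label or None)
        node = FBDNode(age=age, label=label)
        for ch in dnode.child_nodes():
            node.add_child(convert(ch, age - (ch.edge.length or 0.0)))
        return node

    # ages propagate top-down so each parsed branch length is reproduced by
    # a single subtraction on re-serialisation
    root = convert(droot, height)
    # fossil roles: leaves above the present
    for node in _preorder(root):
        if not node.children and node.age > 0.0:
            meta = (fossil_meta or {}).get(node.label)
            node.fossil = meta if meta is not None else FossilInfo("psi")
        # snap zero-length pendants exactly onto the parent age
        if (not node.children and node.parent is not None
                and abs(node.parent.age - node.age) <= _PRESENT_RTOL * scale
                and node.age > 0.0):
            node.age = node.parent.age
    return FBDTree(root)


def _preorder(node: FBDNode):
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


# ---------------------------------------------------------------------------
# Fossil tables
# ---------------------------------------------------------------------------

def write_fossil_table(tree: FBDTree, path_or_buf) -> None:
    """Tab-separated fossil table: label, age, lower, upper, type."""
    rows = []
    for f in tree.fossils():
        rows.append({
            "label": f.label,
            "age": f.age,
            "lower": f.fossil.age_lower if f.fossil.age_lower is not None
            else f.age,
            "upper": f.fossil.age_upper if f.fossil.age_upper is not None
            else f.age,
            "type": "ancestor" if f.is_sampled_ancestor else "tip",
        })
    pd.DataFrame(rows, columns=["label", "age", "lower", "upper", "type"]
                 ).to_csv(path_or_buf, sep="\t", index=False)


def read_fossil_table(path_or_buf) -> dict[str, FossilInfo]:
    """Read a fossil table into a label -> FossilInfo mapping."""
    df = pd.read_csv(path_or_buf, sep="\t")
    if "lower" in df and (df["lower"] > df["upper"]).any():
        bad = df.loc[df["lower"] > df["upper"], "label"].tolist()
        raise ValueError(f"fossil age bounds inverted for {bad}")
    if df["label"].duplicated().any():
        raise ValueError("duplicate fossil labels")
    out = {}
    for _, row in df.iterrows():
        lower = row.get("lower", row["age"])
        upper = row.get("upper", row["age"])
        out[str(row["label"])] = FossilInfo(
            "psi", age_lower=float(lower), age_upper=float(upper))
    return out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_fasta(path_or_buf) -> Alignment:
    records = {}
    for rec in SeqIO.parse(path_or_buf, "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError("no FASTA records found")
    return Alignment.from_strings(records)


def write_fasta(alignment: Alignment, path_or_buf) -> None:
    recs = [SeqRecord(Seq(seq), id=lab, description="")
            for lab, seq in alignment.to_strings().items()]
    SeqIO.write(recs, path_or_buf, "fasta")


def read_nexus(path_or_buf) -> Alignment:
    """Read the characters block of a NEXUS file (interleaved or not)."""
    if hasattr(path_or_buf, "read"):
        data = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            data = fh.read()
    mat = dendropy.DnaCharacterMatrix.get(data=data, schema="nexus")
    records = {}
    for taxon in mat.taxon_namespace:
        records[taxon.label] = str(mat[taxon]).replace(" ", "")
    return Alignment.from_strings(records)


# ---------------------------------------------------------------------------
# Traces and sampled trees
# ---------------------------------------------------------------------------

def write_trace(trace_df: pd.DataFrame, path) -> None:
    trace_df.to_csv(path, sep="\t", index=False)


def write_nexus_trees(trees, path) -> None:
    """Write sampled FBD trees as a NEXUS trees block (Newick inside)."""
    lines = ["#NEXUS", "BEGIN TREES;"]
    for i, tree in enumerate(trees):
        lines.append(f"    TREE sample_{i} = {write_newick(tree)}")
    lines.append("END;")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
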