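"""Rooted phylogenies carrying OGT estimates: the trait-mapping stage.

The phylogeny is strictly an input here (tree inference is out of scope).
Nodes — leaves and labeled internal nodes alike — can carry an
:class:`~asgard_ogt.ogt.OgtEstimate`, and the evolutionary-trajectory table
lists, for every annotated node, the OGT change relative to its nearest
annotated ancestor. Only measured or fitted values are painted onto the
tree; there is no ancestral-state interpolation for unmeasured nodes.

Newick I/O is handled by dendropy. Annotations are exported both inline, as
``[&ogt=...]`` hot comments in an extended-newick dialect, and as a sidecar
TSV; the sidecar is the authoritative record, because comment dialects vary
across toolchains.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import dendropy
import pandas as pd

from .ogt import OgtEstimate


class NewickParseError(ValueError):
    """Malformed newick input."""


class AnnotatedTree:
    """A rooted dendropy tree plus a label -> OgtEstimate mapping.

    Node labels (taxon labels for leaves, node labels for internals) must be
    unique across the tree; every estimate must refer to an existing label.
    """

    def __init__(self, tree: dendropy.Tree, estimates: Optional[Dict[str, OgtEstimate]] = None):
        self.tree = tree
        self.estimates: Dict[str, OgtEstimate] = dict(estimates or {})
        labels = self.labels()
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"duplicate node label {lab!r}")
            seen.add(lab)
        missing = set(self.estimates) - seen
        if missing:
            raise ValueError(f"estimates refer to unknown labels: {sorted(missing)}")

    @staticmethod
    def node_label(node: dendropy.Node) -> Optional[str]:
        if node.taxon is not None and node.taxon.label:
            return str(node.taxon.label)
        return str(node.label) if node.label else None

    def labels(self) -> List[str]:
        """All node labels in preorder (unlabeled internal nodes skipped)."""
        out = []
        for node in self.tree.preorder_node_iter():
            lab = self.node_label(node)
            if lab is not None:
                out.append(lab)
        return out

    def find(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self.node_label(node) == label:
                return node
        raise KeyError(label)

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


def read_newick(text: str) -> AnnotatedTree:
    """Parse a rooted newick string (internal node labels permitted)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    tree.is_rooted = True
    return AnnotatedTree(tree)


def write_newick(atree: AnnotatedTree, annotations: bool = False) -> str:
    """Serialise to newick; optionally embed OGT annotations as hot comments."""
    if annotations:
        for node in atree.tree.preorder_node_iter():
            lab = AnnotatedTree.node_label(node)
            node.annotations.drop(name="ogt")
            node.annotations.drop(name="lifestyle")
            if lab is not None and lab in atree.estimates:
                est = atree.estimates[lab]
                node.annotations.add_new("ogt", est.ogt)
                node.annotations.add_new("lifestyle", est.lifestyle)
    text = atree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        suppress_annotations=not annotations,
    )
    return text.strip() + ("\n" if not text.endswith("\n") else "")


def read_newick_file(path: Union[str, Path]) -> AnnotatedTree:
    return read_newick(Path(path).read_text())


def write_newick_file(atree: AnnotatedTree, path: Union[str, Path], annotations: bool = False) -> None:
    Path(path).write_text(write_newick(atree, annotations=annotations))


def annotate_nodes(atree: AnnotatedTree, estimates: Iterable[OgtEstimate]) -> AnnotatedTree:
    """Attach OGT estimates to tree nodes by label.

    Unknown labels raise (listing all of them); duplicate labels within the
    estimate list raise. Re-applying the same estimates is idempotent.
    Returns a new AnnotatedTree sharing the topology.
    """
    estimates = list(estimates)
    labels = [e.label for e in estimates]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate labels in estimates: {sorted(dupes)}")
    known = set(atree.labels())
    missing = [l for l in labels if l not in known]
    if missing:
        raise ValueError(f"estimate labels not found in tree: {sorted(missing)}")
    merged = dict(atree.estimates)
    merged.update({e.label: e for e in estimates})
    return AnnotatedTree(atree.tree, merged)


def trajectory_table(atree: AnnotatedTree) -> pd.DataFrame:
    """OGT changes along the tree: one row per annotated node with an annotated ancestor.

    The parent in each row is the *nearest annotated ancestor* — unannotated
    intermediate nodes are skipped so that ``delta = ogt - parent_ogt`` is
    always defined. Deltas telescope: along any fully annotated path they sum
    to terminal OGT minus root OGT.
    """
    if not atree.estimates:
        raise ValueError("tree carries no OGT annotations")
    rows = []
    for node in atree.tree.preorder_node_iter():
        lab = AnnotatedTree.node_label(node)
        if lab is None or lab not in atree.estimates:
            continue
        anc_lab = None
        anc = node.parent_node
        while anc is not None:
            cand = AnnotatedTree.node_label(anc)
            if cand is not None and cand in atree.estimates:
                anc_lab = cand
                break
            anc = anc.parent_node
        if anc_lab is None:
            continue
        est = atree.estimates[lab]
        parent_est = atree.estimates[anc_lab]
        rows.append(
            {
                "node": lab,
                "parent": anc_lab,
                "ogt": est.ogt,
                "parent_ogt": parent_est.ogt,
                "delta": est.ogt - parent_est.ogt,
                "lifestyle": est.lifestyle,
            }
        )
    return pd.DataFrame(rows, columns=["node", "parent", "ogt", "parent_ogt", "delta", "lifestyle"])


def annotations_table(atree: AnnotatedTree) -> pd.DataFrame:
    """Sidecar TSV content: node, ogt, ci_lower, ci_upper, lifestyle."""
    rows = [
        {
            "node": e.label,
            "ogt": e.ogt,
            "ci_lower": e.ci_lower,
            "ci_upper": e.ci_upper,
            "lifestyle": e.lifestyle,
        }
        for e in atree.estimates.values()
    ]
    return pd.DataFrame(rows, columns=["node", "ogt", "ci_lower", "ci_upper", "lifestyle"])


def plot_tree(atree: AnnotatedTree, path: Union[str, Path]) -> None:
    """Optional figure: the tree with nodes colored by OGT (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # simple ladder layout: leaves at integer y, internals at child mean
    ys: Dict[int, float] = {}
    for i, leaf in enumerate(atree.tree.leaf_node_iter()):
        ys[id(leaf)] = float(i)
    for node in atree.tree.postorder_internal_node_iter():
        ys[id(node)] = sum(ys[id(c)] for c in node.child_nodes()) / len(node.child_nodes())
    xs: Dict[int, float] = {}
    for node in atree.tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length if node.edge.length is not None else 1.0
        xs[id(node)] = (xs[id(parent)] + edge) if parent is not None else 0.0

    fig, ax = plt.subplots(figsize=(8, max(3, 0.4 * len(atree))))
    cmap = plt.get_cmap("coolwarm")
    vals = [e.ogt for e in atree.estimates.values()] or [20.0, 70.0]
    vmin, vmax = min(vals), max(vals)
    norm = plt.Normalize(vmin=vmin, vmax=max(vmax, vmin + 1e-9))
    for node in atree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            ax.plot([xs[id(parent)], xs[id(node)]], [ys[id(node)], ys[id(node)]], color="0.6")
            ax.plot([xs[id(parent)], xs[id(parent)]], [ys[id(parent)], ys[id(node)]], color="0.6")
        lab = AnnotatedTree.node_label(node)
        if lab is not None:
            est = atree.estimates.get(lab)
            color = cmap(norm(est.ogt)) if est else "0.3"
            ax.plot(xs[id(node)], ys[id(node)], "o", color=color, markersize=7)
            txt = f"{lab}" + (f" ({est.ogt:.1f} degC)" if est else "")
            ax.text(xs[id(node)] + 0.02, ys[id(node)], txt, va="center", fontsize=8)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label="OGT (deg C)")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
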