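"""Structural distance matrices and neighbor-joining trees.

Pairwise structural similarity is converted to a distance
d = 1 - (TM_query + TM_target) / 2 and fed to Saitou-Nei neighbor joining,
which recovers the generating topology and branch lengths exactly on
additive matrices. A combined structure+sequence distance is offered as a
weighted average w * d_struct + (1 - w) * d_seq, with d_seq one minus the
fractional pairwise sequence identity; the weight is an explicit, logged
assumption. Tree inference and the distance-matrix container are backed by
scikit-bio; Newick serialization quotes labels per the Newick convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .structio import Structure
from .superpose import StructAlignment, align_structures

__all__ = [
    "structural_distance_matrix",
    "sequence_distance_matrix",
    "combined_distance_matrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "is_monophyletic",
    "write_phylip",
    "read_phylip",
]


def structural_distance_matrix(
    structures: Sequence[Structure],
    aligner: Callable[[Structure, Structure], StructAlignment] = align_structures,
) -> DistanceMatrix:
    """All-vs-all structural distances, d = 1 - mean(tm_query, tm_target).

    Each unordered pair is aligned once (the aligner is symmetric in its
    TM-scores), so the matrix is symmetric by construction with zero
    diagonal. A failed alignment contributes distance 1 with a warning.
    """
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids")
    if len(structures) < 3:
        raise ValueError("need at least 3 structures")
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                aln = aligner(structures[i], structures[j])
                dij = 1.0 - 0.5 * (aln.tm_query + aln.tm_target)
            except Exception as exc:  # alignment failure -> maximal distance
                warnings.warn(f"alignment {ids[i]} vs {ids[j]} failed ({exc}); distance set to 1")
                dij = 1.0
            d[i, j] = d[j, i] = max(0.0, dij)
    return DistanceMatrix(d, ids)


def sequence_distance_matrix(structures: Sequence[Structure]) -> DistanceMatrix:
    """One minus fractional identity from global pairwise alignment."""
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0, open_gap_score=-1, extend_gap_score=-0.5
    )
    ids = [s.id for s in structures]
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(structures[i].sequence, structures[j].sequence)[0]
            matches = sum(
                a == b
                for a, b in zip(str(aln[0]), str(aln[1]))
                if a != "-" and b != "-"
            )
            ident = matches / max(len(structures[i]), len(structures[j]))
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(d, ids)


def combined_distance_matrix(
    d_struct: DistanceMatrix, d_seq: DistanceMatrix, weight: float = 0.5
) -> DistanceMatrix:
    """Weighted combination w * d_struct + (1 - w) * d_seq (same label sets)."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    if tuple(d_struct.ids) != tuple(d_seq.ids):
        d_seq = d_seq.filter(d_struct.ids)
    return DistanceMatrix(
        weight * d_struct.data + (1.0 - weight) * d_seq.data, d_struct.ids
    )


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Labels are processed in sorted order so ties resolve lexicographically;
    negative branch-length estimates are clamped to zero.
    """
    if m.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    data = m.data
    if not np.allclose(data, data.T) or not np.all(np.isfinite(data)):
        raise ValueError("distance matrix must be symmetric and finite")
    ordered = m.filter(sorted(m.ids))
    return nj(ordered, neg_as_zero=True)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(node: TreeNode) -> str:
    if node.is_tip():
        s = _quote(node.name or "")
    else:
        s = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
        if node.name:
            s += _quote(node.name)
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(t: TreeNode, path: str | Path) -> None:
    """Serialize with branch lengths; labels with spaces are quoted."""
    Path(path).write_text(_to_newick(t) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), convert_underscores=False)


def is_monophyletic(tree: TreeNode, leaves: set[str]) -> bool:
    """Whether ``leaves`` form a clade on some rooting of the unrooted tree.

    True iff an edge of the tree separates exactly this leaf set from the
    rest (trivially true for the complete leaf set).
    """
    all_leaves = {tip.name for tip in tree.tips()}
    if not leaves <= all_leaves:
        raise ValueError("query leaves missing from tree")
    if leaves == all_leaves:
        return True
    outside = next(iter(all_leaves - leaves))
    rooted = tree.copy()
    out_node = rooted.find(outside)
    rooted = rooted.root_at(out_node.parent) if out_node.parent is not None else rooted
    lca = rooted.lca([rooted.find(name) for name in leaves])
    return {tip.name for tip in lca.tips()} == leaves


def write_phylip(m: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance-matrix format."""
    lines = [f"{m.shape[0]}"]
    for label in m.ids:
        row = " ".join(f"{x:.9f}" for x in m[label])
        lines.append(f"{str(label):<10s} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(np.array(rows), labels)
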