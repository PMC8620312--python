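"""Sørensen distances over barcode sets and neighbor-joining trees.

The overlap of two genomes' marker k-mer sets measures their relatedness:
the Sørensen (Dice) distance D(A, B) = 1 − 2|A∩B| / (|A| + |B|) is 0 for
identical sets and 1 for disjoint ones.  A pairwise distance matrix over
the barcodes of one specificity level feeds the classic Saitou–Nei
neighbor-joining agglomeration, which is exact on additive matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .barcode import Barcode, KbarcodeError, ParameterError

logger = logging.getLogger("kbarcode")


class UndefinedDistanceError(KbarcodeError, ValueError):
    """Raised when a distance is undefined (two empty sets)."""


class ValidationError(KbarcodeError, ValueError):
    """Raised for malformed distance matrices."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an ordered label list."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.data.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])


def sorensen_distance(a: Barcode, b: Barcode) -> float:
    """Sørensen–Dice distance between two barcodes: 1 − 2|A∩B|/(|A|+|B|).

    Returned as a fraction in [0, 1]; multiply by 100 to render as the
    percentage shown on tree scale bars.
    """
    if a.params != b.params:
        raise ParameterError("barcodes have different k-mer params")
    na, nb = a.size, b.size
    if na + nb == 0:
        raise UndefinedDistanceError(
            f"Sørensen distance undefined: {a.genome_id} and {b.genome_id} are both empty"
        )
    shared = len(a.kmers.words & b.kmers.words)
    return 1.0 - 2.0 * shared / (na + nb)


def pairwise_distance_matrix(barcodes: Sequence[Barcode]) -> DistanceMatrix:
    """Sørensen distances over all barcode pairs; label order = input order."""
    if len(barcodes) < 3:
        raise ParameterError("need at least 3 barcodes for a distance matrix")
    empty = [b.genome_id for b in barcodes if b.size == 0]
    if empty:
        raise UndefinedDistanceError(
            f"empty barcodes cannot be placed in a distance matrix: {empty}"
        )
    params = barcodes[0].params
    for b in barcodes:
        if b.params != params:
            raise ParameterError("barcodes have different k-mer params")
    n = len(barcodes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sorensen_distance(barcodes[i], barcodes[j])
    return DistanceMatrix(labels=[b.genome_id for b in barcodes], data=d)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou–Nei)
# ---------------------------------------------------------------------------


def _clamped(length: float, context: str) -> float:
    if length < 0:
        logger.info("NJ: clamping negative branch length %.3g at %s", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard agglomeration: at each step the pair (i, j) minimising
    Q(i, j) = (n−2)·d(i, j) − r_i − r_j is joined (r = row sums); limb
    lengths follow the usual formulas and the matrix is reduced with
    d(u, m) = (d(i,m) + d(j,m) − d(i,j)) / 2.

    Determinism: ties in Q are broken by the lexicographically smallest
    (label_i, label_j) pair, where an internal node inherits the smallest
    leaf label beneath it.  Negative branch lengths are clamped to zero
    and the deficit logged.  The result is an unrooted tree represented
    with a trifurcating root.
    """
    n = len(dm)
    if n < 3:
        raise ParameterError("neighbor joining requires >= 3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    # representative label per active node, for deterministic tie-breaks
    reps: list[str] = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        best_ij = (0, 0)
        ii, jj = np.where(q <= qmin + 1e-12)
        for a_, b_ in zip(ii, jj):
            if a_ >= b_:
                continue
            la, lb = reps[active[a_]], reps[active[b_]]
            key = (min(la, lb), max(la, lb))
            if best is None or key < best:
                best = key
                best_ij = (int(a_), int(b_))
        ai, bj = best_ij
        i, j = active[ai], active[bj]
        dij = sub[ai, bj]
        li = 0.5 * dij + (r[ai] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = _clamped(li, f"{reps[i]}")
        cj.length = _clamped(lj, f"{reps[j]}")
        parent.extend([ci, cj])
        # new distances to remaining nodes
        new_row = np.zeros(d.shape[0] + 1)
        for a_ in active:
            if a_ in (i, j):
                continue
            new_row[a_] = 0.5 * (d[i, a_] + d[j, a_] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row[:-1]
        d[: -1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [a_ for a_ in active if a_ not in (i, j)] + [len(nodes) - 1]

    # terminal three-taxon star: closed-form limb lengths
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamped(length, reps[idx])
        root.append(nodes[idx])
    return root


# ---------------------------------------------------------------------------
# Serialization: Newick, PHYLIP square, TSV
# ---------------------------------------------------------------------------


def _fmt_len(x: float | None, sig: int) -> str:
    if x is None:
        x = 0.0
    return f"{x:.{sig}g}"


def _newick_node(node: TreeNode, sig: int) -> str:
    if node.is_tip():
        label = node.name or ""
        label = label.replace(" ", "_")
        return f"{label}:{_fmt_len(node.length, sig)}"
    inner = ",".join(_newick_node(c, sig) for c in node.children)
    if node.parent is None:
        return f"({inner});"
    return f"({inner}):{_fmt_len(node.length, sig)}"


def to_newick(tree: TreeNode, sig_digits: int = 6) -> str:
    """Newick string with branch lengths at the given significant digits."""
    return _newick_node(tree, sig_digits) + "\n"


def write_newick(tree: TreeNode, path: Path | str, sig_digits: int = 6) -> Path:
    path = Path(path)
    path.write_text(to_newick(tree, sig_digits))
    return path


def read_newick(path: Path | str) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip(dm: DistanceMatrix, path: Path | str) -> Path:
    """Square PHYLIP distance matrix (relaxed label width)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for lab, row in zip(dm.labels, dm.data):
            cells = " ".join(f"{v:.10g}" for v in row)
            fh.write(f"{lab}  {cells}\n")
    return path


def read_phylip(path: Path | str) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1 : n + 1]])
    return DistanceMatrix(labels=labels, data=np.array(rows))


def write_distmat_tsv(dm: DistanceMatrix, path: Path | str) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(dm.data, index=dm.labels, columns=dm.labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    return path


def read_distmat_tsv(path: Path | str) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(labels=[str(c) for c in df.columns], data=df.to_numpy())
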