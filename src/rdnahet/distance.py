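"""p-distances, neighbor-joining trees, and haplotype counting.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ.  Gapped sites are handled either by
``pairwise_deletion`` (a site is compared for a pair whenever both members
are ungapped there — the common default) or ``complete_deletion`` (only
columns ungapped in *every* sequence are compared).  Trees are built with the
Saitou–Nei neighbor-joining agglomeration and returned as dendropy trees with
the standard unrooted trifurcation at the seed node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .calling import CloneAlignment
from .errors import InvalidInputError, InvalidParameterError

GAP_MODES = ("pairwise_deletion", "complete_deletion")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of substitutions/site; NaN marks undefined pairs."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidInputError("matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _as_sequences(alignment) -> tuple[list[str], list[str]]:
    if isinstance(alignment, CloneAlignment):
        return alignment.column_chars(), list(alignment.clone_ids)
    seqs = list(alignment)
    return seqs, [f"seq{i + 1}" for i in range(len(seqs))]


def p_distance_matrix(
    alignment,
    labels: list[str] | None = None,
    gap_mode: str = "pairwise_deletion",
) -> DistanceMatrix:
    """Pairwise p-distances over an alignment (list of equal-length strings
    or a :class:`~rdnahet.calling.CloneAlignment`)."""
    if gap_mode not in GAP_MODES:
        raise InvalidParameterError(f"gap_mode must be one of {GAP_MODES}")
    seqs, default_labels = _as_sequences(alignment)
    labels = list(labels) if labels is not None else default_labels
    if len(seqs) < 2:
        raise InvalidInputError("need >= 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise InvalidInputError("sequences must have equal aligned length")
    if len(labels) != len(seqs):
        raise InvalidInputError("labels do not match sequences")

    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
        len(seqs), -1
    )
    ungapped = (mat != b"-") & (mat != b"N")
    if gap_mode == "complete_deletion":
        keep = ungapped.all(axis=0)
        mat = mat[:, keep]
        ungapped = ungapped[:, keep]

    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ungapped[i] & ungapped[j]
            total = int(valid.sum())
            if total == 0:
                warnings.warn(
                    f"no comparable sites for pair ({labels[i]}, {labels[j]}); "
                    "distance undefined",
                    stacklevel=2,
                )
                values[i, j] = values[j, i] = np.nan
                continue
            diff = int((mat[i][valid] != mat[j][valid]).sum())
            values[i, j] = values[j, i] = diff / total
    return DistanceMatrix(labels=labels, values=values)


def distance_summary(d: DistanceMatrix) -> tuple[float, float]:
    """(max, mean) over the off-diagonal upper triangle, ignoring undefined
    pairs."""
    if d.n < 2:
        raise InvalidInputError("need >= 2 sequences for a distance summary")
    iu = np.triu_indices(d.n, k=1)
    vals = d.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.max()), float(vals.mean())


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the lexicographically
    smallest (sorted) label pair.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sibling branch, so the pair's
    total length is preserved.  The returned tree is unrooted (trifurcating
    seed node for > 3 taxa).
    """
    if d.n < 3:
        raise InvalidInputError("neighbor joining needs >= 3 taxa")
    if np.isnan(d.values).any():
        raise InvalidInputError("distance matrix has undefined entries")

    taxa = dendropy.TaxonNamespace(d.labels)
    nodes: list[dendropy.Node] = []
    for label in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    names = list(d.labels)  # tie-break identity of each active cluster
    D = d.values.astype(float).copy()

    def clamp(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return bi, max(bj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                tie = tuple(sorted((names[i], names[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bj = D[i, j] - bi
        bi, bj = clamp(bi, bj)
        parent = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = new_row[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    seed = dendropy.Node()
    if len(nodes) == 3:
        # three-point formulas for the final star
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        b0 = 0.5 * (d01 + d02 - d12)
        b1 = 0.5 * (d01 + d12 - d02)
        b2 = 0.5 * (d02 + d12 - d01)
        for node, b in zip(nodes, (b0, b1, b2)):
            node.edge.length = max(b, 0.0)
            seed.add_child(node)
    else:  # exactly 2 remaining cannot occur for n >= 3
        raise AssertionError("unreachable")

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree, labels: list[str]) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of ``tree`` in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = dist
    return DistanceMatrix(labels=list(labels), values=values)


def count_haplotypes(
    alignment, masked: set[int] | None = None
) -> tuple[int, dict[str, list[str]]]:
    """Collapse sequences identical over unmasked columns into haplotypes.

    Accepts a :class:`~rdnahet.calling.CloneAlignment` (its own mask applies)
    or a list of equal-length strings with an optional set of 0-based masked
    column indices.  Returns the haplotype count and a mapping from each
    haplotype's representative (first member) to the member labels.
    """
    if isinstance(alignment, CloneAlignment):
        seqs = alignment.column_chars()
        labels = list(alignment.clone_ids)
    else:
        seqs = list(alignment)
        labels = [f"seq{i + 1}" for i in range(len(seqs))]
        if masked:
            seqs = [
                "".join(ch for i, ch in enumerate(s) if i not in masked)
                for s in seqs
            ]
    if not seqs:
        raise InvalidInputError("empty alignment")
    groups: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    for label, seq in zip(labels, seqs):
        if seq not in reps:
            reps[seq] = label
            groups[label] = []
        groups[reps[seq]].append(label)
    return len(groups), groups
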