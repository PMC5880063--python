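"""Genetic relatedness of genome groups: Nei DA, UPGMA, bootstrap, PCA.

Groups are sets of records (diploid individuals or diploidized haploid
subgenomes).  Nei's DA distance between two groups is

    DA(x, y) = 1 - (1/L) * sum_loci sum_alleles sqrt(x_a * y_a)

with x_a, y_a the sample allele frequencies.  Trees are UPGMA
(size-weighted average-linkage, ultrametric heights); branch support
comes from resampling loci with replacement.  UPGMA is implemented here
because the tie-break (smallest leaf-label pair, lexicographically) is
part of the contract; scipy's average linkage serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .model import MISSING, IndividualRecord, ValidationError


@dataclass
class DistanceMatrix:
    labels: tuple
    d: np.ndarray
    dropped_loci: list = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix must be symmetric, zero diag")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; leaves carry ``name``."""

    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.name]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def clades(self) -> list:
        """Leaf sets of all internal nodes (including the root)."""
        out = []
        if not self.is_leaf:
            out.append(frozenset(self.leaves()))
            for child, _ in self.children:
                out.extend(child.clades())
        return out

    def internal_nodes(self) -> list:
        out = []
        if not self.is_leaf:
            out.append(self)
            for child, _ in self.children:
                out.extend(child.internal_nodes())
        return out

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: "TreeNode") -> str:
            if node.is_leaf:
                return str(node.name)
            inner = ",".join(
                f"{fmt(child)}:{length:.{digits}f}"
                for child, length in node.children
            )
            label = "" if node.support is None else f"{node.support:.3f}"
            return f"({inner}){label}"

        return fmt(self) + ";"


def _group_frequencies(records: Sequence[IndividualRecord],
                       locus: str) -> dict:
    counts: dict[int, int] = {}
    for rec in records:
        for a in rec.alleles_at(locus):
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()} if total else {}


def nei_da_matrix(groups: Mapping, loci: Sequence[str]) -> DistanceMatrix:
    """Nei's DA distance between all group pairs.

    Loci with zero scored copies in any group are dropped (recorded on the
    result), so every retained locus contributes a frequency profile for
    every group.
    """
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    freqs = {
        (label, locus): _group_frequencies(groups[label], locus)
        for label in labels for locus in loci
    }
    kept = [
        locus for locus in loci
        if all(freqs[(label, locus)] for label in labels)
    ]
    dropped = [l for l in loci if l not in kept]
    if not kept:
        raise ValidationError("no locus scored in every group")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc = 0.0
            for locus in kept:
                fx = freqs[(labels[i], locus)]
                fy = freqs[(labels[j], locus)]
                acc += sum(
                    np.sqrt(fx[a] * fy[a]) for a in set(fx) & set(fy)
                )
            d[i, j] = d[j, i] = float(np.clip(1.0 - acc / len(kept), 0.0, 1.0))
    return DistanceMatrix(labels, d, dropped)


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Size-weighted UPGMA agglomeration with deterministic tie-breaks.

    At each step the pair at minimum distance is joined; exact ties are
    broken by the lexicographically smallest pair of cluster labels, a
    cluster's label being its smallest leaf label.  Heights are
    ultrametric (half the join distance).
    """
    labels = list(dm.labels)
    nodes = {lab: TreeNode(name=lab) for lab in labels}
    sizes = {lab: 1 for lab in labels}
    key = {lab: lab for lab in labels}  # cluster -> smallest leaf label
    dist = {
        frozenset((a, b)): float(dm.d[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    active = set(labels)
    counter = 0
    while len(active) > 1:
        best = None
        for pair, value in dist.items():
            a, b = sorted(pair, key=lambda c: key[c])
            cand = (value, key[a], key[b])
            if best is None or cand < best[0:3]:
                best = (value, key[a], key[b], a, b)
        value, _, _, a, b = best
        height = value / 2.0
        parent = TreeNode(
            children=[
                (nodes[a], height - nodes[a].height),
                (nodes[b], height - nodes[b].height),
            ],
            height=height,
        )
        counter += 1
        new = f"__c{counter}"
        nodes[new] = parent
        sizes[new] = sizes[a] + sizes[b]
        key[new] = min(key[a], key[b])
        active -= {a, b}
        for other in active:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new, other))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        del dist[frozenset((a, b))]
        active.add(new)
    return nodes[active.pop()]


def bootstrap_support(groups: Mapping, loci: Sequence[str], n_reps: int,
                      seed: int = 0) -> TreeNode:
    """UPGMA tree with locus-bootstrap branch support.

    Loci are resampled with replacement ``n_reps`` times; support for each
    internal node of the original tree is the fraction of replicate trees
    containing the same leaf set as a clade.  ``n_reps = 0`` returns the
    tree without support annotations.
    """
    if len(loci) < 2:
        raise ValidationError("bootstrap needs at least 2 loci")
    tree = upgma_tree(nei_da_matrix(groups, loci))
    if n_reps <= 0:
        return tree
    counts = {frozenset(node.leaves()): 0 for node in tree.internal_nodes()}
    rng = np.random.default_rng(seed)
    loci = list(loci)
    for _ in range(n_reps):
        sample = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        try:
            rep_tree = upgma_tree(nei_da_matrix(groups, sample))
        except ValidationError:
            continue
        rep_clades = set(rep_tree.clades())
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in tree.internal_nodes():
        node.support = counts[frozenset(node.leaves())] / n_reps
    return tree


@dataclass
class PcaResult:
    coordinates: np.ndarray  # entity x axis
    explained_pct: np.ndarray
    entity_ids: list
    feature_names: list


def _allele_count_matrix(records: Sequence[IndividualRecord],
                         loci: Sequence[str]):
    columns = []
    for locus in loci:
        alleles = sorted({a for r in records for a in r.alleles_at(locus)})
        columns.extend((locus, a) for a in alleles)
    col_index = {c: i for i, c in enumerate(columns)}
    X = np.full((len(records), len(columns)), np.nan)
    for row, rec in enumerate(records):
        for locus in loci:
            cell = rec.cell(locus)
            scored = [a for a in cell if a != MISSING]
            if not scored:
                continue
            for c in (c for c in columns if c[0] == locus):
                X[row, col_index[c]] = 0.0
            if len(scored) == 1:
                # haploid coding 0/2, matching the self-doubling convention
                X[row, col_index[(locus, scored[0])]] = 2.0
            else:
                for a in scored:
                    X[row, col_index[(locus, a)]] += 1.0
    return X, columns


def pca_mlg(records: Sequence[IndividualRecord], loci: Sequence[str],
            n_axes: int | None = None) -> PcaResult:
    """Centred, standardized PCA of per-allele counts.

    Rows are entities (individuals or subgenome MLGs), columns are allele
    counts (diploid 0/1/2; half-scored cells coded 0/2).  Missing cells
    are imputed by the column mean; zero-variance columns are dropped
    before unit-variance scaling.
    """
    if len(records) < 2:
        raise ValidationError("PCA needs at least 2 records")
    X, columns = _allele_count_matrix(records, loci)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    std = X.std(axis=0)
    keep = std > 1e-12
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    kept_columns = [c for c, k in zip(columns, keep) if k]
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        return PcaResult(
            np.zeros((len(records), 1)), np.zeros(1),
            [r.id for r in records], kept_columns,
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_ * 100.0
    if n_axes is not None:
        coords = coords[:, :n_axes]
        explained = explained[:n_axes]
    return PcaResult(coords, explained, [r.id for r in records], kept_columns)
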