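"""Classification of genomes from their ternary gene-CNV status matrix.

Every gene in every sample carries one of three unordered states
(3 duplicated, 2 deleted, 1 not impacted).  Samples are compared by
Manhattan (Czekanowski) or Euclidean distance and embedded by classical
metric scaling (PCoA); relationships are additionally summarized as an
unrooted tree found by multi-state Fitch parsimony with random-addition
and nearest-neighbor-interchange search, in the spirit of PHYLIP's PARS.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance

from tubervar.cnv_impact import GeneImpact, STATUS_NEUTRAL
from tubervar.tree import UnrootedTree

STATE_CODES = (1, 2, 3)


@dataclass
class CnvStatusMatrix:
    """samples x genes matrix with entries in {1,2,3}."""

    samples: List[str]
    genes: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("matrix shape does not match sample/gene lists")
        if not np.isin(self.values, STATE_CODES).all():
            raise ValueError("status codes must be 1, 2 or 3")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    def row(self, sample: str) -> np.ndarray:
        return self.values[self.samples.index(sample)]

    def informative_only(self) -> "CnvStatusMatrix":
        """Drop genes with the same state in every sample (zero signal)."""
        keep = (self.values != self.values[0]).any(axis=0)
        return CnvStatusMatrix(
            samples=list(self.samples),
            genes=[g for g, k in zip(self.genes, keep) if k],
            values=self.values[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "CnvStatusMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_phylip(self, path) -> None:
        """PHYLIP-style discrete multi-state file: one digit per gene."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.samples)} {len(self.genes)}\n")
            for name, row in zip(self.samples, self.values):
                fh.write(f"{name[:10]:<10}{''.join(str(v) for v in row)}\n")


@dataclass
class DistanceMatrix:
    samples: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal must be zero")


def build_status_matrix(
    impacts: Dict[str, Sequence[GeneImpact]],
    gene_universe: Sequence[str],
) -> CnvStatusMatrix:
    """Assemble the ternary matrix from per-sample impact tables.

    Genes absent from a sample's table are treated as not impacted.
    """
    samples = list(impacts)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample IDs")
    genes = list(gene_universe)
    gene_index = {g: j for j, g in enumerate(genes)}
    values = np.full((len(samples), len(genes)), STATUS_NEUTRAL, dtype=np.int8)
    for i, s in enumerate(samples):
        for imp in impacts[s]:
            j = gene_index.get(imp.gene_id)
            if j is not None:
                values[i, j] = imp.status
    return CnvStatusMatrix(samples, genes, values)


def pairwise_distance(m: CnvStatusMatrix, metric: str = "manhattan") -> DistanceMatrix:
    """Pairwise sample distances over status vectors.

    ``manhattan`` is the Czekanowski distance sum |x_i - y_i|;
    ``euclidean`` is the usual L2 distance.
    """
    scipy_names = {"manhattan": "cityblock", "euclidean": "euclidean"}
    if metric not in scipy_names:
        raise ValueError(f"unknown metric {metric!r}")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(m.values.astype(float), metric=scipy_names[metric])
    )
    return DistanceMatrix(list(m.samples), d)


def pcoa(
    d: DistanceMatrix, n_components: int = 2
) -> Tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling (principal coordinates analysis).

    Double-centers -D^2/2, eigendecomposes, and returns the top
    ``n_components`` coordinate columns scaled by the square root of their
    (positive) eigenvalues, plus the full eigenvalue spectrum in
    descending order.  Negative eigenvalues (possible for non-Euclidean
    distances such as Manhattan) are reported but never embedded.  With a
    Euclidean distance matrix this reproduces PCA scores of the centered
    data up to component sign.
    """
    n = len(d.samples)
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    if n_components > n - 1:
        raise ValueError(f"n_components {n_components} exceeds n-1 = {n - 1}")
    sq = d.values**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ sq @ centerer
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, n_components))
    # eigenvalues within round-off of zero carry no geometry; embedding
    # them would inject noise scaled by sqrt(eps)
    floor = np.abs(eigvals).max() * 1e-12
    for k in range(n_components):
        if eigvals[k] > floor:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    return coords, eigvals


def ordination_frame(
    m: CnvStatusMatrix, metric: str = "manhattan", n_components: int = 2
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Convenience wrapper: distances -> PCoA -> tidy coordinate table."""
    d = pairwise_distance(m, metric=metric)
    coords, eigvals = pcoa(d, n_components=n_components)
    df = pd.DataFrame(
        coords,
        index=m.samples,
        columns=[f"PCo{k + 1}" for k in range(n_components)],
    )
    return df, eigvals


# ---------------------------------------------------------------------------
# Multi-state Fitch parsimony


def _leaf_masks(m: CnvStatusMatrix) -> Dict[str, np.ndarray]:
    # state k in {1,2,3} -> bit (1 << (k-1)); one uint8 per gene
    return {
        s: (1 << (m.values[i] - 1)).astype(np.uint8)
        for i, s in enumerate(m.samples)
    }


def fitch_score(tree: UnrootedTree, m: CnvStatusMatrix) -> int:
    """Minimum number of unordered state changes summed over all genes.

    Fitch's bottom-up pass with states as bitmasks, vectorized over genes;
    the score is independent of the internal node chosen as root.
    """
    tree_labels = set(tree.labels.values())
    if tree_labels != set(m.samples):
        raise ValueError("tree leaves do not match matrix samples")
    return _fitch(tree, _leaf_masks(m))


def _fitch(tree: UnrootedTree, masks: Dict[str, np.ndarray]) -> int:
    """Fitch pass over whatever leaves the tree currently has."""
    internal = [n for n in tree.adj if n not in tree.labels]
    if not internal:  # two-leaf degenerate tree
        a, b = (masks[lab] for lab in tree.labels.values())
        return int(((a & b) == 0).sum())
    root = internal[0]
    # iterative postorder over (node, parent)
    order: List[Tuple[int, int]] = []
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for c in tree.adj[node]:
            if c != parent:
                stack.append((c, node))
    node_mask: Dict[int, np.ndarray] = {}
    score = 0
    for node, parent in reversed(order):
        if node in tree.labels:
            node_mask[node] = masks[tree.labels[node]]
            continue
        children = [c for c in tree.adj[node] if c != parent]
        acc = node_mask[children[0]]
        for c in children[1:]:
            inter = acc & node_mask[c]
            union_needed = inter == 0
            score += int(union_needed.sum())
            acc = np.where(union_needed, acc | node_mask[c], inter)
        node_mask[node] = acc
    return score


def enumerate_topologies(labels: Sequence[str]) -> Iterator[UnrootedTree]:
    """All unrooted binary topologies over ``labels`` (1, 3, 15, 105, ...).

    Built by recursive edge insertion; intended for exhaustive scoring at
    small taxon counts.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def grow(tree: UnrootedTree, remaining: List[str]) -> Iterator[UnrootedTree]:
        if not remaining:
            yield tree
            return
        label, rest = remaining[0], remaining[1:]
        for a, b in list(tree.edges()):
            t2 = tree.copy()
            t2.remove_edge(a, b)
            mid = t2.new_node()
            leaf = t2.new_node(label)
            t2.add_edge(a, mid)
            t2.add_edge(mid, b)
            t2.add_edge(mid, leaf)
            yield from grow(t2, rest)

    yield from grow(UnrootedTree.star(labels[:3]), labels[3:])


def _attach_candidates(tree: UnrootedTree, label: str) -> Iterator[UnrootedTree]:
    for a, b in list(tree.edges()):
        t2 = tree.copy()
        t2.remove_edge(a, b)
        mid = t2.new_node()
        leaf = t2.new_node(label)
        t2.add_edge(a, mid)
        t2.add_edge(mid, b)
        t2.add_edge(mid, leaf)
        yield t2


def _nni_neighbors(tree: UnrootedTree) -> Iterator[UnrootedTree]:
    """The two nearest-neighbor interchanges of every internal edge."""
    for u, v in tree.internal_edges():
        u_sub = sorted(c for c in tree.adj[u] if c != v)
        v_sub = sorted(c for c in tree.adj[v] if c != u)
        if len(u_sub) < 2 or len(v_sub) < 2:
            continue
        b = u_sub[1]
        for c in v_sub:
            t2 = tree.copy()
            t2.remove_edge(u, b)
            t2.remove_edge(v, c)
            t2.add_edge(u, c)
            t2.add_edge(v, b)
            yield t2


def search_parsimony_tree(
    m: CnvStatusMatrix, seed: int = 0, n_restarts: int = 10
) -> Tuple[UnrootedTree, int]:
    """Heuristic minimum-parsimony tree over the matrix samples.

    Each restart adds taxa in random order by greedy stepwise addition,
    then hill-climbs with nearest-neighbor interchanges to a local
    optimum; the best tree over all restarts is returned together with its
    Fitch score.  Ties at every step break on the canonical newick string,
    so the result is deterministic given (seed, n_restarts).
    """
    if len(m.samples) < 4:
        raise ValueError("parsimony search needs at least 4 samples")
    rng = random.Random(seed)
    masks = _leaf_masks(m)
    best_tree: UnrootedTree | None = None
    best_score = None
    best_newick = None
    for _ in range(n_restarts):
        order = list(m.samples)
        rng.shuffle(order)
        tree = UnrootedTree.star(order[:3])
        for label in order[3:]:
            tree = min(
                _attach_candidates(tree, label),
                key=lambda t: (_fitch(t, masks), t.to_newick()),
            )
        score = _fitch(tree, masks)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(tree):
                s = _fitch(cand, masks)
                if s < score:
                    tree, score = cand, s
                    improved = True
                    break
        key = (score, tree.to_newick())
        if best_score is None or key < (best_score, best_newick):
            best_tree, best_score, best_newick = tree, score, key[1]
    assert best_tree is not None
    return best_tree, int(best_score)


def parsimony_score_bounds(m: CnvStatusMatrix) -> Tuple[int, int]:
    """(lower, upper) bounds on the minimum parsimony score of any tree.

    Per gene: at least (distinct states - 1) changes are needed on any
    tree, and assigning every internal node the modal state never needs
    more than the number of taxa carrying a non-modal state.
    """
    lower = upper = 0
    for j in range(len(m.genes)):
        col = m.values[:, j]
        counts = np.bincount(col, minlength=4)[1:]
        distinct = int((counts > 0).sum())
        lower += distinct - 1
        upper += int(len(col) - counts.max())
    return lower, upper
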