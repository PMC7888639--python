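"""Genetic distances and neighbor-joining trees.

Individual-level dissimilarity is allele sharing: at each locus two diploid
genotypes share 2 - |dosage_i - dosage_j| of their 2·2 possible allele-copy
matches, and the dissimilarity is one minus the shared fraction over loci
called in both individuals.  Population-level distance is Nei's standard
genetic distance D = -ln(J_XY / sqrt(J_X J_Y)) on allele frequencies.
Trees are built with the Saitou–Nei neighbor-joining algorithm, which
reconstructs additive distance matrices exactly.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import dendropy
import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    squared: bool = False  # True when entries are on a squared scale

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distance matrix must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, squared: bool = False) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float),
                   squared=squared)


def _pairwise_overlap_sums(calls: np.ndarray, power: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (sum over shared loci of |g_i - g_j|**power, shared locus count)."""
    called = (calls != MISSING)
    X = np.where(called, calls, 0).astype(float)
    W = called.astype(float)
    X2 = X**2
    overlap = W @ W.T
    cross = X @ X.T
    # sum over shared loci of g_i^2 and g_j^2 needs masking by the partner
    gi2 = X2 @ W.T
    s2 = gi2 + gi2.T - 2.0 * cross
    if power == 2:
        return s2, overlap
    if power == 1:
        # |g_i - g_j| differs from (g_i-g_j)^2 only for the (0,2) pair,
        # where the squared term counts 4 instead of 2
        opp = _count_opposite_homozygotes(calls, called)
        return s2 - 2.0 * opp, overlap
    raise ValueError("power must be 1 or 2")


def _count_opposite_homozygotes(calls: np.ndarray, called: np.ndarray) -> np.ndarray:
    hom0 = ((calls == 0) & called).astype(float)
    hom2 = ((calls == 2) & called).astype(float)
    return hom0 @ hom2.T + hom2 @ hom0.T


def allele_sharing_dissimilarity(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Simple codominant allele-sharing dissimilarity between accessions.

    d(i,j) = 1 - shared/(2 L_ij) where shared = Σ_l (2 - |g_i - g_j|) over
    the L_ij loci called in both; raises when a pair has no shared loci.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    s1, overlap = _pairwise_overlap_sums(matrix.calls, power=1)
    off = ~np.eye(matrix.n_accessions, dtype=bool)
    if np.any(overlap[off] == 0):
        raise ValueError("some accession pair has no loci called in both")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = s1 / (2.0 * overlap)
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)  # symmetrize away float noise
    return DistanceMatrix(labels=list(matrix.accessions), values=d, squared=False)


def nei_distance(p_x: np.ndarray, p_y: np.ndarray) -> float:
    """Nei's standard genetic distance between two populations.

    ``p_x``/``p_y`` are per-locus alternate-allele frequencies at the same
    loci.  D = -ln(J_XY / sqrt(J_X J_Y)) with J the mean over loci of the
    within/between sums of squared (products of) allele frequencies.
    Returns +inf with a warning when no alleles are shared anywhere.
    """
    x = np.asarray(p_x, float)
    y = np.asarray(p_y, float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must cover the same loci")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    jx = float(np.mean(x**2 + (1 - x) ** 2))
    jy = float(np.mean(y**2 + (1 - y) ** 2))
    if jxy == 0:
        warnings.warn("populations share no alleles; Nei distance is +inf")
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(freqs_by_pop: dict) -> DistanceMatrix:
    """Pairwise Nei distances from a {label: PopAlleleFreqs} mapping."""
    labels = [str(k) for k in freqs_by_pop]
    vecs = [freqs_by_pop[k].p for k in freqs_by_pop]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(vecs[i], vecs[j])
    return DistanceMatrix(labels=labels, values=d, squared=False)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive distance matrices.

    Ties in the rate-corrected selection criterion are broken toward the
    lexicographically smallest label pair (labels of internal nodes are the
    smallest leaf label in their clade), which keeps runs reproducible.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch; each clamp is logged.
    """
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = d.values.astype(float).copy()
    taxa = dendropy.TaxonNamespace(d.labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in d.labels]
    names = list(d.labels)  # sort key per active node: smallest leaf label
    active = list(range(n))

    def clamp(v_i: float, v_j: float, pair) -> tuple[float, float]:
        if v_i < 0:
            logger.info("NJ: clamped negative branch %.4g at %s", v_i, pair)
            v_j += v_i
            v_i = 0.0
        if v_j < 0:
            logger.info("NJ: clamped negative branch %.4g at %s", v_j, pair)
            v_i += v_j
            v_j = 0.0
        return max(v_i, 0.0), max(v_j, 0.0)

    while len(active) > 2:
        m = len(active)
        act = np.asarray(active)
        sub = D[np.ix_(act, act)]
        rs = sub.sum(axis=1)
        qmat = (m - 2) * sub - rs[:, None] - rs[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = qmat[iu]
        qmin = qvals.min()
        # tie-break among near-minimal pairs: lexicographically smallest labels
        tied = np.flatnonzero(qvals <= qmin + 1e-12)
        best_key, best = None, None
        for t in tied:
            ai, aj = iu[0][t], iu[1][t]
            i, j = int(act[ai]), int(act[aj])
            key = tuple(sorted((names[i], names[j])))
            if best_key is None or key < best_key:
                best_key, best = key, (i, j)
        i, j = best
        r = {k: float(rs[np.flatnonzero(act == k)[0]]) for k in (i, j)}
        v_i = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        v_j = D[i, j] - v_i
        v_i, v_j = clamp(v_i, v_j, best_key)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = v_i
        nodes[j].edge.length = v_j
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.vstack([D, new_row[None, :]])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    # final edge split arbitrarily but reproducibly: all length on one side
    # would bias path lengths, so split evenly
    half = max(D[i, j], 0.0) / 2.0
    nodes[i].edge.length = half
    nodes[j].edge.length = half
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    vals = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            vals[a, b] = vals[b, a] = pdm.distance(taxa[labels[a]], taxa[labels[b]])
    return DistanceMatrix(labels=labels, values=vals)
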