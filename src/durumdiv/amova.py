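"""Two-level hierarchical AMOVA on squared genotype distances.

The analysis partitions the total molecular variance of a panel into
between- and within-population components from pairwise squared distances
(the codominant-genotypic convention: per locus, half the squared Euclidean
distance between allele-count vectors, i.e. (dosage_i - dosage_j)² —
identical genotypes 0, homozygote vs heterozygote 1, opposite homozygotes
4).  The fixation index is Φ = σ²_between / (σ²_between + σ²_within),
significance comes from free permutation of individuals among populations,
and gene flow follows the island-model relation Nm = [(1/FST) - 1]/4.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, _pairwise_overlap_sums
from .io import GenotypeMatrix
from .partition import PopulationPartition


def genotype_sq_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise squared genotype distances, rescaled for missingness.

    d²(i,j) = Σ over loci called in both of (g_i - g_j)², multiplied by
    L / L_ij so that pairs with missing data are comparable to complete
    pairs (average-distance completion).
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    s2, overlap = _pairwise_overlap_sums(matrix.calls, power=2)
    off = ~np.eye(matrix.n_accessions, dtype=bool)
    if np.any(overlap[off] == 0):
        raise ValueError("some accession pair has no loci called in both")
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = s2 * (matrix.n_loci / overlap)
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(0.5 * (d2 + d2.T), 0.0, None)
    return DistanceMatrix(labels=list(matrix.accessions), values=d2, squared=True)


@dataclasses.dataclass
class AmovaTable:
    """df / SS / variance components / percentages plus Φ, Nm and p-value."""

    table: pd.DataFrame  # rows: between, within; columns: source, df, ss, ms
    sigma2_between_raw: float
    sigma2_between: float  # truncated at 0
    sigma2_within: float
    percent_between: float
    percent_within: float
    fst: float
    fst_raw: float
    nm: float
    p_value: float | None = None
    n_permutations: int | None = None

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["variance_component"] = [self.sigma2_between, self.sigma2_within]
        df["variance_component_raw"] = [self.sigma2_between_raw, self.sigma2_within]
        df["percent"] = [self.percent_between, self.percent_within]
        df["fst"] = [self.fst, np.nan]
        df["nm"] = [self.nm, np.nan]
        df["p_value"] = [self.p_value, np.nan]
        df["n_permutations"] = [self.n_permutations, np.nan]
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _phi_and_components(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Return (SS_total, SS_within, sigma2_b_raw, sigma2_w, phi)."""
    N = values.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    ss_total = values.sum() / 2.0 / N
    ss_within = 0.0
    sizes = []
    for u in uniq:
        idx = labels == u
        n_p = int(idx.sum())
        sizes.append(n_p)
        ss_within += values[np.ix_(idx, idx)].sum() / 2.0 / n_p
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    sigma2_w = ss_within / df_w if df_w > 0 else np.nan
    sizes = np.asarray(sizes, float)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sigma2_b = (ms_b - sigma2_w) / n0
    # raw (untruncated) statistic: ties at a truncation floor would distort
    # the permutation distribution
    denom = sigma2_b + sigma2_w
    phi = sigma2_b / denom if denom > 0 else np.nan
    return ss_total, ss_within, sigma2_b, sigma2_w, phi


def amova_two_level(
    d2: DistanceMatrix,
    partition: PopulationPartition,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> AmovaTable:
    """Two-level AMOVA of a squared distance matrix given a hard partition.

    Negative between-population variance components are truncated to zero
    for Φ and the percentage partition; the raw value is retained.  When
    ``n_permutations`` is given, a permutation p-value is attached.
    """
    labels = partition.label_array(d2.labels)
    N = d2.n
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if k >= N:
        raise ValueError("AMOVA needs within-population replication (N > k)")
    ss_total, ss_within, sigma2_b_raw, sigma2_w, phi = _phi_and_components(
        d2.values, labels
    )
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, N - k
    table = pd.DataFrame(
        {
            "source": ["between_populations", "within_populations"],
            "df": [df_b, df_w],
            "ss": [ss_between, ss_within],
            "ms": [ss_between / df_b, ss_within / df_w],
        }
    )
    sigma2_b = max(sigma2_b_raw, 0.0)
    total = sigma2_b + sigma2_w
    if not np.isfinite(total) or total <= 0:
        warnings.warn("degenerate panel: total variance is zero; FST undefined")
        pct_b = pct_w = fst = np.nan
    else:
        pct_b = 100.0 * sigma2_b / total
        pct_w = 100.0 * sigma2_w / total
        fst = sigma2_b / total
    result = AmovaTable(
        table=table,
        sigma2_between_raw=sigma2_b_raw,
        sigma2_between=sigma2_b,
        sigma2_within=sigma2_w,
        percent_between=pct_b,
        percent_within=pct_w,
        fst=fst,
        fst_raw=sigma2_b_raw / (sigma2_b_raw + sigma2_w) if total > 0 else np.nan,
        nm=gene_flow(fst) if np.isfinite(fst) and fst > 0 else np.nan,
    )
    if n_permutations is not None:
        result.p_value = permutation_test(
            d2, partition, n_perm=n_permutations, seed=seed if seed is not None else 0
        )
        result.n_permutations = n_permutations
    return result


def permutation_test(
    d2: DistanceMatrix,
    partition: PopulationPartition,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for Φ: individuals shuffled wholesale among
    populations; p = (1 + #{Φ_perm >= Φ_obs}) / (1 + n_perm)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = partition.label_array(d2.labels)
    *_, phi_obs = _phi_and_components(d2.values, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        *_, phi_p = _phi_and_components(d2.values, perm)
        if np.isnan(phi_p):
            phi_p = -np.inf
        if phi_p >= phi_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def gene_flow(fst: float) -> float:
    """Island-model gene flow Nm = [(1/FST) - 1] / 4 for 0 < FST <= 1."""
    if not (0.0 < fst <= 1.0):
        raise ValueError("gene flow defined only for FST in (0, 1]")
    return ((1.0 / fst) - 1.0) / 4.0
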