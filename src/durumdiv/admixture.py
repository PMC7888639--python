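"""Bayesian admixture clustering, marginal-likelihood scoring and Evanno ΔK.

The model is the classic admixture formulation with uncorrelated cluster
allele frequencies: each individual i has ancestry proportions q_i over K
clusters (Dirichlet(alpha) prior, alpha fixed) and each cluster k has an
alternate-allele frequency p_kl per locus (Beta(lambda, lambda) prior).
Every observed allele copy originates from a latent cluster z; the model
is fitted by pure Gibbs sampling (see :mod:`durumdiv._sampler`).

The per-K model score ("LnP(D)") is the standard approximation
mean(lnL) - var(lnL)/2 over post-burn-in sweeps — not a true marginal
likelihood, but the quantity the ΔK model-selection heuristic is defined
on.  ΔK(K) = |mean_L(K+1) - 2 mean_L(K) + mean_L(K-1)| / sd_L(K), computed
over replicate runs, peaks at the uppermost level of population structure.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._sampler import gibbs_admixture
from .io import GenotypeMatrix
from .partition import PopulationPartition


@dataclasses.dataclass
class McmcSettings:
    """MCMC run design.

    Defaults mirror a conventional full-scale analysis (10,000 burn-in,
    100,000 recorded sweeps, K = 1..10, 5 replicates);
    :meth:`test_scale` gives a reduced design for simulation studies.
    ``sweeps`` counts post-burn-in iterations.
    """

    burn_in: int = 10_000
    sweeps: int = 100_000
    k_range: tuple[int, int] = (1, 10)
    replicates: int = 5
    seed: int = 0
    alpha: float = 1.0
    lambda_: float = 1.0

    def __post_init__(self):
        if self.burn_in < 0 or self.sweeps < 1 or self.replicates < 1:
            raise ValueError("invalid MCMC settings")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")

    @classmethod
    def test_scale(cls, **overrides) -> "McmcSettings":
        """Reduced design: 500 burn-in, 2000 sweeps, K = 1..5, 3 replicates."""
        params = dict(burn_in=500, sweeps=2000, k_range=(1, 5), replicates=3)
        params.update(overrides)
        return cls(**params)


@dataclasses.dataclass
class AdmixtureResult:
    """Posterior summaries of one (K, replicate) run."""

    k: int
    replicate: int
    seed: int
    q_mean: np.ndarray  # (N, k), rows sum to 1
    p_mean: np.ndarray  # (k, L) cluster allele frequencies
    lnpd: float  # mean(lnL) - var(lnL)/2 model score
    accessions: list[str]


def fit_admixture(
    matrix: GenotypeMatrix,
    k: int,
    settings: McmcSettings,
    replicate: int = 1,
    seed: int | None = None,
) -> AdmixtureResult:
    """Fit the admixture model at a fixed K by Gibbs sampling.

    Missing allele copies contribute to no counts and no likelihood terms.
    Reproducible from the seed (``settings.seed`` unless overridden).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.n_accessions == 0 or matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    run_seed = int(settings.seed if seed is None else seed) % (2**32)
    q_mean, pt_mean, lnl = gibbs_admixture(
        np.ascontiguousarray(matrix.calls, dtype=np.int8),
        k,
        settings.burn_in,
        settings.sweeps,
        float(settings.alpha),
        float(settings.lambda_),
        run_seed,
    )
    lnl = np.asarray(lnl)
    lnpd = float(lnl.mean() - lnl.var(ddof=1) / 2.0) if len(lnl) > 1 else float(lnl.mean())
    return AdmixtureResult(
        k=k,
        replicate=replicate,
        seed=run_seed,
        q_mean=q_mean,
        p_mean=pt_mean.T.copy(),
        lnpd=lnpd,
        accessions=list(matrix.accessions),
    )


def run_structure(matrix: GenotypeMatrix, settings: McmcSettings) -> list[AdmixtureResult]:
    """Fit all (K, replicate) combinations of ``settings``.

    Per-run seeds are spawned deterministically from ``settings.seed``.
    """
    ss = np.random.SeedSequence(settings.seed)
    k_lo, k_hi = settings.k_range
    n_runs = (k_hi - k_lo + 1) * settings.replicates
    seeds = ss.generate_state(n_runs)
    results, idx = [], 0
    for k in range(k_lo, k_hi + 1):
        for rep in range(1, settings.replicates + 1):
            results.append(
                fit_admixture(matrix, k, settings, replicate=rep, seed=int(seeds[idx]))
            )
            idx += 1
    return results


@dataclasses.dataclass
class DeltaKTable:
    """Evanno table over K plus the selected K."""

    table: pd.DataFrame  # k, n_replicates, mean_lnpd, sd_lnpd, l_prime, l_doubleprime_abs, delta_k
    chosen_k: int
    uninformative: bool = False  # True when every |L''| is zero (flat likelihood)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["chosen"] = df["k"] == self.chosen_k
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def evanno_deltaK(results: list[AdmixtureResult]) -> DeltaKTable:
    """Evanno second-difference statistic over a K-sweep of replicate runs.

    ΔK is defined only for interior K (both neighbours present) with
    positive replicate standard deviation; K values where sd = 0 are
    flagged (NaN) and excluded from the argmax.  Ties break toward the
    smallest K.
    """
    by_k: dict[int, list[float]] = {}
    for r in results:
        by_k.setdefault(r.k, []).append(r.lnpd)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need at least 3 consecutive K values")
    for k in ks:
        if len(by_k[k]) < 2:
            raise ValueError(f"K={k}: need at least 2 replicates")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        interior = (k - 1 in mean_l) and (k + 1 in mean_l)
        l_prime = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        l_pp = (
            abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1]) if interior else np.nan
        )
        delta = l_pp / sd_l[k] if interior and sd_l[k] > 0 else np.nan
        rows.append((k, len(by_k[k]), mean_l[k], sd_l[k], l_prime, l_pp, delta))
    df = pd.DataFrame(
        rows,
        columns=[
            "k", "n_replicates", "mean_lnpd", "sd_lnpd",
            "l_prime", "l_doubleprime_abs", "delta_k",
        ],
    )
    valid = df["delta_k"].notna()
    if not valid.any():
        raise ValueError("delta-K undefined everywhere (zero replicate variance)")
    sub = df[valid]
    best = sub.loc[sub["delta_k"].idxmax()]
    # ties toward smallest K
    tied = sub[np.isclose(sub["delta_k"], best["delta_k"], rtol=0, atol=0)]
    chosen = int(tied["k"].min())
    uninformative = bool(np.all(sub["l_doubleprime_abs"] == 0))
    if uninformative:
        chosen = int(sub["k"].min())
    return DeltaKTable(table=df, chosen_k=chosen, uninformative=uninformative)


def best_replicate(results: list[AdmixtureResult], k: int) -> AdmixtureResult:
    """The replicate with the highest model score at a given K."""
    at_k = [r for r in results if r.k == k]
    if not at_k:
        raise ValueError(f"no results at K={k}")
    return max(at_k, key=lambda r: r.lnpd)


def hard_assign(result: AdmixtureResult) -> PopulationPartition:
    """Assign each accession to the cluster maximising its ancestry.

    Ties go to the smallest cluster index; the maximal q is kept as an
    admixture-confidence value on the partition.
    """
    q = result.q_mean
    labels = np.argmax(q, axis=1) + 1  # argmax takes the first (smallest) on ties
    conf = q[np.arange(q.shape[0]), labels - 1]
    return PopulationPartition(
        assignments={a: int(c) for a, c in zip(result.accessions, labels)},
        confidence={a: float(v) for a, v in zip(result.accessions, conf)},
    )
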