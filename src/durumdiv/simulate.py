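"""Synthetic SNP panel generator for a selfing crop under island-model divergence.

Allele frequencies follow the Balding–Nichols model: each locus has an
ancestral frequency p drawn uniformly within configurable bounds, and each
deme's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so that deme frequencies
have mean p and variance F·p(1-p) — F is the expected fixation index
between demes.

Genotypes are drawn per individual and locus from the deme frequency, with
an inbreeding (selfing-equilibrium) coefficient F_IS: with probability F_IS
the two allele copies of an individual are identical by descent (one draw,
duplicated), otherwise they are independent.  F_IS = 0 gives
Hardy–Weinberg Binomial(2, p) sampling; the default 0.95 reflects a
predominantly selfing crop and leaves ~2% residual heterozygosity.  With a
positive ``admixture_alpha`` each individual receives Dirichlet deme
weights and every independent allele-copy draw first picks its deme of
origin from those weights.

Missing calls are injected completely at random.  All randomness streams
from a single seeded generator, so a config reproduces its panel exactly.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io import CHROMOSOMES, MARKER_COLUMNS, MISSING, GenotypeMatrix
from .partition import PopulationPartition

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimConfig:
    """Parameters of one synthetic panel.

    Attributes
    ----------
    n_demes : number of source populations (the true K).
    deme_sizes : individuals per deme; sum >= 2.
    n_loci : number of biallelic SNP loci.
    fst_param : Balding–Nichols divergence parameter F, in (0, 1) exclusive.
    ancestral_freq_bounds : uniform bounds for ancestral frequencies,
        default (0.1, 0.9) so the MAF filter does not decimate the panel.
    admixture_alpha : Dirichlet concentration of individual deme weights;
        0 means every individual belongs wholly to its deme.
    missing_rate : MCAR no-call fraction, in [0, 1).
    inbreeding : selfing-equilibrium F_IS in [0, 1]; controls residual
        heterozygosity (~(1 - F_IS)·2pq).
    seed : integer seed for the single random generator.
    """

    n_demes: int
    deme_sizes: tuple[int, ...]
    n_loci: int
    fst_param: float
    ancestral_freq_bounds: tuple[float, float] = (0.1, 0.9)
    admixture_alpha: float = 0.0
    missing_rate: float = 0.02
    inbreeding: float = 0.95
    seed: int = 0

    def __post_init__(self):
        self.deme_sizes = tuple(int(s) for s in self.deme_sizes)
        if self.n_demes != len(self.deme_sizes):
            raise ValueError("n_demes must equal len(deme_sizes)")
        if any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme sizes must be positive")
        if sum(self.deme_sizes) < 2:
            raise ValueError("need at least 2 individuals in total")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 < self.fst_param < 1.0):
            raise ValueError("fst_param must lie strictly inside (0, 1)")
        lo, hi = self.ancestral_freq_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_bounds must be ordered inside (0, 1)")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be nonnegative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding must be in [0, 1]")


@dataclasses.dataclass
class TruthBundle:
    """Ground truth behind a simulated panel."""

    partition: PopulationPartition
    deme_freqs: np.ndarray  # (K, L) alternate-allele frequencies
    ancestral_freqs: np.ndarray  # (L,)


# Table-calibrated presets: a 285-accession panel splitting 207/78 at
# FST 0.19, and its 215-landrace subset splitting 45/27/47/96 at FST 0.24.
_PRESETS = {
    "sp_like": dict(n_demes=2, deme_sizes=(207, 78), fst_param=0.19),
    "etdwl_like": dict(n_demes=4, deme_sizes=(45, 27, 47, 96), fst_param=0.24),
}


def preset(name: str, **overrides) -> SimConfig:
    """Named panel configurations mirroring the study panel and its landrace subset.

    ``sp_like``: 2 demes of (207, 78) accessions, F = 0.19.
    ``etdwl_like``: 4 demes of (45, 27, 47, 96) accessions, F = 0.24.
    Both default to 1000 loci (scaled down from the 11,919-SNP panel).
    Keyword overrides are applied on top of the preset.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[name], n_loci=1000)
    params.update(overrides)
    return SimConfig(**params)


def bounds_for_target_he(he: float) -> tuple[float, float]:
    """Uniform frequency bounds (0.5 - a, 0.5 + a) with E[2p(1-p)] = ``he``.

    For p ~ Uniform(0.5 - a, 0.5 + a), E[He] = 0.5 - 2a²/3, so
    a = sqrt(1.5 (0.5 - he)).  Requires 0 < he < 0.5.
    """
    if not (0.0 < he < 0.5):
        raise ValueError("target He must lie in (0, 0.5)")
    a = math.sqrt(1.5 * (0.5 - he))
    return (0.5 - a, 0.5 + a)


def _marker_table(n_loci: int, rng: np.random.Generator) -> pd.DataFrame:
    """Markers spread evenly over the 14 chromosomes with increasing positions."""
    chroms = [CHROMOSOMES[j % len(CHROMOSOMES)] for j in range(n_loci)]
    order = np.argsort([CHROMOSOMES.index(c) for c in chroms], kind="stable")
    chroms = [chroms[i] for i in order]
    pos, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * 100_000)
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    return pd.DataFrame(
        {
            "marker_id": [f"snp{j + 1:06d}" for j in range(n_loci)],
            "chromosome": chroms,
            "position_bp": pos,
            "allele_ref": _NUCLEOTIDES[ref_idx],
            "allele_alt": _NUCLEOTIDES[alt_idx],
        },
        columns=MARKER_COLUMNS,
    )


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthBundle]:
    """Draw one genotype panel and its ground truth from ``config``."""
    rng = np.random.default_rng(config.seed)
    K, L = config.n_demes, config.n_loci
    N = sum(config.deme_sizes)
    F = config.fst_param

    lo, hi = config.ancestral_freq_bounds
    p_anc = rng.uniform(lo, hi, size=L)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    deme_freqs = rng.beta(a, b, size=(K, L))

    deme_of = np.repeat(np.arange(K), config.deme_sizes)

    if config.admixture_alpha > 0:
        weights = rng.dirichlet(np.full(K, config.admixture_alpha), size=N)
    else:
        weights = np.zeros((N, K))
        weights[np.arange(N), deme_of] = 1.0
    cum_w = np.cumsum(weights, axis=1)

    def draw_copy():
        """One allele copy per (individual, locus): deme of origin, then allele."""
        if config.admixture_alpha > 0:
            u = rng.random((N, L))
            z = (u[:, :, None] > cum_w[:, None, :]).sum(axis=2)
        else:
            z = np.broadcast_to(deme_of[:, None], (N, L))
        freq = deme_freqs[z, np.arange(L)[None, :]]
        allele = rng.random((N, L)) < freq
        return allele.astype(np.int8)

    a1 = draw_copy()
    a2 = draw_copy()
    autozygous = rng.random((N, L)) < config.inbreeding
    a2 = np.where(autozygous, a1, a2)
    calls = (a1 + a2).astype(np.int8)

    if config.missing_rate > 0:
        calls[rng.random((N, L)) < config.missing_rate] = MISSING

    width = max(3, len(str(N)))
    accessions = [f"acc{i + 1:0{width}d}" for i in range(N)]
    matrix = GenotypeMatrix(
        calls=calls, accessions=accessions, markers=_marker_table(L, rng)
    )
    truth = TruthBundle(
        partition=PopulationPartition(
            {acc: int(d) + 1 for acc, d in zip(accessions, deme_of)}
        ),
        deme_freqs=deme_freqs,
        ancestral_freqs=p_anc,
    )
    return matrix, truth
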