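"""Per-population genetic diversity indices.

For each population, per-locus allele frequencies Pi are estimated from
the non-missing calls of its members, and four indices are reported:

* Shannon's information index  I  = -Σ Pi ln Pi   (over the two alleles)
* expected heterozygosity      He = 1 - Σ Pi²
* unbiased heterozygosity      uHe = [n/(n-1)] He  (small-sample correction,
  applied per locus with that locus's number of called individuals; the
  allele-copies convention 2n/(2n-1) is available via ``correction``)
* percentage of polymorphic loci  PPL = 100 · (#loci with both alleles
  observed in the population) / L

Per-locus values are averaged over all loci retained after QC, including
loci monomorphic within the population (which contribute zeros) — this is
how PPL < 100 can coexist with nonzero averages.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .partition import PopulationPartition

DIVERSITY_COLUMNS = ["population", "N", "I", "He", "uHe", "PPL"]


@dataclasses.dataclass
class PopAlleleFreqs:
    """Per-locus alternate-allele frequencies of one population."""

    population: str
    p: np.ndarray  # (L,) alternate-allele frequency; NaN where no calls
    n_called: np.ndarray  # (L,) individuals with calls


def pop_allele_freqs(
    matrix: GenotypeMatrix, partition: PopulationPartition
) -> dict[int, PopAlleleFreqs]:
    """Allele frequencies per population from that population's members."""
    out = {}
    acc_index = {a: i for i, a in enumerate(matrix.accessions)}
    for label in partition.labels():
        rows = [acc_index[a] for a in partition.members(label) if a in acc_index]
        calls = matrix.calls[rows, :]
        called = calls != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(
                n_called > 0,
                np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called),
                np.nan,
            )
        out[label] = PopAlleleFreqs(population=str(label), p=p, n_called=n_called)
    return out


def _per_locus_shannon(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    return terms


def shannon_index(freqs: PopAlleleFreqs) -> float:
    """Mean over loci of -Σ Pi ln Pi; zero-frequency alleles contribute 0."""
    return float(np.nanmean(_per_locus_shannon(freqs.p)))


def expected_het(freqs: PopAlleleFreqs) -> float:
    """Mean over loci of 1 - p² - q²."""
    p = freqs.p
    return float(np.nanmean(1.0 - p**2 - (1.0 - p) ** 2))


def unbiased_het(he: float, n: float) -> float:
    """Apply the small-sample correction n/(n-1) to an He value."""
    if n < 2:
        raise ValueError("unbiased He undefined for n < 2")
    return he * n / (n - 1.0)


def _mean_uhe(freqs: PopAlleleFreqs, correction: str) -> float:
    p = freqs.p
    he = 1.0 - p**2 - (1.0 - p) ** 2
    n = freqs.n_called.astype(float)
    if correction == "individuals":
        base = n
    elif correction == "allele_copies":
        base = 2.0 * n
    else:
        raise ValueError("correction must be 'individuals' or 'allele_copies'")
    ok = base >= 2
    if not ok.all():
        warnings.warn(
            f"population {freqs.population}: {int((~ok).sum())} locus/loci with <2 "
            "callable units excluded from uHe"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        uhe = np.where(ok, he * base / (base - 1.0), np.nan)
    return float(np.nanmean(uhe))


def ppl(freqs: PopAlleleFreqs) -> float:
    """Percentage of loci with both alleles observed in the population."""
    p = freqs.p
    poly = (p > 0) & (p < 1)
    return float(100.0 * poly.sum() / p.size)


def diversity_table(
    matrix: GenotypeMatrix,
    partition: PopulationPartition,
    correction: str = "individuals",
) -> pd.DataFrame:
    """Per-population N, I, He, uHe and PPL (full precision; round for display).

    A final ``mean`` row averages the index columns across populations
    (the cross-population mean PPL etc.).
    """
    freqs = pop_allele_freqs(matrix, partition)
    rows = []
    for label, f in freqs.items():
        n_members = len(partition.members(label))
        if n_members == 0 or np.isnan(f.p).all():
            warnings.warn(f"population {label}: no usable data; NaN row")
            rows.append((str(label), n_members, np.nan, np.nan, np.nan, np.nan))
            continue
        rows.append(
            (
                str(label),
                n_members,
                shannon_index(f),
                expected_het(f),
                _mean_uhe(f, correction),
                ppl(f),
            )
        )
    df = pd.DataFrame(rows, columns=DIVERSITY_COLUMNS)
    mean_row = ["mean", int(df["N"].sum())] + [
        float(df[c].mean()) for c in ["I", "He", "uHe", "PPL"]
    ]
    return pd.concat(
        [df, pd.DataFrame([mean_row], columns=DIVERSITY_COLUMNS)], ignore_index=True
    )
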