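"""Per-locus statistics, marker filters, PIC selection, naive imputation,
and chromosome distribution summaries.

The exclusion filters mirror standard SNP-array practice for inbred crop
panels: markers with minor allele frequency below 5%, missingness above
10% or heterozygosity above 12.5% are dropped (thresholds themselves are
kept — exclusion is strict).  Marker informativeness uses the biallelic
polymorphic information content PIC = 1 - (p² + q²) - 2p²q², maximal at
0.375 for p = 0.5.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CHROMOSOMES, MISSING, GenotypeMatrix

QC_COLUMNS = [
    "marker_id", "n_called", "maf", "missing_rate", "het_rate", "pic", "kept", "reason",
]


def locus_stats(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
    het_max: float = 0.125,
) -> pd.DataFrame:
    """Per-locus QC report: call counts, MAF, missingness, het rate, PIC.

    ``kept`` applies the three filters conjunctively; ``reason`` records the
    first failing filter in the fixed order MAF, missing, het (the kept set
    does not depend on this order).  Loci with zero calls have undefined
    MAF/het/PIC (NaN) and fail the missing filter.
    """
    if matrix.n_accessions < 1:
        raise ValueError("need at least one accession")
    calls = matrix.calls
    N = matrix.n_accessions
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    alt_copies = np.where(called, calls, 0).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt_copies / (2.0 * n_called), np.nan)
        het_rate = np.where(n_called > 0, n_het / n_called, np.nan)
    maf = np.minimum(p, 1.0 - p)
    missing_rate = 1.0 - n_called / N
    q = 1.0 - p
    pic = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2

    fail_maf = ~(maf >= maf_min)  # NaN-aware: undefined MAF counts as failing
    fail_missing = missing_rate > missing_max
    fail_het = ~(het_rate <= het_max)
    # zero-call loci: attributed to the missing filter, as MAF is undefined
    zero = n_called == 0
    fail_maf &= ~zero

    kept = ~(fail_maf | fail_missing | fail_het)
    reason = np.where(
        fail_maf, "maf", np.where(fail_missing, "missing", np.where(fail_het, "het", ""))
    )
    return pd.DataFrame(
        {
            "marker_id": matrix.markers["marker_id"].to_numpy(),
            "n_called": n_called,
            "maf": maf,
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "pic": pic,
            "kept": kept,
            "reason": reason,
        },
        columns=QC_COLUMNS,
    )


def apply_filters(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
    het_max: float = 0.125,
) -> GenotypeMatrix:
    """Drop loci with maf < ``maf_min``, missingness > ``missing_max`` or
    heterozygosity > ``het_max`` (boundary values survive)."""
    if not (0 <= maf_min <= 0.5 and 0 <= missing_max <= 1 and 0 <= het_max <= 1):
        raise ValueError("filter thresholds out of range")
    report = locus_stats(matrix, maf_min=maf_min, missing_max=missing_max, het_max=het_max)
    keep = report["kept"].to_numpy()
    if not keep.any():
        raise ValueError("all loci removed by QC filters: empty panel")
    return matrix.subset_loci(keep)


def impute_missing(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by Binomial(2, p̂) draws at each locus's allele frequency.

    A deliberately naive, seeded stand-in for haplotype-based imputation:
    downstream statistics here depend on allele frequencies only.  Every
    locus must have at least one call (run :func:`apply_filters` first).
    """
    calls = matrix.calls.copy()
    called = calls != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise ValueError(
            "locus with no calls cannot be imputed; run apply_filters first"
        )
    p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
    rng = np.random.default_rng(seed)
    miss_i, miss_j = np.nonzero(~called)
    calls[miss_i, miss_j] = rng.binomial(2, p[miss_j]).astype(np.int8)
    return GenotypeMatrix(
        calls=calls,
        accessions=list(matrix.accessions),
        markers=matrix.markers.copy(),
        origins=matrix.origins,
    )


def select_informative(report: pd.DataFrame, pic_min: float = 0.35) -> list[str]:
    """Marker ids with PIC >= ``pic_min``, in genome order."""
    mask = report["pic"].to_numpy() >= pic_min
    return list(report.loc[mask, "marker_id"])


def chromosome_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """SNP counts per chromosome and per genome (A, B) with percentages.

    One row per chromosome 1A..7B plus 'unknown' (when present) and two
    genome rows; ``percent`` is exact, ``percent_rounded`` is the integer
    reporting value.
    """
    chroms = matrix.markers["chromosome"].astype(str)
    L = matrix.n_loci
    rows = []
    counts = chroms.value_counts()
    for c in CHROMOSOMES:
        rows.append(("chromosome", c, int(counts.get(c, 0))))
    if int(counts.get("unknown", 0)) > 0:
        rows.append(("chromosome", "unknown", int(counts.get("unknown", 0))))
    for genome in "AB":
        n = int(sum(counts.get(c, 0) for c in CHROMOSOMES if c.endswith(genome)))
        rows.append(("genome", genome, n))
    df = pd.DataFrame(rows, columns=["level", "name", "count"])
    df["percent"] = 100.0 * df["count"] / L if L else 0.0
    df["percent_rounded"] = df["percent"].round().astype(int)
    return df
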