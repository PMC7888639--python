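"""Genotype matrix container and HapMap / VCF input-output.

The genotype matrix holds diploid biallelic SNP calls as the dosage of the
alternate allele (0, 1, 2) with ``-1`` marking missing calls, alongside
marker metadata (chromosome, physical position, allele pair) and ordered
accession identifiers.  The HapMap dialect is the tab-separated 11-metadata
column layout (``rs#, alleles, chrom, pos, strand, assembly#, center,
protLSID, assayLSID, panelLSID, QCcode``) followed by one two-letter
genotype column per accession.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: canonical durum wheat chromosome names, genome order 1A..7B
CHROMOSOMES = [f"{n}{g}" for n in range(1, 8) for g in "AB"]

HAPMAP_META_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

#: IUPAC ambiguity codes for heterozygous single-letter calls
IUPAC_HET = {
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
}

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_ref", "allele_alt"]


def normalize_chromosome(name: str) -> str:
    """Map a chromosome label onto {1A..7B}; anything else becomes 'unknown'."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    return s if s in CHROMOSOMES else "unknown"


@dataclasses.dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic SNP marker."""

    marker_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]  # reference-like allele first

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")


@dataclasses.dataclass
class GenotypeMatrix:
    """Accessions x loci diploid dosage calls plus marker/accession metadata.

    Parameters
    ----------
    calls
        ``(N, L)`` integer array of alternate-allele dosages in {0, 1, 2},
        with :data:`MISSING` (-1) for no-calls.
    accessions
        Ordered unique accession identifiers, length ``N``.
    markers
        DataFrame with columns ``marker_id, chromosome, position_bp,
        allele_ref, allele_alt``, one row per locus.
    origins
        Optional accession -> origin-region label mapping.
    """

    calls: np.ndarray
    accessions: list[str]
    markers: pd.DataFrame
    origins: dict[str, str] | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.accessions = [str(a) for a in self.accessions]
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, l = self.calls.shape
        if len(self.accessions) != n:
            raise ValueError(f"{len(self.accessions)} accession ids for {n} call rows")
        if len(self.markers) != l:
            raise ValueError(f"{len(self.markers)} marker rows for {l} call columns")
        if len(set(self.accessions)) != n:
            raise ValueError("duplicate accession ids")
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        self.markers = self.markers.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> float:
        if self.calls.size == 0:
            return 0.0
        return float((self.calls == MISSING).mean())

    # -- subsetting ------------------------------------------------------
    def subset_loci(self, index) -> "GenotypeMatrix":
        """New matrix restricted to loci selected by boolean mask or positions."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            calls=self.calls[:, index].copy(),
            accessions=list(self.accessions),
            markers=self.markers.iloc[index].reset_index(drop=True),
            origins=self.origins,
        )

    def subset_marker_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.markers["marker_id"])}
        try:
            index = [pos[m] for m in ids]
        except KeyError as exc:
            raise KeyError(f"marker id {exc.args[0]!r} not in matrix") from None
        return self.subset_loci(np.asarray(index))

    def subset_accessions(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        index = [pos[a] for a in names]
        return GenotypeMatrix(
            calls=self.calls[index, :].copy(),
            accessions=list(names),
            markers=self.markers.copy(),
            origins=self.origins,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Call-for-call equality including ids, chromosomes and positions."""
        return (
            self.accessions == other.accessions
            and np.array_equal(self.calls, other.calls)
            and list(self.markers["marker_id"]) == list(other.markers["marker_id"])
            and list(self.markers["chromosome"]) == list(other.markers["chromosome"])
            and list(self.markers["position_bp"]) == list(other.markers["position_bp"])
            and list(self.markers["allele_ref"]) == list(other.markers["allele_ref"])
            and list(self.markers["allele_alt"]) == list(other.markers["allele_alt"])
        )


# ---------------------------------------------------------------------------
# HapMap
# ---------------------------------------------------------------------------

def _decode_genotype(token: str, ref: str, alt: str, path, lineno: int) -> int:
    token = token.strip().upper()
    if token in ("NN", "N", "--", "-"):
        return MISSING
    if len(token) == 1:
        if token in IUPAC_HET:
            if IUPAC_HET[token] == frozenset((ref, alt)):
                return 1
            raise ValueError(
                f"{path}:{lineno}: IUPAC code {token!r} inconsistent with alleles {ref}/{alt}"
            )
        token = token + token  # single-letter homozygote
    if len(token) != 2 or any(c not in (ref, alt) for c in token):
        raise ValueError(
            f"{path}:{lineno}: genotype {token!r} not composed of alleles {ref}/{alt}"
        )
    return sum(1 for c in token if c == alt)


def read_hapmap(path) -> GenotypeMatrix:
    """Read a HapMap-format genotype file.

    Both two-letter genotype codes (``AG``) and single-letter IUPAC
    heterozygote codes are accepted; ``NN``/``N`` mean missing.  The allele
    order is taken from the ``alleles`` column (reference-like first).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < len(HAPMAP_META_COLUMNS):
            raise ValueError(
                f"{path}:1: expected at least {len(HAPMAP_META_COLUMNS)} columns, got {len(cols)}"
            )
        accessions = cols[len(HAPMAP_META_COLUMNS):]
        n = len(accessions)
        marker_rows, call_rows = [], []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(HAPMAP_META_COLUMNS) + n:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(HAPMAP_META_COLUMNS) + n} fields, got {len(fields)}"
                )
            marker_id = fields[0]
            if marker_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate marker id {marker_id!r}")
            seen.add(marker_id)
            allele_field = fields[1].upper()
            parts = allele_field.split("/")
            if len(parts) != 2 or any(a not in "ACGT" for a in parts):
                raise ValueError(f"{path}:{lineno}: bad alleles field {fields[1]!r}")
            ref, alt = parts
            chrom = normalize_chromosome(fields[2])
            try:
                pos = int(fields[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad position {fields[3]!r}") from None
            marker_rows.append((marker_id, chrom, pos, ref, alt))
            call_rows.append(
                [_decode_genotype(tok, ref, alt, path, lineno) for tok in fields[len(HAPMAP_META_COLUMNS):]]
            )
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    calls = (
        np.asarray(call_rows, dtype=np.int8).T
        if call_rows
        else np.zeros((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(calls=calls, accessions=accessions, markers=markers)


def write_hapmap(matrix: GenotypeMatrix, path) -> None:
    """Write a genotype matrix in the HapMap dialect (lossless round trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_META_COLUMNS + list(matrix.accessions)) + "\n")
        for j in range(matrix.n_loci):
            m = matrix.markers.iloc[j]
            ref, alt = m["allele_ref"], m["allele_alt"]
            codes = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            meta = [
                str(m["marker_id"]), f"{ref}/{alt}", str(m["chromosome"]),
                str(int(m["position_bp"])), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            geno = [codes[int(g)] for g in matrix.calls[:, j]]
            fh.write("\t".join(meta + geno) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, return_skip_count: bool = False):
    """Read biallelic SNP records from a VCF 4.x file.

    GT fields 0/0, 0/1, 1/1 map to dosages 0, 1, 2; ``./.`` (or any
    half-missing call) maps to missing.  Multiallelic or non-SNP records
    are skipped; the skip count is reported via a warning (and returned
    when ``return_skip_count`` is true).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    marker_rows, call_rows = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        marker_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_rows.append(
            (marker_id, normalize_chromosome(var.CHROM), int(var.POS), var.REF, var.ALT[0])
        )
        row = []
        for g in var.genotypes:
            a = [x for x in g[:-1]]  # drop phasing flag
            if len(a) != 2 or any(x < 0 for x in a):
                row.append(MISSING)
            else:
                row.append(int(a[0] > 0) + int(a[1] > 0))
        call_rows.append(row)
    vcf.close()
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-biallelic-SNP record(s)")
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    calls = (
        np.asarray(call_rows, dtype=np.int8).T
        if call_rows
        else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(calls=calls, accessions=accessions, markers=markers)
    if return_skip_count:
        return matrix, skipped
    return matrix


# ---------------------------------------------------------------------------
# Label TSV
# ---------------------------------------------------------------------------

def write_labels(labels: dict[str, int | str], path) -> None:
    """Write an accession -> population label table (TSV with header)."""
    with open(path, "w") as fh:
        fh.write("accession\tpopulation\n")
        for acc, pop in labels.items():
            fh.write(f"{acc}\t{pop}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["accession", "population"]:
        raise ValueError(f"{path}: expected header 'accession<TAB>population'")
    return dict(zip(df["accession"], df["population"]))
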