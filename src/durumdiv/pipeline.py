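"""Full analysis pipeline: ingest/simulate -> QC -> structure -> ΔK ->
assignment -> AMOVA -> diversity -> distances/trees, with a run manifest.

Every stage writes its table to the output directory as TSV; genotypes are
written as HapMap text and trees as Newick.  All randomness streams from
the single config seed, so two runs with the same config produce
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import (
    McmcSettings,
    best_replicate,
    evanno_deltaK,
    hard_assign,
    run_structure,
)
from .amova import amova_two_level, genotype_sq_distance
from .distance import allele_sharing_dissimilarity, nei_distance_matrix, nj_tree
from .diversity import diversity_table, pop_allele_freqs
from .io import GenotypeMatrix, read_hapmap, read_labels, read_vcf, write_hapmap, write_labels
from .partition import PopulationPartition
from .qc import apply_filters, chromosome_summary, impute_missing, locus_stats, select_informative
from .simulate import SimConfig, preset, simulate_panel

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: a simulation preset name (``preset``) or a
    genotype file path (``genotype_path``, HapMap or VCF by extension).
    Marker-set policies choose between the full filtered panel and the
    PIC-selected subset per stage.
    """

    preset: str | None = None
    sim_overrides: dict = dataclasses.field(default_factory=dict)
    genotype_path: str | None = None
    labels_path: str | None = None
    maf_min: float = 0.05
    missing_max: float = 0.10
    het_max: float = 0.125
    pic_min: float = 0.35
    impute: bool = False
    mcmc: McmcSettings = dataclasses.field(default_factory=McmcSettings.test_scale)
    structure_markers: str = "pic"  # "pic" or "full"
    amova_markers: str = "full"
    n_permutations: int = 999
    uhe_correction: str = "individuals"
    out_dir: str = "durumdiv_out"
    seed: int = 0

    def __post_init__(self):
        if (self.preset is None) == (self.genotype_path is None):
            raise ValueError("exactly one of 'preset' and 'genotype_path' required")
        if self.structure_markers not in ("pic", "full") or self.amova_markers not in ("pic", "full"):
            raise ValueError("marker policies must be 'pic' or 'full'")
        if self.genotype_path is not None and not Path(self.genotype_path).exists():
            raise FileNotFoundError(self.genotype_path)
        if self.labels_path is not None and not Path(self.labels_path).exists():
            raise FileNotFoundError(self.labels_path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            mc = raw["mcmc"]
            if "k_range" in mc:
                mc["k_range"] = tuple(mc["k_range"])
            raw["mcmc"] = McmcSettings(**mc)
        return cls(**raw)


def _stage(name: str, t0: float, detail: str = "") -> None:
    logger.info("stage %-12s %6.1fs  %s", name, time.time() - t0, detail)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written as JSON).

    Stage failures propagate with the stage name in the exception; outputs
    written before the failure are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "durumdiv",
        "version": __version__,
        "seed": config.seed,
        "settings": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "decisions": {
            "admixture_model": "admixture, uncorrelated frequencies, fixed alpha",
            "lnpd_estimator": "mean(lnL) - var(lnL)/2",
            "imputer": "seeded allele-frequency binomial" if config.impute else "none",
            "uhe_correction": config.uhe_correction,
            "structure_markers": config.structure_markers,
            "amova_markers": config.amova_markers,
        },
        "stages": {},
    }
    t0 = time.time()

    # --- input -----------------------------------------------------------
    try:
        if config.preset is not None:
            sim = preset(config.preset, seed=config.seed, **config.sim_overrides)
            matrix, truth = simulate_panel(sim)
            write_hapmap(matrix, out / "simulated.hapmap.txt")
            truth.partition.to_tsv(out / "true_labels.tsv")
            manifest["stages"]["input"] = {
                "source": f"preset:{config.preset}",
                "n_accessions": matrix.n_accessions,
                "n_loci": matrix.n_loci,
            }
        else:
            path = Path(config.genotype_path)
            if path.suffix.lower() == ".vcf":
                matrix = read_vcf(path)
            else:
                matrix = read_hapmap(path)
            if config.labels_path:
                origins = read_labels(config.labels_path)
                matrix.origins = origins
            manifest["stages"]["input"] = {
                "source": str(path),
                "n_accessions": matrix.n_accessions,
                "n_loci": matrix.n_loci,
            }
        _stage("input", t0, f"{matrix.n_accessions} x {matrix.n_loci}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc

    # --- QC --------------------------------------------------------------
    t0 = time.time()
    try:
        report = locus_stats(matrix, config.maf_min, config.missing_max, config.het_max)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.10g")
        filtered = apply_filters(matrix, config.maf_min, config.missing_max, config.het_max)
        if config.impute:
            filtered = impute_missing(filtered, seed=config.seed + 1)
        write_hapmap(filtered, out / "filtered.hapmap.txt")
        chromosome_summary(filtered).to_csv(
            out / "chromosome_summary.tsv", sep="\t", index=False, float_format="%.10g"
        )
        kept_report = locus_stats(filtered, config.maf_min, config.missing_max, config.het_max)
        informative = select_informative(kept_report, config.pic_min)
        with open(out / "informative_markers.txt", "w") as fh:
            fh.write("\n".join(informative) + ("\n" if informative else ""))
        manifest["stages"]["qc"] = {
            "n_loci_kept": filtered.n_loci,
            "n_informative": len(informative),
        }
        _stage("qc", t0, f"kept {filtered.n_loci}, informative {len(informative)}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'qc' failed: {exc}") from exc

    structure_matrix = (
        filtered.subset_marker_ids(informative)
        if config.structure_markers == "pic" and informative
        else filtered
    )
    amova_matrix = (
        filtered.subset_marker_ids(informative)
        if config.amova_markers == "pic" and informative
        else filtered
    )

    # --- structure + ΔK ---------------------------------------------------
    t0 = time.time()
    try:
        settings = dataclasses.replace(config.mcmc, seed=config.seed + 2)
        results = run_structure(structure_matrix, settings)
        runs = [
            {"k": r.k, "replicate": r.replicate, "seed": r.seed, "lnpd": r.lnpd}
            for r in results
        ]
        import pandas as pd

        pd.DataFrame(runs).to_csv(
            out / "structure_runs.tsv", sep="\t", index=False, float_format="%.10g"
        )
        dk = evanno_deltaK(results)
        dk.to_tsv(out / "deltak.tsv")
        chosen_k = dk.chosen_k
        manifest["stages"]["structure"] = {
            "n_runs": len(results),
            "chosen_k": chosen_k,
            "uninformative": dk.uninformative,
        }
        _stage("structure", t0, f"chosen K = {chosen_k}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'structure' failed: {exc}") from exc

    # --- assignment -------------------------------------------------------
    t0 = time.time()
    try:
        best = best_replicate(results, chosen_k)
        partition = hard_assign(best)
        partition.to_tsv(out / "partition.tsv")
        q = best.q_mean
        import pandas as pd

        qdf = pd.DataFrame(q, columns=[f"q_{k}" for k in range(1, best.k + 1)])
        qdf.insert(0, "accession", best.accessions)
        qdf["assigned"] = [partition.assignments[a] for a in best.accessions]
        qdf["max_q"] = [partition.confidence[a] for a in best.accessions]
        qdf.to_csv(out / "q_matrix.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["stages"]["assignment"] = {"sizes": partition.sizes()}
        _stage("assignment", t0, f"sizes {partition.sizes()}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'assignment' failed: {exc}") from exc

    # --- AMOVA ------------------------------------------------------------
    t0 = time.time()
    try:
        if partition.n_populations >= 2:
            d2 = genotype_sq_distance(amova_matrix)
            amova = amova_two_level(
                d2, partition, n_permutations=config.n_permutations, seed=config.seed + 3
            )
            amova.to_tsv(out / "amova.tsv")
            manifest["stages"]["amova"] = {
                "fst": amova.fst,
                "nm": amova.nm,
                "percent_between": amova.percent_between,
                "p_value": amova.p_value,
            }
            _stage("amova", t0, f"FST={amova.fst:.4f}")
        else:
            logger.warning("chosen K = 1: AMOVA skipped")
            manifest["stages"]["amova"] = {"skipped": "chosen K = 1"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'amova' failed: {exc}") from exc

    # --- diversity --------------------------------------------------------
    t0 = time.time()
    try:
        div = diversity_table(amova_matrix, partition, correction=config.uhe_correction)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.10g")
        _stage("diversity", t0)
        manifest["stages"]["diversity"] = {"n_populations": partition.n_populations}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'diversity' failed: {exc}") from exc

    # --- distances and trees ---------------------------------------------
    t0 = time.time()
    try:
        dis = allele_sharing_dissimilarity(structure_matrix)
        dis.to_tsv(out / "dissimilarity.tsv")
        if dis.n >= 3:
            tree = nj_tree(dis)
            with open(out / "nj_accessions.newick", "w") as fh:
                fh.write(tree.as_string(schema="newick"))
        if partition.n_populations >= 2:
            freqs = pop_allele_freqs(amova_matrix, partition)
            nei = nei_distance_matrix(freqs)
            nei.to_tsv(out / "nei_distances.tsv")
            if nei.n >= 3:
                ptree = nj_tree(nei)
                with open(out / "nj_populations.newick", "w") as fh:
                    fh.write(ptree.as_string(schema="newick"))
        _stage("distance", t0)
        manifest["stages"]["distance"] = {"n_accessions": dis.n}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'distance' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
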