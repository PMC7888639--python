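"""Reusable simulation experiments for validating the analysis stages.

These drive the same code paths as the pipeline (simulate -> QC/PIC
selection -> structure -> ΔK, or simulate -> AMOVA) at reduced scale, with
every random draw controlled by one seed, so recovery of the generator's
parameters can be checked reproducibly.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .admixture import DeltaKTable, McmcSettings, evanno_deltaK, run_structure
from .amova import AmovaTable, amova_two_level, genotype_sq_distance
from .qc import locus_stats, select_informative
from .simulate import preset, simulate_panel


@dataclasses.dataclass
class DeltaKExperiment:
    """Outcome of one simulate -> structure -> Evanno run."""

    chosen_k: int
    true_k: int
    table: DeltaKTable
    n_informative: int


def fst_recovery(preset_name: str, seed: int, n_loci: int = 1000) -> AmovaTable:
    """Simulate a preset panel and run AMOVA against the true deme labels."""
    matrix, truth = simulate_panel(preset(preset_name, n_loci=n_loci, seed=seed))
    d2 = genotype_sq_distance(matrix)
    return amova_two_level(d2, truth.partition)


def deltak_experiment(
    preset_name: str,
    n_informative: int,
    k_max: int,
    seed: int,
    settings: McmcSettings | None = None,
    oversample: int = 4,
) -> DeltaKExperiment:
    """One full model-selection experiment on a simulated panel.

    Simulates ``oversample * n_informative`` loci, keeps the PIC-selected
    markers (at most ``n_informative``), fits the admixture model over
    K = 1..k_max and applies the Evanno criterion.
    """
    cfg = preset(preset_name, n_loci=oversample * n_informative, seed=seed)
    matrix, truth = simulate_panel(cfg)
    ids = select_informative(locus_stats(matrix))
    matrix = matrix.subset_marker_ids(ids[:n_informative])
    if settings is None:
        settings = McmcSettings.test_scale(k_range=(1, k_max), seed=seed + 1)
    results = run_structure(matrix, settings)
    dk = evanno_deltaK(results)
    return DeltaKExperiment(
        chosen_k=dk.chosen_k,
        true_k=cfg.n_demes,
        table=dk,
        n_informative=matrix.n_loci,
    )


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2^31) derived from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]
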