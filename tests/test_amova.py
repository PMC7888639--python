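"""AMOVA variance components, FST, permutation test and gene flow."""
import itertools

import numpy as np
import pytest

from durumdiv.amova import (
    _phi_and_components,
    amova_two_level,
    gene_flow,
    genotype_sq_distance,
    permutation_test,
)
from durumdiv.io import MISSING
from durumdiv.partition import PopulationPartition

from conftest import make_matrix


def toy_panel():
    """2 populations x 2 individuals, 1 locus, fully differentiated."""
    m = make_matrix([[0], [0], [2], [2]])
    part = PopulationPartition({"acc001": 1, "acc002": 1, "acc003": 2, "acc004": 2})
    return m, part


class TestSquaredDistance:
    def test_hom_vs_het_is_one(self):
        m = make_matrix([[0], [1]])
        assert genotype_sq_distance(m).values[0, 1] == 1.0

    def test_opposite_homozygotes_four(self):
        m = make_matrix([[0], [2]])
        assert genotype_sq_distance(m).values[0, 1] == 4.0

    def test_identical_rows_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert genotype_sq_distance(m).values[0, 1] == 0.0

    def test_missing_rescaling(self):
        # loci: shared only at locus 1 (d2 = 4 there); L = 2, L_ij = 1 -> 8
        m = make_matrix([[0, MISSING, 0], [2, 2, MISSING], [0, 0, 0]])
        d2 = genotype_sq_distance(m)
        assert d2.values[0, 1] == pytest.approx(4.0 * 3 / 1)


class TestAmovaTwoLevel:
    def test_complete_hand_calculation(self):
        m, part = toy_panel()
        res = amova_two_level(genotype_sq_distance(m), part)
        table = res.table.set_index("source")
        assert table.loc["between_populations", "df"] == 1
        assert table.loc["within_populations", "df"] == 2
        assert table.loc["between_populations", "ss"] == pytest.approx(4.0)
        assert table.loc["within_populations", "ss"] == pytest.approx(0.0)
        assert res.sigma2_within == pytest.approx(0.0)
        assert res.sigma2_between == pytest.approx(2.0)
        assert res.fst == pytest.approx(1.0)
        assert res.percent_between == pytest.approx(100.0)
        assert res.percent_within == pytest.approx(0.0)
        assert res.nm == pytest.approx(0.0)

    def test_ss_additivity(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 25)).astype(np.int8)
        m = make_matrix(calls)
        labels = {a: 1 + i % 3 for i, a in enumerate(m.accessions)}
        part = PopulationPartition(labels)
        res = amova_two_level(genotype_sq_distance(m), part)
        table = res.table.set_index("source")
        d2 = genotype_sq_distance(m).values
        ss_total_direct = d2[np.triu_indices(12, 1)].sum() / 12
        assert (
            table.loc["between_populations", "ss"] + table.loc["within_populations", "ss"]
        ) == pytest.approx(ss_total_direct, abs=1e-9)

    def test_matches_oneway_anova_oracle_single_locus(self):
        # On one locus, AMOVA on (g_i - g_j)^2 must equal classical one-way
        # ANOVA variance components for unequal group sizes (direct oracle).
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=11).astype(np.int8)
        labels = np.array([1] * 4 + [2] * 3 + [3] * 4)
        m = make_matrix(g[:, None])
        part = PopulationPartition(dict(zip(m.accessions, labels)))
        res = amova_two_level(genotype_sq_distance(m), part)

        # oracle: method-of-moments ANOVA components
        N, k = len(g), 3
        grand = g.mean()
        groups = [g[labels == u] for u in (1, 2, 3)]
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
        msb, msw = ssb / (k - 1), ssw / (N - k)
        n0 = (N - sum(len(x) ** 2 for x in groups) / N) / (k - 1)
        sigma_b = (msb - msw) / n0
        assert res.sigma2_within == pytest.approx(msw, abs=1e-9)
        assert res.sigma2_between_raw == pytest.approx(sigma_b, abs=1e-9)

    def test_duplicating_individuals_leaves_fst_nearly_unchanged(self):
        rng = np.random.default_rng(4)
        calls = np.vstack(
            [
                rng.binomial(2, 0.2, size=(30, 40)),
                rng.binomial(2, 0.8, size=(30, 40)),
            ]
        ).astype(np.int8)
        m = make_matrix(calls)
        labels = [1] * 30 + [2] * 30
        part = PopulationPartition(dict(zip(m.accessions, labels)))
        fst1 = amova_two_level(genotype_sq_distance(m), part).fst

        doubled = make_matrix(np.vstack([calls, calls]))
        part2 = PopulationPartition(dict(zip(doubled.accessions, labels + labels)))
        fst2 = amova_two_level(genotype_sq_distance(doubled), part2).fst
        assert fst2 == pytest.approx(fst1, abs=0.02)

    def test_degenerate_panel_nan_with_warning(self):
        m = make_matrix([[1], [1], [1], [1]])
        part = PopulationPartition({a: 1 + i % 2 for i, a in enumerate(m.accessions)})
        with pytest.warns(UserWarning, match="degenerate"):
            res = amova_two_level(genotype_sq_distance(m), part)
        assert np.isnan(res.fst)

    def test_single_population_rejected(self):
        m, _ = toy_panel()
        part = PopulationPartition({a: 1 for a in m.accessions})
        with pytest.raises(ValueError, match="2 populations"):
            amova_two_level(genotype_sq_distance(m), part)


class TestPermutationTest:
    def test_toy_exact_enumeration_oracle(self):
        # enumerate all 6 distinct labelings of the 2x2 toy: 2 reach phi = 1,
        # so the exact p is 1/3; the permutation p must converge to it
        m, part = toy_panel()
        d2 = genotype_sq_distance(m)
        labels = np.array([1, 1, 2, 2])
        *_, phi_obs = _phi_and_components(d2.values, labels)
        hits, total = 0, 0
        for combo in itertools.combinations(range(4), 2):
            lab = np.full(4, 2)
            lab[list(combo)] = 1
            *_, phi = _phi_and_components(d2.values, lab)
            if np.isnan(phi):
                phi = -np.inf
            hits += phi >= phi_obs - 1e-12
            total += 1
        assert total == 6 and hits == 2  # exact-test p = 1/3

        p = permutation_test(d2, part, n_perm=1998, seed=0)
        assert p == pytest.approx(1 / 3, abs=0.05)

    def test_null_calibration(self):
        # random labels on structureless panels: p approximately uniform
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(50):
            calls = rng.binomial(2, 0.5, size=(10, 20)).astype(np.int8)
            m = make_matrix(calls)
            part = PopulationPartition(
                dict(zip(m.accessions, rng.permutation([1] * 5 + [2] * 5)))
            )
            pvals.append(
                permutation_test(genotype_sq_distance(m), part, n_perm=99,
                                 seed=int(rng.integers(2**31)))
            )
        assert 0.4 < np.mean(pvals) < 0.6

    def test_lower_bound_respected(self):
        m, part = toy_panel()
        p = permutation_test(genotype_sq_distance(m), part, n_perm=999, seed=1)
        assert p >= 1 / 1000

    def test_relabeling_invariance(self):
        m, part = toy_panel()
        d2 = genotype_sq_distance(m)
        swapped = PopulationPartition(
            {a: 3 - c for a, c in part.assignments.items()}
        )
        assert permutation_test(d2, part, n_perm=199, seed=3) == permutation_test(
            d2, swapped, n_perm=199, seed=3
        )


class TestGeneFlow:
    @pytest.mark.parametrize("fst,nm", [(0.2, 1.0), (1.0, 0.0), (0.5, 0.25)])
    def test_values(self, fst, nm):
        assert gene_flow(fst) == pytest.approx(nm)

    @pytest.mark.parametrize("fst", [0.0, -0.1, 1.5])
    def test_invalid(self, fst):
        with pytest.raises(ValueError):
            gene_flow(fst)
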