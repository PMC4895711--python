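"""Buffering regression, hierarchical grouping, trends, stoichiometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from oracles import hclust_oracle
from ribotx import buffering, expression
from ribotx.core import GeneModel
from ribotx.simulate import SimulationConfig, simulate_count_matrices, simulate_genome_annotation


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestBufferingCorrelation:
    def test_perfect_anticorrelation(self):
        x = _series([1.0, 2.0, -1.0, 0.5])
        fit = buffering.buffering_correlation(x, -x)
        assert fit.r == pytest.approx(-1.0)
        assert fit.slope == pytest.approx(-1.0)

    def test_independent_noise_has_null_slope(self):
        rng = np.random.default_rng(0)
        x = _series(rng.normal(size=2000))
        y = _series(rng.normal(size=2000))
        fit = buffering.buffering_correlation(x, y)
        assert abs(fit.r) < 3 / np.sqrt(2000)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(1)
        x = _series(rng.normal(scale=1.5, size=1000))
        y = -0.5 * x + rng.normal(scale=0.2, size=1000)
        fit = buffering.buffering_correlation(x, y)
        assert fit.slope == pytest.approx(-0.5, abs=0.1)

    def test_shift_invariance_of_r(self):
        rng = np.random.default_rng(2)
        x = _series(rng.normal(size=300))
        y = _series(rng.normal(size=300))
        a = buffering.buffering_correlation(x, y)
        b = buffering.buffering_correlation(x + 7.3, y)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_subset_and_minimum_size(self):
        x = _series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            buffering.buffering_correlation(x, -x, gene_subset=["g0", "g1"])


class TestHeatmapCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame([[1, 2], [5, 9], [1, 2]], index=list("abc"), dtype=float)
        order, Z = buffering.heatmap_cluster(m)
        assert Z[0, 2] == 0.0  # first merge at distance 0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_line_points_merge_near_pair_first(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        _, Z = buffering.heatmap_cluster(m)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            buffering.heatmap_cluster(pd.DataFrame([[1.0, 2.0]]))

    def test_matches_bruteforce_agglomeration(self):
        """Flat partitions at every k agree with a naive O(n^3) oracle."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(8, 13))
            rows = rng.normal(size=(n, 4))
            m = pd.DataFrame(rows)
            _, Z = buffering.heatmap_cluster(m)
            partitions, _ = hclust_oracle(rows)
            for k in range(1, n + 1):
                labels = fcluster(Z, t=k, criterion="maxclust")
                got = {frozenset(np.where(labels == c)[0]) for c in np.unique(labels)}
                expected = next(p for p in partitions if len(p) == len(got))
                assert got == expected


class TestPatternGroups:
    def test_256_cell_combinatorial_grid(self, default_dataset):
        mrna, rpf = default_dataset["mrna"], default_dataset["rpf"]
        groups = buffering.pattern_groups(mrna, rpf, k=16)
        assert groups.mrna_group.nunique() == 16
        assert groups.rpf_group.nunique() == 16
        grid = {(i, j) for i in range(1, 17) for j in range(1, 17)}
        assert len(grid) == 256
        assert set(groups.combinatorial) <= grid

    def test_partition_is_exhaustive_and_exclusive(self, default_dataset):
        groups = buffering.pattern_groups(default_dataset["mrna"], default_dataset["rpf"])
        comb = groups.combinatorial
        assert len(comb) == len(default_dataset["mrna"])
        assert comb.notna().all()

    def test_k2_separates_monotone_trends(self):
        up = np.outer(np.ones(10), [1, 2, 4, 8]) * np.linspace(1, 3, 10)[:, None]
        down = np.outer(np.ones(10), [8, 4, 2, 1]) * np.linspace(1, 3, 10)[:, None]
        m = pd.DataFrame(np.vstack([up, down]), columns=list("MTLS"))
        groups = buffering.pattern_groups(m, m, k=2)
        first, second = groups.mrna_group.iloc[:10], groups.mrna_group.iloc[10:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_identical_matrices_group_identically(self, default_dataset):
        mrna = default_dataset["mrna"]
        groups = buffering.pattern_groups(mrna, mrna.copy(), k=16)
        assert (groups.mrna_group == groups.rpf_group).all()

    def test_flat_gene_gets_reserved_group(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(1, 100, size=(40, 4)), columns=list("MTLS"))
        m.iloc[0] = 7  # constant profile: correlation distance undefined
        groups = buffering.pattern_groups(m, m, k=4)
        assert groups.mrna_group.iloc[0] == 0
        assert (groups.mrna_group.iloc[1:] > 0).all()


class TestTrendLabels:
    def test_monotone_profiles(self):
        prof = pd.DataFrame(
            np.exp2([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]]) - 1,
            index=list("abc"), columns=list("MTLS"),
        )
        assert buffering.trend_labels(prof).tolist() == ["I", "D", "flat"]

    def test_requires_three_phases(self):
        with pytest.raises(ValueError):
            buffering.trend_labels(pd.DataFrame({"M": [1.0], "T": [2.0]}))

    def test_planted_id_genes_labelled_id(self):
        """mRNA up 2-fold per phase with RPF down yields the ID group."""
        phases = np.arange(4)
        mrna = pd.DataFrame(np.exp2(np.outer(np.ones(5), 2.0 * phases)) * 100, columns=list("MTLS"))
        rpf = pd.DataFrame(np.exp2(np.outer(np.ones(5), -2.0 * phases)) * 100, columns=list("MTLS"))
        combined = buffering.combined_trend(
            buffering.trend_labels(mrna), buffering.trend_labels(rpf)
        )
        assert (combined == "ID").all()


class TestStoichiometry:
    def test_equal_rpf_equal_expectation_zero_error(self):
        genes = [
            GeneModel("a", 1, 1000, "+", operon_id="op", stoichiometry=1),
            GeneModel("b", 2001, 3000, "+", operon_id="op", stoichiometry=1),
        ]
        rpf = pd.DataFrame({"M": [50.0, 50.0]}, index=["a", "b"])
        report = buffering.stoichiometry_check(rpf, genes)
        assert (report.relative_error == 0).all()

    def test_first_member_zero_raises(self):
        genes = [
            GeneModel("a", 1, 1000, "+", operon_id="op", stoichiometry=1),
            GeneModel("b", 2001, 3000, "+", operon_id="op", stoichiometry=4),
        ]
        rpf = pd.DataFrame({"M": [0.0, 50.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            buffering.stoichiometry_check(rpf, genes)

    def test_planted_operons_recovered(self):
        """Ratios recovered over replicate simulated datasets: the 1:4
        operon within 15% and the eight-subunit operon within 20%."""
        reports = []
        for r in range(5):
            cfg = SimulationConfig(seed=100 + r)
            _, genes, truth = simulate_genome_annotation(cfg)
            _, rpf = simulate_count_matrices(genes, truth, cfg)
            norm = expression.normalize(rpf, expression.size_factors(rpf))
            reports.append(buffering.stoichiometry_check(norm, genes).set_index(["operon_id", "gene_id"]))
        obs = np.exp(np.mean([np.log(r.observed_ratio) for r in reports], axis=0))
        combined = reports[0].assign(observed_ratio=obs)
        combined["relative_error"] = (combined.observed_ratio - combined.expected_ratio).abs() / combined.expected_ratio
        assert combined.loc["op_rpl"].relative_error.max() <= 0.15
        assert combined.loc["op_atp"].relative_error.max() <= 0.20


def test_buffering_slope_monotone_in_planted_magnitude():
    """Recovered slopes grow more negative as the planted buffering
    strengthens."""
    recovered = []
    for slope in (0.0, -0.5, -1.0):
        cfg = SimulationConfig(seed=8, buffering_slope=slope)
        _, genes, truth = simulate_genome_annotation(cfg)
        mrna, rpf = simulate_count_matrices(genes, truth, cfg)
        mn = expression.normalize(mrna, expression.size_factors(mrna))
        rn = expression.normalize(rpf, expression.size_factors(rpf))
        te = expression.translation_efficiency(rn, mn)
        dm = np.log2(mn["S"] + 1) - np.log2(mn["M"] + 1)
        dte = expression.te_log2fc(te, ("M", "S"))
        recovered.append(buffering.buffering_correlation(dm, dte).slope)
    assert recovered[0] > recovered[1] > recovered[2]
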