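"""Normalization, expressed cutoff, differential flags and TE."""

import numpy as np
import pandas as pd
import pytest

from ribotx import expression
from ribotx.core import GeneModel
from ribotx.simulate import SimulationConfig, simulate_count_matrices, simulate_genome_annotation


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(expression.size_factors(m), [1.0, 1.0])

    def test_exact_doubling(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = expression.size_factors(m)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-3)

    def test_single_gene_median_of_ratios(self):
        m = pd.DataFrame({"a": [4], "b": [9]})
        sf = expression.size_factors(m)
        assert np.allclose(sf, [4 / 6, 9 / 6])

    def test_no_all_positive_gene_raises(self):
        m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            expression.size_factors(m)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            expression.size_factors(pd.DataFrame({"a": [1, 2]}))

    def test_matches_deseq2_median_of_ratios(self):
        """Cross-check against the DESeq2 reference implementation."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(200, 4)), columns=list("MTLS")
        )
        _, sf_ref = deseq2_norm(counts.T)  # pydeseq2 is samples x genes
        ours = expression.size_factors(counts)
        assert np.allclose(ours.to_numpy(), np.asarray(sf_ref).ravel(), rtol=1e-6)


class TestNormalize:
    def test_unit_factors_leave_values(self):
        m = pd.DataFrame({"a": [10], "b": [20]})
        sf = pd.Series([1.0, 1.0], index=["a", "b"])
        assert expression.normalize(m, sf).equals(m.astype(float))

    def test_division(self):
        m = pd.DataFrame({"a": [10]})
        out = expression.normalize(m, pd.Series([2.0], index=["a"]))
        assert out.loc[0, "a"] == 5

    def test_scaling_invariance_up_to_global_constant(self, default_dataset):
        """Multiplying one sample's raw counts by c rescales that sample's
        size factor, leaving the normalized matrix unchanged up to the single
        global constant shared by all columns (the geometric-mean reference
        absorbs c^(1/m))."""
        m = default_dataset["mrna"].copy()
        scaled = m.copy()
        scaled["T"] = scaled["T"] * 3
        norm_a = expression.normalize(m, expression.size_factors(m))
        norm_b = expression.normalize(scaled, expression.size_factors(scaled))
        ratio = (norm_b / norm_a).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])

    def test_nonpositive_factor_raises(self):
        m = pd.DataFrame({"a": [10]})
        with pytest.raises(ValueError):
            expression.normalize(m, pd.Series([0.0], index=["a"]))


class TestRpkm:
    def test_worked_value(self):
        assert expression.rpkm(10, 1000, 1_000_000) == 10.0

    def test_zero_counts(self):
        assert expression.rpkm(0, 500, 1_000_000) == 0.0

    def test_depth_invariance(self):
        assert expression.rpkm(20, 1000, 2_000_000) == expression.rpkm(10, 1000, 1_000_000)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            expression.rpkm(10, 0, 1_000_000)


class TestExpressedCutoff:
    def test_median_and_strict_inequality(self):
        m = pd.DataFrame(
            {"M": [10.0, 30.0, 50.0, 30.0], "T": [10.0, 30.0, 50.0, 25.0]},
            index=["r1", "r2", "r3", "g"],
        )
        cutoff, flags = expression.expressed_cutoff(m, ["r1", "r2", "r3"])
        assert cutoff == 30.0
        assert not flags["g"]  # max value equals the cutoff: not expressed
        assert flags["r3"]

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            expression.expressed_cutoff(pd.DataFrame({"M": [1.0]}), [])

    def test_cutoff_equals_reference_median_on_synthetic_data(self, default_dataset):
        mrna, genes = default_dataset["mrna"], default_dataset["genes"]
        norm = expression.normalize(mrna, expression.size_factors(mrna))
        ref = [g.gene_id for g in genes if g.category == "secondary_metabolic"]
        cutoff, _ = expression.expressed_cutoff(norm, ref)
        assert cutoff == float(norm.loc[ref, "M"].median())


def test_exclude_terminal_genes_drops_20_each_side():
    genes = [GeneModel(f"g{i:03d}", 100 * i + 1, 100 * i + 50, "+") for i in range(100)]
    kept = expression.exclude_terminal_genes(genes)
    assert len(kept) == 60
    assert kept[0] == "g020" and kept[-1] == "g079"


def test_estimate_dispersion_recovers_planted_alpha():
    rng = np.random.default_rng(3)
    alpha, mean = 0.05, 500.0
    r = 1 / alpha
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mean), size=(2000, 6)),
        columns=["M_1", "M_2", "M_3", "T_1", "T_2", "T_3"],
    )
    est = expression.estimate_dispersion(
        counts, {"M": ["M_1", "M_2", "M_3"], "T": ["T_1", "T_2", "T_3"]}
    )
    assert est == pytest.approx(alpha, rel=0.5)


CONTRASTS = [("M", "T"), ("M", "L"), ("M", "S")]


class TestDifferential:
    def test_identical_phases_not_flagged(self):
        m = pd.DataFrame({p: [100.0, 50.0] for p in "MTLS"})
        res = expression.differential_flags(m, CONTRASTS)
        assert (res.log2fc.to_numpy() == 0).all()
        assert not res.flags.any()

    def test_requires_two_contrasts(self):
        m = pd.DataFrame({p: [100.0] for p in "MT"})
        with pytest.raises(ValueError):
            expression.differential_flags(m, [("M", "T")])

    def test_planted_fourfold_power(self):
        """Planted 4-fold genes at default depth are flagged >= 95%."""
        cfg = SimulationConfig(
            seed=12, genome_length=300_000, n_genes=300, n_tss=50,
            phase_foldchange_sd=0.0, secondary_trend=0.0, buffering_slope=0.0, rpf_noise_sd=0.0,
        )
        _, genes, truth = simulate_genome_annotation(cfg)
        de = truth.mrna_log2fc.index[:40]
        truth.mrna_log2fc.loc[de, ["T", "L", "S"]] = 2.0
        truth.rpf_log2fc.loc[de, ["T", "L", "S"]] = 2.0
        mrna, _ = simulate_count_matrices(genes, truth, cfg)
        norm = expression.normalize(mrna, expression.size_factors(mrna))
        res = expression.differential_flags(norm, CONTRASTS)
        assert res.flags.loc[de].mean() >= 0.95

    def test_null_false_flag_rate(self):
        """Null genes are flagged at most 0.05 + 3 SE of the time."""
        cfg = SimulationConfig(
            seed=11, genome_length=300_000, n_genes=300, n_tss=50,
            phase_foldchange_sd=0.0, secondary_trend=0.0, buffering_slope=0.0, rpf_noise_sd=0.0,
        )
        _, genes, truth = simulate_genome_annotation(cfg)
        mrna, _ = simulate_count_matrices(genes, truth, cfg)
        norm = expression.normalize(mrna, expression.size_factors(mrna))
        res = expression.differential_flags(norm, CONTRASTS)
        n = len(res.flags)
        assert res.flags.mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_tightening_fold_threshold_shrinks_flag_set(self, default_dataset):
        mrna = default_dataset["mrna"]
        norm = expression.normalize(mrna, expression.size_factors(mrna))
        sizes = [
            expression.differential_flags(norm, CONTRASTS, fc_threshold=fc).flags.sum()
            for fc in (1.5, 2.0, 4.0, 8.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestTranslationEfficiency:
    def test_pseudocount_arithmetic(self):
        rpf = pd.DataFrame({"M": [99.0, 0.0]})
        mrna = pd.DataFrame({"M": [49.0, 0.0]})
        te = expression.translation_efficiency(rpf, mrna)
        assert te["M"].tolist() == [2.0, 1.0]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            expression.translation_efficiency(
                pd.DataFrame({"M": [1.0]}), pd.DataFrame({"M": [1.0], "T": [2.0]})
            )

    def test_monotone_in_rpf_and_mrna(self):
        base = expression.translation_efficiency(
            pd.DataFrame({"M": [50.0]}), pd.DataFrame({"M": [50.0]})
        ).iloc[0, 0]
        up_rpf = expression.translation_efficiency(
            pd.DataFrame({"M": [60.0]}), pd.DataFrame({"M": [50.0]})
        ).iloc[0, 0]
        up_mrna = expression.translation_efficiency(
            pd.DataFrame({"M": [50.0]}), pd.DataFrame({"M": [60.0]})
        ).iloc[0, 0]
        assert up_rpf > base > up_mrna

    def test_mrna_doubling_halves_te_in_the_limit(self):
        rpf = pd.DataFrame({"M": [1e6], "T": [1e6]})
        mrna = pd.DataFrame({"M": [1e6], "T": [2e6]})
        te = expression.translation_efficiency(rpf, mrna)
        dte = expression.te_log2fc(te, ("M", "T"))
        assert dte.iloc[0] == pytest.approx(-1.0, abs=1e-4)
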