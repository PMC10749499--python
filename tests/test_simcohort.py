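"""Synthetic cohort generator: determinism, planted effects, round-trips."""

import numpy as np
import pandas as pd
import pytest

from cpgburden import (
    CarrierMatrix,
    ExpressionSpec,
    GeneSpec,
    Population,
    SimConfig,
    TwoHitSpec,
    compute_ts,
    fit_twohit,
    call_loh,
    simulate_cohort,
    simulate_features_and_expression,
    simulate_loh,
    write_fixture,
)
from cpgburden import io as cio


class TestConfigValidation:
    def test_non_positive_sample_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cases=0, n_controls=10)

    def test_population_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(n_cases=5, n_controls=5, populations=[Population("A", 0.6, 1.0), Population("B", 0.6, 0.0)])

    def test_fst_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cases=5, n_controls=5, populations=[Population("A", 1.0, 1.0, fst=1.5)])

    def test_degenerate_carrier_frequency_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cases=5, n_controls=5, genes=[GeneSpec("G", 0.0)])

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_cases=5,
                n_controls=5,
                expression=ExpressionSpec(("a", "b"), {"g": 10}, {"g": 1.5}),
            )


class TestDeterminism:
    def test_identical_config_and_seed_identical_outputs(self):
        cfg = SimConfig(
            n_cases=50,
            n_controls=50,
            populations=[Population("A", 0.5, 0.5, 0.1), Population("B", 0.5, 0.5, 0.1)],
            n_common_variants=30,
            genes=[GeneSpec("G1", 0.05, 1.0)],
            twohit_genes={"G1": TwoHitSpec(0.1, 1.0)},
            seed=77,
        )
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.samples.equals(b.samples)
        assert a.common_genotypes.equals(b.common_genotypes)
        assert a.carriers.data.equals(b.carriers.data)
        assert simulate_loh(cfg, a.carriers, a.samples).equals(simulate_loh(cfg, b.carriers, b.samples))

    def test_different_seeds_differ(self):
        kw = dict(n_cases=100, n_controls=100, genes=[GeneSpec("G1", 0.2)])
        a = simulate_cohort(SimConfig(seed=1, **kw))
        b = simulate_cohort(SimConfig(seed=2, **kw))
        assert not a.carriers.data.equals(b.carriers.data)


class TestPlantedEffects:
    def test_case_carrier_frequency_monotone_in_effect(self):
        """Empirical case carrier frequency is non-decreasing over a beta grid."""
        freqs = []
        for log2_or in [0.0, 1.0, 2.0, 3.0]:
            cfg = SimConfig(
                n_cases=3000,
                n_controls=100,
                genes=[GeneSpec("G", 0.02, log2_or)],
                seed=5,
            )
            data = simulate_cohort(cfg)
            cases = data.samples.index[data.samples["cohort"] == "case"]
            freqs.append(data.carriers.data.loc["G", cases].mean())
        assert all(b >= a for a, b in zip(freqs, freqs[1:]))

    def test_population_offsets_shift_carrier_rates(self):
        cfg = SimConfig(
            n_cases=2000,
            n_controls=2000,
            populations=[Population("A", 0.5, 0.5), Population("B", 0.5, 0.5)],
            genes=[GeneSpec("G", 0.05, 0.0, population_offsets={"B": 1.5})],
            seed=8,
        )
        data = simulate_cohort(cfg)
        pops = data.samples["population"]
        rate_a = data.carriers.data.loc["G", pops[pops == "A"].index].mean()
        rate_b = data.carriers.data.loc["G", pops[pops == "B"].index].mean()
        assert rate_b > rate_a * 1.5

    def test_every_carrier_has_a_qualifying_variant(self):
        cfg = SimConfig(n_cases=60, n_controls=60, genes=[GeneSpec("G1", 0.2), GeneSpec("G2", 0.2)], seed=3)
        data = simulate_cohort(cfg)
        for v in data.variants:
            carriers_from_map = set(data.genotypes[v.variant_id])
            carriers_from_matrix = set(data.carriers.data.columns[data.carriers.data.loc[v.gene_id]])
            assert carriers_from_map == carriers_from_matrix


class TestSimulateLOH:
    def _cfg(self, baseline, d):
        return SimConfig(
            n_cases=2000,
            n_controls=50,
            genes=[GeneSpec("G", 0.3, 0.0)],
            twohit_genes={"G": TwoHitSpec(baseline, d)},
            seed=13,
        )

    def test_only_case_samples_get_copy_number(self):
        cfg = self._cfg(0.1, 0.0)
        data = simulate_cohort(cfg)
        mcn = simulate_loh(cfg, data.carriers, data.samples)
        assert all(s.startswith("case") for s in mcn.columns)

    def test_uncoupled_loh_rates_equal(self):
        cfg = self._cfg(0.2, 0.0)
        data = simulate_cohort(cfg)
        mcn = simulate_loh(cfg, data.carriers, data.samples)
        carrier = data.carriers.data.loc["G", mcn.columns].to_numpy()
        loh = (mcn.loc["G"] == 0).to_numpy()
        assert abs(loh[carrier].mean() - loh[~carrier].mean()) < 0.05

    def test_zero_baseline_means_no_loh_and_ineligible_test(self):
        cfg = self._cfg(0.0, 0.0)
        data = simulate_cohort(cfg)
        mcn = simulate_loh(cfg, data.carriers, data.samples)
        assert (mcn.to_numpy() >= 1).all()
        case_ids = list(mcn.columns)
        cm = CarrierMatrix(data.carriers.data.loc[["G"], case_ids])
        assert not fit_twohit("G", cm, call_loh(mcn)).eligible

    def test_unknown_twohit_gene_raises(self):
        cfg = self._cfg(0.1, 0.0)
        data = simulate_cohort(cfg)
        bad = SimConfig(
            n_cases=10, n_controls=10, genes=[GeneSpec("G", 0.3)], twohit_genes={"MISSING": TwoHitSpec(0.1, 0.0)}
        )
        with pytest.raises(KeyError):
            simulate_loh(bad, data.carriers, data.samples)


class TestFeaturesAndExpression:
    def test_tau_clipped_and_loeuf_positive(self):
        from cpgburden import FeatureCluster

        cfg = SimConfig(
            n_cases=5,
            n_controls=5,
            feature_clusters=[FeatureCluster(1, 200, twohit_mean=0, tau_mean=0.99, loeuf_mean=0.01, tau_sd=0.2, loeuf_sd=0.2)],
            seed=4,
        )
        features, _ = simulate_features_and_expression(cfg)
        assert features["tau"].between(0, 1).all()
        assert (features["loeuf"] > 0).all()

    def test_perfect_correlation_gives_pair_count_ts(self):
        cfg = SimConfig(
            n_cases=5,
            n_controls=5,
            expression=ExpressionSpec(tuple(f"g{i}" for i in range(6)), {"grp": 30}, {"grp": 1.0}),
            seed=2,
        )
        _, expr = simulate_features_and_expression(cfg)
        assert compute_ts(expr["grp"]) == pytest.approx(15.0, abs=1e-6)

    def test_invalid_negative_rho_for_panel_raises(self):
        cfg = SimConfig(
            n_cases=5,
            n_controls=5,
            expression=ExpressionSpec(tuple(f"g{i}" for i in range(10)), {"grp": 30}, {"grp": -0.5}),
            seed=2,
        )
        with pytest.raises(ValueError, match="indefinite"):
            simulate_features_and_expression(cfg)


class TestRoundTrips:
    def test_fixture_round_trips_through_readers(self, tmp_path):
        cfg = SimConfig(
            n_cases=30,
            n_controls=30,
            populations=[Population("A", 0.5, 0.5, 0.1), Population("B", 0.5, 0.5, 0.1)],
            n_common_variants=20,
            genes=[GeneSpec("G1", 0.2, 1.0), GeneSpec("G2", 0.1)],
            twohit_genes={"G1": TwoHitSpec(0.2, 1.0)},
            seed=6,
        )
        data = simulate_cohort(cfg)
        mcn = simulate_loh(cfg, data.carriers, data.samples)
        paths = write_fixture(tmp_path, data, mcn)

        samples = cio.read_samples_tsv(paths["samples"])
        assert samples.equals(data.samples)

        carriers = cio.read_carriers_tsv(paths["carriers"])
        assert carriers.data.equals(data.carriers.data)

        mcn_back = cio.read_gene_table(paths["minor_cn"])
        assert np.array_equal(mcn_back.to_numpy(), mcn.to_numpy())

        dosages = cio.read_common_vcf(paths["common_vcf"])
        assert np.array_equal(dosages.to_numpy(), data.common_genotypes.to_numpy())

    def test_variants_vcf_round_trip_preserves_fields(self, tmp_path):
        from conftest import make_variant
        from cpgburden import Consequence

        variants = [
            make_variant(pos=10, gene_id="A"),
            make_variant(
                pos=20,
                gene_id="B",
                consequence=Consequence.MISSENSE,
                clinvar_labels=frozenset({"Likely pathogenic"}),
                maf_subpop={"EAS": 0.002},
                spliceai_loss_score=0.9,
                in_terminal_exon=True,
            ),
            make_variant(pos=30, gene_id="C", maf_global=None, cohort_detection_freq={"case": 0.003}),
        ] + [make_variant(pos=40 + i, gene_id=f"D{i}") for i in range(7)]
        samples = ["s1", "s2", "s3"]
        genotypes = {v.variant_id: ["s1"] for v in variants}
        path = cio.write_variants_vcf(variants, genotypes, samples, tmp_path / "v.vcf")
        back, genos, back_samples = cio.read_variants_vcf(path)
        assert len(back) == 10
        assert back_samples == samples
        for orig, rt in zip(variants, back):
            assert rt == orig
        assert all(genos[v.variant_id] == ["s1"] for v in variants)

    def test_variants_tsv_round_trip(self, tmp_path):
        from conftest import make_variant
        from cpgburden import Consequence

        variants = [
            make_variant(pos=1),
            make_variant(pos=2, consequence=Consequence.SPLICE_SITE, region_flags=frozenset({"blacklist"})),
            make_variant(pos=3, maf_global=None, cohort_detection_freq={"control": 0.02}),
        ]
        path = cio.write_variants_tsv(variants, tmp_path / "v.tsv")
        back = cio.read_variants_tsv(path)
        assert back == variants
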