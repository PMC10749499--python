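"""Full pipeline on a generated fixture: simulate -> write files ->
classify-variants -> PCA -> burden -> two-hit -> gene clusters -> TS.

Everything travels through the on-disk formats (annotated VCF, TSV
matrices), exactly as the `cpgburden` command-line interface runs it.
"""

import tempfile
from pathlib import Path

import pandas as pd

import cpgburden as cb
from cpgburden.pipeline import RunConfig, run_all

work = Path(tempfile.mkdtemp(prefix="cpgburden_demo_"))

cfg = cb.SimConfig(
    n_cases=300,
    n_controls=300,
    populations=[cb.Population("A", 0.5, 0.5, 0.1), cb.Population("B", 0.5, 0.5, 0.1)],
    n_common_variants=150,
    genes=[cb.GeneSpec("RISK", 0.03, 2.5)] + [cb.GeneSpec(f"N{i:02d}", 0.03) for i in range(20)],
    twohit_genes={"RISK": cb.TwoHitSpec(0.15, 2.0)},
    feature_clusters=[
        cb.FeatureCluster(1, 25, 0.0, 0.1, 1.0),
        cb.FeatureCluster(2, 25, 0.0, 0.9, 1.1),
        cb.FeatureCluster(3, 25, 0.0, 0.9, 0.25),
        cb.FeatureCluster(4, 25, 2.0, 0.5, 0.6),
    ],
    expression=cb.ExpressionSpec(
        tuple(f"g{i}" for i in range(12)), {"obs": 40, "comp": 120}, {"obs": 0.5, "comp": 0.0}
    ),
    seed=2024,
)
data = cb.simulate_cohort(cfg)
minor_cn = cb.simulate_loh(cfg, data.carriers, data.samples)
features, expr = cb.simulate_features_and_expression(cfg)
fixture = work / "fixture"
cb.write_fixture(fixture, data, minor_cn, features, expr)

out = run_all(
    RunConfig(
        out_dir=str(work / "results"),
        samples=str(fixture / "samples.tsv"),
        variants_vcf=str(fixture / "variants.vcf"),
        common_vcf=str(fixture / "common.vcf"),
        minor_cn=str(fixture / "minor_cn.tsv"),
        features=str(fixture / "features.tsv"),
        expr_observed=str(fixture / "expr_obs.tsv"),
        expr_comparison=str(fixture / "expr_comp.tsv"),
        ts_subsample=40,
        ts_resamples=200,
        pca_k=4,
        seed=2024,
    )
)

print("stage artifacts in", out)
for p in sorted(out.iterdir()):
    print("  ", p.name)

burden = pd.read_csv(out / "burden_results.tsv", sep="\t", comment="#", index_col=0)
top = burden[burden["eligible"]].sort_values("p_value").head(3)
print("\ntop burden hits (planted: RISK at log2 OR 2.5):")
print(top[["n_case_carriers", "n_control_carriers", "log2_or", "p_value", "q_value"]].round(4))
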