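"""Immune-checkpoint transcriptional score with a resampling null.

The observed group has coordinated expression across a 38-gene checkpoint
panel (within-panel correlation 0.4); the comparison group does not. TS —
the absolute sum of pairwise Pearson correlations — is computed for the
observed group and compared against 1,000 subsamples of 45 from the
comparison group.
"""

import cpgburden as cb

panel = tuple(f"ICG{i:02d}" for i in range(38))
cfg = cb.SimConfig(
    n_cases=5,
    n_controls=5,
    expression=cb.ExpressionSpec(
        panel_genes=panel,
        n_samples={"carriers": 45, "noncarriers": 400},
        rho={"carriers": 0.4, "noncarriers": 0.0},
    ),
    seed=9,
)
_, expr = cb.simulate_features_and_expression(cfg)

observed = cb.compute_ts(expr["carriers"])
result = cb.resample_null(
    expr["noncarriers"], observed, subsample_size=45, n_resample=1000, seed=9
)
print(f"observed TS          : {observed:.1f}   (max possible = C(38,2) = 703)")
print(f"null TS mean +/- sd  : {result.null_mean:.1f} +/- {result.null_sd:.1f}")
print(f"empirical p          : {result.empirical_p:.4f}")
# The correlated group's TS far exceeds every resampled null draw, so the
# empirical p hits its floor 1/(n_resample+1) — a coordinated immune
# transcriptional program in the observed group.
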