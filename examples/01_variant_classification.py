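"""Classify annotated variants and collapse them to gene-level carriers.

Builds a handful of annotated variants, runs the QC -> rarity ->
pathogenicity cascade, and reports per-gene carrier frequencies.
"""

import pandas as pd

import cpgburden as cb

variants = [
    # clean rare stop-gain: qualifies as a protein-truncating variant (PTV)
    cb.VariantRecord("1", 1001, "C", "T", "PAH", cb.Consequence.STOP_GAIN, maf_global=0.001),
    # rare missense with a ClinVar Pathogenic assertion
    cb.VariantRecord(
        "1", 1002, "G", "A", "PAH", cb.Consequence.MISSENSE,
        clinvar_labels=frozenset({"Pathogenic"}), maf_global=0.002,
    ),
    # frameshift in the terminal exon: excluded from the PTV class
    cb.VariantRecord("1", 1003, "AT", "A", "PAH", cb.Consequence.FRAMESHIFT_INDEL,
                     maf_global=0.001, in_terminal_exon=True),
    # too common (0.8% > 0.5% MAF rule)
    cb.VariantRecord("2", 500, "T", "G", "BRCA2", cb.Consequence.STOP_GAIN, maf_global=0.008),
    # flagged as a gnomAD technical artifact: removed by the prefilter
    cb.VariantRecord("2", 600, "A", "C", "BRCA2", cb.Consequence.STOP_GAIN,
                     maf_global=0.001, gnomad_qc_flags=frozenset({"RF"})),
]

calls = cb.classify_variants(variants)
print("qualifying calls:")
for call in calls:
    print(f"  {call.variant.variant_id}  {call.variant.gene_id}  {sorted(call.class_flags)}")

# ten samples; the two qualifying PAH variants are carried by three samples
samples = [f"s{i}" for i in range(10)]
genotypes = {"1:1001:C:T": ["s0", "s1"], "1:1002:G:A": ["s1", "s2"]}
carriers = cb.build_carrier_matrix(calls, genotypes, samples, class_mode="union")
report = carriers.frequency_report(pd.Series("case", index=samples))
print("\ncarrier report (per gene):")
print(report)
# 3 of 10 samples carry >=1 qualifying PAH variant -> 30%; s1's two variants
# collapse to a single carrier indicator.
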