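"""Readers and writers for the on-disk formats.

Matrices and tables travel as TSV (gene rows x sample columns for carrier,
copy-number and expression matrices). Variants travel either as an annotated
VCF — a plain VCF whose INFO field carries the annotation under the keys
``GENE``, ``CSQ_CONSEQ``, ``CLNSIG``, ``MAF_GLOBAL``, ``MAF_<POP>``,
``SPLICEAI_LOSS``, ``TERMEXON``, ``DOMAIN``, ``QCFLAGS``, ``REGIONFLAGS``
and ``COHORTFREQ`` — or as a flat TSV with the same columns. VCFs are read
with cyvcf2; writing emits plain text (the dialect is uncompressed VCF 4.2).
Gene sets use the GMT format. Result writers prefix a comment header with
the tool version and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .varfilter import GNOMAD_SUBPOPULATIONS, CarrierMatrix, Consequence, VariantRecord

__all__ = [
    "write_samples_tsv",
    "read_samples_tsv",
    "write_carriers_tsv",
    "read_carriers_tsv",
    "write_gene_table",
    "read_gene_table",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_common_vcf",
    "read_common_vcf",
    "read_gmt",
    "provenance_header",
]


def provenance_header(config_hash: str | None = None) -> str:
    from . import __version__

    tag = f"# cpgburden v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag + "\n"


def config_hash(obj: object) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def _write_df(df: pd.DataFrame, path: Path, header: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t")
    return path


def write_samples_tsv(samples: pd.DataFrame, path: str | Path) -> Path:
    return _write_df(samples, Path(path))


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_carriers_tsv(carriers: CarrierMatrix, path: str | Path, header: str | None = None) -> Path:
    return _write_df(carriers.data.astype(int), Path(path), header)


def read_carriers_tsv(path: str | Path, class_mode: str = "union") -> CarrierMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return CarrierMatrix(data=df.astype(bool), class_mode=class_mode)


def write_gene_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> Path:
    """Generic gene-rows table (minor CN, features, expression, results)."""
    return _write_df(df, Path(path), header)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


# ---------------------------------------------------------------------------
# Flat variant TSV dialect

_SET_SEP = "|"


def _set_to_str(s: Iterable[str]) -> str:
    return _SET_SEP.join(sorted(s))


def _str_to_set(s: str) -> frozenset:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return frozenset()
    return frozenset(str(s).split(_SET_SEP))


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene_id": v.gene_id,
            "consequence": v.consequence.value,
            "clinvar_labels": _set_to_str(v.clinvar_labels),
            "maf_global": v.maf_global if v.maf_global is not None else "",
            "spliceai_loss": v.spliceai_loss_score if v.spliceai_loss_score is not None else "",
            "term_exon": int(v.in_terminal_exon),
            "domain": int(v.has_functional_domain),
            "qc_flags": _set_to_str(v.gnomad_qc_flags),
            "region_flags": _set_to_str(v.region_flags),
            "cohort_freq": _SET_SEP.join(f"{k}:{f}" for k, f in sorted(v.cohort_detection_freq.items())),
        }
        for pop in GNOMAD_SUBPOPULATIONS:
            row[f"maf_{pop}"] = v.maf_subpop.get(pop, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_variants_tsv(variants: Iterable[VariantRecord], path: str | Path) -> Path:
    path = Path(path)
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)
    return path


def _row_to_variant(row: pd.Series) -> VariantRecord:
    def opt_float(x):
        if x == "" or pd.isna(x):
            return None
        return float(x)

    maf_subpop = {}
    for pop in GNOMAD_SUBPOPULATIONS:
        val = opt_float(row.get(f"maf_{pop}", ""))
        if val is not None:
            maf_subpop[pop] = val
    cohort_freq = {}
    raw = row.get("cohort_freq", "")
    if isinstance(raw, str) and raw:
        for item in raw.split(_SET_SEP):
            k, f = item.split(":")
            cohort_freq[k] = float(f)
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene_id=str(row["gene_id"]),
        consequence=Consequence(row["consequence"]),
        clinvar_labels=_str_to_set(row.get("clinvar_labels", "")),
        maf_global=opt_float(row.get("maf_global", "")),
        maf_subpop=maf_subpop,
        spliceai_loss_score=opt_float(row.get("spliceai_loss", "")),
        in_terminal_exon=bool(int(row.get("term_exon", 0) or 0)),
        has_functional_domain=bool(int(row.get("domain", 1) if row.get("domain", 1) != "" else 1)),
        gnomad_qc_flags=_str_to_set(row.get("qc_flags", "")),
        region_flags=_str_to_set(row.get("region_flags", "")),
        cohort_detection_freq=cohort_freq,
    )


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return [_row_to_variant(row) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# VCF dialect

_VCF_INFO_HEADER = """##fileformat=VCFv4.2
##source=cpgburden
{contig_lines}##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=CSQ_CONSEQ,Number=1,Type=String,Description="Canonical-transcript consequence">
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="ClinVar labels (| separated, _ for space)">
##INFO=<ID=MAF_GLOBAL,Number=1,Type=Float,Description="Global reference MAF">
{pop_lines}##INFO=<ID=SPLICEAI_LOSS,Number=1,Type=Float,Description="Max of SpliceAI donor/acceptor loss deltas">
##INFO=<ID=TERMEXON,Number=0,Type=Flag,Description="Variant in terminal exon">
##INFO=<ID=DOMAIN,Number=0,Type=Flag,Description="Variant overlaps a functional domain">
##INFO=<ID=QCFLAGS,Number=.,Type=String,Description="gnomAD QC flags">
##INFO=<ID=REGIONFLAGS,Number=.,Type=String,Description="Region flags (blacklist, low_mappability)">
##INFO=<ID=COHORTFREQ,Number=.,Type=String,Description="cohort:detection_frequency pairs">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _vcf_header(samples: list[str] | None, chroms: Sequence[str]) -> str:
    pop_lines = "".join(
        f'##INFO=<ID=MAF_{p},Number=1,Type=Float,Description="{p} reference MAF">\n'
        for p in GNOMAD_SUBPOPULATIONS
    )
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    head = _VCF_INFO_HEADER.format(pop_lines=pop_lines, contig_lines=contig_lines)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + samples
    return head + "\t".join(cols) + "\n"


def _info_field(v: VariantRecord) -> str:
    parts = [f"GENE={v.gene_id}", f"CSQ_CONSEQ={v.consequence.value}"]
    if v.clinvar_labels:
        parts.append("CLNSIG=" + "|".join(sorted(v.clinvar_labels)).replace(" ", "_"))
    if v.maf_global is not None:
        parts.append(f"MAF_GLOBAL={v.maf_global:.6g}")
    for pop, maf in sorted(v.maf_subpop.items()):
        parts.append(f"MAF_{pop}={maf:.6g}")
    if v.spliceai_loss_score is not None:
        parts.append(f"SPLICEAI_LOSS={v.spliceai_loss_score:.4g}")
    if v.in_terminal_exon:
        parts.append("TERMEXON")
    if v.has_functional_domain:
        parts.append("DOMAIN")
    if v.gnomad_qc_flags:
        parts.append("QCFLAGS=" + "|".join(sorted(v.gnomad_qc_flags)))
    if v.region_flags:
        parts.append("REGIONFLAGS=" + "|".join(sorted(v.region_flags)))
    if v.cohort_detection_freq:
        parts.append(
            "COHORTFREQ=" + "|".join(f"{k}:{f:.6g}" for k, f in sorted(v.cohort_detection_freq.items()))
        )
    return ";".join(parts)


def write_variants_vcf(
    variants: Iterable[VariantRecord],
    genotypes: Mapping[str, Iterable[str]] | None,
    samples: list[str] | None,
    path: str | Path,
) -> Path:
    """Annotated VCF; per-sample GT columns mark carriage when genotypes given."""
    path = Path(path)
    variants = list(variants)
    chroms = list(dict.fromkeys(v.chrom for v in variants))
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples if genotypes is not None else None, chroms))
        for v in variants:
            fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", _info_field(v)]
            if genotypes is not None and samples is not None:
                carrier_set = set(genotypes.get(v.variant_id, ()))
                fields.append("GT")
                fields.extend("0/1" if s in carrier_set else "0/0" for s in samples)
            fh.write("\t".join(fields) + "\n")
    return path


def read_variants_vcf(path: str | Path) -> tuple[list[VariantRecord], dict[str, list[str]], list[str]]:
    """Read the annotated VCF dialect via cyvcf2.

    Returns (variants, genotype map variant_id -> carrier sample ids,
    sample ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    genotype_map: dict[str, list[str]] = {}

    def _f(x) -> float:
        # htslib stores INFO floats as float32; restore the written %.6g precision
        return float(f"{float(x):.6g}")

    for rec in vcf:
        info = dict(rec.INFO)
        maf_subpop = {
            pop: _f(info[f"MAF_{pop}"]) for pop in GNOMAD_SUBPOPULATIONS if f"MAF_{pop}" in info
        }
        cohort_freq = {}
        if "COHORTFREQ" in info:
            raw = info["COHORTFREQ"]
            items = raw if isinstance(raw, (list, tuple)) else str(raw).split("|")
            for item in items:
                k, f = str(item).split(":")
                cohort_freq[k] = float(f)

        def _labels(key):
            if key not in info:
                return frozenset()
            raw = info[key]
            items = raw if isinstance(raw, (list, tuple)) else str(raw).split("|")
            return frozenset(str(x).replace("_", " ") for x in items)

        v = VariantRecord(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0] if rec.ALT else ".",
            gene_id=str(info.get("GENE", "")),
            consequence=Consequence(str(info.get("CSQ_CONSEQ", "other"))),
            clinvar_labels=_labels("CLNSIG"),
            maf_global=_f(info["MAF_GLOBAL"]) if "MAF_GLOBAL" in info else None,
            maf_subpop=maf_subpop,
            spliceai_loss_score=_f(info["SPLICEAI_LOSS"]) if "SPLICEAI_LOSS" in info else None,
            in_terminal_exon=bool(info.get("TERMEXON", False)),
            has_functional_domain=bool(info.get("DOMAIN", False)),
            gnomad_qc_flags=frozenset(str(x) for x in _labels("QCFLAGS")),
            region_flags=frozenset(str(x) for x in _labels("REGIONFLAGS")),
            cohort_detection_freq=cohort_freq,
        )
        variants.append(v)
        if samples:
            gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            carriers = [s for s, g in zip(samples, gts) if g in (1, 3)]
            genotype_map[v.variant_id] = carriers
    return variants, genotype_map, samples


def write_common_vcf(genotypes: pd.DataFrame, path: str | Path) -> Path:
    """Dosage matrix (samples x variants, values 0/1/2/NaN) as a GT VCF."""
    path = Path(path)
    samples = list(genotypes.index)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n##source=cpgburden\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + samples) + "\n")
        mat = genotypes.to_numpy(dtype=float)
        for j, vid in enumerate(genotypes.columns):
            gts = ["./." if np.isnan(d) else gt_str[int(d)] for d in mat[:, j]]
            fh.write("\t".join(["1", str(j + 1), str(vid), "A", "C", ".", "PASS", ".", "GT"] + gts) + "\n")
    return path


def read_common_vcf(path: str | Path) -> pd.DataFrame:
    """GT VCF back to a samples x variants dosage matrix (NaN = missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for rec in vcf:
        gts = rec.gt_types
        dosage = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(dosage)
    return pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)), index=samples, columns=ids)


def read_gmt(path: str | Path) -> list:
    """GMT gene sets: set id, description, member genes per tab-separated line."""
    from .burden import GeneSetDefinition

    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSetDefinition(set_id=parts[0], genes=[g for g in parts[2:] if g]))
    return sets
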