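"""Variant table I/O, rare-variant filtering, consequence classification and
gene x sample x type collapsing.

The collapsing unit is the annotated gene symbol; variants are classified into
four mutually exclusive classes — protein-truncating (PTV), missense/other
protein-altering (MIS), synonymous (SYN) and non-coding/other (NON) — and
tallied per (gene, sample, class).  A sample is a *carrier* for a
(gene, class) if it holds at least one qualifying variant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["sample_id", "gene", "consequence", "allele_frequency"]


class VariantType(str, enum.Enum):
    """The four collapsing classes, ordered by decreasing severity."""

    PTV = "PTV"
    MIS = "MIS"
    SYN = "SYN"
    NON = "NON"


#: Sequence Ontology term -> collapsing class.  Unknown terms fall through to NON.
CONSEQUENCE_MAP: dict[str, VariantType] = {
    # protein truncating
    "stop_gained": VariantType.PTV,
    "frameshift_variant": VariantType.PTV,
    "splice_acceptor_variant": VariantType.PTV,
    "splice_donor_variant": VariantType.PTV,
    "start_lost": VariantType.PTV,
    "stop_lost": VariantType.PTV,
    # protein altering, non truncating
    "missense_variant": VariantType.MIS,
    "inframe_insertion": VariantType.MIS,
    "inframe_deletion": VariantType.MIS,
    "protein_altering_variant": VariantType.MIS,
    # synonymous
    "synonymous_variant": VariantType.SYN,
    "stop_retained_variant": VariantType.SYN,
}

_SEVERITY_ORDER = [VariantType.PTV, VariantType.MIS, VariantType.SYN, VariantType.NON]


class VariantTableError(ValueError):
    """Raised for malformed variant tables; message carries line numbers."""


def classify_variant(consequence: str) -> VariantType:
    """Map a consequence annotation to its collapsing class.

    ``consequence`` may carry several ``&``- or ``,``-separated terms (VEP
    style); the most severe class wins (PTV > MIS > SYN > NON).  Terms not in
    :data:`CONSEQUENCE_MAP` are treated as non-coding/other (NON).
    """
    if not consequence or not str(consequence).strip():
        raise ValueError("empty consequence term")
    terms = str(consequence).replace(",", "&").split("&")
    classes = {CONSEQUENCE_MAP.get(t.strip(), VariantType.NON) for t in terms if t.strip()}
    for vt in _SEVERITY_ORDER:
        if vt in classes:
            return vt
    return VariantType.NON


def read_variant_table(path, fmt: str = "tsv", *, vcf_info_keys=("GENE", "CSQCLASS", "AF")):
    """Read a variant table into a DataFrame with :data:`VARIANT_COLUMNS`.

    TSV: tab-separated with header ``sample_id  gene  consequence
    allele_frequency``; a dot or empty field means the allele frequency is
    unknown (absent from population databases) and is kept as missing.

    VCF: a minimally annotated VCF 4.x whose INFO field carries the gene
    symbol, consequence and population allele frequency under
    ``vcf_info_keys``; one record is emitted per sample carrying a non-ref
    genotype.  Requires :mod:`cyvcf2`.
    """
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path, vcf_info_keys)
    raise ValueError(f"unknown variant table format: {fmt!r}")


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required column(s): {', '.join(missing)}")
    errors = []
    af = np.full(len(df), np.nan)
    for i, raw in enumerate(df["allele_frequency"]):
        raw = raw.strip()
        if raw in ("", ".", "NA"):
            continue
        try:
            val = float(raw)
        except ValueError:
            errors.append(f"line {i + 2}: unparseable allele_frequency {raw!r}")
            continue
        if not 0.0 <= val <= 1.0:
            errors.append(f"line {i + 2}: allele_frequency {val} outside [0, 1]")
            continue
        af[i] = val
    for i, gene in enumerate(df["gene"]):
        if not gene.strip():
            errors.append(f"line {i + 2}: empty gene symbol")
    if errors:
        raise VariantTableError(f"{path}: " + "; ".join(errors))
    out = df[["sample_id", "gene", "consequence"]].copy()
    out["allele_frequency"] = af
    return out


def _read_vcf(path, info_keys) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency

    gene_key, csq_key, af_key = info_keys
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        gene = rec.INFO.get(gene_key)
        csq = rec.INFO.get(csq_key)
        if gene is None or csq is None:
            raise VariantTableError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks INFO/{gene_key} or INFO/{csq_key}"
            )
        af = rec.INFO.get(af_key)
        gts = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sidx in np.flatnonzero((gts == 1) | (gts == 3)):
            rows.append((samples[sidx], gene, csq, np.nan if af is None else float(af)))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variant_table(df: pd.DataFrame, path) -> None:
    """Write records as TSV, encoding missing allele frequencies as '.'."""
    out = df[VARIANT_COLUMNS].copy()
    out["allele_frequency"] = out["allele_frequency"].map(
        lambda v: "." if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, sep="\t", index=False)


def filter_rare(df: pd.DataFrame, af_threshold: float = 0.01) -> pd.DataFrame:
    """Keep rare variants: allele frequency < ``af_threshold``.

    Variants with no recorded population frequency are kept — absence from the
    reference databases is itself evidence of rarity.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError(f"af_threshold must be in (0, 1], got {af_threshold}")
    af = df["allele_frequency"]
    return df[af.isna() | (af < af_threshold)].reset_index(drop=True)


@dataclass
class GeneTypeCountMatrix:
    """Per-class gene x sample variant counts with derived carrier indicators.

    ``counts[vt]`` is an ``(n_genes, n_samples)`` non-negative integer array
    aligned to ``genes`` and ``samples``.
    """

    genes: list[str]
    samples: list[str]
    counts: dict[VariantType, np.ndarray] = field(repr=False)

    def __post_init__(self):
        g, s = len(self.genes), len(self.samples)
        for vt, mat in self.counts.items():
            if mat.shape != (g, s):
                raise ValueError(f"count matrix for {vt} has shape {mat.shape}, expected {(g, s)}")
            if (mat < 0).any():
                raise ValueError(f"negative counts in {vt} matrix")

    def carriers(self, vt: VariantType) -> np.ndarray:
        """Boolean (n_genes, n_samples) carrier matrix: count >= 1."""
        return self.counts[vt] >= 1

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def total_count(self) -> int:
        return int(sum(int(m.sum()) for m in self.counts.values()))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (gene, sample_id, variant_type, count), zero rows omitted."""
        frames = []
        for vt, mat in self.counts.items():
            gi, si = np.nonzero(mat)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": np.asarray(self.genes)[gi],
                        "sample_id": np.asarray(self.samples)[si],
                        "variant_type": vt.value,
                        "count": mat[gi, si],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["gene", "sample_id", "variant_type", "count"]
        )


def collapse_counts(
    records: pd.DataFrame,
    samples: list[str],
    genes: list[str] | None = None,
) -> GeneTypeCountMatrix:
    """Tally classified variant records into a :class:`GeneTypeCountMatrix`.

    Every record's sample must appear in ``samples``; unknown samples are an
    error (silent dropping would bias carrier rates).  Genes absent from the
    records but present in ``genes`` get all-zero rows.
    """
    if genes is None:
        genes = sorted(records["gene"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    gene_idx = {g: i for i, g in enumerate(genes)}
    unknown = set(records["sample_id"]) - set(sample_idx)
    if unknown:
        raise ValueError(
            f"{len(unknown)} record sample id(s) not in the sample list: "
            + ", ".join(sorted(unknown)[:5])
            + ("..." if len(unknown) > 5 else "")
        )
    counts = {
        vt: np.zeros((len(genes), len(samples)), dtype=np.int32) for vt in VariantType
    }
    if len(records):
        classes = records["consequence"].map(classify_variant)
        gi = records["gene"].map(gene_idx)
        if gi.isna().any():
            missing = sorted(set(records.loc[gi.isna(), "gene"]))
            raise ValueError(f"record gene(s) not in the gene list: {', '.join(missing[:5])}")
        si = records["sample_id"].map(sample_idx)
        for vt in VariantType:
            mask = (classes == vt).to_numpy()
            if mask.any():
                np.add.at(counts[vt], (gi.to_numpy()[mask], si.to_numpy()[mask]), 1)
    return GeneTypeCountMatrix(genes=list(genes), samples=list(samples), counts=counts)
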