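"""Input/output, QC filtering and cis/trans window resolution.

Genotypes are held as per-variant alt-allele dosages plus genotype-probability
triplets (P(ref-hom), P(het), P(alt-hom)); expression as a gene x sample matrix
with TSS annotations; twin structure as a sample -> (family, zygosity) table.
Coordinates are 1-based inclusive throughout (VCF convention): the cis window
is the closed interval |pos - tss| <= half_width, the trans region is strictly
|pos - tss| > min_distance or another chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "ExpressionTable",
    "TwinCohort",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_expression",
    "write_expression",
    "read_pedigree",
    "write_pedigree",
    "apply_qc_filters",
    "cis_window_variants",
    "trans_mask",
    "CIS_HALF_WIDTH",
    "TRANS_MIN_DISTANCE",
]

CIS_HALF_WIDTH = 1_000_000
TRANS_MIN_DISTANCE = 5_000_000

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">
##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities (ref-hom, het, alt-hom)">
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
"""


class FormatError(ValueError):
    """Raised on malformed or unsupported genotype input."""


@dataclass
class GenotypeTable:
    """Dosages and genotype probabilities for variants x samples.

    Attributes
    ----------
    variants : DataFrame with columns variant_id, chrom, pos, ref, alt, maf, info
        (index 0..n_variants-1; maf computed from dosages, info may be NaN).
    dosage : (n_variants, n_samples) float array, entries in [0, 2].
    gp : (n_variants, n_samples, 3) float array, rows sum to 1.
    samples : list of sample ids, order as in the source file.
    gp_degenerate : bool flag set when GP was reconstructed from DS only.
    haplotypes : optional (n_variants, 2*n_samples) 0/1 array (simulated data
        only; columns 2i, 2i+1 are the two haplotypes of sample i).
    """

    variants: pd.DataFrame
    dosage: np.ndarray
    gp: np.ndarray
    samples: list[str]
    gp_degenerate: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.gp = np.asarray(self.gp, dtype=float)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape inconsistent with variants/samples")
        if self.gp.shape != self.dosage.shape + (3,):
            raise ValueError("gp shape inconsistent with dosage")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["variant_id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[self.index_of(variant_id)]

    def gp_of(self, variant_id: str) -> np.ndarray:
        return self.gp[self.index_of(variant_id)]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[keep],
            gp=self.gp[keep],
            samples=list(self.samples),
            gp_degenerate=self.gp_degenerate,
            haplotypes=None if self.haplotypes is None else self.haplotypes[keep],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeTable(
            variants=self.variants.copy(),
            dosage=self.dosage[:, idx],
            gp=self.gp[:, idx],
            samples=list(sample_ids),
            gp_degenerate=self.gp_degenerate,
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[:, np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))],
        )


@dataclass
class ExpressionTable:
    """Gene x sample phenotype matrix with TSS annotations and a stage tag."""

    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    values: np.ndarray  # (n_genes, n_samples)
    samples: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape inconsistent with genes/samples")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def row(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero((self.genes["gene_id"] == gene_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown gene {gene_id!r}")
        return self.values[int(idx[0])]

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionTable":
        return ExpressionTable(self.genes.copy(), values, list(self.samples), stage)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionTable(
            self.genes.copy(), self.values[:, idx], list(sample_ids), self.stage
        )


@dataclass
class TwinCohort:
    """Sample -> family map with zygosity (MZ, DZ or singleton).

    Families have one or two members; MZ/DZ families exactly two.
    """

    table: pd.DataFrame  # sample_id, family_id, zygosity

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "family_id", "zygosity"):
            if col not in t.columns:
                raise ValueError(f"pedigree table missing column {col!r}")
        bad = set(t["zygosity"]) - {"MZ", "DZ", "singleton"}
        if bad:
            raise ValueError(f"unknown zygosity values {sorted(bad)}")
        for fam, grp in t.groupby("family_id"):
            if grp["zygosity"].nunique() != 1:
                raise ValueError(f"family {fam} has mixed zygosity")
            z = grp["zygosity"].iloc[0]
            if z in ("MZ", "DZ") and len(grp) != 2:
                raise ValueError(f"{z} family {fam} has {len(grp)} members (need 2)")
            if z == "singleton" and len(grp) != 1:
                raise ValueError(f"singleton family {fam} has {len(grp)} members")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def pairs(self, zygosity: str) -> list[tuple[str, str]]:
        out = []
        for _, grp in self.table[self.table["zygosity"] == zygosity].groupby(
            "family_id", sort=True
        ):
            a, b = grp["sample_id"].tolist()
            out.append((a, b))
        return out

    def align(self, sample_ids: list[str]) -> "TwinCohort":
        t = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return TwinCohort(t)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _maf_from_dosage(dosage: np.ndarray) -> np.ndarray:
    f = dosage.mean(axis=1) / 2.0
    return np.minimum(f, 1.0 - f)


def read_genotypes(path: str, format: str = "auto") -> GenotypeTable:
    """Read genotypes from VCF (DS and/or GP FORMAT fields) or TSV.

    When only DS is present, GP is reconstructed as the minimal-entropy
    completion: dosage d in [0,1] -> (1-d, d, 0), d in (1,2] -> (0, 2-d, d-1),
    and the table is flagged ``gp_degenerate``.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _degenerate_gp(dosage: np.ndarray) -> np.ndarray:
    d = np.asarray(dosage, dtype=float)
    gp = np.zeros(d.shape + (3,))
    lo = d <= 1.0
    gp[..., 0] = np.where(lo, 1.0 - d, 0.0)
    gp[..., 1] = np.where(lo, d, 2.0 - d)
    gp[..., 2] = np.where(lo, 0.0, d - 1.0)
    return gp


def _read_vcf(path: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages, gps = [], [], []
    any_gp_missing = False
    for i, rec in enumerate(vcf):
        ds = rec.format("DS")
        gp = rec.format("GP")
        if ds is None and gp is None:
            raise FormatError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}) has neither DS nor GP"
            )
        if gp is not None:
            gp = np.asarray(gp, dtype=float)
            if gp.shape != (len(samples), 3):
                raise FormatError(
                    f"{path}: record {i + 1} has malformed GP field"
                )
            dose = gp[:, 1] + 2.0 * gp[:, 2] if ds is None else np.asarray(ds, float).ravel()
        else:
            any_gp_missing = True
            dose = np.asarray(ds, dtype=float).ravel()
            gp = _degenerate_gp(dose)
        info = rec.INFO.get("INFO", None)
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        rows.append(
            (vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0] if rec.ALT else ".",
             np.nan if info is None else float(info))
        )
        dosages.append(dose)
        gps.append(gp)
    if not rows:
        raise FormatError(f"{path}: no variant records")
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "info"]
    )
    dosage = np.asarray(dosages)
    variants["maf"] = _maf_from_dosage(dosage)
    return GenotypeTable(
        variants=variants[["variant_id", "chrom", "pos", "ref", "alt", "maf", "info"]],
        dosage=dosage,
        gp=np.asarray(gps),
        samples=samples,
        gp_degenerate=any_gp_missing,
    )


def _read_genotype_tsv(path: str) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt", "info"]
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    value_cols = [c for c in df.columns if c not in meta_cols and c != "maf"]
    gp_cols = [c for c in value_cols if c.endswith((":gp0", ":gp1", ":gp2"))]
    ds_cols = [c for c in value_cols if c not in gp_cols]
    samples = ds_cols
    dosage = df[ds_cols].to_numpy(dtype=float)
    if gp_cols:
        gp = np.stack(
            [df[[f"{s}:gp0", f"{s}:gp1", f"{s}:gp2"]].to_numpy(dtype=float) for s in samples],
            axis=1,
        )
        degenerate = False
    else:
        gp = _degenerate_gp(dosage)
        degenerate = True
    variants = df[meta_cols].copy()
    variants["maf"] = _maf_from_dosage(dosage)
    return GenotypeTable(
        variants=variants[["variant_id", "chrom", "pos", "ref", "alt", "maf", "info"]],
        dosage=dosage,
        gp=gp,
        samples=samples,
        gp_degenerate=degenerate,
    )


def write_genotypes_tsv(g: GenotypeTable, path: str, with_gp: bool = True) -> None:
    meta = g.variants[["variant_id", "chrom", "pos", "ref", "alt", "info"]]
    blocks = [meta, pd.DataFrame(g.dosage, columns=g.samples)]
    if with_gp:
        for comp in range(3):
            blocks.append(
                pd.DataFrame(
                    g.gp[:, :, comp], columns=[f"{s}:gp{comp}" for s in g.samples]
                )
            )
    df = pd.concat(blocks, axis=1)
    if with_gp:  # interleave gp columns after the dosage block, grouped by sample
        cols = list(meta.columns) + list(g.samples)
        cols += [f"{s}:gp{c}" for s in g.samples for c in range(3)]
        df = df[cols]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_genotypes_vcf(g: GenotypeTable, path: str) -> None:
    """Write a minimal VCF 4.2 with DS and GP FORMAT fields."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
        for i in order:
            row = g.variants.iloc[i]
            info = "." if pd.isna(row["info"]) else f"INFO={row['info']:.6g}"
            cells = [
                f"{g.dosage[i, j]:.6g}:"
                + ",".join(f"{p:.6g}" for p in g.gp[i, j])
                for j in range(g.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t{info}\tDS:GP\t" + "\t".join(cells) + "\n"
            )


def read_expression(path: str) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["gene_id", "chrom", "tss", "strand"]
    for col in meta:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    stage = "raw"
    if "stage" in df.columns:
        stage = str(df["stage"].iloc[0])
        df = df.drop(columns=["stage"])
    samples = [c for c in df.columns if c not in meta]
    return ExpressionTable(
        genes=df[meta].copy(),
        values=df[samples].to_numpy(dtype=float),
        samples=samples,
        stage=stage,
    )


def write_expression(e: ExpressionTable, path: str) -> None:
    df = pd.concat(
        [
            e.genes.reset_index(drop=True).assign(stage=e.stage),
            pd.DataFrame(e.values, columns=e.samples),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pedigree(path: str) -> TwinCohort:
    df = pd.read_csv(path, sep="\t")
    return TwinCohort(df[["sample_id", "family_id", "zygosity"]].copy())


def write_pedigree(cohort: TwinCohort, path: str) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and windows
# ---------------------------------------------------------------------------


def apply_qc_filters(
    g: GenotypeTable,
    e: ExpressionTable,
    maf_min: float = 0.01,
    info_min: float = 0.8,
    zero_frac_max: float = 0.10,
) -> tuple[GenotypeTable, ExpressionTable, pd.DataFrame]:
    """Remove variants with MAF < maf_min or imputation info < info_min, and
    genes whose fraction of zero values exceeds zero_frac_max.

    Thresholds are strict inequalities on removal: a variant at exactly
    maf_min/info_min is retained. Variants with missing info are retained
    (treated as directly genotyped). Returns the filtered tables plus a
    report DataFrame (kind, id, reason, value).
    """
    records = []
    maf = g.variants["maf"].to_numpy(dtype=float)
    info = g.variants["info"].to_numpy(dtype=float)
    bad_maf = maf < maf_min
    bad_info = ~np.isnan(info) & (info < info_min)
    for i in np.flatnonzero(bad_maf):
        records.append(("variant", g.variants["variant_id"].iloc[i], "maf", maf[i]))
    for i in np.flatnonzero(bad_info & ~bad_maf):
        records.append(("variant", g.variants["variant_id"].iloc[i], "info", info[i]))
    keep_v = ~(bad_maf | bad_info)

    zero_frac = (e.values == 0).mean(axis=1)
    keep_g = zero_frac <= zero_frac_max
    for i in np.flatnonzero(~keep_g):
        records.append(
            ("gene", e.genes["gene_id"].iloc[i], "zero_fraction", zero_frac[i])
        )

    if not keep_v.any():
        warnings.warn("QC removed every variant", stacklevel=2)
    if not keep_g.any():
        warnings.warn("QC removed every gene", stacklevel=2)
    report = pd.DataFrame(records, columns=["kind", "id", "reason", "value"])
    e_out = ExpressionTable(
        e.genes.iloc[keep_g].reset_index(drop=True),
        e.values[keep_g],
        list(e.samples),
        e.stage,
    )
    return g.subset_variants(keep_v), e_out, report


def cis_window_variants(
    g: GenotypeTable, gene: pd.Series | dict, half_width: int = CIS_HALF_WIDTH
) -> list[str]:
    """Variant ids on the gene's chromosome with |pos - tss| <= half_width,
    ordered by position (closed interval; truncated at chromosome ends)."""
    chrom, tss = str(gene["chrom"]), int(gene["tss"])
    on_chrom = g.variants["chrom"].astype(str) == chrom
    if not on_chrom.any():
        warnings.warn(f"no variants on chromosome {chrom}", stacklevel=2)
        return []
    pos = g.variants["pos"].to_numpy(dtype=np.int64)
    sel = on_chrom.to_numpy() & (np.abs(pos - tss) <= half_width)
    idx = np.flatnonzero(sel)
    idx = idx[np.argsort(pos[idx], kind="stable")]
    return g.variants["variant_id"].iloc[idx].tolist()


def trans_mask(
    g: GenotypeTable, gene: pd.Series | dict, min_distance: int = TRANS_MIN_DISTANCE
) -> list[str]:
    """Variant ids on other chromosomes, or on the gene's chromosome strictly
    farther than min_distance from the TSS."""
    chrom, tss = str(gene["chrom"]), int(gene["tss"])
    pos = g.variants["pos"].to_numpy(dtype=np.int64)
    other = g.variants["chrom"].astype(str) != chrom
    far = ~other.to_numpy() & (np.abs(pos - tss) > min_distance)
    idx = np.flatnonzero(other.to_numpy() | far)
    return g.variants["variant_id"].iloc[idx].tolist()
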