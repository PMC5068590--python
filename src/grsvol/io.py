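"""Readers, writers and harmonization for the three external table kinds.

Three table kinds flow through the pipeline:

* GWAS summary statistics (variant, alleles, odds ratio, P) -> :class:`SummaryStats`
* genotype dosages (VCF, PLINK .bed/.bim/.fam, or plain TSV) -> :class:`GenotypeMatrix`
* phenotype/covariate tables (TSV) -> :class:`PhenotypeTable`

Weights are stored as natural-log odds ratios.  Dosages count copies of
``allele_b`` and keep missing entries as NaN; mean imputation happens only at
scoring time.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, HarmonizeError, ValidationError

__all__ = [
    "SummaryStats",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_plink_bed",
    "read_phenotypes",
    "write_phenotypes",
    "harmonize",
    "maf_filter",
    "allele_frequencies",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical summary-statistics column names
SUMSTATS_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "OR", "P")

SS_FIELDS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight", "pvalue"]

VARIANT_FIELDS = ["variant_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class SummaryStats:
    """Per-variant training-GWAS records with log-OR weights.

    ``table`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    weight (natural-log odds ratio), pvalue.  ``rejected`` records row-level
    validation failures from ingestion or harmonization.
    """

    table: pd.DataFrame
    rejected: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SS_FIELDS if c not in t.columns]
        if missing:
            raise ValidationError(f"SummaryStats missing columns: {missing}")
        if t["variant_id"].duplicated().any():
            dups = t.loc[t["variant_id"].duplicated(), "variant_id"].tolist()[:5]
            raise ValidationError(f"duplicate variant_id in summary stats: {dups}")
        if len(t) and (t["pos"] < 1).any():
            raise ValidationError("positions must be >= 1")
        if len(t) and not np.isfinite(t["weight"].to_numpy(float)).all():
            raise ValidationError("non-finite weight")
        p = t["pvalue"].to_numpy(float)
        if len(t) and ((p <= 0) | (p > 1)).any():
            raise ValidationError("pvalue outside (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Series:
        return self.table["variant_id"]

    def restrict(self, variant_ids: Sequence[str]) -> "SummaryStats":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return SummaryStats(self.table.loc[keep].reset_index(drop=True), list(self.rejected))


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages[i, j]`` is the (possibly fractional) count of ``allele_b`` copies
    carried by sample ``i`` at variant ``j``; NaN marks a missing call.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids not unique")
        missing = [c for c in VARIANT_FIELDS if c not in self.variants.columns]
        if missing:
            raise ValidationError(f"variant metadata missing columns: {missing}")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValidationError("dosage outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def column_index(self) -> pd.Series:
        """variant_id -> column position."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["variant_id"])


@dataclass
class PhenotypeTable:
    """Per-sample ROI volumes plus sex, age and intracranial volume.

    ``table`` is indexed by sample_id with columns sex, age, icv and one column
    per ROI (NaN = missing).  Hemispheric columns named ``<roi>_left`` /
    ``<roi>_right`` are averaged into ``<roi>`` at ingestion.
    """

    table: pd.DataFrame
    rois: list[str]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample_id in phenotype table")
        for col in ("sex", "age", "icv"):
            if col not in self.table.columns:
                raise ValidationError(f"phenotype table missing covariate column {col!r}")
        for roi in self.rois:
            if roi not in self.table.columns:
                raise ValidationError(f"phenotype table missing ROI column {roi!r}")
            v = self.table[roi]
            if (v.dropna() <= 0).any():
                raise ValidationError(f"non-positive volume in ROI {roi!r}")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None) -> SummaryStats:
    """Read a whitespace/TSV summary-statistics table.

    Parameters
    ----------
    path
        File with a header row.  Canonical columns are
        ``SNP CHR BP A1 A2 OR P`` (A1 = effect allele).
    dialect
        Optional map from canonical column name to the name used in the file,
        e.g. ``{"SNP": "rsid", "P": "pval"}``.

    Rows with non-ACGT alleles, OR <= 0 or P outside (0, 1] are rejected
    individually and reported in ``SummaryStats.rejected``; the OR column is
    converted to a natural-log weight.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty summary-statistics file: {path}") from None
    colmap = dict(zip(SUMSTATS_COLUMNS, SUMSTATS_COLUMNS))
    if dialect:
        colmap.update(dialect)
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            raise FormatError(f"missing required column {actual!r} (for {canonical})")
    df = pd.DataFrame(
        {
            "variant_id": raw[colmap["SNP"]].astype(str),
            "chrom": raw[colmap["CHR"]].astype(str),
            "pos": pd.to_numeric(raw[colmap["BP"]], errors="coerce"),
            "effect_allele": raw[colmap["A1"]].str.upper(),
            "other_allele": raw[colmap["A2"]].str.upper(),
            "odds_ratio": pd.to_numeric(raw[colmap["OR"]], errors="coerce"),
            "pvalue": pd.to_numeric(raw[colmap["P"]], errors="coerce"),
        }
    )
    rejected: list[dict] = []

    def _reject(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask]:
            rejected.append({"row": int(idx), "variant_id": df.at[idx, "variant_id"], "reason": reason})

    bad_allele = ~(
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    bad_or = ~(df["odds_ratio"] > 0)
    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    bad_pos = ~(df["pos"] >= 1)
    _reject(bad_allele, "invalid alleles")
    _reject(bad_or & ~bad_allele, "odds ratio not strictly positive")
    _reject(bad_p & ~bad_allele & ~bad_or, "P outside (0, 1]")
    _reject(bad_pos & ~bad_allele & ~bad_or & ~bad_p, "invalid position")
    keep = ~(bad_allele | bad_or | bad_p | bad_pos)
    df = df.loc[keep].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "weight": np.log(df["odds_ratio"].to_numpy(float)),
            "pvalue": df["pvalue"].astype(float),
        }
    )
    return SummaryStats(out, rejected)


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write canonical-dialect summary statistics (OR = exp(weight))."""
    t = ss.table
    out = pd.DataFrame(
        {
            "SNP": t["variant_id"],
            "CHR": t["chrom"],
            "BP": t["pos"],
            "A1": t["effect_allele"],
            "A2": t["other_allele"],
            "OR": np.exp(t["weight"].to_numpy(float)),
            "P": t["pvalue"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotype dosages.

    ``format`` is one of ``tsv`` (plain dosage matrix), ``vcf`` (DS field if
    present, otherwise GT allele counts) or ``plink-bed`` (SNP-major
    .bed/.bim/.fam triple; pass the .bed path).  Dosages always count copies of
    ``allele_b``; missing calls stay missing.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "plink-bed":
        return _read_genotypes_bed(path)
    raise FormatError(f"unknown genotype format {format!r} (expected vcf, plink-bed or tsv)")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty genotype file: {path}") from None
    missing = [c for c in VARIANT_FIELDS if c not in raw.columns]
    if missing:
        raise FormatError(f"genotype TSV missing columns: {missing}")
    sample_cols = [c for c in raw.columns if c not in VARIANT_FIELDS]
    if not sample_cols:
        raise FormatError("genotype TSV has no sample columns")
    variants = raw[VARIANT_FIELDS].copy()
    variants["pos"] = variants["pos"].astype(int)
    dosages = raw[sample_cols].to_numpy(dtype=float).T  # rows were variants
    return GenotypeMatrix(list(sample_cols), variants.reset_index(drop=True), dosages)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the plain TSV dosage layout (one row per variant)."""
    df = gm.variants.copy()
    mat = pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)
    pd.concat([df.reset_index(drop=True), mat], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = ALT count, 3 = missing
    samples = list(vcf.samples)
    rows, meta = [], []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}")
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        meta.append(
            {
                "variant_id": vid,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "allele_a": rec.REF.upper(),
                "allele_b": rec.ALT[0].upper(),
            }
        )
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(-1)
            vals = np.where((vals < 0) | (vals > 2), np.nan, vals)
        else:
            # gt_types: 0=hom-ref 1=het 2=hom-alt 3=unknown
            gt = np.asarray(rec.gt_types, dtype=float)
            vals = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        if vals.shape[0] != len(samples):
            raise FormatError(f"sample-count mismatch in VCF record {vid}")
        rows.append(vals)
    if not rows:
        raise FormatError(f"no usable records in VCF {path}")
    variants = pd.DataFrame(meta)
    return GenotypeMatrix(samples, variants, np.asarray(rows).T)


# PLINK .bed codec: SNP-major, 2 bits/genotype, magic 0x6c 0x1b 0x01.
# Bit codes: 00=hom allele1, 01=missing, 10=het, 11=hom allele2.
# We orient dosages to count allele1 (bim col 5), so allele_b = allele1.
_BED_MAGIC = b"\x6c\x1b\x01"
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_genotypes_bed(path: str | Path) -> GenotypeMatrix:
    bed = Path(path)
    bim, fam = bed.with_suffix(".bim"), bed.with_suffix(".fam")
    for p in (bed, bim, fam):
        if not p.exists():
            raise FormatError(f"no such file: {p}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam_df[1].tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None, dtype=str,
        names=["chrom", "variant_id", "cm", "pos", "allele1", "allele2"],
    )
    variants = pd.DataFrame(
        {
            "variant_id": bim_df["variant_id"],
            "chrom": bim_df["chrom"],
            "pos": bim_df["pos"].astype(int),
            "allele_a": bim_df["allele2"].str.upper(),
            "allele_b": bim_df["allele1"].str.upper(),
        }
    )
    n, m = len(sample_ids), len(variants)
    data = bed.read_bytes()
    if data[:3] != _BED_MAGIC:
        raise FormatError(f"{bed}: not a SNP-major PLINK .bed file")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise FormatError(f"{bed}: size inconsistent with {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_plink_bed(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call dosages as a PLINK .bed/.bim/.fam triple.

    Dosages must be in {0, 1, 2} or missing; fractional values are rejected.
    """
    bed = Path(path)
    d = gm.dosages
    hard = np.where(np.isnan(d), 1.0, d)  # placeholder; missing handled below
    if not np.all(np.isin(hard, (0.0, 1.0, 2.0))):
        raise ValidationError("plink-bed output requires hard calls in {0,1,2}")
    n, m = d.shape
    codes = np.full((m, n), 1, dtype=np.uint8)  # 01 = missing
    dT = d.T
    codes[dT == 2.0] = 0b00  # hom allele1 (allele_b)
    codes[dT == 1.0] = 0b10
    codes[dT == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = (
        codes.reshape(m, -1, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(struct.pack(f"{packed.size}B", *packed.reshape(-1)))
    v = gm.variants
    bim = pd.DataFrame(
        {
            0: v["chrom"],
            1: v["variant_id"],
            2: 0,
            3: v["pos"],
            4: v["allele_b"],
            5: v["allele_a"],
        }
    )
    bim.to_csv(bed.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {0: gm.sample_ids, 1: gm.sample_ids, 2: 0, 3: 0, 4: 0, 5: -9}
    )
    fam.to_csv(bed.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, rois: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a TSV phenotype/covariate table.

    Must contain ``sample_id``, ``sex``, ``age``, ``icv``.  ROI columns are
    either plain (one column per ROI) or hemispheric pairs ``<roi>_left`` /
    ``<roi>_right``, which are averaged; a sample missing either side has the
    averaged metric declared missing.  ``rois`` restricts/validates the ROI
    set; by default every non-covariate column (after averaging) is an ROI.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in raw.columns:
        raise FormatError("phenotype table missing 'sample_id' column")
    raw = raw.set_index(raw["sample_id"].astype(str)).drop(columns="sample_id")
    covars = ["sex", "age", "icv"]
    for c in covars:
        if c not in raw.columns:
            raise FormatError(f"phenotype table missing covariate column {c!r}")
    value_cols = [c for c in raw.columns if c not in covars]
    averaged: dict[str, pd.Series] = {}
    used = set()
    for col in value_cols:
        if col.endswith("_left"):
            base = col[: -len("_left")]
            right = f"{base}_right"
            if right in raw.columns:
                averaged[base] = (raw[col] + raw[right]) / 2.0
                used.update((col, right))
    plain = [c for c in value_cols if c not in used and c not in averaged]
    table = raw[covars].copy()
    for name in plain:
        table[name] = raw[name]
    for name, series in averaged.items():
        table[name] = series
    roi_list = list(rois) if rois is not None else plain + list(averaged)
    return PhenotypeTable(table, roi_list)


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    out = pt.table.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# harmonization and frequency filtering
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a1.map(_COMPLEMENT) == a2


def harmonize(
    ss: SummaryStats,
    gm: GenotypeMatrix,
    drop_ambiguous: bool = True,
    match_by: str = "variant_id",
) -> SummaryStats:
    """Restrict summary stats to gm's variants, orienting weights to allele_b.

    Matching is by ``variant_id`` (default) or by ``position`` (chrom+pos).
    For each shared variant the effect/other pair is compared with gm's
    (allele_b, allele_a): an exact match keeps the weight, a swap negates it,
    and the same rules apply after strand complement.  Strand-ambiguous A/T
    and C/G variants are dropped when ``drop_ambiguous`` is set; allele pairs
    that cannot be reconciled are dropped with a per-variant report.
    """
    if len(ss) == 0 or gm.n_variants == 0:
        raise HarmonizeError("empty input to harmonize")
    gv = gm.variants
    if match_by == "variant_id":
        merged = ss.table.merge(
            gv[["variant_id", "allele_a", "allele_b"]], on="variant_id", how="inner"
        )
    elif match_by == "position":
        merged = ss.table.merge(
            gv[["variant_id", "chrom", "pos", "allele_a", "allele_b"]].rename(
                columns={"variant_id": "_gm_id"}
            ),
            on=["chrom", "pos"],
            how="inner",
        )
        merged["variant_id"] = merged.pop("_gm_id")
    else:
        raise ValueError(f"unknown match_by {match_by!r}")
    if merged.empty:
        raise HarmonizeError("no shared variants between summary stats and genotypes")

    rejected = list(ss.rejected)
    ea, oa = merged["effect_allele"], merged["other_allele"]
    ba, bb = merged["allele_a"], merged["allele_b"]
    ambiguous = _is_ambiguous(ea, oa)
    same = (ea == bb) & (oa == ba)
    swapped = (ea == ba) & (oa == bb)
    ea_c, oa_c = ea.map(_COMPLEMENT), oa.map(_COMPLEMENT)
    flip_same = (ea_c == bb) & (oa_c == ba)
    flip_swapped = (ea_c == ba) & (oa_c == bb)

    keep = same | swapped | flip_same | flip_swapped
    if drop_ambiguous:
        keep &= ~ambiguous
        for vid in merged.loc[ambiguous, "variant_id"]:
            rejected.append({"variant_id": vid, "reason": "strand-ambiguous alleles"})
    for vid in merged.loc[~(same | swapped | flip_same | flip_swapped), "variant_id"]:
        rejected.append({"variant_id": vid, "reason": "allele mismatch"})

    out = merged.loc[keep].copy()
    sign = np.where(swapped[keep] | flip_swapped[keep], -1.0, 1.0)
    out["weight"] = out["weight"].to_numpy(float) * sign
    out["effect_allele"] = out["allele_b"]
    out["other_allele"] = out["allele_a"]
    out = out[SS_FIELDS].reset_index(drop=True)
    if out.empty:
        raise HarmonizeError("all shared variants dropped during harmonization")
    return SummaryStats(out, rejected)


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant allele_b frequency from non-missing dosages (NaN if none)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(gm.dosages, axis=0) / 2.0


def maf_filter(ss: SummaryStats, gm: GenotypeMatrix, threshold: float = 0.01) -> SummaryStats:
    """Drop variants whose minor-allele frequency in gm is strictly below threshold.

    Frequency is mean dosage / 2 over non-missing samples, folded to <= 0.5.
    Variants absent from gm are kept with a warning (they cannot be assessed).
    """
    if not 0 < threshold < 0.5:
        raise ValueError("MAF threshold must be in (0, 0.5)")
    freq = allele_frequencies(gm)
    maf = np.minimum(freq, 1.0 - freq)
    maf_by_id = pd.Series(maf, index=gm.variants["variant_id"])
    ss_maf = ss.table["variant_id"].map(maf_by_id)
    absent = ss_maf.isna() & ~ss.table["variant_id"].isin(set(gm.variants["variant_id"]))
    if absent.any():
        warnings.warn(f"{int(absent.sum())} variants absent from genotypes; skipped by MAF filter")
    keep = absent | ~(ss_maf < threshold)
    return SummaryStats(ss.table.loc[keep].reset_index(drop=True), list(ss.rejected))
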