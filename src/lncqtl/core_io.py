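"""Data model, file I/O, configuration and pipeline orchestration.

All genomic coordinates are held 1-based inclusive internally (the VCF/GTF
convention); BED input is parsed as 0-based half-open and converted at the
boundary.  Genotypes are additive alt-allele dosages in {0, 1, 2} with
``NaN`` for missing calls, so the "effect allele" of every reported beta is
the alt allele.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lncqtl")
if not logger.handlers:  # library default: stderr, INFO
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def get_logger(name: str | None = None) -> logging.Logger:
    """Return the package logger, or a child of it."""
    return logger if name is None else logger.getChild(name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "info_score", "maf"]
FEATURE_META_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "biotype"]

EXPRESSION_STAGES = (
    "raw_rpkm",
    "raw_count",
    "filtered",
    "quantile_normalized",
    "inverse_normal",
    "log2",
)


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP (1-based position)."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    info_score: float | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class FeatureMeta:
    """Annotation of one expression feature (1-based inclusive interval)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "lncRNA"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start {self.start} > end {self.end}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    snps : pandas.DataFrame
        One row per SNP with columns ``SNP_META_COLUMNS``; ``info_score`` and
        ``maf`` may be NaN. ``snp_id`` must be unique.
    dosage : ndarray of shape (n_samples, n_snps)
        Alt-allele counts in {0, 1, 2}; NaN marks missing calls.
    call_posterior : ndarray or None
        Optional per-call posterior probabilities in [0, 1], same shape.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    call_posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup}")
        if self.call_posterior is not None and self.call_posterior.shape != self.dosage.shape:
            raise ValueError("call_posterior shape mismatch")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls (folded to <= 0.5)."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosage, axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
        self.snps["maf"] = maf
        return maf

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
            call_posterior=None if self.call_posterior is None else self.call_posterior[:, mask],
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            samples=list(keep),
            snps=self.snps.copy(),
            dosage=self.dosage[idx],
            call_posterior=None if self.call_posterior is None else self.call_posterior[idx],
        )


@dataclass
class ExpressionMatrix:
    """Samples x features expression matrix staged through the pipeline.

    ``stage`` tracks the transform state: raw_rpkm / raw_count -> filtered ->
    quantile_normalized -> inverse_normal (used for association scanning);
    log2 is the alternative reportable scale.
    """

    samples: list[str]
    features: pd.DataFrame
    values: np.ndarray
    stage: str = "raw_rpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if self.stage not in EXPRESSION_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage not in ("raw_rpkm", "raw_count") and np.isnan(self.values).any():
            raise ValueError(f"missing values not allowed at stage {self.stage}")
        self.features = self.features.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return self.features["feature_id"].tolist()

    def subset_features(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            samples=list(self.samples),
            features=self.features.loc[mask].reset_index(drop=True),
            values=self.values[:, mask],
            stage=self.stage,
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in keep]
        return ExpressionMatrix(
            samples=list(keep),
            features=self.features.copy(),
            values=self.values[idx],
            stage=self.stage,
        )


@dataclass
class CovariateTable:
    """Per-sample covariates plus per-sample-per-feature somatic covariates.

    ``latent_factors`` holds K latent expression covariates (default K=5),
    estimated by the pipeline or supplied.  ``scna`` and ``methylation_level``
    are samples x feature_id frames; methylation is the ordinal promoter level
    in {0, 1, 2} (NaN = no probes for that feature).
    """

    samples: list[str]
    age: np.ndarray
    sex: np.ndarray
    purity: np.ndarray
    latent_factors: np.ndarray | None = None
    scna: pd.DataFrame | None = None
    methylation_level: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.samples)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.purity = np.asarray(self.purity, dtype=float)
        for name, arr in (("age", self.age), ("sex", self.sex), ("purity", self.purity)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != {n} samples")
        if not np.isin(self.sex[~np.isnan(self.sex)], (0.0, 1.0)).all():
            raise ValueError("sex must be coded 0/1")
        if self.latent_factors is not None:
            self.latent_factors = np.asarray(self.latent_factors, dtype=float)
            if self.latent_factors.shape[0] != n:
                raise ValueError("latent_factors row count mismatch")
        if self.methylation_level is not None:
            vals = self.methylation_level.to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise ValueError("methylation_level values must be in {0,1,2}")

    def design_matrix(self, include_latent: bool = True) -> np.ndarray:
        """Intercept + age + sex (+ latent factors) design for the scan model.

        Constant covariate columns are dropped (they are collinear with the
        intercept, e.g. sex in a single-sex cohort).
        """
        cols = [c for c in (self.age, self.sex) if np.ptp(c) > 0]
        X = np.column_stack([np.ones(len(self.samples))] + cols)
        if include_latent and self.latent_factors is not None and self.latent_factors.shape[1]:
            X = np.column_stack([X, self.latent_factors])
        return X

    def subset_samples(self, keep: Sequence[str]) -> "CovariateTable":
        idx = [self.samples.index(s) for s in keep]
        return CovariateTable(
            samples=list(keep),
            age=self.age[idx],
            sex=self.sex[idx],
            purity=self.purity[idx],
            latent_factors=None if self.latent_factors is None else self.latent_factors[idx],
            scna=None if self.scna is None else self.scna.iloc[idx],
            methylation_level=None
            if self.methylation_level is None
            else self.methylation_level.iloc[idx],
        )


@dataclass
class GwasCatalogTable:
    """GWAS catalog-style table of risk SNPs: (risk_snp_id, chrom, pos, trait)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"risk_snp_id", "chrom", "pos", "trait"}
        if not need.issubset(self.rows.columns):
            raise ValueError(f"GWAS catalog missing columns {need - set(self.rows.columns)}")
        if (self.rows["pos"] < 1).any():
            raise ValueError("GWAS catalog positions must be 1-based (>= 1)")
        if (self.rows["trait"].astype(str).str.len() == 0).any():
            raise ValueError("empty trait in GWAS catalog")


@dataclass
class PeakSet:
    """ChIP-seq peak intervals for one marker, 0-based half-open, merged."""

    marker_name: str = ""
    cell_line: str = ""
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    # intervals: chrom -> (k, 2) int array of [start0, end), sorted, non-overlapping

    def __post_init__(self) -> None:
        merged = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and (arr[:, 1] <= arr[:, 0]).any():
                raise ValueError(f"peak with end <= start on {chrom}")
            merged[chrom] = _merge_intervals(arr)
        self.intervals = merged

    @property
    def n_intervals(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values()))

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Point-in-peak membership for 1-based positions.

        A 1-based position p corresponds to the 0-based point p-1, which is
        inside the half-open interval [start0, end) iff start0 <= p-1 < end.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(pos.shape, dtype=bool)
        for c in np.unique(chrom):
            arr = self.intervals.get(str(c))
            if arr is None or not len(arr):
                continue
            sel = chrom == c
            p0 = pos[sel] - 1
            idx = np.searchsorted(arr[:, 0], p0, side="right") - 1
            ok = idx >= 0
            ok[ok] = p0[ok] < arr[idx[ok], 1]
            out[sel] = ok
        return out


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    if not len(arr):
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class ImmuneFractionTable:
    """Deconvolved immune-cell fractions per sample (CIBERSORT-style)."""

    samples: list[str]
    cell_types: list[str]
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.fraction.shape != (len(self.samples), len(self.cell_types)):
            raise ValueError("fraction shape mismatch")
        if ((self.fraction < 0) | (self.fraction > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        if (self.fraction.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("row fraction sums exceed 1")

    def subset_samples(self, keep: Sequence[str]) -> "ImmuneFractionTable":
        idx = [self.samples.index(s) for s in keep]
        return ImmuneFractionTable(list(keep), list(self.cell_types), self.fraction[idx])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

MISSING_TOKENS = {"", "NA", "NaN", "nan", "."}


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT field) or a TSV dosage matrix.

    TSV layout: columns ``snp_id chrom pos ref_allele alt_allele info_score``
    followed by one column per sample holding dosages 0/1/2 or NA.
    VCF: dosage = alt-allele count from GT; ``./.`` becomes missing;
    multi-allelic records are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows, dos_cols = [], []
    n_multi = 0
    seen: set[str] = set()
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ValueError(f"duplicate snp_id: {snp_id}")
        seen.add(snp_id)
        info = var.INFO.get("INFO")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        meta_rows.append(
            dict(
                snp_id=snp_id,
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                info_score=np.nan if info is None else float(info),
                maf=np.nan,
            )
        )
        dos_cols.append(dos)
    if n_multi:
        logger.info("read_genotypes: skipped %d multi-allelic records", n_multi)
    snps = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    dosage = np.column_stack(dos_cols) if dos_cols else np.zeros((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in SNP_META_COLUMNS if c in df.columns]
    if "snp_id" not in meta_cols or "chrom" not in meta_cols or "pos" not in meta_cols:
        raise ValueError(f"{path}: genotype TSV needs snp_id/chrom/pos columns")
    sample_cols = [c for c in df.columns if c not in SNP_META_COLUMNS]
    dosage = df[sample_cols].to_numpy(dtype=float).T  # samples x snps
    ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(f"{path}: bad dosage {dosage[i, j]} (sample {sample_cols[i]}, row {j + 2})")
    snps = df[meta_cols].copy()
    for col in SNP_META_COLUMNS:
        if col not in snps.columns:
            snps[col] = np.nan if col in ("info_score", "maf") else ("A" if col == "ref_allele" else "G")
    return GenotypeMatrix(samples=sample_cols, snps=snps[SNP_META_COLUMNS], dosage=dosage)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as the TSV dosage layout read_genotypes accepts."""
    dos = pd.DataFrame(gm.dosage.T, columns=gm.samples)
    df = pd.concat([gm.snps.reset_index(drop=True), dos], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_feature_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"feature_id", "chrom", "start", "end"}
    if not need.issubset(ann.columns):
        raise ValueError(f"{path}: annotation missing columns {need - set(ann.columns)}")
    if "strand" not in ann.columns:
        ann["strand"] = "+"
    if "biotype" not in ann.columns:
        ann["biotype"] = "lncRNA"
    if (ann["start"] > ann["end"]).any():
        bad = ann.loc[ann["start"] > ann["end"], "feature_id"].iloc[0]
        raise ValueError(f"{path}: start > end for feature {bad}")
    return ann[FEATURE_META_COLUMNS]


def read_expression(
    path: str | Path, annotation_path: str | Path, stage: str = "raw_rpkm"
) -> ExpressionMatrix:
    """Read an expression TSV (rows = features, cols = samples) plus annotation.

    Features missing from the annotation are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        df = df.rename(columns={df.columns[0]: "feature_id"})
    ann = read_feature_annotation(annotation_path)
    known = set(ann["feature_id"])
    drop = ~df["feature_id"].isin(known)
    if drop.any():
        logger.warning("read_expression: dropped %d features lacking annotation", int(drop.sum()))
        df = df.loc[~drop]
    sample_cols = [c for c in df.columns if c != "feature_id"]
    try:
        values = df[sample_cols].to_numpy(dtype=float).T
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    ann = ann.set_index("feature_id").loc[df["feature_id"]].reset_index()
    return ExpressionMatrix(samples=sample_cols, features=ann[FEATURE_META_COLUMNS], values=values, stage=stage)


def write_expression(em: ExpressionMatrix, path: str | Path, annotation_path: str | Path | None = None) -> None:
    out = pd.DataFrame(em.values.T, columns=em.samples)
    out.insert(0, "feature_id", em.feature_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if annotation_path is not None:
        em.features.to_csv(annotation_path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    """Read the per-sample covariate TSV: sample_id, age, sex, purity."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "age", "sex", "purity"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: covariate table missing {need - set(df.columns)}")
    return CovariateTable(
        samples=df["sample_id"].astype(str).tolist(),
        age=df["age"].to_numpy(float),
        sex=df["sex"].to_numpy(float),
        purity=df["purity"].to_numpy(float),
    )


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": cov.samples, "age": cov.age, "sex": cov.sex, "purity": cov.purity}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_by_feature(path: str | Path) -> pd.DataFrame:
    """Read a samples x features TSV (first column sample_id) — SCNA/methylation."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_bed(path: str | Path, marker_name: str = "", cell_line: str = "") -> PeakSet:
    """Read a BED3+ file into a PeakSet (0-based half-open; overlaps merged)."""
    intervals: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end {end} <= start {start}")
            intervals.setdefault(chrom, []).append([start, end])
    return PeakSet(
        marker_name=marker_name,
        cell_line=cell_line,
        intervals={c: np.asarray(v, dtype=np.int64) for c, v in intervals.items()},
    )


def read_gwas_catalog(path: str | Path) -> GwasCatalogTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "snp_id" in df.columns and "risk_snp_id" not in df.columns:
        df = df.rename(columns={"snp_id": "risk_snp_id"})
    return GwasCatalogTable(rows=df)


def read_immune_fractions(path: str | Path) -> ImmuneFractionTable:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return ImmuneFractionTable(
        samples=[str(s) for s in df.index],
        cell_types=[str(c) for c in df.columns],
        fraction=df.to_numpy(float),
    )


def write_immune_fractions(tab: ImmuneFractionTable, path: str | Path) -> None:
    df = pd.DataFrame(tab.fraction, index=pd.Index(tab.samples, name="sample_id"), columns=tab.cell_types)
    df.to_csv(path, sep="\t", float_format="%.10g")


def align_samples(*objects) -> list:
    """Subset every object to the ordered intersection of their sample ids.

    The intersection keeps the sample order of the first object; the size of
    the intersection is logged. Objects may be None (passed through).
    """
    sample_sets = [set(o.samples) for o in objects if o is not None]
    if not sample_sets:
        return list(objects)
    common = set.intersection(*sample_sets)
    first = next(o for o in objects if o is not None)
    keep = [s for s in first.samples if s in common]
    logger.info("align_samples: %d shared samples across %d inputs", len(keep), len(sample_sets))
    if not keep:
        raise ValueError("no shared samples across inputs")
    return [None if o is None else o.subset_samples(keep) for o in objects]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds and input paths for a full pipeline run.

    Defaults are the study's analysis settings: purity >= 0.6, INFO >= 0.5,
    MAF >= 5%, missing rate < 5% (best-guess calls at posterior >= 0.7),
    HWE exact p > 1e-6, 1 Mb cis window, cis FDR < 0.1, trans p < 1e-7,
    clumping at r^2 = 0.2 within 500 kb, GWAS LD proxies at r^2 >= 0.5 within
    500 kb, five latent expression factors, and the instrumental-variable
    gates (mRNA CV > 0.5, |Spearman rho| > 0.3, axis FDR < 0.1 with adjusted
    R^2 > 0.1, immune p < 0.05 with R^2 > 0).
    """

    # sample / genotype QC
    purity_min: float = 0.6
    info_min: float = 0.5
    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_min: float = 1e-6
    posterior_min: float = 0.7
    # expression filtering / latent factors
    n_latent_factors: int = 5
    # eQTL scan
    cis_window: int = 1_000_000
    cis_fdr: float = 0.1
    trans_p: float = 1e-7
    clump_r2: float = 0.2
    clump_window: int = 500_000
    # GWAS interception
    gwas_r2: float = 0.5
    gwas_window: int = 500_000
    # instrumental-variable stage
    mrna_cv_min: float = 0.5
    spearman_min: float = 0.3
    axis_fdr: float = 0.1
    axis_adj_r2: float = 0.1
    immune_p_max: float = 0.05
    immune_r2_min: float = 0.0
    # run control
    seed: int = 0
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, lo, hi in [
            ("purity_min", 0, 1),
            ("info_min", 0, 1),
            ("maf_min", 0, 0.5),
            ("miss_max", 0, 1),
            ("hwe_min", 0, 1),
            ("posterior_min", 0, 1),
            ("cis_fdr", 0, 1),
            ("trans_p", 0, 1),
            ("clump_r2", 0, 1),
            ("gwas_r2", 0, 1),
            ("axis_fdr", 0, 1),
            ("immune_p_max", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config: {name}={v} outside [{lo}, {hi}]")
        if self.cis_window <= 0 or self.clump_window <= 0 or self.gwas_window <= 0:
            raise ValueError("config: windows must be positive")
        if self.n_latent_factors < 0:
            raise ValueError("config: n_latent_factors must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full analysis from the files named in ``config.inputs``.

    Required inputs: genotypes (``genotypes`` [+ ``genotype_format``]),
    lncRNA expression (``lncrna``, ``lncrna_annotation``), covariates
    (``covariates``).  Optional: ``scna``, ``methylation_level`` (sample x
    feature TSVs of pre-discretized levels), ``mrna`` + ``mrna_annotation``,
    ``immune_fractions``, ``gwas_catalog``.

    Writes one TSV per stage plus ``run_manifest.json`` into ``outdir`` and
    returns ``outdir``.  The run is deterministic: every stage is a pure
    function of the inputs and thresholds.
    """
    # imported here: orchestration sits above the stage modules
    from . import eqtl as eqtl_mod
    from . import mr as mr_mod
    from . import preprocess as pp
    from . import variance as var_mod

    outdir = Path(outdir)
    inputs = config.inputs
    for key in ("genotypes", "lncrna", "lncrna_annotation", "covariates"):
        if key not in inputs:
            raise ValueError(f"config.inputs missing required path {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(inputs[key])
    for key, p in inputs.items():
        if key != "genotype_format" and not Path(p).exists():
            raise FileNotFoundError(p)
    outdir.mkdir(parents=True, exist_ok=True)

    geno = read_genotypes(inputs["genotypes"], format=inputs.get("genotype_format", "tsv"))
    lnc = read_expression(inputs["lncrna"], inputs["lncrna_annotation"], stage="raw_rpkm")
    cov = read_covariates(inputs["covariates"])
    if "scna" in inputs:
        cov.scna = read_sample_by_feature(inputs["scna"]).reindex(cov.samples)
    if "methylation_level" in inputs:
        cov.methylation_level = read_sample_by_feature(inputs["methylation_level"]).reindex(cov.samples)
    mrna = (
        read_expression(inputs["mrna"], inputs["mrna_annotation"], stage="raw_count")
        if "mrna" in inputs
        else None
    )
    immune = read_immune_fractions(inputs["immune_fractions"]) if "immune_fractions" in inputs else None
    catalog = read_gwas_catalog(inputs["gwas_catalog"]) if "gwas_catalog" in inputs else None

    geno, lnc, cov, mrna, immune = align_samples(geno, lnc, cov, mrna, immune)

    # --- QC ---
    keep = pp.filter_samples_by_purity(cov, threshold=config.purity_min)
    geno, lnc, cov, mrna, immune = (
        geno.subset_samples(keep),
        lnc.subset_samples(keep),
        cov.subset_samples(keep),
        None if mrna is None else mrna.subset_samples(keep),
        None if immune is None else immune.subset_samples(keep),
    )
    geno, geno_report = pp.qc_genotypes(
        geno,
        info_min=config.info_min,
        maf_min=config.maf_min,
        miss_max=config.miss_max,
        hwe_min=config.hwe_min,
        posterior_min=config.posterior_min,
    )
    lnc_filt, expr_report = pp.filter_lncrna_expression(lnc)
    qc_rows = geno_report.to_frame()
    qc_rows = pd.concat([qc_rows, expr_report.to_frame()], ignore_index=True)
    qc_rows.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)

    # --- normalisation + latent factors ---
    lnc_qn = pp.quantile_normalize(lnc_filt)
    lnc_int = pp.inverse_normal(lnc_qn)
    cov.latent_factors = pp.estimate_latent_factors(lnc_int, k=config.n_latent_factors, covariates=cov)

    # --- eQTL scan ---
    cis = eqtl_mod.scan_eqtl(geno, lnc_int, cov, mode="cis", cis_window=config.cis_window)
    trans = eqtl_mod.scan_eqtl(geno, lnc_int, cov, mode="trans", cis_window=config.cis_window)
    if len(cis):
        cis["fdr"] = eqtl_mod.bh_fdr(cis["p"].to_numpy())
    cis_sig = cis[cis["fdr"] < config.cis_fdr] if len(cis) else cis
    trans_sig = trans[trans["p"] < config.trans_p] if len(trans) else trans
    cis.to_csv(outdir / "eqtl_cis.tsv", sep="\t", index=False, float_format="%.6g")
    trans.to_csv(outdir / "eqtl_trans.tsv", sep="\t", index=False, float_format="%.6g")

    clumped = eqtl_mod.clump_all(
        pd.concat([cis_sig, trans_sig], ignore_index=True),
        geno,
        r2_min=config.clump_r2,
        window_bp=config.clump_window,
    )
    clumped.to_csv(outdir / "clumped.tsv", sep="\t", index=False, float_format="%.6g")

    validated = eqtl_mod.validate_all(clumped, geno, lnc_int, cov)
    validated.to_csv(outdir / "validated.tsv", sep="\t", index=False, float_format="%.6g")

    # --- variance partition ---
    variance = var_mod.partition_all(clumped, geno, lnc_int, cov)
    variance.to_csv(outdir / "variance.tsv", sep="\t", index=False, float_format="%.6g")

    # --- GWAS interception + enrichment ---
    from . import overlap_enrichment as enr

    if catalog is not None:
        tags = clumped.loc[clumped["is_tag"], "snp_id"].unique()
        proxies = enr.build_ld_proxies(catalog, geno, r2_min=config.gwas_r2, window_bp=config.gwas_window)
        flags, pct = enr.gwas_intercept(tags, proxies)
        tested = set(pd.concat([cis, trans])["snp_id"].unique()) if len(cis) or len(trans) else set()
        background = sorted(tested - set(tags))
        bg_flags, _ = enr.gwas_intercept(background, proxies)
        fold = enr.fold_enrichment(flags, bg_flags)
        pd.DataFrame(
            {"snp_id": list(tags), "gwas_overlap": flags}
        ).to_csv(outdir / "gwas_overlap.tsv", sep="\t", index=False)
        fold_df = pd.DataFrame([dataclasses.asdict(fold)])
        fold_df.insert(0, "percent_overlap", pct * 100)
        fold_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # --- instrumental-variable stage ---
    if mrna is not None:
        axes = mr_mod.run_axes(
            clumped,
            geno,
            lnc_int,
            mrna,
            cov,
            fdr_max=config.axis_fdr,
            adj_r2_min=config.axis_adj_r2,
            cv_min=config.mrna_cv_min,
            rho_min=config.spearman_min,
        )
        axes.to_csv(outdir / "iv_axes.tsv", sep="\t", index=False, float_format="%.6g")
        if immune is not None:
            imm = mr_mod.run_immune(
                axes,
                geno,
                lnc_int,
                immune,
                cov,
                p_max=config.immune_p_max,
                r2_min=config.immune_r2_min,
            )
            imm.to_csv(outdir / "iv_immune.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "package": "lncqtl",
        "seed": config.seed,
        "thresholds": {k: v for k, v in config.to_dict().items() if k != "inputs"},
        "inputs": {k: str(v) for k, v in inputs.items()},
        "n_samples": geno.n_samples,
        "n_snps_post_qc": geno.n_snps,
        "n_lncrna_post_filter": lnc_filt.n_features,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_pipeline: wrote results to %s", outdir)
    return outdir
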