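"""Genotype matrix container and VCF / label-table I/O.

The central container is :class:`VariantMatrix`: samples x biallelic SNPs
coded as alternate-allele dosages (0, 1, 2, or NaN for missing), with
chromosome/position/allele metadata and optional per-sample population
labels. All downstream statistics (diversity scan, kinship, prediction)
operate on this container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass
class VariantMatrix:
    """Samples x biallelic variants as alt-allele dosages.

    Parameters
    ----------
    sample_ids : list of str
    dosage : ndarray, shape (n_samples, n_variants)
        Values in {0, 1, 2} or NaN for missing.
    chrom : ndarray of str, per variant
    pos : ndarray of int, 1-based position, strictly increasing within chrom
    ref, alt : ndarray of str, single-base alleles
    population_labels : optional per-sample tags (e.g. wild/cultivated/B/R)
    depth : optional per-variant mean read depth (used by the depth filter)
    """

    sample_ids: list
    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    population_labels: np.ndarray | None = None
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n, p = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != p:
                raise ValueError(f"{name} length does not match dosage columns")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if pc.size > 1 and not (np.diff(pc) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.population_labels is not None:
            self.population_labels = np.asarray(self.population_labels, dtype=object)
            if len(self.population_labels) != n:
                raise ValueError("population_labels length mismatch")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if len(self.depth) != p:
                raise ValueError("depth length mismatch")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_counts(self, sample_mask=None):
        """Return (alt_count, total_alleles) per variant over non-missing calls."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask]
        called = ~np.isnan(d)
        alt = np.nansum(d, axis=0)
        tot = 2 * called.sum(axis=0)
        return alt, tot

    def alt_freq(self, sample_mask=None):
        alt, tot = self.allele_counts(sample_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self, sample_mask=None):
        p = self.alt_freq(sample_mask)
        return np.minimum(p, 1 - p)

    def missing_fraction(self):
        return np.isnan(self.dosage).mean(axis=0)

    def take_variants(self, index) -> "VariantMatrix":
        return VariantMatrix(
            sample_ids=list(self.sample_ids),
            dosage=self.dosage[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            population_labels=self.population_labels,
            depth=None if self.depth is None else self.depth[index],
        )

    def take_samples(self, index) -> "VariantMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return VariantMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            dosage=self.dosage[idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            population_labels=None if self.population_labels is None
            else self.population_labels[idx],
            depth=self.depth,
        )

    def equals(self, other: "VariantMatrix") -> bool:
        return (
            list(self.sample_ids) == list(other.sample_ids)
            and self.dosage.shape == other.dosage.shape
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
        )


# -- VCF I/O -----------------------------------------------------------------

def read_vcf(path) -> VariantMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`VariantMatrix`.

    Dosage is the count of alternate alleles from the GT field; half or fully
    missing calls become NaN. Multiallelic records are skipped with a warning.
    An unsorted file raises, naming the first offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (no GT field)")
    chrom, pos, ref, alt, rows, depth = [], [], [], [], [], []
    n_multi = 0
    last = {}
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            raise ValueError(
                f"{path}: unsorted VCF at record {var.CHROM}:{var.POS}"
            )
        last[var.CHROM] = var.POS
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        d = var.INFO.get("DP")
        depth.append(np.nan if d is None else float(d) / len(samples))
    if n_multi:
        logger.warning("%s: skipped %d multiallelic records", path, n_multi)
    depth_arr = np.asarray(depth)
    if np.isnan(depth_arr).all():
        depth_arr = None
    dosage = (np.vstack(rows).T if rows
              else np.empty((len(samples), 0)))
    return VariantMatrix(
        sample_ids=samples, dosage=dosage,
        chrom=np.asarray(chrom, dtype=object), pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object), alt=np.asarray(alt, dtype=object),
        depth=depth_arr,
    )


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(vm: VariantMatrix, path) -> None:
    """Write a :class:`VariantMatrix` as VCF 4.2 (GT only, ./. for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(vm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, vm.sample_ids)) + "\n")
        for j in range(vm.n_variants):
            gts = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in vm.dosage[:, j]
            )
            fh.write(f"{vm.chrom[j]}\t{vm.pos[j]}\t.\t{vm.ref[j]}\t{vm.alt[j]}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_labels(path) -> pd.Series:
    """Read a sample,label CSV into a Series indexed by sample id."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])[df.columns[1]]


# -- filtering ---------------------------------------------------------------

def filter_variants(vm: VariantMatrix, maf_min: float = 0.05,
                    miss_max: float = 0.5,
                    mean_depth_max: float | None = None) -> VariantMatrix:
    """Keep variants with MAF >= maf_min and missing fraction <= miss_max.

    MAF is computed over non-missing alleles only. The mean-depth filter is
    applied only when the matrix carries depth data. Variant order is
    preserved; filtering is idempotent.
    """
    if not (0 <= maf_min <= 1 and 0 <= miss_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    maf = vm.maf()
    keep = (np.nan_to_num(maf, nan=0.0) >= maf_min) & \
           (vm.missing_fraction() <= miss_max)
    if mean_depth_max is not None and vm.depth is not None:
        keep &= ~(vm.depth > mean_depth_max)
    if not keep.any():
        warnings.warn("all variants removed by filter", stacklevel=2)
    return vm.take_variants(np.where(keep)[0])
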