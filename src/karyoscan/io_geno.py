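"""Genotype I/O and site filtering.

Two on-disk formats are supported: multi-sample VCF (plain or bgzipped,
read via cyvcf2) and the VCFtools "012" triplet (``prefix.012`` dosage
table plus ``prefix.012.indv`` and ``prefix.012.pos`` siblings).  Site
filters mirror the standard short-read genotyping pipeline: biallelic SNPs
only, per-genotype minimum depth (failing genotypes set missing), a
site-level mean-depth cap, a minor-allele-frequency floor computed on
non-missing alleles, and a per-site missingness ceiling.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from karyoscan.matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["FilterSpec", "read_genotypes", "write_012", "apply_site_filters"]


@dataclass
class FilterSpec:
    """Site/genotype filter thresholds.

    Defaults reproduce a conservative WGS SNP-panel preparation:
    biallelic SNPs, genotypes below 5 reads set missing, sites with mean
    depth above 25 removed, MAF >= 0.1, and no missing genotypes allowed.
    Set a threshold to ``None`` to disable that filter.
    """

    biallelic_only: bool = True
    min_gt_depth: int | None = 5
    max_mean_depth: float | None = 25.0
    min_maf: float | None = 0.1
    max_missing_frac: float | None = 0.0

    def __post_init__(self) -> None:
        if self.min_maf is not None and not (0.0 <= self.min_maf <= 0.5):
            raise ValueError(f"min_maf must be in [0, 0.5], got {self.min_maf}")
        if self.max_missing_frac is not None and not (0.0 <= self.max_missing_frac <= 1.0):
            raise ValueError(f"max_missing_frac must be in [0, 1], got {self.max_missing_frac}")


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or an 012 triplet.

    Parameters
    ----------
    path
        VCF file, or the 012 prefix / ``.012`` file (sibling ``.indv`` and
        ``.pos`` files must exist).
    format
        ``"vcf"`` or ``"triplet012"``; inferred from the filename when None.
    """
    path = str(path)
    if format is None:
        if path.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
            format = "vcf"
        elif path.endswith(".012") or os.path.exists(path + ".012"):
            format = "triplet012"
        else:
            raise ValueError(f"cannot infer format of {path!r}; pass format=")
    if format == "vcf":
        return _read_vcf(path)
    if format == "triplet012":
        return _read_012(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    have_depth = False
    n_skipped = 0
    for v in vcf:
        # keep biallelic SNPs only; anything else (indel, multi-allelic,
        # missing ALT) is skipped and counted
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        # with gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        try:
            d = v.format("DP")
        except KeyError:
            d = None
        if d is not None and d.shape[0] == len(samples):
            col = d[:, 0].astype(np.int64)
            col[(col < 0) | (col > 10**8)] = -1  # htslib missing sentinels
            depth_cols.append(col.astype(np.int32))
            have_depth = True
        else:
            depth_cols.append(np.full(len(samples), -1, dtype=np.int32))
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if not dosage_cols:
        raise ValueError(f"{path}: no biallelic SNP records found")
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP records", path, n_skipped)
    G = np.column_stack(dosage_cols)
    depth = np.column_stack(depth_cols) if have_depth else None
    mean_depth = np.full(G.shape[1], np.nan)
    if depth is not None:
        md = np.ma.masked_less(depth.astype(float), 0).mean(axis=0)
        mean_depth = np.asarray(md.filled(np.nan))
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "ref": refs, "alt": alts, "mean_depth": mean_depth}
    )
    gm = _sorted_matrix(samples, sites, G, depth)
    return gm


def _sorted_matrix(samples, sites, G, depth) -> GenotypeMatrix:
    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeMatrix(
        samples=samples,
        sites=sites.iloc[order].reset_index(drop=True),
        G=G[:, order],
        gt_depth=depth[:, order] if depth is not None else None,
    )


def _read_012(path: str) -> GenotypeMatrix:
    prefix = path[:-4] if path.endswith(".012") else path
    f012, findv, fpos = prefix + ".012", prefix + ".012.indv", prefix + ".012.pos"
    for f in (f012, findv, fpos):
        if not os.path.exists(f):
            raise FileNotFoundError(f"012 triplet incomplete: missing {f}")
    samples = Path(findv).read_text().split()
    if not samples:
        raise ValueError(f"{findv}: empty sample list")
    pos_df = pd.read_csv(fpos, sep="\t", header=None, names=["chrom", "pos"],
                         dtype={"chrom": str, "pos": np.int64})
    if pos_df.empty:
        raise ValueError(f"{fpos}: no sites")
    body = pd.read_csv(f012, sep="\t", header=None, dtype=np.int64)
    # first column is the VCFtools row index
    G = body.iloc[:, 1:].to_numpy(dtype=np.int8)
    if G.shape != (len(samples), len(pos_df)):
        raise ValueError(
            f"{f012}: matrix shape {G.shape} inconsistent with "
            f"{len(samples)} samples / {len(pos_df)} positions"
        )
    sites = pos_df.assign(ref="N", alt="N", mean_depth=np.nan)
    return _sorted_matrix(samples, sites, G, None)


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_012(gm: GenotypeMatrix, prefix: str | os.PathLike) -> tuple[str, str, str]:
    """Write an 012 triplet (VCFtools dialect, missing encoded as -1).

    Returns the three file paths (``.012``, ``.012.indv``, ``.012.pos``).
    """
    if gm.n_sites == 0 or gm.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    prefix = str(prefix)
    f012, findv, fpos = prefix + ".012", prefix + ".012.indv", prefix + ".012.pos"
    with open(f012, "w") as fh:
        for i in range(gm.n_samples):
            row = "\t".join(str(int(g)) for g in gm.G[i])
            fh.write(f"{i}\t{row}\n")
    Path(findv).write_text("".join(s + "\n" for s in gm.samples))
    with open(fpos, "w") as fh:
        for chrom, pos in zip(gm.sites["chrom"], gm.sites["pos"]):
            fh.write(f"{chrom}\t{int(pos)}\n")
    return f012, findv, fpos


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def apply_site_filters(
    gm: GenotypeMatrix, spec: FilterSpec
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply site/genotype filters in the order depth -> missingness -> MAF.

    Per-genotype depth below ``min_gt_depth`` sets the genotype missing
    (it does not drop the site); the remaining filters drop sites.  Depth
    filters are skipped with a warning when no depth metadata is present.

    Returns the filtered matrix and a report DataFrame with columns
    ``filter`` and ``sites_removed`` (the minDP row counts genotypes set
    missing instead).
    """
    G = gm.G.copy()
    report: list[tuple[str, int]] = []

    if spec.min_gt_depth is not None:
        if gm.gt_depth is None:
            logger.warning("min_gt_depth filter skipped: no per-genotype depth metadata")
            report.append(("min_gt_depth(skipped)", 0))
        else:
            low = (gm.gt_depth >= 0) & (gm.gt_depth < spec.min_gt_depth) & (G != MISSING)
            G[low] = MISSING
            report.append(("min_gt_depth_genotypes_set_missing", int(low.sum())))

    keep = np.ones(gm.n_sites, dtype=bool)

    if spec.max_mean_depth is not None:
        md = gm.sites["mean_depth"].to_numpy(dtype=float)
        if np.isnan(md).all():
            logger.warning("max_mean_depth filter skipped: no site mean-depth metadata")
            report.append(("max_mean_depth(skipped)", 0))
        else:
            drop = md > spec.max_mean_depth
            report.append(("max_mean_depth", int((drop & keep).sum())))
            keep &= ~drop
    if spec.max_missing_frac is not None:
        miss_frac = (G == MISSING).mean(axis=0)
        drop = miss_frac > spec.max_missing_frac + 1e-12
        report.append(("max_missing", int((drop & keep).sum())))
        keep &= ~drop
    if spec.min_maf is not None:
        ok = G != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        alt = np.where(ok, G, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
        drop = ~(maf >= spec.min_maf - 1e-12)  # NaN MAF (all missing) also dropped
        report.append(("min_maf", int((drop & keep).sum())))
        keep &= ~drop

    out = GenotypeMatrix(
        samples=list(gm.samples),
        sites=gm.sites.iloc[np.flatnonzero(keep)].reset_index(drop=True),
        G=G[:, keep],
        gt_depth=gm.gt_depth[:, keep] if gm.gt_depth is not None else None,
    )
    rep = pd.DataFrame(report, columns=["filter", "sites_removed"])
    return out, rep
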