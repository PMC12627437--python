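"""Seeded diploid genotype simulator with known inversion structure.

The generator emulates the statistical structure the scan assumes rather
than a full coalescent: outside inversions every site is an independent
Hardy–Weinberg draw at an allele frequency sampled uniformly on
[maf_min, 0.5] and folded to either allele, giving the shared baseline
heterozygosity.  Inside an inversion each individual carries 0, 1 or 2
copies of a non-recombining alternative arrangement (Hardy–Weinberg on
the arrangement frequency q, or explicit per-sample karyotypes); a
fraction ``divergence`` of the region's SNPs are fixed differences
between arrangements, at which the genotype equals the karyotype — the
reference arrangement carries the REF allele — and the remaining region
SNPs stay baseline.  Ground truth (bounds, karyotypes, fixed-difference
sites) is returned alongside the matrix, so detection, delimitation and
karyotyping are all scoreable.

Baseline sites carry no linkage: independent sites are the cleanest
realization of the method's null.  No sequencing-error or read-level
realism is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from karyoscan import matrix as mx
from karyoscan.matrix import MISSING, GenotypeMatrix

__all__ = ["SimInversion", "SimConfig", "SimTruth", "simulate_dataset",
           "score_detection", "write_vcf"]


@dataclass
class SimInversion:
    chrom: str
    start_bp: int
    end_bp: int
    alt_arrangement_freq: float = 0.5
    divergence: float = 0.9          # fraction of region SNPs fixed between arrangements
    karyotype_mode: str = "hwe"      # "hwe" | "explicit"
    karyotypes: list[int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_arrangement_freq <= 1.0):
            raise ValueError("alt_arrangement_freq must be in [0, 1]")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.karyotype_mode not in ("hwe", "explicit"):
            raise ValueError("karyotype_mode must be 'hwe' or 'explicit'")
        if self.karyotype_mode == "explicit" and self.karyotypes is None:
            raise ValueError("explicit mode requires karyotypes")


@dataclass
class SimConfig:
    n_samples: int = 24
    #: (name, length_bp, n_snps) per chromosome
    chromosomes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr1", 5_000_000, 50_000)])
    maf_min: float = 0.1
    inversions: list[SimInversion] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        for inv in self.inversions:
            if inv.chrom not in names:
                raise ValueError(f"inversion chromosome {inv.chrom!r} not simulated")
            length = dict((c[0], c[1]) for c in self.chromosomes)[inv.chrom]
            if not (1 <= inv.start_bp <= inv.end_bp <= length):
                raise ValueError(f"inversion bounds outside {inv.chrom}")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    inversions: list[SimInversion]
    #: karyotype (copies of the alternative arrangement) per (sample, inversion)
    karyotypes: np.ndarray           # (n_samples, n_inversions), int
    #: global site indices of the fixed differences, per inversion
    fixed_sites: list[np.ndarray]
    #: site positions per chromosome, for boundary errors in SNP units
    positions: dict[str, np.ndarray]


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a genotype matrix and its ground truth from a seeded config."""
    rng = np.random.default_rng(config.seed)
    N = config.n_samples
    chroms, poss, Gs = [], [], []
    positions: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    offset = 0
    for name, length, n_snps in config.chromosomes:
        if n_snps < 1 or n_snps > length:
            raise ValueError(f"{name}: need 1 <= n_snps <= length_bp")
        pos = np.sort(rng.choice(length, size=n_snps, replace=False)) + 1
        f = rng.uniform(config.maf_min, 0.5, size=n_snps)
        flip = rng.random(n_snps) < 0.5
        p_alt = np.where(flip, 1.0 - f, f)
        G = rng.binomial(2, p_alt[None, :], size=(N, n_snps)).astype(np.int8)
        chroms.extend([name] * n_snps)
        poss.append(pos)
        Gs.append(G)
        positions[name] = pos
        offsets[name] = offset
        offset += n_snps

    G = np.concatenate(Gs, axis=1)
    pos_all = np.concatenate(poss)

    karyos = np.zeros((N, len(config.inversions)), dtype=int)
    fixed_sites: list[np.ndarray] = []
    for k, inv in enumerate(config.inversions):
        cpos = positions[inv.chrom]
        local = np.flatnonzero((cpos >= inv.start_bp) & (cpos <= inv.end_bp))
        n_fixed = int(round(inv.divergence * len(local)))
        fixed_local = np.sort(rng.choice(local, size=n_fixed, replace=False))
        fixed_global = fixed_local + offsets[inv.chrom]
        if inv.karyotype_mode == "explicit":
            kappa = np.asarray(inv.karyotypes, dtype=int)
            if kappa.shape != (N,) or not np.isin(kappa, [0, 1, 2]).all():
                raise ValueError("explicit karyotypes must be N values in {0,1,2}")
        else:
            kappa = rng.binomial(2, inv.alt_arrangement_freq, size=N)
        G[:, fixed_global] = kappa[:, None].astype(np.int8)
        karyos[:, k] = kappa
        fixed_sites.append(fixed_global)

    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = MISSING

    gm = mx.from_arrays(
        samples=[f"S{i:03d}" for i in range(N)],
        chrom=chroms, pos=pos_all, G=G,
        ref=["A"] * len(pos_all), alt=["T"] * len(pos_all),
    )
    truth = SimTruth(inversions=list(config.inversions), karyotypes=karyos,
                     fixed_sites=fixed_sites, positions=positions)
    return gm, truth


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

_CALL_TO_INT = {"0/0": 0, "0/1": 1, "1/1": 2}


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def score_detection(truth: SimTruth, result) -> pd.DataFrame:
    """Score a ScanResult against simulator truth.

    One row per true inversion: detected (reciprocal bp overlap >= 0.5
    with some call's influence area), boundary errors in bp and SNPs,
    karyotype accuracy over callable samples; plus one summary row with
    the count of detected regions matching no truth (false positives).
    """
    kary = result.karyotypes_frame()
    rows = []
    matched_ids: set[str] = set()
    for k, inv in enumerate(truth.inversions):
        tspan = (inv.start_bp, inv.end_bp)
        tlen = tspan[1] - tspan[0] + 1
        best = None
        for r in result.regions:
            if r.chrom != inv.chrom:
                continue
            ov = _overlap(tspan, r.influence_area)
            rlen = r.influence_area[1] - r.influence_area[0] + 1
            if ov / tlen >= 0.5 and ov / rlen >= 0.5:
                best = r
                break
        if best is None:
            rows.append({"inversion": k, "chrom": inv.chrom, "detected": False,
                         "boundary_err_bp": np.nan, "boundary_err_snps": np.nan,
                         "karyotype_accuracy": np.nan})
            continue
        matched_ids.add(best.region_id)
        pos = truth.positions[inv.chrom]
        err_bp = max(abs(best.influence_area[0] - tspan[0]),
                     abs(best.influence_area[1] - tspan[1]))
        # boundary error in SNPs: sites between true and detected boundary
        e_start = int(np.abs(np.searchsorted(pos, best.influence_area[0])
                             - np.searchsorted(pos, tspan[0])))
        e_end = int(np.abs(np.searchsorted(pos, best.influence_area[1])
                           - np.searchsorted(pos, tspan[1])))
        kc = kary[kary["region_id"] == best.region_id].set_index("sample")
        calls = kc["call"].map(_CALL_TO_INT)
        truth_k = pd.Series(truth.karyotypes[:, k],
                            index=[f"S{i:03d}" for i in range(len(truth.karyotypes))])
        callable_ = calls.notna()
        acc = float((calls[callable_] == truth_k[calls.index][callable_]).mean()) \
            if callable_.any() else np.nan
        rows.append({"inversion": k, "chrom": inv.chrom, "detected": True,
                     "boundary_err_bp": float(err_bp),
                     "boundary_err_snps": float(max(e_start, e_end)),
                     "karyotype_accuracy": acc})
    n_fp = sum(1 for r in result.regions if r.region_id not in matched_ids)
    rows.append({"inversion": -1, "chrom": "*", "detected": np.nan,
                 "boundary_err_bp": np.nan, "boundary_err_snps": np.nan,
                 "karyotype_accuracy": np.nan, "false_positives": n_fp})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> str:
    """Write a minimal GT-only VCF (uncompressed)."""
    path = str(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gm.chroms:
            sl = gm.chrom_slice(chrom)
            max_pos = int(gm.sites["pos"].iloc[sl.stop - 1])
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sites = gm.sites
        for i in range(gm.n_sites):
            gts = "\t".join(gt_map[int(g)] for g in gm.G[:, i])
            # placeholder alleles when none are recorded (e.g. 012 input)
            ref = sites["ref"].iloc[i] if sites["ref"].iloc[i] != "N" else "A"
            alt = sites["alt"].iloc[i] if sites["alt"].iloc[i] != "N" else "T"
            fh.write(f"{sites['chrom'].iloc[i]}\t{int(sites['pos'].iloc[i])}\t.\t"
                     f"{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def write_truth(truth: SimTruth, path: str | os.PathLike) -> str:
    """Write ground truth as TSV (one row per sample x inversion)."""
    rows = []
    n = truth.karyotypes.shape[0]
    for k, inv in enumerate(truth.inversions):
        for i in range(n):
            rows.append({"sample": f"S{i:03d}", "inversion": k, "chrom": inv.chrom,
                         "start_bp": inv.start_bp, "end_bp": inv.end_bp,
                         "alt_arrangement_freq": inv.alt_arrangement_freq,
                         "divergence": inv.divergence,
                         "karyotype": int(truth.karyotypes[i, k])})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return str(path)
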