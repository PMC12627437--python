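"""Simulation-based performance benchmarks of the detector.

Three study conditions are exercised, all on seeded synthetic data at a
desk scale chosen to mirror a 24-individual WGS panel:

* parameter recovery — 24 samples, three 5 Mb chromosomes of 50,000 SNPs,
  one 1 Mb inversion (10,000 SNPs) at arrangement frequency 0.5 with 90%
  fixed differences, scanned with 1,000-SNP windows and 250-SNP steps;
* a null control with the same dimensions and no inversion;
* a cross-method consistency suite comparing the scan's influence area
  with the homokaryotype F_ST span, the high-r² LD block, local-MDS
  karyotype clusters, and the inside/outside Tajima's D contrast.
"""

from __future__ import annotations

import numpy as np

from karyoscan import popgen
from karyoscan.scan import ScanParams, scan
from karyoscan.simulate import SimConfig, SimInversion, score_detection, simulate_dataset

__all__ = ["parameter_recovery", "null_false_positives", "consistency_suite"]

_CHROMS = [("chr1", 5_000_000, 50_000), ("chr2", 5_000_000, 50_000),
           ("chr3", 5_000_000, 50_000)]
_INV = SimInversion("chr2", 2_000_001, 3_000_000,
                    alt_arrangement_freq=0.5, divergence=0.9)
_PARAMS = ScanParams(window_snps=1_000, step_snps=250)


def _rep_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + i) % 2**31)


def parameter_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    """Detection, delimitation and karyotyping accuracy over replicates."""
    exact, no_fp, errs, accs = 0, 0, [], []
    for i in range(n_reps):
        cfg = SimConfig(n_samples=24, chromosomes=_CHROMS, inversions=[_INV],
                        seed=_rep_seed(seed, i))
        gm, truth = simulate_dataset(cfg)
        res = scan(gm, _PARAMS)
        on_inv = [r for r in res.regions if r.chrom == _INV.chrom]
        elsewhere = [r for r in res.regions if r.chrom != _INV.chrom]
        if len(on_inv) == 1:
            exact += 1
        if not elsewhere:
            no_fp += 1
        sc = score_detection(truth, res)
        row = sc.iloc[0]
        if row["detected"]:
            errs.append(float(row["boundary_err_snps"]))
            accs.append(float(row["karyotype_accuracy"]))
    return {
        "n_reps": n_reps,
        "frac_exactly_one_region_on_inversion_chrom": exact / n_reps,
        "frac_replicates_without_false_positives": no_fp / n_reps,
        "max_boundary_error_snps": max(errs) if errs else float("nan"),
        "mean_boundary_error_snps": float(np.mean(errs)) if errs else float("nan"),
        "min_karyotype_accuracy": min(accs) if accs else float("nan"),
        "mean_karyotype_accuracy": float(np.mean(accs)) if accs else float("nan"),
    }


def null_false_positives(n_reps: int = 100, seed: int = 0) -> dict:
    """Mean spurious region count per chromosome on inversion-free data."""
    n_regions = 0
    n_chrom = len(_CHROMS)
    for i in range(n_reps):
        cfg = SimConfig(n_samples=24, chromosomes=_CHROMS, inversions=[],
                        seed=_rep_seed(seed, 10_000 + i))
        gm, _ = simulate_dataset(cfg)
        n_regions += len(scan(gm, _PARAMS).regions)
    return {
        "n_reps": n_reps,
        "total_false_positive_regions": n_regions,
        "mean_false_positives_per_chromosome": n_regions / (n_reps * n_chrom),
    }


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def _longest_run_span(track, threshold: float) -> tuple[int, int] | None:
    """bp span of the longest contiguous run of windows with value >= threshold."""
    hi = (track["value"] >= threshold).to_numpy()
    best, cur, cur_start = None, 0, 0
    best_len = 0
    for i, h in enumerate(hi):
        if h:
            if cur == 0:
                cur_start = i
            cur += 1
            if cur > best_len:
                best_len, best = cur, (cur_start, i)
        else:
            cur = 0
    if best is None:
        return None
    return (int(track["start_bp"].iloc[best[0]]), int(track["end_bp"].iloc[best[1]]))


def _three_means_1d(x: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D 3-means: centers seeded at min / median / max."""
    centers = np.array([x.min(), np.median(x), x.max()], dtype=float)
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in range(3):
            if (labels == k).any():
                centers[k] = x[labels == k].mean()
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[labels]


def consistency_suite(seed: int = 0) -> dict:
    """Cross-method agreement on one simulated inversion replicate."""
    cfg = SimConfig(n_samples=24, chromosomes=_CHROMS, inversions=[_INV],
                    seed=_rep_seed(seed, 20_000))
    gm, truth = simulate_dataset(cfg)
    res = scan(gm, _PARAMS)
    region = next(r for r in res.regions if r.chrom == _INV.chrom)
    area = region.influence_area

    kary = res.karyotypes_frame()
    kary = kary[kary["region_id"] == region.region_id].set_index("sample")

    # homokaryotype-vs-homokaryotype windowed F_ST
    homo = kary[kary["call"].isin(["0/0", "1/1"])]
    groups = popgen.GroupAssignment(dict(zip(homo.index, homo["call"])))
    chrom_mask = np.asarray(gm.sites["chrom"] == _INV.chrom)
    gm_chrom = gm.subset_sites(chrom_mask)
    fst = popgen.windowed_fst(gm_chrom, groups)
    fst_span = _longest_run_span(fst, 0.9)

    # high-r² LD block over all samples
    pairs = popgen.pairwise_r2(gm, _INV.chrom, seed=_rep_seed(seed, 20_001))
    ld_span = popgen.ld_block_span(pairs, min_partners=3)

    # local MDS on region SNPs; cluster memberships vs karyotype calls
    pos = gm.sites["pos"].to_numpy()
    region_sites = np.flatnonzero(chrom_mask & (pos >= area[0]) & (pos <= area[1]))
    D = popgen.ibs_distance(gm, region_sites)
    coords, _ = popgen.classical_mds(D, n_axes=2)
    clusters = _three_means_1d(coords["axis1"].to_numpy())
    call_to_int = {"0/0": 0, "0/1": 1, "1/1": 2}
    calls = np.array([call_to_int[kary.loc[s, "call"]] for s in gm.samples])
    # the MDS axis orientation is arbitrary: homokaryotypes sit at the two
    # extremes and heterokaryotypes in the middle, so score the better of
    # the two axis orientations
    mds_agreement = max(float((clusters == calls).mean()),
                        float((2 - clusters == calls).mean()))

    # Tajima's D inside vs outside the influence area, all chromosomes
    taj = popgen.windowed_tajimas_d(gm)
    wil = popgen.compare_tajima_in_out(taj, [(region.chrom, area[0], area[1])])

    out = {
        "influence_area": area,
        "fst_span": fst_span,
        "ld_span": ld_span,
        "jaccard_influence_vs_fst": _jaccard(area, fst_span) if fst_span else 0.0,
        "jaccard_influence_vs_ld": _jaccard(area, ld_span) if ld_span else 0.0,
        "jaccard_fst_vs_ld": _jaccard(fst_span, ld_span) if fst_span and ld_span else 0.0,
        "mds_karyotype_agreement": mds_agreement,
        "tajima_wilcoxon_p": wil.p,
        "tajima_median_inside": wil.median_inside,
        "tajima_median_outside": wil.median_outside,
    }
    return out
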