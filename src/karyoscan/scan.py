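"""Sliding-window per-individual mean-genotype scan.

The method rests on one assumption: in freely recombining regions all
individuals of a population share a baseline level of heterozygosity, so
their windowed mean dosages hover around a common value, while a
non-recombining block (an inversion being the archetype) splits
individuals into divergent classes — homokaryotypes near dosage 0 or 2,
heterokaryotypes near 1.  The scan therefore

1. averages dosages per individual in overlapping windows of a fixed SNP
   count (``window_snps``, advancing by ``step_snps``),
2. flags windows where the across-individual spread of means reaches
   ``range_threshold`` and joins runs of them into candidate regions,
3. delimits each region's *influence area* as the span between the first
   and last maximum peaks of homozygosity, where homozygosity of a window
   is the mean of |M - 1| over provisional homokaryotypes, and
4. assigns each individual a karyotype (0/0, 0/1, 1/1) from its mean
   dosage over the influence area.

All window coordinates are reported both as SNP indices and as 1-based
inclusive base-pair spans; BED export is 0-based half-open.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from karyoscan.matrix import MISSING, GenotypeMatrix

__all__ = [
    "WindowGrid",
    "GenotypeTrack",
    "InversionCall",
    "KaryotypeCall",
    "ScanParams",
    "ScanResult",
    "build_windows",
    "window_mean_genotypes",
    "detect_candidate_regions",
    "delimit_influence_area",
    "assign_karyotypes",
    "basal_differentiation",
    "scan",
]


@dataclass
class ScanParams:
    """Tunable parameters of the scan.

    window_snps, step_snps
        Window size and step, in SNP count.  Should be calibrated to SNP
        density: large windows find macro-inversions cheaply, small
        windows resolve fine linkage blocks.
    range_threshold
        Minimum across-sample spread (max - min) of window means for a
        window to count as divergent.  1.0 = one full genotype class.
    min_run, merge_gap
        A candidate region needs at least ``min_run`` divergent windows;
        up to ``merge_gap`` consecutive quiet windows are tolerated
        inside a run.
    peak_tol
        Relative tolerance for "maximum" homozygosity peaks: windows with
        H >= (1 - peak_tol) * max(H) count as peaks, so a flat plateau is
        one long peak.
    t_low, t_high
        Karyotype call boundaries on the mean dosage score (midpoints
        between the ideal scores 0, 1 and 2).
    min_window_callrate
        Minimum fraction of non-missing genotypes for a window mean to be
        defined.
    """

    window_snps: int = 10_000
    step_snps: int = 2_500
    range_threshold: float = 1.0
    min_run: int = 3
    merge_gap: int = 1
    peak_tol: float = 0.05
    t_low: float = 0.5
    t_high: float = 1.5
    min_window_callrate: float = 0.5

    def __post_init__(self) -> None:
        if self.window_snps <= 0 or self.step_snps <= 0:
            raise ValueError("window_snps and step_snps must be positive")
        if self.step_snps > self.window_snps:
            raise ValueError("step_snps must not exceed window_snps")
        if not (0.0 <= self.range_threshold <= 2.0):
            raise ValueError("range_threshold must be in [0, 2]")
        if not (0.0 < self.t_low < self.t_high < 2.0):
            raise ValueError("need 0 < t_low < t_high < 2")


@dataclass
class WindowGrid:
    """Sliding SNP-index windows on one chromosome.

    ``first``/``last`` are inclusive chromosome-local SNP indices;
    ``start_bp``/``end_bp`` the positions of the first and last SNP of
    each window (1-based inclusive).
    """

    chrom: str
    window_snps: int
    step_snps: int
    first: np.ndarray
    last: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.first)


@dataclass
class GenotypeTrack:
    """Windowed mean dosage per individual; NaN where undefined."""

    grid: WindowGrid
    samples: list[str]
    M: np.ndarray  # (n_samples, n_windows), float, NaN = undefined

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        rows = []
        for j, s in enumerate(self.samples):
            rows.append(pd.DataFrame({
                "sample": s, "chrom": g.chrom, "window": np.arange(g.n_windows),
                "start_bp": g.start_bp, "end_bp": g.end_bp,
                "mean_genotype": self.M[j],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class InversionCall:
    """A detected linked region with its delimited influence area."""

    chrom: str
    region_id: str
    candidate_span: tuple[int, int]        # first/last window index, inclusive
    candidate_bp: tuple[int, int]          # bp extent of the candidate windows
    influence_area: tuple[int, int]        # 1-based inclusive bp span
    homozygosity_profile: pd.Series        # H per window index in the neighborhood
    peak_windows: list[int]
    status: str = "ok"                     # "ok" | "undelimited"

    @property
    def n_peaks(self) -> int:
        return len(self.peak_windows)


@dataclass
class KaryotypeCall:
    sample: str
    region_id: str
    score: float                            # mean dosage in the influence area
    call: str                               # "0/0" | "0/1" | "1/1" | "NA"
    margin: float


@dataclass
class ScanResult:
    params: ScanParams
    tracks: dict[str, GenotypeTrack]
    regions: list[InversionCall]
    karyotypes: list[KaryotypeCall]
    basal: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "region_id": r.region_id,
                    "first_window": r.candidate_span[0], "last_window": r.candidate_span[1],
                    "influence_start_bp": r.influence_area[0],
                    "influence_end_bp": r.influence_area[1],
                    "n_peaks": r.n_peaks, "status": r.status,
                }
                for r in self.regions
            ],
            columns=["chrom", "region_id", "first_window", "last_window",
                     "influence_start_bp", "influence_end_bp", "n_peaks", "status"],
        )

    def karyotypes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample": k.sample, "region_id": k.region_id, "score": k.score,
              "call": k.call, "margin": k.margin} for k in self.karyotypes],
            columns=["sample", "region_id", "score", "call", "margin"],
        )

    def write(self, outdir: str | os.PathLike) -> None:
        """Write regions.tsv, regions.bed, karyotypes.tsv, track.tsv.gz, basal.tsv."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.regions_frame().to_csv(os.path.join(outdir, "regions.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "regions.bed"), "w") as fh:
            for r in self.regions:
                # BED is 0-based half-open
                fh.write(f"{r.chrom}\t{r.influence_area[0] - 1}\t{r.influence_area[1]}\t{r.region_id}\n")
        self.karyotypes_frame().to_csv(
            os.path.join(outdir, "karyotypes.tsv"), sep="\t", index=False)
        track = pd.concat([t.to_frame() for t in self.tracks.values()], ignore_index=True)
        with gzip.open(os.path.join(outdir, "track.tsv.gz"), "wt") as fh:
            track.to_csv(fh, sep="\t", index=False)
        self.basal.rename("basal_mean_genotype").rename_axis("sample").to_csv(
            os.path.join(outdir, "basal.tsv"), sep="\t")


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def build_windows(
    chrom: str, positions: np.ndarray, window_snps: int, step_snps: int
) -> WindowGrid:
    """Build the sliding SNP-index window grid for one chromosome.

    Window k covers SNP indices [k*step, k*step + window - 1]; after the
    last full-length window, one terminal clipped window is appended if
    SNPs remain uncovered (it holds fewer than ``window_snps`` SNPs).
    """
    if window_snps <= 0 or step_snps <= 0:
        raise ValueError("window and step must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    if n == 0:
        raise ValueError(f"no SNPs on chromosome {chrom!r}")
    if window_snps >= n:
        starts = [0]
    else:
        n_full = (n - window_snps) // step_snps + 1
        starts = [k * step_snps for k in range(n_full)]
        last_end = starts[-1] + window_snps - 1
        if last_end < n - 1:
            starts.append(n_full * step_snps)
    first = np.asarray(starts, dtype=np.int64)
    last = np.minimum(first + window_snps - 1, n - 1)
    return WindowGrid(
        chrom=chrom, window_snps=window_snps, step_snps=step_snps,
        first=first, last=last,
        start_bp=positions[first], end_bp=positions[last],
    )


def window_mean_genotypes(
    gm: GenotypeMatrix, grid: WindowGrid, min_window_callrate: float = 0.5
) -> GenotypeTrack:
    """Mean non-missing dosage per (sample, window); NaN when the
    non-missing fraction of a window falls below ``min_window_callrate``."""
    sl = gm.chrom_slice(grid.chrom)
    G = gm.G[:, sl]
    ok = G != MISSING
    # cumulative sums give O(1) window aggregation
    csum = np.concatenate(
        [np.zeros((gm.n_samples, 1)), np.cumsum(np.where(ok, G, 0), axis=1)], axis=1)
    ccnt = np.concatenate(
        [np.zeros((gm.n_samples, 1)), np.cumsum(ok, axis=1)], axis=1)
    f, l = grid.first, grid.last
    sums = csum[:, l + 1] - csum[:, f]
    cnts = ccnt[:, l + 1] - ccnt[:, f]
    size = (l - f + 1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(cnts / size >= min_window_callrate, sums / np.maximum(cnts, 1), np.nan)
        M = np.where(cnts == 0, np.nan, M)
    return GenotypeTrack(grid=grid, samples=list(gm.samples), M=M)


def _divergent_windows(track: GenotypeTrack, delta: float) -> np.ndarray:
    M = track.M
    if M.shape[0] < 2:
        raise ValueError("need >= 2 samples to measure across-sample spread")
    defined = ~np.isnan(M)
    enough = defined.sum(axis=0) >= 2
    with np.errstate(all="ignore"):
        spread = np.nanmax(M, axis=0) - np.nanmin(M, axis=0)
    return enough & (spread >= delta)


def detect_candidate_regions(
    track: GenotypeTrack, params: ScanParams
) -> list[tuple[int, int]]:
    """Maximal runs of divergent windows.

    A window is divergent when the spread (max - min over samples) of its
    defined means reaches ``range_threshold``.  Runs may bridge up to
    ``merge_gap`` consecutive quiet windows and must contain at least
    ``min_run`` divergent windows.  Returned as (first_window,
    last_window) inclusive index pairs, sorted by position.
    """
    div = _divergent_windows(track, params.range_threshold)
    spans: list[tuple[int, int]] = []
    i, n = 0, len(div)
    while i < n:
        if not div[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        gap = 0
        while j < n:
            if div[j]:
                end = j
                gap = 0
            else:
                gap += 1
                if gap > params.merge_gap:
                    break
            j += 1
        n_div = int(div[start:end + 1].sum())
        if n_div >= params.min_run:
            spans.append((start, end))
        i = j + 1  # windows end+1..j are quiet, safe to skip
    return spans


def delimit_influence_area(
    track: GenotypeTrack,
    candidate: tuple[int, int],
    gm: GenotypeMatrix,
    params: ScanParams,
    region_id: str = "region",
) -> InversionCall:
    """Delimit a candidate's influence area by homozygosity peaks.

    Provisional homokaryotypes are the samples whose mean dosage across
    the whole candidate span falls at or below ``t_low`` / at or above
    ``t_high``; heterokaryotypes sit near 1 inside the region and would
    dilute the signal.  Window homozygosity H is the mean over those
    samples of |M - 1| (in [0, 1]).  Maximum peaks are the windows within
    the span (plus one buffer window each side) whose H reaches
    (1 - peak_tol) * max(H); the influence area runs from the start of
    the first peak window to the end of the last.  With no provisional
    homokaryotype the call is returned flagged "undelimited" with the
    candidate bp span as fallback.
    """
    grid = track.grid
    w0, w1 = candidate
    sl = gm.chrom_slice(grid.chrom)
    Gc = gm.G[:, sl]
    s0, s1 = int(grid.first[w0]), int(grid.last[w1])
    cand_bp = (int(grid.start_bp[w0]), int(grid.end_bp[w1]))

    span_G = Gc[:, s0:s1 + 1]
    ok = span_G != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        span_mean = np.where(ok.sum(axis=1) > 0,
                             np.where(ok, span_G, 0).sum(axis=1) / np.maximum(ok.sum(axis=1), 1),
                             np.nan)
    homo = (span_mean <= params.t_low) | (span_mean >= params.t_high)

    lo = max(w0 - 1, 0)
    hi = min(w1 + 1, grid.n_windows - 1)
    widx = np.arange(lo, hi + 1)

    if not homo.any():
        return InversionCall(
            chrom=grid.chrom, region_id=region_id, candidate_span=candidate,
            candidate_bp=cand_bp, influence_area=cand_bp,
            homozygosity_profile=pd.Series(np.nan, index=widx),
            peak_windows=[], status="undelimited",
        )

    H = np.nanmean(np.abs(track.M[np.flatnonzero(homo)][:, widx] - 1.0), axis=0)
    profile = pd.Series(H, index=widx)
    hmax = np.nanmax(H)
    peaks = widx[H >= (1.0 - params.peak_tol) * hmax]
    first_pk, last_pk = int(peaks[0]), int(peaks[-1])
    area = (int(grid.start_bp[first_pk]), int(grid.end_bp[last_pk]))
    return InversionCall(
        chrom=grid.chrom, region_id=region_id, candidate_span=candidate,
        candidate_bp=cand_bp, influence_area=area,
        homozygosity_profile=profile, peak_windows=[int(p) for p in peaks],
        status="ok",
    )


def assign_karyotypes(
    gm: GenotypeMatrix, call: InversionCall,
    t_low: float = 0.5, t_high: float = 1.5,
) -> list[KaryotypeCall]:
    """Per-sample karyotype from the mean dosage over the influence area.

    score < t_low -> 0/0 (homokaryotype, reference arrangement);
    t_low <= score <= t_high -> 0/1 (heterokaryotype);
    score > t_high -> 1/1 (alternative arrangement).
    A sample with no genotyped SNP in the area is called NA.
    """
    sl = gm.chrom_slice(call.chrom)
    pos = gm.sites["pos"].to_numpy()[sl]
    in_area = (pos >= call.influence_area[0]) & (pos <= call.influence_area[1])
    Ga = gm.G[:, sl][:, in_area]
    ok = Ga != MISSING
    out: list[KaryotypeCall] = []
    for j, s in enumerate(gm.samples):
        n_ok = int(ok[j].sum())
        if n_ok == 0:
            out.append(KaryotypeCall(s, call.region_id, float("nan"), "NA", float("nan")))
            continue
        score = float(Ga[j][ok[j]].mean())
        if score < t_low:
            kcall = "0/0"
        elif score > t_high:
            kcall = "1/1"
        else:
            kcall = "0/1"
        margin = float(min(abs(score - t_low), abs(score - t_high)))
        out.append(KaryotypeCall(s, call.region_id, score, kcall, margin))
    return out


def basal_differentiation(
    tracks: dict[str, GenotypeTrack] | GenotypeTrack,
    regions: list[InversionCall],
) -> pd.Series:
    """Per-sample mean of window means over all windows outside every
    detected influence area — the individual's basal genome-wide
    genotype level."""
    if isinstance(tracks, GenotypeTrack):
        tracks = {tracks.grid.chrom: tracks}
    samples = next(iter(tracks.values())).samples
    sums = np.zeros(len(samples))
    cnts = np.zeros(len(samples))
    for chrom, tr in tracks.items():
        g = tr.grid
        outside = np.ones(g.n_windows, dtype=bool)
        for r in regions:
            if r.chrom != chrom:
                continue
            overlap = (g.start_bp <= r.influence_area[1]) & (g.end_bp >= r.influence_area[0])
            outside &= ~overlap
        M = tr.M[:, outside]
        ok = ~np.isnan(M)
        sums += np.where(ok, M, 0).sum(axis=1)
        cnts += ok.sum(axis=1)
    if cnts.max() == 0:
        raise ValueError("no windows outside the detected regions")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.Series(vals, index=samples, name="basal_mean_genotype")


def scan(gm: GenotypeMatrix, params: ScanParams | None = None) -> ScanResult:
    """Run the full scan on every chromosome of a genotype matrix."""
    params = params or ScanParams()
    tracks: dict[str, GenotypeTrack] = {}
    regions: list[InversionCall] = []
    karyos: list[KaryotypeCall] = []
    for chrom, sub in gm.iter_chromosomes():
        grid = build_windows(chrom, sub.sites["pos"].to_numpy(),
                             params.window_snps, params.step_snps)
        track = window_mean_genotypes(gm, grid, params.min_window_callrate)
        tracks[chrom] = track
        for i, cand in enumerate(detect_candidate_regions(track, params), start=1):
            rid = f"{chrom}_inv{i}"
            call = delimit_influence_area(track, cand, gm, params, region_id=rid)
            regions.append(call)
            karyos.extend(assign_karyotypes(gm, call, params.t_low, params.t_high))
    basal = basal_differentiation(tracks, regions)
    return ScanResult(params=params, tracks=tracks, regions=regions,
                      karyotypes=karyos, basal=basal)
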