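"""In-memory genotype container shared by all modules.

Genotypes are stored as diploid ALT-allele dosages in the VCFtools "012"
convention: 0 homozygous reference, 1 heterozygous, 2 homozygous
alternative, -1 missing.  Sites are kept in a pandas DataFrame sorted by
(chrom, pos); coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: sentinel dosage for a missing genotype (matches the 012 file dialect)
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "mean_depth"]


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP site."""

    chrom: str
    pos: int  # 1-based
    ref: str = "N"
    alt: str = "N"
    mean_depth: float = np.nan

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """samples x sites dosage matrix with site metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``G``).
    sites : pandas.DataFrame
        One row per SNP with columns chrom, pos, ref, alt, mean_depth,
        sorted by (chrom, pos); pos strictly increasing within a chromosome.
    G : numpy.ndarray of int8, shape (n_samples, n_sites)
        Dosages in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    sites: pd.DataFrame
    G: np.ndarray = field(repr=False)
    #: optional per-genotype read depth, same shape as G, -1 where unknown
    gt_depth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                if col == "mean_depth":
                    self.sites[col] = np.nan
                elif col in ("ref", "alt"):
                    self.sites[col] = "N"
                else:
                    raise ValueError(f"sites frame missing required column {col!r}")
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"G contains {int(bad.sum())} values outside {{0,1,2,{MISSING}}}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions on {c} not strictly increasing")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in order of first appearance."""
        return list(pd.unique(self.sites["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous site-index slice for one chromosome."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no sites on chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping sites selected by a boolean mask or index array."""
        sel = np.asarray(mask_or_index)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[sel].reset_index(drop=True),
            G=self.G[:, sel].copy(),
            gt_depth=self.gt_depth[:, sel].copy() if self.gt_depth is not None else None,
        )

    def iter_chromosomes(self) -> Iterator[tuple[str, "GenotypeMatrix"]]:
        for c in self.chroms:
            yield c, self.subset_sites(np.asarray(self.sites["chrom"] == c))

    def masked(self) -> np.ma.MaskedArray:
        """Masked float view with MISSING masked out."""
        return np.ma.masked_equal(self.G.astype(float), MISSING)

    def alt_freqs(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing genotypes (NaN if none)."""
        ok = self.G != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        alt = np.where(ok, self.G, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def relabelled(self) -> "GenotypeMatrix":
        """Swap REF/ALT labels at every site: dosage g -> 2 - g, alleles swapped."""
        G2 = np.where(self.G == MISSING, MISSING, 2 - self.G).astype(np.int8)
        sites = self.sites.copy()
        sites[["ref", "alt"]] = sites[["alt", "ref"]].to_numpy()
        return GenotypeMatrix(samples=list(self.samples), sites=sites, G=G2)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[["chrom", "pos"]].equals(other.sites[["chrom", "pos"]])
            and np.array_equal(self.G, other.G)
        )


def from_arrays(
    samples: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    G: np.ndarray,
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
    mean_depth: Sequence[float] | None = None,
) -> GenotypeMatrix:
    """Convenience constructor from parallel arrays."""
    n = len(pos)
    sites = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object) if ref is not None else ["N"] * n,
            "alt": np.asarray(alt, dtype=object) if alt is not None else ["N"] * n,
            "mean_depth": np.asarray(mean_depth, dtype=float)
            if mean_depth is not None
            else np.full(n, np.nan),
        }
    )
    return GenotypeMatrix(samples=list(samples), sites=sites, G=np.asarray(G))
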