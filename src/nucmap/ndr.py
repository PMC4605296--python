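"""Internucleosomal distances and nucleosome-depleted region (NDR) calling.

An NDR is the interval between two adjacent called nucleosome peaks with no
peak in its interior; its size is the internucleosomal (center-to-center)
distance.  The genome-wide size distribution summarises chromatin spacing,
and individual loci (e.g. replication-origin NDRs) can be placed on it by
quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .occupancy import NucleosomePeak


@dataclass
class NDR:
    """Peak-free interval between adjacent called peaks (center-to-center)."""

    chrom: str
    start: int
    end: int
    left_peak: int
    right_peak: int

    @property
    def size(self) -> int:
        return self.end - self.start


class NDRSizeDistribution:
    """Multiset of internucleosomal distances with a smoothed density estimate.

    The density is a Gaussian KDE (Silverman bandwidth) evaluated on a
    log-spaced grid, matching the long right tail of NDR sizes.
    """

    def __init__(self, sizes: np.ndarray):
        self.sizes = np.sort(np.asarray(sizes, dtype=float))

    def __len__(self) -> int:
        return len(self.sizes)

    def density(self, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        if len(self.sizes) < 2 or np.ptp(self.sizes) == 0:
            raise ValueError("density needs >= 2 distinct sizes")
        kde = gaussian_kde(self.sizes, bw_method="silverman")
        if grid is None:
            bw = np.sqrt(kde.covariance[0, 0])
            lo = self.sizes.min() - 6 * bw
            hi = self.sizes.max() + 6 * bw
            # log-spaced over the (long-tailed) positive support; fall back to
            # linear when the kernels spill below zero, so the density still
            # integrates to 1 over the grid
            grid = np.geomspace(lo, hi, 8192) if lo > 0 else np.linspace(lo, hi, 8192)
        return grid, kde(grid)

    def quantile(self, size: float) -> float:
        """Empirical CDF: fraction of genome-wide sizes <= size."""
        if len(self.sizes) == 0:
            raise ValueError("empty distribution")
        return float(np.searchsorted(self.sizes, size, side="right") / len(self.sizes))

    def modes(self) -> np.ndarray:
        """Local maxima of the KDE, in ascending size order."""
        grid, dens = self.density()
        idx = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])) + 1
        return grid[idx]

    def write_tsv(self, path) -> None:
        grid, dens = self.density()
        pd.DataFrame({"size": grid, "density": dens}).to_csv(path, sep="\t", index=False)


def _require_sorted(peaks: list[NucleosomePeak]) -> None:
    keys = [(p.chrom, p.center) for p in peaks]
    if keys != sorted(keys):
        raise ValueError("peaks must be sorted by (chrom, center)")


def internucleosomal_distances(peaks: list[NucleosomePeak]) -> NDRSizeDistribution:
    """Distances between adjacent called peaks, per chromosome.

    A chromosome with k >= 2 peaks contributes k-1 center-to-center distances;
    chromosomes with fewer contribute nothing.
    """
    _require_sorted(peaks)
    sizes: list[int] = []
    for i in range(1, len(peaks)):
        if peaks[i].chrom == peaks[i - 1].chrom:
            sizes.append(peaks[i].center - peaks[i - 1].center)
    return NDRSizeDistribution(np.array(sizes, dtype=float))


def call_ndrs(peaks: list[NucleosomePeak]) -> list[NDR]:
    """One NDR per adjacent peak pair: [left center, right center)."""
    _require_sorted(peaks)
    ndrs: list[NDR] = []
    for i in range(1, len(peaks)):
        left, right = peaks[i - 1], peaks[i]
        if left.chrom != right.chrom:
            continue
        ndrs.append(NDR(left.chrom, left.center, right.center, i - 1, i))
    return ndrs


def ndrs_at(
    ndrs: list[NDR],
    query: list[tuple[str, int, int]],
    dist: NDRSizeDistribution | None = None,
) -> pd.DataFrame:
    """NDRs overlapping each query interval, with genome-wide size quantiles.

    Parameters
    ----------
    query
        Intervals as (chrom, start, end), 0-based half-open.
    dist
        Size distribution for the quantile column; computed from ``ndrs``
        when omitted.
    """
    if dist is None:
        dist = NDRSizeDistribution(np.array([n.size for n in ndrs], dtype=float))
    rows = []
    for qchrom, qstart, qend in query:
        for ndr in ndrs:
            if ndr.chrom == qchrom and ndr.start < qend and qstart < ndr.end:
                rows.append(
                    {
                        "query_chrom": qchrom,
                        "query_start": qstart,
                        "query_end": qend,
                        "ndr_start": ndr.start,
                        "ndr_end": ndr.end,
                        "size": ndr.size,
                        "quantile": dist.quantile(ndr.size) if len(dist) else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "query_chrom", "query_start", "query_end",
            "ndr_start", "ndr_end", "size", "quantile",
        ],
    )


def write_ndrs(ndrs: list[NDR], path) -> None:
    """Write NDRs as BED4 + size TSV."""
    with open(path, "w") as fh:
        for i, n in enumerate(ndrs):
            fh.write(f"{n.chrom}\t{n.start}\t{n.end}\tndr{i + 1}\t{n.size}\n")
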