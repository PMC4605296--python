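"""Meta-occupancy around scored feature sites and the score-vs-NDR-size relation.

Built for ChIP-defined replication-origin (ORC) binding sites: average the
nucleosome-occupancy track in a window around every site center to reveal
depletion or enrichment, and relate each site's binding score to the size of
the NDR that contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ndr import NDR
from .occupancy import OccupancyTrack

log = logging.getLogger(__name__)

#: Default ChIP-score floor for "significant" sites.
DEFAULT_MIN_SITE_SCORE = 7.5


@dataclass(frozen=True)
class FeatureSite:
    """A scored point feature (e.g. an ORC binding-site midpoint)."""

    chrom: str
    center: int
    score: float


@dataclass
class MetaProfile:
    """Occupancy averaged over sites, aligned at site centers."""

    offsets: np.ndarray
    mean_occ: np.ndarray
    n_sites: int
    normalization: str
    n_dropped: int = 0

    def write_tsv(self, path) -> None:
        pd.DataFrame({"offset": self.offsets, "mean_occ": self.mean_occ}).to_csv(
            path, sep="\t", index=False
        )


def load_sites(path, min_score: float = DEFAULT_MIN_SITE_SCORE) -> list[FeatureSite]:
    """Read scored sites from BED6 (score in column 5) or a chrom/start/end/score TSV.

    Sites with score >= min_score are kept (inclusive); the site center is the
    interval midpoint, floored for odd widths.
    """
    sites: list[FeatureSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 columns for a scored site")
            score_col = cols[4] if len(cols) >= 5 else cols[3]
            try:
                score = float(score_col)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed score {score_col!r}") from err
            start, end = int(cols[1]), int(cols[2])
            if score >= min_score:
                sites.append(FeatureSite(cols[0], (start + end) // 2, score))
    return sites


def meta_occupancy(
    tracks: OccupancyTrack | dict[str, OccupancyTrack],
    sites: list[FeatureSite],
    half_width: int = 1000,
    normalization: str = "genome-mean",
) -> MetaProfile:
    """Average occupancy at offsets -half_width..+half_width around site centers.

    Sites within half_width of a chromosome end (or on chromosomes without a
    track) are dropped, counted, and logged.  Under genome-mean normalization
    the profile is divided by the mean track value over covered (> 0)
    positions, so a constant track yields a profile of exactly 1.
    """
    if normalization not in ("raw", "genome-mean"):
        raise ValueError("normalization must be 'raw' or 'genome-mean'")
    if isinstance(tracks, OccupancyTrack):
        tracks = {tracks.chrom: tracks}
    acc = np.zeros(2 * half_width + 1)
    n_used = 0
    n_dropped = 0
    for site in sites:
        track = tracks.get(site.chrom)
        if track is None or site.center - half_width < 0 or site.center + half_width >= len(track):
            n_dropped += 1
            continue
        acc += track.values[site.center - half_width : site.center + half_width + 1]
        n_used += 1
    if n_dropped:
        log.warning("dropped %d sites too close to a chromosome end", n_dropped)
    if n_used == 0:
        raise ValueError("no sites retained after edge filtering")
    mean_occ = acc / n_used
    if normalization == "genome-mean":
        pooled = np.concatenate([t.values for t in tracks.values()])
        covered = pooled[pooled > 0]
        if covered.size == 0:
            raise ValueError("cannot normalise: track has no covered positions")
        mean_occ = mean_occ / covered.mean()
    offsets = np.arange(-half_width, half_width + 1)
    return MetaProfile(offsets, mean_occ, n_used, normalization, n_dropped)


@dataclass
class ScoreVsNDRResult:
    """(site score, containing-NDR size) pairs and their rank correlation."""

    pairs: pd.DataFrame
    spearman_rho: float | None
    n_excluded: int


def score_vs_ndr(sites: list[FeatureSite], ndrs: list[NDR]) -> ScoreVsNDRResult:
    """Pair every site with the NDR containing its center (half-open intervals).

    Sites whose center lies in no NDR (e.g. exactly at a peak summit) are
    excluded and counted.  Spearman's rho over the pairs quantifies whether
    stronger-binding sites sit in larger NDRs.
    """
    by_chrom: dict[str, list[NDR]] = {}
    for ndr in ndrs:
        by_chrom.setdefault(ndr.chrom, []).append(ndr)
    starts = {c: np.array([n.start for n in lst]) for c, lst in by_chrom.items()}

    rows = []
    n_excluded = 0
    for site in sites:
        lst = by_chrom.get(site.chrom)
        hit = None
        if lst:
            i = int(np.searchsorted(starts[site.chrom], site.center, side="right")) - 1
            if i >= 0 and lst[i].start <= site.center < lst[i].end:
                hit = lst[i]
        if hit is None:
            n_excluded += 1
            continue
        rows.append(
            {"chrom": site.chrom, "center": site.center, "score": site.score, "ndr_size": hit.size}
        )
    pairs = pd.DataFrame(rows, columns=["chrom", "center", "score", "ndr_size"])
    rho = None
    if len(pairs) >= 3 and pairs["score"].nunique() > 1 and pairs["ndr_size"].nunique() > 1:
        rho = float(spearmanr(pairs["score"], pairs["ndr_size"]).statistic)
    return ScoreVsNDRResult(pairs, rho, n_excluded)
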