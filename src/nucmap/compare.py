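"""Quantitative comparison of occupancy tracks and in-vitro binding profiles.

Two analyses: (1) binned Pearson/Spearman correlation between two per-base
tracks over a region, e.g. observed MNase occupancy vs sequence-predicted
occupancy; (2) the relation between in-vitro protein binding to naked DNA
fragments and mean in-vivo nucleosome occupancy over those fragments — an
inverse relation appears as a negative rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .occupancy import OccupancyTrack


@dataclass
class TrackComparison:
    pearson_r: float
    spearman_rho: float
    bin: int
    n_bins: int
    n_dropped: int = 0


def _as_values(track) -> np.ndarray:
    if isinstance(track, OccupancyTrack):
        return track.values
    return np.asarray(track, dtype=float)


def _bin_means(x: np.ndarray, size: int) -> np.ndarray:
    n = (len(x) // size) * size
    return x[:n].reshape(-1, size).mean(axis=1)


def compare_tracks(a, b, region: tuple[int, int] | None = None, bin: int = 50) -> TrackComparison:
    """Mean-bin both tracks over a region, then correlate the bins.

    Bins where either track is undefined (NaN) are dropped and counted; fewer
    than 3 shared bins is an error.  ``bin=1`` reproduces the unbinned
    correlation.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    va, vb = _as_values(a), _as_values(b)
    if region is None:
        region = (0, min(len(va), len(vb)))
    start, end = region
    if end - start < 3 * bin:
        raise ValueError(f"region length {end - start} < 3 bins of {bin} bp")
    xa = _bin_means(va[start:end], bin)
    xb = _bin_means(vb[start:end], bin)
    ok = np.isfinite(xa) & np.isfinite(xb)
    n_dropped = int((~ok).sum())
    xa, xb = xa[ok], xb[ok]
    if len(xa) < 3:
        raise ValueError("fewer than 3 shared bins after dropping undefined bins")
    r = float(pearsonr(xa, xb).statistic)
    rho = float(spearmanr(xa, xb).statistic)
    return TrackComparison(r, rho, bin, len(xa), n_dropped)


def read_binding_table(path) -> pd.DataFrame:
    """4-column TSV: chrom, start, end, relative binding (non-negative)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :4]
    df.columns = ["chrom", "start", "end", "binding"]
    if (df["binding"] < 0).any() or not np.isfinite(df["binding"]).all():
        raise ValueError("binding values must be finite and non-negative")
    return df


@dataclass
class BindingComparison:
    """Fragment-level (binding, mean occupancy) pairs and their correlations.

    ``spearman_rho`` is None when a correlation is undefined; ``note`` says why.
    """

    pairs: pd.DataFrame
    spearman_rho: float | None
    pearson_r: float | None
    n_dropped: int
    note: str = ""


def occupancy_vs_binding(track: OccupancyTrack, profile: pd.DataFrame) -> BindingComparison:
    """Mean in-vivo occupancy over each in-vitro-assayed fragment vs its binding.

    Fragments of unequal length are summarised by MEAN occupancy so long
    fragments are not overweighted.  Fragments outside the track bounds are
    dropped and counted.  The headline statistic is Spearman's rho: the
    in-vitro-binding/occupancy "inverse" claim is ordinal.
    """
    if not isinstance(profile, pd.DataFrame):
        profile = pd.DataFrame(list(profile), columns=["chrom", "start", "end", "binding"])
    if len(profile) < 3:
        raise ValueError("need >= 3 fragments")
    n = len(track)
    rows = []
    n_dropped = 0
    for row in profile.itertuples(index=False):
        if row.chrom != track.chrom or row.start < 0 or row.end > n or row.end <= row.start:
            n_dropped += 1
            continue
        rows.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "binding": float(row.binding),
                "mean_occupancy": float(track.values[row.start : row.end].mean()),
            }
        )
    pairs = pd.DataFrame(rows, columns=["chrom", "start", "end", "binding", "mean_occupancy"])
    if len(pairs) < 3:
        raise ValueError("fewer than 3 fragments within track bounds")
    if pairs["binding"].nunique() < 2 or pairs["mean_occupancy"].nunique() < 2:
        return BindingComparison(pairs, None, None, n_dropped, note="zero variance")
    rho = float(spearmanr(pairs["binding"], pairs["mean_occupancy"]).statistic)
    r = float(pearsonr(pairs["binding"], pairs["mean_occupancy"]).statistic)
    return BindingComparison(pairs, rho, r, n_dropped)


def spearman_permutation_p(
    x, y, n_perm: int = 999, seed: int = 0, alternative: str = "less"
) -> float:
    """Permutation p-value for Spearman's rho by shuffling y.

    alternative="less" tests for anticorrelation, "greater" for positive
    correlation, "two-sided" for either.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rho = float(spearmanr(x, rng.permutation(y)).statistic)
        if alternative == "less":
            hits += rho <= obs
        elif alternative == "greater":
            hits += rho >= obs
        else:
            hits += abs(rho) >= abs(obs)
    return (1 + hits) / (1 + n_perm)
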