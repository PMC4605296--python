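"""Occupancy tracks, frequency-domain smoothing, and nucleosome peak calling.

The observed nucleosome-occupancy signal is the per-base count of protected
fragments covering each position.  A low-pass Fourier filter removes
base-pair-scale noise while retaining the ~200 bp nucleosomal periodicity;
scored peaks are then called as strict local maxima of the smoothed track
above a percentile threshold, with summits estimating nucleosome dyads.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .fragments import FragmentSet

#: Chunking used to bound memory when Fourier-filtering long chromosomes.
CHUNK_SIZE = 1 << 20
CHUNK_OVERLAP = 2000


@dataclass
class OccupancyTrack:
    """Per-base float signal over one chromosome; ``kind`` is raw or smoothed."""

    chrom: str
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("raw", "smoothed"):
            raise ValueError(f"kind must be raw or smoothed, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeakCallParams:
    """Tunables for the peak caller.

    pc_keep
        Fraction of lowest-frequency components retained by the Fourier filter.
    threshold_pct
        Percentile of the smoothed signal defining the calling threshold
        (computed over covered positions by default).
    min_score
        Peaks with combined score <= min_score are discarded.
    footprint
        Nucleosome footprint (bp); sets the called interval width and the
        fuzziness window.
    min_sep
        Minimum summit separation (bp); closer summits are merged keeping the
        higher (ties -> leftmost).
    """

    pc_keep: float = 0.02
    threshold_pct: float = 50.0
    min_score: float = 0.25
    footprint: int = 147
    min_sep: int = 120
    threshold_over: str = "covered"  # or "all"

    def __post_init__(self) -> None:
        if not 0 < self.pc_keep <= 1:
            raise ValueError("pc_keep must be in (0, 1]")
        if not 0 <= self.threshold_pct <= 100:
            raise ValueError("threshold_pct must be in [0, 100]")
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must be in [0, 1]")
        if self.footprint < 1 or self.min_sep < 1:
            raise ValueError("footprint and min_sep must be >= 1")
        if self.threshold_over not in ("covered", "all"):
            raise ValueError("threshold_over must be 'covered' or 'all'")


@dataclass
class NucleosomePeak:
    """A called nucleosome: summit (dyad estimate), footprint interval and scores."""

    chrom: str
    center: int
    start: int
    end: int
    height: float
    score_h: float
    score_w: float
    score: float


def coverage_track(frags: FragmentSet, chrom: str, dyad_window: int | None = None) -> OccupancyTrack:
    """Full-fragment-span coverage: values[b] = #fragments whose interval contains b.

    With ``dyad_window`` set, each fragment instead contributes over
    midpoint +/- dyad_window (a trimmed, dyad-centred alternative signal).
    """
    if chrom not in frags.chrom_sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    n = frags.chrom_sizes[chrom]
    sub = frags.on(chrom)
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    if dyad_window is not None:
        mids = (starts + ends) // 2
        starts = np.maximum(mids - dyad_window, 0)
        ends = np.minimum(mids + dyad_window + 1, n)
    delta = np.bincount(starts, minlength=n + 1).astype(np.int64)
    delta -= np.bincount(ends, minlength=n + 1)
    values = np.cumsum(delta[:n]).astype(float)
    return OccupancyTrack(chrom, values, "raw")


def _lowpass(x: np.ndarray, n_keep: int) -> np.ndarray:
    spectrum = np.fft.rfft(x)
    spectrum[max(1, n_keep):] = 0.0  # component 0 (the mean) is always retained
    return np.fft.irfft(spectrum, n=len(x))


def fft_smooth(
    track: OccupancyTrack,
    pc_keep: float = 0.02,
    chunk_size: int = CHUNK_SIZE,
    chunk_overlap: int = CHUNK_OVERLAP,
) -> OccupancyTrack:
    """Low-pass filter: zero all but the lowest fraction of rDFT components.

    The zero-frequency component is always retained, so the signal mean is
    preserved.  Chromosomes longer than ``chunk_size`` are filtered in
    overlapping chunks (inner region kept) to bound memory; every chunk uses
    the cutoff *wavelength* implied by pc_keep on the full track, so seams do
    not shift the passband, and the overlap keeps edge ringing out of the
    retained region.
    """
    if not 0 < pc_keep <= 1:
        raise ValueError("pc_keep must be in (0, 1]")
    x = track.values
    n = len(x)
    n_keep = int(np.ceil(pc_keep * (n // 2 + 1)))
    if n <= chunk_size:
        out = _lowpass(x, n_keep)
    else:
        cutoff_wavelength = n / n_keep  # shortest retained period (bp)
        out = np.empty(n)
        for s in range(0, n, chunk_size):
            e = min(s + chunk_size, n)
            ws, we = max(0, s - chunk_overlap), min(n, e + chunk_overlap)
            m_keep = int(np.ceil((we - ws) / cutoff_wavelength))
            out[s:e] = _lowpass(x[ws:we], m_keep)[s - ws : s - ws + (e - s)]
    return OccupancyTrack(track.chrom, out, "smoothed")


def _merge_summits(candidates: np.ndarray, heights: np.ndarray, min_sep: int) -> list[int]:
    """Greedy suppression: accept by descending height (ties -> leftmost); reject
    any candidate within min_sep of an accepted summit."""
    order = np.lexsort((candidates, -heights))
    accepted: list[int] = []
    for idx in order:
        c = int(candidates[idx])
        j = bisect.bisect_left(accepted, c)
        if j > 0 and c - accepted[j - 1] < min_sep:
            continue
        if j < len(accepted) and accepted[j] - c < min_sep:
            continue
        accepted.insert(j, c)
    return accepted


def call_peaks(
    track: OccupancyTrack,
    raw: OccupancyTrack,
    frags: FragmentSet,
    params: PeakCallParams | None = None,
) -> list[NucleosomePeak]:
    """Call scored nucleosome peaks from a smoothed track.

    Summits are strict local maxima of the smoothed signal strictly above the
    ``threshold_pct`` percentile (over covered positions).  Each peak carries
    a height score (normal-CDF standardised smoothed height), a width score
    (1 - MAD of fragment midpoints in the footprint window / footprint/4),
    and their mean as the combined score; peaks with score <= min_score are
    discarded.
    """
    params = params or PeakCallParams()
    if track.kind != "smoothed":
        raise ValueError("call_peaks expects a smoothed track (see fft_smooth)")
    if track.chrom != raw.chrom or len(track) != len(raw):
        raise ValueError("smoothed and raw tracks must cover the same chromosome")
    sm = track.values
    covered = raw.values > 0
    if not covered.any():
        warnings.warn(f"no covered positions on {track.chrom}; no peaks called", stacklevel=2)
        return []
    ref = sm[covered] if params.threshold_over == "covered" else sm
    threshold = np.percentile(ref, params.threshold_pct)

    interior = np.flatnonzero((sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:])) + 1
    interior = interior[sm[interior] > threshold]
    if interior.size == 0:
        return []
    summits = _merge_summits(interior, sm[interior], params.min_sep)

    mu = float(sm[covered].mean())
    sd = float(sm[covered].std())
    mids = frags.midpoints(track.chrom)
    half = params.footprint / 2.0
    n = len(sm)
    peaks: list[NucleosomePeak] = []
    for center in summits:
        height = float(sm[center])
        score_h = float(ndtr((height - mu) / sd)) if sd > 0 else 0.5
        lo = np.searchsorted(mids, center - half, side="left")
        hi = np.searchsorted(mids, center + half, side="right")
        window = mids[lo:hi]
        if window.size == 0:
            score_w = 0.0
        else:
            mad = float(np.median(np.abs(window - np.median(window))))
            score_w = max(0.0, 1.0 - mad / (params.footprint / 4.0))
        score = (score_h + score_w) / 2.0
        if score <= params.min_score:
            continue
        start = max(0, center - params.footprint // 2)
        end = min(n, start + params.footprint)
        peaks.append(
            NucleosomePeak(track.chrom, center, start, end, height, score_h, score_w, score)
        )
    peaks.sort(key=lambda p: p.center)
    return peaks


def write_bedgraph(track: OccupancyTrack, path, clamp_negative: bool = True) -> None:
    """Write a track as bedGraph with adjacent equal values run-length merged.

    Smoothed tracks may dip slightly negative (Gibbs ringing); negatives are
    clamped to 0 at export only, never before peak calling.
    """
    v = track.values
    if clamp_negative:
        v = np.maximum(v, 0.0)
    breaks = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(v)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v[s]:g}\n")


def write_peaks(peaks: list[NucleosomePeak], path) -> None:
    """Write peaks as BED6+ TSV (BED score = combined score scaled to 0-1000)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\theight\tscore_h\tscore_w\n")
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tnuc{i + 1}\t{round(p.score * 1000)}\t.\t"
                f"{p.height:.4f}\t{p.score_h:.4f}\t{p.score_w:.4f}\n"
            )
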