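"""Sequence-based nucleosome preference and equilibrium occupancy.

The model combines the two best-established sequence determinants of
nucleosome formation:

* a ~10 bp periodic preference for flexible AA/TT/TA/AT dinucleotides
  (and anti-phase GC-class dinucleotides) that matches the helical repeat of
  DNA bent around the histone octamer, and
* a strong penalty for poly(dA:dT) homopolymer runs, which are stiff and
  exclude nucleosomes.

Each candidate start position i gets an energy

    E(i) = -alpha * s_per(i) + beta * f_AT5(i)

where s_per is the cosine-weighted dinucleotide periodicity score over the
footprint and f_AT5 the density of AAAAA/TTTTT 5-mers within it.  Occupancy
then follows from the hard-rod (Tonks-gas) equilibrium: nucleosomes are
non-overlapping rods of length L on the sequence, and the exact
partition-function recursion gives the probability each position is covered.
All partition arithmetic is done in log space.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SequencePreferenceModel:
    """Parameters of the sequence-preference energy and the placement ensemble.

    footprint
        Nucleosome length L in bp (DNA wrapped around the octamer).
    period
        Dinucleotide phasing period p in bp (~one helical turn).
    alpha
        Weight of the periodicity reward (dimensionless log-units).
    beta
        Weight of the poly(dA:dT) penalty.
    mu
        Chemical potential: log statistical weight per placed nucleosome,
        controlling overall occupancy.
    """

    footprint: int = 147
    period: float = 10.1
    alpha: float = 1.0
    beta: float = 4.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.footprint < 2:
            raise ValueError("footprint must be >= 2")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        for name in ("period", "alpha", "beta", "mu"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class EnergyTrack:
    """Per-start-position nucleosome energy; entry i is for occupying [i, i+L)."""

    E: np.ndarray
    footprint: int
    has_n: np.ndarray  # per start position: window contains an ambiguous base


@dataclass
class PredictedOccupancy:
    """Equilibrium per-base coverage probability and per-position start probability."""

    occ: np.ndarray
    start_prob: np.ndarray


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N etc.) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE.items():
        lut[ord(base)] = code
    return lut[arr]


def nucleosome_energy(seq: str, model: SequencePreferenceModel | None = None) -> EnergyTrack:
    """Energy E(i) = -alpha*s_per(i) + beta*f_AT5(i) for every start position.

    s_per(i) = (1/L) * sum_{j=0}^{L-2} cos(2*pi*(j - (L-2)/2)/p) * d(i+j), with
    d = +1 for AA/TT/TA/AT dinucleotides, -1 for GG/CC/GC/CG, 0 otherwise
    (including any dinucleotide touching an ambiguous base).  The cosine is
    phased on the window center (the dyad), which makes E invariant under
    reverse complement, as it must be for a strandless particle.  f_AT5(i) is
    the fraction of the L-4 five-mers inside [i, i+L) that are AAAAA or TTTTT;
    5-mers containing N never count.  Windows containing an N are flagged in
    ``has_n``.
    """
    model = model or SequencePreferenceModel()
    L = model.footprint
    code = _encode(seq)
    n = len(code)
    if n < L:
        raise ValueError(f"sequence length {n} shorter than footprint {L}")

    is_at = (code == 0) | (code == 3)
    is_gc = (code == 1) | (code == 2)
    d = np.zeros(n - 1)
    d[is_at[:-1] & is_at[1:]] = 1.0
    d[is_gc[:-1] & is_gc[1:]] = -1.0

    kernel = np.cos(2 * np.pi * (np.arange(L - 1) - (L - 2) / 2.0) / model.period)
    # correlate: s_per_raw[i] = sum_j kernel[j] * d[i+j], i = 0..n-L
    s_per = np.correlate(d, kernel, mode="valid") / L

    is_a = code == 0
    is_t = code == 3
    run_a = _all_in_window(is_a, 5)
    run_t = _all_in_window(is_t, 5)
    five = (run_a | run_t).astype(float)  # five[k]: 5-mer at k is AAAAA or TTTTT
    f_at5 = _window_sum(five, L - 4) / (L - 4)

    has_n = _window_sum((code == 4).astype(float), L) > 0
    E = -model.alpha * s_per + model.beta * f_at5
    return EnergyTrack(E=E, footprint=L, has_n=has_n)


def _all_in_window(mask: np.ndarray, w: int) -> np.ndarray:
    """mask of length n -> length n-w+1 booleans: all w positions True."""
    return _window_sum(mask.astype(float), w) == w


def _window_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _logaddexp(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if b == -math.inf:
        return a
    return a + math.log1p(math.exp(b - a))


def equilibrium_occupancy(
    energy: EnergyTrack, model: SequencePreferenceModel | None = None
) -> PredictedOccupancy:
    """Exact hard-rod equilibrium from the per-position energies.

    Statistical weights w(i) = exp(mu - E(i)).  Forward partial partition
    functions F and their mirror R are built by the recursion
    F(b) = F(b-1) + w(b-L+1) * F(b-L); the start probability is
    start_prob[i] = F(i-1) * w(i) * R(i+L) / Z with Z = F(N-1), and occupancy
    is the L-window sum of start probabilities.  Computed in log space so Z
    cannot overflow for long sequences.
    """
    model = model or SequencePreferenceModel(footprint=energy.footprint)
    L = energy.footprint
    E = np.asarray(energy.E, dtype=float)
    if np.isnan(E).any():
        raise ValueError("energy track contains NaN")
    M = len(E)
    N = M + L - 1
    logw = (model.mu - E).tolist()

    # logF[b+1] holds log F(b); logF[0] = log F(-1) = 0
    logF = [0.0] * (N + 1)
    for b in range(N):
        prev = logF[b]
        i = b - L + 1
        logF[b + 1] = _logaddexp(prev, logw[i] + logF[i]) if i >= 0 else prev
    # logR[b] holds log R(b); logR[N] = 0
    logR = [0.0] * (N + 1)
    for b in range(N - 1, -1, -1):
        nxt = logR[b + 1]
        logR[b] = _logaddexp(nxt, logw[b] + logR[b + L]) if b < M else nxt

    logZ = logF[N]
    logw_arr = np.array(logw)
    log_sp = np.array(logF[:M]) + logw_arr + np.array(logR[L : L + M]) - logZ
    start_prob = np.exp(log_sp)
    occ = np.convolve(start_prob, np.ones(L), mode="full")  # length N
    return PredictedOccupancy(occ=np.minimum(occ, 1.0), start_prob=start_prob)


@dataclass
class CompositionTrack:
    """Sliding-window base fractions (centered windows, step 1).

    Fractions are over unambiguous bases only; a window of all-ambiguous
    bases yields NaN fractions.
    """

    window: int
    centers: np.ndarray
    fA: np.ndarray
    fC: np.ndarray
    fG: np.ndarray
    fT: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"center": self.centers, "fA": self.fA, "fC": self.fC, "fG": self.fG, "fT": self.fT}
        )


def nucleotide_composition(seq: str, window: int = 50) -> CompositionTrack:
    """Base fractions over a sliding window of the given width, step 1."""
    code = _encode(seq)
    n = len(code)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    left = window // 2
    centers = np.arange(left, n - (window - left) + 1)
    counts = {}
    for base, k in _BASE.items():
        counts[base] = _window_sum((code == k).astype(float), window)
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = {b: np.where(denom > 0, c / denom, np.nan) for b, c in counts.items()}
    return CompositionTrack(window, centers, fracs["A"], fracs["C"], fracs["G"], fracs["T"])


@dataclass
class PolyATTract:
    """A poly(dA:dT)-class tract: an A/T run (or high-A/T interval)."""

    chrom: str
    start: int
    end: int
    purity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def find_polyAT_tracts(
    seq: str,
    min_len: int = 20,
    mode: str = "pure",
    purity: float = 0.9,
    chrom: str = "seq",
    subwindow: int = 20,
) -> list[PolyATTract]:
    """Locate nucleosome-excluding poly A/T tracts.

    mode="pure": maximal runs consisting only of A/T, length >= min_len.
    mode="windowed": maximal intervals in which every length-``subwindow``
    subwindow has A/T fraction >= purity, trimmed to the outermost A/T bases,
    then filtered to length >= min_len.  Candidate intervals closer than one
    subwindow can overlap and are merged into one tract (its ``purity`` field
    records the merged tract's actual A/T fraction).  Tracts are sorted and
    non-overlapping.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if mode not in ("pure", "windowed"):
        raise ValueError("mode must be 'pure' or 'windowed'")
    su = seq.upper()
    is_at = np.isin(_encode(su), (0, 3))
    tracts: list[PolyATTract] = []
    if mode == "pure":
        for m in re.finditer(r"[AT]{%d,}" % min_len, su):
            tracts.append(PolyATTract(chrom, m.start(), m.end(), 1.0))
        return tracts

    n = len(su)
    if n < subwindow:
        return []
    ok = _window_sum(is_at.astype(float), subwindow) >= purity * subwindow - 1e-9
    # maximal runs of consecutive passing subwindow starts k0..k1 -> [k0, k1+subwindow)
    intervals: list[list[int]] = []
    k = 0
    while k < len(ok):
        if not ok[k]:
            k += 1
            continue
        k0 = k
        while k < len(ok) and ok[k]:
            k += 1
        start, end = k0, (k - 1) + subwindow
        if intervals and start < intervals[-1][1]:  # merge overlap
            intervals[-1][1] = end
        else:
            intervals.append([start, end])
    for start, end in intervals:
        # trim to outermost A/T bases
        while start < end and not is_at[start]:
            start += 1
        while end > start and not is_at[end - 1]:
            end -= 1
        if end - start >= min_len:
            at_frac = float(is_at[start:end].mean())
            tracts.append(PolyATTract(chrom, start, end, at_frac))
    return tracts


def write_tracts_bed(tracts: list[PolyATTract], path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tracts):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tpolyAT{i + 1}\n")
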