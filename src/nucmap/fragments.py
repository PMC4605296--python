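"""Paired-end MNase fragment I/O, length statistics, and the single-nucleosome size filter.

MNase digestion of chromatin leaves ~147 bp of DNA protected by each
nucleosome.  Paired-end sequencing of the protected material yields fragment
intervals whose length distribution has a mode near 150 bp; restricting to a
127-168 bp window isolates the single-nucleosome population before
positioning analysis.

Coordinates are 0-based half-open throughout; BED/BED-PE files on disk follow
the BED convention.  Fragments are strandless: MNase protection has no
orientation, so any strand field in the input is ignored.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Inclusive single-nucleosome size-filter bounds (bp).
DEFAULT_LEN_MIN = 127
DEFAULT_LEN_MAX = 168

_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class FragmentRecord:
    """One strandless protected-DNA interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """An ordered collection of fragments validated against chromosome sizes.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom``, ``start``, ``end``.
    chrom_sizes
        Mapping chromosome name -> length (bp).  Every record must lie within
        its chromosome.
    provenance
        Free-text label describing where the fragments came from.
    """

    def __init__(self, df: pd.DataFrame, chrom_sizes: dict[str, int], provenance: str = ""):
        df = df.loc[:, _COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad_chrom = ~df["chrom"].isin(chrom_sizes)
        if bad_chrom.any():
            raise ValueError(
                f"{int(bad_chrom.sum())} record(s) on chromosomes absent from chrom_sizes"
            )
        sizes = df["chrom"].map(chrom_sizes).to_numpy()
        if ((df["start"].to_numpy() < 0) | (df["end"].to_numpy() > sizes)).any():
            raise ValueError("record(s) extend beyond chromosome bounds")
        if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
            raise ValueError("record(s) with end <= start")
        self.df = df
        self.chrom_sizes = dict(chrom_sizes)
        self.provenance = provenance

    @classmethod
    def from_records(cls, records, chrom_sizes, provenance: str = "") -> "FragmentSet":
        rows = [(r.chrom, r.start, r.end) for r in records]
        df = pd.DataFrame(rows, columns=_COLUMNS) if rows else pd.DataFrame(columns=_COLUMNS)
        return cls(df, chrom_sizes, provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield FragmentRecord(row.chrom, int(row.start), int(row.end))

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def on(self, chrom: str) -> pd.DataFrame:
        """Records on one chromosome (usage error if unknown)."""
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        return self.df[self.df["chrom"] == chrom]

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted fragment midpoints on one chromosome."""
        sub = self.on(chrom)
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        return np.sort(mids)

    def write_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class LengthHistogram:
    """Fragment-length tally; ``counts[L]`` is the number of fragments of length L."""

    counts: dict[int, int]
    total: int

    @property
    def modal_length(self) -> int | None:
        """Most frequent length (smallest on ties); None for an empty histogram."""
        if not self.counts:
            return None
        return min(self.counts, key=lambda length: (-self.counts[length], length))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for length in sorted(self.counts):
                fh.write(f"{length}\t{self.counts[length]}\n")


@dataclass
class SizeFilterResult:
    """Outcome of the size filter: the retained set plus kept/dropped accounting."""

    fragments: FragmentSet
    n_kept: int
    n_dropped: int
    lo: int
    hi: int


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column TSV of chromosome name and length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out[name] = int(size)
    return out


def _read_bedpe(path) -> tuple[pd.DataFrame, int]:
    """BED-PE mate pairs -> fragment extents (leftmost start to rightmost end)."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_COLUMNS), 0
    if raw.shape[1] < 6:
        raise ValueError(f"BED-PE requires >= 6 columns, got {raw.shape[1]}")
    same = raw[0].astype(str) == raw[3].astype(str)
    n_cross = int((~same).sum())
    sub = raw[same]
    df = pd.DataFrame(
        {
            "chrom": sub[0].astype(str),
            "start": np.minimum(sub[1].to_numpy(int), sub[4].to_numpy(int)),
            "end": np.maximum(sub[2].to_numpy(int), sub[5].to_numpy(int)),
        }
    )
    return df, n_cross


def _read_fragment_tsv(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_COLUMNS)
    if raw.shape[1] < 3:
        raise ValueError(f"fragment TSV requires >= 3 columns, got {raw.shape[1]}")
    return pd.DataFrame(
        {"chrom": raw[0].astype(str), "start": raw[1].astype(int), "end": raw[2].astype(int)}
    )


def _read_bam(path, drop_duplicates: bool = False) -> pd.DataFrame:
    """Reduce proper pairs to fragment intervals.

    Only primary, proper-pair alignments with both mates mapped to the same
    chromosome contribute; each pair is visited once via its leftmost mate
    (template length > 0).  Duplicates are kept unless ``drop_duplicates``.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if (
                not read.is_proper_pair
                or read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.reference_id != read.next_reference_id
                or read.template_length <= 0
            ):
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            start = read.reference_start
            rows.append((read.reference_name, start, start + read.template_length))
    return pd.DataFrame(rows, columns=_COLUMNS) if rows else pd.DataFrame(columns=_COLUMNS)


def read_fragments(
    path,
    format: str,
    chrom_sizes: dict[str, int],
    drop_duplicates: bool = False,
    provenance: str | None = None,
) -> FragmentSet:
    """Read fragments in one of the supported dialects and validate them.

    Records on chromosomes absent from ``chrom_sizes``, or extending beyond a
    chromosome end, are dropped with a logged count; it is an error only if
    every record drops.

    Parameters
    ----------
    format
        One of ``bedpe``, ``bam``, ``fragment-tsv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bedpe":
        df, n_cross = _read_bedpe(path)
        if n_cross:
            log.warning("dropped %d inter-chromosomal mate pairs", n_cross)
    elif format == "fragment-tsv":
        df = _read_fragment_tsv(path)
    elif format == "bam":
        df = _read_bam(path, drop_duplicates=drop_duplicates)
    else:
        raise ValueError(f"unknown format {format!r}; expected bedpe, bam or fragment-tsv")

    n_in = len(df)
    if n_in:
        ok_chrom = df["chrom"].isin(chrom_sizes)
        sizes = df["chrom"].map(chrom_sizes)
        ok = ok_chrom & (df["start"] >= 0) & (df["end"] > df["start"]) & (df["end"] <= sizes.fillna(-1))
        n_drop = int((~ok).sum())
        if n_drop:
            log.warning("dropped %d/%d records failing chromosome-bound validation", n_drop, n_in)
        df = df[ok]
        if df.empty:
            raise ValueError(f"all {n_in} records failed validation against chrom_sizes")
    return FragmentSet(df, chrom_sizes, provenance or f"{format}:{path.name}")


def length_histogram(frags: FragmentSet) -> LengthHistogram:
    """Tally fragment lengths (Fig.-1B-style size distribution)."""
    counts = Counter(int(x) for x in frags.lengths)
    return LengthHistogram(dict(counts), total=len(frags))


def filter_by_length(
    frags: FragmentSet, lo: int = DEFAULT_LEN_MIN, hi: int = DEFAULT_LEN_MAX
) -> SizeFilterResult:
    """Keep fragments with lo <= length <= hi (both bounds inclusive).

    The defaults select the single-nucleosome population.  Input order is
    preserved, and ``n_kept + n_dropped`` always equals the input size.
    """
    if not 1 <= lo <= hi:
        raise ValueError(f"require 1 <= lo <= hi, got lo={lo}, hi={hi}")
    lengths = frags.lengths
    keep = (lengths >= lo) & (lengths <= hi)
    kept = FragmentSet(
        frags.df[keep], frags.chrom_sizes, provenance=f"{frags.provenance}|len[{lo},{hi}]"
    )
    return SizeFilterResult(
        fragments=kept,
        n_kept=int(keep.sum()),
        n_dropped=int((~keep).sum()),
        lo=lo,
        hi=hi,
    )
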