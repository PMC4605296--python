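"""Synthetic MNase libraries with planted ground truth.

Generates a genome of alternating nucleosome-array blocks (GC-biased sequence
with 10 bp AA/TT phasing planted under each dyad, dyads every repeat length)
and nucleosome-depleted blocks (near-pure A/T sequence, no dyads), then
samples protected fragments around the planted dyads with positional jitter
plus a uniform background representing non-nucleosomal digestion products.
Scored point sites can be planted at depleted-block centers, emulating
ChIP-defined origin-binding sites, and an in-vitro binding table can be
derived as a decreasing function of planted occupancy.

Everything is deterministic under (params, seed): each generator draws from
its own seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .profiles import FeatureSite

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic library.

    Defaults emulate a metazoan MNase library: ~150 bp protected fragments
    (sd 8), 197 bp nucleosome repeat, 20 bp dyad jitter, 10% background
    digestion, GC-rich arrays and highly A/T NDR blocks.
    """

    chrom_length: int = 1_000_000
    chrom_name: str = "chrS"
    repeat_length: int = 197
    footprint: int = 147
    array_block_length: int = 3000
    ndr_block_lengths: tuple[int, ...] = (300, 700)
    gc_rich_fraction: float = 0.6
    at_purity: float = 0.95
    n_fragments: int = 200_000
    frag_len_mean: float = 150.0
    frag_len_sd: float = 8.0
    dyad_jitter_sd: float = 20.0
    background_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "chrom_length", "repeat_length", "footprint", "array_block_length",
            "frag_len_mean", "frag_len_sd", "dyad_jitter_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        if not all(x > 0 for x in self.ndr_block_lengths):
            raise ValueError("ndr_block_lengths must be positive")
        if not 0 <= self.gc_rich_fraction <= 1 or not 0 <= self.at_purity <= 1:
            raise ValueError("fractions must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the genome, dyads, depleted blocks, and sites."""

    genome: dict[str, str]
    dyads: np.ndarray
    ndr_blocks: list[tuple[int, int]]
    sites: list[FeatureSite] = field(default_factory=list)
    params: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def make_genome(params: GeneratorParams | None = None) -> SyntheticTruth:
    """Build the synthetic chromosome and its planted architecture.

    Array blocks carry dyads every ``repeat_length`` (first dyad one
    half-footprint inside the block) over GC-biased sequence, with AA/TT
    dinucleotides planted every 10 bp under each dyad; NDR blocks are A/T at
    ``at_purity`` and never contain a dyad.  With an empty
    ``ndr_block_lengths`` the dyads tile the whole chromosome.
    """
    params = params or GeneratorParams()
    min_needed = params.array_block_length + (min(params.ndr_block_lengths) if params.ndr_block_lengths else 0)
    if params.chrom_length < min_needed:
        raise ValueError(
            f"chrom_length {params.chrom_length} too short for one array + one NDR block"
        )
    rng = _rng(params.seed, 1)
    n = params.chrom_length
    gc = params.gc_rich_fraction

    # block layout: array, ndr, array, ndr, ... (ndr lengths cycled);
    # with no NDR blocks the whole chromosome is one array
    blocks: list[tuple[str, int, int]] = []
    if not params.ndr_block_lengths:
        blocks.append(("array", 0, n))
    pos = 0
    ndr_i = 0
    while pos < n and params.ndr_block_lengths:
        end = min(pos + params.array_block_length, n)
        blocks.append(("array", pos, end))
        pos = end
        if pos >= n:
            continue
        w = params.ndr_block_lengths[ndr_i % len(params.ndr_block_lengths)]
        ndr_i += 1
        end = min(pos + w, n)
        blocks.append(("ndr", pos, end))
        pos = end

    p_array = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = np.empty(n, dtype="U1")
    dyads: list[int] = []
    ndr_blocks: list[tuple[int, int]] = []
    half = params.footprint // 2
    for kind, s, e in blocks:
        if kind == "ndr":
            # poly(dA:dT)-style block: concatenated A/T homopolymer runs,
            # contaminated with G/C at rate (1 - at_purity)
            w = e - s
            runs: list[np.ndarray] = []
            filled = 0
            while filled < w:
                r = int(rng.integers(10, 40))
                runs.append(np.full(min(r, w - filled), rng.choice(["A", "T"])))
                filled += r
            block = np.concatenate(runs)[:w]
            contam = rng.random(w) > params.at_purity
            block[contam] = rng.choice(["G", "C"], size=int(contam.sum()))
            seq[s:e] = block
            ndr_blocks.append((s, e))
            continue
        seq[s:e] = rng.choice(_BASES, size=e - s, p=p_array)
        d = s + half
        while d + half < e:
            dyads.append(d)
            # 10 bp AA/TT phasing under the dyad (alternating strands)
            for j, off in enumerate(range(-70, 71, 10)):
                k = d + off
                if s <= k and k + 2 <= e:
                    seq[k : k + 2] = "AA" if j % 2 == 0 else "TT"
            d += params.repeat_length

    dyads_arr = np.array(sorted(dyads), dtype=np.int64)
    for s, e in ndr_blocks:  # generation-time invariant
        assert not ((dyads_arr >= s) & (dyads_arr < e)).any(), "dyad inside an NDR block"
    return SyntheticTruth(
        genome={params.chrom_name: "".join(seq)},
        dyads=dyads_arr,
        ndr_blocks=ndr_blocks,
        params=params,
        seed=params.seed,
    )


def sample_fragments(truth: SyntheticTruth, params: GeneratorParams | None = None) -> FragmentSet:
    """Draw the protected-fragment library around the planted dyads.

    A fraction (1 - background_fraction) of fragments pick a dyad uniformly
    and center on it with Normal jitter; background fragments center
    uniformly.  Lengths are Normal(frag_len_mean, frag_len_sd), rounded,
    clipped to >= 50 bp; fragments are clipped to chromosome bounds.
    """
    params = params or truth.params
    if params.n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = _rng(params.seed, 2)
    chrom = params.chrom_name
    n = truth.chrom_sizes[chrom]
    n_total = params.n_fragments
    n_bg = int(round(params.background_fraction * n_total))
    n_nuc = n_total - n_bg

    centers = np.empty(n_total)
    if n_nuc:
        picks = rng.integers(0, len(truth.dyads), size=n_nuc)
        centers[:n_nuc] = truth.dyads[picks] + rng.normal(0, params.dyad_jitter_sd, size=n_nuc)
    if n_bg:
        centers[n_nuc:] = rng.uniform(0, n, size=n_bg)
    lengths = np.maximum(
        np.rint(rng.normal(params.frag_len_mean, params.frag_len_sd, size=n_total)), 50
    )
    starts = np.clip(np.rint(centers - lengths / 2).astype(np.int64), 0, n - 1)
    ends = np.clip((starts + lengths).astype(np.int64), 1, n)
    starts = np.minimum(starts, ends - 1)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    return FragmentSet(df, truth.chrom_sizes, provenance=f"synthetic(seed={params.seed})")


def make_sites(
    truth: SyntheticTruth,
    n_sites: int,
    score_law: tuple = ("uniform", 5.0, 10.0),
    placement: str = "in-NDR",
) -> list[FeatureSite]:
    """Plant scored point sites, by default at NDR-block centers.

    score_law is ("constant", c), ("uniform", lo, hi) or ("normal", mean, sd).
    placement="uniform" scatters sites anywhere on the chromosome instead.
    """
    rng = _rng(truth.seed, 3)
    chrom = truth.params.chrom_name
    if placement == "in-NDR":
        if n_sites > len(truth.ndr_blocks):
            raise ValueError(
                f"{n_sites} sites requested but only {len(truth.ndr_blocks)} NDR blocks planted"
            )
        chosen = rng.choice(len(truth.ndr_blocks), size=n_sites, replace=False)
        centers = [(truth.ndr_blocks[i][0] + truth.ndr_blocks[i][1]) // 2 for i in sorted(chosen)]
    elif placement == "uniform":
        centers = sorted(int(c) for c in rng.integers(0, truth.chrom_sizes[chrom], size=n_sites))
    else:
        raise ValueError("placement must be 'in-NDR' or 'uniform'")

    kind = score_law[0]
    if kind == "constant":
        scores = np.full(n_sites, float(score_law[1]))
    elif kind == "uniform":
        scores = rng.uniform(score_law[1], score_law[2], size=n_sites)
    elif kind == "normal":
        scores = rng.normal(score_law[1], score_law[2], size=n_sites)
    else:
        raise ValueError(f"unknown score law {kind!r}")
    sites = [FeatureSite(chrom, int(c), float(s)) for c, s in zip(centers, scores)]
    truth.sites = sites
    return sites


def planted_occupancy(truth: SyntheticTruth) -> np.ndarray:
    """Indicator track: 1 where a planted nucleosome footprint covers the base."""
    n = truth.chrom_sizes[truth.params.chrom_name]
    half = truth.params.footprint // 2
    occ = np.zeros(n)
    for d in truth.dyads:
        occ[max(0, d - half) : min(n, d + half + 1)] = 1.0
    return occ


def make_invitro_binding(
    truth: SyntheticTruth,
    region: tuple[int, int] | None = None,
    n_fragments: int = 24,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Synthetic naked-DNA binding table: binding decreases with planted occupancy.

    The region is tiled into equal fragments; each fragment's relative binding
    is max(0, 1 - mean planted occupancy + Normal(0, noise_sd)) — a noisy
    decreasing function of occupancy, emulating a binder that prefers the
    sequences nucleosomes avoid.  The default region tiles ~1.5 kb fragments
    from the chromosome start, the scale of restriction fragments assayed in
    a locus-wide naked-DNA binding experiment.
    """
    rng = _rng(truth.seed, 4)
    chrom = truth.params.chrom_name
    n = truth.chrom_sizes[chrom]
    start, end = region if region is not None else (0, min(n, n_fragments * 1500))
    width = (end - start) // n_fragments
    if width < 1:
        raise ValueError("region too short for the requested number of fragments")
    occ = planted_occupancy(truth)
    rows = []
    for i in range(n_fragments):
        s = start + i * width
        e = s + width
        binding = max(0.0, 1.0 - float(occ[s:e].mean()) + float(rng.normal(0, noise_sd)))
        rows.append({"chrom": chrom, "start": s, "end": e, "binding": binding})
    return pd.DataFrame(rows)


def write_genome_fasta(truth: SyntheticTruth, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in truth.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SyntheticTruth, path) -> None:
    """Structured key-value sidecar recording the planted ground truth."""
    with open(path, "w") as fh:
        fh.write("# synthetic ground truth\n")
        for k, v in asdict(truth.params).items():
            fh.write(f"param\t{k}\t{v}\n")
        fh.write(f"seed\t{truth.seed}\n")
        for d in truth.dyads:
            fh.write(f"dyad\t{truth.params.chrom_name}\t{d}\n")
        for s, e in truth.ndr_blocks:
            fh.write(f"ndr_block\t{truth.params.chrom_name}\t{s}\t{e}\n")
        for site in truth.sites:
            fh.write(f"site\t{site.chrom}\t{site.center}\t{site.score}\n")


def write_sites_bed(sites: list[FeatureSite], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f"{s.chrom}\t{s.center}\t{s.center + 1}\tsite{i + 1}\t{s.score}\t.\n")
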