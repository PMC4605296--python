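import numpy as np
import pytest

import nucmap as nm


def _build_library(params: nm.GeneratorParams) -> dict:
    truth = nm.make_genome(params)
    raw_frags = nm.sample_fragments(truth, params)
    filt = nm.filter_by_length(raw_frags)
    raw = nm.coverage_track(filt.fragments, params.chrom_name)
    smoothed = nm.fft_smooth(raw)
    peaks = nm.call_peaks(smoothed, raw, filt.fragments)
    return {
        "params": params,
        "truth": truth,
        "raw_fragments": raw_frags,
        "filter_result": filt,
        "fragments": filt.fragments,
        "raw": raw,
        "smoothed": smoothed,
        "peaks": peaks,
    }


@pytest.fixture(scope="session")
def default_library():
    """The full default synthetic library: 1 Mb, 200k fragments, seed 1."""
    return _build_library(nm.GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def small_library():
    """A 60 kb library at the default coverage, for cheaper per-module tests."""
    return _build_library(
        nm.GeneratorParams(chrom_length=60_000, n_fragments=12_000, seed=3)
    )


def summit_match_stats(dyads: np.ndarray, centers: np.ndarray, tol: int = 20):
    """(recall, precision): planted dyads with a summit within tol, and vice versa."""
    dyads = np.sort(np.asarray(dyads))
    centers = np.sort(np.asarray(centers))

    def frac_near(query, ref):
        i = np.searchsorted(ref, query)
        left = ref[np.clip(i - 1, 0, len(ref) - 1)]
        right = ref[np.clip(i, 0, len(ref) - 1)]
        return float(
            (np.minimum(np.abs(query - left), np.abs(query - right)) <= tol).mean()
        )

    return frac_near(dyads, centers), frac_near(centers, dyads)
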