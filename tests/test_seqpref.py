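import itertools
import math
import re

import numpy as np
import pytest

import nucmap as nm
from nucmap.seqpref import EnergyTrack, SequencePreferenceModel


def cosine_sum(L, p):
    """Dyad-centered cosine kernel summed over the window's dinucleotides."""
    return sum(math.cos(2 * math.pi * (j - (L - 2) / 2) / p) for j in range(L - 1)) / L


def direct_energy(seq, i, model):
    """Oracle: E(i) by direct summation over the window, no vectorisation."""
    L, p = model.footprint, model.period
    at, gc = {"A", "T"}, {"G", "C"}
    s_per = 0.0
    for j in range(L - 1):
        pair = set(seq[i + j : i + j + 2])
        d = 1.0 if pair <= at else (-1.0 if pair <= gc else 0.0)
        s_per += math.cos(2 * math.pi * (j - (L - 2) / 2) / p) * d
    s_per /= L
    n5 = sum(
        1
        for k in range(i, i + L - 4)
        if seq[k : k + 5] in ("AAAAA", "TTTTT")
    )
    return -model.alpha * s_per + model.beta * n5 / (L - 4)


def enumerate_start_prob(weights, L):
    """Oracle: marginal start probabilities by exhaustive enumeration of all
    non-overlapping placements."""
    M = len(weights)
    marg = np.zeros(M)
    Z = 0.0

    def rec(start_min, w_acc, placed):
        nonlocal Z
        Z += w_acc
        for i in placed:
            marg[i] += w_acc
        for i in range(start_min, M):
            rec(i + L, w_acc * weights[i], placed + [i])

    rec(0, 1.0, [])
    return marg / Z


_RC = str.maketrans("ACGT", "TGCA")


class TestNucleosomeEnergy:
    def test_poly_a_closed_form(self):
        model = SequencePreferenceModel()
        E = nm.nucleosome_energy("A" * 200, model).E
        expect = -model.alpha * cosine_sum(147, model.period) + model.beta
        assert np.allclose(E, expect, atol=1e-12)

    def test_poly_g_sign_symmetry(self):
        model = SequencePreferenceModel()
        E = nm.nucleosome_energy("G" * 200, model).E
        expect = model.alpha * cosine_sum(147, model.period)
        assert np.allclose(E, expect, atol=1e-12)

    def test_phased_dinucleotides_favour_in_phase_starts(self):
        """AA planted every 10 bp on a C background: the in-phase start is
        lower-energy than an out-of-phase one, and both match the direct-sum
        oracle."""
        model = SequencePreferenceModel(footprint=41, period=10.0)
        seq = list("C" * 200)
        for k in range(0, 190, 10):
            seq[k : k + 2] = "AA"
        seq = "".join(seq)
        track = nm.nucleosome_energy(seq, model)
        for i in (0, 5, 20, 25):
            assert track.E[i] == pytest.approx(direct_energy(seq, i, model), abs=1e-12)
        assert track.E[0] < track.E[5]

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        model = SequencePreferenceModel()
        fwd = nm.nucleosome_energy(seq, model).E
        rev = nm.nucleosome_energy(seq.translate(_RC)[::-1], model).E
        assert np.allclose(fwd, rev[::-1], atol=1e-12)

    def test_n_handling(self):
        model = SequencePreferenceModel(footprint=10)
        track = nm.nucleosome_energy("AANAAAAAAAAAAA" + "G" * 10, model)
        assert track.has_n[0] and not track.has_n[5]
        assert np.isfinite(track.E).all()

    def test_short_sequence_is_usage_error(self):
        with pytest.raises(ValueError, match="shorter than footprint"):
            nm.nucleosome_energy("ACGT", SequencePreferenceModel())


class TestEquilibriumOccupancy:
    def test_single_position_two_state(self):
        model = SequencePreferenceModel(footprint=5, mu=0.3)
        E = EnergyTrack(np.array([0.7]), 5, np.zeros(1, bool))
        pred = nm.equilibrium_occupancy(E, model)
        w = math.exp(0.3 - 0.7)
        assert pred.start_prob[0] == pytest.approx(w / (1 + w), abs=1e-12)
        assert np.allclose(pred.occ, w / (1 + w))

    def test_empty_lattice_limit(self):
        model = SequencePreferenceModel(footprint=3, mu=-50.0)
        E = EnergyTrack(np.zeros(98), 3, np.zeros(98, bool))
        pred = nm.equilibrium_occupancy(E, model)
        assert (pred.occ <= 1e-20).all()

    def test_given_small_case_matches_enumeration(self):
        E = np.array([0.5, -1.0, 0.0, 0.3, -0.5])
        model = SequencePreferenceModel(footprint=3, mu=0.0)
        pred = nm.equilibrium_occupancy(EnergyTrack(E, 3, np.zeros(5, bool)), model)
        oracle = enumerate_start_prob(np.exp(-E), 3)
        assert np.allclose(pred.start_prob, oracle, atol=1e-12)

    def test_dp_equals_enumeration_on_grid(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            N = int(rng.integers(3, 13))
            E = rng.normal(0, 1.5, N - 2)
            mu = float(rng.normal(0, 1))
            model = SequencePreferenceModel(footprint=3, mu=mu)
            pred = nm.equilibrium_occupancy(EnergyTrack(E, 3, np.zeros(len(E), bool)), model)
            oracle = enumerate_start_prob(np.exp(mu - E), 3)
            assert np.allclose(pred.start_prob, oracle, atol=1e-9)

    def test_occupancy_is_window_sum_of_start_prob(self):
        rng = np.random.default_rng(5)
        E = rng.normal(0, 2, 300)
        model = SequencePreferenceModel(footprint=20)
        pred = nm.equilibrium_occupancy(EnergyTrack(E, 20, np.zeros(300, bool)), model)
        N = 300 + 20 - 1
        manual = np.zeros(N)
        for i, sp in enumerate(pred.start_prob):
            manual[i : i + 20] += sp
        assert np.allclose(pred.occ, np.minimum(manual, 1.0), atol=1e-9)
        assert (pred.occ >= 0).all() and (pred.occ <= 1).all()
        assert pred.start_prob.sum() <= N / 20 + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_occupancy_monotone_in_mu(self, seed):
        """Raising the chemical potential packs in more nucleosomes: the mean
        occupancy (equivalently the expected particle number) never decreases.
        Per-base occupancy need not be monotone — packing can rearrange."""
        rng = np.random.default_rng(seed)
        E = rng.normal(0, 1, 120)
        means = []
        for mu in (-2.0, -1.0, 0.0, 1.0, 2.0):
            model = SequencePreferenceModel(footprint=10, mu=mu)
            means.append(
                nm.equilibrium_occupancy(EnergyTrack(E, 10, np.zeros(120, bool)), model).occ.mean()
            )
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_nan_energy_rejected(self):
        E = EnergyTrack(np.array([0.0, np.nan]), 3, np.zeros(2, bool))
        with pytest.raises(ValueError, match="NaN"):
            nm.equilibrium_occupancy(E, SequencePreferenceModel(footprint=3))


class TestComposition:
    def test_homopolymer(self):
        track = nm.nucleotide_composition("A" * 100, window=50)
        assert np.allclose(track.fA, 1.0)
        assert np.allclose(track.fC + track.fG + track.fT, 0.0)

    def test_tiled_acgt_is_uniform_at_interior_centers(self):
        track = nm.nucleotide_composition("ACGT" * 25, window=40)
        for f in (track.fA, track.fC, track.fG, track.fT):
            assert np.allclose(f, 0.25)

    def test_fractions_sum_to_one_excluding_ambiguity(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGTN"), size=500, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        track = nm.nucleotide_composition(seq, window=50)
        total = track.fA + track.fC + track.fG + track.fT
        assert np.allclose(total[np.isfinite(total)], 1.0, atol=1e-9)

    def test_window_matches_direct_count(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        track = nm.nucleotide_composition(seq, window=50)
        for idx in (0, 57, len(track.centers) - 1):
            c = track.centers[idx]
            win = seq[c - 25 : c + 25]
            assert track.fA[idx] == pytest.approx(win.count("A") / 50)

    def test_short_sequence_is_usage_error(self):
        with pytest.raises(ValueError):
            nm.nucleotide_composition("ACGT", window=50)


class TestPolyATTracts:
    def test_single_pure_run(self):
        seq = "G" * 10 + "AT" * 40 + "G" * 10
        tracts = nm.find_polyAT_tracts(seq, min_len=20, mode="pure")
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start, t.end, t.length) == (10, 90, 80)

    def test_interrupted_run_fails_pure_but_passes_windowed(self):
        seq = "A" * 19 + "G" + "A" * 19
        assert nm.find_polyAT_tracts(seq, min_len=20, mode="pure") == []
        tracts = nm.find_polyAT_tracts(seq, min_len=20, mode="windowed", purity=0.9)
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (0, 39)
        # oracle: every 20 bp subwindow of the reported interval passes purity
        s, e = tracts[0].start, tracts[0].end
        for k in range(s, e - 19):
            frac = sum(b in "AT" for b in seq[k : k + 20]) / 20
            assert frac >= 0.9

    def test_pure_mode_matches_regex_scan_oracle(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=10_000, p=[0.4, 0.1, 0.1, 0.4]))
        tracts = nm.find_polyAT_tracts(seq, min_len=12, mode="pure")
        oracle = [(m.start(), m.end()) for m in re.finditer(r"[AT]{12,}", seq)]
        assert [(t.start, t.end) for t in tracts] == oracle

    def test_tracts_sorted_and_disjoint(self):
        rng = np.random.default_rng(32)
        seq = "".join(rng.choice(list("ACGT"), size=5_000, p=[0.35, 0.15, 0.15, 0.35]))
        tracts = nm.find_polyAT_tracts(seq, min_len=15, mode="windowed", purity=0.85)
        for a, b in itertools.pairwise(tracts):
            assert a.end <= b.start

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            nm.find_polyAT_tracts("ACGT" * 10, purity=1.5, mode="windowed")


def test_planted_at_blocks_predicted_depleted(small_library):
    """Sign of the observed/predicted concordance: mean predicted occupancy over
    planted poly A:T blocks is below that over the GC-rich array blocks."""
    truth = small_library["truth"]
    seq = truth.genome[truth.params.chrom_name]
    model = SequencePreferenceModel()
    pred = nm.equilibrium_occupancy(nm.nucleosome_energy(seq, model), model)
    in_ndr = np.zeros(len(pred.occ), dtype=bool)
    for s, e in truth.ndr_blocks:
        in_ndr[s:e] = True
    assert pred.occ[in_ndr].mean() < pred.occ[~in_ndr].mean()
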