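"""Duplex scoring, dinucleotide shuffling and censored EVD calibration."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from structatlas.interaction import (EnergyModel, bin_and_fit,
                                     build_background, dinuc_shuffle,
                                     duplex_mfe, filter_hits, fit_censored_evd,
                                     interaction_pvalue, InteractionHit,
                                     score_pairs)
from structatlas.synthetic import SyntheticConfig, simulate_interaction_pairs

from oracles import duplex_oracle

rna = st.text(alphabet="ACGU", min_size=2, max_size=60)


def dinucs(s):
    return Counter(zip(s, s[1:]))


class TestDinucShuffle:
    def test_homopolymer_fixed_point(self):
        assert dinuc_shuffle("AAAA", 0) == "AAAA"

    def test_unique_eulerian_path(self):
        # A->C->G->U is the only valid walk
        for seed in range(5):
            assert dinuc_shuffle("ACGU", seed) == "ACGU"

    @settings(max_examples=60, deadline=None)
    @given(seq=rna, seed=st.integers(0, 2**31 - 1))
    def test_preserves_dinucleotides_and_endpoints(self, seq, seed):
        out = dinuc_shuffle(seq, seed)
        assert dinucs(out) == dinucs(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(out) == Counter(seq)

    def test_deterministic(self):
        s = "ACGUACGGUACGUAGCUAGCAUCGGAUC"
        assert dinuc_shuffle(s, 7) == dinuc_shuffle(s, 7)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            dinuc_shuffle("ACGN", 0)


class TestDuplexMfe:
    def test_no_complementarity_no_hit(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_perfect_gc_duplex_closed_form(self):
        for L in (3, 5, 8):
            h = duplex_mfe("G" * L, "C" * L)
            assert h.mfe == pytest.approx(-3.0 * L)
            assert h.site_length == L and h.gc_frac == 1.0

    def test_site_coordinates_of_embedded_site(self):
        q = "A" * 10 + "GGGGGG" + "A" * 10
        t = "G" * 4 + "CCCCCC" + "G" * 12  # flanks cannot pair A or G
        h = duplex_mfe(q, t)
        assert h.mfe == pytest.approx(-18.0)
        assert h.query_site == (10, 16)
        assert h.target_site == (4, 10)

    def test_symmetry_under_argument_swap(self, rng):
        for _ in range(40):
            q = "".join(rng.choice(list("ACGU"), size=30))
            t = "".join(rng.choice(list("ACGU"), size=25))
            h1 = duplex_mfe(q, t)
            h2 = duplex_mfe(t, q)
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert h1.mfe == pytest.approx(h2.mfe)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 14))
            m = int(rng.integers(4, 14))
            q = "".join(rng.choice(list("ACGU"), size=n))
            t = "".join(rng.choice(list("ACGU"), size=m))
            want = duplex_oracle(q, t)
            got = duplex_mfe(q, t)
            if want is None:
                assert got is None
            else:
                assert got is not None and got.mfe == pytest.approx(want)

    def test_accessibility_penalties_raise_energy(self):
        q, t = "GGGGGG", "CCCCCC"
        base = duplex_mfe(q, t).mfe
        acc = (np.full(6, 0.5), np.full(6, 0.5))
        h = duplex_mfe(q, t, accessibility=acc)
        assert h.mfe == pytest.approx(base + 6.0)  # 1.0 per pair

    def test_bulge_in_planted_site(self):
        # GGG-bulge-GGG against CCCCCC: one bulge beats two separate runs
        q = "GGGAGGG"
        t = "CCCCCC"
        h = duplex_mfe(q, t)
        assert h.mfe == pytest.approx(-3.0 * 6 + 4.0)

    def test_pair_energy_validation(self):
        with pytest.raises(ValueError):
            EnergyModel(pair_energies={"GC": 1.0})


class TestCensoredEvdFit:
    @staticmethod
    def sample(lam, mu, n, rng):
        u = rng.uniform(size=n)
        return mu + np.log(-np.log(1 - u)) / lam

    def test_parameter_recovery_with_censoring(self, rng):
        x = self.sample(0.5, -15.0, 5000, rng)
        lam, mu = fit_censored_evd(x, censor_cutoff=-10.0)
        assert lam == pytest.approx(0.5, rel=0.10)
        assert mu == pytest.approx(-15.0, rel=0.10)

    def test_uncensored_fit_matches_scipy_gumbel(self, rng):
        x = self.sample(0.7, -20.0, 10_000, rng)
        lam, mu = fit_censored_evd(x, censor_cutoff=np.inf)
        loc, scale = sps.gumbel_l.fit(x)
        assert lam == pytest.approx(1 / scale, rel=0.02)
        assert mu == pytest.approx(loc, rel=0.02)

    def test_degenerate_samples_raise(self):
        with pytest.raises(ValueError):
            fit_censored_evd(np.full(100, -20.0), censor_cutoff=-10.0)

    def test_too_few_uncensored_raises(self, rng):
        x = rng.uniform(-9, -1, size=200)  # everything above the cutoff
        with pytest.raises(ValueError, match="uncensored"):
            fit_censored_evd(x, censor_cutoff=-10.0)


class TestBinAndFit:
    @staticmethod
    def homogeneous_background(rng, n=30_000):
        lam, mu = 0.6, -18.0
        u = rng.uniform(size=n)
        mfe = mu + np.log(-np.log(1 - u)) / lam
        return np.array(
            list(zip(mfe, rng.integers(5, 26, size=n), rng.uniform(size=n))),
            dtype=[("mfe", float), ("length", int), ("gc", float)])

    def test_seven_by_seven_gives_49_bins(self, rng):
        bg = self.homogeneous_background(rng)
        evd = bin_and_fit(bg, 7, 7, censor_cutoff=-10.0)
        assert evd.n_bins == 49
        assert len(evd.params) + len(evd.merged_into) >= 49

    def test_every_covariate_maps_to_one_fitted_bin(self, rng):
        bg = self.homogeneous_background(rng, n=5000)
        evd = bin_and_fit(bg, 7, 7, censor_cutoff=-10.0)
        for _ in range(200):
            L = float(rng.integers(1, 40))
            gc = float(rng.uniform())
            assert evd.bin_of(L, gc) in evd.params

    def test_homogeneous_bins_agree(self, rng):
        bg = self.homogeneous_background(rng)
        evd = bin_and_fit(bg, 3, 3, censor_cutoff=-10.0)
        lams = [v[0] for v in evd.params.values()]
        mus = [v[1] for v in evd.params.values()]
        assert max(lams) / min(lams) < 1.25
        assert max(mus) - min(mus) < 1.0


class TestInteractionPvalue:
    def test_p_at_mu(self):
        assert interaction_pvalue(-20.0, (1.0, -20.0)) == \
            pytest.approx(1 - np.exp(-1))

    def test_hand_example(self):
        assert interaction_pvalue(-25.0, (1.0, -20.0)) == \
            pytest.approx(1 - np.exp(-np.exp(-5)))

    def test_limits_and_monotonicity(self):
        assert interaction_pvalue(-1e6, (0.5, -20.0)) == pytest.approx(0.0)
        assert interaction_pvalue(1e3, (0.5, -20.0)) == pytest.approx(1.0)
        grid = np.linspace(-60, -12, 50)  # below float saturation at p = 1
        ps = [interaction_pvalue(m, (0.5, -20.0)) for m in grid]
        assert np.all(np.diff(ps) > 0)

    def test_requires_positive_lambda(self):
        with pytest.raises(ValueError):
            interaction_pvalue(-20.0, (0.0, -20.0))


class TestFilterHits:
    @staticmethod
    def hit(length, mfe, p):
        return InteractionHit("q", "t", (0, length), (0, length), mfe, length,
                              0.5, p)

    def test_strict_boundaries(self):
        assert filter_hits([self.hit(9, -50, 1e-7)]) == []     # length not > 9
        assert filter_hits([self.hit(10, -40.0, 1e-7)]) == []  # mfe not < -40
        assert filter_hits([self.hit(10, -41, 1e-5)]) == []    # p not < 1e-5
        assert len(filter_hits([self.hit(10, -41, 9e-6)])) == 1

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_constructed_list(self):
        hits = [self.hit(15, -45, 1e-7), self.hit(15, -45, 1e-3),
                self.hit(8, -45, 1e-7), self.hit(15, -30, 1e-7),
                self.hit(20, -60, 1e-9)]
        assert filter_hits(hits) == [hits[0], hits[4]]


class TestBuildBackground:
    def test_counting(self):
        bg = build_background([("GGGG", "CCCC")], n_shuffles=1, seed=0)
        assert len(bg) == 1

    def test_deterministic(self, rng):
        pairs = [("".join(rng.choice(list("ACGU"), size=40)),
                  "".join(rng.choice(list("ACGU"), size=40)))
                 for _ in range(3)]
        b1 = build_background(pairs, n_shuffles=5, seed=11)
        b2 = build_background(pairs, n_shuffles=5, seed=11)
        assert np.array_equal(b1, b2)


class TestPlantedSites:
    def test_duplex_search_finds_planted_site(self):
        cfg = SyntheticConfig(seed=5, n_interaction_pairs=8,
                              planted_pair_fraction=1.0)
        pairs = simulate_interaction_pairs(cfg)
        for rec in pairs:
            h = duplex_mfe(rec["query_seq"], rec["target_seq"])
            qs, qe = rec["query_site"]
            assert h is not None
            assert h.query_site[0] < qe and h.query_site[1] > qs  # overlaps
            assert h.mfe <= -40.0

    def test_site_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(interaction_site_length=200, pair_seq_length=100)

    def test_planted_pairs_rank_above_null(self, tiny_config):
        cfg = SyntheticConfig(seed=9, n_interaction_pairs=30,
                              planted_pair_fraction=0.3)
        pairs = simulate_interaction_pairs(cfg)
        bg = build_background([(p["query_seq"], p["target_seq"])
                               for p in pairs], n_shuffles=20, seed=2)
        evd = bin_and_fit(bg, 3, 3, min_per_bin=50)
        hits = score_pairs(pairs, evd)
        planted = {p["query_id"] for p in pairs if p["planted"]}
        p_planted = [h.p_value for h in hits if h.query_id in planted]
        p_null = [h.p_value for h in hits if h.query_id not in planted]
        assert max(p_planted) < min(p_null)
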