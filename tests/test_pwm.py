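"""Motif→k-mer reduction: parsing, PSSM scores, exact p-values, BH, filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from privkmer import pwm
from privkmer.errors import FormatError, UsageError

MEME_TWO_MOTIFS = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.3 C 0.2 G 0.2 T 0.3

MOTIF M1
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.8 0.1 0.05 0.05
0.1 0.7 0.1 0.1
0.05 0.05 0.85 0.05
0.1 0.1 0.1 0.7

MOTIF M2
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
0.25 0.25 0.25 0.25
0.9 0.04 0.03 0.03
"""


@pytest.fixture
def meme_file(tmp_path):
    p = tmp_path / "motifs.meme"
    p.write_text(MEME_TWO_MOTIFS)
    return p


def brute_force_tails(pssm, bg):
    """Exhaustive 4^k enumeration oracle for tail probabilities."""
    weights = {}
    for tup in itertools.product(range(4), repeat=pssm.width):
        s = pssm.int_score(np.array(tup))
        w = float(np.prod([bg[b] for b in tup]))
        weights[s] = weights.get(s, 0.0) + w
    tails, acc = {}, 0.0
    for s in sorted(weights, reverse=True):
        acc += weights[s]
        tails[s] = acc
    return tails


class TestParseMeme:
    def test_two_motifs_with_background(self, meme_file):
        ppms, bg = pwm.parse_meme(meme_file)
        assert [p.motif_id for p in ppms] == ["M1", "M2"]
        assert ppms[0].width == 4 and ppms[1].width == 2
        assert np.allclose(bg, [0.3, 0.2, 0.2, 0.3])
        assert np.allclose(ppms[0].matrix.sum(axis=1), 1.0)

    def test_bad_row_sum_rejected(self, tmp_path):
        bad = MEME_TWO_MOTIFS.replace("0.1 0.1 0.1 0.7", "0.1 0.1 0.1 0.5")
        p = tmp_path / "bad.meme"
        p.write_text(bad)
        with pytest.raises(FormatError, match="sum"):
            pwm.parse_meme(p)

    def test_garbage_file_rejected(self, tmp_path):
        p = tmp_path / "junk.meme"
        p.write_text("not a meme file\n")
        with pytest.raises(FormatError):
            pwm.parse_meme(p)


class TestBuildPssm:
    def test_uniform_ppm_uniform_background_scores_zero(self):
        ppm = pwm.PPM("u", np.full((3, 4), 0.25))
        pssm = pwm.build_pssm(ppm, pseudocount=0.0)
        assert np.allclose(pssm.real_matrix, 0.0)

    def test_certain_base_scores_two_bits(self):
        mat = np.zeros((1, 4))
        mat[0, 0] = 1.0
        pssm = pwm.build_pssm(pwm.PPM("a", mat), pseudocount=0.0)
        assert pssm.real_matrix[0, 0] == pytest.approx(np.log2(4.0))
        # zero-probability cells score -inf but discretise to the lowest bin
        assert np.all(np.isinf(pssm.real_matrix[0, 1:]))
        assert np.all(pssm.int_matrix[0, 1:] == 0)

    def test_pseudocount_keeps_all_scores_finite(self):
        mat = np.zeros((1, 4))
        mat[0, 0] = 1.0
        pssm = pwm.build_pssm(pwm.PPM("a", mat), pseudocount=0.1)
        assert np.all(np.isfinite(pssm.real_matrix))

    def test_discretisation_error_bounded(self, rng):
        mat = rng.dirichlet([0.5] * 4, size=6)
        pssm = pwm.build_pssm(pwm.PPM("r", mat), scale_bins=1000)
        recovered = pssm.int_matrix / pssm.scale + pssm.offset
        assert np.max(np.abs(recovered - pssm.real_matrix)) <= 0.5 / pssm.scale + 1e-12


class TestScoreDistribution:
    def test_width_one_closed_form(self):
        # scores {A: high, others: low} under uniform bg → P(top) = 0.25
        mat = np.array([[0.97, 0.01, 0.01, 0.01]])
        pssm = pwm.build_pssm(pwm.PPM("w1", mat), pseudocount=0.0)
        dist = pwm.score_distribution(pssm)
        top = int(pssm.int_matrix.max())
        assert dist.p_value(top) == pytest.approx(0.25)
        assert dist.p_value(0) == pytest.approx(1.0)

    @given(st.integers(0, 2**32), st.integers(1, 6))
    def test_dp_equals_exhaustive_enumeration(self, seed, k):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet([0.4] * 4, size=k)
        bg = rng.dirichlet([5.0] * 4)
        pssm = pwm.build_pssm(pwm.PPM("r", mat), bg, scale_bins=200)
        dist = pwm.score_distribution(pssm, bg)
        oracle = brute_force_tails(pssm, bg)
        for s, tail in oracle.items():
            assert dist.p_value(s) == pytest.approx(tail, abs=1e-9)

    def test_probability_mass_conserved(self, rng):
        mat = rng.dirichlet([0.3] * 4, size=8)
        pssm = pwm.build_pssm(pwm.PPM("r", mat))
        dist = pwm.score_distribution(pssm)
        assert dist.tail[0] == pytest.approx(1.0, abs=1e-9)


class TestEnumeration:
    def test_record_count_is_four_to_the_k(self, rng):
        mat = rng.dirichlet([0.5] * 4, size=2)
        pssm = pwm.build_pssm(pwm.PPM("r", mat))
        recs = pwm.enumerate_and_score(pssm, pwm.score_distribution(pssm))
        assert len(recs) == 16
        assert len(set(recs.kmer)) == 16

    def test_best_scoring_kmer_has_smallest_p(self, rng):
        mat = rng.dirichlet([0.3] * 4, size=5)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        pssm = pwm.build_pssm(pwm.PPM("r", mat), bg)
        recs = pwm.enumerate_and_score(pssm, pwm.score_distribution(pssm, bg))
        best = recs.loc[recs.int_score.idxmax()]
        assert best.p_value == recs.p_value.min()
        # anti-monotone: higher score never has larger p
        srt = recs.sort_values("int_score")
        assert (srt.p_value.diff().dropna() <= 1e-15).all()

    def test_guard_refuses_oversized_k(self):
        mat = np.full((17, 4), 0.25)
        pssm = pwm.build_pssm(pwm.PPM("big", mat))
        with pytest.raises(UsageError):
            pwm.enumerate_and_score(pssm, pwm.ScoreDistribution(np.ones(1)))

    def test_per_kmer_pvalue_matches_direct_tail(self, rng):
        mat = rng.dirichlet([0.4] * 4, size=4)
        bg = np.array([0.15, 0.35, 0.35, 0.15])
        pssm = pwm.build_pssm(pwm.PPM("r", mat), bg)
        dist = pwm.score_distribution(pssm, bg)
        recs = pwm.enumerate_and_score(pssm, dist)
        oracle = brute_force_tails(pssm, bg)
        from privkmer.encoding import encode_symbols

        for row in recs.sample(20, random_state=1).itertuples():
            s = pssm.int_score(encode_symbols(row.kmer).astype(int))
            assert row.p_value == pytest.approx(oracle[s], abs=1e-9)


class TestBhCorrection:
    def test_hand_computed_step_up_vector(self):
        recs = pd.DataFrame({
            "kmer": ["AA", "AC", "AG", "AT"],
            "score": [4.0, 3.0, 2.0, 1.0],
            "int_score": [4, 3, 2, 1],
            "p_value": [0.01, 0.02, 0.03, 0.04],
        })
        out = pwm.bh_correct(recs)
        assert np.allclose(out.q_value, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones_and_single_record(self):
        recs = pd.DataFrame({"kmer": ["A", "C"], "score": [0, 0],
                             "int_score": [0, 0], "p_value": [1.0, 1.0]})
        assert (pwm.bh_correct(recs).q_value == 1.0).all()
        single = pd.DataFrame({"kmer": ["A"], "score": [1.0],
                               "int_score": [1], "p_value": [0.2]})
        assert pwm.bh_correct(single).q_value.iloc[0] == pytest.approx(0.2)

    @given(st.integers(0, 2**32))
    def test_agrees_with_statsmodels_fdr_bh(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = np.sort(rng.uniform(0, 1, 32))
        recs = pd.DataFrame({
            "kmer": [f"K{i:02d}" for i in range(32)],
            "score": -p, "int_score": np.arange(32)[::-1], "p_value": p,
        })
        ours = pwm.bh_correct(recs).q_value.to_numpy()
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)

    def test_q_monotone_in_p(self, rng):
        mat = rng.dirichlet([0.3] * 4, size=5)
        bg = np.array([0.1, 0.4, 0.4, 0.1])
        pssm = pwm.build_pssm(pwm.PPM("r", mat), bg)
        recs = pwm.bh_correct(
            pwm.enumerate_and_score(pssm, pwm.score_distribution(pssm, bg))
        )
        assert (recs.q_value.diff().dropna() >= -1e-15).all()


class TestFilterAndWrite:
    def _records(self, rng):
        mat = np.array([[0.85, 0.05, 0.05, 0.05]] * 4)
        bg = np.array([0.15, 0.35, 0.35, 0.15])
        pssm = pwm.build_pssm(pwm.PPM("at", mat), bg)
        return pwm.bh_correct(
            pwm.enumerate_and_score(pssm, pwm.score_distribution(pssm, bg))
        )

    def test_threshold_one_keeps_everything(self, tmp_path, rng):
        recs = self._records(rng)
        sig = pwm.filter_and_write(recs, 1.0, str(tmp_path / "all"))
        assert len(sig) == 256
        txt = (tmp_path / "all_kmers.txt").read_text().split()
        assert len(txt) == 256

    def test_txt_and_csv_agree(self, tmp_path, rng):
        recs = self._records(rng)
        pwm.filter_and_write(recs, 0.2, str(tmp_path / "sig"))
        txt = set((tmp_path / "sig_kmers.txt").read_text().split())
        csv = pd.read_csv(tmp_path / "sig_details.csv")
        assert txt == set(csv.kmer)
        assert (csv.q_value <= 0.2).all()

    def test_empty_significant_set_is_valid(self, tmp_path, rng):
        recs = self._records(rng)
        tiny = recs.q_value.min() / 10
        sig = pwm.filter_and_write(recs, tiny, str(tmp_path / "none"))
        assert len(sig) == 0
        assert (tmp_path / "none_kmers.txt").read_text() == ""
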