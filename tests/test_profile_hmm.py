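"""Profile construction, Viterbi scoring, calibration, E-values, logos."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from rdhmm.ensemble_msa import Alignment
from rdhmm.profile_hmm import (
    EVDParams,
    ProfileHMM,
    build,
    calibrate,
    consensus,
    evalue,
    fit_gumbel,
    logo,
    score,
    score_only,
)
from rdhmm.synthetic_fixtures import make_homolog_db

from conftest import brute_force_bits, random_toy_hmm


class TestBuild:
    def test_ungapped_alignment_all_match_states(self, small_ensemble):
        from rdhmm.ensemble_msa import trivial_align

        aln = trivial_align(small_ensemble)
        hmm = build(aln)
        assert hmm.M == aln.n_columns
        assert np.all(hmm.t_mm > hmm.t_mi)
        assert np.all(hmm.t_mm > hmm.t_md)

    def test_two_row_toy_emission_hand_count(self):
        # p(D at col 3) = (1 + 0.2*0.05) / (2 + 0.2)
        aln = Alignment(rows=[("r1", "ACD"), ("r2", "ACE")])
        hmm = build(aln, pseudocount_alpha=0.2)
        d_idx = "ACDEFGHIKLMNPQRSTVWY".index("D")
        assert hmm.match_emissions[2, d_idx] == pytest.approx(
            (1 + 0.2 * 0.05) / 2.2, abs=1e-12)

    def test_rows_normalized(self, small_hmm):
        assert np.allclose(small_hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(small_hmm.t_mm + small_hmm.t_mi + small_hmm.t_md, 1.0)

    def test_majority_gap_columns_become_inserts(self):
        aln = Alignment(rows=[("a", "A-C"), ("b", "A-C"), ("c", "ABC")])
        hmm = build(aln)
        assert hmm.M == 2  # middle column is 2/3 gaps

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build(Alignment(rows=[("a", "--"), ("b", "--")]))

    def test_text_serialization_roundtrip(self, small_hmm):
        again = ProfileHMM.from_text(small_hmm.to_text())
        assert np.allclose(again.match_emissions, small_hmm.match_emissions)
        assert np.allclose(again.t_dd, small_hmm.t_dd)
        assert again.alphabet == small_hmm.alphabet


class TestViterbi:
    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, m):
        """Exhaustive path enumeration oracle over a reduced alphabet."""
        rng = np.random.default_rng(m)
        for rep in range(3):
            hmm = random_toy_hmm(m, seed=10 * m + rep)
            for n in (1, 2, 4, 6):
                for t in range(3):
                    seq = "".join(rng.choice(list("ABCD"), n))
                    want = brute_force_bits(hmm, seq)
                    assert score_only(hmm, seq) == pytest.approx(want, abs=1e-9)
                    bits, _ = score(hmm, seq)
                    assert bits == pytest.approx(want, abs=1e-9)

    def test_flanking_residues_do_not_change_score(self, small_hmm):
        from rdhmm.synthetic_fixtures import consensus_sequence
        from rdhmm.design_engine import random_sequence

        core = consensus_sequence(small_hmm)
        flank_l = random_sequence(50, 1)
        flank_r = random_sequence(50, 2)
        base = score_only(small_hmm, core)
        flanked = score_only(small_hmm, flank_l + core + flank_r)
        assert flanked >= base - 1e-9
        assert abs(flanked - base) <= 0.5

    def test_consensus_outscores_random_sequences(self, small_hmm):
        from rdhmm.design_engine import random_sequence

        cons_bits = score_only(small_hmm, consensus(small_hmm))
        assert cons_bits > 0
        for seed in range(20):
            rnd = random_sequence(small_hmm.M, seed)
            assert cons_bits > score_only(small_hmm, rnd)

    def test_path_consistent_with_sequence(self, small_hmm):
        recs = make_homolog_db(small_hmm, 1, temperature=1.5, seed=3)
        seq = str(recs[0].seq)
        bits, path = score(small_hmm, seq)
        assert bits == pytest.approx(score_only(small_hmm, seq), abs=1e-9)
        matched = path.matched_positions
        assert matched == sorted(matched)
        n_match = sum(1 for op in path.ops if op[0] == "M")
        assert n_match + path.n_deletions == small_hmm.M

    def test_rejects_bad_input(self, small_hmm):
        with pytest.raises(ValueError):
            score_only(small_hmm, "")
        with pytest.raises(ValueError):
            score_only(small_hmm, "AC1")


class TestCalibrate:
    def test_gumbel_recovery_from_synthetic_draws(self):
        rng = np.random.default_rng(12)
        samples = stats.gumbel_r.rvs(loc=-5.0, scale=1 / 0.7, size=5000, random_state=rng)
        mu, lam = fit_gumbel(samples)
        assert mu == pytest.approx(-5.0, abs=0.15)
        assert lam == pytest.approx(0.7, abs=0.05)

    def test_lambda_positive_and_reproducible(self, small_hmm):
        evd = calibrate(small_hmm, n_samples=200, seed=5)
        assert evd.lam > 0
        again = calibrate(small_hmm, n_samples=200, seed=5)
        assert (evd.mu, evd.lam) == (again.mu, again.lam)

    def test_more_samples_tighter_lambda(self, small_hmm):
        spread = []
        for n in (150, 600):
            lams = [calibrate(small_hmm, n_samples=n, seed=s).lam for s in range(8)]
            spread.append(np.std(lams))
        assert spread[1] < spread[0]

    def test_minimum_sample_size(self, small_hmm):
        with pytest.raises(ValueError):
            calibrate(small_hmm, n_samples=50)


class TestEvalue:
    def test_closed_form_at_mu(self):
        evd = EVDParams(mu=10.0, lam=0.5)
        assert evalue(evd, 10.0, 1000) == pytest.approx(
            1000 * (1 - math.exp(-1)), rel=1e-12)

    def test_limits_and_monotonicity(self):
        evd = EVDParams(mu=0.0, lam=0.7)
        assert evalue(evd, 1e6, 1000) == pytest.approx(0.0, abs=1e-12)
        # strictly decreasing wherever the survival has not saturated to 1
        scores = np.linspace(-5, 50, 31)
        es = [evalue(evd, s, 1000) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        # far-left scores saturate at E = n_db
        assert evalue(evd, -1e6, 1000) == 1000.0

    @given(st.floats(-20, 20), st.integers(1, 10**6))
    def test_scales_linearly_with_database_size(self, s, n_db):
        evd = EVDParams(mu=0.0, lam=0.4)
        assert evalue(evd, s, n_db) == pytest.approx(n_db * evalue(evd, s, 1), rel=1e-9)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            EVDParams(mu=0.0, lam=0.0)


class TestLogo:
    def test_background_column_zero_bits(self):
        em = np.full((2, 20), 0.05)
        hmm = _uniform_hmm(em)
        assert logo(hmm).relative_entropy[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_column_log2_20(self):
        em = np.full((1, 20), 1e-12)
        em[0, 0] = 1 - 19e-12
        hmm = _uniform_hmm(em / em.sum(axis=1, keepdims=True))
        assert logo(hmm).relative_entropy[0] == pytest.approx(math.log2(20), abs=1e-6)

    def test_heights_sum_to_relative_entropy(self, small_hmm):
        data = logo(small_hmm)
        assert np.allclose(data.letter_heights.sum(axis=1),
                           data.relative_entropy, atol=1e-9)
        assert np.all(data.relative_entropy >= 0)

    def test_strained_columns_more_conserved_than_helix(self, small_hmm):
        from conftest import helix_columns, turn_columns

        rel = logo(small_hmm).relative_entropy
        assert np.median(rel[turn_columns()]) > np.median(rel[helix_columns()])


def _uniform_hmm(em):
    m = em.shape[0]
    half, third = np.full(m, 0.5), np.full(m, 1 / 3)
    return ProfileHMM(
        match_emissions=em, background=np.full(20, 0.05),
        t_mm=third, t_mi=third, t_md=third,
        t_im=half, t_ii=half, t_dm=half, t_dd=half,
    )


class TestIndependentReferenceImplementation:
    def test_native_separation_agrees_with_plan7_reference(self, small_ensemble, small_hmm):
        """Dual-route check: an independently built Plan7 profile (pyhmmer)
        over the same design alignment must also rank the pseudo-native
        above every background decoy, matching this implementation."""
        pyhmmer = pytest.importorskip("pyhmmer")
        from rdhmm.ensemble_msa import trivial_align
        from rdhmm.synthetic_fixtures import make_decoy_db

        aln = trivial_align(small_ensemble)
        abc = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(name=b"ens", sequences=[
            pyhmmer.easel.TextSequence(name=rid.encode(), sequence=row)
            for rid, row in aln.rows
        ]).digitize(abc)
        bg = pyhmmer.plan7.Background(abc)
        ref_hmm, _, _ = pyhmmer.plan7.Builder(abc).build_msa(msa, bg)

        native = str(make_homolog_db(small_hmm, 1, 1.0, seed=9)[0].seq)
        decoys = make_decoy_db(30, seed=5)
        texts = [("native", native)] + [(r.id, str(r.seq)) for r in decoys]
        block = pyhmmer.easel.DigitalSequenceBlock(abc, [
            pyhmmer.easel.TextSequence(name=n.encode(), sequence=q).digitize(abc)
            for n, q in texts
        ])
        pipe = pyhmmer.plan7.Pipeline(abc, background=bg, E=1e9,
                                      bias_filter=False, F1=1.0, F2=1.0, F3=1.0)
        hits = sorted(pipe.search_hmm(ref_hmm, block), key=lambda h: -h.score)
        top = hits[0].name
        assert (top.decode() if isinstance(top, bytes) else top) == "native"

        ours_native = score_only(small_hmm, native)
        ours_best_decoy = max(score_only(small_hmm, str(r.seq)) for r in decoys)
        assert ours_native > ours_best_decoy
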