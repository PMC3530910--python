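"""Viterbi decoding, call extraction and the generative twin."""

import itertools

import numpy as np
import pytest

import fsfinder as ff
from fsfinder.decoder import (
    LOG_QUARTER,
    NC,
    ConfigError,
    build_emissions,
    build_state_space,
    calls_from_path,
    decode_fragment,
    emit_from_path,
    make_switched_path,
    sample_from_model,
    state_index,
    viterbi,
)
from fsfinder.heuristic_models import DecoderParams


def toy_space(seed, n_states=3, n_symbols=2):
    """Integer-valued toy log-score matrices (exact float arithmetic)."""
    rng = np.random.default_rng(seed)
    log_init = rng.integers(-8, 0, size=n_states).astype(float)
    log_trans = rng.integers(-8, 0, size=(n_states, n_states)).astype(float)
    log_emit_sym = rng.integers(-8, 0, size=(n_states, n_symbols)).astype(float)
    return log_init, log_trans, log_emit_sym


def brute_force_best(log_init, log_trans, log_emit):
    """Exhaustive max over all hidden paths (the independent oracle)."""
    S, L = log_emit.shape
    best = -np.inf
    for path in itertools.product(range(S), repeat=L):
        lp = log_init[path[0]] + log_emit[path[0], 0]
        for t in range(1, L):
            lp += log_trans[path[t - 1], path[t]] + log_emit[path[t], t]
        best = max(best, lp)
    return best


class TestViterbiCore:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_enumeration_on_short_inputs(self, seed):
        log_init, log_trans, log_emit_sym = toy_space(seed)
        for L in range(1, 8):
            for syms in itertools.product(range(2), repeat=L):
                E = log_emit_sym[:, list(syms)]
                _, logp, _ = viterbi(log_init, log_trans, E)
                assert logp == brute_force_best(log_init, log_trans, E)

    def test_tie_break_prefers_lowest_state_index(self):
        # all-equal scores: the path must sit in state 0 throughout
        Z = np.zeros((3, 5))
        path, _, _ = viterbi(np.zeros(3), np.zeros((3, 3)), Z)
        assert (path == 0).all()


class TestStateSpace:
    def test_outgoing_probabilities_sum_to_one(self, model50):
        ss = build_state_space(model50)
        np.testing.assert_allclose(np.exp(ss.log_trans).sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.exp(ss.log_init).sum(), 1.0, atol=1e-9)

    def test_no_direct_strand_change_inside_genes(self, model50):
        T = np.exp(build_state_space(model50).log_trans)
        for f in range(3):
            for g in range(3):
                assert T[state_index(f, "+"), state_index(g, "-")] == 0.0
                assert T[state_index(f, "-"), state_index(g, "+")] == 0.0

    def test_p_fs_zero_forbids_frame_switches(self, model50):
        import dataclasses

        m = dataclasses.replace(model50, params=DecoderParams(p_fs=0.0))
        T = np.exp(build_state_space(m).log_trans)
        assert T[state_index(0, "+"), state_index(1, "+")] == 0.0

    def test_p_fs_exceeding_exit_budget_raises(self, model50):
        import dataclasses

        params = DecoderParams(mean_coding_len=900.0, p_fs=2e-3)  # > 1/900
        m = dataclasses.replace(model50, params=params)
        with pytest.raises(ConfigError):
            build_state_space(m)


class TestEmissions:
    def test_first_five_positions_use_background(self, model50):
        E = build_emissions("ACGTACGTACGT", model50)
        # forward states have no 5-mer context at i < 5
        for f in range(3):
            assert np.allclose(E[state_index(f, "+"), :5], LOG_QUARTER)

    def test_n_windows_are_neutral(self, model50):
        E = build_emissions("ACGTANGTACGTACG", model50)
        # positions whose context or base includes the N fall back to 1/4
        i = 5  # context ACGTAN...: window contains N at several positions
        assert E[state_index(0, "+"), i] == LOG_QUARTER

    def test_mirror_matrix(self, model50):
        seq = "ATGAAACCGTTAGGCATCAGGATCC"
        E = build_emissions(seq, model50)
        Erc = build_emissions(ff.revcomp(seq), model50)
        L = len(seq)
        np.testing.assert_allclose(E[NC], Erc[NC][::-1], atol=1e-12)
        for f in range(3):
            np.testing.assert_allclose(
                E[state_index(f, "+")], Erc[state_index(f, "-")][::-1], atol=1e-12
            )


class TestDecoding:
    def test_noncoding_sequence_decodes_to_all_nc(self, family):
        """Sequences sampled from NC emissions alone should decode NC."""
        model = ff.model_for_gc(family, 50.0)
        ss = build_state_space(model)
        rng = np.random.default_rng(21)
        ok = 0
        for _ in range(100):
            path = np.full(300, NC)
            seq = emit_from_path(model, path, rng)
            decoded, _, _ = ff.viterbi_decode(seq, ss, model)
            ok += (decoded == NC).all()
        assert ok >= 95

    def test_revcomp_yields_mirrored_path(self, model50):
        rng = np.random.default_rng(31)
        path = make_switched_path(300, 31, 270, 150, 0, 1)
        seq = emit_from_path(model50, path, rng)
        ss = build_state_space(model50)
        p1, lp1, _ = ff.viterbi_decode(seq, ss, model50)
        p2, lp2, _ = ff.viterbi_decode(ff.revcomp(seq), ss, model50)
        assert lp1 == pytest.approx(lp2, abs=1e-6)
        swap = {NC: NC}
        for f in range(3):
            swap[state_index(f, "+")] = state_index(f, "-")
            swap[state_index(f, "-")] = state_index(f, "+")
        mirrored = np.array([swap[s] for s in p2[::-1]])
        np.testing.assert_array_equal(p1, mirrored)

    def test_short_sequence_rejected(self, model50):
        with pytest.raises(ValueError):
            decode_fragment("ACGTA", model50)


class TestCallsFromPath:
    def test_all_nc_gives_no_calls(self):
        genes, fss = calls_from_path(np.full(50, NC))
        assert genes == [] and fss == []

    def test_single_switch_gene_and_shift_mapping(self):
        path = np.concatenate(
            [np.full(60, state_index(0, "+")), np.full(60, state_index(2, "+"))]
        )
        genes, fss = calls_from_path(path)
        assert len(genes) == 1 and len(fss) == 1
        g, fs = genes[0], fss[0]
        assert (g.start, g.end) == (1, 120)
        assert g.frames_path == [(0, 1, 60), (2, 61, 120)]
        assert fs.pos == 60
        assert fs.fs_shift == -1  # (2 - 0) mod 3 == 2: deletion-like

    def test_insertion_like_shift(self):
        path = np.concatenate(
            [np.full(30, state_index(1, "+")), np.full(30, state_index(2, "+"))]
        )
        _, fss = calls_from_path(path)
        assert fss[0].fs_shift == 1

    def test_two_genes_without_switch(self):
        path = np.concatenate(
            [
                np.full(40, state_index(0, "+")),
                np.full(20, NC),
                np.full(40, state_index(1, "-")),
            ]
        )
        genes, fss = calls_from_path(path)
        assert len(genes) == 2 and fss == []
        assert [g.strand for g in genes] == ["+", "-"]

    def test_minus_strand_fs_position_is_reading_order_upstream(self):
        # reading order on '-' runs right to left: upstream segment is the
        # rightmost, and the FS sits at its lowest forward coordinate
        path = np.concatenate(
            [np.full(60, state_index(2, "-")), np.full(60, state_index(0, "-"))]
        )
        _, fss = calls_from_path(path)
        assert fss[0].pos == 61
        assert fss[0].upstream_frame == 0 and fss[0].downstream_frame == 2


class TestScores:
    def test_fs_score_positive_and_monotone_in_p_fs(self, family):
        """The Viterbi margin shrinks as the frame-switch prior decreases."""
        import dataclasses

        rng = np.random.default_rng(41)
        m = ff.model_for_gc(family, 50.0)
        path = make_switched_path(600, 61, 540, 300, 0, 1)
        seq = emit_from_path(m, path, rng)
        scores = []
        for p_fs in (1e-3, 3e-4, 1e-4):
            mm = dataclasses.replace(m, params=DecoderParams(p_fs=p_fs))
            _, fss = decode_fragment(seq, mm)
            hits = [fs for fs in fss if abs(fs.pos - 300) <= 20]
            assert hits, f"switch not recovered at p_fs={p_fs}"
            assert hits[0].score >= 0.0
            scores.append(hits[0].score)
        assert scores[0] >= scores[1] >= scores[2]


class TestSampling:
    def test_p_fs_zero_paths_never_switch_frames(self, model50):
        import dataclasses

        m = dataclasses.replace(model50, params=DecoderParams(p_fs=0.0))
        ss = build_state_space(m)
        _, path = sample_from_model(ss, m, 2000, seed=5)
        genes, fss = calls_from_path(path)
        assert fss == []

    def test_seed_reproducibility(self, model50):
        ss = build_state_space(model50)
        s1, p1 = sample_from_model(ss, model50, 500, seed=9)
        s2, p2 = sample_from_model(ss, model50, 500, seed=9)
        assert s1 == s2
        np.testing.assert_array_equal(p1, p2)

    def test_sampled_coding_matches_model_conditionals(self, model50):
        """Empirical next-base conditionals of a long sampled coding
        stretch agree with the model within 3 standard errors (cells with
        enough observations; a small multiple-testing allowance)."""
        from fsfinder.sequence_io import seq_to_ints

        n = 120_000
        path = np.full(n, state_index(0, "+"))
        rng = np.random.default_rng(17)
        seq = emit_from_path(model50, path, rng)
        ints = seq_to_ints(seq)
        counts = np.zeros((3, 1024, 4))
        w5 = 4 ** np.arange(4, -1, -1)
        win = np.lib.stride_tricks.sliding_window_view(ints, 5)[: n - 5]
        ctx = win @ w5
        pos = np.arange(5, n)
        np.add.at(counts, (pos % 3, ctx, ints[5:]), 1)
        checked = inside = 0
        probs = np.exp(model50.coding_logp)
        totals = counts.sum(axis=-1)
        for ph in range(3):
            sel = totals[ph] >= 80
            for c in np.flatnonzero(sel):
                # phase-2 cells renormalize away stop-completing bases; skip
                if ph == 2:
                    continue
                n_obs = totals[ph, c]
                p_hat = counts[ph, c] / n_obs
                se = np.sqrt(probs[ph, c] * (1 - probs[ph, c]) / n_obs)
                inside += int(np.all(np.abs(p_hat - probs[ph, c]) <= 3 * se + 1e-12))
                checked += 1
        assert checked > 50
        assert inside / checked >= 0.95
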