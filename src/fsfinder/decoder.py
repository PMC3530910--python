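"""Frame-aware HMM decoding of fragments into genes and frameshifts.

The state space has seven states: non-coding (NC) and coding-in-frame
C(f, s) for frame f in {0,1,2} on each strand s. A transition between two
coding-frame states inside one gene is a frameshift call. Durations are
geometric; there are no explicit start/stop-codon states — an in-frame
stop triplet instead receives a large emission penalty, which is the
smallest architecture that realizes "frameshift = in-gene frame change".

All arithmetic is in log space (natural log). State ordering is
[NC, C(0,+), C(0,-), C(1,+), C(1,-), C(2,+), C(2,-)] so that numpy's
first-index argmax realizes the deterministic tie-break "prefer NC, then
the lower frame index, then the + strand".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .heuristic_models import FragmentModel
from .sequence_io import seq_to_ints

NC = 0
N_STATES = 7
LOG_QUARTER = math.log(0.25)

# stop codons as base-4 integers (A=0, C=1, G=2, T=3): TAA, TAG, TGA
_STOP_CODES = frozenset((48, 50, 56))
_W5 = 4 ** np.arange(4, -1, -1)
_W3 = 4 ** np.arange(2, -1, -1)


class ConfigError(ValueError):
    """Raised when decoder parameters are mutually inconsistent."""


def state_index(frame: int, strand: str) -> int:
    return 1 + 2 * frame + (0 if strand == "+" else 1)


def state_frame(state: int) -> int:
    return (state - 1) // 2


def state_strand(state: int) -> str:
    return "+" if (state - 1) % 2 == 0 else "-"


@dataclass
class StateSpace:
    """Transition structure of the 7-state frame HMM (log space)."""

    log_init: np.ndarray  # (7,)
    log_trans: np.ndarray  # (7, 7)
    switch_mask: np.ndarray  # (7, 7) bool, True on frame-switch transitions
    params: object = None


@dataclass
class GenePrediction:
    """A maximal coding run; >= 2 frame segments means >= 1 frameshift."""

    fragment_id: str
    start: int
    end: int
    strand: str
    frames_path: list[tuple[int, int, int]]  # (frame, from_nt, to_nt)
    log_odds_score: float = 0.0
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FrameshiftPrediction:
    """A frame change inside one gene.

    pos is the last nt decoded in the upstream frame (1-based, on the
    decoded sequence); fs_shift is +1 for an insertion-like change of
    apparent frame and -1 for a deletion-like one.
    """

    fragment_id: str
    pos: int
    fs_shift: int
    strand: str
    gene: GenePrediction
    upstream_frame: int
    downstream_frame: int
    score: float = 0.0
    filters_failed: set = field(default_factory=set)


def build_state_space(model: FragmentModel) -> StateSpace:
    """Transitions from geometric durations and the frame-switch rate.

    Within a gene the per-nt switch mass p_fs splits evenly over the two
    alternative frames on the same strand; strand changes must pass
    through NC. The initial distribution is duration-proportional.
    """
    p = model.params
    exit_c = 1.0 / p.mean_coding_len
    exit_nc = 1.0 / p.mean_noncoding_len
    if p.p_fs > 0 and p.p_fs >= exit_c:
        raise ConfigError(
            f"p_fs={p.p_fs} >= coding exit probability {exit_c:.3g}; "
            "lower p_fs or mean_coding_len"
        )
    T = np.zeros((N_STATES, N_STATES))
    T[NC, NC] = 1.0 - exit_nc
    switch = np.zeros((N_STATES, N_STATES), dtype=bool)
    for f in range(3):
        for s in "+-":
            i = state_index(f, s)
            T[NC, i] = exit_nc / 6.0
            T[i, NC] = exit_c
            T[i, i] = 1.0 - exit_c - p.p_fs
            for g in range(3):
                if g != f:
                    j = state_index(g, s)
                    T[i, j] = p.p_fs / 2.0
                    switch[i, j] = True
    init = np.empty(N_STATES)
    total = p.mean_noncoding_len + p.mean_coding_len
    init[NC] = p.mean_noncoding_len / total
    init[1:] = p.mean_coding_len / total / 6.0
    with np.errstate(divide="ignore"):
        return StateSpace(np.log(init), np.log(T), switch, p)


def _plus_strand_scores(ints: np.ndarray, model: FragmentModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-position NC score and C(f,+) scores (3, L), forward direction.

    Positions without a full valid 5-mer context (the first five, or any
    window containing N) fall back to the uniform background log(1/4).
    """
    L = len(ints)
    nc = np.full(L, LOG_QUARTER)
    coding = np.full((3, L), LOG_QUARTER)
    if L >= 6:
        win5 = np.lib.stride_tricks.sliding_window_view(ints, 5)[: L - 5]
        ctx = win5 @ _W5
        base = ints[5:]
        valid = (win5 >= 0).all(axis=1) & (base >= 0)
        ctx_s = np.where(valid, ctx, 0)
        base_s = np.where(valid, base, 0)
        nc[5:] = np.where(valid, model.noncoding_logp[ctx_s, base_s], LOG_QUARTER)
        pos = np.arange(5, L)
        for f in range(3):
            phase = (pos - f) % 3
            coding[f, 5:] = np.where(
                valid, model.coding_logp[phase, ctx_s, base_s], LOG_QUARTER
            )
    # in-frame stop penalty on the last base of a stop triplet
    if L >= 3:
        win3 = np.lib.stride_tricks.sliding_window_view(ints, 3)
        cod = win3 @ _W3
        is_stop = (win3 >= 0).all(axis=1) & np.isin(cod, list(_STOP_CODES))
        last = np.flatnonzero(is_stop) + 2  # position of the triplet's last base
        for f in range(3):
            hit = last[(last - f) % 3 == 2]
            coding[f, hit] += model.params.stop_penalty
    return nc, coding


def build_emissions(seq: str, model: FragmentModel) -> np.ndarray:
    """Emission log-score matrix (7 states x L positions).

    Minus-strand coding states score the reverse complement (so decoding
    the reverse complement yields the exactly mirrored matrix); the NC
    score is the mean of the forward and reverse-complement background
    scores, which makes the whole model strand-symmetric by construction.
    """
    ints = seq_to_ints(seq)
    rc_ints = (3 - ints[::-1]) * (ints[::-1] >= 0) + -1 * (ints[::-1] < 0)
    nc_f, cod_f = _plus_strand_scores(ints, model)
    nc_r, cod_r = _plus_strand_scores(rc_ints, model)
    L = len(ints)
    E = np.empty((N_STATES, L))
    E[NC] = 0.5 * (nc_f + nc_r[::-1])
    for f in range(3):
        E[state_index(f, "+")] = cod_f[f]
        E[state_index(f, "-")] = cod_r[f][::-1]
    return E


def viterbi(
    log_init: np.ndarray,
    log_trans: np.ndarray,
    log_emit: np.ndarray,
    banned: np.ndarray | None = None,
    banned_steps: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Generic max-log-probability path decoding.

    log_emit is (S, L). ``banned`` (S, S bool) marks transitions that are
    forbidden at steps t where ``banned_steps[t]`` is True (step t is the
    transition into position t); used for constrained no-frameshift
    re-decoding. Returns (state path, total log-prob, per-position best
    running log-scores). Ties resolve to the lowest state index.
    """
    S, L = log_emit.shape
    dp = log_init + log_emit[:, 0]
    back = np.zeros((L, S), dtype=np.int64)
    trans_banned = None
    if banned is not None:
        trans_banned = np.where(banned, -np.inf, log_trans)
    scores = np.empty(L)
    scores[0] = dp.max()
    for t in range(1, L):
        A = trans_banned if (trans_banned is not None and banned_steps[t]) else log_trans
        cand = dp[:, None] + A
        best_from = np.argmax(cand, axis=0)
        dp = cand[best_from, np.arange(S)] + log_emit[:, t]
        back[t] = best_from
        scores[t] = dp.max()
    last = int(np.argmax(dp))
    path = np.empty(L, dtype=np.int64)
    path[-1] = last
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(dp[last]), scores


def viterbi_decode(
    seq: str, state_space: StateSpace, model: FragmentModel
) -> tuple[np.ndarray, float, np.ndarray]:
    """Decode a fragment; returns (path, log-prob, per-position scores)."""
    if len(seq) < 6:
        raise ValueError("sequences shorter than 6 nt cannot be decoded")
    E = build_emissions(seq, model)
    return viterbi(state_space.log_init, state_space.log_trans, E)


def _shift_label(upstream: int, downstream: int) -> int:
    """Map a frame change to +1 (insertion-like) or -1 (deletion-like).

    A single-nt insertion advances the apparent downstream frame by one,
    so Δ = (downstream - upstream) mod 3 == 1 is insertion-like; Δ == 2
    (i.e. -1 mod 3) is deletion-like.
    """
    delta = (downstream - upstream) % 3
    if delta not in (1, 2):
        raise ValueError("not a frame change")
    return 1 if delta == 1 else -1


def calls_from_path(
    path: np.ndarray, fragment_id: str = "fragment"
) -> tuple[list[GenePrediction], list[FrameshiftPrediction]]:
    """Convert a state path into gene intervals and frameshift points.

    Maximal coding runs become genes; a frame change inside a run becomes
    a FrameshiftPrediction located at the last nt decoded in the upstream
    frame (for minus-strand genes the upstream frame is the rightmost
    segment in forward coordinates).
    """
    L = len(path)
    genes: list[GenePrediction] = []
    fss: list[FrameshiftPrediction] = []
    coding = path != NC
    if not coding.any():
        return genes, fss
    edges = np.flatnonzero(np.diff(np.concatenate(([0], coding.view(np.int8), [0]))))
    for lo, hi in zip(edges[::2], edges[1::2]):  # run covers [lo, hi-1] 0-based
        run = path[lo:hi]
        strands = {state_strand(s) for s in run}
        if len(strands) != 1:
            raise AssertionError("strand change without passing through NC")
        strand = strands.pop()
        segs: list[tuple[int, int, int]] = []  # (frame, from_nt, to_nt) 1-based
        seg_start = lo
        for k in range(lo + 1, hi + 1):
            if k == hi or path[k] != path[k - 1]:
                segs.append((state_frame(path[seg_start]), seg_start + 1, k))
                seg_start = k
        gene = GenePrediction(
            fragment_id=fragment_id,
            start=lo + 1,
            end=hi,
            strand=strand,
            frames_path=segs,
            truncated_left=lo == 0,
            truncated_right=hi == L,
        )
        genes.append(gene)
        # reading order: left-to-right on +, right-to-left on -
        ordered = segs if strand == "+" else segs[::-1]
        for (f_up, a1, b1), (f_dn, a2, b2) in zip(ordered, ordered[1:]):
            pos = b1 if strand == "+" else a1
            fss.append(
                FrameshiftPrediction(
                    fragment_id=fragment_id,
                    pos=pos,
                    fs_shift=_shift_label(f_up, f_dn),
                    strand=strand,
                    gene=gene,
                    upstream_frame=f_up,
                    downstream_frame=f_dn,
                )
            )
    return genes, fss


def decode_fragment(
    seq: str, model: FragmentModel, fragment_id: str = "fragment"
) -> tuple[list[GenePrediction], list[FrameshiftPrediction]]:
    """Full single-fragment decode: Viterbi, calls, gene and FS scores.

    A gene's log-odds score is the emission advantage of its decoded
    coding path over the background state. A frameshift's score is the
    Viterbi log-probability minus that of the best path with frame
    switches forbidden inside the containing gene (a constrained
    re-decode), i.e. the Viterbi margin of the frame change.
    """
    if len(seq) < 6:
        raise ValueError("sequences shorter than 6 nt cannot be decoded")
    ss = build_state_space(model)
    E = build_emissions(seq, model)
    path, logp, _ = viterbi(ss.log_init, ss.log_trans, E)
    genes, fss = calls_from_path(path, fragment_id)
    idx = np.arange(len(path))
    for g in genes:
        sel = slice(g.start - 1, g.end)
        g.log_odds_score = float((E[path[sel], idx[sel]] - E[NC, sel]).sum())
    for g in genes:
        gene_fs = [fs for fs in fss if fs.gene is g]
        if not gene_fs:
            continue
        steps = np.zeros(len(path), dtype=bool)
        steps[g.start : g.end] = True  # transitions landing inside the gene
        _, logp_c, _ = viterbi(ss.log_init, ss.log_trans, E, ss.switch_mask, steps)
        margin = logp - logp_c
        for fs in gene_fs:
            fs.score = margin
    return genes, fss


# ---------------------------------------------------------------------------
# generative twin: exact ancestral sampling from the same model


def sample_path(state_space: StateSpace, length: int, rng: np.random.Generator) -> np.ndarray:
    init = np.exp(state_space.log_init)
    trans = np.exp(state_space.log_trans)
    path = np.empty(length, dtype=np.int64)
    path[0] = rng.choice(N_STATES, p=init)
    for t in range(1, length):
        path[t] = rng.choice(N_STATES, p=trans[path[t - 1]])
    return path


def _sample_base(
    logp_table: np.ndarray, ctx: list[int], rng: np.random.Generator, forbid: set[int] | None = None
) -> int:
    """Sample the next base given a 5-base context (uniform if short)."""
    if len(ctx) < 5:
        probs = np.full(4, 0.25)
    else:
        c = ctx[-5] * 256 + ctx[-4] * 64 + ctx[-3] * 16 + ctx[-2] * 4 + ctx[-1]
        probs = np.exp(logp_table[c] if logp_table.ndim == 2 else logp_table)
    if forbid:
        probs = probs.copy()
        for b in forbid:
            probs[b] = 0.0
        probs /= probs.sum()
    return int(rng.choice(4, p=probs))


def _emit_coding_forward(
    model: FragmentModel, phases: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Sample a coding stretch left-to-right with given per-position phases.

    Bases completing an in-frame stop triplet are excluded and the
    conditional renormalized, mirroring the decoder's stop penalty.
    """
    out: list[int] = []
    for k, ph in enumerate(phases):
        forbid: set[int] = set()
        if ph == 2 and k >= 2 and phases[k - 2] == 0:
            pre = out[-2] * 16 + out[-1] * 4
            forbid = {code - pre for code in _STOP_CODES if 0 <= code - pre < 4}
        if len(out) < 5:
            probs = np.full(4, 0.25)
        else:
            c = out[-5] * 256 + out[-4] * 64 + out[-3] * 16 + out[-2] * 4 + out[-1]
            probs = np.exp(model.coding_logp[ph, c])
        if forbid:
            probs = probs.copy()
            for b in forbid:
                probs[b] = 0.0
            probs /= probs.sum()
        out.append(int(rng.choice(4, p=probs)))
    return out


def emit_from_path(model: FragmentModel, path: np.ndarray, rng: np.random.Generator) -> str:
    """Sample a sequence for a given hidden state path.

    NC and plus-strand coding stretches are sampled left-to-right from
    the model conditionals; minus-strand coding stretches are sampled in
    reading orientation and reverse-complemented into place.
    """
    L = len(path)
    ints = np.full(L, -1, dtype=np.int64)
    nc_ctx: list[int] = []
    i = 0
    while i < L:
        j = i
        if path[i] == NC:
            while j < L and path[j] == NC:
                b = _sample_base(model.noncoding_logp, nc_ctx, rng)
                ints[j] = b
                nc_ctx.append(b)
                j += 1
        else:
            strand = state_strand(path[i])
            while j < L and path[j] != NC and state_strand(path[j]) == strand:
                j += 1
            frames = np.array([state_frame(s) for s in path[i:j]])
            if strand == "+":
                phases = (np.arange(i, j) - frames) % 3
                ints[i:j] = _emit_coding_forward(model, phases, rng)
            else:
                rc_pos = L - 1 - np.arange(i, j)[::-1]  # ascending rc coords
                phases = (rc_pos - frames[::-1]) % 3
                sampled = _emit_coding_forward(model, phases, rng)
                ints[i:j] = (3 - np.array(sampled))[::-1]
            nc_ctx = list(ints[max(0, j - 5) : j])
        i = j
    return "".join("ACGT"[b] for b in ints)


def sample_from_model(
    state_space: StateSpace, model: FragmentModel, length: int, seed: int | np.random.Generator
) -> tuple[str, np.ndarray]:
    """Ancestral sample: (sequence, hidden path) for recovery tests."""
    if length < 6:
        raise ValueError("length must be >= 6")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = sample_path(state_space, length, rng)
    return emit_from_path(model, path, rng), path


def make_switched_path(
    length: int,
    gene_start: int,
    gene_end: int,
    switch_after: int,
    frame_up: int,
    frame_down: int,
    strand: str = "+",
) -> np.ndarray:
    """A hand-built path: one plus-strand-oriented gene with one mid-gene
    frame switch located after 1-based position ``switch_after``."""
    if not 1 <= gene_start <= switch_after < gene_end <= length:
        raise ValueError("switch must lie strictly inside the gene")
    path = np.full(length, NC, dtype=np.int64)
    path[gene_start - 1 : switch_after] = state_index(frame_up, strand)
    path[switch_after : gene_end] = state_index(frame_down, strand)
    return path
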