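"""False-positive filters for raw frameshift predictions.

Three post-processing filters, each evaluated independently:

* Filter I  — a real frameshifted gene spans two overlapping ORFs; the
  downstream ORF should not carry a functional ribosome binding site
  (Shine-Dalgarno motif) of its own. A high RBS score (> 2.0) at the
  downstream ORF's start argues the two ORFs are separate genes, and the
  prediction is removed.
* Filter II — in high-GC fragments (θ > 50) a true frameshift sits far
  from the stop codon that terminates the upstream ORF; predictions too
  close to that stop are removed. The required distance grows linearly
  with θ: d_min(θ) = max(0, a·θ + b).
* Filter III — in low-GC fragments (θ ≤ 50) predictions closer than
  50 nt to a border of the putative frameshifted gene or to either end
  of the fragment are removed.

Filters II and III partition on GC content (θ > 50 vs θ ≤ 50), so at most
one of them can fire on a given fragment. Filters only ever remove
predictions; positions are never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .decoder import FrameshiftPrediction, GenePrediction
from .sequence_io import START_CODONS, STOP_CODONS

_BASE_ORDER = "ACGT"


@dataclass
class RbsModel:
    """A 6-column PWM over ACGT, scored as log-odds (base 2) against a
    uniform background, with the spacer search range in nt upstream of a
    candidate gene start."""

    pwm: np.ndarray  # (6, 4) probabilities
    spacer_min: int = 4
    spacer_max: int = 12

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (6, 4):
            raise ValueError("PWM must be 6 x 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column's probabilities must sum to 1")
        if self.spacer_min < 3 or self.spacer_max > 15:
            raise ValueError("spacer range must lie within [3, 15]")
        self.log_odds = np.log2(np.clip(self.pwm, 1e-12, 1.0) / 0.25)

    @classmethod
    def shine_dalgarno(cls, consensus: str = "AGGAGG", p_consensus: float = 0.85) -> "RbsModel":
        """Default PWM: the Shine-Dalgarno consensus with 85% consensus-base
        probability per column, remainder spread evenly."""
        pwm = np.full((6, 4), (1.0 - p_consensus) / 3.0)
        for i, b in enumerate(consensus):
            pwm[i, _BASE_ORDER.index(b)] = p_consensus
        return cls(pwm)


@dataclass
class FilterConfig:
    """Thresholds for the three filters (distances in nt, θ in percent)."""

    rbs_threshold: float = 2.0
    border_dist: int = 50
    tp_window: int = 20
    gc_split: float = 50.0
    stop_dist_a: float = 2.0  # nt per GC percentage point
    stop_dist_b: float = -60.0  # nt

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_split < 100.0:
            raise ValueError("gc_split must lie in (0, 100)")
        if self.border_dist < 0 or self.tp_window < 0:
            raise ValueError("distances must be >= 0")

    def d_min(self, theta: float) -> float:
        """Minimum required frameshift-to-upstream-stop distance at GC θ."""
        return max(0.0, self.stop_dist_a * theta + self.stop_dist_b)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        data = yaml.safe_load(open(path)) or {}
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})


def score_rbs(seq: str, start_pos: int, strand: str, rbs: RbsModel) -> float:
    """Best PWM log-odds over the spacer range upstream of a gene start.

    start_pos is the 1-based first nt of the candidate start codon. With
    insufficient upstream context for every spacer, returns -inf (the
    sentinel that makes Filter I fail open). N positions contribute 0.
    """
    if not 1 <= start_pos <= len(seq):
        raise ValueError("start_pos outside the sequence")
    best = -math.inf
    for spacer in range(rbs.spacer_min, rbs.spacer_max + 1):
        if strand == "+":
            lo = start_pos - spacer - 6  # 1-based first nt of the 6-mer
            if lo < 1:
                continue
            window = seq[lo - 1 : lo + 5]
        else:
            hi = start_pos + spacer + 6
            if hi > len(seq):
                continue
            window = seq[start_pos + spacer : hi]
            window = window.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        score = 0.0
        for i, b in enumerate(window):
            if b != "N":
                score += rbs.log_odds[i, _BASE_ORDER.index(b)]
        best = max(best, score)
    return best


def _downstream_orf_start(seq: str, fs: FrameshiftPrediction) -> int | None:
    """First in-frame start codon of the downstream-frame ORF 5' of fs.pos.

    The downstream ORF overlaps the upstream one, so its start codon lies
    at or upstream of the frameshift. Scans from the nearest upstream
    in-frame stop (or the sequence start) toward fs.pos; None when no
    start codon exists in that window. Operates in plus-strand reading
    orientation (the pipeline strand-normalizes first).
    """
    f = fs.downstream_frame
    # 0-based codon start indices of frame f at or before fs.pos
    first = f % 3
    last_codon = first + 3 * ((fs.pos - 1 - first) // 3)
    orf_lo = first
    for c in range(last_codon, first - 1, -3):
        if seq[c : c + 3] in STOP_CODONS:
            orf_lo = c + 3
            break
    for c in range(orf_lo, last_codon + 1, 3):
        if seq[c : c + 3] in START_CODONS:
            return c + 1
    return None


def filter_I(
    fs: FrameshiftPrediction, seq: str, rbs: RbsModel, cfg: FilterConfig
) -> bool:
    """True iff the prediction FAILS Filter I (downstream ORF has an RBS).

    Removal requires a strictly greater score than the threshold; an
    unresolvable downstream start or missing upstream context keeps the
    prediction (fail open)."""
    start = _downstream_orf_start(seq, fs)
    if start is None:
        return False
    return bool(score_rbs(seq, start, "+", rbs) > cfg.rbs_threshold)


def filter_II(fs: FrameshiftPrediction, seq: str, theta: float, cfg: FilterConfig) -> bool:
    """True iff the prediction FAILS Filter II (too close to the upstream
    ORF's terminating stop). Applies only to high-GC fragments (θ > 50)."""
    if theta <= cfg.gc_split:
        return False
    f = fs.upstream_frame
    first = f % 3
    # first in-frame codon starting strictly after the frameshift position
    c = first + 3 * max(0, -(-(fs.pos - first) // 3))
    while c + 3 <= len(seq):
        if seq[c : c + 3] in STOP_CODONS:
            return (c + 1) - fs.pos < cfg.d_min(theta)
        c += 3
    return False  # no in-frame stop before the fragment end: keep


def filter_III(
    fs: FrameshiftPrediction,
    gene: GenePrediction,
    fragment_len: int,
    theta: float,
    cfg: FilterConfig,
    left_pad: int = 0,
    right_pad: int = 0,
) -> bool:
    """True iff the prediction FAILS Filter III (too close to a border).

    Applies only to low-GC fragments (θ ≤ 50). The pads extend the
    working sequence to the true fragment borders when the decode ran on
    a sub-interval."""
    if theta > cfg.gc_split:
        return False
    d = min(
        fs.pos - gene.start,
        gene.end - fs.pos,
        fs.pos - 1 + left_pad,
        fragment_len - fs.pos + right_pad,
    )
    return d < cfg.border_dist


def apply_filters(
    predictions: list[FrameshiftPrediction],
    seq: str,
    theta: float,
    rbs: RbsModel,
    cfg: FilterConfig,
    enabled: frozenset[str] = frozenset({"I", "II", "III"}),
    left_pad: int = 0,
    right_pad: int = 0,
) -> list[FrameshiftPrediction]:
    """Evaluate every filter on every prediction and drop the failures.

    All three filters are always evaluated and recorded in
    ``filters_failed`` (so filter-combination studies can reuse one run);
    a prediction is removed iff it fails at least one *enabled* filter.
    """
    unknown = set(enabled) - {"I", "II", "III"}
    if unknown:
        raise ValueError(f"unknown filters: {sorted(unknown)}")
    kept = []
    for fs in predictions:
        failed = set()
        if filter_I(fs, seq, rbs, cfg):
            failed.add("I")
        if filter_II(fs, seq, theta, cfg):
            failed.add("II")
        if filter_III(fs, fs.gene, len(seq), theta, cfg, left_pad, right_pad):
            failed.add("III")
        fs.filters_failed = failed
        if not failed & enabled:
            kept.append(fs)
    return kept
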