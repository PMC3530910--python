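"""GC-content heuristic sequence models.

A short metagenomic fragment carries too little data to train a
species-specific codon model, but oligonucleotide usage in prokaryotes
varies smoothly with genome GC content. This module represents coding
(3-periodic, 5th-order) and non-coding hexamer frequencies as polynomial
functions of GC percent θ, fits the polynomial family from annotated
training genomes, and instantiates a concrete log-probability model for
the θ of a single fragment.

Phase convention: the phase of a coding hexamer is the codon position
(0, 1, 2) of its *last* base relative to the CDS reading frame, i.e.
``(index_of_last_base - cds_start) mod 3`` with 0-based indices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import Annotation, SequenceRecord, gc_percent, revcomp, seq_to_ints

N_HEXAMERS = 4096
N_CONTEXTS = 1024
EPS_FREQ = 1e-6

_HEX_WEIGHTS = 4 ** np.arange(5, -1, -1)


class FitError(ValueError):
    """Raised when the training set cannot support the requested fit."""


@dataclass
class DecoderParams:
    """Duration and frame-switch parameters attached to a FragmentModel.

    mean_coding_len / mean_noncoding_len are geometric-duration means in
    nt; p_fs is the per-coding-nt probability of an in-gene frame switch;
    stop_penalty (nats) is added to the emission of an in-frame stop codon's
    last base.
    """

    mean_coding_len: float = 900.0
    mean_noncoding_len: float = 150.0
    p_fs: float = 1e-3
    stop_penalty: float = -25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fs < 0.1:
            raise ValueError("p_fs must lie in [0, 0.1)")
        if self.mean_coding_len <= 1 or self.mean_noncoding_len <= 1:
            raise ValueError("mean durations must exceed 1 nt")


@dataclass
class GenomeCounts:
    """Hexamer counts for one training genome (pseudocount +1 included)."""

    genome_id: str
    theta: float
    coding: np.ndarray  # (3, 4096) by phase of the hexamer's last base
    noncoding: np.ndarray  # (4096,)


@dataclass
class HeuristicModelFamily:
    """Degree-d polynomial coefficients (in θ, percent scale) per hexamer.

    coding_coeffs: (3, 4096, d+1), noncoding_coeffs: (4096, d+1); the
    trailing axis is ascending powers of θ. Evaluation outside the fitted
    θ range clamps to the nearest boundary.
    """

    coding_coeffs: np.ndarray
    noncoding_coeffs: np.ndarray
    theta_min: float
    theta_max: float
    n_genomes: int
    degree: int

    def frequencies_at(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """Raw polynomial hexamer frequencies at θ, clamped to [ε, 1]."""
        t = min(max(theta, self.theta_min), self.theta_max)
        powers = t ** np.arange(self.degree + 1)
        coding = np.clip(self.coding_coeffs @ powers, EPS_FREQ, 1.0)
        noncoding = np.clip(self.noncoding_coeffs @ powers, EPS_FREQ, 1.0)
        return coding, noncoding


@dataclass
class FragmentModel:
    """Instantiated log-probability tables for one fragment's GC content.

    coding_logp[phase, context, base] is log P(base | preceding 5-mer
    context, codon position of base == phase); noncoding_logp[context, base]
    is the homogeneous background. Conditionals sum to 1 per context.
    """

    theta: float
    coding_logp: np.ndarray  # (3, 1024, 4)
    noncoding_logp: np.ndarray  # (1024, 4)
    params: DecoderParams = field(default_factory=DecoderParams)


def hexamer_index(hexamer: str) -> int:
    ints = seq_to_ints(hexamer)
    if (ints < 0).any() or len(ints) != 6:
        raise ValueError(f"not an ACGT hexamer: {hexamer!r}")
    return int(ints @ _HEX_WEIGHTS)


def hexamer_string(index: int) -> str:
    return "".join("ACGT"[(index >> (2 * k)) & 3] for k in range(5, -1, -1))


def _rolling_hexamers(ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hexamer index ending at each position i >= 5, and a validity mask."""
    L = len(ints)
    if L < 6:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(ints, 6)
    valid = (windows >= 0).all(axis=1)
    idx = windows @ _HEX_WEIGHTS
    return idx, valid


def _count_into(ints: np.ndarray, coding: np.ndarray | None, noncoding: np.ndarray | None) -> None:
    idx, valid = _rolling_hexamers(ints)
    if coding is not None:
        # position of last base within the CDS is i+5 for window i
        last = np.arange(len(idx)) + 5
        for phase in range(3):
            sel = valid & (last % 3 == phase)
            if sel.any():
                coding[phase] += np.bincount(idx[sel], minlength=N_HEXAMERS)
    if noncoding is not None and valid.any():
        noncoding += np.bincount(idx[valid], minlength=N_HEXAMERS)


def count_hexamers(
    genomes: list[tuple[SequenceRecord, list[Annotation]]],
) -> list[GenomeCounts]:
    """Per-genome GC content plus phased coding and noncoding hexamer counts.

    CDS on the minus strand are reverse-complemented before counting, so
    phases are always measured along the reading direction. Non-coding
    counts come from the forward-strand complement of all CDS intervals.
    Every cell carries a +1 pseudocount. Genomes without CDS are skipped
    with a warning.
    """
    out = []
    for rec, anns in genomes:
        cds = [a for a in anns if a.feature == "CDS" and a.seq_id == rec.id]
        if not cds:
            warnings.warn(f"genome {rec.id!r} has no CDS annotation; skipped")
            continue
        coding = np.ones((3, N_HEXAMERS))
        noncoding = np.ones(N_HEXAMERS)
        covered = np.zeros(rec.length, dtype=bool)
        for a in cds:
            sub = rec.seq[a.start - 1 : a.end]
            if a.strand == "-":
                sub = revcomp(sub)
            _count_into(seq_to_ints(sub), coding, None)
            covered[a.start - 1 : a.end] = True
        # maximal uncovered stretches form the noncoding training set
        edges = np.flatnonzero(np.diff(np.concatenate(([True], covered, [True])).astype(np.int8)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            _count_into(seq_to_ints(rec.seq[lo:hi]), None, noncoding)
        out.append(GenomeCounts(rec.id, gc_percent(rec.seq), coding, noncoding))
    return out


def _frequencies(counts: GenomeCounts) -> tuple[np.ndarray, np.ndarray]:
    coding = counts.coding / counts.coding.sum(axis=1, keepdims=True)
    noncoding = counts.noncoding / counts.noncoding.sum()
    return coding, noncoding


def fit_family(summaries: list[GenomeCounts], degree: int = 5) -> HeuristicModelFamily:
    """Least-squares polynomial fit of hexamer frequency against θ.

    Needs at least degree+2 genomes spanning at least 20 GC percentage
    points (degree 0, the per-genome mean, is exempt from the spread
    requirement and accepts a single genome).
    """
    if not summaries:
        raise FitError("no usable training genomes")
    thetas = np.array([s.theta for s in summaries])
    spread = thetas.max() - thetas.min()
    if degree == 0:
        pass
    elif len(summaries) < degree + 2:
        raise FitError(
            f"{len(summaries)} genomes cannot support a degree-{degree} fit; "
            f"need >= {degree + 2} or a lower degree"
        )
    elif spread < 20:
        raise FitError(
            f"training θ spread {spread:.1f} < 20 percentage points; "
            "add genomes or lower the degree"
        )
    cod = np.stack([_frequencies(s)[0] for s in summaries])  # (n, 3, 4096)
    non = np.stack([_frequencies(s)[1] for s in summaries])  # (n, 4096)
    y = np.concatenate([cod.reshape(len(summaries), -1), non], axis=1)
    coeffs = np.polynomial.polynomial.polyfit(thetas, y, degree)  # (d+1, K)
    coeffs = coeffs.T
    return HeuristicModelFamily(
        coding_coeffs=coeffs[: 3 * N_HEXAMERS].reshape(3, N_HEXAMERS, degree + 1),
        noncoding_coeffs=coeffs[3 * N_HEXAMERS :],
        theta_min=float(thetas.min()),
        theta_max=float(thetas.max()),
        n_genomes=len(summaries),
        degree=degree,
    )


def _conditional_logp(freq: np.ndarray) -> np.ndarray:
    """Next-base conditionals from hexamer frequencies, per 5-mer context."""
    shaped = freq.reshape(freq.shape[:-1] + (N_CONTEXTS, 4))
    cond = shaped / shaped.sum(axis=-1, keepdims=True)
    return np.log(cond)


def model_for_gc(
    family: HeuristicModelFamily,
    theta: float,
    params: DecoderParams | None = None,
) -> FragmentModel:
    """Instantiate the model for one fragment's GC percent.

    Polynomials are evaluated at θ (clamped to the fitted range), clamped
    to [1e-6, 1], renormalized per 5-mer context and logged.
    """
    if not 0.0 <= theta <= 100.0:
        raise ValueError(f"θ = {theta} outside [0, 100]")
    coding_freq, noncoding_freq = family.frequencies_at(theta)
    return FragmentModel(
        theta=theta,
        coding_logp=_conditional_logp(coding_freq),
        noncoding_logp=_conditional_logp(noncoding_freq),
        params=params if params is not None else DecoderParams(),
    )


def save_family(family: HeuristicModelFamily, path: str | Path) -> None:
    """Write the family as a diff-able TSV plus a JSON header sidecar.

    Rows: hexamer, phase (0-2 for coding, '-' for noncoding), c0..cD.
    Coefficients are serialized with repr(), which round-trips float64
    bit-exactly.
    """
    path = Path(path)
    meta = {
        "degree": family.degree,
        "n_genomes": family.n_genomes,
        "theta_min": family.theta_min,
        "theta_max": family.theta_max,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1) + "\n")
    with open(path, "w") as fh:
        cols = "\t".join(f"c{k}" for k in range(family.degree + 1))
        fh.write(f"hexamer\tphase\t{cols}\n")
        for phase in range(3):
            for h in range(N_HEXAMERS):
                vals = "\t".join(repr(float(c)) for c in family.coding_coeffs[phase, h])
                fh.write(f"{hexamer_string(h)}\t{phase}\t{vals}\n")
        for h in range(N_HEXAMERS):
            vals = "\t".join(repr(float(c)) for c in family.noncoding_coeffs[h])
            fh.write(f"{hexamer_string(h)}\t-\t{vals}\n")


def load_family(path: str | Path) -> HeuristicModelFamily:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    degree = meta["degree"]
    coding = np.zeros((3, N_HEXAMERS, degree + 1))
    noncoding = np.zeros((N_HEXAMERS, degree + 1))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("hexamer\tphase"):
            raise ValueError(f"{path}: not a model-family TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            h = hexamer_index(parts[0])
            coefs = [float(v) for v in parts[2:]]
            if parts[1] == "-":
                noncoding[h] = coefs
            else:
                coding[int(parts[1]), h] = coefs
    return HeuristicModelFamily(
        coding_coeffs=coding,
        noncoding_coeffs=noncoding,
        theta_min=meta["theta_min"],
        theta_max=meta["theta_max"],
        n_genomes=meta["n_genomes"],
        degree=degree,
    )
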