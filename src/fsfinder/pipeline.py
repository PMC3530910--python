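"""Two-step frameshift-detection pipeline for metagenomic fragments.

Step 1 decodes each input sequence with the frame-switch rate set to
zero — a pure heuristic-model gene finder — which fixes the model choice
(via the fragment's GC content) and partitions the sequence into
same-strand regions. Step 2 re-decodes each region, strand-normalized,
with a positive frame-switch rate to call frameshifts, applies the
false-positive filters, and maps every call back to input coordinates.
Genes overlapping a surviving frameshift are replaced by the
frameshifted gene call; all other step-1 genes are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .decoder import FrameshiftPrediction, GenePrediction, decode_fragment
from .filters import FilterConfig, RbsModel, apply_filters
from .heuristic_models import DecoderParams, HeuristicModelFamily, model_for_gc
from .sequence_io import SequenceRecord, gc_percent, revcomp


@dataclass
class PipelineConfig:
    decoder: DecoderParams = field(default_factory=DecoderParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    rbs: RbsModel = field(default_factory=RbsModel.shine_dalgarno)
    enabled_filters: frozenset = frozenset({"I", "II", "III"})


@dataclass
class StrandGroup:
    """A same-strand region of one source sequence, decoded independently.

    The working sequence is the region's forward-strand slice,
    reverse-complemented for minus-strand groups, so decoding always sees
    genes in plus orientation."""

    source_id: str
    start: int  # 1-based inclusive, source coordinates
    end: int
    strand: str
    theta_model: float
    working_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def map_to_group(pos: int, group: StrandGroup) -> int:
    """Source coordinate -> working (group-local) coordinate."""
    if not group.start <= pos <= group.end:
        raise ValueError("position outside the group interval")
    if group.strand == "+":
        return pos - group.start + 1
    return group.end - pos + 1


def map_back(pos: int, group: StrandGroup) -> int:
    """Working (group-local) coordinate -> source coordinate.

    Affine offset for plus groups; reflection within the interval for
    minus groups. Exact round-trip with map_to_group."""
    if not 1 <= pos <= group.length:
        raise ValueError("internal error: call outside its strand group")
    if group.strand == "+":
        return group.start + pos - 1
    return group.end - pos + 1


def _map_gene_back(gene: GenePrediction, group: StrandGroup) -> GenePrediction:
    a = map_back(gene.start, group)
    b = map_back(gene.end, group)
    start, end = min(a, b), max(a, b)
    frames = gene.frames_path
    if group.strand == "-":
        frames = [
            (f, min(map_back(x, group), map_back(y, group)), max(map_back(x, group), map_back(y, group)))
            for f, x, y in frames
        ][::-1]
    else:
        frames = [(f, map_back(x, group), map_back(y, group)) for f, x, y in frames]
    tl, tr = gene.truncated_left, gene.truncated_right
    if group.strand == "-":
        tl, tr = tr, tl
    return replace(
        gene,
        fragment_id=group.source_id,
        start=start,
        end=end,
        frames_path=frames,
        truncated_left=tl,
        truncated_right=tr,
    )


def _build_groups(
    record: SequenceRecord, genes: list[GenePrediction], theta: float
) -> list[StrandGroup]:
    """Partition the sequence into maximal same-strand regions.

    Consecutive step-1 genes on one strand share a region (a frameshifted
    gene appears to the zero-switch gene finder as two adjacent
    same-strand genes, so splitting between them would hide the switch);
    boundaries fall at the midpoints between adjacent opposite-strand
    genes. Midpoints reflect exactly under reverse complementation, which
    preserves the pipeline's strand-mirror invariant."""
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    L = record.length
    runs: list[list[GenePrediction]] = [[genes[0]]]
    for g in genes[1:]:
        if g.strand == runs[-1][-1].strand:
            runs[-1].append(g)
        else:
            runs.append([g])
    bounds = [0]
    for r1, r2 in zip(runs, runs[1:]):
        bounds.append((r1[-1].end + r2[0].start) // 2)
    bounds.append(L)
    groups = []
    for r, lo, hi in zip(runs, bounds, bounds[1:]):
        start, end = lo + 1, hi
        sub = record.seq[start - 1 : end]
        strand = r[0].strand
        working = revcomp(sub) if strand == "-" else sub
        groups.append(StrandGroup(record.id, start, end, strand, theta, working))
    return groups


def run(
    sequences: list[SequenceRecord],
    family: HeuristicModelFamily,
    cfg: PipelineConfig | None = None,
) -> dict[str, tuple[list[GenePrediction], list[FrameshiftPrediction]]]:
    """Run the full two-step pipeline on a batch of fragments.

    Returns per-sequence (genes, frameshifts), all in source coordinates.
    Sequences yielding no step-1 genes pass through with zero calls.
    """
    cfg = cfg or PipelineConfig()
    out: dict[str, tuple[list, list]] = {}
    for rec in sequences:
        theta = gc_percent(rec.seq)
        gene_params = replace(cfg.decoder, p_fs=0.0)
        model0 = model_for_gc(family, theta, gene_params)
        step1_genes, _ = decode_fragment(rec.seq, model0, rec.id)
        if not step1_genes:
            out[rec.id] = ([], [])
            continue
        model = model_for_gc(family, theta, cfg.decoder)
        final_fs: list[FrameshiftPrediction] = []
        replaced: list[GenePrediction] = []
        shifted_step1: set[int] = set()
        for group in _build_groups(rec, step1_genes, theta):
            genes2, fs2 = decode_fragment(group.working_seq, model, rec.id)
            if not fs2:
                continue
            left_pad = group.start - 1 if group.strand == "+" else rec.length - group.end
            right_pad = rec.length - group.end if group.strand == "+" else group.start - 1
            surviving = apply_filters(
                fs2, group.working_seq, theta, cfg.rbs, cfg.filters,
                cfg.enabled_filters, left_pad, right_pad,
            )
            flip = {"+": "-", "-": "+"}
            for fs in surviving:
                gene_src = _map_gene_back(fs.gene, group)
                # working coordinates are gene-forward; flip strand labels
                # back to source orientation for minus groups
                src_strand = fs.strand if group.strand == "+" else flip[fs.strand]
                gene_src.strand = gene_src.strand if group.strand == "+" else flip[gene_src.strand]
                fs_src = replace(
                    fs,
                    fragment_id=rec.id,
                    pos=map_back(fs.pos, group),
                    strand=src_strand,
                    gene=gene_src,
                    filters_failed=set(fs.filters_failed),
                )
                final_fs.append(fs_src)
                if gene_src not in replaced:
                    replaced.append(gene_src)
                for k, g1 in enumerate(step1_genes):
                    if g1.start <= gene_src.end and gene_src.start <= g1.end:
                        shifted_step1.add(k)
        final_genes = [g for k, g in enumerate(step1_genes) if k not in shifted_step1]
        final_genes += replaced
        final_genes.sort(key=lambda g: (g.start, g.end))
        out[rec.id] = (final_genes, final_fs)
    return out
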