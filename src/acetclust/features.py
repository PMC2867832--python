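"""Promoter architecture and genomic-context annotation.

Rules follow the study design exactly: single-peak (SP) promoters place ≥ 50%
of their tags inside some 4-nt window; CpG/repeat flags require overlap with
the core promoter's level-1 span; gene and lincRNA flags require an element
start inside the strand-relative [−300, +1000] window (closed at both ends);
the TATA scan aligns a position-frequency matrix against the promoter-strand
sequence of the strand-relative [−50, −15] window and keeps relative scores
strictly above 0.75.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Gene, IntervalSet, Promoter, PromoterTable

DEFAULT_GENE_WINDOW = (-300, 1000)
DEFAULT_TATA_WINDOW = (-50, -15)
DEFAULT_TATA_THRESHOLD = 0.75
PWM_PSEUDOCOUNT = 0.8
SP_WINDOW_NT = 4
SP_SHARE = 0.5

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FeatureAnnotation:
    promoter_id: str
    architecture: str  # "SP" or "BR"
    cpg: bool
    gene: bool
    lincrna: bool
    repeat: bool
    repeat_class: str | None
    tata: bool | None  # None = unscanned (window off contig / ambiguous base)
    tata_score: float | None


# ---------------------------------------------------------------------------
# Architecture


def classify_architecture(promoter: Promoter) -> str:
    """SP iff some 4-nt window holds ≥ 50% of the promoter's total tags."""
    total = promoter.total_tags
    if total <= 0:
        raise ValueError(f"promoter {promoter.id}: zero total tags")
    positions = [p for p, _ in promoter.level1]
    tags = [t for _, t in promoter.level1]
    best = 0
    j = 0
    for i in range(len(positions)):
        if j < i:
            j = i
        while j + 1 < len(positions) and positions[j + 1] <= positions[i] + SP_WINDOW_NT - 1:
            j += 1
        best = max(best, sum(tags[i : j + 1]))
    return "SP" if best >= SP_SHARE * total else "BR"


# ---------------------------------------------------------------------------
# Interval overlap


def overlaps_element(
    promoter: Promoter, elements: IntervalSet
) -> tuple[bool, str | None]:
    """Whether the core promoter's extent intersects any element.

    The extent is the half-open genomic span of the level-1 members (minimum
    width 1).  For a hit, the class (name) of the element with the largest
    overlap is returned; ties go to the first element by coordinate.
    """
    ext_start, ext_end = promoter.extent
    best_len, best = 0, None
    for iv in sorted(
        elements.on_chrom(promoter.chrom), key=lambda iv: (iv.start, iv.end)
    ):
        overlap = min(iv.end, ext_end) - max(iv.start, ext_start)
        if overlap > best_len:
            best_len, best = overlap, iv
    return (best is not None), (best.name if best is not None else None)


def _window_genomic(promoter: Promoter, window: tuple[int, int]) -> tuple[int, int]:
    """Strand-relative closed window [w0, w1] as genomic closed bounds."""
    w0, w1 = window
    if promoter.strand == "+":
        return promoter.rep_pos + w0, promoter.rep_pos + w1
    return promoter.rep_pos - w1, promoter.rep_pos - w0


def gene_annotated(
    promoter: Promoter,
    genes: Sequence[Gene],
    window: tuple[int, int] = DEFAULT_GENE_WINDOW,
) -> bool:
    """≥ 1 gene TSS inside the strand-relative window (gene strand ignored)."""
    lo, hi = _window_genomic(promoter, window)
    return any(g.chrom == promoter.chrom and lo <= g.tss <= hi for g in genes)


def lincrna_start(
    promoter: Promoter,
    starts: IntervalSet,
    window: tuple[int, int] = DEFAULT_GENE_WINDOW,
) -> bool:
    """≥ 1 lincRNA start position inside the strand-relative window."""
    lo, hi = _window_genomic(promoter, window)
    return any(
        iv.chrom == promoter.chrom and lo <= iv.start <= hi for iv in starts
    )


# ---------------------------------------------------------------------------
# TATA scan


def pfm_to_log_odds(
    pfm: np.ndarray,
    pseudocount: float = PWM_PSEUDOCOUNT,
    background: float = 0.25,
) -> np.ndarray:
    """Counts → log2-odds against a uniform background, with a per-cell
    pseudocount added before column normalization."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    counts = pfm + pseudocount
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(freqs / background)


def relative_score(sequence: str, pwm: np.ndarray) -> float:
    """Best relative PWM score over all full-width placements in ``sequence``.

    The relative score is (S − S_min)/(S_max − S_min), where S_min/S_max sum
    the per-position minima/maxima of the matrix; it is invariant under affine
    rescaling of the matrix.  Raises if the sequence is shorter than the
    matrix or contains a non-ACGT base.
    """
    m = pwm.shape[1]
    if len(sequence) < m:
        raise ValueError("sequence shorter than the matrix")
    try:
        encoded = [_BASE_INDEX[b] for b in sequence]
    except KeyError as exc:
        raise ValueError(f"ambiguous base {exc} in sequence") from exc
    s_min = float(pwm.min(axis=0).sum())
    s_max = float(pwm.max(axis=0).sum())
    span = s_max - s_min
    cols = np.arange(m)
    best = -np.inf
    for off in range(len(sequence) - m + 1):
        s = float(pwm[encoded[off : off + m], cols].sum())
        best = max(best, s)
    return (best - s_min) / span if span > 0 else 1.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def promoter_window_sequence(
    promoter: Promoter,
    genome: Mapping[str, str],
    window: tuple[int, int] = DEFAULT_TATA_WINDOW,
) -> str | None:
    """Promoter-strand sequence of a strand-relative closed window, or None
    if the window runs off the contig."""
    if promoter.chrom not in genome:
        return None
    seq = genome[promoter.chrom]
    lo, hi = _window_genomic(promoter, window)
    if lo < 0 or hi + 1 > len(seq):
        return None
    sub = seq[lo : hi + 1]
    return sub if promoter.strand == "+" else reverse_complement(sub)


def scan_tata(
    promoter: Promoter,
    genome: Mapping[str, str],
    pfm: np.ndarray,
    rel_threshold: float = DEFAULT_TATA_THRESHOLD,
    window: tuple[int, int] = DEFAULT_TATA_WINDOW,
    pseudocount: float = PWM_PSEUDOCOUNT,
) -> tuple[bool | None, float | None]:
    """Scan the promoter-strand [−50, −15] window against a TATA matrix.

    Returns ``(flag, best relative score)``; the flag is True only for scores
    strictly above the threshold.  An unavailable window (off contig or
    containing an ambiguous base) yields ``(None, None)`` — unscanned.
    """
    sub = promoter_window_sequence(promoter, genome, window)
    if sub is None:
        return None, None
    pwm = pfm_to_log_odds(pfm, pseudocount)
    try:
        best = relative_score(sub, pwm)
    except ValueError:
        return None, None
    return best > rel_threshold, best


def consensus(pfm: np.ndarray) -> str:
    """Per-column argmax letters (ties to A<C<G<T order)."""
    return "".join("ACGT"[i] for i in np.asarray(pfm).argmax(axis=0))


def anti_consensus(pfm: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in np.asarray(pfm).argmin(axis=0))


# ---------------------------------------------------------------------------
# Whole-table annotation


def annotate_promoters(
    promoters: PromoterTable,
    cpg: IntervalSet,
    repeats: IntervalSet,
    genes: Sequence[Gene],
    lincrna_starts: IntervalSet,
    genome: Mapping[str, str] | None = None,
    tata_pfm: np.ndarray | None = None,
    gene_window: tuple[int, int] = DEFAULT_GENE_WINDOW,
    tata_window: tuple[int, int] = DEFAULT_TATA_WINDOW,
    tata_threshold: float = DEFAULT_TATA_THRESHOLD,
) -> list[FeatureAnnotation]:
    out = []
    scan = genome is not None and tata_pfm is not None
    for p in promoters:
        cpg_flag, _ = overlaps_element(p, cpg)
        rpt_flag, rpt_class = overlaps_element(p, repeats)
        tata_flag, tata_score = (
            scan_tata(p, genome, tata_pfm, tata_threshold, tata_window)
            if scan
            else (None, None)
        )
        out.append(
            FeatureAnnotation(
                promoter_id=p.id,
                architecture=classify_architecture(p),
                cpg=cpg_flag,
                gene=gene_annotated(p, genes, gene_window),
                lincrna=lincrna_start(p, lincrna_starts, gene_window),
                repeat=rpt_flag,
                repeat_class=rpt_class,
                tata=tata_flag,
                tata_score=tata_score,
            )
        )
    return out


def annotations_frame(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "architecture": [a.architecture for a in annotations],
            "cpg": [a.cpg for a in annotations],
            "gene": [a.gene for a in annotations],
            "lincrna": [a.lincrna for a in annotations],
            "repeat": [a.repeat for a in annotations],
            "repeat_class": [a.repeat_class for a in annotations],
            "tata": [a.tata for a in annotations],
            "tata_score": [a.tata_score for a in annotations],
        },
        index=pd.Index([a.promoter_id for a in annotations], name="id"),
    )
    return frame


def write_annotations(annotations: Sequence[FeatureAnnotation], path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="id")
    for col in ("cpg", "gene", "lincrna", "repeat"):
        frame[col] = frame[col].astype(bool)
    return frame
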