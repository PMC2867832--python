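"""Two-stage promoter filtering: proximal-promoter removal, then bin coverage.

A promoter with any other promoter (either strand) within ``radius`` bp of its
representative position is discarded together with that neighbour, because the
surrounding probe signal would be a compound of both.  Survivors are then
required to have at least one probe midpoint in every one of the ``n_bins``
bins tiling the window centred on the representative position.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .io import ProbeTrack, PromoterTable

DEFAULT_RADIUS = 2200
DEFAULT_N_BINS = 11
DEFAULT_BIN_SIZE = 400


@dataclass
class FilterReport:
    """Attrition bookkeeping across the two filter stages."""

    n_input: int
    n_after_proximal: int | None = None
    n_after_coverage: int | None = None
    removed: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport(
            n_input=self.n_input,
            n_after_proximal=(
                self.n_after_proximal
                if self.n_after_proximal is not None
                else other.n_after_proximal
            ),
            n_after_coverage=(
                other.n_after_coverage
                if other.n_after_coverage is not None
                else self.n_after_coverage
            ),
            removed={**self.removed, **other.removed},
        )
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_proximal": self.n_after_proximal,
            "n_after_coverage": self.n_after_coverage,
            "removed": dict(self.removed),
        }


def filter_proximal(
    promoters: PromoterTable, radius: int = DEFAULT_RADIUS
) -> tuple[PromoterTable, FilterReport]:
    """Drop every promoter with a neighbour within ``radius`` bp (inclusive).

    Both members of each proximal pair are removed; strand is ignored.
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for p in promoters:
        by_chrom[p.chrom].append(p)
    removed: dict[str, str] = {}
    for chrom_proms in by_chrom.values():
        chrom_proms.sort(key=lambda p: (p.rep_pos, p.id))
        positions = np.array([p.rep_pos for p in chrom_proms])
        for i, p in enumerate(chrom_proms):
            left_close = i > 0 and p.rep_pos - positions[i - 1] <= radius
            right_close = (
                i + 1 < len(chrom_proms) and positions[i + 1] - p.rep_pos <= radius
            )
            if left_close or right_close:
                removed[p.id] = "proximal"
    kept = PromoterTable(tuple(p for p in promoters if p.id not in removed))
    report = FilterReport(
        n_input=len(promoters), n_after_proximal=len(kept), removed=removed
    )
    return kept, report


def bin_edges(rep_pos: int, n_bins: int = DEFAULT_N_BINS, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
    """Genomic edges of the ``n_bins`` bins centred on ``rep_pos`` (half-open)."""
    half = n_bins * bin_size // 2
    return rep_pos - half + bin_size * np.arange(n_bins + 1)


def filter_bin_coverage(
    promoters: PromoterTable,
    probes: ProbeTrack,
    n_bins: int = DEFAULT_N_BINS,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[PromoterTable, FilterReport]:
    """Keep promoters with ≥1 probe midpoint in every bin of their window.

    A window that runs past a chromosome boundary drops the promoter with
    reason ``edge``; a window with an empty bin drops it with ``coverage``.
    """
    half = n_bins * bin_size // 2
    removed: dict[str, str] = {}
    for p in promoters:
        if p.rep_pos - half < 0 or (
            chrom_sizes is not None
            and p.chrom in chrom_sizes
            and p.rep_pos + half > chrom_sizes[p.chrom]
        ):
            removed[p.id] = "edge"
            continue
        cp = probes.chroms.get(p.chrom)
        if cp is None or len(cp) == 0:
            removed[p.id] = "coverage"
            continue
        edges = bin_edges(p.rep_pos, n_bins, bin_size)
        counts = np.diff(np.searchsorted(cp.midpoints, edges))
        if np.any(counts == 0):
            removed[p.id] = "coverage"
    kept = PromoterTable(tuple(p for p in promoters if p.id not in removed))
    report = FilterReport(
        n_input=len(promoters), n_after_coverage=len(kept), removed=removed
    )
    return kept, report
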