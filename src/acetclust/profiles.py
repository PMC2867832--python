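"""Probe scoring, replicate averaging, strand-oriented binning, and cumulative
normalization of the signal around each promoter.

The per-probe score is −10·log10(p); replicate averaging happens on the score
scale, which is identical to taking the geometric mean of the replicate
p-values and then scoring (log identity).  The eleven 400 bp bins tile
[rep−2200, rep+2200); a − strand promoter's bin vector is the reverse of the
genomic bin order so index 0 is always the 5'-most bin.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .io import ChromProbes, ProbeTrack, Promoter, PromoterTable
from .preprocess import DEFAULT_BIN_SIZE, DEFAULT_N_BINS, bin_edges
from .stats import mann_whitney_pvalue


class ProfileError(ValueError):
    """Raised when a profile cannot be computed (e.g. an empty bin)."""


# ---------------------------------------------------------------------------
# Scoring


def pvalue_to_score(p):
    """Score = −10·log10(p) for p in (0, 1]; NaN passes through."""
    arr = np.asarray(p, dtype=float)
    finite = arr[np.isfinite(arr)]
    if np.any((finite <= 0) | (finite > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    score = -10.0 * np.log10(arr)
    # -10*log10(1.0) is -0.0; normalize so scores are non-negative zeros
    score = score + 0.0
    return float(score) if np.isscalar(p) else score


def score_to_pvalue(score):
    """Inverse of :func:`pvalue_to_score`: p = 10^(−score/10)."""
    arr = np.asarray(score, dtype=float)
    p = np.power(10.0, -arr / 10.0)
    return float(p) if np.isscalar(score) else p


def probe_pvalue_from_intensities(
    probes: ChromProbes, index: int, window: int = 300
) -> float:
    """One-sided rank-sum p (treatment > control) for one probe position.

    Pools the treatment and control intensities of all probes whose midpoint
    lies within ``window`` bp of the target probe's midpoint.
    """
    if probes.treatment is None or probes.control is None:
        raise ValueError("probe track carries no intensities")
    mids = probes.midpoints
    target = mids[index]
    lo = int(np.searchsorted(mids, target - window, side="left"))
    hi = int(np.searchsorted(mids, target + window, side="right"))
    treatment = probes.treatment[lo:hi].ravel()
    control = probes.control[lo:hi].ravel()
    treatment = treatment[np.isfinite(treatment)]
    control = control[np.isfinite(control)]
    if treatment.size == 0 or control.size == 0:
        raise ValueError("need at least one value on each side after pooling")
    _, p = mann_whitney_pvalue(treatment, control, alternative="greater")
    return p


# ---------------------------------------------------------------------------
# Replicate averaging


@dataclass
class ScoreTrack:
    """Per-chromosome probe midpoints with replicate-averaged scores."""

    chroms: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (midpoints, scores)

    def for_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.chroms:
            return np.empty(0, dtype=np.int64), np.empty(0)
        return self.chroms[chrom]


def average_replicates(track: ProbeTrack) -> ScoreTrack:
    """Per-probe score = arithmetic mean over replicates of −10·log10(p).

    Probes missing a replicate use the remaining replicates; probes with no
    replicate value at all are dropped (they count as absent for the coverage
    filter, not as score 0).
    """
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, cp in track.chroms.items():
        scores = pvalue_to_score(cp.pvalues)
        present_counts = np.isfinite(scores).sum(axis=1)
        sums = np.nansum(scores, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(present_counts > 0, sums / present_counts, np.nan)
        present = np.isfinite(mean)
        chroms[chrom] = (cp.midpoints[present], mean[present])
    return ScoreTrack(chroms)


# ---------------------------------------------------------------------------
# Binning


@dataclass(frozen=True)
class BinnedProfile:
    """Mean score per bin, ordered 5'→3' relative to the promoter's strand."""

    promoter_id: str
    scores: tuple[float, ...]
    n_bins: int = DEFAULT_N_BINS
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if len(self.scores) != self.n_bins:
            raise ProfileError(
                f"{self.promoter_id}: {len(self.scores)} bins, expected {self.n_bins}"
            )
        if any(s < 0 for s in self.scores):
            raise ProfileError(f"{self.promoter_id}: negative bin score")


@dataclass(frozen=True)
class CumulativeProfile:
    """Normalized 5'→3' cumulative bin profile; non-decreasing, ends at 1."""

    promoter_id: str
    cdf: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.cdf)
        if np.any(np.diff(arr) < -1e-12):
            raise ProfileError(f"{self.promoter_id}: cdf not non-decreasing")
        if abs(arr[-1] - 1.0) > 1e-9:
            raise ProfileError(f"{self.promoter_id}: cdf must end at 1")


def bin_scores(
    promoter: Promoter,
    positions: np.ndarray,
    scores: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinnedProfile:
    """Mean probe score per bin around the representative position.

    Genomic bin i spans [rep − half + i·bin_size, rep − half + (i+1)·bin_size)
    with half = n_bins·bin_size/2; membership is by probe midpoint.  Every bin
    must hold at least one probe (enforce with the coverage filter first).
    """
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=float)
    edges = bin_edges(promoter.rep_pos, n_bins, bin_size)
    in_window = (positions >= edges[0]) & (positions < edges[-1])
    pos_w, sc_w = positions[in_window], scores[in_window]
    idx = (pos_w - edges[0]) // bin_size
    sums = np.bincount(idx, weights=sc_w, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        empty = int(np.argmax(counts == 0))
        raise ProfileError(
            f"{promoter.id}: bin {empty} holds no probes (run the coverage filter)"
        )
    means = sums / counts
    if promoter.strand == "-":
        means = means[::-1]
    return BinnedProfile(promoter.id, tuple(float(v) for v in means), n_bins, bin_size)


def binned_profiles(
    promoters: PromoterTable,
    score_track: ScoreTrack,
    n_bins: int = DEFAULT_N_BINS,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, BinnedProfile]:
    out = {}
    for p in promoters:
        positions, scores = score_track.for_chrom(p.chrom)
        out[p.id] = bin_scores(p, positions, scores, n_bins, bin_size)
    return out


def cumulative_normalize(profile: BinnedProfile) -> CumulativeProfile:
    """5'→3' cumulative sum normalized to end at 1.

    An all-zero profile falls back to the uniform cdf ((i+1)/n_bins), keeping
    the Kolmogorov distance defined and the promoter shape-neutral.
    """
    scores = np.asarray(profile.scores, dtype=float)
    total = scores.sum()
    if total == 0:
        cdf = (np.arange(profile.n_bins) + 1) / profile.n_bins
    else:
        cdf = np.cumsum(scores) / total
    return CumulativeProfile(profile.promoter_id, tuple(float(v) for v in cdf))


def cumulative_profiles(profiles: Mapping[str, BinnedProfile]) -> dict[str, CumulativeProfile]:
    return {pid: cumulative_normalize(bp) for pid, bp in profiles.items()}


# ---------------------------------------------------------------------------
# Metagene histograms


@dataclass(frozen=True)
class MetageneHistogram:
    """Aggregate per-bin score over a promoter set, 5'→3' in promoter
    orientation; ``offsets`` are bin-start offsets relative to rep."""

    offsets: tuple[int, ...]
    values: tuple[float, ...]
    n_promoters: int


def metagene_histogram(
    profiles: Mapping[str, BinnedProfile] | Sequence[BinnedProfile],
    aggregate: Callable[..., np.ndarray] = np.mean,
) -> MetageneHistogram:
    """Aggregate (default: mean) of per-promoter bin scores, bin by bin.

    The arithmetic mean of scores equals −10·log10 of the geometric mean of
    the underlying p-values, so this reproduces a geometric-mean p histogram
    on the score scale.
    """
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    if not items:
        raise ProfileError("empty promoter set")
    n_bins = items[0].n_bins
    bin_size = items[0].bin_size
    if any(bp.n_bins != n_bins or bp.bin_size != bin_size for bp in items):
        raise ProfileError("profiles have mismatched binning")
    matrix = np.array([bp.scores for bp in items], dtype=float)
    values = np.asarray(aggregate(matrix, axis=0), dtype=float)
    half = n_bins * bin_size // 2
    offsets = tuple(-half + i * bin_size for i in range(n_bins))
    return MetageneHistogram(offsets, tuple(float(v) for v in values), len(items))


# ---------------------------------------------------------------------------
# TSV export


def write_profile_matrix(profiles: Mapping[str, BinnedProfile], path) -> None:
    items = sorted(profiles.items())
    if not items:
        raise ProfileError("nothing to write")
    n_bins = items[0][1].n_bins
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"bin_{i}" for i in range(n_bins)) + "\n")
        for pid, bp in items:
            fh.write(pid + "\t" + "\t".join(repr(v) for v in bp.scores) + "\n")


def read_profile_matrix(path) -> dict[str, BinnedProfile]:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_bins = len(header) - 1
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = BinnedProfile(
                fields[0], tuple(float(v) for v in fields[1:]), n_bins=n_bins
            )
    return out


def write_metagene(hist: MetageneHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tvalue\n")
        for off, val in zip(hist.offsets, hist.values):
            fh.write(f"{off}\t{val!r}\n")
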