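"""Synthetic promoter tables, probe tracks, annotations, and genome sequence
with planted ground truth, emulating the tiling-array / CAGE data regime.

Every promoter gets a planted profile shape (upstream / centered / downstream
archetype), a planted architecture (single-peak or broad tag distribution), an
expression tier, and five planted feature flags.  Probes of ``probe_length``
bp spaced at ``probe_spacing`` bp tile each chromosome, with optional masked
runs ("repetitive" gaps); each probe's replicate p-values are
p = 10^(−s/10) for score s = max(0, A·shape(x) + noise).

All randomness derives from ``config.seed`` through per-operation child
streams, so each generator op is deterministic regardless of call order.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from math import ceil, exp

import numpy as np
import pandas as pd

from .io import (
    Gene,
    Interval,
    IntervalSet,
    Promoter,
    PromoterTable,
    ProbeTrack,
    ChromProbes,
)

SHAPE_CLASSES = ("upstream", "centered", "downstream")
FEATURE_FLAGS = ("cpg", "gene", "repeat", "tata", "lincrna")
FEATURE_RATE = 0.5
REPEAT_CLASSES = ("Simple_repeat", "Low_complexity", "SINE", "LINE")

# archetype geometry (bp relative to rep, promoter orientation): invented to
# match the three observed cluster shapes qualitatively
_ARCHETYPES = {
    "upstream": ((-600.0, 400.0, 1.0),),
    "centered": ((-400.0, 300.0, 0.55), (600.0, 300.0, 1.0)),
    "downstream": ((800.0, 500.0, 1.0),),
}
_TIER_AMPLITUDE = {"low": 15.0, "medium": 35.0, "high": 70.0}

_SLOT = 6000  # inter-promoter spacing; > 2·2200 so only planted pairs are proximal
_MARGIN = 2500  # clearance from chromosome ends
_PAIR_OFFSET = 1500  # planted proximal partner distance (≤ 2200)

# rng stream ids per operation
_OP_PROMOTERS, _OP_PROBES, _OP_ANNOT = 11, 22, 33


class SizingError(ValueError):
    """The synthetic genome is too short to place the requested promoters."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_promoters: int = 300
    genome_length: int = 1_200_000
    n_chromosomes: int = 2
    probe_length: int = 25
    probe_spacing: int = 35
    shape_mix: Mapping[str, float] = field(
        default_factory=lambda: {"upstream": 1 / 3, "centered": 1 / 3, "downstream": 1 / 3}
    )
    sp_fraction: float = 0.4
    expression_tiers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (6.0, 20.0),
            "medium": (50.0, 200.0),
            "high": (1000.0, 4000.0),
        }
    )
    noise_sd: float = 5.0
    gap_rate: float = 0.01
    proximal_pair_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be ≥ 1")
        if abs(sum(self.shape_mix.values()) - 1.0) > 1e-9:
            raise ValueError("shape_mix must sum to 1")
        if set(self.shape_mix) - set(SHAPE_CLASSES):
            raise ValueError(f"shape_mix keys must be among {SHAPE_CLASSES}")
        if self.probe_spacing < self.probe_length:
            raise ValueError("probe_spacing must be ≥ probe_length")
        for name, rate in (
            ("sp_fraction", self.sp_fraction),
            ("gap_rate", self.gap_rate),
            ("proximal_pair_rate", self.proximal_pair_rate),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if set(self.expression_tiers) != {"low", "medium", "high"}:
            raise ValueError("expression_tiers needs low/medium/high ranges")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class TruthRecord:
    promoter_id: str
    shape_class: str
    architecture: str
    tier: str
    cpg: bool
    gene: bool
    repeat: bool
    repeat_class: str | None
    tata: bool
    lincrna: bool
    proximal: bool


@dataclass(frozen=True)
class PlantedTruth:
    records: tuple[TruthRecord, ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, pid: str) -> TruthRecord:
        for r in self.records:
            if r.promoter_id == pid:
                return r
        raise KeyError(pid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "shape_class": r.shape_class,
                    "architecture": r.architecture,
                    "tier": r.tier,
                    "cpg": r.cpg,
                    "gene": r.gene,
                    "repeat": r.repeat,
                    "repeat_class": r.repeat_class if r.repeat_class is not None else "",
                    "tata": r.tata,
                    "lincrna": r.lincrna,
                    "proximal": r.proximal,
                }
                for r in self.records
            ],
            index=pd.Index([r.promoter_id for r in self.records], name="id"),
        )


def write_truth(truth: PlantedTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t")


def read_truth(path) -> PlantedTruth:
    frame = pd.read_csv(path, sep="\t", index_col="id", keep_default_na=False)
    records = []
    for pid, row in frame.iterrows():
        records.append(
            TruthRecord(
                promoter_id=str(pid),
                shape_class=row["shape_class"],
                architecture=row["architecture"],
                tier=row["tier"],
                cpg=_as_bool(row["cpg"]),
                gene=_as_bool(row["gene"]),
                repeat=_as_bool(row["repeat"]),
                repeat_class=row["repeat_class"] or None,
                tata=_as_bool(row["tata"]),
                lincrna=_as_bool(row["lincrna"]),
                proximal=_as_bool(row["proximal"]),
            )
        )
    return PlantedTruth(tuple(records))


def _as_bool(v) -> bool:
    return v in (True, "True", 1, "1")


# ---------------------------------------------------------------------------
# Promoters


def _tag_distribution(rng, architecture: str, total: int) -> tuple[tuple[int, int], ...]:
    """Member (offset, tags) around offset 0; offset 0 is the strict argmax.

    SP: one dominant position with 75% of the tags (≥ the 50%/4-nt rule by
    construction).  BR: up to eight positions ≥ 7 bp apart — no 4-nt window
    can span two members — with near-even counts, so the maximal window share
    is max(tags)/total < 50%.
    """
    if architecture == "SP":
        dominant = ceil(0.75 * total)
        rest = total - dominant
        members = {0: dominant}
        minor_offsets = [-12, 9, 18]
        i = 0
        while rest > 0:
            off = minor_offsets[i % len(minor_offsets)]
            give = min(rest, max(1, rest // 2))
            members[off] = members.get(off, 0) + give
            rest -= give
            i += 1
        # keep every minor strictly below the dominant position
        for off in list(members):
            if off != 0 and members[off] >= dominant:
                members[0] += members[off] - dominant + 1
                members[off] = dominant - 1
    else:
        offsets = [-21, -14, -7, 0, 7, 14, 21, 28]
        base, extra = divmod(total, len(offsets))
        counts = [base + (1 if i < extra else 0) for i in range(len(offsets))]
        counts.sort(reverse=True)
        # strict argmax at offset 0: move one tag from the smallest positive count
        donor = max(i for i, c in enumerate(counts) if c > 0)
        if donor != 0:
            counts[donor] -= 1
            counts[0] += 1
        members = {}
        members[0] = counts[0]
        rest_offsets = [o for o in offsets if o != 0]
        for off, c in zip(rest_offsets, counts[1:]):
            if c > 0:
                members[off] = c
    return tuple(sorted(members.items()))


def _placements(config: SyntheticConfig) -> list[tuple[str, int, bool]]:
    """(chrom, rep_pos, is_pair_partner_slot) placements on the slot grid."""
    n_pairs = int(round(config.proximal_pair_rate * config.n_promoters / 2))
    n_paired = 2 * n_pairs
    n_slots = (config.n_promoters - n_paired) + n_pairs
    per_chrom = max(0, (config.genome_length - 2 * _MARGIN) // _SLOT)
    if per_chrom * config.n_chromosomes < n_slots:
        raise SizingError(
            f"genome holds {per_chrom * config.n_chromosomes} promoter slots, "
            f"need {n_slots}; increase genome_length or n_chromosomes"
        )
    slots = []
    for chrom in config.chrom_names():
        for i in range(per_chrom):
            slots.append((chrom, _MARGIN + i * _SLOT))
    placements: list[tuple[str, int, bool]] = []
    slot_iter = iter(slots)
    for _ in range(n_pairs):
        chrom, base = next(slot_iter)
        placements.append((chrom, base, True))
        placements.append((chrom, base + _PAIR_OFFSET, True))
    for _ in range(config.n_promoters - n_paired):
        chrom, base = next(slot_iter)
        placements.append((chrom, base, False))
    return placements


def generate_promoters(config: SyntheticConfig) -> tuple[PromoterTable, PlantedTruth]:
    """Generate the promoter table together with its planted ground truth."""
    rng = np.random.default_rng([config.seed, _OP_PROMOTERS])
    placements = _placements(config)
    shape_names = list(SHAPE_CLASSES)
    shape_probs = [config.shape_mix.get(s, 0.0) for s in shape_names]
    tier_names = ("low", "medium", "high")
    promoters, records = [], []
    width = len(str(config.n_promoters))
    for i, (chrom, rep, proximal) in enumerate(placements):
        pid = f"p{i + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        shape = shape_names[rng.choice(len(shape_names), p=shape_probs)]
        architecture = "SP" if rng.random() < config.sp_fraction else "BR"
        tier = tier_names[rng.integers(0, 3)]
        lo, hi = config.expression_tiers[tier]
        tpm = float(rng.uniform(lo, hi))
        total = max(6, int(round(tpm)))
        level1 = tuple(
            (rep + off, tags) for off, tags in _tag_distribution(rng, architecture, total)
        )
        tpm0 = float(total)  # tag total ≡ tpm under a notional 1e6-tag library
        tpm96 = float(total * exp(rng.normal(0.0, 0.3)))
        flags = {f: bool(rng.random() < FEATURE_RATE) for f in FEATURE_FLAGS}
        rpt_class = REPEAT_CLASSES[rng.integers(0, len(REPEAT_CLASSES))] if flags["repeat"] else None
        promoters.append(
            Promoter(pid, chrom, strand, rep, level1, {"0h": tpm0, "96h": tpm96})
        )
        records.append(
            TruthRecord(
                promoter_id=pid,
                shape_class=shape,
                architecture=architecture,
                tier=tier,
                cpg=flags["cpg"],
                gene=flags["gene"],
                repeat=flags["repeat"],
                repeat_class=rpt_class,
                tata=flags["tata"],
                lincrna=flags["lincrna"],
                proximal=proximal,
            )
        )
    return PromoterTable(tuple(promoters)), PlantedTruth(tuple(records))


# ---------------------------------------------------------------------------
# Probe track


def archetype_signal(shape_class: str, offsets: np.ndarray) -> np.ndarray:
    """Unit-amplitude archetype value at strand-relative offsets (bp)."""
    x = np.asarray(offsets, dtype=float)
    out = np.zeros_like(x)
    for mu, sd, amp in _ARCHETYPES[shape_class]:
        out += amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def _gap_mask(rng, n: int, gap_rate: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if gap_rate > 0 and rng.random() < gap_rate:
            run = int(rng.integers(8, 16))
            mask[i : i + run] = True
            i += run
        else:
            i += 1
    return mask


def generate_probe_track(
    promoters: PromoterTable,
    truth: PlantedTruth,
    config: SyntheticConfig,
    n_replicates: int = 2,
    track_seed: int = 0,
) -> ProbeTrack:
    """Tile every chromosome and plant archetype signal around each promoter.

    Per probe and replicate, s = max(0, Σ_promoters A·shape(x) + N(0, σ)) and
    the emitted p-value is 10^(−s/10).  ``track_seed`` distinguishes tracks
    generated for the same promoter set (e.g. an acetylation-like and a
    polymerase-like track).
    """
    rng = np.random.default_rng([config.seed, _OP_PROBES, track_seed])
    truth_by_id = {r.promoter_id: r for r in truth}
    chroms: dict[str, ChromProbes] = {}
    for chrom in config.chrom_names():
        n = (config.genome_length - config.probe_length) // config.probe_spacing + 1
        starts = np.arange(n, dtype=np.int64) * config.probe_spacing
        ends = starts + config.probe_length
        mids = (starts + ends) // 2
        signal = np.zeros(n)
        for p in promoters:
            if p.chrom != chrom:
                continue
            rec = truth_by_id[p.id]
            amplitude = _TIER_AMPLITUDE[rec.tier]
            lo = int(np.searchsorted(mids, p.rep_pos - 2500))
            hi = int(np.searchsorted(mids, p.rep_pos + 2500))
            offsets = mids[lo:hi] - p.rep_pos
            if p.strand == "-":
                offsets = -offsets
            signal[lo:hi] += amplitude * archetype_signal(rec.shape_class, offsets)
        mask = _gap_mask(rng, n, config.gap_rate)
        pvalues = np.empty((n, n_replicates))
        for rep in range(n_replicates):
            noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd > 0
                else np.zeros(n)
            )
            scores = np.maximum(0.0, signal + noise)
            pvalues[:, rep] = np.power(10.0, -scores / 10.0)
        keep = ~mask
        chroms[chrom] = ChromProbes(starts[keep], ends[keep], pvalues[keep])
    return ProbeTrack(chroms)


# ---------------------------------------------------------------------------
# Annotations + genome


class PlacementError(ValueError):
    """A planted feature window would run off the chromosome end."""


def generate_annotations(
    promoters: PromoterTable,
    truth: PlantedTruth,
    config: SyntheticConfig,
    tata_pfm: np.ndarray | None = None,
) -> tuple[IntervalSet, IntervalSet, tuple[Gene, ...], IntervalSet, dict[str, str]]:
    """Plant CpG/repeat/gene/lincRNA elements and TATA motifs per the truth.

    Flagged promoters get exactly one qualifying element; unflagged promoters
    get none (their TATA scan windows are rewritten until motif-free).
    Returns (cpg, repeats, genes, lincrna_starts, genome).
    """
    from .features import (  # local import to avoid a module cycle
        DEFAULT_TATA_THRESHOLD,
        DEFAULT_TATA_WINDOW,
        anti_consensus,
        consensus,
        pfm_to_log_odds,
        relative_score,
        reverse_complement,
    )
    from .pfm import default_tata_pfm

    if tata_pfm is None:
        tata_pfm = default_tata_pfm()
    rng = np.random.default_rng([config.seed, _OP_ANNOT])
    truth_by_id = {r.promoter_id: r for r in truth}

    # background genome: random bases
    genome_arrays = {
        chrom: rng.integers(0, 4, size=config.genome_length).astype(np.uint8)
        for chrom in config.chrom_names()
    }
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    cpg_records, repeat_records, gene_records, linc_records = [], [], [], []
    w0, w1 = DEFAULT_TATA_WINDOW
    window_len = w1 - w0 + 1
    motif = consensus(tata_pfm)
    anti = anti_consensus(tata_pfm)
    if len(motif) > window_len:
        raise PlacementError("TATA matrix longer than the scan window")
    pwm = pfm_to_log_odds(tata_pfm)

    for p in promoters:
        rec = truth_by_id[p.id]
        seq = genome_arrays[p.chrom]
        ext_start, ext_end = p.extent
        if p.rep_pos - 200 < 0 or p.rep_pos + 200 > config.genome_length:
            raise PlacementError(f"promoter {p.id}: feature window off chromosome end")
        if rec.cpg:
            cpg_records.append(
                Interval(p.chrom, ext_start - 50, ext_end + 50, f"cpg_{p.id}")
            )
        if rec.repeat:
            repeat_records.append(
                Interval(p.chrom, p.rep_pos - 30, p.rep_pos + 40, rec.repeat_class)
            )
        if rec.gene:
            # gene TSS at strand-relative +150, gene on the promoter strand
            if p.strand == "+":
                tss = p.rep_pos + 150
                gene_records.append(Gene(p.chrom, "+", tss, tss + 2000, f"gene_{p.id}"))
            else:
                tss = p.rep_pos - 150
                gene_records.append(Gene(p.chrom, "-", tss - 2000, tss + 1, f"gene_{p.id}"))
        if rec.lincrna:
            gpos = p.rep_pos - 100 if p.strand == "+" else p.rep_pos + 100
            linc_records.append(Interval(p.chrom, gpos, gpos + 1, f"linc_{p.id}"))

        # TATA scan window, on the promoter strand
        if p.strand == "+":
            glo, ghi = p.rep_pos + w0, p.rep_pos + w1
        else:
            glo, ghi = p.rep_pos - w1, p.rep_pos - w0
        if glo < 0 or ghi + 1 > config.genome_length:
            raise PlacementError(f"promoter {p.id}: TATA window off chromosome end")
        if rec.tata:
            offset = int(rng.integers(0, window_len - len(motif) + 1))
            window = list(anti * ((window_len // len(anti)) + 1))[:window_len]
            window[offset : offset + len(motif)] = list(motif)
            window_str = "".join(window)
        else:
            window_str = _motif_free_window(rng, window_len, pwm, DEFAULT_TATA_THRESHOLD)
        genomic = window_str if p.strand == "+" else reverse_complement(window_str)
        seq[glo : ghi + 1] = np.frombuffer(genomic.encode(), dtype=np.uint8)

    # arrays hold 0-3 base codes except where scan windows were written as ASCII
    genome = {}
    for chrom, arr in genome_arrays.items():
        ascii_mask = arr >= 4
        decoded = bases[np.where(ascii_mask, 0, arr)]
        decoded[ascii_mask] = arr[ascii_mask]
        genome[chrom] = decoded.tobytes().decode()
    return (
        IntervalSet(tuple(cpg_records)),
        IntervalSet(tuple(repeat_records)),
        tuple(gene_records),
        IntervalSet(tuple(linc_records)),
        genome,
    )


def _motif_free_window(rng, length: int, pwm: np.ndarray, threshold: float) -> str:
    """Random window re-drawn until its best relative score sits safely below
    the scan threshold."""
    from .features import relative_score

    while True:
        window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if relative_score(window, pwm) < threshold - 0.03:
            return window


# ---------------------------------------------------------------------------
# Convenience bundle


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    promoters: PromoterTable
    truth: PlantedTruth
    track: ProbeTrack
    cpg: IntervalSet
    repeats: IntervalSet
    genes: tuple[Gene, ...]
    lincrna: IntervalSet
    genome: dict[str, str]


def generate_dataset(
    config: SyntheticConfig,
    n_replicates: int = 2,
    with_annotations: bool = True,
) -> SyntheticDataset:
    promoters, truth = generate_promoters(config)
    track = generate_probe_track(promoters, truth, config, n_replicates=n_replicates)
    if with_annotations:
        cpg, repeats, genes, lincrna, genome = generate_annotations(
            promoters, truth, config
        )
    else:
        cpg = IntervalSet(())
        repeats = IntervalSet(())
        genes = ()
        lincrna = IntervalSet(())
        genome = {}
    return SyntheticDataset(
        config, promoters, truth, track, cpg, repeats, genes, lincrna, genome
    )
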