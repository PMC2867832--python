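"""Readers, writers, and core record types for every external file the pipeline touches.

All genomic intervals are 0-based, half-open (BED convention), including the
promoter windows derived elsewhere.  Writers emit the same convention, so a
write→read round trip is the identity.  Malformed input lines are rejected with
a :class:`FormatError` naming the file and line number.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")


class FormatError(ValueError):
    """An input file or in-memory record violates its format contract."""


def _fail(path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# Promoters


@dataclass(frozen=True)
class Promoter:
    """A level-3 core promoter anchored at its representative TSS.

    ``level1`` holds the member TSS positions with their tag counts, sorted by
    position.  ``rep_pos`` must be the member position carrying the maximal tag
    count (ties resolved to the 5'-most, i.e. smallest, position).
    """

    id: str
    chrom: str
    strand: str
    rep_pos: int
    level1: tuple[tuple[int, int], ...]
    tpm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"promoter {self.id}: unknown strand {self.strand!r}")
        if not self.level1:
            raise FormatError(f"promoter {self.id}: no level-1 members")
        positions = [p for p, _ in self.level1]
        if sorted(set(positions)) != positions:
            raise FormatError(f"promoter {self.id}: level-1 positions not sorted/unique")
        if any(t <= 0 for _, t in self.level1):
            raise FormatError(f"promoter {self.id}: non-positive tag count")
        if any(v < 0 for v in self.tpm.values()):
            raise FormatError(f"promoter {self.id}: negative tpm")
        max_tags = max(t for _, t in self.level1)
        rep = min(p for p, t in self.level1 if t == max_tags)
        if self.rep_pos != rep:
            raise FormatError(
                f"promoter {self.id}: rep_pos {self.rep_pos} is not the "
                f"max-tag (5'-most on ties) member position {rep}"
            )

    @property
    def total_tags(self) -> int:
        return sum(t for _, t in self.level1)

    @property
    def extent(self) -> tuple[int, int]:
        """Genomic span of the level-1 members, half-open, minimum width 1."""
        positions = [p for p, _ in self.level1]
        return min(positions), max(positions) + 1


@dataclass(frozen=True)
class PromoterTable:
    """An ordered collection of promoters with unique ids."""

    records: tuple[Promoter, ...]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate promoter ids: {dup[:5]}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.records)

    def by_id(self, pid: str) -> Promoter:
        for p in self.records:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def subset(self, keep_ids) -> "PromoterTable":
        keep = set(keep_ids)
        return PromoterTable(tuple(p for p in self.records if p.id in keep))


# ---------------------------------------------------------------------------
# Probe tracks


@dataclass
class ChromProbes:
    """Sorted, non-overlapping probes on one chromosome.

    ``pvalues`` has shape (n_probes, n_replicates); NaN marks a missing
    replicate measurement.  Optional raw hybridization intensities are carried
    as (n_probes, n_intensity_replicates) arrays.
    """

    starts: np.ndarray
    ends: np.ndarray
    pvalues: np.ndarray
    treatment: np.ndarray | None = None
    control: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.pvalues = np.atleast_2d(np.asarray(self.pvalues, dtype=float))
        n = self.starts.size
        if self.ends.size != n or self.pvalues.shape[0] != n:
            raise FormatError("probe arrays have inconsistent lengths")
        if np.any(self.ends <= self.starts):
            i = int(np.argmax(self.ends <= self.starts))
            raise FormatError(f"probe {i}: empty or inverted interval")
        if n > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            i = int(np.argmax(self.starts[1:] < self.ends[:-1]))
            raise FormatError(f"probe {i + 1}: overlaps or precedes probe {i}")
        finite = self.pvalues[np.isfinite(self.pvalues)]
        if np.any((finite <= 0) | (finite > 1)):
            raise FormatError("probe p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass
class ProbeTrack:
    """Per-chromosome tiling-array probes with replicate p-values."""

    chroms: dict[str, ChromProbes]

    @property
    def n_replicates(self) -> int:
        for cp in self.chroms.values():
            return cp.pvalues.shape[1]
        return 0

    @property
    def n_probes(self) -> int:
        return sum(len(cp) for cp in self.chroms.values())


# ---------------------------------------------------------------------------
# Intervals and genes


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass(frozen=True)
class IntervalSet:
    """BED-like intervals (0-based half-open) with an optional name/class column."""

    records: tuple[Interval, ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def on_chrom(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.records if iv.chrom == chrom]


@dataclass(frozen=True)
class Gene:
    """A refGene-like record; the TSS is txStart on +, txEnd−1 on −."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    name: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.name}: unknown strand {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise FormatError(f"gene {self.name}: txStart must be < txEnd")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


# ---------------------------------------------------------------------------
# Promoter table I/O

_PROM_FIXED = ["id", "chrom", "strand", "rep_pos", "level1"]


def write_promoters(table: PromoterTable, path) -> None:
    timepoints = sorted({tp for p in table for tp in p.tpm})
    with open(path, "w") as fh:
        fh.write("\t".join(_PROM_FIXED + [f"tpm_{tp}" for tp in timepoints]) + "\n")
        for p in table:
            level1 = ",".join(f"{pos}:{tags}" for pos, tags in p.level1)
            row = [p.id, p.chrom, p.strand, str(p.rep_pos), level1]
            row += [repr(float(p.tpm.get(tp, 0.0))) for tp in timepoints]
            fh.write("\t".join(row) + "\n")


def read_promoters(path) -> PromoterTable:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_PROM_FIXED)] != _PROM_FIXED:
            _fail(path, 1, f"bad promoter header {header[:5]}")
        timepoints = [c[4:] for c in header[len(_PROM_FIXED):] if c.startswith("tpm_")]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                _fail(path, lineno, f"expected {len(header)} fields, got {len(fields)}")
            try:
                level1 = tuple(
                    (int(pos), int(tags))
                    for pos, tags in (m.split(":") for m in fields[4].split(","))
                )
                tpm = {
                    tp: float(v)
                    for tp, v in zip(timepoints, fields[len(_PROM_FIXED):])
                }
                records.append(
                    Promoter(fields[0], fields[1], fields[2], int(fields[3]), level1, tpm)
                )
            except (ValueError, FormatError) as exc:
                _fail(path, lineno, str(exc))
    return PromoterTable(tuple(records))


# ---------------------------------------------------------------------------
# Probe track I/O (one bedGraph-like file per replicate: chrom, start, end, p)


def write_probe_track(track: ProbeTrack, paths: Sequence) -> None:
    if len(paths) != track.n_replicates:
        raise ValueError(
            f"need {track.n_replicates} paths (one per replicate), got {len(paths)}"
        )
    for rep, path in enumerate(paths):
        with open(path, "w") as fh:
            for chrom in sorted(track.chroms):
                cp = track.chroms[chrom]
                for start, end, p in zip(cp.starts, cp.ends, cp.pvalues[:, rep]):
                    if np.isnan(p):
                        continue
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(p)!r}\n")


def _read_probe_replicate(path) -> dict[str, list[tuple[int, int, float]]]:
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 fields, got {len(fields)}")
            chrom, start, end, p = fields
            try:
                start_i, end_i, p_f = int(start), int(end), float(p)
            except ValueError:
                _fail(path, lineno, f"unparseable probe record {fields!r}")
            if not (0 < p_f <= 1):
                _fail(path, lineno, f"p-value {p_f} outside (0, 1]")
            rows = out.setdefault(chrom, [])
            if rows and start_i < rows[-1][1]:
                _fail(path, lineno, "probes unsorted or overlapping")
            rows.append((start_i, end_i, p_f))
    return out


def read_probe_track(paths: Sequence, intensity_path=None) -> ProbeTrack:
    """Read one p-value file per replicate and merge on identical coordinates.

    Probes absent from a replicate file get a NaN p-value for that replicate;
    probes absent from all replicates are absent from the track.
    """
    replicates = [_read_probe_replicate(p) for p in paths]
    chroms: dict[str, ChromProbes] = {}
    all_chroms = sorted({c for rep in replicates for c in rep})
    for chrom in all_chroms:
        coords = sorted({(s, e) for rep in replicates for s, e in
                         [(r[0], r[1]) for r in rep.get(chrom, [])]})
        index = {c: i for i, c in enumerate(coords)}
        pvalues = np.full((len(coords), len(replicates)), np.nan)
        for j, rep in enumerate(replicates):
            for start, end, p in rep.get(chrom, []):
                pvalues[index[(start, end)], j] = p
        starts = np.array([s for s, _ in coords], dtype=np.int64)
        ends = np.array([e for _, e in coords], dtype=np.int64)
        chroms[chrom] = ChromProbes(starts, ends, pvalues)
    track = ProbeTrack(chroms)
    if intensity_path is not None:
        _attach_intensities(track, intensity_path)
    return track


def write_intensity_table(track: ProbeTrack, path) -> None:
    first = next(iter(track.chroms.values()))
    if first.treatment is None or first.control is None:
        raise ValueError("track carries no intensities")
    n_t, n_c = first.treatment.shape[1], first.control.shape[1]
    cols = ["chrom", "start", "end"]
    cols += [f"treatment_{i + 1}" for i in range(n_t)]
    cols += [f"control_{i + 1}" for i in range(n_c)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for chrom in sorted(track.chroms):
            cp = track.chroms[chrom]
            for i in range(len(cp)):
                row = [chrom, str(cp.starts[i]), str(cp.ends[i])]
                row += [repr(float(v)) for v in cp.treatment[i]]
                row += [repr(float(v)) for v in cp.control[i]]
                fh.write("\t".join(row) + "\n")


def _attach_intensities(track: ProbeTrack, path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        t_cols = [i for i, c in enumerate(header) if c.startswith("treatment_")]
        c_cols = [i for i, c in enumerate(header) if c.startswith("control_")]
        if header[:3] != ["chrom", "start", "end"] or not t_cols or not c_cols:
            _fail(path, 1, "bad intensity header")
        values: dict[str, dict[tuple[int, int], tuple[list[float], list[float]]]] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                _fail(path, lineno, "field count mismatch")
            key = (int(fields[1]), int(fields[2]))
            values.setdefault(fields[0], {})[key] = (
                [float(fields[i]) for i in t_cols],
                [float(fields[i]) for i in c_cols],
            )
    for chrom, cp in track.chroms.items():
        per_chrom = values.get(chrom, {})
        treatment = np.full((len(cp), len(t_cols)), np.nan)
        control = np.full((len(cp), len(c_cols)), np.nan)
        for i, (s, e) in enumerate(zip(cp.starts, cp.ends)):
            if (s, e) in per_chrom:
                t, c = per_chrom[(s, e)]
                treatment[i], control[i] = t, c
        cp.treatment, cp.control = treatment, control


# ---------------------------------------------------------------------------
# BED4 / gene / lincRNA I/O


def write_intervals(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_intervals(path) -> IntervalSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) not in (3, 4):
                _fail(path, lineno, f"expected 3-4 BED fields, got {len(fields)}")
            try:
                name = fields[3] if len(fields) == 4 else "."
                records.append(Interval(fields[0], int(fields[1]), int(fields[2]), name))
            except (ValueError, FormatError) as exc:
                _fail(path, lineno, str(exc))
    return IntervalSet(tuple(records))


_GENE_HEADER = ["chrom", "strand", "txStart", "txEnd", "name"]


def write_genes(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{g.name}\n")


def read_genes(path) -> tuple[Gene, ...]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_HEADER:
            _fail(path, 1, f"bad gene header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                _fail(path, lineno, f"expected 5 fields, got {len(fields)}")
            try:
                genes.append(Gene(fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4]))
            except (ValueError, FormatError) as exc:
                _fail(path, lineno, str(exc))
    return tuple(genes)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Position-frequency matrices (JASPAR text layout, rows A/C/G/T)

_PFM_ROWS = "ACGT"


def read_pfm(path) -> np.ndarray:
    """Read a 4-row count matrix; returns shape (4, length), row order A,C,G,T."""
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base = None
            if line[0] in _PFM_ROWS and (len(line) == 1 or not line[1].isdigit() or line[1].isspace()):
                base, line = line[0], line[1:]
            body = line.replace("[", " ").replace("]", " ")
            try:
                values = [float(v) for v in body.split()]
            except ValueError:
                _fail(path, lineno, f"unparseable matrix row {line!r}")
            if base is None:
                base = _PFM_ROWS[len(order)] if len(order) < 4 else None
            if base is None or base in rows:
                _fail(path, lineno, "more than four matrix rows")
            rows[base] = values
            order.append(base)
    if sorted(rows) != list(_PFM_ROWS):
        raise FormatError(f"{path}: need exactly rows A, C, G, T; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged matrix rows {lengths}")
    pfm = np.array([rows[b] for b in _PFM_ROWS], dtype=float)
    if np.any(pfm < 0):
        raise FormatError(f"{path}: negative counts")
    return pfm


def write_pfm(pfm: np.ndarray, path, name: str = "motif") -> None:
    pfm = np.asarray(pfm, dtype=float)
    if pfm.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip(_PFM_ROWS, pfm):
            body = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {body} ]\n")
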