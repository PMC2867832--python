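"""End-to-end orchestration: synthesize/load → filter → profile → cluster →
annotate → test → report.

Every named constant of the analysis (proximal radius 2,200 bp; 11 bins of
400 bp; k = 3; TATA threshold 0.75 and window −50/−15; gene window
−300/+1,000; SP rule 4 nt / 50%; tier fraction 10%) is a defaulted parameter
of :class:`PipelineConfig`.  Runs are deterministic under a fixed seed and the
report carries a config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import (
    ClusterResult,
    build_distance_matrix,
    cross_tabulate_clusterings,
    k_medoids,
    label_clusters,
)
from .features import annotate_promoters, annotations_frame
from .io import (
    PromoterTable,
    read_fasta,
    read_genes,
    read_intervals,
    read_pfm,
    read_probe_track,
    read_promoters,
)
from .pfm import default_tata_pfm
from .preprocess import FilterReport, filter_bin_coverage, filter_proximal
from .profiles import average_replicates, binned_profiles, cumulative_profiles
from .stats import (
    BINARY_FEATURES,
    chi_square_test,
    expression_tiers,
    feature_by_cluster_table,
    fisher_exact,
    repeat_fraction_by_tier,
)
from .synth import SyntheticConfig, generate_annotations, generate_probe_track, generate_promoters

log = logging.getLogger("acetclust")


@dataclass(frozen=True)
class PipelineConfig:
    # data source: synthetic config, or input paths
    synthetic: SyntheticConfig | None = None
    promoter_path: str | None = None
    probe_paths: tuple[str, ...] = ()
    second_probe_paths: tuple[str, ...] = ()
    cpg_path: str | None = None
    repeat_path: str | None = None
    gene_path: str | None = None
    lincrna_path: str | None = None
    fasta_path: str | None = None
    pfm_path: str | None = None
    # analysis parameters
    radius: int = 2200
    n_bins: int = 11
    bin_size: int = 400
    k: int = 3
    tata_threshold: float = 0.75
    tata_window: tuple[int, int] = (-50, -15)
    gene_window: tuple[int, int] = (-300, 1000)
    tier_fraction: float = 0.10
    timepoint: str = "0h"
    second_track: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.radius, self.n_bins, self.bin_size, self.k) <= 0:
            raise ValueError("radius, n_bins, bin_size and k must be positive")
        if self.gene_window[0] >= self.gene_window[1]:
            raise ValueError("malformed gene window")
        if self.tata_window[0] >= self.tata_window[1]:
            raise ValueError("malformed TATA window")
        if self.synthetic is None and self.promoter_path is None:
            raise ValueError("need either a synthetic config or input paths")

    def hash(self) -> str:
        def _default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    filter: dict
    cluster_sizes: dict
    assignments: dict
    medoids: list
    objective: float
    feature_tests: dict
    feature_tables: dict
    tiers: dict
    repeat_fraction_by_tier: dict
    cross_tabulation: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return decorator


@_stage("load")
def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        synth_cfg = config.synthetic
        promoters, truth = generate_promoters(synth_cfg)
        track = generate_probe_track(promoters, truth, synth_cfg, track_seed=0)
        second = (
            generate_probe_track(promoters, truth, synth_cfg, track_seed=1)
            if config.second_track
            else None
        )
        cpg, repeats, genes, lincrna, genome = generate_annotations(
            promoters, truth, synth_cfg
        )
        pfm = default_tata_pfm()
        return promoters, track, second, cpg, repeats, genes, lincrna, genome, pfm
    promoters = read_promoters(config.promoter_path)
    track = read_probe_track(list(config.probe_paths))
    second = (
        read_probe_track(list(config.second_probe_paths))
        if config.second_probe_paths
        else None
    )
    cpg = read_intervals(config.cpg_path)
    repeats = read_intervals(config.repeat_path)
    genes = read_genes(config.gene_path)
    lincrna = read_intervals(config.lincrna_path)
    genome = read_fasta(config.fasta_path) if config.fasta_path else None
    pfm = read_pfm(config.pfm_path) if config.pfm_path else default_tata_pfm()
    return promoters, track, second, cpg, repeats, genes, lincrna, genome, pfm


@_stage("cluster")
def _cluster_track(promoters, track, config: PipelineConfig) -> tuple[ClusterResult, dict]:
    scores = average_replicates(track)
    profiles = binned_profiles(promoters, scores, config.n_bins, config.bin_size)
    cdfs = cumulative_profiles(profiles)
    dm = build_distance_matrix(cdfs)
    result = k_medoids(dm, k=config.k, seed=config.seed)
    result = label_clusters(result, profiles)
    return result, profiles


def run(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and return the structured report."""
    promoters, track, second, cpg, repeats, genes, lincrna, genome, pfm = _load_inputs(
        config
    )
    log.info("loaded %d promoters, %d probes", len(promoters), track.n_probes)

    try:
        kept, report_prox = filter_proximal(promoters, config.radius)
        kept, report_cov = filter_bin_coverage(
            kept, track, config.n_bins, config.bin_size
        )
        if second is not None:
            # both clusterings run on one promoter universe, so coverage must
            # hold on both tracks
            kept, report_cov2 = filter_bin_coverage(
                kept, second, config.n_bins, config.bin_size
            )
            report_cov = report_cov.merge(report_cov2)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("filter", exc) from exc
    filter_report: FilterReport = report_prox.merge(report_cov)
    log.info(
        "filtering: %d -> %d (proximal) -> %d (coverage)",
        filter_report.n_input,
        filter_report.n_after_proximal,
        filter_report.n_after_coverage,
    )
    if len(kept) < max(2, config.k):
        raise StageError("filter", ValueError("too few promoters survive filtering"))

    result, profiles = _cluster_track(kept, track, config)

    try:
        annotations = annotate_promoters(
            kept,
            cpg,
            repeats,
            genes,
            lincrna,
            genome=genome,
            tata_pfm=pfm,
            gene_window=config.gene_window,
            tata_window=config.tata_window,
            tata_threshold=config.tata_threshold,
        )
        ann = annotations_frame(annotations)
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    try:
        labels = {pid: result.label_of(pid) for pid in result.assignment}
        tables, tests = {}, {}
        testable = [f for f in BINARY_FEATURES if f != "tata" or ann["tata"].notna().all()]
        for feature in testable:
            table = feature_by_cluster_table(labels, ann, feature)
            tables[feature] = {
                "rows": list(table.index),
                "columns": list(table.columns),
                "cells": table.values.astype(int).tolist(),
            }
            if (table.values.sum(axis=0) > 0).all() and (table.values.sum(axis=1) > 0).all():
                tests[feature] = chi_square_test(table.values).corrected(len(testable)).to_dict()
        # SP × TATA enrichment (architecture against the TATA flag), 2×2
        if ann["tata"].notna().all():
            sp = ann["architecture"] == "SP"
            tata = ann["tata"].astype(bool)
            cells = np.array(
                [
                    [int((sp & tata).sum()), int((sp & ~tata).sum())],
                    [int((~sp & tata).sum()), int((~sp & ~tata).sum())],
                ]
            )
            if (cells.sum(axis=0) > 0).all() and (cells.sum(axis=1) > 0).all():
                tests["sp_x_tata"] = fisher_exact(cells).corrected(1).to_dict()

        tiers = expression_tiers(
            kept, config.timepoint, config.tier_fraction, strict=False
        )
        repeat_fractions = repeat_fraction_by_tier(tiers, ann)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", exc) from exc

    cross_tab = None
    if second is not None:
        second_result, _ = _cluster_track(kept, second, config)
        table = cross_tabulate_clusterings(result, second_result)
        cross_tab = {
            "rows": list(table.index),
            "columns": list(table.columns),
            "cells": table.values.astype(int).tolist(),
        }

    sizes = {str(k): v for k, v in sorted(result.sizes().items(), key=lambda kv: str(kv[0]))}
    report = RunReport(
        filter=filter_report.to_dict(),
        cluster_sizes=sizes,
        assignments={pid: str(result.label_of(pid)) for pid in sorted(result.assignment)},
        medoids=list(result.medoid_ids),
        objective=result.objective,
        feature_tests=tests,
        feature_tables=tables,
        tiers={
            "timepoint": tiers.timepoint,
            "n_low": tiers.n_low,
            "n_high": tiers.n_high,
            "low_max_tpm": tiers.low_max_tpm,
            "high_min_tpm": tiers.high_min_tpm,
            "tier_by_id": dict(sorted(tiers.tier_by_id.items())),
        },
        repeat_fraction_by_tier=repeat_fractions,
        cross_tabulation=cross_tab,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    return report


def write_report(report: RunReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def read_report(path) -> RunReport:
    data = json.loads(Path(path).read_text())
    return RunReport(**data)


def compare_timepoints(report_a: RunReport, report_b: RunReport) -> dict:
    """Per-promoter cluster-label agreement (after optimal label matching)
    and per-feature test concordance between two runs."""
    ids_a, ids_b = set(report_a.assignments), set(report_b.assignments)
    if ids_a != ids_b:
        raise ValueError("reports cover different promoter universes")
    labels_a = report_a.assignments
    labels_b = report_b.assignments
    names = sorted({*labels_a.values(), *labels_b.values()})
    best_rate, best_perm = -1.0, None
    for perm in itertools.permutations(names):
        mapping = dict(zip(names, perm))
        hits = sum(1 for pid in labels_a if mapping[labels_b[pid]] == labels_a[pid])
        rate = hits / len(labels_a)
        if rate > best_rate:
            best_rate, best_perm = rate, mapping
    features = sorted(set(report_a.feature_tests) & set(report_b.feature_tests))
    concordance = {
        f: {
            "p_a": report_a.feature_tests[f]["p"],
            "p_b": report_b.feature_tests[f]["p"],
            "both_significant_0.05": bool(
                report_a.feature_tests[f]["p"] < 0.05
                and report_b.feature_tests[f]["p"] < 0.05
            ),
        }
        for f in features
    }
    return {
        "label_agreement": best_rate,
        "label_matching": best_perm,
        "feature_concordance": concordance,
    }
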