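"""End-to-end orchestration of the single and time-series clustering branches.

The full protocol chains every stage: counts -> low-abundance
filter -> relative abundances -> (a) per-sample Euclidean distances or
(b) per-series DTW distances -> kNN -> shared-nearest-neighbor Jaccard
similarity -> Ward's linkage with automatic gap cut and greedy-modularity
community detection -> NMI of the two clusterers against each other and
against the true labels.  It runs on the total dataset in species mode
(minimum 2 clusters) and on each species-specific slice in individual
mode (solutions with two or fewer clusters are discarded, minimum 3),
then attributes the separations to families with LASSO and summarises
core/persistent taxa per series.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution, clustering, data_io, evaluation, similarity
from .attribution import LassoConfig, LassoSelection
from .clustering import Labeling, labeling_from_assignment
from .data_io import AbundanceTable, CountTable, MicrobiotaSeries, SampleRecord
from .evaluation import ClusteringReport, ReportRow, build_report
from .synthetic_data import GeneratorConfig, GroundTruth, generate_dataset

logger = logging.getLogger(__name__)

APPROACHES = ("single", "timeseries", "both")


def derived_min_clusters(label_mode: str) -> int:
    """2 clusters allowed when species are sought, else at least 3."""
    return 2 if label_mode == "species" else 3


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Either ``counts_path``/``metadata_path`` or a ``generator`` config
    must be provided.  ``min_clusters=None`` derives the default rule
    from the label mode (2 for species, 3 otherwise).
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    taxa_as_rows: bool = False
    generator: GeneratorConfig | None = None
    approach: str = "both"
    label_mode: str = "species"
    min_total: int = 10
    knn_k: int | None = None
    dtw_band: int | None = None
    dtw_normalize: bool = False
    min_clusters: int | None = None
    nmi_norm: str = "sqrt"
    lasso: LassoConfig = field(default_factory=LassoConfig)
    presence_threshold: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        has_files = self.counts_path is not None and self.metadata_path is not None
        if not has_files and self.generator is None:
            raise ValueError("provide counts_path+metadata_path or a generator config")
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.label_mode not in data_io.LABEL_MODES:
            raise ValueError(f"label_mode must be one of {data_io.LABEL_MODES}")
        if self.nmi_norm not in evaluation.NMI_NORMS:
            raise ValueError(f"nmi_norm must be one of {evaluation.NMI_NORMS}")

    def resolved_min_clusters(self) -> int:
        return (
            self.min_clusters
            if self.min_clusters is not None
            else derived_min_clusters(self.label_mode)
        )


def load_inputs(
    cfg: RunConfig,
) -> tuple[CountTable, list[SampleRecord], GroundTruth | None]:
    """Read counts and metadata from disk, or draw them from the generator."""
    cfg.validate()
    if cfg.counts_path is not None and cfg.metadata_path is not None:
        table = data_io.read_count_table(cfg.counts_path, taxa_as_rows=cfg.taxa_as_rows)
        records = data_io.read_metadata(cfg.metadata_path)
        logger.info(
            "loaded %d samples x %d families from %s",
            *table.shape,
            cfg.counts_path,
        )
        return table, records, None
    gen = dataclasses.replace(cfg.generator, seed=cfg.generator.seed)
    table, records, truth = generate_dataset(gen)
    return table, records, truth


# ---------------------------------------------------------------------------
# shared clustering core


def _cluster_distance_matrix(
    D: similarity.DistanceMatrix,
    true_assignments: Mapping[str, Mapping[str, str]],
    mode: str,
    *,
    slice_name: str,
    approach: str,
    knn_k: int | None,
    min_clusters: int,
    nmi_norm: str,
) -> tuple[ClusteringReport, dict[str, Labeling]]:
    k = knn_k if knn_k is not None else similarity.default_knn_k(len(D))
    logger.info(
        "[%s/%s] distance matrix %dx%d -> kNN (k=%d) -> Jaccard",
        approach,
        slice_name,
        len(D),
        len(D),
        k,
    )
    neighbors = similarity.knn_neighbor_sets(D, k)
    S = similarity.jaccard_from_neighbors(neighbors)
    dend = clustering.ward_linkage(clustering.similarity_to_dissimilarity(S))
    ward = clustering.cut_by_height_gap(dend, min_clusters)
    com = clustering.community_detection(S)
    labelings = {"ward": ward, "community": com}
    true_labelings = {
        m: labeling_from_assignment(D.item_ids, assignment, mode=m)
        for m, assignment in true_assignments.items()
    }
    report = build_report(
        labelings,
        true_labelings,
        mode,
        slice_name=slice_name,
        approach=approach,
        nmi_norm=nmi_norm,
    )
    row = report.rows[0]
    logger.info(
        "[%s/%s] ward k=%d com k=%d | NMI com/ward=%.3f ward/true=%.3f com/true=%.3f",
        approach,
        slice_name,
        row.n_clusters_ward,
        row.n_clusters_com,
        row.nmi_com_ward,
        row.nmi_ward_true,
        row.nmi_com_true,
    )
    return report, labelings


def _prepare_slice(
    table: CountTable,
    records: Sequence[SampleRecord],
    species: str | None,
    min_total: int,
) -> tuple[AbundanceTable, list[SampleRecord]]:
    """Restrict to one species (or keep all), then re-filter and re-normalise."""
    if species is None:
        subset, kept = table, list(records)
    else:
        kept = [r for r in records if r.species_label == species]
        wanted = {r.sample_id for r in kept}
        rows = [i for i, s in enumerate(table.sample_ids) if s in wanted]
        subset = CountTable(
            tuple(table.sample_ids[i] for i in rows), table.family_ids, table.counts[rows]
        )
    filtered = data_io.filter_low_abundance(subset, min_total)
    return data_io.to_relative_abundance(filtered), kept


def _series_true_assignments(
    series_list: Sequence[MicrobiotaSeries],
) -> dict[str, dict[str, str]]:
    return {
        "species": {s.series_id: s.species_label for s in series_list},
        "individual": {s.series_id: s.individual_id for s in series_list},
        "site": {s.series_id: s.site_id for s in series_list},
    }


def _sample_true_assignments(
    records: Sequence[SampleRecord],
) -> dict[str, dict[str, str]]:
    return {
        mode: data_io.labels_from_records(records, mode)
        for mode in data_io.LABEL_MODES
    }


# ---------------------------------------------------------------------------
# public entry points


def run_single_clustering(
    cfg: RunConfig, *, species: str | None = None
) -> ClusteringReport:
    """Single-sample branch: every sample clustered individually."""
    table, records, _ = load_inputs(cfg)
    report, _ = single_clustering(
        table,
        records,
        label_mode=cfg.label_mode,
        species=species,
        min_total=cfg.min_total,
        knn_k=cfg.knn_k,
        min_clusters=cfg.resolved_min_clusters(),
        nmi_norm=cfg.nmi_norm,
    )
    return report


def single_clustering(
    table: CountTable,
    records: Sequence[SampleRecord],
    *,
    label_mode: str,
    species: str | None = None,
    min_total: int = 10,
    knn_k: int | None = None,
    min_clusters: int | None = None,
    nmi_norm: str = "sqrt",
) -> tuple[ClusteringReport, dict[str, Labeling]]:
    abundances, kept = _prepare_slice(table, records, species, min_total)
    D = similarity.sample_distance_matrix(abundances)
    return _cluster_distance_matrix(
        D,
        _sample_true_assignments(kept),
        label_mode,
        slice_name=species or "total",
        approach="single",
        knn_k=knn_k,
        min_clusters=(
            min_clusters if min_clusters is not None else derived_min_clusters(label_mode)
        ),
        nmi_norm=nmi_norm,
    )


def run_timeseries_clustering(
    cfg: RunConfig, *, species: str | None = None
) -> ClusteringReport:
    """Time-series branch: whole per-individual series compared via DTW."""
    table, records, _ = load_inputs(cfg)
    report, _ = timeseries_clustering(
        table,
        records,
        label_mode=cfg.label_mode,
        species=species,
        min_total=cfg.min_total,
        knn_k=cfg.knn_k,
        dtw_band=cfg.dtw_band,
        dtw_normalize=cfg.dtw_normalize,
        min_clusters=cfg.resolved_min_clusters(),
        nmi_norm=cfg.nmi_norm,
    )
    return report


def timeseries_clustering(
    table: CountTable,
    records: Sequence[SampleRecord],
    *,
    label_mode: str,
    species: str | None = None,
    min_total: int = 10,
    knn_k: int | None = None,
    dtw_band: int | None = None,
    dtw_normalize: bool = False,
    min_clusters: int | None = None,
    nmi_norm: str = "sqrt",
) -> tuple[ClusteringReport, dict[str, Labeling]]:
    abundances, kept = _prepare_slice(table, records, species, min_total)
    series_list = data_io.assemble_series(abundances, kept)
    if len(series_list) < 2:
        raise ValueError("time-series clustering needs at least 2 series")
    D = similarity.series_distance_matrix(
        series_list, band=dtw_band, normalize=dtw_normalize
    )
    return _cluster_distance_matrix(
        D,
        _series_true_assignments(series_list),
        label_mode,
        slice_name=species or "total",
        approach="timeseries",
        knn_k=knn_k,
        min_clusters=(
            min_clusters if min_clusters is not None else derived_min_clusters(label_mode)
        ),
        nmi_norm=nmi_norm,
    )


@dataclass(frozen=True)
class ProtocolResult:
    """Everything the full protocol produces: the per-slice report table,
    the raw labelings, the three LASSO selections and the per-series
    taxon summary."""

    report: ClusteringReport
    labelings: dict[tuple[str, str], dict[str, Labeling]]  # (approach, slice) -> clusterer
    selections: dict[str, LassoSelection]  # "species" or f"individual:{species}"
    taxon_summary: pd.DataFrame
    truth: GroundTruth | None = None


def run_full_protocol(cfg: RunConfig) -> ProtocolResult:
    """Both branches on the total (species mode) and per-species slices
    (individual mode), plus LASSO attribution and taxon summaries."""
    cfg.validate()
    table, records, truth = load_inputs(cfg)
    species_labels = list(dict.fromkeys(r.species_label for r in records))

    report: ClusteringReport | None = None
    labelings: dict[tuple[str, str], dict[str, Labeling]] = {}

    approaches = ("single", "timeseries") if cfg.approach == "both" else (cfg.approach,)
    slices: list[tuple[str | None, str]] = [(None, "species")]
    slices += [(sp, "individual") for sp in species_labels]

    for approach in approaches:
        for species, mode in slices:
            runner = single_clustering if approach == "single" else timeseries_clustering
            kwargs = dict(
                label_mode=mode,
                species=species,
                min_total=cfg.min_total,
                knn_k=cfg.knn_k,
                min_clusters=(
                    cfg.min_clusters
                    if cfg.min_clusters is not None
                    else derived_min_clusters(mode)
                ),
                nmi_norm=cfg.nmi_norm,
            )
            if approach == "timeseries":
                kwargs.update(dtw_band=cfg.dtw_band, dtw_normalize=cfg.dtw_normalize)
            part, labs = runner(table, records, **kwargs)
            labelings[(approach, species or "total")] = labs
            report = part if report is None else report.merged(part)

    # LASSO attribution from the true labels: species over the total
    # dataset, individuals within each species slice
    lasso_cfg = dataclasses.replace(cfg.lasso, seed=cfg.seed)
    selections: dict[str, LassoSelection] = {}
    total_ab, total_records = _prepare_slice(table, records, None, cfg.min_total)
    species_of = data_io.labels_from_records(total_records, "species")
    ind_of = {r.sample_id: r.individual_id for r in total_records}
    y_species = [species_of[s] for s in total_ab.sample_ids]
    # hold out whole individuals: longitudinal samples are not independent
    g_ind = [ind_of[s] for s in total_ab.sample_ids]
    selections["species"] = attribution.lasso_select(
        total_ab, y_species, lasso_cfg, groups=g_ind
    )
    for sp in species_labels:
        ab, kept = _prepare_slice(table, records, sp, cfg.min_total)
        y_ind = [data_io.labels_from_records(kept, "individual")[s] for s in ab.sample_ids]
        selections[f"individual:{sp}"] = attribution.lasso_select(ab, y_ind, lasso_cfg)

    series_list = data_io.assemble_series(total_ab, total_records)
    taxon_summary = attribution.summarize_series(series_list, cfg.presence_threshold)

    assert report is not None
    return ProtocolResult(
        report=report,
        labelings=labelings,
        selections=selections,
        taxon_summary=taxon_summary,
        truth=truth,
    )


def write_protocol_outputs(result: ProtocolResult, outdir: str | Path) -> None:
    """Persist the protocol bundle as deterministic TSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.write_tsv(outdir / "report.tsv")
    result.report.write_json(outdir / "report.json")
    for (approach, slice_name), labs in result.labelings.items():
        for clusterer, labeling in labs.items():
            labeling.write_tsv(outdir / f"labels_{approach}_{slice_name}_{clusterer}.tsv")
    for key, sel in result.selections.items():
        sel.write_tsv(outdir / f"lasso_{key.replace(':', '_')}.tsv")
    result.taxon_summary.to_csv(
        outdir / "taxon_summary.tsv", sep="\t", index=False, encoding="utf-8"
    )
    logger.info("protocol outputs written to %s", outdir)
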