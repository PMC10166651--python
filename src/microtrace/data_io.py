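"""Reading, validation, filtering and normalisation of longitudinal taxon tables.

The analytical unit is a samples x families table of 16S read counts
(rows = fecal samples, columns = taxa, typically bacterial families)
plus a metadata table linking each sample to a species, an individual,
a site (zoo), a sampling series and a day index within that series.
Counts are normalised to per-sample relative abundances before any
distance computation; per-individual day-by-day series are assembled
from the metadata for the time-series clustering branch.

All files are plain UTF-8 TSV so the artifact has no binary format
dependency.  Row labels are treated as opaque taxon identifiers: the
pipeline is agnostic to taxonomic rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance on relative-abundance row sums
ROW_SUM_TOL = 1e-9

METADATA_COLUMNS = ("sample_id", "species", "individual", "site", "series", "day")

LABEL_MODES = ("species", "individual", "site")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class CountTable:
    """Integer read counts, orientation samples x families.

    A sample with an all-zero row is tolerated here (it can arise from an
    aggressive abundance filter) but rejected by
    :func:`to_relative_abundance`, which is the first consumer that needs
    a nonzero total.
    """

    sample_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.family_ids, "family")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.family_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.family_ids)} families"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            finite = np.isfinite(counts.astype(float))
            if not finite.all():
                i, j = np.argwhere(~finite)[0]
                raise ValueError(
                    f"non-numeric count at sample {self.sample_ids[i]!r}, "
                    f"family {self.family_ids[j]!r}"
                )
            if np.any(counts != np.floor(counts)):
                i, j = np.argwhere(counts != np.floor(counts))[0]
                raise ValueError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, family {self.family_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count {counts[i, j]} at sample {self.sample_ids[i]!r}, "
                f"family {self.family_ids[j]!r}"
            )
        zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
        if zero_rows.size:
            logger.warning(
                "%d sample(s) have zero total counts (first: %s)",
                zero_rows.size,
                self.sample_ids[zero_rows[0]],
            )
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.family_ids)
        )


@dataclass(frozen=True)
class AbundanceTable:
    """Relative abundances in [0, 1]; every row sums to 1 within ``ROW_SUM_TOL``."""

    sample_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.family_ids, "family")
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.sample_ids), len(self.family_ids)):
            raise ValueError("proportions shape does not match ids")
        if np.any(~np.isfinite(props)) or np.any(props < 0) or np.any(props > 1):
            raise ValueError("proportions must be finite and within [0, 1]")
        sums = props.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"row for sample {self.sample_ids[i]!r} sums to {sums[i]!r}, not 1"
            )
        object.__setattr__(self, "proportions", props)

    @property
    def shape(self) -> tuple[int, int]:
        return self.proportions.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=list(self.sample_ids), columns=list(self.family_ids)
        )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one fecal sample."""

    sample_id: str
    species_label: str
    individual_id: str
    site_id: str
    series_id: str
    day_index: int

    def __post_init__(self) -> None:
        if int(self.day_index) != self.day_index or self.day_index < 1:
            raise ValueError(
                f"day_index must be a positive integer, got {self.day_index!r} "
                f"for sample {self.sample_id!r}"
            )
        object.__setattr__(self, "day_index", int(self.day_index))


@dataclass(frozen=True)
class MicrobiotaSeries:
    """One individual's ordered day-by-day relative-abundance profiles.

    Days missing from the collection are simply absent: profile rows are
    ordered by ``day_indices`` and the series may be shorter than the
    nominal collection window.  Downstream DTW absorbs unequal lengths.
    """

    series_id: str
    individual_id: str
    species_label: str
    site_id: str
    day_indices: tuple[int, ...]
    family_ids: tuple[str, ...]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.day_indices)
        if len(days) == 0:
            raise ValueError(f"series {self.series_id!r} has no sampled days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"day indices of series {self.series_id!r} must increase")
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.shape != (len(days), len(self.family_ids)):
            raise ValueError(
                f"profiles shape {profiles.shape} does not match "
                f"{len(days)} days x {len(self.family_ids)} families"
            )
        sums = profiles.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            raise ValueError(f"profile rows of series {self.series_id!r} must sum to 1")
        object.__setattr__(self, "day_indices", days)
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        object.__setattr__(self, "profiles", profiles)

    def __len__(self) -> int:
        return len(self.day_indices)


# ---------------------------------------------------------------------------
# feature-table I/O


def read_count_table(path: str | Path, *, taxa_as_rows: bool = False) -> CountTable:
    """Read a tab-separated feature table of integer counts.

    By default the first column holds sample ids and the header holds
    family ids; ``taxa_as_rows=True`` accepts the transposed orientation
    common in amplicon exports.  The returned table is always samples x
    families and preserves the input ordering.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if taxa_as_rows:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    family_ids = [str(f) for f in df.columns]
    _check_unique(sample_ids, "sample")
    _check_unique(family_ids, "family")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric count {df.iat[i, j]!r} at sample {sample_ids[i]!r}, "
            f"family {family_ids[j]!r}"
        )
    return CountTable(tuple(sample_ids), tuple(family_ids), numeric.to_numpy())


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV (samples as rows, deterministic order)."""
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# metadata I/O


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata (TSV: sample_id, species, individual, site, series, day)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {', '.join(missing)}")
    if not np.issubdtype(df["day"].dtype, np.integer):
        raise ValueError("metadata column 'day' must contain integers")
    records = [
        SampleRecord(
            sample_id=str(row.sample_id),
            species_label=str(row.species),
            individual_id=str(row.individual),
            site_id=str(row.site),
            series_id=str(row.series),
            day_index=int(row.day),
        )
        for row in df.itertuples(index=False)
    ]
    validate_records(records)
    return records


def validate_records(records: Sequence[SampleRecord]) -> None:
    _check_unique([r.sample_id for r in records], "sample")
    seen: set[tuple[str, int]] = set()
    last_day: dict[str, int] = {}
    for r in records:
        key = (r.series_id, r.day_index)
        if key in seen:
            raise ValueError(f"duplicate (series, day) pair: {key!r}")
        seen.add(key)
        if r.series_id in last_day and r.day_index <= last_day[r.series_id]:
            raise ValueError(
                f"day indices of series {r.series_id!r} must be strictly increasing "
                f"in collection order (day {r.day_index} after {last_day[r.series_id]})"
            )
        last_day[r.series_id] = r.day_index


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "species": [r.species_label for r in records],
            "individual": [r.individual_id for r in records],
            "site": [r.site_id for r in records],
            "series": [r.series_id for r in records],
            "day": [r.day_index for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def labels_from_records(
    records: Sequence[SampleRecord], mode: str
) -> dict[str, str]:
    """Map sample_id -> true label for a label mode (species | individual | site)."""
    if mode not in LABEL_MODES:
        raise ValueError(f"unknown label mode {mode!r}; expected one of {LABEL_MODES}")
    attr = {"species": "species_label", "individual": "individual_id", "site": "site_id"}[mode]
    return {r.sample_id: getattr(r, attr) for r in records}


# ---------------------------------------------------------------------------
# filtering, normalisation, series assembly


def filter_low_abundance(table: CountTable, min_total: int = 10) -> CountTable:
    """Drop families whose dataset-wide total is below ``min_total`` reads.

    The default of 10 reads reproduces the conventional low-abundance
    cutoff for amplicon feature tables.  The retained family set is
    exactly those with a column sum >= ``min_total``; the sample set is
    unchanged.  Idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.counts.sum(axis=0)
    keep = totals >= min_total
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all {len(table.family_ids)} families fall below min_total={min_total}; "
            "lower the threshold"
        )
    if n_removed:
        logger.info(
            "filter_low_abundance: removed %d of %d families (< %d reads)",
            n_removed,
            len(table.family_ids),
            min_total,
        )
    kept_ids = tuple(f for f, k in zip(table.family_ids, keep) if k)
    return CountTable(table.sample_ids, kept_ids, table.counts[:, keep])


def to_relative_abundance(table: CountTable) -> AbundanceTable:
    """Convert counts to per-sample proportions (each row divided by its sum)."""
    sums = table.counts.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count; "
            "cannot normalise to proportions"
        )
    props = table.counts / sums[:, None]
    return AbundanceTable(table.sample_ids, table.family_ids, props)


def assemble_series(
    table: AbundanceTable, records: Sequence[SampleRecord]
) -> list[MicrobiotaSeries]:
    """Group samples of one individual's sampling series into day-ordered profiles.

    Every sample in the table must carry a metadata record; series that
    match no table sample are dropped with a warning.  The result
    partitions the table's samples: each appears in exactly one series.
    """
    validate_records(records)
    by_sample = {r.sample_id: r for r in records}
    for sid in table.sample_ids:
        if sid not in by_sample:
            raise ValueError(f"sample {sid!r} has no metadata record")
    sample_index = {sid: i for i, sid in enumerate(table.sample_ids)}

    series_order: list[str] = []
    grouped: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.series_id not in grouped:
            grouped[r.series_id] = []
            series_order.append(r.series_id)
        if r.sample_id in sample_index:
            grouped[r.series_id].append(r)

    out: list[MicrobiotaSeries] = []
    for series_id in series_order:
        members = sorted(grouped[series_id], key=lambda r: r.day_index)
        if not members:
            logger.warning("series %s matches no sample in the table; omitted", series_id)
            continue
        rows = [sample_index[r.sample_id] for r in members]
        out.append(
            MicrobiotaSeries(
                series_id=series_id,
                individual_id=members[0].individual_id,
                species_label=members[0].species_label,
                site_id=members[0].site_id,
                day_indices=tuple(r.day_index for r in members),
                family_ids=table.family_ids,
                profiles=table.proportions[rows, :],
            )
        )
    return out
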