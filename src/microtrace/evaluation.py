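"""Agreement between labelings: normalized mutual information and reports.

NMI is computed from the label contingency table with natural
logarithms, NMI = I(a; b) / norm(H(a), H(b)).  The default normaliser is
the geometric mean sqrt(H(a) * H(b)); ``max`` and ``arithmetic`` are
available because published values can shift slightly between variants,
and the chosen normaliser is recorded in every report header.  Degenerate
partitions follow the explicit convention: two single-cluster labelings
agree perfectly (NMI 1), a single-cluster labeling against a non-trivial
one carries no information (NMI 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Labeling

NMI_NORMS = ("sqrt", "max", "arithmetic")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi_labels(a: Sequence, b: Sequence, norm: str = "sqrt") -> float:
    """NMI between two equal-length label sequences (cluster ids arbitrary)."""
    if norm not in NMI_NORMS:
        raise ValueError(f"unknown NMI normalisation {norm!r}; expected one of {NMI_NORMS}")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("labelings must be non-empty sequences of equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1.0)
    row = contingency.sum(axis=1)
    col = contingency.sum(axis=0)
    h_a = _entropy(row)
    h_b = _entropy(col)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    nz = contingency > 0
    # identical partitions up to renaming: exactly one nonzero per row and
    # column; short-circuit so nmi(a, a) is exactly 1
    if (nz.sum(axis=0) == 1).all() and (nz.sum(axis=1) == 1).all():
        return 1.0
    p = contingency[nz] / n
    outer = (row[:, None] * col[None, :])[nz] / (n * n)
    mi = float((p * np.log(p / outer)).sum())
    mi = max(mi, 0.0)
    normaliser = {
        "sqrt": np.sqrt(h_a * h_b),
        "max": max(h_a, h_b),
        "arithmetic": (h_a + h_b) / 2.0,
    }[norm]
    return float(min(mi / normaliser, 1.0))


def nmi(a: Labeling, b: Labeling, norm: str = "sqrt") -> float:
    """NMI between two Labelings over the same items in the same order."""
    if a.item_ids != b.item_ids:
        raise ValueError("labelings cover different item sets or orderings")
    return nmi_labels(a.labels, b.labels, norm=norm)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportRow:
    """One (dataset slice, approach) row of the clustering report."""

    slice_name: str  # "total" or a species label
    approach: str  # "single" | "timeseries"
    label_mode: str  # "species" | "individual" | "site"
    n_items: int
    nmi_com_ward: float
    nmi_ward_true: float
    nmi_com_true: float
    n_clusters_ward: int
    n_clusters_com: int


@dataclass(frozen=True)
class ClusteringReport:
    """Collection of report rows plus the NMI normalisation used."""

    rows: tuple[ReportRow, ...]
    nmi_norm: str = "sqrt"

    def __post_init__(self) -> None:
        for r in self.rows:
            for v in (r.nmi_com_ward, r.nmi_ward_true, r.nmi_com_true):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"NMI {v!r} outside [0, 1] in row {r!r}")
            if r.n_clusters_ward < 1 or r.n_clusters_com < 1:
                raise ValueError("cluster counts must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slice": r.slice_name,
                    "approach": r.approach,
                    "label_mode": r.label_mode,
                    "n_items": r.n_items,
                    "nmi_com_ward": r.nmi_com_ward,
                    "nmi_ward_true": r.nmi_ward_true,
                    "nmi_com_true": r.nmi_com_true,
                    "n_clusters_ward": r.n_clusters_ward,
                    "n_clusters_com": r.n_clusters_com,
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# nmi_norm={self.nmi_norm}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "nmi_norm": self.nmi_norm,
            "rows": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def merged(self, other: "ClusteringReport") -> "ClusteringReport":
        if other.nmi_norm != self.nmi_norm:
            raise ValueError("cannot merge reports with different NMI normalisations")
        return ClusteringReport(self.rows + other.rows, self.nmi_norm)


def build_report(
    labelings: Mapping[str, Labeling],
    true_labels: Mapping[str, Labeling],
    mode: str,
    *,
    slice_name: str = "total",
    approach: str = "single",
    nmi_norm: str = "sqrt",
) -> ClusteringReport:
    """Assemble one report row from the two clusterers and the true labels.

    ``labelings`` must provide keys ``"ward"`` and ``"community"``;
    ``true_labels`` maps label modes to the true Labeling of the same
    items.
    """
    for key in ("ward", "community"):
        if key not in labelings:
            raise ValueError(f"labelings is missing the {key!r} clusterer")
    if mode not in true_labels:
        raise ValueError(f"no true labels available for mode {mode!r}")
    ward = labelings["ward"]
    com = labelings["community"]
    truth = true_labels[mode]
    row = ReportRow(
        slice_name=slice_name,
        approach=approach,
        label_mode=mode,
        n_items=len(ward.item_ids),
        nmi_com_ward=nmi(com, ward, norm=nmi_norm),
        nmi_ward_true=nmi(ward, truth, norm=nmi_norm),
        nmi_com_true=nmi(com, truth, norm=nmi_norm),
        n_clusters_ward=ward.n_clusters,
        n_clusters_com=com.n_clusters,
    )
    return ClusteringReport((row,), nmi_norm)
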