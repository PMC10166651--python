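"""Which bacterial families drive the separations: LASSO and taxon summaries.

Given true labels (species, individual or site), an L1-penalised
multinomial logistic regression on z-standardised family proportions
selects the families that best discriminate the classes; the penalty
strength is chosen by stratified cross-validated deviance on a geometric
grid, and families with any nonzero coefficient at the chosen strength
form the selected set.  Complementing the model-based selection, simple
descriptive calls summarise each series: a family is a *core* taxon when
it appears in every consecutive sample of the series, a *persistent*
taxon when it is present on at least two consecutive sampling days, and
its abundance is reported as mean +/- sample standard deviation of the
daily percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .data_io import AbundanceTable, MicrobiotaSeries

logger = logging.getLogger(__name__)

#: coefficients of magnitude below this are treated as exact zeros
COEF_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class LassoConfig:
    """Cross-validated L1 logistic regression settings.

    ``c_grid`` is the inverse-regularisation grid (sklearn's C).
    ``selection_rule`` picks the strength from the held-out deviance
    curve: ``"1se"`` (default) takes the strongest penalty within one
    standard error of the best mean score, ``"min"`` takes the best mean
    score outright.  With few independent sampling series the CV curve
    is noisy and the plain minimum chases chance dips — it retains
    spurious features even for permuted labels — so the one-standard-error
    convention is the default.
    """

    n_folds: int = 5
    c_grid: tuple[float, ...] = tuple(np.geomspace(1e-3, 1e2, 21))
    selection_rule: str = "1se"
    max_iter: int = 30000
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_rule not in ("1se", "min"):
            raise ValueError("selection_rule must be '1se' or 'min'")


@dataclass(frozen=True)
class LassoSelection:
    """Outcome of the penalised fit: per-class coefficients over families
    (on the standardised scale) and the selected family set."""

    classes: tuple[str, ...]
    family_ids: tuple[str, ...]
    coefficients: np.ndarray  # (n_classes or 1, n_families), dropped features = 0
    selected: tuple[str, ...]
    c_chosen: float
    cv_scores: dict[float, float]  # C -> mean CV deviance score (higher is better)
    dropped_constant: tuple[str, ...] = ()

    def coefficient_frame(self) -> pd.DataFrame:
        index = list(self.classes) if self.coefficients.shape[0] > 1 else ["contrast"]
        return pd.DataFrame(self.coefficients, index=index, columns=list(self.family_ids))

    def write_tsv(self, path: str | Path) -> None:
        df = self.coefficient_frame().T
        df.index.name = "family_id"
        df["selected"] = [f in set(self.selected) for f in self.family_ids]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# model=multinomial_l1_logistic C={self.c_chosen:g}\n")
            df.to_csv(fh, sep="\t")


def lasso_select(
    X: AbundanceTable,
    y: Sequence[str],
    config: LassoConfig | None = None,
    *,
    groups: Sequence[str] | None = None,
) -> LassoSelection:
    """Select discriminating families by cross-validated L1 logistic regression.

    Proportions are z-standardised per family; constant families are
    dropped with a log note (their coefficients are reported as zero).
    Requires at least two classes with at least two samples each so the
    stratified folds are well defined.

    ``groups`` (typically the series id of each sample) makes the folds
    group-aware: all samples of one series are held out together.
    Longitudinal samples of the same individual are strongly dependent,
    so sample-level folds leak series identity into the held-out score
    and the CV-minimum rule then retains spurious features even for
    permuted labels.  Pass groups whenever the classes span multiple
    series (species or site labels); for individual labels each class is
    essentially one series, so grouping is neither possible nor needed.
    """
    config = config or LassoConfig()
    y = np.asarray([str(v) for v in y])
    if y.shape[0] != len(X.sample_ids):
        raise ValueError("y must provide one label per sample")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for feature selection")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer than 2 samples")

    props = X.proportions
    keep = props.std(axis=0) > 0
    dropped = tuple(f for f, k in zip(X.family_ids, keep) if not k)
    if dropped:
        logger.info("lasso_select: dropping %d constant families", len(dropped))
    if not keep.any():
        raise ValueError("all family columns are constant")
    Z = StandardScaler().fit_transform(props[:, keep])

    n_folds = min(config.n_folds, int(counts.min()))
    if groups is not None:
        groups = np.asarray([str(g) for g in groups])
        if groups.shape[0] != y.shape[0]:
            raise ValueError("groups must provide one entry per sample")
        n_folds = min(n_folds, np.unique(groups).size)
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=config.seed
        )
        cv = list(splitter.split(Z, y, groups))
    else:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    path = LogisticRegressionCV(
        Cs=list(config.c_grid),
        cv=cv,
        l1_ratios=(1.0,),  # pure L1 penalty
        solver="saga",
        scoring="neg_log_loss",
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
        refit=False,
        use_legacy_attributes=False,
    )
    path.fit(Z, y)

    # held-out deviance score per C, averaged over folds (higher is better)
    scores = np.asarray(path.scores_)[:, 0, :]  # (n_folds, n_Cs)
    mean_scores = scores.mean(axis=0)
    grid = np.asarray(path.Cs_)
    j_best = int(np.argmax(mean_scores))
    if config.selection_rule == "min":
        j = j_best
    else:
        se = scores.std(axis=0, ddof=1) / math.sqrt(scores.shape[0])
        # strongest penalty (smallest C) whose mean score is within 1 SE
        j = int(np.flatnonzero(mean_scores >= mean_scores[j_best] - se[j_best])[0])
    c_chosen = float(grid[j])

    model = LogisticRegression(
        C=c_chosen,
        l1_ratio=1.0,  # pure L1
        solver="saga",
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    )
    model.fit(Z, y)

    coef_kept = model.coef_.copy()
    coef_kept[np.abs(coef_kept) < COEF_ZERO_TOL] = 0.0
    coef = np.zeros((coef_kept.shape[0], len(X.family_ids)))
    coef[:, keep] = coef_kept
    selected = tuple(
        f for j2, f in enumerate(X.family_ids) if np.any(coef[:, j2] != 0.0)
    )
    cv_scores = {float(c): float(s) for c, s in zip(grid, mean_scores)}
    logger.info(
        "lasso_select: %d classes, rule=%s chose C=%g, selected %d/%d families",
        classes.size,
        config.selection_rule,
        c_chosen,
        len(selected),
        len(X.family_ids),
    )
    return LassoSelection(
        classes=tuple(str(c) for c in model.classes_),
        family_ids=X.family_ids,
        coefficients=coef,
        selected=selected,
        c_chosen=c_chosen,
        cv_scores=cv_scores,
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# descriptive taxon calls


def core_taxa(series: MicrobiotaSeries, presence_threshold: float = 0.0) -> set[str]:
    """Families exceeding the presence threshold on every sampled day."""
    present = series.profiles > presence_threshold
    core = present.all(axis=0)
    return {f for f, c in zip(series.family_ids, core) if c}


def persistent_taxa(series: MicrobiotaSeries, presence_threshold: float = 0.0) -> set[str]:
    """Families present on at least two consecutive sampling days.

    Consecutive means adjacent day indices (calendar days d and d + 1),
    not merely adjacent positions in the sample sequence; a family seen
    on days 1 and 3 only is not persistent even if day 2 was unsampled.
    """
    if len(series) < 2:
        logger.warning(
            "persistent_taxa: series %s has a single sample; returning empty set",
            series.series_id,
        )
        return set()
    present = series.profiles > presence_threshold
    days = np.asarray(series.day_indices)
    adjacent = np.flatnonzero(np.diff(days) == 1)
    persistent = np.zeros(len(series.family_ids), dtype=bool)
    for t in adjacent:
        persistent |= present[t] & present[t + 1]
    return {f for f, p in zip(series.family_ids, persistent) if p}


def abundance_summary(
    series: MicrobiotaSeries, presence_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-family mean +/- sd (percent) over the series' sampled days.

    Standard deviation uses the n - 1 denominator; a single-day series
    reports sd 0.00 and flags the convention in ``single_day``.
    """
    pct = series.profiles * 100.0
    mean = pct.mean(axis=0)
    single = len(series) < 2
    sd = np.zeros_like(mean) if single else pct.std(axis=0, ddof=1)
    core = core_taxa(series, presence_threshold)
    persistent = persistent_taxa(series, presence_threshold) if not single else set()
    return pd.DataFrame(
        {
            "series_id": series.series_id,
            "family_id": list(series.family_ids),
            "mean_pct": mean,
            "sd_pct": sd,
            "core": [f in core for f in series.family_ids],
            "persistent": [f in persistent for f in series.family_ids],
            "n_days": len(series),
            "single_day": single,
        }
    )


def summarize_series(
    series_list: Sequence[MicrobiotaSeries], presence_threshold: float = 0.0
) -> pd.DataFrame:
    """Concatenated abundance summaries for a collection of series."""
    frames = [abundance_summary(s, presence_threshold) for s in series_list]
    return pd.concat(frames, ignore_index=True)
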