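"""Synthetic longitudinal compositional microbiome datasets with planted truth.

The generator emulates a two-species zoo study design: a handful of
individuals per species, each sampled on up to eight consecutive days,
with a carnivore-like species occasionally skipping days (no daily
defecation).  Family-level structure is planted on three nested scales:

* species-core families shifted up by a fixed log-scale effect for every
  member of that species,
* individual-signature families with a per-individual random log-scale
  effect shared by both series of the same individual,
* day-to-day fluctuation as an AR(1) process on the log scale, plus a
  subset of sporadically present low-abundance families that drop to
  exact zero on random days.

For family ``f`` on day ``t`` of individual ``i`` of species ``s`` the
latent log-abundance is

    lambda = beta_f + sigma_species * 1[f in core(s)]
                    + u_{i,f}       * 1[f in signature(i)]
                    + v_{z,f} + eps_{t,f}

with ``beta_f ~ N(0,1)`` per dataset, ``u_{i,f} ~ N(0, sigma_individual)``,
``v_{z,f} ~ N(0, sigma_site)`` (off by default) and ``eps`` an AR(1)
process with lag-1 correlation ``rho_day`` and marginal sd ``sigma_day``.
Day profiles are the softmax of lambda over the families present that
day (a logistic-normal composition), and observed counts are multinomial
with a log-uniform sequencing depth.  Everything flows from one seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CountTable, SampleRecord

logger = logging.getLogger(__name__)

ROLE_SPECIES_CORE = "species_core"
ROLE_SIGNATURE = "individual_signature"
ROLE_SPORADIC = "sporadic"
ROLE_BACKGROUND = "background"
ROLES = (ROLE_SPECIES_CORE, ROLE_SIGNATURE, ROLE_SPORADIC, ROLE_BACKGROUND)


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the simulated study; defaults mirror the zoo design
    (2 species, 7 series each, up to 8 consecutive days, sequencing depth
    between 5,836 and 230,928 reads per sample)."""

    n_species: int = 2
    series_per_species: int = 7
    #: individuals per species; series beyond this count are second series
    #: of the first individuals (6 + 5 individuals -> 1 + 2 repeat series).
    #: ``None`` means one individual per series.
    individuals_per_species: tuple[int, ...] | None = (6, 5)
    n_days: int = 8
    n_families: int = 30
    families_core_per_species: int = 4
    families_signature_per_individual: int = 3
    sigma_species: float = 2.0
    sigma_individual: float = 1.0
    sigma_day: float = 0.5
    rho_day: float = 0.3
    sporadic_fraction: float = 0.2
    sporadic_presence_prob: float = 0.4
    miss_prob_per_species: tuple[float, ...] = (0.15, 0.0)
    depth_range: tuple[int, int] = (5836, 230928)
    sigma_site: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.series_per_species < 1:
            raise ValueError("n_species and series_per_species must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.families_core_per_species < 0 or self.families_signature_per_individual < 0:
            raise ValueError("per-species/per-individual family counts must be >= 0")
        n_core = self.n_species * self.families_core_per_species
        n_sporadic = self._n_sporadic()
        if n_core + n_sporadic > self.n_families:
            raise ValueError(
                f"{n_core} core + {n_sporadic} sporadic families exceed "
                f"n_families={self.n_families}"
            )
        if self.families_signature_per_individual > self._n_signature_pool():
            raise ValueError(
                f"families_signature_per_individual={self.families_signature_per_individual} "
                f"exceeds the {self._n_signature_pool()} signature-eligible families"
            )
        for name in ("sigma_species", "sigma_individual", "sigma_day", "sigma_site"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.rho_day) < 1:
            raise ValueError("|rho_day| must be < 1")
        for name in ("sporadic_fraction", "sporadic_presence_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        miss = self._miss_probs()
        if any(not 0 <= p <= 1 for p in miss):
            raise ValueError("miss probabilities must lie in [0, 1]")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be positive and ordered")
        inds = self._individuals_per_species()
        if len(inds) != self.n_species:
            raise ValueError("individuals_per_species length must equal n_species")
        if any(m < 1 or m > self.series_per_species for m in inds):
            raise ValueError(
                "individuals per species must lie in [1, series_per_species]"
            )
        if any(self.series_per_species > 2 * m for m in inds):
            raise ValueError("at most two series per individual are supported")

    def _n_sporadic(self) -> int:
        return int(round(self.sporadic_fraction * self.n_families))

    def _n_signature_pool(self) -> int:
        """Signature-eligible families: half of the non-core, non-sporadic
        pool (rounded up), so a comparable set of structure-free background
        families always remains."""
        pool = self.n_families - self.n_species * self.families_core_per_species - self._n_sporadic()
        if self.families_signature_per_individual == 0:
            return 0
        return min(pool, max(self.families_signature_per_individual, -(-pool // 2)))

    def _miss_probs(self) -> tuple[float, ...]:
        miss = self.miss_prob_per_species
        if isinstance(miss, (int, float)):
            return (float(miss),) * self.n_species
        if len(miss) == self.n_species:
            return tuple(float(p) for p in miss)
        if len(miss) == 1:
            return (float(miss[0]),) * self.n_species
        raise ValueError("miss_prob_per_species must have one entry per species")

    def _individuals_per_species(self) -> tuple[int, ...]:
        if self.individuals_per_species is None:
            return (self.series_per_species,) * self.n_species
        if len(self.individuals_per_species) != self.n_species:
            # permit the 2-species default under a different n_species only
            # when it can be broadcast sensibly
            raise ValueError("individuals_per_species length must equal n_species")
        return tuple(int(m) for m in self.individuals_per_species)


@dataclass(frozen=True)
class FamilyRole:
    """Planted role of one family: exactly one of the four categories."""

    family_id: str
    role: str
    species_label: str | None = None
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown family role {self.role!r}")


@dataclass(frozen=True)
class SeriesTruth:
    series_id: str
    individual_id: str
    species_label: str
    site_id: str


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels of a synthetic dataset: one row per series plus one
    role row per family (roles partition the family set)."""

    series: tuple[SeriesTruth, ...]
    family_roles: tuple[FamilyRole, ...]

    def __post_init__(self) -> None:
        ids = [fr.family_id for fr in self.family_roles]
        if len(set(ids)) != len(ids):
            raise ValueError("family roles must cover each family exactly once")

    def families_with_role(self, role: str, species_label: str | None = None) -> tuple[str, ...]:
        out = []
        for fr in self.family_roles:
            if fr.role != role:
                continue
            if species_label is not None and fr.species_label != species_label:
                continue
            out.append(fr.family_id)
        return tuple(out)

    @property
    def species_labels(self) -> tuple[str, ...]:
        seen = dict.fromkeys(s.species_label for s in self.series)
        return tuple(seen)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[CountTable, list[SampleRecord], GroundTruth]:
    """Draw one synthetic dataset; identical configs and seeds give
    identical output (a single ``numpy`` Generator drives every draw, in
    a fixed order)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_fam = config.n_families
    width = max(2, len(str(n_fam)))
    families = [f"F{i + 1:0{width}d}" for i in range(n_fam)]
    species_labels = [f"sp{s + 1}" for s in range(config.n_species)]

    # --- deterministic role layout: cores first, then sporadics, then the
    # signature/background pool (ids are arbitrary, so index order is fine)
    n_core_each = config.families_core_per_species
    core_idx = {
        s: list(range(s * n_core_each, (s + 1) * n_core_each))
        for s in range(config.n_species)
    }
    n_core_total = config.n_species * n_core_each
    n_sporadic = config._n_sporadic()
    sporadic_idx = list(range(n_core_total, n_core_total + n_sporadic))
    pool_idx = list(range(n_core_total + n_sporadic, n_fam))
    # only the first half of the pool is signature-eligible; the rest stays
    # background so false-selection rates can be measured against it
    sig_pool_idx = pool_idx[: config._n_signature_pool()]

    inds_per_species = config._individuals_per_species()
    miss_probs = config._miss_probs()

    # individuals and their series (repeat series go to the first individuals)
    individuals: list[tuple[int, str, str]] = []  # (species index, individual, site)
    series_plan: list[tuple[int, str, str, str]] = []  # (species idx, ind, site, series)
    for s in range(config.n_species):
        m = inds_per_species[s]
        ind_ids = [f"{species_labels[s]}_ind{j + 1}" for j in range(m)]
        sites = [f"zoo{j // 2 + 1}" for j in range(m)]
        for ind, site in zip(ind_ids, sites):
            individuals.append((s, ind, site))
            series_plan.append((s, ind, site, f"{ind}_ts1"))
        for j in range(config.series_per_species - m):
            series_plan.append((s, ind_ids[j], sites[j], f"{ind_ids[j]}_ts2"))

    # --- random draws, fixed order; effects are scaled standard normals so
    # that paired seeds stay coupled when a sigma changes
    beta = rng.standard_normal(n_fam)

    signature_idx: dict[str, np.ndarray] = {}
    u: dict[str, np.ndarray] = {}  # per individual, dense over families
    for _, ind, _ in individuals:
        if config.families_signature_per_individual:
            chosen = np.sort(
                rng.choice(sig_pool_idx, size=config.families_signature_per_individual, replace=False)
            )
        else:
            chosen = np.empty(0, dtype=np.int64)
        z = rng.standard_normal(chosen.size)
        signature_idx[ind] = chosen
        dense = np.zeros(n_fam)
        dense[chosen] = config.sigma_individual * z
        u[ind] = dense

    site_ids = sorted({site for _, _, site in individuals})
    v = {
        site: config.sigma_site * rng.standard_normal(n_fam) for site in site_ids
    }

    core_shift = {
        s: np.isin(np.arange(n_fam), core_idx[s]).astype(float) * config.sigma_species
        for s in range(config.n_species)
    }

    log_lo, log_hi = math.log(config.depth_range[0]), math.log(config.depth_range[1] + 1)

    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    count_rows: list[np.ndarray] = []

    for s, ind, site, series_id in series_plan:
        n_days = config.n_days
        # day availability (carnivore-like species may skip days entirely)
        missed = rng.random(n_days) < miss_probs[s]
        if missed.all():
            missed[0] = False  # a series always contributes at least one sample
        # AR(1) daily fluctuation with marginal sd sigma_day
        z = rng.standard_normal((n_days, n_fam))
        eps = np.empty((n_days, n_fam))
        eps[0] = config.sigma_day * z[0]
        innov_sd = config.sigma_day * math.sqrt(1.0 - config.rho_day**2)
        for t in range(1, n_days):
            eps[t] = config.rho_day * eps[t - 1] + innov_sd * z[t]
        # sporadic families present only on random days
        present = np.ones((n_days, n_fam), dtype=bool)
        if sporadic_idx:
            present[:, sporadic_idx] = (
                rng.random((n_days, len(sporadic_idx))) < config.sporadic_presence_prob
            )
        depths = np.exp(rng.uniform(log_lo, log_hi, n_days)).astype(np.int64)
        depths = np.clip(depths, config.depth_range[0], config.depth_range[1])

        lam = beta + core_shift[s] + u[ind] + v[site] + eps
        for t in range(n_days):
            if missed[t]:
                continue
            mask = present[t]
            if not mask.any():  # cannot happen unless every family is sporadic
                mask = np.ones(n_fam, dtype=bool)
            logits = np.where(mask, lam[t], -np.inf)
            logits = logits - logits.max()
            p = np.exp(logits)
            p /= p.sum()
            counts = rng.multinomial(int(depths[t]), p)
            day = t + 1
            sid = f"{series_id}_d{day}"
            sample_ids.append(sid)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    species_label=species_labels[s],
                    individual_id=ind,
                    site_id=site,
                    series_id=series_id,
                    day_index=day,
                )
            )
            count_rows.append(counts)

    table = CountTable(tuple(sample_ids), tuple(families), np.vstack(count_rows))

    roles: list[FamilyRole] = []
    sig_members = {
        f: tuple(ind for _, ind, _ in individuals if f in set(signature_idx[ind].tolist()))
        for f in range(n_fam)
    }
    for f in range(n_fam):
        fid = families[f]
        which_core = [s for s in range(config.n_species) if f in core_idx[s]]
        if which_core:
            roles.append(
                FamilyRole(fid, ROLE_SPECIES_CORE, species_label=species_labels[which_core[0]])
            )
        elif f in sporadic_idx:
            roles.append(FamilyRole(fid, ROLE_SPORADIC))
        elif sig_members[f]:
            roles.append(FamilyRole(fid, ROLE_SIGNATURE, individual_ids=sig_members[f]))
        else:
            roles.append(FamilyRole(fid, ROLE_BACKGROUND))

    truth = GroundTruth(
        series=tuple(
            SeriesTruth(series_id, ind, species_labels[s], site)
            for s, ind, site, series_id in series_plan
        ),
        family_roles=tuple(roles),
    )
    logger.info(
        "generated %d samples over %d series (%d families, seed=%d)",
        len(sample_ids),
        len(series_plan),
        n_fam,
        config.seed,
    )
    return table, records, truth


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialise ground truth as one TSV with a record_type discriminator."""
    rows = []
    for st in truth.series:
        rows.append(
            {
                "record_type": "series",
                "id": st.series_id,
                "role": "",
                "species": st.species_label,
                "individuals": st.individual_id,
                "site": st.site_id,
            }
        )
    for fr in truth.family_roles:
        rows.append(
            {
                "record_type": "family",
                "id": fr.family_id,
                "role": fr.role,
                "species": fr.species_label or "",
                "individuals": ";".join(fr.individual_ids),
                "site": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    series = []
    roles = []
    for row in df.itertuples(index=False):
        if row.record_type == "series":
            series.append(
                SeriesTruth(
                    series_id=row.id,
                    individual_id=row.individuals,
                    species_label=row.species,
                    site_id=row.site,
                )
            )
        elif row.record_type == "family":
            roles.append(
                FamilyRole(
                    family_id=row.id,
                    role=row.role,
                    species_label=row.species or None,
                    individual_ids=tuple(x for x in row.individuals.split(";") if x),
                )
            )
        else:
            raise ValueError(f"unknown record_type {row.record_type!r}")
    return GroundTruth(series=tuple(series), family_roles=tuple(roles))
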