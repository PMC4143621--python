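"""Null trait simulation: a polygenic quantitative trait and a random binary trait.

The quantitative trait is multivariate normal within each pedigree with mean
``trait_mean + age_mean_slope * age`` and covariance
``trait_sd**2 * (h2 * 2*Phi + (1 - h2) * I)`` where ``Phi`` is the kinship
matrix — the standard additive polygenic model, independent of all marker
genotypes by construction.  The binary traits are (a) the quantitative trait
dichotomized at a founder quantile, and (b) affection assigned at random with
a fixed prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Affection, PedigreeSet, kinship_matrix
from .synthetic_data import (
    STAGE_AFFECTION,
    STAGE_TRAIT,
    SimulationConfig,
    stage_rng,
)


@dataclass
class QuantitativeTraitReplicates:
    """Trait values, individuals x replicates, plus the generating parameters."""

    individual_ids: list[str]
    family_ids: list[str]
    ages: np.ndarray              # (n,) years; NaN when unknown
    values: np.ndarray            # (n, n_replicates)
    heritability: float
    age_mean_slope: float
    trait_sd: float
    trait_mean: float
    _row: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._row = {iid: k for k, iid in enumerate(self.individual_ids)}

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def value(self, individual_id: str, replicate: int) -> float:
        return float(self.values[self._row[individual_id], replicate])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: family, individual, replicate, value."""
        n, r = self.values.shape
        return pd.DataFrame(
            {
                "family_id": np.repeat(self.family_ids, r),
                "individual_id": np.repeat(self.individual_ids, r),
                "replicate": np.tile(np.arange(r), n),
                "value": self.values.ravel(),
            }
        )


@dataclass
class AffectionReplicates:
    """Affection codes (LINKAGE 0/1/2), individuals x replicates."""

    individual_ids: list[str]
    family_ids: list[str]
    codes: np.ndarray             # (n, n_replicates) int8 of Affection values
    cutoff: float | None = None   # dichotomization cutoff, when applicable
    _row: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._row = {iid: k for k, iid in enumerate(self.individual_ids)}

    @property
    def n_replicates(self) -> int:
        return self.codes.shape[1]

    def affection(self, individual_id: str, replicate: int) -> Affection:
        return Affection(int(self.codes[self._row[individual_id], replicate]))

    def replicate_map(self, replicate: int) -> dict[str, Affection]:
        col = self.codes[:, replicate]
        return {
            iid: Affection(int(col[k]))
            for k, iid in enumerate(self.individual_ids)
        }

    def affected_fraction(self, individual_ids=None) -> float:
        """Pooled fraction affected among known statuses, over all replicates."""
        codes = self.codes
        if individual_ids is not None:
            rows = [self._row[i] for i in individual_ids]
            codes = codes[rows]
        known = codes != Affection.UNKNOWN
        if not known.any():
            return float("nan")
        return float((codes[known] == Affection.AFFECTED).mean())


def _pedigree_ids_ages(peds: PedigreeSet):
    ids, fams, ages = [], [], []
    for p in peds:
        for ind in p:
            ids.append(ind.id)
            fams.append(p.family_id)
            ages.append(np.nan if ind.age is None else float(ind.age))
    return ids, fams, np.array(ages)


def simulate_polygenic_trait(
    peds: PedigreeSet, config: SimulationConfig
) -> QuantitativeTraitReplicates:
    """Draw ``n_replicates`` independent polygenic trait vectors per pedigree.

    Individuals with unknown age get the baseline mean.  Replicate ``r``
    draws only from the (seed, r) stream, so single replicates can be
    regenerated in isolation.
    """
    config.validate()
    h2 = config.heritability
    ids, fams, ages = _pedigree_ids_ages(peds)
    chols: list[np.ndarray] = []
    means: list[np.ndarray] = []
    for p in peds:
        phi2 = 2.0 * kinship_matrix(p).values
        cov = config.trait_sd**2 * (h2 * phi2 + (1.0 - h2) * np.eye(len(p)))
        try:
            chols.append(np.linalg.cholesky(cov))
        except np.linalg.LinAlgError:
            # valid kinship with h2 <= 1 keeps cov PD; guard with a jitter
            jitter = 1e-8 * config.trait_sd**2
            chols.append(np.linalg.cholesky(cov + jitter * np.eye(len(p))))
        a = np.array([np.nan if i.age is None else i.age for i in p], dtype=float)
        a = np.nan_to_num(a, nan=0.0)
        means.append(config.trait_mean + config.age_mean_slope * a)
    n = len(ids)
    values = np.empty((n, config.n_replicates))
    for r in range(config.n_replicates):
        rng = stage_rng(config.seed, STAGE_TRAIT, r)
        chunks = []
        for L, mu in zip(chols, means):
            z = rng.standard_normal(L.shape[0])
            chunks.append(mu + L @ z)
        values[:, r] = np.concatenate(chunks)
    return QuantitativeTraitReplicates(
        individual_ids=ids,
        family_ids=fams,
        ages=ages,
        values=values,
        heritability=h2,
        age_mean_slope=config.age_mean_slope,
        trait_sd=config.trait_sd,
        trait_mean=config.trait_mean,
    )


def dichotomize_by_founder_quantile(
    traits: QuantitativeTraitReplicates,
    peds: PedigreeSet,
    config: SimulationConfig,
) -> AffectionReplicates:
    """Affected = trait value strictly below the pooled founder quantile.

    A single cutoff is estimated as the ``founder_quantile`` quantile
    (linear-interpolation estimator) of founder values pooled across every
    available replicate, then applied to each replicate separately; missing
    values map to unknown affection.
    """
    founder_ids = [i.id for p in peds for i in p.founders()]
    if not founder_ids:
        raise ValueError("no founders with trait values; cannot set a cutoff")
    rows = [traits._row[i] for i in founder_ids if i in traits._row]
    if not rows:
        raise ValueError("no founders with trait values; cannot set a cutoff")
    pooled = traits.values[rows].ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no founders with trait values; cannot set a cutoff")
    cutoff = float(np.quantile(pooled, config.founder_quantile))
    codes = np.where(
        np.isnan(traits.values),
        np.int8(Affection.UNKNOWN),
        np.where(
            traits.values < cutoff,
            np.int8(Affection.AFFECTED),
            np.int8(Affection.UNAFFECTED),
        ),
    ).astype(np.int8)
    return AffectionReplicates(
        individual_ids=list(traits.individual_ids),
        family_ids=list(traits.family_ids),
        codes=codes,
        cutoff=cutoff,
    )


def assign_random_affection(
    peds: PedigreeSet, config: SimulationConfig
) -> AffectionReplicates:
    """Complete-null binary trait: i.i.d. affected with the configured prevalence."""
    config.validate()
    ids, fams, _ = _pedigree_ids_ages(peds)
    n = len(ids)
    codes = np.empty((n, config.n_replicates), dtype=np.int8)
    for r in range(config.n_replicates):
        rng = stage_rng(config.seed, STAGE_AFFECTION, r)
        aff = rng.random(n) < config.prevalence
        codes[:, r] = np.where(
            aff, np.int8(Affection.AFFECTED), np.int8(Affection.UNAFFECTED)
        )
    return AffectionReplicates(
        individual_ids=ids, family_ids=fams, codes=codes
    )


def estimate_heritability_from_sibs(
    traits: QuantitativeTraitReplicates, peds: PedigreeSet
) -> tuple[float, int]:
    """Recover h2 as twice the age-adjusted full-sib correlation.

    Under the additive polygenic model full sibs correlate at h2/2 once the
    age trend in the mean is removed.  Values are residualized on age by a
    pooled least-squares fit; one sib pair is taken per sibship (the first
    two children) so pairs are mutually independent and a Fisher-z interval
    on the correlation is valid; pairs are double-entered (both orders) and
    the Pearson correlation doubled.  Returns (h2_hat, n_pairs) where
    n_pairs counts pair-replicate observations.
    """
    ages = np.nan_to_num(traits.ages, nan=0.0)
    n, R = traits.values.shape
    X = np.column_stack([np.ones(n), ages])
    beta, *_ = np.linalg.lstsq(X, traits.values, rcond=None)
    resid = traits.values - X @ beta           # (n, R)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    n_pairs = 0
    for p in peds:
        for children in p.nuclear_families().values():
            rows = [traits._row[c] for c in children if c in traits._row]
            if len(rows) >= 2:
                xs.append(resid[rows[0]])
                ys.append(resid[rows[1]])
                n_pairs += R
    if not xs:
        raise ValueError("no full-sib pairs in the pedigree set")
    x = np.concatenate([np.concatenate(xs), np.concatenate(ys)])
    y = np.concatenate([np.concatenate(ys), np.concatenate(xs)])
    r = float(np.corrcoef(x, y)[0, 1])
    return 2.0 * r, n_pairs


def write_phenotype_table(
    traits: QuantitativeTraitReplicates | None,
    affections: AffectionReplicates,
    path,
) -> None:
    """Tab-separated: family, individual, replicate, value, affection code."""
    with open(path, "w") as fh:
        fh.write("family_id\tindividual_id\treplicate\tvalue\taffection\n")
        n, r = affections.codes.shape
        for k in range(n):
            iid = affections.individual_ids[k]
            fam = affections.family_ids[k]
            for rep in range(r):
                if traits is not None:
                    v = traits.values[traits._row[iid], rep]
                    vtxt = "NA" if np.isnan(v) else repr(float(v))
                else:
                    vtxt = "NA"
                fh.write(
                    f"{fam}\t{iid}\t{rep}\t{vtxt}\t{int(affections.codes[k, rep])}\n"
                )
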