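"""Synthetic study generator: extended pedigrees, gene-dropped markers, masks.

Emulates a family WGS linkage study at desk scale: ~20 multi-generation
pedigrees of 30-90 members, dense biallelic markers with a rare-variant-heavy
frequency spectrum, optional founder-haplotype LD blocks, and a fraction of
individuals (founders preferentially) with no genotype data.  Everything is
a pure function of (config, seed).

Seed-splitting rule: every stage draws from
``numpy.random.default_rng(SeedSequence(seed, spawn_key=(STAGE, index...)))``
with a fixed integer code per stage, so any stage (or any single replicate)
can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import GenotypeMatrix, MarkerInfo
from .pedigree import Individual, Pedigree, PedigreeSet, Sex

# stage codes for the seed-splitting rule
STAGE_PEDIGREE = 1
STAGE_MARKERS = 2
STAGE_GENEDROP = 3
STAGE_MASK = 4
STAGE_TRAIT = 5
STAGE_AFFECTION = 6


def stage_rng(seed: int, stage: int, *index: int) -> np.random.Generator:
    """Deterministic per-stage (and per-replicate) random stream."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(stage, *index))
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated study design: 20 extended pedigrees of
    30-90 members over 4 generations, a rare-variant-heavy marker spectrum
    (70% of markers with MAF below 1%), a null quantitative trait with
    heritability 0.68 whose mean decreases with age, dichotomization at the
    20% founder quantile, a 10% random-affection prevalence, and 50 trait
    replicates.  Markers default to effectively unlinked loci
    (``intermarker_spacing_cm`` large); dense maps with LD are obtained by
    shrinking the spacing and setting ``founder_haplotype_pool``.
    """

    n_pedigrees: int = 20
    pedigree_size_range: tuple[int, int] = (30, 90)
    n_generations: int = 4
    n_markers: int = 10_000
    # (proportion, (maf_low, maf_high)) mixture classes
    marker_maf_spectrum: tuple = ((0.7, (0.0, 0.01)), (0.3, (0.01, 0.5)))
    founder_haplotype_pool: int = 0
    ld_block_size: int = 20
    intermarker_spacing_cm: float = 1000.0
    ungenotyped_fraction: float = 0.3
    founder_mask_weight: float = 3.0
    heritability: float = 0.68
    age_mean_slope: float = -0.5
    trait_mean: float = 100.0
    trait_sd: float = 15.0
    prevalence: float = 0.10
    founder_quantile: float = 0.20
    n_replicates: int = 50
    seed: int = 0
    # pedigree growth parameters (children per couple = 1 + Poisson(rate))
    mean_extra_children: float = 2.8
    marry_prob: float = 0.65

    def validate(self) -> None:
        for name in (
            "ungenotyped_fraction", "heritability", "prevalence",
            "founder_quantile", "marry_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.pedigree_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad pedigree_size_range {self.pedigree_size_range}")
        for name in ("n_generations", "n_markers", "n_replicates"):
            if getattr(self, name) < 0 or (name == "n_generations" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        total = sum(p for p, _ in self.marker_maf_spectrum)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("marker_maf_spectrum proportions must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pedigree_size_range"] = list(self.pedigree_size_range)
        d["marker_maf_spectrum"] = [
            [p, list(rng)] for p, rng in self.marker_maf_spectrum
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pedigree_size_range" in d:
            d["pedigree_size_range"] = tuple(d["pedigree_size_range"])
        if "marker_maf_spectrum" in d:
            d["marker_maf_spectrum"] = tuple(
                (p, tuple(rng)) for p, rng in d["marker_maf_spectrum"]
            )
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator, generation: int) -> float:
    """Founder generation oldest (~90y), each later generation ~23y younger."""
    return float(np.clip(rng.normal(90.0 - 23.0 * generation, 6.0), 1.0, 105.0))


def _grow_pedigree(
    fam_id: str, config: SimulationConfig, rng: np.random.Generator
) -> Pedigree:
    ped = Pedigree(fam_id)
    serial = [0]

    def new_ind(sex: Sex, gen: int, father=None, mother=None) -> Individual:
        serial[0] += 1
        ind = Individual(
            id=f"{fam_id}_{serial[0]:03d}",
            family_id=fam_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
            age=_draw_age(rng, gen),
        )
        ped.add(ind)
        return ind

    pa = new_ind(Sex.MALE, 0)
    ma = new_ind(Sex.FEMALE, 0)
    couples = [(pa.id, ma.id)]
    for gen in range(1, config.n_generations):
        next_couples: list[tuple[str, str]] = []
        for fa, mo in couples:
            n_children = 1 + rng.poisson(config.mean_extra_children)
            for _ in range(n_children):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = new_ind(sex, gen, father=fa, mother=mo)
                last = gen == config.n_generations - 1
                if not last and rng.random() < config.marry_prob:
                    spouse = new_ind(
                        Sex.FEMALE if sex == Sex.MALE else Sex.MALE, gen
                    )
                    if sex == Sex.MALE:
                        next_couples.append((child.id, spouse.id))
                    else:
                        next_couples.append((spouse.id, child.id))
        couples = next_couples
    return ped


def generate_pedigree_set(config: SimulationConfig) -> PedigreeSet:
    """Loop-free multi-generation pedigrees with sizes in the configured range.

    Each pedigree grows from a single founder couple; married-in spouses are
    founders.  Growth is resampled until the size lands in range (an
    unreachable range raises after 1000 attempts).
    """
    config.validate()
    lo, hi = config.pedigree_size_range
    peds = []
    for k in range(config.n_pedigrees):
        rng = stage_rng(config.seed, STAGE_PEDIGREE, k)
        fam_id = f"F{k + 1:02d}"
        for attempt in range(1000):
            ped = _grow_pedigree(fam_id, config, rng)
            if lo <= len(ped) <= hi:
                break
        else:
            raise ValueError(
                f"could not grow a pedigree of {lo}-{hi} members in "
                f"{config.n_generations} generations; adjust the growth "
                "parameters"
            )
        ped.validate()
        peds.append(ped)
    return PedigreeSet(peds)


# ---------------------------------------------------------------------------
# Markers and gene dropping
# ---------------------------------------------------------------------------

def generate_markers(config: SimulationConfig) -> list[MarkerInfo]:
    """Marker map with the configured MAF mixture spectrum, one chromosome."""
    config.validate()
    rng = stage_rng(config.seed, STAGE_MARKERS)
    props = np.array([p for p, _ in config.marker_maf_spectrum])
    bounds = [b for _, b in config.marker_maf_spectrum]
    classes = rng.choice(len(props), size=config.n_markers, p=props)
    mafs = np.empty(config.n_markers)
    for ci, (mlo, mhi) in enumerate(bounds):
        sel = classes == ci
        mafs[sel] = rng.uniform(mlo, mhi, size=int(sel.sum()))
    return [
        MarkerInfo(
            marker_id=f"M{j + 1:06d}",
            chromosome="1",
            position_bp=1 + 10_000 * j,
            position_cm=j * config.intermarker_spacing_cm,
            true_maf=float(mafs[j]),
        )
        for j in range(config.n_markers)
    ]


def haldane_theta(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction from distance in cM."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cm, dtype=float)))


def _haplotype_pool(
    mafs: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray | None:
    """Population-level pool, (pool_n, n_markers); None when LD is off.

    The pool is drawn once and shared by the founders of every pedigree, so
    within-block LD is a property of the population, not of one family.
    Blocks are independent of each other.
    """
    if config.founder_haplotype_pool <= 0:
        return None
    return (
        rng.random((config.founder_haplotype_pool, len(mafs))) < mafs
    ).astype(np.int8)


def _founder_haplotypes(
    n_haps: int, mafs: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator, pool: np.ndarray | None,
) -> np.ndarray:
    """(n_haps, n_markers) 0/1 haplotypes; a pool induces LD blocks."""
    M = len(mafs)
    if pool is None:
        return (rng.random((n_haps, M)) < mafs).astype(np.int8)
    out = np.empty((n_haps, M), dtype=np.int8)
    for start in range(0, M, config.ld_block_size):
        stop = min(start + config.ld_block_size, M)
        picks = rng.integers(0, pool.shape[0], size=n_haps)
        out[:, start:stop] = pool[picks, start:stop]
    return out


def gene_drop_genotypes(
    peds: PedigreeSet,
    markers: list[MarkerInfo],
    config: SimulationConfig,
) -> GenotypeMatrix:
    """Drop founder alleles down every pedigree with recombination.

    Founder haplotypes are drawn from the population frequencies (or from a
    finite per-block haplotype pool when LD is requested); each meiosis
    recombines between adjacent markers with the Haldane fraction of their
    map distance (0.5 across chromosomes).  Dosages count minor alleles.
    """
    rng = stage_rng(config.seed, STAGE_GENEDROP)
    mafs = np.array([m.true_maf for m in markers], dtype=float)
    M = len(markers)
    cm = np.array([m.position_cm for m in markers])
    chrom = np.array([m.chromosome for m in markers])
    if M > 1:
        theta = haldane_theta(np.diff(cm))
        theta[chrom[1:] != chrom[:-1]] = 0.5
    else:
        theta = np.empty(0)

    pool = _haplotype_pool(mafs, config, rng)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    for ped in peds:
        order = ped.topological_order()
        founders = [i for i in order if ped[i].is_founder]
        fh = _founder_haplotypes(2 * len(founders), mafs, config, rng, pool)
        haps: dict[str, np.ndarray] = {}
        for k, fid in enumerate(founders):
            haps[fid] = fh[2 * k : 2 * k + 2]
        for iid in order:
            ind = ped[iid]
            if ind.is_founder:
                continue
            gametes = []
            for pid in (ind.father_id, ind.mother_id):
                parental = haps[pid]
                recomb = rng.random(M - 1) < theta if M > 1 else np.empty(0, bool)
                which = np.empty(M, dtype=np.intp)
                if M:
                    which[0] = rng.integers(0, 2)
                    np.bitwise_xor.accumulate(
                        np.concatenate(([which[0]], recomb.astype(np.intp))),
                        out=which,
                    )
                gametes.append(parental[which, np.arange(M)])
            haps[iid] = np.stack(gametes)
        for iid in ped.ids:
            samples.append(iid)
            rows.append(haps[iid].sum(axis=0, dtype=np.int8))
    dosages = (
        np.stack(rows) if rows else np.zeros((0, M), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, dosages)


def mask_ungenotyped(
    geno: GenotypeMatrix, peds: PedigreeSet, config: SimulationConfig
) -> GenotypeMatrix:
    """Blank out round(fraction x N) individuals, founders preferentially.

    Founders are ``founder_mask_weight`` times likelier to be masked than
    non-founders (emulating studies where many founders predate genotyping).
    Updates the ``genotyped`` flags on the pedigree members and returns a new
    matrix; the input matrix is untouched.
    """
    rng = stage_rng(config.seed, STAGE_MASK)
    out = geno.copy()
    n_total = out.n_samples
    n_mask = round(config.ungenotyped_fraction * n_total)
    founder_ids = {i.id for p in peds for i in p.founders()}
    weights = np.array(
        [config.founder_mask_weight if s in founder_ids else 1.0 for s in out.samples]
    )
    probs = weights / weights.sum()
    masked_idx = rng.choice(n_total, size=n_mask, replace=False, p=probs)
    masked = {out.samples[i] for i in masked_idx}
    out.dosages[masked_idx] = GenotypeMatrix.MISSING
    for p in peds:
        for ind in p:
            ind.genotyped = ind.id not in masked
    return out
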