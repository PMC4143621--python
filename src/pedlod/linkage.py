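"""Two-point parametric linkage: Elston-Stewart peeling and LOD scores.

The joint state of one individual is an ordered pair of two-locus haplotypes
(trait allele d/D x marker allele, 4 haplotypes, 16 ordered diplotypes).
Founder diplotypes follow linkage-equilibrium haplotype frequencies; each
meiosis transmits a parental haplotype with probability (1-theta)/2 and each
recombinant with theta/2; the trait locus acts through the penetrance vector
of a :class:`TraitModel` and the marker through an indicator of the observed
minor-allele dosage.  The pedigree likelihood is computed exactly on
loop-free pedigrees by peeling over the marriage graph, with per-step
rescaling so 90-member pedigrees at MAF 1e-4 stay in range.  LOD scores are
log10 L(theta) - log10 L(0.5).

:func:`brute_force_log_likelihood` is an independent enumeration oracle:
it sums the same factorization over every joint diplotype assignment with a
single unoptimized einsum (no peeling), and is the ground truth the peeling
implementation is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import (
    Affection,
    Pedigree,
    PedigreeError,
    PedigreeSet,
    marriage_graph,
)

LN10 = math.log(10.0)

# haplotype h = 2*t + m with t = disease-allele indicator, m = minor-allele
# indicator; ordered diplotype g = 4*h_pat + h_mat
_PAT = np.arange(16) // 4
_MAT = np.arange(16) % 4
_N_DISEASE = _PAT // 2 + _MAT // 2          # 0, 1 or 2 copies of D
_MARKER_DOSAGE = _PAT % 2 + _MAT % 2        # minor-allele dosage of the state


class LoopedPedigreeError(PedigreeError):
    """Peeling requested on a pedigree whose marriage graph has a cycle."""


class MendelianInconsistencyError(PedigreeError):
    """Marker data impossible under any recombination fraction."""


@dataclass(frozen=True)
class TraitModel:
    """Parametric disease model: allele frequency and penetrances (dd, Dd, DD).

    The default is the reduced-penetrance dominant model used for null-rate
    scans: disease allele D at frequency 0.01, penetrance 0.05 for dd and
    0.5 for carriers.
    """

    disease_allele_freq: float = 0.01
    penetrances: tuple[float, float, float] = (0.05, 0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        if len(self.penetrances) != 3 or any(
            not 0.0 <= f <= 1.0 for f in self.penetrances
        ):
            raise ValueError("penetrances must be three probabilities")

    @classmethod
    def fully_penetrant_dominant(cls, disease_allele_freq: float = 0.01):
        return cls(disease_allele_freq, (0.0, 1.0, 1.0))

    def penetrance_vector(self, affection: Affection) -> np.ndarray:
        """(16,) probability of the observed affection for each diplotype."""
        f = np.asarray(self.penetrances)[_N_DISEASE]
        if affection == Affection.AFFECTED:
            return f
        if affection == Affection.UNAFFECTED:
            return 1.0 - f
        return np.ones(16)


@dataclass
class LodResult:
    """Per-family and total LOD (log10 units) for one marker at one theta."""

    marker_id: str
    theta: float
    family_lod: dict[str, float]
    total_lod: float
    theta_hat: float | None = None
    max_lod: float | None = None


# ---------------------------------------------------------------------------
# Model tensors
# ---------------------------------------------------------------------------

def gamete_probs(theta: float) -> np.ndarray:
    """(16, 4): probability a parent of each diplotype transmits each haplotype."""
    gam = np.zeros((16, 4))
    for g in range(16):
        a, b = _PAT[g], _MAT[g]
        rec1 = 2 * (a // 2) + (b % 2)   # trait from a, marker from b
        rec2 = 2 * (b // 2) + (a % 2)
        gam[g, a] += (1.0 - theta) / 2.0
        gam[g, b] += (1.0 - theta) / 2.0
        gam[g, rec1] += theta / 2.0
        gam[g, rec2] += theta / 2.0
    return gam


def transmission_tensor(theta: float) -> np.ndarray:
    """(child, father, mother) diplotype transmission probabilities."""
    gam = gamete_probs(theta)
    return gam[:, _PAT].T[:, :, None] * gam[:, _MAT].T[:, None, :]


def founder_prior(mafs: np.ndarray, model: TraitModel) -> np.ndarray:
    """(M, 16) linkage-equilibrium diplotype prior per marker."""
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    pD = model.disease_allele_freq
    pt = np.array([1.0 - pD, pD])
    hap = np.empty((len(mafs), 4))
    for h in range(4):
        pm = np.where(h % 2 == 1, mafs, 1.0 - mafs)
        hap[:, h] = pt[h // 2] * pm
    return hap[:, _PAT] * hap[:, _MAT]


_EVIDENCE = np.ones((4, 16))  # row d+1: indicator of marker dosage d; row 0 missing
for _d in range(3):
    _EVIDENCE[_d + 1] = (_MARKER_DOSAGE == _d).astype(float)


def marker_evidence(dosages: np.ndarray) -> np.ndarray:
    """(M, 16) indicator of the observed dosage; missing (-1) is all-ones."""
    d = np.asarray(dosages, dtype=int)
    return _EVIDENCE[d + 1]


# ---------------------------------------------------------------------------
# Peeling
# ---------------------------------------------------------------------------

class _PeelPlan:
    """Marriage-graph structure of one loop-free pedigree, ready to peel."""

    def __init__(self, p: Pedigree):
        g = marriage_graph(p)
        if nx.cycle_basis(g):
            raise LoopedPedigreeError(
                f"family {p.family_id} contains loops; break them before peeling"
            )
        self.pedigree = p
        self.fams: list[tuple[str, str, tuple[str, ...]]] = [
            (fa, mo, tuple(children))
            for (fa, mo), children in p.nuclear_families().items()
        ]
        self.person_fams: dict[str, list[int]] = {i: [] for i in p.ids}
        for fi, (fa, mo, children) in enumerate(self.fams):
            self.person_fams[fa].append(fi)
            self.person_fams[mo].append(fi)
            for c in children:
                self.person_fams[c].append(fi)
        self.roots = [
            next(n for n in comp if not isinstance(n, tuple))
            for comp in nx.connected_components(g)
        ]


def _rescale(vec: np.ndarray, ls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mx = vec.max(axis=1)
    safe = mx > 0
    np.divide(vec, mx[:, None], out=vec, where=safe[:, None])
    logmx = np.zeros_like(mx)
    np.log(mx, out=logmx, where=safe)
    return vec, ls + logmx


def _peel(plan: _PeelPlan, unary: Mapping[str, np.ndarray], T: np.ndarray) -> np.ndarray:
    """(M,) natural-log likelihood; -inf where the likelihood is exactly 0."""
    M = next(iter(unary.values())).shape[0]
    T_cf = T.reshape(16, 256)           # [child, father*16 + mother]

    def person_message(pid: str, from_fam: int) -> tuple[np.ndarray, np.ndarray]:
        v = np.array(unary[pid], dtype=float, copy=True)
        ls = np.zeros(M)
        for fi in plan.person_fams[pid]:
            if fi == from_fam:
                continue
            fv, fls = fam_message(fi, pid)
            v *= fv
            ls += fls
        return _rescale(v, ls)

    def fam_message(fi: int, via: str) -> tuple[np.ndarray, np.ndarray]:
        fa, mo, children = plan.fams[fi]
        P = np.ones((M, 16, 16))
        ls = np.zeros(M)
        if fa != via:
            vf, l = person_message(fa, fi)
            P *= vf[:, :, None]
            ls += l
        if mo != via:
            vm, l = person_message(mo, fi)
            P *= vm[:, None, :]
            ls += l
        for c in children:
            if c == via:
                continue
            vc, l = person_message(c, fi)
            P *= (vc @ T_cf).reshape(M, 16, 16)
            ls += l
        if via == fa:
            res = P.sum(axis=2)
        elif via == mo:
            res = P.sum(axis=1)
        else:
            res = P.reshape(M, 256) @ T_cf.T
        return _rescale(res, ls)

    total = np.zeros(M)
    for root in plan.roots:
        v, ls = person_message(root, from_fam=-1)
        s = v.sum(axis=1)
        logs = np.full(M, -np.inf)
        np.log(s, out=logs, where=s > 0)
        total = total + logs + np.where(s > 0, ls, 0.0)
    return total


def _as_dosage_arrays(
    p: Pedigree, marker_dosages: Mapping[str, object], M: int
) -> dict[str, np.ndarray]:
    out = {}
    for iid in p.ids:
        d = marker_dosages.get(iid)
        if d is None:
            out[iid] = np.full(M, -1, dtype=int)
        else:
            out[iid] = np.atleast_1d(np.asarray(d, dtype=int))
    return out


def _build_unary(
    p: Pedigree,
    dosage_arrays: Mapping[str, np.ndarray],
    prior: np.ndarray,
    model: TraitModel,
    affection: Mapping[str, Affection] | None,
) -> dict[str, np.ndarray]:
    unary = {}
    for ind in p:
        aff = affection[ind.id] if affection is not None else ind.affection
        u = marker_evidence(dosage_arrays[ind.id]) * model.penetrance_vector(aff)
        if ind.is_founder:
            u = u * prior
        unary[ind.id] = u
    return unary


def pedigree_log_likelihood_markers(
    p: Pedigree,
    marker_dosages: Mapping[str, np.ndarray],
    marker_mafs: np.ndarray,
    model: TraitModel,
    theta: float,
    affection: Mapping[str, Affection] | None = None,
) -> np.ndarray:
    """Natural-log likelihood of trait + marker data, batched over markers.

    ``marker_dosages`` maps individual id to an (M,) dosage vector (missing
    entries -1; absent individuals are fully missing); ``marker_mafs`` gives
    the minor-allele frequency per marker.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta={theta} outside [0, 0.5]")
    mafs = np.atleast_1d(np.asarray(marker_mafs, dtype=float))
    if np.any((mafs <= 0.0) | (mafs >= 1.0)):
        raise ValueError("marker MAF must be strictly inside (0, 1)")
    plan = _PeelPlan(p)
    M = len(mafs)
    dosage_arrays = _as_dosage_arrays(p, marker_dosages, M)
    prior = founder_prior(mafs, model)
    unary = _build_unary(p, dosage_arrays, prior, model, affection)
    return _peel(plan, unary, transmission_tensor(theta))


def pedigree_log_likelihood(
    p: Pedigree,
    marker_dosages: Mapping[str, object],
    marker_maf: float,
    model: TraitModel,
    theta: float,
    affection: Mapping[str, Affection] | None = None,
) -> float:
    """Single-marker natural-log pedigree likelihood (-inf if impossible)."""
    single = {
        iid: None if d is None else np.array([d])
        for iid, d in marker_dosages.items()
    }
    return float(
        pedigree_log_likelihood_markers(
            p, single, np.array([marker_maf]), model, theta, affection
        )[0]
    )


# ---------------------------------------------------------------------------
# LOD scores
# ---------------------------------------------------------------------------

def _iter_pedigrees(peds: Pedigree | PedigreeSet) -> list[Pedigree]:
    return [peds] if isinstance(peds, Pedigree) else list(peds)


def twopoint_lod(
    peds: Pedigree | PedigreeSet,
    marker_dosages: Mapping[str, object],
    marker_maf: float,
    model: TraitModel,
    theta: float = 0.0,
    marker_id: str = "",
    affection: Mapping[str, Affection] | None = None,
) -> LodResult:
    """Two-point LOD at one theta: per family log10 L(theta) - log10 L(0.5).

    A family whose marker data is impossible under any theta (zero
    likelihood at theta = 0.5) raises :class:`MendelianInconsistencyError`;
    a zero likelihood at the tested theta only is reported as a -inf family
    LOD, which propagates into the total.
    """
    family_lod: dict[str, float] = {}
    for p in _iter_pedigrees(peds):
        num = pedigree_log_likelihood(
            p, marker_dosages, marker_maf, model, theta, affection
        )
        den = pedigree_log_likelihood(
            p, marker_dosages, marker_maf, model, 0.5, affection
        )
        if den == -np.inf:
            raise MendelianInconsistencyError(
                f"family {p.family_id}: marker data impossible at theta = 0.5 "
                f"(Mendelian inconsistency) for marker {marker_id or '?'}"
            )
        family_lod[p.family_id] = (num - den) / LN10
    total = sum(family_lod.values())
    return LodResult(
        marker_id=marker_id, theta=theta, family_lod=family_lod, total_lod=total
    )


DEFAULT_THETA_GRID = tuple(
    np.unique(np.concatenate([[0.0, 0.001], np.round(np.arange(0.0, 0.501, 0.01), 3)]))
)


def maximize_theta(
    peds: Pedigree | PedigreeSet,
    marker_dosages: Mapping[str, object],
    marker_maf: float,
    model: TraitModel,
    grid: Sequence[float] = DEFAULT_THETA_GRID,
    marker_id: str = "",
    affection: Mapping[str, Affection] | None = None,
    tie_tol: float = 1e-9,
) -> LodResult:
    """Maximize the total LOD over a theta grid; ties break toward smaller theta.

    Grid values whose LOD is within ``tie_tol`` of the running maximum count
    as ties (flat profiles carry float noise well below that).
    """
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("theta grid is empty")
    if grid[0] != 0.0 or grid[-1] != 0.5 or any(
        t < 0.0 or t > 0.5 for t in grid
    ):
        raise ValueError("theta grid must lie in [0, 0.5] and contain 0 and 0.5")
    ped_list = _iter_pedigrees(peds)
    dens = {
        p.family_id: pedigree_log_likelihood(
            p, marker_dosages, marker_maf, model, 0.5, affection
        )
        for p in ped_list
    }
    for fam, den in dens.items():
        if den == -np.inf:
            raise MendelianInconsistencyError(
                f"family {fam}: marker data impossible at theta = 0.5 "
                f"(Mendelian inconsistency) for marker {marker_id or '?'}"
            )
    best: LodResult | None = None
    for t in grid:
        fl = {}
        for p in ped_list:
            num = pedigree_log_likelihood(
                p, marker_dosages, marker_maf, model, t, affection
            )
            fl[p.family_id] = (num - dens[p.family_id]) / LN10
        total = sum(fl.values())
        if best is None or total > best.total_lod + tie_tol:
            best = LodResult(
                marker_id=marker_id, theta=t, family_lod=fl, total_lod=total
            )
    best.theta_hat = best.theta
    best.max_lod = best.total_lod
    return best


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

_MAX_BRUTE_MEMBERS = 8
_MAX_BRUTE_STATES = 5e8


def brute_force_log_likelihood(
    p: Pedigree,
    marker_dosages: Mapping[str, object],
    marker_maf: float,
    model: TraitModel,
    theta: float,
    affection: Mapping[str, Affection] | None = None,
) -> float:
    """Exhaustive sum over all joint ordered-diplotype assignments.

    Ground truth for :func:`pedigree_log_likelihood` on pedigrees of at most
    8 members.  States whose single-individual evidence is exactly zero are
    skipped (they contribute nothing to the sum); the remaining joint space
    is summed with one unoptimized einsum, i.e. plain nested loops.
    """
    if len(p) > _MAX_BRUTE_MEMBERS:
        raise ValueError(
            f"brute force limited to {_MAX_BRUTE_MEMBERS} members; "
            f"family {p.family_id} has {len(p)}"
        )
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta={theta} outside [0, 0.5]")
    if not 0.0 < marker_maf < 1.0:
        raise ValueError("marker MAF must be strictly inside (0, 1)")
    dosage_arrays = _as_dosage_arrays(p, marker_dosages, 1)
    prior = founder_prior(np.array([marker_maf]), model)
    unary = _build_unary(p, dosage_arrays, prior, model, affection)
    T = transmission_tensor(theta)

    ids = p.ids
    letters = {iid: chr(ord("a") + k) for k, iid in enumerate(ids)}
    cand = {iid: np.nonzero(unary[iid][0] > 0)[0] for iid in ids}
    n_states = 1.0
    for c in cand.values():
        if c.size == 0:
            return -np.inf
        n_states *= c.size
    if n_states > _MAX_BRUTE_STATES:
        raise ValueError(
            f"enumeration would visit {n_states:.2g} joint states; too large"
        )
    subs, ops = [], []
    for iid in ids:
        subs.append(letters[iid])
        ops.append(unary[iid][0][cand[iid]])
    for ind in p:
        if ind.is_founder:
            continue
        subs.append(letters[ind.id] + letters[ind.father_id] + letters[ind.mother_id])
        ops.append(
            T[np.ix_(cand[ind.id], cand[ind.father_id], cand[ind.mother_id])]
        )
    total = float(np.einsum(",".join(subs) + "->", *ops, optimize=False))
    return math.log(total) if total > 0.0 else -np.inf


# ---------------------------------------------------------------------------
# Batched genome scan
# ---------------------------------------------------------------------------

class TwoPointScan:
    """Batched two-point scan of one marker panel over a pedigree set.

    Precomputes, per pedigree, the marker-side factor of every individual's
    peeling state (evidence x founder prior) so that scanning a new
    replicate only multiplies in the trait penetrances.  The LOD denominator
    uses the exact factorization at theta = 0.5 (trait and marker loci
    independent): log L(0.5) = trait-only log-likelihood + marker-only
    log-likelihood, where the marker-only term is shared by all replicates.
    """

    def __init__(self, peds: PedigreeSet, geno: GenotypeMatrix, model: TraitModel):
        self.model = model
        self.family_ids = [p.family_id for p in peds]
        mafs = np.array(
            [np.nan if m.estimated_maf is None else m.estimated_maf
             for m in geno.markers],
            dtype=float,
        )
        if np.isnan(mafs).any():
            raise ValueError(
                "markers have no estimated_maf; run estimate_founder_maf first"
            )
        if np.any((mafs <= 0) | (mafs >= 1)):
            raise ValueError("estimated MAF outside (0, 1)")
        self.mafs = mafs
        self.marker_ids = [m.marker_id for m in geno.markers]
        M = geno.n_markers
        prior = founder_prior(mafs, model)
        self._plans: list[_PeelPlan] = []
        self._marker_unary: list[dict[str, np.ndarray]] = []
        for p in peds:
            plan = _PeelPlan(p)
            mu = {}
            for ind in p:
                d = geno.row(ind.id) if ind.id in geno else np.full(M, -1, int)
                u = marker_evidence(d)
                if ind.is_founder:
                    u = u * prior
                mu[ind.id] = u
            self._plans.append(plan)
            self._marker_unary.append(mu)
        # marker-only log-likelihood per family (affection all unknown)
        self._marker_loglik = np.stack(
            [
                _peel(plan, mu, transmission_tensor(0.5))
                for plan, mu in zip(self._plans, self._marker_unary)
            ],
            axis=1,
        )                                   # (M, n_families)
        for k, fam in enumerate(self.family_ids):
            bad = np.nonzero(self._marker_loglik[:, k] == -np.inf)[0]
            if bad.size:
                raise MendelianInconsistencyError(
                    f"family {fam}: Mendelian-inconsistent marker data at "
                    f"{self.marker_ids[bad[0]]}"
                )

    def _trait_loglik(self, plan: _PeelPlan, affection) -> float:
        p = plan.pedigree
        prior0 = founder_prior(np.array([0.5]), self.model)
        unary = {}
        for ind in p:
            aff = affection[ind.id] if affection is not None else ind.affection
            u = np.tile(self.model.penetrance_vector(aff), (1, 1)).astype(float)
            if ind.is_founder:
                u = u * prior0
            unary[ind.id] = u
        return float(_peel(plan, unary, transmission_tensor(0.5))[0])

    def lods(
        self,
        affection: Mapping[str, Affection] | None = None,
        theta: float = 0.0,
    ) -> np.ndarray:
        """(n_markers, n_families) LOD matrix at the given theta."""
        T = transmission_tensor(theta)
        cols = []
        for plan, mu in zip(self._plans, self._marker_unary):
            pen = {
                ind.id: self.model.penetrance_vector(
                    affection[ind.id] if affection is not None else ind.affection
                )
                for ind in plan.pedigree
            }
            unary = {iid: mu[iid] * pen[iid] for iid in mu}
            num = _peel(plan, unary, T)
            cols.append(num - self._trait_loglik(plan, affection))
        num_mat = np.stack(cols, axis=1)
        return (num_mat - self._marker_loglik) / LN10

    def lod_results(
        self,
        affection: Mapping[str, Affection] | None = None,
        theta: float = 0.0,
    ) -> Iterable[LodResult]:
        """Stream per-marker LodResults (one per marker, all families)."""
        lod = self.lods(affection, theta)
        for j, mid in enumerate(self.marker_ids):
            fl = dict(zip(self.family_ids, lod[j]))
            yield LodResult(
                marker_id=mid, theta=theta, family_lod=fl,
                total_lod=float(lod[j].sum()),
            )


def write_lod_table(
    path,
    geno: GenotypeMatrix,
    family_ids: Sequence[str],
    lod: np.ndarray,
    theta: float,
) -> None:
    """Stream per-marker LODs: id, map info, MAF, theta, total, per-family."""
    with open(path, "w") as fh:
        fh.write(
            "marker_id\tchrom\tpos\testimated_maf\ttheta\ttotal_lod\t"
            + "\t".join(f"lod_{f}" for f in family_ids)
            + "\n"
        )
        for j, m in enumerate(geno.markers):
            row = lod[j]
            fh.write(
                f"{m.marker_id}\t{m.chromosome}\t{m.position_bp}\t"
                f"{m.estimated_maf:.6g}\t{theta:g}\t{row.sum():.6f}\t"
                + "\t".join(f"{v:.6f}" for v in row)
                + "\n"
            )
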