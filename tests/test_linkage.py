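import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedlod.linkage import (
    DEFAULT_THETA_GRID,
    LoopedPedigreeError,
    MendelianInconsistencyError,
    TraitModel,
    TwoPointScan,
    brute_force_log_likelihood,
    founder_prior,
    gamete_probs,
    maximize_theta,
    pedigree_log_likelihood,
    transmission_tensor,
    twopoint_lod,
)
from pedlod.allele_freq import estimate_founder_maf
from pedlod.pedigree import Affection, Pedigree, Sex
from pedlod.phenotypes import assign_random_affection
from pedlod.synthetic_data import (
    SimulationConfig,
    gene_drop_genotypes,
    generate_markers,
    generate_pedigree_set,
    mask_ungenotyped,
)

from conftest import (
    as_set,
    drop_single_marker,
    ind,
    random_affection,
    random_small_pedigree,
)

MODEL = TraitModel()
A, U = Affection.AFFECTED, Affection.UNAFFECTED


def phase_known_family(n_children=4, child_dosages=None):
    """Fully informative nuclear family with grandparents fixing the phase.

    Under the full-penetrance dominant model the affected father is an
    obligate D/minor coupling heterozygote; each affected child with dosage
    1 is a nonrecombinant paternal meiosis.
    """
    members = [
        ind("GF", sex=Sex.MALE, aff=A),
        ind("GM", sex=Sex.FEMALE, aff=U),
        ind("FA", "P", "GF", "GM", sex=Sex.MALE, aff=A),
        ind("MO", sex=Sex.FEMALE, aff=U),
    ]
    dosages = {"GF": 2, "GM": 0, "FA": 1, "MO": 0}
    child_dosages = child_dosages or [1] * n_children
    for k, d in enumerate(child_dosages):
        members.append(ind(f"C{k}", "P", "FA", "MO", aff=A))
        dosages[f"C{k}"] = d
    return Pedigree("P", members), dosages


class TestModelTensors:
    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    @settings(deadline=None, max_examples=30)
    def test_gamete_probs_rows_sum_to_one(self, theta):
        assert np.allclose(gamete_probs(theta).sum(axis=1), 1.0)

    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    @settings(deadline=None, max_examples=30)
    def test_transmission_normalized(self, theta):
        T = transmission_tensor(theta)
        assert np.allclose(T.sum(axis=0), 1.0)

    def test_founder_prior_sums_to_one(self):
        prior = founder_prior(np.array([1e-4, 0.2, 0.5]), MODEL)
        assert np.allclose(prior.sum(axis=1), 1.0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            TraitModel(disease_allele_freq=0.0)
        with pytest.raises(ValueError):
            TraitModel(penetrances=(0.1, 1.2, 0.5))


class TestPedigreeLikelihood:
    def test_single_untyped_founder_probability_one(self):
        solo = as_set(Pedigree("S", [ind("X", "S")]))["S"]
        assert pedigree_log_likelihood(solo, {}, 0.3, MODEL, 0.1) == pytest.approx(0.0)

    def test_likelihood_is_log_probability(self, trio):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dosages = drop_single_marker(trio, 0.3, rng)
            aff = random_affection(trio, rng)
            ll = pedigree_log_likelihood(trio, dosages, 0.3, MODEL, 0.1, aff)
            assert ll <= 1e-12

    def test_factorizes_at_free_recombination(self, first_cousin_pedigree):
        p = first_cousin_pedigree
        rng = np.random.default_rng(1)
        dosages = drop_single_marker(p, 0.4, rng)
        aff = random_affection(p, rng)
        unknown = {i: Affection.UNKNOWN for i in p.ids}
        missing = {i: None for i in p.ids}
        full = pedigree_log_likelihood(p, dosages, 0.4, MODEL, 0.5, aff)
        trait_only = pedigree_log_likelihood(p, missing, 0.4, MODEL, 0.5, aff)
        marker_only = pedigree_log_likelihood(p, dosages, 0.4, MODEL, 0.5, unknown)
        assert full == pytest.approx(trait_only + marker_only, rel=1e-12)

    def test_looped_pedigree_rejected(self, two_brothers_loop):
        with pytest.raises(LoopedPedigreeError):
            pedigree_log_likelihood(two_brothers_loop, {}, 0.3, MODEL, 0.0)

    def test_invalid_theta_and_maf(self, trio):
        with pytest.raises(ValueError):
            pedigree_log_likelihood(trio, {}, 0.3, MODEL, 0.7)
        with pytest.raises(ValueError):
            pedigree_log_likelihood(trio, {}, 0.0, MODEL, 0.1)

    def test_underflow_safety_large_pedigree_rare_marker(self):
        cfg = SimulationConfig(n_pedigrees=1, pedigree_size_range=(85, 95), seed=3)
        p = next(iter(generate_pedigree_set(cfg)))
        dosages = {i.id: 0 for i in p}
        dosages[p.founders()[0].id] = 1  # one copy of a 1e-4 allele
        aff = {i.id: (A if k % 7 == 0 else U) for k, i in enumerate(p)}
        ll = pedigree_log_likelihood(p, dosages, 1e-4, MODEL, 0.0, aff)
        assert np.isfinite(ll)


class TestOracleEquivalence:
    def test_brute_force_permutation_invariant(self, trio):
        rng = np.random.default_rng(2)
        dosages = drop_single_marker(trio, 0.3, rng)
        reversed_ped = Pedigree("T", list(reversed(list(trio))))
        a = brute_force_log_likelihood(trio, dosages, 0.3, MODEL, 0.1)
        b = brute_force_log_likelihood(reversed_ped, dosages, 0.3, MODEL, 0.1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_brute_force_rejects_large_pedigrees(self):
        cfg = SimulationConfig(n_pedigrees=1, pedigree_size_range=(20, 40), seed=5)
        p = next(iter(generate_pedigree_set(cfg)))
        with pytest.raises(ValueError, match="limited"):
            brute_force_log_likelihood(p, {}, 0.3, MODEL, 0.0)

    def test_peeling_equals_enumeration_fuzz(self):
        """200 random small pedigrees, random data/model/theta."""
        rng = np.random.default_rng(12345)
        n_neg_inf = 0
        for _ in range(200):
            ped = random_small_pedigree(rng)
            maf = float(rng.uniform(0.05, 0.5))
            theta = float(rng.choice([0.0, rng.uniform(0, 0.5), 0.5]))
            dosages = drop_single_marker(ped, maf, rng)
            aff = random_affection(ped, rng)
            model = (
                MODEL
                if rng.random() < 0.7
                else TraitModel.fully_penetrant_dominant(0.05)
            )
            a = pedigree_log_likelihood(ped, dosages, maf, model, theta, aff)
            b = brute_force_log_likelihood(ped, dosages, maf, model, theta, aff)
            if b == -np.inf:
                n_neg_inf += 1
                assert a == -np.inf
            else:
                assert a == pytest.approx(b, rel=1e-10)
        assert n_neg_inf < 100  # most fuzzed cases are informative


class TestTwoPointLod:
    def test_lod_zero_at_free_recombination(self, first_cousin_pedigree):
        p = first_cousin_pedigree
        rng = np.random.default_rng(3)
        dosages = drop_single_marker(p, 0.3, rng)
        aff = random_affection(p, rng)
        res = twopoint_lod(p, dosages, 0.3, MODEL, theta=0.5, affection=aff)
        assert res.total_lod == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in res.family_lod.values())

    def test_total_is_family_sum(self):
        import dataclasses as dc

        from pedlod.pedigree import PedigreeSet

        rng = np.random.default_rng(4)
        renamed = []
        for k in range(3):
            p = random_small_pedigree(rng)
            q = Pedigree(f"F{k}")
            for i in p:
                q.add(
                    dc.replace(
                        i,
                        id=f"F{k}_{i.id}",
                        family_id=f"F{k}",
                        father_id=None if i.father_id is None else f"F{k}_{i.father_id}",
                        mother_id=None if i.mother_id is None else f"F{k}_{i.mother_id}",
                    )
                )
            renamed.append(q)
        ped_set = PedigreeSet(renamed)
        dosages = {}
        for p in renamed:
            dosages.update(drop_single_marker(p, 0.3, rng))
        aff = {}
        for p in renamed:
            aff.update(random_affection(p, rng))
        res = twopoint_lod(ped_set, dosages, 0.3, MODEL, theta=0.05, affection=aff)
        assert res.total_lod == pytest.approx(sum(res.family_lod.values()), abs=1e-9)

    def test_phase_known_closed_form(self):
        ped, dosages = phase_known_family(n_children=4)
        fp = TraitModel.fully_penetrant_dominant(0.01)
        res = twopoint_lod(ped, dosages, 0.3, fp, theta=0.0)
        assert res.total_lod == pytest.approx(4 * math.log10(2), rel=1e-9)

    def test_obligate_recombinant_gives_minus_inf(self):
        ped, dosages = phase_known_family(child_dosages=[1, 1, 1, 0])
        fp = TraitModel.fully_penetrant_dominant(0.01)
        res = twopoint_lod(ped, dosages, 0.3, fp, theta=0.0)
        assert res.total_lod == -np.inf

    def test_mendelian_inconsistency_raises(self, trio):
        dosages = {"F": 0, "M": 0, "C": 2}
        with pytest.raises(MendelianInconsistencyError, match="family T"):
            twopoint_lod(trio, dosages, 0.3, MODEL, theta=0.0)


class TestMaximizeTheta:
    def test_uninformative_marker_flat_profile(self, trio):
        dosages = {i: None for i in trio.ids}
        res = maximize_theta(trio, dosages, 0.3, MODEL)
        assert res.theta_hat == 0.0  # tie-break toward smaller theta
        assert res.max_lod == pytest.approx(0.0, abs=1e-12)

    def test_max_at_least_lod_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            ped = random_small_pedigree(rng)
            dosages = drop_single_marker(ped, 0.3, rng)
            aff = random_affection(ped, rng)
            res = maximize_theta(ped, dosages, 0.3, MODEL, affection=aff)
            lod0 = twopoint_lod(ped, dosages, 0.3, MODEL, 0.0, affection=aff)
            assert res.max_lod >= lod0.total_lod - 1e-12

    def test_coarse_grid_close_to_dense_grid(self):
        rng = np.random.default_rng(7)
        coarse = np.linspace(0.0, 0.5, 51)
        dense = np.linspace(0.0, 0.5, 501)
        for _ in range(20):
            ped = random_small_pedigree(rng)
            dosages = drop_single_marker(ped, 0.4, rng)
            aff = random_affection(ped, rng)
            mc = maximize_theta(ped, dosages, 0.4, MODEL, grid=coarse, affection=aff)
            md = maximize_theta(ped, dosages, 0.4, MODEL, grid=dense, affection=aff)
            if np.isfinite(md.max_lod):
                assert md.max_lod - mc.max_lod < 0.01

    def test_bad_grids(self, trio):
        with pytest.raises(ValueError):
            maximize_theta(trio, {}, 0.3, MODEL, grid=[])
        with pytest.raises(ValueError):
            maximize_theta(trio, {}, 0.3, MODEL, grid=[0.0, 0.25])


@pytest.fixture(scope="module")
def scan_study():
    cfg = SimulationConfig(
        n_pedigrees=3, pedigree_size_range=(20, 50), n_markers=40,
        marker_maf_spectrum=((0.5, (0.001, 0.01)), (0.5, (0.01, 0.5))),
        ungenotyped_fraction=0.2, n_replicates=2, seed=8,
    )
    peds = generate_pedigree_set(cfg)
    geno = gene_drop_genotypes(peds, generate_markers(cfg), cfg)
    geno = mask_ungenotyped(geno, peds, cfg)
    estimate_founder_maf(geno, peds)
    aff = assign_random_affection(peds, cfg)
    return cfg, peds, geno, aff


class TestTwoPointScan:
    @pytest.fixture
    def study(self, scan_study):
        return scan_study

    @pytest.mark.parametrize("theta", [0.0, 0.1])
    def test_matches_per_marker_api(self, study, theta):
        """The batched scan equals marker-by-marker twopoint_lod."""
        cfg, peds, geno, aff = study
        scan = TwoPointScan(peds, geno, MODEL)
        aff_map = aff.replicate_map(0)
        lod = scan.lods(aff_map, theta)
        rng = np.random.default_rng(9)
        for j in rng.choice(geno.n_markers, size=6, replace=False):
            dosages = {
                s: int(geno.row(s)[j]) if geno.row(s)[j] >= 0 else None
                for s in geno.samples
            }
            ref = twopoint_lod(
                peds, dosages, geno.markers[j].estimated_maf, MODEL,
                theta, affection=aff_map,
            )
            for k, fam in enumerate(scan.family_ids):
                assert lod[j, k] == pytest.approx(ref.family_lod[fam], abs=1e-9)

    def test_lod_results_stream(self, study):
        cfg, peds, geno, aff = study
        scan = TwoPointScan(peds, geno, MODEL)
        results = list(scan.lod_results(aff.replicate_map(1)))
        assert len(results) == geno.n_markers
        for r in results[:5]:
            assert r.total_lod == pytest.approx(
                sum(r.family_lod.values()), abs=1e-9
            )

    def test_requires_estimated_maf(self, study):
        cfg, peds, geno, _ = study
        bare = geno.copy()
        for m in bare.markers:
            m.estimated_maf = None
        with pytest.raises(ValueError, match="estimated_maf"):
            TwoPointScan(peds, bare, MODEL)
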