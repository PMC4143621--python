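import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedlod.pedigree import Affection
from pedlod.phenotypes import (
    AffectionReplicates,
    QuantitativeTraitReplicates,
    assign_random_affection,
    dichotomize_by_founder_quantile,
    estimate_heritability_from_sibs,
    simulate_polygenic_trait,
)
from pedlod.synthetic_data import SimulationConfig, generate_pedigree_set


@pytest.fixture(scope="module")
def peds_and_cfg():
    cfg = SimulationConfig(
        n_pedigrees=8, pedigree_size_range=(30, 90), n_replicates=20, seed=17
    )
    return generate_pedigree_set(cfg), cfg


class TestPolygenicTrait:
    def test_h2_zero_relatives_uncorrelated(self):
        cfg = SimulationConfig(
            n_pedigrees=5, pedigree_size_range=(30, 90), heritability=0.0,
            n_replicates=200, seed=23,
        )
        peds = generate_pedigree_set(cfg)
        traits = simulate_polygenic_trait(peds, cfg)
        h2_hat, n_pairs = estimate_heritability_from_sibs(traits, peds)
        # r = h2_hat/2 should be within ~3 SE of 0
        se = 1.0 / np.sqrt(n_pairs - 3)
        assert abs(h2_hat / 2.0) < 3 * se

    def test_sib_correlation_recovers_h2(self):
        cfg = SimulationConfig(
            n_pedigrees=30, pedigree_size_range=(30, 90), heritability=0.68,
            n_replicates=7, seed=29,
        )
        peds = generate_pedigree_set(cfg)
        traits = simulate_polygenic_trait(peds, cfg)
        h2_hat, n_pairs = estimate_heritability_from_sibs(traits, peds)
        assert n_pairs >= 2000
        z = np.arctanh(h2_hat / 2.0) - np.arctanh(0.34)
        assert abs(z) < 1.96 / np.sqrt(n_pairs - 3)

    def test_age_slope_recovered(self, peds_and_cfg):
        peds, cfg = peds_and_cfg
        traits = simulate_polygenic_trait(peds, cfg)
        ages = np.nan_to_num(traits.ages, nan=0.0)
        X = np.column_stack([np.ones(len(ages)), ages])
        y = traits.values.mean(axis=1)
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(
            resid @ resid / (len(y) - 2) / ((ages - ages.mean()) ** 2).sum()
        )
        assert beta[1] < 0
        assert abs(beta[1] - cfg.age_mean_slope) < 3 * se

    def test_replicate_independence_and_determinism(self, peds_and_cfg):
        peds, cfg = peds_and_cfg
        t1 = simulate_polygenic_trait(peds, cfg)
        t2 = simulate_polygenic_trait(peds, cfg)
        assert np.array_equal(t1.values, t2.values)
        # replicates are distinct draws
        assert not np.array_equal(t1.values[:, 0], t1.values[:, 1])

    def test_trait_independent_of_genotypes(self, peds_and_cfg):
        """Null trait: dosage-trait correlation centered on zero."""
        from pedlod.synthetic_data import gene_drop_genotypes
        from pedlod.genotypes import MarkerInfo

        peds, cfg = peds_and_cfg
        markers = [
            MarkerInfo(marker_id=f"M{j}", position_cm=j * 1e4, true_maf=0.4)
            for j in range(300)
        ]
        geno = gene_drop_genotypes(peds, markers, cfg)
        traits = simulate_polygenic_trait(peds, cfg)
        rows = np.array([geno._row[i] for i in traits.individual_ids])
        G = geno.dosages[rows].astype(float)
        y = traits.values[:, 0] - traits.values[:, 0].mean()
        g = G - G.mean(axis=0)
        r = (g * y[:, None]).sum(axis=0) / (
            np.sqrt((g**2).sum(axis=0)) * np.sqrt((y**2).sum())
        )
        assert abs(r.mean()) < 3.0 / np.sqrt(len(markers) * len(y))


def _manual_traits(values_by_id, founders, n_rep=1):
    ids = list(values_by_id)
    vals = np.array([[values_by_id[i]] * n_rep for i in ids], dtype=float)
    return QuantitativeTraitReplicates(
        individual_ids=ids,
        family_ids=["F"] * len(ids),
        ages=np.zeros(len(ids)),
        values=vals,
        heritability=0.68,
        age_mean_slope=-0.5,
        trait_sd=15.0,
        trait_mean=100.0,
    )


class TestDichotomize:
    def _founder_only_ped(self, n):
        from conftest import as_set, ind
        from pedlod.pedigree import Pedigree, Sex

        members = [
            ind(f"I{k}", "F", sex=Sex.MALE if k % 2 else Sex.FEMALE)
            for k in range(n)
        ]
        return as_set(Pedigree("F", members))

    def test_hand_computed_quantile(self):
        peds = self._founder_only_ped(10)
        vals = {f"I{k}": float(k + 1) for k in range(10)}
        traits = _manual_traits(vals, peds)
        cfg = SimulationConfig(founder_quantile=0.20, n_replicates=1)
        aff = dichotomize_by_founder_quantile(traits, peds, cfg)
        assert aff.cutoff == pytest.approx(2.8)
        affected = {
            i for i in vals if aff.affection(i, 0) == Affection.AFFECTED
        }
        assert affected == {"I0", "I1"}  # values 1 and 2

    def test_all_identical_zero_affected(self):
        peds = self._founder_only_ped(6)
        traits = _manual_traits({f"I{k}": 5.0 for k in range(6)}, peds)
        cfg = SimulationConfig(founder_quantile=0.20)
        aff = dichotomize_by_founder_quantile(traits, peds, cfg)
        assert (aff.codes == Affection.UNAFFECTED).all()

    def test_pooled_founder_affected_fraction(self):
        cfg = SimulationConfig(
            n_pedigrees=10, pedigree_size_range=(30, 90), n_replicates=50,
            seed=31,
        )
        peds = generate_pedigree_set(cfg)
        traits = simulate_polygenic_trait(peds, cfg)
        aff = dichotomize_by_founder_quantile(traits, peds, cfg)
        founder_ids = [i.id for p in peds for i in p.founders()]
        frac = aff.affected_fraction(founder_ids)
        n = len(founder_ids) * cfg.n_replicates
        assert abs(frac - 0.20) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_monotone_in_quantile(self):
        cfg = SimulationConfig(
            n_pedigrees=3, pedigree_size_range=(30, 90), n_replicates=5, seed=37
        )
        peds = generate_pedigree_set(cfg)
        traits = simulate_polygenic_trait(peds, cfg)
        prev: set = set()
        for q in (0.05, 0.10, 0.20, 0.40):
            cfg_q = dataclasses.replace(cfg, founder_quantile=q)
            aff = dichotomize_by_founder_quantile(traits, peds, cfg_q)
            cur = set(zip(*np.nonzero(aff.codes == Affection.AFFECTED)))
            assert prev <= cur  # affected set grows with the quantile
            prev = cur

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2, max_size=30,
        ),
        st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(deadline=None, max_examples=50)
    def test_cutoff_is_pooled_quantile_property(self, values, q):
        peds = self._founder_only_ped(len(values))
        traits = _manual_traits(
            {f"I{k}": v for k, v in enumerate(values)}, peds
        )
        cfg = SimulationConfig(founder_quantile=q)
        aff = dichotomize_by_founder_quantile(traits, peds, cfg)
        assert aff.cutoff == pytest.approx(np.quantile(values, q))
        n_aff = int((aff.codes == Affection.AFFECTED).sum())
        assert n_aff == int(sum(v < aff.cutoff for v in values))

    def test_missing_values_unknown(self):
        peds = self._founder_only_ped(4)
        traits = _manual_traits({f"I{k}": float(k) for k in range(4)}, peds)
        traits.values[2, 0] = np.nan
        cfg = SimulationConfig(founder_quantile=0.5)
        aff = dichotomize_by_founder_quantile(traits, peds, cfg)
        assert aff.affection("I2", 0) == Affection.UNKNOWN


class TestRandomAffection:
    @pytest.mark.parametrize("prev,expect", [(0.0, Affection.UNAFFECTED),
                                             (1.0, Affection.AFFECTED)])
    def test_degenerate_prevalences(self, prev, expect):
        cfg = SimulationConfig(
            n_pedigrees=2, pedigree_size_range=(10, 40), prevalence=prev,
            n_replicates=3, seed=41,
        )
        peds = generate_pedigree_set(cfg)
        aff = assign_random_affection(peds, cfg)
        assert (aff.codes == expect).all()

    def test_prevalence_recovered(self):
        cfg = SimulationConfig(
            n_pedigrees=10, pedigree_size_range=(30, 90), prevalence=0.10,
            n_replicates=50, seed=43,
        )
        peds = generate_pedigree_set(cfg)
        aff = assign_random_affection(peds, cfg)
        n = aff.codes.size
        frac = aff.affected_fraction()
        assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n)
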