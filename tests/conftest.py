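import numpy as np
import pytest

from pedlod.pedigree import Affection, Individual, Pedigree, PedigreeSet, Sex


def ind(iid, fam="P", fa=None, mo=None, sex=Sex.MALE, aff=Affection.UNKNOWN,
        age=None):
    return Individual(
        id=iid, family_id=fam, father_id=fa, mother_id=mo, sex=sex,
        affection=aff, age=age,
    )


@pytest.fixture
def trio():
    return Pedigree("T", [
        ind("F", "T", sex=Sex.MALE),
        ind("M", "T", sex=Sex.FEMALE),
        ind("C", "T", "F", "M"),
    ])


@pytest.fixture
def first_cousin_pedigree():
    """8 members: grandparents, two sibs with spouses, two first cousins."""
    return Pedigree("K", [
        ind("GF", "K", sex=Sex.MALE),
        ind("GM", "K", sex=Sex.FEMALE),
        ind("S1", "K", "GF", "GM", sex=Sex.MALE),
        ind("S2", "K", "GF", "GM", sex=Sex.FEMALE),
        ind("W1", "K", sex=Sex.FEMALE),
        ind("H2", "K", sex=Sex.MALE),
        ind("C1", "K", "S1", "W1", sex=Sex.MALE),
        ind("C2", "K", "H2", "S2", sex=Sex.FEMALE),
    ])


@pytest.fixture
def two_brothers_loop():
    """A woman with children by each of two brothers (marriage loop)."""
    return Pedigree("L", [
        ind("GF", "L", sex=Sex.MALE),
        ind("GM", "L", sex=Sex.FEMALE),
        ind("B1", "L", "GF", "GM", sex=Sex.MALE),
        ind("B2", "L", "GF", "GM", sex=Sex.MALE),
        ind("W", "L", sex=Sex.FEMALE, aff=Affection.UNAFFECTED),
        ind("C1", "L", "B1", "W"),
        ind("C2", "L", "B2", "W", sex=Sex.FEMALE),
    ])


def random_small_pedigree(rng: np.random.Generator, max_members: int = 8) -> Pedigree:
    """Random loop-free pedigree of 3..max_members members.

    Growth moves only attach new founders as spouses, so the marriage graph
    stays a tree by construction.
    """
    target = int(rng.integers(3, max_members + 1))
    serial = [0]
    ped = Pedigree("R")

    def add(fa=None, mo=None, sex=None):
        serial[0] += 1
        if sex is None:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        i = ind(f"I{serial[0]}", "R", fa, mo, sex=sex)
        ped.add(i)
        return i

    fa = add(sex=Sex.MALE)
    mo = add(sex=Sex.FEMALE)
    couples = [(fa.id, mo.id)]
    add(fa.id, mo.id)
    while len(ped) < target:
        if rng.random() < 0.5:
            f, m = couples[int(rng.integers(len(couples)))]
            add(f, m)
        else:
            # marry off a random member to a brand-new founder
            member = ped[list(ped.members)[int(rng.integers(len(ped)))]]
            spouse = add(sex=Sex.FEMALE if member.sex == Sex.MALE else Sex.MALE)
            pair = (
                (member.id, spouse.id)
                if member.sex == Sex.MALE
                else (spouse.id, member.id)
            )
            couples.append(pair)
            if len(ped) < target:
                add(*pair)
    return ped


def drop_single_marker(ped: Pedigree, maf: float, rng: np.random.Generator,
                       miss_prob: float = 0.2, max_missing: int = 2) -> dict:
    """Gene-drop one biallelic marker; returns id -> dosage (None = missing).

    At most ``max_missing`` individuals are masked so the enumeration oracle
    stays within reach.
    """
    alleles: dict[str, tuple[int, int]] = {}
    for iid in ped.topological_order():
        i = ped[iid]
        if i.is_founder:
            alleles[iid] = (int(rng.random() < maf), int(rng.random() < maf))
        else:
            pa = alleles[i.father_id][int(rng.integers(2))]
            ma = alleles[i.mother_id][int(rng.integers(2))]
            alleles[iid] = (pa, ma)
    dosages: dict[str, int | None] = {k: a + b for k, (a, b) in alleles.items()}
    n_missing = 0
    for iid in ped.ids:
        if n_missing < max_missing and rng.random() < miss_prob:
            dosages[iid] = None
            n_missing += 1
    return dosages


def random_affection(ped: Pedigree, rng: np.random.Generator) -> dict:
    return {
        iid: Affection(int(rng.integers(0, 3))) for iid in ped.ids
    }


def as_set(*peds: Pedigree) -> PedigreeSet:
    return PedigreeSet(peds)
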