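import numpy as np
import pytest

from kinlr.pedigree import FEMALE, MALE, Individual, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20120825)


@pytest.fixture
def toy_pedigree():
    """Founder couple, two daughters, one grandchild per daughter, one son."""
    return Pedigree(
        [
            Individual("gf", MALE),
            Individual("gm", FEMALE),
            Individual("d1", FEMALE, father_id="gf", mother_id="gm"),
            Individual("d2", FEMALE, father_id="gf", mother_id="gm"),
            Individual("s1", MALE, father_id="gf", mother_id="gm"),
            Individual("h1", MALE),
            Individual("h2", MALE),
            Individual("c1", FEMALE, father_id="h1", mother_id="d1"),
            Individual("c2", MALE, father_id="h2", mother_id="d2"),
        ]
    )


def chain_pedigree(depth: int, sex: str, link: str) -> Pedigree:
    """A single uniparental chain: X0 is the founder, X{depth} the last descendant."""
    inds = [Individual("X0", sex)]
    for i in range(1, depth + 1):
        kwargs = {("father_id" if link == "father" else "mother_id"): f"X{i-1}"}
        inds.append(Individual(f"X{i}", sex, **kwargs))
    return Pedigree(inds)


def two_branch_matriline(g_a: int, g_b: int) -> Pedigree:
    """One ancestress with two daughter lines of depth g_a and g_b."""
    inds = [Individual("anc", FEMALE)]
    for branch, depth in (("a", g_a), ("b", g_b)):
        prev = "anc"
        for i in range(1, depth + 1):
            ind_id = f"{branch}{i}"
            inds.append(Individual(ind_id, FEMALE, mother_id=prev))
            prev = ind_id
    return Pedigree(inds)
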