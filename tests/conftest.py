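import numpy as np
import pytest

from elbowgen.pedigree import PedigreeRecord, topological_sort_pedigree


def random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.3):
    """Messy random pedigree: arbitrary parent links respecting order,
    including single-known-parent individuals."""
    recs = []
    sexes = []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = None
        if i > 1 and rng.random() > p_founder:
            males = [j for j in range(i) if sexes[j] == "M"]
            females = [j for j in range(i) if sexes[j] == "F"]
            if males and rng.random() < 0.9:
                sire = f"I{rng.choice(males):04d}"
            if females and rng.random() < 0.9:
                dam = f"I{rng.choice(females):04d}"
        recs.append(PedigreeRecord(f"I{i:04d}", sire_id=sire, dam_id=dam, sex=sex))
        sexes.append(sex)
    return topological_sort_pedigree(recs)


@pytest.fixture
def trio():
    return topological_sort_pedigree(
        [
            PedigreeRecord("A", sex="M"),
            PedigreeRecord("B", sex="F"),
            PedigreeRecord("C", sire_id="A", dam_id="B", sex="M"),
        ]
    )


@pytest.fixture
def fullsib_inbred():
    """Two founders, two full sibs, and the sibs' (inbred) offspring."""
    return topological_sort_pedigree(
        [
            PedigreeRecord("A", sex="M"),
            PedigreeRecord("B", sex="F"),
            PedigreeRecord("S1", sire_id="A", dam_id="B", sex="M"),
            PedigreeRecord("S2", sire_id="A", dam_id="B", sex="F"),
            PedigreeRecord("O", sire_id="S1", dam_id="S2", sex="M"),
        ]
    )
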