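import pytest

from prediag.knowledge_base import DiseaseRecord, KnowledgeBase, SymptomRecord
from prediag.synthetic import SyntheticKBConfig, generate_disjoint_kb, generate_kb


def make_kb(symptoms, diseases, associations, n_observed=4, n_appeared=2,
            part_map=None):
    """Hand-build a small KB; parts default to observed i -> appeared ((i-1)%n)+1."""
    if part_map is None:
        part_map = {i: (i - 1) % n_appeared + 1 for i in range(1, n_observed + 1)}
    return KnowledgeBase(
        symptoms=[SymptomRecord(*s) for s in symptoms],
        diseases=[DiseaseRecord(*d) for d in diseases],
        associations=[tuple(a) for a in associations],
        observed_parts={i: f"obs_{i}" for i in range(1, n_observed + 1)},
        appeared_parts={i: f"app_{i}" for i in range(1, n_appeared + 1)},
        part_map=part_map,
    )


@pytest.fixture
def toy_kb():
    """2 diseases x 3 symptoms; disease 1 on part 1 has symptoms {1,2},
    disease 2 on part 2 has symptom {3}. Parts: observed==appeared (identity)."""
    return make_kb(
        symptoms=[(1, "itch", 1), (2, "hair loss", 1), (3, "cough", 2)],
        diseases=[(1, "dermatitis", 1), (2, "bronchitis", 2)],
        associations=[(1, 1, 1), (2, 1, 2), (3, 2, 3)],
        n_observed=2, n_appeared=2, part_map={1: 1, 2: 2},
    )


@pytest.fixture(scope="session")
def disjoint_kb():
    """20 diseases x 5 private symptoms each, part-consistent (oracle fixture)."""
    return generate_disjoint_kb(20, symptoms_per_disease=5, parts=6, seed=7)


@pytest.fixture(scope="session")
def default_kb():
    """Full-scale synthetic KB at the reference database's statistics."""
    return generate_kb(SyntheticKBConfig(seed=11))
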