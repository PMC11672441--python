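"""Seeded synthetic knowledge-base generators.

The reference database behind this system (textbook-derived canine
symptoms and diseases) is not publicly distributable, so these generators
produce structurally comparable stand-ins: 241 symptoms over 16 observed
parts, 249 diseases over 12 appeared parts, 3-12 symptoms per disease, a
surjective observed→appeared part map, and at least 50 diseases with >= 5
symptoms. Disease-symptom draws are part-coherent with a configurable
cross-part contamination rate ``rho``: with probability 1−rho a disease
draws a symptom whose observed part maps onto the disease's own appeared
part, otherwise from any other part's pool.

``generate_disjoint_kb`` builds the oracle fixture: pairwise-disjoint,
part-consistent symptom sets, so the unique maximal-overlap disease for any
noiseless query is its target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knowledge_base import (
    DiseaseRecord,
    KnowledgeBase,
    SymptomRecord,
    validate_kb,
)

__all__ = ["SyntheticKBConfig", "generate_kb", "generate_disjoint_kb"]


@dataclass(frozen=True)
class SyntheticKBConfig:
    n_symptoms: int = 241
    n_diseases: int = 249
    n_observed_parts: int = 16
    n_appeared_parts: int = 12
    symptoms_per_disease: tuple[int, int] = (3, 12)
    cross_part_rate: float = 0.2
    min_eligible: int = 50
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_observed_parts < self.n_appeared_parts or self.n_appeared_parts < 1:
            raise ValueError("need n_observed_parts >= n_appeared_parts >= 1")
        lo, hi = self.symptoms_per_disease
        if lo < 1 or hi < lo:
            raise ValueError("symptoms_per_disease range must satisfy 1 <= lo <= hi")
        if not 0 <= self.cross_part_rate <= 1:
            raise ValueError("cross_part_rate must be in [0, 1]")
        if hi > self.n_symptoms:
            raise ValueError("per-disease symptom count cannot exceed the symptom pool")


def _vocab(prefix: str, n: int) -> dict[int, str]:
    return {i: f"{prefix}_{i:02d}" for i in range(1, n + 1)}


def _attempt(config: SyntheticKBConfig, rng: np.random.Generator) -> KnowledgeBase:
    n_op, n_ap = config.n_observed_parts, config.n_appeared_parts

    # Surjective observed->appeared map: a permuted block covers every
    # appeared part, the remaining observed parts map uniformly.
    targets = list(rng.permutation(np.arange(1, n_ap + 1)))
    targets += [int(p) for p in rng.integers(1, n_ap + 1, size=n_op - n_ap)]
    part_map = {op: int(targets[op - 1]) for op in range(1, n_op + 1)}

    observed_of = rng.integers(1, n_op + 1, size=config.n_symptoms)
    symptoms = [
        SymptomRecord(i + 1, f"symptom_{i + 1:03d}", int(observed_of[i]))
        for i in range(config.n_symptoms)
    ]
    mapped = np.array([part_map[int(p)] for p in observed_of])  # per symptom

    appeared_of = rng.integers(1, n_ap + 1, size=config.n_diseases)
    diseases = [
        DiseaseRecord(i + 1, f"disease_{i + 1:03d}", int(appeared_of[i]))
        for i in range(config.n_diseases)
    ]

    pools = {p: np.flatnonzero(mapped == p) + 1 for p in range(1, n_ap + 1)}
    all_ids = np.arange(1, config.n_symptoms + 1)

    lo, hi = config.symptoms_per_disease
    associations: list[tuple[int, int, int]] = []
    aid = 1
    for d in diseases:
        n_s = int(rng.integers(lo, hi + 1))
        own = pools[d.appeared_part]
        other = all_ids[~np.isin(all_ids, own)]
        k_own = int(rng.binomial(n_s, 1.0 - config.cross_part_rate))
        k_own = min(k_own, len(own))
        k_other = min(n_s - k_own, len(other))
        chosen: list[int] = []
        if k_own:
            chosen += [int(s) for s in rng.choice(own, size=k_own, replace=False)]
        if k_other:
            chosen += [int(s) for s in rng.choice(other, size=k_other, replace=False)]
        for s in sorted(chosen):
            associations.append((aid, d.disease_id, s))
            aid += 1

    return KnowledgeBase(
        symptoms=symptoms,
        diseases=diseases,
        associations=associations,
        observed_parts=_vocab("observed", n_op),
        appeared_parts=_vocab("appeared", n_ap),
        part_map=part_map,
    )


def generate_kb(config: SyntheticKBConfig | None = None) -> KnowledgeBase:
    """Generate a seeded synthetic knowledge base at the configured scale.

    Regenerates with a fresh sub-seed until at least ``min_eligible``
    diseases carry >= 5 symptoms; raises after ``max_retries`` attempts.
    """
    config = config or SyntheticKBConfig()
    master = np.random.default_rng(config.seed)
    for _ in range(config.max_retries):
        rng = np.random.default_rng(int(master.integers(2**31)))
        kb = _attempt(config, rng)
        counts = kb.incidence_matrix.sum(axis=1)
        if int((counts >= 5).sum()) >= config.min_eligible:
            violations = validate_kb(kb)
            if violations:  # pragma: no cover - generator bug guard
                raise RuntimeError(f"generated KB failed validation: {violations}")
            return kb
    raise RuntimeError(
        f"could not satisfy min_eligible={config.min_eligible} within "
        f"{config.max_retries} attempts; config likely infeasible"
    )


def generate_disjoint_kb(
    n_diseases: int,
    symptoms_per_disease: int = 5,
    parts: int = 12,
    seed: int = 0,
) -> KnowledgeBase:
    """Oracle fixture: pairwise-disjoint, part-consistent symptom sets.

    Disease i owns its private block of ``symptoms_per_disease`` symptoms,
    all registered on the disease's own part (identity part map), so any
    query drawn from one disease overlaps no other.
    """
    if n_diseases < 1 or symptoms_per_disease < 1 or parts < 1:
        raise ValueError("n_diseases, symptoms_per_disease and parts must be >= 1")
    rng = np.random.default_rng(seed)
    disease_parts = [int(p) for p in rng.integers(1, parts + 1, size=n_diseases)]

    symptoms: list[SymptomRecord] = []
    diseases: list[DiseaseRecord] = []
    associations: list[tuple[int, int, int]] = []
    sid = 1
    aid = 1
    for i in range(n_diseases):
        z = i + 1
        part = disease_parts[i]
        diseases.append(DiseaseRecord(z, f"disease_{z:03d}", part))
        for _ in range(symptoms_per_disease):
            symptoms.append(SymptomRecord(sid, f"symptom_{sid:03d}", part))
            associations.append((aid, z, sid))
            sid += 1
            aid += 1

    kb = KnowledgeBase(
        symptoms=symptoms,
        diseases=diseases,
        associations=associations,
        observed_parts=_vocab("observed", parts),
        appeared_parts=_vocab("appeared", parts),
        part_map={p: p for p in range(1, parts + 1)},
    )
    violations = validate_kb(kb)
    if violations:  # pragma: no cover
        raise RuntimeError(f"generated KB failed validation: {violations}")
    return kb
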