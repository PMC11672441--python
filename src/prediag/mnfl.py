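"""Multi-layered neuro-fuzzy learner (MNFL).

The engine is a four-layer feed-forward structure over the knowledge base.
Only the query's symptom nodes are active in the input layer; three weight
systems then score every disease:

* **W1 — symptom relevance.** Each symptom is placed at coordinates
  ``(n_diseases/N_D, n_parts/N_P)``: the normalised number of diseases that
  present it and the normalised number of appeared parts those diseases span.
  A symptom shared by few diseases on few body systems is *specific*; its
  point lies near the "related" centroid (0,0) and gets fuzzy membership
  (weight) near 1. A ubiquitous, unspecific symptom lies near the
  "unrelated" centroid (1,1) and is damped toward 0.

* **W2 — part-consistent symptom-disease connection.** The query symptom's
  observed part is projected onto an appeared part via the part map. For
  diseases manifesting on a *different* part the connection weight is the
  fixed penalty −0.5. Among same-part candidate diseases the weight is the
  fuzzy membership computed from Euclidean distances between the symptom's
  one-hot indicator and each candidate's L1-normalised symptom profile, so
  diseases in which the symptom is more specific sit closer and receive more
  weight.

* **Disease activation.** A disease's net input is the mean over query
  symptoms of ``w1 * w2``; diseases with strictly positive output are
  *activated*. Part-mismatched symptoms therefore drag a disease's
  activation down instead of merely not helping — this is what blunts the
  cascade of a wrong observation.

* **W3 — disease-neighbourhood refinement.** For each activated candidate
  target t, every activated disease z is placed at
  ``x = 1 - |S_z ∩ S_t| / max(|S_z|,|S_t|)`` (shared-symptom dissimilarity)
  and ``y = 1 - ||S_z|-|S_t|| / max(|S_z|,|S_t|)`` (size agreement), so the
  target itself sits exactly at (0,1). Membership toward the target centroid
  (0,1) against the anti-centroid (1,0), weighted by each disease's
  activation and averaged over activated nodes, gives the final score.

The final ranking keeps the top five scores, ties broken by ascending id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fuzzy import FuzzyConfig, fuzzy_membership, membership_matrix
from .knowledge_base import KnowledgeBase, Query
from .ranking import TOP_K, RankedDiagnosis

__all__ = [
    "SymptomCoords",
    "W1Weights",
    "W2Weights",
    "DiseaseActivation",
    "compute_symptom_coords",
    "compute_w1",
    "compute_w2",
    "activate_diseases",
    "refine_w3",
    "mnfl_infer",
]

logger = logging.getLogger(__name__)

PART_MISMATCH_PENALTY = -0.5


@dataclass(frozen=True)
class SymptomCoords:
    """Per-symptom (x, y) relevance coordinates, aligned with ``kb.symptom_ids``."""

    symptom_ids: np.ndarray
    x: np.ndarray  # n_diseases(s) / N_D
    y: np.ndarray  # n_appeared_parts(s) / N_P


@dataclass(frozen=True)
class W1Weights:
    """Per-query-symptom relevance weights (input activation x_k = 1, y_k = w_k)."""

    symptom_ids: tuple[int, ...]
    d_related: np.ndarray
    d_unrelated: np.ndarray
    u: np.ndarray  # membership to the Related cluster
    w: np.ndarray  # = u


@dataclass(frozen=True)
class W2Weights:
    """(query symptom x disease) connection weights; −0.5 marks part mismatch."""

    symptom_ids: tuple[int, ...]
    disease_ids: np.ndarray
    w: np.ndarray  # shape (n_query, n_diseases)


@dataclass(frozen=True)
class DiseaseActivation:
    disease_ids: np.ndarray
    y: np.ndarray          # mean weighted input per disease
    activated: np.ndarray  # boolean, y > 0
    n: int                 # query length


def compute_symptom_coords(kb: KnowledgeBase) -> SymptomCoords:
    """Place every symptom in the W1 relevance plane.

    x is the fraction of diseases presenting the symptom; y the fraction of
    appeared parts covered by those diseases. A symptom in no disease sits
    at (0, 0).
    """
    inc = kb.incidence_matrix
    n_d = max(len(kb.disease_ids), 1)
    n_p = max(len(kb.appeared_parts), 1)
    x = inc.sum(axis=0) / n_d

    part_ids = np.array(sorted(kb.appeared_parts), dtype=int)
    onehot = (kb.disease_appeared[None, :] == part_ids[:, None])  # parts x diseases
    covered = (onehot.astype(np.int32) @ inc) > 0                 # parts x symptoms
    y = covered.sum(axis=0) / n_p
    return SymptomCoords(symptom_ids=kb.symptom_ids, x=x, y=y)


def compute_w1(
    kb: KnowledgeBase, query: Query, config: FuzzyConfig | None = None
) -> W1Weights:
    """W1 relevance weight for each query symptom (membership to (0,0) vs (1,1))."""
    config = config or FuzzyConfig()
    query.validate_against(kb)
    coords = compute_symptom_coords(kb)
    idx = np.array([kb.symptom_index[s] for s in query.symptom_ids])
    x, y = coords.x[idx], coords.y[idx]
    d0 = np.hypot(x, y)
    d1 = np.hypot(x - 1.0, y - 1.0)
    u = membership_matrix(
        np.column_stack([d0, d1]), m=config.m, zero_tol=config.epsilon
    )[:, 0]
    return W1Weights(
        symptom_ids=query.symptom_ids, d_related=d0, d_unrelated=d1, u=u, w=u
    )


def compute_w2(
    kb: KnowledgeBase, query: Query, config: FuzzyConfig | None = None
) -> W2Weights:
    """Part-consistent connection weights between query symptoms and diseases.

    For each query symptom the observed part is mapped to an appeared part;
    diseases on any other part receive the fixed −0.5 penalty. Within the
    same-part candidate set, weights are fuzzy memberships over Euclidean
    distances from the symptom's one-hot indicator to each candidate's
    normalised symptom profile (memberships sum to 1 over the candidates).
    """
    config = config or FuzzyConfig()
    query.validate_against(kb)
    n_dis = len(kb.disease_ids)
    w = np.full((len(query), n_dis), PART_MISMATCH_PENALTY)
    sq_norms = kb.profile_sq_norms
    for i, (obs_part, sid) in enumerate(query.entries):
        p = kb.mapped_part(obs_part)
        cand = np.flatnonzero(kb.disease_appeared == p)
        if cand.size == 0:
            logger.warning(
                "no candidate disease on appeared part %d for symptom %d; "
                "all diseases penalized", p, sid)
            continue
        k = kb.symptom_index[sid]
        d_sq = 1.0 - 2.0 * kb.profiles[cand, k] + sq_norms[cand]
        d = np.sqrt(np.clip(d_sq, 0.0, None))
        u = fuzzy_membership(d, m=config.m, zero_tol=config.epsilon)
        w[i, cand] = np.where(u > 0, u, PART_MISMATCH_PENALTY)
    return W2Weights(symptom_ids=query.symptom_ids, disease_ids=kb.disease_ids, w=w)


def activate_diseases(w1: W1Weights, w2: W2Weights, query: Query) -> DiseaseActivation:
    """Mean weighted input per disease: y_z = (1/n) Σ_i w1_i · w2_zi (x_i = 1)."""
    if w1.symptom_ids != query.symptom_ids or w2.symptom_ids != query.symptom_ids:
        raise ValueError("w1/w2 were not computed from this query")
    n = len(query)
    y = (w1.w @ w2.w) / n
    return DiseaseActivation(
        disease_ids=w2.disease_ids, y=y, activated=y > 0, n=n
    )


def refine_w3(
    kb: KnowledgeBase,
    activations: DiseaseActivation,
    config: FuzzyConfig | None = None,
) -> dict[int, float]:
    """Neighbourhood-refined final score for every activated candidate target.

    Returns {disease_id: final_score} over activated diseases; empty when
    nothing is activated (no inference possible).
    """
    config = config or FuzzyConfig()
    act_idx = np.flatnonzero(activations.activated)
    n_act = act_idx.size
    if n_act == 0:
        return {}
    act_ids = activations.disease_ids[act_idx]
    act_y = activations.y[act_idx]

    rows = np.array([kb.disease_index[int(z)] for z in act_ids])
    inc = kb.incidence_matrix[rows].astype(np.int64)
    sizes = inc.sum(axis=1)
    overlap = inc @ inc.T
    max_sz = np.maximum.outer(sizes, sizes)
    max_sz = np.maximum(max_sz, 1)  # activated diseases always have symptoms
    x = 1.0 - overlap / max_sz
    y = 1.0 - np.abs(np.subtract.outer(sizes, sizes)) / max_sz

    d_target = np.hypot(x, y - 1.0)   # centroid (0, 1): the target itself
    d_anti = np.hypot(x - 1.0, y)     # anti-centroid (1, 0)
    u = membership_matrix(
        np.stack([d_target.ravel(), d_anti.ravel()], axis=1),
        m=config.m, zero_tol=config.epsilon,
    )[:, 0].reshape(n_act, n_act)

    scores = (u * act_y[None, :]).sum(axis=1) / n_act
    return {int(z): float(s) for z, s in zip(act_ids, scores)}


def mnfl_infer(
    kb: KnowledgeBase, query: Query, config: FuzzyConfig | None = None
) -> RankedDiagnosis:
    """Full MNFL pipeline: W1 → W2 → activation → W3 → top-5 ranking."""
    config = config or FuzzyConfig()
    w1 = compute_w1(kb, query, config)
    w2 = compute_w2(kb, query, config)
    act = activate_diseases(w1, w2, query)
    scores = refine_w3(kb, act, config)
    if not scores:
        return RankedDiagnosis.empty()
    ids = list(scores)
    return RankedDiagnosis.from_scores(ids, [scores[z] for z in ids], k=TOP_K)
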