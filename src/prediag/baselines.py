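"""Comparator inference engines: the PFCM-R clustering family and FHAL.

**PFCM-R.** Fuzzy c-means (FCM) is noise-sensitive; possibilistic c-means
(PCM) relaxes the sum-to-one constraint and reads memberships as
*typicalities*, but tends to produce coincident clusters. PFCM blends both
objectives,

    J = Σ_ik (a·u_ik^m + b·t_ik^η) d_ik² + Σ_i γ_i Σ_k (1 − t_ik)^η ,

with memberships u (rows summing to 1) and typicalities t in [0,1]. The
regularized variant implemented here adds a quadratic membership penalty
``λ Σ u²`` that flattens the solution surface — memberships are pulled
toward uniform, which stabilises fits on small data. The regularised
membership update has the closed form ``u_ik ∝ 1/(a·d_ik² + λ)``, exact for
membership fuzzifier m = 2 (the default); for λ > 0 with m ≠ 2 the fit
refuses rather than silently breaking the descent guarantee.

For diagnosis, each disease is a *fixed prototype* — its L1-normalised
symptom profile — and the query is embedded as the normalised indicator of
its symptoms. The score blends fuzzy membership over distances to all
prototypes with possibilistic typicality (``score = a·u + b·t``).

**FHAL.** A double-layered fuzzy association learner. The input layer holds
the query symptoms, the middle layer the 12 appeared body parts, and the
output layer the diseases. Three count-derived matrices connect them: w1
(how strongly a symptom points at each part), w2 (how strongly a part
points at each disease, weighted by repertoire size) and w3 (direct
symptom→disease association, 1/|S_z| per presented symptom). The first
layer elects a dominant part and filters query symptoms whose support for
it falls below ``τ`` times the dominant part's mean per-symptom support —
this is how wrongly observed symptoms are kept out of the second cycle.
The final score blends the direct and the part-mediated indirect routes
with weight ``α``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fuzzy import FuzzyConfig, fuzzy_membership, membership_matrix
from .knowledge_base import KnowledgeBase, Query
from .ranking import TOP_K, RankedDiagnosis

__all__ = [
    "PFCMParams",
    "ClusterModel",
    "FHALWeights",
    "fcm_fit",
    "pfcm_r_fit",
    "pfcmr_infer",
    "fhal_train",
    "fhal_infer",
]

logger = logging.getLogger(__name__)

_GAMMA_FLOOR = 1e-12


@dataclass(frozen=True)
class PFCMParams:
    """PFCM-R blend parameters.

    a, b  -- weights of the membership and typicality terms (a+b > 0)
    eta   -- typicality exponent (> 1)
    gamma -- per-cluster penalty scales; None = estimate from an FCM pre-pass
    lam   -- quadratic membership regularization strength (>= 0)
    """

    a: float = 1.0
    b: float = 1.0
    eta: float = 2.0
    gamma: np.ndarray | None = None
    lam: float = 0.1

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise ValueError("need a >= 0, b >= 0, a + b > 0")
        if not self.eta > 1:
            raise ValueError("eta must be > 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class ClusterModel:
    centroids: np.ndarray
    memberships: np.ndarray
    typicalities: np.ndarray | None
    objective_trace: list[float]
    converged: bool


def _kmeanspp_init(points: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++-style centroid draw from the data."""
    n = points.shape[0]
    centroids = [points[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((points[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(-1),
            axis=1,
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids.append(points[rng.integers(n)])
        else:
            centroids.append(points[rng.choice(n, p=d2 / total)])
    return np.asarray(centroids, dtype=float)


def _distance_matrix(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return np.sqrt(
        np.maximum(
            ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(-1), 0.0
        )
    )


def fcm_fit(points, c: int, config: FuzzyConfig | None = None) -> ClusterModel:
    """Standard fuzzy c-means with seeded k-means++ initialisation.

    Alternates exact membership and centroid updates, so the recorded
    objective trace is non-increasing.
    """
    config = config or FuzzyConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if c < 1 or c > n:
        raise ValueError(f"cluster count c={c} must be in 1..{n}")
    rng = np.random.default_rng(config.seed)
    v = _kmeanspp_init(pts, c, rng)

    trace: list[float] = []
    converged = False
    u = np.full((n, c), 1.0 / c)
    for _ in range(config.max_iter):
        d = _distance_matrix(pts, v)
        u = membership_matrix(d, m=config.m, zero_tol=config.epsilon)
        um = u ** config.m
        denom = um.sum(axis=0)
        v = np.where(
            denom[:, None] > 0, (um.T @ pts) / np.maximum(denom, 1e-300)[:, None], v
        )
        d = _distance_matrix(pts, v)
        j = float((um * d**2).sum())
        trace.append(j)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < config.tol:
            converged = True
            break
    return ClusterModel(
        centroids=v, memberships=u, typicalities=None,
        objective_trace=trace, converged=converged,
    )


def _pfcm_memberships(
    d: np.ndarray, params: PFCMParams, config: FuzzyConfig
) -> np.ndarray:
    if params.lam == 0:
        return membership_matrix(d, m=config.m, zero_tol=config.epsilon)
    if config.m != 2.0:
        raise ValueError(
            "the quadratic membership regularizer (lam > 0) requires m = 2"
        )
    inv = 1.0 / (params.a * d**2 + params.lam)
    return inv / inv.sum(axis=1, keepdims=True)


def _typicalities(d: np.ndarray, gamma: np.ndarray, params: PFCMParams) -> np.ndarray:
    if params.b == 0:
        return np.ones_like(d)
    ratio = params.b * d**2 / np.maximum(gamma[None, :], _GAMMA_FLOOR)
    return 1.0 / (1.0 + ratio ** (1.0 / (params.eta - 1.0)))


def pfcm_r_fit(
    points,
    c: int,
    params: PFCMParams | None = None,
    config: FuzzyConfig | None = None,
) -> ClusterModel:
    """Regularized possibilistic fuzzy c-means fit.

    An FCM pre-pass supplies the initial centroids and the per-cluster
    penalty scales γ_i (within-cluster mean fuzzy distance); then membership,
    typicality and centroid updates alternate, each exactly minimising its
    block of the objective, so the trace is non-increasing.
    """
    params = params or PFCMParams()
    config = config or FuzzyConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if c < 1 or c > n:
        raise ValueError(f"cluster count c={c} must be in 1..{n}")

    pre = fcm_fit(pts, c, config)
    v = pre.centroids.copy()
    if params.gamma is not None:
        gamma = np.asarray(params.gamma, dtype=float)
    else:
        d = _distance_matrix(pts, v)
        um = pre.memberships ** config.m
        gamma = (um * d**2).sum(axis=0) / np.maximum(um.sum(axis=0), _GAMMA_FLOOR)
    gamma = np.maximum(gamma, _GAMMA_FLOOR)

    trace: list[float] = []
    converged = False
    u = pre.memberships
    t = np.ones((n, c))
    for _ in range(config.max_iter):
        d = _distance_matrix(pts, v)
        u = _pfcm_memberships(d, params, config)
        t = _typicalities(d, gamma, params)
        wgt = params.a * u**config.m + params.b * t**params.eta
        denom = wgt.sum(axis=0)
        v = np.where(
            denom[:, None] > 0, (wgt.T @ pts) / np.maximum(denom, 1e-300)[:, None], v
        )
        d = _distance_matrix(pts, v)
        wgt = params.a * u**config.m + params.b * t**params.eta
        j = float(
            (wgt * d**2).sum()
            + (gamma * ((1.0 - t) ** params.eta).sum(axis=0)).sum()
            + params.lam * (u**2).sum()
        )
        trace.append(j)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < config.tol:
            converged = True
            break
    return ClusterModel(
        centroids=v, memberships=u, typicalities=t,
        objective_trace=trace, converged=converged,
    )


def _prototype_gamma(profiles: np.ndarray) -> float:
    """Scalar typicality scale: mean pairwise squared distance among prototypes."""
    n = profiles.shape[0]
    if n < 2:
        return 1.0
    sq = np.einsum("ij,ij->i", profiles, profiles)
    total = 2.0 * n * sq.sum() - 2.0 * float(profiles.sum(axis=0) @ profiles.sum(axis=0))
    return max(total / (n * (n - 1)), _GAMMA_FLOOR)


def pfcmr_infer(
    kb: KnowledgeBase,
    query: Query,
    params: PFCMParams | None = None,
    config: FuzzyConfig | None = None,
) -> RankedDiagnosis:
    """Prototype-based PFCM-R diagnosis.

    Each disease is a fixed prototype (its L1-normalised symptom profile);
    the query is embedded as the normalised indicator of its symptoms, and
    ``score_z = a·u_z + b·t_z`` blends fuzzy membership over distances to
    all prototypes with possibilistic typicality at a scale set by the
    prototype cloud itself.
    """
    params = params or PFCMParams()
    config = config or FuzzyConfig()
    query.validate_against(kb)
    q = np.zeros(len(kb.symptom_ids))
    for sid in query.symptom_ids:
        q[kb.symptom_index[sid]] = 1.0
    q /= q.sum()

    diff = kb.profiles - q[None, :]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    u = fuzzy_membership(d, m=config.m, zero_tol=config.epsilon)
    gamma = np.full(d.shape, _prototype_gamma(kb.profiles))
    t = _typicalities(d[None, :], gamma, params)[0]
    scores = params.a * u + params.b * t
    return RankedDiagnosis.from_scores(kb.disease_ids, scores, k=TOP_K)


# ---------------------------------------------------------------------------
# FHAL
# ---------------------------------------------------------------------------

@dataclass
class FHALWeights:
    """Trained association matrices of the double-layered learner.

    w1 -- (symptom x part): fraction of the symptom's diseases on each part
    w2 -- (part x disease): size-weighted indicator, row-normalised per part
    w3 -- (symptom x disease): 1/|S_z| for associated pairs, else 0
    tau -- first-layer pass fraction in (0, 1]
    alpha -- direct/indirect blend in [0, 1]
    """

    part_ids: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    tau: float = 0.5
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def fhal_train(kb: KnowledgeBase, tau: float = 0.5, alpha: float = 0.5) -> FHALWeights:
    """Derive the three FHAL association matrices from knowledge-base counts."""
    inc = kb.incidence_matrix.astype(float)  # diseases x symptoms
    part_ids = np.array(sorted(kb.appeared_parts), dtype=int)
    onpart = (kb.disease_appeared[None, :] == part_ids[:, None]).astype(float)

    # w1[s, p]: of the diseases containing s, the fraction appearing on part p
    count_sp = (onpart @ inc).T                       # symptoms x parts
    totals = count_sp.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(totals > 0, count_sp / totals, 0.0)

    # w2[p, z]: indicator that z appears on p, weighted by |S_z|, row-normalised
    sizes = inc.sum(axis=1)                           # |S_z|
    weighted = onpart * sizes[None, :]
    rowsum = weighted.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w2 = np.where(rowsum > 0, weighted / rowsum, 0.0)

    # w3[s, z]: direct association strength
    with np.errstate(invalid="ignore", divide="ignore"):
        w3 = np.where(sizes[None, :] > 0, inc.T / sizes[None, :], 0.0)

    return FHALWeights(part_ids=part_ids, w1=w1, w2=w2, w3=w3, tau=tau, alpha=alpha)


def fhal_infer(
    kb: KnowledgeBase,
    weights: FHALWeights,
    query: Query,
    config: FuzzyConfig | None = None,
) -> RankedDiagnosis:
    """Double-layered inference: dominant-part filtering, then blended scoring.

    The first layer accumulates part activations A_p = Σ_{s∈query} w1[s,p],
    elects the dominant part p* (ties to the smaller id) and retains only
    query symptoms with w1[s,p*] >= tau·(A_{p*}/n). Retained symptoms drive
    the indirect (part-mediated) route; the direct route always uses the
    full query. If every symptom is filtered, scoring falls back to the
    direct route alone.
    """
    query.validate_against(kb)
    qidx = np.array([kb.symptom_index[s] for s in query.symptom_ids])
    n = len(query)

    a_part = weights.w1[qidx].sum(axis=0)
    p_star = int(np.argmax(a_part))  # part_ids sorted => first max = smallest id
    threshold = weights.tau * a_part[p_star] / n
    retained = qidx[weights.w1[qidx, p_star] >= threshold]

    direct = weights.w3[qidx].sum(axis=0)
    if retained.size == 0:
        logger.warning("all query symptoms filtered by the first layer; "
                       "using direct associations only")
        scores = direct
    else:
        part_pos = np.searchsorted(weights.part_ids, kb.disease_appeared)
        support = weights.w1[retained][:, part_pos].sum(axis=0)
        w2_own = weights.w2[part_pos, np.arange(len(kb.disease_ids))]
        indirect = support * w2_own
        scores = weights.alpha * direct + (1.0 - weights.alpha) * indirect
    return RankedDiagnosis.from_scores(kb.disease_ids, scores, k=TOP_K)
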