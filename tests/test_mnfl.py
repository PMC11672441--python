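import numpy as np
import pytest

from prediag.fuzzy import FuzzyConfig, fuzzy_membership
from prediag.knowledge_base import Query
from prediag.mnfl import (
    PART_MISMATCH_PENALTY,
    DiseaseActivation,
    W1Weights,
    W2Weights,
    activate_diseases,
    compute_symptom_coords,
    compute_w1,
    compute_w2,
    mnfl_infer,
    refine_w3,
)
from tests.conftest import make_kb


def query_for(kb, disease_id, n=None):
    sids = sorted(kb.disease_symptoms[disease_id])
    if n is not None:
        sids = sids[:n]
    return Query(tuple((kb.symptom_by_id[s].observed_part, s) for s in sids))


class TestSymptomCoords:
    def test_counting_oracle(self):
        # 10 diseases, 12 appeared parts; symptom 1 in 2 diseases on 1 part
        kb = make_kb(
            symptoms=[(1, "s1", 1), (2, "s2", 1)],
            diseases=[(i, f"d{i}", (i - 1) % 12 + 1) for i in range(1, 11)],
            associations=[(1, 1, 1), (2, 2, 1)],  # diseases 1,2 both on part 1/2
            n_observed=12, n_appeared=12,
            part_map={i: i for i in range(1, 13)},
        )
        coords = compute_symptom_coords(kb)
        i = kb.symptom_index[1]
        n_dis, n_parts = 2, 2  # diseases 1 (part 1) and 2 (part 2)
        assert coords.x[i] == pytest.approx(n_dis / 10)
        assert coords.y[i] == pytest.approx(n_parts / 12)
        # orphan symptom sits at the Related centroid
        j = kb.symptom_index[2]
        assert (coords.x[j], coords.y[j]) == (0.0, 0.0)

    def test_ubiquitous_symptom_at_opposite_corner(self):
        kb = make_kb(
            symptoms=[(1, "s", 1)],
            diseases=[(1, "d1", 1), (2, "d2", 2)],
            associations=[(1, 1, 1), (2, 2, 1)],
            n_observed=2, n_appeared=2, part_map={1: 1, 2: 2},
        )
        coords = compute_symptom_coords(kb)
        assert (coords.x[0], coords.y[0]) == (1.0, 1.0)


class TestW1:
    def test_centroid_extremes(self):
        # symptom 1 ubiquitous -> (1,1) -> weight 0; symptom 2 specific
        kb = make_kb(
            symptoms=[(1, "common", 1), (2, "specific", 1)],
            diseases=[(1, "d1", 1), (2, "d2", 2)],
            associations=[(1, 1, 1), (2, 2, 1), (3, 1, 2)],
            n_observed=2, n_appeared=2, part_map={1: 1, 2: 2},
        )
        w1 = compute_w1(kb, Query(((1, 1), (1, 2))))
        assert w1.w[0] == pytest.approx(0.0)   # at the Unrelated centroid
        assert w1.w[1] == pytest.approx(0.5)   # (0.5, 0.5): equidistant

    def test_equidistant_point_gets_half(self):
        # 2 diseases, 2 appeared parts, symptom in 1 disease on 1 part -> (0.5, 0.5)
        kb = make_kb(
            symptoms=[(1, "s", 1)],
            diseases=[(1, "d1", 1), (2, "d2", 2)],
            associations=[(1, 1, 1)],
            n_observed=2, n_appeared=2, part_map={1: 1, 2: 2},
        )
        w1 = compute_w1(kb, Query(((1, 1),)))
        assert w1.w[0] == pytest.approx(0.5)

    def test_orphan_symptom_fully_related(self, toy_kb):
        kb = make_kb(
            symptoms=[(1, "orphan", 1), (2, "s", 1)],
            diseases=[(1, "d", 1)],
            associations=[(1, 1, 2)],
            n_observed=2, n_appeared=2, part_map={1: 1, 2: 2},
        )
        w1 = compute_w1(kb, Query(((1, 1),)))
        assert w1.w[0] == pytest.approx(1.0)


class TestW2:
    def test_part_mismatch_gets_exact_penalty(self, toy_kb):
        # symptom 3 maps to appeared part 2; disease 1 appears on part 1
        w2 = compute_w2(toy_kb, Query(((2, 3),)))
        z = np.where(w2.disease_ids == 1)[0][0]
        assert w2.w[0, z] == PART_MISMATCH_PENALTY

    def test_single_candidate_gets_full_weight(self, toy_kb):
        # only disease 2 appears on part 2
        w2 = compute_w2(toy_kb, Query(((2, 3),)))
        z = np.where(w2.disease_ids == 2)[0][0]
        assert w2.w[0, z] == pytest.approx(1.0)

    def test_candidate_memberships_match_profile_distances(self):
        # two candidates on the matching part; dual-route check against the
        # membership formula applied to hand-computed profile distances
        kb = make_kb(
            symptoms=[(1, "s1", 1), (2, "s2", 1), (3, "s3", 1)],
            diseases=[(1, "contains s1", 1), (2, "does not", 1)],
            associations=[(1, 1, 1), (2, 1, 2), (3, 2, 2), (4, 2, 3)],
            n_observed=1, n_appeared=1, part_map={1: 1},
        )
        w2 = compute_w2(kb, Query(((1, 1),)))
        # profiles: d1 = (.5,.5,0), d2 = (0,.5,.5); one-hot e1 = (1,0,0)
        d = np.array([np.sqrt(0.25 + 0.25), np.sqrt(1 + 0.25 + 0.25)])
        expected = fuzzy_membership(d, m=2.0)
        assert w2.w[0] == pytest.approx(expected, abs=1e-12)
        assert w2.w[0].sum() == pytest.approx(1.0)


class TestActivation:
    def _mk(self, w1_vals, w2_matrix, query):
        w1 = W1Weights(
            symptom_ids=query.symptom_ids,
            d_related=np.zeros(len(query)), d_unrelated=np.ones(len(query)),
            u=np.asarray(w1_vals, float), w=np.asarray(w1_vals, float),
        )
        w2m = np.asarray(w2_matrix, float)
        w2 = W2Weights(
            symptom_ids=query.symptom_ids,
            disease_ids=np.arange(1, w2m.shape[1] + 1), w=w2m,
        )
        return w1, w2

    def test_all_mismatched_hits_penalty_floor(self):
        q = Query(((1, 1), (1, 2)))
        w1, w2 = self._mk([1.0, 1.0], [[-0.5], [-0.5]], q)
        act = activate_diseases(w1, w2, q)
        assert act.y[0] == pytest.approx(-0.5)
        assert not act.activated[0]

    def test_single_term_mean(self):
        q = Query(((1, 1),))
        w1, w2 = self._mk([0.8], [[1.0]], q)
        act = activate_diseases(w1, w2, q)
        assert act.y[0] == pytest.approx(0.8)

    def test_mixed_contributions_average(self):
        q = Query(((1, 1), (1, 2)))
        w1, w2 = self._mk([1.0, 1.0], [[1.0], [-0.5]], q)
        act = activate_diseases(w1, w2, q)
        assert act.y[0] == pytest.approx(0.25)
        assert act.activated[0]

    def test_rejects_mismatched_query(self):
        q1, q2 = Query(((1, 1),)), Query(((1, 2),))
        w1, w2 = self._mk([1.0], [[1.0]], q1)
        with pytest.raises(ValueError):
            activate_diseases(w1, w2, q2)


class TestW3:
    def test_single_activated_scores_own_activation(self, disjoint_kb):
        act = DiseaseActivation(
            disease_ids=np.array([3]), y=np.array([0.7]),
            activated=np.array([True]), n=5,
        )
        scores = refine_w3(disjoint_kb, act)
        assert scores == {3: pytest.approx(0.7)}

    def test_identical_symptom_sets_full_membership(self):
        kb = make_kb(
            symptoms=[(1, "a", 1), (2, "b", 1)],
            diseases=[(1, "d1", 1), (2, "d2", 1)],
            associations=[(1, 1, 1), (2, 1, 2), (3, 2, 1), (4, 2, 2)],
            n_observed=1, n_appeared=1, part_map={1: 1},
        )
        act = DiseaseActivation(
            disease_ids=np.array([1, 2]), y=np.array([0.5, 0.5]),
            activated=np.array([True, True]), n=2,
        )
        scores = refine_w3(kb, act)
        # both at (0,1) for either target: u = 1 for all pairs
        assert scores[1] == pytest.approx(0.5)
        assert scores[2] == pytest.approx(0.5)

    def test_disjoint_equal_size_neighbour(self, disjoint_kb):
        # disjoint, equal-sized sets land at (1,1): equidistant -> u = 0.5
        act = DiseaseActivation(
            disease_ids=np.array([1, 2]), y=np.array([0.6, 0.4]),
            activated=np.array([True, True]), n=5,
        )
        scores = refine_w3(disjoint_kb, act)
        assert scores[1] == pytest.approx((1.0 * 0.6 + 0.5 * 0.4) / 2)
        assert scores[2] == pytest.approx((0.5 * 0.6 + 1.0 * 0.4) / 2)

    def test_no_activation_yields_empty(self, disjoint_kb):
        act = DiseaseActivation(
            disease_ids=np.array([1]), y=np.array([-0.1]),
            activated=np.array([False]), n=5,
        )
        assert refine_w3(disjoint_kb, act) == {}


class TestInference:
    def test_disjoint_kb_recovers_every_target(self, disjoint_kb):
        for z in disjoint_kb.disease_ids:
            ranking = mnfl_infer(disjoint_kb, query_for(disjoint_kb, int(z)))
            assert ranking.disease_ids[0] == z

    def test_ranking_never_exceeds_five(self, default_kb):
        q = query_for(default_kb, eligible_first(default_kb), n=5)
        assert len(mnfl_infer(default_kb, q)) <= 5

    def test_permutation_invariance(self, disjoint_kb):
        q = query_for(disjoint_kb, 5)
        perm = Query(tuple(reversed(q.entries)))
        assert mnfl_infer(disjoint_kb, q) == mnfl_infer(disjoint_kb, perm)

    def test_deterministic_across_runs(self, default_kb):
        q = query_for(default_kb, eligible_first(default_kb), n=5)
        assert mnfl_infer(default_kb, q) == mnfl_infer(default_kb, q)

    def test_tie_break_ascending_id(self):
        # two diseases with identical symptom sets tie exactly -> smaller id first
        # (a third disease keeps the query symptoms off the (1,1) corner)
        kb = make_kb(
            symptoms=[(1, "a", 1), (2, "b", 1), (3, "c", 1)],
            diseases=[(1, "d1", 1), (2, "d2", 1), (3, "d3", 1)],
            associations=[(1, 1, 1), (2, 1, 2), (3, 2, 1), (4, 2, 2), (5, 3, 3)],
            n_observed=1, n_appeared=1, part_map={1: 1},
        )
        ranking = mnfl_infer(kb, Query(((1, 1), (1, 2))))
        assert ranking.disease_ids[:2] == (1, 2)
        assert ranking.entries[0][1] == pytest.approx(ranking.entries[1][1])

    def test_appending_mismatched_symptom_never_raises_activation(self, default_kb):
        from prediag.knowledge_base import eligible_targets
        targets = eligible_targets(default_kb)[:10]
        for t in targets:
            q = query_for(default_kb, t, n=4)
            part_t = default_kb.disease_by_id[t].appeared_part
            extra = next(
                (int(s) for s in default_kb.symptom_ids
                 if default_kb.mapped_part(
                     default_kb.symptom_by_id[int(s)].observed_part) != part_t
                 and int(s) not in q.symptom_ids),
                None,
            )
            assert extra is not None
            q_plus = Query(q.entries + (
                (default_kb.symptom_by_id[extra].observed_part, extra),))
            zi = np.where(default_kb.disease_ids == t)[0][0]
            for query, label in [(q, "base"), (q_plus, "appended")]:
                w1 = compute_w1(default_kb, query)
                w2 = compute_w2(default_kb, query)
                act = activate_diseases(w1, w2, query)
                if label == "base":
                    base_y = act.y[zi]
                else:
                    assert act.y[zi] <= base_y + 1e-12


def eligible_first(kb):
    from prediag.knowledge_base import eligible_targets
    return eligible_targets(kb)[0]
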