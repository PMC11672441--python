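"""Rank diseases for one owner query with all three fuzzy engines.

Uses a disjoint-symptom oracle knowledge base (each disease owns a private,
part-consistent symptom block) so the correct answer is unambiguous: the
query below lists the five symptoms of disease 7, and every engine should
put disease 7 first.
"""

from prediag import ENGINE_NAMES, Query, generate_disjoint_kb, get_engine

kb = generate_disjoint_kb(n_diseases=20, symptoms_per_disease=5, parts=6, seed=1)

target = 7
entries = tuple(
    (kb.symptom_by_id[s].observed_part, s)
    for s in sorted(kb.disease_symptoms[target])
)
query = Query(entries)
print(f"query: symptoms of disease {target}: {list(query.symptom_ids)}\n")

for name in ENGINE_NAMES:
    ranking = get_engine(name).infer(kb, query)
    print(f"{name.upper():6s} top-5:")
    for z, score in ranking:
        mark = " <-- target" if z == target else ""
        print(f"   disease {z:3d}  score {score:.4f}{mark}")
# Scores are engine-specific fuzzy strengths (not probabilities); only the
# order matters, and all three engines recover the target at rank 1 here.
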