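"""Generate a synthetic symptom-disease knowledge base and inspect it.

The generator emulates the structure of a textbook-derived canine database:
241 observable symptoms over 16 owner-facing body parts, 249 diseases over
12 clinical body systems, and part-coherent symptom draws with 20%
cross-part contamination.
"""

from prediag import SyntheticKBConfig, eligible_targets, generate_kb, symptom_stats, write_kb

kb = generate_kb(SyntheticKBConfig(seed=42))

print(f"symptoms:  {len(kb.symptoms)} over {len(kb.observed_parts)} observed parts")
print(f"diseases:  {len(kb.diseases)} over {len(kb.appeared_parts)} appeared parts")
print(f"associations: {len(kb.associations)}")
print(f"eligible targets (>=5 symptoms): {len(eligible_targets(kb, 5))}")

sid = int(kb.symptom_ids[0])
n_dis, n_parts = symptom_stats(kb, sid)
print(f"symptom {sid}: occurs in {n_dis} diseases spanning {n_parts} body systems")
# A symptom in few diseases on few systems is highly specific -- the MNFL
# engine weights exactly this.

path = write_kb(kb, "scratch/example_kb", format="csv-dir")
print(f"wrote the six CSV tables to {path}/")
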