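# Methods

## Setting and data model

The system answers owner queries against a relational knowledge base of
five core tables — symptoms (each tagged with one of 16 *observed* body
parts, the owner-facing vocabulary), diseases (each tagged with one of 12
*appeared* body systems, the clinical vocabulary), a disease–symptom
association table, and the two part vocabularies — plus a sixth table
mapping each observed part to exactly one appeared part. The two
vocabularies are never linked by the tables themselves, yet every engine
must compare an owner's observed part with a disease's appeared part, so
the package makes the projection an explicit, required input (`part_map`)
rather than guessing a correspondence. Synthetic generators emit it;
hand-built knowledge bases must supply it.

From the associations a binary disease × symptom incidence matrix is
derived; its L1-normalised rows are the *disease profiles* used throughout.
A query is an ordered list of (observed part, symptom) pairs, 1–20 entries,
no duplicate symptoms, each pair's part agreeing with the symptom's
registered part.

Eligibility for benchmarking is `|S_z| ≥ min_symptoms` with default 5. The
source material states the threshold both as "more than five" and "at least
5"; we adopt ≥ 5 and expose the parameter.

## Shared membership rule

All engines use the fuzzy c-means membership function: for distances
`d_1..d_c` to `c` centroids and fuzzifier `m > 1`,
`u_i = 1 / Σ_j (d_i/d_j)^{2/(m−1)}`. Memberships lie in [0,1] and sum to 1.
When a distance falls at or below the floor `ε = 1e-12` the point is taken
to coincide with that centroid and the unit membership is split equally
among all coincident centroids — the standard convention that removes the
division by zero and keeps the function total. The fuzzifier is nowhere
prescribed by the source description; we use the universal FCM default
`m = 2`, exposed in `FuzzyConfig`.

## MNFL

**W1 (symptom relevance).** Each symptom is embedded at
`(n_diseases/N_D, n_parts/N_P)` where `n_diseases` counts diseases
presenting it, `n_parts` the distinct appeared parts those diseases span,
and the denominators are the total disease count and the appeared-part
vocabulary size, so coordinates lie in [0,1]² consistent with the cluster
centroids: "related" at (0,0), "unrelated" at (1,1). The weight is the
membership toward (0,0): rare, system-specific symptoms count fully,
ubiquitous ones are damped.

**W2 (part-consistent connection).** The query symptom's observed part is
projected via `part_map`; every disease on a *different* appeared part
receives the fixed penalty −0.5. Among the same-part candidates, the
original description names only "the Euclidean distance between the c
cluster centroids and the k-th symptom" without defining the embedding;
our reconstruction embeds disease z as its L1-normalised profile and the
symptom as its one-hot indicator, giving
`d² = 1 − 2·p_z[k] + ‖p_z‖²`. Memberships are normalised within the
candidate set (they sum to 1 over it); a candidate whose membership is
exactly zero (possible only in the coincidence convention) also falls to
−0.5, matching the stated zero-membership branch. If no disease lives on
the mapped part, every disease is penalised for that symptom and the event
is logged.

**Activation.** Disease z's output is the mean over the n query symptoms of
`w1_i · w2_zi` (input activations are 1). Whether n should count all query
symptoms or only part-matched ones is not determinable from the source; we
use all, so penalties dilute the mean honestly. A disease is *activated*
iff its output is strictly positive. This is the mechanism that blunts
cascading errors: a wrong part doesn't merely fail to help, it subtracts.

**W3 (neighbourhood refinement).** For each activated candidate target t,
every activated z is placed at
`x = 1 − |S_z∩S_t| / max(|S_z|,|S_t|)`,
`y = 1 − ||S_z|−|S_t|| / max(|S_z|,|S_t|)`,
so z = t sits exactly at (0,1), the stated target position (the printed
axes are inverted so that shared symptoms and size agreement are extremal
at the target; this is the only reading that puts the self-point on the
target centroid). Membership is computed toward (0,1) against the
anti-centroid (1,0), and the final score is the activation-weighted mean
membership over the activated set. The ranking keeps the top five scores,
ties broken by ascending disease id.

### Why MNFL's absolute accuracy is low on realistic synthetic data

On the disjoint-symptom oracle fixture MNFL is exact (100% top-1 on
noiseless queries). On the full-scale synthetic base with 20% cross-part
associations its top-1 accuracy is a few percent, although degradation in
noise remains strictly monotone. The cause is structural in the
reconstruction: W2 memberships are normalised over all (~20) same-part
candidate diseases, so a genuinely associated disease receives ~0.05 —
while a single query symptom whose part maps elsewhere contributes a full
−0.5. One cross-part (but truly associated) symptom therefore drives the
target's mean activation negative and it never reaches the ranking. The W3
average further favours diseases central to the activated neighbourhood
over the most-activated disease. Both behaviours follow directly from the
stated formulas; the undefined details (the W2 embedding and whether its
space is one- or two-dimensional) are reconstructed and documented, and a
different resolution of those unknowns could well reproduce the much
higher absolute accuracies reported for the original private database.

## FHAL

Weights are count-derived, deterministic, and precomputed once per
knowledge base (re-fitting per query would add nondeterminism and cost
without changing any tested behaviour):

* `w1[s,p]` — fraction of the diseases containing s that appear on part p
  (rows of occurring symptoms sum to 1);
* `w2[p,z]` — indicator that z appears on p, weighted by repertoire size
  `|S_z|` and row-normalised within the part;
* `w3[s,z]` — direct association, `1/|S_z|` if (z,s) associated else 0.

Inference elects the dominant part `p* = argmax_p A_p` with
`A_p = Σ_{s∈query} w1[s,p]` (ties to the smaller part id) and retains query
symptoms with `w1[s,p*] ≥ τ · A_{p*}/n` — τ times the dominant part's mean
per-symptom support; τ defaults to 0.5 since "relatively high association"
is otherwise unquantified. Retained symptoms drive the indirect route
`Σ_s w1[s,part(z)]·w2[part(z),z]`; the direct route `Σ_s w3[s,z]` always
uses the full query; the final score blends them with α = 0.5. If the
filter removes everything, scoring falls back to the direct route and the
event is logged.

## PFCM-R

The possibilistic–fuzzy blend minimises
`J = Σ_ik (a·u^m + b·t^η) d² + Σ_i γ_i Σ_k (1−t)^η + λ Σ u²` over
memberships u (rows summing to 1), typicalities t ∈ [0,1] and centroids.
The final quadratic term is the regulariser: because Σu = 1 per point, it
is minimised by uniform memberships, so λ > 0 flattens the membership
surface and stabilises small-sample fits. Updates alternate and each step
minimises its own block exactly, so the objective trace is non-increasing
(asserted in tests at 1e-9):

* memberships: standard FCM form for λ = 0; for λ > 0 the closed form
  `u_ik ∝ 1/(a·d² + λ)`, exact when the membership fuzzifier is 2. For
  λ > 0 with m ≠ 2 no closed form exists and the fit raises rather than
  losing the descent guarantee.
* typicalities: `t = 1/(1 + (b·d²/γ_i)^{1/(η−1)})` with per-cluster scales
  γ_i estimated from an FCM pre-pass (within-cluster mean fuzzy distance);
  the pre-pass also supplies initial centroids, themselves seeded by a
  k-means++-style draw.
* centroids: weighted means with weights `a·u^m + b·t^η`.

Defaults a = b = 1, m = η = 2, λ = 0.1.

For diagnosis the engine does not cluster freely: each disease is a fixed
prototype (its profile), the query is the normalised indicator of its
symptoms, and `score_z = a·u_z + b·t_z` with u the membership over
distances to all prototypes and t the typicality at a single scalar scale
γ, the mean pairwise squared distance among prototypes. A scalar (rather
than per-prototype) scale keeps the degenerate all-equal-distance case
fully symmetric, so such queries fall back to ascending-id order.

## Noise benchmark

Targets are the eligible diseases with at least `query_size` symptoms
(targets below that are excluded with a warning); an optional `n_targets`
draws a seeded subsample, and the reference protocol uses 50. Noise0 is a
seeded uniform sample of `query_size = 5` associated symptoms (for a
disease with exactly five, the full set). Level L+1 replaces one uniformly
chosen still-relevant slot with a uniform symptom not associated with the
target and not already in the query — noise may belong to other diseases
or to none, and levels are strictly nested. Whether the original protocol
sampled or fixed the five relevant symptoms is unstated; we sample with
the seed. Accuracy is `100 × hits / n_targets` for k ∈ {1, 3}, averaged
over replicates (population SD reported). Replicates beyond the reference
design's single pass exist to make the monotone-degradation property
testable; engine failures on a query are logged and scored as misses.
Reports serialise deterministically (sorted keys, fixed precision), so one
seed gives byte-identical JSON/CSV.

## Synthetic knowledge bases

The full-scale generator matches the reference statistics: 241 symptoms
uniformly over 16 observed parts, 249 diseases uniformly over 12 appeared
parts, a surjective part map (a permuted block covers every appeared part,
remaining observed parts map uniformly), and per-disease symptom counts
uniform on 3..12 — a right-skew-free spread that yields ~190 eligible
diseases, comfortably above the required 50. Each disease draws a
`Binomial(n_s, 1−ρ)` share of its symptoms from the pool whose observed
part maps to its own appeared part and the rest from other pools, with
ρ = 0.2 as the default contamination; the empirical cross-part fraction
tracks ρ to within 0.05 at this scale (clipping to pool sizes makes small
configurations deviate — pools of at least the per-disease maximum are
needed for exact purity at ρ = 0). Generation retries with fresh sub-seeds
until the eligibility floor is met. What the generator does **not**
emulate: real co-occurrence structure between diseases, correlated symptom
sharing within body systems, or clinical text — so passing benchmarks show
robustness of the inference machinery under controlled corruption, not
clinical accuracy.

The disjoint generator assigns each disease a private, part-consistent
symptom block (identity part map), making the maximal-overlap disease
unique — the oracle used by the perfect-recovery tests.

## Numerical and design choices

* Zero-distance convention: equal split among coincident centroids,
  threshold `ε = 1e-12`.
* Activation threshold: strictly positive output.
* All rankings: at most five entries, descending score, ties by ascending
  disease id.
* Clustering convergence: absolute objective change < 1e-9, cap 300
  iterations.
* Seeds: every stochastic path (generators, noise sets, centroid
  initialisation, replicate sub-seeds) flows from a single
  `numpy.random.default_rng` seed; derived sub-seeds stay below 2³¹.
* Problem sizes in the shipped tests and the acceptance script — 50
  targets, 10 replicates, 100 random clustering datasets — were chosen as
  the reference protocol's own scale; the whole suite runs in seconds.

## Limitations

The engines are reconstructions at the points noted above (W2 embedding,
PFCM-R update details, FHAL weight formulas and threshold), each resolved
by the most conservative reading that reproduces the stated qualitative
behaviour. Absolute accuracies on synthetic data characterise the
implementation under the generator's assumptions only; no claim about
agreement with clinical data or with accuracies measured on the original
private database is made or testable here.
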