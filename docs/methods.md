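# Methods

This note documents the model, the defaults and why they were chosen,
what the synthetic generator does and does not emulate, and the numerical
conventions the implementation commits to.

## Graph model and RDA resolution

The knowledge graph is an in-memory structure of insertion-ordered node
dictionaries plus explicit edge lists. No database server is involved:
desk-scale graphs (hundreds of nodes, tens of thousands of edges) need no
index machinery, and determinism is easier to guarantee when iteration
order is exactly input-table row order. `export_cypher` emits one
CREATE/MERGE statement per node and edge for anyone who wants the same
graph inside Neo4j; symptom nodes are merged inline within their
INDICATES statements so the statement count equals `|V| + |E|` of the
reported statistics.

RDA bands are inclusive on both ends (`19–30` covers ages 19 through 30),
and overlapping bands for the same (gender, state) pair are rejected at
construction. Physiological-state resolution is a genuinely open design
point: RDA tables print plain gender × age rows, while pregnancy targets
are conventionally stored as separate per-state properties with no age
qualifier. We resolve as follows: if the profile declares a state
(pregnant/lactating) and the nutrient has a matching state key covering
the profile, that key wins; otherwise the plain (gender, age) band
applies. State keys are stored with a wide 0–120 band in the bundled
fixtures, making the override total. A lactating profile for a nutrient
with no lactation key silently falls back to the age band — a fallback,
not an error, because state-specific allowances exist only for a minority
of nutrients.

## Semantic ETL

Column codes resolve in three steps: verbatim vocabulary hit, exact
abbreviation-map lookup, then embedding cosine similarity against the
scientific-name vocabulary with strict threshold τ > 0.5 (the strict
inequality is deliberate; a 0.50 match is rejected). Fuzzy decisions —
accepted or not — are logged as (stage, term, candidate, similarity,
accepted) records so an ingest is auditable; exact hits are not logged,
so a fully canonical ingest has an empty log. Unresolvable food-table
columns are dropped (logged, rejected); unresolvable disease or RDA
references are errors, because silently dropping a clinical requirement
would change the meaning of a disease node.

Units are normalized within {g, mg, mcg} by exact powers of 1000. RDA
amounts are converted to each nutrient's canonical unit before graph
construction, so ranking never mixes units.

Missing composition cells are imputed by k-NN within the food's category:
donors are the k = 5 nearest same-category foods observing the nutrient,
by Euclidean distance over the nutrients observed in both foods after
rescaling every column to mg (so gram-scale macronutrients do not drown
microgram-scale vitamins). Fewer than k donors: use all; none: global
nutrient mean; a nutrient observed nowhere is an error. k = 5 is a
conventional small-neighborhood choice — the method is specified by its
category-average construction, not by a tuned k — and is configurable.
Distances are computed on observed values only (normalization before
imputation), which avoids feeding imputed values back into the distance
metric. Imputation can be disabled (`ETLConfig.impute = False`) for
sparse hand-curated tables where a blank cell means "nutrient absent"
(no CONTAINS_NUTRIENT edge) rather than "measurement missing"; the
bundled walkthrough fixture is of this kind.

## Embedding and disease matching

The default embedder hashes padded character 3-grams of the lowercased,
punctuation-stripped text into 384 bins (keyed blake2b, fixed seed) and
L2-normalizes the counts. It is deterministic, dependency-free, and
adequate for the vocabulary-alignment and alias-matching tasks in scope;
it is *not* a semantic model — paraphrases with no shared trigrams will
not match, which is why disease nodes carry symptom aliases. A
transformer sentence encoder can be substituted behind the same
`embed(text) -> unit vector` contract; similarity values are
model-specific and are never asserted against fixed constants in tests,
only argmax identities and threshold behavior are.

Disease matching embeds both disease labels and symptom aliases and takes
the global argmax (alias hits map to their disease); ties break to the
lexicographically smaller disease name. Comorbidity queries return only
the single best disease — merging nutrient targets across multiple
diseases has no defined combination rule and is out of scope.

## Ranking

The score is the plain cosine between the capped vector and the all-ones
target, in [0, 1]. One scoring ambiguity deserves a note: a
capped-cosine score cannot exceed 1, yet magnitude-weighted variants
(score = cosine × Σ V_f[i]) are sometimes used to let high-magnitude
foods overtake better-balanced ones. We implement plain cosine as the
default and tested contract — it is the formulation that actually
delivers the anti-superfood guarantee (uniform vector scores 1, one-hot
scores 1/√n) — and expose `cosine_magnitude` as an optional mode for
experimentation.

Candidates are foods with at least one CONTAINS_NUTRIENT edge into the
required set; foods lacking every required nutrient are excluded before
scoring rather than scored zero, so an empty result is a diagnosable
error instead of a list of zeros. Sorting is descending by score with
ties broken by ascending food code; scores are rounded to 12 decimals in
the sort key so that mathematically tied scores computed through
different floating-point paths (two one-hot foods, or a uniform RDA
rescaling) tie exactly and fall through to the code tie-break. Stored
scores keep full precision; display rounding (2 decimals) is applied only
at the interface.

## Metrics and experiments

* Relevance: a food is relevant iff at least `min_satisfied = 2` required
  nutrients reach `tau_cov = 20` %DV. The per-nutrient threshold in the
  relevance rule reuses the coverage threshold τ for consistency; both
  are configurable.
* NDCG uses binary gains `(2^rel − 1)/log2(i + 1)` and is defined as 0
  when the ideal DCG is 0 (no relevant item) — a convention, since the
  ratio is otherwise undefined.
* Rank stability is the Spearman coefficient computed from the printed
  formula `1 − 6 Σ d_i² / (n(n² − 1))` with average ranks on ties; tests
  cross-check it against `scipy.stats.spearmanr` over all permutations up
  to n = 5.
* Balance variance is the population variance (1/N) of the capped [0, 1]
  components — fractional scale, so reported magnitudes are comparable
  across diseases with different target counts.
* The perturbation protocol ranks the full candidate list at baseline and
  with all RDA targets scaled by (1 + δ), δ = ±0.10 by default, and
  reports the stability coefficient over common candidates plus top-k
  overlap. When no cap binds at either scale, cosine ranking is invariant
  under uniform RDA scaling, so instability arises only from caps
  engaging or releasing.
* The ablation protocol ranks the top k under capped-cosine and under
  uncapped summation and compares the mean balance variance of the two
  top-k sets. Direction, not magnitude, is the claim: capping lowers
  top-k variance. The acceptance test asserts this as a sign test over 20
  generator seeds (40 foods, 5 superfoods, 5 balanced foods, k = 5 — a
  size chosen to keep the whole suite fast while leaving the effect far
  from marginal).

## Synthetic data

The generator emits the four raw tables with: log-normal food amounts per
nutrient (positive, heavy-tailed, like real composition data) with
category-level multiplicative shifts; planted superfoods (one required
nutrient at 3–10× its adult-female reference RDA, other required
nutrients exactly 0 — a one-hot capped vector by construction); planted
balanced foods (40–80% of the reference RDA on every required nutrient of
the anchor disease); and missing cells injected at rate (1 − density)
into the non-planted foods only. Default shape: 50 foods × 12 nutrients ×
5 diseases, density 1.0, 3 + 3 planted foods, chosen as the smallest
scale at which ranking, imputation and both experiment protocols are all
exercised.

What the generator does **not** emulate: real nutrient–nutrient
correlations, bioavailability, preparation effects, or the actual
sparsity pattern of a licensed food-composition ingest. Passing tests
demonstrate the algorithmic properties (capping, balance preference,
stability, determinism) — they are not evidence about recommendation
quality on real dietary data. The walkthrough fixture's folate amounts
are synthetic reconstructions (57 mcg and 142.5 mcg, i.e. 0.10 and 0.25
of the 570 mcg pregnancy target) chosen to make the worked-example capped
vectors come out at round values; they are flagged as such in the source.

## Meal plan and generation guard

Slot assignment is deterministic round-robin in rank order (breakfast,
lunch, snack, dinner; the top-10 yields sizes 3/3/2/2). Which food
culturally belongs to which slot is a presentation concern with no
principled rule at this layer; round-robin is our convention. Rationales
are templated from trace values only, and `validate_plan` enforces the
whitelist property mechanically: any food outside the ranked list, or any
cited (nutrient, amount, %DV) triple absent from that food's trace, is a
violation. An external text generator, if plugged in, must pass the same
validator before display; the core pipeline and tests never invoke one.

## Known limitations

Single-disease targeting only; no portion sizes, meal-level aggregation
constraints, or multi-day planning. The lexical embedder's recall on
colloquial symptom phrasings is limited (mitigated by aliases). RDA
fallbacks treat a missing lactation/pregnancy key as "use the ordinary
band", which may understate state-specific needs for sparsely specified
nutrients. Amounts are per 100 g edible portion throughout; density of
consumption is not modeled.
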