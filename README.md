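# nutrigraph

A deterministic, explainable recommendation engine for disease-aware
dietary planning, built around a disease–nutrient–food knowledge graph
with demographic Recommended Dietary Allowance (RDA) constraints. It is
aimed at nutrition-informatics researchers and decision-support builders
who need recommendations that are traceable (every suggestion carries its
Disease → Nutrient → Food derivation) and reproducible (no stochastic
generation anywhere in the ranking path).

## The model

A knowledge graph `G = (V, E)` holds three node types and three edge
types:

```
(:Disease)-[:REQUIRES]->(:Nutrient)
(:Food)-[:CONTAINS_NUTRIENT]->(:Nutrient)     # amount per 100 g
(:Symptom)-[:INDICATES]->(:Disease)
```

Nutrient nodes carry RDA values keyed by gender, inclusive age band, and
physiological state (pregnancy/lactation overrides the age band). A user
profile `U = (A_demo, I_query)` combines demographics with a free-text
query; the query is embedded (deterministic hashed character 3-grams by
default, 384 dimensions) and matched to the disease node `D` maximizing
cosine similarity over disease labels and symptom aliases, accepted only
above a threshold τ = 0.5.

For the matched disease with required nutrients `N_req` and
profile-resolved targets `RDA_user`, each candidate food `f` gets a
capped nutrient vector

```
V_f[i] = min(Amount_f,i / RDA_user,i, 1.0)
```

and is scored by cosine similarity to the all-ones ideal target
`V_target = (1, …, 1)`:

```
S(f, U) = cos(V_f, V_target) = Σ_i V_f[i] / (√n · ‖V_f‖₂)
```

Capping is what suppresses "superfood bias": a food spiking one nutrient
scores at most `1/√n`, while a food at a uniform fraction of every target
scores exactly 1. An uncapped summation score `Σ_i Amount_i / RDA_i` is
included as the ablation baseline that exhibits the bias. Six evaluation
metrics are provided: Precision@k and binary-gain NDCG@k under a
relevance rule (≥ 2 required nutrients at ≥ 20 %DV), Spearman
rank-stability under RDA perturbation, mean %DV deviation, nutrient
coverage, and nutrient-balance variance.

Foods enter the graph through a semantic ETL pipeline: technical column
codes (e.g. `protcnt`) resolve to scientific nutrient names exactly or by
embedding similarity (τ > 0.5), units are normalized within {g, mg, mcg},
and missing composition cells are filled by category-restricted k-NN
imputation. A meal-plan formatter assigns ranked foods round-robin to
Thali slots (breakfast/lunch/snack/dinner) and a whitelist guard rejects
any plan citing foods or numbers not present in the ranked trace — the
mechanical stand-in for constraining a generative formatter.

## Worked example

Write the bundled pregnancy/anemia fixture to CSV and ask for a
recommendation:

```
nutrigraph simulate --preset walkthrough --out fixture/
nutrigraph recommend --data-dir fixture/ \
    --age 28 --gender female --state pregnant --query "hemoglobin low"
```

Output (traces elided):

```json
{
  "disease": "Iron Deficiency Anemia",
  "similarity": 1.0,
  "targets": {
    "Folic Acid": {"rda": 570.0, "unit": "mcg"},
    "Iron":       {"rda": 27.0,  "unit": "mg"},
    "Vitamin C":  {"rda": 65.0,  "unit": "mg"}
  },
  "ranked": [
    {"code": "B001", "name": "Spinach (Palak)",            "score": 0.88,
     "vector": {"Folic Acid": 0.25, "Iron": 0.11, "Vitamin C": 0.46}},
    {"code": "B002", "name": "Drumstick Leaves (Moringa)", "score": 0.72,
     "vector": {"Folic Acid": 0.1,  "Iron": 0.17, "Vitamin C": 1.0}},
    {"code": "A003", "name": "Bajra (Pearl Millet)",       "score": 0.58,
     "vector": {"Folic Acid": 0.0,  "Iron": 0.24, "Vitamin C": 0.0}}
  ]
}
```

The query hits the "hemoglobin low" symptom alias, pregnancy RDA targets
are resolved (iron 27 mg, vitamin C 65 mg, folate 570 mcg), and each
food's capped vector is scored against the all-ones ideal: spinach's
moderate-but-broad profile (cosine 0.88) outranks moringa, whose vitamin
C is capped at 1.0 but whose other components are small (0.72), and both
outrank the single-nutrient foods tied at `1/√3 ≈ 0.58`. Appending
`--meal-plan` adds a slot assignment whose rationales cite only traced
amounts, e.g. *"Spinach (Palak) provides 142.5 mcg Folic Acid per 100 g
(25.0% of the daily target); 2.9 mg Iron per 100 g (10.7% of the daily
target); …"*.

Other subcommands: `etl` (graph statistics + resolution log), `evaluate`
(the six metrics as JSON), `simulate` (seeded synthetic tables with
planted balanced foods and superfoods), `export-cypher` (CREATE/MERGE
statements for an optional Neo4j deployment).

## Limitations

The package ships no licensed food-composition data; synthetic tables
emulate the real ingest's shape, not its nutrient correlations. The
default embedder is lexical, so matching quality on colloquial symptom
descriptions is below that of a trained sentence encoder (a transformer
embedder can be plugged in behind the same contract). See
`docs/methods.md` for modeling choices, defaults, and caveats. This is a
decision-support research tool, not medical advice.
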