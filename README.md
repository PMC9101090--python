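# telerec

Self-adaptive recommendation of telemedicine specialists from electronic
medical record (EMR) text.

Telemedicine platforms accumulate consultation logs in which patients'
conditions are described in free text, while the specialists best suited to
a new patient are buried among hundreds of colleagues. `telerec` is for
researchers and platform engineers studying content-based doctor
recommendation under two practical constraints: *data sparsity* (patients
rarely rate doctors, and privacy limits what can be collected beyond the
EMR itself) and *cold start* (newly registered specialists have no
history to be recommended from).

## The method

Given a consultation log, specialist profiles (expertise labels + a
service rating) and a binary specialist × attribute knowledge matrix, the
pipeline ranks specialists for a target EMR in four stages:

1. **Patient features.** Each EMR is the TF-IDF-weighted mean of the
   word2vec-style vectors of its f distinct feature words,
   `d_i = (1/f) Σ_k v_k · tfidf(w_k, d_i)`, compared by cosine
   similarity. A specialist's initial index `ini_score` is the highest
   similarity among the patients they treated; the top 10 form the
   candidate set.
2. **Cold-start repair.** Missing knowledge-matrix cells are filled by
   observed column frequency (≥ 0.5 → 1). Newly registered specialists
   (fewer than three consultations) with weighted-Jaccard knowledge
   similarity ≥ 0.7 to a candidate h get
   `ini_score'_j = ini_score_j + (1/q) Σ_h ini_score_h · Sim(j,h)` and
   join the pool.
3. **Semantic extension.** Per-specialist documents (their diagnosed
   EMRs) are modeled with collapsed-Gibbs LDA; document–topic profiles
   are compared with base-2 Jensen–Shannon divergence
   (`short_score = 1 − D_JS`), and topic-space neighbors of candidates
   join the pool. The topic count is picked at the elbow of the
   perplexity curve over a K grid.
4. **Activity-weighted fusion.** Activity is time-decayed consultation
   share `AC_j = Σ_t N_j(t) e^{−t} / N(t)`, normalized to `LAC_j`;
   `prof_score = LAC × ini_score × short_score`. Patient preference
   answers set weights (ω_p, ω_q), ratings give a normalized
   `qos_score`, and the final ranking follows
   `compre_score = ω_p · prof_score' + ω_q · qos_score`.

Since real consultation logs are private, the package ships a synthetic
world generator with planted ground truth (topic-word matrix, specialist
mixtures, best-match specialists), which is what the tests and the
reproduction script run against. See `docs/methods.md` for assumptions,
parameters and limitations.

## Worked example

```python
from telerec import WorldConfig, generate_world, SpecialistRecommender

world = generate_world(WorldConfig(seed=42))      # 50 specialists, 1000 EMRs
est = SpecialistRecommender(seed=42)
est.fit(world.records, world.knowledge, world.profiles, world.dictionaries)
rec = est.recommend(world.target_text, preference=("Extremely like", "Like"))
for e in rec.entries[:5]:
    print(f"{e.specialist_id}  ini={e.ini_score:.3f} short={e.short_score:.3f} "
          f"lac={e.lac:.3f} prof'={e.prof_score_normalized:.3f} "
          f"qos={e.qos_score:.3f} compre={e.compre_score:.3f}")
```

prints

```
S019  ini=0.974 short=1.000 lac=1.000 prof'=1.000 qos=0.854 compre=0.938
S033  ini=0.998 short=1.000 lac=0.638 prof'=0.654 qos=0.901 compre=0.760
S030  ini=0.958 short=1.000 lac=0.534 prof'=0.526 qos=0.705 compre=0.603
S022  ini=0.958 short=0.807 lac=0.546 prof'=0.434 qos=0.653 compre=0.528
S029  ini=0.974 short=0.918 lac=0.298 prof'=0.274 qos=0.855 compre=0.523
```

Each row is one recommended specialist with the full score breakdown: the
patient-similarity index (`ini`), topic-space similarity (`short`),
normalized activity (`lac`), pool-normalized professional score (`prof'`),
normalized service quality (`qos`) and the fused score (`compre`) under
the chosen preference weights (here ω_p = 4/7, ω_q = 3/7). S019 leads
through high activity and similarity; S033 of the ground-truth best-match
list follows despite lower activity. `est.stage_log_` records the
candidate pool after every stage (initial → cold-start → extension →
fused).

The same pipeline is scriptable from the shell:

```bash
telerec simulate --out world/ --seed 42
telerec recommend --consultations world/consultations.csv \
    --profiles world/profiles.json --knowledge world/knowledge.csv \
    --stopwords world/stopwords.txt --synonyms world/synonyms.tsv \
    --target-emr world/target_emr.txt \
    --pref-prof "Extremely like" --pref-qos "Like" --out rec.json --log log.json
telerec evaluate --recommendation rec.json --truth world/truth.json \
    --profiles world/profiles.json
telerec topics --consultations world/consultations.csv --k 5
```

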