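# thermosocial

Analysis pipeline for functional infrared thermography of social events
in wild chimpanzees.

Peri-nasal skin temperature tracks autonomic state: sympathetic
vasoconstriction (stress) cools the nose, parasympathetic activity
warms it. Given thermal pictures of focal males taken during ordinary
social events — grooming, play, aggression, copulation, snake
encounters — plus audience metadata and long-term interaction logs,
this package asks two questions a behavioural ecologist cares about:

1. Do social event types cluster into cooperative / competitive /
   intermediate classes by their thermal signatures?
2. Which audience members (the alpha male, females, the subject's
   mother, bond partners) moderate the thermal response, and in which
   direction?

It is aimed at researchers running thermal-imaging field studies, and
ships a synthetic-data generator that emulates such a study with known
ground truth, so every stage can be validated by parameter recovery.

## The method

**Angle correction.** Subjects rarely face the camera and oblique views
read colder. Per-event mean temperatures at 7 head-orientation
categories form a partially observed events × angles matrix `X`;
missing cells (notably the *facing* column) are completed by regularized
iterative PCA: initialize with column means, then iterate

    center columns → SVD → reconstruct with top-r components,
    each singular value shrunk s ← (s² − σ̂²)/s → refill missing cells

until the imputed cells stop changing. The facing-equivalent
temperature of each event is its observed facing mean, or the imputed
facing cell otherwise. Models work on `log(T_nose)`.

**Social indices.** The Composite Relationship Index for a focal and
partner *j* is

    CRI = (Grooming_fj + Proximity5m_fj − 5·Aggressions_fj) / TotalFocalOccurrences

with severe aggressions counted twice inside the aggression block; the
three highest scores above zero define bond partners. Dominance is an
Elo rating updated after each decided agonistic interaction or
pant-grunt: the winner gains `k·(1 − p)` with
`p = 1/(1 + 10^((r_loser − r_winner)/400))`.

**Event clustering.** Each event type is profiled by its per-subject
mean residual log temperature (after removing ambient-temperature and
prior-movement effects estimated on resting baselines), plus its
overall mean and SD. Profiles are standardized and clustered with
Ward's minimum-variance criterion; the number of clusters maximizes the
mean silhouette width `s(i) = (b−a)/max(a,b)`.

**Audience models.** Gaussian linear mixed models with crossed random
intercepts for subject identity and prior movement, centered ambient
temperature as a control, fitted with statsmodels `MixedLM`. Candidate
audience terms are searched exhaustively (all marginality-respecting
subsets) and ranked by AICc = AIC + 2k(k+1)/(n−k−1); the best model is
compared to its null by a likelihood-ratio test, terms are tested with
Wald chi-squares, and factor levels compared through estimated marginal
means with Tukey-adjusted pairwise contrasts.

## Worked example

```python
from thermosocial import GeneratorConfig
from thermosocial.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(generator=GeneratorConfig(seed=1), seed=1)
report = run_pipeline(config)

imp = report["imputation"]
print(f"events: {imp['n_events']}, imputed facing values: "
      f"{imp['n_imputed']} ({imp['imputed_pct']:.2f}%)")
print("chosen k:", report["clustering"]["chosen_k"])
for role, d in report["cluster_model"]["descriptives"].items():
    print(f"  {role}: {d['mean']:.2f} ± {d['sd']:.2f} °C (n={d['n']})")
coop = report["analyses"]["cooperation"]
print("cooperation best terms:", coop["best_terms"],
      "LRT χ²(%d) = %.2f, p = %.2g" % (coop["lrt"]["df"],
                                       coop["lrt"]["chisq"],
                                       coop["lrt"]["p"]))
```

prints (seed 1):

```
events: 1397, imputed facing values: 631 (45.17%)
chosen k: 3
  baseline: 32.20 ± 1.84 °C (n=392)
  competitive: 32.22 ± 2.49 °C (n=402)
  cooperative: 33.03 ± 1.17 °C (n=402)
  intermediate: 33.92 ± 1.29 °C (n=201)
cooperation best terms: ['alpha_35', 'z_elo'] LRT χ²(2) = 19.99, p = 4.6e-05
```

Reading this: 45% of events lacked a facing-angle picture and received
an imputed facing temperature; the 15 social event types fall into
three thermal clusters (here recovering the generator's planted
partition exactly, adjusted Rand = 1); and on cooperative events the
selected audience model contains the planted alpha-male-presence
effect (cooler noses when the alpha is within 35 m) plus the subject's
own Elo rank.

The same pipeline runs from the shell on CSV inputs:

```sh
thermosocial simulate --seed 7 --out data/        # synthetic study
thermosocial validate data/
thermosocial run --input-dir data/ --seed 7 --out results/
```

Externally deposited tables with different column headers can be
ingested by passing a column mapping in the pipeline config (see
`PipelineConfig.column_map`); the report then carries the agreement of
the estimated partition with the published three-cluster reference as
`clustering.ari_vs_reference`.

## Layout

- `thermosocial.simulate` — synthetic study generator + ground truth
- `thermosocial.preprocess` — time-window filter, angle matrix,
  regularized iterative PCA, event correction
- `thermosocial.social` — CRI, bond partners, Elo, hierarchy stability
- `thermosocial.clustering` — profiles, Ward tree, silhouette k-choice
- `thermosocial.lmm` — `TemperatureLMM` / `LMMResults`, AICc, all-subsets
  selection, LRT, Wald tests, EMM contrasts, confound calibration
- `thermosocial.pipeline` / `thermosocial.cli` — orchestration, I/O,
  validation, reports

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
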