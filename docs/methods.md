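# Methods

This note documents the modelling choices behind `thermosocial`: what
the pipeline assumes, what the synthetic-data generator emulates, which
defaults matter, and where the design was genuinely open.

## Generative model of a thermal field study

The generator (`thermosocial.simulate`) emulates a six-month study of
nine adult male chimpanzees. Its event-level model is the one the
analysis assumes:

    T_event (°C) = μ_cluster
                 + δ_{cluster,subject}      (thermal signature)
                 + u_subject                 (random intercept)
                 + m_movement                (prior-movement offset)
                 + β_amb (ambient − 25)
                 + audience terms            (cluster-specific)
                 + ε_event

    T_picture   = T_event + angle bias + ε_picture

Pictures per event follow `min(1 + Poisson(2), 13)` inside the 1–13
range observed in the field; capture times are uniform on 15–300 s
after event onset. A configurable fraction of events (default 0.46)
has no facing-angle picture, matching the fraction of values the
angle-correction step must impute.

Key default choices, with rationale:

- **Event roster.** 15 social event-type labels (grooming enters as
  given / received / mutual) plus a resting baseline; 67 events per
  social type (~1000 social events) and 392 baseline events — the scale
  of the motivating field study.
- **Cluster means** 33.6 / 32.8 / 33.6 / 33.1 °C for the cooperative
  (A), competitive (B), intermediate (C) and baseline classes.
- **Variance decomposition.** The observed per-class SDs
  (1.66 / 2.10 / 1.45 / 2.16 °C) constrain only the *total* dispersion.
  The generator splits each total into a stable subject-by-class
  signature (`cluster_subject_sds`, defaults 1.3 / 1.7 / 1.3 / 1.3 °C)
  plus event-level noise (`cluster_sds`, 0.85 / 1.07 / 0.35 / 1.64 °C),
  with `event_sd² = total² − signature² − 0.29 − audience-term
  variance` (0.29 °C² covers the subject intercept, movement and
  ambient contributions). Treating the large competitive-class spread
  as mostly between-subject reflects stress reactivity being a stable
  individual trait; it also makes the class structure identifiable from
  per-subject profiles, which is what the clustering stage relies on.
- **Audience moderators**: alpha presence −0.5 °C on cooperative
  events (difference of the reported presence/absence means), mother
  presence −2.1 °C on copulations (same), +0.2 °C per female within
  10 m on competitive events and +0.5 °C per male within 10 m on
  copulations (orders of magnitude consistent with the reported test
  statistics at the reported sample sizes).
- **Angle bias** 0 (facing) to −1.1 °C (rear views); **movement**
  0 / −0.3 / −0.8 °C for none / steps / travel; **ambient slope**
  0.1 °C/°C with ambient uniform on 20–30 °C (tropical-forest daytime
  range; the field distribution is unreported).
- **Interaction logs.** Affiliative 15-min occurrence counts are
  Poisson per dyad-month (grooming 2, proximity 3), multiplied by 4 on
  bonded dyads. Bonds form a random mutual, (near-)3-regular graph so
  that top-3 CRI recovery is well-posed (on 9 subjects one male ends up
  with a fourth partner; a strictly 3-regular graph on an odd-degree-sum
  vertex set does not exist). Agonistic outcomes follow a logistic
  model on true-rank difference (steepness 1 per rank unit);
  pant-grunts are directed up the hierarchy with the same fidelity.
  Observation effort is 300 focal occurrences per subject-month.

What the generator does *not* emulate: pixel-level thermal images,
autocorrelated weather, demography beyond the nine focal males,
seasonal changes in association, unbalanced event sampling across
subjects, and observation gaps. Passing recovery tests therefore shows
the pipeline is correct *under its own assumptions*, not that field
data meet them.

## Angle correction

The events × angles matrix uses rows = events and columns = the 7
orientation categories — the only layout in which observed non-facing
temperatures can inform a missing facing value through inter-column
correlation. The completion is EM-PCA with spectral shrinkage: at each
iteration columns are centered on current filled-in values, the top
`rank` (default 2) components are kept, and each retained singular
value is shrunk by `s ← (s² − σ̂²)/s` with `σ̂²` the mean discarded
squared singular value. Shrinkage biases imputed cells toward column
means (the usual variance/bias trade of regularization); accordingly
the zero-noise consistency check is on the *paired mean* difference
against naive per-event means, while exact cell recovery is only
guaranteed for exactly low-rank matrices with regularization off.

Numerical behavior: convergence is linear; the default tolerance
(1e−6 on the summed squared change of imputed cells) is reached in
roughly 2000 iterations on a full-size study, so the pipeline default
`max_iter` is 5000. With regularization on, the iteration has a tiny
limit cycle near 1e−9; tolerances below that are unreachable and the
imputer then returns the last iterate with `converged=False`. Observed
cells are never modified, exactly. Imputed facing values outside
20–42 °C are flagged and excluded from downstream models.

Open alternative, not taken: adjusting every non-facing measurement
toward facing and averaging all adjusted pictures, instead of imputing
one facing value per event. The per-event formulation matches the
reported count of corrected values being a fraction of *events*.

## Social indices

CRI uses grooming in either direction, resting within 5 m, and
aggressions in which the focal took part on either side (displays,
chases, threats; severe aggressions doubled), the aggression block
multiplied by five to put event counts on the 15-min-occurrence scale,
all over the focal's total observation effort. Pant-grunts enter the
Elo rating only (they are submission signals, not aggression).
Elo defaults: k = 100, start = 1000 — the conventional constants for
the continuous-update method; final scores are z-standardized.
Tie-breaks in bond-partner selection (equal CRI) go by total
interaction count, then partner id, for determinism. Hierarchy
stability is reported as the Spearman correlation between first-half
and second-half Elo ratings; 0.8 is a descriptive benchmark, never
enforced.

## Event clustering

Feature construction is the one genuinely under-determined step, since
"clustering events by their temperatures" admits many encodings. The
choice here: per-subject mean residual log temperature per event type
(residuals remove the ambient slope and movement offsets estimated on
baseline events with subject as a random factor), plus the type's
overall mean and SD, all columns z-scored. Per-subject profiles are
robust to unequal event counts and capture individual signatures;
missing subject × type cells (impossible under balanced defaults, but
possible in field data) are filled with the subject's grand-mean
residual to keep vectors comparable. A distributional alternative
(e.g. pairwise Wasserstein distances between per-type temperature
distributions) was considered and not pursued.

Ward linkage on Euclidean distances (Ward's criterion is only defined
for squared Euclidean geometry); cophenetic correlations are reported
for Ward and single linkage as a linkage-adequacy diagnostic. The cut
maximizes mean silhouette width over k = 2…7, ties toward smaller k;
singleton clusters get silhouette 0 by convention. The baseline is
excluded from clustering and re-enters as the reference level of the
cluster comparison model.

Cluster labels are arbitrary, so roles are assigned by marker types,
the way cell clusters are annotated by marker genes: the cluster
holding the grooming types is *cooperative*, the one holding overt
agonism (aggression, display, dominant arrival) is *competitive*,
anything else *intermediate*. Assigning roles by mean temperature is
tempting but fragile: audience effects and realized subject signatures
can shift observed cluster means by several tenths of a degree.

## Mixed models and selection

All models: Gaussian LMM on log temperature, random intercepts for
subject identity and prior movement (crossed, via variance components
over a single grouping), centered ambient temperature as a control
present in every model including nulls. Movement has only three
levels; treating it as a random factor follows the source design, and
`LMMSpec(random_factors=...)` accepts any factor list for users who
prefer it fixed.

Selection machinery:

- **ML vs REML.** ML for everything compared across fixed-effect
  structures (AICc ranking, LRTs); REML for the reported coefficients
  of the selected model. Standard mixed-model selection practice.
- **AICc** counts k = fixed coefficients + variance components +
  residual variance, matching the convention of the usual automated
  selection tooling. n ≤ k + 1 yields +∞ with a warning.
- **Dredge** enumerates all subsets respecting marginality
  (interactions only with their main effects); AICc ties under 1e−8
  resolve toward fewer terms. The default candidate lists are the
  audience variables available in the event tables (alpha presence,
  female/male counts at 10 m, mother presence, subject Elo; the
  grooming model adds role, partner-is-alpha and their interaction) —
  five or fewer per analysis, keeping each search ≤ 32 fits.
- **Per-term Wald chi-squares** (`β̂'V⁻¹β̂` over each term's
  coefficients with the others retained) reproduce a type-II Anova
  table for the additive models used here.
- **Contrasts** are Tukey-adjusted differences of estimated marginal
  means (equal weights over other factors' levels, covariates at their
  means), with residual degrees of freedom n − rank(X). Satterthwaite
  or Kenward–Roger df would differ slightly; the df rule is reported
  alongside every contrast so the discrepancy is visible.
- **Confound calibration** screens ambient temperature, humidity,
  camera distance and prior movement on baseline events, one LMM each
  with subject as random factor; confounds at p < 0.05 are controlled
  downstream. The ambient mean recorded here defines the centering
  used everywhere else.

## Pipeline conventions

Events are analyzed only if at least one other individual was within
35 m (the party rule) and only pictures 15–300 s after event onset are
used. Copulation is analyzed as its own subset of the competitive
cluster. Analyses with fewer than 20 events are skipped, not failed.
Reports are JSON with sorted keys; a fixed config and seed reproduces
the report bit-for-bit. The per-analysis n in the report equals the
row count surviving the stated filters.

## Problem sizes in the test-suite and acceptance runs

Simulation-based checks use sizes chosen to make each check sharp but
cheap: 200 replicates (n = 500) for coefficient coverage, 1000 null
replicates (n = 120, 6 subjects) for type-I calibration, 10 full
pipeline runs at generator defaults for structure recovery, and 20
interaction-log replicates for bond recovery. The whole suite runs in
about two minutes on one CPU.

## Known limitations

- The regularized imputer's shrinkage biases individual imputed cells;
  only aggregate quantities are unbiased in the zero-noise limit.
- With 9 subjects, z-scored Elo and any subject-level covariate are
  estimated from 9 points; their selection frequencies in small-sample
  model searches are noisy.
- Exact three-cluster recovery at generator defaults occurs in most
  but not all seeds (~85% over the seeds examined during development);
  silhouette-based k selection is the noisiest pipeline stage.
- Wald/LRT inference is asymptotic; no small-sample (Kenward–Roger)
  correction is provided.
- The deposited-data ingest path is exercised against synthetic tables
  written in an external-style layout; real deposited tables may need
  additional column mappings.
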