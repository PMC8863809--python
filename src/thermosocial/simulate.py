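"""Synthetic field data with known ground truth.

Emulates a thermal-imaging field study of adult male chimpanzees: for
each social event a handful of thermal pictures of the subject's face is
taken at varying view angles, event metadata (audience composition,
prior movement, weather) is recorded, and six months of long-term
dyadic interaction logs feed the social indices.  The generative model
mirrors the structure the downstream analysis assumes —

    event temperature (deg C) =
        cluster mean
      + cluster-by-subject signature
      + subject random intercept
      + prior-movement offset
      + ambient slope * (ambient - mean ambient)
      + audience moderator terms (cluster-specific)
      + event noise

    picture temperature = event temperature + angle bias + picture noise

so every downstream stage (angle correction, clustering, mixed-model
selection) can be tested against planted truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Event-type labels.  Grooming enters as its three subtypes (given /
# received / mutual), so 15 social labels plus the resting baseline.
CLUSTER_A_TYPES = (
    "grooming_given",
    "grooming_received",
    "grooming_mutual",
    "playing",
    "patrolling",
    "female_inspection",
)
CLUSTER_B_TYPES = (
    "dominant_arrival",
    "display",
    "copulation",
    "hearing_screams",
    "aggression",
    "feeding",
)
CLUSTER_C_TYPES = ("meat_solicitation", "female_solicitation", "snake_encounter")
EVENT_TYPES: tuple[str, ...] = CLUSTER_A_TYPES + CLUSTER_B_TYPES + CLUSTER_C_TYPES
BASELINE = "baseline"

DEFAULT_CLUSTER_MAP: dict[str, str] = (
    {t: "A" for t in CLUSTER_A_TYPES}
    | {t: "B" for t in CLUSTER_B_TYPES}
    | {t: "C" for t in CLUSTER_C_TYPES}
    | {BASELINE: "baseline"}
)

# Seven ordered head-orientation categories; "facing" (head-camera angle
# < 45 degrees) is the reference and carries zero bias by definition.
ANGLE_CATEGORIES: tuple[str, ...] = (
    "facing",
    "quarter_left",
    "quarter_right",
    "profile_left",
    "profile_right",
    "rear_left",
    "rear_right",
)

MOVEMENT_LEVELS = ("no_movement", "steps", "travel")

GROOMING_TYPES = ("grooming_given", "grooming_received", "grooming_mutual")

AGONISTIC_KINDS = ("aggression", "chase", "threat", "severe")
AFFILIATIVE_KINDS = ("groom", "prox5m")

#: sentinel receiver for observation-effort rows in interactions.csv
EFFORT_RECEIVER = "TOTAL"


def _default_cluster_means() -> dict[str, float]:
    # reference condition means per cluster (deg C)
    return {"A": 33.6, "B": 32.8, "C": 33.6, "baseline": 33.1}


def _default_cluster_sds() -> dict[str, float]:
    # event-level noise chosen so that the TOTAL dispersion of generated
    # temperatures (event noise + subject-by-cluster signature + subject
    # intercept + movement + ambient + audience terms) matches the
    # observed per-cluster SDs of 1.66/2.10/1.45/2.16 C:
    #   event_sd^2 = total^2 - signature_sd^2
    #                - 0.29 (subject/movement/ambient)
    #                - cluster's audience-term variance
    return {"A": 0.85, "B": 1.07, "C": 0.35, "baseline": 1.64}


def _default_cluster_subject_sds() -> dict[str, float]:
    # stable per-subject thermal signature per event class; the large
    # competitive-cluster dispersion is mostly between-subject (stress
    # reactivity is a stable individual trait)
    return {"A": 1.3, "B": 1.7, "C": 1.3, "baseline": 1.3}


def _default_movement_effects() -> dict[str, float]:
    # locomotion cools the peri-nasal area
    return {"no_movement": 0.0, "steps": -0.3, "travel": -0.8}


def _default_angle_bias() -> dict[str, float]:
    # off-axis views read colder; facing is the unbiased reference
    return {
        "facing": 0.0,
        "quarter_left": -0.35,
        "quarter_right": -0.35,
        "profile_left": -0.7,
        "profile_right": -0.7,
        "rear_left": -1.1,
        "rear_right": -1.1,
    }


def _default_audience_effects() -> dict[str, float]:
    return {
        # deg C shift on cooperative (cluster A) events when the alpha
        # male is in the party (within 35 m)
        "alpha_presence_cooperative": -0.5,
        # deg C per female within 10 m on competitive (cluster B) events
        "female_count_competitive": 0.2,
        # deg C per male within 10 m on copulation events
        "male_count_copulation": 0.5,
        # deg C shift on copulation events when the mother is in the party
        "mother_presence_copulation": -2.1,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic field study.

    Defaults reproduce the scale of the real study: 9 focal males, 15
    social event-type labels plus baseline, ~1000 social events, 392
    resting (baseline) events, 1-13 pictures per event, 46% of events
    lacking a facing-angle picture, and 6 months of long-term logs.
    """

    n_subjects: int = 9
    n_events_per_type: int = 67
    n_baseline_events: int = 392
    event_types: tuple[str, ...] = tuple(EVENT_TYPES) + (BASELINE,)
    cluster_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLUSTER_MAP))
    cluster_means: dict[str, float] = field(default_factory=_default_cluster_means)
    cluster_sds: dict[str, float] = field(default_factory=_default_cluster_sds)
    #: SD (deg C) of the per-(cluster, subject) thermal signature; gives
    #: event types of the same cluster a shared subject profile so the
    #: cluster structure is identifiable from per-subject features.
    cluster_subject_sds: dict[str, float] = field(
        default_factory=_default_cluster_subject_sds)
    subject_sd: float = 0.3
    movement_effects: dict[str, float] = field(default_factory=_default_movement_effects)
    ambient_slope: float = 0.1
    ambient_range: tuple[float, float] = (20.0, 30.0)
    angle_bias: dict[str, float] = field(default_factory=_default_angle_bias)
    audience_effects: dict[str, float] = field(default_factory=_default_audience_effects)
    picture_sd: float = 0.3
    pictures_per_event: tuple[int, int] = (1, 13)
    missing_facing_prob: float = 0.46
    months_longterm: int = 6
    #: number of focal males with a living mother in the community
    n_mothers: int = 5
    #: mean 15-min focal occurrences per subject per month
    focal_occurrences_per_month: int = 300
    #: mean affiliative occurrences per dyad-month: {groom, prox5m}
    groom_rate: float = 2.0
    prox_rate: float = 3.0
    bond_multiplier: float = 4.0
    n_bond_partners: int = 3
    #: mean decided agonistic interactions per (ordered) dyad-month
    agonistic_rate: float = 1.0
    pantgrunt_rate: float = 1.5
    #: logistic steepness of win probability per unit true-rank difference
    hierarchy_steepness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_events_per_type < 1 or self.n_baseline_events < 1:
            raise ValueError("need at least one event per type")
        for name in ("subject_sd", "picture_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(sd < 0 for sd in self.cluster_sds.values()):
            raise ValueError("cluster SDs must be non-negative")
        if any(sd < 0 for sd in self.cluster_subject_sds.values()):
            raise ValueError("cluster signature SDs must be non-negative")
        if not 0.0 <= self.missing_facing_prob <= 1.0:
            raise ValueError("missing_facing_prob must be a probability")
        missing = set(self.event_types) - set(self.cluster_map)
        if missing:
            raise ValueError(f"cluster_map does not cover event types: {sorted(missing)}")
        if self.angle_bias.get("facing", None) != 0.0:
            raise ValueError("angle_bias['facing'] must be exactly 0")
        lo, hi = self.pictures_per_event
        if not (1 <= lo <= hi):
            raise ValueError("pictures_per_event must be a non-empty positive range")
        if not 0 <= self.n_mothers <= self.n_subjects:
            raise ValueError("n_mothers must be between 0 and n_subjects")

    @property
    def subjects(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_subjects)]


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a generated dataset.

    Never written into the analysis-facing tables; the analysis must
    recover these quantities from the data alone.
    """

    subject_intercepts: dict[str, float]
    cluster_subject_effects: dict[str, dict[str, float]]
    elo_order: list[str]  # highest-ranked (alpha) first
    bond_partners: dict[str, list[str]]
    audience_effects: dict[str, float]
    #: realized event-level temperature (deg C), before angle bias and
    #: picture noise; keyed by event_id
    event_temperature: dict[str, float]
    config: GeneratorConfig

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cfg = d.pop("config")
        for key in ("event_types", "pictures_per_event", "ambient_range"):
            cfg[key] = list(cfg[key])
        d["config"] = cfg
        return d


def _simulate_events(cfg: GeneratorConfig, rng: np.random.Generator,
                     truth_intercepts: dict[str, float],
                     cluster_subject: dict[str, dict[str, float]],
                     alpha_id: str, mothers: set[str]) -> pd.DataFrame:
    subjects = cfg.subjects
    eff = cfg.audience_effects
    ambient_mid = 0.5 * (cfg.ambient_range[0] + cfg.ambient_range[1])
    rows = []
    eid = 0
    for etype in cfg.event_types:
        n_ev = cfg.n_baseline_events if etype == BASELINE else cfg.n_events_per_type
        cluster = cfg.cluster_map[etype]
        for i in range(n_ev):
            eid += 1
            subject = subjects[(i + eid) % len(subjects)]
            movement = rng.choice(MOVEMENT_LEVELS, p=[0.4, 0.35, 0.25])
            ambient = rng.uniform(*cfg.ambient_range)
            humidity = rng.uniform(40.0, 95.0)
            distance = rng.uniform(7.0, 15.0)

            n_males_35 = min(int(rng.poisson(3)), 8)
            n_females_35 = min(int(rng.poisson(5)), 30)
            alpha_35 = 0
            if subject != alpha_id:
                alpha_35 = int(rng.random() < 0.5)
            if alpha_35 and n_males_35 == 0:
                n_males_35 = 1
            if n_males_35 + n_females_35 == 0:
                n_females_35 = 1  # party rule: at least one other present
            alpha_10 = int(alpha_35 and rng.random() < 0.5)
            n_males_10 = int(rng.binomial(n_males_35, 0.4))
            n_males_10 = max(n_males_10, alpha_10)
            n_females_10 = int(rng.binomial(n_females_35, 0.4))
            mother_35 = int(subject in mothers and rng.random() < 0.4)
            mother_10 = int(mother_35 and rng.random() < 0.5)

            partner_id = ""
            groom_role = ""
            if etype in GROOMING_TYPES:
                groom_role = etype.split("_", 1)[1]
                if subject != alpha_id and rng.random() < 0.25:
                    partner_id = alpha_id
                else:
                    partner_id = rng.choice([s for s in subjects if s != subject])

            temp = cfg.cluster_means[cluster]
            temp += cluster_subject[cluster][subject]
            temp += truth_intercepts[subject]
            temp += cfg.movement_effects[movement]
            temp += cfg.ambient_slope * (ambient - ambient_mid)
            if cluster == "A":
                temp += eff["alpha_presence_cooperative"] * alpha_35
            if cluster == "B":
                temp += eff["female_count_competitive"] * n_females_10
            if etype == "copulation":
                temp += eff["male_count_copulation"] * n_males_10
                temp += eff["mother_presence_copulation"] * mother_35
            temp += rng.normal(0.0, cfg.cluster_sds[cluster])

            rows.append(dict(
                event_id=f"E{eid:05d}", subject_id=subject, event_type=etype,
                movement=movement, ambient_c=round(ambient, 2),
                humidity_pct=round(humidity, 1), distance_m=round(distance, 1),
                alpha_35=alpha_35, alpha_10=alpha_10,
                mother_35=mother_35, mother_10=mother_10,
                n_males_10=n_males_10, n_males_35=n_males_35,
                n_females_10=n_females_10, n_females_35=n_females_35,
                partner_id=partner_id, groom_role=groom_role,
                true_temp=temp,
            ))
    return pd.DataFrame(rows)


def _simulate_pictures(cfg: GeneratorConfig, rng: np.random.Generator,
                       events: pd.DataFrame) -> pd.DataFrame:
    non_facing = [a for a in ANGLE_CATEGORIES if a != "facing"]
    lo, hi = cfg.pictures_per_event
    rows = []
    for ev in events.itertuples():
        # right-skewed picture count: most events yield a few usable shots
        n_pic = int(np.clip(1 + rng.poisson(2), lo, hi))
        has_facing = rng.random() >= cfg.missing_facing_prob
        angles = []
        for j in range(n_pic):
            if has_facing and (j == 0 or rng.random() < 0.5):
                angles.append("facing")
            else:
                angles.append(rng.choice(non_facing))
        secs = np.sort(rng.integers(15, 301, size=n_pic))
        for angle, sec in zip(angles, secs):
            temp = ev.true_temp + cfg.angle_bias[angle] + rng.normal(0.0, cfg.picture_sd)
            rows.append(dict(event_id=ev.event_id, subject_id=ev.subject_id,
                             angle=angle, temp_c=round(float(temp), 3),
                             sec_after_event=int(sec)))
    return pd.DataFrame(rows)


def _simulate_interactions(cfg: GeneratorConfig, rng: np.random.Generator,
                           elo_order: list[str],
                           bonds: dict[str, list[str]]) -> pd.DataFrame:
    """Six months of dyadic logs among the focal males.

    Affiliative records (groom, prox5m) are 15-min occurrence counts per
    unordered dyad per month; bond dyads get an elevated rate.  Agonistic
    records are decided events whose winner follows a logistic model on
    true-rank difference; pant-grunts are directed subordinate-to-dominant.
    Observation effort is stored as kind="effort" rows with the TOTAL
    receiver sentinel.
    """
    subjects = cfg.subjects
    rank_score = {s: float(len(elo_order) - i) for i, s in enumerate(elo_order)}
    bonded = {frozenset((a, b)) for a, bs in bonds.items() for b in bs}
    rows = []
    for month in range(1, cfg.months_longterm + 1):
        for i, a in enumerate(subjects):
            rows.append(dict(month=month, actor=a, receiver=EFFORT_RECEIVER,
                             kind="effort",
                             count=int(rng.poisson(cfg.focal_occurrences_per_month))))
            for b in subjects[i + 1:]:
                mult = cfg.bond_multiplier if frozenset((a, b)) in bonded else 1.0
                for kind, rate in (("groom", cfg.groom_rate), ("prox5m", cfg.prox_rate)):
                    c = int(rng.poisson(rate * mult))
                    if c:
                        rows.append(dict(month=month, actor=a, receiver=b,
                                         kind=kind, count=c))
                # decided agonistic interactions
                n_ag = rng.poisson(cfg.agonistic_rate)
                p_a_wins = 1.0 / (1.0 + np.exp(-cfg.hierarchy_steepness
                                               * (rank_score[a] - rank_score[b])))
                for _ in range(n_ag):
                    winner, loser = (a, b) if rng.random() < p_a_wins else (b, a)
                    kind = rng.choice(AGONISTIC_KINDS, p=[0.4, 0.25, 0.25, 0.1])
                    rows.append(dict(month=month, actor=winner, receiver=loser,
                                     kind=kind, count=1))
                n_pg = rng.poisson(cfg.pantgrunt_rate)
                for _ in range(n_pg):
                    dominant, sub = (a, b) if rank_score[a] > rank_score[b] else (b, a)
                    if rng.random() > p_correct_direction(cfg.hierarchy_steepness,
                                                          rank_score[a], rank_score[b]):
                        dominant, sub = sub, dominant
                    rows.append(dict(month=month, actor=sub, receiver=dominant,
                                     kind="pantgrunt", count=1))
    return pd.DataFrame(rows)


def p_correct_direction(steepness: float, sa: float, sb: float) -> float:
    """Probability a pant-grunt goes in the rank-consistent direction."""
    return 1.0 / (1.0 + np.exp(-steepness * abs(sa - sb)))


def _mutual_bond_graph(subjects: list[str], degree: int,
                       rng: np.random.Generator) -> dict[str, list[str]]:
    """Random mutual bond graph, (near-)regular of the given degree.

    Bonds are symmetric, so each focal's planted partner set is exactly
    his graph neighborhood and top-k CRI recovery is well-posed.  When
    n * degree is odd one subject gets an extra partner (a strictly
    regular graph does not exist then).
    """
    n = len(subjects)
    degree = min(degree, n - 1)
    degrees = np.full(n, degree)
    if degrees.sum() % 2:
        degrees[int(rng.integers(n))] += 1
    for _ in range(500):  # configuration model with rejection
        stubs = np.repeat(np.arange(n), degrees)
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        edges: set[tuple[int, int]] = set()
        for a, b in pairs:
            a, b = int(min(a, b)), int(max(a, b))
            if a == b or (a, b) in edges:
                break
            edges.add((a, b))
        else:
            adj: dict[str, list[str]] = {s: [] for s in subjects}
            for a, b in edges:
                adj[subjects[a]].append(subjects[b])
                adj[subjects[b]].append(subjects[a])
            return {s: sorted(v) for s, v in adj.items()}
    raise RuntimeError("failed to sample a simple bond graph")


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (pictures, events, interactions, truth).

    Deterministic given ``config`` (including ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = config.subjects

    intercepts = {s: float(rng.normal(0.0, config.subject_sd)) for s in subjects}
    clusters = sorted(set(config.cluster_map.values()))
    cluster_subject = {
        c: {s: float(rng.normal(0.0, config.cluster_subject_sds.get(c, 0.0)))
            for s in subjects}
        for c in clusters
    }
    elo_order = list(rng.permutation(subjects))
    alpha_id = elo_order[0]
    mothers = set(rng.choice(subjects, size=config.n_mothers, replace=False))
    bonds = _mutual_bond_graph(subjects, config.n_bond_partners, rng)

    events = _simulate_events(config, rng, intercepts, cluster_subject, alpha_id, mothers)
    pictures = _simulate_pictures(config, rng, events)
    interactions = _simulate_interactions(config, rng, elo_order, bonds)
    event_temperature = dict(zip(events["event_id"],
                                 events["true_temp"].astype(float)))
    events = events.drop(columns=["true_temp"])

    truth = SyntheticTruth(
        subject_intercepts=intercepts,
        cluster_subject_effects=cluster_subject,
        elo_order=elo_order,
        bond_partners=bonds,
        audience_effects=dict(config.audience_effects),
        event_temperature=event_temperature,
        config=config,
    )
    return pictures, events, interactions, truth


def write_fixture(dataset, directory) -> dict[str, Path]:
    """Write a generated dataset as three CSV tables plus truth.json."""
    pictures, events, interactions, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pictures": directory / "pictures.csv",
        "events": directory / "events.csv",
        "interactions": directory / "interactions.csv",
        "truth": directory / "truth.json",
    }
    pictures.to_csv(paths["pictures"], index=False)
    events.to_csv(paths["events"], index=False)
    interactions.to_csv(paths["interactions"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths


def read_fixture(directory) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back the three CSV tables written by :func:`write_fixture`."""
    directory = Path(directory)
    pictures = pd.read_csv(directory / "pictures.csv")
    events = pd.read_csv(directory / "events.csv",
                         dtype={"partner_id": str, "groom_role": str},
                         keep_default_na=False, na_values=[])
    for col in ("ambient_c", "humidity_pct", "distance_m"):
        events[col] = events[col].astype(float)
    for col in ("alpha_35", "alpha_10", "mother_35", "mother_10",
                "n_males_10", "n_males_35", "n_females_10", "n_females_35"):
        events[col] = events[col].astype(int)
    interactions = pd.read_csv(directory / "interactions.csv")
    return pictures, events, interactions
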