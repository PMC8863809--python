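"""CRI, bond-partner selection and Elo-rating dominance scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermosocial import (GeneratorConfig, InteractionLog, compute_cri,
                          compute_elo, generate_dataset, select_bond_partners)
from thermosocial.social import (AGGRESSION_BLOCK_WEIGHT, SEVERE_WEIGHT,
                                 cri_matrix, hierarchy_stability)


def _log(records, effort):
    frame = pd.DataFrame(records, columns=["month", "actor", "receiver",
                                           "kind", "count"])
    for subject, count in effort.items():
        frame = pd.concat([frame, pd.DataFrame([{
            "month": 1, "actor": subject, "receiver": "TOTAL",
            "kind": "effort", "count": count}])], ignore_index=True)
    return InteractionLog.from_frame(frame)


def test_cri_printed_formula_substitution():
    # G=10, R=5, A=1 plain aggression, T=100 -> (10 + 5 - 5*1)/100 = 0.10
    log = _log([(1, "F", "J", "groom", 10),
                (1, "F", "J", "prox5m", 5),
                (1, "J", "F", "aggression", 1)], {"F": 100})
    assert compute_cri(log, "F")["J"] == pytest.approx(0.10)


def test_cri_severe_aggression_counts_double():
    # G=4, R=6, one severe aggression (A=2), T=50 -> (4 + 6 - 5*2)/50 = 0
    log = _log([(1, "F", "J", "groom", 4),
                (1, "F", "J", "prox5m", 6),
                (1, "F", "J", "severe", 1)], {"F": 50})
    assert compute_cri(log, "F")["J"] == pytest.approx(0.0)


def test_cri_agrees_with_brute_force_tally():
    rng = np.random.default_rng(0)
    subjects = [f"M{i}" for i in range(5)]
    kinds = ["groom", "prox5m", "aggression", "chase", "threat", "severe",
             "pantgrunt"]
    rows = []
    for _ in range(300):
        a, b = rng.choice(subjects, size=2, replace=False)
        rows.append((int(rng.integers(1, 7)), a, b, rng.choice(kinds),
                     int(rng.integers(1, 4))))
    log = _log(rows, {s: 500 for s in subjects})
    focal = "M0"
    cri = compute_cri(log, focal)
    for partner in cri.index:
        g = r = a_plain = a_severe = 0
        for month, actor, receiver, kind, count in rows:
            pair = {actor, receiver}
            if pair != {focal, partner}:
                continue
            if kind == "groom":
                g += count
            elif kind == "prox5m":
                r += count
            elif kind in ("aggression", "chase", "threat"):
                a_plain += count
            elif kind == "severe":
                a_severe += count
            # pant-grunts deliberately excluded from CRI
        expected = (g + r - AGGRESSION_BLOCK_WEIGHT
                    * (a_plain + SEVERE_WEIGHT * a_severe)) / 500
        assert cri[partner] == pytest.approx(expected)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(g=st.integers(0, 50), r=st.integers(0, 50), a=st.integers(0, 10),
       t=st.integers(1, 500), scale=st.integers(2, 5))
def test_cri_invariant_under_common_scaling(g, r, a, t, scale):
    def cri_of(gg, rr, aa, tt):
        log = _log([(1, "F", "J", "groom", gg),
                    (1, "F", "J", "prox5m", rr),
                    (1, "F", "J", "aggression", aa)], {"F": tt})
        return compute_cri(log, "F")["J"]

    assert cri_of(g * scale, r * scale, a * scale, t * scale) == \
        pytest.approx(cri_of(g, r, a, t))


def test_bond_selection_respects_sign_restriction():
    cri = pd.Series({"P1": 0.3, "P2": 0.2, "P3": 0.1, "P4": 0.05, "P5": -0.1})
    bond, non_bond = select_bond_partners(cri)
    assert bond == ["P1", "P2", "P3"]
    assert non_bond == ["P5"]


def test_bond_set_empty_when_all_cri_negative():
    cri = pd.Series({"P1": -0.3, "P2": -0.2, "P3": -0.1})
    bond, non_bond = select_bond_partners(cri)
    assert bond == []
    assert non_bond == ["P1", "P2", "P3"]
    assert set(bond).isdisjoint(non_bond)


def test_elo_equal_ratings_split_k():
    log = _log([(1, "A", "B", "severe", 1)], {"A": 10, "B": 10})
    state = compute_elo(log, k_factor=100.0, start_rating=1000.0)
    assert state.ratings["A"] == pytest.approx(1050.0)
    assert state.ratings["B"] == pytest.approx(950.0)


def test_elo_conserves_total_rating_after_every_update():
    rng = np.random.default_rng(1)
    subjects = [f"M{i}" for i in range(6)]
    rows = []
    for _ in range(200):
        a, b = rng.choice(subjects, size=2, replace=False)
        rows.append((int(rng.integers(1, 7)), a, b,
                     rng.choice(["severe", "chase", "threat", "pantgrunt"]), 1))
    log = _log(rows, {s: 10 for s in subjects})
    state = compute_elo(log, k_factor=100.0, start_rating=1000.0)
    total0 = len(subjects) * 1000.0
    running = {s: 1000.0 for s in subjects}
    for row in state.history.itertuples():
        running[row.winner] = row.winner_after
        running[row.loser] = row.loser_after
        assert sum(running.values()) == pytest.approx(total0, abs=1e-6)


def test_elo_z_scores_invariant_to_start_rating():
    rows = [(1, "A", "B", "chase", 1), (2, "B", "C", "threat", 1),
            (3, "A", "C", "severe", 2)]
    log = _log(rows, {s: 10 for s in "ABC"})
    z1 = compute_elo(log, start_rating=1000.0).z_scores
    z2 = compute_elo(log, start_rating=0.0).z_scores
    for s in "ABC":
        assert z1[s] == pytest.approx(z2[s], abs=1e-9)
    zs = np.array(list(z1.values()))
    assert zs.mean() == pytest.approx(0.0, abs=1e-12)
    assert zs.std() == pytest.approx(1.0, abs=1e-12)


def test_pant_grunt_receiver_wins():
    log = _log([(1, "Sub", "Dom", "pantgrunt", 1)], {"Sub": 10, "Dom": 10})
    state = compute_elo(log)
    assert state.ratings["Dom"] > state.ratings["Sub"]


def test_subject_without_interactions_keeps_start_rating():
    log = _log([(1, "A", "B", "severe", 1)], {"A": 10, "B": 10, "C": 10})
    state = compute_elo(log, start_rating=1000.0)
    assert state.ratings["C"] == 1000.0
    assert "C" not in state.interacted


def test_steep_hierarchy_fully_recovered_by_elo():
    cfg = GeneratorConfig(n_events_per_type=1, n_baseline_events=1,
                          hierarchy_steepness=50.0, agonistic_rate=4.0,
                          seed=21)
    *_, interactions, truth = generate_dataset(cfg)
    log = InteractionLog.from_frame(interactions)
    state = compute_elo(log)
    assert state.order == truth.elo_order


def test_planted_bonds_recovered_by_top3_cri():
    hits = total = 0
    for seed in range(30, 45):
        cfg = GeneratorConfig(n_events_per_type=1, n_baseline_events=1,
                              seed=seed)
        *_, interactions, truth = generate_dataset(cfg)
        log = InteractionLog.from_frame(interactions)
        for focal, planted in truth.bond_partners.items():
            bond, _ = select_bond_partners(compute_cri(log, focal), log)
            hits += len(set(bond) & set(planted))
            total += min(len(planted), 3)
    assert hits / total >= 0.9


def test_hierarchy_stability_near_one_for_stable_hierarchy():
    cfg = GeneratorConfig(n_events_per_type=1, n_baseline_events=1,
                          hierarchy_steepness=50.0, agonistic_rate=4.0,
                          seed=22)
    *_, interactions, _ = generate_dataset(cfg)
    rho = hierarchy_stability(InteractionLog.from_frame(interactions))
    assert rho > 0.8


def test_cri_matrix_covers_all_focals(small_dataset):
    *_, interactions, truth = small_dataset
    log = InteractionLog.from_frame(interactions)
    mat = cri_matrix(log)
    n = truth.config.n_subjects
    assert set(mat["focal"]) == set(truth.config.subjects)
    assert len(mat) == n * (n - 1)


def test_cri_requires_observation_effort():
    log = _log([(1, "F", "J", "groom", 1)], {"J": 10})
    with pytest.raises(ValueError):
        compute_cri(log, "F")
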