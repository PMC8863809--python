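"""Social indices from long-term interaction logs.

Two indices drive the audience-effect analysis:

* the Composite Relationship Index (CRI), a dyadic score combining
  socio-positive 15-min occurrences (grooming in either direction or
  mutual, resting within 5 m) and socio-negative events (aggressions,
  weighted), normalized by observation effort:

      CRI(focal, j) = (G + R - 5 * A) / T

  where severe aggressions count double inside A and the whole
  aggression block is multiplied by five to put event counts on the
  scale of 15-min occurrence counts.  The focal's three highest scores
  above zero define his bond partners; the three lowest below zero his
  non-bond partners.

* the Elo rating, a sequential dominance score updated after every
  decided agonistic interaction (severe aggressions, chases, threats)
  and every pant-grunt (the receiver of this unidirectional submissive
  call is the winner).  Final scores are standardized to z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import EFFORT_RECEIVER

#: interaction kinds entering the CRI aggression block
CRI_AGGRESSION_KINDS = ("aggression", "chase", "threat", "severe")
#: kinds entering Elo (pant-grunts included; plain displays/aggressions
#: without a clear agonistic winner do not, per the hierarchy definition)
ELO_KINDS = ("severe", "chase", "threat", "pantgrunt")

AGGRESSION_BLOCK_WEIGHT = 5.0
SEVERE_WEIGHT = 2.0


@dataclass
class InteractionLog:
    """Long-term dyadic records plus per-focal observation effort."""

    records: pd.DataFrame  # columns: month, actor, receiver, kind, count
    effort: dict[str, int]  # subject -> total 15-min focal occurrences

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionLog":
        """Split a raw interactions table into records and effort rows."""
        required = {"month", "actor", "receiver", "kind", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"interaction table missing columns: {sorted(missing)}")
        is_effort = frame["kind"] == "effort"
        effort = (frame.loc[is_effort].groupby("actor")["count"].sum().astype(int)
                  .to_dict())
        records = frame.loc[~is_effort].reset_index(drop=True)
        if (records["actor"] == records["receiver"]).any():
            raise ValueError("interaction records with actor == receiver")
        if (records["count"] < 0).any():
            raise ValueError("negative interaction counts")
        return cls(records=records, effort=effort)

    @property
    def subjects(self) -> list[str]:
        subs = set(self.records["actor"]) | set(self.records["receiver"])
        subs.discard(EFFORT_RECEIVER)
        subs |= set(self.effort)
        return sorted(subs)


def compute_cri(log: InteractionLog, focal: str) -> pd.Series:
    """CRI of ``focal`` with every partner appearing in the log.

    Grooming and 5-m proximity count in either direction; aggressions
    count whether the focal was aggressor or victim, with severe
    aggressions weighted double; the aggression block is multiplied by
    five.  Denominator is the focal's total observation effort.
    """
    T = log.effort.get(focal, 0)
    if T <= 0:
        raise ValueError(f"no observation effort recorded for focal {focal!r}")
    rec = log.records
    involves = (rec["actor"] == focal) | (rec["receiver"] == focal)
    sub = rec.loc[involves].copy()
    sub["partner"] = np.where(sub["actor"] == focal, sub["receiver"], sub["actor"])

    partners = sorted(set(log.subjects) - {focal})
    out = pd.Series(0.0, index=pd.Index(partners, name="partner"), name="cri")
    for partner, grp in sub.groupby("partner"):
        if partner not in out.index:
            continue
        g = grp.loc[grp["kind"] == "groom", "count"].sum()
        r = grp.loc[grp["kind"] == "prox5m", "count"].sum()
        plain = grp.loc[grp["kind"].isin(("aggression", "chase", "threat")), "count"].sum()
        severe = grp.loc[grp["kind"] == "severe", "count"].sum()
        a = plain + SEVERE_WEIGHT * severe
        out[partner] = (g + r - AGGRESSION_BLOCK_WEIGHT * a) / T
    return out


def cri_matrix(log: InteractionLog) -> pd.DataFrame:
    """CRI for every (focal, partner) pair with recorded effort."""
    rows = []
    for focal in log.subjects:
        if log.effort.get(focal, 0) <= 0:
            continue
        cri = compute_cri(log, focal)
        for partner, value in cri.items():
            rows.append(dict(focal=focal, partner=partner, cri=value))
    return pd.DataFrame(rows)


def select_bond_partners(cri: pd.Series, log: InteractionLog | None = None,
                         n: int = 3) -> tuple[list[str], list[str]]:
    """Top-``n`` positive-CRI partners (bond) and bottom-``n`` negative
    (non-bond).

    Either set may have fewer than ``n`` members if not enough partners
    have the required sign.  Ties are broken by total interaction count
    with the focal (descending; only available when ``log`` is given),
    then by partner id, for determinism.
    """
    totals = pd.Series(0.0, index=cri.index)
    if log is not None:
        rec = log.records
        for partner in cri.index:
            inv = ((rec["actor"] == partner) | (rec["receiver"] == partner))
            totals[partner] = rec.loc[inv, "count"].sum()
    order = pd.DataFrame({"cri": cri, "total": totals}).sort_index()
    # stable sort after sorting the index => ties resolve by partner id
    order = order.sort_values(["cri", "total"], ascending=[False, False],
                              kind="mergesort")
    bond = [p for p in order.index[order["cri"] > 0][:n]]
    low = pd.DataFrame({"cri": cri, "total": totals}).sort_index()
    low = low.sort_values(["cri", "total"], ascending=[True, False],
                          kind="mergesort")
    non_bond = [p for p in low.index[low["cri"] < 0][:n]]
    return bond, non_bond


@dataclass
class EloState:
    """Ratings after sequentially processing an interaction log."""

    ratings: dict[str, float]
    z_scores: dict[str, float]
    history: pd.DataFrame  # step, winner, loser, p_expected, winner_after, loser_after
    k_factor: float
    start_rating: float
    interacted: set[str] = field(default_factory=set)

    @property
    def order(self) -> list[str]:
        """Subjects from highest to lowest final rating."""
        return sorted(self.ratings, key=lambda s: (-self.ratings[s], s))


def _elo_sequence(records: pd.DataFrame) -> pd.DataFrame:
    """Decided (winner, loser) sequence in chronological (month, row) order."""
    rec = records.loc[records["kind"].isin(ELO_KINDS)].copy()
    rec = rec.sort_values("month", kind="mergesort")  # stable within month
    rec = rec.loc[rec.index.repeat(rec["count"].astype(int))]
    winner = np.where(rec["kind"] == "pantgrunt", rec["receiver"], rec["actor"])
    loser = np.where(rec["kind"] == "pantgrunt", rec["actor"], rec["receiver"])
    return pd.DataFrame({"winner": winner, "loser": loser})


def compute_elo(log: InteractionLog, k_factor: float = 100.0,
                start_rating: float = 1000.0,
                subjects: list[str] | None = None) -> EloState:
    """Sequential Elo update over the log's decided interactions.

    Winner gains ``k * (1 - p)`` where ``p`` is the expected win
    probability ``1 / (1 + 10**((r_loser - r_winner)/400))``; the loser
    loses the same amount, so total rating mass is conserved exactly.
    """
    subjects = list(subjects) if subjects is not None else log.subjects
    ratings = {s: float(start_rating) for s in subjects}
    interacted: set[str] = set()
    hist = []
    seq = _elo_sequence(log.records)
    for step, row in enumerate(seq.itertuples(index=False)):
        w, l = row.winner, row.loser
        if w not in ratings or l not in ratings:
            continue
        p = 1.0 / (1.0 + 10.0 ** ((ratings[l] - ratings[w]) / 400.0))
        delta = k_factor * (1.0 - p)
        ratings[w] += delta
        ratings[l] -= delta
        interacted |= {w, l}
        hist.append(dict(step=step, winner=w, loser=l, p_expected=p,
                         winner_after=ratings[w], loser_after=ratings[l]))
    finals = np.array([ratings[s] for s in subjects])
    sd = finals.std(ddof=0)
    z = (finals - finals.mean()) / sd if sd > 0 else np.zeros_like(finals)
    return EloState(ratings=ratings,
                    z_scores=dict(zip(subjects, z.tolist())),
                    history=pd.DataFrame(hist), k_factor=k_factor,
                    start_rating=start_rating, interacted=interacted)


def hierarchy_stability(log: InteractionLog, k_factor: float = 100.0,
                        start_rating: float = 1000.0) -> float:
    """Spearman correlation between first-half and second-half Elo ranks.

    A descriptive check of hierarchy stability over the logging window;
    values near 1 indicate a stable rank order.  Reported, not enforced.
    """
    months = sorted(log.records["month"].unique())
    if len(months) < 2:
        return float("nan")
    half = months[len(months) // 2]
    first = log.records.loc[log.records["month"] < half]
    second = log.records.loc[log.records["month"] >= half]
    subjects = log.subjects
    e1 = compute_elo(InteractionLog(first, log.effort), k_factor, start_rating, subjects)
    e2 = compute_elo(InteractionLog(second, log.effort), k_factor, start_rating, subjects)
    r1 = [e1.ratings[s] for s in subjects]
    r2 = [e2.ratings[s] for s in subjects]
    rho = spearmanr(r1, r2).statistic
    return float(rho)
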