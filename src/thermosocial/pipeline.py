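"""End-to-end orchestration: raw tables -> structured analysis report.

Stages: validate -> time-window filter + angle correction -> per-event
aggregation -> CRI / Elo / bond partners -> baseline confound
calibration -> event-type clustering -> the cluster comparison model ->
audience-effect model selection on the cooperative cluster, grooming
events, the competitive cluster and copulations.  The report is a plain
dict serialized to JSON (bit-identical under a fixed config and seed)
plus an optional Markdown summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .simulate import (BASELINE, GeneratorConfig, generate_dataset,
                       ANGLE_CATEGORIES, GROOMING_TYPES, MOVEMENT_LEVELS)
from .preprocess import (PHYSIO_BOUNDS, build_angle_matrix, correct_events,
                         filter_time_window, impute_regularized_pca)
from .social import (InteractionLog, compute_elo, cri_matrix,
                     hierarchy_stability, select_bond_partners, compute_cri)
from .clustering import (adjusted_rand, build_profiles, choose_k_silhouette,
                         reference_partition, ward_cluster)
from .lmm import (LMMSpec, TemperatureLMM, calibrate_confounds, dredge_select,
                  lrt, pairwise_contrasts, term_chisq)

logger = logging.getLogger(__name__)

PICTURE_COLUMNS = ("event_id", "subject_id", "angle", "temp_c", "sec_after_event")
EVENT_COLUMNS = ("event_id", "subject_id", "event_type", "movement",
                 "ambient_c", "humidity_pct", "distance_m",
                 "alpha_35", "alpha_10", "mother_35", "mother_10",
                 "n_males_10", "n_males_35", "n_females_10", "n_females_35",
                 "partner_id", "groom_role")
INTERACTION_COLUMNS = ("month", "actor", "receiver", "kind", "count")

#: marker event types anchoring cluster roles: grooming is cooperative
#: by definition, overt agonism competitive
COOPERATIVE_MARKERS = GROOMING_TYPES
COMPETITIVE_MARKERS = ("aggression", "display", "dominant_arrival")

DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "cooperation": ("alpha_35", "z_elo", "n_females_10", "mother_35", "n_males_10"),
    "grooming": ("groom_role", "partner_is_alpha",
                 "groom_role:partner_is_alpha", "alpha_35", "z_elo"),
    "competition": ("n_females_10", "alpha_35", "n_males_10", "mother_35", "z_elo"),
    "copulation": ("n_males_10", "mother_35", "n_females_10", "alpha_35"),
}


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, method settings, output paths."""

    #: directory containing pictures.csv / events.csv / interactions.csv,
    #: or None to generate synthetic data from ``generator``
    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    #: optional external-name -> internal-name column mapping per table
    column_map: dict[str, dict[str, str]] = field(default_factory=dict)
    pca_rank: int = 2
    pca_tol: float = 1e-6
    pca_max_iter: int = 5000
    elo_k: float = 100.0
    elo_start: float = 1000.0
    k_range: tuple[int, int] = (2, 7)
    candidate_terms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CANDIDATES.items()})
    #: minimum events for an audience analysis to run
    min_events: int = 20
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.input_dir is None and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    def config_hash(self) -> str:
        payload = _sanitize(dataclasses.asdict(self))
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sanitize(obj):
    """Make a nested structure JSON-serializable and deterministic."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = sorted(obj) if isinstance(obj, set) else obj
        return [_sanitize(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return [_sanitize(r) for r in obj.to_dict(orient="records")]
    return obj


def load_tables(input_dir, column_map: dict | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three input CSVs, applying an optional column mapping."""
    input_dir = Path(input_dir)
    frames = {}
    for name in ("pictures", "events", "interactions"):
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        kw = {}
        if name == "events":
            kw = dict(dtype={"partner_id": str, "groom_role": str},
                      keep_default_na=False, na_values=[])
        try:
            df = pd.read_csv(path, **kw)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        mapping = (column_map or {}).get(name)
        if mapping:
            df = df.rename(columns=mapping)
        frames[name] = df
    ev = frames["events"]
    for col in ("ambient_c", "humidity_pct", "distance_m"):
        if col in ev.columns:
            ev[col] = pd.to_numeric(ev[col])
    for col in ("alpha_35", "alpha_10", "mother_35", "mother_10",
                "n_males_10", "n_males_35", "n_females_10", "n_females_35"):
        if col in ev.columns:
            ev[col] = pd.to_numeric(ev[col]).astype(int)
    return frames["pictures"], frames["events"], frames["interactions"]


def validate_inputs(pictures: pd.DataFrame, events: pd.DataFrame,
                    interactions: pd.DataFrame) -> dict:
    """Schema, range and referential-integrity checks.

    Returns ``{"errors": [...], "warnings": [...], "ok": bool}``; errors
    carry enough location detail (table, column, row indices) to find
    the offending cells.
    """
    errors, warnings_ = [], []

    def _check_columns(df, required, table):
        missing = set(required) - set(df.columns)
        if missing:
            errors.append(f"{table}: missing columns {sorted(missing)}")
        return not missing

    ok_p = _check_columns(pictures, PICTURE_COLUMNS, "pictures")
    ok_e = _check_columns(events, EVENT_COLUMNS, "events")
    ok_i = _check_columns(interactions, INTERACTION_COLUMNS, "interactions")

    if ok_p:
        # clearly impossible readings are errors; merely non-physiological
        # ones are warnings (the preprocessing filter drops them)
        bad = pictures.index[~pictures["temp_c"].between(0.0, 60.0)].tolist()
        if bad:
            errors.append(f"pictures: temp_c outside instrument range [0, 60] "
                          f"at rows {bad[:10]}" + ("..." if len(bad) > 10 else ""))
        lo, hi = PHYSIO_BOUNDS
        odd = pictures.index[~pictures["temp_c"].between(lo, hi)].tolist()
        odd = [r for r in odd if r not in bad]
        if odd:
            warnings_.append(f"pictures: temp_c outside physiological bounds "
                             f"[{lo}, {hi}] at rows {odd[:10]}; these pictures "
                             "are dropped during preprocessing")
        bad = pictures.index[pictures["sec_after_event"] < 0].tolist()
        if bad:
            errors.append(f"pictures: negative sec_after_event at rows {bad[:10]}")
        unknown = sorted(set(pictures["angle"]) - set(ANGLE_CATEGORIES))
        if unknown:
            errors.append(f"pictures: unknown angle categories {unknown}")
    if ok_e:
        unknown = sorted(set(events["movement"]) - set(MOVEMENT_LEVELS))
        if unknown:
            errors.append(f"events: unknown movement levels {unknown}")
        for col in ("n_males_10", "n_males_35", "n_females_10", "n_females_35"):
            if (events[col] < 0).any():
                errors.append(f"events: negative counts in {col}")
        bad10 = events.index[(events["n_males_10"] > events["n_males_35"])
                             | (events["n_females_10"] > events["n_females_35"])
                             | (events["alpha_10"] > events["alpha_35"])
                             | (events["mother_10"] > events["mother_35"])].tolist()
        if bad10:
            errors.append(f"events: 10 m audience exceeds 35 m audience at rows "
                          f"{bad10[:10]}")
        if events["event_id"].duplicated().any():
            errors.append("events: duplicated event_id values")
    if ok_p and ok_e:
        orphan = sorted(set(pictures["event_id"]) - set(events["event_id"]))
        if orphan:
            errors.append(f"pictures reference unknown event ids {orphan[:10]}"
                          + ("..." if len(orphan) > 10 else ""))
    if ok_i and ok_e:
        log_subjects = set(interactions["actor"])
        focal = set(events["subject_id"])
        missing = sorted(focal - log_subjects)
        if missing:
            warnings_.append(f"focal subjects absent from interaction logs: {missing}")
        if (interactions["count"] < 0).any():
            errors.append("interactions: negative counts")

    return {"errors": errors, "warnings": warnings_, "ok": not errors}


def _descriptives(df: pd.DataFrame, group: str,
                  value: str = "corrected_temp_c") -> dict:
    g = df.groupby(group)[value]
    return {str(k): {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                     "n": int(v.size)}
            for k, v in g}


def _audience_analysis(name: str, data: pd.DataFrame, candidates,
                       min_events: int) -> dict:
    """Dredge over the candidate terms, LRT vs null, per-term Wald tests."""
    candidates = [c for c in candidates
                  if all(data[v].nunique() > 1 for v in c.split(":"))
                  ]
    out: dict = {"n": int(len(data))}
    if len(data) < min_events:
        out["status"] = "skipped"
        out["reason"] = f"fewer than {min_events} events"
        return out
    base = LMMSpec()
    table, best_spec = dredge_select(data, base, candidates)
    best_fit = TemperatureLMM(data, best_spec).fit("ML")
    null_fit = TemperatureLMM(data, base.null).fit("ML")
    stat, df, p = lrt(best_fit, null_fit)
    reml = TemperatureLMM(data, best_spec).fit("REML") if best_spec.fixed_terms \
        else best_fit
    out.update(
        status="ok",
        candidates=list(candidates),
        best_terms=sorted(best_spec.fixed_terms),
        model_table=table.head(10).to_dict(orient="records"),
        lrt={"chisq": stat, "df": df, "p": p},
        anova=term_chisq(best_fit).to_dict(orient="records"),
        coefficients={k: {"estimate": float(reml.fe_params[k]),
                          "se": float(reml.bse_fe[k])}
                      for k in reml.fe_params.index},
        aicc_best=best_fit.aicc,
        converged=bool(best_fit.converged),
    )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report dict.

    Re-running with an identical config (and seed, for synthetic input)
    reproduces the report bit-for-bit.  Any stage failure truncates the
    report at that stage with ``status: "failed"`` and the error message.
    """
    report: dict = {
        "provenance": {
            "version": _version,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        "status": "ok",
    }
    try:
        return _run_stages(config, report)
    except Exception as exc:  # noqa: BLE001 - report carries the failure
        logger.exception("pipeline failed")
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        return report


def _run_stages(config: PipelineConfig, report: dict) -> dict:
    # --- input ---------------------------------------------------------
    if config.input_dir is not None:
        pictures, events, interactions = load_tables(config.input_dir,
                                                     config.column_map)
        truth = None
    else:
        pictures, events, interactions, truth = generate_dataset(config.generator)
    report["stage"] = "validate"
    validation = validate_inputs(pictures, events, interactions)
    report["validation"] = validation
    if not validation["ok"]:
        raise ValueError("input validation failed: " + "; ".join(validation["errors"]))

    # --- angle correction ---------------------------------------------
    report["stage"] = "correct"
    kept = filter_time_window(pictures)
    matrix = build_angle_matrix(kept)
    completed = impute_regularized_pca(matrix, rank=config.pca_rank,
                                       tol=config.pca_tol,
                                       max_iter=config.pca_max_iter)
    corrected = correct_events(completed)
    report["imputation"] = {
        "n_events": int(len(corrected)),
        "n_imputed": int(corrected["was_imputed"].sum()),
        "imputed_pct": float(100.0 * corrected["was_imputed"].mean()),
        "n_excluded": int(corrected["excluded"].sum()),
        "converged": bool(completed.converged),
        "n_iter": int(completed.n_iter),
    }
    corrected = corrected.loc[~corrected["excluded"]]

    # --- analysis table ------------------------------------------------
    data = corrected.merge(events, on="event_id", how="inner", validate="1:1")
    # party rule: at least one other individual within 35 m
    in_party = (data["n_males_35"] + data["n_females_35"]) >= 1
    data = data.loc[in_party].reset_index(drop=True)

    # --- social indices -------------------------------------------------
    report["stage"] = "social"
    log = InteractionLog.from_frame(interactions)
    elo = compute_elo(log, k_factor=config.elo_k, start_rating=config.elo_start)
    alpha_id = elo.order[0]
    bonds = {}
    for focal in log.subjects:
        if log.effort.get(focal, 0) > 0:
            cri = compute_cri(log, focal)
            bond, non_bond = select_bond_partners(cri, log)
            bonds[focal] = {"bond": bond, "non_bond": non_bond}
    report["social"] = {
        "alpha": alpha_id,
        "elo_order": elo.order,
        "z_elo": {s: elo.z_scores[s] for s in sorted(elo.z_scores)},
        "hierarchy_stability": hierarchy_stability(log, config.elo_k,
                                                   config.elo_start),
        "bonds": bonds,
        "cri": cri_matrix(log).to_dict(orient="records"),
    }
    data["z_elo"] = data["subject_id"].map(elo.z_scores).fillna(0.0)
    data["partner_is_alpha"] = (data["partner_id"] == alpha_id).astype(int)

    # --- baseline confound calibration ----------------------------------
    report["stage"] = "confounds"
    baseline = data.loc[data["event_type"] == BASELINE]
    if len(baseline) < 10:
        raise ValueError(f"only {len(baseline)} baseline events; cannot "
                         "calibrate confounds")
    conf = calibrate_confounds(baseline)
    report["confounds"] = {
        "tests": conf.tests.to_dict(orient="records"),
        "controlled": conf.controlled,
        "ambient_mean": conf.ambient_mean,
    }
    data = conf.center_ambient(data)

    # residual model for clustering features: ambient slope + movement
    # offsets estimated on baseline with subject as random factor
    resid_spec = LMMSpec(fixed_terms=("ambient_centered", "movement"),
                         random_factors=("subject_id",), control=None)
    resid_fit = TemperatureLMM(baseline.assign(
        ambient_centered=baseline["ambient_c"] - conf.ambient_mean), resid_spec
    ).fit("REML")
    slope = float(resid_fit.fe_params.get("ambient_centered", 0.0))
    movement_effects = {m: 0.0 for m in sorted(data["movement"].unique())}
    for name, value in resid_fit.fe_params.items():
        if name.startswith("movement["):
            movement_effects[name.split("T.")[1].rstrip("]")] = float(value)

    # --- clustering ------------------------------------------------------
    report["stage"] = "clustering"
    profiles = build_profiles(data, ambient_slope=slope,
                              movement_effects=movement_effects)
    result = ward_cluster(profiles)
    result = choose_k_silhouette(result, profiles,
                                 k_range=range(config.k_range[0],
                                               config.k_range[1] + 1))
    # name clusters by marker event types (the way cell clusters are
    # annotated by marker genes): grooming marks the cooperative
    # cluster, overt agonism the competitive one; audience effects can
    # shift observed cluster means, so means only break ties
    cluster_means = {}
    for cid in sorted(set(result.assignment.values())):
        types = [t for t, c in result.assignment.items() if c == cid]
        cluster_means[cid] = float(
            data.loc[data["event_type"].isin(types), "corrected_temp_c"].mean())

    def _marker_pick(markers, exclude, fallback):
        counts = {cid: sum(1 for t, c in result.assignment.items()
                           if c == cid and t in markers)
                  for cid in cluster_means if cid not in exclude}
        if counts and max(counts.values()) > 0:
            return max(sorted(counts), key=counts.get)
        return fallback

    coop_id = _marker_pick(COOPERATIVE_MARKERS, (),
                           max(cluster_means, key=cluster_means.get))
    comp_id = _marker_pick(COMPETITIVE_MARKERS, (coop_id,),
                           min((c for c in cluster_means if c != coop_id),
                               key=cluster_means.get))
    role = {cid: "intermediate" for cid in cluster_means}
    role[comp_id] = "competitive"
    role[coop_id] = "cooperative"
    type_role = {t: role[c] for t, c in result.assignment.items()}
    data["cluster"] = data["event_type"].map(type_role).fillna(BASELINE)

    clustering_report = {
        "chosen_k": result.chosen_k,
        "assignment": {t: int(c) for t, c in sorted(result.assignment.items())},
        "roles": {t: type_role[t] for t in sorted(type_role)},
        "silhouette_by_k": {str(k): v for k, v in sorted(result.silhouette_by_k.items())},
        "silhouette_widths": {t: v for t, v in sorted(result.silhouette_widths.items())},
        "cophenetic": result.cophenetic,
    }
    if set(result.assignment) == set(reference_partition()):
        clustering_report["ari_vs_reference"] = adjusted_rand(
            result.assignment, reference_partition())
    report["clustering"] = clustering_report

    # --- cluster model ---------------------------------------------------
    report["stage"] = "cluster_model"
    spec = LMMSpec(fixed_terms=("cluster",))
    fit = TemperatureLMM(data, spec).fit("ML")
    null_fit = TemperatureLMM(data, spec.null).fit("ML")
    stat, df, p = lrt(fit, null_fit)
    report["cluster_model"] = {
        "n": int(len(data)),
        "lrt": {"chisq": stat, "df": df, "p": p},
        "anova": term_chisq(fit).to_dict(orient="records"),
        "contrasts": pairwise_contrasts(fit, "cluster").to_dict(orient="records"),
        "descriptives": _descriptives(data, "cluster"),
    }

    # --- audience models -------------------------------------------------
    report["stage"] = "audience_models"
    subsets = {
        "cooperation": data.loc[data["cluster"] == "cooperative"],
        "grooming": data.loc[data["groom_role"] != ""],
        "competition": data.loc[data["cluster"] == "competitive"],
        "copulation": data.loc[data["event_type"] == "copulation"],
    }
    report["analyses"] = {}
    for name, subset in subsets.items():
        candidates = config.candidate_terms.get(name, ())
        try:
            report["analyses"][name] = _audience_analysis(
                name, subset.reset_index(drop=True), candidates,
                config.min_events)
        except Exception as exc:  # one failed analysis must not kill the rest
            logger.exception("analysis %s failed", name)
            report["analyses"][name] = {"status": "failed",
                                        "error": f"{type(exc).__name__}: {exc}",
                                        "n": int(len(subset))}

    if truth is not None:
        report["truth_recovery"] = _truth_recovery(report, data, truth)

    report["stage"] = "done"
    report = _sanitize(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        (out / "report.md").write_text(render_markdown(report))
    return report


def _truth_recovery(report: dict, data: pd.DataFrame, truth) -> dict:
    """Compare pipeline outputs with the generator's planted truth."""
    from scipy.stats import spearmanr

    cfg = truth.config
    true_part = {t: {"A": 1, "B": 2, "C": 3}[c]
                 for t, c in cfg.cluster_map.items() if c in ("A", "B", "C")}
    est_part = {t: c for t, c in report["clustering"]["assignment"].items()}
    ari = adjusted_rand(est_part, true_part) if set(est_part) == set(true_part) \
        else float("nan")
    est_order = report["social"]["elo_order"]
    rho = float(spearmanr(range(len(truth.elo_order)),
                          [est_order.index(s) for s in truth.elo_order]).statistic)
    bond_hits, bond_total = 0, 0
    for focal, planted in truth.bond_partners.items():
        est = set(report["social"]["bonds"].get(focal, {}).get("bond", []))
        bond_hits += len(est & set(planted))
        bond_total += len(planted)
    return {
        "ari_clusters": ari,
        "elo_spearman": rho,
        "alpha_recovered": bool(report["social"]["alpha"] == truth.elo_order[0]),
        "bond_recovery_rate": bond_hits / bond_total if bond_total else float("nan"),
    }


def render_markdown(report: dict) -> str:
    """Short human-readable summary of a report dict."""
    lines = [
        "# Thermal imaging analysis report",
        "",
        f"- status: {report.get('status')}",
        f"- seed: {report.get('provenance', {}).get('seed')}",
        f"- config hash: {report.get('provenance', {}).get('config_hash')}",
    ]
    if "imputation" in report:
        imp = report["imputation"]
        lines += ["", "## Angle correction",
                  f"- events: {imp['n_events']}, imputed: {imp['n_imputed']} "
                  f"({imp['imputed_pct']:.2f}%)"]
    if "clustering" in report:
        cl = report["clustering"]
        lines += ["", "## Event clustering",
                  f"- chosen k: {cl['chosen_k']}",
                  f"- cophenetic (ward/single): "
                  f"{cl['cophenetic'].get('ward'):.3f} / "
                  f"{cl['cophenetic'].get('single'):.3f}"]
    if "cluster_model" in report:
        t = report["cluster_model"]["lrt"]
        lines += ["", "## Cluster model",
                  f"- LRT: chi2({t['df']}) = {t['chisq']:.2f}, p = {t['p']:.4g}"]
        for grp, d in sorted(report["cluster_model"]["descriptives"].items()):
            lines.append(f"- {grp}: {d['mean']:.2f} +/- {d['sd']:.2f} C "
                         f"(n = {d['n']})")
    for name, ana in (report.get("analyses") or {}).items():
        lines += ["", f"## {name.capitalize()} model"]
        if ana.get("status") != "ok":
            lines.append(f"- {ana.get('status')}: {ana.get('reason', ana.get('error', ''))}")
            continue
        t = ana["lrt"]
        lines.append(f"- n = {ana['n']}; best terms: "
                     f"{', '.join(ana['best_terms']) or '(null)'}")
        lines.append(f"- LRT vs null: chi2({t['df']}) = {t['chisq']:.2f}, "
                     f"p = {t['p']:.4g}")
    return "\n".join(lines) + "\n"
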