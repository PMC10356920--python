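"""End-to-end study orchestration and estimator-recovery experiments.

``run_study`` executes the full pipeline for one claims database:
cohort extraction (models 1 and 2: minimum follow-up and exposure window of
12 and 24 months), composite-outcome identification, risk-set sampling of
1:10 matched sets, Q1/Q2 exposure classification, baseline covariates, and
conditional-logistic fits — crude and adjusted overall fits for each
(model, quartile) pattern plus per-statin multi-indicator fits.  All
randomness is seeded; identical configuration yields byte-identical output
files.

``recovery_experiment`` repeats simulate → analyze over R replicates with
derived seeds and aggregates how well the estimated exposure odds ratio
recovers the simulated hazard ratio: mean/SD of the estimate, 95% CI
coverage of the true value, and the Wald rejection rate at p < 0.05.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .claims import ClaimsDatabase, read_claims, write_claims
from .clogit import ClogitResult, SeparationError, fit_clogit
from .config import COVARIATE_ORDER, CodeConfig, load_code_config
from .cohort import MODELS, AttritionLog, ModelSpec, build_cohort
from .exposure import (
    SUBSTANCES,
    ExposureThresholds,
    classify_exposure_frame,
    count_statins_bulk,
    covariate_table,
    exposure_thresholds,
)
from .matching import MatchingParams, SamplingLog, sample_matched_sets, sets_to_frame
from .simulate import SimulationConfig, simulate


@dataclass
class StudyConfig:
    sim: SimulationConfig | None = None
    patients_csv: str | None = None
    events_csv: str | None = None
    models: tuple[str, ...] = ("model1", "model2")
    quartiles: tuple[str, ...] = ("q1", "q2")
    matching: MatchingParams = field(default_factory=MatchingParams)
    per_statin: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.models or not self.quartiles:
            raise ValueError("at least one model and one exposure definition required")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        for q in self.quartiles:
            if q not in ("q1", "q2"):
                raise ValueError(f"unknown quartile {q!r}")
        if self.sim is None and not (self.patients_csv and self.events_csv):
            raise ValueError("either an embedded simulation or input CSV paths required")


@dataclass
class ModelArtifacts:
    spec: ModelSpec
    cohort: pd.DataFrame
    attrition: AttritionLog
    sets_frame: pd.DataFrame
    sampling_log: SamplingLog
    thresholds: ExposureThresholds
    exposures: pd.DataFrame  # per set member, counts + flags
    covariates: pd.DataFrame  # per cohort patient in sets
    baseline: pd.DataFrame


@dataclass
class StudyReport:
    models: dict[str, ModelArtifacts]
    or_table: pd.DataFrame
    per_statin_table: pd.DataFrame

    def pattern(self, model: str, quartile: str, analysis: str) -> pd.DataFrame:
        t = self.or_table
        return t[
            (t["model"] == model) & (t["quartile"] == quartile) & (t["analysis"] == analysis)
        ]


def _members_with_features(
    db: ClaimsDatabase,
    cohort: pd.DataFrame,
    sets_frame: pd.DataFrame,
    spec: ModelSpec,
    code_config: CodeConfig,
) -> tuple[pd.DataFrame, ExposureThresholds, pd.DataFrame, pd.DataFrame]:
    members = sets_frame.merge(
        cohort[["patient_id", "sex", "age_at_entry", "entry_date", "observation_months"]],
        on="patient_id",
        how="left",
    )
    counts = count_statins_bulk(db, members, spec.exposure_window_months, code_config)
    user_counts = counts.loc[counts["total_count"] >= 1, "total_count"]
    thresholds = exposure_thresholds(user_counts.tolist(), spec.model_id)
    exposures = classify_exposure_frame(counts, thresholds)
    covs = covariate_table(db, members[["patient_id", "entry_date"]], code_config)
    members = members.merge(
        exposures.drop(columns=["index_date"]), on=["set_id", "patient_id"], how="left"
    )
    members = members.merge(covs, on="patient_id", how="left")
    members = members.sort_values(["set_id", "role", "patient_id"]).reset_index(drop=True)
    return members, thresholds, exposures, covs


def _design_sets(members: pd.DataFrame, columns: list[str]) -> list[np.ndarray]:
    """Per-set design matrices, case row first (members pre-sorted)."""
    X = members[columns].to_numpy(dtype=float)
    sizes = members.groupby("set_id", sort=True).size().to_numpy()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return [X[a:b] for a, b in zip(offsets[:-1], offsets[1:])]


def _result_rows(
    res: ClogitResult | None,
    model: str,
    quartile: str,
    analysis: str,
    term_names: list[str],
    error: str | None = None,
) -> list[dict]:
    rows = []
    if res is None:
        for name in term_names:
            rows.append(
                dict(
                    model=model,
                    quartile=quartile,
                    analysis=analysis,
                    term=name,
                    beta=np.nan,
                    se=np.nan,
                    or_point=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    p=np.nan,
                    converged=False,
                    note=error or "",
                )
            )
        return rows
    for t in res.terms:
        rows.append(
            dict(
                model=model,
                quartile=quartile,
                analysis=analysis,
                term=t.name,
                beta=t.beta,
                se=t.se,
                or_point=t.or_point,
                ci_low=t.ci_low,
                ci_high=t.ci_high,
                p=t.p,
                converged=res.converged and t.informative,
                note="" if t.informative else "no within-set variation",
            )
        )
    return rows


def _fit_or_flag(sets, names, model, quartile, analysis) -> list[dict]:
    try:
        res = fit_clogit(sets, names)
        return _result_rows(res, model, quartile, analysis, names)
    except SeparationError as exc:
        return _result_rows(None, model, quartile, analysis, names, error=str(exc))


def _baseline_table(members: pd.DataFrame, thresholds: ExposureThresholds) -> pd.DataFrame:
    """Case/control characteristics table in the published layout."""

    def col(role: str) -> pd.DataFrame:
        return members[members["role"] == role]

    rows: list[tuple[str, str, str]] = []

    def med_iqr(s: pd.Series) -> str:
        if not len(s):
            return "-"
        return f"{s.median():.0f}[{s.quantile(0.25):.0f}-{s.quantile(0.75):.0f}]"

    def n_pct(mask: pd.Series, denom: int) -> str:
        n = int(mask.sum())
        pct = 100.0 * n / denom if denom else 0.0
        return f"{n}({pct:.1f})"

    cases, controls = col("case"), col("control")
    rows.append(("n", str(len(cases)), str(len(controls))))
    rows.append(("age_median_iqr", med_iqr(cases["age_at_entry"]), med_iqr(controls["age_at_entry"])))
    rows.append(
        ("male_n_pct", n_pct(cases["sex"] == "M", len(cases)), n_pct(controls["sex"] == "M", len(controls)))
    )
    rows.append(
        (
            "observation_months_median_iqr",
            med_iqr(cases["observation_months"]),
            med_iqr(controls["observation_months"]),
        )
    )
    rows.append(
        (
            "statin_once_or_more_n_pct",
            n_pct(cases["total_count"] >= 1, len(cases)),
            n_pct(controls["total_count"] >= 1, len(controls)),
        )
    )
    rows.append(
        (
            "statin_count_median_iqr_users",
            med_iqr(cases.loc[cases["total_count"] >= 1, "total_count"]),
            med_iqr(controls.loc[controls["total_count"] >= 1, "total_count"]),
        )
    )
    for flag, label in (("exposed_q1", "q1_exposure_n_pct"), ("exposed_q2", "q2_exposure_n_pct")):
        rows.append((label, n_pct(cases[flag], len(cases)), n_pct(controls[flag], len(controls))))
    for name in COVARIATE_ORDER:
        rows.append((name, n_pct(cases[name], len(cases)), n_pct(controls[name], len(controls))))
    out = pd.DataFrame(rows, columns=["variable", "cases", "controls"])
    out.attrs["thresholds"] = (thresholds.q1, thresholds.q2)
    return out


def run_study(
    config: StudyConfig, code_config: CodeConfig | None = None
) -> StudyReport:
    cc = code_config if code_config is not None else load_code_config()
    if config.sim is not None:
        db, truth = simulate(config.sim, cc)
    else:
        db = read_claims(config.patients_csv, config.events_csv)
        truth = None

    models: dict[str, ModelArtifacts] = {}
    or_rows: list[dict] = []
    statin_rows: list[dict] = []
    for mi, model_id in enumerate(config.models):
        spec = MODELS[model_id]
        cohort, attrition = build_cohort(db, spec, cc)
        params = replace(config.matching, seed=config.matching.seed + 1000 * mi)
        sets, slog = sample_matched_sets(cohort, params)
        sets_frame = sets_to_frame(sets)
        if not len(sets_frame):
            raise RuntimeError(f"{model_id}: no matched sets could be formed")
        members, thresholds, exposures, covs = _members_with_features(
            db, cohort, sets_frame, spec, cc
        )
        baseline = _baseline_table(members, thresholds)
        models[model_id] = ModelArtifacts(
            spec, cohort, attrition, sets_frame, slog, thresholds, members, covs, baseline
        )

        for quartile in config.quartiles:
            flag = f"exposed_{quartile}"
            crude_sets = _design_sets(members, [flag])
            or_rows += _fit_or_flag(crude_sets, ["statin"], model_id, quartile, "crude")
            adj_cols = [flag, *COVARIATE_ORDER]
            adj_names = ["statin", *COVARIATE_ORDER]
            adj_sets = _design_sets(members, adj_cols)
            or_rows += _fit_or_flag(adj_sets, adj_names, model_id, quartile, "adjusted")

            if config.per_statin:
                sub_cols = [f"{s}_{quartile}" for s in SUBSTANCES]
                statin_rows += _fit_or_flag(
                    _design_sets(members, sub_cols),
                    list(SUBSTANCES),
                    model_id,
                    quartile,
                    "crude",
                )
                statin_rows += _fit_or_flag(
                    _design_sets(members, sub_cols + list(COVARIATE_ORDER)),
                    list(SUBSTANCES) + list(COVARIATE_ORDER),
                    model_id,
                    quartile,
                    "adjusted",
                )

    report = StudyReport(
        models=models,
        or_table=pd.DataFrame(or_rows),
        per_statin_table=pd.DataFrame(statin_rows),
    )
    if config.out_dir:
        _write_outputs(config, report, db)
    return report


# ---------------------------------------------------------------------------
# persistence


def _fmt_or_row(r: pd.Series) -> str:
    if not np.isfinite(r["or_point"]):
        return "-"
    return f"{r['or_point']:.2f}({r['ci_low']:.2f}-{r['ci_high']:.2f})"


def _write_outputs(config: StudyConfig, report: StudyReport, db: ClaimsDatabase) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_claims(db, out / "patients.csv", out / "events.csv")
    attrition = {}
    for model_id, art in report.models.items():
        mdir = out / model_id
        mdir.mkdir(exist_ok=True)
        coh = art.cohort.copy()
        for c in ("entry_date", "last_dyslipidemia_date", "index_date", "observation_end"):
            coh[c] = coh[c].dt.strftime("%Y-%m-%d")
        coh.to_csv(mdir / "cohort.csv", index=False)
        sf = art.sets_frame.copy()
        sf["index_date"] = sf["index_date"].dt.strftime("%Y-%m-%d")
        sf.to_csv(mdir / "matched_sets.csv", index=False)
        exp = art.exposures.copy()
        exp["index_date"] = exp["index_date"].dt.strftime("%Y-%m-%d")
        exp["entry_date"] = exp["entry_date"].dt.strftime("%Y-%m-%d")
        exp.to_csv(mdir / "exposures.csv", index=False)
        art.covariates.to_csv(mdir / "covariates.csv", index=False)
        art.baseline.to_csv(mdir / "baseline.csv", index=False)
        attrition[model_id] = art.attrition.as_dict()
        with open(mdir / "sampling_log.json", "w") as fh:
            json.dump(art.sampling_log.as_dict(), fh, indent=1, sort_keys=True)
        with open(mdir / "thresholds.json", "w") as fh:
            json.dump(dataclasses.asdict(art.thresholds), fh, indent=1, sort_keys=True)
    with open(out / "attrition.json", "w") as fh:
        json.dump(attrition, fh, indent=1, sort_keys=True)
    report.or_table.to_csv(out / "results.csv", index=False)
    if len(report.per_statin_table):
        report.per_statin_table.to_csv(out / "results_per_statin.csv", index=False)
    _write_report_md(out / "report.md", report)


def _write_report_md(path: Path, report: StudyReport) -> None:
    lines = ["# Nested case-control study report", ""]
    for model_id, art in report.models.items():
        lines.append(f"## {model_id}")
        lines.append("")
        lines.append("### Attrition")
        lines.append("")
        lines.append(f"- patients in database: {art.attrition.n_input}")
        for s in art.attrition.steps:
            lines.append(f"- {s.label}: excluded {s.n_excluded}, remaining {s.n_remaining}")
        lines.append("")
        lines.append(
            f"Matched sets: {art.sampling_log.n_sets} "
            f"(cases without eligible controls: {len(art.sampling_log.dropped_cases)})"
        )
        lines.append(
            f"Exposure thresholds: Q1={art.thresholds.q1}, Q2={art.thresholds.q2} "
            f"(from {art.thresholds.n_contributing} statin users)"
        )
        lines.append("")
        lines.append("### Baseline characteristics")
        lines.append("")
        lines.append(art.baseline.to_markdown(index=False))
        lines.append("")
    lines.append("## Odds ratios for open-angle glaucoma (statin exposure)")
    lines.append("")
    t = report.or_table
    stat = t[t["term"] == "statin"]
    for _, r in stat.iterrows():
        p = f", p={r['p']:.3f}" if np.isfinite(r["p"]) else ""
        lines.append(
            f"- {r['model']} {r['quartile'].upper()} {r['analysis']}: {_fmt_or_row(r)}{p}"
        )
    lines.append("")
    if len(report.per_statin_table):
        lines.append("## Per-statin odds ratios")
        lines.append("")
        ps = report.per_statin_table
        for _, r in ps[ps["term"].isin(SUBSTANCES)].iterrows():
            lines.append(
                f"- {r['model']} {r['quartile'].upper()} {r['analysis']} "
                f"{r['term']}: {_fmt_or_row(r)}"
            )
        lines.append("")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# estimator recovery


@dataclass
class RecoveryMetrics:
    replicates: int
    n_converged: int
    true_or: float
    mean_or: float
    sd_or: float
    coverage: float
    rejection_rate: float
    failures: list[str]

    def as_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "n_converged": self.n_converged,
            "true_or": self.true_or,
            "mean_or": self.mean_or,
            "sd_or": self.sd_or,
            "coverage": self.coverage,
            "rejection_rate": self.rejection_rate,
            "failures": self.failures,
        }


def fit_single_pattern(
    db: ClaimsDatabase,
    model_id: str,
    quartile: str,
    match_seed: int,
    code_config: CodeConfig,
    adjusted: bool = True,
):
    """One (model, quartile) exposure fit on a database; returns the statin
    TermResult of the (adjusted by default) conditional-logistic model."""
    spec = MODELS[model_id]
    cohort, _ = build_cohort(db, spec, code_config)
    sets, _ = sample_matched_sets(cohort, MatchingParams(seed=match_seed))
    sets_frame = sets_to_frame(sets)
    if not len(sets_frame):
        raise RuntimeError("no matched sets")
    members, thresholds, _, _ = _members_with_features(
        db, cohort, sets_frame, spec, code_config
    )
    flag = f"exposed_{quartile}"
    if adjusted:
        cols, names = [flag, *COVARIATE_ORDER], ["statin", *COVARIATE_ORDER]
    else:
        cols, names = [flag], ["statin"]
    res = fit_clogit(_design_sets(members, cols), names)
    if not res.converged:
        raise RuntimeError("fit did not converge")
    return res.term("statin")


def recovery_experiment(
    sim_config: SimulationConfig,
    replicates: int,
    model_id: str = "model1",
    quartile: str = "q1",
    base_seed: int = 0,
    adjusted: bool = True,
    code_config: CodeConfig | None = None,
) -> RecoveryMetrics:
    """R independent simulate→analyze cycles; aggregates exposure-OR recovery.

    Replicate r uses simulation seed ``base_seed + r`` (and the same value
    for control sampling).  Non-converged or degenerate replicates are
    recorded in ``failures`` and excluded from the aggregates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cc = code_config if code_config is not None else load_code_config()
    true_or = float(np.exp(sim_config.log_or.get("statin", 0.0)))
    ors: list[float] = []
    covered: list[bool] = []
    rejected: list[bool] = []
    failures: list[str] = []
    for r in range(replicates):
        cfg = replace(sim_config, seed=base_seed + r)
        db, _ = simulate(cfg, cc)
        try:
            term = fit_single_pattern(
                db, model_id, quartile, match_seed=base_seed + r, code_config=cc,
                adjusted=adjusted,
            )
        except (SeparationError, RuntimeError, ValueError) as exc:
            failures.append(f"replicate {r}: {exc}")
            continue
        if not term.informative or not np.isfinite(term.se):
            failures.append(f"replicate {r}: exposure term uninformative")
            continue
        ors.append(term.or_point)
        covered.append(term.ci_low <= true_or <= term.ci_high)
        rejected.append(term.p < 0.05)
    n_ok = len(ors)
    return RecoveryMetrics(
        replicates=replicates,
        n_converged=n_ok,
        true_or=true_or,
        mean_or=float(np.mean(ors)) if n_ok else np.nan,
        sd_or=float(np.std(ors, ddof=1)) if n_ok > 1 else np.nan,
        coverage=float(np.mean(covered)) if n_ok else np.nan,
        rejection_rate=float(np.mean(rejected)) if n_ok else np.nan,
        failures=failures,
    )
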