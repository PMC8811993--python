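"""End-to-end cohort analysis: response classification, report tables,
ROC comparisons and the stepwise multivariate model.

A run takes a cohort table (synthetic, quantified from images, or loaded
from CSV), classifies each eye as responsive (< 5 anti-VEGF injections in
year one) or refractory (>= 5, or persistent edema after three monthly
injections), and writes group-comparison and ROC report tables plus a JSON
provenance record under a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats, synthetic
from .score import QuantifyConfig, average_graders, quantify_eye
from .types import SelectionTrace

__all__ = [
    "RunConfig",
    "classify_response",
    "snellen_to_logmar",
    "run_pipeline",
    "make_report",
    "quantify_cohort_images",
    "cohort_schema",
]

log = logging.getLogger("faleak")

try:
    _VERSION = version("faleak")
except PackageNotFoundError:  # pragma: no cover - not installed
    _VERSION = "unknown"

_CONTINUOUS_VARS = [
    ("age", "Age (years)"),
    ("followup_months", "Follow-up duration (months)"),
    ("injections_year1", "Number of anti-VEGF injections in first year"),
    ("baseline_logmar", "Baseline logMAR BCVA"),
    ("logmar_1yr", "LogMAR BCVA at 1 year"),
    ("crt_pre", "Pre-treatment CRT (um)"),
    ("crt_best_post", "Post-treatment best CRT (um)"),
    ("crt_1yr", "CRT at 1 year (um)"),
    ("parafoveal_mgv", "Mean gray value over parafoveal region"),
    ("perifoveal_mgv", "Mean gray value over perifoveal region"),
]

_CATEGORICAL_VARS = [
    ("laterality", "Eye (OD : OS)", "OD"),
    ("sex", "Sex (male : female)", "M"),
    ("brvo_type", "Type of BRVO (major : macular)", "major"),
    ("edema_cystoid", "Cystoid macular edema (yes : no)", True),
    ("edema_diffuse", "Diffuse retinal thickening (yes : no)", True),
    ("edema_serous", "Serous retinal detachment (yes : no)", True),
]

_PREDICTORS = ["crt_pre", "crt_best_post", "parafoveal_mgv", "perifoveal_mgv"]
_BASELINE_CANDIDATES = ["crt_pre", "parafoveal_mgv", "perifoveal_mgv"]
_REFERENCE = "crt_pre"


def classify_response(injections_year1: int, persistent_after_3_monthly: bool) -> str:
    """Response grouping rule for a treated eye.

    Refractory iff the eye needed >= 5 anti-VEGF injections in the first
    year OR had persistent macular edema after three monthly injections;
    responsive otherwise.  Requires a treated eye (>= 1 injection).
    """
    inj = int(injections_year1)
    if inj < 1:
        raise ValueError("classification applies to treated eyes (>= 1 injection)")
    if inj >= 5 or bool(persistent_after_3_monthly):
        return "refractory"
    return "responsive"


def snellen_to_logmar(snellen_fraction: float) -> float:
    """Convert a Snellen fraction (e.g. 20/40 -> 0.5) to logMAR, -log10(f)."""
    f = float(snellen_fraction)
    if f <= 0:
        raise ValueError("Snellen fraction must be positive")
    return float(-np.log10(f))


def cohort_schema(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the documented column schema."""
    missing = [c for c in synthetic.COHORT_COLUMNS if c not in df.columns
               and not c.endswith(("_true", "_grader1", "_grader2"))]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")
    if (df["crt_pre"] <= 0).any():
        raise ValueError("CRT values must be positive")
    for col in ("baseline_logmar", "logmar_1yr"):
        if not np.isfinite(df[col]).all():
            raise ValueError(f"{col} contains non-finite values")
    return df


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def make_report(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the group-comparison and ROC report tables.

    The first table summarises every demographic/clinical variable per
    group with the matched test (pooled t for continuous, uncorrected
    Pearson chi-square for categorical).  The second reports each
    quantitative predictor's AUC for refractory-vs-responsive with its
    DeLong 95% CI and the paired DeLong p against the pre-treatment CRT
    reference.
    """
    df = cohort_schema(cohort)
    resp = df[df["group"] == "responsive"]
    refr = df[df["group"] == "refractory"]
    if len(resp) < 2 or len(refr) < 2:
        raise ValueError("each group needs >= 2 eyes for the report")

    rows = []
    for col, label, positive in _CATEGORICAL_VARS:
        a = int((resp[col] == positive).sum())
        b = int((refr[col] == positive).sum())
        table = [[a, len(resp) - a], [b, len(refr) - b]]
        try:
            _, p = stats.chi_square_2x2(table)
            p_txt = _fmt_p(p)
        except ValueError:  # a level absent from both groups (tiny cohorts)
            p_txt = "n/a"
        rows.append({
            "variable": label,
            "responsive": f"{a} : {len(resp) - a}",
            "refractory": f"{b} : {len(refr) - b}",
            "test": "chi-square",
            "p_value": p_txt,
        })
    for col, label in _CONTINUOUS_VARS:
        _, p = stats.two_sample_t(resp[col], refr[col])
        rows.append({
            "variable": label,
            "responsive": _mean_sd(resp[col]),
            "refractory": _mean_sd(refr[col]),
            "test": "t-test",
            "p_value": _fmt_p(p),
        })
    table1 = pd.DataFrame(rows)

    labels = (df["group"] == "refractory").astype(int).to_numpy()
    comps = stats.roc_comparison(df[_PREDICTORS], labels, reference=_REFERENCE)
    table2 = pd.DataFrame([
        {
            "predictor": c.predictor_name,
            "auc": f"{c.auc:.3f}",
            "ci95_low": f"{c.ci95[0]:.3f}",
            "ci95_high": f"{c.ci95[1]:.3f}",
            "delong_p_vs_crt_pre": ("reference" if c.delong_p_vs_reference is None
                                    else _fmt_p(c.delong_p_vs_reference)),
        }
        for c in comps
    ])
    return table1, table2


def _stepwise(df: pd.DataFrame, p_stay: float) -> SelectionTrace:
    """Screen baseline predictors at p < 0.05, then backward-eliminate."""
    resp = df[df["group"] == "responsive"]
    refr = df[df["group"] == "refractory"]
    candidates = [c for c in _BASELINE_CANDIDATES
                  if stats.two_sample_t(resp[c], refr[c])[1] < 0.05]
    y = (df["group"] == "refractory").astype(int).to_numpy()
    if not candidates:
        return SelectionTrace(p_stay=p_stay)
    return stats.backward_stepwise_logistic(df[candidates], y, p_stay=p_stay)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    ``source`` selects where the cohort comes from: "cohort" draws the
    statistical cohort directly, "images" renders per-eye FA pairs and
    quantifies them (two simulated graders re-run the pipeline with an
    independently jittered fovea pick, mimicking the manual step), and
    "csv" loads an existing cohort table from ``input_csv``.
    """

    source: str = "cohort"
    out_dir: str | Path = "faleak-run"
    seed: int = 0
    n_responsive: int = 47
    n_refractory: int = 42
    p_stay: float = 0.05
    input_csv: str | Path | None = None
    image_size: int = 512
    fovea_jitter_sd_px: float = 2.0
    quantify: QuantifyConfig = field(
        default_factory=lambda: QuantifyConfig(align=False)
    )
    debug_images: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("cohort", "images", "csv"):
            raise ValueError("source must be 'cohort', 'images' or 'csv'")
        if self.source == "csv" and self.input_csv is None:
            raise ValueError("source='csv' requires input_csv")
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must lie in (0, 1)")
        if self.n_responsive < 2 or self.n_refractory < 2:
            raise ValueError("group sizes must be >= 2")


def quantify_cohort_images(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Render and quantify per-eye synthetic FA pairs for a whole cohort.

    Responsive eyes get mild macular leakage scenes, refractory eyes severe
    ones; each eye is scored by two simulated graders whose only
    disagreement is an independent jitter of the fovea pick.  Returns the
    cohort table (quantified scores replacing the drawn ones) and the
    number of eyes skipped because quantification failed.
    """
    rng = np.random.default_rng(config.seed)
    base = synthetic.generate_cohort(synthetic.CohortParams(
        n_responsive=config.n_responsive, n_refractory=config.n_refractory,
        seed=config.seed,
    ))
    rows, failures = [], 0
    for _, rec in base.iterrows():
        scen_fn = (synthetic.responsive_scenario if rec["group"] == "responsive"
                   else synthetic.refractory_scenario)
        eye_seed = int(rng.integers(0, 2**31 - 1))
        params = scen_fn(seed=eye_seed, image_size=config.image_size)
        pair, _ = synthetic.generate_fa_pair(params)
        pair.eye_id = rec["eye_id"]
        try:
            results = []
            for gid in ("grader1", "grader2"):
                jitter = np.round(rng.normal(0, config.fovea_jitter_sd_px, 2))
                jpair = dataclasses.replace(
                    pair,
                    fovea=(int(pair.fovea[0] + jitter[0]),
                           int(pair.fovea[1] + jitter[1])),
                )
                cfg = dataclasses.replace(config.quantify, grader_id=gid)
                results.append(quantify_eye(jpair, config=cfg))
            avg = average_graders(*results)
        except Exception as exc:  # noqa: BLE001 - per-eye QC failure
            log.warning("skipping %s: %s", rec["eye_id"], exc)
            failures += 1
            continue
        rec = rec.copy()
        for region, r1, r2, a in (
            ("parafoveal", results[0].parafoveal_mgv,
             results[1].parafoveal_mgv, avg.parafoveal_mgv),
            ("perifoveal", results[0].perifoveal_mgv,
             results[1].perifoveal_mgv, avg.perifoveal_mgv),
        ):
            rec[f"{region}_mgv_grader1"] = r1
            rec[f"{region}_mgv_grader2"] = r2
            rec[f"{region}_mgv"] = a
        rows.append(rec)
    if not rows:
        raise ValueError("no eyes were successfully quantified")
    return pd.DataFrame(rows).reset_index(drop=True), failures


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and write all artefacts under the run directory.

    Outputs: ``cohort.csv``, ``table1.csv`` (group comparison),
    ``table2.csv`` (ROC/DeLong), ``stepwise.json`` (selection trace),
    ``run_summary.json`` and ``provenance.json``.  The run fails if more
    than 20% of eyes fail quantification.  Deterministic given config +
    seed (report numbers use fixed decimal formatting).
    """
    out = Path(config.out_dir)
    failures = 0
    if config.source == "cohort":
        cohort = synthetic.generate_cohort(synthetic.CohortParams(
            n_responsive=config.n_responsive, n_refractory=config.n_refractory,
            seed=config.seed,
        ))
    elif config.source == "images":
        cohort, failures = quantify_cohort_images(config)
        if failures > 0.2 * (config.n_responsive + config.n_refractory):
            raise RuntimeError(f"{failures} eyes failed quantification (> 20%)")
    else:
        src = Path(config.input_csv)
        if not src.exists():
            raise FileNotFoundError(f"input cohort CSV not found: {src}")
        cohort = pd.read_csv(src)
        if len(cohort) == 0:
            raise ValueError("input cohort CSV is empty")

    # classification from the raw treatment course; must match any stored label
    cohort = cohort.copy()
    cohort["group"] = [
        classify_response(i, p)
        for i, p in zip(cohort["injections_year1"],
                        cohort["persistent_after_3_monthly"])
    ]
    cohort_schema(cohort)

    table1, table2 = make_report(cohort)
    trace = _stepwise(cohort, config.p_stay)

    out.mkdir(parents=True, exist_ok=True)
    num_cols = {c: 1 for c in ("parafoveal_mgv", "perifoveal_mgv",
                               "parafoveal_mgv_true", "perifoveal_mgv_true",
                               "parafoveal_mgv_grader1", "parafoveal_mgv_grader2",
                               "perifoveal_mgv_grader1", "perifoveal_mgv_grader2")}
    serial = cohort.copy()
    for c, nd in num_cols.items():
        if c in serial.columns:
            serial[c] = serial[c].round(nd)
    for c in serial.select_dtypes(include="float").columns:
        serial[c] = serial[c].round(3)
    serial.to_csv(out / "cohort.csv", index=False)
    table1.to_csv(out / "table1.csv", index=False)
    table2.to_csv(out / "table2.csv", index=False)

    (out / "stepwise.json").write_text(json.dumps({
        "p_stay": trace.p_stay,
        "removed": [
            {"step": s, "variable": v, "p_at_removal": round(p, 3)}
            for s, v, p in trace.removed
        ],
        "final": {
            k: {"coef": round(d["coef"], 4),
                "odds_ratio": round(d["odds_ratio"], 4),
                "or_ci95": [round(d["or_ci95"][0], 4), round(d["or_ci95"][1], 4)],
                "p": round(d["p"], 4)}
            for k, d in trace.final.items()
        },
        "separation_flag": trace.separation_flag,
    }, indent=2))

    n_resp = int((cohort["group"] == "responsive").sum())
    n_total = len(cohort)
    (out / "run_summary.json").write_text(json.dumps({
        "n_eyes": n_total,
        "n_responsive": n_resp,
        "n_refractory": n_total - n_resp,
        "responsive_percent": round(100.0 * n_resp / n_total),
        "eyes_failed": failures,
    }, indent=2))

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["out_dir"] = str(cfg_dict["out_dir"])
    if cfg_dict.get("input_csv") is not None:
        cfg_dict["input_csv"] = str(cfg_dict["input_csv"])
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    (out / "provenance.json").write_text(json.dumps({
        "software": "faleak",
        "version": _VERSION,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }, indent=2))
    return out
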