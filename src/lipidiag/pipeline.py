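"""End-to-end orchestration: simulate -> cohort -> normalize -> stats ->
mvstats -> evaluate -> report, driven by one YAML/dict configuration.

Every stage writes plain CSV/JSON artifacts into the output directory and
the run manifest records the configuration snapshot, seeds, per-stage
status and SHA-256 digests of every artifact, so a completed run can be
re-executed and verified bit-for-bit.  The rendered report only formats
stage artifacts; it never computes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostic, multivariate as mv, normalization, univariate
from .cohort import CohortTable, PeakTable, cohort_summary, group_difference_test, load_cohort
from .diagnostic import FeatureSet, compare_feature_sets
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "normalize", "stats", "mvstats", "evaluate", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "cohort": {"hb_threshold": 20.0},
    "normalize": {"rsd_ceiling": 30.0},
    "stats": {"comparisons": [["AA", "CTRL"], ["CRC", "CTRL"], ["CRC", "AA"]]},
    "mvstats": {
        "n_components": 2,
        "covariates": ["fit_stand"],
        "contrasts": [["CRC", "CTRL"], ["CRC", "AA"], ["AA", "CTRL"]],
        "outlier_alpha": 0.05,
    },
    "evaluate": {
        "comparisons": [["CRC", "CTRL"], ["CRC", "AA"], ["AA", "CTRL"], [["AA", "CRC"], "CTRL"]],
        "feature_sets": ["fit", "fit+ces", "fit+2ces"],
        "n_split_seeds": 10,
        "n_trees": 500,
    },
}


class ConfigError(ValueError):
    pass


def load_config(source) -> dict:
    """Merge a YAML file / dict over the defaults, validating sections."""
    if source is None:
        user: dict = {}
    elif isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    else:
        user = dict(source)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(cfg.get(k), dict):
            if not isinstance(v, dict):
                raise ConfigError(f"config section {k!r} must be a mapping")
            cfg[k].update(v)
        else:
            cfg[k] = v
    for section in ("stats", "mvstats", "evaluate"):
        if section not in cfg or cfg[section] is None:
            raise ConfigError(f"missing stage section: {section!r}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    out_dir: str
    stages: dict = field(default_factory=dict)   # stage -> {status, artifacts}
    digests: dict = field(default_factory=dict)  # relative path -> sha256

    def record(self, stage: str, status: str, artifacts: list[Path], out_dir: Path) -> None:
        rel = [str(p.relative_to(out_dir)) for p in artifacts]
        self.stages[stage] = {"status": status, "artifacts": rel}
        for p, r in zip(artifacts, rel):
            if p.exists():
                self.digests[r] = _sha256(p)

    def save(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        payload = {
            "config": self.config,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": self.stages,
            "digests": self.digests,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path


def run_pipeline(config=None, out_dir: str | Path = "results", seed: int | None = None) -> RunManifest:
    """Execute all stages in order; on a stage failure, later stages are
    skipped and the manifest marks the failure."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, int(cfg["seed"]), str(out))
    state: dict = {}
    failed = False
    for stage in STAGES:
        if failed:
            manifest.record(stage, "skipped", [], out)
            continue
        try:
            artifacts = _STAGE_FUNCS[stage](cfg, out, state)
            manifest.record(stage, "completed", artifacts, out)
        except Exception as exc:  # noqa: BLE001 - fail the stage, keep the manifest
            log.error("stage %s failed: %s", stage, exc)
            manifest.record(stage, f"failed: {exc}", [], out)
            failed = True
    manifest.save(out)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out: Path, state: dict) -> list[Path]:
    sim_cfg = SimulationConfig.from_dict({**cfg.get("simulate", {}), "seed": cfg["seed"]})
    cohort, peaks, truth = simulate_study(sim_cfg)
    state.update(cohort=cohort, peaks=peaks, truth=truth)
    paths = [out / n for n in ("cohort.csv", "peaks.csv", "runs.csv", "features.csv", "truth.json")]
    cohort.to_csv(paths[0])
    peaks.to_csvs(paths[1], paths[2], paths[3])
    truth.to_json(paths[4])
    return paths


def _stage_cohort(cfg: dict, out: Path, state: dict) -> list[Path]:
    cohort: CohortTable = state["cohort"]
    summary = cohort_summary(cohort)
    path = out / "cohort_summary.csv"
    summary.to_csv(path)
    tests = []
    df = cohort.data
    for var, vals in (
        ("age", df["age"]),
        ("fecal_hb", df["fecal_hb"]),
        ("gender", (df["gender"] == "F").astype(float)),
        ("fit_categorical", df["fit_positive"].astype(float)),
    ):
        r = group_difference_test(vals, df["group"], variable=var)
        row = {"variable": var, "anova_p": r.anova_p, "levene_p": r.levene_p,
               "levene_center": "median"}
        for a, b, p in r.pairwise:
            row[f"games_howell_{a}_vs_{b}"] = p
        tests.append(row)
    tpath = out / "cohort_tests.csv"
    pd.DataFrame(tests).to_csv(tpath, index=False)
    return [path, tpath]


def _stage_normalize(cfg: dict, out: Path, state: dict) -> list[Path]:
    peaks: PeakTable = state["peaks"]
    normalized, model = normalization.normalize(peaks)
    state["normalized"] = normalized
    state["norm_model"] = model
    report = normalization.qc_report(model, cfg["normalize"].get("rsd_ceiling", 30.0))
    paths = [out / "normalized.csv", out / "normalized_runs.csv",
             out / "normalized_features.csv", out / "norm_model.json", out / "qc_report.csv"]
    normalized.to_csvs(paths[0], paths[1], paths[2])
    model.to_json(paths[3])
    report.to_csv(paths[4])
    return paths


def _stage_stats(cfg: dict, out: Path, state: dict) -> list[Path]:
    comparisons = [tuple(c) for c in cfg["stats"]["comparisons"]]
    results, heatmap = univariate.comparison_table(state["normalized"], state["cohort"], comparisons)
    state["stats"] = results
    p1, p2 = out / "stats.csv", out / "heatmap_log2fc.csv"
    results.to_csv(p1, index=False)
    heatmap.to_csv(p2)
    return [p1, p2]


def _stage_mvstats(cfg: dict, out: Path, state: dict) -> list[Path]:
    mcfg = cfg["mvstats"]
    cohort: CohortTable = state["cohort"]
    normalized: PeakTable = state["normalized"]
    spec = mv.PreprocessSpec(include_covariates=tuple(mcfg.get("covariates", ())))
    X, _ = mv.preprocess(normalized.study_abundance(), cohort, spec)
    groups = cohort.group_of(X.index)

    pca = mv.fit_pca(X, n_components=max(2, int(mcfg.get("n_components", 2))))
    outliers = mv.detect_outliers(pca, mcfg.get("outlier_alpha", 0.05))
    kept = X.index.difference(outliers, sort=False)
    Xk, gk = X.loc[kept], groups.loc[kept]

    summary: dict = {"outliers_removed": list(map(str, outliers)), "pca": pca.summary(), "oplsda": {}}
    plsda = mv.fit_plsda(Xk, gk, n_components=int(mcfg.get("n_components", 2)),
                         cv_seed=cfg["seed"])
    summary["plsda"] = plsda.summary()
    paths = [out / "mv_summary.json", out / "plsda_scores.csv", out / "plsda_classification.csv"]
    plsda.scores.to_csv(paths[1])
    clist = mv.classification_list(plsda, gk)
    clist.table.to_csv(paths[2], index=False)

    for contrast in mcfg.get("contrasts", []):
        pos, neg = contrast
        pair = gk.isin([pos, neg])
        model = mv.fit_oplsda(Xk.loc[pair.index[pair]], gk[pair],
                              n_components=int(mcfg.get("n_components", 2)),
                              cv_seed=cfg["seed"], positive_class=pos)
        name = f"{pos}_vs_{neg}"
        info = model.summary()
        info["valid"] = bool(model.cv_anova_p < 0.05 and model.q2 > 0)
        if not info["valid"]:
            info["note"] = "no valid model (CV-ANOVA p >= 0.05 or Q2 <= 0)"
        summary["oplsda"][name] = info
        sel = mv.select_variables(model.vip, model.p_corr)
        volcano = pd.DataFrame({"p_corr": model.p_corr, "vip": model.vip})
        volcano["selected"] = volcano.index.isin(sel.index)
        vp = out / f"oplsda_{name}_volcano.csv"
        volcano.rename_axis("feature_id").to_csv(vp)
        paths.append(vp)
        cl = mv.classification_list(model, gk[pair])
        pct = mv.classification_percentage_table(cl, gk[pair])
        cp = out / f"oplsda_{name}_classification.csv"
        pct.to_csv(cp)
        paths.append(cp)
    Path(paths[0]).write_text(json.dumps(summary, indent=2, default=str))
    state["mv_summary"] = summary
    return paths


def _stage_evaluate(cfg: dict, out: Path, state: dict) -> list[Path]:
    ecfg = cfg["evaluate"]
    cohort: CohortTable = state["cohort"]
    normalized: PeakTable = state["normalized"]
    study = normalized.study_abundance()
    # classifier inputs: log2 abundances of panel lipids + raw fecal Hb
    panel = [c for c in study.columns if c in set(diagnostic.CE_PANEL)]
    with np.errstate(divide="ignore"):
        data = np.log2(study[panel].where(study[panel] > 0))
    data[diagnostic.FIT_COLUMN] = cohort.data.loc[data.index, "fecal_hb"]
    data = diagnostic.impute_missing(data, seed=cfg["seed"])
    comparisons = [
        (tuple(p) if isinstance(p, list) else p, tuple(n) if isinstance(n, list) else n)
        for p, n in (tuple(c) for c in ecfg["comparisons"])
    ]
    fsets = [FeatureSet.named(n) for n in ecfg.get("feature_sets", ["fit", "fit+ces"])]
    seeds = [cfg["seed"] + i for i in range(int(ecfg.get("n_split_seeds", 10)))]
    rf = diagnostic.RandomForestConfig(n_trees=int(ecfg.get("n_trees", 500)))
    metrics, deltas = compare_feature_sets(
        data, cohort.data["group"], comparisons, fsets, seeds, rf
    )
    p1, p2 = out / "diagnostic_metrics.csv", out / "diagnostic_deltas.csv"
    metrics.to_csv(p1, index=False)
    deltas.to_csv(p2, index=False)
    state["metrics"] = metrics
    return [p1, p2]


def _stage_report(cfg: dict, out: Path, state: dict) -> list[Path]:
    return [render_report(out)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cohort": _stage_cohort,
    "normalize": _stage_normalize,
    "stats": _stage_stats,
    "mvstats": _stage_mvstats,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# report rendering (formatting only -- no computation)
# ---------------------------------------------------------------------------


def _table_text(df: pd.DataFrame, index: bool = True) -> str:
    try:  # markdown tables when the optional tabulate backend is present
        return df.to_markdown(index=index)
    except ImportError:
        return "```\n" + df.to_string(index=index) + "\n```"


def _fmt_csv(path: Path, max_rows: int | None = None, index_col=0) -> str:
    df = pd.read_csv(path, index_col=index_col)
    if max_rows is not None and len(df) > max_rows:
        df = df.head(max_rows)
    return _table_text(df.round(4))


def render_report(out_dir: str | Path) -> Path:
    """Assemble ``report.md`` from whatever stage artifacts exist.

    Missing artifacts mark their section unavailable; regeneration is
    idempotent because the report is a pure formatting of the files.
    """
    out = Path(out_dir)
    lines = ["# Fecal lipidomics diagnostic pipeline report", ""]

    def section(title: str, fname: str, **kw):
        lines.append(f"## {title}")
        path = out / fname
        if path.exists():
            try:
                lines.append(_fmt_csv(path, **kw))
            except Exception as exc:  # noqa: BLE001
                lines.append(f"_section unavailable ({exc})_")
        else:
            lines.append("_section unavailable_")
        lines.append("")

    section("Cohort description", "cohort_summary.csv")
    section("Cohort covariate tests", "cohort_tests.csv", index_col=None)
    section("QC reproducibility (first 20 features)", "qc_report.csv", max_rows=20)
    sig = out / "stats.csv"
    lines.append("## Univariate statistics (significant features)")
    if sig.exists():
        df = pd.read_csv(sig)
        if "significant" in df:
            df = df[df["significant"]].sort_values(["comparison", "q_value"])
        lines.append(_table_text(df.round(4), index=False))
    else:
        lines.append("_section unavailable_")
    lines.append("")
    lines.append("## Latent-variable models")
    mvp = out / "mv_summary.json"
    if mvp.exists():
        lines.append("```json")
        lines.append(mvp.read_text().strip())
        lines.append("```")
    else:
        lines.append("_section unavailable_")
    lines.append("")
    for p in sorted(out.glob("oplsda_*_volcano.csv")):
        name = p.stem.replace("_volcano", "")
        lines.append(f"## Selected variables: {name}")
        df = pd.read_csv(p, index_col=0)
        lines.append(_table_text(df[df["selected"]].sort_values("vip", ascending=False).round(4)))
        lines.append("")
    for p in sorted(out.glob("oplsda_*_classification.csv")):
        lines.append(f"## Classification list summary: {p.stem.replace('_classification', '')}")
        lines.append(_table_text(pd.read_csv(p, index_col=0).round(2)))
        lines.append("")
    section("Random-forest diagnostic metrics", "diagnostic_metrics.csv", index_col=None)
    section("AUC deltas versus FIT alone", "diagnostic_deltas.csv", index_col=None)

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
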