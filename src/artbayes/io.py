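"""File formats, configuration, logging and the end-to-end pipeline.

All interchange is tidy CSV: a design file (one row per trial per version),
a gameplay file (one row per trial per subject), posterior summary and
draws tables, scores and associations.  Trial and opportunity indices are
1-based in every file.  A pipeline run serialises its fully-resolved config
next to the outputs and emits a manifest with a config hash and seed so
reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from artbayes import __version__
from artbayes.inference import FitResult, HierarchicalModelSpec, fit_hierarchical, point_estimates
from artbayes.model import COLLECTED, FORCED_FAIL, SubjectPlay, TrialOutcome
from artbayes.simulate import CovariateSpec, GroupSpec, simulate_cohort, simulate_covariates, substream
from artbayes.stats import adjusted_score, associate, bf_interpretation, bf_ttest, cohort_table, permutation_test
from artbayes.task import ProbabilitySchedule, TaskDesign, build_schedule, generate_max_casts, make_versions

__all__ = [
    "GAMEPLAY_COLUMNS",
    "read_gameplay",
    "write_gameplay",
    "read_designs",
    "write_designs",
    "load_config",
    "run_pipeline",
    "setup_logging",
]

log = logging.getLogger("artbayes")

GAMEPLAY_COLUMNS = [
    "subject_id", "group", "version", "trial", "p_yellow",
    "max_casts", "n_casts", "outcome", "points_banked",
]
DESIGN_COLUMNS = ["version", "trial", "p_yellow", "max_casts"]

_CONFIG_KEYS = {
    "seed", "out_dir", "log_level", "stages", "design", "simulate",
    "fit", "score", "associate", "gameplay", "covariates_file",
}
_STAGES = ("simulate", "fit", "score", "associate", "report")


class GameplayFormatError(ValueError):
    """Raised for structurally invalid gameplay files, with line numbers."""


def setup_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Configure stderr logging; JSON-lines format for pipeline embedding."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _Json(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps(
                    {"ts": self.formatTime(record), "level": record.levelname,
                     "name": record.name, "msg": record.getMessage()}
                )
        handler.setFormatter(_Json())
    else:
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("artbayes")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper()))


def write_gameplay(plays: list[SubjectPlay], path) -> None:
    rows = []
    for p in plays:
        for k, t in enumerate(p.trials, start=1):
            if t.max_casts is None:
                raise ValueError(
                    f"subject {p.subject_id} trial {k}: max_casts required for file output"
                )
            rows.append(
                {
                    "subject_id": p.subject_id, "group": p.group,
                    "version": p.version_label, "trial": k,
                    "p_yellow": t.p_yellow, "max_casts": t.max_casts,
                    "n_casts": t.n_casts, "outcome": t.ended_by,
                    "points_banked": t.points_banked,
                }
            )
    pd.DataFrame(rows, columns=GAMEPLAY_COLUMNS).to_csv(path, index=False)


def read_gameplay(path) -> list[SubjectPlay]:
    """Read and validate a gameplay CSV into SubjectPlay objects.

    Every invalid row is reported with its 1-based file line number; any
    invalid row makes the whole read fail.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAMEPLAY_COLUMNS if c not in df.columns]
    if missing:
        raise GameplayFormatError(f"{path}: missing columns {missing}")
    errors: list[str] = []
    plays: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            outcome = str(row.outcome)
            if outcome not in (COLLECTED, FORCED_FAIL):
                raise ValueError(f"unknown outcome label {outcome!r}")
            if int(row.n_casts) > int(row.max_casts):
                raise ValueError(
                    f"n_casts {row.n_casts} exceeds max_casts {row.max_casts}"
                )
            trial = TrialOutcome(
                p_yellow=float(row.p_yellow),
                n_casts=int(row.n_casts),
                ended_by=outcome,
                points_banked=int(row.points_banked),
                max_casts=int(row.max_casts),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        sid = str(row.subject_id)
        rec = plays.setdefault(
            sid, {"group": str(row.group), "version": str(row.version), "trials": []}
        )
        rec["trials"].append((int(row.trial), trial))
    if errors:
        raise GameplayFormatError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    out = []
    for sid, rec in plays.items():
        rec["trials"].sort(key=lambda kt: kt[0])
        out.append(
            SubjectPlay(
                subject_id=sid, group=rec["group"], version_label=rec["version"],
                trials=tuple(t for _, t in rec["trials"]),
            )
        )
    return out


def write_designs(designs: list[TaskDesign], path) -> None:
    rows = []
    for d in designs:
        p = d.schedule.as_array()
        for k in range(d.n_trials):
            rows.append(
                {"version": d.version_label, "trial": k + 1,
                 "p_yellow": p[k], "max_casts": d.max_casts[k]}
            )
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, index=False)


def read_designs(path) -> list[TaskDesign]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise GameplayFormatError(f"{path}: missing columns {missing}")
    out = []
    for version, sub in df.groupby("version", sort=False):
        sub = sub.sort_values("trial")
        p = tuple(float(x) for x in sub["p_yellow"])
        # infer block size from runs of constant probability
        block = 1
        arr = np.asarray(p)
        for b in range(len(arr), 0, -1):
            if len(arr) % b == 0 and np.all(arr.reshape(-1, b) == arr.reshape(-1, b)[:, :1]):
                block = b
                break
        schedule = ProbabilitySchedule(p_yellow=p, block_size=block)
        out.append(
            TaskDesign(schedule=schedule,
                       max_casts=tuple(int(x) for x in sub["max_casts"]),
                       version_label=str(version))
        )
    return out


def load_config(path) -> dict:
    """Load a YAML/JSON pipeline config, rejecting unknown top-level keys."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _build_designs(cfg: dict, seed: int) -> list[TaskDesign]:
    d = cfg.get("design", {})
    schedule = build_schedule(
        n_trials=int(d.get("n_trials", 30)),
        p_start=float(d.get("p_start", 0.05)),
        p_increment=float(d.get("p_increment", 0.05)),
        block_size=int(d.get("block_size", 5)),
    )
    rng = substream(seed, "design")
    base = generate_max_casts(schedule, rng)
    return make_versions(base, int(d.get("n_versions", 1)), rng)


def _group_specs(cfg: dict) -> list[GroupSpec]:
    return [
        GroupSpec(
            n_subjects=int(g["n_subjects"]), gamma_mean=float(g["gamma_mean"]),
            beta_mean=float(g["beta_mean"]),
            log_sd_gamma=float(g.get("log_sd_gamma", 0.2)),
            log_sd_beta=float(g.get("log_sd_beta", 0.2)),
            label=str(g["label"]),
        )
        for g in cfg.get("simulate", {}).get("groups", [])
    ]


def _covariate_specs(cfg: dict) -> list[CovariateSpec]:
    return [
        CovariateSpec(
            name=str(c["name"]), target_param=str(c.get("target_param", "none")),
            correlation=float(c.get("correlation", 0.0)),
            mean=float(c.get("mean", 0.0)), sd=float(c.get("sd", 1.0)),
        )
        for c in cfg.get("simulate", {}).get("covariates", [])
    ]


def _draws_frame(fit: FitResult) -> pd.DataFrame:
    rows = []
    for group, draws in fit.draws.items():
        for name, arr in draws.items():
            n_chains, n_draws = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "parameter": name,
                        "chain": np.repeat(np.arange(n_chains) + 1, n_draws),
                        "draw": np.tile(np.arange(n_draws) + 1, n_chains),
                        "value": arr.reshape(-1),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the configured stages end to end and return the manifest.

    Stage order is simulate -> fit -> score -> associate -> report; any
    subset may be configured, but later stages require either the earlier
    stage or an input file (``gameplay``) to be present.  Any stage failure
    propagates with its stage name; earlier outputs are left on disk.
    """
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "artbayes_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", _STAGES))
    bad = [s for s in stages if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    plays: list[SubjectPlay] | None = None
    covariates: pd.DataFrame | None = None
    fit_result: FitResult | None = None
    estimates: pd.DataFrame | None = None

    if "simulate" in stages:
        log.info("stage simulate: seed=%d", seed)
        designs = _build_designs(config, seed)
        write_designs(designs, out / "design.csv")
        groups = _group_specs(config)
        if not groups:
            raise ValueError("stage simulate: no groups configured")
        plays, truth = simulate_cohort(groups, designs[0], seed)
        write_gameplay(plays, out / "gameplay.csv")
        truth.to_csv(out / "truth.csv", index=False)
        files = ["design.csv", "gameplay.csv", "truth.csv"]
        cov_specs = _covariate_specs(config)
        if cov_specs:
            covariates = simulate_covariates(truth, cov_specs, seed)
            covariates.to_csv(out / "covariates.csv", index=False)
            files.append("covariates.csv")
        manifest["stages"]["simulate"] = {"outputs": files}
    elif any(s in stages for s in ("fit", "score", "associate", "report")):
        src = config.get("gameplay")
        if src is None:
            raise ValueError(
                "configuration error: no 'simulate' stage and no 'gameplay' input file"
            )
        plays = read_gameplay(src)
        manifest["stages"]["load"] = {"inputs": [str(src)]}
        if config.get("covariates_file"):
            covariates = pd.read_csv(config["covariates_file"])

    if "fit" in stages:
        log.info("stage fit: %d subjects", len(plays))
        fcfg = dict(config.get("fit", {}))
        spec = HierarchicalModelSpec(seed=seed, **fcfg)
        fit_result = fit_hierarchical(plays, spec)
        fit_result.summary.to_csv(out / "posterior_summary.csv", index=False)
        fit_result.diagnostics.to_csv(out / "diagnostics.csv", index=False)
        _draws_frame(fit_result).to_csv(out / "draws.csv", index=False)
        estimates = point_estimates(fit_result.summary)
        estimates.to_csv(out / "point_estimates.csv", index=False)
        manifest["stages"]["fit"] = {
            "outputs": ["posterior_summary.csv", "diagnostics.csv",
                        "draws.csv", "point_estimates.csv"],
            "converged": fit_result.converged,
        }
        if not fit_result.converged:
            log.warning("stage fit: R-hat threshold not reached; outputs marked unconverged")

    table: pd.DataFrame | None = None
    if "score" in stages:
        log.info("stage score")
        table = cohort_table(plays, estimates, covariates)
        table.to_csv(out / "scores.csv", index=False)
        manifest["stages"]["score"] = {"outputs": ["scores.csv"]}

    assoc_rows = []
    if "associate" in stages:
        log.info("stage associate")
        if table is None:
            table = cohort_table(plays, estimates, covariates)
        pairs = config.get("associate", {}).get("pairs", [])
        family = config.get("associate", {}).get("family")
        for pair in pairs:
            res = associate(
                table, pair["x"], pair["y"],
                transform_y=pair.get("transform_y", "none"),
                family=family or (len(pairs) if len(pairs) > 1 else None),
            )
            assoc_rows.append(
                {"x": res.x, "y": res.y, "n": res.n, "r": res.r, "p": res.p,
                 "transform": res.transform, "family": res.family,
                 "p_bonferroni": res.p_bonferroni}
            )
        pd.DataFrame(
            assoc_rows,
            columns=["x", "y", "n", "r", "p", "transform", "family", "p_bonferroni"],
        ).to_csv(out / "associations.csv", index=False)
        manifest["stages"]["associate"] = {"outputs": ["associations.csv"]}

    if "report" in stages:
        log.info("stage report")
        if table is None:
            table = cohort_table(plays, estimates, covariates)
        lines = ["# Cohort report", ""]
        lines.append(f"Subjects: {len(table)} in groups "
                     f"{sorted(table['group'].unique().tolist())}")
        lines.append("")
        lines.append("## Adjusted score by group")
        for g, sub in table.groupby("group"):
            vals = sub["adjusted_score"].dropna()
            lines.append(f"- {g}: mean {vals.mean():.2f}, sd {vals.std(ddof=1):.2f} "
                         f"(n={len(vals)}; missing={sub['adjusted_score'].isna().sum()})")
        groups_present = sorted(table["group"].unique().tolist())
        if len(groups_present) == 2:
            a = table.loc[table["group"] == groups_present[0], "adjusted_score"].dropna()
            b = table.loc[table["group"] == groups_present[1], "adjusted_score"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                bf = bf_ttest(a, b)
                pperm = permutation_test(a, b, seed=seed)
                lines.append("")
                lines.append("## Group comparison of adjusted score")
                lines.append(f"- BF10 = {bf:.3f} ({bf_interpretation(bf)})")
                lines.append(f"- permutation p = {pperm:.4f}")
        if fit_result is not None:
            lines.append("")
            lines.append("## Group-level posteriors")
            grp = fit_result.summary.query("level == 'group'")
            for _, r in grp[grp["parameter"].str.startswith("group_mean")].iterrows():
                lines.append(
                    f"- {r['group']} {r['parameter']}: mean {r['mean']:.3f} "
                    f"(95% CI {r['q2.5']:.3f}, {r['q97.5']:.3f}; rhat {r['rhat']:.3f})"
                )
            if not fit_result.converged:
                lines.append("- WARNING: unconverged fit (R-hat threshold exceeded)")
        if assoc_rows:
            lines.append("")
            lines.append("## Associations")
            for r in assoc_rows:
                lines.append(
                    f"- {r['x']} vs {r['y']} ({r['transform']}): "
                    f"r = {r['r']:.3f}, p = {r['p']:.4f}, n = {r['n']}"
                )
        (out / "report.md").write_text("\n".join(lines) + "\n")
        manifest["stages"]["report"] = {"outputs": ["report.md"]}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
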