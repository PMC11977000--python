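"""End-to-end orchestration: simulate -> process -> derive -> fit -> report.

A run is a directory of CSV tables plus a machine-readable manifest.
Every source of randomness flows from the single run seed, so rerunning
an identical configuration reproduces every output byte for byte.
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
import yaml

from . import __version__, accelerometry, coda, derived, regression, synthetic
from .schema import OUTCOMES, PART_COLUMNS, PARTS

__all__ = ["RunConfig", "load_config", "run_pipeline", "render_report"]

log = logging.getLogger("coda_activity")

_DESCRIPTIVE_COLUMNS = [
    "age9", "age10", "aphv9", "aphv10", "body_mass", "lean_mass",
    "lean_mass_index", "fat_mass_index", "baseline_diameter", "sbp9", "dbp9",
    "map9", "tag", "chol_hdl", "insulin", "pwc170", "crf_scaled_lean",
    "st_min", "lpa_min", "mvpa_min", "fmd", "dc", "pwv", "cvd_risk",
]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    outdir: str | Path = "run"
    seed: int = 0
    n_participants: int = 1000
    use_streams: bool = True
    days: int = 4
    kappa: float = coda.WAKING_DAY_MINUTES
    outcomes: tuple[str, ...] = OUTCOMES
    strata: tuple[str, ...] = regression.STRATA
    unadjusted: bool = True
    interactions: bool = True
    wear_rules: dict = field(default_factory=dict)
    cohort_overrides: dict = field(default_factory=dict)
    stream_overrides: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["outcomes"] = list(self.outcomes)
        d["strata"] = list(self.strata)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file mirroring :class:`RunConfig` fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("outcomes", "strata"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    path.write_text(f"# seed={seed} package=coda-activity {__version__}\n" + df.to_csv(index=False))


def read_run_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the seed-stamp comment header."""
    return pd.read_csv(path, comment="#")


def _descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in _DESCRIPTIVE_COLUMNS:
        if col not in cohort.columns:
            continue
        entry = {"variable": col}
        for label, sub in (
            ("group", cohort),
            ("boys", cohort[cohort["sex"] == "M"]),
            ("girls", cohort[cohort["sex"] == "F"]),
        ):
            vals = sub[col].dropna()
            entry[f"{label}_mean"] = vals.mean()
            entry[f"{label}_sd"] = vals.std(ddof=1)
            entry[f"{label}_n"] = len(vals)
        rows.append(entry)
    return pd.DataFrame(rows)


def _geometric_means(cohort: pd.DataFrame, kappa: float) -> pd.DataFrame:
    comp_cols = [PART_COLUMNS[p] for p in PARTS]
    rows = []
    for label, sub in (
        ("group", cohort),
        ("boys", cohort[cohort["sex"] == "M"]),
        ("girls", cohort[cohort["sex"] == "F"]),
    ):
        comp = sub[comp_cols].dropna().to_numpy(float)
        if len(comp) == 0:
            continue
        gm_min = coda.geometric_mean_composition(comp, kappa)
        gm_pct = coda.geometric_mean_composition(comp, 100.0)
        for part, mins, pct in zip(PARTS, gm_min, gm_pct):
            rows.append(
                {"stratum": label, "part": part, "gm_min_per_day": mins,
                 "gm_percent": pct, "n": len(comp)}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic study; returns the run directory.

    Stages: cohort simulation; optional epoch-stream simulation and
    accelerometer processing (replacing the analytic compositions by the
    processed ones); derived measures; descriptive, geometric-mean and
    association tables; manifest and rendered report.  Any stage error
    is re-raised annotated with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seed = config.seed
    stage = "init"
    try:
        stage = "simulate-cohort"
        spec = synthetic.CohortSpec(
            n_participants=config.n_participants,
            kappa=config.kappa,
            seed=seed,
            **config.cohort_overrides,
        )
        cohort, truth = synthetic.generate_cohort(spec)
        log.info("stage %s: %d participants", stage, len(cohort))
        _write_csv(cohort, outdir / "cohort.csv", seed)
        _write_csv(synthetic.truth_frame(truth), outdir / "truth.csv", seed)

        rules = accelerometry.WearRules(**config.wear_rules)
        if config.use_streams:
            stage = "simulate-streams"
            epochs, stream_truth = synthetic.streams_for_cohort(
                cohort, days=config.days, seed=seed + 1, **config.stream_overrides
            )
            log.info("stage %s: %d epochs", stage, len(epochs))
            stage = "process-accelerometry"
            day_df, person_df = accelerometry.process_epochs(epochs, rules)
            _write_csv(day_df, outdir / "days.csv", seed)
            _write_csv(person_df, outdir / "person_summaries.csv", seed)
            excl = accelerometry.exclusion_report(person_df)
            _write_csv(excl, outdir / "exclusions.csv", seed)
            log.info("stage %s: exclusions %s", stage, excl.to_dict("records"))
            included = person_df[person_df["included"]].set_index("participant_id")
            comp_cols = [PART_COLUMNS[p] for p in PARTS]
            # re-close processed mean daily minutes to the waking-day total
            comp = coda.closure(included[comp_cols].to_numpy(float), config.kappa)
            cohort = cohort[cohort["participant_id"].isin(included.index)].copy()
            cohort.loc[:, comp_cols] = comp
            log.info("stage %s: %d participants included", stage, len(cohort))

        stage = "derive"
        cohort["map9"] = derived.mean_arterial_pressure(cohort["sbp9"], cohort["dbp9"])
        cohort["cvd_risk_components"] = derived.clustered_cvd_risk(cohort)
        fit = derived.allometric_fit(cohort["pwc170"], cohort["lean_mass"], cohort["sex"])
        cohort["crf_scaled_lean_fitted"] = fit.scaled_values
        scaling_check = derived.validate_scaling(
            fit.scaled_values, cohort["lean_mass"].to_numpy(), cohort["sex"].to_numpy()
        )
        log.info(
            "stage %s: allometric exponent b=%.3f (SE %.3f), scaling check passed=%s",
            stage, fit.exponent_b, fit.exponent_se, scaling_check["passed"],
        )
        _write_csv(cohort, outdir / "cohort_derived.csv", seed)

        stage = "descriptives"
        _write_csv(_descriptives(cohort), outdir / "descriptives.csv", seed)
        _write_csv(
            _geometric_means(cohort, config.kappa), outdir / "geometric_means.csv", seed
        )

        stage = "fit-associations"
        adj = regression.association_table(
            cohort, outcomes=config.outcomes, strata=config.strata, adjusted=True
        )
        _write_csv(adj, outdir / "association_adjusted.csv", seed)
        if config.unadjusted:
            unadj = regression.association_table(
                cohort, outcomes=config.outcomes, strata=config.strata, adjusted=False
            )
            _write_csv(unadj, outdir / "association_unadjusted.csv", seed)
        if config.interactions:
            stage = "fit-interactions"
            rows = []
            for outcome in config.outcomes:
                res = regression.interaction_model(cohort, outcome)
                rows.append(
                    {
                        "outcome": outcome,
                        "female_z1_coef": res["female_z1"]["coef"],
                        "female_z1_p": res["female_z1"]["p"],
                        "female_z2_coef": res["female_z2"]["coef"],
                        "female_z2_p": res["female_z2"]["p"],
                        "joint_F": res["joint_F"],
                        "joint_p": res["joint_p"],
                        "n": res["n"],
                    }
                )
            _write_csv(pd.DataFrame(rows), outdir / "interactions.csv", seed)

        stage = "manifest"
        cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
        manifest = {
            "package_version": __version__,
            "seed": seed,
            "config": config.to_jsonable(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "n_simulated": config.n_participants,
            "n_analysed": int(len(cohort)),
            "allometric_exponent": fit.exponent_b,
            "scaling_check_passed": bool(scaling_check["passed"]),
            "tables": sorted(p.name for p in outdir.glob("*.csv")),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

        stage = "report"
        render_report(outdir)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def _fmt_assoc_block(table: pd.DataFrame, outcome: str, strata) -> list[str]:
    lines = []
    sub = table[table["outcome"] == outcome]
    for _, row in sub[sub["stratum"] == strata[0]].iterrows():
        parts = [f"{row['label']:<16}"]
        for stratum in strata:
            cell = sub[(sub["stratum"] == stratum) & (sub["part"] == row["part"])]
            if cell.empty or not np.isfinite(cell.iloc[0]["beta_ilr1"]):
                parts.append(f"{'not estimable':<34}")
                continue
            c = cell.iloc[0]
            txt = f"{c['beta_ilr1']:.3f} ({c['ci_low']:.3f} to {c['ci_high']:.3f}) p={c['p_value']:.3f}"
            if c["significant"]:
                txt = f"**{txt}**"
            parts.append(f"{txt:<34}")
        lines.append("  ".join(parts))
    return lines


def render_report(run_dir: str | Path) -> str:
    """Render the run's tables as a plain-text summary (report.txt).

    Association cells follow the journal convention of bolding
    (``**...**``) estimates significant at alpha = 0.05; strata that
    could not be fitted are rendered as not-estimable.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"coda-activity run report (seed={manifest['seed']}, "
        f"version {manifest['package_version']})",
        f"participants analysed: {manifest['n_analysed']} of {manifest['n_simulated']} simulated",
        "",
    ]
    gm_path = run_dir / "geometric_means.csv"
    if gm_path.exists():
        gm = read_run_csv(gm_path)
        lines.append("Compositional geometric means (min/day and % of waking time)")
        for stratum in gm["stratum"].unique():
            sub = gm[gm["stratum"] == stratum]
            cells = ", ".join(
                f"{r['part'].upper()} {r['gm_min_per_day']:.1f} ({r['gm_percent']:.1f}%)"
                for _, r in sub.iterrows()
            )
            lines.append(f"  {stratum:<6} n={sub['n'].iloc[0]:<6} {cells}")
        lines.append("")
    outcome_names = {
        "fmd": "Endothelial function (FMD %)",
        "pwv": "Arterial stiffness (PWV m/s)",
        "dc": "Arterial elasticity (DC % per mmHg)",
        "cvd_risk": "Clustered CVD risk score",
    }
    for name, title in (
        ("association_adjusted.csv", "Adjusted associations"),
        ("association_unadjusted.csv", "Unadjusted associations"),
    ):
        path = run_dir / name
        if not path.exists():
            continue
        table = read_run_csv(path)
        strata = [s for s in ("group", "boys", "girls") if s in set(table["stratum"])]
        lines.append(f"{title} (beta_ilr1, 95% CI; ** = significant)")
        header = "  ".join([f"{'':<16}"] + [f"{s:<34}" for s in strata])
        lines.append(header)
        for outcome in table["outcome"].unique():
            lines.append(f"{outcome_names.get(outcome, outcome)}")
            lines.extend(_fmt_assoc_block(table, outcome, strata))
        lines.append("")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
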