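"""End-to-end orchestration: simulate -> cohorts -> describe -> fit -> diagnose.

A :class:`RunConfig` (YAML round-trippable) names the inputs, windows,
eligibility threshold, analysis flags and seed; :func:`run_all` executes every
stage, writes all tables under the output directory, logs row counts after
each filter, and finishes with a manifest listing every output file with its
SHA-256 content hash.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, descriptives, diagnostics, iv, simulate

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_DATE_FIELDS = ("study_start", "study_end", "pre_start", "pre_end")


@dataclass
class RunConfig:
    """Everything one full run needs; round-trips through YAML."""

    out_dir: str = "teleiv_out"
    log_path: str | None = None       # None -> simulate a study log
    pre_log_path: str | None = None   # None -> simulate a prepandemic log
    seed: int = 0
    study_start: date = date(2020, 6, 1)
    study_end: date = date(2023, 5, 31)
    pre_start: date = date(2017, 1, 1)
    pre_end: date = date(2019, 8, 31)
    min_npv: int = 10
    exclude_clinicians: list = field(default_factory=list)
    loo_instrument: bool = False
    cluster: bool = False          # cluster SEs by clinician
    welch: bool = False            # Welch instead of pooled-variance t test
    weight_by_n: bool = False      # weight diagnostic cells by size
    sex_covariate: bool = False    # restore sex to the adjustment set
    sim_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for f in _DATE_FIELDS:
            d[f] = d[f].isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for f in _DATE_FIELDS:
            if f in d and isinstance(d[f], str):
                d[f] = date.fromisoformat(d[f])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        for p in (self.log_path, self.pre_log_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input log not found: {p}")
        if self.min_npv < 1:
            raise ValueError("min_npv must be >= 1")
        self.sim_config()  # raises on bad overrides

    def sim_config(self) -> simulate.SimulationConfig:
        cfg = simulate.SimulationConfig(
            seed=self.seed,
            study_start=self.study_start,
            study_end=self.study_end,
            pre_start=self.pre_start,
            pre_end=self.pre_end,
            **self.sim_overrides,
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fits_frame(results: dict[str, iv.FitResult]) -> pd.DataFrame:
    return pd.DataFrame([fr.to_dict() for fr in results.values()])


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    try:
        config.validate()
    except Exception as e:
        raise PipelineError("config", e) from e
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    # --- simulate -----------------------------------------------------
    try:
        if config.log_path is None:
            cfg = config.sim_config()
            visits, truth = simulate.generate_study_log(cfg)
            save(visits, "visits_study.csv")
            truth.save(out / "truth")
            written.extend(sorted((out / "truth").iterdir()))
        else:
            visits = cohort.read_visit_log(config.log_path)
        if config.pre_log_path is None:
            cfg = config.sim_config()
            pre_visits = simulate.generate_prepandemic_log(cfg)
            save(pre_visits, "visits_pre.csv")
        else:
            pre_visits = cohort.read_visit_log(config.pre_log_path)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("simulate", e) from e
    logger.info("visit rows: study=%d pre=%d", len(visits), len(pre_visits))

    # --- cohorts ------------------------------------------------------
    try:
        analytic, profiles = cohort.build_cohort(
            visits, config.study_start, config.study_end,
            min_npv=config.min_npv, exclude_clinicians=config.exclude_clinicians,
            loo_instrument=config.loo_instrument,
        )
        pre_analytic, pre_profiles = cohort.build_cohort(
            pre_visits, config.pre_start, config.pre_end,
            min_npv=config.min_npv, exclude_clinicians=config.exclude_clinicians,
        )
        save(analytic, "cohort_study.csv")
        save(profiles, "profiles_study.csv")
        save(pre_analytic, "cohort_pre.csv")
        save(pre_profiles, "profiles_pre.csv")
    except Exception as e:
        raise PipelineError("build-cohort", e) from e
    logger.info("analytic records: study=%d pre=%d", len(analytic), len(pre_analytic))

    # --- descriptives -------------------------------------------------
    try:
        save(descriptives.baseline_table(analytic, welch=config.welch),
             "table_baseline.csv")
        save(descriptives.diagnosis_table(analytic), "table_diagnosis.csv")
        save(descriptives.followup_rate_matrix(analytic), "table_rates.csv")
    except Exception as e:
        raise PipelineError("describe", e) from e

    # --- fits ---------------------------------------------------------
    try:
        cluster_by = "clinician_id" if config.cluster else None
        primary = iv.run_primary(
            analytic, include_sex=config.sex_covariate, cluster_by=cluster_by
        )
        sens = iv.run_sensitivities(
            analytic, include_sex=config.sex_covariate, cluster_by=cluster_by
        )
        save(_fits_frame(primary), "fits_primary.csv")
        for name, results in sens.items():
            save(_fits_frame(results), f"fits_{name}.csv")
        blob = {
            "primary": {k: v.to_dict() for k, v in primary.items()},
            **{
                name: {k: v.to_dict() for k, v in results.items()}
                for name, results in sens.items()
            },
        }
        path = out / "fits.json"
        path.write_text(json.dumps(blob, indent=1, sort_keys=True))
        written.append(path)
    except Exception as e:
        raise PipelineError("fit", e) from e

    # --- diagnostics --------------------------------------------------
    try:
        ex = diagnostics.exclusion_test(
            pre_analytic, profiles, min_npv=config.min_npv,
            weight_by_n=config.weight_by_n,
        )
        ind = diagnostics.independence_test(
            pre_analytic, analytic, profiles, min_npv=config.min_npv,
            weight_by_n=config.weight_by_n,
        )
        save(pd.DataFrame([dataclasses.asdict(ex), dataclasses.asdict(ind)]),
             "diagnostics.csv")
    except Exception as e:
        raise PipelineError("diagnose", e) from e

    manifest = {
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
        "n_analytic": int(len(analytic)),
        "n_pre_analytic": int(len(pre_analytic)),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
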