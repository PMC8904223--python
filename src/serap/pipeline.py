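"""Configuration-driven orchestration of the full study flow.

simulate -> clean -> split -> impute -> derive -> score -> evaluate ->
report, with one global seed fanned out to independent per-stage child
seeds, an audit log of every parameter and row-id digest, and byte-stable
artifacts (same config => identical output files).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from . import scorers, survival_eval
from .score_derivation import DeriveConfig, derive_score
from .synthetic_cohort import (
    EVENT_COL,
    ID_COL,
    TIME_COL,
    CohortSpec,
    generate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "compare_scores", "PipelineError"]

#: published SERAP risk bands (closed integer intervals over the 0-40 range)
DEFAULT_BANDS: tuple[tuple[int, int], ...] = (
    (0, 4), (5, 9), (10, 14), (15, 19), (20, 24), (25, 40),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class RunConfig:
    """Everything one run needs; serializable to/from YAML."""

    seed: int = 0
    input_csv: str | None = None                  # None: simulate
    simulate: Mapping[str, Any] = field(default_factory=dict)  # CohortSpec overrides
    split: Mapping[str, Any] = field(default_factory=lambda: {
        "mode": "temporal+random",
        "train_fraction": 0.8,
        "temporal_key": "admission_year",
        "holdout_values": [2016],
    })
    derive: Mapping[str, Any] = field(default_factory=dict)    # DeriveConfig overrides
    include_derived: bool = True
    builtin_tables: Sequence[str] = ("SERAP", "LACE", "HOSPITAL")
    horizons: Sequence[float] = (7, 14, 21, 30, 60, 90)
    bands: Sequence[Sequence[int]] = DEFAULT_BANDS
    bootstrap_B: int = 200
    classification_horizon: float = 30.0
    outdir: str = "serap_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["builtin_tables"] = list(self.builtin_tables)
        d["horizons"] = [float(h) for h in self.horizons]
        d["bands"] = [list(b) for b in self.bands]
        return d


def _child_seeds(seed: int, n: int = 5) -> list[int]:
    """Stage seeds fanned out from the global seed (all < 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _id_digest(df: pd.DataFrame) -> str:
    ids = df[ID_COL].to_numpy() if ID_COL in df.columns else df.index.to_numpy()
    return hashlib.sha256(np.sort(np.asarray(ids)).tobytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def compare_scores(
    episodes: pd.DataFrame,
    tables: Mapping[str, scorers.ScoreTable],
    horizons: Sequence[float] = (7, 14, 21, 30, 60, 90),
    B: int = 200,
    seed: int = 0,
) -> tuple[dict[str, survival_eval.EvalReport], str]:
    """Paired evaluation of several score tables on the same episodes.

    All tables are scored on the same rows and bootstrapped over identical
    resample indices; the digest of those indices is returned for audit.
    """
    scores_by_name = {}
    for name, table in tables.items():
        missing = [v for v in table.variable_names if v not in episodes.columns]
        if missing:
            raise KeyError(f"table {name!r}: episodes lack columns {missing}")
        scores_by_name[name] = table.apply(episodes)
    return survival_eval.evaluate_many(
        scores_by_name,
        episodes[TIME_COL].to_numpy(float),
        episodes[EVENT_COL].to_numpy(int),
        horizons=horizons,
        B=B,
        seed=seed,
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full flow; returns the run directory.

    Artifacts: cohort.csv, cleaned train/validation/test CSVs, derived score
    table JSON + parsimony/ranking CSVs, per-table evaluation report CSV,
    risk-profile CSV, KM-per-band CSV, classification CSV, and run_log.json
    with every seed, parameter and partition digest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    sim_seed, split_seed, derive_seed, eval_seed, cls_seed = seeds
    logged_config = config.to_dict()
    logged_config.pop("outdir")  # artifact location, not a run parameter
    log: dict[str, Any] = {"config": logged_config, "child_seeds": {
        "simulate": sim_seed, "split": split_seed, "derive": derive_seed,
        "evaluate": eval_seed, "classification": cls_seed}}

    # --- input ---------------------------------------------------------
    if config.input_csv:
        cohort = pd.read_csv(config.input_csv)
    else:
        spec = CohortSpec(seed=sim_seed, **dict(config.simulate))
        cohort = _stage("simulate")(generate_cohort)(spec)
    _write_csv(cohort, outdir / "cohort.csv")
    log["n_episodes"] = int(len(cohort))

    # --- clean ---------------------------------------------------------
    cohort, nulled = _stage("clean")(prep.flag_outliers)(cohort)
    log["outliers_nulled"] = {k: int(v) for k, v in nulled.items()}

    # --- split ---------------------------------------------------------
    scheme = prep.SplitScheme(seed=split_seed, **{
        k: (tuple(v) if k == "holdout_values" else v) for k, v in config.split.items()
    })
    train, validation, test = _stage("split")(prep.split_cohort)(cohort, scheme)
    if len(test) == 0:  # random mode: evaluate on the validation partition
        test = validation
    log["partitions"] = {
        "train": {"n": int(len(train)), "id_digest": _id_digest(train)},
        "validation": {"n": int(len(validation)), "id_digest": _id_digest(validation)},
        "test": {"n": int(len(test)), "id_digest": _id_digest(test)},
    }

    # --- impute --------------------------------------------------------
    (train, validation, test), medians = _stage("impute")(prep.impute_median)(
        train, [validation, test]
    )
    log["imputation_medians"] = {k: float(v) for k, v in medians.items()}
    _write_csv(train, outdir / "train.csv")
    _write_csv(validation, outdir / "validation.csv")
    _write_csv(test, outdir / "test.csv")

    # --- derive --------------------------------------------------------
    tables: dict[str, scorers.ScoreTable] = {}
    if config.include_derived:
        dconf = DeriveConfig(seed=derive_seed, **dict(config.derive))
        result = _stage("derive")(derive_score)(train, validation, dconf)
        result.score_table.to_json(outdir / "derived_score_table.json")
        _write_csv(result.parsimony_curve.to_frame(), outdir / "parsimony_curve.csv")
        _write_csv(result.ranking.to_frame(), outdir / "variable_ranking.csv")
        tables["derived"] = result.score_table
        log["derived"] = {"n_variables": result.n_variables,
                          "variables": result.score_table.variable_names,
                          "score_range": list(result.score_table.score_range())}

    builtin = scorers.builtin_tables()
    for name in config.builtin_tables:
        if name not in builtin:
            raise PipelineError(f"stage 'score' failed: unknown builtin table {name!r}")
        tables[name] = builtin[name]

    # LACE consumes the Charlson index computed from the comorbidity flags
    if "LACE" in tables and "charlson_index" not in test.columns:
        test = test.copy()
        test["charlson_index"] = _stage("score")(prep.charlson_index)(test)

    # --- evaluate ------------------------------------------------------
    reports, digest = _stage("evaluate")(compare_scores)(
        test, tables, horizons=config.horizons, B=config.bootstrap_B, seed=eval_seed,
    )
    log["bootstrap"] = {"B": int(config.bootstrap_B), "resample_digest": digest}
    _write_csv(pd.concat([r.to_frame() for r in reports.values()], ignore_index=True),
               outdir / "eval_report.csv")

    # --- risk profile + KM bands (first table in evaluation order) ------
    profile_table = next(iter(tables.values()))
    scores = profile_table.apply(test)
    lo, hi = profile_table.score_range()
    bands = [tuple(b) for b in config.bands]
    if bands[-1][1] < hi or bands[0][0] > lo:
        bands = [(lo, hi)]  # config bands do not cover this table's range
    profile = _stage("report")(scorers.risk_profile)(
        scores, test, bands, horizons=config.horizons,
    )
    _write_csv(profile.to_frame(), outdir / "risk_profile.csv")
    km_rows = []
    for lo_b, hi_b in bands:
        mask = (scores >= lo_b) & (scores <= hi_b)
        if not mask.any():
            continue
        curve = survival_eval.km_estimate(
            test.loc[mask, TIME_COL], test.loc[mask, EVENT_COL])
        for t, s in zip(curve.times, curve.survival):
            km_rows.append({"band": f"{lo_b}-{hi_b}", "time_days": t, "survival": s})
    _write_csv(pd.DataFrame(km_rows), outdir / "km_bands.csv")

    # --- classification at the fixed horizon ----------------------------
    cls_frames = []
    for name, table in tables.items():
        block = _stage("classify")(survival_eval.classification_with_ci)(
            table.apply(test), test[TIME_COL].to_numpy(float),
            test[EVENT_COL].to_numpy(int),
            horizon=config.classification_horizon,
            B=config.bootstrap_B, seed=cls_seed,
        )
        frame = block.to_frame()
        frame.insert(0, "score", name)
        cls_frames.append(frame)
        log.setdefault("classification", {})[name] = {
            "cutoff": block.cutoff, "n_excluded": block.n_excluded}
    _write_csv(pd.concat(cls_frames, ignore_index=True), outdir / "classification.csv")

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
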