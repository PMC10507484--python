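"""Strategy-comparison reports: tidy tables plus a reproducibility manifest.

The report bundle mirrors the shape of the published comparison: weighted
eligibility proportions per strategy and race/ethnicity, percentage change
in the number eligible relative to the standard model, and the mean
standard-model benefit among the people whose eligibility status changed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort_io import read_cohort
from .strategies import (STRATEGIES, EligibilityConfig, ModelSet,
                         population_eligibility, preventable_burden)
from .submodel import load_default_submodels, load_submodel

log = logging.getLogger("lyfsct")

__all__ = ["RunConfig", "ReportBundle", "run_strategy_comparison",
           "load_model_set", "write_reports"]


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str
    models_dir: Optional[str] = None       # None -> bundled defaults
    output_dir: str = "reports"
    strategies: Sequence[str] = STRATEGIES
    threshold_days: float = 16.2
    complete_cases: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        if "standard" not in self.strategies:
            raise ValueError("the strategy list must include 'standard'")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["strategies"] = list(self.strategies)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass(frozen=True)
class ReportBundle:
    eligibility: pd.DataFrame       # strategy x group summaries
    percent_change: pd.DataFrame    # vs standard, per strategy x group
    burden: pd.DataFrame            # preventable deaths / gainable life-years
    manifest: dict


def load_model_set(models_dir: Optional[Union[str, Path]]) -> ModelSet:
    if models_dir is None:
        return ModelSet.from_mapping(load_default_submodels())
    d = Path(models_dir)
    return ModelSet.from_mapping({
        name: load_submodel(d / f"{name}.json")
        for name in ("lcdrat", "lcdrat_norace", "acm", "acm_norace")})


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_strategy_comparison(config: RunConfig) -> ReportBundle:
    """Score every configured strategy on the cohort and tabulate."""
    t0 = time.perf_counter()
    cohort = read_cohort(config.cohort_path, complete_cases=config.complete_cases)
    models = load_model_set(config.models_dir)
    cfg = EligibilityConfig(threshold_days=config.threshold_days)
    log.info("scoring %d records under %d strategies",
             len(cohort), len(config.strategies))

    summaries, burdens = [], []
    for strategy in config.strategies:
        t = time.perf_counter()
        summaries.append(population_eligibility(cohort, strategy, models, cfg))
        burdens.append(preventable_burden(cohort, strategy, models, cfg))
        log.info("strategy %-20s %.2fs", strategy, time.perf_counter() - t)
    eligibility = pd.concat(summaries, ignore_index=True)
    burden = pd.concat(burdens, ignore_index=True)

    std = eligibility[eligibility["strategy"] == "standard"].set_index("group")
    rows = []
    for strategy in config.strategies:
        if strategy == "standard":
            continue
        sub = eligibility[eligibility["strategy"] == strategy]
        for _, row in sub.iterrows():
            base = float(std.loc[row["group"], "weighted_eligible"])
            change = (100.0 * (row["weighted_eligible"] - base) / base
                      if base > 0 else float("nan"))
            rows.append({
                "strategy": strategy,
                "group": row["group"],
                "pct_change_eligible": change,
                "mean_std_days_newly_eligible": row["mean_std_days_newly_eligible"],
                "mean_std_days_newly_ineligible": row["mean_std_days_newly_ineligible"],
            })
    percent_change = pd.DataFrame(rows)

    import lifelines
    import numpy
    manifest = {
        "lyfsct_version": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "cohort_path": str(config.cohort_path),
        "cohort_sha256": _sha256(config.cohort_path),
        "models_dir": config.models_dir or "bundled-defaults",
        "strategies": list(config.strategies),
        "threshold_days": config.threshold_days,
        "n_records": int(len(cohort)),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return ReportBundle(eligibility=eligibility, percent_change=percent_change,
                        burden=burden, manifest=manifest)


def write_reports(bundle: ReportBundle, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the bundle as tidy CSVs plus a JSON manifest.

    Byte-identical for identical inputs: the manifest's timing field is the
    only nondeterministic value and is excluded from the written manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "eligibility": out / "eligibility_by_strategy.csv",
        "percent_change": out / "percent_change_vs_standard.csv",
        "burden": out / "preventable_burden.csv",
        "manifest": out / "manifest.json",
    }
    bundle.eligibility.to_csv(paths["eligibility"], index=False,
                              float_format="%.17g")
    bundle.percent_change.to_csv(paths["percent_change"], index=False,
                                 float_format="%.17g")
    bundle.burden.to_csv(paths["burden"], index=False, float_format="%.17g")
    manifest = {k: v for k, v in bundle.manifest.items() if k != "elapsed_s"}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
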