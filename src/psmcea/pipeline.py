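"""Stage orchestration and CSV/JSON result serialization.

Stages run in dependency order (curves -> traces -> costs/outcomes -> ICER ->
DSA/PSA -> subgroups).  Every output CSV starts with a ``#`` comment line
declaring its column units; a run log records the seed, package version and
a hash of the configuration, so a run is fully reproducible from its output
directory.
"""

from __future__ import annotations

import json
import logging
from importlib import metadata
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .icer import evaluate_base_case, run_dsa, run_psa
from .psm import build_trace
from .simulate import TrialSimConfig, simulate_ipd
from .subgroups import run_subgroups

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("base-case", "dsa", "psa", "subgroups", "simulate")

log = logging.getLogger("psmcea")


def _write_csv(df: pd.DataFrame, path: Path, units: str) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# {units}\n")
        df.to_csv(fh, index=False)
    return path


def run_pipeline(
    config: AnalysisConfig,
    stages: list[str],
    out_dir: str | Path,
    seed: int = 0,
    psa_n: int = 10_000,
) -> dict:
    """Execute the requested stages, writing CSV outputs plus a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    results: dict = {"outputs": []}

    def record(path: Path) -> None:
        results["outputs"].append(str(path))

    try:
        if "base-case" in stages or "dsa" in stages or "psa" in stages:
            res, outcomes = evaluate_base_case(config)
            results["base_case"] = res
            if "base-case" in stages:
                record(
                    _write_csv(
                        res.to_series().to_frame().T,
                        out / "ce_result.csv",
                        "costs in USD (discounted); qalys in QALYs; icer in USD/QALY",
                    )
                )
                for label, oc in outcomes.items():
                    record(
                        _write_csv(
                            oc.costs.to_series().to_frame().T,
                            out / f"cost_breakdown_{label}.csv",
                            "all columns USD, discounted",
                        )
                    )
                    trace = build_trace(config.arm_model(label), config.grid)
                    record(
                        _write_csv(
                            trace.to_frame(),
                            out / f"trace_{label}.csv",
                            "time_months in months; pf/pd/dead/new_deaths are cohort fractions",
                        )
                    )
        if "dsa" in stages:
            tornado = run_dsa(config)
            results["dsa"] = tornado
            record(
                _write_csv(
                    tornado,
                    out / "tornado.csv",
                    "bounds in parameter units; icer_low/icer_high/span in USD/QALY",
                )
            )
        if "psa" in stages:
            psa = run_psa(config, n=psa_n, seed=seed)
            results["psa"] = psa
            record(
                _write_csv(
                    psa.draws,
                    out / "psa_draws.csv",
                    "costs in USD; qalys in QALYs; one row per Monte Carlo draw",
                )
            )
            record(
                _write_csv(
                    psa.ceac,
                    out / "ceac.csv",
                    "wtp in USD/QALY; p_cost_effective is a probability",
                )
            )
        if "subgroups" in stages:
            sg = run_subgroups(config, n=psa_n, seed=seed)
            results["subgroups"] = sg
            record(
                _write_csv(
                    sg,
                    out / "subgroups.csv",
                    "hr_os dimensionless; icer in USD/QALY; ce_probability at the WTP threshold",
                )
            )
        if "simulate" in stages:
            sim = simulate_ipd(TrialSimConfig(), seed=seed)
            frames = [ipd.to_frame().assign(endpoint=ep) for (_, ep), ipd in sim.items()]
            df = pd.concat(frames, ignore_index=True)
            results["simulated_ipd"] = df
            record(
                _write_csv(
                    df,
                    out / "simulated_ipd.csv",
                    "time_months in months; event 1=event 0=censored",
                )
            )
    except Exception:
        log.exception("pipeline stage failed; partial outputs: %s", results["outputs"])
        raise

    try:
        version = metadata.version("psmcea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    run_log = {
        "seed": seed,
        "psa_n": psa_n,
        "stages": list(stages),
        "package_version": version,
        "config_hash": config.config_hash(),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    record(out / "run_log.json")
    return results
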