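"""End-to-end pipeline: fit prevalence, get transitions, simulate, report.

Each run writes a manifest (config, seeds, package version, input row
counts, output row counts) so any run can be repeated bit-identically from
the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as eio
from .config import RunConfig
from .errors import ExpowinError
from .microsim import (
    SimulationConfig,
    censor_to_estimation_year,
    initialize_cohort,
    occupational_turnover,
    period_prevalence,
    point_prevalence,
    simulate_window,
)
from .prevalence import PrevalenceTrendModel, aggregate_proportions
from .transitions import MultinomialTransitionModel, match_pseudo_panel
from .uncertainty import (
    SimulationInputs,
    Z95,
    bootstrap_period_prevalence,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class _Stage:
    """Context manager that re-raises with the failing stage's name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            if isinstance(exc, ExpowinError):
                exc.args = (f"[stage {self.name}] {exc.args[0]}",
                            *exc.args[1:])
        else:
            logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(),
                      "config_digest": config.digest(),
                      "version": __version__, "rows": {}}

    sim_config = SimulationConfig(
        window_start=config.window_start, window_end=config.window_end,
        estimation_year=config.estimation_year, n=config.cohort_size,
        rule=config.rule, seed=config.seed)

    with _Stage("read-inputs"):
        population = eio.read_population(config.population)
        life_table = eio.read_life_table(config.life_table)
        manifest["rows"]["population"] = len(population)

    with _Stage("fit-prevalence"):
        surveys = eio.read_cross_sections(config.cross_sections)
        manifest["rows"]["cross_sections"] = len(surveys)
        props = aggregate_proportions(surveys)
        model1 = PrevalenceTrendModel(
            year_origin=config.window_start).fit(props)
        prev_table = model1.predict_table(config.window_start)
        eio.write_prevalence(prev_table, out / "prevalence.csv")
        manifest["rows"]["prevalence"] = len(prev_table)

    with _Stage("transitions"):
        sd_by_sex = None
        if config.fixed_transitions:
            parsed = eio.read_transition_table(config.fixed_transitions)
            key = config.fixed_transitions_sex
            if key in parsed:
                mats = {"female": parsed[key]["matrix"].probs,
                        "male": parsed[key]["matrix"].probs}
                sd = (parsed[key]["upper_pct"]
                      - parsed[key]["lower_pct"]) / (2 * Z95) / 100.0
                sd_by_sex = {"female": sd, "male": sd}
            else:
                mats = {s: parsed[s]["matrix"].probs for s in parsed}
                sd_by_sex = {
                    s: (parsed[s]["upper_pct"] - parsed[s]["lower_pct"])
                    / (2 * Z95) / 100.0 for s in parsed}
            transitions = mats
        else:
            panel = eio.read_panel(config.panel)
            manifest["rows"]["panel"] = len(panel)
            years = sorted(panel["year"].unique())
            pairs = match_pseudo_panel(panel[panel["year"] == years[0]],
                                       panel[panel["year"] == years[1]])
            model2 = MultinomialTransitionModel().fit(pairs)
            transitions = model2
            table = pd.concat([model2.table_with_ur(s, 40.0)
                               for s in ("female", "male")])
            eio.write_transition_table(table, out / "transitions.csv")

    with _Stage("simulate"):
        cohort = initialize_cohort(population, prev_table, sim_config)
        trans_input = ({s: _tm(m) for s, m in transitions.items()}
                       if isinstance(transitions, dict) else transitions)
        simulate_window(cohort, trans_input, life_table, sim_config)
        censor_to_estimation_year(cohort, life_table,
                                  sim_config.estimation_year, sim_config)
        period = period_prevalence(cohort, rule=config.rule)
        point = point_prevalence(cohort, config.window_start)
        ot = occupational_turnover(period, point)
        eio.write_period_prevalence(period, out / "period_prevalence.csv")
        period.merge(ot, on=["sex", "age_group", "category"]).to_csv(
            out / "period_prevalence_ot.csv", index=False,
            float_format="%.10g")
        manifest["rows"]["period_prevalence"] = len(period)
        manifest["ot_metadata"] = "OT = period / point (point x OT = period)"

    if config.run_bootstrap:
        with _Stage("bootstrap"):
            prev_map = {}
            for (sex, grp), cell in prev_table.groupby(["sex", "age_group"]):
                vec = np.zeros(len(cell))
                vec[cell["category"].to_numpy(int)] = \
                    cell["proportion"].to_numpy()
                prev_map[(sex, grp)] = vec
            mats = ({s: _tm(m).probs for s, m in transitions.items()}
                    if isinstance(transitions, dict) else None)
            if mats is None:
                raise ExpowinError(
                    "bootstrap requires fixed transition matrices")
            inputs = SimulationInputs(
                population=population, prevalence=prev_map, matrices=mats,
                life_table=life_table, matrices_sd=sd_by_sex)
            boot = bootstrap_period_prevalence(
                inputs, sim_config, B=config.bootstrap_b, seed=config.seed,
                backend=config.backend, toggles=config.toggles)
            eio.write_period_prevalence(boot, out / "period_prevalence_ur.csv")
            manifest["rows"]["bootstrap"] = len(boot)

    manifest["outputs"] = sorted(p.name for p in out.glob("*.csv"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _tm(m):
    from .transitions import TransitionMatrix

    return m if isinstance(m, TransitionMatrix) else TransitionMatrix(
        probs=np.asarray(m, dtype=float))
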