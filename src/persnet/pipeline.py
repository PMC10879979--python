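"""End-to-end orchestration and report emission.

``run_pipeline`` drives simulate → metrics → analyses and writes the
publication-style report tables:

* ``group_comparison.csv`` — 18 features, pwMS vs controls;
* ``pwms_associations.csv`` — 18 features × 3 PROs, covariate-
  adjusted coefficients (plus the control-arm PROMIS battery);
* ``moderation_promis.csv`` — MS-diagnosis moderation per feature;
* ``paired_changes.csv`` — within-subject prepandemic→pandemic
  changes per arm;
* ``omnibus.json`` / ``qq_<outcome>.csv`` — permutation-calibrated Fisher
  omnibus and Q-Q envelope data;
* ``run_log.json`` — per-analysis complete-case n and exclusion counts.

The module also hosts the replication experiments used for calibration
scoring: coefficient-recovery across many simulated cohorts, contraction
calibration, and omnibus rejection-rate calibration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from persnet.codebook import Codebook, default_codebook
from persnet.cohort_io import link_timepoints, read_cohort, write_cohort
from persnet.cross_sectional import (
    CONTROL_COVARIATES,
    PWMS_COVARIATES,
    build_analysis_table,
    compare_groups,
    comparisons_to_frame,
    moderation_battery,
    regression_battery,
)
from persnet.longitudinal import (
    CONTROL_CHANGE_COVARIATES,
    PWMS_CHANGE_COVARIATES,
    build_paired_table,
    paired_change_battery,
    permutation_omnibus,
    qq_envelope,
    qq_to_frame,
)
from persnet.network_metrics import features_table
from persnet.records import CohortTable
from persnet.synthetic import (
    GeneratorConfig,
    apply_contraction,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either the three input CSV paths or a generator config must be given.
    """

    out_dir: str | Path = "results"
    participants: Optional[str | Path] = None
    alters: Optional[str | Path] = None
    ties: Optional[str | Path] = None
    generator: Optional[GeneratorConfig] = None
    analyses: tuple[str, ...] = ("cross_sectional", "moderation", "longitudinal")
    alpha: float = 0.05
    permutations: int = 10_000
    seed: Optional[int] = None

    def validate(self) -> None:
        paths = (self.participants, self.alters, self.ties)
        if self.generator is None:
            missing = [
                name
                for name, p in zip(("participants", "alters", "ties"), paths)
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise ValueError(
                    f"no generator configured and input table(s) missing: {missing}"
                )
        if "longitudinal" in self.analyses and self.permutations < 99:
            raise ValueError("longitudinal analysis needs at least 99 permutations")


def _load_or_simulate(config: RunConfig, cb: Codebook) -> tuple[CohortTable, dict]:
    log: dict = {}
    if config.generator is not None:
        sim = simulate_cohort(config.generator, seed=config.seed, codebook=cb)
        if config.generator.design == "longitudinal":
            sim = apply_contraction(sim, seed=None if config.seed is None else config.seed + 1,
                                    codebook=cb)
        log["source"] = "simulated"
        log["n_entries"] = len(sim.cohort)
        return sim.cohort, log
    cohort = read_cohort(config.participants, config.alters, config.ties, cb)
    log["source"] = str(config.participants)
    log["n_entries"] = len(cohort)
    return cohort, log


def run_pipeline(config: RunConfig, codebook: Codebook | None = None) -> dict[str, Path]:
    """Execute the configured analyses and write report files.

    Deterministic given ``config.seed``; returns {report name: path}.
    """
    config.validate()
    cb = codebook or default_codebook()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, log = _load_or_simulate(config, cb)
    files: dict[str, Path] = {}

    feats = features_table(cohort, cb)
    files["features"] = out / "features.csv"
    feats.to_csv(files["features"], index=False)

    pandemic = cohort.select(timepoint="pandemic")
    if "cross_sectional" in config.analyses:
        pan_feats = feats[feats["timepoint"] == "pandemic"]
        comparison = comparisons_to_frame(compare_groups(pan_feats, alpha=config.alpha))
        files["group_comparison"] = out / "group_comparison.csv"
        comparison.to_csv(files["group_comparison"], index=False)

        data = build_analysis_table(pandemic, cb)
        pwms = data[data["group"] == "pwMS"]
        associations = regression_battery(pwms, covariates=PWMS_COVARIATES, alpha=config.alpha)
        files["pwms_associations"] = out / "pwms_associations.csv"
        associations.to_csv(files["pwms_associations"], index=False)
        log["association_n"] = {
            f"{r.feature}/{r.outcome}": int(r.n) for r in associations.itertuples()
        }

        controls = data[data["group"] == "control"]
        ctl = regression_battery(
            controls,
            outcomes=("promis_pf",),
            covariates=CONTROL_COVARIATES,
            alpha=config.alpha,
        )
        files["control_associations"] = out / "control_promis_associations.csv"
        ctl.to_csv(files["control_associations"], index=False)

    if "moderation" in config.analyses:
        data = build_analysis_table(pandemic, cb)
        moder = moderation_battery(data, covariates=CONTROL_COVARIATES)
        files["moderation"] = out / "moderation_promis.csv"
        moder.to_csv(files["moderation"], index=False)

    if "longitudinal" in config.analyses:
        pairs = link_timepoints(cohort)
        log["longitudinal_pairs"] = len(pairs)
        if pairs:
            paired_tables = []
            omnibus_results = {}
            for group, covs, outcomes in (
                ("pwMS", PWMS_CHANGE_COVARIATES, ("pdds", "msrs_r", "promis_pf")),
                ("control", CONTROL_CHANGE_COVARIATES, ("promis_pf",)),
            ):
                gpairs = [p for p in pairs if p.pandemic.participant.group == group]
                if not gpairs:
                    continue
                paired = build_paired_table(gpairs, cb)
                changes = paired_change_battery(paired)
                changes.insert(0, "group", group)
                paired_tables.append(changes)
                single_cohort = paired["cohort_id"].nunique() < 2
                for outcome in outcomes:
                    res = permutation_omnibus(
                        paired,
                        outcome,
                        covariates=covs,
                        cohort_col=None if single_cohort else "cohort_id",
                        B=config.permutations,
                        seed=config.seed,
                    )
                    omnibus_results[f"{group}/{outcome}"] = {
                        "k": res.k,
                        "chi_sq": res.chi_sq,
                        "analytic_p": res.analytic_p,
                        "empirical_p": res.empirical_p,
                        "B": res.B,
                        "seed": res.seed,
                    }
                    env = qq_envelope(res.observed_p, res.permuted_p)
                    qq_path = out / f"qq_{group}_{outcome}.csv"
                    qq_to_frame(env).to_csv(qq_path, index=False)
                    files[f"qq_{group}_{outcome}"] = qq_path
            files["paired_changes"] = out / "paired_changes.csv"
            pd.concat(paired_tables, ignore_index=True).to_csv(files["paired_changes"], index=False)
            files["omnibus"] = out / "omnibus.json"
            with open(files["omnibus"], "w") as fh:
                json.dump(omnibus_results, fh, indent=2)

    files["log"] = out / "run_log.json"
    with open(files["log"], "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    logger.info("pipeline wrote %d report files to %s", len(files), out)
    return files


def simulate_to_csv(
    config: GeneratorConfig, out_dir: str | Path, seed: Optional[int] = None
) -> dict[str, Path]:
    """Simulate a cohort and write the three input CSVs plus the truth table."""
    sim = simulate_cohort(config, seed=seed)
    if config.design == "longitudinal":
        sim = apply_contraction(sim, seed=None if seed is None else seed + 1)
    paths = write_cohort(sim.cohort, out_dir)
    truth_path = Path(out_dir) / "ground_truth.csv"
    sim.truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# calibration / recovery experiments


def recovery_experiment(
    arm: str = "pwMS",
    n_replicates: int = 200,
    n: Optional[int] = None,
    effect: Optional[float] = None,
    seed: int = 0,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Coefficient recovery for the negative-influence association.

    Simulates ``n_replicates`` cohorts of one arm with the configured true
    coefficient (pwMS: effect on MSRS-R adjusting age, disease duration,
    employment, income; controls: effect on PROMIS Physical Function
    adjusting age, employment, income), fits the covariate-adjusted OLS on
    each, and returns one row per replicate with the estimated beta and
    complete-case n.
    """
    cb = codebook or default_codebook()
    feature = "pct_negative_influence"
    if arm == "pwMS":
        outcome, covs = "msrs_r", PWMS_COVARIATES
    elif arm == "control":
        outcome, covs = "promis_pf", CONTROL_COVARIATES
    else:
        raise ValueError(arm)
    from persnet.cross_sectional import feature_outcome_regression

    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for rep_seed in seeds:
        kwargs = {}
        if effect is not None:
            key = (
                "negative_influence_effect_msrsr"
                if arm == "pwMS"
                else "negative_influence_effect_promis_control"
            )
            kwargs[key] = effect
        config = GeneratorConfig.cross_sectional(**kwargs)
        if arm == "pwMS":
            config = dataclasses.replace(
                config,
                pwms=dataclasses.replace(config.pwms, n=n or config.pwms.n),
                controls=dataclasses.replace(config.controls, n=0),
            )
        else:
            config = dataclasses.replace(
                config,
                pwms=dataclasses.replace(config.pwms, n=0),
                controls=dataclasses.replace(config.controls, n=n or config.controls.n),
            )
        sim = simulate_cohort(config, seed=int(rep_seed), codebook=cb)
        data = build_analysis_table(sim.cohort.select(group=arm), cb)
        res = feature_outcome_regression(data, feature, outcome, covs)
        true_beta = float(
            sim.truth.query("group == @arm and feature == @feature and outcome == @outcome")[
                "beta"
            ].iloc[0]
        )
        rows.append(
            {"seed": int(rep_seed), "beta": res.beta, "n": res.n, "true_beta": true_beta}
        )
    return pd.DataFrame(rows)


def contraction_size_experiment(
    n_participants: int = 1000, seed: int = 0, codebook: Codebook | None = None
) -> dict[str, float]:
    """Mean pwMS network size before/after the default contraction operator."""
    cb = codebook or default_codebook()
    config = GeneratorConfig.longitudinal(n_pwms=n_participants, n_controls=0)
    sim = simulate_cohort(config, seed=seed, codebook=cb)
    paired = apply_contraction(sim, seed=seed + 1, codebook=cb)
    pre = [e.network.size for e in paired.cohort if e.participant.timepoint == "prepandemic"]
    post = [e.network.size for e in paired.cohort if e.participant.timepoint == "pandemic"]
    return {
        "n": n_participants,
        "mean_size_prepandemic": float(np.mean(pre)),
        "mean_size_pandemic": float(np.mean(post)),
    }


def omnibus_calibration_experiment(
    n_runs: int = 100,
    n_pwms: int = 230,
    B: int = 999,
    outcome: str = "msrs_r",
    alpha: float = 0.05,
    seed: int = 0,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Empirical p of the permutation omnibus across null-generated cohorts.

    Under the null longitudinal generator (no feature→PRO effects) the
    empirical p is uniform, so rejection at ``alpha`` should occur in about
    ``alpha`` of runs.  Returns one row per run with the empirical p.
    """
    cb = codebook or default_codebook()
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    rows = []
    for run_seed in seeds:
        config = GeneratorConfig.longitudinal(n_pwms=n_pwms, n_controls=0)
        sim = simulate_cohort(config, seed=int(run_seed), codebook=cb)
        paired_sim = apply_contraction(sim, seed=int(run_seed) + 1, codebook=cb)
        pairs = link_timepoints(paired_sim.cohort)
        paired = build_paired_table(pairs, cb)
        res = permutation_omnibus(
            paired,
            outcome,
            covariates=PWMS_CHANGE_COVARIATES,
            B=B,
            seed=int(run_seed) + 2,
        )
        rows.append(
            {
                "seed": int(run_seed),
                "empirical_p": res.empirical_p,
                "analytic_p": res.analytic_p,
                "reject": res.empirical_p <= alpha,
            }
        )
    return pd.DataFrame(rows)
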