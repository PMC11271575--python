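"""End-to-end workflow: single-ancestry fits -> joint grid -> ensemble.

`run_study` executes the whole method on synthetic data in memory and
is the engine behind the `run` CLI subcommand and the reproducibility
script. Tuning data are assumed to exist for the target population
only; every population's single-ancestry path is therefore scored on
the target tuning set (tuning-on-target mode).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import evaluate as ev
from . import simulate as sim
from .ld_reference import build_shared_index
from .prosper_core import PenaltyGrid, solve_prosper_grid
from .single_ancestry import select_reference_params, solve_lassosum_path

logger = logging.getLogger(__name__)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Fan a top-level seed out into n independent 31-bit stage seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def file_checksum(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


@dataclass
class StudyResult:
    """Everything `run_study` produced, plus the headline metrics."""

    config: sim.SimConfig
    target: str
    reference_params: dict            # population -> (delta0, lambda0)
    solution: object
    ensemble_model: object
    collapsed_weights: pd.DataFrame
    metrics: dict = field(default_factory=dict)
    lassosum_weights: dict = field(default_factory=dict)


def run_study(config: sim.SimConfig, target: str | None = None,
              grid_lengths: tuple[int, int] = (10, 10),
              folds: int = 10, keep_traces: bool = False) -> StudyResult:
    pops = list(config.populations)
    target = target or pops[-1]
    seeds = derive_seeds(config.seed, 4 + len(pops))

    ld_by_pop, snp_table, member, freqs = sim.gen_ld_blocks(config)
    truth = sim.simulate_effects(config, ld_by_pop)
    sumstats = [sim.simulate_sumstats(truth, ld_by_pop[pop], config.n_gwas[i],
                                      seed=seeds[i])
                for i, pop in enumerate(pops)]
    tune_panel, tune_pheno = sim.simulate_cohort(
        truth, ld_by_pop[target], config.n_tune, seed=seeds[len(pops)])
    valid_panel, valid_pheno = sim.simulate_cohort(
        truth, ld_by_pop[target], config.n_valid, seed=seeds[len(pops) + 1])
    y_tune = tune_pheno["phenotype"].to_numpy()
    y_valid = valid_pheno["phenotype"].to_numpy()

    # stage 1: single-ancestry paths, tuned on the target cohort
    reference_params, lasso_weights, lasso_tune_scores = {}, {}, {}
    for ss in sumstats:
        path = solve_lassosum_path(ss, ld_by_pop[ss.population])
        reference_params[ss.population] = select_reference_params(
            path, tune_panel, y_tune)
        di = int(np.where(path.deltas == reference_params[ss.population][0])[0][0])
        li = int(np.where(path.lambdas == reference_params[ss.population][1])[0][0])
        best = path.beta_series(di, li)
        lasso_weights[ss.population] = best
        lasso_tune_scores[ss.population] = tune_panel.standardize().score(best)

    # stage 2: joint penalized regression over the (lambda, c) grid
    shared = build_shared_index(sumstats)
    grid = PenaltyGrid.from_reference(sumstats, reference_params,
                                      lambda_length=grid_lengths[0],
                                      c_length=grid_lengths[1])
    solution = solve_prosper_grid(sumstats, ld_by_pop, grid, shared=shared,
                                  keep_traces=keep_traces)

    # stage 3: super-learning ensemble on the target tuning cohort
    candidates = ens.candidate_prs_matrix(solution, tune_panel)
    model = ens.superlearn_combine(candidates, y_tune, folds=folds,
                                   seed=seeds[len(pops) + 2])
    collapsed = ens.collapse_weights(model, solution, snp_meta=snp_table)

    # evaluation on the held-out validation cohort
    vstd = valid_panel.standardize()
    final_score = vstd.score(collapsed.set_index("snp_id")["weight"])
    prosper_r2 = ev.residualized_r2(y_valid, None, final_score)
    target_lasso_r2 = ev.residualized_r2(
        y_valid, None, vstd.score(lasso_weights[target]))
    prs_tune = pd.DataFrame(lasso_tune_scores)
    wts, _ = ens.weighted_prs_baseline(prs_tune, y_tune)
    weighted_score = sum(wts[pop] * vstd.score(lasso_weights[pop]) for pop in pops)
    weighted_r2 = ev.residualized_r2(y_valid, None, weighted_score)

    metrics = {
        "target": target,
        "n_candidates": candidates.n_candidates,
        "prosper_r2": prosper_r2,
        "target_lassosum_r2": target_lasso_r2,
        "weighted_prs_r2": weighted_r2,
        "relative_improvement_vs_lassosum": (
            ev.relative_improvement(prosper_r2, target_lasso_r2)
            if target_lasso_r2 > 0 else np.nan),
    }
    return StudyResult(config, target, reference_params, solution, model,
                       collapsed, metrics, lasso_weights)
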