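"""Canonical synthetic experiment configurations and runners.

Two regimes are exercised end to end on planted benchmarks:

* ``scenario1`` — link prediction without ground truth for absents: 20% of
  the observed positives are hidden, structural-hole links are true but
  never observed, and only a fraction of non-edges carry absent labels.
* ``scenario2`` — aggressive prediction where most target links are
  unobserved: a small mask, every remaining non-edge labeled absent, so
  the target's positive set is much larger than the input's.

The runners score the hidden part of the target with either the
full pipeline (structural marking + sampled negatives), a purely random
negative selection at the same rate, or raw MF (every unobserved pair
trained as a negative).
"""

from __future__ import annotations

import statistics
from dataclasses import replace

from .evaluation import EvalResult, evaluate_scores, evaluation_universe
from .mf_model import MFParams, build_training_set, score_all_unobserved, train
from .overlap_nss import (
    NSSParams,
    marked_pairs_for_network,
    select_negatives,
    select_negatives_random,
)
from .synthetic import PlantedConfig, generate_planted

__all__ = [
    "scenario_config",
    "scenario_nss_params",
    "default_mf_params",
    "run_trial",
    "mean_scores",
]

_SCENARIOS = {
    "scenario1": PlantedConfig(
        n_left=60,
        n_right=80,
        n_blocks=6,
        block_size_range=(8, 10),
        overlap_fraction=0.4,
        hide_fraction=0.2,
        hole_link_fraction=1.0,
        absent_label_rate=0.3,
    ),
    "scenario2": PlantedConfig(
        n_left=60,
        n_right=80,
        n_blocks=6,
        block_size_range=(8, 10),
        overlap_fraction=0.4,
        hide_fraction=0.1,
        hole_link_fraction=1.0,
        absent_label_rate=1.0,
    ),
}

_RHO = {"scenario1": 0.25, "scenario2": 0.3}


def scenario_config(name: str, seed: int) -> PlantedConfig:
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    return replace(_SCENARIOS[name], seed=seed)


def scenario_nss_params(name: str, sample_rate: float, seed: int) -> NSSParams:
    return NSSParams(alpha=2, rho=_RHO[name], sample_rate=sample_rate, seed=seed)


def default_mf_params(seed: int) -> MFParams:
    return MFParams(k=16, lam=0.02, gamma=0.02, max_iters=30, seed=seed)


def run_trial(
    scenario: str,
    selection: str,
    seed: int,
    sample_rate: float = 0.5,
) -> EvalResult:
    """One end-to-end run: generate, select negatives, train, evaluate.

    ``selection``: 'fca' (marking + sampling), 'random' (sampling only) or
    'none' (raw MF over every unobserved pair).
    """
    cfg = scenario_config(scenario, seed)
    _, input_net, split = generate_planted(cfg)
    nss = scenario_nss_params(scenario, sample_rate, seed)
    if selection == "fca":
        marked = marked_pairs_for_network(input_net, nss)
        negatives = select_negatives(input_net, marked, nss)
    elif selection == "random":
        negatives = select_negatives_random(input_net, nss)
    elif selection == "none":
        negatives = set(input_net.unobserved_pairs())
    else:
        raise ValueError(f"unknown selection {selection!r}")
    model = train(build_training_set(input_net, negatives), default_mf_params(seed))
    scores = dict(score_all_unobserved(model, input_net))
    return evaluate_scores(*evaluation_universe(split, scores, mode="hidden"))


def mean_scores(
    scenario: str,
    selection: str,
    seeds: range,
    sample_rate: float = 0.5,
) -> tuple[float, float]:
    """Mean (AUC, AUPR) of a selection mode over the given seeds."""
    results = [run_trial(scenario, selection, s, sample_rate) for s in seeds]
    return (
        statistics.mean(r.auc for r in results),
        statistics.mean(r.aupr for r in results),
    )
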