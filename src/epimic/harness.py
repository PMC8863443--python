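"""Type-I-error and statistical-power experiments for the MIC contrast test.

Each experiment cell simulates replicate case-control datasets from a
two-locus disease model, runs the permutation test on the designated
functional SNP pair, and reports the rejection rate at level alpha:

    power (or type-I error) = m1 / replicates,

where m1 counts replicates with p <= alpha.  Replicate seeds derive
deterministically from (master seed, replicate index), so cells are
reproducible and resumable in any order.

Scenarios
---------
``type1_no_effect``   flat odds table (gamma), no signal anywhere.
``type1_marginal``    one-locus marginal recessive odds model; the
                      designated pair is the marginal SNP plus a null SNP.
``power_nme``         randomly generated pure/strict epistasis model at a
                      target heritability / MAF / prevalence.
``power_me``          one of the six published marginal-effect models.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .epistasis import pairwise_scan, permutation_test
from .simulate import (SimConfig, generate_pure_strict_model, sample_dataset,
                       table1_model, table2_model)

__all__ = [
    "SCENARIOS",
    "ExperimentConfig",
    "PowerResult",
    "build_model",
    "run_replicate",
    "estimate_power",
    "estimate_type1",
    "average_power_over_models",
    "run_grid",
]

SCENARIOS = ("type1_no_effect", "type1_marginal", "power_nme", "power_me")


@dataclass
class ExperimentConfig:
    """One experiment cell: a model family, its parameters, and run sizes."""

    scenario: str
    h: Optional[float] = None            # NME heritability target
    maf: float = 0.2
    prevalence: float = 0.2
    gamma: float = 1.0                   # null-model baseline odds
    theta: float = 5.0                   # marginal-model odds multiplier
    table2_index: Optional[int] = None   # ME model selector
    n: int = 4000
    replicates: int = 100
    alpha: float = 0.05
    m: int = 1000                        # permutations per test
    exponent: float = 0.8
    seed: int = 0
    p_total: int = 10
    noise_maf: Optional[float] = None
    model_seed: Optional[int] = None     # NME model generation seed
    scan_all: bool = False               # success requires top rank too

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.scenario == "power_nme" and self.h is None:
            raise ValueError("power_nme needs a heritability target h")
        if self.scenario == "power_me" and self.table2_index is None:
            raise ValueError("power_me needs a table2_index")


@dataclass
class PowerResult:
    """Rejection-rate estimate over replicate datasets."""

    m1: int
    replicates: int
    power: float
    se: float
    alpha: float
    pvalues: list = field(default_factory=list)


def build_model(config: ExperimentConfig):
    """The penetrance model an experiment cell simulates from."""
    if config.scenario == "type1_no_effect":
        return table1_model("no_effect", gamma=config.gamma, maf=config.maf)
    if config.scenario == "type1_marginal":
        return table1_model("marginal_recessive", gamma=config.gamma,
                            theta=config.theta, maf=config.maf)
    if config.scenario == "power_nme":
        return generate_pure_strict_model(config.h, config.maf,
                                          config.prevalence,
                                          seed=config.model_seed)
    return table2_model(config.table2_index)


def _sub_seeds(seed: int, *key: int):
    state = np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def run_replicate(config: ExperimentConfig, replicate_index: int, model=None):
    """Simulate one dataset and test the designated functional pair.

    Returns ``(success, pvalue)`` with success := (p <= alpha).  With
    ``scan_all`` the full pairwise scan runs and success additionally
    requires the functional pair to rank first (smallest p, ties broken by
    larger delta).
    """
    if model is None:
        model = build_model(config)
    sim_seed, perm_seed = _sub_seeds(config.seed, replicate_index)
    G, y = sample_dataset(SimConfig(model, n=config.n,
                                    p_total=config.p_total,
                                    noise_maf=config.noise_maf,
                                    seed=sim_seed))
    if config.scan_all:
        scan = pairwise_scan(G, y, m=config.m, alpha=config.alpha,
                             seed=perm_seed, exponent=config.exponent)
        ranked = sorted(scan.pairs, key=lambda r: (r.pvalue, -r.delta))
        causal = next(r for r in scan.pairs
                      if {r.snp_i, r.snp_j} == {"P1", "P2"})
        top = {ranked[0].snp_i, ranked[0].snp_j} == {"P1", "P2"}
        return (causal.pvalue <= config.alpha) and top, causal.pvalue
    result = permutation_test(G.values[:, 0], G.values[:, 1], y, m=config.m,
                              seed=perm_seed, exponent=config.exponent,
                              snp_i="P1", snp_j="P2")
    return result.pvalue <= config.alpha, result.pvalue


def _estimate(config: ExperimentConfig, model=None) -> PowerResult:
    if model is None:
        model = build_model(config)
    pvalues = []
    m1 = 0
    for idx in range(config.replicates):
        success, p = run_replicate(config, idx, model=model)
        m1 += int(success)
        pvalues.append(p)
    power = m1 / config.replicates
    se = float(np.sqrt(power * (1 - power) / config.replicates))
    return PowerResult(m1=m1, replicates=config.replicates, power=power,
                       se=se, alpha=config.alpha, pvalues=pvalues)


def estimate_power(config: ExperimentConfig, model=None) -> PowerResult:
    """Power of the test under an epistatic or marginal-effect model."""
    if config.scenario not in ("power_nme", "power_me"):
        raise ValueError("estimate_power expects a power scenario")
    return _estimate(config, model=model)


def estimate_type1(config: ExperimentConfig) -> PowerResult:
    """Rejection rate under a null (no-epistasis) model; expected ~ alpha."""
    if config.scenario not in ("type1_no_effect", "type1_marginal"):
        raise ValueError("estimate_type1 expects a type1 scenario")
    return _estimate(config)


def average_power_over_models(config: ExperimentConfig, n_models: int = 5):
    """Average NME power across independently generated pure/strict models.

    Each model is generated with a seed derived from the cell seed and the
    model index, and evaluated with its own replicate stream.  Returns
    ``(mean_power, [PowerResult, ...])``.
    """
    if config.scenario != "power_nme":
        raise ValueError("model averaging applies to the power_nme scenario")
    results = []
    for k in range(n_models):
        model_seed, cell_seed = _sub_seeds(config.seed, 7001, k)
        cfg = replace(config, model_seed=model_seed, seed=cell_seed)
        model = build_model(cfg)
        results.append(estimate_power(cfg, model=model))
    mean_power = float(np.mean([r.power for r in results]))
    return mean_power, results


def run_grid(configs: Sequence[ExperimentConfig]) -> pd.DataFrame:
    """Run a list of experiment cells and return a long-format table.

    One row per cell, in input order; duplicate cells (identical scenario
    and parameters) are rejected.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("empty experiment grid")
    keys = [(c.scenario, c.h, c.maf, c.prevalence, c.gamma, c.theta,
             c.table2_index, c.n, c.alpha, c.m, c.seed) for c in configs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate experiment cells in grid")
    rows = []
    for cfg in configs:
        if cfg.scenario.startswith("type1"):
            res = estimate_type1(cfg)
            model_id = cfg.scenario
        elif cfg.scenario == "power_nme":
            res = estimate_power(cfg)
            model_id = f"nme(h={cfg.h},maf={cfg.maf})"
        else:
            res = estimate_power(cfg)
            model_id = f"me:{cfg.table2_index}"
        rows.append({
            "scenario": cfg.scenario, "h": cfg.h, "maf": cfg.maf,
            "n": cfg.n, "model_id": model_id,
            "replicates": res.replicates, "m1": res.m1,
            "power": res.power, "se": res.se, "alpha": cfg.alpha,
            "m": cfg.m, "seed": cfg.seed,
        })
    return pd.DataFrame(rows)
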