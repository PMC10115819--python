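"""Reusable validation experiments: samplers against exact oracles,
parameter recovery, null calibration, rule-mining equivalence, causal
recovery, and the end-to-end pipeline check.

These experiments back both the test suite and the reproduction script;
each is a pure function of its arguments and seed so reported numbers
are recomputable.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from . import causal, interactions, preprocess, rules
from .maxent import (FitSettings, MaxEntParams, exact_distribution, fit,
                     gibbs_sample, significance)
from .landscape import find_minima
from .synthetic import (BUTYRATE_CHEMICAL, BUTYRATE_PRODUCER_GENUS,
                        METHANOGEN_GENUS, generate_community, generate_sem,
                        generate_study, random_ground_truth)

__all__ = [
    "gibbs_vs_exact_tv",
    "parameter_recovery",
    "null_calibration",
    "landscape_worked_example",
    "brute_force_rules",
    "rules_oracle_agreement",
    "lingam_recovery",
    "internal_standard_experiment",
    "pipeline_smoke",
]


# ---------------------------------------------------------------------------
# Sampler vs exact distribution


def gibbs_vs_exact_tv(n_components: int = 5, seed: int = 0,
                      n_sweeps: int = 100_000, scale: float = 1.0,
                      env: tuple[float, float] = (0.0, 0.0)) -> float:
    """Total-variation distance between Gibbs samples and enumeration."""
    model = random_ground_truth(n_components, seed, scale=scale)
    states, probs = exact_distribution(model.params, env)
    samples = gibbs_sample(model.params, env, n_sweeps=n_sweeps, seed=seed,
                           burn_in=min(1000, n_sweeps // 10))
    idx = (samples.astype(np.int64)
           @ (1 << np.arange(n_components))).astype(np.int64)
    emp = np.bincount(idx, minlength=2 ** n_components) / idx.size
    return 0.5 * float(np.abs(emp - probs).sum())


# ---------------------------------------------------------------------------
# Parameter recovery


def parameter_recovery(seed: int = 0, n_components: int = 8,
                       n_per_env: int = 2000, backend: str = "sa",
                       settings: Optional[FitSettings] = None
                       ) -> dict[str, float]:
    """Fit on data simulated from known parameters; pooled Pearson r.

    Truth is U(-1, 1) over all of (h, J, g_a, g_s); the environment grid
    is the study design (treatment {0,1} x stages {0, 0.53, 1}).
    """
    model = random_ground_truth(n_components, seed, scale=1.0)
    comp, env = generate_community(model, n_per_env, seed=seed + 1)
    settings = settings or FitSettings(backend=backend)
    if settings.backend != backend:
        settings = FitSettings(**{**vars(settings), "backend": backend})
    result = fit(comp, env, settings=settings, seed=seed + 2)
    truth = model.params.as_vector()
    fitted = result.params.as_vector()
    r = float(np.corrcoef(truth, fitted)[0, 1])
    rmse = float(np.sqrt(np.mean((truth - fitted) ** 2)))
    return {"pearson_r": r, "rmse": rmse,
            "n_samples": comp.values.shape[0]}


# ---------------------------------------------------------------------------
# Null calibration of the repeated-run p-values


def null_calibration(seed: int = 0, n_datasets: int = 200,
                     n_reps: int = 200, n_per_env: int = 60,
                     n_components: int = 2, alpha: float = 0.05
                     ) -> dict[str, float]:
    """Rejection rate of g_a p-values when the true g_a is zero.

    Each dataset comes from a fresh ground truth with h, J, g_s drawn
    U(-1, 1) and g_a = 0, sampled exactly over the study's environment
    grid; a calibrated procedure rejects about alpha of the time.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    total = 0
    settings = FitSettings(backend="exact")
    for d in range(n_datasets):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        model = random_ground_truth(n_components, sub, scale=1.0,
                                    null_g_a=True)
        comp, env = generate_community(model, n_per_env, seed=sub + 1)
        res = significance(comp, env, settings=settings, n_reps=n_reps,
                           seed=sub + 2)
        p_ga = res.p_values.g_a
        rejected += int(np.sum(p_ga <= alpha))
        total += p_ga.size
    return {"rejection_rate": rejected / total, "n_pvalues": total,
            "alpha": alpha}


# ---------------------------------------------------------------------------
# Landscape worked example


def landscape_worked_example() -> pd.DataFrame:
    """Two-component system J12 = 1, h = (-0.1, -0.1) at eps = (0, 0).

    By enumeration of the 4 states the strict minima are (0,0) at energy
    0 and (1,1) at energy -0.8.
    """
    params = MaxEntParams(h=np.array([-0.1, -0.1]),
                          J=np.array([[0.0, 1.0], [1.0, 0.0]]),
                          g_a=np.zeros(2), g_s=np.zeros(2))
    summary = find_minima(params, (0.0, 0.0))
    return summary.to_frame()


# ---------------------------------------------------------------------------
# Association-rule oracle


def brute_force_rules(transactions, min_support: float,
                      min_confidence: float) -> set[tuple]:
    """Exhaustive rule enumeration: every disjoint antecedent/consequent
    pair over the full item universe, metrics by direct counting.

    Returns hashable (antecedent, consequent, support, confidence, lift)
    tuples with itemsets as sorted tuples and metrics rounded to 12
    decimals, for set comparison against the level-wise miner.
    """
    txs = (transactions.transactions
           if hasattr(transactions, "transactions") else list(transactions))
    n = len(txs)
    universe = sorted({i for t in txs for i in t})
    out = set()
    for size in range(2, len(universe) + 1):
        for itemset in combinations(universe, size):
            fs = frozenset(itemset)
            s_full = sum(1 for t in txs if fs <= t) / n
            if s_full < min_support:
                continue
            for r in range(1, size):
                for ante in combinations(itemset, r):
                    a = frozenset(ante)
                    c = fs - a
                    s_a = sum(1 for t in txs if a <= t) / n
                    conf = s_full / s_a
                    if conf >= min_confidence:
                        s_c = sum(1 for t in txs if c <= t) / n
                        out.add((tuple(sorted(a)), tuple(sorted(c)),
                                 round(s_full, 12), round(conf, 12),
                                 round(conf / s_c, 12)))
    return out


def _ruleset_as_tuples(rs: rules.RuleSet) -> set[tuple]:
    out = set()
    for _, row in rs.rules.iterrows():
        out.add((tuple(sorted(row["antecedent"])),
                 tuple(sorted(row["consequent"])),
                 round(row["support"], 12), round(row["confidence"], 12),
                 round(row["lift"], 12)))
    return out


def rules_oracle_agreement(seed: int = 0, n_trials: int = 100,
                           max_items: int = 6,
                           max_transactions: int = 20) -> float:
    """Fraction of random small instances where the level-wise miner
    reproduces the brute-force rule set exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n_items = int(rng.integers(2, max_items + 1))
        n_tx = int(rng.integers(4, max_transactions + 1))
        items = [chr(ord("A") + i) for i in range(n_items)]
        txs = []
        for _ in range(n_tx):
            mask = rng.random(n_items) < rng.uniform(0.2, 0.8)
            txs.append(frozenset(i for i, m in zip(items, mask) if m))
        min_s = float(rng.uniform(0.1, 0.5))
        min_c = float(rng.uniform(0.5, 0.9))
        mined = rules.mine_rules(txs, min_support=min_s,
                                 min_confidence=min_c)
        if _ruleset_as_tuples(mined) == brute_force_rules(txs, min_s, min_c):
            agree += 1
    return agree / n_trials


# ---------------------------------------------------------------------------
# Causal recovery


def lingam_recovery(seed: int = 0, n_seeds: int = 100, n: int = 5000
                    ) -> dict[str, float]:
    """Order recovery and strength RMSE on a 3-variable uniform chain.

    True model: x2 = 1.2 x1 + e2, x3 = -0.8 x2 + 0.5 x1 + e3, uniform
    disturbances; columns shuffled before estimation.
    """
    B_true = np.array([[0.0, 0.0, 0.0],
                       [1.2, 0.0, 0.0],
                       [0.5, -0.8, 0.0]])
    noise = [("uniform", 1.0)] * 3
    correct = 0
    sq_errors = []
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        sem = generate_sem(B_true, noise, n=n, seed=sub)
        model = causal.estimate(sem.data)
        # map back to true variable ids via the column names v<j>
        recovered = [int(model.variables[i][1:]) for i in model.causal_order]
        if recovered == [0, 1, 2]:
            correct += 1
        # compare strengths on the true-variable grid
        B_hat = np.zeros_like(B_true)
        for ci, child in enumerate(model.variables):
            for pi, parent in enumerate(model.variables):
                B_hat[int(child[1:]), int(parent[1:])] = model.B[ci, pi]
        sq_errors.append(np.mean((B_hat - B_true) ** 2))
    return {"order_recovery_rate": correct / n_seeds,
            "strength_rmse": float(np.sqrt(np.mean(sq_errors))),
            "n": n}


def internal_standard_experiment(seed: int = 0, n: int = 5000,
                                 noise_frac: float = 0.05
                                 ) -> dict[str, float]:
    """Family = dominant genus + a small other-genus remainder.

    The family aggregate is the genus plus ``noise_frac`` of independent
    lognormal remainder, so the direct strength genus -> family should
    sit near 1.  The two variables are nearly collinear, so resolving
    their direction needs a decent sample size; the default matches the
    scale of the chain-recovery experiment.
    """
    rng = np.random.default_rng(seed)
    genus = rng.lognormal(0.0, 0.8, n)
    other = rng.lognormal(0.0, 0.8, n) * noise_frac
    family = genus + other
    ctc = (np.arange(n) % 2).astype(float)
    response = -1.5 * ctc + rng.laplace(0.0, 0.5, n)
    data = pd.DataFrame({"CTC": ctc, "genus": genus, "family": family,
                         "response": response})
    model = causal.estimate(data)
    report = causal.internal_standard_check(model, [("genus", "family")])
    return {"coefficient": float(report["coefficient"].iloc[0]),
            "verdict_pass": float(report["verdict"].iloc[0] == "pass"),
            "n": n}


# ---------------------------------------------------------------------------
# End-to-end pipeline smoke


def pipeline_smoke(seed: int = 0, n_seeds: int = 20,
                   settings: Optional[FitSettings] = None
                   ) -> dict[str, float]:
    """Simulate -> preprocess -> fit -> classify -> causal, repeatedly.

    Checks that the planted methanogen-like genus lands in a g_a > 0
    group, the planted butyrate producer in a g_a < 0 group, and that the
    treatment variable receives a negative direct strength onto fecal
    butyrate in the causal stage.
    """
    settings = settings or FitSettings(n_iter=3000, n_chains=40,
                                       backend="sa")
    rng = np.random.default_rng(seed)
    methanogen_pos = butyrate_neg = ctc_butyrate_neg = 0
    for _ in range(n_seeds):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        study = generate_study(n_animals=12, seed=sub,
                               effect_profile="dysbiosis")
        comp, env = preprocess.preprocess_study(
            study.abundance, study.chemicals, study.metadata)
        result = fit(comp, env, settings=settings, seed=sub + 1)
        classes = interactions.classify_response(result.params)
        by_name = classes.set_index("component")
        if METHANOGEN_GENUS in by_name.index and \
                by_name.loc[METHANOGEN_GENUS, "g_a"] > 0:
            methanogen_pos += 1
        if BUTYRATE_PRODUCER_GENUS in by_name.index and \
                by_name.loc[BUTYRATE_PRODUCER_GENUS, "g_a"] < 0:
            butyrate_neg += 1
        # causal stage on per-animal changes from day 3; the run config
        # pairs the treatment indicator with the growth stage so the
        # large day-to-day drift does not mask the treatment effect
        values = pd.DataFrame({
            BUTYRATE_CHEMICAL: study.chemicals[BUTYRATE_CHEMICAL],
        })
        deltas = causal.delta_transform(values, study.metadata)
        deltas.insert(0, "CTC", (study.metadata["group"] == "CON")
                      .astype(float))
        deltas.insert(1, "stage", study.metadata["day"].astype(int)
                      .map(preprocess.DAY_TO_STAGE).astype(float))
        model = causal.estimate(deltas)
        order = model.ordered_variables
        if order.index("CTC") < order.index(BUTYRATE_CHEMICAL) and \
                model.strength("CTC", BUTYRATE_CHEMICAL) < 0:
            ctc_butyrate_neg += 1
    return {"methanogen_ga_positive_rate": methanogen_pos / n_seeds,
            "butyrate_producer_ga_negative_rate": butyrate_neg / n_seeds,
            "ctc_butyrate_negative_rate": ctc_butyrate_neg / n_seeds,
            "n_seeds": n_seeds}
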