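"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: path enumeration
instead of dynamic programming, explicit pair counting instead of rank
statistics, individual-level Monte-Carlo instead of closed-form cohort
propagation.
"""

import numpy as np
from scipy.stats import norm


def enumerate_best_path(values, means, variances, self_transition):
    """Exhaustive maximum-probability state path over all k^n paths."""
    values = np.asarray(values, dtype=float)
    means = np.asarray(means, dtype=float)
    sd = np.sqrt(np.asarray(variances, dtype=float))
    k, n = len(means), len(values)
    off = (1.0 - self_transition) / (k - 1)
    log_a = np.log(np.full((k, k), off) + np.eye(k) * (self_transition - off))
    log_pi = np.log(np.full(k, 1.0 / k))
    log_b = norm.logpdf(values[:, None], means[None, :], sd[None, :])

    paths = np.indices((k,) * n).reshape(n, -1).T  # (k^n, n)
    lp = log_pi[paths[:, 0]] + log_b[0, paths[:, 0]]
    for t in range(1, n):
        lp += log_a[paths[:, t - 1], paths[:, t]] + log_b[t, paths[:, t]]
    return paths[np.argmax(lp)]


def auc_by_pair_counting(scores, labels):
    """AUC as explicit case/control pair comparison (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    total, wins = 0, 0.0
    for c in scores[labels]:
        for h in scores[~labels]:
            total += 1
            if c > h:
                wins += 1
            elif c == h:
                wins += 0.5
    return wins / total


def best_cutoff_exhaustive(scores, labels, target_specificity):
    """Smallest candidate cutoff achieving the target specificity, by
    scanning every candidate explicitly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ctrl = scores[~labels]
    candidates = sorted(set(scores)) + [ctrl.max() + 1e-9]
    achieving = [c for c in candidates
                 if np.mean(ctrl < c) >= target_specificity]
    return min(achieving) if achieving else ctrl.max() + 1e-9


def monte_carlo_interception(params, n=100_000, seed=0):
    """Individual-level simulation of the stage-shift interception model."""
    rng = np.random.default_rng(seed)
    ns = len(params.stages)
    stage = np.zeros(n, dtype=int)
    undiagnosed = np.ones(n, dtype=bool)
    assigned = np.zeros(n)
    sens = np.asarray(params.sensitivity)
    prog = np.asarray(params.progression)
    surv = np.asarray(params.survival_5yr)
    base = np.asarray(params.baseline_stage_dist)
    tests = params.test_years()
    for t in range(params.horizon_years):
        if t in tests:
            caught = undiagnosed & (rng.random(n) < sens[stage])
            assigned[caught] = surv[stage[caught]]
            undiagnosed &= ~caught
        move = undiagnosed & (rng.random(n) < prog[stage])
        clinical = move & (stage == ns - 1)
        stage[move & ~clinical] += 1
        if clinical.any():
            st = rng.choice(ns, size=int(clinical.sum()), p=base)
            assigned[clinical] = surv[st]
            undiagnosed &= ~clinical
    if undiagnosed.any():
        st = rng.choice(ns, size=int(undiagnosed.sum()), p=base)
        assigned[undiagnosed] = surv[st]
    return float(assigned.mean()), float(assigned.std(ddof=1) / np.sqrt(n))
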