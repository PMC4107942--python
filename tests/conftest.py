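"""Shared fixtures and independent oracles for the test suite.

The brute-force functions here are deliberately written as plain double
loops, independent of the package's vectorized implementations, so they can
serve as oracles for the template-counting, ROC and FDR code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from sampenmap import CohortSpec, RunConfig, simulate_cohort
from sampenmap.pipeline import preprocess_subject
from sampenmap.simulate import TINY_GRID


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_counts(x, m: int, tau: int, r_abs: float) -> tuple[int, int]:
    """Ordered template-pair match counts by exhaustive O(N^2 * m) loops.

    Both lengths use start indices 0 .. N - m*tau - 1 and the inclusive
    Chebyshev criterion; self-pairs (j == i) are skipped explicitly.
    """
    x = np.asarray(x, dtype=float)
    n_t = x.size - m * tau
    b_m = b_m1 = 0
    for i in range(n_t):
        for j in range(n_t):
            if j == i:
                continue
            d = 0.0
            for k in range(m):
                d = max(d, abs(x[i + k * tau] - x[j + k * tau]))
            if d <= r_abs:
                b_m += 1
                if max(d, abs(x[i + m * tau] - x[j + m * tau])) <= r_abs:
                    b_m1 += 1
    return b_m, b_m1


def brute_force_roc_area(young, old) -> float:
    """ROC area by exhaustive pair enumeration (ties count one half)."""
    young, old = list(young), list(old)
    wins = 0.0
    for a in young:
        for b in old:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(young) * len(old))


def brute_force_operating_point(young, old):
    """Exhaustive threshold search mirroring the documented selection rule.

    Candidates are midpoints between consecutive distinct pooled scores;
    maximize accuracy, tie-break by Youden index, then lowest threshold.
    Returns (threshold, sensitivity, specificity, accuracy) in percent.
    """
    young = np.asarray(young, dtype=float)
    old = np.asarray(old, dtype=float)
    pooled = np.unique(np.concatenate([young, old]))
    cands = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else pooled
    best = None
    for thr in cands:
        sens = 100.0 * np.mean(young >= thr)
        spec = 100.0 * np.mean(old < thr)
        acc = 100.0 * (np.sum(young >= thr) + np.sum(old < thr)) / (young.size + old.size)
        key = (acc, sens + spec, -thr)
        if best is None or key > best[0]:
            best = (key, float(thr), sens, spec, acc)
    return best[1:]


def brute_force_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values from the textbook formula."""
    p = np.asarray(p_values, dtype=float)
    M = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(M)
    running = 1.0
    for rank in range(M, 0, -1):
        running = min(running, p[order[rank - 1]] * M / rank)
        q_sorted[rank - 1] = running
    q = np.empty(M)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Cohort fixtures (session-scoped: simulation and preprocessing are shared)
# ---------------------------------------------------------------------------

TINY_SPEC = CohortSpec(n_young=5, n_old=5, grid=TINY_GRID, master_seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """5 vs 5 subjects on a 16x16x8 grid; fast enough for repeated use."""
    subjects, roster = simulate_cohort(TINY_SPEC)
    return subjects, roster


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_cohort):
    """The tiny cohort pushed through the default preprocessing chain."""
    subjects, _ = tiny_cohort
    config = RunConfig()
    out = []
    for s in subjects:
        vol, mask = preprocess_subject(s.volume, config)
        out.append((s, vol, mask))
    return out
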