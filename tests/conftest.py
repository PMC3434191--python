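"""Shared fixtures and independent oracles for the test suite.

The expensive multi-seed selection experiments are session-scoped so that
module invariants and end-to-end checks share one computation.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest
from scipy.optimize import minimize

from srcshave import (
    LabeledDataset,
    ShavingConfig,
    benchmark_config,
    generate,
    integration_config,
)
from srcshave.pipeline import run_selection

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def l1_oracle_objective(A: np.ndarray, y: np.ndarray, eps: float) -> float:
    """BPDN optimum via the split-variable reformulation solved by SLSQP.

    min 1'(u+v)  s.t.  u, v >= 0,  ||A(u-v) - y||^2 <= eps^2.
    Independent of the package's FISTA/bisection path.
    """
    m, n = A.shape

    def con(z):
        x = z[:n] - z[n:]
        return eps**2 - float(((A @ x - y) ** 2).sum())

    # several starts guard against SLSQP line-search stalls
    x_ls, *_ = np.linalg.lstsq(A, y, rcond=None)
    starts = [np.zeros(2 * n),
              np.concatenate([np.maximum(x_ls, 0), np.maximum(-x_ls, 0)]),
              np.full(2 * n, 0.1)]
    best = None
    for z0 in starts:
        res = minimize(
            lambda z: float(z.sum()),
            z0,
            method="SLSQP",
            bounds=[(0.0, None)] * (2 * n),
            constraints=[{"type": "ineq", "fun": con}],
            options={"maxiter": 3000, "ftol": 1e-14},
        )
        if res.success and con(res.x) >= -1e-9:
            val = float(res.x.sum())
            best = val if best is None else min(best, val)
    if best is None:
        # fall back to an interior-point method; still independent of the
        # package's first-order path
        from scipy.optimize import NonlinearConstraint
        res = minimize(
            lambda z: float(z.sum()), starts[1], method="trust-constr",
            bounds=[(0.0, None)] * (2 * n),
            constraints=[NonlinearConstraint(con, 0.0, np.inf)],
            options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
        )
        assert con(res.x) >= -1e-9, "oracle found no feasible point"
        best = float(res.x.sum())
    return best


def hypergeometric_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric tail summation."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    k = a + c
    N = n1 + n2
    denom = comb(N, k)

    def pmf(x: int) -> float:
        return comb(n1, x) * comb(n2, k - x) / denom

    pa = pmf(a)
    lo, hi = max(0, k - n2), min(k, n1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= pa * (1 + 1e-9))


def make_dataset(values, status, kind="expression", prefix="v") -> LabeledDataset:
    values = np.asarray(values, dtype=float)
    return LabeledDataset(
        data_type=kind,
        values=values,
        variable_ids=[f"{prefix}{i + 1}" for i in range(values.shape[0])],
        sample_ids=[f"s{j + 1}" for j in range(values.shape[1])],
        status=np.asarray(status, dtype=int),
    )


# ---------------------------------------------------------------------------
# heavy multi-seed experiments (shared)
# ---------------------------------------------------------------------------

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Combined-mode selection on the planted benchmark for seeds 1-5.

    Yields per seed: (set of planted genes, SelectionResult).
    """
    runs = {}
    for seed in SEEDS:
        expr, snp, gmap, truth = generate(benchmark_config(seed))
        res = run_selection("combined", ShavingConfig(seed=seed),
                            expr=expr, snp=snp, gmap=gmap)
        runs[seed] = ({pg.gene for pg in truth}, res)
    return runs


@pytest.fixture(scope="session")
def integration_runs():
    """Combined vs single-type selection on the weak-joint-gene fixture.

    Yields per seed: (weak gene, combined / expression / snp results).
    """
    runs = {}
    for seed in SEEDS:
        expr, snp, gmap, truth = generate(integration_config(seed))
        weak = next(pg.gene for pg in truth if pg.mode == "both")
        cfg = ShavingConfig(seed=seed)
        runs[seed] = (
            weak,
            run_selection("combined", cfg, expr=expr, snp=snp, gmap=gmap),
            run_selection("expression", cfg, expr=expr, gmap=gmap),
            run_selection("snp", cfg, snp=snp, gmap=gmap),
        )
    return runs
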