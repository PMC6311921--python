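"""Synthetic-data generator and the type-I error / power study.

The generator emulates a correlated gene-expression design: sample columns
are drawn from a zero-mean multivariate normal with AR(1) covariance
``Sigma_ij = rho^|i-j|``, and a continuous phenotype is built as the
equal-weight average of ``T1`` randomly chosen gene rows plus ``T2 = T - T1``
independent standard-normal noise vectors, all scaled by ``1/T``.  ``T1 = 0``
therefore gives a phenotype independent of the matrix (the global null), and
raising ``T1`` strengthens the aggregate gene-set signal while diluting the
noise share.

Defaults follow the study design this package targets: ``N = 100`` samples,
``T = 30`` phenotype components, ``B = 1000`` permutations, ``R = 1000``
replicates and ``alpha = 0.05``; all are plain dataclass fields so
desk-scale runs simply pass smaller values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .combiners import PARTITION_PRESETS, PartitionScheme
from .engine import METHODS, run_all
from .marginal import ExpressionMatrix, dichotomize_phenotype, permuted_pvalues

__all__ = [
    "Scenario",
    "PowerCurve",
    "simulate_dataset",
    "simulate_phenotype",
    "ar1_matrix",
    "run_scenario_once",
    "estimate_type1",
    "estimate_power",
    "aauc",
    "robustness_study",
]


@dataclass(frozen=True)
class Scenario:
    """Parameters of one simulation condition."""

    m: int = 100  # genes in the set
    N: int = 100  # samples
    rho: float = 0.0  # AR(1) correlation decay between adjacent genes
    T: int = 30  # phenotype components (signal + noise)
    T1: int = 0  # signal genes; 0 = global null
    B: int = 1000  # permutations per replicate
    R: int = 1000  # replicates
    alpha: float = 0.05
    seed: Optional[int] = 0
    test: str = "pearson"  # marginal test; "t" pairs with median dichotomization

    def __post_init__(self) -> None:
        if not (0 <= self.T1 <= self.T):
            raise ValueError("need 0 <= T1 <= T")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.N < 4:
            raise ValueError("need N >= 4")
        if self.T1 > self.m:
            raise ValueError("T1 cannot exceed the number of genes m")


@dataclass(frozen=True)
class PowerCurve:
    """Estimated power across the signal-gene grid, plus its average."""

    t1_grid: tuple[int, ...]
    power: pd.DataFrame = field(repr=False)  # index T1, one column per method
    aauc: dict[str, float]
    mc_se: pd.DataFrame = field(repr=False)


def ar1_matrix(m: int, N: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """m x N matrix whose columns are i.i.d. N(0, Sigma), Sigma_ij = rho^|i-j|.

    Uses the AR(1) recursion x_i = rho*x_{i-1} + sqrt(1-rho^2)*eps_i (the
    closed-form banded Cholesky), so the cost is O(mN) for any m.
    """
    Z = rng.standard_normal((m, N))
    if rho == 0.0:
        return Z
    X = np.empty_like(Z)
    X[0] = Z[0]
    c = np.sqrt(1.0 - rho * rho)
    for i in range(1, m):
        X[i] = rho * X[i - 1] + c * Z[i]
    return X


def simulate_phenotype(
    X: np.ndarray, T1: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous phenotype: 1/T-weighted sum of T1 random gene rows and
    T - T1 standard-normal noise vectors.  Returns (y, signal_row_indices)."""
    m, N = X.shape
    if T1 > m:
        raise ValueError("T1 cannot exceed the number of genes m")
    rows = rng.choice(m, size=T1, replace=False) if T1 > 0 else np.empty(0, int)
    signal = X[rows].sum(axis=0) if T1 > 0 else np.zeros(N)
    noise = rng.standard_normal((T - T1, N)).sum(axis=0) if T > T1 else np.zeros(N)
    return (signal + noise) / T, rows


def simulate_dataset(
    sc: Scenario, rng: np.random.Generator
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """One replicate's (expression matrix, continuous phenotype, signal rows)."""
    X = ar1_matrix(sc.m, sc.N, sc.rho, rng)
    y, rows = simulate_phenotype(X, sc.T1, sc.T, rng)
    return ExpressionMatrix.from_arrays(X), y, rows


def run_scenario_once(
    sc: Scenario,
    rng: np.random.Generator,
    methods: Sequence[str] = METHODS,
    scheme: PartitionScheme | None = None,
    cdf_include_observed: bool = False,
) -> dict[str, float]:
    """Generate one dataset, dichotomize, permute, and return per-method
    adjusted p-values (one shared permutation ensemble)."""
    X, y, _ = simulate_dataset(sc, rng)
    ph = dichotomize_phenotype(y)
    perm_seed = int(rng.integers(2**31 - 1))
    ens = permuted_pvalues(X, ph, B=sc.B, seed=perm_seed, test=sc.test)
    results = run_all(
        ens, methods=methods, scheme=scheme, cdf_include_observed=cdf_include_observed
    )
    return {name: r.p_adjusted for name, r in results.items()}


def _binom_se(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / n))


def estimate_type1(
    sc: Scenario,
    methods: Sequence[str] = METHODS,
    scheme: PartitionScheme | None = None,
    both_conventions: bool = False,
) -> pd.DataFrame:
    """Type-I error: rejection rate at ``alpha`` over R null replicates.

    Requires ``T1 = 0`` so the phenotype is independent of the matrix.  With
    ``both_conventions=True`` each replicate is also scored with the observed
    row included in the layer CDFs (the exchangeable variant), and the table
    gains a ``convention`` column for comparing the two.
    """
    if sc.T1 != 0:
        raise ValueError("type-I estimation requires T1 = 0")
    conventions = [False, True] if both_conventions else [False]
    children = np.random.SeedSequence(sc.seed).spawn(sc.R)
    hits = {(c, m): 0 for c in conventions for m in methods}
    for child in children:
        for conv in conventions:
            rng_rep = np.random.default_rng(child)  # same data for both conventions
            pvals = run_scenario_once(
                sc, rng_rep, methods=methods, scheme=scheme,
                cdf_include_observed=conv,
            )
            for m, p in pvals.items():
                hits[(conv, m)] += p < sc.alpha
    records = []
    for conv in conventions:
        for m in methods:
            rate = hits[(conv, m)] / sc.R
            records.append(
                {
                    "method": m,
                    "convention": "cdf_with_observed" if conv else "null_only",
                    "rate": rate,
                    "mc_se": _binom_se(rate, sc.R),
                    "R": sc.R,
                    "alpha": sc.alpha,
                }
            )
    df = pd.DataFrame(records)
    return df if both_conventions else df.drop(columns="convention")


def estimate_power(
    sc: Scenario,
    methods: Sequence[str] = METHODS,
    t1_grid: Sequence[int] = tuple(range(1, 31)),
    scheme: PartitionScheme | None = None,
    aauc_rule: str = "mean",
) -> PowerCurve:
    """Power across the T1 grid and its average (AAUC) per method.

    Each grid point runs R fresh replicates (new matrix, new signal rows, new
    permutations).  AAUC is the arithmetic mean of the grid's power values
    (``aauc_rule="trapezoid"`` uses the trapezoid rule normalised by the grid
    span instead; the difference is O(1/len(grid))).
    """
    if any(t < 1 for t in t1_grid):
        raise ValueError("power grid requires T1 >= 1")
    rng = np.random.default_rng(sc.seed)
    power = {}
    se = {}
    for t1 in t1_grid:
        sc_t1 = replace(sc, T1=int(t1))
        hits = {m: 0 for m in methods}
        for _ in range(sc.R):
            pvals = run_scenario_once(sc_t1, rng, methods=methods, scheme=scheme)
            for m, p in pvals.items():
                hits[m] += p < sc.alpha
        power[t1] = {m: hits[m] / sc.R for m in methods}
        se[t1] = {m: _binom_se(power[t1][m], sc.R) for m in methods}
    power_df = pd.DataFrame(power).T.loc[list(t1_grid), list(methods)]
    se_df = pd.DataFrame(se).T.loc[list(t1_grid), list(methods)]
    aauc_vals = {m: aauc(power_df[m].to_numpy(), rule=aauc_rule) for m in methods}
    return PowerCurve(tuple(int(t) for t in t1_grid), power_df, aauc_vals, se_df)


def aauc(power_values: Sequence[float], rule: str = "mean") -> float:
    """Average area under the power curve (area divided by grid length)."""
    v = np.asarray(power_values, dtype=float)
    if rule == "mean":
        return float(v.mean())
    if rule == "trapezoid":
        if v.size == 1:
            return float(v[0])
        return float(np.trapezoid(v, dx=1.0) / (v.size - 1))
    raise ValueError(f"unknown AAUC rule {rule!r}")


def plot_power_curve(curve: PowerCurve, path: str) -> None:
    """Save a power-vs-T1 plot (one line per method) to ``path`` (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method in curve.power.columns:
        ax.plot(curve.t1_grid, curve.power[method],
                label=f"{method} (AAUC {curve.aauc[method]:.3f})")
    ax.set_xlabel("signal genes T1")
    ax.set_ylabel("power at alpha")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def robustness_study(
    sc: Scenario,
    presets: dict[str, tuple] | None = None,
    t1_grid: Sequence[int] = tuple(range(1, 31)),
) -> pd.DataFrame:
    """AAUC of the multi-partition test under each partition preset.

    All presets are evaluated on the *same* replicates and permutation
    ensembles (the partition scheme only changes how the shared p-value
    ensemble is summarised), so the reported max-min spread isolates the
    effect of the preset choice.  Returns one row per preset plus the spread.
    """
    if presets is None:
        presets = PARTITION_PRESETS
    schemes = {name: PartitionScheme(c) for name, c in presets.items()}
    rng = np.random.default_rng(sc.seed)
    hits = {name: {t1: 0 for t1 in t1_grid} for name in schemes}
    for t1 in t1_grid:
        sc_t1 = replace(sc, T1=int(t1))
        for _ in range(sc.R):
            X, y, _ = simulate_dataset(sc_t1, rng)
            ph = dichotomize_phenotype(y)
            perm_seed = int(rng.integers(2**31 - 1))
            ens = permuted_pvalues(X, ph, B=sc.B, seed=perm_seed, test=sc.test)
            for name, scheme in schemes.items():
                res = run_all(ens, methods=("rpcmp",), scheme=scheme)
                hits[name][t1] += res["rpcmp"].p_adjusted < sc.alpha
    records = []
    for name in schemes:
        curve = [hits[name][t1] / sc.R for t1 in t1_grid]
        records.append({"preset": name, "aauc": aauc(curve)})
    df = pd.DataFrame(records)
    df["spread"] = df["aauc"].max() - df["aauc"].min()
    return df
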