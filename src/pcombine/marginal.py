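"""Per-gene marginal tests and the permutation ensemble of their p-values.

A gene-set test starts from an ``m x N`` expression matrix and a binary
phenotype.  Each gene is scored by a two-sample test (Student's t by default,
a normal-approximation Wilcoxon rank-sum as the robust alternative), and the
null distribution of everything downstream is obtained by recomputing those
per-gene p-values under ``B`` random permutations of the phenotype labels.

The permutation loop is the hot path of the whole package, so both tests are
vectorized over all ``B + 1`` label vectors at once: for a binary label matrix
``Z`` the group sums needed by the t statistic are ``X @ Z.T`` and
``(X**2) @ Z.T``, and the rank-sum statistic is ``ranks @ Z.T`` with the gene
ranks computed a single time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Phenotype",
    "NullEnsemble",
    "MAX_PERMUTATIONS",
    "dichotomize_phenotype",
    "marginal_pvalues",
    "permuted_pvalues",
]

#: Guard against accidentally astronomical permutation counts.
MAX_PERMUTATIONS = 10**6


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes-by-samples numeric matrix with identifier metadata.

    ``values`` has one row per gene and one column per sample; no missing
    values are allowed and gene identifiers must be unique.
    """

    values: np.ndarray = field(repr=False)
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 2:
            raise ValueError("expression matrix must be m x N with m >= 1, N >= 2")
        if np.any(~np.isfinite(v)):
            raise ValueError("expression matrix contains missing/non-finite values")
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(gene_ids) != v.shape[0] or len(sample_ids) != v.shape[1]:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene identifiers must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_arrays(cls, values, gene_ids=None, sample_ids=None) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[0])]
        if sample_ids is None:
            sample_ids = [f"s{j}" for j in range(values.shape[1])]
        return cls(values, tuple(gene_ids), tuple(sample_ids))

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset by gene identifier, preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], tuple(gene_ids), self.sample_ids)


@dataclass(frozen=True)
class Phenotype:
    """Binary group labels for the samples, optionally with the raw values
    they were dichotomized from."""

    labels: np.ndarray
    raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if labels.sum() == 0 or labels.sum() == labels.size:
            raise ValueError("both phenotype groups must be non-empty")
        object.__setattr__(self, "labels", labels)
        if self.raw is not None:
            raw = np.asarray(self.raw, dtype=float)
            if raw.shape != labels.shape:
                raise ValueError("raw phenotype length must match labels")
            object.__setattr__(self, "raw", raw)

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class NullEnsemble:
    """(B+1) x m matrix of per-gene p-values; row 0 is the observed phenotype,
    rows 1..B come from random label permutations."""

    pmat: np.ndarray = field(repr=False)
    B: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pmat = np.asarray(self.pmat, dtype=float)
        if pmat.ndim != 2 or pmat.shape[0] != self.B + 1:
            raise ValueError("pmat must have B + 1 rows")
        if np.any(pmat <= 0.0) or np.any(pmat > 1.0):
            raise ValueError("ensemble p-values must lie in (0, 1]")
        object.__setattr__(self, "pmat", pmat)

    @property
    def n_genes(self) -> int:
        return self.pmat.shape[1]

    def subset_genes(self, columns: Sequence[int]) -> "NullEnsemble":
        """Column-subset (e.g. to one gene set); permutations are shared, so
        this equals rebuilding the ensemble from the row-subset matrix."""
        return NullEnsemble(self.pmat[:, list(columns)], self.B, self.seed)


def dichotomize_phenotype(raw: Sequence[float]) -> Phenotype:
    """Median-split a continuous phenotype into two groups.

    Samples strictly above the median get label 1.  If ties at the median
    empty one group, tied samples are reassigned in stable order until both
    groups are populated.  All-identical values are rejected.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 4:
        raise ValueError("need at least 4 phenotype values")
    if np.any(~np.isfinite(raw)):
        raise ValueError("phenotype contains non-finite values")
    if np.all(raw == raw[0]):
        raise ValueError("degenerate phenotype: all values identical")
    med = float(np.median(raw))
    labels = (raw > med).astype(int)
    if labels.sum() == 0:
        # everything <= median: move the trailing half of the tied samples up
        tied = np.flatnonzero(raw == med)
        k = max(1, tied.size // 2)
        labels[tied[-k:]] = 1
    elif labels.sum() == labels.size:  # pragma: no cover - needs NaN-free raw > med everywhere
        tied = np.flatnonzero(raw == med)
        k = max(1, tied.size // 2)
        labels[tied[:k]] = 0
    return Phenotype(labels=labels, raw=raw)


def _t_pvalues_rows(
    X: np.ndarray, label_rows: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Two-sided two-sample t p-values for every (gene, label row) pair.

    Returns an ``R x m`` array for an ``m x N`` matrix and ``R x N`` binary
    label matrix.  Genes with zero within-group variance get p = 1.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(label_rows, dtype=float)
    m, N = X.shape
    n1 = Z.sum(axis=1)  # (R,)
    n0 = N - n1
    if np.any(n1 < 2) or np.any(n0 < 2):
        raise ValueError("each group needs at least 2 samples for the t test")
    X2 = X * X
    S1 = X @ Z.T  # (m, R)
    Q1 = X2 @ Z.T
    S = X.sum(axis=1, keepdims=True)
    Q = X2.sum(axis=1, keepdims=True)
    S0 = S - S1
    Q0 = Q - Q1
    mean1 = S1 / n1
    mean0 = S0 / n0
    # centered sums of squares; clip tiny negative values from cancellation
    ss1 = np.clip(Q1 - S1 * S1 / n1, 0.0, None)
    ss0 = np.clip(Q0 - S0 * S0 / n0, 0.0, None)
    diff = mean1 - mean0
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            v1 = ss1 / np.maximum(n1 - 1, 1)
            v0 = ss0 / np.maximum(n0 - 1, 1)
            se2 = v1 / n1 + v0 / n0
            df = se2**2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
                + (v0 / n0) ** 2 / np.maximum(n0 - 1, 1)
            )
            t = diff / np.sqrt(se2)
        else:
            pooled = (ss1 + ss0) / (N - 2)
            se2 = pooled * (1.0 / n1 + 1.0 / n0)
            df = np.full_like(se2, N - 2)
            t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance carries no evidence against the null
    degenerate = se2 <= 0.0
    if np.any(degenerate):
        n_bad = int(np.count_nonzero(degenerate.any(axis=1)))
        logger.debug("%d gene(s) with zero pooled variance; p set to 1", n_bad)
        p = np.where(degenerate, 1.0, p)
    return np.minimum(p, 1.0).T


def _pearson_pvalues_rows(X: np.ndarray, pheno_rows: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the Pearson-correlation t test for every
    (gene, phenotype row) pair.

    The statistic ``t = r * sqrt((N-2)/(1-r^2))`` is Student-t with ``N - 2``
    degrees of freedom; with a binary 0/1 phenotype it coincides with the
    pooled two-sample t test (point-biserial correlation).  Unlike the label
    tests this keeps the magnitude of a continuous phenotype.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(pheno_rows, dtype=float)
    N = X.shape[1]
    if N < 4:
        raise ValueError("pearson test needs N >= 4")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    ynorm = np.sqrt((Yc**2).sum(axis=1))
    den = xnorm[:, None] * ynorm[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip((Xc @ Yc.T) / den, -1.0, 1.0)
        t = r * np.sqrt((N - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), N - 2)
    p = np.where(den <= 0.0, 1.0, p)  # constant gene or constant phenotype
    return np.minimum(p, 1.0).T


def _wilcoxon_pvalues_rows(X: np.ndarray, label_rows: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values (normal approximation with tie
    correction and continuity correction) for every (gene, label row) pair."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(label_rows, dtype=float)
    m, N = X.shape
    n1 = Z.sum(axis=1)
    n0 = N - n1
    ranks = stats.rankdata(X, axis=1)  # midranks, fixed across permutations
    R1 = ranks @ Z.T  # (m, R)
    mu = n1 * (N + 1) / 2.0
    # tie correction per gene
    tie_term = np.zeros(m)
    for i in range(m):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = float((counts**3 - counts).sum())
    var = (n1 * n0 / 12.0) * ((N + 1) - tie_term[:, None] / (N * (N - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(R1 - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.clip(z, 0.0, None))
    p = np.where(var <= 0.0, 1.0, p)
    return np.minimum(p, 1.0).T


def marginal_pvalues(
    X: ExpressionMatrix,
    ph: Phenotype,
    test: str = "t",
    welch: bool = False,
    clamp: float = 1e-300,
) -> np.ndarray:
    """Two-sided per-gene p-values for the observed phenotype.

    ``test`` is ``"t"`` (Student's pooled-variance two-sample t, or Welch if
    ``welch=True``), ``"wilcoxon"``, or ``"pearson"`` (correlation t test on
    the continuous phenotype when available, labels otherwise).  Exact zeros
    are clamped to ``clamp`` so downstream log transforms stay finite.
    """
    if X.n_samples != ph.n_samples:
        raise ValueError("phenotype length does not match sample count")
    Z = ph.labels[None, :]
    if test == "t":
        p = _t_pvalues_rows(X.values, Z, welch=welch)[0]
    elif test == "wilcoxon":
        p = _wilcoxon_pvalues_rows(X.values, Z)[0]
    elif test == "pearson":
        y = ph.raw if ph.raw is not None else ph.labels.astype(float)
        p = _pearson_pvalues_rows(X.values, y[None, :])[0]
    else:
        raise ValueError(f"unknown test {test!r}")
    return np.clip(p, clamp, 1.0)


def permuted_pvalues(
    X: ExpressionMatrix,
    ph: Phenotype,
    B: int,
    seed: Optional[int] = None,
    test: str = "t",
    welch: bool = False,
) -> NullEnsemble:
    """Observed plus B label-permutation p-value vectors as one ensemble.

    Permutations are uniform random shuffles of the observed labels, generated
    from a Philox counter stream keyed by ``seed`` (reproducible and
    independent of chunking).  Exact-zero p-values are clamped to
    ``1 / (10 (B + 1))`` so that log-based combiners remain finite.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B > MAX_PERMUTATIONS:
        raise ValueError(f"B={B} exceeds the configured maximum {MAX_PERMUTATIONS}")
    if X.n_samples != ph.n_samples:
        raise ValueError("phenotype length does not match sample count")
    rng = np.random.Generator(np.random.Philox(key=0 if seed is None else seed))
    N = X.n_samples
    keys = rng.random((B, N))
    order = np.argsort(keys, axis=1)
    if test == "pearson":
        y = ph.raw if ph.raw is not None else ph.labels.astype(float)
    else:
        y = ph.labels
    Z = np.empty((B + 1, N), dtype=float)
    Z[0] = y
    Z[1:] = y[order]
    if test == "t":
        pmat = _t_pvalues_rows(X.values, Z, welch=welch)
    elif test == "wilcoxon":
        pmat = _wilcoxon_pvalues_rows(X.values, Z)
    elif test == "pearson":
        pmat = _pearson_pvalues_rows(X.values, Z)
    else:
        raise ValueError(f"unknown test {test!r}")
    floor = 1.0 / (10.0 * (B + 1))
    zeros = pmat == 0.0
    if np.any(zeros):
        warnings.warn(
            f"{int(np.count_nonzero(zeros))} exact-zero p-value(s) clamped to "
            f"{floor:g}",
            stacklevel=2,
        )
        pmat = np.where(zeros, floor, pmat)
    return NullEnsemble(pmat=pmat, B=B, seed=seed)
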