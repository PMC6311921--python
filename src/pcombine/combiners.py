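"""Pure p-value combination kernels.

The statistics here operate on a single vector of per-gene p-values and are
deliberately free of any permutation machinery: the empirical CDFs that the
group-combined (GCP) and multi-partition (rPCMP) statistics require are passed
in, so the same kernels serve both the observed data and every permuted
replicate scored by :mod:`pcombine.engine`.

Conventions
-----------
* All p-values live in ``(0, 1]``; a zero p-value is rejected because every
  combiner takes logs.
* Partition intervals are left-open, right-closed: a p-value equal to a cutoff
  belongs to the group below it.
* Empirical CDFs use the ``#{v <= x} / (n + 1)`` estimator so that ``1 - F``
  never vanishes and products of survival factors stay strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PartitionScheme",
    "EmpiricalCDF",
    "DEFAULT_PARTITIONS",
    "PARTITION_PRESETS",
    "DEFAULT_GCP_CUTOFFS",
    "DEFAULT_TPM_XI",
    "DEFAULT_ARTP_KS",
    "fisher_statistic",
    "fct_pvalue",
    "tpm_statistic",
    "rtp_statistic",
    "artp_minp",
    "group_sums",
    "gcp_statistic",
    "rpcmp_statistic",
]

#: The five cutoff vectors used jointly by the multi-partition statistic.
DEFAULT_PARTITIONS: tuple[tuple[float, ...], ...] = (
    (0.01, 0.1),
    (0.001, 0.05),
    (0.01, 0.05),
    (0.001, 0.01, 0.1),
    (0.001, 0.01, 0.05),
)

#: Single-partition cutoffs used by the plain group-combined statistic.
DEFAULT_GCP_CUTOFFS: tuple[float, ...] = (0.001, 0.05)

#: Truncation threshold for the truncated product method.
DEFAULT_TPM_XI: float = 0.5

#: Candidate truncation ranks for the adaptive rank truncated product.
DEFAULT_ARTP_KS: tuple[int, ...] = tuple(range(1, 11))


def _leave_one_out_presets() -> dict[str, tuple[tuple[float, ...], ...]]:
    presets: dict[str, tuple[tuple[float, ...], ...]] = {"set0": DEFAULT_PARTITIONS}
    for i in range(len(DEFAULT_PARTITIONS)):
        presets[f"set{i + 1}"] = tuple(
            c for j, c in enumerate(DEFAULT_PARTITIONS) if j != i
        )
    return presets


#: ``set0`` is the full five-partition default; ``set1``..``set5`` drop one
#: partition each (robustness study presets).
PARTITION_PRESETS: dict[str, tuple[tuple[float, ...], ...]] = _leave_one_out_presets()


@dataclass(frozen=True)
class PartitionScheme:
    """L ordered cutoff vectors partitioning ``(0, 1]`` into interval groups.

    Each cutoff vector ``0 < xi_1 < ... < xi_J < 1`` defines ``J`` groups
    ``(xi_{j-1}, xi_j]`` (with ``xi_0 = 0``) plus, when ``terminal_group`` is
    set, a closing group ``(xi_J, 1]`` so every p-value belongs to exactly one
    group.  Dropping the terminal group reproduces the narrower reading in
    which p-values above the last cutoff are discarded.
    """

    cutoffs: tuple[tuple[float, ...], ...]
    terminal_group: bool = True

    def __post_init__(self) -> None:
        if len(self.cutoffs) < 1:
            raise ValueError("PartitionScheme needs at least one partition")
        norm = []
        for vec in self.cutoffs:
            v = tuple(float(x) for x in vec)
            if len(v) < 1:
                raise ValueError("each partition needs at least one cutoff")
            if any(not (0.0 < x < 1.0) for x in v):
                raise ValueError(f"cutoffs must lie in (0, 1): {v}")
            if any(b <= a for a, b in zip(v, v[1:])):
                raise ValueError(f"cutoffs must be strictly increasing: {v}")
            norm.append(v)
        object.__setattr__(self, "cutoffs", tuple(norm))

    @property
    def n_partitions(self) -> int:
        return len(self.cutoffs)

    def edges(self, l: int) -> np.ndarray:
        """Interval edges ``[0, xi_1, ..., xi_J(, 1)]`` for partition ``l``."""
        vec = self.cutoffs[l]
        hi = (1.0,) if self.terminal_group else ()
        return np.asarray((0.0, *vec, *hi), dtype=float)

    def n_groups(self, l: int) -> int:
        return len(self.cutoffs[l]) + (1 if self.terminal_group else 0)

    @classmethod
    def preset(cls, name: str, terminal_group: bool = True) -> "PartitionScheme":
        try:
            return cls(PARTITION_PRESETS[name], terminal_group=terminal_group)
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PARTITION_PRESETS)}"
            ) from None


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF ``F(x) = #{v <= x} / (n + 1)``.

    The ``n + 1`` denominator keeps ``1 - F(x)`` strictly positive even at the
    sample maximum, which the product-form statistics below rely on.
    """

    sorted_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.sorted_values, dtype=float))
        if v.size < 1:
            raise ValueError("empirical CDF needs at least one value")
        object.__setattr__(self, "sorted_values", v)

    @property
    def n(self) -> int:
        return int(self.sorted_values.size)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        counts = np.searchsorted(self.sorted_values, x, side="right")
        return counts / (self.n + 1)


def _checked_pvalues(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("expected a non-empty 1-D p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def fisher_statistic(p: Sequence[float]) -> float:
    """Fisher's combined statistic ``Phi = -2 * sum(log p_i)`` (>= 0)."""
    p = _checked_pvalues(p)
    return float(-2.0 * np.log(p).sum())


def fct_pvalue(p: Sequence[float]) -> float:
    """Analytic Fisher combination p-value.

    Under independence ``Phi`` is chi-squared with ``2m`` degrees of freedom;
    returns its upper tail.  For correlated p-values prefer the permutation
    version in :func:`pcombine.engine.run_fct`.
    """
    p = _checked_pvalues(p)
    return float(stats.chi2.sf(fisher_statistic(p), df=2 * p.size))


def tpm_statistic(p: Sequence[float], xi: float = DEFAULT_TPM_XI) -> float:
    """Truncated product ``W = prod p_i^{1[p_i <= xi]}``; small is significant.

    P-values above the threshold contribute a factor of one, so a vector with
    nothing at or below ``xi`` yields the empty product ``W = 1``.
    """
    p = _checked_pvalues(p)
    if not (0.0 < xi < 1.0):
        raise ValueError("xi must lie in (0, 1)")
    return float(np.exp(np.log(p, where=p <= xi, out=np.zeros_like(p)).sum()))


def rtp_statistic(p: Sequence[float], K: int) -> float:
    """Rank truncated product of the ``K`` smallest p-values."""
    p = _checked_pvalues(p)
    if not (1 <= K <= p.size):
        raise ValueError(f"K must be in [1, {p.size}], got {K}")
    smallest = np.sort(p)[:K]
    return float(np.exp(np.log(smallest).sum()))


def artp_minp(s: Sequence[float]) -> float:
    """Minimum over the per-truncation empirical p-values (ARTP's MinP)."""
    s = np.asarray(s, dtype=float)
    if s.size < 1:
        raise ValueError("artp_minp needs at least one per-truncation p-value")
    if np.any(s <= 0.0) or np.any(s > 1.0):
        raise ValueError("per-truncation p-values must lie in (0, 1]")
    return float(s.min())


def group_sums(p: Sequence[float], scheme: PartitionScheme) -> list[np.ndarray]:
    """Per-group statistics ``S_{j,l} = -2 sum log p_i 1{xi_{j-1} < p_i <= xi_j}``.

    Returns one array per partition ``l`` with entries ordered by group.  With
    the terminal group enabled the groups tile ``(0, 1]``, so for every
    partition ``sum_j S_{j,l}`` equals :func:`fisher_statistic` exactly.
    """
    p = _checked_pvalues(p)
    neg2logp = -2.0 * np.log(p)
    out = []
    for l in range(scheme.n_partitions):
        edges = scheme.edges(l)
        # right-closed intervals: p == cutoff goes to the lower group
        idx = np.searchsorted(edges, p, side="left") - 1
        n_groups = scheme.n_groups(l)
        keep = (idx >= 0) & (idx < n_groups)
        sums = np.bincount(idx[keep], weights=neg2logp[keep], minlength=n_groups)
        out.append(sums[:n_groups])
    return out


def gcp_statistic(S_l: Sequence[float], cdfs: Sequence[EmpiricalCDF]) -> float:
    """Group-combined p-value ``GCP_l = prod_j (1 - F_{j,l}(S_{j,l}))``.

    ``cdfs`` are the null CDFs of the per-group sums, one per group, built
    from a permutation ensemble.  Small values are significant.
    """
    S_l = np.asarray(S_l, dtype=float)
    if len(cdfs) != S_l.size:
        raise ValueError(f"expected {S_l.size} CDFs, got {len(cdfs)}")
    factors = [1.0 - F(S) for F, S in zip(cdfs, S_l)]
    return float(np.prod(factors))


def rpcmp_statistic(gcp_values: Sequence[float], cdfs: Sequence[EmpiricalCDF]) -> float:
    """Multi-partition statistic ``rPCMP = prod_l (1 - G_l(GCP_l))``.

    ``G_l`` is the null CDF of the l-th partition's group-combined value.  A
    very significant partition has a small ``GCP_l``, hence ``G_l`` near zero
    and a factor near one: large rPCMP values are significant.
    """
    gcp_values = np.asarray(gcp_values, dtype=float)
    if len(cdfs) != gcp_values.size:
        raise ValueError(f"expected {gcp_values.size} CDFs, got {len(cdfs)}")
    factors = [1.0 - G(g) for G, g in zip(cdfs, gcp_values)]
    return float(np.prod(factors))
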