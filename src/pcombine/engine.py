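"""Single-layer permutation engine for all five group tests.

The multi-partition statistic nests three empirical distributions (per-group
sums, per-partition group-combined values, and the outer product), which a
literal implementation would estimate with three nested permutation rounds.
Instead, one shared ensemble of ``B`` phenotype permutations supplies every
layer: the null CDFs are built from the permutation rows and then *every* row
— including each permutation itself — is scored against them.  That deliberate
reuse is what makes the three-layer statistic estimable in a single pass, and
the same ensemble drives the Fisher, truncated-product, rank-truncated and
group-combined baselines so that method comparisons share one set of
permutations.

Adjusted p-values use the ``(1 + #extreme) / (B + 1)`` counting rule with ties
counted as extreme, so every reported p-value lies in ``[1/(B+1), 1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .combiners import (
    DEFAULT_ARTP_KS,
    DEFAULT_GCP_CUTOFFS,
    DEFAULT_PARTITIONS,
    DEFAULT_TPM_XI,
    PartitionScheme,
)
from .marginal import NullEnsemble

__all__ = [
    "CombinerResult",
    "LayerDiagnostics",
    "run_fct",
    "run_tpm",
    "run_artp",
    "run_gcp",
    "run_rpcmp",
    "run_all",
    "results_table",
]

METHODS = ("fct", "tpm", "artp", "gcp", "rpcmp")


@dataclass(frozen=True)
class CombinerResult:
    """Outcome of one combination method on one ensemble."""

    method: str
    statistic: float
    direction: str  # "small_is_significant" | "large_is_significant"
    p_adjusted: float
    B: int
    null_statistics: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass(frozen=True)
class LayerDiagnostics:
    """All three layers of the multi-partition statistic, for every ensemble
    row (row 0 observed).  Useful for plotting the stacked null
    distributions."""

    group_sums: tuple[np.ndarray, ...]  # per partition: (B+1, J_l) arrays
    gcp: np.ndarray  # (B+1, L)
    rpcmp: np.ndarray  # (B+1,)
    scheme: PartitionScheme

    def frames(self) -> dict[str, pd.DataFrame]:
        """Tidy data frames (one per layer) for export or plotting."""
        rows = []
        for l, S in enumerate(self.group_sums):
            for j in range(S.shape[1]):
                rows.append(
                    pd.DataFrame(
                        {
                            "partition": l,
                            "group": j,
                            "row": np.arange(S.shape[0]),
                            "value": S[:, j],
                        }
                    )
                )
        inner = pd.concat(rows, ignore_index=True)
        mid = pd.concat(
            [
                pd.DataFrame(
                    {
                        "partition": l,
                        "row": np.arange(self.gcp.shape[0]),
                        "value": self.gcp[:, l],
                    }
                )
                for l in range(self.gcp.shape[1])
            ],
            ignore_index=True,
        )
        outer = pd.DataFrame({"row": np.arange(self.rpcmp.size), "value": self.rpcmp})
        return {"group_sums": inner, "gcp": mid, "rpcmp": outer}


def _group_sum_matrix(
    pmat: np.ndarray, scheme: PartitionScheme, l: int
) -> np.ndarray:
    """(B+1) x J_l matrix of -2*sum(log p) over each interval group."""
    edges = scheme.edges(l)
    n_groups = scheme.n_groups(l)
    neg2logp = -2.0 * np.log(pmat)
    idx = np.searchsorted(edges, pmat, side="left") - 1  # group index per entry
    keep = (idx >= 0) & (idx < n_groups)
    # accumulate row-wise: flatten (row, group) to one bincount
    flat = np.where(keep, idx, 0) + n_groups * np.arange(pmat.shape[0])[:, None]
    weights = np.where(keep, neg2logp, 0.0)
    out = np.bincount(
        flat.ravel(), weights=weights.ravel(), minlength=n_groups * pmat.shape[0]
    ).reshape(pmat.shape[0], n_groups)
    return out


def _ecdf_columns(values: np.ndarray, null_rows: slice) -> np.ndarray:
    """Evaluate, per column, the null ECDF ``#{v <= x}/(n+1)`` at every row.

    ``values`` is (B+1, G); the CDF of each column is built from
    ``values[null_rows]`` and evaluated at all B+1 rows of that column.
    """
    null_vals = values[null_rows]
    n = null_vals.shape[0]
    out = np.empty_like(values)
    for g in range(values.shape[1]):
        sv = np.sort(null_vals[:, g])
        out[:, g] = np.searchsorted(sv, values[:, g], side="right") / (n + 1)
    return out


def _null_slice(B: int, include_observed: bool) -> slice:
    return slice(0, B + 1) if include_observed else slice(1, B + 1)


def _empirical_p(null_stats: np.ndarray, observed: float, direction: str) -> float:
    if direction == "large_is_significant":
        extreme = int(np.count_nonzero(null_stats >= observed))
    else:
        extreme = int(np.count_nonzero(null_stats <= observed))
    return (1 + extreme) / (null_stats.size + 1)


def _check_degenerate(ens: NullEnsemble) -> bool:
    if np.all(ens.pmat == ens.pmat[0]):
        warnings.warn("degenerate ensemble: all rows identical; p_adjusted = 1")
        return True
    return False


def run_fct(ens: NullEnsemble) -> CombinerResult:
    """Permutation Fisher combination test: Phi = -2*sum(log p), large
    significant."""
    phi = -2.0 * np.log(ens.pmat).sum(axis=1)
    p_adj = 1.0 if _check_degenerate(ens) else _empirical_p(
        phi[1:], phi[0], "large_is_significant"
    )
    return CombinerResult("fct", float(phi[0]), "large_is_significant", p_adj,
                          ens.B, phi[1:])


def run_tpm(ens: NullEnsemble, xi: float = DEFAULT_TPM_XI) -> CombinerResult:
    """Permutation truncated product method at threshold ``xi``; small
    significant.  Comparisons run on log W to avoid underflow."""
    if not (0.0 < xi < 1.0):
        raise ValueError("xi must lie in (0, 1)")
    logp = np.log(ens.pmat)
    logW = np.where(ens.pmat <= xi, logp, 0.0).sum(axis=1)
    p_adj = 1.0 if _check_degenerate(ens) else _empirical_p(
        logW[1:], logW[0], "small_is_significant"
    )
    return CombinerResult("tpm", float(np.exp(logW[0])), "small_is_significant",
                          p_adj, ens.B, logW[1:])


def run_artp(
    ens: NullEnsemble, Ks: Sequence[int] = DEFAULT_ARTP_KS
) -> CombinerResult:
    """Adaptive rank truncated product over candidate truncation ranks ``Ks``.

    For each K the per-row statistic is the product of the K smallest
    p-values (held in log space); its empirical p-value ``s_K`` is the
    fraction of permutation rows with a product at least as small, and the
    reported statistic is ``MinP = min_K s_K`` with its own permutation
    adjustment.
    """
    Ks = tuple(int(k) for k in Ks)
    m = ens.n_genes
    if len(Ks) < 1 or any(not (1 <= k <= m) for k in Ks):
        raise ValueError(f"Ks must be non-empty and within [1, {m}]")
    logp_sorted = np.sort(np.log(ens.pmat), axis=1)
    cums = np.cumsum(logp_sorted, axis=1)
    logW = cums[:, [k - 1 for k in Ks]]  # (B+1, L)
    s = np.empty_like(logW)
    for col in range(logW.shape[1]):
        sv = np.sort(logW[1:, col])
        s[:, col] = np.searchsorted(sv, logW[:, col], side="right") / (ens.B + 1)
    minp = s.min(axis=1)
    p_adj = 1.0 if _check_degenerate(ens) else _empirical_p(
        minp[1:], minp[0], "small_is_significant"
    )
    return CombinerResult("artp", float(minp[0]), "small_is_significant", p_adj,
                          ens.B, minp[1:])


def _gcp_layers(
    ens: NullEnsemble, scheme: PartitionScheme, include_observed: bool
) -> tuple[tuple[np.ndarray, ...], np.ndarray]:
    """Group-sum matrices and the (B+1, L) matrix of group-combined values."""
    rows = _null_slice(ens.B, include_observed)
    all_S = []
    gcp = np.empty((ens.B + 1, scheme.n_partitions))
    for l in range(scheme.n_partitions):
        S = _group_sum_matrix(ens.pmat, scheme, l)
        F = _ecdf_columns(S, rows)
        gcp[:, l] = np.prod(1.0 - F, axis=1)
        all_S.append(S)
    return tuple(all_S), gcp


def run_gcp(
    ens: NullEnsemble,
    cutoffs: Sequence[float] = DEFAULT_GCP_CUTOFFS,
    terminal_group: bool = True,
    cdf_include_observed: bool = False,
) -> CombinerResult:
    """Group-combined p-value for a single cutoff vector; small significant.

    Each interval group's ``-2*sum(log p)`` is referred to its permutation
    null CDF; the statistic is the product of the survival factors.
    """
    scheme = PartitionScheme((tuple(cutoffs),), terminal_group=terminal_group)
    _, gcp = _gcp_layers(ens, scheme, cdf_include_observed)
    vals = gcp[:, 0]
    p_adj = 1.0 if _check_degenerate(ens) else _empirical_p(
        vals[1:], vals[0], "small_is_significant"
    )
    return CombinerResult("gcp", float(vals[0]), "small_is_significant", p_adj,
                          ens.B, vals[1:])


def run_rpcmp(
    ens: NullEnsemble,
    scheme: PartitionScheme | None = None,
    min_B: int = 20,
    cdf_include_observed: bool = False,
) -> tuple[CombinerResult, LayerDiagnostics]:
    """Multi-partition statistic with the single-layer permutation null.

    Steps: (1) per-group sums for every ensemble row; (2) per-(partition,
    group) null CDFs from the permutation rows; (3) group-combined value per
    row; (4) per-partition null CDFs of those values; (5) the outer product
    per row; (6) adjusted p by counting permutation rows with a statistic at
    least as large as the observed one.

    ``cdf_include_observed=True`` also feeds row 0 into the CDFs, which makes
    all B+1 rows exchangeable (a sensitivity check on the layer reuse).
    """
    if scheme is None:
        scheme = PartitionScheme(DEFAULT_PARTITIONS)
    if ens.B < min_B:
        raise ValueError(f"B={ens.B} below the practical floor {min_B}")
    rows = _null_slice(ens.B, cdf_include_observed)
    all_S, gcp = _gcp_layers(ens, scheme, cdf_include_observed)
    G = _ecdf_columns(gcp, rows)
    rpcmp = np.prod(1.0 - G, axis=1)
    p_adj = 1.0 if _check_degenerate(ens) else _empirical_p(
        rpcmp[1:], rpcmp[0], "large_is_significant"
    )
    result = CombinerResult("rpcmp", float(rpcmp[0]), "large_is_significant",
                            p_adj, ens.B, rpcmp[1:])
    return result, LayerDiagnostics(all_S, gcp, rpcmp, scheme)


def run_all(
    ens: NullEnsemble,
    methods: Sequence[str] = METHODS,
    scheme: PartitionScheme | None = None,
    gcp_cutoffs: Sequence[float] = DEFAULT_GCP_CUTOFFS,
    tpm_xi: float = DEFAULT_TPM_XI,
    artp_Ks: Sequence[int] = DEFAULT_ARTP_KS,
    cdf_include_observed: bool = False,
) -> dict[str, CombinerResult]:
    """Run the requested methods on one shared ensemble (identical
    permutations for every method)."""
    out: dict[str, CombinerResult] = {}
    for method in methods:
        if method == "fct":
            out[method] = run_fct(ens)
        elif method == "tpm":
            out[method] = run_tpm(ens, xi=tpm_xi)
        elif method == "artp":
            Ks = tuple(k for k in artp_Ks if k <= ens.n_genes) or (1,)
            out[method] = run_artp(ens, Ks=Ks)
        elif method == "gcp":
            out[method] = run_gcp(
                ens, cutoffs=gcp_cutoffs, cdf_include_observed=cdf_include_observed
            )
        elif method == "rpcmp":
            out[method], _ = run_rpcmp(
                ens, scheme=scheme, cdf_include_observed=cdf_include_observed
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def results_table(
    results: dict[str, CombinerResult], set_id: str = "-", seed=None
) -> pd.DataFrame:
    """Tidy one-row-per-method results table."""
    return pd.DataFrame(
        [
            {
                "set_id": set_id,
                "method": r.method,
                "statistic": r.statistic,
                "p_adjusted": r.p_adjusted,
                "B": r.B,
                "seed": seed,
            }
            for r in results.values()
        ]
    )
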