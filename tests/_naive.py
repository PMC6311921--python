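"""Literal, loop-based reimplementation of every combiner and counting rule.

This is the independent oracle for the vectorized engine: plain Python
loops, explicit interval membership checks and explicit count-based CDFs,
kept deliberately free of numpy vectorization tricks.  Only suitable for
tiny ensembles (B <= a few dozen, m <= a few dozen).
"""

import math


def naive_ecdf(values, x):
    return sum(1 for v in values if v <= x) / (len(values) + 1)


def naive_fisher(p):
    return -2.0 * sum(math.log(pi) for pi in p)


def naive_tpm(p, xi):
    w = 1.0
    for pi in p:
        if pi <= xi:
            w *= pi
    return w


def naive_log_tpm(p, xi):
    return sum(math.log(pi) for pi in p if pi <= xi)


def naive_rtp_log(p, K):
    return sum(math.log(pi) for pi in sorted(p)[:K])


def naive_group_sums(p, cutoffs, terminal=True):
    edges = [0.0] + list(cutoffs) + ([1.0] if terminal else [])
    S = [0.0] * (len(edges) - 1)
    for pi in p:
        for j in range(len(edges) - 1):
            if edges[j] < pi <= edges[j + 1]:
                S[j] += -2.0 * math.log(pi)
    return S


def naive_fct_run(pmat):
    B = len(pmat) - 1
    phi = [naive_fisher(row) for row in pmat]
    count = sum(1 for b in range(1, B + 1) if phi[b] >= phi[0])
    return phi, (1 + count) / (B + 1)


def naive_tpm_run(pmat, xi):
    B = len(pmat) - 1
    lw = [naive_log_tpm(row, xi) for row in pmat]
    count = sum(1 for b in range(1, B + 1) if lw[b] <= lw[0])
    return lw, (1 + count) / (B + 1)


def naive_artp_run(pmat, Ks):
    B = len(pmat) - 1
    logW = [[naive_rtp_log(row, K) for K in Ks] for row in pmat]
    s = [
        [
            sum(1 for b2 in range(1, B + 1) if logW[b2][k] <= logW[b][k]) / (B + 1)
            for k in range(len(Ks))
        ]
        for b in range(B + 1)
    ]
    minp = [min(row) for row in s]
    count = sum(1 for b in range(1, B + 1) if minp[b] <= minp[0])
    return minp, (1 + count) / (B + 1)


def naive_gcp_values(pmat, partitions, include_observed=False, terminal=True):
    """Per-row group-combined value for each partition's cutoff vector."""
    B = len(pmat) - 1
    null_idx = list(range(0, B + 1)) if include_observed else list(range(1, B + 1))
    gcp = [[None] * len(partitions) for _ in range(B + 1)]
    all_S = []
    for l, cutoffs in enumerate(partitions):
        S_rows = [naive_group_sums(row, cutoffs, terminal) for row in pmat]
        all_S.append(S_rows)
        for b in range(B + 1):
            prod = 1.0
            for j in range(len(S_rows[0])):
                null_vals = [S_rows[b2][j] for b2 in null_idx]
                prod *= 1.0 - naive_ecdf(null_vals, S_rows[b][j])
            gcp[b][l] = prod
    return all_S, gcp


def naive_gcp_run(pmat, cutoffs, include_observed=False, terminal=True):
    B = len(pmat) - 1
    _, gcp = naive_gcp_values(pmat, [cutoffs], include_observed, terminal)
    vals = [row[0] for row in gcp]
    count = sum(1 for b in range(1, B + 1) if vals[b] <= vals[0])
    return vals, (1 + count) / (B + 1)


def naive_rpcmp_run(pmat, partitions, include_observed=False, terminal=True):
    B = len(pmat) - 1
    null_idx = list(range(0, B + 1)) if include_observed else list(range(1, B + 1))
    all_S, gcp = naive_gcp_values(pmat, partitions, include_observed, terminal)
    rp = []
    for b in range(B + 1):
        prod = 1.0
        for l in range(len(partitions)):
            null_vals = [gcp[b2][l] for b2 in null_idx]
            prod *= 1.0 - naive_ecdf(null_vals, gcp[b][l])
        rp.append(prod)
    count = sum(1 for b in range(1, B + 1) if rp[b] >= rp[0])
    return all_S, gcp, rp, (1 + count) / (B + 1)
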