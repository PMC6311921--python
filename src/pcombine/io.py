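"""File I/O and the real-data gene-set testing workflow.

Supports the delimited-text formats the field actually exchanges: a
genes-by-samples expression matrix (TSV/CSV, gene identifiers in the first
column, sample identifiers in the header), a two-column phenotype table, and
gene sets in GMT.  The workflow computes one shared permutation ensemble for
the full matrix and scores every gene set against column subsets of it, so
subsetting commutes with testing and a fixed seed yields a byte-identical
report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .combiners import PartitionScheme
from .engine import METHODS, run_all
from .marginal import ExpressionMatrix, Phenotype, dichotomize_phenotype, permuted_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "load_expression",
    "load_phenotype",
    "load_gmt",
    "test_gene_sets",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, ordered gene sets (e.g. GO terms) and where they came from."""

    sets: dict[str, tuple[str, ...]]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(
        self,
        universe: Sequence[str],
        min_size: int = 1,
        max_size: Optional[int] = None,
    ) -> "GeneSetCollection":
        """Intersect each set with ``universe`` and apply the size filter;
        sets that vanish or fall outside the size window are dropped (with a
        warning for sets with no gene in the universe)."""
        uni = set(universe)
        kept: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            present = tuple(g for g in genes if g in uni)
            if not present:
                logger.warning("gene set %s has no gene in the matrix; dropped", name)
                continue
            if len(present) < min_size or (
                max_size is not None and len(present) > max_size
            ):
                continue
            kept[name] = present
        return GeneSetCollection(kept, source=self.source)


def load_expression(path: str | Path, sep: Optional[str] = None) -> ExpressionMatrix:
    """Read a genes-by-samples matrix (first column gene IDs, header sample
    IDs).  The delimiter is sniffed from the extension unless given."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns))
    )


def load_phenotype(
    path: str | Path, sample_ids: Sequence[str], sep: str = "\t"
) -> Phenotype:
    """Read a two-column (sample_id, label-or-value) table and align it to
    the matrix's sample order.  Binary 0/1 columns are used as labels
    directly; anything else is median-dichotomized."""
    df = pd.read_csv(path, sep=sep, header=None, names=["sample_id", "value"])
    df["sample_id"] = df["sample_id"].astype(str)
    lookup = dict(zip(df["sample_id"], df["value"]))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"phenotype file lacks samples: {missing[:5]}...")
    values = np.asarray([float(lookup[s]) for s in sample_ids])
    if set(np.unique(values)) <= {0.0, 1.0}:
        return Phenotype(labels=values.astype(int), raw=values)
    return dichotomize_phenotype(values)


def load_gmt(
    path: str | Path,
    min_size: int = 1,
    max_size: Optional[int] = None,
    universe: Optional[Sequence[str]] = None,
) -> GeneSetCollection:
    """Parse a GMT file (tab-delimited: name, description, member genes...).

    Duplicate genes within a set are removed with a warning; duplicate set
    names or structurally short lines raise with the line number.  If a
    ``universe`` is supplied the size filter applies after intersection,
    mirroring a "5 to 10 genes present on the platform" style selection.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: set %s contains duplicate genes; deduplicated",
                    path, lineno, name,
                )
            if not deduped:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = deduped
    coll = GeneSetCollection(sets, source=str(path))
    if universe is not None or min_size > 1 or max_size is not None:
        coll = coll.restricted(
            universe if universe is not None else
            tuple({g for gs in sets.values() for g in gs}),
            min_size=min_size,
            max_size=max_size,
        )
    return coll


def test_gene_sets(
    X: ExpressionMatrix,
    ph: Phenotype,
    sets: GeneSetCollection,
    methods: Sequence[str] = METHODS,
    B: int = 1000,
    seed: Optional[int] = 0,
    scheme: PartitionScheme | None = None,
    min_size: int = 1,
    max_size: Optional[int] = None,
    test: str = "t",
    fdr: bool = False,
) -> pd.DataFrame:
    """Group p-values for every gene set; one row per (set, method).

    One permutation ensemble is computed for the whole matrix and each set is
    scored on its column subset, so all sets (and all methods) share the same
    permutations.  The report is sorted so the most significant set under the
    multi-partition test comes first (falling back to the first requested
    method when it is not run).  ``fdr=True`` appends a Benjamini-Hochberg
    column per method; by default raw group p-values are reported.
    """
    filtered = sets.restricted(X.gene_ids, min_size=min_size, max_size=max_size)
    if len(filtered) == 0:
        raise ValueError("no gene set survives filtering against the matrix")
    if X.n_samples != ph.n_samples:
        raise ValueError("phenotype length does not match sample count")
    full_ens = permuted_pvalues(X, ph, B=B, seed=seed, test=test)
    col_index = {g: i for i, g in enumerate(X.gene_ids)}
    rows = []
    for name, genes in filtered.sets.items():
        t0 = time.perf_counter()
        ens = full_ens.subset_genes([col_index[g] for g in genes])
        results = run_all(ens, methods=methods, scheme=scheme)
        for method, r in results.items():
            rows.append(
                {
                    "set_id": name,
                    "set_size": len(genes),
                    "method": method,
                    "statistic": r.statistic,
                    "p_adjusted": r.p_adjusted,
                    "B": B,
                    "seed": seed,
                }
            )
        logger.info(
            "set %s (%d genes) tested in %.2fs", name, len(genes),
            time.perf_counter() - t0,
        )
    report = pd.DataFrame(rows)
    sort_method = "rpcmp" if "rpcmp" in methods else methods[0]
    order = (
        report[report["method"] == sort_method]
        .sort_values(["p_adjusted", "set_id"], kind="stable")["set_id"]
        .tolist()
    )
    report["set_id"] = pd.Categorical(report["set_id"], categories=order, ordered=True)
    report = report.sort_values(["set_id", "method"], kind="stable").reset_index(
        drop=True
    )
    report["set_id"] = report["set_id"].astype(str)
    if fdr:
        from scipy.stats import false_discovery_control

        report["p_bh"] = np.nan
        for method in methods:
            mask = report["method"] == method
            report.loc[mask, "p_bh"] = false_discovery_control(
                report.loc[mask, "p_adjusted"].to_numpy(), method="bh"
            )
    return report
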