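"""Filtering and summarizing PheWAS hits.

The pipeline consumes p-values computed upstream; it never performs
association testing or multiple-testing correction.  All thresholds use a
strict ``<`` inequality, the single convention applied throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .records import PhewasHit


def filter_by_p(hits: Iterable[PhewasHit], alpha: float) -> list[PhewasHit]:
    """Hits with ``p < alpha`` (strict), order preserved.

    Monotone in alpha: a smaller threshold always yields a subset.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    return [h for h in hits if h.p_value < alpha]


def top_hits(hits: Iterable[PhewasHit], n: int, alpha: float = 1.0) -> list[PhewasHit]:
    """The ``n`` most significant hits below ``alpha``.

    Sorted ascending by p with deterministic (snp_id, phenotype) tie-break;
    fewer than ``n`` are returned when the filter leaves fewer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = filter_by_p(hits, alpha)
    kept.sort(key=lambda h: (h.p_value, h.snp_id, h.phenotype))
    return kept[:n]


@dataclass(slots=True)
class GenePhenotypeSummary:
    """Per-gene distribution of phenotype association p-values."""

    gene_symbol: str
    n_hits: int
    min_p: float
    median_p: float
    neglog10_quartiles: tuple[float, float, float]  # q1, median, q3 of -log10 p
    top_phenotypes: list[tuple[str, float]]  # (phenotype, p), p < label threshold


def gene_phenotype_summary(hits: Iterable[PhewasHit],
                           label_threshold: float = 1e-5,
                           max_labels: int = 10) -> list[GenePhenotypeSummary]:
    """One summary per gene present, sorted by gene symbol.

    Quartiles are taken on the -log10 transform (the scale the distribution
    is displayed on).  ``top_phenotypes`` lists the phenotypes below the
    label threshold, most significant first, capped at ``max_labels``.
    """
    per_gene: dict[str, list[PhewasHit]] = defaultdict(list)
    for hit in hits:
        per_gene[hit.gene_symbol].append(hit)
    summaries: list[GenePhenotypeSummary] = []
    for gene in sorted(per_gene):
        gene_hits = per_gene[gene]
        p = np.array([h.p_value for h in gene_hits])
        neglog = -np.log10(p)
        labeled = sorted(
            ((h.phenotype, h.p_value) for h in gene_hits if h.p_value < label_threshold),
            key=lambda kv: (kv[1], kv[0]))[:max_labels]
        summaries.append(GenePhenotypeSummary(
            gene_symbol=gene,
            n_hits=len(gene_hits),
            min_p=float(p.min()),
            median_p=float(np.median(p)),
            neglog10_quartiles=tuple(float(q) for q in np.percentile(neglog, [25, 50, 75])),
            top_phenotypes=labeled,
        ))
    return summaries


def summaries_to_frame(summaries: Iterable[GenePhenotypeSummary]) -> pd.DataFrame:
    rows = [(s.gene_symbol, s.n_hits, s.min_p, s.median_p,
             *s.neglog10_quartiles,
             ";".join(f"{name}({p:.3g})" for name, p in s.top_phenotypes))
            for s in summaries]
    return pd.DataFrame(rows, columns=[
        "gene", "n_hits", "min_p", "median_p",
        "neglog10_q1", "neglog10_median", "neglog10_q3", "top_phenotypes"])


def manhattan_table(hits: Iterable[PhewasHit]) -> pd.DataFrame:
    """Long table (phenotype, category, -log10 p) for external plotting."""
    rows = [(h.phenotype, h.phenotype_category, float(-np.log10(h.p_value)))
            for h in hits]
    return pd.DataFrame(rows, columns=["phenotype", "category", "neglog10_p"])
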