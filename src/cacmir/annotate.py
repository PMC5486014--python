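"""Functional enrichment and gene-disease association mapping.

Enrichment is a plain upper-tail hypergeometric test over user-supplied
term -> gene tables with Benjamini-Hochberg adjustment; no server-specific
background correction is applied, so p-values from annotation servers with
their own backgrounds are comparable only qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError


@dataclass
class AnnotationSet:
    term_id: str
    term_name: str
    category: str  # pathway / GO-BP / GO-CC / GO-MF
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ParameterError(f"annotation term {self.term_id!r} has no genes")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    overlap_genes: tuple
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GeneDiseaseAssoc:
    gene_symbol: str
    disease_name: str
    cui: str

    def __post_init__(self) -> None:
        if not self.cui:
            raise ParameterError("gene-disease association lacks a CUI")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    annotation_sets: Sequence[AnnotationSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each term.

    The universe defaults to all genes appearing in the annotation table;
    query genes and term genes are intersected with it.  Results are BH
    adjusted and sorted by p-value (ties by term id).
    """
    if universe is None:
        universe = set().union(*(t.genes for t in annotation_sets)) if annotation_sets else set()
    universe = set(universe)
    if not universe:
        raise ParameterError("enrich: empty gene universe")
    query = set(query_genes) & universe
    N, n = len(universe), len(query)

    raw = []
    for term in annotation_sets:
        term_genes = term.genes & universe
        overlap = tuple(sorted(term_genes & query))
        k, K = len(overlap), len(term_genes)
        p = hypergeom_tail(k, N, K, n) if K else 1.0
        raw.append((term, overlap, k, K, p))
    adj = adjust_bh([r[4] for r in raw])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            category=term.category,
            overlap_genes=overlap,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            p_adjusted=pa,
            significant=p < alpha,
        )
        for (term, overlap, k, K, p), pa in zip(raw, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjustment, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("adjust_bh: p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class DiseaseMap:
    by_disease: dict                 # disease name -> sorted gene list
    n_associations: int              # deduplicated (gene, CUI) pairs retained

    @property
    def gene_counts(self) -> dict:
        return {d: len(g) for d, g in self.by_disease.items()}


def map_diseases(
    query_genes: Iterable[str],
    associations: Iterable[GeneDiseaseAssoc],
    keyword: str | None = None,
    cui_allowlist: Iterable[str] | None = None,
) -> DiseaseMap:
    """Restrict associations to the query genes and group them by disease.

    Associations are deduplicated by (gene, CUI); ``keyword`` applies a
    case-insensitive substring filter on disease names, and an optional CUI
    allow-list narrows concepts further.  Output is invariant to input row
    order and duplication.
    """
    query = set(query_genes)
    allow = set(cui_allowlist) if cui_allowlist is not None else None
    kw = keyword.lower() if keyword else None
    seen: set[tuple[str, str]] = set()
    grouped: dict[str, set] = {}
    for assoc in associations:
        if assoc.gene_symbol not in query:
            continue
        if allow is not None and assoc.cui not in allow:
            continue
        if kw is not None and kw not in assoc.disease_name.lower():
            continue
        key = (assoc.gene_symbol, assoc.cui)
        if key in seen:
            continue
        seen.add(key)
        grouped.setdefault(assoc.disease_name, set()).add(assoc.gene_symbol)
    by_disease = {d: sorted(g) for d, g in sorted(grouped.items())}
    return DiseaseMap(by_disease=by_disease, n_associations=len(seen))


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> list[AnnotationSet]:
    """TSV with columns term_id, term_name, category, gene (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets = []
    for (term_id, term_name, category), grp in df.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        sets.append(AnnotationSet(term_id, term_name, category, frozenset(grp["gene"])))
    return sets


def read_associations(path: str | Path) -> list[GeneDiseaseAssoc]:
    """TSV with columns gene, disease, cui."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [GeneDiseaseAssoc(r.gene, r.disease, r.cui) for r in df.itertuples()]
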