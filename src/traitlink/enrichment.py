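"""Hypergeometric gene-set enrichment against any annotation source.

Given a background of N genes of which n are annotated to a term, a query of
M genes (after intersection with the background) containing k annotated
genes, the probability of drawing exactly k annotated genes in a sample of n
without replacement is the hypergeometric mass

    p(X = k) = C(M, k) * C(N - M, n - k) / C(N, n)

and the enrichment p-value is the upper tail

    p = 1 - sum_{i=0}^{k-1} p(X = i) = P(X >= k),

computed here as the direct upper sum in log-space for numerical stability at
genome scale (N ~ 40k). A term is flagged enriched when its raw p-value falls
below the significance level (0.05 by convention); Benjamini-Hochberg
q-values are reported alongside but do not drive the flag unless requested.

The same engine serves every annotation source — trait ontology, gene
ontology, metabolic pathways, or co-expression modules — which is what makes
the per-source results directly cross-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentError",
    "BackgroundMismatchError",
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeom_pmf",
    "enrichment_pvalue",
    "enrich",
    "results_to_frame",
    "cross_compare",
]


class EnrichmentError(Exception):
    pass


class BackgroundMismatchError(EnrichmentError):
    """No query gene overlaps the annotation background."""


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(N: int, n: int, M: int, k: int) -> float:
    """P(X = k): C(M,k) C(N-M,n-k) / C(N,n), in log-space.

    Returns 0.0 for k outside the support [max(0, n+M-N), min(M, n)].
    """
    if not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"need 0 <= n, M <= N; got N={N}, n={n}, M={M}")
    if k < max(0, n + M - N) or k > min(M, n):
        return 0.0
    return float(np.exp(_log_binom(M, k) + _log_binom(N - M, n - k) - _log_binom(N, n)))


def enrichment_pvalue(N: int, n: int, M: int, k: int) -> float:
    """Upper-tail P(X >= k); equals 1 - sum_{i<k} pmf(i); 1.0 when k <= 0."""
    if k <= 0:
        return 1.0
    hi = min(M, n)
    if k > hi:
        return 0.0
    return float(min(1.0, sum(hypergeom_pmf(N, n, M, i) for i in range(k, hi + 1))))


class AnnotationSet:
    """A term -> gene-set mapping over a stated background universe.

    ``source`` labels where the annotation comes from (TO | GO | PC |
    module). Terms that end up with no genes after intersection with the
    background are dropped; every annotated gene must be a background member
    (genes outside a user-supplied background are silently restricted to it,
    matching the convention of intersecting against an expressed-gene
    universe).
    """

    def __init__(
        self,
        term_to_genes: Mapping[str, Iterable[str]],
        background: Iterable[str] | None = None,
        source: str = "TO",
    ):
        all_annotated = set()
        for gs in term_to_genes.values():
            all_annotated |= set(gs)
        self.background: frozenset[str] = (
            frozenset(background) if background is not None else frozenset(all_annotated)
        )
        self.source = source
        self.term_to_genes: dict[str, frozenset[str]] = {}
        for term, gs in term_to_genes.items():
            inside = frozenset(gs) & self.background
            if inside:
                self.term_to_genes[term] = inside

    @property
    def n_background(self) -> int:
        return len(self.background)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)

    def restrict(self, background: Iterable[str]) -> "AnnotationSet":
        """Intersect with a user-supplied background (e.g. expressed genes)."""
        new_bg = self.background & frozenset(background)
        return AnnotationSet(self.term_to_genes, background=new_bg, source=self.source)

    @classmethod
    def from_tsv(cls, path, source: str | None = None,
                 background: Iterable[str] | None = None) -> "AnnotationSet":
        """Read a term_id/gene_id TSV (optional third 'source' column)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        tcol = cols.get("term_id", df.columns[0])
        gcol = cols.get("gene_id", df.columns[1])
        mapping: dict[str, set[str]] = {}
        for t, g in zip(df[tcol], df[gcol]):
            mapping.setdefault(str(t), set()).add(str(g))
        if source is None:
            source = str(df[cols["source"]].iloc[0]) if "source" in cols and len(df) else "TO"
        return cls(mapping, background=background, source=source)

    def to_tsv(self, path) -> None:
        rows = [
            {"term_id": t, "gene_id": g, "source": self.source}
            for t in self.terms
            for g in sorted(self.term_to_genes[t])
        ]
        pd.DataFrame(rows, columns=["term_id", "gene_id", "source"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one term's hypergeometric test.

    k: query genes carrying the term; M: query genes inside the background;
    n: background genes carrying the term; N: background size.
    """

    term_id: str
    k: int
    M: int
    n: int
    N: int
    p_value: float
    enriched: bool
    q_value: float | None = None
    source: str = "TO"


def enrich(
    query: Sequence[str],
    ann: AnnotationSet,
    alpha: float = 0.05,
    flag_on_qvalue: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation in the query.

    Duplicate query genes are collapsed; M counts only query genes present
    in the background. One result is produced per term with n > 0, sorted
    by ascending p-value then term id. BH q-values are attached; the
    ``enriched`` flag uses the raw p-value unless ``flag_on_qvalue``.

    Raises
    ------
    BackgroundMismatchError
        If no query gene lies in the background (lists up to 10 offenders).
    """
    if not query:
        raise ValueError("query gene list is empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    qset = frozenset(query)
    inside = qset & ann.background
    if not inside:
        offenders = sorted(qset)[:10]
        raise BackgroundMismatchError(
            f"no query gene found in the {ann.source} background "
            f"(first offenders: {offenders})"
        )
    M, N = len(inside), ann.n_background

    raw: list[tuple[str, int, int, float]] = []
    for term in ann.terms:
        genes = ann.term_to_genes[term]
        n = len(genes)
        k = len(genes & inside)
        raw.append((term, k, n, enrichment_pvalue(N, n, M, k)))

    pvals = [p for *_, p in raw]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []

    results = [
        EnrichmentResult(
            term_id=term, k=k, M=M, n=n, N=N, p_value=p,
            enriched=bool((q if flag_on_qvalue else p) < alpha),
            q_value=float(q), source=ann.source,
        )
        for (term, k, n, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with the queryitem/querytotal/bgitem/bgtotal column
    names used by the published supplementary enrichment tables."""
    return pd.DataFrame(
        [
            {
                "source": r.source,
                "term_id": r.term_id,
                "queryitem": r.k,
                "querytotal": r.M,
                "bgitem": r.n,
                "bgtotal": r.N,
                "pvalue": r.p_value,
                "qvalue": r.q_value,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )


def cross_compare(
    results_per_source: Mapping[str, Sequence[EnrichmentResult]],
    enriched_only: bool = True,
) -> pd.DataFrame:
    """Align enrichment results from several sources into one report.

    Rows are keyed by (source, term) — the same accession appearing in two
    sources yields two distinct rows — and p-values are never fused across
    sources. By default only enriched terms are reported; sources that
    contribute nothing are still named, with a warning flag.
    """
    if len(results_per_source) < 2:
        raise ValueError("cross_compare needs results from at least 2 sources")
    cols = ["source", "term_id", "queryitem", "querytotal", "bgitem", "bgtotal",
            "pvalue", "qvalue", "enriched", "empty_source_warning"]
    frames = []
    for label, results in results_per_source.items():
        kept = [r for r in results if r.enriched] if enriched_only else list(results)
        if kept:
            df = results_to_frame(kept)
            df["source"] = label
            df["empty_source_warning"] = False
        else:
            # name the silent source with a warning row
            df = pd.DataFrame([{"source": label, "term_id": "",
                                "empty_source_warning": True}])
        frames.append(df)
    table = pd.concat(frames, ignore_index=True).reindex(columns=cols)
    real = table[table["term_id"] != ""]
    dup = real.duplicated(subset=["source", "term_id"])
    if dup.any():
        first = real.loc[dup.index[dup], ["source", "term_id"]].iloc[0]
        raise EnrichmentError(
            f"duplicated (source, term) key: ({first['source']}, {first['term_id']})"
        )
    return table.sort_values(["source", "pvalue", "term_id"],
                             na_position="last").reset_index(drop=True)
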