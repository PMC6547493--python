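"""False-positive-rate simulation for enrichment testing.

A gene set drawn uniformly at random from the background carries no signal,
so any term an enrichment test flags on it is a false positive. Repeating
the draw many times at several set sizes estimates the test's empirical
false-positive rate (FPR) as a function of query size — the design used to
compare trait-ontology against gene-ontology enrichment.

Two FPR estimators are available, because "rate of significant term
enrichment" admits both readings:

* ``per_term`` (default): per replicate, the fraction of tested terms with
  p < alpha, averaged over replicates. Because the discrete upper-tail test
  satisfies P(p <= alpha) <= alpha under the null, this estimator is
  conservative (never exceeds alpha beyond Monte-Carlo error).
* ``any_hit``: the share of replicates flagging at least one term.

The estimator used is tagged in the summary. Randomness flows from a single
seed; per-size substreams are derived deterministically so the full grid is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet, enrich

__all__ = ["FprConfig", "FprSummary", "simulate_fpr", "compare_fpr"]

DEFAULT_SET_SIZES = (20, 40, 60, 80, 100, 200, 500, 1000)


@dataclass(frozen=True)
class FprConfig:
    """Design of an FPR experiment.

    ``set_sizes`` defaults to the 20-1000 grid of the published design;
    ``replicates`` defaults to 1000 random draws per size. ``estimator`` is
    ``per_term`` or ``any_hit`` (see module docstring).
    """

    seed: int
    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES
    replicates: int = 1000
    alpha: float = 0.05
    estimator: str = "per_term"
    source: str = "TO"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 1 for s in self.set_sizes):
            raise ValueError("set sizes must be positive")
        if self.estimator not in ("per_term", "any_hit"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0,1), got {self.alpha}")


@dataclass
class FprSummary:
    """Per-size FPR estimates: mean, standard error, replicate count."""

    table: pd.DataFrame  # columns: size, mean_fpr, se, replicates
    estimator: str
    source: str
    alpha: float

    def mean_fpr(self, size: int) -> float:
        return float(self.table.set_index("size").loc[size, "mean_fpr"])

    def se(self, size: int) -> float:
        return float(self.table.set_index("size").loc[size, "se"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "source", self.source)
        out["estimator"] = self.estimator
        out.to_csv(path, sep="\t", index=False)


def simulate_fpr(ann: AnnotationSet, config: FprConfig) -> FprSummary:
    """Estimate the enrichment FPR by repeated uniform random gene draws.

    Per replicate a gene set of the given size is drawn without replacement
    from the annotation background (the enrichment "input" universe, not the
    whole genome), enriched at ``config.alpha``, and scored by the configured
    estimator. Bit-reproducible for a fixed seed.
    """
    background = np.array(sorted(ann.background))
    for s in config.set_sizes:
        if s > len(background):
            raise ValueError(
                f"set size {s} exceeds background size {len(background)}"
            )
    # independent, deterministic substream per size
    children = np.random.SeedSequence(config.seed).spawn(len(config.set_sizes))
    rows = []
    for size, ss in zip(config.set_sizes, children):
        rng = np.random.default_rng(ss)
        rates = np.empty(config.replicates)
        for i in range(config.replicates):
            genes = rng.choice(background, size=size, replace=False)
            if config.alpha == 0.0:
                rates[i] = 0.0
                continue
            results = enrich(list(genes), ann, alpha=config.alpha)
            n_sig = sum(r.p_value < config.alpha for r in results)
            if config.estimator == "per_term":
                rates[i] = n_sig / len(results) if results else 0.0
            else:
                rates[i] = 1.0 if n_sig else 0.0
        mean = float(rates.mean())
        se = float(rates.std(ddof=1) / np.sqrt(config.replicates)) if config.replicates > 1 else 0.0
        rows.append({"size": size, "mean_fpr": mean, "se": se,
                     "replicates": config.replicates})
    return FprSummary(
        table=pd.DataFrame(rows),
        estimator=config.estimator,
        source=config.source,
        alpha=config.alpha,
    )


def compare_fpr(summaries: Mapping[str, FprSummary]) -> pd.DataFrame:
    """Pair FPR summaries from several sources side by side.

    All summaries must share a size grid. For each source pair and size the
    report carries the difference of means and a descriptive two-proportion
    z statistic (difference over the pooled standard error) — descriptive
    because replicate term counts differ between sources.
    """
    if len(summaries) < 2:
        raise ValueError("compare_fpr needs at least 2 summaries")
    labels = sorted(summaries)
    grids = {label: tuple(summaries[label].table["size"]) for label in labels}
    first = grids[labels[0]]
    for label in labels[1:]:
        if grids[label] != first:
            raise ValueError(
                f"size grids differ: {labels[0]}={first} vs {label}={grids[label]}"
            )
    rows = []
    for size in first:
        row: dict = {"size": size}
        for label in labels:
            row[f"mean_fpr_{label}"] = summaries[label].mean_fpr(size)
            row[f"se_{label}"] = summaries[label].se(size)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                diff = row[f"mean_fpr_{a}"] - row[f"mean_fpr_{b}"]
                pooled = np.hypot(row[f"se_{a}"], row[f"se_{b}"])
                row[f"diff_{a}_vs_{b}"] = diff
                row[f"z_{a}_vs_{b}"] = diff / pooled if pooled > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
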