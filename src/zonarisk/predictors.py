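"""Collinearity screening of predictor layers.

Bioclimatic predictors are strongly inter-correlated (e.g. annual mean
temperature vs. mean temperature of the warmest quarter). Before fitting a
niche model, the pairwise Pearson correlation matrix is computed over
jointly valid cells and layers are eliminated iteratively until no retained
pair exceeds the |r| cutoff (0.7 by default). The elimination rule is the
"find correlation" heuristic: at each step the worst pair is located and
the member with the larger mean absolute correlation against all other
retained layers is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import PredictorStack

logger = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix plus the outcome of iterative elimination."""

    matrix: pd.DataFrame
    cutoff: float = 0.7
    dropped: list[str] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)  # constant layers

    @property
    def retained(self) -> list[str]:
        return [n for n in self.matrix.columns if n not in set(self.dropped)]

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def pearson_matrix(
    stack: PredictorStack,
    max_cells: int | None = None,
    seed: int | None = None,
) -> CorrelationReport:
    """Pairwise Pearson correlations over jointly valid cells.

    Complete-case: only cells valid in *every* layer enter, so all pairs are
    computed on one common sample. ``max_cells`` optionally subsamples that
    set (seeded) for speed on large grids. A constant layer has undefined
    correlations; it is flagged, reported as NaN in the matrix, and treated
    as uncorrelated (r = 0) by the elimination step.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 layers for a correlation matrix")
    valid = stack.valid
    rows, cols = np.nonzero(valid)
    if rows.size < 3:
        raise ValueError(f"need >= 3 jointly valid cells, found {rows.size}")
    if max_cells is not None and rows.size > max_cells:
        rng = np.random.default_rng(seed)
        pick = rng.choice(rows.size, size=max_cells, replace=False)
        rows, cols = rows[pick], cols[pick]
    X = stack.table(rows, cols)

    sd = X.std(axis=0)
    constant = sd == 0
    undefined = [n for n, c in zip(names, constant) if c]
    if undefined:
        logger.warning("constant layers have undefined correlations: %s", undefined)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    matrix = pd.DataFrame(r, index=names, columns=names)
    return CorrelationReport(matrix=matrix, undefined=undefined)


def eliminate_correlated(report: CorrelationReport, cutoff: float = 0.7) -> CorrelationReport:
    """Iteratively drop layers until no retained pair has |r| > cutoff.

    While any retained pair exceeds the cutoff, the pair with the largest
    |r| is found and the member with the larger mean absolute correlation
    against all other retained layers is dropped (ties broken by layer-name
    order: the lexicographically later name is dropped). Each step removes
    exactly one layer, so termination is guaranteed.
    """
    names = list(report.matrix.columns)
    absr = report.matrix.abs().to_numpy().copy()
    absr = np.where(np.isnan(absr), 0.0, absr)  # constant layers: treat as r=0
    np.fill_diagonal(absr, 0.0)

    alive = list(range(len(names)))
    dropped: list[str] = []
    while len(alive) > 1:
        sub = absr[np.ix_(alive, alive)]
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= cutoff:
            break
        a, b = alive[worst[0]], alive[worst[1]]
        # mean |r| of each member against all other retained layers
        mean_a = sub[worst[0]].sum() / (len(alive) - 1)
        mean_b = sub[worst[1]].sum() / (len(alive) - 1)
        if mean_a > mean_b:
            out = a
        elif mean_b > mean_a:
            out = b
        else:  # deterministic tie-break on layer name
            out = max(a, b, key=lambda i: names[i])
        logger.info(
            "dropping %s (|r|=%.3f with %s; mean|r| %.3f vs %.3f)",
            names[out], sub[worst], names[a if out == b else b], mean_a, mean_b,
        )
        dropped.append(names[out])
        alive.remove(out)

    return CorrelationReport(
        matrix=report.matrix,
        cutoff=cutoff,
        dropped=dropped,
        undefined=list(report.undefined),
    )


def select_variables(
    stack: PredictorStack,
    cutoff: float = 0.7,
    max_cells: int | None = None,
    seed: int | None = None,
) -> tuple[PredictorStack, CorrelationReport]:
    """Convenience: correlation matrix + elimination + subset the stack."""
    report = eliminate_correlated(pearson_matrix(stack, max_cells=max_cells, seed=seed), cutoff=cutoff)
    return stack.subset(report.retained), report
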