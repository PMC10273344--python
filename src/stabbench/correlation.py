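"""Complete-observation Spearman correlation matrices.

All agreement in the benchmark is measured as Spearman's rho computed on
the complete paired observations of each source pair: variants missing
either value are dropped before ranking, ties get average ranks, and
pairs with too few shared observations or zero rank variance are flagged
undefined rather than silently set to 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonization import HarmonizedScores
from .score_model import ScoreTable

DEFAULT_MIN_SHARED_N = 3  # rho is degenerate below this


@dataclass(frozen=True)
class CorrelationEntry:
    source_a: str
    source_b: str
    rho: Optional[float]
    n_shared: int
    defined: bool


@dataclass
class CorrelationMatrix:
    entries: list[CorrelationEntry]
    metric: str  # ddg | abs_ddg
    scope: str   # pooled_all_variants | per_dataset:<id>

    def get(self, a: str, b: str) -> CorrelationEntry:
        for e in self.entries:
            if {e.source_a, e.source_b} == {a, b} or (a == b == e.source_a):
                return e
        raise KeyError((a, b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source_a, e.source_b, self.metric, self.scope,
              e.rho if e.defined else np.nan, e.n_shared, e.defined)
             for e in self.entries],
            columns=["source_a", "source_b", "metric", "scope", "rho",
                     "n_shared", "defined"],
        )

    def to_square(self) -> pd.DataFrame:
        ids = sorted({e.source_a for e in self.entries} | {e.source_b for e in self.entries})
        m = pd.DataFrame(np.nan, index=ids, columns=ids)
        for e in self.entries:
            val = e.rho if e.defined else np.nan
            m.loc[e.source_a, e.source_b] = val
            m.loc[e.source_b, e.source_a] = val
        return m


def spearman_complete(
    x_values: Sequence[float] | np.ndarray | pd.Series,
    y_values: Sequence[float] | np.ndarray | pd.Series,
    min_shared_n: int = DEFAULT_MIN_SHARED_N,
) -> tuple[Optional[float], int, bool]:
    """Spearman's rho on complete paired observations.

    Returns (rho, n_shared, defined). Pairs with either value missing are
    dropped; defined requires n_shared >= min_shared_n and at least two
    distinct values in each margin.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned by variant")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < min_shared_n or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None, n, False
    rho = stats.spearmanr(x, y).statistic
    return float(rho), n, True


def _pairwise_matrix(
    wide: pd.DataFrame, ids: Sequence[str], metric: str, scope: str,
    min_shared_n: int,
) -> CorrelationMatrix:
    entries = []
    for i, a in enumerate(ids):
        xa = wide[a] if a in wide.columns else pd.Series(dtype=float)
        n_self = int(xa.notna().sum())
        entries.append(CorrelationEntry(a, a, 1.0 if n_self >= min_shared_n else None,
                                        n_self, n_self >= min_shared_n))
        for b in ids[i + 1:]:
            if a in wide.columns and b in wide.columns:
                rho, n, ok = spearman_complete(wide[a], wide[b], min_shared_n)
            else:
                rho, n, ok = None, 0, False
            entries.append(CorrelationEntry(a, b, rho, n, ok))
    return CorrelationMatrix(entries, metric, scope)


def pooled_predictor_matrix(
    table: HarmonizedScores | ScoreTable,
    predictors: Sequence[str],
    metric: str = "ddg",
    min_shared_n: int = DEFAULT_MIN_SHARED_N,
) -> CorrelationMatrix:
    """Predictor-vs-predictor matrix over variants pooled from all genes."""
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    df = (table.table if isinstance(table, HarmonizedScores) else table)
    wide = df.wide(predictors)
    return _pairwise_matrix(wide, list(predictors), metric, "pooled_all_variants",
                            min_shared_n)


def predictor_dms_matrix(
    table: HarmonizedScores | ScoreTable,
    predictors: Sequence[str],
    dms_sources: Sequence[str],
    metric: str = "ddg",
    min_shared_n: int = DEFAULT_MIN_SHARED_N,
) -> dict[str, CorrelationMatrix]:
    """Per-DMS-dataset predictor correlations on each dataset's own gene.

    Each DMS source is restricted to the variants of its own gene(s); the
    returned mapping has one matrix of (predictor, dms) entries per
    dataset, with undefined entries flagged.
    """
    st = table.table if isinstance(table, HarmonizedScores) else table
    df = st.df
    out: dict[str, CorrelationMatrix] = {}
    for dms in dms_sources:
        genes = df.loc[df["source"] == dms, "gene"].unique()
        sub = ScoreTable(df[df["gene"].isin(genes)])
        wide = sub.wide(list(predictors) + [dms])
        entries = []
        for p in predictors:
            if p in wide.columns and dms in wide.columns:
                rho, n, ok = spearman_complete(wide[p], wide[dms], min_shared_n)
            else:
                rho, n, ok = None, 0, False
            entries.append(CorrelationEntry(p, dms, rho, n, ok))
        out[dms] = CorrelationMatrix(entries, metric, f"per_dataset:{dms}")
    return out


def mean_benchmark_rho(matrices: dict[str, CorrelationMatrix]) -> float:
    """Arithmetic mean of all defined (predictor, dataset) rho values."""
    rhos = [e.rho for m in matrices.values() for e in m.entries if e.defined]
    if not rhos:
        raise ValueError("no defined correlation entries")
    return float(np.mean(rhos))


def write_matrices(
    matrices: Iterable[CorrelationMatrix], tidy_path: str | Path
) -> None:
    tidy = pd.concat([m.to_frame() for m in matrices], ignore_index=True)
    tidy.to_csv(tidy_path, sep="\t", index=False, float_format="%.6g")
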