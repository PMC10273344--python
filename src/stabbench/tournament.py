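"""Pairwise-comparison tournament ranking of predictors.

For every DMS dataset and every unordered predictor pair, each
predictor's Spearman rho against the DMS scores is computed on the
three-way shared variant subset (both predictors and the assay value
present), rounded to two decimals, and compared: the larger signed rho
earns a point, a draw after rounding earns half a point each. Duels are
held only when neither predictor is completely missing the dataset.
Final scores are each predictor's points divided by its own number of
successful comparisons, with a 95% binomial (Wilson) interval on that
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .correlation import DEFAULT_MIN_SHARED_N, spearman_complete
from .harmonization import HarmonizedScores
from .score_model import ScoreTable


@dataclass
class TournamentResult:
    predictor_id: str
    points: float
    n_comparisons: int
    normalized_score: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    metric: str = "ddg"


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01)."""
    factor = 10 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def _round(x: float, decimals: int, mode: str) -> float:
    if mode == "half_away_from_zero":
        return round_half_away(x, decimals)
    if mode == "bankers":
        return round(x, decimals)
    raise ValueError(f"unknown rounding mode {mode!r}")


def pairwise_duel(
    rho_a: Optional[float],
    rho_b: Optional[float],
    rounding: str = "half_away_from_zero",
) -> Optional[tuple[float, float]]:
    """One duel: compare two correlations rounded to two decimals.

    Larger signed value wins 1 point; a draw after rounding gives each
    half a point. Returns None (duel skipped, no comparison counted) when
    either rho is undefined.
    """
    if rho_a is None or rho_b is None:
        return None
    ra, rb = _round(rho_a, 2, rounding), _round(rho_b, 2, rounding)
    if ra > rb:
        return (1.0, 0.0)
    if rb > ra:
        return (0.0, 1.0)
    return (0.5, 0.5)


def binomial_ci(
    points: float, n_comparisons: int, method: str = "wilson"
) -> tuple[Optional[float], Optional[float]]:
    """95% binomial CI on the normalized score p = points/n.

    Half-points make p a pseudo-proportion; the interval treats it as a
    binomial success fraction, as the R binom.confint usage implies.
    Returns (None, None) when no comparisons were held.
    """
    if n_comparisons < 1:
        return None, None
    lo, hi = proportion_confint(points, n_comparisons, alpha=0.05, method=method)
    return float(lo), float(hi)


def run_tournament(
    table: HarmonizedScores | ScoreTable,
    predictors: Sequence[str],
    dms_sources: Sequence[str],
    metric: str = "ddg",
    *,
    min_shared_n: int = DEFAULT_MIN_SHARED_N,
    rounding: str = "half_away_from_zero",
    ci_method: str = "wilson",
    subset: str = "three_way",
) -> list[TournamentResult]:
    """Run the full tournament over all datasets and predictor pairs.

    ``subset`` chooses the variant set each duel's correlations use:
    "three_way" (default) re-computes both rho values on variants where
    both predictors and the DMS value exist; "per_predictor" uses each
    predictor's own full shared set with the dataset.
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    if not dms_sources:
        raise ValueError("need at least one DMS dataset")
    if subset not in ("three_way", "per_predictor"):
        raise ValueError(f"unknown subset semantics {subset!r}")
    st = table.table if isinstance(table, HarmonizedScores) else table
    df = st.df

    points = {p: 0.0 for p in predictors}
    counts = {p: 0 for p in predictors}
    for dms in dms_sources:
        genes = df.loc[df["source"] == dms, "gene"].unique()
        sub = df[df["gene"].isin(genes)]
        wide = ScoreTable(sub).wide(list(predictors) + [dms])
        if dms not in wide.columns:
            continue
        # "completely missing" rule: a predictor with no shared variants
        # with this dataset sits out all of its duels here
        present = [
            p for p in predictors
            if p in wide.columns and (wide[p].notna() & wide[dms].notna()).any()
        ]
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                if subset == "three_way":
                    m = wide[a].notna() & wide[b].notna() & wide[dms].notna()
                    rho_a, _, ok_a = spearman_complete(wide[a][m], wide[dms][m],
                                                       min_shared_n)
                    rho_b, _, ok_b = spearman_complete(wide[b][m], wide[dms][m],
                                                       min_shared_n)
                else:
                    rho_a, _, ok_a = spearman_complete(wide[a], wide[dms], min_shared_n)
                    rho_b, _, ok_b = spearman_complete(wide[b], wide[dms], min_shared_n)
                outcome = pairwise_duel(rho_a if ok_a else None,
                                        rho_b if ok_b else None, rounding)
                if outcome is None:
                    continue
                pa, pb = outcome
                points[a] += pa
                points[b] += pb
                counts[a] += 1
                counts[b] += 1

    results = []
    for p in predictors:
        n = counts[p]
        score = points[p] / n if n else None
        lo, hi = binomial_ci(points[p], n, ci_method) if n else (None, None)
        results.append(TournamentResult(p, points[p], n, score, lo, hi, metric))
    results.sort(key=lambda r: (-(r.normalized_score if r.normalized_score is not None
                                  else -1.0), r.predictor_id))
    return results


def results_frame(results: Sequence[TournamentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.predictor_id, r.metric, r.points, r.n_comparisons,
          r.normalized_score, r.ci_low, r.ci_high) for r in results],
        columns=["predictor", "metric", "points", "n_comparisons",
                 "normalized_score", "ci_low", "ci_high"],
    )


def write_ranking(results: Sequence[TournamentResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
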