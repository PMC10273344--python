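"""Assay-class aggregation of per-dataset correlations.

DMS datasets fall into five broad assay classes (abundance, growth,
binding, activity, viral replication). Per predictor and class, the
per-dataset Spearman rho values are summarized on the Fisher-z scale:
z = atanh(rho), mean and a 95% CI mean(z) +/- 1.96*sd(z)/sqrt(m), all
back-transformed with tanh. The CI describes dataset-to-dataset
dispersion. Group-restricted tournament reruns use identical tournament
semantics on the class's dataset subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix, DEFAULT_MIN_SHARED_N, predictor_dms_matrix
from .harmonization import HarmonizedScores
from .score_model import ScoreTable, SourceMeta, as_meta_map
from .tournament import TournamentResult, run_tournament

ASSAY_CLASSES = ("abundance", "growth", "binding", "activity", "viral_replication")
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class GroupSummary:
    assay_class: str
    predictor_id: str
    mean_rho: float            # tanh of the z-scale mean
    mean_rho_raw: float        # plain mean of per-dataset rho
    m_datasets: int
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_defined: bool


def group_mean_ci(
    rhos: Sequence[float], assay_class: str, predictor_id: str,
    ci_mode: str = "between_dataset",
) -> GroupSummary:
    """Fisher-z summary of one predictor's per-dataset correlations.

    ``ci_mode`` "between_dataset" (default) uses sd(z)/sqrt(m) across the
    m datasets; "per_correlation" is unavailable here because it needs the
    per-dataset n (use :func:`group_summaries` for that variant).
    """
    r = np.asarray(rhos, dtype=float)
    if r.size == 0:
        raise ValueError(f"no correlations for class {assay_class!r}")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|rho| = 1 has infinite Fisher z")
    z = np.arctanh(r)
    mean_z = float(np.mean(z))
    m = int(r.size)
    if m >= 2:
        se = float(np.std(z, ddof=1)) / np.sqrt(m)
        lo, hi = float(np.tanh(mean_z - Z95 * se)), float(np.tanh(mean_z + Z95 * se))
        defined = True
    else:
        lo = hi = None
        defined = False
    return GroupSummary(
        assay_class, predictor_id,
        mean_rho=float(np.tanh(mean_z)),
        mean_rho_raw=float(np.mean(r)),
        m_datasets=m, ci_low=lo, ci_high=hi, ci_defined=defined,
    )


def datasets_in_class(
    meta: Mapping[str, SourceMeta], assay_class: str
) -> list[str]:
    if assay_class not in ASSAY_CLASSES:
        raise ValueError(f"unknown assay class {assay_class!r}")
    ids = sorted(s for s, m in meta.items()
                 if m.role == "dms" and m.assay_class == assay_class)
    if not ids:
        raise ValueError(f"no DMS datasets in class {assay_class!r}")
    return ids


def group_summaries(
    matrices: Mapping[str, CorrelationMatrix],
    meta: Mapping[str, SourceMeta] | Sequence[SourceMeta],
    predictors: Sequence[str],
) -> list[GroupSummary]:
    """Summarize per-dataset predictor-DMS matrices by assay class."""
    meta_map = as_meta_map(meta)
    out = []
    for cls in ASSAY_CLASSES:
        ds = [d for d in matrices
              if d in meta_map and meta_map[d].assay_class == cls]
        if not ds:
            continue
        for p in predictors:
            rhos = []
            for d in ds:
                for e in matrices[d].entries:
                    if e.defined and {e.source_a, e.source_b} == {p, d}:
                        rhos.append(e.rho)
            if rhos:
                out.append(group_mean_ci(rhos, cls, p))
    return out


def restrict_and_rerun(
    table: HarmonizedScores | ScoreTable,
    assay_class: str,
    meta: Mapping[str, SourceMeta] | Sequence[SourceMeta],
    predictors: Sequence[str],
    metric: str = "ddg",
    **tournament_options,
) -> list[TournamentResult]:
    """Rerun the tournament restricted to one assay class's datasets.

    Predictor and VEP-style sources can be mixed freely in ``predictors``;
    raw ddG (not |ddG|) is the conventional metric for group analyses.
    """
    meta_map = as_meta_map(meta)
    dms = datasets_in_class(meta_map, assay_class)
    return run_tournament(table, predictors, dms, metric, **tournament_options)


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.assay_class, s.predictor_id, s.mean_rho_raw, s.mean_rho,
          s.m_datasets, s.ci_low, s.ci_high) for s in summaries],
        columns=["assay_class", "predictor", "mean_rho_raw",
                 "mean_rho_ztransformed", "m", "ci_low", "ci_high"],
    )


def write_summaries(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", index=False, float_format="%.6g")
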