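"""Score harmonization: direction adjustment, REU rescaling, |ddG| and
the Foldetta consensus.

After harmonization every predictor value is in kcal/mol with higher =
more destabilizing, and every DMS value is oriented so higher = more
damaging. Each applied transform is recorded in a per-source log so the
raw table is exactly reconstructable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .score_model import ScoreTable, SourceMeta, ValidationError, as_meta_map

ROSETTA_REU_PER_KCAL = 2.94  # empirical REU -> kcal/mol scaling divisor


@dataclass
class HarmonizedScores:
    """A direction-adjusted (and possibly rescaled) score table.

    ``transform_log`` maps source_id -> {"sign": ±1, "scale": s}; applying
    value * sign / scale to each raw value reproduces the harmonized table.
    """

    table: ScoreTable
    transform_log: dict[str, dict[str, float]] = field(default_factory=dict)

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.transform_log, fh, indent=2, sort_keys=True)


def adjust_directions(
    table: ScoreTable | HarmonizedScores,
    meta: Mapping[str, SourceMeta] | Iterable[SourceMeta],
) -> HarmonizedScores:
    """Orient every source so higher = more destabilizing / more damaging.

    Sources with direction -1 are negated; +1 sources pass through. The
    operation is idempotent: flags already consumed into the transform log
    are not applied again. No recentering to the wild-type reference is
    performed (rank statistics are shift-invariant).
    """
    meta_map = as_meta_map(meta)
    if isinstance(table, HarmonizedScores):
        prior_log = dict(table.transform_log)
        df = table.table.df.copy()
    else:
        prior_log = {}
        df = table.df.copy()
    log = dict(prior_log)
    for source in df["source"].unique():
        if source not in meta_map:
            raise ValidationError(f"no direction flag for source {source!r}")
        if source in prior_log:
            continue  # already harmonized
        sign = meta_map[source].direction
        if sign == -1:
            df.loc[df["source"] == source, "value"] *= -1.0
        log[source] = {"sign": float(sign), "scale": 1.0}
    return HarmonizedScores(ScoreTable(df), log)


def rescale_rosetta(
    table: ScoreTable | HarmonizedScores,
    meta: Mapping[str, SourceMeta] | Iterable[SourceMeta],
    sources: Optional[Iterable[str]] = None,
) -> HarmonizedScores:
    """Divide REU-unit sources by 2.94 to bring them onto kcal/mol.

    Applying it to a source whose declared units are not REU is a unit
    error.
    """
    meta_map = as_meta_map(meta)
    if isinstance(table, HarmonizedScores):
        log = dict(table.transform_log)
        df = table.table.df.copy()
    else:
        log = {}
        df = table.df.copy()
    if sources is None:
        sources = [s for s in df["source"].unique() if
                   s in meta_map and meta_map[s].units == "reu"]
    for source in sources:
        if source not in meta_map or meta_map[source].units != "reu":
            raise ValidationError(f"source {source!r} is not declared in REU units")
        df.loc[df["source"] == source, "value"] /= ROSETTA_REU_PER_KCAL
        entry = log.setdefault(source, {"sign": 1.0, "scale": 1.0})
        entry["scale"] = entry.get("scale", 1.0) * ROSETTA_REU_PER_KCAL
    return HarmonizedScores(ScoreTable(df), log)


def foldetta(
    table: ScoreTable | HarmonizedScores,
    foldx_source: str = "foldx",
    rosetta_source: str = "rosetta",
    mode: str = "raw",
    consensus_id: str = "foldetta",
) -> tuple[ScoreTable, int]:
    """Per-variant consensus of FoldX and (already rescaled) Rosetta.

    raw mode: (foldx + rosetta)/2. absolute mode: (|foldx| + |rosetta|)/2,
    i.e. absolute values are taken before averaging. Variants missing
    either input yield no consensus value; the count of such skipped
    variants is returned alongside the consensus table.
    """
    if mode not in ("raw", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    df = (table.table if isinstance(table, HarmonizedScores) else table).df
    wide = df[df["source"].isin([foldx_source, rosetta_source])].pivot_table(
        index=["gene", "position", "wt", "mut"], columns="source",
        values="value", aggfunc="first",
    )
    for s in (foldx_source, rosetta_source):
        if s not in wide.columns:
            wide[s] = float("nan")
    complete = wide.dropna(subset=[foldx_source, rosetta_source])
    n_skipped = len(wide) - len(complete)
    fx, ro = complete[foldx_source], complete[rosetta_source]
    vals = (fx.abs() + ro.abs()) / 2.0 if mode == "absolute" else (fx + ro) / 2.0
    out = complete.reset_index()[["gene", "position", "wt", "mut"]].copy()
    out["source"] = consensus_id
    out["value"] = vals.to_numpy()
    return ScoreTable(out), n_skipped


def to_absolute(
    table: ScoreTable | HarmonizedScores,
    sources: Iterable[str],
    suffix: str = "_abs",
) -> ScoreTable:
    """Replace selected predictor values by |value|, emitting new sources
    named with ``suffix``. DMS sources are left untouched (pass only
    predictor ids). Idempotent on already-absolute values."""
    df = (table.table if isinstance(table, HarmonizedScores) else table).df
    keep = df[df["source"].isin(set(sources))].copy()
    keep["value"] = keep["value"].abs()
    keep["source"] = keep["source"] + suffix
    rest = df[~df["source"].isin(set(sources))]
    return ScoreTable(pd.concat([rest, keep], ignore_index=True))
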