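"""Rank-normalized agreement maps between DMS scores and |ddG|.

Both score columns are rank normalized to [0, 1] (average ranks,
(rank-1)/(n-1)) after removing apparent gain-of-function variants, and
the normalized stability value is subtracted from the normalized DMS
score. A positive delta means the stability predictor underpredicts the
variant's functional effect relative to the assay; a negative delta
means it overpredicts; zero means agreement on relative severity.
Per-position medians summarize the map for structure coloring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from .score_model import ScoreTable, SourceMeta, VariantKey
from .structure_mapping import MappingResult

SENTINEL_BFACTOR = 999.90  # unmapped residues; real deltas clamp to +/-99.99


@dataclass
class AgreementMap:
    predictor_id: str
    dms_id: str
    per_variant_delta: dict[VariantKey, float]
    per_position_delta: dict[int, float]
    excluded_variants: list[VariantKey] = field(default_factory=list)


def rank_normalize(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Map a score column onto [0, 1] by average ranks: (rank-1)/(n-1).

    The minimum maps to 0, the maximum to 1, ties share the average-rank
    image. A constant column has no rank order and is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("rank normalization needs >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return (ranks - 1.0) / (x.size - 1.0)


def gof_filter(
    dms_values: Mapping[VariantKey, float] | pd.Series,
    wt_reference: Optional[float],
    direction: int,
) -> tuple[list[VariantKey], list[VariantKey]]:
    """Drop variants indicating improved function relative to wild type.

    ``direction`` is the raw-score convention: +1 when higher = more
    damaging (improvement = score strictly below the reference), -1 when
    higher = more fit (improvement = strictly above). Scores exactly at
    the reference are retained. Returns (retained, excluded).
    """
    if wt_reference is None:
        raise ValueError(
            "gain-of-function filter needs wt_reference; set it in SourceMeta"
        )
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    items = dms_values.items() if hasattr(dms_values, "items") else dms_values
    retained, excluded = [], []
    for key, value in items:
        improved = value < wt_reference if direction == 1 else value > wt_reference
        (excluded if improved else retained).append(key)
    return retained, excluded


def agreement_delta(
    dms_norm: Mapping[VariantKey, float], ddg_norm: Mapping[VariantKey, float]
) -> dict[VariantKey, float]:
    """delta = normalized DMS - normalized stability, per variant."""
    if set(dms_norm) != set(ddg_norm):
        raise ValueError("normalized columns cover different variant sets")
    return {k: dms_norm[k] - ddg_norm[k] for k in dms_norm}


def per_position_median(deltas: Mapping[VariantKey, float]) -> dict[int, float]:
    """Median delta over all retained variants at each position."""
    by_pos: dict[int, list[float]] = {}
    for key, d in deltas.items():
        by_pos.setdefault(key.position, []).append(d)
    return {pos: float(np.median(v)) for pos, v in sorted(by_pos.items())}


def build_agreement_map(
    table: ScoreTable,
    dms_id: str,
    predictor_id: str,
    meta: Mapping[str, SourceMeta],
    *,
    use_absolute: bool = True,
    filter_before_normalize: bool = True,
) -> AgreementMap:
    """End-to-end agreement map for one (DMS dataset, predictor) pair.

    |ddG| is the conventional stability input (``use_absolute``); the
    gain-of-function filter runs on raw DMS scores before normalization
    by default, and both columns are normalized on the retained variants
    that carry both scores.
    """
    wide = table.wide([dms_id, predictor_id]).dropna()
    if wide.empty:
        raise ValueError(f"no shared variants between {dms_id} and {predictor_id}")
    variants = [VariantKey(g, int(p), w, m) for g, p, w, m in wide.index]
    dms_raw = dict(zip(variants, wide[dms_id].to_numpy(dtype=float)))
    ddg_raw = wide[predictor_id].to_numpy(dtype=float)
    if use_absolute:
        ddg_raw = np.abs(ddg_raw)
    ddg_map = dict(zip(variants, ddg_raw))

    src = meta[dms_id]
    retained, excluded = gof_filter(dms_raw, src.wt_reference, src.direction)
    if filter_before_normalize:
        keys = retained
    else:
        keys = variants
    # orient so higher normalized DMS = more damaging before ranking
    dms_n = dict(zip(keys, rank_normalize([src.direction * dms_raw[k] for k in keys])))
    ddg_n = dict(zip(keys, rank_normalize([ddg_map[k] for k in keys])))
    if not filter_before_normalize:
        dms_n = {k: dms_n[k] for k in retained}
        ddg_n = {k: ddg_n[k] for k in retained}
    deltas = agreement_delta(dms_n, ddg_n)
    return AgreementMap(
        predictor_id=predictor_id, dms_id=dms_id,
        per_variant_delta=deltas,
        per_position_delta=per_position_median(deltas),
        excluded_variants=excluded,
    )


def write_agreement_tables(
    amap: AgreementMap, variant_path: str | Path, position_path: str | Path
) -> None:
    with open(variant_path, "w") as fh:
        fh.write("gene\tposition\twt\tmut\tdelta\n")
        for k in sorted(amap.per_variant_delta):
            fh.write(f"{k.gene_id}\t{k.position}\t{k.wt_aa}\t{k.mut_aa}\t"
                     f"{amap.per_variant_delta[k]:.6g}\n")
    with open(position_path, "w") as fh:
        fh.write("position\tmedian_delta\n")
        for pos, d in amap.per_position_delta.items():
            fh.write(f"{pos}\t{d:.6g}\n")


def export_position_attributes(
    amap: AgreementMap,
    mapping: Sequence[MappingResult],
    structure_path: str | Path,
    defattr_path: str | Path,
    pdb_out_path: str | Path,
) -> list[int]:
    """Write ChimeraX-style defattr and a B-factor-colored structure copy.

    Residues mapped to a per-position delta get B = 100*delta clamped to
    [-99.99, 99.99]; residues with no delta get the sentinel 999.90.
    Returns the positions that could not be placed on the structure.
    """
    # per-position delta on structure residues, via the variant mapping
    pos_to_residue: dict[int, tuple[str, int]] = {}
    for r in mapping:
        if r.target_kind == "pdb" and r.variant.position in amap.per_position_delta:
            pos_to_residue[r.variant.position] = (r.chain_id, r.residue_number)
    if not pos_to_residue:
        raise ValueError("no agreement positions are mapped to the structure")

    with open(defattr_path, "w") as fh:
        fh.write("attribute: agreementDelta\nmatch mode: 1-to-1\nrecipient: residues\n")
        for pos, (chain, resnum) in sorted(pos_to_residue.items()):
            fh.write(f"\t/{chain}:{resnum}\t{amap.per_position_delta[pos]:.4f}\n")

    residue_delta = {
        (chain, resnum): amap.per_position_delta[pos]
        for pos, (chain, resnum) in pos_to_residue.items()
    }
    st = gemmi.read_structure(str(structure_path))
    unplaced: set[int] = set(amap.per_position_delta) - set(pos_to_residue)
    placed: set[tuple[str, int]] = set()
    for model in st:
        for ch in model:
            for res in ch:
                key = (ch.name, res.seqid.num)
                delta = residue_delta.get(key)
                if delta is None:
                    b = SENTINEL_BFACTOR
                else:
                    b = float(np.clip(100.0 * delta, -99.99, 99.99))
                    placed.add(key)
                for atom in res:
                    atom.b_iso = b
    missing_on_structure = set(residue_delta) - placed
    for pos, key in pos_to_residue.items():
        if key in missing_on_structure:
            unplaced.add(pos)
    st.setup_entities()
    st.write_pdb(str(pdb_out_path))
    return sorted(unplaced)
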