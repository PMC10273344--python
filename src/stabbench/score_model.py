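"""Domain types and I/O for long-format variant score tables.

The pipeline's universal currency is a long-format table of per-variant
scores from many sources (stability predictors and DMS datasets), plus
per-source metadata describing each source's role, direction convention,
units and assay class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# IUPAC three-letter -> one-letter, canonical residues only
THREE_TO_ONE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
}

TABLE_COLUMNS = ["gene", "position", "wt", "mut", "source", "value"]


class FormatError(ValueError):
    """Malformed input file (bad header, unparsable row structure)."""


class ValidationError(ValueError):
    """Table content violates an invariant (duplicates, bad metadata)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single amino acid substitution in a reference protein.

    Positions are 1-based indices into the reference (UniProt-style)
    protein sequence; ``wt_aa``/``mut_aa`` are one-letter codes.
    """

    gene_id: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for aa, name in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"{name} {aa!r} is not a canonical amino acid")
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"synonymous variant {self.gene_id} {self.wt_aa}{self.position}{self.mut_aa}"
            )

    def __str__(self) -> str:
        return f"{self.gene_id}:{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ScoreRecord:
    variant: VariantKey
    source_id: str
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(f"non-finite value for {self.variant}/{self.source_id}")


@dataclass(frozen=True)
class SourceMeta:
    """Per-source metadata.

    ``direction`` is +1 when higher raw values already mean more
    destabilizing/damaging, -1 when higher values mean more stable/fit.
    ``wt_reference`` is the raw DMS score of the wild-type/neutral
    reference, used only by the gain-of-function filter.
    """

    source_id: str
    role: str  # predictor | dms | vep
    direction: int = 1
    units: str = "unitless"  # kcal_per_mol | reu | unitless
    assay_class: str = "not_applicable"
    structure_context: str = "not_applicable"  # monomer | complex | not_applicable
    wt_reference: Optional[float] = None

    _ROLES = frozenset({"predictor", "dms", "vep"})
    _UNITS = frozenset({"kcal_per_mol", "reu", "unitless"})
    _CLASSES = frozenset(
        {"abundance", "growth", "binding", "activity", "viral_replication", "not_applicable"}
    )

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValidationError(f"{self.source_id}: unknown role {self.role!r}")
        if self.direction not in (1, -1):
            raise ValidationError(f"{self.source_id}: direction must be +1 or -1")
        if self.units not in self._UNITS:
            raise ValidationError(f"{self.source_id}: unknown units {self.units!r}")
        if self.assay_class not in self._CLASSES:
            raise ValidationError(f"{self.source_id}: unknown assay_class {self.assay_class!r}")
        if (self.assay_class != "not_applicable") != (self.role == "dms"):
            raise ValidationError(
                f"{self.source_id}: assay_class must be set iff role is 'dms'"
            )
        if self.structure_context != "not_applicable" and self.role != "predictor":
            raise ValidationError(
                f"{self.source_id}: structure_context applies only to predictors"
            )


class ScoreTable:
    """Long-format per-variant score table backed by a pandas DataFrame.

    Columns: gene, position, wt, mut, source, value. The (variant, source)
    pair is unique; retrieval by (variant, source) is deterministic.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"score table missing columns: {missing}")
        df = df[TABLE_COLUMNS].copy()
        df["position"] = df["position"].astype(int)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["gene", "position", "wt", "mut", "source"])
        if dup.any():
            key = df[dup].iloc[0]
            raise ValidationError(
                "duplicate (variant, source): "
                f"{key['gene']}:{key['wt']}{key['position']}{key['mut']}/{key['source']}"
            )
        if not np.isfinite(df["value"]).all():
            raise ValidationError("score table contains non-finite values")
        self._df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[ScoreRecord]) -> "ScoreTable":
        rows = [
            (r.variant.gene_id, r.variant.position, r.variant.wt_aa,
             r.variant.mut_aa, r.source_id, r.value)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=TABLE_COLUMNS))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sources(self) -> list[str]:
        return sorted(self._df["source"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        a = self._df.sort_values(TABLE_COLUMNS[:5]).reset_index(drop=True)
        b = other._df.sort_values(TABLE_COLUMNS[:5]).reset_index(drop=True)
        return a.equals(b)

    def get(self, variant: VariantKey, source_id: str) -> Optional[float]:
        d = self._df
        m = (
            (d["gene"] == variant.gene_id)
            & (d["position"] == variant.position)
            & (d["wt"] == variant.wt_aa)
            & (d["mut"] == variant.mut_aa)
            & (d["source"] == source_id)
        )
        hit = d.loc[m, "value"]
        return None if hit.empty else float(hit.iloc[0])

    def subset_sources(self, source_ids: Iterable[str]) -> "ScoreTable":
        keep = set(source_ids)
        return ScoreTable(self._df[self._df["source"].isin(keep)])

    def wide(self, sources: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Pivot to a variant x source matrix (NaN where unobserved)."""
        d = self._df if sources is None else self.subset_sources(sources)._df
        return d.pivot_table(
            index=["gene", "position", "wt", "mut"],
            columns="source", values="value", aggfunc="first",
        )

    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(g, int(p), w, m)
            for g, p, w, m in self._df[["gene", "position", "wt", "mut"]]
            .drop_duplicates()
            .itertuples(index=False)
        ]

    def write_long_tsv(self, path: str | Path) -> None:
        d = self._df.copy()
        d["value"] = d["value"].map(lambda v: format_sig(v, 6))
        d.to_csv(path, sep="\t", index=False)


def format_sig(value: float, digits: int = 6) -> str:
    """Serialize at a fixed number of significant digits (round-trip safe)."""
    return f"{value:.{digits}g}"


@dataclass
class ParseLog:
    records_read: int = 0
    records_kept: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def records_skipped(self) -> int:
        return sum(self.skipped.values())

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


# HGVS protein single-substitution, three-letter codes: p.Leu64Pro
_HGVS_SUB = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_HGVS_SYN = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)=\)?$")


def parse_hgvs_pro(hgvs: str, gene_id: str) -> tuple[Optional[VariantKey], Optional[str]]:
    """Parse a protein-level HGVS string into a VariantKey.

    Returns (key, None) on success or (None, skip_reason). Only
    single-substitution p. syntax with three-letter codes is accepted;
    synonymous, nonsense, multi-substitution and anything else is skipped.
    """
    hgvs = hgvs.strip()
    if _HGVS_SYN.match(hgvs):
        return None, "synonymous"
    if ";" in hgvs or "[" in hgvs:
        return None, "multi_substitution"
    m = _HGVS_SUB.match(hgvs)
    if not m:
        return None, "unparsable"
    wt3, pos, mut3 = m.groups()
    if mut3 == "Ter" or wt3 == "Ter":
        return None, "nonsense"
    if wt3 not in THREE_TO_ONE or mut3 not in THREE_TO_ONE:
        return None, "noncanonical"
    wt, mut = THREE_TO_ONE[wt3], THREE_TO_ONE[mut3]
    if wt == mut:
        return None, "synonymous"
    return VariantKey(gene_id, int(pos), wt, mut), None


def read_score_table(
    path: str | Path,
    format: str = "long_tsv",
    *,
    gene_id: Optional[str] = None,
    source_id: Optional[str] = None,
) -> tuple[ScoreTable, ParseLog]:
    """Read a score table from disk.

    ``long_tsv`` expects the canonical header
    gene/position/wt/mut/source/value. ``mavedb_csv`` expects MaveDB-style
    columns ``hgvs_pro`` and ``score`` and requires ``gene_id`` and
    ``source_id``; rows that are synonymous, multi-substitution, nonsense,
    or unparsable are skipped and counted in the returned ParseLog.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    log = ParseLog()
    if format == "long_tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "source": str})
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: malformed header, missing {missing}")
        log.records_read = len(df)
        keys = set()
        for row in df.itertuples(index=False):
            VariantKey(str(row.gene), int(row.position), str(row.wt), str(row.mut))
            k = (row.gene, row.position, row.wt, row.mut, row.source)
            if k in keys:
                raise ValidationError(f"{path}: duplicate (variant, source) {k}")
            keys.add(k)
        log.records_kept = len(df)
        return ScoreTable(df), log
    if format == "mavedb_csv":
        if gene_id is None or source_id is None:
            raise ValueError("mavedb_csv requires gene_id and source_id")
        df = pd.read_csv(path)
        if "hgvs_pro" not in df.columns or "score" not in df.columns:
            raise FormatError(f"{path}: malformed header, need hgvs_pro and score columns")
        rows = []
        seen: dict[VariantKey, float] = {}
        for hgvs, score in zip(df["hgvs_pro"], df["score"]):
            log.records_read += 1
            if pd.isna(score):
                log.skip("missing_score")
                continue
            key, reason = parse_hgvs_pro(str(hgvs), gene_id)
            if key is None:
                log.skip(reason)
                continue
            if key in seen:
                if seen[key] != float(score):
                    raise ValidationError(f"{path}: conflicting duplicate for {key}")
                log.skip("duplicate")
                continue
            seen[key] = float(score)
            rows.append((gene_id, key.position, key.wt_aa, key.mut_aa, source_id, float(score)))
            log.records_kept += 1
        return ScoreTable(pd.DataFrame(rows, columns=TABLE_COLUMNS)), log
    raise ValueError(f"unknown format {format!r}")


@dataclass
class ValidationReport:
    per_source_counts: dict[str, int]
    orphan_sources: list[str]

    @property
    def ok(self) -> bool:
        return not self.orphan_sources


def validate_against_meta(
    table: ScoreTable, meta: Mapping[str, SourceMeta] | Iterable[SourceMeta]
) -> ValidationReport:
    """Check that every source in the table has exactly one SourceMeta.

    Raises ValidationError naming the orphan sources if any are missing;
    otherwise returns per-source record counts.
    """
    meta_map = as_meta_map(meta)
    counts = table.df["source"].value_counts().to_dict() if len(table) else {}
    orphans = sorted(s for s in counts if s not in meta_map)
    report = ValidationReport(per_source_counts=counts, orphan_sources=orphans)
    if orphans:
        raise ValidationError(f"sources without metadata: {orphans}")
    return report


def as_meta_map(meta: Mapping[str, SourceMeta] | Iterable[SourceMeta]) -> dict[str, SourceMeta]:
    if isinstance(meta, Mapping):
        return dict(meta)
    out: dict[str, SourceMeta] = {}
    for m in meta:
        if m.source_id in out:
            raise ValidationError(f"duplicate metadata for {m.source_id}")
        out[m.source_id] = m
    return out


def read_source_meta(path: str | Path) -> dict[str, SourceMeta]:
    """Read SourceMeta from a YAML mapping keyed by source_id."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for source_id, fields in raw.items():
        fields = dict(fields or {})
        fields.setdefault("source_id", source_id)
        out[source_id] = SourceMeta(**fields)
    return out


def write_source_meta(meta: Mapping[str, SourceMeta], path: str | Path) -> None:
    payload = {}
    for source_id, m in meta.items():
        d = {
            "role": m.role, "direction": m.direction, "units": m.units,
            "assay_class": m.assay_class, "structure_context": m.structure_context,
        }
        if m.wt_reference is not None:
            d["wt_reference"] = float(m.wt_reference)
        payload[source_id] = d
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
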