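"""Synthetic score tables and structure fixtures with planted truth.

A Gaussian copula generates per-variant scores for one pseudo-DMS dataset
plus a panel of pseudo-predictors with an exactly specified Spearman
correlation matrix: latent multivariate-normal draws are pushed through
per-source marginal quantile transforms (which preserve ranks), then
direction flips and MCAR missingness are applied. The planted matrix,
flips and latent effects are returned as a truth record so downstream
stages can be tested against known structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .score_model import ScoreTable, SourceMeta, TABLE_COLUMNS

import pandas as pd

MARGINAL_KINDS = ("gaussian", "ddg_like", "fitness_like")


def spearman_to_latent_pearson(rho_s):
    """Latent Gaussian Pearson correlation giving Spearman ``rho_s``.

    Standard copula identity r = 2*sin(pi*rho_s/6); monotone and odd with
    fixed points at -1, 0, 1.
    """
    arr = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError(f"Spearman correlation out of [-1, 1]: {rho_s}")
    out = 2.0 * np.sin(np.pi * arr / 6.0)
    return float(out) if np.isscalar(rho_s) else out


def latent_pearson_to_spearman(r):
    """Inverse of :func:`spearman_to_latent_pearson`: rho_s = (6/pi)*arcsin(r/2)."""
    arr = np.asarray(r, dtype=float)
    out = (6.0 / np.pi) * np.arcsin(arr / 2.0)
    return float(out) if np.isscalar(r) else out


@dataclass
class SyntheticSpec:
    """Contract for one pseudo-dataset: sources, planted correlations,
    marginals, missingness, direction flips and a seed."""

    source_ids: list[str]
    target_spearman: np.ndarray
    n_variants: int
    marginal_kinds: dict[str, str] = field(default_factory=dict)
    missing_rate: dict[str, float] = field(default_factory=dict)
    direction_flips: dict[str, int] = field(default_factory=dict)
    assay_class: str = "abundance"
    gene_id: str = "SYNTH1"
    dms_source: Optional[str] = None  # defaults to the first source
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_spearman = np.asarray(self.target_spearman, dtype=float)
        k = len(self.source_ids)
        if self.target_spearman.shape != (k, k):
            raise ValueError("target_spearman shape does not match source_ids")
        if not np.allclose(self.target_spearman, self.target_spearman.T):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(self.target_spearman), 1.0):
            raise ValueError("target_spearman must have unit diagonal")
        if np.any(np.abs(self.target_spearman) > 1):
            raise ValueError("target_spearman entries must lie in [-1, 1]")
        if self.dms_source is None:
            self.dms_source = self.source_ids[0]
        for s in self.source_ids:
            self.marginal_kinds.setdefault(s, "gaussian")
            self.missing_rate.setdefault(s, 0.0)
            self.direction_flips.setdefault(s, 1)
        for s, kind in self.marginal_kinds.items():
            if kind not in MARGINAL_KINDS:
                raise ValueError(f"{s}: unknown marginal kind {kind!r}")
        for s, p in self.missing_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{s}: missing_rate {p} outside [0, 1]")
        for s, f in self.direction_flips.items():
            if f not in (1, -1):
                raise ValueError(f"{s}: direction flip must be +1 or -1")

    def latent_pearson(self) -> np.ndarray:
        """Converted latent correlation matrix; raises if not PSD."""
        r = spearman_to_latent_pearson(self.target_spearman)
        np.fill_diagonal(r, 1.0)
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-10:
            raise ValueError(
                f"latent Pearson matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.6g}); no silent repair is applied"
            )
        return r


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a synthetic table."""

    target_spearman: np.ndarray
    latent_pearson: np.ndarray
    source_ids: list[str]
    direction_flips: dict[str, int]
    seed: int
    latent: np.ndarray  # n_variants x k latent Gaussians, pre-transform
    truth_effect: np.ndarray  # designated per-variant true-effect column

    def planted_rho(self, source_a: str, source_b: str) -> float:
        i = self.source_ids.index(source_a)
        j = self.source_ids.index(source_b)
        return float(self.target_spearman[i, j])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_ids": self.source_ids,
            "target_spearman": self.target_spearman.tolist(),
            "latent_pearson": self.latent_pearson.tolist(),
            "direction_flips": self.direction_flips,
            "seed": self.seed,
            "truth_effect": np.round(self.truth_effect, 6).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _mixture_ppf(u: np.ndarray, weights, means, sds) -> np.ndarray:
    """Quantile function of a Gaussian mixture by monotone interpolation.

    The mixture CDF is tabulated on a dense grid spanning the components'
    supports; linear interpolation of its inverse is strictly monotone, so
    ranks (hence Spearman) are preserved exactly up to grid resolution.
    """
    lo = min(m - 8 * s for m, s in zip(means, sds))
    hi = max(m + 8 * s for m, s in zip(means, sds))
    grid = np.linspace(lo, hi, 4096)
    cdf = np.zeros_like(grid)
    for w, m, s in zip(weights, means, sds):
        cdf += w * stats.norm.cdf(grid, loc=m, scale=s)
    return np.interp(u, cdf, grid)


def _marginal_transform(z: np.ndarray, kind: str) -> np.ndarray:
    """Map standard-normal latents through a marginal's quantile function.

    All transforms are strictly increasing, so the copula's rank structure
    is untouched.
    """
    if kind == "gaussian":
        return z
    u = stats.norm.cdf(z)
    if kind == "ddg_like":
        # destabilization-heavy: shifted gamma, mode near 0, long positive tail
        return stats.gamma.ppf(u, a=2.0, scale=1.2) - 1.2
    if kind == "fitness_like":
        # bimodal fitness: functional mode near wild type (1.0), null mode near 0
        return _mixture_ppf(u, weights=(0.55, 0.45), means=(1.0, 0.0), sds=(0.12, 0.2))
    raise ValueError(f"unknown marginal kind {kind!r}")


def generate_scores(
    spec: SyntheticSpec,
) -> tuple[ScoreTable, dict[str, SourceMeta], TruthRecord]:
    """Draw a synthetic ScoreTable + SourceMeta + truth record from ``spec``.

    Identical specs (including seed) produce byte-identical tables. The
    truth-effect column is the latent Gaussian of the designated DMS
    source before flips and missingness.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.source_ids)
    n = spec.n_variants
    corr = spec.latent_pearson()
    # eigen factorization tolerates PSD-but-singular matrices (e.g. rho = 1)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    latent = rng.standard_normal((n, k)) @ factor.T

    positions = np.arange(1, n + 1)
    aa = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
    wt_idx = rng.integers(0, 20, size=n)
    mut_off = rng.integers(1, 20, size=n)
    mut_idx = (wt_idx + mut_off) % 20

    rows = []
    for j, source in enumerate(spec.source_ids):
        vals = _marginal_transform(latent[:, j], spec.marginal_kinds[source])
        vals = vals * spec.direction_flips[source]
        keep = rng.random(n) >= spec.missing_rate[source]
        for i in np.nonzero(keep)[0]:
            rows.append(
                (spec.gene_id, int(positions[i]), aa[wt_idx[i]], aa[mut_idx[i]],
                 source, float(vals[i]))
            )
    table = ScoreTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))

    meta = {}
    for source in spec.source_ids:
        is_dms = source == spec.dms_source
        meta[source] = SourceMeta(
            source_id=source,
            role="dms" if is_dms else "predictor",
            # flipped sources need direction -1 so harmonization restores them
            direction=spec.direction_flips[source],
            units="unitless" if is_dms else "kcal_per_mol",
            assay_class=spec.assay_class if is_dms else "not_applicable",
            structure_context="not_applicable" if is_dms else "monomer",
            wt_reference=None,
        )
    truth = TruthRecord(
        target_spearman=spec.target_spearman.copy(),
        latent_pearson=corr,
        source_ids=list(spec.source_ids),
        direction_flips=dict(spec.direction_flips),
        seed=spec.seed,
        latent=latent,
        truth_effect=latent[:, spec.source_ids.index(spec.dms_source)].copy(),
    )
    return table, meta, truth


def factor_model_spearman(loadings: Sequence[float]) -> np.ndarray:
    """Spearman matrix implied by a one-factor Gaussian model.

    Source j equals loading_j * F + sqrt(1 - loading_j^2) * eps_j on the
    latent scale, so the latent Pearson between j and l is
    loading_j * loading_l; the returned matrix converts that to Spearman.
    Used to plant a shared "true effect" with known per-source fidelity.
    """
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) > 1):
        raise ValueError("factor loadings must lie in [-1, 1]")
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return latent_pearson_to_spearman(r)


def generate_benchmark(
    predictor_rhos: Mapping[str, float],
    n_datasets: int,
    n_variants: int,
    seed: int,
    assay_classes: Optional[Sequence[str]] = None,
    dms_marginal: str = "fitness_like",
    predictor_marginal: str = "ddg_like",
    missing_rate: float = 0.0,
    per_dataset_rhos: Optional[Sequence[Mapping[str, float]]] = None,
) -> tuple[ScoreTable, dict[str, SourceMeta], dict[tuple[str, str], float]]:
    """Multi-dataset benchmark with a shared predictor panel.

    Each pseudo-dataset gets its own gene and DMS source; every predictor
    has the planted Spearman correlation ``predictor_rhos`` with each
    dataset's DMS scores (overridable per dataset via
    ``per_dataset_rhos``). The joint model is a one-factor copula with
    the DMS latent as the factor, so predictor-predictor structure is
    implied rather than separately specified. Returns the combined
    table, metadata, and the planted (dms_id, predictor) -> rho map.
    """
    predictors = list(predictor_rhos)
    if per_dataset_rhos is None:
        per_dataset_rhos = [predictor_rhos] * n_datasets

    def target_for(rhos: Mapping[str, float]) -> np.ndarray:
        lam = np.array([spearman_to_latent_pearson(rhos[p]) for p in predictors])
        latent_r = np.outer(np.concatenate([[1.0], lam]),
                            np.concatenate([[1.0], lam]))
        np.fill_diagonal(latent_r, 1.0)
        target = latent_pearson_to_spearman(latent_r)
        np.fill_diagonal(target, 1.0)
        return target

    rng = np.random.default_rng(seed)
    dataset_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    if assay_classes is None:
        assay_classes = ["abundance"] * n_datasets

    frames, meta, planted = [], {}, {}
    for d in range(n_datasets):
        dms_id = f"dms_{d + 1}"
        rhos_d = per_dataset_rhos[d]
        spec = SyntheticSpec(
            source_ids=[dms_id] + predictors,
            target_spearman=target_for(rhos_d),
            n_variants=n_variants,
            marginal_kinds={dms_id: dms_marginal,
                            **{p: predictor_marginal for p in predictors}},
            missing_rate={s: missing_rate for s in [dms_id] + predictors},
            assay_class=assay_classes[d],
            gene_id=f"GENE{d + 1}",
            dms_source=dms_id,
            seed=int(dataset_seeds[d]),
        )
        table_d, meta_d, _ = generate_scores(spec)
        frames.append(table_d.df)
        meta.update(meta_d)
        for p in predictors:
            planted[(dms_id, p)] = float(rhos_d[p])
    table = ScoreTable(pd.concat(frames, ignore_index=True))
    return table, meta, planted


# ---------------------------------------------------------------------------
# Structure fixtures
# ---------------------------------------------------------------------------

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureChain:
    chain_id: str
    sequence: str
    first_resnum: int = 1
    # positions (1-based in the chain sequence) that get a duplicate CA with altloc B
    altloc_positions: tuple[int, ...] = ()


@dataclass
class FixtureStructure:
    """Declarative description of a minimal PDB fixture."""

    structure_id: str
    chains: list[FixtureChain]
    resolution: Optional[float] = 2.0  # None => NMR-style, no REMARK 2 value
    # each assembly: list of (chain_id, n_copies); defaults to one assembly of all chains
    assemblies: Optional[list[list[tuple[str, int]]]] = None
    n_models: int = 1


def _seqres_lines(chain_id: str, sequence: str) -> list[str]:
    lines = []
    res3 = [ONE_TO_THREE[a] for a in sequence]
    for i in range(0, len(res3), 13):
        chunk = " ".join(res3[i : i + 13])
        lines.append(f"SEQRES {i // 13 + 1:3d} {chain_id} {len(res3):4d}  {chunk}")
    return lines


def _biomt(op_index: int, shift: float) -> list[str]:
    rows = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
    out = []
    for r, (a, b, c) in enumerate(rows, start=1):
        t = shift if r == 1 else 0.0
        out.append(
            f"REMARK 350   BIOMT{r} {op_index:3d} {a:9.6f} {b:9.6f} {c:9.6f} {t:14.5f}"
        )
    return out


def write_fixture_pdb(fixture: FixtureStructure, path: str | Path) -> Path:
    """Write a minimal, parseable PDB file for one fixture structure.

    Emits SEQRES, CA-only ATOM records with sequential numbering, REMARK 2
    resolution, REMARK 350 biological-assembly transforms, optional altloc
    duplicates and multiple MODELs (NMR-style).
    """
    path = Path(path)
    # PDB HEADER columns: classification 11-50, depDate 51-59, idCode 63-66
    lines = [f"HEADER    {'SYNTHETIC FIXTURE':<40s}{'01-JAN-00':<9s}   {fixture.structure_id:<4s}"]
    if fixture.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {fixture.resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    assemblies = fixture.assemblies
    if assemblies is None:
        assemblies = [[(c.chain_id, 1) for c in fixture.chains]]
    for bi, asm in enumerate(assemblies, start=1):
        lines.append(f"REMARK 350 BIOMOLECULE: {bi}")
        for chain_id, n_copies in asm:
            lines.append(f"REMARK 350 APPLY THE FOLLOWING TO CHAINS: {chain_id}")
            for op in range(1, n_copies + 1):
                lines += _biomt(op, shift=(op - 1) * 50.0)
    for chain in fixture.chains:
        lines += _seqres_lines(chain.chain_id, chain.sequence)

    serial = 1

    def atom_lines() -> list[str]:
        nonlocal serial
        out = []
        for chain in fixture.chains:
            for i, aa in enumerate(chain.sequence):
                resnum = chain.first_resnum + i
                alts = [" "]
                if (i + 1) in chain.altloc_positions:
                    alts = ["A", "B"]
                for ai, alt in enumerate(alts):
                    x = 3.8 * i + 0.1 * ai
                    occ = 1.0 if alt == " " else (0.6 if alt == "A" else 0.4)
                    out.append(
                        f"ATOM  {serial:5d}  CA {alt}{ONE_TO_THREE[aa]} "
                        f"{chain.chain_id}{resnum:4d}    "
                        f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{occ:6.2f}{0.0:6.2f}"
                        f"           C"
                    )
                    serial += 1
            out.append(f"TER   {serial:5d}      {ONE_TO_THREE[chain.sequence[-1]]} "
                       f"{chain.chain_id}{chain.first_resnum + len(chain.sequence) - 1:4d}")
            serial += 1
        return out

    if fixture.n_models > 1:
        for mi in range(1, fixture.n_models + 1):
            lines.append(f"MODEL     {mi:4d}")
            lines += atom_lines()
            lines.append("ENDMDL")
    else:
        lines += atom_lines()
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def generate_fixture_structures(
    fixtures: Sequence[FixtureStructure], out_dir: str | Path
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_fixture_pdb(f, out_dir / f"{f.structure_id}.pdb") for f in fixtures]
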