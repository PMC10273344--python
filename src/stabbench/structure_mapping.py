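"""Variant-to-structure mapping.

Maps single amino acid variants onto experimental structures using three
rules: (1) a chain is eligible when it aligns to the human reference
protein with strictly more than 90% identity over at least 50 aligned
residues; (2) for non-human chains, the variant residue and its aligned
immediate neighbors must match the human wild-type sequence; (3) among
admissible candidates, best resolution wins, then largest (first)
biological assembly, then lexicographic structure id. Variants with no
admissible experimental structure fall back to AlphaFold-model positions
(UniProt numbering); the rest are unmapped with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

from .score_model import VariantKey

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

MIN_IDENTITY = 0.90   # strict: eligibility requires identity > this
MIN_ALIGNED_LENGTH = 50


@dataclass
class ChainRecord:
    structure_id: str
    chain_id: str
    sequence: str
    residue_numbers: list[int]
    is_human_entry: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.structure_id}/{self.chain_id}: empty chain")
        if len(self.sequence) != len(self.residue_numbers):
            raise ValueError("sequence and residue numbering lengths differ")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")


@dataclass
class StructureRecord:
    structure_id: str
    resolution: Optional[float]  # Angstroms; None for NMR/models
    experimental_method: str     # xray | cryoem | nmr | model
    assemblies: list[list[str]]  # multisets of chain ids, file order
    chains: list[ChainRecord]
    n_frames: int = 1

    def __post_init__(self) -> None:
        if not self.assemblies:
            raise ValueError(f"{self.structure_id}: needs at least one assembly")
        if self.experimental_method == "nmr" and self.n_frames < 1:
            raise ValueError("NMR records carry a frame count >= 1")

    @property
    def first_assembly_size(self) -> int:
        return len(self.assemblies[0])


@dataclass
class AlignedRegion:
    """Aligned (non-gap) column pairs between a chain and the human sequence."""

    human_to_chain: dict[int, int]   # 1-based human position -> chain sequence index
    n_aligned: int
    n_identical: int

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_aligned if self.n_aligned else 0.0


@dataclass
class MappingResult:
    variant: VariantKey
    target_kind: str  # pdb | alphafold | unmapped
    structure_id: Optional[str] = None
    chain_id: Optional[str] = None
    residue_number: Optional[int] = None
    uniprot_position: Optional[int] = None
    provenance: list[str] = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "local"
    return al


def align_chain(chain_sequence: str, human_sequence: str) -> AlignedRegion:
    """Affine-gap alignment of a chain against the full human sequence.

    Identity is computed over aligned (non-gap) columns only; the region
    length is the number of such columns.
    """
    aln = _aligner().align(human_sequence, chain_sequence)[0]
    human_to_chain: dict[int, int] = {}
    n_ident = 0
    for (hs, he), (cs, ce) in zip(*aln.aligned):
        for off in range(he - hs):
            hpos = hs + off + 1  # 1-based human position
            cidx = cs + off
            human_to_chain[hpos] = cidx
            if human_sequence[hpos - 1] == chain_sequence[cidx]:
                n_ident += 1
    return AlignedRegion(human_to_chain, len(human_to_chain), n_ident)


def chain_eligibility(
    chain: ChainRecord, human_sequence: str
) -> tuple[bool, AlignedRegion]:
    """Eligible iff identity strictly > 90% over >= 50 aligned residues."""
    if not human_sequence:
        raise ValueError("human sequence is empty")
    region = align_chain(chain.sequence, human_sequence)
    eligible = (
        region.n_aligned >= MIN_ALIGNED_LENGTH and region.identity > MIN_IDENTITY
    )
    return eligible, region


def nonhuman_residue_check(
    chain: ChainRecord,
    variant: VariantKey,
    human_sequence: str,
    region: AlignedRegion,
) -> tuple[bool, str]:
    """Non-human chains: variant residue and aligned neighbors must match
    the human wild type.

    Neighbors that do not exist (sequence or alignment terminus) are
    skipped; an aligned neighbor that differs rejects the candidate.
    """
    pos = variant.position
    if pos not in region.human_to_chain:
        return False, "outside aligned region"
    if chain.sequence[region.human_to_chain[pos]] != human_sequence[pos - 1]:
        return False, "residue differs from human wild type"
    for npos in (pos - 1, pos + 1):
        if npos < 1 or npos > len(human_sequence):
            continue  # human terminus: neighbor does not exist
        cidx = region.human_to_chain.get(npos)
        if cidx is None:
            continue  # no aligned chain residue at this neighbor
        if chain.sequence[cidx] != human_sequence[npos - 1]:
            return False, f"neighbor at human position {npos} differs"
    return True, "residue and aligned neighbors match"


@dataclass
class Candidate:
    structure: StructureRecord
    chain: ChainRecord
    residue_number: int


def select_structure(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Order admissible candidates by the mapping preference.

    Best (lowest) resolution first; unresolved structures (NMR, models)
    sort after all resolved ones; then largest first biological assembly;
    then lexicographic structure id as the final deterministic tie-break.
    """
    return sorted(
        candidates,
        key=lambda c: (
            c.structure.resolution if c.structure.resolution is not None else float("inf"),
            -c.structure.first_assembly_size,
            c.structure.structure_id,
            c.chain.chain_id,
        ),
    )


def read_structure(
    path: str | Path, human_chain_ids: Iterable[str] = ()
) -> StructureRecord:
    """Parse a PDB or mmCIF file into a StructureRecord.

    Altloc duplicates collapse to the first occurring entry, NMR ensembles
    reduce to the first model, and assemblies keep file order so "first
    biological assembly" is well defined. Chains listed in
    ``human_chain_ids`` are flagged as human entries.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unparsable structure file: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    info = dict(st.info)
    structure_id = (info.get("_entry.id", "") or st.name or path.stem).strip() or path.stem
    n_frames = len(st)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if n_frames > 1:
        method, resolution = "nmr", None
    elif resolution is None:
        method = "model"
    else:
        method = "xray"

    human = set(human_chain_ids)
    model = st[0]  # NMR: first frame only
    chains: list[ChainRecord] = []
    for ch in model:
        seq, nums = [], []
        seen: set[int] = set()
        for res in ch:
            one = _THREE_TO_ONE.get(res.name)
            if one is None:
                continue  # hetero/non-standard residues are not mapping targets
            num = res.seqid.num
            if num in seen:
                continue  # microheterogeneity: first occurring entry wins
            seen.add(num)
            seq.append(one)
            nums.append(num)
        if seq:
            chains.append(
                ChainRecord(structure_id, ch.name, "".join(seq), nums,
                            is_human_entry=ch.name in human)
            )
    if not chains:
        raise ValueError(f"{path}: no polymer chains with standard residues")

    assemblies: list[list[str]] = []
    for asm in st.assemblies:
        members: list[str] = []
        for gen in asm.generators:
            for _ in gen.operators:
                members.extend(gen.chains)
        if members:
            assemblies.append(members)
    if not assemblies:
        assemblies = [[c.chain_id for c in chains]]
    return StructureRecord(structure_id, resolution, method, assemblies, chains, n_frames)


def map_variants(
    variants: Iterable[VariantKey],
    structures: Sequence[StructureRecord],
    human_sequences: Mapping[str, str],
    gene_chains: Optional[Mapping[str, set[tuple[str, str]]]] = None,
) -> list[MappingResult]:
    """Map each variant to its preferred structure residue.

    ``human_sequences`` gives the reference protein per gene.
    ``gene_chains`` optionally restricts which (structure_id, chain_id)
    pairs belong to each gene; by default every chain is tested against
    every gene's sequence and eligibility decides.
    Every variant lands in exactly one of {pdb, alphafold, unmapped}.
    """
    # eligibility is per (gene, structure, chain): cache the alignments
    eligibility: dict[tuple[str, str, str], tuple[bool, AlignedRegion]] = {}

    def eligible_region(gene: str, st: StructureRecord, ch: ChainRecord):
        key = (gene, st.structure_id, ch.chain_id)
        if key not in eligibility:
            eligibility[key] = chain_eligibility(ch, human_sequences[gene])
        return eligibility[key]

    results: list[MappingResult] = []
    for variant in variants:
        gene = variant.gene_id
        prov: list[str] = []
        if gene not in human_sequences:
            results.append(MappingResult(variant, "unmapped",
                                         provenance=["no human sequence for gene"]))
            continue
        seq = human_sequences[gene]
        if variant.position > len(seq):
            results.append(MappingResult(variant, "unmapped",
                                         provenance=["position out of range"]))
            continue
        if seq[variant.position - 1] != variant.wt_aa:
            results.append(MappingResult(
                variant, "unmapped",
                provenance=["wild-type mismatch with reference sequence"]))
            continue

        candidates: list[Candidate] = []
        for st in structures:
            for ch in st.chains:
                if gene_chains is not None and (
                    (st.structure_id, ch.chain_id) not in gene_chains.get(gene, set())
                ):
                    continue
                ok, region = eligible_region(gene, st, ch)
                label = f"{st.structure_id}/{ch.chain_id}"
                if not ok:
                    prov.append(
                        f"{label}: ineligible (identity {region.identity:.3f} "
                        f"over {region.n_aligned} aligned residues)"
                    )
                    continue
                cidx = region.human_to_chain.get(variant.position)
                if cidx is None:
                    prov.append(f"{label}: outside aligned region")
                    continue
                if ch.sequence[cidx] != variant.wt_aa:
                    prov.append(f"{label}: residue differs from human wild type")
                    continue
                if not ch.is_human_entry:
                    ok_nh, why = nonhuman_residue_check(ch, variant, seq, region)
                    if not ok_nh:
                        prov.append(f"{label}: {why}")
                        continue
                    prov.append(f"{label}: non-human chain admitted ({why})")
                else:
                    prov.append(f"{label}: human chain admitted")
                candidates.append(Candidate(st, ch, ch.residue_numbers[cidx]))

        if candidates:
            best = select_structure(candidates)[0]
            prov.append(
                f"selected {best.structure.structure_id}/{best.chain.chain_id} "
                f"(resolution {best.structure.resolution}, "
                f"assembly size {best.structure.first_assembly_size})"
            )
            results.append(MappingResult(
                variant, "pdb",
                structure_id=best.structure.structure_id,
                chain_id=best.chain.chain_id,
                residue_number=best.residue_number,
                provenance=prov,
            ))
        else:
            prov.append("no admissible experimental structure; AlphaFold fallback")
            results.append(MappingResult(
                variant, "alphafold",
                uniprot_position=variant.position,
                provenance=prov,
            ))
    return results


def write_mapping_report(results: Sequence[MappingResult], path: str | Path) -> None:
    """Mapping report TSV: one row per variant with target and provenance."""
    with open(path, "w") as fh:
        fh.write("gene\tposition\twt\tmut\ttarget_kind\tstructure_id\tchain\t"
                 "residue_number\tprovenance\n")
        for r in results:
            v = r.variant
            fh.write(
                f"{v.gene_id}\t{v.position}\t{v.wt_aa}\t{v.mut_aa}\t{r.target_kind}\t"
                f"{r.structure_id or ''}\t{r.chain_id or ''}\t"
                f"{r.residue_number if r.residue_number is not None else ''}\t"
                f"{'; '.join(r.provenance)}\n"
            )
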