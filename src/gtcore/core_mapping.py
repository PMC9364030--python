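"""GT-A core-position definitions and alignment-column ↔ structure-residue mapping.

The GT-A catalytic domain is described on a 231-column consensus alignment.
A small set of those columns form the conserved hydrophobic core, split into
three (overlapping) evolutionary layers:

* ``PBC`` — the miniature core of the phosphate-binding cassette,
* ``ROSSMANN_SHARED`` — positions shared with Rossmann-fold enzymes at large
  (they tether the PBC to the N-lobe),
* ``GTA_SPECIFIC`` — positions unique to GT-As, tethering the PBC to the
  C-lobe αF-helix that carries the catalytic base (the xED-Asp).

The C-lobe tether proper is the column pair (156, 183); the xED-Asp sits at
column 180.  Exemplar residue labels use GT2 numbering (PDB 2Z87).

Position maps connecting alignment columns to author residue numbers per
structure chain are consumed as TSV (they originate from profile-HMM
alignments produced elsewhere; building profiles is out of scope here).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio import SeqIO

from .structure_io import Residue, StructureModel

logger = logging.getLogger(__name__)

N_COLUMNS = 231

# column -> exemplar residue label in GT2 (PDB 2Z87) numbering
CORE_EXEMPLARS = {
    1: "I154",
    2: "V155",
    3: "I156",
    13: "L165",
    17: "L169",
    20: "L172",
    32: "V183",
    33: "I184",
    34: "V185",
    86: "V235",
    87: "A236",
    100: "V249",
    156: "F340",
    183: "F365",
}


class Mechanism(str, Enum):
    INVERTING = "inverting"
    RETAINING = "retaining"
    RETAINING_GT2_RELATED = "retaining_gt2_related"
    UNKNOWN = "unknown"

    @property
    def is_retaining(self) -> bool:
        return self in (Mechanism.RETAINING, Mechanism.RETAINING_GT2_RELATED)


@dataclass(frozen=True)
class CoreDefinition:
    """The published hydrophobic-core column sets (membership is by sets, not a
    partition: column 100 belongs to both the PBC and the GT-A-specific layer,
    and 86/87 to both the PBC and the Rossmann-shared layer)."""

    pbc: frozenset = frozenset({86, 87, 100})
    rossmann_shared: frozenset = frozenset({1, 2, 3, 13, 17, 20, 32, 33, 34, 86, 87})
    gta_specific: frozenset = frozenset({100, 156, 183})
    tether_pair: tuple = (156, 183)
    xed_column: int = 180
    n_columns: int = N_COLUMNS
    exemplars: dict = field(default_factory=lambda: dict(CORE_EXEMPLARS))

    @property
    def all_core(self) -> frozenset:
        return self.pbc | self.rossmann_shared | self.gta_specific

    def category(self, column: int) -> set:
        out = set()
        if column in self.pbc:
            out.add("PBC")
        if column in self.rossmann_shared:
            out.add("ROSSMANN_SHARED")
        if column in self.gta_specific:
            out.add("GTA_SPECIFIC")
        return out


@dataclass
class ChainMap:
    """Column → author residue number for one structure chain."""

    structure: str
    chain: str
    columns: dict[int, int]
    family: str = ""
    mechanism: Mechanism = Mechanism.UNKNOWN

    def residue_to_column(self) -> dict[int, int]:
        return {v: k for k, v in self.columns.items()}


@dataclass
class PositionMap:
    """Alignment column ↔ structure residue correspondences, per chain."""

    entries: dict[tuple[str, str], ChainMap] = field(default_factory=dict)

    def chains(self):
        return list(self.entries)

    def get(self, structure: str, chain: str) -> ChainMap | None:
        return self.entries.get((structure, chain))

    def chain_for_model(self, model: StructureModel) -> ChainMap | None:
        """Find the entry for a (possibly chain-split) model.

        Accepts either pdb_id == structure with a single chain, or the
        ``pdbid_chain`` naming produced by ``split_chains``.
        """
        for chain_id in model.chains:
            cm = self.get(model.pdb_id, chain_id)
            if cm is not None:
                return cm
            if model.pdb_id.endswith(f"_{chain_id}"):
                cm = self.get(model.pdb_id[: -len(chain_id) - 1], chain_id)
                if cm is not None:
                    return cm
        return None


REQUIRED_PMAP_COLUMNS = ["structure", "chain", "column", "res_seq", "family", "mechanism"]


def load_position_map(source) -> PositionMap:
    """Load a position map from TSV (path, buffer, or DataFrame).

    Required columns: structure, chain, column, res_seq, family, mechanism.
    Unmapped alignment columns are simply absent (deletions); duplicate
    (structure, chain, column) rows and out-of-range columns are errors.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = [c for c in REQUIRED_PMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"position map missing required column(s): {missing}")
    bad = df[(df["column"] < 1) | (df["column"] > N_COLUMNS)]
    if len(bad):
        raise ValueError(
            f"position map column outside [1, {N_COLUMNS}]: "
            f"{sorted(bad['column'].unique())[:5]}"
        )
    dup = df.duplicated(subset=["structure", "chain", "column"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate position-map row for ({first['structure']}, "
            f"{first['chain']}, column {first['column']})"
        )
    pmap = PositionMap()
    for (structure, chain), sub in df.groupby(["structure", "chain"], sort=False):
        fam = str(sub["family"].iloc[0])
        try:
            mech = Mechanism(str(sub["mechanism"].iloc[0]).lower())
        except ValueError:
            mech = Mechanism.UNKNOWN
        cols = dict(zip(sub["column"].astype(int), sub["res_seq"].astype(int)))
        if sorted(cols) != list(cols):
            cols = dict(sorted(cols.items()))
        pmap.entries[(str(structure), str(chain))] = ChainMap(
            structure=str(structure), chain=str(chain), columns=cols,
            family=fam, mechanism=mech,
        )
    return pmap


def position_map_frame(pmap: PositionMap) -> pd.DataFrame:
    """Inverse of :func:`load_position_map` (for writing TSV)."""
    rows = []
    for cm in pmap.entries.values():
        for col, res in cm.columns.items():
            rows.append(
                dict(structure=cm.structure, chain=cm.chain, column=col,
                     res_seq=res, family=cm.family, mechanism=cm.mechanism.value)
            )
    return pd.DataFrame(rows, columns=REQUIRED_PMAP_COLUMNS)


def resolve_columns(
    model: StructureModel, pmap: PositionMap, columns
) -> list[tuple[int, Residue | None]]:
    """Return the structure residue for each requested alignment column.

    A column maps to ``None`` when it is unmapped for this chain or the
    mapped residue is missing from the coordinates (disordered region);
    both absences are logged.  A chain absent from the map is an error.
    """
    cm = pmap.chain_for_model(model)
    if cm is None:
        raise KeyError(f"no position-map entry for structure {model.pdb_id!r}")
    out = []
    for col in columns:
        res_seq = cm.columns.get(int(col))
        if res_seq is None:
            logger.debug("%s: column %d unmapped", model.pdb_id, col)
            out.append((int(col), None))
            continue
        res = model.get_residue(cm.chain, res_seq)
        if res is None:
            logger.debug(
                "%s: column %d maps to residue %d absent from coordinates",
                model.pdb_id, col, res_seq,
            )
        out.append((int(col), res))
    return out


# ---------------------------------------------------------------------------
# alignment-level summaries


@dataclass
class AlignmentSet:
    """A gapped multiple sequence alignment with per-sequence group labels."""

    ids: list[str]
    groups: list[str]
    sequences: list[str]
    n_columns: int

    def __post_init__(self):
        for s in self.sequences:
            if len(s) != self.n_columns:
                raise ValueError("all sequences must share the alignment length")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, column: int) -> str:
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} outside [1, {self.n_columns}]")
        return "".join(s[column - 1] for s in self.sequences)


def read_alignment(fasta_source, group_of=None) -> AlignmentSet:
    """Read a gapped FASTA alignment.

    ``group_of`` maps a record id to its group label (callable or dict);
    default takes the substring after the last '|' in the id, else ''.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        raise ValueError("empty alignment")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if group_of is None:
        groups = [i.rsplit("|", 1)[1] if "|" in i else "" for i in ids]
    elif callable(group_of):
        groups = [group_of(i) for i in ids]
    else:
        groups = [group_of.get(i, "") for i in ids]
    return AlignmentSet(ids=ids, groups=groups, sequences=seqs, n_columns=len(seqs[0]))


def column_frequencies(
    aln: AlignmentSet, column: int, top_k: int = 10
) -> dict[str, list[tuple[str, float]]]:
    """Top-k residue frequencies at one column, per sequence group.

    Fractions are over non-gap characters; ties sort alphabetically.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    col = aln.column(column)
    out: dict[str, list[tuple[str, float]]] = {}
    for group in dict.fromkeys(aln.groups):
        chars = [c for c, g in zip(col, aln.groups) if g == group and c != "-"]
        counts = Counter(chars)
        total = sum(counts.values())
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        out[group] = [(aa, n / total) for aa, n in ranked] if total else []
    return out


def gap_percentages(aln: AlignmentSet) -> np.ndarray:
    """Percentage of gap characters per column, over all sequences."""
    arr = np.array([list(s) for s in aln.sequences])
    return 100.0 * (arr == "-").mean(axis=0)


def column_entropy(aln: AlignmentSet, base: float = 2.0) -> np.ndarray:
    """Shannon entropy per column over non-gap residues.

    A plain descriptive conservation score for plots; it is *not* an
    evolutionary-rate estimate (no tree, no substitution model).
    """
    out = np.zeros(aln.n_columns)
    for j in range(aln.n_columns):
        chars = [s[j] for s in aln.sequences if s[j] != "-"]
        if not chars:
            out[j] = np.nan
            continue
        counts = np.array(list(Counter(chars).values()), dtype=float)
        p = counts / counts.sum()
        out[j] = -(p * np.log(p)).sum() / math.log(base)
    return out
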