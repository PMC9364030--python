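"""Read, split, filter, and write PDB-format structures and multi-model trajectories.

Coordinates are held in a small chain/residue/atom hierarchy
(:class:`StructureModel`) that every downstream analysis consumes.  Parsing
is delegated to Biopython's ``Bio.PDB`` machinery; a light pre-scan adds the
line-number diagnostics that permissive PDB parsers swallow.

Only the PDB format is supported (ATOM/HETATM/MODEL/ENDMDL/REMARK 2).
Trajectories are multi-model PDB files; binary formats (DCD/XTC) and
mmCIF are out of scope.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; names the offending line."""


class TopologyError(ValueError):
    """Raised when trajectory frames disagree on their atom set."""


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,)

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class Residue:
    """One residue of one chain, keyed by author numbering.

    ``icode`` carries the (rare) PDB insertion code so that e.g. 52 and 52A
    remain distinct keys.
    """

    chain_id: str
    res_seq: int
    res_name: str
    atoms: list[Atom]
    icode: str = ""

    @property
    def res_key(self) -> str:
        return f"{self.res_seq}{self.icode}"

    @property
    def is_water(self) -> bool:
        return self.res_name == "HOH"

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in STANDARD_AA or self.res_name == "UNK"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names=None, heavy_only: bool = True) -> np.ndarray:
        sel = [
            a
            for a in self.atoms
            if (names is None or a.name in names) and not (heavy_only and a.is_hydrogen)
        ]
        if not sel:
            return np.empty((0, 3))
        return np.stack([a.coords for a in sel])


@dataclass
class StructureModel:
    """A single coordinate model: residues grouped by chain, plus header data."""

    pdb_id: str
    model_index: int = 0
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    meta: dict = field(default_factory=dict)

    def residues(self):
        for reslist in self.chains.values():
            yield from reslist

    def get_residue(self, chain_id: str, res_seq: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.res_seq == res_seq and r.icode == icode:
                return r
        return None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def atom_keys(self) -> frozenset:
        return frozenset(
            (r.chain_id, r.res_key, a.name) for r in self.residues() for a in r.atoms
        )

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the amino-acid residues of a chain, in order."""
        from Bio.Data.IUPACData import protein_letters_3to1

        out = []
        for r in self.chains.get(chain_id, []):
            if r.is_amino_acid:
                out.append(protein_letters_3to1.get(r.res_name.capitalize(), "X"))
        return "".join(out)


@dataclass
class FrameSeries:
    """An ordered trajectory of models sharing a single topology."""

    frames: list[StructureModel]
    frame_interval: float | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# parsing


def _prescan(pdb_text: str) -> float | None:
    """Validate coordinate fields line-by-line; return REMARK 2 resolution."""
    resolution = None
    n_atom_lines = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            n_atom_lines += 1
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed {what} coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None
        elif rec == "REMARK" and line[7:10].strip() == "2" and "RESOLUTION" in line:
            tail = line.split("RESOLUTION", 1)[1].lstrip(". ")
            for tok in tail.split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
    if n_atom_lines == 0:
        raise PDBParseError("no ATOM/HETATM records found (empty input?)")
    return resolution


def parse_structure(pdb_text: str, pdb_id: str = "struct") -> list[StructureModel]:
    """Parse PDB text into one :class:`StructureModel` per MODEL record.

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties go to the first-listed, conventionally altloc A).  Waters are
    retained as HOH residues; hydrogens are parsed and flagged.
    """
    resolution = _prescan(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure(pdb_id, io.StringIO(pdb_text))
    if resolution is None:
        resolution = bio_struct.header.get("resolution")

    models: list[StructureModel] = []
    for mi, bio_model in enumerate(bio_struct):
        model = StructureModel(pdb_id=pdb_id, model_index=mi, resolution=resolution)
        for bio_chain in bio_model:
            reslist: list[Residue] = []
            for bio_res in bio_chain:
                hetflag, resseq, icode = bio_res.get_id()
                res_name = bio_res.get_resname().strip()
                if hetflag == "W":
                    res_name = "HOH"
                atoms = []
                for bio_atom in bio_res:
                    # DisorderedAtom delegates to its highest-occupancy child.
                    # Coordinates are snapped back to the file's fixed 3-decimal
                    # precision (the parser holds them as float32 internally).
                    atoms.append(
                        Atom(
                            name=bio_atom.get_name(),
                            element=(bio_atom.element or "").strip() or _guess_element(bio_atom.get_name()),
                            coords=np.round(np.array(bio_atom.get_coord(), dtype=float), 3),
                        )
                    )
                if atoms:
                    reslist.append(
                        Residue(
                            chain_id=bio_chain.id,
                            res_seq=int(resseq),
                            res_name=res_name,
                            atoms=atoms,
                            icode=icode.strip(),
                        )
                    )
            if reslist:
                model.chains[bio_chain.id] = reslist
        models.append(model)
    return models


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # element-aligned: single-letter elements start in column 14
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(models, resolution: float | None = None) -> str:
    """Serialize one model or a list of models to PDB text.

    Multi-model input gets MODEL/ENDMDL framing (trajectory convention).
    Coordinates are fixed-width %8.3f, the PDB precision.
    """
    if isinstance(models, StructureModel):
        models = [models]
    models = list(models)
    lines: list[str] = []
    res = resolution if resolution is not None else models[0].resolution
    if res is not None:
        lines.append(f"REMARK   2 RESOLUTION. {res:8.2f} ANGSTROMS.")
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 0
        for chain_id in model.chains:
            for r in model.chains[chain_id]:
                record = "HETATM" if (r.is_water or not r.is_amino_acid) else "ATOM  "
                for a in r.atoms:
                    serial += 1
                    lines.append(
                        f"{record}{min(serial, 99999):5d} "
                        f"{_format_atom_name(a.name, a.element)} "
                        f"{r.res_name:<3s} {chain_id:1s}{r.res_seq:4d}{r.icode or ' ':1s}   "
                        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
                    )
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# operations


def split_chains(model: StructureModel) -> list[StructureModel]:
    """Split a model into one single-chain model per amino-acid-bearing chain.

    Each output keeps the parent resolution and gets ``pdb_id + '_' + chain``.
    Waters stay with the chain whose id they share.
    """
    out = []
    for chain_id, reslist in model.chains.items():
        if not any(r.is_amino_acid for r in reslist):
            continue
        child = StructureModel(
            pdb_id=f"{model.pdb_id}_{chain_id}",
            model_index=model.model_index,
            chains={chain_id: reslist},
            resolution=model.resolution,
            meta=dict(model.meta, parent=model.pdb_id),
        )
        out.append(child)
    return out


def filter_by_resolution(models, max_res: float = 2.5) -> list[StructureModel]:
    """Keep models with resolution strictly below ``max_res`` Å.

    Models lacking a resolution (NMR, predicted) are dropped and logged.
    """
    if max_res <= 0:
        raise ValueError("max_res must be positive")
    kept = []
    n_missing = 0
    for m in models:
        if m.resolution is None:
            n_missing += 1
            continue
        if m.resolution < max_res:
            kept.append(m)
    if n_missing:
        logger.warning(
            "filter_by_resolution: dropped %d model(s) with no recorded resolution",
            n_missing,
        )
    return kept


def read_trajectory(multi_model_pdb: str, frame_interval: float | None = None) -> FrameSeries:
    """Read a multi-model PDB as a trajectory, enforcing one shared topology."""
    frames = parse_structure(multi_model_pdb, pdb_id="traj")
    ref_keys = frames[0].atom_keys()
    for i, frame in enumerate(frames[1:], start=1):
        if frame.atom_keys() != ref_keys:
            raise TopologyError(
                f"frame {i} atom set differs from frame 0 "
                f"(e.g. {sorted(ref_keys ^ frame.atom_keys())[:3]})"
            )
    return FrameSeries(frames=frames, frame_interval=frame_interval)
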