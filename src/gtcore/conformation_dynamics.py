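"""Side-chain dihedral analysis and D-in/D-out state occupancy.

The catalytic base of inverting GT-As (the xED-Asp) flips between two
rotameric conformations: buried and water-coordinated ("D-in") versus
acceptor-facing ("D-out").  This module computes chi1/chi2 torsions per
frame of a multi-model-PDB trajectory, assigns each frame to the nearest
reference conformation on the (chi1, chi2) torus, and summarizes the
per-replicate D-in:D-out occupancy ratio.  A distance-only water-bridge
detector reports waters simultaneously coordinating the Asp carboxylate
and a partner hydroxyl (the T336-style tether water).

Reference (chi1, chi2) pairs are user-supplied — typically measured from
the two conformers seen in a crystal structure — because the states are
defined operationally, not by fixed angular windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structure_io import FrameSeries, Residue, StructureModel

logger = logging.getLogger(__name__)


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    IUPAC sign convention: looking down the p2→p3 bond, a clockwise
    rotation from the p1 side to the p4 side is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang) if ang != -180.0 else 180.0


def wrap_angle(a: float) -> float:
    """Wrap degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else float(a)


def canonicalize_chi2(chi2: float) -> float:
    """Fold an Asp/Asn-like chi2 into (-90, 90].

    The Asp carboxylate is 2-fold symmetric (OD1/OD2 interchange shifts
    chi2 by 180°); folding removes the labelling ambiguity.
    """
    a = wrap_angle(chi2)
    if a > 90.0:
        a -= 180.0
    elif a <= -90.0:
        a += 180.0
    return float(a)


# chi-defining atom quartets (standard rotamer-library definitions)
CHI1_ATOMS = {
    "ARG": ("N", "CA", "CB", "CG"), "ASN": ("N", "CA", "CB", "CG"),
    "ASP": ("N", "CA", "CB", "CG"), "CYS": ("N", "CA", "CB", "SG"),
    "GLN": ("N", "CA", "CB", "CG"), "GLU": ("N", "CA", "CB", "CG"),
    "HIS": ("N", "CA", "CB", "CG"), "ILE": ("N", "CA", "CB", "CG1"),
    "LEU": ("N", "CA", "CB", "CG"), "LYS": ("N", "CA", "CB", "CG"),
    "MET": ("N", "CA", "CB", "CG"), "PHE": ("N", "CA", "CB", "CG"),
    "PRO": ("N", "CA", "CB", "CG"), "SER": ("N", "CA", "CB", "OG"),
    "THR": ("N", "CA", "CB", "OG1"), "TRP": ("N", "CA", "CB", "CG"),
    "TYR": ("N", "CA", "CB", "CG"), "VAL": ("N", "CA", "CB", "CG1"),
}
CHI2_ATOMS = {
    "ARG": ("CA", "CB", "CG", "CD"), "ASN": ("CA", "CB", "CG", "OD1"),
    "ASP": ("CA", "CB", "CG", "OD1"), "GLN": ("CA", "CB", "CG", "CD"),
    "GLU": ("CA", "CB", "CG", "CD"), "HIS": ("CA", "CB", "CG", "ND1"),
    "ILE": ("CA", "CB", "CG1", "CD1"), "LEU": ("CA", "CB", "CG", "CD1"),
    "LYS": ("CA", "CB", "CG", "CD"), "MET": ("CA", "CB", "CG", "SD"),
    "PHE": ("CA", "CB", "CG", "CD1"), "PRO": ("CA", "CB", "CG", "CD"),
    "TRP": ("CA", "CB", "CG", "CD1"), "TYR": ("CA", "CB", "CG", "CD1"),
}


@dataclass(frozen=True)
class DihedralPair:
    chi1: float | None
    chi2: float | None
    frame_index: int = 0


def chi_angles(res: Residue, frame_index: int = 0) -> DihedralPair:
    """chi1/chi2 from the standard atom quartets; None when undefined.

    Residues without a chi1 (Gly, Ala) return (None, None); residues
    without a chi2 (Ser, Thr, Val, Cys) return chi2 = None.  Missing
    defining atoms yield None with a log entry.
    """

    def _measure(quartet):
        if quartet is None:
            return None
        atoms = [res.atom(n) for n in quartet]
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(quartet, atoms) if a is None]
            logger.debug("%s%s: missing chi atom(s) %s", res.res_name, res.res_key, missing)
            return None
        return torsion(*(a.coords for a in atoms))

    return DihedralPair(
        chi1=_measure(CHI1_ATOMS.get(res.res_name)),
        chi2=_measure(CHI2_ATOMS.get(res.res_name)),
        frame_index=frame_index,
    )


class State(str, Enum):
    D_IN = "D_in"
    D_OUT = "D_out"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class StateReference:
    """A reference (chi1, chi2) point defining one conformational state."""

    label: State
    chi1_ref: float
    chi2_ref: float


def _torus_distance(chi1, chi2, ref: StateReference) -> float:
    d1 = wrap_angle(chi1 - ref.chi1_ref)
    d2 = wrap_angle(chi2 - ref.chi2_ref)
    return float(np.hypot(d1, d2))


def validate_references(refs) -> tuple[StateReference, StateReference]:
    refs = tuple(refs)
    if len(refs) != 2 or refs[0].label == refs[1].label:
        raise ValueError("need two references with distinct labels")
    sep = np.hypot(
        wrap_angle(refs[0].chi1_ref - refs[1].chi1_ref),
        wrap_angle(refs[0].chi2_ref - refs[1].chi2_ref),
    )
    if sep < 30.0:
        raise ValueError(f"references only {sep:.1f} degrees apart on the torus; need >= 30")
    return refs


def classify_state(
    d: DihedralPair,
    refs,
    rejection_radius: float = 90.0,
    canonicalize: bool = True,
) -> State:
    """Nearest-reference assignment on the (chi1, chi2) torus.

    Frames farther than ``rejection_radius`` from both references, frames
    with undefined angles, and exact ties are UNDEFINED.  ``canonicalize``
    folds chi2 into (-90, 90] before comparison (Asp OD1/OD2 ambiguity).
    """
    refs = validate_references(refs)
    if d.chi1 is None or d.chi2 is None:
        return State.UNDEFINED
    chi2 = canonicalize_chi2(d.chi2) if canonicalize else d.chi2
    dists = [_torus_distance(d.chi1, chi2, r) for r in refs]
    if min(dists) > rejection_radius or dists[0] == dists[1]:
        return State.UNDEFINED
    return refs[int(np.argmin(dists))].label


@dataclass
class StateTrace:
    """Per-frame state assignments plus the occupancy summary of a replicate."""

    states: list[State]
    chi_series: list[DihedralPair]
    replicate_id: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def n_undefined(self) -> int:
        return sum(s is State.UNDEFINED for s in self.states)

    @property
    def occupancy(self) -> dict[str, float]:
        """D-in/D-out fractions over *defined* frames (they sum to 1)."""
        n_in = sum(s is State.D_IN for s in self.states)
        n_out = sum(s is State.D_OUT for s in self.states)
        total = n_in + n_out
        if total == 0:
            return {State.D_IN.value: float("nan"), State.D_OUT.value: float("nan")}
        return {State.D_IN.value: n_in / total, State.D_OUT.value: n_out / total}

    @property
    def undefined_fraction(self) -> float:
        return self.n_undefined / self.n_frames if self.n_frames else float("nan")

    def summary(self) -> dict:
        occ = self.occupancy
        return {
            "replicate": self.replicate_id,
            "n_frames": self.n_frames,
            "occupancy": occ,
            "ratio_in_out": (
                f"{100 * occ[State.D_IN.value]:.0f}:{100 * occ[State.D_OUT.value]:.0f}"
                if not np.isnan(occ[State.D_IN.value]) else "undefined"
            ),
            "undefined_fraction": self.undefined_fraction,
        }


def _select_residue(frame: StructureModel, selector: str) -> Residue:
    """Resolve a 'chain:res_seq' selector to exactly one residue."""
    try:
        chain_id, res_seq = selector.split(":")
        res_seq = int(res_seq)
    except ValueError:
        raise ValueError(f"selector must look like 'A:333', got {selector!r}") from None
    hits = [r for r in frame.chains.get(chain_id, []) if r.res_seq == res_seq]
    if len(hits) != 1:
        raise ValueError(f"selector {selector!r} matches {len(hits)} residues")
    return hits[0]


def occupancy_trace(
    frames: FrameSeries,
    selector: str,
    refs,
    rejection_radius: float = 90.0,
    canonicalize: bool = True,
    replicate_id: str = "",
) -> StateTrace:
    """Classify the selected residue in every frame and summarize occupancy."""
    refs = validate_references(refs)
    states, series = [], []
    for i, frame in enumerate(frames):
        res = _select_residue(frame, selector)
        d = chi_angles(res, frame_index=i)
        series.append(d)
        states.append(classify_state(d, refs, rejection_radius, canonicalize))
    return StateTrace(states=states, chi_series=series, replicate_id=replicate_id)


HYDROXYL_OXYGEN = {"SER": "OG", "THR": "OG1", "TYR": "OH"}


def water_bridge(
    frame: StructureModel, asp: Residue, partner: Residue, d_cut: float = 3.5
) -> list[str]:
    """Waters bridging the Asp carboxylate and a partner hydroxyl.

    A water counts when its O lies within ``d_cut`` Å of at least one of
    OD1/OD2 *and* of the partner's side-chain hydroxyl oxygen.  Distance
    criterion only — no angle term, since the inputs rarely carry usable
    hydrogens.  Returns ``chain:res_seq`` water identifiers.
    """
    oxy_name = HYDROXYL_OXYGEN.get(partner.res_name)
    if oxy_name is None:
        raise ValueError(f"partner residue {partner.res_name} has no side-chain hydroxyl")
    partner_o = partner.atom(oxy_name)
    if partner_o is None:
        raise ValueError(f"partner residue lacks its {oxy_name} atom")
    asp_oxy = [a for n in ("OD1", "OD2") if (a := asp.atom(n)) is not None]
    if not asp_oxy:
        raise ValueError("asp residue lacks carboxylate oxygens OD1/OD2")
    out = []
    for res in frame.residues():
        if not res.is_water:
            continue
        wo = res.atom("O") or res.atom("OW")
        if wo is None:
            continue
        near_asp = any(np.linalg.norm(wo.coords - a.coords) <= d_cut for a in asp_oxy)
        near_partner = np.linalg.norm(wo.coords - partner_o.coords) <= d_cut
        if near_asp and near_partner:
            out.append(f"{res.chain_id}:{res.res_key}")
    return out
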