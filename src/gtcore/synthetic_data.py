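"""Synthetic fixtures with machine-readable ground truth.

Every generator here stands in for an external corpus the analyses were
designed for — crystal-structure sets, microsecond MD trajectories,
variant-database extracts, plate-reader exports — at desk scale and with
the planted truth returned alongside the artifact.  Structures are
geometric scaffolds (idealized backbones with explicitly placed
side-chain atoms), not physically realistic proteins: every downstream
computation is geometric or statistical, so only the planted geometry
matters.

All generators are deterministic under (parameters, seed): one
``numpy.random.default_rng(seed)`` stream per artifact.

Default study conditions (used throughout the tests):

* mechanism sets: 60 inverting chains with tether distance ~ N(5.5, 0.75²) Å
  and 60 retaining chains from the mixture 0.3·N(5.5, 0.75²) + 0.7·N(9.5, 0.8²)
  (the 5.5 Å component is the GT2-related retaining subpopulation);
* trajectories: two-state chi schedules at programmed D-in:D-out ratios
  with 15° angular noise;
* kinetics: the doubling concentration grids 0.3125–5 mM (acceptor) and
  0.0625–1 mM (donor);
* melts: 25–95 °C ramp read every 0.5 °C, enzyme transition in the
  40–70 °C window, optional tag transition at 88 °C.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformation_dynamics import State, StateReference
from .core_mapping import (
    CORE_EXEMPLARS,
    N_COLUMNS,
    ChainMap,
    CoreDefinition,
    Mechanism,
)
from .pbc_network import CoordFragment
from .structure_io import Atom, Residue, StructureModel, write_structure

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

RES_SEQ_OFFSET = 100  # author residue number = alignment column + offset


# ---------------------------------------------------------------------------
# internal coordinate placement (NeRF)


def place_atom(a, b, c, bond_length: float, bond_angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given positions a-b-c, |c-D|, angle(b,c,D) and the
    dihedral a-b-c-D (degrees), such that measuring the dihedral back with
    :func:`gtcore.conformation_dynamics.torsion` returns ``dihedral``."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    phi = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # minus sign on the n component matches the clockwise-positive convention
    # used by torsion(), so the pair are exact inverses
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# single structures with a programmed tether distance


def _grid_position(i: int, spacing: float = 8.0) -> np.ndarray:
    return spacing * np.array([i % 12, (i // 12) % 12, i // 144], dtype=float)


def _backbone_atoms(center: np.ndarray, rng) -> list[Atom]:
    jit = rng.normal(0, 0.05, size=(5, 3))
    return [
        Atom("N", "N", center + np.array([-1.2, 0.6, 0.0]) + jit[0]),
        Atom("CA", "C", center + jit[1]),
        Atom("C", "C", center + np.array([1.2, 0.6, 0.0]) + jit[2]),
        Atom("O", "O", center + np.array([1.9, -0.3, 0.0]) + jit[3]),
        Atom("CB", "C", center + np.array([0.0, -1.4, 0.6]) + jit[4]),
    ]


def make_structure(
    tether_distance: float,
    resolution: float | None = 1.8,
    seed: int = 0,
    structure_id: str = "SYN1",
    chain: str = "A",
    family: str = "GT2",
    mechanism: Mechanism = Mechanism.INVERTING,
    deleted_columns=(),
    n_columns: int = N_COLUMNS,
) -> tuple[str, pd.DataFrame, dict]:
    """A single chain mapping all alignment columns, with the closest
    side-chain heavy-atom pair between the residues at the tether columns
    (156, 183) placed at exactly ``tether_distance`` Å.

    ``deleted_columns`` stay in the position map but are omitted from the
    coordinates (a disordered-loop stand-in).  Returns
    (pdb_text, position-map DataFrame, ground truth).
    """
    if tether_distance <= 0:
        raise ValueError("tether_distance must be positive")
    # PDB coordinates are fixed-width %.3f; quantize so the planted distance
    # survives a write/read round trip exactly
    tether_distance = round(float(tether_distance), 3)
    core = CoreDefinition()
    t1, t2 = core.tether_pair
    if tether_distance > 200.0:
        raise ValueError("tether_distance infeasible for this scaffold (> 200 A)")
    rng = np.random.default_rng(seed)
    deleted = set(int(c) for c in deleted_columns)
    residues = []
    anchor = np.array([-60.0, -60.0, -60.0])  # tether site, away from the grid
    for col in range(1, n_columns + 1):
        res_seq = col + RES_SEQ_OFFSET
        if col in deleted:
            continue
        center = _grid_position(col - 1)
        if col in (t1, t2):
            # PHE stand-ins with a two-atom side chain pinning the minimum
            # pair distance: CB...CB across the anchor axis is the minimum.
            off = 0.0 if col == t1 else tether_distance
            sign = -1.0 if col == t1 else 1.0
            atoms = [
                Atom("N", "N", center + np.array([-1.2, 0.6, 0.0])),
                Atom("CA", "C", center),
                Atom("C", "C", center + np.array([1.2, 0.6, 0.0])),
                Atom("O", "O", center + np.array([1.9, -0.3, 0.0])),
                Atom("CB", "C", anchor + np.array([off, 0.0, 0.0])),
                Atom("CG", "C", anchor + np.array([off + sign * 1.5, 0.0, 0.0])),
            ]
            name = "PHE"
        else:
            atoms = _backbone_atoms(center, rng)
            name = "ALA"
        residues.append(Residue(chain_id=chain, res_seq=res_seq, res_name=name, atoms=atoms))
    model = StructureModel(
        pdb_id=structure_id, chains={chain: residues}, resolution=resolution
    )
    pdb_text = write_structure(model, resolution=resolution)
    pmap_rows = pd.DataFrame(
        [
            dict(structure=structure_id, chain=chain, column=col,
                 res_seq=col + RES_SEQ_OFFSET, family=family, mechanism=mechanism.value)
            for col in range(1, n_columns + 1)
        ]
    )
    truth = {
        "structure": structure_id,
        "tether_distance_A": float(tether_distance),
        "resolution_A": resolution,
        "deleted_columns": sorted(deleted),
        "seed": int(seed),
    }
    return pdb_text, pmap_rows, truth


@dataclass
class MixtureComponent:
    weight: float
    mean: float
    sd: float


DEFAULT_INVERTING = MixtureComponent(1.0, 5.5, 0.75)
DEFAULT_RETAINING = (
    MixtureComponent(0.3, 5.5, 0.75),   # GT2-related retaining subpopulation
    MixtureComponent(0.7, 9.5, 0.8),
)


def _sample_mixture(rng, components, n) -> tuple[np.ndarray, np.ndarray]:
    comps = list(components)
    w = np.array([c.weight for c in comps], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(comps), size=n, p=w)
    vals = np.array([rng.normal(comps[i].mean, comps[i].sd) for i in idx])
    return np.clip(vals, 0.5, None), idx


def make_mechanism_set(
    n_inv: int = 60,
    n_ret: int = 60,
    inv_dist: MixtureComponent = DEFAULT_INVERTING,
    ret_dist=DEFAULT_RETAINING,
    seed: int = 0,
    resolution_range: tuple[float, float] = (1.0, 2.45),
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """A two-mechanism structure set with planted tether distances.

    Inverting tether distances are Normal; retaining ones come from a
    two-component mixture whose low mode is labelled GT2-related
    retaining.  Returns (structures {id: pdb text}, position-map
    DataFrame, per-structure truth DataFrame).
    """
    if n_inv < 2 or n_ret < 2:
        raise ValueError("need at least 2 structures per mechanism")
    rng = np.random.default_rng(seed)
    inv_d, _ = _sample_mixture(rng, [inv_dist], n_inv)
    ret_d, ret_comp = _sample_mixture(
        rng, ret_dist if isinstance(ret_dist, (list, tuple)) else [ret_dist], n_ret
    )
    structures: dict[str, str] = {}
    pmap_frames, truth_rows = [], []
    specs = [("INV", i, d, Mechanism.INVERTING, "GTinv") for i, d in enumerate(inv_d)]
    low_mode = min(
        range(len(ret_dist)), key=lambda i: ret_dist[i].mean
    ) if isinstance(ret_dist, (list, tuple)) and len(ret_dist) > 1 else -1
    for i, d in enumerate(ret_d):
        mech = (
            Mechanism.RETAINING_GT2_RELATED
            if low_mode >= 0 and ret_comp[i] == low_mode
            else Mechanism.RETAINING
        )
        specs.append(("RET", i, d, mech, "GTret"))
    for tag, i, d, mech, fam in specs:
        sid = f"{tag}{i:03d}"
        res = float(rng.uniform(*resolution_range))
        text, pmap_df, struct_truth = make_structure(
            tether_distance=float(d), resolution=res,
            seed=int(rng.integers(2**31)), structure_id=sid,
            family=fam, mechanism=mech,
        )
        structures[sid] = text
        pmap_frames.append(pmap_df)
        truth_rows.append(
            dict(structure=sid, tether_distance_A=struct_truth["tether_distance_A"],
                 resolution_A=res, mechanism=mech.value, family=fam)
        )
    return structures, pd.concat(pmap_frames, ignore_index=True), pd.DataFrame(truth_rows)


def make_distance_table(
    n_inv: int = 60,
    n_ret: int = 60,
    inv_dist: MixtureComponent = DEFAULT_INVERTING,
    ret_dist=DEFAULT_RETAINING,
    seed: int = 0,
    pair: tuple[int, int] = (156, 183),
):
    """Tether-distance records sampled directly from the programmed
    distributions, bypassing structure generation.

    Statistically identical to running the measurement pipeline over
    :func:`make_mechanism_set` output (the structures pin the planted
    distance exactly); used where many replicate tables are needed.
    """
    from .tether_analysis import AtomScope, DistanceTable

    rng = np.random.default_rng(seed)
    inv_d, _ = _sample_mixture(rng, [inv_dist], n_inv)
    ret_d, _ = _sample_mixture(
        rng, ret_dist if isinstance(ret_dist, (list, tuple)) else [ret_dist], n_ret
    )
    i, j = sorted(pair)
    rows = [
        dict(structure=f"INV{k:03d}", chain="A", col_i=i, col_j=j,
             distance_A=float(d), family="GTinv", mechanism=Mechanism.INVERTING.value)
        for k, d in enumerate(inv_d)
    ] + [
        dict(structure=f"RET{k:03d}", chain="A", col_i=i, col_j=j,
             distance_A=float(d), family="GTret", mechanism=Mechanism.RETAINING.value)
        for k, d in enumerate(ret_d)
    ]
    return DistanceTable(records=pd.DataFrame(rows), atom_scope=AtomScope.SIDECHAIN_HEAVY)


# ---------------------------------------------------------------------------
# trajectories with programmed chi-state schedules

DEFAULT_REFS = (
    StateReference(State.D_IN, chi1_ref=-60.0, chi2_ref=40.0),
    StateReference(State.D_OUT, chi1_ref=65.0, chi2_ref=-40.0),
)

ASP_RES_SEQ = 333
THR_RES_SEQ = 336
WATER_RES_SEQ = 901


def _asp_atoms(chi1: float, chi2: float) -> dict[str, np.ndarray]:
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.52 * np.array([np.cos(np.radians(68.0)), np.sin(np.radians(68.0)), 0.0])
    cb = place_atom(c, n, ca, 1.53, 110.5, -122.0)
    cg = place_atom(n, ca, cb, 1.52, 113.0, chi1)
    od1 = place_atom(ca, cb, cg, 1.25, 119.0, chi2)
    od2 = place_atom(ca, cb, cg, 1.25, 119.0, chi2 + 180.0)
    o = c + np.array([0.6, 1.0, 0.0])
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "CG": cg, "OD1": od1, "OD2": od2}


def _schedule_from_ratio(ratio_in: float, n_frames: int, rng) -> list[State]:
    """Exact-count two-state schedule: round(ratio·n) D-in frames, shuffled."""
    n_in = int(round(ratio_in * n_frames))
    states = [State.D_IN] * n_in + [State.D_OUT] * (n_frames - n_in)
    rng.shuffle(states)
    return states


def make_trajectory(
    schedule=0.5,
    refs=DEFAULT_REFS,
    sigma_angle: float = 15.0,
    n_frames: int = 1000,
    seed: int = 0,
    bridging_water: bool = True,
    replicate_id: str = "rep1",
) -> tuple[str, dict]:
    """A multi-model PDB trajectory of a miniature Asp/Thr system whose
    tracked Asp is rebuilt frame-by-frame at the scheduled reference
    (chi1, chi2) plus Gaussian angular noise.

    ``schedule`` is either a target D-in fraction (exact frame counts,
    shuffled) or an explicit per-frame list of :class:`State` labels.
    With ``bridging_water`` a water oxygen bridges the Asp carboxylate
    and the Thr hydroxyl in D-in frames only (it is parked far away in
    D-out frames so the topology stays constant).
    """
    rng = np.random.default_rng(seed)
    if isinstance(schedule, (int, float)):
        states = _schedule_from_ratio(float(schedule), n_frames, rng)
    else:
        states = [State(s) for s in schedule]
        n_frames = len(states)
    by_label = {r.label: r for r in refs}

    # Thr hydroxyl sits a fixed 3.0 A from the noise-free D-in OD1 position
    din = by_label[State.D_IN]
    od1_in = _asp_atoms(din.chi1_ref, din.chi2_ref)["OD1"]
    og1 = od1_in + np.array([3.0, 0.0, 0.0])
    thr_static = {
        "N": og1 + np.array([1.8, 1.8, 0.5]),
        "CA": og1 + np.array([1.2, 1.2, 1.5]),
        "C": og1 + np.array([2.4, 1.0, 2.2]),
        "O": og1 + np.array([3.2, 1.8, 2.4]),
        "CB": og1 + np.array([1.0, 0.2, 0.3]),
        "OG1": og1,
        "CG2": og1 + np.array([1.3, -1.0, 0.8]),
    }
    far_water = np.array([120.0, 120.0, 120.0])

    frames = []
    chi1_truth, chi2_truth = [], []
    for fi, state in enumerate(states):
        ref = by_label[state]
        chi1 = ref.chi1_ref + (rng.normal(0.0, sigma_angle) if sigma_angle > 0 else 0.0)
        chi2 = ref.chi2_ref + (rng.normal(0.0, sigma_angle) if sigma_angle > 0 else 0.0)
        chi1_truth.append(chi1)
        chi2_truth.append(chi2)
        asp_pos = _asp_atoms(chi1, chi2)
        residues = [
            Residue("A", ASP_RES_SEQ, "ASP",
                    [Atom(nm, nm[0], xyz) for nm, xyz in asp_pos.items()]),
            Residue("A", THR_RES_SEQ, "THR",
                    [Atom(nm, nm[0], xyz) for nm, xyz in thr_static.items()]),
        ]
        if bridging_water:
            wpos = (
                (asp_pos["OD1"] + og1) / 2.0 if state is State.D_IN else far_water
            )
            residues.append(Residue("A", WATER_RES_SEQ, "HOH", [Atom("O", "O", wpos)]))
        frames.append(
            StructureModel(pdb_id="traj", model_index=fi, chains={"A": list(residues)})
        )
    pdb_text = write_structure(frames)
    truth = {
        "replicate": replicate_id,
        "n_frames": n_frames,
        "states": [s.value for s in states],
        "ratio_in": sum(s is State.D_IN for s in states) / n_frames,
        "chi1": chi1_truth,
        "chi2": chi2_truth,
        "sigma_angle": sigma_angle,
        "refs": {r.label.value: [r.chi1_ref, r.chi2_ref] for r in refs},
        "asp_selector": f"A:{ASP_RES_SEQ}",
        "thr_selector": f"A:{THR_RES_SEQ}",
        "bridging_water": bridging_water,
        "seed": int(seed),
    }
    return pdb_text, truth


# ---------------------------------------------------------------------------
# alignments


def make_alignment(
    n_sequences: int = 200,
    n_columns: int = N_COLUMNS,
    column_profiles: dict[int, dict[str, float]] | None = None,
    gap_rate=0.0,
    group_labels=("inverting", "retaining"),
    seed: int = 0,
) -> tuple[str, dict]:
    """A gapped FASTA alignment with controlled column composition.

    ``column_profiles`` plants exact residue distributions at chosen
    columns; the remaining columns get a random consensus residue at 60%
    plus uniform background.  ``gap_rate`` is a global float or a
    per-column dict; gaps overwrite residue draws.  Sequence ids carry
    the group label after '|'.  Returns (fasta text, truth).
    """
    rng = np.random.default_rng(seed)
    column_profiles = column_profiles or {}
    if not isinstance(gap_rate, dict):
        gap_rate = {c: float(gap_rate) for c in range(1, n_columns + 1)}
    consensus = rng.choice(list(AA1), size=n_columns)
    groups = [group_labels[i % len(group_labels)] for i in range(n_sequences)]
    seqs = np.empty((n_sequences, n_columns), dtype="<U1")
    for j in range(n_columns):
        col = j + 1
        if col in column_profiles:
            aas = list(column_profiles[col])
            p = np.array([column_profiles[col][a] for a in aas], dtype=float)
            p /= p.sum()
            seqs[:, j] = rng.choice(aas, size=n_sequences, p=p)
        else:
            background = rng.choice(list(AA1), size=n_sequences)
            take_cons = rng.random(n_sequences) < 0.6
            seqs[:, j] = np.where(take_cons, consensus[j], background)
        gr = gap_rate.get(col, 0.0)
        if gr > 0:
            seqs[rng.random(n_sequences) < gr, j] = "-"
    lines = []
    for i in range(n_sequences):
        lines.append(f">seq{i:04d}|{groups[i]}")
        lines.append("".join(seqs[i]))
    truth = {
        "n_sequences": n_sequences,
        "n_columns": n_columns,
        "column_profiles": {str(k): v for k, v in column_profiles.items()},
        "gap_rate": {str(k): v for k, v in gap_rate.items() if v > 0},
        "groups": groups,
        "seed": int(seed),
    }
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# mutation tables


def default_core_hit_plan(total_core: int = 42, tether: int = 7) -> dict[int, int]:
    """Distribute planted core hits over core columns, ``tether`` of them
    on the tether pair (156, 183)."""
    core = CoreDefinition()
    plan: dict[int, int] = {}
    t1, t2 = core.tether_pair
    plan[t1] = tether - tether // 2
    plan[t2] = tether // 2
    others = sorted(core.all_core - set(core.tether_pair))
    remaining = total_core - tether
    if remaining < 0:
        raise ValueError("tether count exceeds total core count")
    for k in range(remaining):
        col = others[k % len(others)]
        plan[col] = plan.get(col, 0) + 1
    return {k: v for k, v in plan.items() if v > 0}


def make_mutation_table(
    n_rows: int = 400,
    core_hit_plan: dict[int, int] | None = None,
    duplicate_fraction: float = 0.25,
    seed: int = 0,
    family: str = "GT8-LARGE",
) -> tuple[pd.DataFrame, ChainMap, dict]:
    """A mutation TSV with planted core hits and exact-count duplicate rows.

    Of ``n_rows`` total rows, ``round(duplicate_fraction * n_rows)`` are
    byte-identical copies of earlier rows (the patient/sample pruning
    target); the remainder are unique mutational events.  Core hits follow
    ``core_hit_plan`` (column -> count); filler events sit at positions
    mapping to non-core columns.  Returns (table, the family's position
    map, truth).
    """
    rng = np.random.default_rng(seed)
    core = CoreDefinition()
    plan = core_hit_plan if core_hit_plan is not None else default_core_hit_plan()
    n_dup = int(round(duplicate_fraction * n_rows))
    n_unique = n_rows - n_dup
    n_hits = sum(plan.values())
    if n_hits > n_unique:
        raise ValueError("core hit plan larger than unique row budget")

    offset = 120
    cmap = ChainMap(
        structure=family, chain="A",
        columns={c: c + offset for c in range(1, N_COLUMNS + 1)},
        family=family, mechanism=Mechanism.RETAINING,
    )
    non_core = sorted(set(range(1, N_COLUMNS + 1)) - core.all_core)

    rows = []
    uid = 0

    def _event(column: int):
        nonlocal uid
        ref = CORE_EXEMPLARS.get(column, "L000")[0]
        alt = rng.choice([a for a in AA1 if a != ref])
        row = dict(
            gene_or_family=family,
            patient_id=f"PT{uid:05d}",
            sample_id=f"SM{uid:05d}",
            position=column + offset,
            ref_aa=ref,
            alt_aa=str(alt),
            source="synthetic",
        )
        uid += 1
        return row

    for column, count in sorted(plan.items()):
        for _ in range(count):
            rows.append(_event(column))
    for _ in range(n_unique - n_hits):
        rows.append(_event(int(rng.choice(non_core))))
    dup_idx = rng.integers(0, n_unique, size=n_dup)
    rows.extend(dict(rows[i]) for i in dup_idx)
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    truth = {
        "n_rows": n_rows,
        "n_unique": n_unique,
        "n_duplicates": n_dup,
        "total_core": n_hits,
        "tether": sum(plan.get(c, 0) for c in core.tether_pair),
        "plan": {str(k): v for k, v in sorted(plan.items())},
        "family": family,
        "seed": int(seed),
    }
    return df, cmap, truth


# ---------------------------------------------------------------------------
# assay curves

ACCEPTOR_GRID_MM = np.array([0.3125, 0.625, 1.25, 2.5, 5.0])
DONOR_GRID_MM = np.array([0.0625, 0.125, 0.25, 0.5, 1.0])


def make_mm_assay(
    km: float = 0.5,
    vmax: float = 10.0,
    grid=None,
    noise_cv: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    substrate: str = "acceptor",
) -> tuple[pd.DataFrame, dict]:
    """Saturation data on a doubling concentration grid with multiplicative
    Gaussian noise (coefficient of variation ``noise_cv``)."""
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = ACCEPTOR_GRID_MM if substrate == "acceptor" else DONOR_GRID_MM
    grid = np.asarray(grid, dtype=float)
    conc = np.repeat(grid, n_replicates)
    v = vmax * conc / (km + conc)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
    df = pd.DataFrame({"concentration_mM": conc, "rate": v})
    truth = {"Km_mM": km, "Vmax": vmax, "noise_cv": noise_cv,
             "substrate": substrate, "seed": int(seed)}
    return df, truth


def make_melt_curve(
    tm: float = 55.0,
    amplitude: float = 1000.0,
    width: float = 1.8,
    secondary_tm: float | None = None,
    secondary_amplitude: float = 400.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    t_min: float = 25.0,
    t_max: float = 95.0,
    t_step: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """A rising-logistic melt curve (optionally two transitions) on a
    25–95 °C ramp read every ``t_step`` °C."""
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + t_step / 2, t_step)
    f = baseline + amplitude / (1.0 + np.exp(-(t - tm) / width))
    if secondary_tm is not None:
        f = f + secondary_amplitude / (1.0 + np.exp(-(t - secondary_tm) / width))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    df = pd.DataFrame({"temperature_C": t, "fluorescence": f})
    truth = {"Tm_C": tm, "secondary_Tm_C": secondary_tm, "width_C": width,
             "noise_sd": noise_sd, "seed": int(seed)}
    return df, truth


def make_assay(kind: str, seed: int = 0, **params):
    """Dispatcher: kind 'mm' -> :func:`make_mm_assay`, 'melt' ->
    :func:`make_melt_curve`."""
    if kind == "mm":
        return make_mm_assay(seed=seed, **params)
    if kind == "melt":
        return make_melt_curve(seed=seed, **params)
    raise ValueError(f"unknown assay kind {kind!r}")


# ---------------------------------------------------------------------------
# fragment families (PBC network benchmark)


def _helix_template(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.stack(
        [2.3 * np.cos(np.radians(100.0) * i), 2.3 * np.sin(np.radians(100.0) * i), 1.5 * i],
        axis=1,
    )


def _strand_template(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.stack([3.3 * i, 1.0 * (-1.0) ** i, np.zeros(n)], axis=1)


def make_fragment_families(
    n_per_family: int = 8,
    n_points: int = 15,
    jitter: float = 0.1,
    seed: int = 0,
) -> tuple[list[CoordFragment], dict]:
    """Two planted fragment families (helical vs extended templates), each
    member jittered and placed under a random rigid motion.

    Within-family RMSD stays near ``jitter``·√2; between-family RMSD is
    several Å by template construction, so connected components at any
    intermediate cutoff recover the families exactly.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    templates = {"helix": _helix_template(n_points), "strand": _strand_template(n_points)}
    labels = tuple(range(86, 86 + n_points))
    frags, families = [], {}
    for fam, tmpl in templates.items():
        for k in range(n_per_family):
            pts = tmpl + rng.normal(0.0, jitter, size=tmpl.shape)
            rot = Rotation.random(random_state=rng).as_matrix()
            pts = pts @ rot.T + rng.uniform(-30, 30, size=3)
            fid = f"{fam}{k:02d}"
            frags.append(CoordFragment(source_id=fid, labels=labels, coords=pts))
            families[fid] = fam
    truth = {"families": families, "jitter": jitter, "n_points": n_points, "seed": int(seed)}
    return frags, truth


# ---------------------------------------------------------------------------
# sequence groups (identity-clustering benchmark)


def make_sequence_groups(
    n_groups: int = 5,
    members_per_group: int = 6,
    length: int = 200,
    group_divergence: float = 0.22,
    member_divergence: float = 0.025,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Planted sequence clusters: group templates diverge ~``2×22%`` from a
    common ancestor (≈60% between-group identity) and members mutate
    ~2.5% of positions (≈95% within-group identity)."""
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(list(AA1), size=length)

    def _mutate(seq, rate):
        seq = seq.copy()
        k = int(round(rate * length))
        pos = rng.choice(length, size=k, replace=False)
        for p in pos:
            seq[p] = rng.choice([a for a in AA1 if a != seq[p]])
        return seq

    sequences, truth_groups = {}, {}
    for g in range(n_groups):
        template = _mutate(ancestor, group_divergence)
        gname = string.ascii_uppercase[g]
        for m in range(members_per_group):
            sid = f"grp{gname}_{m:02d}"
            sequences[sid] = "".join(_mutate(template, member_divergence))
            truth_groups[sid] = gname
    truth = {"groups": truth_groups, "n_groups": n_groups, "seed": int(seed)}
    return sequences, truth
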