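"""Minimum inter-residue distances at aligned core positions and the
inverting-vs-retaining comparison.

The central readout is the C-lobe tether: the minimum side-chain
heavy-atom distance between the residues mapped to alignment columns 156
and 183.  Inverting GT-As keep this pair in van der Waals contact
(~4–7 Å); retaining GT-As are bimodal, with a second population near
10 Å.  The module measures those distances over a structure set, reduces
sequence redundancy CD-HIT-style, aggregates all-vs-all medians, and runs
the two-group t test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core_mapping import CoreDefinition, Mechanism, PositionMap, resolve_columns
from .structure_io import Residue

logger = logging.getLogger(__name__)


class AtomScope(str, Enum):
    """Which atoms of a residue enter the minimum-distance search."""

    SIDECHAIN_HEAVY = "sidechain_heavy"
    ALL_HEAVY = "all_heavy"
    CB_ONLY = "cb_only"


def _scope_coords(res: Residue, scope: AtomScope) -> np.ndarray:
    if scope is AtomScope.ALL_HEAVY:
        return res.coords(heavy_only=True)
    if scope is AtomScope.CB_ONLY:
        cb = res.atom("CB")
        if cb is None:  # glycine
            cb = res.atom("CA")
        return np.empty((0, 3)) if cb is None else cb.coords[None, :]
    # side-chain heavy atoms; glycine falls back to CA
    pts = np.stack(
        [a.coords for a in res.atoms if not a.is_hydrogen and not a.is_backbone]
    ) if any(not a.is_hydrogen and not a.is_backbone for a in res.atoms) else np.empty((0, 3))
    if pts.shape[0] == 0:
        ca = res.atom("CA")
        if ca is not None:
            logger.debug("%s %s: no side-chain heavy atoms, falling back to CA",
                         res.res_name, res.res_key)
            return ca.coords[None, :]
    return pts


def min_residue_distance(res_a: Residue, res_b: Residue, scope=AtomScope.SIDECHAIN_HEAVY) -> float:
    """Minimum Euclidean distance (Å) over all in-scope atom pairs."""
    scope = AtomScope(scope)
    a = _scope_coords(res_a, scope)
    b = _scope_coords(res_b, scope)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError(
            f"no atoms in scope {scope.value} for "
            f"{res_a.res_name}{res_a.res_key} / {res_b.res_name}{res_b.res_key}"
        )
    return float(cdist(a, b).min())


@dataclass
class DistanceTable:
    """Per-chain minimum distances for core column pairs.

    ``records`` columns: structure, chain, col_i, col_j, distance_A,
    family, mechanism.  One row per (chain, column pair); the atom scope
    is uniform for the whole table.
    """

    records: pd.DataFrame
    atom_scope: AtomScope = AtomScope.SIDECHAIN_HEAVY

    COLUMNS = ["structure", "chain", "col_i", "col_j", "distance_A", "family", "mechanism"]

    def pair(self, col_i: int, col_j: int) -> pd.DataFrame:
        i, j = sorted((col_i, col_j))
        r = self.records
        return r[(r["col_i"] == i) & (r["col_j"] == j)]


def core_distance_table(
    models,
    pmap: PositionMap,
    core: CoreDefinition | None = None,
    scope=AtomScope.SIDECHAIN_HEAVY,
    columns=None,
) -> DistanceTable:
    """Measure all core-column pair distances for every chain in ``models``.

    Chains missing either residue of a pair skip that pair (logged).
    """
    core = core or CoreDefinition()
    scope = AtomScope(scope)
    cols = sorted(columns) if columns is not None else sorted(core.all_core)
    rows = []
    for model in models:
        cm = pmap.chain_for_model(model)
        if cm is None:
            logger.warning("no position map for %s; skipped", model.pdb_id)
            continue
        resolved = dict(resolve_columns(model, pmap, cols))
        for ci, cj in itertools.combinations(cols, 2):
            ra, rb = resolved.get(ci), resolved.get(cj)
            if ra is None or rb is None:
                logger.debug("%s: pair (%d, %d) skipped (missing residue)",
                             model.pdb_id, ci, cj)
                continue
            rows.append(
                dict(structure=cm.structure, chain=cm.chain, col_i=ci, col_j=cj,
                     distance_A=min_residue_distance(ra, rb, scope),
                     family=cm.family, mechanism=cm.mechanism.value)
            )
    return DistanceTable(
        records=pd.DataFrame(rows, columns=DistanceTable.COLUMNS), atom_scope=scope
    )


def median_matrix(table: DistanceTable) -> pd.DataFrame:
    """All-vs-all median distance per column pair (symmetric, zero diagonal).

    Cells with no records are NaN.  Median of an even-count sample is the
    mean of the middle two.
    """
    r = table.records
    cols = sorted(set(r["col_i"]) | set(r["col_j"]))
    mat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    med = r.groupby(["col_i", "col_j"])["distance_A"].median()
    for (i, j), v in med.items():
        mat.loc[i, j] = v
        mat.loc[j, i] = v
    for c in cols:
        mat.loc[c, c] = 0.0
    return mat


# ---------------------------------------------------------------------------
# redundancy reduction (CD-HIT-style greedy clustering)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned positions / length of the shorter sequence.

    Global alignment under an identity scheme (match 1, mismatch 0, affine
    gaps), so the score *is* the number of identically aligned positions.
    Note CD-HIT proper uses word filtering and its own length convention;
    this is the shorter-sequence convention on exact alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 1.0
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-0.1,
    )
    for attr in ("open_end_gap_score", "extend_end_gap_score"):
        setattr(aligner, attr, 0)  # free end gaps (overhangs are not penalized)
    matches = aligner.score(seq_a, seq_b)
    # gap penalties can only reduce the score below the match count
    best = max(matches, 0.0)
    return float(best) / min(len(seq_a), len(seq_b))


@dataclass
class ClusterResult:
    representatives: list[str]
    assignment: dict[str, str]  # member id -> representative id

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def greedy_identity_cluster(sequences: dict[str, str], threshold: float = 0.90) -> ClusterResult:
    """Greedy longest-first identity clustering (CD-HIT-style).

    Sequences are sorted longest first; each joins the first existing
    representative with identity >= threshold, else founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for sid, s in sequences.items():
        if not s:
            raise ValueError(f"empty sequence for {sid!r}")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for sid in order:
        for rep in reps:
            if pairwise_identity(sequences[sid], sequences[rep]) >= threshold:
                assignment[sid] = rep
                break
        else:
            reps.append(sid)
            assignment[sid] = sid
    return ClusterResult(representatives=reps, assignment=assignment)


# ---------------------------------------------------------------------------
# mechanism comparison


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    medians: tuple[float, float]
    t_statistic: float
    p_value: float
    variant: str  # "welch" | "student"

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_names),
            "n": list(self.n),
            "means": list(self.means),
            "medians": list(self.medians),
            "t": self.t_statistic,
            "p_two_tailed": self.p_value,
            "variant": self.variant,
        }


def _mechanism_group(mech: str) -> str | None:
    m = Mechanism(mech)
    if m is Mechanism.INVERTING:
        return "inverting"
    if m.is_retaining:
        return "retaining"
    return None  # UNKNOWN excluded from group statistics


def compare_mechanisms(
    table: DistanceTable,
    pair: tuple[int, int] = (156, 183),
    variant: str = "welch",
) -> GroupComparison:
    """Two-tailed t test of tether distances, inverting vs retaining.

    GT2-related retaining chains count as retaining (they are the ~5 Å
    mode of the retaining mixture).  Welch by default; Student pooled
    variance by flag.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    sub = table.pair(*pair).copy()
    sub["group"] = sub["mechanism"].map(_mechanism_group)
    groups = {}
    for g in ("inverting", "retaining"):
        vals = sub.loc[sub["group"] == g, "distance_A"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 records")
        groups[g] = vals
    a, b = groups["inverting"], groups["retaining"]
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        group_names=("inverting", "retaining"),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(np.median(a)), float(np.median(b))),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        variant=variant,
    )


def group_density(values, grid=None) -> pd.DataFrame:
    """Gaussian KDE (Silverman bandwidth) density export for violin plots."""
    values = np.asarray(values, dtype=float)
    if grid is None:
        pad = 3 * values.std(ddof=1) if len(values) > 1 else 1.0
        grid = np.linspace(values.min() - pad, values.max() + pad, 256)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    return pd.DataFrame({"distance_A": grid, "density": kde(grid)})


def find_modes(values, n_modes: int = 2, grid_points: int = 512) -> list[float]:
    """Locations of the ``n_modes`` largest local maxima of the KDE.

    Used to recover the two modes of the retaining tether-distance
    distribution; returned sorted by location.
    """
    values = np.asarray(values, dtype=float)
    pad = 3 * values.std(ddof=1)
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_points)
    dens = stats.gaussian_kde(values, bw_method="silverman")(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.where(interior)[0] + 1
    if len(idx) == 0:
        idx = np.array([int(np.argmax(dens))])
    top = idx[np.argsort(dens[idx])[::-1][:n_modes]]
    return sorted(float(grid[i]) for i in top)
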