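"""All-vs-all structural similarity of phosphate-binding-cassette fragments.

Fragments are alignment-matched Cα point sets; pairwise similarity is the
RMSD after optimal proper-rotation superposition (Kabsch).  Because the
residue correspondence already comes from the position map, no alignment
search is needed: superposition on matched labels replaces a structural
aligner.  Pairs below an RMSD cutoff (2.5 Å by default) become edges of an
undirected graph; connected components are the reported clusters (spring
layouts are emitted for drawing only).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_mapping import PositionMap, resolve_columns
from .structure_io import StructureModel

logger = logging.getLogger(__name__)

# default fragment span: the PBC columns (β4–αD–β6 region)
DEFAULT_PBC_COLUMNS = tuple(range(86, 101))


@dataclass
class CoordFragment:
    """An ordered, labelled Cα point set from one structure."""

    source_id: str
    labels: tuple
    coords: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if self.coords.shape[0] != len(self.labels):
            raise ValueError("labels and coords length mismatch")
        if self.coords.shape[0] < 3:
            raise ValueError("fragment needs at least 3 points")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.labels)


def extract_fragment(
    model: StructureModel, pmap: PositionMap, columns=DEFAULT_PBC_COLUMNS
) -> CoordFragment:
    """Cα coordinates at the requested alignment columns, in column order.

    Columns that do not resolve (unmapped, missing residue, missing CA)
    are dropped with a log entry; fewer than 3 survivors is an error.
    """
    labels, pts = [], []
    for col, res in resolve_columns(model, pmap, columns):
        ca = res.atom("CA") if res is not None else None
        if ca is None:
            logger.debug("%s: column %d dropped from fragment", model.pdb_id, col)
            continue
        labels.append(col)
        pts.append(ca.coords)
    if len(labels) < 3:
        raise ValueError(
            f"{model.pdb_id}: only {len(labels)} of {len(tuple(columns))} "
            "columns resolvable; need >= 3"
        )
    return CoordFragment(source_id=model.pdb_id, labels=tuple(labels), coords=np.stack(pts))


def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def kabsch_rmsd(a: CoordFragment, b: CoordFragment) -> float:
    """RMSD (Å) after optimal rigid superposition on shared labels.

    Correspondence is by label; reflections are excluded (proper rotations
    only), so mirror images have a genuinely nonzero RMSD.
    """
    shared = [lab for lab in a.labels if lab in set(b.labels)]
    if len(shared) < 3:
        raise ValueError(
            f"fragments {a.source_id} and {b.source_id} share only "
            f"{len(shared)} labels; need >= 3"
        )
    ia = {lab: i for i, lab in enumerate(a.labels)}
    ib = {lab: i for i, lab in enumerate(b.labels)}
    p = a.coords[[ia[lab] for lab in shared]]
    q = b.coords[[ib[lab] for lab in shared]]
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    r = _kabsch_rotation(p, q)
    diff = p @ r.T - q
    return float(np.sqrt((diff**2).sum() / len(shared)))


@dataclass
class SimilarityGraph:
    """RMSD-thresholded similarity network over fragments."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [(i, j, d["rmsd"]) for i, j, d in self.graph.edges(data=True)]


def build_network(fragments, cutoff: float = 2.5) -> SimilarityGraph:
    """Evaluate all C(n,2) pairs; keep edges with RMSD <= cutoff (inclusive)."""
    fragments = list(fragments)
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    g = nx.Graph()
    g.add_nodes_from(f.source_id for f in fragments)
    for fa, fb in itertools.combinations(fragments, 2):
        rmsd = kabsch_rmsd(fa, fb)
        if rmsd <= cutoff:
            g.add_edge(fa.source_id, fb.source_id, rmsd=rmsd)
    return SimilarityGraph(graph=g, cutoff=cutoff)


def cluster_components(sg: SimilarityGraph) -> dict[str, int]:
    """Connected components as cluster labels (0, 1, ... by decreasing size)."""
    comps = sorted(nx.connected_components(sg.graph), key=lambda c: (-len(c), sorted(c)[0]))
    return {node: k for k, comp in enumerate(comps) for node in sorted(comp)}


def spring_layout(sg: SimilarityGraph, seed: int = 0) -> dict[str, np.ndarray]:
    """Edge-weighted 2-D spring layout for drawing (closer = lower RMSD)."""
    g = sg.graph.copy()
    for i, j, d in g.edges(data=True):
        d["weight"] = 1.0 / (d["rmsd"] + 0.1)
    return nx.spring_layout(g, weight="weight", seed=seed)


def write_edge_list(sg: SimilarityGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\trmsd_A\n")
        for i, j, rmsd in sorted(sg.edges):
            fh.write(f"{i}\t{j}\t{rmsd:.4f}\n")


def write_graphml(sg: SimilarityGraph, path) -> None:
    nx.write_graphml(sg.graph, path)
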