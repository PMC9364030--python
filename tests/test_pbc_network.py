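import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from gtcore.pbc_network import (
    CoordFragment,
    build_network,
    cluster_components,
    extract_fragment,
    kabsch_rmsd,
)
from gtcore import synthetic_data as syn


def rotation_grid_rmsd(p, q, coarse_deg=15.0):
    """Independent oracle: minimize RMSD over proper rotations by Euler-grid
    search plus local refinement (never uses the Kabsch solution)."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)

    def rms(euler):
        r = Rotation.from_euler("zyx", euler, degrees=True).as_matrix()
        d = p @ r.T - q
        return np.sqrt((d**2).sum() / len(p))

    grid = np.arange(-180.0, 180.0, coarse_deg)
    best, best_e = np.inf, None
    for a in grid:
        for b in np.arange(-90.0, 90.1, coarse_deg):
            for c in grid:
                v = rms((a, b, c))
                if v < best:
                    best, best_e = v, (a, b, c)
    res = minimize(rms, best_e, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return min(best, float(res.fun))


def frag(coords, labels=None, source="f"):
    coords = np.asarray(coords, dtype=float)
    labels = tuple(labels) if labels is not None else tuple(range(len(coords)))
    return CoordFragment(source_id=source, labels=labels, coords=coords)


class TestKabsch:
    def test_identical_fragments_zero(self):
        a = frag(np.random.default_rng(0).normal(size=(10, 3)))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = frag(rng.normal(size=(12, 3)) * 5)
        for _ in range(20):
            r = Rotation.random(random_state=rng).as_matrix()
            b = frag(a.coords @ r.T + rng.normal(scale=20, size=3), source="g")
            assert kabsch_rmsd(a, b) < 1e-8

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = frag(rng.normal(size=(8, 3)))
        b = frag(rng.normal(size=(8, 3)), source="g")
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_mirror_toy_matches_rotation_grid_oracle(self):
        # planar triangle: its mirror IS reachable by a proper rotation,
        # and both routes agree on (essentially) zero
        a = frag([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        b = frag([(0, 0, 0), (1, 0, 0), (0, -1, 0)], source="g")
        assert kabsch_rmsd(a, b) == pytest.approx(
            rotation_grid_rmsd(a.coords, b.coords), abs=1e-3
        )

    def test_chiral_mirror_matches_oracle_and_is_nonzero(self):
        # non-planar quartet: the mirror image cannot be superposed by any
        # proper rotation, and the residual matches the grid-search oracle
        pts = np.array([(0, 0, 0), (1.5, 0, 0), (0, 1.2, 0), (0.4, 0.4, 1.7)])
        a = frag(pts)
        b = frag(pts * np.array([1.0, 1.0, -1.0]), source="g")
        got = kabsch_rmsd(a, b)
        assert got == pytest.approx(rotation_grid_rmsd(a.coords, b.coords), abs=1e-3)
        assert got > 0.1

    def test_label_matching_subsets(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3)) * 4
        a = frag(pts, labels=range(10))
        b = frag(pts[2:], labels=range(2, 10), source="g")
        assert kabsch_rmsd(a, b) < 1e-10

    def test_too_few_shared_labels(self):
        a = frag(np.eye(3), labels=[1, 2, 3])
        b = frag(np.eye(3), labels=[3, 4, 5], source="g")
        with pytest.raises(ValueError, match="share"):
            kabsch_rmsd(a, b)

    def test_rmsd_monotone_in_jitter(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(15, 3)) * 5
        a = frag(base)
        amps = np.linspace(0.05, 2.5, 50)
        noise = rng.normal(size=base.shape)
        rmsds = [kabsch_rmsd(a, frag(base + amp * noise, source="g")) for amp in amps]
        rho, _ = spearmanr(amps, rmsds)
        assert rho > 0.95


class TestExtractFragment:
    def test_full_span(self, single_structure):
        model, pmap, _ = single_structure
        f = extract_fragment(model, pmap, columns=range(86, 101))
        assert len(f) == 15
        assert f.labels == tuple(range(86, 101))

    def test_missing_residue_dropped(self):
        from gtcore import parse_structure
        from gtcore.core_mapping import load_position_map

        text, pmap_df, truth = syn.make_structure(5.0, seed=5, deleted_columns=[90])
        model = parse_structure(text, truth["structure"])[0]
        f = extract_fragment(model, load_position_map(pmap_df), columns=range(86, 101))
        assert len(f) == 14
        assert 90 not in f.labels

    def test_too_few_columns_error(self):
        from gtcore import parse_structure
        from gtcore.core_mapping import load_position_map

        text, pmap_df, truth = syn.make_structure(5.0, seed=6, deleted_columns=[87, 88])
        model = parse_structure(text, truth["structure"])[0]
        with pytest.raises(ValueError, match=">= 3"):
            extract_fragment(model, load_position_map(pmap_df), columns=[86, 87, 88, 89])


class TestNetwork:
    def test_identical_fragments_complete_graph(self):
        pts = np.random.default_rng(7).normal(size=(5, 3)) * 3
        frags = [frag(pts, source=f"n{i}") for i in range(3)]
        sg = build_network(frags, cutoff=2.5)
        assert sg.graph.number_of_edges() == 3
        assert all(r == pytest.approx(0.0, abs=1e-9) for _, _, r in sg.edges)

    def test_distant_fragments_no_edge(self):
        rng = np.random.default_rng(8)
        a = frag(rng.normal(size=(6, 3)), source="a")
        b = frag(rng.normal(size=(6, 3)) * 12, source="b")
        assert kabsch_rmsd(a, b) > 2.5  # construction check
        sg = build_network([a, b], cutoff=2.5)
        assert sg.graph.number_of_edges() == 0

    def test_planted_families_edges_within_only(self):
        frags, truth = syn.make_fragment_families(seed=9)
        sg = build_network(frags, cutoff=2.5)
        fam = truth["families"]
        for i, j, _ in sg.edges:
            assert fam[i] == fam[j]
        # every within-family pair connected at this jitter level
        assert sg.graph.number_of_edges() == 2 * (8 * 7 // 2)

    def test_components_match_planted_families(self):
        frags, truth = syn.make_fragment_families(seed=10)
        clusters = cluster_components(build_network(frags, cutoff=2.5))
        fam = truth["families"]
        label_of = {}
        for node, k in clusters.items():
            label_of.setdefault(k, fam[node])
            assert label_of[k] == fam[node]
        assert len(label_of) == 2

    def test_empty_edge_set_gives_singletons(self):
        import networkx as nx

        from gtcore.pbc_network import SimilarityGraph

        g = nx.Graph()
        g.add_nodes_from("abcd")
        clusters = cluster_components(SimilarityGraph(graph=g, cutoff=2.5))
        assert len(set(clusters.values())) == 4
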