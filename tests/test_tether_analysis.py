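import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import distance_table_from_values, make_residue
from gtcore.tether_analysis import (
    AtomScope,
    compare_mechanisms,
    core_distance_table,
    find_modes,
    greedy_identity_cluster,
    median_matrix,
    min_residue_distance,
    pairwise_identity,
)
from gtcore import synthetic_data as syn


def brute_force_min_distance(res_a, res_b):
    best = np.inf
    for a in res_a.atoms:
        for b in res_b.atoms:
            if a.is_hydrogen or b.is_hydrogen:
                continue
            if a.is_backbone or b.is_backbone:
                continue
            best = min(best, float(np.linalg.norm(a.coords - b.coords)))
    return best


def random_residue(rng, chain="A", res_seq=1):
    n_side = rng.integers(1, 8)
    atoms = {"N": rng.normal(size=3), "CA": rng.normal(size=3), "C": rng.normal(size=3)}
    for k in range(n_side):
        atoms[f"X{k}C"] = rng.normal(scale=4.0, size=3)
    res = make_residue("UNK", {}, chain, res_seq)
    from gtcore.structure_io import Atom

    res.atoms = [Atom(n if n in ("N", "CA", "C") else f"C{n}", "C" if "C" in n else n[0], v)
                 for n, v in atoms.items()]
    return res


class TestMinResidueDistance:
    def test_forced_minimum(self):
        ra = make_residue("UNK", {"CB": (0, 0, 0), "CG": (1, 0, 0)})
        rb = make_residue("UNK", {"CB": (4, 0, 0), "CG": (6, 0, 0)}, res_seq=2)
        assert min_residue_distance(ra, rb) == pytest.approx(3.0)

    def test_identity_is_zero(self):
        ra = make_residue("UNK", {"CB": (1, 2, 3), "CG": (2, 2, 3)})
        assert min_residue_distance(ra, ra) == 0.0

    def test_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ra, rb = random_residue(rng), random_residue(rng, res_seq=2)
            d = min_residue_distance(ra, rb)
            assert min_residue_distance(rb, ra) == pytest.approx(d, abs=1e-12)
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(scale=10, size=3)
            from gtcore.structure_io import Atom

            move = lambda r, rs: make_residue(
                "UNK", {a.name: rot @ a.coords + shift for a in r.atoms}, res_seq=rs
            )
            assert min_residue_distance(move(ra, 1), move(rb, 2)) == pytest.approx(d, abs=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ra, rb = random_residue(rng), random_residue(rng, res_seq=2)
            assert min_residue_distance(ra, rb) == pytest.approx(
                brute_force_min_distance(ra, rb), abs=1e-9
            )

    def test_glycine_falls_back_to_ca(self):
        gly = make_residue("GLY", {"N": (0, 1, 0), "CA": (0, 0, 0), "C": (1, 0, 0), "O": (2, 0, 0)})
        other = make_residue("UNK", {"CB": (0, 0, 5)}, res_seq=2)
        assert min_residue_distance(gly, other) == pytest.approx(5.0)

    def test_cb_only_scope(self):
        ra = make_residue("UNK", {"CB": (0, 0, 0), "CG": (3.9, 0, 0)})
        rb = make_residue("UNK", {"CB": (4, 0, 0), "CG": (4.1, 0, 0)}, res_seq=2)
        assert min_residue_distance(ra, rb, AtomScope.CB_ONLY) == pytest.approx(4.0)


class TestCoreDistanceTable:
    def test_pair_count_is_n_choose_2(self, single_structure):
        model, pmap, _ = single_structure
        table = core_distance_table([model], pmap, columns=[1, 86, 156])
        assert len(table.records) == 3

    def test_planted_tether_distances_recovered_exactly(self, small_mechanism_set):
        chains, pmap, truth = small_mechanism_set
        table = core_distance_table(chains, pmap, columns=[156, 183])
        merged = table.records.merge(truth, on="structure")
        assert len(merged) == len(truth)
        np.testing.assert_allclose(
            merged["distance_A"], merged["tether_distance_A"], atol=1e-6
        )

    def test_missing_column_skips_only_its_pairs(self):
        from gtcore import parse_structure
        from gtcore.core_mapping import load_position_map

        text, pmap_df, truth = syn.make_structure(5.0, seed=3, deleted_columns=[183])
        model = parse_structure(text, truth["structure"])[0]
        table = core_distance_table(
            [model], load_position_map(pmap_df), columns=[1, 156, 183]
        )
        pairs = set(zip(table.records["col_i"], table.records["col_j"]))
        assert pairs == {(1, 156)}


class TestMedianMatrix:
    def test_odd_and_even_medians(self):
        table = distance_table_from_values([3.0, 5.0, 7.0], [4.0, 6.0])
        sub_inv = table.records[table.records.mechanism == "inverting"]
        assert sub_inv["distance_A"].median() == 5.0
        mat = median_matrix(table)
        # pooled over both groups: {3,4,5,6,7} -> 5
        assert mat.loc[156, 183] == pytest.approx(5.0)
        assert mat.loc[183, 156] == mat.loc[156, 183]
        assert mat.loc[156, 156] == 0.0

    def test_even_count_mean_of_middle_two(self):
        table = distance_table_from_values([4.0, 6.0], [])
        table.records = table.records[table.records.mechanism == "inverting"]
        assert median_matrix(table).loc[156, 183] == pytest.approx(5.0)


class TestIdentityClustering:
    def test_identical_sequences_one_cluster(self):
        res = greedy_identity_cluster({"a": "MKLV", "b": "MKLV"})
        assert res.n_clusters == 1

    def test_disjoint_sequences_two_clusters(self):
        res = greedy_identity_cluster({"a": "AAAA", "b": "WWWW"})
        assert res.n_clusters == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            greedy_identity_cluster({"a": ""})

    def test_identity_definition_shorter_sequence(self):
        # 4 identical positions over min length 4
        assert pairwise_identity("MKLVAA", "MKLV") == pytest.approx(1.0)

    def test_planted_groups_recovered(self):
        seqs, truth = syn.make_sequence_groups(n_groups=3, members_per_group=4, seed=8)
        res = greedy_identity_cluster(seqs, threshold=0.90)
        assert res.n_clusters == 3
        # members cluster with their own group's representative
        for sid, rep in res.assignment.items():
            assert truth["groups"][sid] == truth["groups"][rep]


class TestCompareMechanisms:
    def test_closed_form_student(self):
        table = distance_table_from_values([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        comp = compare_mechanisms(table, variant="student")
        # pooled-variance t = (2-5)/sqrt(1*(1/3+1/3)) = -3.6742, df = 4
        assert comp.t_statistic == pytest.approx(-3.674234614, abs=1e-6)
        assert comp.p_value == pytest.approx(0.021311641, abs=1e-6)

    def test_identical_groups_null(self):
        table = distance_table_from_values([2.0, 4.0, 6.0], [2.0, 4.0, 6.0])
        comp = compare_mechanisms(table)
        assert comp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_group_swap_flips_t_keeps_p(self):
        table = distance_table_from_values([1.0, 2.0, 3.5], [4.0, 5.5, 6.0])
        swapped = distance_table_from_values([4.0, 5.5, 6.0], [1.0, 2.0, 3.5])
        a, b = compare_mechanisms(table), compare_mechanisms(swapped)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_small_group_rejected(self):
        table = distance_table_from_values([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_mechanisms(table)

    def test_separated_groups_give_tiny_p(self):
        table = syn.make_distance_table(seed=13)
        comp = compare_mechanisms(table)
        assert comp.p_value < 1e-6
        assert comp.medians[1] - comp.medians[0] > 2.0


def test_bimodal_mode_recovery():
    rng = np.random.default_rng(21)
    comp = np.where(rng.random(300) < 0.3, rng.normal(5.5, 0.75, 300), rng.normal(9.5, 0.8, 300))
    modes = find_modes(comp, n_modes=2)
    assert modes[0] == pytest.approx(5.5, abs=0.5)
    assert modes[1] == pytest.approx(9.5, abs=0.5)
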