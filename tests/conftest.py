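import numpy as np
import pandas as pd
import pytest

from gtcore import parse_structure, split_chains
from gtcore.core_mapping import Mechanism, load_position_map
from gtcore.structure_io import Atom, Residue
from gtcore.tether_analysis import AtomScope, DistanceTable
from gtcore import synthetic_data as syn


def make_residue(name, atoms, chain="A", res_seq=1):
    """Residue from {atom_name: (x, y, z)} with elements inferred."""
    return Residue(
        chain_id=chain,
        res_seq=res_seq,
        res_name=name,
        atoms=[Atom(n, n[0], np.asarray(xyz, float)) for n, xyz in atoms.items()],
    )


def distance_table_from_values(inv_values, ret_values, pair=(156, 183)) -> DistanceTable:
    """Tether-pair DistanceTable with given per-group distances."""
    i, j = sorted(pair)
    rows = [
        dict(structure=f"I{k}", chain="A", col_i=i, col_j=j, distance_A=float(v),
             family="inv", mechanism=Mechanism.INVERTING.value)
        for k, v in enumerate(inv_values)
    ] + [
        dict(structure=f"R{k}", chain="A", col_i=i, col_j=j, distance_A=float(v),
             family="ret", mechanism=Mechanism.RETAINING.value)
        for k, v in enumerate(ret_values)
    ]
    return DistanceTable(records=pd.DataFrame(rows), atom_scope=AtomScope.SIDECHAIN_HEAVY)


@pytest.fixture(scope="session")
def small_mechanism_set():
    """10+10-chain planted mechanism set, parsed and ready for analysis."""
    structures, pmap_df, truth = syn.make_mechanism_set(n_inv=10, n_ret=10, seed=42)
    chains = []
    for sid, text in structures.items():
        chains.extend(split_chains(parse_structure(text, sid)[0]))
    return chains, load_position_map(pmap_df), truth


@pytest.fixture(scope="session")
def single_structure():
    """One planted structure (tether 5.5 Å) with its map and truth."""
    text, pmap_df, truth = syn.make_structure(5.5, resolution=1.8, seed=7)
    model = parse_structure(text, truth["structure"])[0]
    return model, load_position_map(pmap_df), truth
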