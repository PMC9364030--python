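# gtcore

Structural-informatics toolkit for the hydrophobic core of fold-A
glycosyltransferases (GT-As).

GT-As are Rossmann-fold-like enzymes that transfer sugars from nucleotide
donors onto acceptor substrates, with either inverting or retaining
stereochemical outcomes. Their catalytic domain is described on a
231-column consensus alignment on which a conserved hydrophobic core can
be split into three evolutionary layers: a miniature core inside the
phosphate-binding cassette (PBC), positions shared with Rossmann-fold
enzymes generally, and a GT-A-specific *C-lobe tether* — the column pair
(156, 183) — that clamps the PBC to the αF-helix carrying the catalytic
base (the xED-Asp, column 180).

`gtcore` implements the quantitative analyses built on that picture:

- **Tether distances** — minimum side-chain heavy-atom distances between
  aligned core positions across a structure set, with CD-HIT-style
  redundancy reduction, all-vs-all median matrices, and a Welch/Student
  two-tailed *t* test of inverting vs retaining enzymes. Inverting GT-As
  hold the tether in van der Waals contact (~4–7 Å); retaining GT-As are
  bimodal with an upper mode near 10 Å (the low mode is the "GT2-related"
  retaining subpopulation).
- **PBC similarity networks** — all-vs-all Kabsch-superposition RMSD of
  alignment-matched Cα fragments, thresholded (2.5 Å default) into an
  undirected graph whose connected components are the reported clusters.
- **Conformational occupancy** — chi1/chi2 side-chain dihedrals per frame
  of a multi-model-PDB trajectory, nearest-reference classification of
  the xED-Asp into D-in (buried, water-coordinated) vs D-out
  (acceptor-facing) states on the (chi1, chi2) torus, per-replicate
  D-in:D-out ratios, and distance-based water-bridge detection.
- **Variant mapping** — nonsynonymous mutation tables deduplicated on the
  (family, patient, sample, position, alt) event key and mapped through
  per-family position maps onto core columns, with core/tether counts.
- **Assay fits** — Michaelis–Menten nonlinear least squares
  (v = Vmax·[S]/(Km+[S])) with kcat/Km efficiencies and mutant-vs-wt fold
  changes, and thermal-shift Tm extraction from the smoothed dF/dT
  maximum of melt curves.
- **Synthetic data** — deterministic generators for every input class
  (structures with planted tether geometry, two-mechanism structure sets,
  chi-schedule trajectories, alignments, mutation tables, assay curves),
  each emitting machine-readable ground truth.

## Worked example

Generate a 60+60-chain two-mechanism structure set, measure the (156, 183)
tether distances, and compare mechanisms:

```python
from gtcore import (parse_structure, split_chains, filter_by_resolution,
                    core_distance_table, compare_mechanisms)
from gtcore.core_mapping import load_position_map
from gtcore import synthetic_data as syn

structures, pmap_df, truth = syn.make_mechanism_set(n_inv=60, n_ret=60, seed=11)
pmap = load_position_map(pmap_df)
chains = []
for sid, text in structures.items():
    chains.extend(split_chains(parse_structure(text, sid)[0]))
chains = filter_by_resolution(chains, 2.5)        # strict "< 2.5 Å"
table = core_distance_table(chains, pmap, columns=[156, 183])
print(compare_mechanisms(table, variant="welch").to_dict())
```

Output (abridged):

```
means:   [5.60, 8.21]        # Å, inverting vs retaining
medians: [5.52, 9.07]
t: -9.18   p_two_tailed: 7.0e-14   variant: welch
```

The inverting median sits at the planted contact distance (~5.5 Å), the
retaining group is pulled upward by its ~9.5 Å mode, and the two
mechanisms separate decisively. The same stages are scriptable from the
shell (`gtcore simulate structures`, `gtcore run config.yaml`,
`gtcore kinetics`, `gtcore melt`, ...).

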