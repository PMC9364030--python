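"""End-to-end orchestration of the analysis stages from one YAML config.

Stages run in dependency order (structure I/O and mapping feed the tether,
network, conformer and variant stages); each enabled stage writes its
tables next to a resolved-config copy and a JSON run report.  Parameter
defaults are the study conditions: 2.5 Å resolution cutoff, 0.90 identity
threshold, 2.5 Å RMSD cutoff, tether pair (156, 183), Welch t test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import assay_analysis, conformation_dynamics, pbc_network, tether_analysis
from .core_mapping import CoreDefinition, load_position_map
from .structure_io import filter_by_resolution, parse_structure, read_trajectory, split_chains
from .variant_core_mapping import map_and_count, parse_mutations

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("tether", "network", "conformers", "variants", "kinetics", "melt")


@dataclass
class PipelineConfig:
    stages: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "gtcore_out"
    # inputs
    structures_dir: str | None = None
    position_map: str | None = None
    trajectory: str | None = None
    mutations: str | None = None
    kinetics_csv: str | None = None
    melt_csv: str | None = None
    # parameters (defaults = study conditions)
    resolution_cutoff: float = 2.5
    identity_threshold: float = 0.90
    rmsd_cutoff: float = 2.5
    tether_pair: tuple = (156, 183)
    test_variant: str = "welch"
    atom_scope: str = "sidechain_heavy"
    pbc_columns: tuple = tuple(range(86, 101))
    cluster_redundancy: bool = True
    state_references: dict = field(
        default_factory=lambda: {"D_in": [-60.0, 40.0], "D_out": [65.0, -40.0]}
    )
    residue_selector: str | None = None
    melt_window: tuple = (40.0, 70.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        needs = {
            "tether": ("structures_dir", "position_map"),
            "network": ("structures_dir", "position_map"),
            "conformers": ("trajectory", "residue_selector"),
            "variants": ("mutations", "position_map"),
            "kinetics": ("kinetics_csv",),
            "melt": ("melt_csv",),
        }
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for attr in needs[stage]:
                val = getattr(self, attr)
                if val is None:
                    raise ValueError(f"stage {stage!r} requires config key {attr!r}")
                if attr.endswith(("_dir", "_map", "csv")) or attr in ("trajectory", "mutations"):
                    if not Path(val).exists():
                        raise FileNotFoundError(f"stage {stage!r}: input {val!r} not found")


def _load_chains(cfg: PipelineConfig):
    pmap = load_position_map(cfg.position_map)
    chains = []
    for path in sorted(Path(cfg.structures_dir).glob("*.pdb")):
        for model in parse_structure(path.read_text(), pdb_id=path.stem):
            chains.extend(split_chains(model))
    chains = filter_by_resolution(chains, cfg.resolution_cutoff)
    return chains, pmap


def _redundancy_filter(chains, threshold: float):
    seqs = {}
    for m in chains:
        chain_id = next(iter(m.chains))
        seq = m.chain_sequence(chain_id)
        if seq:
            seqs[m.pdb_id] = seq
    result = tether_analysis.greedy_identity_cluster(seqs, threshold)
    keep = set(result.representatives)
    return [m for m in chains if m.pdb_id in keep], result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run report."""
    config.validate()  # pre-flight: fail before any computation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    report: dict = {"stages": {}, "outputs": [], "warnings": []}
    core = CoreDefinition()

    chains = pmap = None
    if any(s in config.stages for s in ("tether", "network")):
        chains, pmap = _load_chains(config)
        report["n_chains_after_resolution_filter"] = len(chains)

    if "tether" in config.stages:
        work = chains
        if config.cluster_redundancy:
            work, clus = _redundancy_filter(chains, config.identity_threshold)
            report["stages"]["tether"] = {"n_representatives": clus.n_clusters}
        table = tether_analysis.core_distance_table(
            work, pmap, core, scope=config.atom_scope
        )
        table.records.to_csv(out / "distances.csv", index=False)
        tether_analysis.median_matrix(table).to_csv(out / "median_matrix.csv")
        pair = tuple(config.tether_pair)
        comp = tether_analysis.compare_mechanisms(table, pair, config.test_variant)
        with open(out / "mechanism_comparison.json", "w") as fh:
            json.dump(comp.to_dict(), fh, indent=2)
        sub = table.pair(*pair)
        for mech_group in ("inverting", "retaining"):
            mask = sub["mechanism"].map(
                lambda m: tether_analysis._mechanism_group(m) == mech_group
            )
            if mask.sum() >= 2:
                tether_analysis.group_density(
                    sub.loc[mask, "distance_A"].to_numpy()
                ).to_csv(out / f"density_{mech_group}.csv", index=False)
        report["stages"].setdefault("tether", {}).update(
            n_records=len(table.records), p_value=comp.p_value
        )
        report["outputs"] += ["distances.csv", "median_matrix.csv", "mechanism_comparison.json"]

    if "network" in config.stages:
        frags = []
        for m in chains:
            try:
                frags.append(pbc_network.extract_fragment(m, pmap, config.pbc_columns))
            except (ValueError, KeyError) as exc:
                report["warnings"].append(f"network: {exc}")
        sg = pbc_network.build_network(frags, cutoff=config.rmsd_cutoff)
        clusters = pbc_network.cluster_components(sg)
        pbc_network.write_edge_list(sg, out / "pbc_edges.tsv")
        pbc_network.write_graphml(sg, out / "pbc_network.graphml")
        with open(out / "pbc_clusters.tsv", "w") as fh:
            fh.write("node\tcluster\n")
            for node, k in sorted(clusters.items()):
                fh.write(f"{node}\t{k}\n")
        report["stages"]["network"] = {
            "n_fragments": len(frags),
            "n_edges": sg.graph.number_of_edges(),
            "n_clusters": len(set(clusters.values())),
        }
        report["outputs"] += ["pbc_edges.tsv", "pbc_network.graphml", "pbc_clusters.tsv"]

    if "conformers" in config.stages:
        frames = read_trajectory(Path(config.trajectory).read_text())
        refs = tuple(
            conformation_dynamics.StateReference(
                conformation_dynamics.State(lbl), chi1, chi2
            )
            for lbl, (chi1, chi2) in config.state_references.items()
        )
        trace = conformation_dynamics.occupancy_trace(
            frames, config.residue_selector, refs, replicate_id=Path(config.trajectory).stem
        )
        with open(out / "occupancy.json", "w") as fh:
            json.dump(trace.summary(), fh, indent=2)
        with open(out / "states.csv", "w") as fh:
            fh.write("frame,chi1,chi2,state\n")
            for i, (d, s) in enumerate(zip(trace.chi_series, trace.states)):
                chi1 = "" if d.chi1 is None else f"{d.chi1:.3f}"
                chi2 = "" if d.chi2 is None else f"{d.chi2:.3f}"
                fh.write(f"{i},{chi1},{chi2},{s.value}\n")
        report["stages"]["conformers"] = trace.summary()
        report["outputs"] += ["occupancy.json", "states.csv"]

    if "variants" in config.stages:
        records = parse_mutations(config.mutations)
        pmap_v = load_position_map(config.position_map)
        fam_maps = {
            cm.family: cm for cm in pmap_v.entries.values()
        }
        summary = map_and_count(records, fam_maps, core)
        with open(out / "variant_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        if summary.hits is not None:
            summary.hits.to_csv(out / "variant_hits.tsv", sep="\t", index=False)
        report["stages"]["variants"] = {
            "total_core": summary.total_core, "tether": summary.tether,
            "n_after_dedup": summary.n_after_dedup,
        }
        report["outputs"] += ["variant_summary.json", "variant_hits.tsv"]

    if "kinetics" in config.stages:
        series = assay_analysis.read_saturation_csv(config.kinetics_csv)
        fit = assay_analysis.fit_mm(series)
        with open(out / "kinetic_fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        report["stages"]["kinetics"] = {"Km_mM": fit.km, "Vmax": fit.vmax,
                                        "converged": fit.converged}
        report["outputs"].append("kinetic_fit.json")

    if "melt" in config.stages:
        curve = assay_analysis.read_melt_csv(config.melt_csv, window=config.melt_window)
        res = assay_analysis.melt_tm(curve)
        with open(out / "melt_fit.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2)
        report["stages"]["melt"] = res.to_dict()
        report["outputs"].append("melt_fit.json")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
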