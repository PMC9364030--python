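"""Map cancer missense variants onto aligned GT-A core positions.

Mutation tables (one row per observed nonsynonymous variant, with patient
and sample identifiers) are deduplicated on the mutational event — the
(family, patient, sample, position, alt allele) key — and each surviving
record is translated from protein numbering to an alignment column via a
per-family position map.  Hits at hydrophobic-core columns and at the
C-lobe tether pair (156, 183) are counted, with per-position and
per-family breakdowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_mapping import ChainMap, CoreDefinition, PositionMap

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["gene_or_family", "patient_id", "sample_id", "position", "ref_aa", "alt_aa"]
DEDUP_KEY = ["gene_or_family", "patient_id", "sample_id", "position", "alt_aa"]

# Kyte–Doolittle hydropathy classes for annotating property changes
_HYDROPHOBIC = set("AVILMFWC")


def hydrophobicity_change(ref_aa: str, alt_aa: str) -> str:
    r, a = ref_aa in _HYDROPHOBIC, alt_aa in _HYDROPHOBIC
    if r and not a:
        return "hydrophobic_to_polar"
    if not r and a:
        return "polar_to_hydrophobic"
    return "conserved_class"


def parse_mutations(source) -> pd.DataFrame:
    """Read a mutation TSV; drop synonymous rows (ref == alt) with a log count.

    Raises on missing required columns or non-integer positions (the error
    names the offending data line).
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", dtype=str
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing required column(s): {missing}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"non-integer position {df['position'].iloc[i]!r} at data line {i + 2}"
        )
    df = df.assign(position=pos.astype(int))
    if (df["position"] < 1).any():
        i = int((df["position"] < 1).idxmax())
        raise ValueError(f"position < 1 at data line {i + 2}")
    syn = df["ref_aa"] == df["alt_aa"]
    if syn.any():
        logger.info("parse_mutations: dropped %d synonymous row(s)", int(syn.sum()))
    return df[~syn].reset_index(drop=True)


def dedupe(records: pd.DataFrame) -> pd.DataFrame:
    """Unique mutational events: first occurrence per dedup key is kept.

    The key is (family, patient, sample, position, alt allele): the same
    substitution in two patients is two events; two report rows for one
    patient-sample are one.
    """
    return records.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)


@dataclass
class CoreHitSummary:
    n_input: int
    n_after_dedup: int
    total_core: int
    tether: int
    per_position: dict[int, int] = field(default_factory=dict)
    per_family: dict[str, int] = field(default_factory=dict)
    unmapped_families: list[str] = field(default_factory=list)
    hits: pd.DataFrame | None = None
    # recurrent-hotspot view: distinct (family, position) core sites
    distinct_core_sites: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "total_core": self.total_core,
            "tether": self.tether,
            "distinct_core_sites": self.distinct_core_sites,
            "per_position": {str(k): v for k, v in sorted(self.per_position.items())},
            "per_family": dict(sorted(self.per_family.items())),
            "unmapped_families": self.unmapped_families,
        }


def _family_column_map(pmap: PositionMap | ChainMap) -> dict[int, int]:
    """residue position -> alignment column for one family."""
    if isinstance(pmap, ChainMap):
        return pmap.residue_to_column()
    if not pmap.entries:
        return {}
    first = next(iter(pmap.entries.values()))
    return first.residue_to_column()


def map_and_count(
    records: pd.DataFrame,
    pmaps: dict[str, PositionMap | ChainMap],
    core: CoreDefinition | None = None,
    reference_seqs: dict[str, str] | None = None,
    drop_ref_mismatch: bool = False,
) -> CoreHitSummary:
    """Deduplicate, map to alignment columns, and count core/tether hits.

    ``pmaps`` maps each family label to its position map.  When
    ``reference_seqs`` supplies a family's protein sequence, the reported
    ref allele is cross-checked; mismatches are logged and, with
    ``drop_ref_mismatch``, excluded.
    """
    core = core or CoreDefinition()
    n_input = len(records)
    records = dedupe(records)
    n_dedup = len(records)

    col_maps = {}
    unmapped_families = sorted(
        f for f in records["gene_or_family"].unique() if f not in pmaps
    )
    if unmapped_families:
        logger.warning("no position map for families: %s", unmapped_families)
    for fam, pm in pmaps.items():
        col_maps[fam] = _family_column_map(pm)

    hit_rows = []
    per_position: dict[int, int] = {}
    per_family: dict[str, int] = {}
    for row in records.itertuples(index=False):
        fam = row.gene_or_family
        cmap = col_maps.get(fam)
        if cmap is None:
            continue
        column = cmap.get(int(row.position))
        if column is None or column not in core.all_core:
            continue
        if reference_seqs and fam in reference_seqs:
            seq = reference_seqs[fam]
            if 1 <= row.position <= len(seq) and seq[row.position - 1] != row.ref_aa:
                logger.warning(
                    "%s position %d: table ref %s != reference %s",
                    fam, row.position, row.ref_aa, seq[row.position - 1],
                )
                if drop_ref_mismatch:
                    continue
        per_position[column] = per_position.get(column, 0) + 1
        per_family[fam] = per_family.get(fam, 0) + 1
        hit_rows.append(
            dict(
                gene_or_family=fam, patient_id=row.patient_id, sample_id=row.sample_id,
                position=int(row.position), ref_aa=row.ref_aa, alt_aa=row.alt_aa,
                column=column, is_tether=column in core.tether_pair,
                hydrophobicity=hydrophobicity_change(row.ref_aa, row.alt_aa),
            )
        )
    hits = pd.DataFrame(
        hit_rows,
        columns=["gene_or_family", "patient_id", "sample_id", "position", "ref_aa",
                 "alt_aa", "column", "is_tether", "hydrophobicity"],
    )
    tether = sum(per_position.get(c, 0) for c in core.tether_pair)
    distinct_sites = (
        hits[["gene_or_family", "column"]].drop_duplicates().shape[0] if len(hits) else 0
    )
    return CoreHitSummary(
        n_input=n_input,
        n_after_dedup=n_dedup,
        total_core=int(sum(per_position.values())),
        tether=int(tether),
        per_position=per_position,
        per_family=per_family,
        unmapped_families=unmapped_families,
        hits=hits,
        distinct_core_sites=int(distinct_sites),
    )
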