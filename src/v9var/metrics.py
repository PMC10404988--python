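"""Summary statistics: per-genome profiles, environmental OTU matching,
five-protocol diversity comparison, and multilevel pairwise similarity.

These mirror the reporting layer of the pipeline: how many V9 reads,
barcodes, OTUs (under both definitions) and ASVs a genome/transcriptome
carries; whether its predominant and minor OTUs are found in an
environmental metabarcoding community; how OTU/ASV counts per taxon depend
on the inference protocol; and how pairwise V9 identity is distributed at
the intragenomic, intra-species, inter-species, intra-taxon and inter-taxon
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .align import ScoringScheme, global_identity
from .cluster import Swarm, SwarmConfig, swarm_d1
from .denoise import ASV, DenoiseConfig, denoise_reads, denoise_paired
from .extract import Barcode, dereplicate
from .readprep import Read

__all__ = [
    "GenomeProfile",
    "OTUMatchRecord",
    "SimilarityRecord",
    "LabeledUnit",
    "genome_profile",
    "match_to_environment",
    "compare_protocols",
    "protocol_summary",
    "similarity_levels",
    "PROTOCOLS",
]

PROTOCOLS = (
    "swarm_on_barcodes",
    "denoise_merged",
    "denoise_paired",
    "denoise_merged+swarm",
    "denoise_paired+swarm",
)


@dataclass
class GenomeProfile:
    """One genome/transcriptome's summary row (post contamination removal)."""

    source_id: str
    n_v9_reads: int
    n_barcodes: int
    top_barcode_fraction: float
    n_otu97: int | None
    n_swarms: int | None
    n_asvs: int | None
    best_hit_identities: list[float] = field(default_factory=list)


@dataclass
class OTUMatchRecord:
    otu_id: str
    source_id: str
    rank: str  # "predominant" or "minor"
    env_reads: int

    @property
    def found(self) -> bool:
        return self.env_reads > 0


@dataclass
class SimilarityRecord:
    level: str
    pid: float
    unit_a: str
    unit_b: str


@dataclass
class LabeledUnit:
    id: str
    sequence: str
    source: str
    species: str
    genus: str
    taxon: str


def genome_profile(
    source_id: str,
    barcodes: list[Barcode],
    swarms: list[Swarm] | None = None,
    clusters97: list | None = None,
    asvs: list[ASV] | None = None,
    best_hit_identities: list[float] | None = None,
) -> GenomeProfile:
    """Assemble the per-genome statistics row.

    Counts for stages that were not run are reported as None (absent), not
    zero.  ``top_barcode_fraction`` is the fraction of V9 reads carried by
    the most abundant barcode.
    """
    if not barcodes:
        raise ValueError("genome_profile needs at least one barcode")
    total = sum(b.count for b in barcodes)
    top = max(b.count for b in barcodes)
    return GenomeProfile(
        source_id=source_id,
        n_v9_reads=total,
        n_barcodes=len(barcodes),
        top_barcode_fraction=top / total,
        n_otu97=len(clusters97) if clusters97 is not None else None,
        n_swarms=len(swarms) if swarms is not None else None,
        n_asvs=len(asvs) if asvs is not None else None,
        best_hit_identities=list(best_hit_identities or []),
    )


def match_to_environment(
    source_units,
    env_table: pd.DataFrame,
    source_id: str = "",
    swarm_cfg: SwarmConfig | None = None,
) -> list[OTUMatchRecord]:
    """Co-cluster one source's units with environmental barcodes.

    ``env_table`` is a (prefiltered) barcode-by-sample count table.  Source
    units and environmental barcodes are pooled into one dereplicated set
    and swarm-clustered; each swarm containing at least one source unit
    becomes a record whose ``env_reads`` is the summed environmental count
    of its members.  The swarm holding the source's most abundant unit is
    the predominant OTU; every other source swarm is minor.
    """
    env_totals = env_table.sum(axis=1).to_dict()
    source_counts: dict[str, int] = {}
    for u in source_units:
        source_counts[u.sequence] = source_counts.get(u.sequence, 0) + u.count
    pooled: dict[str, int] = dict(source_counts)
    for seq, n in env_totals.items():
        pooled[seq] = pooled.get(seq, 0) + int(n)
    barcodes = [Barcode(seq, n, "pooled") for seq, n in pooled.items() if n > 0]
    swarms = swarm_d1(barcodes, swarm_cfg)

    top_source_seq = max(source_counts, key=lambda s: (source_counts[s], s))
    records = []
    for sw in swarms:
        member_seqs = [m.sequence for m in sw.members]
        if not any(s in source_counts for s in member_seqs):
            continue
        env_reads = int(sum(env_totals.get(s, 0) for s in member_seqs))
        rank = "predominant" if top_source_seq in member_seqs else "minor"
        records.append(OTUMatchRecord(sw.seed.sequence, source_id, rank, env_reads))
    assert sum(1 for r in records if r.rank == "predominant") == 1
    return records


def _count_protocols(
    merged_reads: list[Read],
    pairs=None,
    denoise_cfg: DenoiseConfig | None = None,
    swarm_cfg: SwarmConfig | None = None,
) -> dict[str, int | None]:
    cfg = denoise_cfg or DenoiseConfig()
    barcodes = dereplicate([(r.bases, "") for r in merged_reads])
    counts: dict[str, int | None] = {}
    counts["swarm_on_barcodes"] = len(swarm_d1(barcodes, swarm_cfg))
    asvs_m = denoise_reads(merged_reads, cfg=cfg)
    counts["denoise_merged"] = len(asvs_m)
    asv_barcodes = [Barcode(a.sequence, a.count, "") for a in asvs_m]
    counts["denoise_merged+swarm"] = len(swarm_d1(asv_barcodes, swarm_cfg)) if asv_barcodes else 0
    if pairs is not None:
        asvs_p = denoise_paired(pairs, cfg)
        counts["denoise_paired"] = len(asvs_p)
        pb = [Barcode(a.sequence, a.count, "") for a in asvs_p]
        counts["denoise_paired+swarm"] = len(swarm_d1(pb, swarm_cfg)) if pb else 0
    else:
        counts["denoise_paired"] = None
        counts["denoise_paired+swarm"] = None
    return counts


def compare_protocols(
    taxa: dict[str, dict],
    denoise_cfg: DenoiseConfig | None = None,
    swarm_cfg: SwarmConfig | None = None,
) -> pd.DataFrame:
    """Per-taxon OTU/ASV counts under the five inference protocols.

    ``taxa`` maps a taxon label to ``{"merged": [Read, ...]}`` with an
    optional ``"pairs"`` entry of ReadPairs for the paired protocol.
    Returns a DataFrame indexed by taxon with one column per protocol
    (absent protocols are NA).
    """
    rows = {}
    for taxon in sorted(taxa):
        inputs = taxa[taxon]
        rows[taxon] = _count_protocols(
            inputs["merged"], inputs.get("pairs"), denoise_cfg, swarm_cfg
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(PROTOCOLS))
    df.index.name = "taxon"
    return df


def protocol_summary(df: pd.DataFrame) -> dict[str, float]:
    """Median (and mean) inter-protocol ratios across taxa.

    ``swarm_vs_denoised`` is the per-taxon ratio of swarm-on-barcodes OTUs to
    denoised ASVs (paired protocol when available, merged otherwise);
    ``swarm_collapse_of_asvs`` is the fold-change from applying swarm
    clustering to the merged-protocol ASVs.
    """
    denom = df["denoise_paired"].fillna(df["denoise_merged"])
    ratio = (df["swarm_on_barcodes"] / denom).replace([np.inf, -np.inf], np.nan).dropna()
    collapse = (
        (df["denoise_merged"] / df["denoise_merged+swarm"])
        .replace([np.inf, -np.inf], np.nan)
        .dropna()
    )
    out = {
        "median_swarm_vs_denoised": float(ratio.median()) if len(ratio) else float("nan"),
        "mean_swarm_vs_denoised": float(ratio.mean()) if len(ratio) else float("nan"),
        "median_swarm_collapse_of_asvs": float(collapse.median()) if len(collapse) else float("nan"),
        "frac_taxa_swarm_highest": float(
            (df["swarm_on_barcodes"] >= df[["denoise_merged", "denoise_paired"]].max(axis=1, skipna=True)).mean()
        ),
    }
    return out


_LEVEL_ORDER = ("intragenomic", "intra_species", "inter_species", "intra_taxon", "inter_taxon")


def _pair_level(a: LabeledUnit, b: LabeledUnit) -> str:
    if a.source == b.source:
        return "intragenomic"
    if a.species == b.species:
        return "intra_species"
    if a.genus == b.genus:
        return "inter_species"
    if a.taxon == b.taxon:
        return "intra_taxon"
    return "inter_taxon"


def similarity_levels(
    units: list[LabeledUnit], scoring: ScoringScheme | None = None
) -> list[SimilarityRecord]:
    """All pairwise identities, each pair assigned its most specific level."""
    if len(units) < 2:
        raise ValueError("similarity_levels needs at least two units")
    records = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            a, b = units[i], units[j]
            pid = global_identity(a.sequence, b.sequence, scoring)
            records.append(SimilarityRecord(_pair_level(a, b), pid, a.id, b.id))
    return records
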