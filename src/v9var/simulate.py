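"""Synthetic genomes/transcriptomes and environmental amplicon communities.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-copy rRNA locus carrying one dominant and up to ``k-1``
minor V9 variants at a configurable edit distance and copy-weight vector;
quality-dependent substitution and indel sequencing errors; cross-phylum
contaminant reads whose V9 has low (< 0.80 by default) global identity to
the dominant variant; two-parent single-breakpoint chimeric amplicons; and
multi-sample environmental abundance tables with a long rare tail.

Every read is tracked in a :class:`TruthTable` so that extraction,
denoising, clustering and contamination classification can be scored
against ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import global_identity
from .readprep import Read

__all__ = [
    "SimConfig",
    "TruthTable",
    "EnvCommunityConfig",
    "simulate_genome_reads",
    "simulate_env_samples",
    "pairs_from_reads",
    "reads_to_fastq",
]

_BASES = np.array(list("ACGT"))
V9_LENGTH_RANGE = (104, 137)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def nominal_error_rates(qualities=range(0, 94)) -> dict[int, float]:
    """Phred-nominal substitution probability 10^(-q/10) per quality score."""
    return {int(q): 10.0 ** (-q / 10.0) for q in qualities}


@dataclass
class SimConfig:
    """Parameters of one synthetic genome/transcriptome V9 locus."""

    seed: int = 0
    n_variants: int = 1
    variant_divergence: int = 2
    copy_weights: tuple[float, ...] | None = None
    v9_length: int = 123
    depth: int = 1000
    read_length: int = 0  # 0: each read spans the whole V9 copy
    quality: int = 30  # constant per-position quality profile
    quality_profile: tuple[int, ...] | None = None
    error_rate_by_quality: dict[int, float] | None = None
    indel_rate: float = 0.0
    contamination_fraction: float = 0.0
    contaminant_max_identity: float = 0.75
    chimera_fraction: float = 0.0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (V9_LENGTH_RANGE[0] <= self.v9_length <= V9_LENGTH_RANGE[1]):
            raise ValueError(f"v9_length must lie in {V9_LENGTH_RANGE}")
        if self.copy_weights is None:
            self.copy_weights = tuple([1.0 / self.n_variants] * self.n_variants)
        if len(self.copy_weights) != self.n_variants:
            raise ValueError("copy_weights length must equal n_variants")
        if any(w <= 0 for w in self.copy_weights):
            raise ValueError("copy_weights must be positive")
        total = float(sum(self.copy_weights))
        if abs(total - 1.0) > 1e-9:
            self.copy_weights = tuple(w / total for w in self.copy_weights)
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ValueError("contamination_fraction must be in [0, 1)")
        if not (0.0 <= self.chimera_fraction < 1.0):
            raise ValueError("chimera_fraction must be in [0, 1)")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.error_rate_by_quality is None:
            self.error_rate_by_quality = nominal_error_rates()
        if any(not (0.0 <= p <= 1.0) for p in self.error_rate_by_quality.values()):
            raise ValueError("error rates must be probabilities")
        # a minor variant must stay clearly above the contaminant identity band
        min_variant_identity = 1.0 - self.variant_divergence / self.v9_length
        if (
            self.n_variants > 1
            and min_variant_identity < self.contaminant_max_identity + 0.05
        ):
            raise ValueError(
                "variant_divergence so large that minor variants collide with "
                "the contaminant identity band"
            )

    def qualities(self, length: int) -> np.ndarray:
        if self.quality_profile is not None:
            prof = np.asarray(self.quality_profile, dtype=int)
            reps = int(np.ceil(length / len(prof)))
            return np.tile(prof, reps)[:length]
        return np.full(length, self.quality, dtype=int)


@dataclass
class TruthTable:
    """Ground truth for one simulated genome: who every read really is."""

    true_variant_sequences: list[str]
    true_counts: np.ndarray
    contaminant_ids: set[str]
    chimeric_ids: set[str]
    per_read_template: dict[str, int]
    contaminant_sequence: str = ""

    def category(self, read_id: str) -> str:
        if read_id in self.contaminant_ids:
            return "contaminant"
        if read_id in self.chimeric_ids:
            return "chimera"
        return "variant"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rid, self.category(rid), self.per_read_template.get(rid, -1))
            for rid in sorted(
                set(self.per_read_template)
                | self.contaminant_ids
                | self.chimeric_ids
            )
        ]
        return pd.DataFrame(rows, columns=["read_id", "category", "template_index"])


def _mutate_variant(rng, dominant: str, divergence: int) -> str:
    """Apply exactly ``divergence`` substitutions at distinct positions."""
    seq = list(dominant)
    positions = rng.choice(len(seq), size=divergence, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _apply_errors(rng, template: str, quals: np.ndarray, cfg: SimConfig) -> str:
    """Quality-dependent substitutions, then uniformly placed indels."""
    seq = list(template)
    for i, q in enumerate(quals[: len(seq)]):
        p = cfg.error_rate_by_quality.get(int(q), 10.0 ** (-int(q) / 10.0))
        if p > 0 and rng.random() < p:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, 3)]
    if cfg.indel_rate > 0:
        n_events = rng.binomial(len(seq), cfg.indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5 and len(seq) > 1:
                del seq[pos]
            else:
                seq.insert(pos, str(rng.choice(_BASES)))
    return "".join(seq)


def _draw_contaminant(rng, dominant: str, max_identity: float) -> str:
    """Rejection-sample an unrelated V9 template below the identity ceiling."""
    for _ in range(200):
        cand = _random_seq(rng, len(dominant))
        if global_identity(cand, dominant) < max_identity:
            return cand
    raise RuntimeError("could not sample a sufficiently divergent contaminant")


def simulate_genome_reads(cfg: SimConfig) -> tuple[list[Read], TruthTable]:
    """Emit reads from a multi-copy V9 locus plus contaminants and chimeras.

    The dominant variant is generated first; each minor variant is at exactly
    ``cfg.variant_divergence`` substitutions from it.  Read categories
    (variant / contaminant / chimera) partition the read set, and category
    draws use ``cfg.copy_weights`` for the variant templates.
    """
    rng = np.random.default_rng(cfg.seed)
    dominant = _random_seq(rng, cfg.v9_length)
    variants = [dominant]
    seen = {dominant}
    while len(variants) < cfg.n_variants:
        cand = _mutate_variant(rng, dominant, cfg.variant_divergence)
        if cand not in seen:
            seen.add(cand)
            variants.append(cand)

    contaminant = ""
    if cfg.contamination_fraction > 0:
        contaminant = _draw_contaminant(rng, dominant, cfg.contaminant_max_identity)

    reads: list[Read] = []
    true_counts = np.zeros(cfg.n_variants, dtype=int)
    contaminant_ids: set[str] = set()
    chimeric_ids: set[str] = set()
    per_read_template: dict[str, int] = {}
    weights = np.asarray(cfg.copy_weights)

    for n in range(cfg.depth):
        rid = f"sim{cfg.seed}_read{n}"
        u = rng.random()
        if u < cfg.chimera_fraction and cfg.n_variants >= 1:
            a = variants[rng.choice(cfg.n_variants, p=weights)]
            b = variants[rng.choice(cfg.n_variants, p=weights)]
            lo, hi = 10, min(len(a), len(b)) - 10
            bp = int(rng.integers(lo, hi)) if hi > lo else len(a) // 2
            template = a[:bp] + b[bp:]
            chimeric_ids.add(rid)
        elif u < cfg.chimera_fraction + cfg.contamination_fraction:
            template = contaminant
            contaminant_ids.add(rid)
        else:
            idx = int(rng.choice(cfg.n_variants, p=weights))
            template = variants[idx]
            true_counts[idx] += 1
            per_read_template[rid] = idx
        quals = cfg.qualities(len(template) + 16)
        bases = _apply_errors(rng, template, quals, cfg)
        if cfg.read_length and len(bases) > cfg.read_length:
            bases = bases[: cfg.read_length]
        reads.append(Read(rid, bases, list(quals[: len(bases)])))

    truth = TruthTable(
        true_variant_sequences=variants,
        true_counts=true_counts,
        contaminant_ids=contaminant_ids,
        chimeric_ids=chimeric_ids,
        per_read_template=per_read_template,
        contaminant_sequence=contaminant,
    )
    assert int(true_counts.sum()) == cfg.depth - len(contaminant_ids) - len(
        chimeric_ids
    )
    return reads, truth


@dataclass
class EnvCommunityConfig:
    """A heavy-tailed multi-sample environmental community."""

    seed: int = 0
    n_samples: int = 4
    n_taxa: int = 50
    depth: int = 5000  # reads per sample
    power: float = 1.8  # rank-abundance exponent: p_i ~ (i+1)^-power
    v9_length: int = 123
    templates: list[str] | None = None  # override the random taxa
    plant_rare: bool = True

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("the environmental prefilter needs >= 2 samples")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")


def simulate_env_samples(
    cfg: EnvCommunityConfig,
) -> tuple[pd.DataFrame, dict]:
    """Sample-by-barcode count table under a power-law rank-abundance curve.

    Returns ``(table, truth)`` where the table is indexed by barcode sequence
    with one column per sample, and the truth dict records the taxon
    templates and which barcodes the occupancy/abundance prefilter should
    remove.  When ``plant_rare`` is set, one taxon confined to a single
    sample (1 read) and one taxon with a total of 2 reads are planted so the
    prefilter always has something to act on.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.templates is not None:
        templates = list(cfg.templates)
    else:
        templates = []
        seen: set[str] = set()
        while len(templates) < cfg.n_taxa:
            s = _random_seq(rng, cfg.v9_length)
            if s not in seen:
                seen.add(s)
                templates.append(s)
    n = len(templates)
    p = (np.arange(1, n + 1, dtype=float)) ** (-cfg.power)
    p /= p.sum()
    counts = np.zeros((n, cfg.n_samples), dtype=int)
    for s in range(cfg.n_samples):
        counts[:, s] = rng.multinomial(cfg.depth, p)

    planted: list[str] = []
    if cfg.plant_rare:
        while len(planted) < 2:
            s = _random_seq(rng, cfg.v9_length)
            if s not in templates and s not in planted:
                planted.append(s)
        single = np.zeros((1, cfg.n_samples), dtype=int)
        single[0, 0] = 1  # one sample only
        doublet = np.zeros((1, cfg.n_samples), dtype=int)
        doublet[0, 0] = 1
        doublet[0, min(1, cfg.n_samples - 1)] = 1  # total of 2 reads
        counts = np.vstack([counts, single, doublet])
        templates = templates + planted

    table = pd.DataFrame(
        counts,
        index=templates,
        columns=[f"sample_{s}" for s in range(cfg.n_samples)],
    )
    # the emitted table, like a real dereplicated table, lists observed
    # barcodes only; unobserved templates stay in the truth record
    table = table.loc[table.sum(axis=1) > 0]
    occupancy = (table > 0).sum(axis=1)
    total = table.sum(axis=1)
    removable = set(table.index[(occupancy < 2) | (total < 3)])
    truth = {
        "templates": templates,
        "planted": planted,
        "prefilter_removable": removable,
    }
    return table, truth


def pairs_from_reads(reads: list[Read], read_length: int):
    """Split each read into an overlapping forward/reverse mate pair.

    The forward mate is the first ``read_length`` bases, the reverse mate
    the reverse complement of the last ``read_length`` bases (as a
    sequencer would report it).  Reads shorter than ``read_length`` are
    skipped.  Mates overlap whenever ``2 * read_length > len(read)``.
    """
    from .readprep import ReadPair

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    pairs = []
    for r in reads:
        if len(r.bases) < read_length:
            continue
        fwd = Read(r.id + "/1", r.bases[:read_length], r.qualities[:read_length])
        tail = r.bases[-read_length:]
        tail_q = r.qualities[-read_length:]
        rev = Read(
            r.id + "/2",
            "".join(comp[b] for b in reversed(tail)),
            list(reversed(tail_q)),
        )
        pairs.append(ReadPair(fwd, rev))
    return pairs


def reads_to_fastq(reads: list[Read]) -> str:
    """Render reads as Sanger/Phred+33 FASTQ text (deterministic)."""
    buf = io.StringIO()
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.qualities)
        buf.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
    return buf.getvalue()
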