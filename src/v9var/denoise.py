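"""Divisive amplicon denoising with a quality-dependent error model.

The denoiser partitions dereplicated unique sequences around centers.  For
a unique ``j`` in a partition with center ``c`` carrying ``N_c`` reads, the
probability that a read of ``c`` is miscalled as exactly ``j`` is

    rho_j = prod over alignment columns of P(c_base -> j_base | quality),

so the expected number of such reads is ``lambda_j = rho_j * N_c``.  The
abundance p-value asks how surprising ``j``'s observed count is under a
Poisson(lambda_j) conditioned on being observed at all:

    p_j = P(X >= n_j | X >= 1),  X ~ Poisson(lambda_j),

which is identically 1 for singletons — a singleton can never found a new
partition.  While the smallest p-value falls below ``omega_a`` (1e-40 by
default), that unique is promoted to a new center and every unique is
reassigned to the center most likely to have produced it.  Partition
centers with their aggregated counts are the ASVs.

The error model is learned self-consistently: denoise, re-estimate
substitution rates from the mismatches between uniques and their partition
centers binned by quality, regularize each rate to be monotone
non-increasing in quality (isotonic regression with a probability floor),
and repeat until the transition matrix stabilizes.

Bimera (two-parent chimera) removal follows the consensus rule: an ASV
exactly reconstructable as a left-prefix of one sufficiently more abundant
ASV plus a right-suffix of another is flagged, and removed when flagged in
more than a configured fraction of the samples where it was testable.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson
from sklearn.isotonic import IsotonicRegression

from .align import global_align
from .readprep import Read, discard_n_and_truncate

__all__ = [
    "UniqueSeq",
    "ErrorModel",
    "DenoiseConfig",
    "ASV",
    "dereplicate_with_quality",
    "error_probability",
    "abundance_p_value",
    "denoise_sample",
    "denoise_reads",
    "learn_error_model",
    "remove_bimeras_consensus",
    "denoise_paired",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
MAX_Q = 93


@dataclass
class UniqueSeq:
    """A dereplicated sequence with positionwise mean quality over its reads."""

    sequence: str
    count: int
    mean_quals: np.ndarray


@dataclass
class ASV:
    sequence: str
    count: int
    source_id: str = ""


@dataclass
class DenoiseConfig:
    omega_a: float = 1e-40
    max_selfconsist_rounds: int = 10
    pool_mode: str = "pooled"  # or "per_sample"
    bimera: str = "consensus"  # or "off"
    min_fold_parent_overabundance: float = 2.0
    consensus_sample_fraction: float = 0.9
    indel_prob: float = 1e-5  # per gap column in unique-vs-center alignments
    prob_floor: float = 1e-7
    band: int = 16
    trunc_len: int = 80
    paired_min_overlap: int = 12

    def __post_init__(self):
        if not (0.0 < self.omega_a < 1.0):
            raise ValueError("omega_a must be in (0, 1)")
        if self.max_selfconsist_rounds < 1:
            raise ValueError("max_selfconsist_rounds must be >= 1")


class ErrorModel:
    """Per-(from, to, quality) substitution probabilities, rows normalized."""

    def __init__(self, p: np.ndarray, learned: bool = False):
        if p.shape != (4, 4, MAX_Q + 1):
            raise ValueError("error model must have shape (4, 4, 94)")
        self.p = p
        self.learned = learned

    @classmethod
    def from_quality(cls, floor: float = 1e-7) -> "ErrorModel":
        """Phred-nominal model: total miscall rate 10^(-q/10), split evenly."""
        p = np.zeros((4, 4, MAX_Q + 1))
        q = np.arange(MAX_Q + 1)
        err = np.maximum(10.0 ** (-q / 10.0), 3 * floor)
        for a in range(4):
            for b in range(4):
                p[a, b, :] = err / 3.0 if a != b else 1.0 - err
        return cls(p, learned=False)

    def log_p(self) -> np.ndarray:
        return np.log(np.maximum(self.p, 1e-300))


def dereplicate_with_quality(reads: list[Read]) -> list[UniqueSeq]:
    """Collapse reads into uniques, averaging qualities position by position.

    Reads containing undetermined bases are dropped (they cannot enter the
    4-letter error model).  Output sorted by count descending, then
    sequence.
    """
    groups: dict[str, list[list[int]]] = defaultdict(list)
    for r in reads:
        if "N" in r.bases:
            continue
        groups[r.bases].append(r.qualities)
    out = []
    for seq, quals in groups.items():
        arr = np.asarray(quals, dtype=float)
        mean = np.rint(arr.mean(axis=0)).astype(int)
        out.append(UniqueSeq(seq, len(quals), mean))
    out.sort(key=lambda u: (-u.count, u.sequence))
    return out


def _log_rho(
    unique: UniqueSeq, center: str, logp: np.ndarray, cfg: DenoiseConfig
) -> float:
    """log of the probability that a read of ``center`` is read as ``unique``."""
    useq = unique.sequence
    q = np.minimum(unique.mean_quals, MAX_Q)
    if len(useq) == len(center):
        ui = np.fromiter((_BASE_INDEX[b] for b in useq), dtype=int, count=len(useq))
        ci = np.fromiter((_BASE_INDEX[b] for b in center), dtype=int, count=len(center))
        if int((ui != ci).sum()) <= 6:  # gapless alignment is optimal here
            return float(logp[ci, ui, q].sum())
    aln = global_align(center, useq, band=cfg.band)
    total = 0.0
    upos = 0
    log_indel = math.log(cfg.indel_prob)
    for cb, ub in zip(aln.aligned_a, aln.aligned_b):
        if cb == "-" or ub == "-":
            total += log_indel
            if ub != "-":
                upos += 1
            continue
        qq = int(min(unique.mean_quals[upos], MAX_Q))
        total += float(logp[_BASE_INDEX[cb], _BASE_INDEX[ub], qq])
        upos += 1
    return total


def error_probability(
    unique: UniqueSeq,
    center: str,
    model: ErrorModel,
    cfg: DenoiseConfig | None = None,
) -> float:
    """The error-production probability rho of ``unique`` from ``center``."""
    cfg = cfg or DenoiseConfig()
    return math.exp(_log_rho(unique, center, model.log_p(), cfg))


def abundance_p_value(n_j: int, expected: float) -> float:
    """P(X >= n_j | X >= 1) for X ~ Poisson(expected); 1 by definition at n_j=1."""
    if n_j < 1:
        raise ValueError("n_j must be >= 1")
    if n_j == 1:
        return 1.0
    if expected <= 0.0:
        return 0.0
    denom = -math.expm1(-expected)  # P(X >= 1), accurate for small lambda
    return float(poisson.sf(n_j - 1, expected) / denom)


@dataclass
class _Partition:
    center: int  # index into uniques
    members: list[int]


def _divide(
    uniques: list[UniqueSeq], model: ErrorModel, cfg: DenoiseConfig
) -> list[_Partition]:
    """The divisive loop; returns final partitions over ``uniques`` indices."""
    if not uniques:
        return []
    order = sorted(range(len(uniques)), key=lambda i: (-uniques[i].count, uniques[i].sequence))
    logp = model.log_p()
    cache: dict[tuple[int, int], float] = {}

    def lrho(j: int, c: int) -> float:
        key = (j, c)
        if key not in cache:
            cache[key] = _log_rho(uniques[j], uniques[c].sequence, logp, cfg)
        return cache[key]

    centers = [order[0]]
    assign = {j: 0 for j in order}
    for _ in range(len(uniques)):
        reads = [0] * len(centers)
        for j, p in assign.items():
            reads[p] += uniques[j].count
        worst = None  # (p_value, -count, sequence, j)
        for j, p in assign.items():
            if j == centers[p]:
                continue
            lam = math.exp(lrho(j, centers[p]) + math.log(reads[p]))
            pval = abundance_p_value(uniques[j].count, lam)
            if pval < cfg.omega_a:
                key = (pval, -uniques[j].count, uniques[j].sequence)
                if worst is None or key < worst[0]:
                    worst = (key, j)
        if worst is None:
            break
        centers.append(worst[1])
        for j in order:  # reassign everything to the most likely center
            if j in centers:
                assign[j] = centers.index(j)
            else:
                scores = [lrho(j, c) for c in centers]
                assign[j] = int(np.argmax(scores))
    partitions = [ _Partition(c, []) for c in centers ]
    for j in order:
        partitions[assign[j]].members.append(j)
    return partitions


def denoise_sample(
    uniques: list[UniqueSeq],
    model: ErrorModel | None = None,
    cfg: DenoiseConfig | None = None,
    source_id: str = "",
) -> list[ASV]:
    """Denoise one sample of dereplicated uniques into ASVs."""
    cfg = cfg or DenoiseConfig()
    model = model or ErrorModel.from_quality(cfg.prob_floor)
    parts = _divide(uniques, model, cfg)
    asvs = [
        ASV(
            uniques[p.center].sequence,
            sum(uniques[j].count for j in p.members),
            source_id,
        )
        for p in parts
    ]
    asvs.sort(key=lambda a: (-a.count, a.sequence))
    return asvs


def denoise_reads(
    reads: list[Read],
    model: ErrorModel | None = None,
    cfg: DenoiseConfig | None = None,
    source_id: str = "",
) -> list[ASV]:
    """Convenience wrapper: dereplicate with qualities, then denoise."""
    return denoise_sample(dereplicate_with_quality(reads), model, cfg, source_id)


def _tally_transitions(
    uniques: list[UniqueSeq], parts: list[_Partition], counts: np.ndarray
):
    for p in parts:
        center = uniques[p.center].sequence
        for j in p.members:
            u = uniques[j]
            if len(u.sequence) != len(center):
                continue  # indel-bearing uniques are rare and skip the sub tally
            q = np.minimum(u.mean_quals, MAX_Q)
            for pos, (cb, ub) in enumerate(zip(center, u.sequence)):
                counts[_BASE_INDEX[cb], _BASE_INDEX[ub], q[pos]] += u.count


def _rates_from_counts(counts: np.ndarray, floor: float) -> np.ndarray:
    """Observed rates, nearest-quality fill for empty bins, isotonic smoothing."""
    p = np.zeros_like(counts, dtype=float)
    qgrid = np.arange(MAX_Q + 1)
    for a in range(4):
        row_tot = counts[a].sum(axis=0)  # per quality
        observed = row_tot > 0
        for b in range(4):
            if a == b:
                continue
            rate = np.zeros(MAX_Q + 1)
            if observed.any():
                rate[observed] = counts[a, b, observed] / row_tot[observed]
                # empty bins inherit the nearest observed quality's rate
                obs_q = qgrid[observed]
                nearest = obs_q[np.abs(qgrid[:, None] - obs_q[None, :]).argmin(axis=1)]
                rate[~observed] = rate[nearest[~observed]]
                weights = np.where(observed, row_tot, 1e-6)
                iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
                rate = iso.fit_transform(qgrid, rate, sample_weight=weights)
            p[a, b] = np.maximum(rate, floor)
        p[a, a] = 1.0 - p[a].sum(axis=0)
    return p


def learn_error_model(
    samples: list[list[UniqueSeq]], cfg: DenoiseConfig | None = None
) -> ErrorModel:
    """Self-consistent error-rate learning.

    Alternates denoising with re-estimation of the substitution rates from
    observed unique-vs-center mismatches binned by quality, until the
    transition matrix changes by less than 1e-6 in max-norm or the round
    budget is exhausted.  ``learned`` is True iff convergence was reached.
    """
    cfg = cfg or DenoiseConfig()
    if not samples:
        raise ValueError("learn_error_model needs at least one sample")
    model = ErrorModel.from_quality(cfg.prob_floor)
    for _ in range(cfg.max_selfconsist_rounds):
        counts = np.zeros((4, 4, MAX_Q + 1))
        for uniques in samples:
            parts = _divide(uniques, model, cfg)
            _tally_transitions(uniques, parts, counts)
        new_p = _rates_from_counts(counts, cfg.prob_floor)
        delta = float(np.abs(new_p - model.p).max())
        model = ErrorModel(new_p, learned=False)
        if delta < 1e-6:
            model.learned = True
            break
    return model


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _is_bimera(child: str, parents: list[str]) -> bool:
    if len(parents) < 2:
        return False
    best_lcp = {p: _lcp(child, p) for p in parents}
    best_lcs = {p: _lcp(child[::-1], p[::-1]) for p in parents}
    for pa in parents:
        for pb in parents:
            if pa == pb:
                continue
            if (
                best_lcp[pa] >= 1
                and best_lcs[pb] >= 1
                and best_lcp[pa] + best_lcs[pb] >= len(child)
            ):
                return True
    return False


def remove_bimeras_consensus(
    per_sample_asvs: list[list[ASV]], cfg: DenoiseConfig | None = None
) -> list[list[ASV]]:
    """Consensus bimera removal across samples.

    Within each sample an ASV is flagged when it can be reconstructed with
    one breakpoint and zero mismatches as a left-prefix of one parent plus a
    right-suffix of another, both parents at least
    ``min_fold_parent_overabundance`` times more abundant.  An ASV is
    removed from every sample when it was flagged in more than
    ``consensus_sample_fraction`` of the samples where it was testable
    (i.e. had at least two candidate parents).
    """
    cfg = cfg or DenoiseConfig()
    flagged: dict[str, int] = defaultdict(int)
    testable: dict[str, int] = defaultdict(int)
    for sample in per_sample_asvs:
        for asv in sample:
            parents = [
                p.sequence
                for p in sample
                if p.sequence != asv.sequence
                and p.count >= cfg.min_fold_parent_overabundance * asv.count
            ]
            if len(parents) < 2:
                continue
            testable[asv.sequence] += 1
            if _is_bimera(asv.sequence, parents):
                flagged[asv.sequence] += 1
    removed = {
        seq
        for seq, n_test in testable.items()
        if n_test > 0 and flagged[seq] / n_test > cfg.consensus_sample_fraction
    }
    return [[a for a in sample if a.sequence not in removed] for sample in per_sample_asvs]


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def denoise_paired(
    pairs,
    cfg: DenoiseConfig | None = None,
    model_fwd: ErrorModel | None = None,
    model_rev: ErrorModel | None = None,
    source_id: str = "",
) -> list[ASV]:
    """The paired 80/80-truncation protocol.

    Both mates are truncated to ``cfg.trunc_len`` (shorter pairs dropped),
    the forward and reverse streams are denoised independently, denoised
    mate pairs are merged by exact ungapped overlap (at least
    ``paired_min_overlap`` identical bases, zero mismatches; incompatible
    pairs are dropped), and bimeras are removed from the merged table.

    Two templates differing only in a stretch that neither truncated mate
    reaches collapse into one ASV — an inherent limitation of this mode.
    """
    cfg = cfg or DenoiseConfig()
    fwd, rev = [], []
    for pair in pairs:
        tf = discard_n_and_truncate([pair.forward], trunc_len=cfg.trunc_len)
        tr = discard_n_and_truncate([pair.reverse], trunc_len=cfg.trunc_len)
        if tf and tr:
            fwd.append(tf[0])
            rev.append(tr[0])
    if not fwd:
        return []
    fu = dereplicate_with_quality(fwd)
    ru = dereplicate_with_quality(rev)
    fparts = _divide(fu, model_fwd or ErrorModel.from_quality(cfg.prob_floor), cfg)
    rparts = _divide(ru, model_rev or ErrorModel.from_quality(cfg.prob_floor), cfg)
    fmap = {fu[j].sequence: fu[p.center].sequence for p in fparts for j in p.members}
    rmap = {ru[j].sequence: ru[p.center].sequence for p in rparts for j in p.members}

    merged_counts: dict[str, int] = defaultdict(int)
    for f, r in zip(fwd, rev):
        fa = fmap.get(f.bases)
        ra = rmap.get(r.bases)
        if fa is None or ra is None:
            continue
        rrc = _revcomp(ra)
        merged = None
        for L in range(min(len(fa), len(rrc)), cfg.paired_min_overlap - 1, -1):
            if fa[len(fa) - L :] == rrc[:L]:
                merged = fa + rrc[L:]
                break
        if merged is not None:
            merged_counts[merged] += 1
    asvs = [ASV(seq, n, source_id) for seq, n in merged_counts.items()]
    asvs.sort(key=lambda a: (-a.count, a.sequence))
    if cfg.bimera == "consensus":
        asvs = remove_bimeras_consensus([asvs], cfg)[0]
    return asvs
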