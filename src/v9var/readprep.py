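"""Read quality filtering, pair merging, and amplicon primer trimming.

These are the pre-extraction / pre-denoising passes: a mean-Phred filter,
best-ungapped-overlap pair merging, substitution-only primer trimming, and
the truncation / N / expected-errors filter used ahead of denoising.  All
passes are order-preserving and idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "ReadPair",
    "mean_quality_filter",
    "merge_pairs",
    "trim_amplicon_primers",
    "discard_n_and_truncate",
    "read_fastq",
    "write_fastq",
]


@dataclass
class Read:
    """A sequence with per-base Phred qualities."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.id}: bases and qualities differ in length")

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    @property
    def expected_errors(self) -> float:
        return sum(10.0 ** (-q / 10.0) for q in self.qualities)


@dataclass
class ReadPair:
    forward: Read
    reverse: Read


def read_fastq(path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        out.append(
            Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(reads: list[Read], handle) -> None:
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.qualities)
        handle.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def mean_quality_filter(reads: list[Read], threshold: float = 20.0) -> list[Read]:
    """Keep reads whose arithmetic mean Phred quality is >= threshold.

    A read with mean exactly at the threshold is retained (only "below"
    is removed).  Zero-length reads are dropped and logged.
    """
    kept = []
    for r in reads:
        if not r.bases:
            logger.warning("dropping zero-length read %s", r.id)
            continue
        if r.mean_quality >= threshold:
            kept.append(r)
    return kept


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _best_overlap(f: Read, rrc_bases: str, min_overlap: int, max_mm_frac: float):
    """Best ungapped suffix(f)/prefix(revcomp(r)) overlap, or None.

    Score = matches - mismatches; ties resolved toward the longer overlap.
    """
    best = None
    max_len = min(len(f.bases), len(rrc_bases))
    for L in range(min_overlap, max_len + 1):
        fs = f.bases[len(f.bases) - L :]
        rp = rrc_bases[:L]
        mism = sum(1 for x, y in zip(fs, rp) if x != y)
        if mism / L > max_mm_frac:
            continue
        score = (L - mism) - mism
        if best is None or (score, L) > (best[0], best[1]):
            best = (score, L, mism)
    return best


def merge_pairs(
    pairs: list[ReadPair],
    min_overlap: int = 20,
    max_overlap_mismatch_fraction: float = 0.1,
) -> tuple[list[Read], list[ReadPair]]:
    """Merge mate pairs by their best ungapped overlap.

    The reverse mate is reverse-complemented and slid against the forward
    mate; the highest-scoring overlap of length >= ``min_overlap`` with a
    mismatch fraction <= the threshold is used.  Disagreeing overlap columns
    resolve to the higher-quality base; the merged quality of every overlap
    column is the max of the two mates' qualities.
    """
    merged, unmerged = [], []
    for pair in pairs:
        f, r = pair.forward, pair.reverse
        rrc = _revcomp(r.bases)
        rq = list(reversed(r.qualities))
        hit = _best_overlap(f, rrc, min_overlap, max_overlap_mismatch_fraction)
        if hit is None:
            unmerged.append(pair)
            continue
        _, L, _ = hit
        off = len(f.bases) - L
        bases, quals = list(f.bases[:off]), list(f.qualities[:off])
        for k in range(L):
            fb, fq = f.bases[off + k], f.qualities[off + k]
            rb, q2 = rrc[k], rq[k]
            if fb == rb:
                bases.append(fb)
            else:
                bases.append(fb if fq >= q2 else rb)
            quals.append(max(fq, q2))
        bases.extend(rrc[L:])
        quals.extend(rq[L:])
        merged.append(Read(f.id, "".join(bases), quals))
    return merged, unmerged


def _find_primer_5p(bases: str, primer: str, error_rate: float) -> int | None:
    """Leftmost full-length primer occurrence within the mismatch budget.

    Returns the end position of the primer footprint (trim point) or None.
    """
    plen = len(primer)
    budget = math.floor(error_rate * plen)
    for start in range(0, len(bases) - plen + 1):
        mism = sum(1 for x, y in zip(bases[start : start + plen], primer) if x != y)
        if mism <= budget:
            return start + plen
    return None


def _trim_3p_readthrough(bases: str, primer_rc: str, error_rate: float, min_overlap: int) -> int:
    """Trim point for a (possibly partial) 3' read-through primer, else len(bases)."""
    plen = len(primer_rc)
    for start in range(max(0, len(bases) - plen), len(bases) - min_overlap + 1):
        window = bases[start:]
        mism = sum(1 for x, y in zip(window, primer_rc) if x != y)
        if mism <= math.floor(error_rate * len(window)):
            return start
    return len(bases)


def trim_amplicon_primers(
    pairs: list[ReadPair],
    forward_primer: str,
    reverse_primer: str,
    error_rate: float = 0.2,
    min_length: int = 50,
    min_overlap: int = 4,
) -> list[ReadPair]:
    """Remove amplicon primers (substitution-only matching, no indels).

    Each mate must carry its 5' primer (forward primer on the forward mate,
    reverse primer on the reverse mate) within ``error_rate`` mismatch
    fraction, else the pair is discarded.  When read-through occurs, the
    reverse-complemented opposite primer at the 3' end is also removed
    (suffix overlaps down to ``min_overlap`` bases are recognized there).
    Pairs whose trimmed mates fall below ``min_length`` are discarded.
    """
    out = []
    f_rc = _revcomp(forward_primer)
    r_rc = _revcomp(reverse_primer)
    for pair in pairs:
        trimmed = []
        for read, p5, p3rc in (
            (pair.forward, forward_primer, r_rc),
            (pair.reverse, reverse_primer, f_rc),
        ):
            start = _find_primer_5p(read.bases, p5, error_rate)
            if start is None:
                trimmed = None
                break
            end = _trim_3p_readthrough(read.bases[start:], p3rc, error_rate, min_overlap)
            trimmed.append(
                Read(read.id, read.bases[start : start + end], read.qualities[start : start + end])
            )
        if trimmed is None or any(len(t.bases) < min_length for t in trimmed):
            continue
        out.append(ReadPair(trimmed[0], trimmed[1]))
    return out


def discard_n_and_truncate(
    reads: list[Read],
    max_n: int = 0,
    trunc_q: int = 0,
    trunc_len: int = 0,
    max_expected_errors: float = math.inf,
) -> list[Read]:
    """Truncation and quality filtering ahead of denoising.

    Order of operations: truncate at the first base with quality < trunc_q
    (if trunc_q > 0); crop to trunc_len, discarding shorter reads (if
    trunc_len > 0); discard reads with more than max_n undetermined bases;
    discard reads whose expected-error sum exceeds max_expected_errors.
    """
    kept = []
    for r in reads:
        bases, quals = r.bases, r.qualities
        if trunc_q > 0:
            cut = len(bases)
            for i, q in enumerate(quals):
                if q < trunc_q:
                    cut = i
                    break
            bases, quals = bases[:cut], quals[:cut]
        if trunc_len > 0:
            if len(bases) < trunc_len:
                continue
            bases, quals = bases[:trunc_len], quals[:trunc_len]
        if bases.count("N") > max_n:
            continue
        if sum(10.0 ** (-q / 10.0) for q in quals) > max_expected_errors:
            continue
        kept.append(Read(r.id, bases, quals))
    return kept
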