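"""Identify full-length V9 regions in reads and dereplicate them into barcodes.

A read is searched against each V9 reference with an infix (glocal)
alignment: the reference must be covered from its first to its last base,
the read's ends are free.  The single best-identity hit is kept, and
accepted only when identity (identical columns / alignment columns) reaches
the cutoff (80% by default).  Accepted read substrings are dereplicated
per source into barcodes; sequences containing undetermined (N) bases are
removed first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from .readprep import Read
from .refdb import V9Reference

__all__ = ["ExtractionHit", "Barcode", "find_v9", "extract_v9", "dereplicate"]


@dataclass
class ExtractionHit:
    read_id: str
    ref_id: str
    identity: float
    query_interval: tuple[int, int]  # 0-based half-open on the read
    sequence: str  # the extracted read substring
    full_span: bool = True


@dataclass(order=True)
class Barcode:
    """A dereplicated unique V9 sequence with its read count."""

    sequence: str
    count: int
    source_id: str = ""

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("barcode count must be >= 1")
        if "N" in self.sequence:
            raise ValueError("barcodes must not contain undetermined bases")


def _alignment_identity(result, ref: str, read_bases: str) -> float:
    """Identity over alignment columns from an edlib path (infix mode)."""
    nice = edlib.getNiceAlignment(result, ref, read_bases)
    matched = nice["matched_aligned"]
    return matched.count("|") / len(matched) if matched else 0.0


def find_v9(
    read: Read, v9refs: list[V9Reference], min_identity: float = 0.8
) -> ExtractionHit | None:
    """Best full-span hit of any reference inside the read, or None.

    The reference is aligned globally, the read locally (free ends), which
    enforces the full-span rule by construction.  Among references the
    best identity wins; ties break toward the lexicographically smaller
    reference id.  Hits below ``min_identity`` are rejected.
    """
    if not v9refs:
        raise ValueError("find_v9 requires a non-empty reference set")
    best = None
    for ref in v9refs:
        k = int(len(ref.v9_sequence) * (1.0 - min_identity) * 2) + 2
        res = edlib.align(ref.v9_sequence, read.bases, mode="HW", task="path", k=k)
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        start, end = res["locations"][0]
        end += 1
        ident = _alignment_identity(res, ref.v9_sequence, read.bases)
        key = (-ident, ref.id)
        if best is None or key < best[0]:
            best = (key, ref, ident, (start, end))
    if best is None:
        return None
    _, ref, ident, (start, end) = best
    if ident < min_identity:
        return None
    return ExtractionHit(
        read_id=read.id,
        ref_id=ref.id,
        identity=ident,
        query_interval=(start, end),
        sequence=read.bases[start:end],
    )


def extract_v9(
    reads: list[Read],
    v9refs: list[V9Reference],
    source_id: str = "",
    min_identity: float = 0.8,
) -> list[Barcode]:
    """Run find_v9 over all reads and dereplicate the hits into barcodes."""
    hits = []
    for r in reads:
        h = find_v9(r, v9refs, min_identity=min_identity)
        if h is not None:
            hits.append((h.sequence, source_id))
    return dereplicate(hits)


def dereplicate(sequences: list[tuple[str, str]]) -> list[Barcode]:
    """Exact-identity grouping per source into count-sorted barcodes.

    Sequences containing N are removed beforehand.  Output is sorted by
    count descending, ties broken lexicographically by sequence (within
    each source; sources sorted by id).
    """
    per_source: dict[str, Counter] = {}
    for seq, src in sequences:
        if "N" in seq:
            continue
        per_source.setdefault(src, Counter())[seq] += 1
    out: list[Barcode] = []
    for src in sorted(per_source):
        counts = per_source[src]
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out.extend(Barcode(seq, n, src) for seq, n in ordered)
    return out
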