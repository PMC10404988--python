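"""Build the V9 reference database by locating universal primers per sequence.

Full-length 18S rRNA references (PR2-style headers carrying rank-delimited
taxonomy) are scanned for the universal eukaryotic V9 primers 389F
(``TTGTACACACCGCCC``) and 1510R (``CCTTCYGCAGGTTCACCTAC``), allowing up to 5
substitutions per primer (IUPAC-aware on the primer side only).  The V9
region is the segment strictly between the two primer footprints.  If the
primer pair is not found on the given strand, the reverse strand is tried,
and the extracted region is reported in the record's own orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "ReferenceSeq",
    "PrimerPair",
    "V9Reference",
    "locate_primer",
    "build_v9_reference",
    "read_reference_fasta",
    "write_v9_fasta",
]

FORWARD_PRIMER = "TTGTACACACCGCCC"  # 389F
REVERSE_PRIMER = "CCTTCYGCAGGTTCACCTAC"  # 1510R

V9_EXPECTED_LENGTH = (104, 137)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class ReferenceSeq:
    id: str
    taxonomy: list[str]
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if not self.taxonomy:
            raise ValueError(f"{self.id}: taxonomy must have at least one rank")


@dataclass
class PrimerPair:
    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER
    max_mismatches: int = 5

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class V9Reference:
    id: str
    taxonomy: list[str]
    v9_sequence: str
    source_interval: tuple[int, int]  # 0-based half-open on the parent record


def _mismatches(window: str, primer: str) -> int:
    """IUPAC-aware Hamming distance over one primer-length window.

    A degenerate primer base matches any of its expansions; degenerate
    bases in the subject get no credit (they count as mismatches unless the
    primer base's expansion happens to contain that literal base, which for
    subject codes outside ACGT it never does).
    """
    mism = 0
    for p, s in zip(primer, window):
        if s not in _IUPAC.get(p.upper(), ""):
            mism += 1
    return mism


def locate_primer(
    sequence: str, primer: str, max_mismatches: int = 5
) -> list[tuple[int, int]]:
    """All ungapped primer sites within the mismatch budget, best-first.

    Returns ``(start, mismatch_count)`` tuples sorted by mismatch count,
    then leftmost position.  Empty sequence (or one shorter than the
    primer) yields an empty list.
    """
    plen = len(primer)
    seq = sequence.upper()
    hits = []
    for start in range(0, len(seq) - plen + 1):
        mism = _mismatches(seq[start : start + plen], primer)
        if mism <= max_mismatches:
            hits.append((start, mism))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def _extract_on_strand(seq: str, primers: PrimerPair):
    """Locate forward primer and revcomp(reverse primer); return (start, end) of the core."""
    fwd_hits = locate_primer(seq, primers.forward, primers.max_mismatches)
    rev_rc = str(Seq(primers.reverse).reverse_complement())
    rev_hits = locate_primer(seq, rev_rc, primers.max_mismatches)
    if not fwd_hits or not rev_hits:
        return None
    # lowest-mismatch then leftmost forward site
    f_start, _ = fwd_hits[0]
    core_start = f_start + len(primers.forward)
    # lowest-mismatch then rightmost reverse site downstream of the forward site
    best_mm = min(m for _, m in rev_hits)
    downstream = [s for s, m in rev_hits if m == best_mm and s >= core_start]
    if not downstream:
        return None
    core_end = max(downstream)
    return core_start, core_end


def build_v9_reference(
    refs: list[ReferenceSeq], primers: PrimerPair | None = None
) -> list[V9Reference]:
    """Extract the V9 region (exclusive of both primer footprints) per reference.

    References lacking either primer site on both strands, or whose reverse
    site lies upstream of the forward site, are skipped with a warning.
    Extracted lengths outside the expected 104-137 nt span are logged but
    kept.
    """
    primers = primers or PrimerPair()
    out = []
    for ref in refs:
        seq = ref.sequence.upper()
        interval = _extract_on_strand(seq, primers)
        if interval is not None:
            start, end = interval
            core = seq[start:end]
        else:
            flipped = str(Seq(seq).reverse_complement())
            rc_interval = _extract_on_strand(flipped, primers)
            if rc_interval is None:
                logger.warning("%s: primer pair not found on either strand; skipped", ref.id)
                continue
            s, e = rc_interval
            core = str(Seq(flipped[s:e]).reverse_complement())
            start, end = len(seq) - e, len(seq) - s
        if not core:
            logger.warning("%s: empty V9 core; skipped", ref.id)
            continue
        lo, hi = V9_EXPECTED_LENGTH
        if not (lo <= len(core) <= hi):
            logger.warning(
                "%s: extracted V9 length %d outside expected span [%d, %d]",
                ref.id, len(core), lo, hi,
            )
        out.append(V9Reference(ref.id, ref.taxonomy, core, (start, end)))
    return out


def read_reference_fasta(path, taxonomy_delimiter: str = ";") -> list[ReferenceSeq]:
    """Read PR2-style FASTA: ``>id;rank1;rank2;...`` (delimiter configurable)."""
    refs = []
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.description
        parts = header.split(taxonomy_delimiter)
        rid = parts[0].strip()
        taxonomy = [p.strip() for p in parts[1:] if p.strip()] or ["Unknown"]
        refs.append(ReferenceSeq(rid, taxonomy, str(rec.seq)))
    return refs


def write_v9_fasta(v9refs: list[V9Reference], handle, taxonomy_delimiter: str = ";"):
    for v in v9refs:
        tax = taxonomy_delimiter.join(v.taxonomy)
        handle.write(f">{v.id}{taxonomy_delimiter}{tax}\n{v.v9_sequence}\n")
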