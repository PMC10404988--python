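"""Best-hit taxonomic annotation and contamination classification.

Annotation is global:global best-hit search of each barcode/ASV against the
V9 reference set under the pipeline's affine-gap scoring scheme.  The two
contamination rules operate on identity to the most abundant unit of a
genome/transcriptome: barcodes below 80% identity to the top barcode are
classed as foreign-phylum contamination; ASVs below 90% identity to the top
ASV are classed as putative contaminants, while those at 90-100% are
retained as intragenomic variability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentResult, ScoringScheme, global_align, global_identity
from .extract import Barcode
from .refdb import V9Reference

__all__ = [
    "BARCODE_IDENTITY_FLOOR",
    "ASV_IDENTITY_FLOOR",
    "Annotation",
    "ContaminationVerdict",
    "annotate",
    "classify_contamination",
    "remove_contaminant_barcodes",
    "ScoringScheme",
    "global_identity",
    "global_align",
    "AlignmentResult",
]

BARCODE_IDENTITY_FLOOR = 0.80
ASV_IDENTITY_FLOOR = 0.90


@dataclass
class Annotation:
    query_id: str
    best_ref_id: str
    identity: float
    taxonomy: list[str]


@dataclass
class ContaminationVerdict:
    unit_id: str
    level: str  # "barcode" or "asv"
    rank: int  # 1 = most abundant
    identity_to_top: float
    klass: str  # dominant | retained_intragenomic | foreign_phylum | putative_contaminant


def annotate(
    queries,
    v9refs: list[V9Reference],
    scoring: ScoringScheme | None = None,
) -> list[Annotation]:
    """One best global-identity hit per query; ties break to the smaller ref id.

    Queries may be barcodes or ASVs (anything with a ``sequence``); their
    identifier is the sequence itself when no ``id`` attribute exists.
    """
    if not v9refs:
        raise ValueError("annotate requires a non-empty reference set")
    refs = sorted(v9refs, key=lambda r: r.id)
    out = []
    for q in queries:
        seq = q.sequence if hasattr(q, "sequence") else str(q)
        qid = getattr(q, "id", seq)
        best = None
        for ref in refs:
            ident = global_identity(seq, ref.v9_sequence, scoring)
            if best is None or ident > best[0]:
                best = (ident, ref)
        out.append(Annotation(qid, best[1].id, best[0], best[1].taxonomy))
    return out


def _identity_floor(level: str) -> float:
    if level == "barcode":
        return BARCODE_IDENTITY_FLOOR
    if level == "asv":
        return ASV_IDENTITY_FLOOR
    raise ValueError("level must be 'barcode' or 'asv'")


def classify_contamination(
    units, level: str, scoring: ScoringScheme | None = None
) -> list[ContaminationVerdict]:
    """Rank units by abundance and apply the identity-to-top rule.

    The most abundant unit is the reference point (class ``dominant``).
    Every other unit's global identity to it decides its class: below the
    level's floor (80% for barcodes, 90% for ASVs) it is contamination
    (``foreign_phylum`` at the barcode level, ``putative_contaminant`` at
    the ASV level), otherwise ``retained_intragenomic``.
    """
    floor = _identity_floor(level)
    contaminant_class = "foreign_phylum" if level == "barcode" else "putative_contaminant"
    ranked = sorted(units, key=lambda u: (-u.count, u.sequence))
    verdicts = []
    for rank, unit in enumerate(ranked, start=1):
        uid = getattr(unit, "id", unit.sequence)
        if rank == 1:
            verdicts.append(ContaminationVerdict(uid, level, 1, 1.0, "dominant"))
            continue
        ident = global_identity(unit.sequence, ranked[0].sequence, scoring)
        klass = contaminant_class if ident < floor else "retained_intragenomic"
        verdicts.append(ContaminationVerdict(uid, level, rank, ident, klass))
    return verdicts


def remove_contaminant_barcodes(
    barcodes: list[Barcode], level: str = "barcode", scoring: ScoringScheme | None = None
) -> tuple[list[Barcode], list[Barcode]]:
    """Split units into (retained, removed) under the level's identity rule."""
    verdicts = classify_contamination(barcodes, level, scoring)
    ranked = sorted(barcodes, key=lambda u: (-u.count, u.sequence))
    retained, removed = [], []
    for unit, v in zip(ranked, verdicts):
        if v.klass in ("dominant", "retained_intragenomic"):
            retained.append(unit)
        else:
            removed.append(unit)
    return retained, removed
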