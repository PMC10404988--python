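"""Affine-gap global alignment and percent identity for short rRNA barcodes.

The scoring convention follows the nucleotide scheme used throughout the
pipeline: match +1, mismatch -3, and a gap of length L costs
``gap_open + gap_extend * L`` (so the first base of a gap costs
``gap_open + gap_extend``).  Identity is defined as the number of identical
columns divided by the total number of alignment columns, gap columns
included — the one definition used by extraction, clustering, contamination
classification and annotation alike.

Sequences here are at most ~140 nt, so the full dynamic program is cheap;
the band parameter exists to bound work in inner loops (denoising compares
thousands of near-identical pairs) while remaining exact for the drift such
pairs can exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScoringScheme", "AlignmentResult", "global_align", "global_identity"]

_NEG = -1.0e18


@dataclass(frozen=True)
class ScoringScheme:
    """Global affine-gap nucleotide scoring (match 1, mismatch -3, gap 5+2L)."""

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    n_columns: int
    n_identical: int

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 1.0


def _fill_matrices(a: str, b: str, scoring: ScoringScheme, band: int | None):
    """Gotoh dynamic program.  Returns the three state matrices.

    M ends in an aligned pair, X ends with a gap in ``b`` (consumes ``a``),
    Y ends with a gap in ``a`` (consumes ``b``).  Rows are positions in
    ``a``, columns positions in ``b``.  Scores stay integer-valued, so all
    float arithmetic is exact and tie detection is safe.
    """
    n, m = len(a), len(b)
    opn = scoring.gap_open + scoring.gap_extend  # cost of a gap's first base
    ext = scoring.gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j_idx = np.arange(1, m + 1)
    Y[0, 1:] = -(scoring.gap_open + ext * j_idx)
    i_idx = np.arange(1, n + 1)
    X[1:, 0] = -(scoring.gap_open + ext * i_idx)

    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    delta = m - n
    ramp = ext * np.arange(m + 1)

    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], scoring.match, scoring.mismatch)
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = best_prev + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - opn, X[i - 1, 1:] - ext
        )
        if band is not None:
            lo = i + min(0, delta) - band
            hi = i + max(0, delta) + band
            mask = (j_idx < lo) | (j_idx > hi)
            M[i, 1:][mask] = _NEG
            X[i, 1:][mask] = _NEG
        # Y via running max: Y[i,j] = max_{k<j} (max(M,X)[i,k] - opn - ext*(j-1-k))
        Z = np.maximum(M[i], X[i])
        running = np.maximum.accumulate(Z + ramp)[:-1]
        Y[i, 1:] = running - opn - ext * (j_idx - 1)
        if band is not None:
            Y[i, 1:][mask] = _NEG
    return M, X, Y


def _traceback(a, b, M, X, Y, scoring: ScoringScheme):
    """Deterministic traceback: on ties prefer diagonal (M), then up (X), then left (Y)."""
    opn = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    i, j = len(a), len(b)
    scores = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(scores))  # argmax picks the first (M) on ties
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == 0:  # M: a[i-1] aligned to b[j-1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - (
                scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            )
            i, j = i - 1, j - 1
            for s, val in ((0, M[i, j]), (1, X[i, j]), (2, Y[i, j])):
                if val == target:
                    state = s
                    break
        elif state == 1:  # X: a[i-1] against a gap
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if M[i, j] - opn == val:
                state = 0
            elif X[i, j] - ext == val:
                state = 1
            else:
                state = 2
        else:  # Y: b[j-1] against a gap
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if M[i, j] - opn == val:
                state = 0
            elif Y[i, j] - ext == val:
                state = 2
            else:
                state = 1
        if i == 0 and j == 0:
            break
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _banded_matrices(s: str, t: str, scoring: ScoringScheme, band: int | None):
    """Fill matrices at a certified band, escalating until provably optimal.

    A path leaving a band of half-width w must contain at least
    ``|len(t)-len(s)| + 2w + 2`` gap columns, so its score is bounded by
    ``match * (min(n,m) - w - 1) - 2*gap_open - gap_extend*(|delta|+2w+2)``.
    Once the banded score reaches that bound no out-of-band path can win and
    the banded result equals the full dynamic program; otherwise the band
    doubles, falling back to the full matrix.
    """
    n, m = len(s), len(t)
    delta = abs(m - n)
    w = band
    while w is not None and w < max(n, m):
        M, X, Y = _fill_matrices(s, t, scoring, w)
        score = max(M[-1, -1], X[-1, -1], Y[-1, -1])
        bound = (
            scoring.match * (min(n, m) - w - 1)
            - 2 * scoring.gap_open
            - scoring.gap_extend * (delta + 2 * w + 2)
        )
        if score > _NEG / 2 and score >= bound:
            return M, X, Y
        w *= 2
    return _fill_matrices(s, t, scoring, None)


def global_align(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    band: int | None = None,
) -> AlignmentResult:
    """Optimal global alignment of two nucleotide strings.

    ``band=None`` fills the full matrix; an integer band restricts the
    diagonal offset to ``[min(0, len(b)-len(a)) - band, max(0, ...) + band]``.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    scoring = scoring or ScoringScheme()
    # canonical argument order: co-optimal tracebacks can differ in column
    # count, so identity is defined on the lexicographically ordered pair
    swapped = (len(a), a) > (len(b), b)
    s, t = (b, a) if swapped else (a, b)
    if band is not None:
        M, X, Y = _banded_matrices(s, t, scoring, band)
    else:
        M, X, Y = _fill_matrices(s, t, scoring, None)
    score = max(M[-1, -1], X[-1, -1], Y[-1, -1])
    aa, bb = _traceback(s, t, M, X, Y, scoring)
    if swapped:
        aa, bb = bb, aa
    ident = sum(1 for x, y in zip(aa, bb) if x == y and x != "-")
    return AlignmentResult(float(score), aa, bb, len(aa), ident)


def global_identity(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    band: int | None = 16,
) -> float:
    """Percent identity (fraction in [0, 1]) under the global scoring scheme."""
    return global_align(a, b, scoring=scoring, band=band).identity
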