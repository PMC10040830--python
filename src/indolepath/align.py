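"""Pairwise protein alignment with affine gap penalties.

Wraps Bio.Align.PairwiseAligner (Gotoh algorithm, C implementation) to produce
the quantities the homology filter consumes: raw score, percent identity over
alignment columns (gaps included in the denominator), and query/subject
coverage from the aligned span.  Gap costs follow the BLAST convention: a gap
of length k costs ``gap_open + k * gap_extend``.

E-values use the Karlin–Altschul formula E = K·m·n·exp(−λS) with gapped
parameters declared in :class:`KarlinParams`; the defaults are the standard
published values for BLOSUM62 with gap open 11 / extend 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "KarlinParams",
    "ProteinRecord",
    "AA_ALPHABET",
    "local_align",
    "global_align",
    "local_score",
    "estimate_evalue",
    "bitscore",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Default scoring scheme (declared here; overridable per call and via RunConfig).
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains residues outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KarlinParams:
    """Gapped Karlin–Altschul parameters (lambda in 1/bits-nat, K unitless)."""

    lam: float = 0.267
    K: float = 0.041


@dataclass(frozen=True)
class AlignmentResult:
    raw_score: float
    bitscore: float
    identity_pct: float
    query_cover_pct: float
    subject_cover_pct: float
    evalue: float
    aligned_pairs: int
    # 1-based inclusive aligned spans (0 = no aligned region)
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    alignment_columns: int = 0


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def _aligner(mode: str, matrix_name: str, gap_open: float, gap_extend: float):
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix(matrix_name)
    # first gap position costs open+extend, each further position costs extend
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -float(gap_extend)
    return al


def _check(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"empty {label} sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label} sequence contains unknown residue(s) {sorted(bad)}")


def local_score(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal Smith–Waterman score only (cheap screen before full traceback)."""
    _check(a, "query")
    _check(b, "subject")
    return float(_aligner("local", matrix, gap_open, gap_extend).score(a, b))


def _stats_from_alignment(aln, la: int, lb: int, karlin: KarlinParams) -> AlignmentResult:
    counts = aln.counts()
    identities = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    coords = aln.coordinates
    span_a = int(coords[0, -1] - coords[0, 0])
    span_b = int(coords[1, -1] - coords[1, 0])
    score = float(aln.score)
    ev = estimate_evalue(max(score, 0.0), la, lb, karlin)
    return AlignmentResult(
        raw_score=score,
        bitscore=bitscore(score, karlin),
        identity_pct=100.0 * identities / columns if columns else 0.0,
        query_cover_pct=100.0 * span_a / la,
        subject_cover_pct=100.0 * span_b / lb,
        evalue=ev,
        aligned_pairs=int(counts.identities + counts.mismatches),
        query_start=int(coords[0, 0]) + 1,
        query_end=int(coords[0, -1]),
        subject_start=int(coords[1, 0]) + 1,
        subject_end=int(coords[1, -1]),
        alignment_columns=int(columns),
    )


def local_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    karlin: KarlinParams = KarlinParams(),
) -> AlignmentResult:
    """Optimal affine-gap local alignment of query ``a`` against subject ``b``.

    Identity is computed over alignment columns including gap columns;
    coverage is the aligned span divided by the full sequence length, for the
    query and the subject respectively.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    _check(sa, "query")
    _check(sb, "subject")
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    alns = aligner.align(sa, sb)
    if len(sa) and alns.score <= 0:
        # no positive-scoring local alignment: report an empty result
        return AlignmentResult(
            raw_score=max(0.0, float(alns.score)),
            bitscore=bitscore(max(0.0, float(alns.score)), karlin),
            identity_pct=0.0,
            query_cover_pct=0.0,
            subject_cover_pct=0.0,
            evalue=estimate_evalue(0.0, len(sa), len(sb), karlin),
            aligned_pairs=0,
        )
    return _stats_from_alignment(alns[0], len(sa), len(sb), karlin)


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    karlin: KarlinParams = KarlinParams(),
) -> AlignmentResult:
    """Needleman–Wunsch global alignment; identity over alignment columns."""
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    _check(sa, "query")
    _check(sb, "subject")
    aligner = _aligner("global", matrix, gap_open, gap_extend)
    alns = aligner.align(sa, sb)
    return _stats_from_alignment(alns[0], len(sa), len(sb), karlin)


def estimate_evalue(
    raw_score: float, query_len: int, subject_len: int, karlin: KarlinParams = KarlinParams()
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return karlin.K * query_len * subject_len * math.exp(-karlin.lam * raw_score)


def bitscore(raw_score: float, karlin: KarlinParams = KarlinParams()) -> float:
    """Normalized score S' = (λS − ln K) / ln 2."""
    return (karlin.lam * raw_score - math.log(karlin.K)) / math.log(2.0)
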