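"""Enzyme-homolog detection in strain proteomes.

Every strain protein is aligned locally against every reference enzyme
sequence; a hit passes iff identity >= 30%, E-value <= 1e-3, and both query
and subject coverage >= 70% (all comparisons inclusive, the thresholds of a
standard DIAMOND/BLASTP protein homology screen).  Hits are summarised per
enzyme family as a count of distinct strain proteins with at least one passing
hit, plus the identity of the best hit (best = highest bitscore, ties broken
by higher identity, then lexicographic subject id).

Externally produced searches in the 12-column BLAST tabular dialect can be
imported through :func:`import_external_hits` and are re-filtered under the
same thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from . import align as _al
from .align import AlignmentResult, KarlinParams, ProteinRecord
from .network import ReferenceDB

__all__ = [
    "Thresholds",
    "EnzymeHit",
    "StrainAnnotation",
    "search_homologs",
    "import_external_hits",
]


@dataclass(frozen=True)
class Thresholds:
    """Homology acceptance thresholds; defaults are the standard screen values."""

    min_identity: float = 30.0
    max_evalue: float = 1e-3
    min_query_cover: float = 70.0
    min_subject_cover: float = 70.0

    def __post_init__(self) -> None:
        for pct in (self.min_identity, self.min_query_cover, self.min_subject_cover):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percent threshold out of [0,100]: {pct}")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")

    def passes(self, r: AlignmentResult) -> bool:
        return (
            r.identity_pct >= self.min_identity
            and r.evalue <= self.max_evalue
            and r.query_cover_pct >= self.min_query_cover
            and r.subject_cover_pct >= self.min_subject_cover
        )


@dataclass(frozen=True)
class EnzymeHit:
    strain_id: str
    enzyme_abbrev: str
    query_id: str
    subject_id: str
    alignment: AlignmentResult


def _hit_rank(h: EnzymeHit):
    # best-first ordering: bitscore desc, identity desc, subject id asc
    return (-h.alignment.bitscore, -h.alignment.identity_pct, h.subject_id)


@dataclass
class StrainAnnotation:
    """Passing homology hits for one strain, grouped by enzyme family."""

    strain_id: str
    hits: dict[str, list[EnzymeHit]] = field(default_factory=dict)

    def add(self, hit: EnzymeHit) -> None:
        self.hits.setdefault(hit.enzyme_abbrev, []).append(hit)

    @property
    def count(self) -> dict[str, int]:
        """Distinct strain proteins with >=1 passing hit, per enzyme family."""
        return {e: len({h.query_id for h in hs}) for e, hs in self.hits.items() if hs}

    @property
    def best_hit(self) -> dict[str, EnzymeHit]:
        return {e: min(hs, key=_hit_rank) for e, hs in self.hits.items() if hs}

    @property
    def best_identity(self) -> dict[str, float]:
        return {e: h.alignment.identity_pct for e, h in self.best_hit.items()}

    def restrict_to_best_family(self) -> "StrainAnnotation":
        """Keep, for each strain protein, only its single best enzyme family."""
        best_for_query: dict[str, EnzymeHit] = {}
        for hs in self.hits.values():
            for h in hs:
                cur = best_for_query.get(h.query_id)
                if cur is None or _hit_rank(h) < _hit_rank(cur):
                    best_for_query[h.query_id] = h
        out = StrainAnnotation(self.strain_id)
        for hs in self.hits.values():
            for h in hs:
                if best_for_query[h.query_id].enzyme_abbrev == h.enzyme_abbrev:
                    out.add(h)
        return out


def search_homologs(
    proteome: list[ProteinRecord],
    refdb: ReferenceDB,
    thresholds: Thresholds = Thresholds(),
    strain_id: str = "strain",
    matrix: str = _al.DEFAULT_MATRIX,
    gap_open: float = _al.DEFAULT_GAP_OPEN,
    gap_extend: float = _al.DEFAULT_GAP_EXTEND,
    karlin: KarlinParams = KarlinParams(),
    unique_best_family: bool = False,
) -> StrainAnnotation:
    """Align all proteome x reference pairs and retain thresholded hits.

    A score-only pass screens each pair first; the full traceback (needed for
    identity and coverage) is computed only when the score alone could clear
    the E-value threshold.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    ann = StrainAnnotation(strain_id)
    for q in proteome:
        for sid in sorted(refdb.records):
            abbrev, sseq = refdb.records[sid]
            s = _al.local_score(q.sequence, sseq, matrix, gap_open, gap_extend)
            if _al.estimate_evalue(max(s, 0.0), len(q.sequence), len(sseq), karlin) \
                    > thresholds.max_evalue:
                continue
            res = _al.local_align(q.sequence, sseq, matrix, gap_open, gap_extend, karlin)
            if thresholds.passes(res):
                ann.add(EnzymeHit(strain_id, abbrev, q.id, sid, res))
    if unique_best_family:
        ann = ann.restrict_to_best_family()
    return ann


_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def import_external_hits(
    tabular_path: str | Path,
    refdb: ReferenceDB,
    thresholds: Thresholds,
    query_lengths: dict[str, int],
    subject_lengths: dict[str, int] | None = None,
    strain_id: str = "strain",
    unique_best_family: bool = False,
) -> StrainAnnotation:
    """Re-filter a 12-column tabular homology file under the same thresholds.

    Coverage is recomputed from the 1-based inclusive alignment coordinates and
    the supplied sequence lengths.  Rows whose subject id is absent from the
    reference database are skipped with a warning count attached to the
    returned annotation as ``skipped_unknown_subjects``.
    """
    import warnings

    if subject_lengths is None:
        subject_lengths = {sid: len(refdb.sequence(sid)) for sid in refdb.records}
    ann = StrainAnnotation(strain_id)
    skipped = 0
    for ln, line in enumerate(Path(tabular_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 12:
            raise ValueError(f"line {ln}: expected 12 tab-separated columns, got {len(parts)}")
        try:
            qid, sid = parts[0], parts[1]
            pident = float(parts[2])
            qstart, qend = int(parts[6]), int(parts[7])
            sstart, send = int(parts[8]), int(parts[9])
            evalue = float(parts[10])
            bits = float(parts[11])
        except ValueError as exc:
            raise ValueError(f"line {ln}: malformed field ({exc})") from exc
        if sid not in refdb.records:
            skipped += 1
            continue
        if qid not in query_lengths:
            raise ValueError(f"line {ln}: unknown query id {qid!r}")
        qlen, slen = query_lengths[qid], subject_lengths[sid]
        qcov = 100.0 * (abs(qend - qstart) + 1) / qlen
        scov = 100.0 * (abs(send - sstart) + 1) / slen
        res = AlignmentResult(
            raw_score=math.nan,
            bitscore=bits,
            identity_pct=pident,
            query_cover_pct=qcov,
            subject_cover_pct=scov,
            evalue=evalue,
            aligned_pairs=int(parts[3]) - int(parts[5]),
            query_start=min(qstart, qend),
            query_end=max(qstart, qend),
            subject_start=min(sstart, send),
            subject_end=max(sstart, send),
            alignment_columns=int(parts[3]),
        )
        if thresholds.passes(res):
            ann.add(EnzymeHit(strain_id, refdb.enzyme_of(sid), qid, sid, res))
    if skipped:
        warnings.warn(f"{skipped} row(s) referenced unknown subject ids and were skipped")
    ann.skipped_unknown_subjects = skipped  # type: ignore[attr-defined]
    if unique_best_family:
        ann = ann.restrict_to_best_family()
    return ann
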