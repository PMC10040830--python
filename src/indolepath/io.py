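"""Standard-format readers/writers and run configuration."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import AA_ALPHABET, ProteinRecord
from .homology import StrainAnnotation, Thresholds

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_table",
    "read_concentrations",
    "read_metadata",
    "annotation_summary_table",
    "hit_table",
    "write_tsv",
]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; JSON round-trippable.

    Defaults reproduce the published analysis settings: identity >= 30%,
    E <= 1e-3, covers >= 70%, BLOSUM62 open 11 extend 1 with the standard
    gapped Karlin-Altschul parameters, detection threshold 0 ng/mL, BH alpha
    0.05, HdhD counted as fldH.
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    network: str = "default"
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    alpha: float = 0.05
    detection_threshold: float = 0.0
    hdhd_as_fldh: bool = True
    unique_best_family: bool = False
    include_ipya_in_accuracy: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path: str | Path | None = None) -> str:
        doc = dataclasses.asdict(self)
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, document: str | Path) -> "RunConfig":
        if isinstance(document, Path) or (
            isinstance(document, str) and not document.lstrip().startswith("{")
        ):
            document = Path(document).read_text()
        doc = json.loads(document)
        thr = Thresholds(**doc.pop("thresholds", {}))
        return cls(thresholds=thr, **doc)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein multi-FASTA: ids from the first header token,
    sequences uppercased; empty files, duplicate ids and illegal residues
    raise."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} in {path} has illegal residue(s) {sorted(bad)}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Strain x metabolite ng/mL table; blank cells = unmeasured."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Strain metadata TSV with at least ``species`` (and usually ``source``)."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "species" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'species' column")
    return meta


def annotation_summary_table(annotations: list[StrainAnnotation]) -> pd.DataFrame:
    """Long-format ``strain, enzyme, count, best_identity, best_subject,
    best_evalue`` table."""
    rows = []
    for ann in annotations:
        best = ann.best_hit
        for e in sorted(ann.count):
            h = best[e]
            rows.append(
                {
                    "strain": ann.strain_id,
                    "enzyme": e,
                    "count": ann.count[e],
                    "best_identity": round(h.alignment.identity_pct, 1),
                    "best_subject": h.subject_id,
                    "best_evalue": h.alignment.evalue,
                }
            )
    return pd.DataFrame(rows, columns=[
        "strain", "enzyme", "count", "best_identity", "best_subject", "best_evalue"
    ])


def hit_table(annotations: list[StrainAnnotation]) -> pd.DataFrame:
    """All passing hits in the 12-column tabular homology dialect
    (1-based inclusive coordinates)."""
    rows = []
    for ann in annotations:
        for e in sorted(ann.hits):
            for h in ann.hits[e]:
                a = h.alignment
                rows.append(
                    {
                        "qseqid": h.query_id,
                        "sseqid": h.subject_id,
                        "pident": round(a.identity_pct, 3),
                        "length": a.alignment_columns,
                        "mismatch": a.aligned_pairs
                        - round(a.identity_pct * a.alignment_columns / 100.0),
                        "gapopen": a.alignment_columns - a.aligned_pairs,
                        "qstart": a.query_start,
                        "qend": a.query_end,
                        "sstart": a.subject_start,
                        "send": a.subject_end,
                        "evalue": a.evalue,
                        "bitscore": round(a.bitscore, 1),
                    }
                )
    return pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
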