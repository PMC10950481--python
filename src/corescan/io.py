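"""FASTA/BED/TSV readers and writers shared by the library and the CLI.

Input FASTA is read with Biopython (gzip-transparent by file suffix) and
uppercased; IUPAC ambiguity codes other than N are degraded to N with a
warning, so downstream scoring stays conservative. The TSS column is
attached either as one fixed 1-based index for all records or from a BED6
file of per-record TSS positions.

Two coordinate conventions are written, never mixed in one file: hit TSVs
use the zero-free TSS-relative axis (+1 = TSS base); BED6 export uses
0-based half-open absolute coordinates with the score scaled to 0..1000.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .composite import AnnotatedHit
from .motif_model import MotifModelError, ScoringMatrix
from .scanner import MotifHit, SequenceRecord, tss_absolute

__all__ = [
    "read_fasta",
    "write_fasta",
    "auto_gc",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_bed",
]

_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})

HIT_COLUMNS = [
    "seq_id",
    "element",
    "strand",
    "start_tss_rel",
    "anchor_tss_rel",
    "score",
    "length",
    "composite_rule",
    "anchor_id",
    "spacing",
    "orphan_flag",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_bed_tss(path) -> dict[str, int]:
    """BED6 of per-record TSS bases: name column 4 keys the FASTA record id,
    the 0-based start is the TSS base, so tss_index = start + 1."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise MotifModelError(f"{path}: BED file needs at least 4 columns (through name)")
    return {str(row[3]): int(row[1]) + 1 for row in bed.itertuples(index=False)}


def read_fasta(
    path,
    tss_index: int | None = None,
    bed: str | Path | None = None,
    mask_lowercase: bool = False,
) -> list[SequenceRecord]:
    """Read promoter windows and attach TSS columns.

    Exactly one of ``tss_index`` (fixed-width windows) or ``bed``
    (heterogeneous widths) must be given. Records shorter than their TSS
    index, or absent from the BED, are rejected with a named warning.
    Lowercase (soft-masked) bases are treated as normal bases unless
    ``mask_lowercase`` is set, in which case they become N.
    """
    if (tss_index is None) == (bed is None):
        raise MotifModelError("provide exactly one of tss_index or a BED file of TSS offsets")
    tss_map = _read_bed_tss(bed) if bed is not None else None
    records: list[SequenceRecord] = []
    n_ambiguous = 0
    with _open_text(path) as fh:
        try:
            parsed = list(SeqIO.parse(fh, "fasta"))
        except ValueError as exc:
            raise MotifModelError(f"{path}: malformed FASTA: {exc}") from None
        for rec in parsed:
            seq = str(rec.seq)
            if mask_lowercase:
                seq = "".join("N" if c.islower() else c for c in seq)
            seq = seq.upper().translate(_AMBIGUOUS)
            n_ambiguous += sum(1 for a, b in zip(str(rec.seq).upper(), seq) if a != b)
            if tss_map is not None:
                if rec.id not in tss_map:
                    warnings.warn(f"record {rec.id!r}: no TSS entry in BED; rejected", stacklevel=2)
                    continue
                tss = tss_map[rec.id]
            else:
                tss = int(tss_index)
            if len(seq) < tss or tss < 1:
                warnings.warn(
                    f"record {rec.id!r}: length {len(seq)} shorter than tss_index {tss}; rejected",
                    stacklevel=2,
                )
                continue
            records.append(SequenceRecord(id=rec.id, sequence=seq, tss_index=tss))
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} ambiguous IUPAC base(s) degraded to N", stacklevel=2
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Plain 60-column FASTA; deterministic byte-for-byte for equal input."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def auto_gc(records: Iterable[SequenceRecord]) -> float:
    """Pooled GC fraction over A/C/G/T bases only (N excluded)."""
    gc = at = 0
    for rec in records:
        s = rec.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise MotifModelError("no A/C/G/T bases in input; cannot estimate GC")
    return gc / (gc + at)


def write_hits_tsv(hits: Sequence[MotifHit | AnnotatedHit], path) -> None:
    """Hit table on the TSS-relative axis; scores printed to 3 decimals.

    Annotated hits add the composite columns (rule, anchor id, spacing,
    orphan flag); plain hits leave them empty.
    """
    rows = []
    for h in hits:
        ann = h if isinstance(h, AnnotatedHit) else None
        hit = ann.hit if ann is not None else h
        rows.append(
            {
                "seq_id": hit.seq_id,
                "element": hit.element,
                "strand": hit.strand,
                "start_tss_rel": hit.start_tss_rel,
                "anchor_tss_rel": hit.anchor_tss_rel,
                "score": f"{hit.score:.3f}",
                "length": hit.length,
                "composite_rule": (
                    f"{ann.rule.dependent}<-{ann.rule.anchor}"
                    if ann is not None and ann.rule is not None
                    else ""
                ),
                "anchor_id": ann.anchor_id if ann is not None and ann.anchor_id else "",
                "spacing": ann.spacing if ann is not None and ann.spacing is not None else "",
                "orphan_flag": int(ann.orphan) if ann is not None else 0,
            }
        )
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[AnnotatedHit]:
    """Read a hit TSV back into annotated hits (inverse of write_hits_tsv)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(HIT_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise MotifModelError(f"{path}: missing columns {sorted(missing)}")
    out: list[AnnotatedHit] = []
    for row in df.itertuples(index=False):
        hit = MotifHit(
            seq_id=str(row.seq_id),
            element=str(row.element),
            strand=str(row.strand),
            start_tss_rel=int(row.start_tss_rel),
            anchor_tss_rel=int(row.anchor_tss_rel),
            score=float(row.score),
            length=int(row.length),
        )
        spacing = getattr(row, "spacing", "")
        orphan = bool(int(getattr(row, "orphan_flag", 0) or 0))
        out.append(
            AnnotatedHit(
                hit=hit,
                rule=None,
                anchor_id=str(getattr(row, "anchor_id", "")) or None,
                spacing=int(spacing) if str(spacing) != "" else None,
                orphan=orphan,
            )
        )
    return out


def write_bed(
    hits: Sequence[MotifHit | AnnotatedHit],
    records: Iterable[SequenceRecord],
    matrices: Mapping[str, ScoringMatrix],
    path,
) -> None:
    """BED6 export in absolute coordinates (0-based half-open).

    The BED score is the hit score as a fraction of the element's maximal
    score, scaled to 0..1000 and clipped at 0.
    """
    tss_by_id = {rec.id: rec.tss_index for rec in records}
    with open(path, "w") as fh:
        for h in hits:
            hit = h.hit if isinstance(h, AnnotatedHit) else h
            tss = tss_by_id[hit.seq_id]
            five_prime = tss_absolute(hit.start_tss_rel, tss)
            if hit.strand == "+":
                left0, right = five_prime - 1, five_prime - 1 + hit.length
            else:
                left0, right = five_prime - hit.length, five_prime
            max_score = matrices[hit.element].max_score
            scaled = int(round(max(0.0, min(1.0, hit.score / max_score)) * 1000)) if max_score > 0 else 0
            fh.write(
                f"{hit.seq_id}\t{left0}\t{right}\t{hit.element}\t{scaled}\t{hit.strand}\n"
            )
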