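"""Dataset containers and tabular interchange formats.

The unit of analysis is a genome *segment* with total read counts from the
matched normal and tumor samples, carrying the heterozygous SNP sites that
fall inside it, each with B-allele and total read counts in both samples.

Two tab-separated files carry a dataset:

``segments.tsv``
    columns: segment_id, chrom, start, end, reads_normal, reads_tumor,
    is_baseline (0/1; optional on input).

``snp_sites.tsv``
    columns: segment_id, position, b_normal, d_normal, b_tumor, d_tumor.

Coordinates are 0-based half-open internally (BED convention); 1-based
inclusive input is converted at the boundary.  Lines starting with '#' are
comments; a header row is required.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SNPSiteRecord",
    "SegmentRecord",
    "Dataset",
    "FormatError",
    "read_segments",
    "read_counts",
    "write_counts",
    "validate_dataset",
]


class FormatError(ValueError):
    """Malformed input file (carries file context and, where known, a line)."""


@dataclass
class SNPSiteRecord:
    """Allele counts at one heterozygous SNP site (both samples)."""

    position: int
    b_normal: int
    d_normal: int
    b_tumor: int
    d_tumor: int


@dataclass
class SegmentRecord:
    """One segment with per-sample read totals and its SNP sites."""

    chrom: str
    start: int
    end: int
    segment_id: str
    reads_normal: int
    reads_tumor: int
    sites: list[SNPSiteRecord] = field(default_factory=list)
    is_baseline: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class Dataset:
    """An ordered collection of segments plus free-form metadata."""

    segments: list[SegmentRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    def baseline_ids(self) -> set[str]:
        return {s.segment_id for s in self.segments if s.is_baseline}


_DIALECTS = ("BED", "1-based-inclusive")


def read_segments(
    path: str | Path, dialect: str = "BED"
) -> list[tuple[str, int, int, str]]:
    """Read a BED3+name segmentation; return (chrom, start, end, id) tuples
    normalized to 0-based half-open coordinates, in file order."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    out: list[tuple[str, int, int, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, seg_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if dialect == "1-based-inclusive":
                start -= 1
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start ({start}) >= end ({end}) "
                    "after 0-based half-open normalization"
                )
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start coordinate")
            if seg_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate segment id {seg_id!r}")
            seen.add(seg_id)
            out.append((chrom, start, end, seg_id))
    return out


_SEG_COLS = ["segment_id", "chrom", "start", "end", "reads_normal", "reads_tumor"]
_SNP_COLS = ["segment_id", "position", "b_normal", "d_normal", "b_tumor", "d_tumor"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"segment_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_counts(segments_path: str | Path, snp_path: str | Path) -> Dataset:
    """Load a dataset from its two TSVs (see module docstring for layout)."""
    seg_df = _read_tsv(segments_path, _SEG_COLS)
    snp_df = _read_tsv(snp_path, _SNP_COLS)

    segments: dict[str, SegmentRecord] = {}
    for row in seg_df.itertuples(index=False):
        seg_id = str(row.segment_id)
        if seg_id in segments:
            raise FormatError(f"{segments_path}: duplicate segment id {seg_id!r}")
        if row.start >= row.end:
            raise FormatError(
                f"{segments_path}: segment {seg_id!r} has start >= end"
            )
        segments[seg_id] = SegmentRecord(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            segment_id=seg_id,
            reads_normal=int(row.reads_normal),
            reads_tumor=int(row.reads_tumor),
            is_baseline=bool(getattr(row, "is_baseline", 0)),
        )
    for row in snp_df.itertuples(index=False):
        seg_id = str(row.segment_id)
        if seg_id not in segments:
            raise FormatError(
                f"{snp_path}: SNP row references unknown segment {seg_id!r}"
            )
        b_n, d_n = int(row.b_normal), int(row.d_normal)
        b_t, d_t = int(row.b_tumor), int(row.d_tumor)
        if not (0 <= b_n <= d_n) or not (0 <= b_t <= d_t):
            raise FormatError(
                f"{snp_path}: segment {seg_id!r} position {row.position}: "
                "B-allele count exceeds depth (or is negative)"
            )
        segments[seg_id].sites.append(
            SNPSiteRecord(int(row.position), b_n, d_n, b_t, d_t)
        )
    for seg in segments.values():
        seg.sites.sort(key=lambda s: s.position)
    return Dataset(segments=list(segments.values()))


def write_counts(
    dataset: Dataset, segments_path: str | Path, snp_path: str | Path
) -> None:
    """Write a dataset to its two TSVs; exact integer round-trip with
    :func:`read_counts`."""
    seg_rows = [
        {
            "segment_id": s.segment_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "reads_normal": s.reads_normal,
            "reads_tumor": s.reads_tumor,
            "is_baseline": int(s.is_baseline),
        }
        for s in dataset.segments
    ]
    snp_rows = [
        {
            "segment_id": s.segment_id,
            "position": site.position,
            "b_normal": site.b_normal,
            "d_normal": site.d_normal,
            "b_tumor": site.b_tumor,
            "d_tumor": site.d_tumor,
        }
        for s in dataset.segments
        for site in s.sites
    ]
    pd.DataFrame(seg_rows, columns=_SEG_COLS + ["is_baseline"]).to_csv(
        segments_path, sep="\t", index=False
    )
    pd.DataFrame(snp_rows, columns=_SNP_COLS).to_csv(snp_path, sep="\t", index=False)


@dataclass
class Diagnostic:
    segment_id: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.segment_id}] {self.reason}"


def validate_dataset(dataset: Dataset) -> list[Diagnostic]:
    """Check all container invariants; empty list means the dataset is clean."""
    diags: list[Diagnostic] = []
    seen: set[str] = set()
    if dataset.n_segments == 0:
        diags.append(Diagnostic("<dataset>", "dataset has no segments"))
    for seg in dataset.segments:
        if seg.segment_id in seen:
            diags.append(Diagnostic(seg.segment_id, "duplicate segment id"))
        seen.add(seg.segment_id)
        if seg.start >= seg.end:
            diags.append(Diagnostic(seg.segment_id, "start >= end"))
        if seg.reads_normal <= 0:
            diags.append(Diagnostic(seg.segment_id, "zero normal depth"))
        if seg.reads_tumor < 0:
            diags.append(Diagnostic(seg.segment_id, "negative tumor depth"))
        for site in seg.sites:
            if not (seg.start <= site.position < seg.end):
                diags.append(
                    Diagnostic(
                        seg.segment_id,
                        f"site position {site.position} outside segment "
                        f"[{seg.start}, {seg.end})",
                    )
                )
            if not (0 <= site.b_normal <= site.d_normal):
                diags.append(
                    Diagnostic(seg.segment_id, "normal B count exceeds depth")
                )
            if not (0 <= site.b_tumor <= site.d_tumor):
                diags.append(
                    Diagnostic(seg.segment_id, "tumor B count exceeds depth")
                )
    return diags
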