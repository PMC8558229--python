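"""Genomic intervals, promoter windows and open-chromatin track algebra.

All coordinates are 0-based half-open (BED convention). The motif search
space for a gene is the intersection of a window around its TSS with the
merged DNase-accessible track, so the two primitives here are a sorted-sweep
union (:func:`merge_tracks`) and a window/track intersection
(:func:`accessible_subregions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import MalformedIntervalError, XbpTargetsError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise MalformedIntervalError("interval has an empty chromosome name")
        if not (0 <= self.start < self.end):
            raise MalformedIntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise MalformedIntervalError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TSSAnnotation:
    """A transcription start site: ``tss`` is a 0-based position."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise XbpTargetsError(f"gene {self.gene_id}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise XbpTargetsError(
                f"gene {self.gene_id}: TSS strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """The TSS-anchored search window for one gene.

    The default flanks (10 kb each side) give the 20 kb promoter window in
    which XBP1-binding motifs are counted. The interval may be shorter than
    ``flank_upstream + flank_downstream`` when clipped at a sequence boundary.
    """

    gene_id: str
    interval: GenomicInterval
    flank_upstream: int = 10_000
    flank_downstream: int = 10_000


def _validated(intervals: Iterable, *, context: str = "track") -> list[GenomicInterval]:
    out = []
    for i, item in enumerate(intervals):
        if isinstance(item, GenomicInterval):
            out.append(item)
        else:
            try:
                out.append(GenomicInterval(*item))
            except MalformedIntervalError as exc:
                raise MalformedIntervalError(f"{context} record {i}: {exc}") from exc
    return out


def merge_tracks(
    tracks: Sequence[Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union of one or more interval tracks as disjoint sorted intervals.

    Overlapping and bookended (``end == next start``) intervals are fused, so
    the result is the minimal sorted representation of the base-pair union —
    the merge applied to the two HeLa DNase I accessibility tracks before
    motif counting. Strand is dropped (accessibility is unstranded).
    """
    pooled: list[GenomicInterval] = []
    for t, track in enumerate(tracks):
        pooled.extend(_validated(track, context=f"track {t}"))
    pooled.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in pooled:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def promoter_window(
    tss: TSSAnnotation,
    flank_up: int = 10_000,
    flank_down: int = 10_000,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """TSS-anchored window, strand-aware and clipped to the chromosome.

    On the plus strand the window is ``[tss - flank_up, tss + flank_down)``;
    on the minus strand the flanks are mirrored. Clipping never produces a
    negative-length interval, but a TSS outside the chromosome is an error.
    """
    if flank_up < 0 or flank_down < 0:
        raise XbpTargetsError(f"gene {tss.gene_id}: flanks must be >= 0")
    if chrom_length is not None and tss.tss >= chrom_length:
        raise XbpTargetsError(
            f"gene {tss.gene_id}: TSS {tss.tss} is outside {tss.chrom} "
            f"(length {chrom_length})"
        )
    if tss.strand == "+":
        start, end = tss.tss - flank_up, tss.tss + flank_down
    else:
        start, end = tss.tss - flank_down, tss.tss + flank_up
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    # tss is inside the chromosome and flanks are >= 0, so start <= tss < end
    # except the degenerate flank_up = flank_down = 0 case.
    if end <= start:
        end = start + 1
    return PromoterWindow(
        gene_id=tss.gene_id,
        interval=GenomicInterval(tss.chrom, start, end, tss.strand),
        flank_upstream=flank_up,
        flank_downstream=flank_down,
    )


def accessible_subregions(
    window: PromoterWindow,
    open_chromatin: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Intersect a promoter window with a merged open-chromatin track.

    Returns disjoint sorted intervals; the empty list when nothing of the
    window is accessible. ``open_chromatin`` must already be merged
    (see :func:`merge_tracks`).
    """
    w = window.interval
    out = []
    for iv in open_chromatin:
        if iv.chrom != w.chrom:
            continue
        if iv.start >= w.end:
            break
        if iv.end <= w.start:
            continue
        out.append(GenomicInterval(w.chrom, max(iv.start, w.start), min(iv.end, w.end)))
    return out
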