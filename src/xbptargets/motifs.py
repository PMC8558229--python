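"""Degenerate-consensus motif scanning, per-gene counting and clustering.

The XBP1-binding consensus used throughout the pipeline is the 12-mer
``GACGTGKCMTWW`` (K = G/T, M = A/C, W = A/T). Scanning is exact IUPAC
matching: every window of motif length is tested on the plus strand against
the pattern and, optionally, against its reverse complement; overlapping
instances on either strand are all reported and counted separately, because
the biological question is how many binding sites a promoter offers, not a
non-redundant tiling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
import numpy as np

from .errors import (
    InvalidMotifError,
    InvalidSequenceError,
    UndefinedCorrelationError,
    XbpTargetsError,
)
from .intervals import GenomicInterval, PromoterWindow, accessible_subregions

#: IUPAC nucleotide codes -> the set of bases each matches. ``N`` in a
#: *sequence* matches no code (unknown base, never counted as a site).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: The XBP1 consensus (Hocomoco M00402 logo).
XBP1_CONSENSUS = "GACGTGKCMTWW"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence or IUPAC pattern."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate consensus over the 15-letter IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise InvalidMotifError("empty motif pattern")
        p = self.pattern.upper()
        for i, ch in enumerate(p):
            if ch not in IUPAC_CODES:
                raise InvalidMotifError(
                    f"invalid IUPAC code {ch!r} at position {i} in {self.pattern!r}"
                )
        object.__setattr__(self, "pattern", p)

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, word: str) -> bool:
        """Exact IUPAC match of ``word`` (plus strand, no ambiguity in word)."""
        if len(word) != len(self.pattern):
            return False
        return all(b in IUPAC_CODES[c] for b, c in zip(word, self.pattern))

    def _regex(self) -> re.Pattern[str]:
        return re.compile(
            "".join("[" + "".join(sorted(IUPAC_CODES[c])) + "]" for c in self.pattern)
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif instance; coordinates are plus-strand half-open.

    ``matched_sequence`` is the plus-strand slice of the hit even for
    minus-strand matches.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matched_sequence: str


@dataclass(frozen=True)
class GeneMotifReport:
    """Per-gene motif tally over the accessible promoter search space."""

    gene_id: str
    n_hits: int
    n_clusters: int
    searched_bases: int


_VALID_SEQ = re.compile(r"[ACGTN]*\Z")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        pos = next(i for i, c in enumerate(seq) if c not in "ACGTN")
        raise InvalidSequenceError(
            f"invalid nucleotide {seq[pos]!r} at position {pos}"
        )
    return seq


def scan_iupac(
    sequence: str,
    motif: IUPACMotif | str,
    both_strands: bool = True,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifHit]:
    """All exact matches of ``motif`` in ``sequence``.

    Overlapping matches are all reported. Hits are sorted by start, plus
    strand before minus at the same position. ``offset`` shifts reported
    coordinates so windows extracted from a chromosome report genomic
    positions.
    """
    if not isinstance(motif, IUPACMotif):
        motif = IUPACMotif(motif)
    seq = _check_sequence(sequence)
    hits: list[MotifHit] = []
    patterns = [(motif._regex(), "+")]
    if both_strands:
        rc = IUPACMotif(reverse_complement(motif.pattern))
        patterns.append((rc._regex(), "-"))
    k = len(motif)
    for regex, strand in patterns:
        pos = 0
        while True:
            m = regex.search(seq, pos)
            if m is None:
                break
            s = m.start()
            hits.append(MotifHit(chrom, offset + s, offset + s + k, strand, seq[s : s + k]))
            pos = s + 1  # step one base to catch overlapping instances
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def count_motifs_per_gene(
    genome: Mapping[str, str],
    windows: Sequence[PromoterWindow],
    open_chromatin: Sequence[GenomicInterval],
    motif: IUPACMotif | str,
    both_strands: bool = True,
    cluster_max_gap: int = 500,
) -> list[GeneMotifReport]:
    """Count motif instances per gene inside accessible promoter DNA.

    A hit counts only if fully contained in one accessible subregion of the
    gene's promoter window (scanning is done within each subregion, so
    containment is structural). ``open_chromatin`` must be merged.
    """
    if not isinstance(motif, IUPACMotif):
        motif = IUPACMotif(motif)
    reports = []
    for window in windows:
        chrom = window.interval.chrom
        if chrom not in genome:
            raise XbpTargetsError(
                f"gene {window.gene_id}: chromosome {chrom!r} absent from genome"
            )
        hits: list[MotifHit] = []
        searched = 0
        for sub in accessible_subregions(window, open_chromatin):
            searched += len(sub)
            seq = genome[chrom][sub.start : sub.end]
            hits.extend(
                scan_iupac(seq, motif, both_strands, chrom=chrom, offset=sub.start)
            )
        hits.sort(key=lambda h: (h.start, h.strand))
        n_clusters, _ = find_homotypic_clusters(hits, max_gap=cluster_max_gap)
        reports.append(
            GeneMotifReport(window.gene_id, len(hits), n_clusters, searched)
        )
    return reports


def find_homotypic_clusters(
    hits: Iterable[MotifHit],
    max_gap: int = 500,
) -> tuple[int, list[GenomicInterval]]:
    """Maximal runs of >= 2 hits whose consecutive starts are <= ``max_gap`` apart.

    Homotypic clusters — several instances of the same motif in close
    proximity — can potentiate a factor's effect, so they are tallied
    alongside raw instance counts. Returns ``(count, cluster_spans)`` where a
    span covers the first hit's start to the last hit's end.
    """
    if max_gap < 0:
        raise XbpTargetsError("max_gap must be >= 0")
    ordered = sorted(hits, key=lambda h: (h.start, h.strand))
    spans: list[GenomicInterval] = []
    run: list[MotifHit] = []
    for hit in ordered:
        if run and hit.start - run[-1].start <= max_gap:
            run.append(hit)
        else:
            if len(run) >= 2:
                spans.append(
                    GenomicInterval(run[0].chrom, run[0].start, max(h.end for h in run))
                )
            run = [hit]
    if len(run) >= 2:
        spans.append(
            GenomicInterval(run[0].chrom, run[0].start, max(h.end for h in run))
        )
    return len(spans), spans


def correlate_counts_with_response(
    reports: Iterable[GeneMotifReport],
    responses: Mapping[str, float],
    use_clusters: bool = False,
) -> tuple[float, float]:
    """Pearson correlation of per-gene motif (or cluster) counts with response.

    ``responses`` maps gene_id to a fold change (> 0); the correlation is
    computed against log2 fold change. Returns ``(r, p)`` with a two-sided p
    from the t-distribution on n − 2 df. Genes lacking a response are
    skipped; fewer than 3 pairs or zero variance raise
    :class:`UndefinedCorrelationError`.
    """
    counts, log_fc = [], []
    for rep in reports:
        if rep.gene_id in responses:
            counts.append(rep.n_clusters if use_clusters else rep.n_hits)
            log_fc.append(np.log2(responses[rep.gene_id]))
    if len(counts) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 genes with both count and response, got {len(counts)}"
        )
    x = np.asarray(counts, dtype=float)
    y = np.asarray(log_fc, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in counts or responses")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
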