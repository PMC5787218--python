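"""Retrieval of intact element copies from genome sequences.

Mirrors a MAK-"Member"-style search: local alignment of a short element
consensus against a genome, an e-value cutoff, an end-mismatch tolerance
deciding intactness, flank extraction, target-site-duplication (TSD)
detection, and deduplication of identical flank+element+flank records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentHit, KarlinParams, Scoring, local_align
from .seqio import GenomeSet

logger = logging.getLogger("sinescan")

INTACT = "intact"
NEAR_INTACT_5 = "near_intact_5trunc"
NEAR_INTACT_3 = "near_intact_3trunc"


@dataclass(frozen=True)
class ConsensusElement:
    """The query element: a short consensus sequence (e.g. a 181-bp SINE)."""

    element_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SearchParams:
    """Thresholds for element retrieval.

    ``evalue_max`` is the hit-significance cutoff; ``end_mismatch_tol`` is
    how far (nt) an alignment may stop short of either consensus end and
    still count that end as reached; ``flank_len`` is the flank window;
    ``tsd_range`` the permitted direct-repeat lengths.
    """

    evalue_max: float = 1e-3
    end_mismatch_tol: int = 20
    flank_len: int = 500
    scoring: Scoring = field(default_factory=Scoring)
    karlin: KarlinParams | None = None
    tsd_range: tuple[int, int] = (5, 15)
    word_size: int = 11

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.end_mismatch_tol < 0 or self.flank_len < 0:
            raise ValueError("tolerances must be >= 0")
        if self.tsd_range[0] > self.tsd_range[1]:
            raise ValueError("tsd_range min must be <= max")
        if self.karlin is None:
            self.karlin = KarlinParams.for_scoring(self.scoring)


@dataclass
class InsertionLocus:
    """One genomic element copy with flanks and optional TSD.

    ``flank5`` immediately precedes ``[start, end)`` and ``flank3``
    immediately follows, so flank5 + element_seq + flank3 reproduces the
    genome slice around the locus.
    """

    locus_id: str
    genome_id: str
    chrom: str
    start: int
    end: int
    strand: str
    intactness: str
    hit: AlignmentHit | None
    element_seq: str
    flank5: str
    flank3: str
    tsd: str | None = None


def extract_flanks(genome: GenomeSet, chrom: str, start: int, end: int,
                   flank_len: int) -> tuple[str, str]:
    """Genomic sequence adjacent to ``[start, end)``, clipped at contig
    edges (actual lengths may be shorter than ``flank_len``)."""
    seq = genome.sequences[chrom]
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"interval [{start},{end}) outside {chrom}")
    return seq[max(0, start - flank_len):start], seq[end:end + flank_len]


def detect_tsd(flank5: str, flank3: str,
               tsd_range: tuple[int, int] = (5, 15)) -> str | None:
    """Longest exact match between a flank5 suffix and flank3 prefix with
    length inside ``tsd_range`` (longest-wins), else None."""
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    lo, hi = tsd_range
    for length in range(min(hi, len(flank5), len(flank3)), lo - 1, -1):
        if flank5[-length:] == flank3[:length]:
            return flank5[-length:]
    return None


def _intactness(hit: AlignmentHit, qlen: int, tol: int) -> str | None:
    """Intact if the alignment reaches within ``tol`` of both consensus
    ends; one-end failures are flagged nearly intact; both-end failures
    return None (locus dropped)."""
    ok5 = hit.qstart <= tol
    ok3 = (qlen - hit.qend) <= tol
    if ok5 and ok3:
        return INTACT
    if ok3:
        return NEAR_INTACT_5
    if ok5:
        return NEAR_INTACT_3
    return None


def find_insertions(genome: GenomeSet, consensus: ConsensusElement,
                    params: SearchParams | None = None) -> list[InsertionLocus]:
    """Search every chromosome for element copies and build loci.

    Every returned locus has e-value <= ``params.evalue_max``; flanks and
    TSD are populated.  Output is sorted by (chrom, start).
    """
    params = params or SearchParams()
    if len(genome) == 0:
        raise ValueError("empty genome")
    if consensus.length < params.tsd_range[1]:
        raise ValueError("consensus shorter than maximum TSD length")
    search_space = 2 * genome.total_length()
    loci: list[InsertionLocus] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        hits = local_align(
            consensus.sequence, seq, scoring=params.scoring,
            word_size=params.word_size, chrom=chrom, karlin=params.karlin,
            search_space=search_space,
        )
        for hit in hits:
            if hit.evalue > params.evalue_max:
                continue
            flag = _intactness(hit, consensus.length, params.end_mismatch_tol)
            if flag is None:
                continue
            flank5, flank3 = extract_flanks(genome, chrom, hit.start, hit.end,
                                            params.flank_len)
            tsd = None
            if flank5 and flank3:
                tsd = detect_tsd(flank5, flank3, params.tsd_range)
            loci.append(InsertionLocus(
                locus_id=f"{genome.genome_id}:{chrom}:{hit.start}-{hit.end}",
                genome_id=genome.genome_id, chrom=chrom,
                start=hit.start, end=hit.end, strand=hit.strand,
                intactness=flag, hit=hit,
                element_seq=seq[hit.start:hit.end],
                flank5=flank5, flank3=flank3, tsd=tsd,
            ))
    loci.sort(key=lambda l: (l.chrom, l.start, l.locus_id))
    return loci


def dedup_loci(loci) -> list[InsertionLocus]:
    """Collapse loci whose (flank5, element, flank3) strings are identical.

    The first representative in (chrom, start, locus_id) order survives;
    output order is deterministic and the operation is idempotent.
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.locus_id))
    seen: set[tuple[str, str, str]] = set()
    kept: list[InsertionLocus] = []
    for loc in ordered:
        key = (loc.flank5, loc.element_seq, loc.flank3)
        if key in seen:
            logger.info("dedup: dropping %s (identical to retained locus)",
                        loc.locus_id)
            continue
        seen.add(key)
        kept.append(loc)
    return kept
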