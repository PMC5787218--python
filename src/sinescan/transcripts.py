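"""Element-containing transcripts, maturity calls and CDS impact.

A transcript carrying the element in a retained intron is found by the
same local-alignment engine used for genomes.  Whether a sequence is a
genuine mature (spliced) transcript or a genomic-DNA contaminant is
decided from its hit structure against the genome: one full-length
contiguous hit means genomic-like; several collinear partial hits
separated by intron-sized gaps mean mature.  Splice variants are grouped
per gene and the predicted protein-length consequence of the element is
computed from CDS spans (annotated, else longest ORF).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentHit, KarlinParams, Scoring, local_align
from .search import ConsensusElement, SearchParams
from .seqio import GenomeSet

logger = logging.getLogger("sinescan")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sequence: str
    cds_span: tuple[int, int] | None = None  # 0-based half-open on transcript
    exon_blocks: list[tuple[int, int]] | None = None  # genomic, optional

    def __post_init__(self) -> None:
        if self.cds_span is not None:
            s, e = self.cds_span
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(
                    f"CDS span {self.cds_span} outside transcript "
                    f"{self.transcript_id}")


class Maturity(enum.Enum):
    mature = "mature"
    genomic_like = "genomic_like"
    unresolved = "unresolved"


@dataclass
class MaturityCall:
    call: Maturity
    n_hits: int
    coverage: float  # fraction of transcript covered by qualifying hits


@dataclass
class VariantSet:
    gene_id: str
    variant_ids: list[str]
    n_total: int
    n_with_element: int

    def __post_init__(self) -> None:
        if not (1 <= self.n_with_element <= self.n_total):
            raise ValueError("need 1 <= n_with_element <= n_total")


@dataclass
class CdsImpact:
    variant_id: str
    protein_length: int  # aa
    element_overlaps_cds: bool
    start_codon_in_element: bool
    incomplete_cds: bool = False
    counterpart_protein_length: int | None = None

    @property
    def shorter_than_counterpart(self) -> bool | None:
        if self.counterpart_protein_length is None:
            return None
        return self.protein_length < self.counterpart_protein_length


def find_element_transcripts(transcripts: Iterable[TranscriptRecord],
                             consensus: ConsensusElement,
                             params: SearchParams | None = None,
                             ) -> dict[str, list[AlignmentHit]]:
    """Transcripts with at least one qualifying element hit.

    Hits whose query coverage of the consensus is partial (an element end
    split away by splicing) are still reported; callers can inspect
    qstart/qend.
    """
    params = params or SearchParams()
    out: dict[str, list[AlignmentHit]] = {}
    for tr in transcripts:
        hits = [h for h in local_align(
            consensus.sequence, tr.sequence, scoring=params.scoring,
            word_size=params.word_size, chrom=tr.transcript_id,
            karlin=params.karlin,
            search_space=2 * len(tr.sequence))
            if h.evalue <= params.evalue_max]
        if hits:
            out[tr.transcript_id] = hits
    return out


def _merge_query_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(ivs):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def classify_maturity(transcript: TranscriptRecord, genome: GenomeSet,
                      evalue_max: float = 1e-100,
                      scoring: Scoring = Scoring(),
                      single_hit_cov: float = 0.99,
                      multi_hit_cov: float = 0.90,
                      max_intron: int = 50_000) -> MaturityCall:
    """Decide mature vs genomic-like from transcript-to-genome hits.

    One hit covering >= ``single_hit_cov`` of the transcript at 100%
    identity -> genomic_like.  Two or more partial hits, collinear on one
    strand of one chromosome with gaps (introns) <= ``max_intron``,
    jointly covering >= ``multi_hit_cov`` -> mature.  Anything else,
    including single-exon transcripts whose structure cannot distinguish
    the two, is unresolved.
    """
    karlin = KarlinParams.for_scoring(scoring)
    space = 2 * genome.total_length()
    tlen = len(transcript.sequence)
    hits: list[AlignmentHit] = []
    for chrom in sorted(genome.sequences):
        # long queries: demand >= 8 clustered seed words per candidate
        # window, so isolated chance word matches do not spawn windows
        hits.extend(h for h in local_align(
            transcript.sequence, genome.sequences[chrom], scoring=scoring,
            chrom=chrom, karlin=karlin, search_space=space,
            min_cluster_seeds=8)
            if h.evalue <= evalue_max)
    if not hits:
        logger.warning("transcript %s: no genome hit at E <= %g",
                       transcript.transcript_id, evalue_max)
        return MaturityCall(Maturity.unresolved, 0, 0.0)

    single_exon = (transcript.exon_blocks is not None
                   and len(transcript.exon_blocks) == 1)
    for h in hits:
        qcov = (h.qend - h.qstart) / tlen
        if qcov >= single_hit_cov and h.pident == 100.0:
            if single_exon:
                # a known single-exon transcript is indistinguishable from
                # genomic DNA by hit structure: flagged, not guessed
                return MaturityCall(Maturity.unresolved, 1, qcov)
            return MaturityCall(Maturity.genomic_like, 1, qcov)

    by_loc: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_loc.setdefault((h.chrom, h.strand), []).append(h)
    best: MaturityCall | None = None
    for (_, strand), group in sorted(by_loc.items()):
        if len(group) < 2:
            continue
        group.sort(key=lambda h: h.qstart)
        subj = [(h.start, h.end) for h in group]
        order_ok = all(b1[0] >= a1[1] for a1, b1 in zip(subj, subj[1:])) \
            if strand == "+" else \
            all(b1[1] <= a1[0] for a1, b1 in zip(subj, subj[1:]))
        gaps_ok = all(
            0 < (b1[0] - a1[1] if strand == "+" else a1[0] - b1[1]) <= max_intron
            for a1, b1 in zip(subj, subj[1:]))
        if not (order_ok and gaps_ok):
            continue
        cov = sum(b - a for a, b in _merge_query_intervals(
            [(h.qstart, h.qend) for h in group])) / tlen
        if cov >= multi_hit_cov:
            cand = MaturityCall(Maturity.mature, len(group), cov)
            if best is None or cand.coverage > best.coverage:
                best = cand
    if best is not None:
        return best
    cov = sum(b - a for a, b in _merge_query_intervals(
        [(h.qstart, h.qend) for h in hits])) / tlen
    return MaturityCall(Maturity.unresolved, len(hits), cov)


def group_variants(element_transcript_ids: Iterable[str],
                   all_transcripts: Iterable[TranscriptRecord],
                   ) -> tuple[list[VariantSet], dict]:
    """One VariantSet per gene with >= 1 element-containing variant.

    The summary reports the number of such genes, how many have >= 2
    total variants, and the min/max variant count; it is invariant to
    input order.
    """
    with_element = set(element_transcript_ids)
    by_gene: dict[str, list[str]] = {}
    for tr in all_transcripts:
        by_gene.setdefault(tr.gene_id, []).append(tr.transcript_id)
    sets: list[VariantSet] = []
    for gene_id in sorted(by_gene):
        tids = sorted(by_gene[gene_id])
        n_el = sum(1 for t in tids if t in with_element)
        if n_el == 0:
            continue
        sets.append(VariantSet(gene_id, tids, len(tids), n_el))
    summary = {
        "n_genes": len(sets),
        "n_multi_variant": sum(1 for s in sets if s.n_total >= 2),
        "min_variants": min((s.n_total for s in sets), default=0),
        "max_variants": max((s.n_total for s in sets), default=0),
    }
    return sets, summary


def longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG..stop open reading frame, forward frames only.

    Returns a half-open span including the stop codon, or None.
    """
    seq = seq.upper()
    best: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best


def _protein_length(seq: str, span: tuple[int, int]) -> tuple[int, bool]:
    cds = seq[span[0]:span[1]]
    incomplete = len(cds) % 3 != 0
    n_codons = len(cds) // 3
    if not incomplete and cds[-3:] in STOP_CODONS:
        return n_codons - 1, False
    return n_codons, incomplete


def cds_impact(variant: TranscriptRecord,
               element_hit: tuple[int, int] | AlignmentHit,
               counterpart: TranscriptRecord | None = None) -> CdsImpact:
    """Predicted protein-length consequence of the element in a variant.

    ``element_hit`` is the element interval on the variant's sequence.
    CDS spans come from annotation, else the longest-ORF fallback; a CDS
    whose length is not a multiple of 3 is flagged incomplete and its
    length floored.
    """
    if isinstance(element_hit, AlignmentHit):
        el = (element_hit.start, element_hit.end)
    else:
        el = tuple(element_hit)

    def _span(tr: TranscriptRecord) -> tuple[int, int]:
        if tr.cds_span is not None:
            return tr.cds_span
        orf = longest_orf(tr.sequence)
        if orf is None:
            raise ValueError(f"no CDS span and no ORF in {tr.transcript_id}")
        return orf

    span = _span(variant)
    plen, incomplete = _protein_length(variant.sequence, span)
    cp_len = None
    if counterpart is not None:
        cp_len, _ = _protein_length(counterpart.sequence, _span(counterpart))
    return CdsImpact(
        variant_id=variant.transcript_id,
        protein_length=plen,
        element_overlaps_cds=max(el[0], span[0]) < min(el[1], span[1]),
        start_codon_in_element=el[0] <= span[0] < el[1],
        incomplete_cds=incomplete,
        counterpart_protein_length=cp_len,
    )


# ---------------------------------------------------------------------------
# Packaged splice-variant fixture
# ---------------------------------------------------------------------------

def load_variant_table(path=None) -> pd.DataFrame:
    """Per-gene splice-variant counts (the packaged 50-gene panel by
    default): gene_id, location, n_variants, n_with_element."""
    if path is None:
        path = resources.files("sinescan.data") / "table2_variants.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype={"n_variants": int,
                                                 "n_with_element": int})
    need = {"gene_id", "n_variants", "n_with_element"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def variant_sets_from_table(df: pd.DataFrame) -> tuple[list[VariantSet], dict]:
    """Build VariantSets (with synthetic variant ids) from a count table
    and return them with the same summary as :func:`group_variants`."""
    sets = [
        VariantSet(r["gene_id"],
                   [f"{r['gene_id']}.{i + 1}" for i in range(r["n_variants"])],
                   int(r["n_variants"]), int(r["n_with_element"]))
        for _, r in df.iterrows()
    ]
    summary = {
        "n_genes": len(sets),
        "n_multi_variant": sum(1 for s in sets if s.n_total >= 2),
        "min_variants": min((s.n_total for s in sets), default=0),
        "max_variants": max((s.n_total for s in sets), default=0),
    }
    return sets, summary
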