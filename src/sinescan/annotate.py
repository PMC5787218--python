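"""Classification of insertion loci relative to gene models and TE annotations.

Two modes are provided.  Interval mode (the default when positioned gene
models exist) classifies the element interval against exon/intron
structure, proximal windows, ncRNA and TE features.  Similarity mode
reproduces the flank-homology approach used when no positioned
annotation is available: the merged 5'+3' flanks are aligned against
cDNA/CDS/ncRNA/TE sequence databases and the best qualifying hit decides
the category with precedence gene > ncRNA > TE.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .align import KarlinParams, Scoring, local_align
from .seqio import FeatureTable

logger = logging.getLogger("sinescan")


class SiteCategory(enum.Enum):
    exon = "exon"
    intron = "intron"
    exon_intron_junction = "exon_intron_junction"
    proximal_upstream = "proximal_upstream"
    proximal_downstream = "proximal_downstream"
    ncRNA = "ncRNA"
    te_classI = "te_classI"
    te_classII = "te_classII"
    intergenic = "intergenic"


GENE_ASSOCIATED = frozenset({
    SiteCategory.exon, SiteCategory.intron, SiteCategory.exon_intron_junction,
    SiteCategory.proximal_upstream, SiteCategory.proximal_downstream,
})


@dataclass
class AnnotParams:
    proximal_window: int = 500
    evalue_max: float = 1e-10
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if self.proximal_window < 0:
            raise ValueError("proximal_window must be >= 0")


@dataclass
class SiteAnnotation:
    locus_id: str
    category: SiteCategory
    gene_id: str | None = None
    distance: int = 0  # 0 if inside the feature


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return min(a1, b1) - max(a0, b0)


def classify_site(locus, gene_models: FeatureTable,
                  te_annotations: FeatureTable | None = None,
                  params: AnnotParams | None = None) -> SiteAnnotation:
    """Assign exactly one primary category to a locus by interval logic.

    Precedence is gene > ncRNA > TE > intergenic; proximal orientation
    follows the gene strand (upstream = 5' of the gene).  Ties between
    equally near genes go to the lexicographically smaller gene_id.
    """
    params = params or AnnotParams()
    start, end = locus.start, locus.end
    chrom_feats = gene_models.on_chrom(locus.chrom)
    if len(chrom_feats) == 0 and (te_annotations is None
                                  or len(te_annotations.on_chrom(locus.chrom)) == 0):
        logger.warning("locus %s: chromosome %s absent from annotation",
                       locus.locus_id, locus.chrom)
        return SiteAnnotation(locus.locus_id, SiteCategory.intergenic)

    genes = chrom_feats[(chrom_feats["kind"] == "gene")
                        & (chrom_feats["biotype"] == "protein_coding")]

    # containment / overlap with a protein-coding gene body
    for _, g in genes.sort_values(["start", "gene_id"]).iterrows():
        if _overlap(start, end, g["start"], g["end"]) <= 0:
            continue
        exon_ivs: list[tuple[int, int]] = []
        for tid in gene_models.transcripts_of(g["gene_id"]):
            exon_ivs.extend(gene_models.exons_of(tid))
        inside_exon = any(e0 <= start and end <= e1 for e0, e1 in exon_ivs)
        if inside_exon:
            return SiteAnnotation(locus.locus_id, SiteCategory.exon,
                                  g["gene_id"])
        touches_exon = any(_overlap(start, end, e0, e1) > 0
                           for e0, e1 in exon_ivs)
        if touches_exon:
            return SiteAnnotation(locus.locus_id,
                                  SiteCategory.exon_intron_junction,
                                  g["gene_id"])
        if g["start"] <= start and end <= g["end"]:
            return SiteAnnotation(locus.locus_id, SiteCategory.intron,
                                  g["gene_id"])
        return SiteAnnotation(locus.locus_id, SiteCategory.exon_intron_junction,
                              g["gene_id"])

    # proximal window, nearest gene wins; tie -> smaller gene_id (logged)
    best: tuple[int, str, SiteCategory] | None = None
    for _, g in genes.iterrows():
        if end <= g["start"]:
            dist = g["start"] - end
            side_upstream = g["strand"] != "-"
        elif start >= g["end"]:
            dist = start - g["end"]
            side_upstream = g["strand"] == "-"
        else:
            continue
        if dist > params.proximal_window:
            continue
        cat = (SiteCategory.proximal_upstream if side_upstream
               else SiteCategory.proximal_downstream)
        cand = (dist, g["gene_id"], cat)
        if best is None or cand[:2] < best[:2]:
            if best is not None and cand[0] == best[0]:
                logger.info("locus %s: equidistant genes %s/%s, choosing %s",
                            locus.locus_id, best[1], cand[1],
                            min(best[1], cand[1]))
            best = cand
    if best is not None:
        return SiteAnnotation(locus.locus_id, best[2], best[1], best[0])

    # ncRNA containment
    nc = chrom_feats[(chrom_feats["kind"] == "ncRNA")
                     | ((chrom_feats["kind"] == "gene")
                        & (chrom_feats["biotype"] != "protein_coding"))]
    for _, f in nc.sort_values(["start", "gene_id"]).iterrows():
        if _overlap(start, end, f["start"], f["end"]) > 0:
            return SiteAnnotation(locus.locus_id, SiteCategory.ncRNA,
                                  f["gene_id"] or None)

    # TE intervals: class read from biotype ("te_classI" / "te_classII")
    if te_annotations is not None:
        for _, f in te_annotations.on_chrom(locus.chrom).sort_values(
                ["start"]).iterrows():
            if _overlap(start, end, f["start"], f["end"]) > 0:
                cat = (SiteCategory.te_classII
                       if "II" in str(f["biotype"]) else SiteCategory.te_classI)
                return SiteAnnotation(locus.locus_id, cat)

    return SiteAnnotation(locus.locus_id, SiteCategory.intergenic)


def annotate_by_similarity(flank5: str, flank3: str,
                           cdna_db: Mapping[str, str] | None = None,
                           cds_db: Mapping[str, str] | None = None,
                           ncrna_db: Mapping[str, str] | None = None,
                           te_db: Mapping[str, str] | None = None,
                           te_classes: Mapping[str, str] | None = None,
                           evalue_max: float = 1e-10,
                           scoring: Scoring = Scoring()) -> SiteCategory:
    """Categorize a locus by aligning its merged flanks against databases.

    The best hit with E <= ``evalue_max`` decides the category with
    precedence gene (cDNA/CDS) > ncRNA > TE; no qualifying hit means
    intergenic.  ``te_classes`` maps TE record ids to "I"/"II"
    (default I).
    """
    if not any((cdna_db, cds_db, ncrna_db, te_db)):
        raise ValueError("at least one database must be non-empty")
    query = flank5 + flank3
    karlin = KarlinParams.for_scoring(scoring)

    def _best_e(db: Mapping[str, str] | None) -> tuple[float, str | None]:
        if not db:
            return (float("inf"), None)
        space = 2 * sum(len(s) for s in db.values())
        best, best_id = float("inf"), None
        for name, seq in sorted(db.items()):
            for hit in local_align(query, seq, scoring=scoring, chrom=name,
                                   karlin=karlin, search_space=space):
                if hit.evalue < best:
                    best, best_id = hit.evalue, name
        return best, best_id

    gene_e = min(_best_e(cdna_db)[0], _best_e(cds_db)[0])
    if gene_e <= evalue_max:
        return SiteCategory.exon  # gene category (flanks match transcribed seq)
    if _best_e(ncrna_db)[0] <= evalue_max:
        return SiteCategory.ncRNA
    te_e, te_id = _best_e(te_db)
    if te_e <= evalue_max:
        cls = (te_classes or {}).get(te_id or "", "I")
        return SiteCategory.te_classII if "II" in cls else SiteCategory.te_classI
    return SiteCategory.intergenic


def _pct(count: int, total: int) -> float:
    """Percent rounded half-up to one decimal (printed-table style)."""
    if total == 0:
        return 0.0
    return float((Decimal(100 * count) / Decimal(total))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class AnnotationSummary:
    """Per-category counts and percentages over a set of annotations."""

    counts: dict[SiteCategory, int]
    total: int
    percent: dict[SiteCategory, float]
    gene_associated_count: int
    gene_associated_percent: float
    ncrna_percent: float
    te_percent: float
    transcribed_percent: float
    empty_input: bool = False


def summarize_annotation(annotations: Iterable[SiteAnnotation]) -> AnnotationSummary:
    counts = {cat: 0 for cat in SiteCategory}
    for ann in annotations:
        counts[ann.category] += 1
    return summarize_counts(counts)


def summarize_counts(counts: Mapping[SiteCategory, int]) -> AnnotationSummary:
    """Summary arithmetic from per-category counts.

    gene-associated = exon + intron + junction + proximal up/downstream;
    transcribed = gene-associated + ncRNA (TE-resident insertions are
    excluded from "transcribed").
    """
    full = {cat: int(counts.get(cat, 0)) for cat in SiteCategory}
    total = sum(full.values())
    gene_n = sum(full[c] for c in GENE_ASSOCIATED)
    te_n = full[SiteCategory.te_classI] + full[SiteCategory.te_classII]
    nc_n = full[SiteCategory.ncRNA]
    if total == 0:
        logger.warning("annotation summary over empty input")
    return AnnotationSummary(
        counts=full, total=total,
        percent={cat: _pct(n, total) for cat, n in full.items()},
        gene_associated_count=gene_n,
        gene_associated_percent=_pct(gene_n, total),
        ncrna_percent=_pct(nc_n, total),
        te_percent=_pct(te_n, total),
        transcribed_percent=_pct(gene_n + nc_n, total),
        empty_input=(total == 0),
    )
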