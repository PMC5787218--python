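"""Cross-genome comparison of insertion loci.

Two insertions in different genomes are called the same event (shared)
when the sequence immediately flanking the element matches exactly on
both sides over k bp.  Distribution tables tally loci per homoeologous
chromosome group and subgenome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("sinescan")

DEFAULT_FLANK_K = 50


def flank_key(locus, k: int = DEFAULT_FLANK_K) -> tuple[str, str] | None:
    """Terminal k bp of flank5 + initial k bp of flank3, or None when a
    clipped flank is shorter than k (the locus is excluded from matching)."""
    if len(locus.flank5) < k or len(locus.flank3) < k:
        logger.warning("locus %s: flank shorter than k=%d, skipped",
                       locus.locus_id, k)
        return None
    return (locus.flank5[-k:], locus.flank3[:k])


@dataclass(frozen=True)
class SharedInsertion:
    locus_id_a: str
    genome_a: str
    locus_id_b: str
    genome_b: str


def shared_insertions(loci_a: Sequence, loci_b: Sequence,
                      k: int = DEFAULT_FLANK_K) -> list[SharedInsertion]:
    """Pairs of loci with exactly matching insertion-site flanks.

    Both flank k-mers must match.  Pairing is one-to-one: loci sharing a
    key are sorted by coordinate on each side and zipped, so the relation
    is symmetric and input-order invariant; multi-matches are logged.
    """
    def _index(loci):
        by_key: dict[tuple[str, str], list] = {}
        for loc in sorted(loci, key=lambda l: (l.chrom, l.start, l.locus_id)):
            key = flank_key(loc, k)
            if key is not None:
                by_key.setdefault(key, []).append(loc)
        return by_key

    idx_a, idx_b = _index(loci_a), _index(loci_b)
    pairs: list[SharedInsertion] = []
    for key in idx_a.keys() & idx_b.keys():
        la, lb = idx_a[key], idx_b[key]
        if len(la) > 1 or len(lb) > 1:
            logger.info("flank key with multiple matches (%d vs %d loci); "
                        "pairing by coordinate order", len(la), len(lb))
        for a, b in zip(la, lb):
            pairs.append(SharedInsertion(a.locus_id, a.genome_id,
                                         b.locus_id, b.genome_id))
    pairs.sort(key=lambda p: (p.locus_id_a, p.locus_id_b))
    return pairs


def shared_fraction(subgenome_loci: Sequence, donor_loci: Sequence,
                    k: int = DEFAULT_FLANK_K) -> float | None:
    """Percent of ``subgenome_loci`` shared with ``donor_loci``
    (one-decimal, half-up).  None (flagged) for an empty subgenome set."""
    if len(subgenome_loci) == 0:
        logger.warning("shared_fraction over empty subgenome set: undefined")
        return None
    n_shared = len(shared_insertions(subgenome_loci, donor_loci, k))
    return float((Decimal(100 * n_shared) / Decimal(len(subgenome_loci)))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Subgenome distribution
# ---------------------------------------------------------------------------

SubgenomeMap = Mapping[str, tuple[int, str]]  # chrom -> (group 1..7, label)


def read_subgenome_map(path: str | Path) -> dict[str, tuple[int, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"chrom", "group", "subgenome"}
    if not need.issubset(df.columns):
        raise ValueError(f"subgenome map needs columns {sorted(need)}")
    return {r["chrom"]: (int(r["group"]), r["subgenome"])
            for _, r in df.iterrows()}


def write_subgenome_map(mapping: SubgenomeMap, path: str | Path) -> None:
    rows = [{"chrom": c, "group": g, "subgenome": s}
            for c, (g, s) in sorted(mapping.items())]
    pd.DataFrame(rows, columns=["chrom", "group", "subgenome"]).to_csv(
        path, sep="\t", index=False)


@dataclass
class DistributionTable:
    """Counts per (homoeologous group, subgenome) plus the unmapped tally.

    Invariant: cell sum + unmapped == grand total.
    """

    cells: pd.DataFrame  # index=group, columns=subgenome labels
    unmapped: int
    total: int

    def subgenome_totals(self) -> dict[str, int]:
        return {c: int(self.cells[c].sum()) for c in self.cells.columns}


def distribution(loci: Iterable, mapping: SubgenomeMap) -> DistributionTable:
    """Tally loci per (group, subgenome); unmapped chromosomes count as
    unmapped."""
    labels = sorted({s for _, s in mapping.values()})
    groups = sorted({g for g, _ in mapping.values()})
    cells = pd.DataFrame(0, index=groups, columns=labels, dtype=int)
    unmapped = 0
    total = 0
    for loc in loci:
        total += 1
        entry = mapping.get(loc.chrom)
        if entry is None:
            unmapped += 1
            continue
        g, s = entry
        cells.loc[g, s] += 1
    return DistributionTable(cells=cells, unmapped=unmapped, total=total)
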