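"""In-silico PCR genotyping of insertion presence/absence.

Primers designed from the element's flanking sequences amplify a short
product when the locus is empty and a product longer by roughly the
element length (plus any target-site duplication) when it is full.
Per-accession calls aggregate to per-species presence ("full site in at
least one accession"), and presence patterns across ploidy groups map to
evolutionary-origin classes.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .seqio import GenomeSet, revcomp

logger = logging.getLogger("sinescan")

DEFAULT_MAX_PRODUCT = 5000
DEFAULT_LEN_TOL = 20  # bp slack when matching empty + element arithmetic


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    gene_id: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for name, p in (("fwd", self.fwd), ("rev", self.rev)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 nt")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{name} primer contains non-ACGT characters")


@dataclass
class Amplicon:
    template_id: str
    start: int
    end: int  # half-open; includes both primer footprints
    allele: str | None = None  # "full" / "empty", set during genotyping

    @property
    def length(self) -> int:
        return self.end - self.start


class GenotypeCall(enum.Enum):
    full = "full"
    empty = "empty"
    both = "both"
    none = "none"
    ambiguous = "ambiguous"


class PolymorphismClass(enum.Enum):
    monomorphic_present = "monomorphic_present"
    hexaploid_only = "hexaploid_only"
    tetra_and_hexaploid = "tetra_and_hexaploid"
    diploid_inherited_AA = "diploid_inherited_AA"
    diploid_inherited_BB = "diploid_inherited_BB"
    diploid_inherited_DD = "diploid_inherited_DD"
    multiple_diploid = "multiple_diploid"
    other = "other"


PLOIDY_GROUPS = ("diploid_AA", "diploid_BB", "diploid_DD",
                 "tetraploid", "hexaploid")


def find_primer_sites(template: str, primer: str) -> dict[str, list[int]]:
    """Exact, case-insensitive primer matches on both strands.

    '+' positions are starts of the primer itself; '-' positions are
    starts of its reverse complement on the template.
    """
    if not template:
        raise ValueError("empty template")
    t = template.upper()
    out: dict[str, list[int]] = {"+": [], "-": []}
    for strand, probe in (("+", primer.upper()), ("-", revcomp(primer))):
        pos = t.find(probe)
        while pos != -1:
            out[strand].append(pos)
            pos = t.find(probe, pos + 1)
    return out


def predict_amplicons(template_id: str, template: str, pair: PrimerPair,
                      max_len: int = DEFAULT_MAX_PRODUCT) -> list[Amplicon]:
    """Every properly oriented primer-site combination with span <= max_len.

    Product length is inclusive of both primer footprints.  Both template
    orientations are considered (fwd on plus with rev pointing back, and
    the mirror arrangement).
    """
    fwd_sites = find_primer_sites(template, pair.fwd)
    rev_sites = find_primer_sites(template, pair.rev)
    products: list[Amplicon] = []
    # fwd anneals to plus strand at i, rev anneals pointing upstream at j
    for i in fwd_sites["+"]:
        for j in rev_sites["-"]:
            end = j + len(pair.rev)
            if end > i and end - i <= max_len and j >= i:
                products.append(Amplicon(template_id, i, end))
    # mirror orientation: rev on plus strand, fwd pointing upstream
    for i in rev_sites["+"]:
        for j in fwd_sites["-"]:
            end = j + len(pair.fwd)
            if end > i and end - i <= max_len and j >= i:
                products.append(Amplicon(template_id, i, end))
    uniq = {(a.start, a.end): a for a in products}
    return sorted(uniq.values(), key=lambda a: (a.start, a.end))


def _call_accession(lengths: Sequence[int], contains_element: Sequence[bool],
                    empty_len: int | None, element_len: int,
                    tol: int) -> GenotypeCall:
    if not lengths:
        return GenotypeCall.none
    full = empty = other = 0
    for ln, has_el in zip(lengths, contains_element):
        if has_el or (empty_len is not None
                      and abs(ln - (empty_len + element_len)) <= tol):
            full += 1
        elif empty_len is not None and abs(ln - empty_len) <= tol:
            empty += 1
        else:
            other += 1
    if other and not (full or empty):
        return GenotypeCall.ambiguous
    if full and empty:
        return GenotypeCall.both
    if full:
        return GenotypeCall.full
    if empty:
        return GenotypeCall.empty
    return GenotypeCall.ambiguous


def genotype(panel: Mapping[str, GenomeSet], pair: PrimerPair,
             element_len: int, consensus: str | None = None,
             max_len: int = DEFAULT_MAX_PRODUCT,
             tol: int = DEFAULT_LEN_TOL) -> dict[str, GenotypeCall]:
    """Per-accession full/empty calls for one primer pair.

    A product is "full" when it contains the element (substring of the
    product or its reverse complement, if a consensus is supplied) or
    when its length matches empty + element within ``tol``; the shortest
    product observed across the panel anchors the empty-site length.
    """
    if not panel:
        raise ValueError("empty accession panel")
    per_acc: dict[str, tuple[list[int], list[bool]]] = {}
    all_lengths: list[tuple[int, bool]] = []
    for acc, genome in panel.items():
        lengths: list[int] = []
        has_el: list[bool] = []
        for chrom, seq in genome.sequences.items():
            for amp in predict_amplicons(chrom, seq, pair, max_len=max_len):
                prod = seq[amp.start:amp.end]
                contains = bool(consensus) and (
                    consensus.upper() in prod or revcomp(consensus) in prod)
                lengths.append(amp.length)
                has_el.append(contains)
                all_lengths.append((amp.length, contains))
        per_acc[acc] = (lengths, has_el)
    empties = [ln for ln, contains in all_lengths if not contains]
    empty_len = min(empties) if empties else None
    if empty_len is None and all_lengths:
        # all products carry the element: infer the empty arithmetic
        empty_len = min(ln for ln, _ in all_lengths) - element_len
    return {acc: _call_accession(lengths, has_el, empty_len, element_len, tol)
            for acc, (lengths, has_el) in per_acc.items()}


def species_presence(calls: Mapping[str, GenotypeCall],
                     species_of: Mapping[str, str]) -> dict[str, bool | None]:
    """Presence per species: full site in at least one accession.

    Species whose accessions are all uncallable (none/ambiguous) get
    None (missing).
    """
    out: dict[str, bool | None] = {}
    for acc, call in calls.items():
        sp = species_of[acc]
        cur = out.get(sp)
        if call in (GenotypeCall.full, GenotypeCall.both):
            out[sp] = True
        elif call is GenotypeCall.empty:
            if cur is not True:
                out[sp] = False
        else:
            out.setdefault(sp, None)
    return out


def classify_polymorphism(row: Mapping[str, bool | None],
                          groups: Mapping[str, str]) -> PolymorphismClass:
    """Map a per-species presence pattern to an evolutionary-origin class.

    ``groups`` assigns each species one of: diploid_AA, diploid_BB,
    diploid_DD, tetraploid, hexaploid.  None presence values (missing
    data) are excluded from classification.  Total over all patterns:
    every input maps to exactly one class.
    """
    for sp in groups:
        if sp not in row:
            raise ValueError(f"missing species in presence row: {sp!r}")
    observed = {sp: v for sp, v in row.items() if v is not None}
    if observed and all(observed.values()):
        return PolymorphismClass.monomorphic_present

    def _present(group: str) -> bool:
        return any(v for sp, v in observed.items() if groups.get(sp) == group)

    def _observed(group: str) -> bool:
        return any(groups.get(sp) == group for sp in observed)

    dip_present = [g for g in ("diploid_AA", "diploid_BB", "diploid_DD")
                   if _present(g)]
    if len(dip_present) > 1:
        return PolymorphismClass.multiple_diploid
    if len(dip_present) == 1:
        return PolymorphismClass[f"diploid_inherited_{dip_present[0][-2:]}"]
    tetra, hexa = _present("tetraploid"), _present("hexaploid")
    if tetra and (hexa or not _observed("hexaploid")):
        return PolymorphismClass.tetra_and_hexaploid
    if hexa and not tetra:
        return PolymorphismClass.hexaploid_only
    return PolymorphismClass.other


def count_classes(classes) -> Counter:
    return Counter(classes)


# ---------------------------------------------------------------------------
# Packaged genotype-table fixture (40 genes x species presence + location)
# ---------------------------------------------------------------------------

TABLE1_SPECIES = ("AA", "BB_searsii", "BB_speltoides", "DD", "AABB", "AABBDD")

TABLE1_GROUPS = {
    "AA": "diploid_AA",
    "BB_searsii": "diploid_BB",
    "BB_speltoides": "diploid_BB",
    "DD": "diploid_DD",
    "AABB": "tetraploid",
    "AABBDD": "hexaploid",
}


def load_genotype_table(path=None) -> pd.DataFrame:
    """Load a site-specific PCR genotype table (the packaged 40-gene panel
    by default).  Presence columns hold 1/0/NA."""
    if path is None:
        path = resources.files("sinescan.data") / "table1_genotypes.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    need = {"case", "gene_id", "location", *TABLE1_SPECIES}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    return df


def presence_rows(df: pd.DataFrame):
    """Yield (case, presence row dict, location) from a genotype table."""
    for _, r in df.iterrows():
        row: dict[str, bool | None] = {}
        for sp in TABLE1_SPECIES:
            v = r[sp]
            row[sp] = None if v == "NA" else bool(int(v))
        yield r["case"], row, r["location"]
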