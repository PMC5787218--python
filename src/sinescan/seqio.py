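"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  GFF3 is
1-based inclusive and is converted at the I/O boundary; BED6 output is
0-based half-open natively.  TSV locus reports carry the internal
convention and document it in the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sinescan")

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSet:
    """A named collection of chromosome/contig sequences.

    Sequences are stored uppercase; only A, C, G, T and N are permitted.
    """

    genome_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) < 1:
                raise ValueError(f"empty sequence for record {name!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet`.

    Lowercase is folded to uppercase.  Characters outside A/C/G/T/N,
    duplicate headers and empty records are rejected with an error naming
    the offending record.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header: {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSet(genome_id=genome_id or path.stem, sequences=sequences)


def write_fasta(genome: GenomeSet | Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    seqs = genome.sequences if isinstance(genome, GenomeSet) else genome
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Feature tables (gene models, TE annotations)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "chrom", "start", "end", "strand", "kind", "gene_id", "transcript_id", "biotype",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass
class FeatureTable:
    """Tabular genomic features with 0-based half-open coordinates.

    ``kind`` is the feature type (gene, mRNA, exon, CDS, ncRNA, te, ...);
    ``biotype`` defaults to ``protein_coding`` for gene models.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"FeatureTable missing columns: {missing}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("FeatureTable requires start < end for every row")
        bad = set(self.df["strand"]) - _VALID_STRANDS
        if bad:
            raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "FeatureTable":
        df = pd.DataFrame(list(rows), columns=FEATURE_COLUMNS)
        return cls(df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind]

    def genes(self) -> pd.DataFrame:
        return self.of_kind("gene")

    def exons_of(self, transcript_id: str) -> list[tuple[int, int]]:
        sub = self.df[(self.df["kind"] == "exon")
                      & (self.df["transcript_id"] == transcript_id)]
        return sorted(zip(sub["start"], sub["end"]))

    def transcripts_of(self, gene_id: str) -> list[str]:
        sub = self.df[(self.df["kind"] == "mRNA") & (self.df["gene_id"] == gene_id)]
        return list(sub["transcript_id"])

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


def read_gff3(path: str | Path) -> FeatureTable:
    """Parse GFF3 gene models into a :class:`FeatureTable`.

    1-based inclusive GFF coordinates become 0-based half-open.  Exons are
    validated against their parent transcript span; the biotype attribute
    defaults to ``protein_coding``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows: list[dict] = []
    spans: dict[str, tuple[int, int, str]] = {}

    def _strand(f) -> str:
        if f.strand not in _VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {f.strand!r} for {f.id}")
        return f.strand

    for f in db.all_features(order_by=("seqid", "start")):
        start, end = f.start - 1, f.end  # GFF 1-based inclusive -> half-open
        kind = f.featuretype
        attrs = dict(f.attributes)
        biotype = (attrs.get("biotype") or ["protein_coding"])[0]
        gene_id = transcript_id = ""
        if kind == "gene" or kind.endswith("RNA_gene"):
            gene_id = f.id
            spans[f.id] = (start, end, "gene")
        elif kind in ("mRNA", "transcript", "ncRNA"):
            gene_id = (attrs.get("Parent") or [f.id])[0]
            transcript_id = f.id
            spans[f.id] = (start, end, kind)
        elif kind in ("exon", "CDS"):
            parent = (attrs.get("Parent") or [""])[0]
            transcript_id = parent
            pspan = spans.get(parent)
            if pspan is not None and not (pspan[0] <= start and end <= pspan[1]):
                raise ValueError(
                    f"{kind} [{start},{end}) outside parent {parent} span "
                    f"[{pspan[0]},{pspan[1]})"
                )
            if pspan is not None:
                gene_id = next(
                    (r["gene_id"] for r in rows
                     if r["transcript_id"] == parent and r["kind"] in
                     ("mRNA", "transcript", "ncRNA")), "")
        rows.append({
            "chrom": f.seqid, "start": start, "end": end, "strand": _strand(f),
            "kind": kind, "gene_id": gene_id, "transcript_id": transcript_id,
            "biotype": biotype,
        })
    return FeatureTable.from_rows(rows)


def write_gff3(features: FeatureTable, path: str | Path,
               source: str = "sinescan") -> None:
    """Emit a FeatureTable as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in features.df.iterrows():
            attrs = []
            if r["kind"] == "gene" or r["kind"] == "ncRNA" and not r["transcript_id"]:
                attrs.append(f"ID={r['gene_id']}")
            elif r["kind"] in ("mRNA", "transcript"):
                attrs.append(f"ID={r['transcript_id']};Parent={r['gene_id']}")
            elif r["kind"] in ("exon", "CDS"):
                attrs.append(f"Parent={r['transcript_id']}")
            if r["biotype"] and r["biotype"] != "protein_coding":
                attrs.append(f"biotype={r['biotype']}")
            fh.write("\t".join([
                str(r["chrom"]), source, str(r["kind"]),
                str(r["start"] + 1), str(r["end"]), ".", str(r["strand"]), ".",
                ";".join(attrs) or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Insertion-locus tables
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = [
    "locus_id", "genome", "chrom", "start", "end", "strand", "intactness",
    "evalue", "tsd", "category", "gene_id", "flank5", "flank3",
]


def write_insertion_table(loci, tsv_path: str | Path,
                          bed_path: str | Path | None = None,
                          annotations: Mapping[str, object] | None = None) -> None:
    """Write loci as a fixed-column TSV and optionally a BED6 file.

    ``annotations`` maps locus_id to a SiteAnnotation-like object with
    ``category`` and ``gene_id`` attributes.  Coordinates are 0-based
    half-open in both outputs; BED name is the locus_id.
    """
    rows = []
    for loc in loci:
        ann = (annotations or {}).get(loc.locus_id)
        rows.append({
            "locus_id": loc.locus_id, "genome": loc.genome_id,
            "chrom": loc.chrom, "start": loc.start, "end": loc.end,
            "strand": loc.strand, "intactness": loc.intactness,
            "evalue": loc.hit.evalue if loc.hit is not None else "",
            "tsd": loc.tsd or "",
            "category": getattr(ann, "category", "").value if ann else "",
            "gene_id": getattr(ann, "gene_id", "") or "" if ann else "",
            "flank5": loc.flank5, "flank3": loc.flank3,
        })
    df = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in rows:
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}"
                         f"\t{r['locus_id']}\t.\t{r['strand']}\n")


def read_insertion_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read a locus TSV back as a DataFrame with the documented columns."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"tsd": str, "category": str,
                                                "gene_id": str},
                     keep_default_na=False)
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
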