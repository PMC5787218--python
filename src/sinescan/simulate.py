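"""Seeded generators for genomes, gene models, planted element insertions,
polyploid panels, transcripts and qPCR tables, with ground-truth tables.

Everything is a pure function of its spec, including the seed: the same
spec yields byte-identical outputs.  Planted insertions realize the
element biology — an optional target-site duplication (TSD) flanking the
element, optional end truncation — at positions consistent with a
requested site category, and downstream feature coordinates are shifted
accordingly.

Default scales (3 chromosomes x 500 kb, 50 genes, 50 insertions) keep a
full search-annotate-compare pipeline run under a couple of minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .search import ConsensusElement
from .seqio import FeatureTable, GenomeSet, revcomp
from .transcripts import TranscriptRecord

logger = logging.getLogger("sinescan")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, rng, base_probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    rng = _rng(rng)
    idx = rng.choice(4, size=length, p=list(base_probs))
    return BASES[idx].tobytes().decode("ascii")


def random_element(length: int = 181, seed=0) -> ConsensusElement:
    """A random consensus element (default: SINE-sized, 181 bp)."""
    return ConsensusElement(f"element_{length}bp_seed{seed}",
                            random_sequence(length, _rng(seed)))


@dataclass(frozen=True)
class InsertionPlan:
    """One requested insertion: where (category), with what TSD length
    (0 = none, else 5-15), and an optional end truncation."""

    category: str = "intron"  # intron|exon|proximal_upstream|proximal_downstream|intergenic
    tsd_len: int = 0
    truncation: tuple[str, int] | None = None  # ("5"|"3", nt)

    def __post_init__(self) -> None:
        if self.tsd_len != 0 and not (5 <= self.tsd_len <= 15):
            raise ValueError("tsd_len must be 0 or in 5..15")
        if self.truncation is not None and self.truncation[0] not in ("5", "3"):
            raise ValueError("truncation end must be '5' or '3'")


@dataclass
class SimulationSpec:
    """Study-condition knobs for the generators."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (220, 400)
    intron_len: tuple[int, int] = (300, 800)
    n_insertions: int = 50
    insertions: list[InsertionPlan] | None = None
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    proximal_window: int = 500
    min_insertion_spacing: int = 1500
    retention_prob: float = 0.3
    contamination_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (*self.base_probs, self.retention_prob,
                  self.contamination_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.base_probs) - 1) > 1e-9:
            raise ValueError("base_probs must sum to 1")

    def plans(self) -> list[InsertionPlan]:
        if self.insertions is not None:
            return list(self.insertions)
        return [InsertionPlan()] * self.n_insertions


# ---------------------------------------------------------------------------
# Genome + gene models
# ---------------------------------------------------------------------------

def simulate_genome(spec: SimulationSpec):
    """i.i.d. background sequence with non-overlapping multi-exon genes.

    Returns (GenomeSet, FeatureTable, gene truth DataFrame).  Raises when
    the requested genes cannot be placed without overlap.
    """
    rng = _rng(spec.seed)
    sequences = {
        f"chr{i + 1}": random_sequence(spec.chrom_length, rng, spec.base_probs)
        for i in range(spec.n_chroms)
    }
    genome = GenomeSet(genome_id=f"sim{spec.seed}", sequences=sequences)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    margin = 2000
    per_chrom = [spec.n_genes // spec.n_chroms + (1 if i < spec.n_genes % spec.n_chroms else 0)
                 for i in range(spec.n_chroms)]
    gi = 0
    for ci, chrom in enumerate(sequences):
        cursor = margin
        for _ in range(per_chrom[ci]):
            n_ex = int(rng.integers(spec.exons_per_gene[0],
                                    spec.exons_per_gene[1] + 1))
            ex_lens = rng.integers(spec.exon_len[0], spec.exon_len[1] + 1,
                                   size=n_ex)
            in_lens = rng.integers(spec.intron_len[0], spec.intron_len[1] + 1,
                                   size=n_ex - 1)
            glen = int(ex_lens.sum() + in_lens.sum())
            gap = int(rng.integers(2000, 4000))
            start = cursor + gap
            if start + glen > spec.chrom_length - margin:
                raise ValueError(
                    f"cannot place {spec.n_genes} genes without overlap on "
                    f"{spec.n_chroms} x {spec.chrom_length} bp chromosomes")
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gi + 1:04d}"
            tid = f"{gene_id}.t1"
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k])))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    pos += int(in_lens[k])
            end = pos
            rows.append(dict(chrom=chrom, start=start, end=end, strand=strand,
                             kind="gene", gene_id=gene_id, transcript_id="",
                             biotype="protein_coding"))
            rows.append(dict(chrom=chrom, start=start, end=end, strand=strand,
                             kind="mRNA", gene_id=gene_id, transcript_id=tid,
                             biotype="protein_coding"))
            for e0, e1 in exons:
                rows.append(dict(chrom=chrom, start=e0, end=e1, strand=strand,
                                 kind="exon", gene_id=gene_id,
                                 transcript_id=tid, biotype="protein_coding"))
            truth_rows.append(dict(gene_id=gene_id, chrom=chrom, start=start,
                                   end=end, strand=strand, n_exons=n_ex))
            cursor = end
            gi += 1
    features = FeatureTable.from_rows(rows)
    return genome, features, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Insertion planting
# ---------------------------------------------------------------------------

def _introns_of(features: FeatureTable, gene_id: str) -> list[tuple[str, int, int]]:
    out = []
    gene = features.df[(features.df["kind"] == "gene")
                       & (features.df["gene_id"] == gene_id)].iloc[0]
    for tid in features.transcripts_of(gene_id):
        exons = features.exons_of(tid)
        for (a0, a1), (b0, b1) in zip(exons, exons[1:]):
            out.append((gene["chrom"], a1, b0))
    return out


def _candidate_ranges(category: str, genome: GenomeSet,
                      features: FeatureTable | None,
                      window: int) -> list[tuple[str, int, int]]:
    """Position ranges [a, b) satisfying a site category, precomputed once."""
    pad = 10
    if features is None or len(features) == 0:
        if category != "intergenic":
            raise ValueError(
                f"category {category!r} requested but no gene models")
        return [(chrom, window + 50, len(seq) - window - 50)
                for chrom, seq in sorted(genome.sequences.items())
                if len(seq) > 2 * window + 200]

    genes = features.genes().sort_values(["chrom", "start"])
    out: list[tuple[str, int, int]] = []
    if category == "intron":
        for gene_id in genes["gene_id"]:
            for chrom, a, b in _introns_of(features, gene_id):
                if b - a > 2 * pad + 20:
                    out.append((chrom, a + pad, b - pad))
    elif category == "exon":
        for _, g in genes.iterrows():
            for tid in features.transcripts_of(g["gene_id"]):
                for a, b in features.exons_of(tid):
                    if b - a > 2 * pad + 20:
                        out.append((g["chrom"], a + pad, b - pad))
    elif category in ("proximal_upstream", "proximal_downstream"):
        for _, g in genes.iterrows():
            before = (category == "proximal_upstream") == (g["strand"] != "-")
            if before:
                a, b = g["start"] - window + 50, g["start"] - 20
            else:
                a, b = g["end"] + 20, g["end"] + window - 50
            gsub = genes[genes["chrom"] == g["chrom"]]
            clear = all(
                o["gene_id"] == g["gene_id"]
                or b + window + 200 <= o["start"] or a - window - 200 >= o["end"]
                for _, o in gsub.iterrows())
            if clear and 0 < a < b:
                out.append((g["chrom"], a, b))
    elif category == "intergenic":
        # gaps between genes (and chromosome ends) with clearance
        for chrom, seq in sorted(genome.sequences.items()):
            gsub = genes[genes["chrom"] == chrom]
            bounds = [(0, 0)] + sorted(zip(gsub["start"], gsub["end"])) \
                + [(len(seq), len(seq))]
            for (_, prev_end), (next_start, _) in zip(bounds, bounds[1:]):
                a = max(prev_end + window + 100, window + 50)
                b = min(next_start - window - 100, len(seq) - window - 50)
                if b > a:
                    out.append((chrom, a, b))
    else:
        raise ValueError(f"unknown category {category!r}")
    if not out:
        raise ValueError(f"no site satisfies category {category!r}")
    return out


def plant_insertions(genome: GenomeSet, consensus: ConsensusElement,
                     plans, features: FeatureTable | None = None,
                     rng=0, proximal_window: int = 500,
                     min_spacing: int = 1500,
                     existing_truth: pd.DataFrame | None = None):
    """Insert element copies at category-consistent positions.

    Each insertion places element (optionally end-truncated) followed by
    a copy of the ``tsd_len`` bases immediately preceding the insertion
    point, so that the flank5 suffix equals the flank3 prefix.  Feature
    coordinates and any ``existing_truth`` intervals are shifted past the
    insertions.  Returns (GenomeSet, FeatureTable, truth DataFrame).
    """
    rng = _rng(rng)
    ranges: dict[str, list[tuple[str, int, int]]] = {}
    chosen: list[tuple[str, int, InsertionPlan]] = []
    for plan in plans:
        if plan.category not in ranges:
            ranges[plan.category] = _candidate_ranges(
                plan.category, genome, features, proximal_window)
        cand = ranges[plan.category]
        placed = False
        for _ in range(300):
            chrom, a, b = cand[int(rng.integers(len(cand)))]
            pos = int(rng.integers(a, b))
            if pos < max(plan.tsd_len, 1):
                continue
            if all(c != chrom or abs(pos - p) >= min_spacing
                   for c, p, _ in chosen):
                chosen.append((chrom, pos, plan))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place insertion with category {plan.category!r} "
                f"(spacing {min_spacing} bp)")

    new_seqs = dict(genome.sequences)
    truth_rows: list[dict] = []
    offsets: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted({c for c, _, _ in chosen}):
        at = sorted([(p, plan) for c, p, plan in chosen if c == chrom])
        seq = genome.sequences[chrom]
        parts: list[str] = []
        prev = 0
        off = 0
        offs: list[tuple[int, int]] = []
        for pos, plan in at:
            elem = consensus.sequence
            if plan.truncation is not None:
                end_, nt = plan.truncation
                elem = elem[nt:] if end_ == "5" else elem[:len(elem) - nt]
            tsd = seq[pos - plan.tsd_len:pos] if plan.tsd_len else ""
            parts.append(seq[prev:pos])
            parts.append(elem)
            parts.append(tsd)
            ins_len = len(elem) + len(tsd)
            truth_rows.append(dict(
                genome=genome.genome_id, chrom=chrom,
                start=pos + off, end=pos + off + len(elem),
                category=plan.category, tsd=tsd,
                truncation_end=plan.truncation[0] if plan.truncation else "",
                truncation_nt=plan.truncation[1] if plan.truncation else 0,
            ))
            offs.append((pos, ins_len))
            off += ins_len
            prev = pos
        parts.append(seq[prev:])
        new_seqs[chrom] = "".join(parts)
        offsets[chrom] = offs

    cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, offs in offsets.items():
        pos_arr = np.array([p for p, _ in offs], dtype=np.int64)
        len_cum = np.cumsum([L for _, L in offs]).astype(np.int64)
        cum[chrom] = (pos_arr, len_cum)

    def _shift(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        starts = df["start"].to_numpy(np.int64, copy=True)
        ends = df["end"].to_numpy(np.int64, copy=True)
        for chrom, (pos_arr, len_cum) in cum.items():
            m = (df["chrom"] == chrom).to_numpy()
            if not m.any():
                continue
            # start shifts for insertions at p <= start; end for p < end
            i_s = np.searchsorted(pos_arr, starts[m], side="right")
            i_e = np.searchsorted(pos_arr, ends[m], side="left")
            starts[m] += np.where(i_s > 0, len_cum[np.maximum(i_s - 1, 0)], 0)
            ends[m] += np.where(i_e > 0, len_cum[np.maximum(i_e - 1, 0)], 0)
        df["start"], df["end"] = starts, ends
        return df

    new_features = (FeatureTable(_shift(features.df))
                    if features is not None else None)
    truth = pd.DataFrame(truth_rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    if existing_truth is not None and len(existing_truth):
        truth = pd.concat([_shift(existing_truth), truth],
                          ignore_index=True).sort_values(
            ["chrom", "start"]).reset_index(drop=True)
    mutated = GenomeSet(genome_id=genome.genome_id, sequences=new_seqs)
    return mutated, new_features, truth


# ---------------------------------------------------------------------------
# Polyploid panels
# ---------------------------------------------------------------------------

def simulate_polyploid(diploids, labels, consensus: ConsensusElement | None = None,
                       extra_insertions: dict[str, int] | None = None,
                       rng=0, genome_id: str = "polyploid"):
    """Merge diploid genomes into one polyploid with labelled subgenomes.

    ``diploids`` is a sequence of (GenomeSet, insertion-truth DataFrame);
    chromosomes are copied verbatim (shared insertions keep identical
    flanks) and renamed ``<label>_<chrom>``.  ``extra_insertions`` plants
    additional intergenic-style polyploid-only copies per subgenome
    label.  Returns (GenomeSet, subgenome map, truth DataFrame).
    """
    if len(diploids) < 2:
        raise ValueError("need at least two diploid genomes")
    rng = _rng(rng)
    sequences: dict[str, str] = {}
    submap: dict[str, tuple[int, str]] = {}
    truth_frames = []
    for (genome, truth), label in zip(diploids, labels):
        for gi, chrom in enumerate(sorted(genome.sequences)):
            name = f"{label}_{chrom}"
            sequences[name] = genome.sequences[chrom]
            submap[name] = (gi + 1, label)
        if truth is not None and len(truth):
            t = truth.copy()
            t["chrom"] = [f"{label}_{c}" for c in t["chrom"]]
            t["genome"] = genome_id
            t["subgenome"] = label
            t["shared_with"] = genome.genome_id
            truth_frames.append(t)
    poly = GenomeSet(genome_id=genome_id, sequences=sequences)
    truth = (pd.concat(truth_frames, ignore_index=True)
             if truth_frames else pd.DataFrame())

    if extra_insertions:
        if consensus is None:
            raise ValueError("extra insertions require a consensus element")
        for label, n in sorted(extra_insertions.items()):
            sub = GenomeSet(genome_id=genome_id, sequences={
                c: s for c, s in poly.sequences.items()
                if submap[c][1] == label})
            existing = (truth[truth["subgenome"] == label]
                        if len(truth) else None)
            mutated, _, merged = plant_insertions(
                sub, consensus, [InsertionPlan(category="intergenic")] * n,
                features=None, rng=rng, existing_truth=existing)
            poly.sequences.update(mutated.sequences)
            merged["genome"] = genome_id
            merged["subgenome"] = label
            if "shared_with" in merged.columns:
                merged["shared_with"] = merged["shared_with"].fillna("")
            else:
                merged["shared_with"] = ""
            rest = truth[truth["subgenome"] != label] if len(truth) else truth
            truth = pd.concat([rest, merged], ignore_index=True)
    if len(truth):
        truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    return poly, submap, truth


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def simulate_transcripts(genome: GenomeSet, features: FeatureTable,
                         insertion_truth: pd.DataFrame | None,
                         retention_prob: float = 0.3,
                         contamination_prob: float = 0.0,
                         rng=0):
    """Per-gene transcript variants with optional element-containing
    intron retention and genomic-DNA contamination.

    Every gene yields a fully spliced variant; genes whose intron carries
    a planted element additionally yield, with probability
    ``retention_prob``, a variant retaining that intron.  With
    probability ``contamination_prob`` a raw genome slice is emitted and
    labelled contamination in the truth table.  Returns
    (list[TranscriptRecord], truth DataFrame).
    """
    rng = _rng(rng)
    records: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    el = insertion_truth if insertion_truth is not None else pd.DataFrame()
    for _, g in features.genes().sort_values(["chrom", "start"]).iterrows():
        gene_id, chrom, strand = g["gene_id"], g["chrom"], g["strand"]
        seq = genome.sequences[chrom]
        tid0 = features.transcripts_of(gene_id)
        exons = features.exons_of(tid0[0]) if tid0 else []
        if not exons:
            continue

        def _assemble(blocks) -> str:
            s = "".join(seq[a:b] for a, b in blocks)
            return revcomp(s) if strand == "-" else s

        spliced_id = f"{gene_id}.v1"
        records.append(TranscriptRecord(spliced_id, gene_id, _assemble(exons)))
        truth_rows.append(dict(transcript_id=spliced_id, gene_id=gene_id,
                               kind="spliced", has_element=False))

        retained_intron = None
        if len(el):
            sub = el[(el["chrom"] == chrom) & (el["category"] == "intron")]
            for (a0, a1), (b0, b1) in zip(exons, exons[1:]):
                hitting = sub[(sub["start"] >= a1) & (sub["end"] <= b0)]
                if len(hitting):
                    retained_intron = (a1, b0)
                    break
        if retained_intron is not None and rng.random() < retention_prob:
            blocks = []
            for a, b in exons:
                if blocks and blocks[-1][1] == retained_intron[0] \
                        and a == retained_intron[1]:
                    blocks[-1] = (blocks[-1][0], b)
                else:
                    blocks.append((a, b))
            rid = f"{gene_id}.v2"
            records.append(TranscriptRecord(rid, gene_id, _assemble(blocks)))
            truth_rows.append(dict(transcript_id=rid, gene_id=gene_id,
                                   kind="retained", has_element=True))
        if rng.random() < contamination_prob:
            a = max(0, g["start"] - 100)
            b = min(len(seq), g["end"] + 100)
            cid = f"{gene_id}.gdna"
            records.append(TranscriptRecord(cid, gene_id, seq[a:b]))
            truth_rows.append(dict(transcript_id=cid, gene_id=gene_id,
                                   kind="contamination",
                                   has_element=bool(
                                       len(el) and len(el[(el["chrom"] == chrom)
                                                          & (el["start"] >= a)
                                                          & (el["end"] <= b)]))))
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# In-silico PCR panels
# ---------------------------------------------------------------------------

def simulate_insertion_site_panel(presence: dict[str, list[bool]],
                                  consensus: ConsensusElement,
                                  rng=0, tsd_len: int = 0,
                                  primer_len: int = 22,
                                  empty_product_len: int = 220):
    """Accession genomes sharing one locus, with or without the element.

    ``presence`` maps species -> per-accession carrier flags.  Returns
    (panel dict accession -> GenomeSet, PrimerPair, species_of dict,
    truth DataFrame).  Full-site minus empty-site product length equals
    element length + tsd_len by construction.
    """
    from .pcr import PrimerPair

    rng = _rng(rng)
    template = random_sequence(700, rng)
    f0 = 60
    r1 = f0 + empty_product_len  # product end (inclusive of rev primer)
    fwd = template[f0:f0 + primer_len]
    rev = revcomp(template[r1 - primer_len:r1])
    insert_at = f0 + empty_product_len // 2
    tsd = template[insert_at - tsd_len:insert_at] if tsd_len else ""
    full_seq = (template[:insert_at] + consensus.sequence + tsd
                + template[insert_at:])
    panel: dict[str, GenomeSet] = {}
    species_of: dict[str, str] = {}
    rows = []
    for species in sorted(presence):
        for i, carrier in enumerate(presence[species]):
            acc = f"{species}_{i + 1}"
            seq = full_seq if carrier else template
            panel[acc] = GenomeSet(genome_id=acc, sequences={"locus": seq})
            species_of[acc] = species
            rows.append(dict(accession=acc, species=species, carrier=carrier))
    pair = PrimerPair("sim_pair", "sim_gene", fwd, rev)
    return panel, pair, species_of, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def simulate_qpcr(true_fold: float, efficiency: float = 1.0,
                  noise_sd: float = 0.2, n_bio: int = 3, n_tech: int = 3,
                  seed=0, transcript: str = "target",
                  reference_sample: str = "reference",
                  test_sample: str = "test") -> pd.DataFrame:
    """Ct table whose expected relative quantity equals ``true_fold``.

    The test sample's target Ct is shifted by -log_base(true_fold)
    relative to the reference sample (base = 2 x efficiency); Gaussian
    noise of ``noise_sd`` cycles is added per technical replicate.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = _rng(seed)
    base = 2.0 * efficiency
    ref_target, ref_ref = 28.0, 20.0
    shift = float(np.log(true_fold) / np.log(base))
    rows = []
    for sample, tgt_ct in ((reference_sample, ref_target),
                           (test_sample, ref_target - shift)):
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append(dict(
                    sample=sample, transcript=transcript, bio_rep=b,
                    tech_rep=t,
                    target_ct=tgt_ct + (rng.normal(0, noise_sd)
                                        if noise_sd else 0.0),
                    reference_ct=ref_ref + (rng.normal(0, noise_sd)
                                            if noise_sd else 0.0),
                    efficiency=efficiency))
    return pd.DataFrame(rows)
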