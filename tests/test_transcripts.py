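"""Element-containing transcripts, maturity calls, variant groups, CDS."""

import numpy as np
import pytest

from sinescan.search import SearchParams
from sinescan.simulate import (
    InsertionPlan,
    SimulationSpec,
    plant_insertions,
    random_sequence,
    simulate_genome,
    simulate_transcripts,
)
from sinescan.seqio import GenomeSet
from sinescan.transcripts import (
    Maturity,
    TranscriptRecord,
    VariantSet,
    cds_impact,
    classify_maturity,
    find_element_transcripts,
    group_variants,
    load_variant_table,
    longest_orf,
    variant_sets_from_table,
)


@pytest.fixture(scope="module")
def retention_sim(consensus):
    spec = SimulationSpec(seed=5, n_chroms=1, chrom_length=200_000, n_genes=8)
    genome, features, _ = simulate_genome(spec)
    mutated, feats, truth = plant_insertions(
        genome, consensus, [InsertionPlan("intron")] * 6,
        features=features, rng=7)
    records, t_truth = simulate_transcripts(
        mutated, feats, truth, retention_prob=1.0, contamination_prob=1.0,
        rng=8)
    return mutated, records, t_truth


def test_element_transcripts_match_retention_truth(retention_sim, consensus):
    """Transcripts retaining an element-containing intron carry a full-span
    hit; fully spliced ones carry none."""
    _, records, truth = retention_sim
    hits = find_element_transcripts(records, consensus)
    want = set(truth[truth.has_element]["transcript_id"])
    assert set(hits) == want
    for tid in (t for t in want if t.endswith(".v2")):
        (hit,) = [h for h in hits[tid] if h.qend - h.qstart > 150]
        assert (hit.qstart, hit.qend) == (0, consensus.length)


def test_split_element_reported_with_partial_coverage(consensus):
    """An element end split away by splicing leaves a flagged partial hit."""
    rng_part = consensus.sequence[:100]
    seq = random_sequence(400, 41) + rng_part
    rec = TranscriptRecord("t1", "g1", seq)
    hits = find_element_transcripts([rec], consensus,
                                    SearchParams(evalue_max=1e-3))
    (hit,) = hits["t1"]
    assert hit.qend - hit.qstart == 100 < consensus.length


def test_maturity_calls_on_simulated_transcripts(retention_sim):
    """Spliced and retained variants map as collinear partial hits (mature);
    genomic slices map as one full-length hit (genomic-like)."""
    genome, records, truth = retention_sim
    by_id = {r.transcript_id: r for r in records}
    want = {"spliced": Maturity.mature, "retained": Maturity.mature,
            "contamination": Maturity.genomic_like}
    for r in truth.itertuples():
        call = classify_maturity(by_id[r.transcript_id], genome)
        assert call.call is want[r.kind], r.transcript_id


def test_verbatim_slice_genomic_like_but_known_single_exon_unresolved():
    """A verbatim genome slice is genomic-like; the same sequence known to
    be a single-exon gene's true transcript stays unresolved (the hit
    structure cannot distinguish the two)."""
    genome_seq = random_sequence(50_000, 17)
    genome = GenomeSet("g", {"c": genome_seq})
    slice_seq = genome_seq[10_000:11_000]
    call = classify_maturity(TranscriptRecord("t", "g1", slice_seq), genome)
    assert call.call is Maturity.genomic_like
    annotated = TranscriptRecord("t2", "g1", slice_seq,
                                 exon_blocks=[(10_000, 11_000)])
    assert classify_maturity(annotated, genome).call is Maturity.unresolved


def test_no_hit_is_unresolved(consensus):
    genome = GenomeSet("g", {"c": random_sequence(20_000, 23)})
    tr = TranscriptRecord("t", "g1", random_sequence(800, 29))
    assert classify_maturity(tr, genome).call is Maturity.unresolved


def test_group_variants_counts_and_invariance(retention_sim, consensus):
    _, records, truth = retention_sim
    hits = find_element_transcripts(records, consensus)
    sets, summary = group_variants(hits.keys(), records)
    want_genes = set(truth[truth.has_element]["gene_id"])
    assert {s.gene_id for s in sets} == want_genes
    for s in sets:
        assert 1 <= s.n_with_element <= s.n_total
    # permutation invariance
    _, summary2 = group_variants(reversed(list(hits.keys())),
                                 list(reversed(records)))
    assert summary == summary2


def test_single_variant_gene():
    rec = TranscriptRecord("t1", "g1", "ACGT" * 50)
    sets, summary = group_variants(["t1"], [rec])
    assert sets[0].n_total == 1 and sets[0].n_with_element == 1
    assert summary["n_multi_variant"] == 0


def test_variant_set_validation():
    with pytest.raises(ValueError):
        VariantSet("g", ["a"], 1, 2)


def test_packaged_variant_table_counts():
    """The packaged splice-variant panel holds 50 multi-variant genes with
    2 to 9 variants each, every one carrying >= 1 element variant."""
    df = load_variant_table()
    sets, summary = variant_sets_from_table(df)
    assert summary["n_genes"] == 50
    assert summary["n_multi_variant"] == 50
    assert summary["min_variants"] == 2
    assert summary["max_variants"] == 9


def test_retention_fraction_recovered_within_binomial_bound(consensus):
    """With retention probability 0.3 planted over ~200 genes, the detected
    fraction of element-containing variant sets lies within 3 binomial
    standard deviations of 0.3."""
    p = 0.3
    spec = SimulationSpec(seed=42, n_chroms=2, chrom_length=800_000,
                          n_genes=200, n_insertions=0)
    genome, features, _ = simulate_genome(spec)
    mutated, feats, truth = plant_insertions(
        genome, consensus, [InsertionPlan("intron")] * 200,
        features=features, rng=43)
    records, t_truth = simulate_transcripts(
        mutated, feats, truth, retention_prob=p, rng=44)
    hits = find_element_transcripts(records, consensus)
    sets, _ = group_variants(hits.keys(), records)
    n_eligible = t_truth["gene_id"].nunique()
    detected = len(sets) / n_eligible
    bound = 3 * np.sqrt(p * (1 - p) / n_eligible)
    assert abs(detected - p) <= bound
    # detection itself is exact: detected sets == genes with retained truth
    assert {s.gene_id for s in sets} \
        == set(t_truth[t_truth.has_element]["gene_id"])


# ---------------------------------------------------------------------------
# CDS impact
# ---------------------------------------------------------------------------

def _with_orf(n_codons, stop=True, lead=7):
    rng = np.random.default_rng(n_codons)
    codons = ["GCT", "GAA", "TGG", "CTT"]
    body = "".join(rng.choice(codons) for _ in range(n_codons - 1))
    return "C" * lead + "ATG" + body + ("TAA" if stop else "GCA") + "CC"


def test_cds_impact_shorter_protein_flag():
    long_t = TranscriptRecord("reg", "g", _with_orf(600), cds_span=(7, 7 + 600 * 3 + 3))
    short_t = TranscriptRecord("el", "g", _with_orf(433), cds_span=(7, 7 + 433 * 3 + 3))
    imp = cds_impact(short_t, (100, 281), counterpart=long_t)
    assert imp.protein_length == 433
    assert imp.counterpart_protein_length == 600
    assert imp.shorter_than_counterpart is True
    assert imp.element_overlaps_cds is True


def test_element_past_stop_does_not_overlap_cds():
    t = TranscriptRecord("v", "g", _with_orf(50) + "T" * 300,
                         cds_span=(7, 7 + 50 * 3 + 3))
    imp = cds_impact(t, (250, 431))
    assert imp.element_overlaps_cds is False
    assert imp.start_codon_in_element is False


def test_start_codon_inside_element():
    t = TranscriptRecord("v", "g", _with_orf(50), cds_span=(7, 7 + 50 * 3 + 3))
    imp = cds_impact(t, (0, 60))
    assert imp.start_codon_in_element is True


def test_incomplete_cds_flagged_and_floored():
    t = TranscriptRecord("v", "g", "C" * 10 + "ATGGCTGA" + "A" * 10,
                         cds_span=(10, 17))  # 7 nt CDS
    imp = cds_impact(t, (0, 5))
    assert imp.incomplete_cds is True
    assert imp.protein_length == 2  # floor(7/3)


def test_longest_orf_fallback():
    seq = _with_orf(40)
    t = TranscriptRecord("v", "g", seq)  # no annotated CDS
    imp = cds_impact(t, (0, 5))
    orf = longest_orf(seq)
    assert orf is not None and seq[orf[0]:orf[0] + 3] == "ATG"
    assert imp.protein_length == (orf[1] - orf[0]) // 3 - 1
    assert longest_orf("CCCCCCCC") is None
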