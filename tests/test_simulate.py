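"""Generator determinism, self-consistency and construction guarantees."""

import pytest

from sinescan.simulate import (
    InsertionPlan,
    SimulationSpec,
    plant_insertions,
    simulate_genome,
    simulate_insertion_site_panel,
    simulate_polyploid,
    simulate_qpcr,
    simulate_transcripts,
)


def test_same_seed_byte_identical():
    spec = SimulationSpec(seed=9, n_chroms=2, chrom_length=60_000, n_genes=6)
    g1, f1, t1 = simulate_genome(spec)
    g2, f2, t2 = simulate_genome(spec)
    assert g1.sequences == g2.sequences
    assert f1.df.equals(f2.df)
    assert t1.equals(t2)


def test_zero_genes_pure_intergenic():
    spec = SimulationSpec(seed=1, n_chroms=1, chrom_length=30_000, n_genes=0)
    g, features, truth = simulate_genome(spec)
    assert len(features) == 0 and truth.empty
    assert len(g.sequences["chr1"]) == 30_000


def test_gene_count_matches_spec():
    spec = SimulationSpec(seed=4, n_chroms=3, chrom_length=200_000, n_genes=31)
    _, features, truth = simulate_genome(spec)
    assert len(features.genes()) == len(truth) == 31


def test_unplaceable_genes_raise():
    spec = SimulationSpec(seed=4, n_chroms=1, chrom_length=20_000, n_genes=50)
    with pytest.raises(ValueError, match="without overlap"):
        simulate_genome(spec)


def test_planted_sequence_self_consistency(consensus):
    """Every truth interval sliced from the emitted genome reproduces the
    planted (possibly truncated) element."""
    spec = SimulationSpec(seed=6, n_chroms=1, chrom_length=120_000, n_genes=8)
    genome, features, _ = simulate_genome(spec)
    plans = [InsertionPlan("intron", tsd_len=9),
             InsertionPlan("exon"),
             InsertionPlan("intergenic", truncation=("5", 30)),
             InsertionPlan("intergenic", truncation=("3", 25))]
    mutated, _, truth = plant_insertions(genome, consensus, plans,
                                         features=features, rng=10)
    for r in truth.itertuples():
        elem = consensus.sequence
        if r.truncation_end == "5":
            elem = elem[r.truncation_nt:]
        elif r.truncation_end == "3":
            elem = elem[:len(elem) - r.truncation_nt]
        assert mutated.sequences[r.chrom][r.start:r.end] == elem
        if r.tsd:
            # duplication: flank5 suffix equals flank3 prefix
            seq = mutated.sequences[r.chrom]
            assert seq[r.start - len(r.tsd):r.start] \
                == seq[r.end:r.end + len(r.tsd)] == r.tsd


def test_truncation_shortens_planted_copy(consensus):
    spec = SimulationSpec(seed=6, n_chroms=1, chrom_length=50_000, n_genes=0)
    genome, _, _ = simulate_genome(spec)
    mutated, _, truth = plant_insertions(
        genome, consensus, [InsertionPlan("intergenic", truncation=("5", 30))],
        features=None, rng=2)
    r = truth.iloc[0]
    assert r["end"] - r["start"] == consensus.length - 30


def test_feature_coordinates_shifted_consistently(consensus):
    """Gene sequences are unchanged by upstream insertions (coordinates
    shift, content does not — except where an element lands inside)."""
    spec = SimulationSpec(seed=12, n_chroms=1, chrom_length=120_000, n_genes=8)
    genome, features, _ = simulate_genome(spec)
    mutated, feats, truth = plant_insertions(
        genome, consensus, [InsertionPlan("intergenic")] * 5,
        features=features, rng=13)
    for (_, old), (_, new) in zip(features.genes().iterrows(),
                                  feats.genes().iterrows()):
        old_seq = genome.sequences[old["chrom"]][old["start"]:old["end"]]
        new_seq = mutated.sequences[new["chrom"]][new["start"]:new["end"]]
        assert old_seq == new_seq


def test_category_unsatisfiable_raises(consensus):
    spec = SimulationSpec(seed=1, n_chroms=1, chrom_length=30_000, n_genes=0)
    genome, features, _ = simulate_genome(spec)
    with pytest.raises(ValueError, match="intron"):
        plant_insertions(genome, consensus, [InsertionPlan("intron")],
                         features=features, rng=1)


def test_polyploid_union_and_map_coverage(trio):
    poly, submap = trio["poly"], trio["submap"]
    assert set(poly.sequences) == set(submap)
    # subgenome chromosomes carry the diploid sequence plus any extras:
    # with zero extra insertions the copy is verbatim
    d_a = trio["diploid_a"]
    poly0, submap0, truth0 = simulate_polyploid(
        [(d_a, trio["truth_a"]), (trio["diploid_d"], trio["truth_d"])],
        ["A", "D"])
    for chrom, seq in d_a.sequences.items():
        assert poly0.sequences[f"A_{chrom}"] == seq
    assert len(truth0) == len(trio["truth_a"]) + len(trio["truth_d"])


def test_polyploid_requires_two_diploids(trio):
    with pytest.raises(ValueError):
        simulate_polyploid([(trio["diploid_a"], trio["truth_a"])], ["A"])


def test_transcript_retention_prob_one_and_zero(consensus):
    spec = SimulationSpec(seed=20, n_chroms=1, chrom_length=150_000, n_genes=6)
    genome, features, _ = simulate_genome(spec)
    mutated, feats, truth = plant_insertions(
        genome, consensus, [InsertionPlan("intron")] * 4,
        features=features, rng=21)
    recs, t_truth = simulate_transcripts(mutated, feats, truth,
                                         retention_prob=1.0, rng=22)
    per_gene = t_truth.groupby("gene_id")["transcript_id"].count()
    el_genes = set(t_truth[t_truth.has_element]["gene_id"])
    for gene, n in per_gene.items():
        assert n == (2 if gene in el_genes else 1)
    recs0, t0 = simulate_transcripts(mutated, feats, truth,
                                     retention_prob=0.0, rng=22)
    assert not t0.has_element.any()


def test_panel_construction_arithmetic(consensus):
    panel, pair, species_of, truth = simulate_insertion_site_panel(
        {"S": [True, False]}, consensus, rng=3, tsd_len=11)
    full = panel["S_1"].sequences["locus"]
    empty = panel["S_2"].sequences["locus"]
    assert len(full) - len(empty) == consensus.length + 11
    assert consensus.sequence in full and consensus.sequence not in empty


def test_qpcr_table_determinism_and_validation():
    a = simulate_qpcr(3.0, seed=5)
    b = simulate_qpcr(3.0, seed=5)
    assert a.equals(b)
    with pytest.raises(ValueError):
        simulate_qpcr(0.0)


def test_spec_validation():
    with pytest.raises(ValueError):
        SimulationSpec(retention_prob=1.5)
    with pytest.raises(ValueError):
        InsertionPlan(tsd_len=3)
    with pytest.raises(ValueError):
        InsertionPlan(truncation=("x", 5))
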