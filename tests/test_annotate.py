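"""Origin classification, exon composition, isoform grouping, summaries."""

import pytest

from circsam.annotate import (
    annotate_catalog,
    classify_origin,
    exon_composition,
    isoform_groups,
    multi_gene_circs,
    percentage,
    summarize_catalog,
)
from circsam.consensus import CircRNA
from circsam.genome import GeneModel, Interval, locus_id


def _circ(chrom, start, end):
    iv = Interval(chrom, start, end, ".")
    return CircRNA(circ_id=locus_id(iv), locus=iv, tools_supporting={"t"})


def _gene5(gene_id="g5", chrom="Chr1"):
    # 5 exons of 100 nt separated by 100-nt introns, starting at 100
    exons = [Interval(chrom, 100 + 200 * i, 200 + 200 * i, "+") for i in range(5)]
    return GeneModel(gene_id=gene_id, chromosome=chrom, strand="+", exons=exons)


def test_exonic_middle_classification():
    gene = _gene5()
    # exons 2-3 span genomic [300, 600)
    ann = classify_origin(_circ("Chr1", 300, 600), [gene])
    assert ann.category == "exonic"
    assert ann.parent_genes == ["g5"]
    assert ann.exon_indices == [2, 3]
    assert ann.exon_position_class == "middle"
    assert ann.exon_count == 2
    assert ann.mature_length_nt == 200
    assert ann.genomic_span_nt == 300


def test_intronic_and_intergenic():
    gene = _gene5()
    intronic = classify_origin(_circ("Chr1", 210, 290), [gene])
    assert intronic.category == "intronic" and intronic.parent_genes == ["g5"]
    desert = classify_origin(_circ("Chr1", 5000, 5400), [gene])
    assert desert.category == "intergenic" and desert.parent_genes == []


def test_unannotated_chromosome_warns():
    gene = _gene5()
    with pytest.warns(UserWarning):
        ann = classify_origin(_circ("ChrX", 10, 50), [gene])
    assert ann.category == "intergenic"


def test_exon_composition_classes():
    gene = _gene5()
    first = exon_composition(Interval("Chr1", 100, 200), gene)
    assert first == (1, "first", 100)
    last = exon_composition(Interval("Chr1", 900, 1000), gene)
    assert last[1] == "last"
    mixed = exon_composition(Interval("Chr1", 100, 1000), gene)
    assert mixed == (5, "mixed", 500)
    single = GeneModel(
        gene_id="s1", chromosome="Chr1", strand="+",
        exons=[Interval("Chr1", 0, 150, "+")],
    )
    assert exon_composition(Interval("Chr1", 0, 150), single)[1] == "single_exon_gene"
    with pytest.raises(ValueError):
        exon_composition(Interval("Chr1", 210, 290), gene)  # intron only


def test_multi_gene_detection():
    a = _gene5("ga")
    b = GeneModel(
        gene_id="gb", chromosome="Chr1", strand="+",
        exons=[Interval("Chr1", 1100, 1200, "+"), Interval("Chr1", 1300, 1400, "+")],
    )
    ann = classify_origin(_circ("Chr1", 900, 1200), [a, b])
    assert sorted(ann.parent_genes) == ["ga", "gb"]
    assert ann in multi_gene_circs([ann])
    solo = classify_origin(_circ("Chr1", 300, 600), [a, b])
    assert multi_gene_circs([solo]) == []


def test_isoform_groups():
    a = _gene5("ga")
    anns = [
        classify_origin(_circ("Chr1", 300, 600), [a]),
        classify_origin(_circ("Chr1", 500, 800), [a]),
    ]
    assert isoform_groups(anns) == {2: 1}
    assert isoform_groups([]) == {}


def test_percentage_rounding():
    assert percentage(354, 384) == 92.19
    assert percentage(1, 1) == 100.0
    with pytest.raises(ValueError):
        percentage(1, 0)


def test_summary_percentages_sum(sim_default):
    from circsam.consensus import filter_supported, merge_tools_and_conditions, read_calls

    calls = read_calls(sim_default.paths["calls_dir"])
    design = {c: {"r1", "r2", "r3"} for c in sim_default.config.conditions}
    catalog, _ = merge_tools_and_conditions(filter_supported(calls, design))
    anns = annotate_catalog(catalog, sim_default.genes)
    summary = summarize_catalog(anns)
    assert abs(sum(summary["category_percent"].values()) - 100.0) <= 0.02
    assert sum(summary["category_counts"].values()) == summary["n"]
    for a in anns:
        assert a.mature_length_nt <= a.genomic_span_nt


def test_truth_exon_counts_recovered(sim_default):
    from circsam.consensus import filter_supported, merge_tools_and_conditions, read_calls

    calls = read_calls(sim_default.paths["calls_dir"])
    design = {c: {"r1", "r2", "r3"} for c in sim_default.config.conditions}
    catalog, _ = merge_tools_and_conditions(filter_supported(calls, design))
    anns = {a.circ_id: a for a in annotate_catalog(catalog, sim_default.genes)}
    for t in sim_default.circ_truth:
        a = anns.get(t.circ_id)
        assert a is not None
        assert a.category == "exonic"
        assert a.exon_count == t.exon_count
        assert a.mature_length_nt == t.mature_length
        if len(t.gene_ids) == 1:
            assert a.parent_genes == t.gene_ids
            assert a.exon_indices == t.exon_indices
        else:
            assert sorted(a.parent_genes) == sorted(t.gene_ids)
    # planted multi-gene circs are detected as such
    truth_multi = {t.circ_id for t in sim_default.circ_truth if len(t.gene_ids) >= 2}
    found_multi = {a.circ_id for a in multi_gene_circs(list(anns.values()))}
    assert truth_multi <= found_multi
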