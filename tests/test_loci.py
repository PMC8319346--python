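"""Anchor-based locus delineation and the tailocin keyword heuristic."""

import logging

import pytest

import tailoseq as ts
from tailoseq.errors import AmbiguousAnchorError, AnchorNotFoundError, SplitLocusError
from tailoseq.loci import DEFAULT_ANCHORS, KeywordConfig
from tailoseq.simulate import pao1_ortholog_map


def _contig(specs, contig="c1", start=1):
    """specs: list of (locus_tag, name) or (locus_tag, name, product)."""
    genes = []
    pos = start
    for spec in specs:
        tag, name = spec[0], spec[1]
        product = spec[2] if len(spec) > 2 else ""
        genes.append(
            ts.Gene(locus_tag=tag, contig=contig, start=pos, end=pos + 899,
                    strand="+", product=product, name=name)
        )
        pos += 1000
    return genes


def _genome(specs, strain="toy", **kwargs):
    return ts.AnnotatedGenome(strain=strain, contigs={"c1": _contig(specs, **kwargs)})


MUTS, CINA = DEFAULT_ANCHORS["tailocin"]


def test_forward_region_between_anchors():
    specs = [("t0", "mutS")] + [(f"t{i}", None) for i in range(1, 13)] + [("t13", "cinA")]
    region = ts.find_anchor_region(_genome(specs), MUTS, CINA)
    assert region.locus_tags() == [f"t{i}" for i in range(1, 13)]
    assert "t0" not in region.locus_tags() and "t13" not in region.locus_tags()
    # 12 genes of 900 bp with 100 bp gaps, plus the two flanking gaps
    assert region.length_bp == 12 * 1000 + 100


def test_reversed_anchor_order_is_orientation_free():
    region = ts.find_anchor_region(
        _genome([("a", "cinA"), ("b", None), ("c", "mutS")]), MUTS, CINA
    )
    assert region.locus_tags() == ["b"]


def test_contig_flip_invariance():
    specs = [("t0", "mutS"), ("t1", None), ("t2", None), ("t3", "cinA")]
    fwd = ts.find_anchor_region(_genome(specs), MUTS, CINA)
    flipped = _genome(list(reversed(specs)))
    rev = ts.find_anchor_region(flipped, MUTS, CINA)
    assert set(fwd.locus_tags()) == set(rev.locus_tags())
    assert fwd.length_bp == rev.length_bp


def test_anchor_error_paths():
    with pytest.raises(AnchorNotFoundError):
        ts.find_anchor_region(_genome([("a", "mutS"), ("b", None)]), MUTS, CINA)
    with pytest.raises(AmbiguousAnchorError):
        ts.find_anchor_region(
            _genome([("a", "mutS"), ("b", "mutS"), ("c", "cinA")]), MUTS, CINA
        )
    split = ts.AnnotatedGenome(
        strain="toy",
        contigs={"c1": _contig([("a", "mutS")]), "c2": _contig([("b", "cinA")], contig="c2")},
    )
    with pytest.raises(SplitLocusError):
        ts.find_anchor_region(split, MUTS, CINA)


def test_tailocin_keyword_classification():
    structural = ["tail fiber protein", "tail sheath", "tail tube", "baseplate protein",
                  "tail spike", "holin"]
    specs = [(f"t{i}", None, structural[i] if i < 6 else "hypothetical protein") for i in range(12)]
    region = ts.LocusRegion("tailocin", "toy", _contig(specs))
    positive, labels = ts.classify_tailocin_region(region)
    assert positive
    assert labels["t0"] == "structural" and labels["t11"] == "other"

    # one capsid gene flips the call: intact prophage, not a tailocin
    specs_capsid = specs[:-1] + [("t11", None, "major capsid protein")]
    region2 = ts.LocusRegion("tailocin", "toy", _contig(specs_capsid))
    positive2, labels2 = ts.classify_tailocin_region(region2)
    assert not positive2 and labels2["t11"] == "forbidden"

    # too few genes
    small = ts.LocusRegion("tailocin", "toy", _contig(specs[:5]))
    assert not ts.classify_tailocin_region(small)[0]
    # empty region is negative, not an error
    assert not ts.classify_tailocin_region(ts.LocusRegion("tailocin", "toy", []))[0]


def test_delineate_all_recovers_generator_truth():
    for seed in range(1, 4):
        cfg = ts.PanelConfig(n_strains=6, n_clades=3, seed=seed)
        genomes, _, truth = ts.generate_strain_panel(cfg)
        for genome in genomes:
            regions = ts.delineate_all(genome, pao1_ortholog_map())
            assert regions["tailocin"].is_tailocin_positive
            assert ts.osa_orthogroup_set(regions["OSA"]) == set(truth["osa_sets"][genome.strain])
            assert len(regions["core"].genes) == 16
            assert len(regions["CPA"].genes) == 13


def test_missing_osa_anchor_warns_and_omits(caplog):
    specs = [("a", "mutS")] + [(f"t{i}", None, "tail protein") for i in range(12)] + [("z", "cinA")]
    genome = _genome(specs)  # no ihfB/wbpM anywhere
    with caplog.at_level(logging.WARNING):
        regions = ts.delineate_all(genome)
    assert "OSA" not in regions and "tailocin" in regions
    assert any("OSA" in rec.message for rec in caplog.records)


def test_include_3prime_anchor_adds_wbpm():
    cfg = ts.PanelConfig(n_strains=2, n_clades=1, seed=1)
    genomes, _, _ = ts.generate_strain_panel(cfg)
    base = ts.delineate_all(genomes[0])["OSA"]
    extended = ts.delineate_all(genomes[0], include_3prime_anchor=True)["OSA"]
    assert len(extended.genes) == len(base.genes) + 1
    assert extended.genes[-1].name == "wbpM"


def test_osa_orthogroup_set_semantics():
    genes = [
        ts.Gene("x1", "c1", 1, 900, orthogroup="OG1"),
        ts.Gene("x2", "c1", 1001, 1900, orthogroup="OG1"),
        ts.Gene("x3", "c1", 2001, 2900, orthogroup="OG2"),
        ts.Gene("x4", "c1", 3001, 3900, orthogroup=None),
    ]
    region = ts.LocusRegion("OSA", "toy", genes)
    assert ts.osa_orthogroup_set(region) == {"OG1", "OG2", "singleton:x4"}
    assert ts.osa_orthogroup_set(ts.LocusRegion("OSA", "toy", [])) == set()
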