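"""Delineation of tailocin and LPS biosynthetic gene clusters.

Tailocin clusters sit between the conserved genes *mutS* and *cinA*, a
known prophage integration hotspot; the O-specific antigen (OSA) cluster
is bounded by *himD*/*ihfB* on the 5' side and *wbpM* on the 3' side.
LPS-core and common-polysaccharide-antigen (CPA) clusters are defined by
orthology to the P. aeruginosa PAO1 reference ranges PA4997-PA5012 and
PA5447-PA5459 rather than by flanking anchors. A candidate region
between mutS and cinA is classified as tailocin-encoding with a keyword
heuristic: enough genes with phage-structural products (tail, sheath,
tube, baseplate, fiber, spike, lysis, holin), and none annotated as
capsid, terminase, integrase or portal — the gene complement that
separates a headless tailocin from an intact prophage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import AmbiguousAnchorError, AnchorNotFoundError, SplitLocusError

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "AnnotatedGenome",
    "LocusRegion",
    "AnchorSpec",
    "KeywordConfig",
    "DEFAULT_ANCHORS",
    "find_anchor_region",
    "classify_tailocin_region",
    "delineate_all",
    "osa_orthogroup_set",
]


@dataclass(frozen=True)
class Gene:
    """One gene model; coordinates 1-based inclusive."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    orthogroup: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start {self.start} > end {self.end}")


@dataclass
class AnnotatedGenome:
    """Ordered gene models per contig for one strain."""

    strain: str
    contigs: dict[str, list[Gene]]

    def __post_init__(self) -> None:
        for name, genes in self.contigs.items():
            self.contigs[name] = sorted(genes, key=lambda g: (g.start, g.end))

    def all_genes(self) -> list[Gene]:
        return [g for genes in self.contigs.values() for g in genes]


@dataclass
class LocusRegion:
    """A delineated cluster: tailocin, OSA, core or CPA."""

    region_type: str
    strain: str
    genes: list[Gene]
    anchors: tuple[str, str] | None = None
    length_bp: int = 0
    is_tailocin_positive: bool | None = None

    def locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.genes]


@dataclass(frozen=True)
class AnchorSpec:
    """An anchor gene, matched by any of its names or by orthogroup id."""

    names: frozenset[str] = frozenset()
    orthogroup: str | None = None
    label: str = ""

    def matches(self, gene: Gene) -> bool:
        if gene.name is not None and gene.name.lower() in self.names:
            return True
        return self.orthogroup is not None and gene.orthogroup == self.orthogroup


def anchor(*names: str, orthogroup: str | None = None) -> AnchorSpec:
    return AnchorSpec(
        names=frozenset(n.lower() for n in names), orthogroup=orthogroup, label=names[0] if names else str(orthogroup)
    )


DEFAULT_ANCHORS: dict[str, tuple[AnchorSpec, AnchorSpec]] = {
    "tailocin": (anchor("mutS"), anchor("cinA")),
    "OSA": (anchor("himD", "ihfB"), anchor("wbpM")),
}


def find_anchor_region(
    genome: AnnotatedGenome, anchor_a: AnchorSpec, anchor_b: AnchorSpec, region_type: str = "region"
) -> LocusRegion:
    """All genes strictly between two single-copy anchor genes.

    Orientation-free: either anchor may come first on the contig, and
    strands are ignored. The anchors themselves are excluded.
    ``length_bp`` spans from the end of the upstream anchor + 1 to the
    start of the downstream anchor - 1.
    """
    hits: dict[int, list[Gene]] = {0: [], 1: []}
    for gene in genome.all_genes():
        for i, spec in enumerate((anchor_a, anchor_b)):
            if spec.matches(gene):
                hits[i].append(gene)
    for i, spec in zip(hits, (anchor_a, anchor_b)):
        if not hits[i]:
            raise AnchorNotFoundError(f"{genome.strain}: anchor {spec.label!r} not found")
        if len(hits[i]) > 1:
            tags = [g.locus_tag for g in hits[i]]
            raise AmbiguousAnchorError(f"{genome.strain}: anchor {spec.label!r} duplicated ({tags})")
    ga, gb = hits[0][0], hits[1][0]
    if ga.contig != gb.contig:
        raise SplitLocusError(
            f"{genome.strain}: anchors {anchor_a.label!r}/{anchor_b.label!r} on different contigs"
        )
    upstream, downstream = (ga, gb) if ga.start <= gb.start else (gb, ga)
    between = [
        g
        for g in genome.contigs[ga.contig]
        if g.start > upstream.end and g.end < downstream.start
    ]
    return LocusRegion(
        region_type=region_type,
        strain=genome.strain,
        genes=between,
        anchors=(ga.locus_tag, gb.locus_tag),
        length_bp=max(0, (downstream.start - 1) - (upstream.end + 1) + 1),
    )


@dataclass(frozen=True)
class KeywordConfig:
    """Keyword heuristic separating tailocin loci from intact prophages."""

    structural: tuple[str, ...] = (
        "tail", "sheath", "tube", "baseplate", "fiber", "fibre", "spike", "lysis", "holin", "phage",
    )
    forbidden: tuple[str, ...] = ("capsid", "terminase", "integrase", "portal")
    min_genes: int = 10
    min_structural_fraction: float = 0.25


def classify_tailocin_region(
    region: LocusRegion, keywords: KeywordConfig = KeywordConfig()
) -> tuple[bool, dict[str, str]]:
    """Flag a mutS-cinA candidate region as tailocin-encoding or not.

    Returns ``(positive, labels)`` where ``labels`` maps each locus_tag
    to ``"structural"``, ``"forbidden"`` or ``"other"``. Positive
    requires enough genes, a sufficient structural-keyword fraction, and
    no forbidden (head/lysogeny) products.
    """
    labels: dict[str, str] = {}
    n_structural = 0
    any_forbidden = False
    for gene in region.genes:
        product = gene.product.lower()
        if any(k in product for k in keywords.forbidden):
            labels[gene.locus_tag] = "forbidden"
            any_forbidden = True
        elif any(k in product for k in keywords.structural):
            labels[gene.locus_tag] = "structural"
            n_structural += 1
        else:
            labels[gene.locus_tag] = "other"
    n = len(region.genes)
    positive = (
        n >= keywords.min_genes
        and not any_forbidden
        and n > 0
        and n_structural / n >= keywords.min_structural_fraction
    )
    return positive, labels


def _orthology_region(genome: AnnotatedGenome, orthogroups: set[str], region_type: str) -> LocusRegion | None:
    genes = [g for g in genome.all_genes() if g.orthogroup in orthogroups]
    if not genes:
        return None
    genes = sorted(genes, key=lambda g: (g.contig, g.start))
    span = genes[-1].end - genes[0].start + 1 if genes[0].contig == genes[-1].contig else 0
    return LocusRegion(region_type=region_type, strain=genome.strain, genes=genes, length_bp=span)


def delineate_all(
    genome: AnnotatedGenome,
    pao1_map: dict[str, str] | None = None,
    anchors: dict[str, tuple[AnchorSpec, AnchorSpec]] | None = None,
    keywords: KeywordConfig = KeywordConfig(),
    include_3prime_anchor: bool = False,
) -> dict[str, LocusRegion]:
    """Extract tailocin, OSA, core and CPA regions from one genome.

    ``pao1_map`` maps PAO1 locus tags to orthogroup ids; core/CPA
    regions are the genes carrying those orthogroups (an
    orthology-defined set, not an anchor span). A cluster whose anchors
    or orthologs are absent is omitted with a logged warning.
    ``include_3prime_anchor`` appends the 3' OSA anchor (wbpM) itself to
    the OSA gene list.
    """
    anchors = anchors or DEFAULT_ANCHORS
    out: dict[str, LocusRegion] = {}
    for region_type, (spec_a, spec_b) in anchors.items():
        try:
            region = find_anchor_region(genome, spec_a, spec_b, region_type=region_type)
        except (AnchorNotFoundError, AmbiguousAnchorError, SplitLocusError) as exc:
            logger.warning("%s: %s region omitted: %s", genome.strain, region_type, exc)
            continue
        if region_type == "tailocin":
            region.is_tailocin_positive, _ = classify_tailocin_region(region, keywords)
        if region_type == "OSA" and include_3prime_anchor:
            tag = region.anchors[1]
            wbpm = next(g for g in genome.all_genes() if g.locus_tag == tag)
            region.genes = region.genes + [wbpm]
        out[region_type] = region

    if pao1_map:
        core_ogs = {og for tag, og in pao1_map.items() if "PA4997" <= tag <= "PA5012"}
        cpa_ogs = {og for tag, og in pao1_map.items() if "PA5447" <= tag <= "PA5459"}
        for region_type, ogs in (("core", core_ogs), ("CPA", cpa_ogs)):
            region = _orthology_region(genome, ogs, region_type)
            if region is None:
                logger.warning("%s: %s region omitted: no orthologs found", genome.strain, region_type)
            else:
                out[region_type] = region
    return out


def osa_orthogroup_set(region: LocusRegion) -> set[str]:
    """Presence/absence orthogroup set of an OSA region.

    Genes without an orthogroup assignment become singleton
    pseudo-orthogroups named ``singleton:<locus_tag>`` so private genes
    still count in Jaccard unions.
    """
    return {
        g.orthogroup if g.orthogroup is not None else f"singleton:{g.locus_tag}"
        for g in region.genes
    }
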