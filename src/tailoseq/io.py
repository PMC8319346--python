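"""Readers and writers for every file format the pipeline touches.

Dialects: tables are UTF-8, tab-separated with a header row; ``#``
starts a comment line. GFF3 follows the v3 spec (1-based inclusive
coordinates); protein FASTA ids are locus tags; orthogroup membership
uses the OrthoFinder ``Orthogroups.tsv`` dialect (first column the
orthogroup id, then one comma-separated member column per strain).
Validation failures raise :class:`~tailoseq.errors.FormatError` naming
the offending line or cell.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .loci import AnnotatedGenome, Gene
from .osa import Dendrogram

__all__ = [
    "read_pool", "write_pool",
    "read_counts", "write_counts",
    "read_samples", "write_samples",
    "read_orthogroups", "write_orthogroups", "annotate_orthogroups",
    "read_genome_gff", "write_genome_gff",
    "read_proteins", "write_proteins",
    "read_matrix_csv", "write_matrix_csv",
    "read_empai", "write_empai",
    "read_newick", "write_newick",
    "read_json", "write_json",
]

_BARCODE_RE = re.compile(r"^[ACGT]+$")

POOL_COLUMNS = ["barcode", "scaffold", "strand", "pos", "locus_tag", "gene_fraction"]
SAMPLE_COLUMNS = ["sample", "condition", "replicate", "is_time0", "tailocin_source", "time0_sample"]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs)


def _require(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_pool(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, POOL_COLUMNS, path)
    for i, bc in enumerate(df["barcode"]):
        if not _BARCODE_RE.match(bc):
            raise FormatError(f"{path}: line {i + 2}: barcode {bc!r} not over A/C/G/T")
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate barcode {dup!r}")
    df["pos"] = df["pos"].astype(int)
    df["gene_fraction"] = df["gene_fraction"].astype(float)
    if ((df["gene_fraction"] < 0) | (df["gene_fraction"] > 1)).any():
        bad = df.index[(df["gene_fraction"] < 0) | (df["gene_fraction"] > 1)][0]
        raise FormatError(f"{path}: line {bad + 2}: gene_fraction outside [0, 1]")
    return df[POOL_COLUMNS]


def write_pool(pool: pd.DataFrame, path: str | Path) -> None:
    pool[POOL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "barcode":
        raise FormatError(f"{path}: first column must be 'barcode'")
    df = df.set_index("barcode")
    out = {}
    for col in df.columns:
        try:
            values = pd.to_numeric(df[col])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in column {col!r}: {exc}") from exc
        neg = values < 0
        if neg.any():
            bc = values.index[neg][0]
            raise FormatError(f"{path}: negative count at barcode {bc!r}, sample {col!r}")
        if (values % 1 != 0).any():
            bc = values.index[values % 1 != 0][0]
            raise FormatError(f"{path}: non-integer count at barcode {bc!r}, sample {col!r}")
        out[col] = values.astype(int)
    return pd.DataFrame(out, index=df.index)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="barcode")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, SAMPLE_COLUMNS, path)
    df["replicate"] = df["replicate"].astype(int)
    df["is_time0"] = df["is_time0"].map(
        {"True": True, "False": False, "1": True, "0": False, "true": True, "false": False}
    )
    if df["is_time0"].isna().any():
        raise FormatError(f"{path}: is_time0 must be boolean")
    return df[SAMPLE_COLUMNS]


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthogroups (OrthoFinder Orthogroups.tsv dialect)
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path) -> dict[str, dict[str, str]]:
    """Return {strain: {locus_tag: orthogroup id}}."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: orthogroup table needs an id column plus >=1 strain column")
    og_col = df.columns[0]
    out: dict[str, dict[str, str]] = {strain: {} for strain in df.columns[1:]}
    for _, row in df.iterrows():
        og = row[og_col]
        for strain in df.columns[1:]:
            cell = row[strain].strip()
            if not cell:
                continue
            for tag in cell.split(","):
                out[strain][tag.strip()] = og
    return out


def write_orthogroups(genomes: list[AnnotatedGenome], path: str | Path) -> None:
    """Write the orthogroup membership of a genome list, OrthoFinder style."""
    membership: dict[str, dict[str, list[str]]] = {}
    for genome in genomes:
        for gene in genome.all_genes():
            if gene.orthogroup is None:
                continue
            membership.setdefault(gene.orthogroup, {}).setdefault(genome.strain, []).append(gene.locus_tag)
    strains = [g.strain for g in genomes]
    rows = []
    for og in sorted(membership):
        rows.append([og] + [", ".join(membership[og].get(s, [])) for s in strains])
    pd.DataFrame(rows, columns=["Orthogroup"] + strains).to_csv(path, sep="\t", index=False)


def annotate_orthogroups(genome: AnnotatedGenome, mapping: dict[str, str]) -> AnnotatedGenome:
    """Return a copy of ``genome`` with orthogroup ids from {locus_tag: og}."""
    contigs = {
        name: [dataclasses.replace(g, orthogroup=mapping.get(g.locus_tag, g.orthogroup)) for g in genes]
        for name, genes in genome.contigs.items()
    }
    return AnnotatedGenome(strain=genome.strain, contigs=contigs)


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA
# ---------------------------------------------------------------------------

def write_genome_gff(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, genes in genome.contigs.items():
            for g in genes:
                attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
                if g.name:
                    attrs.append(f"gene={g.name}")
                if g.product:
                    attrs.append(f"product={g.product}")
                if g.orthogroup:
                    attrs.append(f"orthogroup={g.orthogroup}")
                fh.write(
                    "\t".join(
                        [contig, "tailoseq", "gene", str(g.start), str(g.end), ".", g.strand, ".", ";".join(attrs)]
                    )
                    + "\n"
                )


def read_genome_gff(path: str | Path, strain: str | None = None) -> AnnotatedGenome:
    """Parse gene/CDS features; features without a locus_tag are skipped."""
    import logging

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    contigs: dict[str, list[Gene]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        tags = feat.attributes.get("locus_tag")
        if not tags:
            logging.getLogger(__name__).warning("%s: feature without locus_tag skipped at %s:%d",
                                                path, feat.seqid, feat.start)
            continue
        if feat.start > feat.end:
            raise FormatError(f"{path}: feature {tags[0]}: start > end")
        gene = Gene(
            locus_tag=tags[0],
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            product=feat.attributes.get("product", [""])[0],
            orthogroup=(feat.attributes.get("orthogroup") or [None])[0],
            name=(feat.attributes.get("gene") or [None])[0],
        )
        contigs.setdefault(feat.seqid, []).append(gene)
    return AnnotatedGenome(strain=strain or Path(path).stem, contigs=contigs)


def write_proteins(genome: AnnotatedGenome, path: str | Path, sequences: dict[str, str] | None = None) -> None:
    """Protein FASTA, ids = locus tags; placeholder sequences by default."""
    records = []
    for g in genome.all_genes():
        seq = (sequences or {}).get(g.locus_tag) or "M" + "A" * 29
        records.append(SeqRecord(Seq(seq), id=g.locus_tag, description=g.product))
    SeqIO.write(records, str(path), "fasta")


def read_proteins(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# matrices, emPAI, newick, JSON
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label=matrix.index.name or "strain")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_empai(table: pd.DataFrame, path: str | Path) -> None:
    table[["protein", "sample", "empai", "is_tailocin"]].to_csv(path, sep="\t", index=False)


def read_empai(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require(df, ["protein", "sample", "empai", "is_tailocin"], path)
    df["empai"] = df["empai"].astype(float)
    df["is_tailocin"] = df["is_tailocin"].map(
        {"True": True, "False": False, "1": True, "0": False, "true": True, "false": False}
    )
    if df["is_tailocin"].isna().any():
        raise FormatError(f"{path}: is_tailocin must be boolean")
    return df


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def read_newick(path: str | Path) -> Dendrogram:
    return Dendrogram.from_newick(Path(path).read_text())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
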