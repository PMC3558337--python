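"""Reading and writing genomes, feature tables, and gene orders.

Three annotation formats are supported losslessly:

* a GFF3 dialect (1-based inclusive, per the standard) with ``gene_class``,
  ``start_codon``, ``stop_codon`` and ``anticodon`` attributes;
* a compact TSV dialect mirroring published mitogenome organization tables:
  ``gene  class  start  end  strand  start_codon  stop_codon [anticodon]``;
* FASTA for single-record genome sequences (via Biopython).

Two transcriptions of published annotation tables ship with the package as
layout templates: ``bxylophilus_table1.tsv`` (14,778 bp pine wood nematode
mitogenome) and ``pvulnus_table1.tsv`` (21,656 bp walnut root-lesion
nematode mitogenome).
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import CANONICAL_GENES
from .genome import CircularGenome, FeatureTable, GeneFeature

PathLike = Union[str, Path]

#: declared genome lengths of the packaged annotation templates
TEMPLATE_LENGTHS = {"bxylophilus": 14778, "pvulnus": 21656}


class ParseError(ValueError):
    """Malformed annotation line, with 1-based line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_genome(path: PathLike, topology: str = "circular") -> CircularGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return CircularGenome(id=rec.id, residues=str(rec.seq), topology=topology)


def write_genome(genome: CircularGenome, path: PathLike):
    rec = SeqRecord(Seq(genome.residues), id=genome.id, description=f"topology={genome.topology}")
    SeqIO.write([rec], str(path), "fasta")


_MISSING = (".", "", "-")


def _clean(token: str) -> Optional[str]:
    return None if token in _MISSING else token


def read_table_tsv(path: PathLike, genome_id: Optional[str] = None) -> FeatureTable:
    """Read the tabular annotation dialect (tab-separated, '#' comments)."""
    feats = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "gene":  # header
                continue
            if len(cols) < 5:
                raise ParseError(path, lineno, f"expected >=5 columns, found {len(cols)}")
            name, klass = cols[0], cols[1]
            try:
                start, end = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from None
            if start < 1 or end < 1:
                raise ParseError(path, lineno, f"coordinates must be >= 1, got {start}, {end}")
            strand = cols[4]
            start_codon = _clean(cols[5]) if len(cols) > 5 else None
            stop_codon = _clean(cols[6]) if len(cols) > 6 else None
            anticodon = _clean(cols[7]) if len(cols) > 7 else None
            if klass != "NCR" and name not in CANONICAL_GENES:
                warnings.warn(f"{path}:{lineno}: unknown gene name {name!r}")
            try:
                feats.append(GeneFeature(name, klass, start, end, strand,
                                         start_codon, stop_codon, anticodon))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return FeatureTable(genome_id or path.stem, feats)


def write_table_tsv(table: FeatureTable, path_or_handle):
    def fmt(f: GeneFeature) -> str:
        return "\t".join([
            f.name, f.klass, str(f.start), str(f.end), f.strand,
            f.start_codon or ".", f.stop_codon or ".", f.anticodon or ".",
        ])

    header = "gene\tclass\tstart\tend\tstrand\tstart_codon\tstop_codon\tanticodon"
    lines = [header] + [fmt(f) for f in table.features]
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        Path(path_or_handle).write_text(text)


_GFF_TYPES = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "NCR": "region"}


def write_gff3(table: FeatureTable, path: PathLike):
    lines = ["##gff-version 3"]
    for f in table.features:
        attrs = [f"ID={f.name}", f"gene_class={f.klass}"]
        for key in ("start_codon", "stop_codon", "anticodon"):
            val = getattr(f, key)
            if val:
                attrs.append(f"{key}={val}")
        lines.append("\t".join([
            table.genome_id, "mitocomp", _GFF_TYPES.get(f.klass, "region"),
            str(f.start), str(f.end), ".", f.strand, ".", ";".join(attrs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: PathLike) -> FeatureTable:
    feats = []
    genome_id = None
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, found {len(cols)}")
            genome_id = genome_id or cols[0]
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from None
            if start < 1 or end < 1:
                raise ParseError(path, lineno, "GFF3 coordinates are 1-based; found < 1")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            name = attrs.get("ID")
            if not name:
                raise ParseError(path, lineno, "missing ID attribute")
            klass = attrs.get("gene_class")
            if klass is None:
                raise ParseError(path, lineno, "missing gene_class attribute")
            if klass != "NCR" and name not in CANONICAL_GENES:
                warnings.warn(f"{path}:{lineno}: unknown gene name {name!r}")
            try:
                feats.append(GeneFeature(
                    name, klass, start, end, cols[6],
                    attrs.get("start_codon"), attrs.get("stop_codon"), attrs.get("anticodon"),
                ))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    if genome_id is None:
        raise ValueError(f"{path}: no features found")
    return FeatureTable(genome_id, feats)


def read_feature_table(path: PathLike) -> FeatureTable:
    """Dispatch on extension: .gff/.gff3 vs tabular dialect."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    return read_table_tsv(path)


def load_template_table(species: str) -> FeatureTable:
    """Packaged annotation template: ``bxylophilus`` or ``pvulnus``."""
    if species not in TEMPLATE_LENGTHS:
        raise KeyError(f"unknown template {species!r}; choose from {sorted(TEMPLATE_LENGTHS)}")
    ref = resources.files("mitocomp.data") / f"{species}_table1.tsv"
    with resources.as_file(ref) as p:
        return read_table_tsv(p, genome_id=species)


def load_codon_usage_counts() -> pd.DataFrame:
    """Published per-codon counts and percentages for both template genomes.

    Columns: codon, aa, bx_count, pv_count, bx_pct, pv_pct.
    """
    ref = resources.files("mitocomp.data") / "codon_usage_counts.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"codon": str, "aa": str})


def read_gene_orders(path: PathLike) -> dict:
    """Gene-order file: ``genome_id<TAB>comma-separated gene labels`` per line."""
    orders = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genome_id, genes = line.split("\t")
            orders[genome_id] = tuple(g.strip() for g in genes.split(","))
    return orders


def write_gene_orders(orders: dict, path: PathLike):
    lines = [f"{gid}\t{','.join(genes)}" for gid, genes in orders.items()]
    Path(path).write_text("\n".join(lines) + "\n")
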