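"""Genome representation, native-format I/O and standard-format importers.

The native representation of a genome is an ordered list of protein-coding
genes per chromosome (or scaffold — treated identically), serialized as a
tab-separated gene table plus a protein FASTA keyed by gene id.  Gene order
is the coordinate system every downstream stage ranks against: ranks are
0-based consecutive integers in table-row order within each chromosome.
Nucleotide coordinates are 1-based inclusive (GenBank convention) and
optional, as are strands and non-coding features.

Importers convert GenBank / EMBL flat files and structured-header FASTA
into the native pair of files so that :func:`read_genome` round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

STRANDS = ("+", "-", ".")

GENE_TABLE_COLUMNS = ("chromosome", "id", "start", "end", "strand")
PAIRS_COLUMNS = ("genomeA_gene", "genomeB_gene", "kind", "similarity_pct",
                 "match_len", "lenA", "lenB", "syntenic")
BLOCKS_BLOCK_PREFIX = "#BLOCK"


@dataclass
class Gene:
    """A protein-coding gene at a fixed position in its chromosome's order."""

    id: str
    genome_id: str
    chromosome: str
    rank: int
    protein: str
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"gene {self.id!r}: empty protein sequence")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id!r}: bad strand {self.strand!r}")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError(f"gene {self.id!r}: end < start")

    @property
    def length(self) -> int:
        return len(self.protein)


@dataclass
class Feature:
    """A non-coding annotation (tRNA, pseudogene, LTR, ...)."""

    id: str
    kind: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"feature {self.id!r}: end < start")


@dataclass
class Genome:
    """Ordered genes per chromosome plus optional features and centromeres."""

    id: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, Gene] = {}
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g.rank != i:
                    raise ValueError(
                        f"genome {self.id!r}: rank {g.rank} of gene {g.id!r} on "
                        f"{chrom!r} is not consecutive (expected {i})")
                if g.id in self._index:
                    raise ValueError(f"genome {self.id!r}: duplicate gene id {g.id!r}")
                self._index[g.id] = g

    def genes(self) -> Iterator[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def chromosome_nt_length(self, chrom: str) -> Optional[int]:
        ends = [g.end for g in self.chromosomes[chrom] if g.end is not None]
        fends = [f.end for f in self.features if f.chromosome == chrom]
        ends.extend(fends)
        return max(ends) if ends else None


def _parse_opt_int(text: str) -> Optional[int]:
    text = text.strip()
    return None if text in ("", ".") else int(text)


def read_genome(gene_table_path: str | os.PathLike,
                protein_fasta_path: str | os.PathLike,
                genome_id: Optional[str] = None) -> Genome:
    """Read the native gene table + protein FASTA into a :class:`Genome`.

    Ranks are assigned by table-row order within each chromosome; rows of
    different chromosomes may be interleaved.  Every table row must have a
    FASTA sequence and vice versa.
    """
    gene_table_path = Path(gene_table_path)
    if genome_id is None:
        genome_id = gene_table_path.stem.removesuffix(".genes")
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
        gid = rec.id.split("|")[0]
        proteins[gid] = str(rec.seq).rstrip("*")

    chromosomes: dict[str, list[Gene]] = {}
    seen: set[str] = set()
    with open(gene_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_TABLE_COLUMNS:
            raise ValueError(f"bad gene-table header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            chrom, gid, start, end, strand = line.rstrip("\n").split("\t")
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r} in {gene_table_path}")
            seen.add(gid)
            if gid not in proteins:
                raise ValueError(
                    f"gene {gid!r} has no sequence in {protein_fasta_path}")
            genes = chromosomes.setdefault(chrom, [])
            genes.append(Gene(id=gid, genome_id=genome_id, chromosome=chrom,
                              rank=len(genes), protein=proteins[gid],
                              start=_parse_opt_int(start), end=_parse_opt_int(end),
                              strand=strand if strand in STRANDS else "."))
    extra = sorted(set(proteins) - seen)
    if extra:
        raise ValueError(f"FASTA ids with no gene-table row: {', '.join(extra)}")
    return Genome(id=genome_id, chromosomes=chromosomes)


def write_genome(genome: Genome, gene_table_path: str | os.PathLike,
                 protein_fasta_path: str | os.PathLike) -> None:
    """Write a genome back to the native table + FASTA pair."""
    with open(gene_table_path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genome.genes():
            fh.write("\t".join([
                g.chromosome, g.id,
                "." if g.start is None else str(g.start),
                "." if g.end is None else str(g.end),
                g.strand]) + "\n")
    with open(protein_fasta_path, "w") as fh:
        for g in genome.genes():
            fh.write(f">{g.id}\n{g.protein}\n")


# ---------------------------------------------------------------------------
# standard-format importers
# ---------------------------------------------------------------------------

@dataclass
class ImportSummary:
    gene_table: Path
    protein_fasta: Path
    n_genes: int
    n_skipped: int


def _cds_identifier(feat, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"cds{index}"


def import_standard(path: str | os.PathLike, format: str,
                    out_dir: str | os.PathLike,
                    genome_id: Optional[str] = None) -> ImportSummary:
    """Convert GenBank / EMBL / structured-header FASTA to the native files.

    For flat files each sequence record is a chromosome and each CDS a gene,
    ordered by ascending start coordinate.  Proteins come from the
    ``/translation`` qualifier or, failing that, from standard-table
    translation of the CDS nucleotide span; a CDS offering neither is
    skipped and counted.  FASTA input must use ``id|chrom|start|end|strand``
    headers with the protein as the sequence.
    """
    import logging

    path = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genome_id is None:
        genome_id = path.stem
    rows: list[tuple[str, str, Optional[int], Optional[int], str]] = []
    prots: dict[str, str] = {}
    n_skipped = 0

    if format in ("genbank", "embl"):
        for rec in SeqIO.parse(str(path), format):
            chrom_rows = []
            idx = 0
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                idx += 1
                gid = _cds_identifier(feat, idx)
                if "translation" in feat.qualifiers:
                    protein = str(feat.qualifiers["translation"][0])
                else:
                    try:
                        table = int(feat.qualifiers.get("transl_table", ["1"])[0])
                        protein = str(feat.extract(rec.seq).translate(
                            table=table, to_stop=True))
                    except Exception:
                        protein = ""
                if not protein:
                    logging.getLogger(__name__).warning(
                        "skipping CDS %s: no translation and no usable "
                        "nucleotide sequence", gid)
                    n_skipped += 1
                    continue
                start = int(feat.location.start) + 1  # to 1-based inclusive
                end = int(feat.location.end)
                strand = {1: "+", -1: "-"}.get(feat.location.strand, ".")
                chrom_rows.append((start, end, gid, strand, protein.rstrip("*")))
            chrom_rows.sort(key=lambda r: (r[0], r[1], r[2]))
            for start, end, gid, strand, protein in chrom_rows:
                rows.append((rec.id, gid, start, end, strand))
                prots[gid] = protein
    elif format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split()[0].split("|")
            if len(parts) != 5:
                raise ValueError(
                    f"FASTA header {rec.description!r} is not id|chrom|start|end|strand")
            gid, chrom, start, end, strand = parts
            rows.append((chrom, gid, _parse_opt_int(start), _parse_opt_int(end),
                         strand if strand in STRANDS else "."))
            prots[gid] = str(rec.seq).rstrip("*")
    else:
        raise ValueError(f"unknown format {format!r}")

    gene_table = out_dir / f"{genome_id}.genes.tsv"
    protein_fasta = out_dir / f"{genome_id}.prot.fasta"
    with open(gene_table, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for chrom, gid, start, end, strand in rows:
            fh.write("\t".join([chrom, gid,
                                "." if start is None else str(start),
                                "." if end is None else str(end), strand]) + "\n")
    with open(protein_fasta, "w") as fh:
        for _, gid, _, _, _ in rows:
            fh.write(f">{gid}\n{prots[gid]}\n")
    return ImportSummary(gene_table, protein_fasta, len(rows), n_skipped)


# ---------------------------------------------------------------------------
# results serialization (pairs / blocks / breakpoints)
# ---------------------------------------------------------------------------

def _fmt_opt(v) -> str:
    return "." if v is None else str(v)


def write_results(blocks, pairs, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the homology-pairs and synteny-blocks TSV files.

    ``pairs`` is every homology relationship found (RBH — syntenic or not —
    and the non-RBH completions); ``blocks`` the reconstructed synteny
    blocks.  Fails before writing anything if the directory is unwritable.
    Files round-trip through :func:`read_results`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    pairs_path = out_dir / "pairs.tsv"
    blocks_path = out_dir / "blocks.tsv"

    with open(pairs_path, "w") as fh:
        fh.write("\t".join(PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write("\t".join([
                p.gene_a.id, p.gene_b.id, p.kind,
                f"{p.result.similarity_pct:.2f}", str(p.result.match_len),
                str(len(p.gene_a.protein)), str(len(p.gene_b.protein)),
                "1" if p.syntenic else "0"]) + "\n")

    with open(blocks_path, "w") as fh:
        fh.write("# block header: %s id chromA chromB rankA_start rankA_end "
                 "rankB_start rankB_end ntA_start ntA_end ntB_start ntB_end "
                 "orientation n_anchors n_completions\n" % BLOCKS_BLOCK_PREFIX)
        fh.write("# member line: role geneA geneB\n")
        for b in blocks:
            fh.write("\t".join([
                BLOCKS_BLOCK_PREFIX, b.id, b.chrom_a, b.chrom_b,
                str(b.span_a[0]), str(b.span_a[1]),
                str(b.span_b[0]), str(b.span_b[1]),
                _fmt_opt(b.nt_span_a[0] if b.nt_span_a else None),
                _fmt_opt(b.nt_span_a[1] if b.nt_span_a else None),
                _fmt_opt(b.nt_span_b[0] if b.nt_span_b else None),
                _fmt_opt(b.nt_span_b[1] if b.nt_span_b else None),
                str(b.orientation), str(len(b.anchors)),
                str(len(b.completions))]) + "\n")
            for a in b.anchors:
                fh.write(f"ANCHOR\t{a.pair.gene_a.id}\t{a.pair.gene_b.id}\n")
            for c in b.completions:
                fh.write(f"COMPLETION\t{c.gene_a.id}\t{c.gene_b.id}\n")
    return {"pairs": pairs_path, "blocks": blocks_path}


def read_results(out_dir: str | os.PathLike, genome_a: Genome, genome_b: Genome):
    """Parse the files written by :func:`write_results` back into objects."""
    from .homology import AlignmentResult, HomologyPair
    from .synteny import make_block

    out_dir = Path(out_dir)
    pairs: list[HomologyPair] = []
    by_key: dict[tuple[str, str], HomologyPair] = {}
    with open(out_dir / "pairs.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PAIRS_COLUMNS:
            raise ValueError(f"bad pairs header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            ga, gb, kind, sim, mlen, la, lb, synt = line.rstrip("\n").split("\t")
            res = AlignmentResult(score_0_100=float(sim), similarity_pct=float(sim),
                                  match_len=int(mlen),
                                  len_query=min(int(la), int(lb)),
                                  len_target=max(int(la), int(lb)))
            p = HomologyPair(gene_a=genome_a[ga], gene_b=genome_b[gb], kind=kind,
                             result=res, syntenic=synt == "1")
            pairs.append(p)
            by_key[(ga, gb)] = p

    blocks = []
    current = None
    with open(out_dir / "blocks.tsv") as fh:
        for line in fh:
            if line.startswith("# ") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == BLOCKS_BLOCK_PREFIX:
                if current is not None:
                    blocks.append(make_block(**current))
                current = {"block_id": fields[1], "genome_a": genome_a,
                           "genome_b": genome_b, "anchor_pairs": [],
                           "completion_pairs": []}
            elif fields[0] == "ANCHOR":
                current["anchor_pairs"].append(by_key[(fields[1], fields[2])])
            elif fields[0] == "COMPLETION":
                current["completion_pairs"].append(by_key[(fields[1], fields[2])])
    if current is not None:
        blocks.append(make_block(**current))
    return blocks, pairs


BREAKPOINTS_COLUMNS = ("genome", "chromosome", "left_block", "right_block",
                       "n_genes", "length_nt", "gene_ids", "feature_ids")


def write_breakpoints(regions, path: str | os.PathLike) -> Path:
    """Serialize breakpoint regions to TSV (one row per region)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(BREAKPOINTS_COLUMNS) + "\n")
        for r in regions:
            fh.write("\t".join([
                r.genome_id, r.chromosome, r.left_block, r.right_block,
                str(r.length_genes), _fmt_opt(r.length_nt),
                ",".join(r.gene_ids) or ".",
                ",".join(r.feature_ids) or "."]) + "\n")
    return path
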