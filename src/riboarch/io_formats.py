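"""Readers, writers and dataset-assembly steps for every external format.

Covers: gene annotation tables (GFF3 or headered TSV), Infernal ``cmsearch``
``--tblout`` (format 1) hit tables, FASTA sequences, and the riboswitch
class→family mapping. Also performs the two dataset-assembly operations that
precede any analysis: picking one representative genome per species (the
strain with the most genes) and extracting the strand-aware intergenic region
upstream of each gene.
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._records import AptamerHit, GeneRecord, IntergenicRegion, revcomp

GENE_TABLE_COLUMNS = [
    "genome_id",
    "species",
    "phylum",
    "contig",
    "start",
    "end",
    "strand",
    "gene_id",
    "cog_id",
]


class FamilyMap(dict):
    """Total, single-valued mapping riboswitch class → family name.

    Plain dict semantics; ``families`` exposes the image (the set of family
    names), whose size is the family count of the collection.
    """

    @property
    def families(self) -> set[str]:
        return set(self.values())

    @property
    def n_classes(self) -> int:
        return len(self)

    @property
    def n_families(self) -> int:
        return len(self.families)


def packaged_family_map() -> FamilyMap:
    """The packaged riboswitch class→family mapping (50 classes, 27 families).

    Synthetic reconstruction: the multi-member families and singletons that
    are explicitly enumerated in the literature on ligand-based riboswitch
    family clustering are verbatim; the remaining classes are plausible
    Rfam-era riboswitch classes added to reach the documented cardinality.
    """
    return read_family_map(Path(__file__).parent / "data" / "riboswitch_families.synthetic.tsv")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------


def _sorted_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    return sorted(genes, key=lambda g: (g.genome_id, g.contig, g.start, g.end, g.gene_id))


def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read gene annotations from a headered TSV or a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open;
    TSV tables are expected to already use the internal convention. Records
    come back sorted by (genome, contig, start).
    """
    path = Path(path)
    if dialect == "tsv":
        genes = _read_gene_tsv(path)
    elif dialect == "gff3":
        genes = _read_gene_gff3(path)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    _check_unique_ids(genes)
    return _sorted_genes(genes)


def _check_unique_ids(genes: Sequence[GeneRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.genome_id, g.gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r} in genome {g.genome_id!r}")
        seen.add(key)


def _read_gene_tsv(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return genes
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in GENE_TABLE_COLUMNS[:-1] if c not in header]
        if missing:
            raise ValueError(f"{path}: gene table header missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                cog = fields[idx["cog_id"]] if "cog_id" in idx else ""
                genes.append(
                    GeneRecord(
                        genome_id=fields[idx["genome_id"]],
                        species=fields[idx["species"]],
                        phylum=fields[idx["phylum"]],
                        contig=fields[idx["contig"]],
                        start=int(fields[idx["start"]]),
                        end=int(fields[idx["end"]]),
                        strand=fields[idx["strand"]],
                        gene_id=fields[idx["gene_id"]],
                        cog_id=cog or None,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed gene table row: {exc}") from exc
    return genes


def _read_gene_gff3(path: Path) -> list[GeneRecord]:
    """Minimal GFF3 gene reader.

    Only ``gene``/``CDS`` features are kept. Genome, species, phylum and COG
    context ride in the attributes column (``genome_id=...;species=...;
    phylum=...;cog_id=...``); absent attributes default to the empty string
    so plain single-genome GFF3 files still load.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from exc
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start after conversion ({start1}..{end1})")
            attrs = dict(
                item.split("=", 1) for item in attrs_s.split(";") if "=" in item
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"{seqid}:{start}-{end}"
            genes.append(
                GeneRecord(
                    genome_id=attrs.get("genome_id", ""),
                    species=attrs.get("species", ""),
                    phylum=attrs.get("phylum", ""),
                    contig=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    cog_id=attrs.get("cog_id") or None,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in _sorted_genes(genes):
            fh.write(
                "\t".join(
                    [
                        g.genome_id,
                        g.species,
                        g.phylum,
                        g.contig,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.gene_id,
                        g.cog_id or "",
                    ]
                )
                + "\n"
            )


def select_representatives(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Keep, per species, only the genome with the largest gene count.

    Ties are broken by the lexicographically smallest genome id so that
    repeated builds pick the same representative. Idempotent.
    """
    genes = list(genes)
    counts: dict[str, collections.Counter] = collections.defaultdict(collections.Counter)
    for g in genes:
        counts[g.species][g.genome_id] += 1
    keep: set[str] = set()
    for species, genome_counts in counts.items():
        best = min(genome_counts, key=lambda gid: (-genome_counts[gid], gid))
        keep.add(best)
    return _sorted_genes(g for g in genes if g.genome_id in keep)


# ---------------------------------------------------------------------------
# intergenic regions
# ---------------------------------------------------------------------------


def extract_intergenic(
    genes: Iterable[GeneRecord],
    sequences: Mapping[str, str],
    min_len: int = 1,
) -> list[IntergenicRegion]:
    """One upstream intergenic region per gene, in transcript orientation.

    The region runs from the gene's 5' boundary (in its transcription
    direction) to the nearest annotated gene body on either strand, or to the
    contig edge. Zero-length gaps yield no region. Minus-strand regions are
    stored reverse-complemented (see IntergenicRegion).
    """
    regions: list[IntergenicRegion] = []
    by_contig: dict[tuple[str, str], list[GeneRecord]] = collections.defaultdict(list)
    for g in genes:
        by_contig[(g.genome_id, g.contig)].append(g)
    for (genome_id, contig), contig_genes in sorted(by_contig.items()):
        if contig not in sequences:
            raise KeyError(f"contig {contig!r} of genome {genome_id!r} missing from sequences")
        seq = sequences[contig]
        clen = len(seq)
        contig_genes = sorted(contig_genes, key=lambda g: (g.start, g.end))
        for g in contig_genes:
            if g.end > clen:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of contig {contig} ({g.end} > {clen})"
                )
        for g in contig_genes:
            others = [o for o in contig_genes if o is not g]
            if g.strand == "+":
                lo = 0
                for o in others:
                    if o.start < g.start:
                        lo = max(lo, min(o.end, g.start))
                start, end = lo, g.start
            else:
                hi = clen
                for o in others:
                    if o.end > g.end:
                        hi = min(hi, max(o.start, g.end))
                start, end = g.end, hi
            if end - start < min_len:
                continue
            subseq = seq[start:end]
            if g.strand == "-":
                subseq = revcomp(subseq)
            regions.append(
                IntergenicRegion(
                    genome_id=genome_id,
                    contig=contig,
                    start=start,
                    end=end,
                    downstream_gene_id=g.gene_id,
                    orientation=g.strand,
                    sequence=subseq,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file → {id: uppercase sequence} (wrapped or unwrapped input)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def regions_to_fasta(regions: Iterable[IntergenicRegion], path: str | Path) -> None:
    write_fasta({r.region_id: r.sequence for r in regions}, path)


# ---------------------------------------------------------------------------
# Infernal tblout
# ---------------------------------------------------------------------------

# cmsearch --tblout (fmt 1) column order, whitespace-separated:
# target name, target accession, query name, query accession, mdl,
# mdl from, mdl to, seq from, seq to, strand, trunc, pass, gc, bias,
# score, E-value, inc, description of target
_TBLOUT_NCOL = 18


def read_tblout(path: str | Path) -> list[AptamerHit]:
    """Parse an Infernal ``cmsearch --tblout`` (format 1) hit table.

    1-based inclusive coordinates (reversed for minus-strand hits) are
    normalized to 0-based half-open on the plus strand of the target.
    """
    hits: list[AptamerHit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, _TBLOUT_NCOL - 1)
            if len(fields) < _TBLOUT_NCOL - 1:
                raise ValueError(f"{path}:{lineno}: expected >= {_TBLOUT_NCOL - 1} tblout columns")
            target, _tacc, query = fields[0], fields[1], fields[2]
            strand = fields[9]
            try:
                seq_from, seq_to = int(fields[7]), int(fields[8])
                score = float(fields[14])
                evalue = float(fields[15])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric tblout field: {exc}") from exc
            if strand == "-":
                seq_from, seq_to = seq_to, seq_from
            start, end = seq_from - 1, seq_to
            hits.append(
                AptamerHit(
                    hit_id=f"{target}:{start}-{end}:{query}",
                    model_class=query,
                    start=start,
                    end=end,
                    strand=strand,
                    bit_score=score,
                    evalue=evalue,
                    region_ref=target,
                )
            )
    return hits


def write_tblout(hits: Iterable[AptamerHit], path: str | Path) -> None:
    """Write hits back out in the cmsearch tabular dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(
            "#target name\taccession\tquery name\taccession\tmdl\tmdl from\tmdl to"
            "\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\tE-value\tinc"
            "\tdescription of target\n"
        )
        for h in hits:
            if h.strand == "-":
                seq_from, seq_to = h.end, h.start + 1
            else:
                seq_from, seq_to = h.start + 1, h.end
            fh.write(
                " ".join(
                    [
                        h.region_ref or "-",
                        "-",
                        h.model_class,
                        "-",
                        "cm",
                        "1",
                        str(h.end - h.start),
                        str(seq_from),
                        str(seq_to),
                        h.strand,
                        "no",
                        "1",
                        "0.50",
                        "0.0",
                        f"{h.bit_score:.1f}",
                        f"{h.evalue:.3g}",
                        "!",
                        "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# family map
# ---------------------------------------------------------------------------


def read_family_map(path: str | Path) -> FamilyMap:
    """Two-column (class, family) TSV → FamilyMap; duplicate classes with
    conflicting families are an error; class names match case-sensitively."""
    fam = FamilyMap()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            cls, family = fields
            if lineno == 1 and (cls.lower(), family.lower()) == ("class", "family"):
                continue
            if cls in fam and fam[cls] != family:
                raise ValueError(
                    f"{path}:{lineno}: class {cls!r} mapped to both {fam[cls]!r} and {family!r}"
                )
            fam[cls] = family
    return fam


def assign_families(hits: Iterable[AptamerHit], fam: Mapping[str, str]) -> list[AptamerHit]:
    """Attach the family label to each hit; unknown classes keep family=''."""
    out = []
    for h in hits:
        family = fam.get(h.model_class, "")
        note = h.note if family else _append_note(h.note, "unknown-class")
        out.append(
            AptamerHit(
                **{**h.__dict__, "family": family, "note": note}
            )
        )
    return out


def assign_regions(
    hits: Iterable[AptamerHit], regions: Iterable[IntergenicRegion]
) -> list[AptamerHit]:
    """Fill genome/contig context from each hit's target region."""
    by_id = {r.region_id: r for r in regions}
    out = []
    for h in hits:
        r = by_id.get(h.region_ref)
        if r is None:
            raise KeyError(f"hit {h.hit_id}: target region {h.region_ref!r} not found")
        if h.end > len(r):
            raise ValueError(
                f"hit {h.hit_id} extends past region {r.region_id} ({h.end} > {len(r)})"
            )
        out.append(AptamerHit(**{**h.__dict__, "genome_id": r.genome_id, "contig": r.contig}))
    return out


def _append_note(note: str, extra: str) -> str:
    return f"{note};{extra}" if note else extra
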