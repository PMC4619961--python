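"""Reading and writing the pipeline's genomic file formats.

Genomes enter as GFF3 gene models plus FASTA coding/protein sequences;
pairwise protein similarity can enter as a 12-column tabular hit file
(the classic ``blastp -outfmt 6`` layout). Results leave as tab-separated
block/dating tables and a Circos-compatible links file.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "HomologyHit",
    "FormatError",
    "ConsistencyError",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_hits_table",
    "write_hits_table",
    "write_block_table",
    "read_block_table",
    "write_circos_links",
]


class FormatError(ValueError):
    """A file violates the expected format (duplicate ids, bad columns...)."""


class ConsistencyError(ValueError):
    """Cross-file references do not line up (e.g. GFF gene absent from FASTA)."""


def _translate(cds: str) -> str:
    """Translate a CDS with the standard code, trailing stop removed."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: location, strand, CDS and protein.

    ``start``/``end`` are 1-based inclusive genomic coordinates. The CDS is
    the spliced coding sequence in reading direction; ``protein`` must equal
    its standard-code translation with the trailing stop removed. Ambiguous
    bases (N) are tolerated in the CDS; downstream codon statistics skip
    codons containing them.
    """

    gene_id: str
    species_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str
    protein: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.cds) % 3 != 0 or len(self.cds) < 9:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds)} not a multiple of 3 >= 9"
            )
        if _translate(self.cds) != self.protein:
            raise ValueError(f"{self.gene_id}: protein does not match CDS translation")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeAnnotation:
    """All gene models of one species, sorted by (chromosome, start)."""

    species_id: str
    chromosomes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r} in {self.species_id}")
            self._by_id[g.gene_id] = g
            length = self.chromosomes.get(g.chromosome)
            if length is not None and g.end > length:
                raise ValueError(
                    f"{g.gene_id} ends at {g.end} beyond {g.chromosome} length {length}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r} in {self.species_id}") from None

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def genes_in_window(self, chromosome: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end] by at least one bp."""
        return [
            g
            for g in self.genes
            if g.chromosome == chromosome and g.start <= end and g.end >= start
        ]


@dataclass(frozen=True)
class HomologyHit:
    """A scored, directional pairwise protein match."""

    query_id: str
    subject_id: str
    score: float
    e_value: float | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit stored for {self.query_id}")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("negative E-value")
        if self.identity is not None and not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping id -> upper-case sequence.

    The id is the first whitespace-delimited token of the header. Duplicate
    ids and empty files raise :class:`FormatError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(
    path: str | Path,
    fasta: Mapping[str, str],
    species_id: str | None = None,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from a GFF3 file plus sequences.

    ``fasta`` may be keyed by transcript/gene id (a CDS FASTA, used verbatim)
    or by chromosome id (a genome FASTA, from which each CDS is assembled in
    transcript order and reverse-complemented on the minus strand). When a
    gene has several mRNAs the longest CDS represents it. Genes without any
    CDS are skipped with a warning; a CDS that cannot be resolved against
    ``fasta`` raises :class:`ConsistencyError`.

    Chromosome lengths are taken from ``##sequence-region`` pragmas when
    present, else from the genome FASTA, else from the rightmost feature.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    if species_id is None:
        species_id = path.stem

    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best_cds: str | None = None
        best_len = -1
        transcripts = list(db.children(gene, featuretype="mRNA")) or [gene]
        for tx in transcripts:
            cds_parts = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
            if cds_parts:
                cds = _assemble_cds(cds_parts, gene.strand, fasta, tx.id, gene.id)
            elif tx.id in fasta:
                cds = fasta[tx.id].upper()
            elif gene.id in fasta:
                cds = fasta[gene.id].upper()
            else:
                continue
            if len(cds) > best_len:
                best_len = len(cds)
                best_cds = cds
        if best_cds is None:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                species_id=species_id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds=best_cds,
                protein=_translate(best_cds),
            )
        )

    if not chrom_lengths:
        for g in genes:
            chrom = g.chromosome
            if chrom in fasta:
                chrom_lengths[chrom] = len(fasta[chrom])
            else:
                chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), g.end)
    return GenomeAnnotation(species_id=species_id, chromosomes=chrom_lengths, genes=genes)


def _assemble_cds(
    cds_parts, strand: str, fasta: Mapping[str, str], tx_id: str, gene_id: str
) -> str:
    """Assemble a spliced CDS from genomic spans, or fall back to a CDS FASTA."""
    seqid = cds_parts[0].seqid
    if seqid in fasta:
        genome = fasta[seqid].upper()
        pieces = [genome[f.start - 1 : f.end] for f in cds_parts]
        cds = "".join(pieces)
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds
    for key in (tx_id, gene_id):
        if key in fasta:
            return fasta[key].upper()
    raise ConsistencyError(
        f"cannot resolve CDS for transcript {tx_id!r}: no chromosome "
        f"{seqid!r}, transcript or gene id present in the FASTA"
    )


def write_gff(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (gene + mRNA + single CDS per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosomes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chromosomes[chrom]}\n")
        for g in annotation.genes:
            base = f"{g.chromosome}\tmicrosynteny\t"
            coords = f"\t{g.start}\t{g.end}\t.\t{g.strand}\t"
            fh.write(base + "gene" + coords + f".\tID={g.gene_id}\n")
            fh.write(base + "mRNA" + coords + f".\tID={g.gene_id}.1;Parent={g.gene_id}\n")
            fh.write(base + "CDS" + coords + f"0\tID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n")


# ---------------------------------------------------------------------------
# Tabular hits (blastp -outfmt 6 layout)

_HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tabular hit file into best-hit-per-pair records.

    Percent identity is converted to a fraction, self-hits are dropped, and
    multiple hits for one (query, subject) pair are reduced to the lowest
    E-value (ties broken by the highest bit score).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", names=_HIT_COLUMNS, comment="#",
            dtype={"query": str, "subject": str},
        )
    except pd.errors.EmptyDataError:
        return []
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            raise FormatError(f"non-numeric value in column {col!r} of {path}")
    df = df[df["query"] != df["subject"]]
    df = df.sort_values(["evalue", "bitscore"], ascending=[True, False])
    df = df.drop_duplicates(subset=["query", "subject"], keep="first")
    return [
        HomologyHit(
            query_id=row.query,
            subject_id=row.subject,
            score=float(row.bitscore),
            e_value=float(row.evalue),
            identity=float(row.pident) / 100.0,
        )
        for row in df.itertuples()
    ]


def write_hits_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ident = 100.0 * (h.identity if h.identity is not None else 0.0)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{ident:.1f}\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.e_value if h.e_value is not None else 0.0:.3g}\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Block table & Circos links

_BLOCK_COLUMNS = [
    "anchor_a", "anchor_b", "scope", "n_conserved_pairs", "orientation",
    "syntenic_quality", "conserved_microsynteny", "mean_ks", "sd_ks", "date_mya",
]


def write_block_table(blocks: Iterable, path: str | Path) -> None:
    """Write one row per synteny block: anchors, pair count, orientation,
    quality, and (when dated) mean Ks +/- s.d. and the clock date in mya."""
    rows = []
    for b in blocks:
        dating = getattr(b, "dating", None)
        rows.append(
            {
                "anchor_a": b.region_a.anchor,
                "anchor_b": b.region_b.anchor,
                "scope": b.scope,
                "n_conserved_pairs": b.n_pairs,
                "orientation": b.orientation,
                "syntenic_quality": round(b.quality, 4),
                "conserved_microsynteny": b.conserved_microsynteny,
                "mean_ks": "NA" if dating is None or dating.mean_ks is None
                else round(dating.mean_ks, 4),
                "sd_ks": "NA" if dating is None or dating.sd_ks is None
                else round(dating.sd_ks, 4),
                "date_mya": "NA" if dating is None or dating.date_mya is None
                else round(dating.date_mya, 4),
            }
        )
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_block_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"anchor_a": str, "anchor_b": str})


def write_circos_links(blocks: Iterable, path: str | Path) -> None:
    """Write each conserved gene pair as a Circos link line:
    ``chrA startA endA chrB startB endB`` (1-based inclusive)."""
    with open(path, "w") as fh:
        for b in blocks:
            for p in b.pairs:
                if p.coords_a is None or p.coords_b is None:
                    raise ValueError(
                        f"pair ({p.gene_a}, {p.gene_b}) lacks genomic coordinates"
                    )
                ca, cb = p.coords_a, p.coords_b
                fh.write(f"{ca[0]} {ca[1]} {ca[2]} {cb[0]} {cb[1]} {cb[2]}\n")
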