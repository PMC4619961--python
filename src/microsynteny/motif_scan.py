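"""CCCH zinc-finger motif detection and anchor-gene selection.

The CCCH motif is three cysteines and a histidine with bounded spacers,
C-X4-15-C-X4-6-C-X3-H. Plant subfamily-IX members characteristically carry
two such motifs. The scanner reports non-overlapping motifs greedily left to
right, preferring the shortest legal spacing at each start position, so that
domain counts are reproducible. Unknown residues (X) may occupy spacer
positions but never stand in for C or H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_io import GenomeAnnotation

__all__ = ["MotifHit", "X1_RANGE", "X2_RANGE", "X3", "find_ccch_motifs",
           "count_domains", "select_anchors"]

X1_RANGE = range(4, 16)   # spacer between first and second cysteine
X2_RANGE = range(4, 7)    # spacer between second and third cysteine
X3 = 3                    # spacer between third cysteine and the histidine


@dataclass(frozen=True)
class MotifHit:
    """One CCCH motif occurrence, 1-based inclusive protein coordinates."""

    protein_id: str
    start: int
    end: int
    spacers: tuple[int, int, int]

    def __post_init__(self) -> None:
        x1, x2, x3 = self.spacers
        if x1 not in X1_RANGE or x2 not in X2_RANGE or x3 != X3:
            raise ValueError(f"illegal spacers {self.spacers}")
        if self.end - self.start + 1 != x1 + x2 + x3 + 4:
            raise ValueError("span inconsistent with spacers")


def _match_at(protein: str, i: int) -> tuple[int, int] | None:
    """Smallest-span (x1, then x2) CCCH match starting at 0-based index i."""
    n = len(protein)
    if protein[i] != "C":
        return None
    for x1 in X1_RANGE:
        j = i + 1 + x1
        if j >= n or protein[j] != "C":
            continue
        for x2 in X2_RANGE:
            k = j + 1 + x2
            h = k + 1 + X3
            if h < n and protein[k] == "C" and protein[h] == "H":
                return (x1, x2)
    return None


def find_ccch_motifs(protein: str, protein_id: str = "") -> list[MotifHit]:
    """Scan a protein left to right for non-overlapping CCCH motifs.

    At each position the shortest legal spacing wins; the scan resumes just
    past the reported histidine (greedy non-overlap). Returns hits in
    coordinate order; an empty sequence yields an empty list.
    """
    hits: list[MotifHit] = []
    i = 0
    n = len(protein)
    while i < n:
        m = _match_at(protein, i)
        if m is None:
            i += 1
            continue
        x1, x2 = m
        span = x1 + x2 + X3 + 4
        hits.append(
            MotifHit(protein_id=protein_id, start=i + 1, end=i + span,
                     spacers=(x1, x2, X3))
        )
        i += span
    return hits


def count_domains(annotation: GenomeAnnotation) -> dict[str, int]:
    """Number of CCCH motifs in each gene's protein."""
    return {
        g.gene_id: len(find_ccch_motifs(g.protein, g.gene_id))
        for g in annotation.genes
    }


def select_anchors(
    annotation: GenomeAnnotation,
    min_domains: int = 2,
    id_list: Sequence[str] | None = None,
) -> list[str]:
    """Choose the anchor genes whose neighbourhoods seed synteny scans.

    An explicit ``id_list`` wins verbatim (subfamily membership is usually
    curated rather than derivable from motif counts alone); otherwise every
    gene with at least ``min_domains`` motifs is an anchor.
    """
    if id_list is not None:
        for gid in id_list:
            if gid not in annotation:
                raise KeyError(f"anchor id {gid!r} not present in annotation "
                               f"{annotation.species_id!r}")
        return list(id_list)
    if min_domains < 1:
        raise ValueError("min_domains must be >= 1")
    counts = count_domains(annotation)
    return [g.gene_id for g in annotation.genes if counts[g.gene_id] >= min_domains]


def motif_table(proteins: Mapping[str, str]) -> Iterable[MotifHit]:
    """Motif hits over a whole protein set, in input order."""
    for pid, seq in proteins.items():
        yield from find_ccch_motifs(seq, pid)
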