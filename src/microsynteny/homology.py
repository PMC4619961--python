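"""Pairwise protein similarity and the family's match rules.

At genome-project scale similarity evidence normally arrives as an external
tabular hit file; for desk-scale and simulated data this module produces it
internally with an exact global aligner (BLOSUM62, affine gaps) plus a
Karlin-Altschul-style surrogate E-value, so the same thresholds
(1e-10 within species, 1e-20 between species) apply to both sources.

On top of the hits sit the two rules used to classify family expansion:
the best nonself-match of a gene, and tandem-duplicate detection (family
members separated by at most ``max_intervening`` non-family genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeAnnotation, HomologyHit

__all__ = [
    "AlignmentResult",
    "align_global",
    "alignment_score",
    "score_to_surrogate_evalue",
    "build_hits",
    "best_nonself_match",
    "detect_tandem",
    "tandem_arrays",
]

# Gapped BLOSUM62 statistics used for the surrogate E-value. These are fixed
# documented constants, not fitted to any external search engine.
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    # A gap of length L costs gap_open + gap_extend * L.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """A global protein alignment: gapped rows, score, and column identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def _check_residues(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence for {label}")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {label}")


def align_global(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> AlignmentResult:
    """Optimal global alignment of two proteins under BLOSUM62.

    Affine gap cost ``gap_open + gap_extend * length``. Identity is the
    fraction of identical columns among columns where neither row is gapped.
    """
    _check_residues(a, "sequence a")
    _check_residues(b, "sequence b")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = next(iter(aligner.align(a, b)))
    row_a, row_b = str(alignment[0]), str(alignment[1])
    nongap = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    ident = sum(x == y for x, y in nongap) / len(nongap) if nongap else 0.0
    return AlignmentResult(
        aligned_a=row_a, aligned_b=row_b, score=float(alignment.score), identity=ident
    )


def alignment_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Score-only variant of :func:`align_global` (much faster in bulk)."""
    _check_residues(a, "sequence a")
    _check_residues(b, "sequence b")
    return float(_make_aligner(gap_open, gap_extend).score(a, b))


def score_to_surrogate_evalue(
    score: float, len_a: int, len_b: int, db_size: int | None = None
) -> float:
    """Map an alignment score to a surrogate expectation value.

    Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)`` with fixed
    gapped BLOSUM62 constants; n is the subject length or, when given, the
    total database size in residues. Monotone decreasing in the score.
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("sequence lengths must be >= 1")
    n = db_size if db_size is not None else len_b
    return KA_K * len_a * n * math.exp(-KA_LAMBDA * score)


def build_hits(
    proteins: Mapping[str, str],
    pairs: Iterable[tuple[str, str]] | None = None,
    db_size: int | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[HomologyHit]:
    """Internally computed hits for the given id pairs (all-vs-all if None).

    Hits are directional: each unordered pair yields (a, b) and (b, a) with
    the same score and E-value. Scores are computed once per unordered pair.
    """
    ids = list(proteins)
    if pairs is None:
        wanted = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    else:
        seen: set[frozenset[str]] = set()
        wanted = []
        for a, b in pairs:
            key = frozenset((a, b))
            if a != b and key not in seen:
                seen.add(key)
                wanted.append((a, b))
    if db_size is None:
        db_size = sum(len(s) for s in proteins.values())
    hits: list[HomologyHit] = []
    for a, b in wanted:
        score = alignment_score(proteins[a], proteins[b], gap_open, gap_extend)
        e = score_to_surrogate_evalue(score, len(proteins[a]), len(proteins[b]), db_size)
        hits.append(HomologyHit(query_id=a, subject_id=b, score=score, e_value=e))
        hits.append(HomologyHit(query_id=b, subject_id=a, score=score, e_value=e))
    return hits


def best_nonself_match(
    gene: str, hits: Iterable[HomologyHit], threshold: float
) -> HomologyHit | None:
    """The lowest-E qualifying hit with this gene as query, or None.

    Ties are broken by the higher score, then the lexicographically smaller
    subject id, so the result is independent of hit-list order.
    """
    best: HomologyHit | None = None
    for h in hits:
        if h.query_id != gene or h.subject_id == gene:
            continue
        if h.e_value is None or h.e_value > threshold:
            continue
        if best is None:
            best = h
            continue
        key = (h.e_value, -h.score, h.subject_id)
        best_key = (best.e_value, -best.score, best.subject_id)
        if key < best_key:
            best = h
    return best


def detect_tandem(
    annotation: GenomeAnnotation,
    family: Sequence[str],
    max_intervening: int = 1,
) -> list[tuple[str, str]]:
    """Tandem-duplicate pairs within a gene family.

    Two family members form a tandem pair when they lie on the same
    chromosome with at most ``max_intervening`` non-family genes between
    them. Runs of nearby members are chained: three consecutive members
    yield two pairs. Pairs are reported smaller-coordinate gene first.
    """
    fam = set(family)
    for gid in fam:
        annotation.gene(gid)  # raises on unknown ids
    pairs: list[tuple[str, str]] = []
    chroms = sorted({annotation.gene(g).chromosome for g in fam})
    for chrom in chroms:
        ordered = annotation.genes_on(chrom)
        member_idx = [i for i, g in enumerate(ordered) if g.gene_id in fam]
        for i, j in zip(member_idx, member_idx[1:]):
            if j - i - 1 <= max_intervening:
                pairs.append((ordered[i].gene_id, ordered[j].gene_id))
    return pairs


def tandem_arrays(pairs: Iterable[tuple[str, str]]) -> list[set[str]]:
    """Group chained tandem pairs into arrays (connected components)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return list(groups.values())
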