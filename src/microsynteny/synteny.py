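"""Anchor-centred microsynteny detection.

Every family member (anchor) seeds a window of 100 kb upstream and
downstream of its gene span. For each pair of anchor regions - within or
between species - flanking genes are matched one-to-one by best homology
(E-value at most 1e-10 within a species, 1e-20 between species), and the
two regions form a synteny block when at least three non-anchor conserved
pairs remain. Blocks carry an orientation call (same / opposite / mixed
gene order), a tandem-corrected syntenic quality in (0, 1], and a
conserved-microsynteny flag (at least 80% of pairs order- and
strand-concordant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .genome_io import GenomeAnnotation, HomologyHit
from .homology import alignment_score, score_to_surrogate_evalue, tandem_arrays

__all__ = [
    "AnchorRegion",
    "ConservedPair",
    "SyntenyBlock",
    "DEFAULT_WINDOW",
    "WITHIN_SPECIES_EVALUE",
    "BETWEEN_SPECIES_EVALUE",
    "MIN_CONSERVED_PAIRS",
    "extract_region",
    "match_regions",
    "call_block",
    "classify_orientation",
    "conserved_microsynteny_flag",
    "syntenic_quality",
    "scan_all",
]

DEFAULT_WINDOW = 100_000          # bp up- and downstream of the anchor span
WITHIN_SPECIES_EVALUE = 1e-10
BETWEEN_SPECIES_EVALUE = 1e-20
MIN_CONSERVED_PAIRS = 3
CONSERVED_FRACTION = 0.80         # conserved-microsynteny threshold, inclusive


@dataclass
class AnchorRegion:
    """The genes within the anchor-centred window of one genome."""

    anchor: str
    species_id: str
    chromosome: str
    window_start: int
    window_end: int
    flanking: list[str]           # gene ids sorted by start, anchor included


@dataclass(frozen=True)
class ConservedPair:
    """One matched flanking-gene pair with coordinates and strand agreement."""

    gene_a: str
    gene_b: str
    same_strand: bool
    e_value: float
    coords_a: tuple[str, int, int] | None = None
    coords_b: tuple[str, int, int] | None = None
    is_anchor_pair: bool = False


@dataclass
class SyntenyBlock:
    """Two anchor regions plus their conserved gene pairs."""

    region_a: AnchorRegion
    region_b: AnchorRegion
    pairs: list[ConservedPair]
    n_pairs: int                  # conserved flanking pairs (anchors excluded)
    orientation: str              # same | opposite | mixed
    quality: float
    scope: str                    # within-species | between-species
    conserved_microsynteny: bool = False
    dating: object | None = None

    @property
    def anchor_pair(self) -> tuple[str, str]:
        return (self.region_a.anchor, self.region_b.anchor)


def extract_region(
    annotation: GenomeAnnotation, anchor: str, window: int = DEFAULT_WINDOW
) -> AnchorRegion:
    """Window of ``window`` bp either side of the anchor's span.

    Any gene overlapping the window by at least one bp belongs to the
    region; the anchor itself always does. The window is clipped to the
    chromosome.
    """
    g = annotation.gene(anchor)
    chrom_len = annotation.chromosomes.get(g.chromosome)
    start = max(1, g.start - window)
    end = g.end + window
    if chrom_len is not None:
        end = min(end, chrom_len)
    flanking = [x.gene_id for x in annotation.genes_in_window(g.chromosome, start, end)]
    if anchor not in flanking:
        flanking.append(anchor)
    return AnchorRegion(
        anchor=anchor,
        species_id=annotation.species_id,
        chromosome=g.chromosome,
        window_start=start,
        window_end=end,
        flanking=flanking,
    )


def match_regions(
    region_a: AnchorRegion,
    region_b: AnchorRegion,
    hits: Iterable[HomologyHit],
    threshold: float,
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
) -> list[ConservedPair]:
    """One-to-one greedy pairing of flanking genes by best hit.

    Qualifying cross-region hits (either direction) are reduced to one
    E-value per unordered gene pair, sorted ascending, and accepted while
    neither gene is already paired. Each accepted pair is annotated with
    strand agreement and genomic coordinates; pairs are returned in
    region-a coordinate order.
    """
    set_a = set(region_a.flanking)
    set_b = set(region_b.flanking)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for h in hits:
        if h.e_value is None or h.e_value > threshold:
            continue
        if h.query_id in set_a and h.subject_id in set_b:
            key = (h.query_id, h.subject_id)
        elif h.query_id in set_b and h.subject_id in set_a:
            key = (h.subject_id, h.query_id)
        else:
            continue
        if key[0] == key[1]:
            continue
        cur = best.get(key)
        if cur is None or (h.e_value, -h.score) < cur:
            best[key] = (h.e_value, -h.score)
    ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[ConservedPair] = []
    for (ga, gb), (e, _neg) in ranked:
        if ga in used_a or gb in used_b:
            continue
        used_a.add(ga)
        used_b.add(gb)
        ma = annotation_a.gene(ga)
        mb = annotation_b.gene(gb)
        pairs.append(
            ConservedPair(
                gene_a=ga,
                gene_b=gb,
                same_strand=(ma.strand == mb.strand),
                e_value=e,
                coords_a=(ma.chromosome, ma.start, ma.end),
                coords_b=(mb.chromosome, mb.start, mb.end),
                is_anchor_pair=(ga == region_a.anchor and gb == region_b.anchor),
            )
        )
    pairs.sort(key=lambda p: (p.coords_a[1], p.gene_a))
    return pairs


def call_block(
    region_a: AnchorRegion,
    region_b: AnchorRegion,
    pairs: Sequence[ConservedPair],
    min_pairs: int = MIN_CONSERVED_PAIRS,
    count_anchor: bool = False,
    tandem_pairs: Iterable[tuple[str, str]] = (),
) -> SyntenyBlock | None:
    """Call a synteny block when enough conserved flanking pairs exist.

    The anchor-anchor pair is excluded from the count unless
    ``count_anchor`` is set (it still appears in ``pairs``). Returns None
    below the threshold.
    """
    n = sum(1 for p in pairs if count_anchor or not p.is_anchor_pair)
    if n < min_pairs:
        return None
    scope = (
        "within-species"
        if region_a.species_id == region_b.species_id
        else "between-species"
    )
    block = SyntenyBlock(
        region_a=region_a,
        region_b=region_b,
        pairs=list(pairs),
        n_pairs=n,
        orientation="same",
        quality=0.0,
        scope=scope,
    )
    block.orientation = classify_orientation(block)
    block.quality = syntenic_quality(block, tandem_pairs)
    block.conserved_microsynteny = conserved_microsynteny_flag(block)
    return block


def _order_relations(block: SyntenyBlock) -> tuple[int, int, list[int]]:
    """Concordant/discordant counts over all pair-of-pairs relations.

    Returns (concordant, discordant, per-pair concordant-majority votes
    under the dominant direction).
    """
    pairs = block.pairs
    pos_b = [p.coords_b[1] for p in pairs]
    n = len(pairs)
    conc = disc = 0
    for i, j in combinations(range(n), 2):
        if pos_b[j] > pos_b[i]:
            conc += 1
        elif pos_b[j] < pos_b[i]:
            disc += 1
    ascending = conc >= disc
    votes = []
    for i in range(n):
        good = 0
        for j in range(n):
            if i == j:
                continue
            forward = (pos_b[j] - pos_b[i]) * (j - i) > 0
            if forward == ascending:
                good += 1
        votes.append(good)
    return conc, disc, votes


def classify_orientation(block: SyntenyBlock) -> str:
    """Gene-order concordance between the two regions.

    With pairs sorted along region a, Kendall-type concordance of their
    region-b positions: all concordant -> ``same``, all discordant ->
    ``opposite``, anything else -> ``mixed``.
    """
    if len(block.pairs) < 2:
        return "same"
    conc, disc, _ = _order_relations(block)
    if disc == 0:
        return "same"
    if conc == 0:
        return "opposite"
    return "mixed"


def conserved_microsynteny_flag(block: SyntenyBlock) -> bool:
    """True when >= 80% of pairs keep both order and transcriptional
    orientation (inclusive at the 80% boundary).

    A pair is order-concordant when it agrees with the block's dominant
    direction against a majority of the other pairs, and
    strand-concordant when its strand agreement matches that direction
    (same strands for parallel blocks, flipped strands for inverted ones).
    """
    pairs = block.pairs
    if not pairs:
        return False
    if len(pairs) == 1:
        return pairs[0].same_strand
    conc, disc, votes = _order_relations(block)
    ascending = conc >= disc
    n = len(pairs)
    good = 0
    for i, p in enumerate(pairs):
        order_ok = votes[i] * 2 >= (n - 1)
        strand_ok = p.same_strand == ascending
        if order_ok and strand_ok:
            good += 1
    return good / n >= CONSERVED_FRACTION


def syntenic_quality(
    block: SyntenyBlock, tandem_pairs: Iterable[tuple[str, str]] = ()
) -> float:
    """Fraction of region genes that form conserved pairs.

    ``2 * pairs / (genes_a + genes_b)`` after collapsing each tandem array
    to a single representative (its left-most member) in both the region
    gene counts and the pairing.
    """
    drop: set[str] = set()
    for array in tandem_arrays(tandem_pairs):
        for region in (block.region_a, block.region_b):
            members = [g for g in region.flanking if g in array]
            drop.update(members[1:])
    genes_a = [g for g in block.region_a.flanking if g not in drop]
    genes_b = [g for g in block.region_b.flanking if g not in drop]
    if not genes_a or not genes_b:
        raise ValueError("empty region after tandem collapse")
    kept_pairs = [
        p for p in block.pairs if p.gene_a not in drop and p.gene_b not in drop
    ]
    return min(1.0, 2.0 * len(kept_pairs) / (len(genes_a) + len(genes_b)))


@dataclass
class _HitSource:
    """Supplies qualifying hits per region pair, computing them on demand."""

    annotations: Mapping[str, GenomeAnnotation]
    hits: list[HomologyHit] | None = None
    db_size: int = 0
    _cache: dict[frozenset, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.db_size == 0:
            self.db_size = sum(
                len(g.protein) for a in self.annotations.values() for g in a.genes
            )

    def for_regions(
        self, region_a: AnchorRegion, region_b: AnchorRegion, threshold: float
    ) -> list[HomologyHit]:
        if self.hits is not None:
            return self.hits
        ann_a = self.annotations[region_a.species_id]
        ann_b = self.annotations[region_b.species_id]
        out: list[HomologyHit] = []
        for ga in region_a.flanking:
            pa = ann_a.gene(ga).protein
            for gb in region_b.flanking:
                if ga == gb:
                    continue
                key = frozenset((ga, gb))
                if key not in self._cache:
                    pb = ann_b.gene(gb).protein
                    score = alignment_score(pa, pb)
                    e = score_to_surrogate_evalue(score, len(pa), len(pb), self.db_size)
                    self._cache[key] = (score, e)
                score, e = self._cache[key]
                if e <= threshold:
                    out.append(
                        HomologyHit(query_id=ga, subject_id=gb, score=score, e_value=e)
                    )
        return out


def scan_all(
    annotations: Mapping[str, GenomeAnnotation],
    anchors: Mapping[str, Sequence[str]],
    hits: Sequence[HomologyHit] | None = None,
    within_evalue: float = WITHIN_SPECIES_EVALUE,
    between_evalue: float = BETWEEN_SPECIES_EVALUE,
    window: int = DEFAULT_WINDOW,
    min_pairs: int = MIN_CONSERVED_PAIRS,
    count_anchor: bool = False,
    tandem_pairs: Iterable[tuple[str, str]] = (),
) -> list[SyntenyBlock]:
    """Evaluate every unordered anchor pair and return the called blocks.

    ``anchors`` maps species id to its anchor gene ids. External hits are
    used when given; otherwise similarity is computed internally with the
    exact aligner and surrogate E-values. Anchor pairs whose windows
    overlap on the same chromosome (trivial self-synteny) are skipped.
    Output order is deterministic: anchors sorted by (species, chromosome,
    start, id).
    """
    tandem_pairs = list(tandem_pairs)
    regions: list[AnchorRegion] = []
    for sp in sorted(annotations):
        ann = annotations[sp]
        for gid in sorted(
            anchors.get(sp, ()),
            key=lambda g: (ann.gene(g).chromosome, ann.gene(g).start, g),
        ):
            regions.append(extract_region(ann, gid, window))
    source = _HitSource(annotations=annotations, hits=list(hits) if hits else None)
    blocks: list[SyntenyBlock] = []
    for ra, rb in combinations(regions, 2):
        if (
            ra.species_id == rb.species_id
            and ra.chromosome == rb.chromosome
            and ra.window_start <= rb.window_end
            and rb.window_start <= ra.window_end
        ):
            continue
        within = ra.species_id == rb.species_id
        threshold = within_evalue if within else between_evalue
        region_hits = source.for_regions(ra, rb, threshold)
        pairs = match_regions(
            ra, rb, region_hits, threshold,
            annotations[ra.species_id], annotations[rb.species_id],
        )
        block = call_block(
            ra, rb, pairs,
            min_pairs=min_pairs,
            count_anchor=count_anchor,
            tandem_pairs=tandem_pairs,
        )
        if block is not None:
            blocks.append(block)
    return blocks
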