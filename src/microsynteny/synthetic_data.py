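"""Simulation of multi-species genomes with a known evolutionary history.

The generator emulates the statistical structure the analysis assumes:
several grass-like genomes descended from a common ancestor along a known
species tree, with planted segmental/tandem duplications, inversions,
gene losses and translocations at known times, and coding sequences
diverging under a synonymous clock (default 6.5e-9 substitutions per
synonymous site per year) with a chosen dN/dS (omega, default 0.2).

Sequence evolution is a per-site Poisson event model classified NG86-style:
synonymous events are placed proportionally to each codon's synonymous
site count (positions weighted by their synonymous fraction over non-stop
changes) and likewise for nonsynonymous events, so the expected number of
synonymous substitutions per synonymous site over a branch of ``t`` years
is ``rate * t`` and the nonsynonymous expectation is ``omega`` times that.
Substitutions that would create stop codons never occur; there are no
indels, so orthologous coding sequences stay alignable column by column.

Every copy event (speciation or duplication) is recorded in a gene
genealogy, from which the ground truth exposes true pairwise divergence
times, expected Ks values, and the set of anchor-region pairs a synteny
scan should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneModel, GenomeAnnotation, write_fasta, write_gff
from .molecular_evolution import CODON_TABLE, GRASS_SYN_RATE, SENSE_CODONS
from .synteny import MIN_CONSERVED_PAIRS, extract_region

__all__ = [
    "SimEvent",
    "SimulationConfig",
    "SimGene",
    "Genealogy",
    "SimulationTruth",
    "ScenarioResult",
    "simulate_ancestor",
    "evolve_sequence",
    "apply_events",
    "simulate_scenario",
    "paperlike_config",
    "write_scenario",
]

_BASES = "ACGT"
_NON_CH_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TABLE[c] not in ("C", "H")
)
_EVENT_KINDS = {
    "segmental_duplication",
    "tandem_duplication",
    "inversion",
    "gene_loss",
    "translocation",
}


@dataclass(frozen=True)
class SimEvent:
    """One planted structural event on a lineage at a time in mya.

    ``lineage`` names the species the carrying branch leads to: a single
    species for a terminal branch, several for a shared internal branch,
    all species for the root branch. ``start_index``/``n_genes`` select a
    gene run on ``chromosome`` at event time.
    """

    kind: str
    time_mya: float
    lineage: tuple[str, ...]
    chromosome: str
    start_index: int
    n_genes: int
    dest_chromosome: str | None = None
    dest_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time_mya <= 0 or self.n_genes < 1 or self.start_index < 0:
            raise ValueError("event parameters out of range")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    seed: int
    species: tuple[str, ...] = ("osa", "sbi", "zma")
    divergence_times: tuple[float, ...] = (60.0, 15.0)  # mya, descending
    n_chromosomes: int = 2
    genes_per_chromosome: int = 40
    mean_gene_length: int = 400          # codons
    intergenic_mean: int = 10_000        # bp
    syn_rate: float = GRASS_SYN_RATE     # /synonymous site/year
    omega: float = 0.2                   # dN/dS
    anchors: tuple[tuple[str, int], ...] = ()   # (chromosome, gene index)
    events: tuple[SimEvent, ...] = ()
    loss_fraction: float = 0.0           # random terminal gene loss

    def __post_init__(self) -> None:
        if len(self.divergence_times) != len(self.species) - 1:
            raise ValueError("need one divergence time per split")
        if list(self.divergence_times) != sorted(self.divergence_times, reverse=True):
            raise ValueError("divergence times must be descending")
        if any(t <= 0 for t in self.divergence_times):
            raise ValueError("divergence times must be positive")
        if self.syn_rate <= 0 or self.omega < 0:
            raise ValueError("rates must be positive (omega >= 0)")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction in [0, 1)")


@dataclass
class SimGene:
    """Mutable per-gene state during simulation."""

    gid: str
    strand: str
    cds: str
    node: int


State = dict[str, list[SimGene]]


class Genealogy:
    """Gene genealogy over copy events (speciations and duplications).

    Each node is a gene lineage; a node's ``start`` is the time (mya) of
    the copy event that created it. The divergence time of two extant
    genes is the age of the event at which their lineages separated.
    """

    def __init__(self) -> None:
        self.parent: dict[int, int | None] = {}
        self.start: dict[int, float] = {}
        self._next = 0

    def new_node(self, parent: int | None, time_mya: float) -> int:
        nid = self._next
        self._next += 1
        self.parent[nid] = parent
        self.start[nid] = time_mya
        return nid

    def root(self, node: int) -> int:
        while self.parent[node] is not None:
            node = self.parent[node]
        return node

    def divergence_time(self, n1: int, n2: int) -> float | None:
        """Time (mya) since the two lineages separated; None if unrelated."""
        if n1 == n2:
            return 0.0
        path1: dict[int, int] = {}
        cur: int | None = n1
        while cur is not None:
            path1[cur] = len(path1)
            cur = self.parent[cur]
        cur = n2
        below2: int | None = None
        while cur is not None and cur not in path1:
            below2 = cur
            cur = self.parent[cur]
        if cur is None:
            return None
        common = cur
        # node just below the common ancestor on path1
        below1: int | None = None
        walk: int | None = n1
        while walk != common:
            below1 = walk
            walk = self.parent[walk]
        times = []
        if below1 is not None:
            times.append(self.start[below1])
        if below2 is not None:
            times.append(self.start[below2])
        return max(times) if times else 0.0


@dataclass
class EventRecord:
    kind: str
    time_mya: float
    lineage: tuple[str, ...]
    source_genes: tuple[str, ...]
    new_genes: tuple[str, ...] = ()


@dataclass
class SimulationTruth:
    """Planted history: genealogy, event log, anchors and losses."""

    genealogy: Genealogy
    gene_node: dict[str, int] = field(default_factory=dict)
    anchor_roots: set[int] = field(default_factory=set)
    events: list[EventRecord] = field(default_factory=list)
    lost_genes: list[str] = field(default_factory=list)
    syn_rate: float = GRASS_SYN_RATE
    omega: float = 0.2

    def divergence_time(self, gene_a: str, gene_b: str) -> float | None:
        return self.genealogy.divergence_time(
            self.gene_node[gene_a], self.gene_node[gene_b]
        )

    def expected_ks(self, gene_a: str, gene_b: str) -> float | None:
        t = self.divergence_time(gene_a, gene_b)
        if t is None:
            return None
        return 2.0 * self.syn_rate * t * 1e6

    def is_anchor(self, gene: str) -> bool:
        return self.genealogy.root(self.gene_node[gene]) in self.anchor_roots

    def anchors_by_species(
        self, annotations: Mapping[str, GenomeAnnotation]
    ) -> dict[str, list[str]]:
        return {
            sp: [g.gene_id for g in ann.genes if self.is_anchor(g.gene_id)]
            for sp, ann in annotations.items()
        }

    def homology_root(self, gene: str) -> int:
        return self.genealogy.root(self.gene_node[gene])

    def expected_blocks(
        self,
        annotations: Mapping[str, GenomeAnnotation],
        window: int,
        min_pairs: int = MIN_CONSERVED_PAIRS,
        count_anchor: bool = False,
    ) -> dict[frozenset[str], int]:
        """Anchor pairs a synteny scan should call, from ancestry alone.

        For every unordered anchor-region pair (same windows and
        same-chromosome-overlap skip as the scanner), flanking genes are
        matched one-to-one within shared-ancestor groups; the anchor-anchor
        pair is excluded from the count unless ``count_anchor``. Returns
        a mapping from the anchor-pair key to the expected pair count for
        pairs reaching ``min_pairs``.
        """
        anchors = self.anchors_by_species(annotations)
        regions = []
        for sp in sorted(annotations):
            ann = annotations[sp]
            for gid in sorted(
                anchors[sp], key=lambda g: (ann.gene(g).chromosome, ann.gene(g).start)
            ):
                regions.append(extract_region(ann, gid, window))
        expected: dict[frozenset[str], int] = {}
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                ra, rb = regions[i], regions[j]
                if (
                    ra.species_id == rb.species_id
                    and ra.chromosome == rb.chromosome
                    and ra.window_start <= rb.window_end
                    and rb.window_start <= ra.window_end
                ):
                    continue
                roots_a: dict[int, int] = {}
                for g in ra.flanking:
                    roots_a[self.homology_root(g)] = (
                        roots_a.get(self.homology_root(g), 0) + 1
                    )
                roots_b: dict[int, int] = {}
                for g in rb.flanking:
                    roots_b[self.homology_root(g)] = (
                        roots_b.get(self.homology_root(g), 0) + 1
                    )
                n = sum(
                    min(ca, roots_b.get(r, 0)) for r, ca in roots_a.items()
                )
                anchors_related = (
                    self.homology_root(ra.anchor) == self.homology_root(rb.anchor)
                )
                if not count_anchor and anchors_related and n > 0:
                    n -= 1
                if n >= min_pairs:
                    expected[frozenset((ra.anchor, rb.anchor))] = n
        return expected


# ---------------------------------------------------------------------------
# Sequence evolution


@lru_cache(maxsize=None)
def _codon_profile(codon: str):
    """Per-codon mutation menu with NG86 weights.

    Returns (syn_choices, S, nonsyn_choices, N) where each choice is
    (weight, position, mutant codon) and weights are 1/(valid changes at
    that position), so the weight totals equal the NG86 site counts.
    """
    syn: list[tuple[float, int, str]] = []
    nonsyn: list[tuple[float, int, str]] = []
    aa = CODON_TABLE[codon]
    for pos in range(3):
        mutants = [
            codon[:pos] + b + codon[pos + 1 :] for b in _BASES if b != codon[pos]
        ]
        valid = [m for m in mutants if CODON_TABLE[m] != "*"]
        if not valid:
            continue
        w = 1.0 / len(valid)
        for m in valid:
            if CODON_TABLE[m] == aa:
                syn.append((w, pos, m))
            else:
                nonsyn.append((w, pos, m))
    S = sum(w for w, _, _ in syn)
    N = sum(w for w, _, _ in nonsyn)
    return tuple(syn), S, tuple(nonsyn), N


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def evolve_sequence(
    cds: str,
    years: float,
    syn_rate: float = GRASS_SYN_RATE,
    omega: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Evolve a stop-free CDS for ``years`` years under the clock model.

    Synonymous events are Poisson with mean ``syn_rate * years`` per
    synonymous site, nonsynonymous events ``omega`` times that per
    nonsynonymous site; events are interleaved in random order and
    multiple hits at a site are allowed. Stop codons are never created.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    rng = _as_rng(rng)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(CODON_TABLE.get(c, "*") == "*" for c in codons):
        raise ValueError("CDS contains a stop codon or is not codon-sized")
    sw = np.array([_codon_profile(c)[1] for c in codons])
    nw = np.array([_codon_profile(c)[3] for c in codons])
    d_syn = syn_rate * years
    d_nonsyn = omega * syn_rate * years
    n_s = rng.poisson(d_syn * sw.sum())
    n_n = rng.poisson(d_nonsyn * nw.sum())
    kinds = np.array(["S"] * n_s + ["N"] * n_n)
    rng.shuffle(kinds)
    for kind in kinds:
        weights = sw if kind == "S" else nw
        total = weights.sum()
        if total <= 0:
            continue
        ci = int(rng.choice(len(codons), p=weights / total))
        syn, S, nonsyn, N = _codon_profile(codons[ci])
        choices, tot = (syn, S) if kind == "S" else (nonsyn, N)
        if not choices:
            continue
        probs = np.array([w for w, _, _ in choices]) / tot
        pick = int(rng.choice(len(choices), p=probs))
        codons[ci] = choices[pick][2]
        _, sw[ci], _, nw[ci] = _codon_profile(codons[ci])
    return "".join(codons)


def _evolve_state(
    state: State, years: float, config: SimulationConfig, rng: np.random.Generator
) -> None:
    if years <= 0:
        return
    for genes in state.values():
        for g in genes:
            g.cds = evolve_sequence(g.cds, years, config.syn_rate, config.omega, rng)


# ---------------------------------------------------------------------------
# Ancestor


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def _anchor_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A family CDS carrying exactly two CCCH motifs.

    Outside the planted motifs the protein avoids C and H so the motif
    count is exactly two by construction.
    """
    n_codons = max(n_codons, 80)
    body = [
        _NON_CH_CODONS[i]
        for i in rng.choice(len(_NON_CH_CODONS), size=n_codons - 1)
    ]

    def plant(pos: int) -> None:  # 0-based codon index of the motif's first C
        layout = ["TGC", None, None, None, None, "TGC", None, None, None, None,
                  "TGC", None, None, None, "CAC"]
        for off, codon in enumerate(layout):
            if codon is not None:
                body[pos + off] = codon

    plant(10)
    plant(40)
    return "ATG" + "".join(body)


def simulate_ancestor(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[State, Genealogy, set[int]]:
    """Lay out the ancestral genome: random stop-free genes, planted anchors.

    Returns the mutable genome state, the genealogy seeded with one root
    node per gene, and the set of anchor root nodes.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    genealogy = Genealogy()
    anchor_positions = set(config.anchors)
    anchor_roots: set[int] = set()
    state: State = {}
    counter = 1
    t0 = _clock_start(config)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        genes: list[SimGene] = []
        for gi in range(config.genes_per_chromosome):
            n_codons = max(200, int(rng.normal(config.mean_gene_length,
                                               0.15 * config.mean_gene_length)))
            is_anchor = (chrom, gi) in anchor_positions
            cds = _anchor_cds(n_codons, rng) if is_anchor else _random_cds(n_codons, rng)
            node = genealogy.new_node(None, t0)
            if is_anchor:
                anchor_roots.add(node)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(SimGene(gid=f"g{counter:04d}", strand=strand, cds=cds, node=node))
            counter += 1
        state[chrom] = genes
    return state, genealogy, anchor_roots


def _clock_start(config: SimulationConfig) -> float:
    times = [0.0, *config.divergence_times]
    times += [e.time_mya for e in config.events]
    return max(times)


# ---------------------------------------------------------------------------
# Structural events


class _IdFactory:
    def __init__(self) -> None:
        self.n = 0

    def copy_id(self, base: str) -> str:
        self.n += 1
        return f"{base}.d{self.n}"


def _apply_structural_event(
    state: State,
    event: SimEvent,
    genealogy: Genealogy,
    ids: _IdFactory,
    rng: np.random.Generator,
) -> EventRecord:
    genes = state.get(event.chromosome)
    if genes is None:
        raise ValueError(f"unknown chromosome {event.chromosome!r}")
    lo, hi = event.start_index, event.start_index + event.n_genes
    if hi > len(genes):
        raise ValueError(
            f"{event.kind} at {event.chromosome}[{lo}:{hi}] exceeds chromosome"
        )
    segment = genes[lo:hi]
    source_ids = tuple(g.gid for g in segment)
    new_ids: tuple[str, ...] = ()

    if event.kind == "inversion":
        inverted = [
            SimGene(g.gid, "-" if g.strand == "+" else "+", g.cds, g.node)
            for g in reversed(segment)
        ]
        state[event.chromosome][lo:hi] = inverted
    elif event.kind == "gene_loss":
        del state[event.chromosome][lo:hi]
    elif event.kind in ("segmental_duplication", "tandem_duplication", "translocation"):
        copies = []
        for g in segment:
            if event.kind == "translocation":
                copies.append(g)
                continue
            node = genealogy.new_node(g.node, event.time_mya)
            copies.append(SimGene(ids.copy_id(g.gid), g.strand, g.cds, node))
        if event.kind == "tandem_duplication":
            state[event.chromosome][hi:hi] = copies
        else:
            if event.kind == "translocation":
                del state[event.chromosome][lo:hi]
            dest_chrom = event.dest_chromosome
            if dest_chrom is None:
                others = [c for c in sorted(state) if c != event.chromosome]
                dest_chrom = others[int(rng.integers(len(others)))] if others else event.chromosome
            dest_genes = state[dest_chrom]
            di = event.dest_index
            if di is None:
                di = int(rng.integers(len(dest_genes) + 1))
            dest_genes[di:di] = copies
        if event.kind != "translocation":
            new_ids = tuple(g.gid for g in copies)
    return EventRecord(
        kind=event.kind,
        time_mya=event.time_mya,
        lineage=event.lineage,
        source_genes=source_ids,
        new_genes=new_ids,
    )


def apply_events(
    annotation: GenomeAnnotation,
    events: Sequence[SimEvent],
    seed: int = 0,
) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Apply structural events to a single static genome (no sequence change).

    A convenience for exercising the event machinery on its own; the full
    scenario simulator interleaves events with sequence evolution along
    the species tree.
    """
    rng = np.random.default_rng(seed)
    genealogy = Genealogy()
    state: State = {}
    for g in annotation.genes:
        node = genealogy.new_node(None, max((e.time_mya for e in events), default=1.0))
        state.setdefault(g.chromosome, []).append(
            SimGene(g.gid if hasattr(g, "gid") else g.gene_id, g.strand, g.cds, node)
        )
    truth = SimulationTruth(genealogy=genealogy)
    ids = _IdFactory()
    for event in sorted(events, key=lambda e: -e.time_mya):
        truth.events.append(_apply_structural_event(state, event, genealogy, ids, rng))
    cfg = SimulationConfig(seed=seed, species=("x",), divergence_times=())
    ann, _ = _layout(state, annotation.species_id, cfg, rng)
    truth.gene_node = {
        g.gid: g.node for genes in state.values() for g in genes
    }
    return ann, truth


# ---------------------------------------------------------------------------
# Scenario


@dataclass
class ScenarioResult:
    config: SimulationConfig
    annotations: dict[str, GenomeAnnotation]
    cds: dict[str, dict[str, str]]
    truth: SimulationTruth

    @property
    def proteins(self) -> dict[str, dict[str, str]]:
        return {
            sp: {g.gene_id: g.protein for g in ann.genes}
            for sp, ann in self.annotations.items()
        }

    def anchors(self) -> dict[str, list[str]]:
        return self.truth.anchors_by_species(self.annotations)


def _split_state(
    state: State, genealogy: Genealogy, time_mya: float, prefix: str | None
) -> State:
    """Copy a genome state at a speciation, giving every gene a new node."""
    child: State = {}
    for chrom, genes in state.items():
        child[chrom] = [
            SimGene(
                gid=f"{prefix}_{g.gid}" if prefix else g.gid,
                strand=g.strand,
                cds=g.cds,
                node=genealogy.new_node(g.node, time_mya),
            )
            for g in genes
        ]
    return child


def _layout(
    state: State,
    species_id: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Assign coordinates and build the annotation + CDS set."""
    from Bio.Seq import Seq

    genes: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    for chrom in sorted(state):
        pos = 0
        for g in state[chrom]:
            gap = 200 + int(rng.exponential(config.intergenic_mean))
            start = pos + gap
            end = start + len(g.cds) - 1
            pos = end
            prot = str(Seq(g.cds).translate())
            genes.append(
                GeneModel(
                    gene_id=g.gid,
                    species_id=species_id,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=g.strand,
                    cds=g.cds,
                    protein=prot,
                )
            )
            cds_map[g.gid] = g.cds
        chrom_lengths[chrom] = pos + config.intergenic_mean
    return (
        GenomeAnnotation(species_id=species_id, chromosomes=chrom_lengths, genes=genes),
        cds_map,
    )


def simulate_scenario(config: SimulationConfig) -> ScenarioResult:
    """Run the full multi-species simulation for one configuration.

    Deterministic for a fixed config (including seed). The species tree is
    a caterpillar: at each divergence time the next listed species splits
    off from the remaining lineage.
    """
    rng = np.random.default_rng(config.seed)
    state, genealogy, anchor_roots = simulate_ancestor(config, rng)
    truth = SimulationTruth(
        genealogy=genealogy,
        anchor_roots=anchor_roots,
        syn_rate=config.syn_rate,
        omega=config.omega,
    )
    ids = _IdFactory()

    def lineage_events(labels: tuple[str, ...], t_from: float, t_to: float):
        out = [
            e
            for e in config.events
            if tuple(sorted(e.lineage)) == tuple(sorted(labels))
            and t_to < e.time_mya <= t_from
        ]
        return sorted(out, key=lambda e: -e.time_mya)

    def run_branch(
        state: State, labels: tuple[str, ...], t_from: float, t_to: float
    ) -> State:
        t = t_from
        for e in lineage_events(labels, t_from, t_to):
            _evolve_state(state, (t - e.time_mya) * 1e6, config, rng)
            t = e.time_mya
            truth.events.append(
                _apply_structural_event(state, e, genealogy, ids, rng)
            )
        _evolve_state(state, (t - t_to) * 1e6, config, rng)
        return state

    annotations: dict[str, GenomeAnnotation] = {}
    cds: dict[str, dict[str, str]] = {}

    remaining = list(config.species)
    times = list(config.divergence_times)
    t_now = _clock_start(config)
    current = state
    while remaining:
        labels = tuple(remaining)
        if len(remaining) == 1:
            current = run_branch(current, labels, t_now, 0.0)
            _finalize_species(
                current, remaining[0], config, rng, annotations, cds, truth, genealogy
            )
            break
        t_split = times.pop(0)
        current = run_branch(current, labels, t_now, t_split)
        sp = remaining.pop(0)
        side = _split_state(current, genealogy, t_split, sp)
        side = run_branch(side, (sp,), t_split, 0.0)
        _finalize_species(side, sp, config, rng, annotations, cds, truth, genealogy)
        cont_prefix = remaining[0] if len(remaining) == 1 else None
        current = _split_state(current, genealogy, t_split, cont_prefix)
        t_now = t_split

    if config.loss_fraction > 0:
        for sp in list(annotations):
            ann = annotations[sp]
            kept: list[GeneModel] = []
            for g in ann.genes:
                is_anchor = genealogy.root(truth.gene_node[g.gene_id]) in anchor_roots
                if not is_anchor and rng.random() < config.loss_fraction:
                    truth.lost_genes.append(g.gene_id)
                    del truth.gene_node[g.gene_id]
                    del cds[sp][g.gene_id]
                else:
                    kept.append(g)
            annotations[sp] = GenomeAnnotation(
                species_id=sp, chromosomes=ann.chromosomes, genes=kept
            )
    return ScenarioResult(config=config, annotations=annotations, cds=cds, truth=truth)


def _finalize_species(
    state: State,
    species: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    annotations: dict[str, GenomeAnnotation],
    cds: dict[str, dict[str, str]],
    truth: SimulationTruth,
    genealogy: Genealogy,
) -> None:
    ann, cds_map = _layout(state, species, config, rng)
    annotations[species] = ann
    cds[species] = cds_map
    for genes in state.values():
        for g in genes:
            truth.gene_node[g.gid] = g.node


# ---------------------------------------------------------------------------
# The standard scenario


def paperlike_config(seed: int, loss_fraction: float = 0.0) -> SimulationConfig:
    """Three grass-like species splitting at 60 and 15 mya with five planted
    segmental-duplication groups, an inversion, a tandem array and a
    translocation.

    Five ancestral family (anchor) genes carry two CCCH motifs each; the
    duplications copy 8-gene runs centred on an anchor, one on the root
    branch (echoing an old whole-genome-duplication-era event) and the
    rest lineage-specific, the youngest at 15 and 12 mya.
    """
    anchors = (("chr1", 8), ("chr1", 20), ("chr1", 32), ("chr2", 8), ("chr2", 20))
    all_sp = ("osa", "sbi", "zma")
    events = (
        # five segmental duplication groups
        SimEvent("segmental_duplication", 70.0, all_sp, "chr1", 5, 8,
                 dest_chromosome="chr2", dest_index=30),
        SimEvent("segmental_duplication", 45.0, ("osa",), "chr1", 17, 8,
                 dest_chromosome="chr2", dest_index=14),
        SimEvent("segmental_duplication", 30.0, ("sbi", "zma"), "chr1", 29, 8,
                 dest_chromosome="chr2", dest_index=2),
        # indices account for the older insertions present on each lineage
        SimEvent("segmental_duplication", 15.0, ("zma",), "chr2", 13, 8,
                 dest_chromosome="chr1", dest_index=38),
        SimEvent("segmental_duplication", 12.0, ("zma",), "chr2", 25, 8,
                 dest_chromosome="chr1", dest_index=12),
        # an inversion inside the osa duplicated copy (3 genes)
        SimEvent("inversion", 40.0, ("osa",), "chr2", 16, 3),
        # a tandem copy of a zma family gene
        SimEvent("tandem_duplication", 8.0, ("zma",), "chr1", 28, 1),
        # a neutral translocation in sbi
        SimEvent("translocation", 10.0, ("sbi",), "chr2", 34, 3,
                 dest_chromosome="chr1", dest_index=0),
    )
    return SimulationConfig(
        seed=seed,
        species=all_sp,
        divergence_times=(60.0, 15.0),
        n_chromosomes=2,
        genes_per_chromosome=40,
        mean_gene_length=400,
        intergenic_mean=10_000,
        omega=0.2,
        anchors=anchors,
        events=events,
        loss_fraction=loss_fraction,
    )


def write_scenario(result: ScenarioResult, outdir: str | Path) -> None:
    """Write per-species FASTA (CDS and protein), GFF3 and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, ann in result.annotations.items():
        write_gff(ann, outdir / f"{sp}.gff3")
        write_fasta(result.cds[sp], outdir / f"{sp}.cds.fasta")
        write_fasta(
            {g.gene_id: g.protein for g in ann.genes}, outdir / f"{sp}.protein.fasta"
        )
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("kind\ttime_mya\tlineage\tsource_genes\tnew_genes\n")
        for e in result.truth.events:
            fh.write(
                f"{e.kind}\t{e.time_mya}\t{'+'.join(e.lineage)}\t"
                f"{','.join(e.source_genes)}\t{','.join(e.new_genes)}\n"
            )
    anchors = result.anchors()
    with open(outdir / "truth_anchors.tsv", "w") as fh:
        fh.write("species\tgene_id\n")
        for sp in sorted(anchors):
            for gid in anchors[sp]:
                fh.write(f"{sp}\t{gid}\n")
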