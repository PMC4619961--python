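"""End-to-end orchestration: genomes in, dated synteny blocks and a tree out.

The run mirrors the family-evolution analysis shape: select anchors
(motif scan or curated id list), detect tandem duplicates, scan all
anchor-region pairs for microsynteny, estimate NG86 Ka/Ks for every
conserved pair, date each block with the synonymous clock, profile the
anchor pairs with sliding-window Ka/Ks, and build a bootstrapped NJ tree
of the family proteins. Every stage is re-runnable on its own through the
module functions; the pipeline only sequences them and writes the report
bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import genome_io, homology, molecular_evolution as me, motif_scan, phylogeny
from . import synteny as synteny_mod
from .genome_io import GenomeAnnotation
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "summarize_family", "summarize_orf_lengths", "selection_screen"]


@dataclass
class PipelineConfig:
    """All run parameters, with the analysis defaults baked in."""

    species: dict[str, dict[str, str]] = field(default_factory=dict)
    # species id -> {"gff": path, "cds": path, "proteins": optional path}
    anchor_ids: dict[str, list[str]] | None = None
    min_domains: int = 2
    within_evalue: float = synteny_mod.WITHIN_SPECIES_EVALUE
    between_evalue: float = synteny_mod.BETWEEN_SPECIES_EVALUE
    window: int = synteny_mod.DEFAULT_WINDOW
    min_pairs: int = synteny_mod.MIN_CONSERVED_PAIRS
    count_anchor: bool = False
    max_intervening: int = 1
    ks_max: float = me.KS_SATURATION
    rate: float = me.GRASS_SYN_RATE
    sliding_window: int = 150
    sliding_step: int = 9
    bootstrap: int = 1000
    seed: int = 0
    hits_table: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.within_evalue <= 0 or self.between_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        for sp, paths in self.species.items():
            for key in ("gff", "cds"):
                if key not in paths:
                    raise ValueError(f"species {sp!r} lacks a {key!r} path")
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"{sp}: missing {key} file {paths[key]}")


@dataclass
class PipelineResult:
    annotations: dict[str, GenomeAnnotation]
    anchors: dict[str, list[str]]
    motif_counts: dict[str, int]
    best_matches: list
    tandem_pairs: list[tuple[str, str]]
    blocks: list[SyntenyBlock]
    pair_estimates: dict[tuple[str, str], me.KaKsEstimate]
    profiles: dict[tuple[str, str], me.SlidingWindowProfile]
    tree: phylogeny.TreeNode | None
    log: dict


def _load_annotations(config: PipelineConfig) -> dict[str, GenomeAnnotation]:
    annotations = {}
    for sp, paths in config.species.items():
        fasta = genome_io.read_fasta(paths["cds"])
        annotations[sp] = genome_io.read_gff(paths["gff"], fasta, species_id=sp)
    return annotations


def _all_proteins(annotations: Mapping[str, GenomeAnnotation]) -> dict[str, str]:
    return {
        g.gene_id: g.protein for ann in annotations.values() for g in ann.genes
    }


def pair_kaks(
    annotations: Mapping[str, GenomeAnnotation],
    gene_a: str,
    gene_b: str,
) -> me.KaKsEstimate:
    """Protein-guided NG86 Ka/Ks for one gene pair."""
    ga = gb = None
    for ann in annotations.values():
        if gene_a in ann:
            ga = ann.gene(gene_a)
        if gene_b in ann:
            gb = ann.gene(gene_b)
    if ga is None or gb is None:
        raise KeyError(f"pair ({gene_a}, {gene_b}) not found in annotations")
    aln = homology.align_global(ga.protein, gb.protein)
    ca = me.back_translate(aln, ga.cds, gb.cds, source_pair=(gene_a, gene_b))
    return me.ng86_kaks(ca)


def selection_screen(
    estimates: Mapping[tuple[str, str], me.KaKsEstimate]
) -> dict[str, float]:
    """Summary of the purifying-selection screen over defined Ka/Ks ratios."""
    ratios = [e.ratio for e in estimates.values() if e.ratio is not None]
    if not ratios:
        return {"n": 0, "fraction_below_1": float("nan"), "mean_ratio": float("nan")}
    below = sum(1 for r in ratios if r < 1.0)
    return {
        "n": len(ratios),
        "fraction_below_1": below / len(ratios),
        "mean_ratio": sum(ratios) / len(ratios),
    }


def summarize_orf_lengths(lengths: Sequence[int]) -> dict[str, int]:
    """Min/max/mean protein length; the mean is truncated to an integer
    (the family literature's reporting convention)."""
    if not lengths:
        raise ValueError("no lengths")
    return {
        "n": len(lengths),
        "min_aa": min(lengths),
        "max_aa": max(lengths),
        "mean_aa": int(sum(lengths) / len(lengths)),
    }


def summarize_family(
    annotations: Mapping[str, GenomeAnnotation], anchors: Mapping[str, Sequence[str]]
):
    """Per-gene roster (ORF aa, location) plus length summary statistics."""
    rows = []
    for sp in sorted(annotations):
        ann = annotations[sp]
        for gid in anchors.get(sp, ()):
            g = ann.gene(gid)
            rows.append(
                {
                    "gene_id": gid,
                    "species": sp,
                    "orf_aa": len(g.protein),
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                }
            )
    summary = summarize_orf_lengths([r["orf_aa"] for r in rows])
    return rows, summary


def run_pipeline(
    config: PipelineConfig,
    annotations: Mapping[str, GenomeAnnotation] | None = None,
) -> PipelineResult:
    """Run every stage on the configured (or supplied) genomes.

    Deterministic for a fixed config and seed; any stage failure aborts
    with the stage name in the exception message.
    """
    config.validate()
    if annotations is None:
        annotations = _load_annotations(config)
    log: dict = {"parameters": {k: v for k, v in vars(config).items()}, "stages": []}

    def stage(name: str):
        log["stages"].append(name)
        logger.info("stage: %s", name)

    stage("anchors")
    anchors: dict[str, list[str]] = {}
    motif_counts: dict[str, int] = {}
    for sp, ann in annotations.items():
        counts = motif_scan.count_domains(ann)
        motif_counts.update(counts)
        if config.anchor_ids is not None:
            anchors[sp] = motif_scan.select_anchors(
                ann, id_list=config.anchor_ids.get(sp, [])
            )
        else:
            anchors[sp] = motif_scan.select_anchors(ann, min_domains=config.min_domains)

    stage("homology")
    hits = None
    if config.hits_table:
        hits = genome_io.read_hits_table(config.hits_table)
    best_matches = []
    if hits is not None:
        flat_anchors = [g for sp in anchors for g in anchors[sp]]
        for gid in flat_anchors:
            m = homology.best_nonself_match(gid, hits, config.within_evalue)
            if m is not None:
                best_matches.append(m)

    stage("tandem")
    tandem_pairs: list[tuple[str, str]] = []
    for sp, ann in annotations.items():
        tandem_pairs.extend(
            homology.detect_tandem(ann, anchors[sp], config.max_intervening)
        )

    stage("synteny")
    blocks = synteny_mod.scan_all(
        annotations,
        anchors,
        hits=hits,
        within_evalue=config.within_evalue,
        between_evalue=config.between_evalue,
        window=config.window,
        min_pairs=config.min_pairs,
        count_anchor=config.count_anchor,
        tandem_pairs=tandem_pairs,
    )

    stage("kaks")
    pair_estimates: dict[tuple[str, str], me.KaKsEstimate] = {}
    for block in blocks:
        ests = []
        for p in block.pairs:
            if p.is_anchor_pair:
                continue
            key = (p.gene_a, p.gene_b)
            if key not in pair_estimates:
                pair_estimates[key] = pair_kaks(annotations, *key)
            ests.append(pair_estimates[key])
        if ests:
            block.dating = me.date_block(ests, rate=config.rate)

    stage("sliding-window")
    profiles: dict[tuple[str, str], me.SlidingWindowProfile] = {}
    for block in blocks:
        key = block.anchor_pair
        if key in profiles:
            continue
        try:
            ga = annotations[block.region_a.species_id].gene(key[0])
            gb = annotations[block.region_b.species_id].gene(key[1])
            aln = homology.align_global(ga.protein, gb.protein)
            ca = me.back_translate(aln, ga.cds, gb.cds, source_pair=key)
            profiles[key] = me.sliding_window(
                ca, config.sliding_window, config.sliding_step
            )
        except ValueError as err:
            logger.warning("sliding window skipped for %s: %s", key, err)

    stage("tree")
    tree = None
    family = {
        gid: annotations[sp].gene(gid).protein
        for sp in sorted(anchors)
        for gid in anchors[sp]
    }
    if len(family) >= 3:
        lengths = {len(s) for s in family.values()}
        aligned = family if len(lengths) == 1 else phylogeny.align_family(family)
        tree = phylogeny.bootstrap_support(
            aligned, replicates=config.bootstrap, seed=config.seed
        )

    result = PipelineResult(
        annotations=dict(annotations),
        anchors=anchors,
        motif_counts=motif_counts,
        best_matches=best_matches,
        tandem_pairs=tandem_pairs,
        blocks=blocks,
        pair_estimates=pair_estimates,
        profiles=profiles,
        tree=tree,
        log=log,
    )
    if config.outdir:
        write_report(result, config)
    return result


def write_report(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_io.write_block_table(result.blocks, outdir / "blocks.tsv")
    genome_io.write_circos_links(result.blocks, outdir / "circos_links.txt")
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("gene_id\tn_motifs\n")
        for gid, n in sorted(result.motif_counts.items()):
            fh.write(f"{gid}\t{n}\n")
    with open(outdir / "kaks_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tS\tN\tKs\tKa\tka_ks\tsaturated\n")
        for (a, b), e in sorted(result.pair_estimates.items()):
            ratio = "NA" if e.ratio is None else f"{e.ratio:.4f}"
            fh.write(
                f"{a}\t{b}\t{e.S:.2f}\t{e.N:.2f}\t{e.Ks:.4f}\t{e.Ka:.4f}\t"
                f"{ratio}\t{int(e.saturated)}\n"
            )
    with open(outdir / "sliding_windows.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tstart\tend\tKa\tKs\tka_ks\tshort\n")
        for (a, b), prof in sorted(result.profiles.items()):
            for w in prof.windows:
                ratio = "NA" if w.ratio is None else f"{w.ratio:.4f}"
                fh.write(
                    f"{a}\t{b}\t{w.start}\t{w.end}\t{w.Ka:.4f}\t{w.Ks:.4f}\t"
                    f"{ratio}\t{int(w.short)}\n"
                )
    if result.tree is not None:
        (outdir / "family_tree.nwk").write_text(result.tree.newick() + "\n")
    if result.best_matches:
        genome_io.write_hits_table(result.best_matches, outdir / "best_matches.tsv")
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(result.log, fh, default_flow_style=False)
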