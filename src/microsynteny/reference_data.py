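"""Published characteristics of the 27 grass CCCH subfamily-IX genes.

Two small tables used as worked-example inputs: the family roster (gene
name, species, ORF length in amino acids, chromosome and genomic span)
and the reported synteny-block statistics (conserved flanking-pair count,
mean synonymous sites, mean Ks with its standard deviation, and the
published clock date in mya). Reproducing the Ks values themselves
requires the original genome releases and is not attempted here; the
tables serve the summary statistics and the clock arithmetic.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["FamilyGene", "BlockStats", "CCCH_IX_GENES", "CCCH_IX_BLOCKS"]


class FamilyGene(NamedTuple):
    name: str
    species: str        # Os | Zm | Sb
    orf_aa: int
    chromosome: str
    start: int
    end: int


class BlockStats(NamedTuple):
    anchor_a: str
    anchor_b: str
    n_flanking: int
    syn_sites: float
    mean_ks: float
    sd_ks: float
    date_mya: float


CCCH_IX_GENES: tuple[FamilyGene, ...] = (
    FamilyGene("OsC3H2", "Os", 386, "Os1", 4949047, 4951126),
    FamilyGene("OsC3H10", "Os", 225, "Os1", 30824689, 30825670),
    FamilyGene("OsC3H24", "Os", 764, "Os3", 28008600, 28012204),
    FamilyGene("OsC3H33", "Os", 601, "Os5", 1662021, 1664438),
    FamilyGene("OsC3H35", "Os", 464, "Os5", 5846045, 5848291),
    FamilyGene("OsC3H37", "Os", 255, "Os5", 26171092, 26172349),
    FamilyGene("OsC3H50", "Os", 657, "Os7", 22840986, 22843954),
    FamilyGene("OsC3H52", "Os", 280, "Os7", 28233256, 28234642),
    FamilyGene("OsC3H67", "Os", 619, "Os12", 20018555, 20021302),
    FamilyGene("ZmC3H4", "Zm", 746, "Zm1", 263731420, 263734946),
    FamilyGene("ZmC3H10", "Zm", 360, "Zm2", 205904041, 205906953),
    FamilyGene("ZmC3H12", "Zm", 370, "Zm3", 6681798, 6683631),
    FamilyGene("ZmC3H28", "Zm", 482, "Zm5", 12382780, 12384893),
    FamilyGene("ZmC3H34", "Zm", 416, "Zm6", 1823029, 1825102),
    FamilyGene("ZmC3H38", "Zm", 394, "Zm6", 132663265, 132665063),
    FamilyGene("ZmC3H39", "Zm", 270, "Zm6", 160013893, 160016282),
    FamilyGene("ZmC3H43", "Zm", 656, "Zm7", 158677416, 158680576),
    FamilyGene("ZmC3H51", "Zm", 378, "Zm8", 20669510, 20671733),
    FamilyGene("ZmC3H53", "Zm", 262, "Zm8", 124841672, 124843159),
    FamilyGene("ZmC3H54", "Zm", 372, "Zm8", 131041707, 131043172),
    FamilyGene("ZmC3H63", "Zm", 594, "Zm10", 27949011, 27951381),
    FamilyGene("SbC3H2", "Sb", 745, "Sb1", 10009063, 10012269),
    FamilyGene("SbC3H10", "Sb", 680, "Sb2", 71102658, 71104964),
    FamilyGene("SbC3H12", "Sb", 350, "Sb3", 3207828, 3209693),
    FamilyGene("SbC3H44", "Sb", 533, "Sb8", 44663680, 44665480),
    FamilyGene("SbC3H45", "Sb", 611, "Sb9", 2607622, 2610024),
    FamilyGene("SbC3H47", "Sb", 399, "Sb9", 8731871, 8733975),
)

CCCH_IX_BLOCKS: tuple[BlockStats, ...] = (
    BlockStats("OsC3H2", "OsC3H35", 5, 299.25, 1.0927, 0.4254, 84.0538),
    BlockStats("OsC3H2", "SbC3H47", 3, 292.50, 1.0915, 0.4868, 83.9615),
    BlockStats("OsC3H2", "SbC3H12", 13, 268.75, 0.5470, 0.2981, 42.0769),
    BlockStats("OsC3H2", "ZmC3H51", 3, 293.00, 0.7827, 0.4078, 60.2077),
    BlockStats("OsC3H35", "SbC3H12", 5, 274.42, 0.9811, 0.3190, 75.4692),
    BlockStats("OsC3H35", "SbC3H47", 3, 296.67, 0.4635, 0.1314, 35.6538),
    BlockStats("SbC3H12", "SbC3H47", 3, 271.58, 0.8632, 0.5594, 66.4000),
    BlockStats("SbC3H12", "ZmC3H51", 3, 275.17, 0.2552, 0.0552, 19.6308),
    BlockStats("OsC3H35", "ZmC3H38", 3, 302.58, 0.9811, 0.6874, 75.4692),
    BlockStats("OsC3H10", "OsC3H37", 7, 173.67, 0.7084, 0.2090, 54.4923),
    BlockStats("OsC3H10", "ZmC3H39", 6, 169.08, 0.6818, 0.1138, 52.4462),
    BlockStats("OsC3H37", "ZmC3H39", 6, 193.00, 0.5051, 0.0373, 38.8538),
    BlockStats("OsC3H37", "ZmC3H53", 5, 197.83, 0.5696, 0.1238, 43.8154),
    BlockStats("OsC3H50", "ZmC3H10", 9, 289.33, 0.5867, 0.1815, 45.1285),
    BlockStats("OsC3H50", "SbC3H10", 16, 515.00, 0.5893, 0.1738, 45.3308),
    BlockStats("OsC3H50", "ZmC3H34", 5, 298.42, 0.6653, 0.1309, 51.1769),
    BlockStats("OsC3H50", "ZmC3H43", 6, 501.00, 0.6014, 0.1371, 46.2615),
    BlockStats("SbC3H10", "ZmC3H10", 7, 292.67, 0.1816, 0.0469, 13.9692),
    BlockStats("SbC3H10", "ZmC3H34", 5, 307.92, 0.1692, 0.0579, 13.0154),
    BlockStats("SbC3H10", "ZmC3H43", 6, 514.33, 0.1498, 0.0200, 11.5231),
    BlockStats("ZmC3H10", "ZmC3H34", 3, 275.50, 0.2019, 0.0367, 15.5308),
    BlockStats("ZmC3H10", "ZmC3H43", 4, 291.83, 0.1990, 0.0326, 15.3077),
    BlockStats("ZmC3H34", "ZmC3H43", 5, 310.50, 0.0157, 0.0352, 1.2077),
    BlockStats("OsC3H24", "SbC3H2", 14, 572.67, 0.8338, 0.4394, 64.1385),
    BlockStats("OsC3H24", "ZmC3H4", 4, 571.75, 0.6299, 0.2791, 48.4539),
    BlockStats("OsC3H24", "ZmC3H28", 5, 359.50, 0.5979, 0.1667, 45.9923),
    BlockStats("SbC3H2", "ZmC3H4", 4, 570.75, 0.1853, 0.1206, 14.2538),
    BlockStats("SbC3H2", "ZmC3H28", 5, 359.92, 0.1921, 0.0503, 14.7769),
    BlockStats("ZmC3H4", "ZmC3H28", 4, 361.00, 0.2170, 0.0754, 16.6923),
    BlockStats("OsC3H33", "SbC3H45", 9, 458.25, 0.5963, 0.1419, 45.8692),
    BlockStats("SbC3H45", "ZmC3H54", 3, 269.67, 0.2567, 0.0433, 19.7462),
)
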