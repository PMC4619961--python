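"""Codon-level evolutionary statistics.

Implements Nei-Gojobori (1986) counting of synonymous/nonsynonymous sites
and differences with Jukes-Cantor multiple-hit correction, the synonymous
molecular clock ``T = Ks / (2 * rate) * 1e-6`` mya (grass silent-site rate
6.5e-9 substitutions/synonymous site/year by default), per-block dating
with a Ks > 2 saturation filter, and sliding-window Ka/Ks profiles
(150 bp window, 9 bp step by default).

Site counting follows the NG86 convention: at each codon position the
synonymous fraction is taken over the single-base changes that do not
create a stop codon, so S + N = 3 per codon. Multi-difference codons are
classified by averaging over all orderings of the single-step mutational
paths, excluding paths that pass through a stop codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .homology import AlignmentResult

__all__ = [
    "CodonAlignment",
    "KaKsEstimate",
    "BlockDating",
    "WindowStat",
    "SlidingWindowProfile",
    "GRASS_SYN_RATE",
    "KS_SATURATION",
    "back_translate",
    "ng86_site_count",
    "ng86_diff_count",
    "ng86_kaks",
    "jukes_cantor",
    "date_from_ks",
    "date_block",
    "sliding_window",
]

GRASS_SYN_RATE = 6.5e-9   # synonymous substitutions / synonymous site / year
KS_SATURATION = 2.0       # Ks above this is considered saturated

_BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TABLE) if CODON_TABLE[c] != "*"
)


def _is_sense(codon: str) -> bool:
    return CODON_TABLE.get(codon, "*") != "*"


@dataclass(frozen=True)
class CodonAlignment:
    """Paired codon columns from the gapless part of a protein alignment."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    source_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")
        for c in itertools.chain(self.codons_a, self.codons_b):
            if len(c) != 3 or any(b not in _BASES for b in c):
                raise ValueError(f"not an unambiguous codon: {c!r}")
            if not _is_sense(c):
                raise ValueError(f"stop codon {c!r} in alignment")

    def __len__(self) -> int:
        return len(self.codons_a)

    def slice(self, start: int, stop: int) -> "CodonAlignment":
        return CodonAlignment(
            self.codons_a[start:stop], self.codons_b[start:stop], self.source_pair
        )


@dataclass(frozen=True)
class KaKsEstimate:
    """NG86 site/difference counts and corrected distances for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None
    saturated: bool
    n_codons: int


@dataclass
class BlockDating:
    """Synonymous-clock dating of one synteny block.

    The mean and sample (n-1) standard deviation are taken over the
    non-saturated per-pair Ks values; the date applies the clock to the
    mean. A block whose pairs are all saturated is undatable (None fields).
    """

    pair_ks: list[float] = field(default_factory=list)
    mean_ks: float | None = None
    sd_ks: float | None = None
    date_mya: float | None = None
    n_used: int = 0
    n_saturated: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class WindowStat:
    start: int            # bp, 1-based on the ungapped codon alignment
    end: int              # bp, inclusive
    Ka: float
    Ks: float
    ratio: float | None   # None when Ks is 0 (or infinite)
    short: bool = False


@dataclass(frozen=True)
class SlidingWindowProfile:
    windows: tuple[WindowStat, ...]


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def ng86_site_count(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Per position, the synonymous fraction of the three single-base changes,
    with changes into stop codons excluded from the denominator; fractions
    sum with their complements so S + N = 3.
    """
    if not _is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        syn_changes = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if not _is_sense(mutant):
                continue
            valid += 1
            if CODON_TABLE[mutant] == aa:
                syn_changes += 1
        if valid:
            syn += syn_changes / valid
    return (syn, 3.0 - syn)


@lru_cache(maxsize=None)
def ng86_diff_count(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous differences between two sense codons.

    Differences at one position are classified directly; two or three
    differences are averaged over all orderings of the single-step paths,
    skipping any path that passes through a stop codon. If every path is
    blocked by stops (never the case for sense endpoints and <= 3 steps,
    but kept as a safeguard) all paths are used.
    """
    if not _is_sense(codon_a) or not _is_sense(codon_b):
        raise ValueError("stop codon input")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if not _is_sense(nxt):
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return (syn, nonsyn)

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [
            p for p in (walk_all_stops(codon_a, codon_b, order)
                        for order in itertools.permutations(diff_pos))
        ]
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return (syn, nonsyn)


def walk_all_stops(codon_a: str, codon_b: str, order: tuple[int, ...]) -> tuple[int, int]:
    """Path classification counting stop intermediates as nonsynonymous."""
    cur = codon_a
    syn = nonsyn = 0
    for pos in order:
        nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
        if CODON_TABLE[nxt] == CODON_TABLE[cur]:
            syn += 1
        else:
            nonsyn += 1
        cur = nxt
    return (syn, nonsyn)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction ``d = -(3/4) ln(1 - 4p/3)``; inf at p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(ca: CodonAlignment) -> KaKsEstimate:
    """NG86 Ka/Ks for one codon alignment.

    Site counts are averaged between the two sequences; proportions are
    Jukes-Cantor corrected. The estimate is flagged saturated when
    Ks > 2 (including the undefined p >= 3/4 case, reported as inf).
    The ratio is undefined (None) when Ks is 0 or infinite.
    """
    if len(ca) < 1:
        raise ValueError("empty codon alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca_i, cb_i in zip(ca.codons_a, ca.codons_b):
        sa, _ = ng86_site_count(ca_i)
        sb, _ = ng86_site_count(cb_i)
        s_a += sa
        s_b += sb
        ds, dn = ng86_diff_count(ca_i, cb_i)
        sd += ds
        nd += dn
    n_cod = len(ca)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_cod - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    saturated = Ks > KS_SATURATION
    ratio = (Ka / Ks) if 0.0 < Ks < math.inf and Ka < math.inf else None
    return KaKsEstimate(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, saturated=saturated, n_codons=n_cod,
    )


# ---------------------------------------------------------------------------
# Back-translation


def back_translate(
    alignment: AlignmentResult, cds_a: str, cds_b: str,
    source_pair: tuple[str, str] = ("", ""),
) -> CodonAlignment:
    """Map a gapped protein alignment back onto its two CDSs.

    Each gapless aligned column becomes a codon column; columns with a gap
    on either side are dropped, as are codon columns containing ambiguous
    bases or stops. The CDS must translate to the ungapped protein rows
    (trailing stop codons are ignored); a mismatch raises with the
    offending codon index.
    """
    rows = (alignment.aligned_a, alignment.aligned_b)
    seqs = (cds_a.upper(), cds_b.upper())
    idx = [0, 0]
    codons: list[list[str]] = [[], []]
    for col, (x, y) in enumerate(zip(*rows)):
        residues = (x, y)
        ok = True
        col_codons = []
        for side in range(2):
            if residues[side] == "-":
                continue
            i = idx[side]
            codon = seqs[side][3 * i : 3 * i + 3]
            if len(codon) != 3:
                raise ValueError(
                    f"CDS {side} exhausted at codon {i} (alignment column {col})"
                )
            aa = CODON_TABLE.get(codon)
            if aa is None:
                aa = "X" if any(b not in _BASES for b in codon) else None
            res = residues[side]
            if aa not in (None, "X") and aa != "*" and res not in ("X", aa):
                raise ValueError(
                    f"translation mismatch on side {side} at codon {i}: "
                    f"codon {codon} -> {aa}, aligned residue {res}"
                )
            col_codons.append(codon)
            idx[side] += 1
        if "-" in residues:
            continue
        for codon in col_codons:
            if any(b not in _BASES for b in codon) or not _is_sense(codon):
                ok = False
        if ok:
            codons[0].append(col_codons[0])
            codons[1].append(col_codons[1])
    return CodonAlignment(tuple(codons[0]), tuple(codons[1]), source_pair)


# ---------------------------------------------------------------------------
# Clock dating


def date_from_ks(ks: float, rate: float = GRASS_SYN_RATE) -> float:
    """Divergence time in mya from a synonymous distance.

    ``T = ks / (2 * rate) * 1e-6``, reported to 4 decimals.
    """
    if ks < 0:
        raise ValueError("negative Ks")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return round(ks / (2.0 * rate) * 1e-6, 4)


def date_block(
    estimates: Sequence[KaKsEstimate] | Iterable[KaKsEstimate],
    rate: float = GRASS_SYN_RATE,
) -> BlockDating:
    """Date a duplication block from its per-pair Ks values.

    Saturated pairs (Ks > 2) are excluded; the clock is applied to the mean
    of the rest. With a single usable pair the s.d. is reported as 0 and
    the dating flagged degenerate. All pairs saturated -> undatable.
    """
    estimates = list(estimates)
    all_ks = [e.Ks for e in estimates]
    usable = [e.Ks for e in estimates if not e.saturated]
    dating = BlockDating(
        pair_ks=all_ks,
        n_used=len(usable),
        n_saturated=len(all_ks) - len(usable),
    )
    if not usable:
        return dating
    mean = sum(usable) / len(usable)
    if len(usable) > 1:
        var = sum((k - mean) ** 2 for k in usable) / (len(usable) - 1)
        sd = math.sqrt(var)
    else:
        sd = 0.0
        dating.degenerate = True
    dating.mean_ks = mean
    dating.sd_ks = sd
    dating.date_mya = date_from_ks(mean, rate)
    return dating


# ---------------------------------------------------------------------------
# Sliding window


def sliding_window(
    ca: CodonAlignment, window: int = 150, step: int = 9
) -> SlidingWindowProfile:
    """Sliding-window Ka/Ks along a codon alignment.

    Window and step are in bp and must be codon-sized (divisible by 3).
    Windows start at bp 1, 1+step, ... while they fit entirely; an
    alignment shorter than one window yields a single short-flagged
    whole-length window.
    """
    if window % 3 != 0 or step % 3 != 0:
        raise ValueError("window and step must be divisible by 3")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    length = 3 * len(ca)
    stats: list[WindowStat] = []
    if length < window:
        est = ng86_kaks(ca)
        stats.append(
            WindowStat(start=1, end=length, Ka=est.Ka, Ks=est.Ks,
                       ratio=est.ratio, short=True)
        )
        return SlidingWindowProfile(tuple(stats))
    start = 1
    while start + window - 1 <= length:
        c0 = (start - 1) // 3
        c1 = c0 + window // 3
        est = ng86_kaks(ca.slice(c0, c1))
        stats.append(
            WindowStat(start=start, end=start + window - 1,
                       Ka=est.Ka, Ks=est.Ks, ratio=est.ratio)
        )
        start += step
    return SlidingWindowProfile(tuple(stats))
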