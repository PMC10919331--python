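"""Provirus detection via flanking direct repeats (att sites).

Integrase-mediated integration of a circular genome duplicates a short
attachment sequence: the integrated element ends up flanked by two identical
direct repeats (attL/attR), one commonly overlapping a tRNA gene and the other
sitting next to the integrase gene. This module finds such repeat pairs,
scores the genomic evidence, reconstructs the excised circular genome with
its single reconstituted att copy (attV), and predicts the PCR products that
distinguish the integrated from the excised state.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .records import Feature, GenomeRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FinderConfig:
    """Tunable parameters of the direct-repeat provirus finder.

    ``min_element_len``/``max_element_len`` bound the separation of the two
    repeat start positions, which equals the length of the excised circle.
    """

    min_repeat_len: int = 15
    max_repeat_len: int = 100
    min_element_len: int = 5000
    max_element_len: int = 50000
    require_trna_overlap: bool = False
    max_integrase_distance: int = 2000
    max_mismatches: int = 0

    def __post_init__(self):
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_element_len > self.max_element_len:
            raise ValueError("min_element_len > max_element_len")
        if self.min_repeat_len < 4:
            raise ValueError("min_repeat_len must be >= 4")


@dataclass
class RepeatPair:
    """A maximal pair of exact direct repeats: seq[start1:start1+length] == seq[start2:start2+length]."""

    start1: int
    start2: int
    length: int

    @property
    def separation(self) -> int:
        return self.start2 - self.start1


@dataclass
class ProvirusCall:
    genome_id: str
    attL: Feature
    attR: Feature
    repeat_seq: str = ""
    trna_overlap: Optional[Feature] = None
    integrase_adjacent: Optional[Feature] = None
    integrase_distance: Optional[int] = None
    circular_genome: str = ""
    score: float = 0.0

    @property
    def interior(self) -> tuple[int, int]:
        """Full element span attL.start..attR.end (repeat-inclusive)."""
        return (self.attL.start, self.attR.end)

    @property
    def interior_len(self) -> int:
        return self.attR.end - self.attL.start

    @property
    def circle_len(self) -> int:
        return self.attR.start - self.attL.start


def find_direct_repeats(genome: GenomeRecord, cfg: FinderConfig = None) -> list[RepeatPair]:
    """Find all maximal direct repeat pairs with separation inside the element window.

    Seeds with an exact k-mer index (k = ``min_repeat_len``), extends each
    seeded pair to maximality on both sides, and deduplicates. With
    ``max_mismatches`` > 0 the extension tolerates that many mismatches in
    total, trimmed back so both ends of the reported repeat match exactly.
    Pairs are sorted by (repeat length desc, separation asc, leftmost asc).
    """
    cfg = cfg or FinderConfig()
    seq = genome.seq
    n = len(seq)
    k = cfg.min_repeat_len
    if n < 2 * k + cfg.min_element_len:
        log.info("genome %s too short (%d bp) for repeat search", genome.id, n)
        return []

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[seq[i : i + k]].append(i)

    seen: set[tuple[int, int, int]] = set()
    pairs: list[RepeatPair] = []
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a_idx in range(len(positions)):
            for b_idx in range(a_idx + 1, len(positions)):
                i, j = positions[a_idx], positions[b_idx]
                sep = j - i
                if not (cfg.min_element_len <= sep <= cfg.max_element_len):
                    continue
                pair = _extend_pair(seq, i, j, k, cfg.max_mismatches)
                key = (pair.start1, pair.start2, pair.length)
                if key in seen:
                    continue
                seen.add(key)
                if pair.length <= cfg.max_repeat_len:
                    pairs.append(pair)
    pairs.sort(key=lambda p: (-p.length, p.separation, p.start1))
    return pairs


def _extend_pair(seq: str, i: int, j: int, length: int, max_mismatches: int) -> RepeatPair:
    if max_mismatches == 0:
        while i > 0 and seq[i - 1] == seq[j - 1]:
            i -= 1
            j -= 1
        while j + length < len(seq) and seq[i + length] == seq[j + length]:
            length += 1
        return RepeatPair(i, j, length)
    # mismatch-tolerant: greedy extension with a shared Hamming budget; after
    # each direction, mismatching flank positions are trimmed off and their
    # budget refunded, so the reported repeat starts and ends on exact matches
    budget = max_mismatches
    right_ext: list[bool] = []
    while j + length < len(seq):
        match = seq[i + length] == seq[j + length]
        if not match and budget == 0:
            break
        if not match:
            budget -= 1
        right_ext.append(match)
        length += 1
    while right_ext and not right_ext[-1]:
        right_ext.pop()
        length -= 1
        budget += 1
    left_ext: list[bool] = []
    while i > 0 and j - i > length:  # stop before repeats would overlap
        match = seq[i - 1] == seq[j - 1]
        if not match and budget == 0:
            break
        if not match:
            budget -= 1
        i -= 1
        j -= 1
        left_ext.append(match)
    while left_ext and not left_ext[-1]:
        left_ext.pop()
        i += 1
        j += 1
        budget += 1
    return RepeatPair(i, j, length)


# evidence bonuses for the documented scoring heuristic
TRNA_BONUS = 50.0
INTEGRASE_BONUS = 50.0


def call_proviruses(genome: GenomeRecord, cfg: FinderConfig = None) -> list[ProvirusCall]:
    """Turn repeat pairs into scored provirus calls using the genome's annotations.

    Evidence: a tRNA feature intersecting either repeat (att sites commonly
    overlap tRNA genes), and an integrase CDS within ``max_integrase_distance``
    bp of either repeat. score = repeat_length + 50 per evidence type.
    Overlapping calls are resolved keeping the highest score, ties broken by
    longer repeat, then leftmost.
    """
    cfg = cfg or FinderConfig()
    pairs = find_direct_repeats(genome, cfg)
    trnas = genome.features_of_kind("tRNA")
    integrases = genome.features_of_kind("integrase")

    calls: list[ProvirusCall] = []
    for p in pairs:
        attL = Feature("repeat", p.start1, p.start1 + p.length, "+", "attL")
        attR = Feature("repeat", p.start2, p.start2 + p.length, "+", "attR")
        trna = next((t for t in trnas if t.overlaps(attL) or t.overlaps(attR)), None)
        if cfg.require_trna_overlap and trna is None:
            continue
        best_int, best_d = None, None
        for g in integrases:
            d = min(g.gap_to(attL), g.gap_to(attR))
            if d <= cfg.max_integrase_distance and (best_d is None or d < best_d):
                best_int, best_d = g, d
        call = ProvirusCall(
            genome_id=genome.id,
            attL=attL,
            attR=attR,
            repeat_seq=genome.seq[attL.start : attL.end],
            trna_overlap=trna,
            integrase_adjacent=best_int,
            integrase_distance=best_d,
        )
        call.score = p.length + TRNA_BONUS * (trna is not None) + INTEGRASE_BONUS * (best_int is not None)
        call.circular_genome = excise_circularize(call, genome)
        calls.append(call)

    calls.sort(key=lambda c: (-c.score, -len(c.attL), c.attL.start))
    kept: list[ProvirusCall] = []
    for c in calls:
        if all(not _spans_overlap(c, k) for k in kept):
            kept.append(c)
    return kept


def _spans_overlap(a: ProvirusCall, b: ProvirusCall) -> bool:
    return a.attL.start < b.attR.end and b.attL.start < a.attR.end


def excise_circularize(call: ProvirusCall, genome: GenomeRecord) -> str:
    """Reconstruct the excised circular genome, attV copy at position 0.

    Excision leaves one att copy in the chromosome and one on the circle, so
    the circle is ``genome[attL.end:attR.end]`` rotated to put the retained
    att copy first; its length equals ``attR.start - attL.start``.
    """
    attL, attR = call.attL, call.attR
    if attR.start < attL.end:
        raise ValueError("malformed call: attR precedes attL")
    seq = genome.seq
    if seq[attL.start : attL.end] != seq[attR.start : attR.end]:
        raise ValueError("att copies differ; not an exact direct repeat")
    return seq[attR.start : attR.end] + seq[attL.end : attR.start]


def reintegrate(call: ProvirusCall, genome: GenomeRecord) -> str:
    """Inverse of excision: insert the circle back between the host flanks."""
    circle = call.circular_genome or excise_circularize(call, genome)
    return genome.seq[: call.attL.start] + circle + call.repeat_seq + genome.seq[call.attR.end :]


@dataclass
class PcrConfig:
    min_primer_len: int = 12
    max_product: int = 10000
    max_mismatches: int = 0


def _binding_sites(template: str, primer: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        sites, start = [], 0
        while True:
            i = template.find(primer, start)
            if i < 0:
                return sites
            sites.append(i)
            start = i + 1
    m = len(primer)
    return [
        i
        for i in range(len(template) - m + 1)
        if sum(a != b for a, b in zip(template[i : i + m], primer)) <= max_mismatches
    ]


def insilico_pcr(
    template: str,
    topology: str,
    fwd_primer: str,
    rev_primer: str,
    cfg: PcrConfig = None,
) -> list[int]:
    """Predict PCR product sizes on a linear or circular template.

    Product length runs from the forward primer's 5' start to the reverse
    primer's 5' start on the opposite strand, inclusive of both primers.
    Circular templates permit junction-spanning products. Both primer
    orientations are considered. Products above ``max_product`` are dropped;
    the list is sorted ascending.
    """
    cfg = cfg or PcrConfig()
    template = template.upper()
    for name, p in (("fwd", fwd_primer), ("rev", rev_primer)):
        if len(p) < cfg.min_primer_len:
            raise ValueError(f"{name} primer shorter than {cfg.min_primer_len} nt")
        if set(p.upper()) - set("ACGT"):
            raise ValueError(f"{name} primer contains non-ACGT characters")
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    n = len(template)
    search = template + template if topology == "circular" else template

    products: set[int] = set()
    for plus, minus in ((fwd, rev), (rev, fwd)):
        starts = _binding_sites(search, plus, cfg.max_mismatches)
        ends = [i + len(minus) for i in _binding_sites(search, revcomp(minus), cfg.max_mismatches)]
        for s in starts:
            if topology == "circular" and s >= n:
                continue
            for e in ends:
                # reverse-primer site must begin at or after the forward start
                if e - len(minus) < s:
                    continue
                length = e - s
                if 0 < length <= min(cfg.max_product, n):
                    products.add(length)
    return sorted(products)
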