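"""ORF calling and cross-genome protein-identity synteny.

ORFs are called with the bacterial/archaeal genetic code (table 11) on both
strands; homology between consecutive genomes is summarized as reciprocal-best
links shaded by global amino-acid identity, the standard genome-alignment
ribbon view for small viral genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .provirus import revcomp

DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})
_TABLE11 = unambiguous_dna_by_id[11]
_STOPS = frozenset(_TABLE11.stop_codons)


@dataclass
class OrfRecord:
    """A predicted coding region; coordinates 0-based half-open on the forward strand.

    For origin-spanning ORFs on circular genomes ``end`` may exceed the genome
    length; positions are then taken modulo the length.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    translation: str
    index: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def _translate_orf(nt: str) -> str:
    """Translate an ORF including its stop codon; alternative starts become M."""
    aa = str(Seq(nt[:-3]).translate(table=11))
    return "M" + aa[1:] if aa else aa


def _scan_frame(seq: str, frame: int, min_aa: int, starts: frozenset, limit: int) -> list[tuple[int, int]]:
    """Yield (start, end) of ORFs in one forward frame of ``seq``.

    Each stop-anchored segment yields at most one ORF, from its most upstream
    permitted start codon — this collapses nested same-frame ORFs to the
    longest. ``limit``: only ORFs with start < limit are reported (used to
    deduplicate scans over a doubled circular sequence).
    """
    out = []
    first_start = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in _STOPS:
            if first_start is not None and first_start < limit:
                end = i + 3
                if (end - first_start) // 3 - 1 >= min_aa:
                    out.append((first_start, end))
            first_start = None
        elif first_start is None and codon in starts:
            first_start = i
        i += 3
    return out


def call_orfs(
    genome: str,
    topology: str = "linear",
    min_aa: int = 30,
    starts=DEFAULT_STARTS,
    genome_id: str = "genome",
) -> list[OrfRecord]:
    """Call ORFs on both strands in all three frames (genetic code 11).

    An ORF runs from the most upstream permitted start codon to the first
    in-frame stop; nested same-frame ORFs collapse to the longest. Circular
    topology permits origin-spanning ORFs. Output is sorted by forward-strand
    start and numbered 1..n.
    """
    genome = genome.upper()
    starts = frozenset(starts)
    n = len(genome)
    records: list[OrfRecord] = []
    for strand, seq in (("+", genome), ("-", revcomp(genome))):
        scan_seq = seq + seq if topology == "circular" else seq
        found: set[tuple[int, int]] = set()
        for frame in range(3):
            for s, e in _scan_frame(scan_seq, frame, min_aa, starts, limit=n):
                if e - s > n:  # an ORF cannot be longer than the genome
                    continue
                found.add((s, e))
        for s, e in found:
            nt = scan_seq[s:e]
            if strand == "+":
                fs, fe = s, e
            else:
                # [s,e) on the (doubled) reverse complement maps to forward
                # [2n-e, 2n-s) when it wraps the origin, else [n-e, n-s)
                fs, fe = (2 * n - e, 2 * n - s) if e > n else (n - e, n - s)
            records.append(
                OrfRecord(
                    genome_id=genome_id,
                    start=fs,
                    end=fe,
                    strand=strand,
                    translation=_translate_orf(nt),
                )
            )
    records.sort(key=lambda r: (r.start % n, r.end, r.strand))
    for i, r in enumerate(records, 1):
        r.index = i
    return records


# --------------------------------------------------------------- identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gaps: a gap of length L costs 11 + (L-1)*1
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Percent identity and coverage from a global BLOSUM62 alignment.

    Identity = matching columns / aligned columns with terminal gap columns
    excluded, x100. Coverage = columns where both sequences have a residue /
    length of the shorter sequence. The operand pair is canonically ordered
    before alignment so the result is symmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    swapped = (b, a) < (a, b)
    x, y = (b, a) if swapped else (a, b)
    aln = _make_aligner().align(x, y)[0]
    sx, sy = str(aln[0]), str(aln[1])
    # trim terminal gap columns
    lo = 0
    hi = len(sx)
    while lo < hi and (sx[lo] == "-" or sy[lo] == "-"):
        lo += 1
    while hi > lo and (sx[hi - 1] == "-" or sy[hi - 1] == "-"):
        hi -= 1
    core_x, core_y = sx[lo:hi], sy[lo:hi]
    columns = len(core_x)
    matches = sum(1 for p, q in zip(core_x, core_y) if p == q and p != "-")
    aligned_both = sum(1 for p, q in zip(sx, sy) if p != "-" and q != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = aligned_both / min(len(a), len(b))
    return identity, coverage


@dataclass
class HomologLink:
    orf_a: OrfRecord
    orf_b: OrfRecord
    identity: float
    coverage: float


def build_synteny_map(
    genomes: list[str],
    orfs: list[list[OrfRecord]],
    min_identity: float = 20.0,
    min_coverage: float = 0.5,
) -> list[HomologLink]:
    """Reciprocal-best homolog links between consecutive genomes.

    ``genomes`` gives the display order (ids); ``orfs[i]`` are the ORFs of
    genome i. For each adjacent pair, all-vs-all identities are computed and
    only reciprocal best hits above the thresholds are kept, so each ORF
    appears in at most one link per genome pair.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    links: list[HomologLink] = []
    for gi in range(len(genomes) - 1):
        top, bottom = orfs[gi], orfs[gi + 1]
        if not top or not bottom:
            continue
        scores = {}
        for oa in top:
            for ob in bottom:
                scores[(oa.index, ob.index)] = pairwise_identity(oa.translation, ob.translation)
        best_a = {}
        for oa in top:
            cands = [(scores[(oa.index, ob.index)][0], ob.index) for ob in bottom]
            best_a[oa.index] = max(cands)[1]
        best_b = {}
        for ob in bottom:
            cands = [(scores[(oa.index, ob.index)][0], oa.index) for oa in top]
            best_b[ob.index] = max(cands)[1]
        by_index_a = {o.index: o for o in top}
        by_index_b = {o.index: o for o in bottom}
        for oa in top:
            bi = best_a[oa.index]
            if best_b[bi] != oa.index:
                continue
            ident, cov = scores[(oa.index, bi)]
            if ident >= min_identity and cov >= min_coverage:
                links.append(HomologLink(oa, by_index_b[bi], ident, cov))
    return links


def plot_synteny(
    genomes: list[str],
    lengths: list[int],
    orfs: list[list[OrfRecord]],
    links: list[HomologLink],
    path: str,
) -> None:
    """Draw the genome-alignment ribbon plot (grayscale shading ~ identity) to SVG."""
    fig, ax = plt.subplots(figsize=(10, 1.6 * len(genomes)))
    row = {gid: len(genomes) - 1 - i for i, gid in enumerate(genomes)}
    for gid, length, olist in zip(genomes, lengths, orfs):
        y = row[gid]
        ax.plot([0, length], [y, y], color="black", lw=1)
        for o in olist:
            ax.arrow(
                o.start if o.strand == "+" else o.end,
                y,
                (o.end - o.start) * (1 if o.strand == "+" else -1),
                0,
                width=0.08,
                head_width=0.16,
                head_length=min(150, len(o) / 3),
                length_includes_head=True,
                fc="steelblue",
                ec="black",
                lw=0.3,
            )
        ax.text(-0.01 * max(lengths), y, gid, ha="right", va="center", fontsize=8)
    for ln in links:
        ya, yb = row[ln.orf_a.genome_id], row[ln.orf_b.genome_id]
        shade = 1.0 - ln.identity / 100.0  # darker = more identical
        ax.fill(
            [ln.orf_a.start, ln.orf_a.end, ln.orf_b.end, ln.orf_b.start],
            [ya - 0.1, ya - 0.1, yb + 0.1, yb + 0.1],
            color=str(0.15 + 0.75 * shade),
            alpha=0.8,
            lw=0,
        )
    ax.set_ylim(-0.5, len(genomes) - 0.5)
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
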