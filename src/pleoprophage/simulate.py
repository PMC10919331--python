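"""Synthetic fixtures with machine-readable ground truth.

Three generator families: chromosomes with a planted provirus flanked by
exact direct repeats (emulating a tRNA-integrated pleomorphic provirus),
protein sets with planted N-glycosylation sequon counts per host-lineage
group, and toy 3D structures with planted salt bridges and hydrophobic
clusters. Each generator draws from its own named pseudo-random stream
derived from a single integer seed, so adding generators never perturbs
existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import Atom, Feature, GenomeRecord, ProteinRecord, StructureModel
from .provirus import ProvirusCall

_NT = np.array(list("ACGT"))

# fixed stream ids, one per generator
_STREAM_GENOME = 101
_STREAM_PROTEIN = 202
_STREAM_STRUCTURE = 303


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=n, p=p))


@dataclass
class FixtureSpec:
    """Parameters of the planted-provirus chromosome generator.

    Defaults mirror the study configuration this package targets: a ~100-kb
    chromosome region carrying a 17.9-kb provirus flanked by 27-nt exact
    direct repeats, one repeat overlapping a tRNA gene and an integrase CDS
    just inside the other.
    """

    seed: int = 1
    genome_len: int = 100_000
    provirus_len: int = 17_900
    repeat_len: int = 27
    trna_overlap: bool = True
    integrase_offset: int = 200
    n_decoy_repeats: int = 2
    gc: float = 0.5

    def __post_init__(self):
        if self.provirus_len + 2 * self.repeat_len >= self.genome_len:
            raise ValueError("provirus plus repeats must fit inside the genome")
        if self.provirus_len <= self.repeat_len:
            raise ValueError("provirus_len must exceed repeat_len")


def make_genome_with_provirus(spec: FixtureSpec) -> tuple[GenomeRecord, ProvirusCall]:
    """Plant a provirus with exact direct repeats into a random chromosome.

    Layout: left flank | att | provirus core | att | right flank, so the
    separation of the two repeat starts — and hence the excised circle
    length — equals ``provirus_len``. Decoy repeat pairs 6 nt shorter than
    the true att are planted in the flanks to stress specificity. Returns
    the genome plus the ground-truth call (including the expected circle).
    """
    rng = _rng(spec.seed, _STREAM_GENOME)
    att = _random_nt(rng, spec.repeat_len, spec.gc)
    core_len = spec.provirus_len - spec.repeat_len
    core = _random_nt(rng, core_len, spec.gc)
    margin = 2500
    total_flank = spec.genome_len - spec.provirus_len - spec.repeat_len
    lo = margin
    hi = total_flank - margin
    if hi <= lo:
        raise ValueError("genome too small for the requested provirus and margins")
    attl_start = int(rng.integers(lo, hi))
    left = _random_nt(rng, attl_start, spec.gc)
    right = _random_nt(rng, total_flank - attl_start, spec.gc)

    # break the repeat exactly at the planted boundaries, otherwise matching
    # flank bases would make the maximal repeat longer than the att
    def _different(base: str) -> str:
        return "ACGT"[("ACGT".index(base) + 1) % 4]

    if left[-1] == core[-1]:
        left = left[:-1] + _different(core[-1])
    if right[0] == core[0]:
        right = _different(core[0]) + right[1:]

    seq = left + att + core + att + right
    assert len(seq) == spec.genome_len
    attl = Feature("repeat", attl_start, attl_start + spec.repeat_len, "+", "attL")
    attr_start = attl_start + spec.provirus_len
    attr = Feature("repeat", attr_start, attr_start + spec.repeat_len, "+", "attR")

    features: list[Feature] = []
    trna = None
    if spec.trna_overlap:
        trna = Feature("tRNA", max(0, attl.start - 45), attl.start + 10, "-", "tRNA-Gly")
        features.append(trna)
    integrase = None
    if spec.integrase_offset >= 0:
        g_end = attr.start - spec.integrase_offset
        g_start = g_end - 900
        if g_start > attl.end:
            integrase = Feature("integrase", g_start, g_end, "-", "int")
            features.append(integrase)

    # decoy direct repeats, shorter than the true att, planted in the flanks
    decoy_len = max(12, spec.repeat_len - 6)
    seq_list = list(seq)
    for d in range(spec.n_decoy_repeats):
        decoy = _random_nt(rng, decoy_len, spec.gc)
        placed = False
        for _ in range(50):
            p1 = int(rng.integers(100, max(101, attl.start - 2 * decoy_len - 100))) if attl.start > 400 else None
            if p1 is None:
                break
            sep = int(rng.integers(6000, 12000))
            p2 = p1 + sep
            if p2 + decoy_len < attl.start - 50:
                seq_list[p1 : p1 + decoy_len] = decoy
                seq_list[p2 : p2 + decoy_len] = decoy
                placed = True
                break
        if not placed and spec.n_decoy_repeats:
            # fall back to the right flank
            base = attr.end + 100
            if base + 14000 + decoy_len < spec.genome_len - 100:
                p1 = base + d * 200
                p2 = p1 + 7000
                seq_list[p1 : p1 + decoy_len] = decoy
                seq_list[p2 : p2 + decoy_len] = decoy
    seq = "".join(seq_list)

    genome = GenomeRecord(id=f"synthetic_chr_seed{spec.seed}", seq=seq, topology="linear", features=features)
    truth = ProvirusCall(
        genome_id=genome.id,
        attL=attl,
        attR=attr,
        repeat_seq=att,
        trna_overlap=trna,
        integrase_adjacent=integrase,
        integrase_distance=spec.integrase_offset if integrase else None,
        circular_genome=att + core,
    )
    return genome, truth


# background alphabet excludes N so sequons occur only where planted;
# X slots exclude both N and P
_AA_BACKGROUND = np.array(list("ACDEFGHIKLMQRSTVWY"))
_AA_X = np.array(list("ACDEFGHIKLMQRSTVWY"))


def make_protein_set(
    n_per_group: int,
    sequon_rates: dict[str, float],
    seed: int = 1,
    length: int = 400,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Generate grouped protein sequences with Poisson-planted sequon counts.

    Sequences contain no background asparagines, so the number of counted
    sequons equals the planted number exactly. Returns the records and a
    truth mapping from protein id to planted sequon count.
    """
    rng = _rng(seed, _STREAM_PROTEIN)
    records, truth = [], {}
    for group, rate in sequon_rates.items():
        for i in range(n_per_group):
            seq = rng.choice(_AA_BACKGROUND, size=length)
            k = int(rng.poisson(rate))
            k = min(k, length // 4)  # keep motifs non-overlapping
            if k:
                slots = (rng.permutation(length // 4)[:k]) * 4
                for s in slots:
                    seq[s] = "N"
                    seq[s + 1] = rng.choice(_AA_X)
                    seq[s + 2] = "S" if rng.random() < 0.5 else "T"
            pid = f"{group}_vp4_{i}"
            records.append(ProteinRecord(id=pid, seq="".join(seq), group=group))
            truth[pid] = k
    return records, truth


@dataclass
class StructureTruth:
    bridges: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(default_factory=list)
    clusters: list[list[tuple[str, int, str]]] = field(default_factory=list)


_POLAR = ["SER", "THR", "ASN", "GLN", "GLY"]
_CHARGED = ["ASP", "GLU", "LYS", "ARG", "HIS"]
_HPHOB = ["LEU", "ILE", "VAL", "PHE", "MET", "ALA"]

_SIDE_ATOMS = {
    "ASP": ("CB", "OD1", "OD2"),
    "GLU": ("CB", "OE1", "OE2"),
    "LYS": ("CB", "NZ"),
    "ARG": ("CB", "NE", "NH1", "NH2"),
    "HIS": ("CB", "ND1", "NE2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CD1"),
    "VAL": ("CB", "CG1", "CG2"),
    "PHE": ("CB", "CG", "CZ"),
    "MET": ("CB", "CG", "SD"),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1"),
    "ASN": ("CB", "OD1", "ND2"),
    "GLN": ("CB", "OE1", "NE2"),
    "GLY": (),
}


def _self_avoiding_walk(rng: np.random.Generator, n: int, step: float = 3.8, min_dist: float = 4.2) -> np.ndarray:
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(200):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * step
            cand = pts[-1] + v
            d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1) if len(pts) > 1 else np.array([min_dist + 1])
            if d.min() >= min_dist:
                pts.append(cand)
                break
        else:  # restart the tail on pathological dead ends
            pts.append(pts[-1] + rng.normal(size=3) * step)
    return np.asarray(pts)


def make_toy_structure(
    n_res: int = 50,
    planted_bridges: int = 2,
    planted_cluster_sizes: tuple[int, ...] = (4,),
    seed: int = 1,
) -> tuple[StructureModel, StructureTruth]:
    """Build a pseudo-protein on a self-avoiding walk with planted features.

    CA atoms sit on a 3.8-A self-avoiding random walk; each residue carries
    idealized side-chain pseudo-atoms near its CA. For each planted salt
    bridge an acidic carboxylate oxygen is moved within 3.0 A of a basic
    nitrogen; planted hydrophobic clusters have their side-chain atoms packed
    into a tight ball (pairwise within 4.0 A). Background residues include
    charged and hydrophobic ones, so chance features may exist; they are
    detectable by the same rules (truth lists only the planted features).
    """
    rng = _rng(seed, _STREAM_STRUCTURE)
    need = 2 * planted_bridges + sum(planted_cluster_sizes)
    if n_res < need + 2:
        raise ValueError(f"n_res={n_res} too small for the planted features ({need} residues)")
    ca = _self_avoiding_walk(rng, n_res)
    pool = list(_POLAR) * 4 + list(_CHARGED) + list(_HPHOB)
    names = [pool[i] for i in rng.integers(0, len(pool), size=n_res)]

    order = rng.permutation(n_res)
    cursor = 0
    bridge_pairs = []
    for _ in range(planted_bridges):
        ia, ib = int(order[cursor]), int(order[cursor + 1])
        cursor += 2
        names[ia] = str(rng.choice(["ASP", "GLU"]))
        names[ib] = str(rng.choice(["LYS", "ARG", "HIS"]))
        bridge_pairs.append((ia, ib))
    cluster_sets = []
    for size in planted_cluster_sizes:
        members = [int(order[cursor + j]) for j in range(size)]
        cursor += size
        for m in members:
            names[m] = str(rng.choice(["LEU", "ILE", "PHE", "VAL"]))
        cluster_sets.append(members)

    coords: dict[int, dict[str, np.ndarray]] = {}
    for i in range(n_res):
        at = {"CA": ca[i]}
        for j, an in enumerate(_SIDE_ATOMS[names[i]]):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            at[an] = ca[i] + direction * (1.5 + 0.5 * j)
        coords[i] = at

    truth = StructureTruth()
    for ia, ib in bridge_pairs:
        basic_atom = _SIDE_ATOMS[names[ib]][-1]
        acid_atom = _SIDE_ATOMS[names[ia]][-1]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[ia][acid_atom] = coords[ib][basic_atom] + direction * 3.0
        truth.bridges.append((("A", ia + 1, names[ia]), ("A", ib + 1, names[ib])))
    for members in cluster_sets:
        center = ca[members[0]] + rng.normal(size=3)
        for m in members:
            for an in _SIDE_ATOMS[names[m]]:
                if an == "CB":
                    continue
                coords[m][an] = center + rng.normal(size=3) * 0.6
        truth.clusters.append(sorted(("A", m + 1, names[m]) for m in members))

    atoms = [
        Atom("A", i + 1, names[i], an, float(xyz[0]), float(xyz[1]), float(xyz[2]))
        for i in range(n_res)
        for an, xyz in coords[i].items()
    ]
    model = StructureModel(protein_id=f"toy_seed{seed}", atoms=atoms)
    return model, truth
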