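"""Adaptation-signature scoring of VP4-like fusogens.

Sequence-level: N-glycosylation sequons (N-X-S/T, X != P). Structure-level:
salt bridges between acidic and basic side chains, hydrophobic side-chain
contact clusters, and a surface-charge summary using a CA-neighbor-count
burial proxy. Group differences are assessed with the unpaired two-sided
Student t-test (pooled variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from .records import ProteinRecord, StructureModel

log = logging.getLogger(__name__)

ACIDIC = {"ASP", "GLU"}
BASIC = {"ARG", "LYS", "HIS"}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
# residue charges at pH 7; HIS participates in salt-bridge contacts but is
# treated as neutral in the net-charge sum
RESIDUE_CHARGE = {"ASP": -1, "GLU": -1, "ARG": +1, "LYS": +1}


@dataclass(frozen=True)
class SequonHit:
    protein_id: str
    position: int  # 1-based index of the N
    triplet: str


def count_sequons(protein: ProteinRecord) -> list[SequonHit]:
    """Find all N-glycosylation sequons N-X-S/T with X any residue but proline.

    Every overlapping window is scanned, so overlapping sequons (e.g. NNSS)
    are each counted.
    """
    seq = protein.seq.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            hits.append(SequonHit(protein.id, i + 1, seq[i : i + 3]))
    return hits


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple[str, int, str]  # (chain, residue number, residue name)
    basic: tuple[str, int, str]
    distance: float


def _charged_atoms(model: StructureModel, atom_sets: dict) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    keys, coords = [], []
    for (chain, num), res in model.residues().items():
        names = atom_sets.get(res["name"])
        if names is None:
            continue
        present = [n for n in names if n in res["atoms"]]
        if not present:
            log.warning("residue %s %s%d missing charged side-chain atoms; skipped", res["name"], chain, num)
            continue
        for n in present:
            keys.append((chain, num, res["name"]))
            coords.append(res["atoms"][n])
    return keys, np.asarray(coords, dtype=float).reshape(-1, 3)


def find_salt_bridges(model: StructureModel, cutoff: float = 4.0) -> list[SaltBridge]:
    """Salt bridges: any acidic carboxylate O within ``cutoff`` A of a basic N.

    One bridge is reported per residue pair, carrying the minimum atom-pair
    distance; sorted by chain and residue number.
    """
    akeys, acoords = _charged_atoms(model, ACIDIC_ATOMS)
    bkeys, bcoords = _charged_atoms(model, BASIC_ATOMS)
    if not akeys or not bkeys:
        return []
    d = cdist(acoords, bcoords)
    best: dict[tuple, float] = {}
    for ai, bi in zip(*np.nonzero(d <= cutoff)):
        pair = (akeys[ai], bkeys[bi])
        dist = float(d[ai, bi])
        if pair not in best or dist < best[pair]:
            best[pair] = dist
    bridges = [SaltBridge(acidic=a, basic=b, distance=dist) for (a, b), dist in best.items()]
    bridges.sort(key=lambda sb: (sb.acidic, sb.basic))
    return bridges


@dataclass
class HydrophobicCluster:
    members: list[tuple[str, int, str]]
    size: int


def find_hydrophobic_clusters(
    model: StructureModel, contact: float = 4.5, min_size: int = 3
) -> list[HydrophobicCluster]:
    """Connected components of hydrophobic residues in side-chain contact.

    Two hydrophobic residues are in contact when any pair of their side-chain
    heavy atoms lies within ``contact`` A. Components with at least
    ``min_size`` members are reported, largest first.
    """
    keys, coords, owner = [], [], []
    for (chain, num), res in model.residues().items():
        if res["name"] not in HYDROPHOBIC:
            continue
        key = (chain, num, res["name"])
        side = [xyz for n, xyz in res["atoms"].items() if n not in BACKBONE_ATOMS and not n.startswith("H")]
        if not side:
            continue
        keys.append(key)
        for xyz in side:
            coords.append(xyz)
            owner.append(len(keys) - 1)
    if not keys:
        return []
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    d = cdist(coords, coords)
    g = nx.Graph()
    g.add_nodes_from(range(len(keys)))
    for i, j in zip(*np.nonzero(d <= contact)):
        if owner[i] != owner[j]:
            g.add_edge(int(owner[i]), int(owner[j]))
    clusters = [
        HydrophobicCluster(members=sorted(keys[i] for i in comp), size=len(comp))
        for comp in nx.connected_components(g)
        if len(comp) >= min_size
    ]
    clusters.sort(key=lambda c: (-c.size, c.members))
    return clusters


@dataclass
class SurfaceCharge:
    net_charge: int
    exposed_negative_fraction: float
    defined: bool  # False when no exposed charged residues exist


def surface_charge(
    model: StructureModel,
    exposure_neighbor_radius: float = 10.0,
    exposure_max_neighbors: int = 18,
) -> SurfaceCharge:
    """Net residue charge and the exposed-acidic fraction of charged residues.

    A residue counts as exposed when its CA has at most
    ``exposure_max_neighbors`` other CA atoms within the radius — a burial
    proxy that needs no solvent-accessibility computation.
    """
    residues = model.residues()
    cas, names = [], []
    for res in residues.values():
        if "CA" in res["atoms"]:
            cas.append(res["atoms"]["CA"])
            names.append(res["name"])
    if len(cas) < 10:
        raise ValueError("structure has fewer than 10 CA residues; exposure proxy is meaningless")
    cas = np.asarray(cas)
    d = cdist(cas, cas)
    neighbor_counts = (d <= exposure_neighbor_radius).sum(axis=1) - 1  # exclude self
    exposed = neighbor_counts <= exposure_max_neighbors
    net = sum(RESIDUE_CHARGE.get(n, 0) for n in names)
    exp_acid = sum(1 for n, e in zip(names, exposed) if e and n in ACIDIC)
    exp_charged = sum(1 for n, e in zip(names, exposed) if e and (n in ACIDIC or n in {"ARG", "LYS"}))
    if exp_charged == 0:
        return SurfaceCharge(net_charge=net, exposed_negative_fraction=0.0, defined=False)
    return SurfaceCharge(net, exp_acid / exp_charged, True)


@dataclass
class SignatureReport:
    protein_id: str
    group: Optional[str]
    n_sequons: int = 0
    n_salt_bridges: int = 0
    n_clusters: int = 0
    net_charge: int = 0
    exposed_negative_fraction: float = 0.0


def build_report(
    protein: ProteinRecord,
    structure: Optional[StructureModel] = None,
    trim_range: Optional[tuple[int, int]] = None,
) -> SignatureReport:
    """Aggregate all signatures for one protein.

    ``trim_range`` (1-based inclusive residue range) restricts the sequence to
    a user-supplied core, e.g. after removing terminal transmembrane spans.
    """
    seq = protein.seq
    if trim_range:
        seq = seq[trim_range[0] - 1 : trim_range[1]]
        protein = ProteinRecord(protein.id, seq, protein.group)
    rep = SignatureReport(protein_id=protein.id, group=protein.group)
    rep.n_sequons = len(count_sequons(protein))
    if structure is not None:
        rep.n_salt_bridges = len(find_salt_bridges(structure))
        rep.n_clusters = len(find_hydrophobic_clusters(structure))
        sc = surface_charge(structure)
        rep.net_charge = sc.net_charge
        rep.exposed_negative_fraction = sc.exposed_negative_fraction
    return rep


@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def ttest_unpaired(xs, ys) -> GroupComparison:
    """Student's unpaired two-sided t-test with pooled variance.

    t = (mean1 - mean2) / sqrt(s_p^2 (1/n1 + 1/n2)), df = n1 + n2 - 2;
    the p-value comes from the t distribution's survival function.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1, m2 = xs.mean(), ys.mean()
    v1, v2 = xs.var(ddof=1), ys.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return GroupComparison(0.0, 1.0, m1, m2, 0.0, 0.0, n1, n2)
        warnings.warn("zero pooled variance with unequal means; p set to 0")
        return GroupComparison(np.inf if m1 > m2 else -np.inf, 0.0, m1, m2, 0.0, 0.0, n1, n2)
    tval = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * t_dist.sf(abs(tval), df=n1 + n2 - 2)
    return GroupComparison(float(tval), float(p), float(m1), float(m2), float(np.sqrt(v1)), float(np.sqrt(v2)), n1, n2)


FEATURES = ("n_sequons", "n_salt_bridges", "n_clusters", "net_charge", "exposed_negative_fraction")


def compare_groups(reports: list[SignatureReport], feature: str, groups: tuple[str, str]) -> GroupComparison:
    """Unpaired t-test of one signature feature between two host-lineage groups."""
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")
    ga, gb = groups
    xs = [getattr(r, feature) for r in reports if r.group == ga]
    ys = [getattr(r, feature) for r in reports if r.group == gb]
    return ttest_unpaired(xs, ys)
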