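"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately uses a different algorithm than the implementation
it checks: diagonal run-scanning instead of k-mer seeding, full-matrix Gotoh
DP instead of Biopython's aligner, regex lookahead instead of the window
scanner, all-atom-pair loops instead of cdist-based detection, and a plain
union-find instead of networkx components.
"""

from __future__ import annotations

import math
import re

import numpy as np
from Bio.Align import substitution_matrices

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR"}
BACKBONE = {"N", "CA", "C", "O", "OXT"}


def brute_force_repeat_pairs(seq, min_len, max_len, min_sep, max_sep):
    """All maximal exact direct-repeat pairs via per-diagonal run scanning."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    out = set()
    for d in range(min_sep, min(max_sep, n - min_len) + 1):
        eq = (arr[:-d] == arr[d:]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            length = int(e - s)
            if min_len <= length <= max_len:
                out.add((int(s), int(s) + d, length))
    return out


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(a, b, gap_open=-11.0, gap_extend=-1.0):
    """Optimal global affine-gap alignment score (gap of L costs open+(L-1)*extend).

    Terminal gaps are penalized, matching a fully global alignment.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    Y = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Y[i, 0] = gap_open + (i - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_extend, Y[i, j - 1] + gap_open)
            Y[i, j] = max(M[i - 1, j] + gap_open, Y[i - 1, j] + gap_extend, X[i - 1, j] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


_SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


def regex_sequon_positions(seq):
    """1-based sequon positions via overlap-aware regex lookahead."""
    return [m.start() + 1 for m in _SEQUON_RE.finditer(seq)]


def _residue_atoms(model):
    res = {}
    for a in model.atoms:
        entry = res.setdefault((a.chain, a.res_number), {"name": a.res_name, "atoms": {}})
        entry["atoms"].setdefault(a.atom_name, (a.x, a.y, a.z))
    return res


def brute_force_salt_bridges(model, cutoff=4.0):
    """Acidic/basic residue pairs with any charged-atom pair within cutoff."""
    residues = _residue_atoms(model)
    pairs = {}
    items = list(residues.items())
    for (ka, ra) in items:
        names_a = ACIDIC_ATOMS.get(ra["name"])
        if not names_a:
            continue
        for (kb, rb) in items:
            names_b = BASIC_ATOMS.get(rb["name"])
            if not names_b:
                continue
            dmin = None
            for an in names_a:
                if an not in ra["atoms"]:
                    continue
                for bn in names_b:
                    if bn not in rb["atoms"]:
                        continue
                    d = math.dist(ra["atoms"][an], rb["atoms"][bn])
                    if dmin is None or d < dmin:
                        dmin = d
            if dmin is not None and dmin <= cutoff:
                pairs[((ka[0], ka[1], ra["name"]), (kb[0], kb[1], rb["name"]))] = dmin
    return pairs


def brute_force_clusters(model, contact=4.5, min_size=3):
    """Hydrophobic contact components via explicit union-find."""
    residues = _residue_atoms(model)
    keys, sides = [], []
    for (chain, num), r in residues.items():
        if r["name"] not in HYDROPHOBIC:
            continue
        side = [xyz for n, xyz in r["atoms"].items() if n not in BACKBONE and not n.startswith("H")]
        if side:
            keys.append((chain, num, r["name"]))
            sides.append(side)
    parent = list(range(len(keys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if any(math.dist(p, q) <= contact for p in sides[i] for q in sides[j]):
                parent[find(i)] = find(j)
    comps = {}
    for i, k in enumerate(keys):
        comps.setdefault(find(i), []).append(k)
    return sorted(
        (sorted(members) for members in comps.values() if len(members) >= min_size),
        key=lambda m: (-len(m), m),
    )


def brute_force_exposure(model, radius=10.0, max_neighbors=18):
    """Per-residue exposure labels by counting CA neighbors with plain loops."""
    residues = _residue_atoms(model)
    cas = [(k, r["atoms"]["CA"]) for k, r in residues.items() if "CA" in r["atoms"]]
    labels = {}
    for k, ca in cas:
        n = sum(1 for k2, ca2 in cas if k2 != k and math.dist(ca, ca2) <= radius)
        labels[k] = n <= max_neighbors
    return labels
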