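"""Core domain types shared across the pipeline.

All genomic intervals are 0-based, half-open ``[start, end)`` on the forward
strand. Conversion to 1-based inclusive coordinates happens only inside the
GFF/GenBank readers and writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

NUCLEOTIDES = set("ACGTN")
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")

FEATURE_KINDS = ("tRNA", "integrase", "CDS", "repeat", "other")


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a genome (0-based half-open)."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Feature") -> bool:
        return self.start < other.end and other.start < self.end

    def gap_to(self, other: "Feature") -> int:
        """End-to-nearest-end distance between two intervals; 0 if they overlap."""
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with optional feature annotations."""

    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"invalid topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.label!r} [{f.start},{f.end}) outside genome "
                    f"{self.id!r} of length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally tagged with a host-lineage group."""

    id: str
    seq: str
    group: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - AA_LETTERS - {"*"}
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid letters {sorted(bad)}")


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    """Labeled atoms of one protein model (coordinates in Angstrom)."""

    protein_id: str
    atoms: list[Atom]

    def __post_init__(self):
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate in atom {a}")

    def residues(self) -> dict[tuple[str, int], dict]:
        """Group atoms by (chain, residue number) preserving order.

        Returns a mapping to ``{"name": res_name, "atoms": {atom_name: (x,y,z)}}``.
        """
        out: dict[tuple[str, int], dict] = {}
        for a in self.atoms:
            key = (a.chain, a.res_number)
            entry = out.setdefault(key, {"name": a.res_name, "atoms": {}})
            entry["atoms"].setdefault(a.atom_name, (a.x, a.y, a.z))
        return out

    def n_residues(self) -> int:
        return len({(a.chain, a.res_number) for a in self.atoms})


__all__ = [
    "Feature",
    "GenomeRecord",
    "ProteinRecord",
    "Atom",
    "StructureModel",
    "FEATURE_KINDS",
]
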