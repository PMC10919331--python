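"""Readers and writers for the formats the pipeline touches.

FASTA and GenBank go through Biopython; PDB and mmCIF go through gemmi.
GFF3 and BED are flat tab-separated formats serialized directly. All readers
normalize to the internal convention: 0-based half-open intervals, uppercase
sequences over {A,C,G,T,N}.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Iterable, Optional

import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import Atom, Feature, GenomeRecord, ProteinRecord, StructureModel

log = logging.getLogger(__name__)

# keyword list used to promote a CDS to kind=integrase; configurable because
# annotation pipelines label tyrosine recombinases inconsistently
INTEGRASE_KEYWORDS = ("integrase", "recombinase", "xerc", "xerd")

_NON_ACGTN = re.compile(r"[^ACGTN]")


def _clean_nt(seq: str, context: str) -> str:
    s = str(seq).upper()
    if _NON_ACGTN.search(s):
        n_bad = len(_NON_ACGTN.findall(s))
        log.warning("%s: %d non-ACGTN characters replaced with N", context, n_bad)
        s = _NON_ACGTN.sub("N", s)
    return s


def _is_integrase(texts: Iterable[str], keywords=INTEGRASE_KEYWORDS) -> bool:
    joined = " ".join(texts).lower()
    return any(k in joined for k in keywords)


def _features_from_genbank(rec) -> list[Feature]:
    feats = []
    for f in rec.features:
        if f.type not in ("tRNA", "CDS"):
            continue
        start = int(f.location.start)
        end = int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        quals = f.qualifiers
        texts = [t for key in ("product", "note", "function", "gene") for t in quals.get(key, [])]
        label = next(iter(quals.get("gene", []) or quals.get("product", []) or quals.get("locus_tag", [])), "")
        if f.type == "tRNA":
            kind = "tRNA"
        elif _is_integrase(texts):
            kind = "integrase"
        else:
            kind = "CDS"
        feats.append(Feature(kind=kind, start=start, end=end, strand=strand, label=label))
    return feats


def read_genome(path: str, format: str = "fasta") -> list[GenomeRecord]:
    """Read FASTA or GenBank into GenomeRecords.

    GenBank tRNA features map to kind=tRNA; CDS features whose annotation
    mentions an integrase keyword map to kind=integrase, others to kind=CDS.
    A ``topology=circular`` token in a FASTA description, or the GenBank
    topology field, marks the record circular.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported genome format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    out = []
    try:
        for i, rec in enumerate(SeqIO.parse(path, format)):
            topology = "linear"
            if format == "genbank":
                topology = rec.annotations.get("topology", "linear")
                feats = _features_from_genbank(rec)
            else:
                feats = []
                if "circular" in rec.description.lower():
                    topology = "circular"
            out.append(
                GenomeRecord(
                    id=rec.id,
                    seq=_clean_nt(rec.seq, f"{path}:{rec.id}"),
                    topology=topology if topology in ("linear", "circular") else "linear",
                    features=feats,
                )
            )
    except ValueError as e:
        raise ValueError(f"{path}: parse error in record {len(out) + 1}: {e}") from e
    if not out:
        raise ValueError(f"{path}: no {format} records found")
    return out


def read_proteins(path: str, groups: Optional[dict[str, str]] = None) -> list[ProteinRecord]:
    """Read a protein FASTA; ``groups`` maps record id to host-lineage label."""
    groups = groups or {}
    out = [
        ProteinRecord(id=rec.id, seq=str(rec.seq).upper(), group=groups.get(rec.id))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not out:
        raise ValueError(f"{path}: no fasta records found")
    return out


# ---------------------------------------------------------------- structures


def read_structure(path: str, format: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF protein model.

    Waters and heteroatoms are excluded. Alternate locations are resolved to
    the highest-occupancy conformer, ties to the first one encountered.
    """
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if format == "pdb":
        st = gemmi.read_pdb(path)
    elif format == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unsupported structure format {format!r}")
    st.setup_entities()
    atoms: list[Atom] = []
    has_ca = False
    for chain in st[0]:
        for res in chain:
            if res.is_water() or res.het_flag != "A":
                continue
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for name, at in best.items():
                if name == "CA":
                    has_ca = True
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_number=res.seqid.num,
                        res_name=res.name,
                        atom_name=name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                    )
                )
    if not atoms or not has_ca:
        raise ValueError(f"{path}: no protein atoms (CA) found")
    return StructureModel(protein_id=st.name or os.path.basename(path), atoms=atoms)


def _structure_to_gemmi(model: StructureModel) -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy their argument, so group atoms first
    # and only then build the hierarchy bottom-up
    grouped: dict[str, dict[int, tuple[str, list[Atom]]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain, {}).setdefault(a.res_number, (a.res_name, []))[1].append(a)
    st = gemmi.Structure()
    st.name = model.protein_id
    gmodel = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        ch = gemmi.Chain(chain_name)
        for num in sorted(residues):
            res_name, atoms = residues[num]
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.occ = 1.0
                at.element = gemmi.Element(a.atom_name[0])
                res.add_atom(at)
            ch.add_residue(res)
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str, format: Optional[str] = None) -> None:
    """Write a StructureModel as PDB or mmCIF (chosen from the extension)."""
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = _structure_to_gemmi(model)
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unsupported structure format {format!r}")


# ------------------------------------------------------------ flat writers


def write_fasta(records, path: str) -> None:
    """Write GenomeRecords or ProteinRecords as FASTA wrapped at 60 columns."""
    seqrecs = []
    for r in records:
        desc = ""
        if isinstance(r, GenomeRecord) and r.topology == "circular":
            desc = "topology=circular"
        elif isinstance(r, ProteinRecord) and r.group:
            desc = f"group={r.group}"
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


def write_genbank(genome: GenomeRecord, path: str) -> None:
    """Write a GenomeRecord as a minimal GenBank flat file (fixture dialect)."""
    rec = SeqRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in genome.features:
        ftype = "tRNA" if f.kind == "tRNA" else "CDS"
        quals = {}
        if f.kind == "integrase":
            quals["product"] = ["integrase"]
        if f.label:
            quals["gene"] = [f.label]
        loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], path, "genbank")


_GFF_TYPE = {"tRNA": "tRNA", "integrase": "CDS", "CDS": "CDS", "repeat": "repeat_region", "other": "region"}


def write_gff(features: Iterable[Feature], path: str, seqid: str = "seq") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.label:
                attrs.append(f"Name={f.label}")
            if f.kind == "integrase":
                attrs.append("product=integrase")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "pleoprophage",
                        _GFF_TYPE[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def read_gff(path: str) -> list[Feature]:
    """Read a GFF3 file back into Features (inverse of :func:`write_gff`)."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "tRNA":
                kind = "tRNA"
            elif ftype in ("CDS", "gene"):
                kind = "integrase" if _is_integrase(attr_map.values()) else "CDS"
            elif ftype in ("repeat_region", "direct_repeat"):
                kind = "repeat"
            else:
                kind = "other"
            feats.append(
                Feature(
                    kind=kind,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    label=attr_map.get("Name", ""),
                )
            )
    return feats


def write_bed(features: Iterable[Feature], path: str, seqid: str = "seq") -> None:
    """Write features as BED (0-based half-open, as internally)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{seqid}\t{f.start}\t{f.end}\t{f.label or f.kind}\t0\t{f.strand}\n")
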