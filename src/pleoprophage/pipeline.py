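"""End-to-end orchestration: find -> excise -> annotate -> synteny -> signatures.

A run is driven by one YAML config, writes stage-named subdirectories, and
records a manifest with the config hash and per-file checksums so identical
configs yield byte-identical, verifiable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .genome_io import read_genome, read_gff, read_proteins, read_structure, write_fasta, write_gff
from .orfs import build_synteny_map, call_orfs, plot_synteny
from .provirus import FinderConfig, call_proviruses
from .records import GenomeRecord, ProteinRecord
from .signatures import FEATURES, build_report, compare_groups

log = logging.getLogger(__name__)

CALLS_SCHEMA = [
    "genome_id", "attL_start", "attL_end", "attR_start", "attR_end", "repeat_len",
    "repeat_seq", "interior_len", "circle_len", "trna_overlap", "integrase_distance", "score",
]
ORFS_SCHEMA = ["genome_id", "index", "start", "end", "strand", "length_aa"]
LINKS_SCHEMA = ["genome_a", "orf_a", "genome_b", "orf_b", "identity", "coverage"]
REPORTS_SCHEMA = [
    "protein_id", "group", "n_sequons", "n_salt_bridges", "n_clusters",
    "net_charge", "exposed_negative_fraction",
]


@dataclass
class RunConfig:
    genome: str
    annotations: Optional[str] = None
    out_dir: str = "run"
    seed: int = 1
    log_level: str = "INFO"
    finder: FinderConfig = field(default_factory=FinderConfig)
    orf_min_aa: int = 30
    orf_starts: tuple[str, ...] = ("ATG", "GTG", "TTG")
    synteny_genomes: list[str] = field(default_factory=list)
    protein_fasta: Optional[str] = None
    group_manifest: Optional[str] = None
    structures_dir: Optional[str] = None
    compare: Optional[tuple[str, str]] = None
    compare_feature: str = "n_sequons"


def validate_config(path: str) -> RunConfig:
    """Load and validate a YAML run config, reporting all errors at once."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError([f"config file not found: {path}"])
    except yaml.YAMLError as e:
        raise ConfigError([f"invalid YAML: {e}"])
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(["config must be a non-empty mapping"])

    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    if "genome" not in raw:
        errors.append("missing required key: genome")

    finder_raw = raw.get("finder", {})
    finder = FinderConfig()
    if isinstance(finder_raw, dict):
        fknown = {f.name for f in dataclasses.fields(FinderConfig)}
        bad = [k for k in finder_raw if k not in fknown]
        errors.extend(f"unknown finder key: {k}" for k in bad)
        try:
            finder = FinderConfig(**{k: v for k, v in finder_raw.items() if k not in bad})
        except (TypeError, ValueError) as e:
            errors.append(f"finder config invalid: {e}")
    else:
        errors.append("finder must be a mapping")

    for key in ("genome", "annotations", "protein_fasta", "group_manifest"):
        p = raw.get(key)
        if isinstance(p, str) and not os.path.exists(p):
            errors.append(f"{key}: path does not exist: {p}")
    for p in raw.get("synteny_genomes", []) or []:
        if not os.path.exists(p):
            errors.append(f"synteny_genomes: path does not exist: {p}")
    if raw.get("compare") is not None and len(raw["compare"]) != 2:
        errors.append("compare must name exactly two groups")
    if raw.get("compare_feature", "n_sequons") not in FEATURES:
        errors.append(f"compare_feature must be one of {FEATURES}")

    if errors:
        raise ConfigError(errors)
    kwargs = {k: v for k, v in raw.items() if k in known and k != "finder"}
    if "compare" in kwargs and kwargs["compare"] is not None:
        kwargs["compare"] = tuple(kwargs["compare"])
    if "orf_starts" in kwargs:
        kwargs["orf_starts"] = tuple(kwargs["orf_starts"])
    return RunConfig(finder=finder, **kwargs)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: str, schema: list[str]) -> None:
    df = df.reindex(columns=schema)
    df.to_csv(path, sep="\t", index=False)
    with open(path + ".schema.json", "w") as fh:
        json.dump({"columns": schema}, fh, indent=1)


def run_pipeline(cfg: RunConfig) -> str:
    """Run every configured stage; returns the run directory.

    Stage outputs land under ``<out_dir>/<stage>/``; ``manifest.json``
    records the config hash, package version, and a checksum for every
    output file. Reruns with an identical config reproduce identical
    checksums.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"))
    logging.getLogger().addHandler(fh)
    log.info("seed = %d", cfg.seed)
    outputs: list[str] = []
    try:
        genomes = _read_annotated_genome(cfg)
        stage = os.path.join(cfg.out_dir, "find")
        os.makedirs(stage, exist_ok=True)
        all_calls = []
        circles: list[GenomeRecord] = []
        for g in genomes:
            calls = call_proviruses(g, cfg.finder)
            for ci, c in enumerate(calls):
                all_calls.append(
                    {
                        "genome_id": c.genome_id,
                        "attL_start": c.attL.start,
                        "attL_end": c.attL.end,
                        "attR_start": c.attR.start,
                        "attR_end": c.attR.end,
                        "repeat_len": len(c.attL),
                        "repeat_seq": c.repeat_seq,
                        "interior_len": c.interior_len,
                        "circle_len": c.circle_len,
                        "trna_overlap": c.trna_overlap is not None,
                        "integrase_distance": c.integrase_distance,
                        "score": c.score,
                    }
                )
                circles.append(
                    GenomeRecord(id=f"{c.genome_id}_provirus{ci + 1}", seq=c.circular_genome, topology="circular")
                )
            feats = [f for c in calls for f in (c.attL, c.attR)]
            write_gff(feats, os.path.join(stage, f"{g.id}.att.gff3"), seqid=g.id)
            outputs.append(os.path.join(stage, f"{g.id}.att.gff3"))
        _write_table(pd.DataFrame(all_calls), os.path.join(stage, "calls.tsv"), CALLS_SCHEMA)
        outputs.append(os.path.join(stage, "calls.tsv"))
        if circles:
            write_fasta(circles, os.path.join(stage, "circles.fasta"))
            outputs.append(os.path.join(stage, "circles.fasta"))

        stage = os.path.join(cfg.out_dir, "annotate")
        os.makedirs(stage, exist_ok=True)
        orf_rows, proteins = [], []
        orfs_per_circle = []
        for circ in circles:
            orfs = call_orfs(circ.seq, "circular", cfg.orf_min_aa, cfg.orf_starts, genome_id=circ.id)
            orfs_per_circle.append(orfs)
            for o in orfs:
                orf_rows.append(
                    {
                        "genome_id": o.genome_id,
                        "index": o.index,
                        "start": o.start,
                        "end": o.end,
                        "strand": o.strand,
                        "length_aa": len(o.translation),
                    }
                )
                proteins.append(ProteinRecord(id=f"{o.genome_id}_orf{o.index}", seq=o.translation))
        _write_table(pd.DataFrame(orf_rows), os.path.join(stage, "orfs.tsv"), ORFS_SCHEMA)
        outputs.append(os.path.join(stage, "orfs.tsv"))
        if proteins:
            write_fasta(proteins, os.path.join(stage, "proteins.fasta"))
            outputs.append(os.path.join(stage, "proteins.fasta"))

        if len(circles) >= 2 or cfg.synteny_genomes:
            stage = os.path.join(cfg.out_dir, "synteny")
            os.makedirs(stage, exist_ok=True)
            syn_genomes = [c.id for c in circles]
            syn_lengths = [len(c.seq) for c in circles]
            syn_orfs = orfs_per_circle
            for path in cfg.synteny_genomes:
                for g in read_genome(path, "fasta"):
                    syn_genomes.append(g.id)
                    syn_lengths.append(len(g.seq))
                    syn_orfs.append(call_orfs(g.seq, g.topology, cfg.orf_min_aa, cfg.orf_starts, genome_id=g.id))
            if len(syn_genomes) >= 2:
                links = build_synteny_map(syn_genomes, syn_orfs)
                rows = [
                    {
                        "genome_a": ln.orf_a.genome_id,
                        "orf_a": ln.orf_a.index,
                        "genome_b": ln.orf_b.genome_id,
                        "orf_b": ln.orf_b.index,
                        "identity": round(ln.identity, 2),
                        "coverage": round(ln.coverage, 3),
                    }
                    for ln in links
                ]
                _write_table(pd.DataFrame(rows), os.path.join(stage, "links.tsv"), LINKS_SCHEMA)
                outputs.append(os.path.join(stage, "links.tsv"))
                plot_synteny(syn_genomes, syn_lengths, syn_orfs, links, os.path.join(stage, "synteny.svg"))
                outputs.append(os.path.join(stage, "synteny.svg"))

        if cfg.protein_fasta:
            stage = os.path.join(cfg.out_dir, "signatures")
            os.makedirs(stage, exist_ok=True)
            groups = {}
            if cfg.group_manifest:
                man = pd.read_csv(cfg.group_manifest, sep="\t")
                groups = dict(zip(man.iloc[:, 0], man.iloc[:, 1]))
            prots = read_proteins(cfg.protein_fasta, groups)
            reports = []
            for p in prots:
                st = None
                if cfg.structures_dir:
                    cand = os.path.join(cfg.structures_dir, f"{p.id}.pdb")
                    if os.path.exists(cand):
                        st = read_structure(cand)
                reports.append(build_report(p, st))
            rows = [dataclasses.asdict(r) for r in reports]
            _write_table(pd.DataFrame(rows), os.path.join(stage, "reports.tsv"), REPORTS_SCHEMA)
            outputs.append(os.path.join(stage, "reports.tsv"))
            if cfg.compare:
                cmp_res = compare_groups(reports, cfg.compare_feature, cfg.compare)
                with open(os.path.join(stage, "comparison.json"), "w") as f:
                    json.dump(dataclasses.asdict(cmp_res), f, indent=1)
                outputs.append(os.path.join(stage, "comparison.json"))
    except Exception:
        log.exception("pipeline stage failed; partial outputs retained in %s", cfg.out_dir)
        raise
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    cfg_dict = dataclasses.asdict(cfg)
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "outputs": {os.path.relpath(p, cfg.out_dir): _sha256(p) for p in outputs},
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return cfg.out_dir


def _read_annotated_genome(cfg: RunConfig) -> list[GenomeRecord]:
    fmt = "genbank" if cfg.genome.endswith((".gb", ".gbk", ".gbff", ".genbank")) else "fasta"
    genomes = read_genome(cfg.genome, fmt)
    if cfg.annotations:
        feats = read_gff(cfg.annotations)
        genomes[0].features.extend(feats)
    return genomes
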