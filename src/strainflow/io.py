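"""Readers and writers for every interchange format, plus run configuration.

Formats are plain text throughout: pileup TSV (sample_id, gene_id,
0-based pos, nA, nC, nG, nT), genus count TSV (samples × genera),
metadata/biomarker CSV, truth JSON, gene-per-record reference FASTA, and
newick trees.  A ``RunConfig`` gathers every pipeline threshold and is
serialized (with a hash) into each output manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_cohort import BASES, AlleleCountTable, GeneCatalog

PILEUP_COLUMNS = ["sample_id", "gene_id", "pos", "nA", "nC", "nG", "nT"]

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def write_pileup_tsv(table: AlleleCountTable, path) -> None:
    table.to_long_frame().to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path, catalog: GeneCatalog) -> AlleleCountTable:
    """Read a pileup TSV; duplicate (sample, gene, pos) rows are summed
    with a warning; negative counts or malformed positions raise a parse
    error naming the line."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    if list(frame.columns) != PILEUP_COLUMNS:
        raise ValueError(f"pileup header must be exactly {PILEUP_COLUMNS}")
    for col in ["pos", "nA", "nC", "nG", "nT"]:
        bad = pd.to_numeric(frame[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"malformed value in column {col!r} at line {line}")
    counts = frame[["nA", "nC", "nG", "nT"]].to_numpy()
    if (counts < 0).any():
        line = int(np.argwhere((counts < 0).any(axis=1))[0][0]) + 2
        raise ValueError(f"negative count at line {line}")
    dup = frame.duplicated(subset=["sample_id", "gene_id", "pos"])
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate pileup rows summed")
        frame = (
            frame.groupby(["sample_id", "gene_id", "pos"], as_index=False, sort=False)[
                ["nA", "nC", "nG", "nT"]
            ].sum()
        )
    return AlleleCountTable.from_long_frame(frame, catalog)


def read_vcf_allele_counts(path, catalog: GeneCatalog) -> AlleleCountTable:
    """Import a minimal VCF into an allele-count table.

    Expects CHROM = gene id, 1-based POS (converted to 0-based), single-base
    REF/ALT alleles, and a per-sample AD (allelic depths) field.  Non-SNV
    alleles are skipped with a warning; missing AD entries contribute no
    counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    gidx = catalog.gene_index()
    counts = {
        s: np.zeros((catalog.total_length, 4), dtype=np.uint32) for s in samples
    }
    skipped = 0
    for rec in vcf:
        if rec.CHROM not in gidx:
            raise KeyError(f"VCF contig {rec.CHROM!r} not in catalog")
        alleles = [rec.REF] + list(rec.ALT)
        if any(len(a) != 1 or a not in _BASE_CODE for a in alleles):
            skipped += 1
            continue
        g = gidx[rec.CHROM]
        pos0 = rec.POS - 1
        if not 0 <= pos0 < catalog.lengths[g]:
            raise ValueError(f"VCF POS {rec.POS} outside gene {rec.CHROM}")
        flat = catalog.offsets[g] + pos0
        ad = rec.format("AD")
        if ad is None:
            continue
        for si, s in enumerate(samples):
            for a, d in zip(alleles, ad[si]):
                if d > 0:
                    counts[s][flat, _BASE_CODE[a]] += int(d)
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNV VCF records")
    return AlleleCountTable(catalog, counts)


# ---------------------------------------------------------------------------
# FASTA references, catalogs, trees
# ---------------------------------------------------------------------------


def write_fasta_refs(
    sequences: dict[str, np.ndarray], catalog: GeneCatalog, path
) -> None:
    """Write reference strains gene-per-record (``>strain|gene_id``)."""
    records = []
    for sid, seq in sequences.items():
        for g, gid in enumerate(catalog.gene_ids):
            sub = seq[catalog.offsets[g]: catalog.offsets[g + 1]]
            records.append(
                SeqRecord(Seq("".join(BASES[sub])), id=f"{sid}|{gid}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_fasta_refs(path, catalog: GeneCatalog) -> dict[str, np.ndarray]:
    """Read gene-per-record references; IDs must match catalog gene ids."""
    per_strain: dict[str, dict[str, np.ndarray]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"reference record id {rec.id!r} must be 'strain|gene_id'")
        sid, gid = rec.id.split("|", 1)
        per_strain.setdefault(sid, {})[gid] = np.array(
            [_BASE_CODE[b] for b in str(rec.seq).upper()], dtype=np.int8
        )
    gidx = catalog.gene_index()
    out = {}
    for sid, genes in per_strain.items():
        missing = [g for g in catalog.gene_ids if g not in genes]
        unknown = [g for g in genes if g not in gidx]
        if missing or unknown:
            raise ValueError(
                f"reference {sid}: missing genes {missing[:5]}, unknown genes {unknown[:5]}"
            )
        seq = np.empty(catalog.total_length, dtype=np.int8)
        for gid, arr in genes.items():
            g = gidx[gid]
            if arr.shape[0] != catalog.lengths[g]:
                raise ValueError(f"reference {sid} gene {gid}: length mismatch")
            seq[catalog.offsets[g]: catalog.offsets[g + 1]] = arr
        out[sid] = seq
    return out


def write_catalog_json(catalog: GeneCatalog, path) -> None:
    payload = {
        "gene_ids": catalog.gene_ids,
        "lengths": catalog.lengths.tolist(),
        "sequence": "".join(BASES[catalog.sequence]),
    }
    Path(path).write_text(json.dumps(payload))


def read_catalog_json(path) -> GeneCatalog:
    payload = json.loads(Path(path).read_text())
    seq = np.array([_BASE_CODE[b] for b in payload["sequence"]], dtype=np.int8)
    return GeneCatalog(payload["gene_ids"], np.asarray(payload["lengths"]), seq)


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def read_table(path, **kwargs) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, **kwargs)


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every pipeline threshold plus paths and seeds, serialized for provenance."""

    outdir: str = "strainflow_out"
    seed: int = 0
    # typing thresholds
    af_threshold: float = 0.90
    min_depth: int = 4
    min_reads: int = 250
    min_genes: int = 10
    gene_low_af_max: float = 0.20
    low_abund_threshold: float = 0.0016
    probiotic_radius: float = 0.001
    het_max: float = 0.002
    min_shared: int = 1000
    # community typing
    kmax: int = 15
    restarts: int = 10
    library_size: int = 10000
    # ecology / trial
    n_perm: int = 1000
    margin: float = -3.6
    # synthetic generation
    simulate: dict = field(default_factory=dict)
    tree_max_tips: int = 150

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, stage: str, outputs: dict[str, str], outdir) -> None:
    """Per-stage manifest: resolved config, hash, and output file hashes."""
    man = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": {},
    }
    for name, p in outputs.items():
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.exists() else None
        man["outputs"][name] = {"path": str(p), "sha256": digest}
    Path(outdir, f"manifest_{stage}.json").write_text(json.dumps(man, indent=2))
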