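"""Readers and writers for the plain-text formats the pipeline uses.

FASTA for protein sequences (via Biopython), tab-delimited manifests and
ligand tables with headers, BED-like interval files (0-based half-open),
per-residue K tracks, flat JSON metric reports and JSON model checkpoints
(config + parameters + vocabulary hashes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import (
    LIGAND_MAX_LEN,
    PROTEIN_MAX_LEN,
    encode_protein,
    encode_smiles,
    protein_vocabulary,
    smiles_vocabulary,
)
from .model import ModelConfig
from .objectives import LabeledBatch
from .splitting import MANIFEST_COLUMNS, check_manifest

__all__ = [
    "read_fasta", "write_fasta",
    "read_ligand_table", "write_ligand_table", "read_smiles_lines",
    "read_manifest", "write_manifest",
    "read_bed", "write_bed",
    "write_track", "read_track",
    "write_metric_report", "read_metric_report",
    "save_checkpoint", "load_checkpoint",
    "build_batches",
    "validate_real_smiles",
]


# ------------------------------------------------------------------ sequences

def read_fasta(path) -> dict:
    """Multi-record FASTA -> ordered {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_ligand_table(path) -> dict:
    """TSV with header (ligand_id, smiles) -> {id: smiles}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["ligand_id", "smiles"]:
        raise ValueError("ligand table must have columns: ligand_id, smiles")
    return dict(zip(df["ligand_id"], df["smiles"]))


def write_ligand_table(path, ligands: Mapping[str, str]) -> None:
    pd.DataFrame({"ligand_id": list(ligands), "smiles": list(ligands.values())}) \
        .to_csv(path, sep="\t", index=False)


def read_smiles_lines(path) -> list[str]:
    """One-SMILES-per-line text file."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ------------------------------------------------------------------- manifest

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return check_manifest(df)


def write_manifest(path, manifest: pd.DataFrame) -> None:
    cols = MANIFEST_COLUMNS + [c for c in manifest.columns if c not in MANIFEST_COLUMNS]
    manifest[cols].to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ intervals

def read_bed(path) -> dict:
    """BED-like file -> {protein_id: [(start, end, name), ...]} (0-based half-open)."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        pid, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "."
        out.setdefault(pid, []).append((start, end, name))
    return out


def write_bed(path, intervals: Mapping[str, Sequence[tuple]]) -> None:
    lines = []
    for pid, ivs in intervals.items():
        for iv in ivs:
            start, end = iv[0], iv[1]
            name = iv[2] if len(iv) > 2 else "."
            lines.append(f"{pid}\t{int(start)}\t{int(end)}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------- tracks

def write_track(path, tracks: Mapping[str, np.ndarray]) -> None:
    """Per-residue K tracks as TSV (protein_id, position, k)."""
    rows = []
    for pid, track in tracks.items():
        for pos, k in enumerate(np.asarray(track)):
            rows.append((pid, pos, float(k)))
    pd.DataFrame(rows, columns=["protein_id", "position", "k"]) \
        .to_csv(path, sep="\t", index=False)


def read_track(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {pid: grp.sort_values("position")["k"].to_numpy()
            for pid, grp in df.groupby("protein_id", sort=False)}


# -------------------------------------------------------------------- reports

def write_metric_report(path, report: Mapping) -> None:
    payload = {k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in dict(report).items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metric_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- checkpoints

CHECKPOINT_FORMAT = 1


def save_checkpoint(path, config: ModelConfig, params: Mapping[str, np.ndarray]) -> None:
    """JSON checkpoint: model config, full-precision parameters, vocab hashes."""
    payload = {
        "format": CHECKPOINT_FORMAT,
        "config": config.to_dict(),
        "vocab_hashes": {
            "protein": protein_vocabulary().sha256(),
            "smiles": smiles_vocabulary().sha256(),
        },
        "params": {k: v.tolist() for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> tuple[ModelConfig, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unsupported checkpoint format: {payload.get('format')}")
    hashes = payload.get("vocab_hashes", {})
    if hashes.get("protein") != protein_vocabulary().sha256() or \
            hashes.get("smiles") != smiles_vocabulary().sha256():
        raise ValueError("checkpoint vocabulary hashes do not match the installed vocabularies")
    config = ModelConfig.from_dict(payload["config"])
    params = {k: np.array(v, dtype=float) for k, v in payload["params"].items()}
    return config, params


# ------------------------------------------------------------------- batching

def build_batches(
    manifest: pd.DataFrame,
    sequences: Mapping[str, str],
    ligands: Mapping[str, str],
    protein_max_len: int = PROTEIN_MAX_LEN,
    ligand_max_len: int = LIGAND_MAX_LEN,
) -> dict:
    """Encode a manifest into one :class:`LabeledBatch` per task.

    Encodings are computed once per unique protein/ligand and reused.
    Returns ``{"classification": batch, "regression": batch}`` (keys only
    for tasks present in the manifest).
    """
    check_manifest(manifest)
    pvocab, svocab = protein_vocabulary(), smiles_vocabulary()
    prot_enc = {pid: encode_protein(sequences[pid], pvocab, max_len=protein_max_len)
                for pid in manifest["protein_id"].unique()}
    lig_enc = {lid: encode_smiles(ligands[lid], svocab, max_len=ligand_max_len)
               for lid in manifest["ligand_id"].unique()}
    out: dict = {}
    for task, group in manifest.groupby("task", sort=False):
        out[task] = LabeledBatch(
            Xp=np.stack([prot_enc[p].matrix for p in group["protein_id"]]),
            Xl=np.stack([lig_enc[l].matrix for l in group["ligand_id"]]),
            y=group["label"].to_numpy(dtype=float),
            task=task,
            ids=list(zip(group["protein_id"], group["ligand_id"])),
        )
    return out


def validate_real_smiles(smiles: Sequence[str]) -> list[bool]:
    """Chemical validity check for real SMILES via RDKit (optional extra)."""
    try:
        from rdkit import Chem  # lazy: only needed when realism checks are requested
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES validity checks need the 'chem' extra (rdkit)") from exc
    return [Chem.MolFromSmiles(s) is not None for s in smiles]
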