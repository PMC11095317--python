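"""File-format plumbing: FASTA records, pair tables, feature tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqfeat import ProteinRecord, sanitize_sequence, feature_names


def read_fasta(path) -> list[ProteinRecord]:
    """Multi-record FASTA; the id is the first whitespace token of the header.

    Sequences are sanitized (uppercased, non-canonical residues stripped with
    a warning); records left empty by sanitization raise.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq), record_id=rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_feature_table(path, ids: list[str], X: np.ndarray, full: bool = True) -> None:
    """TSV: id column plus named 3036 columns (or d reduced columns)."""
    X = np.atleast_2d(X)
    cols = feature_names() if full else [f"PC{i+1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["id"].astype(str).tolist(), df.drop(columns="id").to_numpy(float)


def read_pair_table(path) -> pd.DataFrame:
    """TSV/CSV with columns ligand_id, receptor_id and optionally label."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"ligand_id", "receptor_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_pair_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_predictions(path, ligands, receptors, probabilities, labels) -> None:
    pd.DataFrame(
        {
            "ligand_id": ligands,
            "receptor_id": receptors,
            "probability": probabilities,
            "label": labels,
        }
    ).to_csv(path, sep="\t", index=False)


def ensure_outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
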