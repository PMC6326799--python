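"""Readers and writers for the pipeline's file formats.

TSV everywhere for tables, TIFF (CZYX) for image stacks, FASTA for protein
sequences, 12-column tabular alignment output for homology hits. The LFQ
matrix dialect mirrors a minimal proteinGroups layout: ``Protein IDs``,
``LFQ intensity <sample>`` columns, and ``Reverse`` / ``Potential
contaminant`` / ``Only identified by site`` flag columns marked ``+``.
Missing quantitation is written as 0 and read back as missing, matching the
convention of the upstream software that produces such tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nucfish.enrichment import LfqMatrix
from nucfish.images import read_stack, write_stack  # re-exported  # noqa: F401

LFQ_PREFIX = "LFQ intensity "
FLAG_MAP = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_by_site",
}
HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, records) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seqs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# LFQ matrices


def write_lfq_tsv(path, matrix: LfqMatrix) -> None:
    out = pd.DataFrame(index=matrix.values.index.rename("Protein IDs"))
    for col in matrix.values.columns:
        out[LFQ_PREFIX + col] = matrix.values[col].fillna(0.0)
    for file_col, attr in FLAG_MAP.items():
        out[file_col] = np.where(matrix.flags[attr], "+", "")
    out.to_csv(path, sep="\t")


def read_lfq_tsv(path, condition_of: dict[str, str] | None = None) -> LfqMatrix:
    """Read the minimal proteinGroups dialect written by :func:`write_lfq_tsv`.

    Sample conditions default to the text before the last underscore of each
    sample name (``ctrl_1`` -> ``ctrl``); pass ``condition_of`` to override.
    """
    df = pd.read_csv(path, sep="\t", index_col="Protein IDs")
    df.index.name = None
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"{path}: no '{LFQ_PREFIX}<sample>' columns found")
    samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    values = df[lfq_cols].copy()
    values.columns = samples
    values = values.replace(0.0, np.nan)
    flags = pd.DataFrame(False, index=df.index, columns=list(FLAG_MAP.values()))
    for file_col, attr in FLAG_MAP.items():
        if file_col in df.columns:
            flags[attr] = df[file_col].fillna("").astype(str).str.strip() == "+"
    if condition_of is None:
        condition_of = {s: s.rsplit("_", 1)[0] for s in samples}
    return LfqMatrix(values=values, condition_of=condition_of, flags=flags)


# ---------------------------------------------------------------------------
# homology hit tables (12-column tabular alignment output, no header)


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(HIT_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(HIT_COLUMNS)} tab-separated columns, "
            f"got {df.shape[1]}"
        )
    df.columns = HIT_COLUMNS
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative e-value")
    return df


def write_hit_table(path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col in HIT_COLUMNS:
        if col not in out.columns:
            out[col] = 0
    out[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# scenes, molecules, spots


def scene_truth_frame(scene) -> pd.DataFrame:
    """Ground-truth molecule table of a scene (one row per probe position)."""
    rows = []
    for i, mol in enumerate(scene.molecules):
        for ch, pos in sorted(mol.probe_positions.items()):
            rows.append(
                {
                    "molecule": i,
                    "species": mol.species,
                    "location": mol.true_location,
                    "oriented_5prime_out": mol.oriented_5prime_out,
                    "channel": ch,
                    "z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule", "species", "location", "oriented_5prime_out",
            "channel", "z_um", "y_um", "x_um",
        ],
    )


def spots_frame(spots) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": [s.channel for s in spots],
            "z_um": [s.position[0] for s in spots],
            "y_um": [s.position[1] for s in spots],
            "x_um": [s.position[2] for s in spots],
            "peak_intensity": [s.peak_intensity for s in spots],
        }
    )


def molecules_frame(molecules) -> pd.DataFrame:
    rows = []
    for i, mol in enumerate(molecules):
        for ch, spot in sorted(mol.spots.items()):
            coord = mol.coords.get(ch)
            rows.append(
                {
                    "molecule": i,
                    "species": mol.species,
                    "location": mol.location,
                    "channel": ch,
                    "z_um": spot.position[0],
                    "y_um": spot.position[1],
                    "x_um": spot.position[2],
                    "percent_dapi": coord.percent if coord else np.nan,
                    "side": coord.side if coord else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule", "species", "location", "channel",
            "z_um", "y_um", "x_um", "percent_dapi", "side",
        ],
    )
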