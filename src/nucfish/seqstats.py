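"""Q-rich window scanning and reciprocal-best-hit homology classification.

Two sequence-level statistics used to characterize RNA-granule proteomes:

* **Q-rich regions** — a protein sequence is divided into consecutive,
  non-overlapping 60-mers; a 60-mer is Q-rich if it contains at least seven
  of the scored residue (glutamine by default; glutamine-rich low-complexity
  stretches are the hallmark of prion-like RNA-granule proteins). The
  reported density is Q-rich windows per 100 amino acids.
* **Reciprocal best hits (RBH)** — a protein has a homologue in another taxon
  when its top forward alignment hit, searched back against the source
  proteome, returns the original protein as the top hit with an e-value
  below 1e-5. The per-taxon flags are summarized into unique /
  shared-in-k categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class QRichScore:
    """Q-rich window count and length-normalized density for one protein."""

    protein_id: str
    length: int
    n_qrich_windows: int
    density: float  # windows per 100 aa


def extended_rna_length_um(n_nucleotides: int, nm_per_nt: float = 0.34) -> float:
    """Theoretical contour length (um) of a fully extended RNA.

    Uses the standard axial rise per nucleotide (0.34 nm); e.g. a 22,197-nt
    transcript extends to ~7.5 um — far beyond the observed spread of its
    probe signals, which stay within ~0.5 um of each other.
    """
    if n_nucleotides < 0:
        raise ValueError("n_nucleotides must be non-negative")
    return n_nucleotides * nm_per_nt / 1000.0


def qrich_scan(
    sequence: str,
    protein_id: str = "",
    window: int = 60,
    min_count: int = 7,
    residue: str = "Q",
    frame_offset: int = 0,
    sliding: bool = False,
) -> QRichScore:
    """Count residue-rich windows in a protein sequence.

    The sequence is divided into consecutive non-overlapping ``window``-mers
    starting at ``frame_offset``; a window counts when it holds at least
    ``min_count`` copies of ``residue`` (exact match; ambiguity codes and
    lower case never match). The trailing remainder shorter than ``window``
    is not scored. ``sliding=True`` switches to a per-position sliding
    window for sensitivity analyses; the density denominator is the full
    sequence length in both modes.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window <= 0 or min_count <= 0:
        raise ValueError("window and min_count must be positive")
    if not 0 <= frame_offset < window:
        raise ValueError("frame_offset must lie in [0, window)")
    length = len(sequence)
    count = 0
    if sliding:
        for start in range(0, length - window + 1):
            if sequence[start:start + window].count(residue) >= min_count:
                count += 1
    else:
        for start in range(frame_offset, length - window + 1, window):
            if sequence[start:start + window].count(residue) >= min_count:
                count += 1
    return QRichScore(
        protein_id=protein_id,
        length=length,
        n_qrich_windows=count,
        density=count / length * 100.0,
    )


def qrich_scan_records(records, **kwargs) -> pd.DataFrame:
    """Scan ``(id, sequence)`` pairs; returns one row per protein."""
    scores = [qrich_scan(seq, pid, **kwargs) for pid, seq in records]
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in scores],
            "length": [s.length for s in scores],
            "n_qrich_windows": [s.n_qrich_windows for s in scores],
            "density": [s.density for s in scores],
        }
    ).set_index("protein_id")


def qrich_compare(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> dict:
    """Sorted per-group density tables plus group means, for plotting.

    Expects frames from :func:`qrich_scan_records`; densities are sorted
    descending within each group (the standard presentation of this
    statistic) and the summary reports each group's mean density.
    """
    if scores_a.empty or scores_b.empty:
        raise ValueError("both groups must be non-empty")
    sa = scores_a["density"].sort_values(ascending=False).reset_index()
    sb = scores_b["density"].sort_values(ascending=False).reset_index()
    return {
        "group_a": sa,
        "group_b": sb,
        "mean_a": float(scores_a["density"].mean()),
        "mean_b": float(scores_b["density"].mean()),
    }


# ---------------------------------------------------------------------------
# reciprocal best hits


def _top_hit(df: pd.DataFrame, query: str):
    """Best hit of a query: lowest e-value, then highest bit score, then
    lexicographically smallest subject id."""
    rows = df[df["query"] == query]
    if rows.empty:
        return None
    rows = rows.sort_values(
        ["evalue", "bitscore", "subject"], ascending=[True, False, True],
        kind="stable",
    )
    return rows.iloc[0]


def rbh_classify(
    forward_hits: dict[str, pd.DataFrame],
    reverse_hits: dict[str, pd.DataFrame],
    protein_ids: list[str],
    evalue_cutoff: float = 1e-5,
    cutoff_on: str = "reverse",
) -> pd.DataFrame:
    """Per-protein, per-taxon reciprocal-best-hit homology calls.

    For each taxon: take the protein's top forward hit; the protein has a
    homologue there iff the reverse top hit of that subject is the original
    protein and the e-value condition (strictly below ``evalue_cutoff``)
    holds on the reverse hit (``cutoff_on="reverse"``, the default reading),
    the forward hit, or both. Proteins with no qualifying taxon are
    ``unique``; otherwise the category is ``shared_in_k`` for k qualifying
    taxa. Returns a frame indexed by protein with one boolean column per
    taxon plus ``n_taxa`` and ``category``.
    """
    if cutoff_on not in ("reverse", "forward", "both"):
        raise ValueError(f"unknown cutoff_on {cutoff_on!r}")
    taxa = sorted(forward_hits)
    if sorted(reverse_hits) != taxa:
        raise ValueError("forward and reverse tables must cover the same taxa")
    flags = pd.DataFrame(False, index=list(protein_ids), columns=taxa)
    for taxon in taxa:
        fwd, rev = forward_hits[taxon], reverse_hits[taxon]
        for pid in protein_ids:
            top_f = _top_hit(fwd, pid)
            if top_f is None:
                continue
            top_r = _top_hit(rev, top_f["subject"])
            if top_r is None or top_r["subject"] != pid:
                continue
            ok_f = top_f["evalue"] < evalue_cutoff
            ok_r = top_r["evalue"] < evalue_cutoff
            ok = {"reverse": ok_r, "forward": ok_f, "both": ok_f and ok_r}[cutoff_on]
            if ok:
                flags.loc[pid, taxon] = True
    n_taxa = flags.sum(axis=1)
    category = n_taxa.map(lambda k: "unique" if k == 0 else f"shared_in_{k}")
    out = flags.copy()
    out["n_taxa"] = n_taxa
    out["category"] = category
    return out
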