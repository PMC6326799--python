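"""Two-condition LFQ enrichment statistics with permutation FDR.

The downstream statistics of a label-free quantitative proteomics comparison
(e.g. purified nuclei with versus without a splicing block): remove decoy /
contaminant / only-by-site rows and rows without enough quantified
replicates; log2-transform; impute missing values from a down-shifted,
narrowed normal per sample column (missing-not-at-random imputation, width
0.3, downshift 1.8 in column-sd units); then call enrichment with an
S0-moderated Welch t statistic whose significance frontier is set by
permutation (250 balanced relabelings) at a target FDR (0.05), S0 = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ["reverse", "contaminant", "only_by_site"]


@dataclass
class LfqMatrix:
    """Proteins x samples quantitation with flags and explicit missingness.

    ``values`` holds raw (not log) LFQ intensities with NaN for missing;
    ``condition_of`` maps sample column to condition label; ``flags`` is a
    boolean frame with columns ``reverse``, ``contaminant``, ``only_by_site``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    flags: pd.DataFrame | None = None
    log2: bool = False

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=FLAG_COLUMNS
            )
        missing = set(self.values.columns) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        seen = []
        for s in self.values.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]


@dataclass
class EnrichmentResult:
    """Per-protein moderated statistics and significance calls."""

    table: pd.DataFrame  # log2fc, d, t_welch, p_welch, significant, direction
    s0: float
    n_randomizations: int
    fdr_level: float
    seed: int | None
    frontier: float = np.nan
    estimated_fdr: float = np.nan

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def filter_matrix(
    matrix: LfqMatrix, min_valid: int = 2, mode: str = "any_condition"
) -> LfqMatrix:
    """Remove flagged rows and rows with too few quantified replicates.

    A row is kept when at least ``min_valid`` of its replicates are quantified
    in at least one condition (``mode="any_condition"``, the default — this
    retains on/off proteins that are entirely absent from one condition) or
    in every condition (``mode="each_condition"``).
    """
    flagged = matrix.flags.any(axis=1)
    values = matrix.values.loc[~flagged]
    per_cond = pd.DataFrame(
        {c: values[matrix.samples_of(c)].notna().sum(axis=1) for c in matrix.conditions}
    )
    if mode == "any_condition":
        keep = (per_cond >= min_valid).any(axis=1)
    elif mode == "each_condition":
        keep = (per_cond >= min_valid).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logger.info(
        "filter_matrix: removed %d flagged rows, %d under-quantified rows; %d kept",
        int(flagged.sum()), int((~keep).sum()), int(keep.sum()),
    )
    return LfqMatrix(
        values=values.loc[keep].copy(),
        condition_of=dict(matrix.condition_of),
        flags=matrix.flags.loc[~flagged].loc[keep].copy(),
        log2=matrix.log2,
    )


def log2_transform(matrix: LfqMatrix) -> LfqMatrix:
    """Elementwise log2 of the intensities; missing entries stay missing."""
    v = matrix.values
    if ((v <= 0) & v.notna()).any().any():
        raise ValueError("non-positive intensity; cannot log2-transform")
    return LfqMatrix(
        values=np.log2(v),
        condition_of=dict(matrix.condition_of),
        flags=matrix.flags.copy(),
        log2=True,
    )


def impute_mnar(
    matrix: LfqMatrix, width: float = 0.3, downshift: float = 1.8, seed: int = 0
) -> LfqMatrix:
    """Impute missing log2 values from a down-shifted narrow normal.

    Per sample column with observed mean m and standard deviation s, missing
    entries are drawn from Normal(m - downshift*s, (width*s)^2) — emulating
    that missing LFQ values are predominantly low-abundance. Observed entries
    are untouched. Each column needs at least two observed values.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for col in values.columns:
        v = values[col]
        obs = v.dropna()
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        n_missing = int(v.isna().sum())
        if n_missing == 0:
            continue
        m, s = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(m - downshift * s, width * s, size=n_missing)
        values.loc[v.isna(), col] = draws
    return LfqMatrix(
        values=values,
        condition_of=dict(matrix.condition_of),
        flags=matrix.flags.copy(),
        log2=matrix.log2,
    )


# ---------------------------------------------------------------------------
# S0-moderated Welch statistic with permutation FDR


def _moderated_d(x1: np.ndarray, x2: np.ndarray, s0: float) -> np.ndarray:
    """d = (mean2 - mean1) / (welch_se + s0), row-wise.

    With s0 = 0 this is exactly the Welch t statistic.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    denom = se + s0
    if s0 == 0 and np.any(denom == 0):
        raise ZeroDivisionError(
            "degenerate variance with s0=0; the moderated statistic needs s0 > 0"
        )
    return (m2 - m1) / denom


def _balanced_relabelings(n1: int, n2: int):
    """Balanced reassignments of the sample columns to group 1.

    The identity split and its complement are excluded: a null distribution
    containing the true grouping would re-observe every real effect and
    saturate the estimated FDR, which is exactly what balanced permutation
    schemes are designed to avoid.
    """
    cols = list(range(n1 + n2))
    identity = tuple(range(n1))
    complement = tuple(range(n1, n1 + n2)) if n1 == n2 else None
    return [
        t for t in (tuple(c) for c in combinations(cols, n1))
        if t != identity and t != complement
    ]


def sam_welch_test(
    matrix: LfqMatrix,
    s0: float = 0.5,
    n_randomizations: int = 250,
    fdr: float = 0.05,
    seed: int = 0,
    exact: bool = False,
    fdr_estimator: str = "mean",
    conditions: tuple[str, str] | None = None,
) -> EnrichmentResult:
    """S0-moderated Welch test with a permutation-calibrated FDR frontier.

    The per-protein statistic is ``d = (mean2 - mean1) / (se_welch + s0)``.
    Its null distribution is built from balanced relabelings of the sample
    columns: ``n_randomizations`` draws with replacement from the C(n,k)
    balanced splits (``exact=True`` enumerates them all instead). A protein
    is significant when |d| exceeds the smallest frontier at which the
    estimated FDR — the mean (or median) permutation exceedance count over
    the observed exceedance count — is at or below ``fdr``. Two-sided, with a
    symmetric frontier.

    The contrast is condition2 minus condition1 with the two conditions in
    sorted label order (so relabelling the conditions negates every d and
    fold change); pass ``conditions=(cond1, cond2)`` to fix the direction
    explicitly.
    """
    if matrix.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    conds = sorted(matrix.conditions) if conditions is None else list(conditions)
    if len(conds) != 2 or set(conds) != set(matrix.conditions):
        raise ValueError(f"need exactly 2 conditions, got {matrix.conditions}")
    cols1 = matrix.samples_of(conds[0])
    cols2 = matrix.samples_of(conds[1])
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need at least 2 samples per condition")
    data = matrix.values[cols1 + cols2].to_numpy(dtype=float)
    n1 = len(cols1)

    d_obs = _moderated_d(data[:, :n1], data[:, n1:], s0)
    x1, x2 = data[:, :n1], data[:, n1:]
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    t_welch, p_welch = stats.ttest_ind(x2, x1, axis=1, equal_var=False)

    splits = _balanced_relabelings(n1, data.shape[1] - n1)
    if exact:
        chosen = splits
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(splits), size=n_randomizations)
        chosen = [splits[i] for i in idx]
    all_cols = set(range(data.shape[1]))
    perm_abs = []
    for grp1 in chosen:
        grp2 = sorted(all_cols - set(grp1))
        d_perm = _moderated_d(data[:, list(grp1)], data[:, grp2], s0)
        perm_abs.append(np.abs(d_perm))
    perm_abs = np.asarray(perm_abs)  # (n_perm, n_proteins)

    # frontier scan over observed |d| values, largest first
    abs_obs = np.abs(d_obs)
    candidates = np.unique(abs_obs)[::-1]
    agg = np.mean if fdr_estimator == "mean" else np.median
    if fdr_estimator not in ("mean", "median"):
        raise ValueError(f"unknown fdr_estimator {fdr_estimator!r}")
    # the empirical FDR curve is noisy and need not be monotone in t; the
    # significant set is the largest one whose estimated FDR is controlled,
    # i.e. the smallest candidate threshold with FDR <= target
    frontier = np.inf
    est_fdr = np.nan
    for t in candidates:
        observed_calls = int(np.sum(abs_obs >= t))
        null_calls = float(agg(np.sum(perm_abs >= t, axis=1)))
        fdr_t = null_calls / observed_calls if observed_calls else np.inf
        if fdr_t <= fdr:
            frontier = float(t)
            est_fdr = fdr_t
    significant = abs_obs >= frontier

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "d": d_obs,
            "t_welch": t_welch,
            "p_welch": p_welch,
            "significant": significant,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        },
        index=matrix.values.index,
    )
    return EnrichmentResult(
        table=table,
        s0=s0,
        n_randomizations=len(chosen),
        fdr_level=fdr,
        seed=None if exact else seed,
        frontier=frontier,
        estimated_fdr=est_fdr,
    )


def volcano_table(result: EnrichmentResult) -> pd.DataFrame:
    """Volcano-plot-ready table: log2FC, -log10 Welch p, calls, direction."""
    t = result.table
    return pd.DataFrame(
        {
            "log2fc": t["log2fc"],
            "neg_log10_p": -np.log10(t["p_welch"]),
            "significant": t["significant"],
            "direction": t["direction"],
        },
        index=t.index,
    )


def plot_volcano(result: EnrichmentResult, ax=None):
    """Scatter the volcano table; significant proteins in red."""
    import matplotlib.pyplot as plt

    tab = volcano_table(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sig = tab["significant"]
    ax.scatter(tab.loc[~sig, "log2fc"], tab.loc[~sig, "neg_log10_p"],
               s=8, c="grey", alpha=0.6, label="not significant")
    ax.scatter(tab.loc[sig, "log2fc"], tab.loc[sig, "neg_log10_p"],
               s=10, c="crimson", label="significant")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p (Welch)")
    ax.legend(frameon=False, fontsize=8)
    return ax
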