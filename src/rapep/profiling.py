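"""Class-comparison profiling: positional residue enrichment, average
composition differences, and single-feature rankings.

All operations return tidy :class:`pandas.DataFrame` tables that can be
written straight to TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datasets import AMINO_ACIDS, PeptideDataset
from .features import kmer_composition, terminal_18mer


def positional_enrichment(
    pos: PeptideDataset, neg: PeptideDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-position, per-residue enrichment between two peptide classes.

    Peptides are mapped to their fixed 18-mer terminal representation
    (N-terminal 9-mer + C-terminal 9-mer); each (position, residue) cell is
    tested with a two-sided Fisher exact test on the 2x2 occurrence table.
    ``direction`` is ``enriched``/``depleted`` (w.r.t. the positive class)
    when p <= alpha, otherwise ``none``.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    mats = {}
    for name, ds in (("pos", pos), ("neg", neg)):
        s18s = [terminal_18mer(p) for p in ds]
        counts = np.zeros((18, 20), dtype=int)
        for s in s18s:
            for i, r in enumerate(s):
                counts[i, AMINO_ACIDS.index(r)] += 1
        mats[name] = counts
    n_pos, n_neg = len(pos), len(neg)
    rows = []
    for i in range(18):
        for j, r in enumerate(AMINO_ACIDS):
            a = int(mats["pos"][i, j])
            c = int(mats["neg"][i, j])
            _, p_val = stats.fisher_exact([[a, n_pos - a], [c, n_neg - c]])
            pf, nf = a / n_pos, c / n_neg
            if p_val <= alpha and pf > nf:
                direction = "enriched"
            elif p_val <= alpha and pf < nf:
                direction = "depleted"
            else:
                direction = "none"
            rows.append(
                dict(position=i + 1, residue=r, pos_freq=pf, neg_freq=nf,
                     p_value=float(p_val), direction=direction)
            )
    return pd.DataFrame(rows)


def composition_comparison(pos: PeptideDataset, neg: PeptideDataset) -> pd.DataFrame:
    """Mean amino-acid composition per class with t-test p-values.

    One row per residue: mean percent composition in each class, the mean
    difference (positive minus negative) and a two-sided independent
    t-test p-value.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    def aac_frame(ds):
        return pd.DataFrame([kmer_composition(p, 1) for p in ds])

    fp, fn = aac_frame(pos), aac_frame(neg)
    rows = []
    for r in AMINO_ACIDS:
        col = f"AAC_{r}"
        a, b = fp[col].to_numpy(), fn[col].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p_val = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            dict(feature=col, mean_pos=a.mean(), mean_neg=b.mean(),
                 mean_diff=a.mean() - b.mean(),
                 p_value=float(p_val) if np.isfinite(p_val) else 1.0)
        )
    df = pd.DataFrame(rows)
    df["rank"] = (
        df["mean_diff"].abs().rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("rank").reset_index(drop=True)


def minmax_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each column to [0, 1]; constant columns map to 0."""
    lo, hi = m.min(axis=0), m.max(axis=0)
    span = (hi - lo).replace(0.0, np.inf)
    return (m - lo) / span


def univariate_rank(
    m: pd.DataFrame, labels, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Mean-difference feature ranking after min-max normalization.

    Features are filtered to two-sided t-test p <= ``p_cutoff`` and ranked
    by absolute mean difference (descending; ties broken by feature name).
    Constant features carry no class information and are excluded.
    """
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    norm = minmax_normalize(m)
    # constant features carry no class signal; drop before testing
    norm = norm.loc[:, norm.nunique(axis=0) > 1]
    a = norm.loc[np.asarray(y) == 1]
    b = norm.loc[np.asarray(y) == 0]
    mean_pos, mean_neg = a.mean(axis=0), b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_vals = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0)
    df = pd.DataFrame(
        dict(feature=norm.columns, mean_pos=mean_pos.to_numpy(),
             mean_neg=mean_neg.to_numpy(),
             mean_diff=(mean_pos - mean_neg).to_numpy(), p_value=p_vals)
    )
    df = df[np.isfinite(df["p_value"]) & (df["p_value"] <= p_cutoff)].copy()
    df["abs_diff"] = df["mean_diff"].abs()
    df = df.sort_values(["abs_diff", "feature"], ascending=[False, True])
    df = df.drop(columns="abs_diff").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def single_feature_auc(m: pd.DataFrame, labels) -> pd.DataFrame:
    """AUC of each feature used directly as a ranking score for the
    positive class (rank statistic, ties averaged); ranked descending."""
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise ValueError("need at least 1 sample per class")
    aucs = [roc_auc_score(y, m[col].to_numpy()) for col in m.columns]
    df = pd.DataFrame(dict(feature=m.columns, auc=aucs))
    df = df.sort_values(["auc", "feature"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
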