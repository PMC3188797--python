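"""Unsupervised association between chromatin signal and expression.

Two complementary views: per-bin Spearman correlation profiles of each
feature against expression, and two-cluster hierarchical splits whose
between-cluster expression t-score measures how well the signal at a bin
(or the 160-bin profile of one feature) discriminates highly from lowly
expressed transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .binning import BinTensor, TranscriptAnnotation, normalize_columns

__all__ = [
    "ExpressionTable",
    "AssociationProfile",
    "ClusterSplit",
    "spearman_profile",
    "filter_transcripts",
    "cluster_split_by_features",
    "cluster_split_by_bins",
    "welch_t",
]


class ExpressionTable:
    """Transcript x stage table of RPKM values.

    Expression enters all statistics on the log scale,
    ``log2(RPKM + 1)``; Spearman correlations are unaffected by the
    (monotone) transform, t-tests and group means use it.
    """

    def __init__(self, rpkm: pd.DataFrame):
        if (rpkm.values < 0).any():
            raise ValueError("RPKM values must be nonnegative")
        if rpkm.index.duplicated().any():
            raise ValueError("duplicate transcript ids in expression table")
        self.rpkm = rpkm.astype(float)

    @property
    def stages(self) -> list[str]:
        return list(self.rpkm.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.rpkm.index)

    def values(self, stage: str) -> pd.Series:
        if stage not in self.rpkm.columns:
            raise KeyError(f"stage {stage!r} not in expression table ({self.stages})")
        return self.rpkm[stage]

    def log_values(self, stage: str) -> pd.Series:
        return np.log2(self.values(stage) + 1.0)

    def to_tsv(self, path) -> None:
        df = self.rpkm.copy()
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class AssociationProfile:
    """Feature x bin matrix of Spearman rho, with per-cell pair counts."""

    rho: pd.DataFrame
    n_used: pd.DataFrame

    def peak_bin(self, feature: str) -> str:
        """Bin label with the largest |rho| for one feature."""
        row = self.rho.loc[feature].abs()
        return str(row.idxmax())


@dataclass
class ClusterSplit:
    """Top-level two-cluster split and its expression discrimination."""

    labels: pd.Series  # 1/2 per transcript
    t: float
    p_value: float
    orientation: str  # 'positive' if the higher-signal cluster is higher expressed

    @property
    def t_score(self) -> float:
        """|t|, the bin's (or feature's) discrimination score."""
        return abs(self.t) if np.isfinite(self.t) else np.nan


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch unequal-variance two-sample t statistic and two-sided p.

    Degenerate case (no variance anywhere, equal means) returns (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def spearman_profile(
    tensor: BinTensor,
    expr: ExpressionTable,
    stage: str,
    min_pairs: int = 10,
) -> AssociationProfile:
    """Spearman rho of every (feature, bin) signal against expression.

    Pairwise-complete over transcripts with unmasked signal; average ranks on
    ties.  Cells with fewer than ``min_pairs`` usable transcripts are masked
    (NaN) rather than raising.
    """
    shared = [t for t in tensor.transcript_ids if t in expr.rpkm.index]
    if not shared:
        raise ValueError("no transcripts shared between tensor and expression table")
    sub = tensor.subset_transcripts(shared)
    y = expr.values(stage).loc[shared].to_numpy()
    m, k = len(sub.feature_names), len(sub.bin_labels)
    rho = np.full((m, k), np.nan)
    n_used = np.zeros((m, k), dtype=int)
    for j in range(m):
        for b in range(k):
            x = sub.values[:, j, b]
            ok = ~sub.mask[:, j, b]
            n = int(ok.sum())
            n_used[j, b] = n
            if n < min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            if np.all(xs == xs[0]) or np.all(ys == ys[0]):
                continue  # constant input: rho undefined, leave masked
            rho[j, b] = stats.spearmanr(xs, ys).statistic
    return AssociationProfile(
        rho=pd.DataFrame(rho, index=sub.feature_names, columns=sub.bin_labels),
        n_used=pd.DataFrame(n_used, index=sub.feature_names, columns=sub.bin_labels),
    )


def filter_transcripts(
    annotations: list[TranscriptAnnotation],
    mode: str,
    universe: list[TranscriptAnnotation] | None = None,
) -> list[TranscriptAnnotation]:
    """Sensitivity-analysis transcript filters.

    ``long``            length strictly greater than 8 kb (no TSS/TTS window
                        overlap within the transcript);
    ``isolated``        nearest other transcript at least 4 kb away
                        (end-to-start gap, any strand); distances are
                        measured against ``universe`` (default: the input
                        list), so filters compose when the full annotation
                        set is passed as the universe;
    ``single_isoform``  gene has exactly one transcript;
    ``chromosome:<c>``  transcripts on chromosome ``<c>`` (X-vs-autosome
                        analyses).
    """
    if mode == "long":
        return [t for t in annotations if t.length > 8000]
    if mode == "isolated":
        others = universe if universe is not None else annotations
        by_chrom: dict[str, list[TranscriptAnnotation]] = {}
        for t in others:
            by_chrom.setdefault(t.chrom, []).append(t)
        keep = []
        for t in annotations:
            gap = np.inf
            for other in by_chrom.get(t.chrom, []):
                if other.transcript_id == t.transcript_id:
                    continue
                if other.start >= t.end:
                    gap = min(gap, other.start - t.end)
                elif other.end <= t.start:
                    gap = min(gap, t.start - other.end)
                else:
                    gap = 0  # overlap
            if gap >= 4000:
                keep.append(t)
        return keep
    if mode == "single_isoform":
        counts: dict[str, int] = {}
        for t in annotations:
            counts[t.gene_id] = counts.get(t.gene_id, 0) + 1
        return [t for t in annotations if counts[t.gene_id] == 1]
    if mode.startswith("chromosome:"):
        chrom = mode.split(":", 1)[1]
        return [t for t in annotations if t.chrom == chrom]
    raise ValueError(
        f"unknown filter mode {mode!r}; expected long, isolated, "
        "single_isoform or chromosome:<name>"
    )


def _top_split(X: np.ndarray) -> np.ndarray:
    """Cut a complete-linkage Euclidean hierarchy at the top branch."""
    Z = linkage(X, method="complete", metric="euclidean")
    return fcluster(Z, t=2, criterion="maxclust")


def _split_stats(
    X: pd.DataFrame, labels: np.ndarray, log_expr: pd.Series
) -> ClusterSplit:
    lbl = pd.Series(labels, index=X.index, name="cluster")
    n1, n2 = int((labels == 1).sum()), int((labels == 2).sum())
    if min(n1, n2) < 2:
        return ClusterSplit(lbl, np.nan, np.nan, "undefined")
    e1 = log_expr.loc[lbl[lbl == 1].index]
    e2 = log_expr.loc[lbl[lbl == 2].index]
    t, p = welch_t(e1, e2)
    mean_sig = np.nanmean(X.values, axis=1)
    s1 = float(np.nanmean(mean_sig[labels == 1]))
    s2 = float(np.nanmean(mean_sig[labels == 2]))
    higher_signal = 1 if s1 >= s2 else 2
    higher_expr = 1 if e1.mean() >= e2.mean() else 2
    orientation = "positive" if higher_signal == higher_expr else "negative"
    return ClusterSplit(lbl, t, p, orientation)


def cluster_split_by_features(
    A_bin: pd.DataFrame, expr: ExpressionTable, stage: str
) -> ClusterSplit:
    """Two-cluster split of transcripts on one bin's normalised feature matrix.

    ``A_bin`` is the per-bin n x m matrix after :func:`normalize_columns`
    (rows with any NaN are dropped).  The split's |t| on log expression is
    the bin's discrimination score.
    """
    X = A_bin.dropna(axis=0)
    if len(X) < 4:
        raise ValueError("need at least 4 complete transcripts to cluster")
    labels = _top_split(X.to_numpy())
    log_expr = expr.log_values(stage)
    return _split_stats(X, labels, log_expr.loc[X.index])


def cluster_split_by_bins(
    tensor: BinTensor, feature: str, expr: ExpressionTable, stage: str
) -> ClusterSplit:
    """Two-cluster split on one feature's whole bin profile (all 160 bins).

    Bin columns are normalised as usual; masked cells are imputed to 0 after
    normalisation (the column median) so no transcript is dropped.
    """
    log_expr = expr.log_values(stage)
    prof = tensor.feature_matrix(feature)
    prof = prof.loc[[t for t in prof.index if t in log_expr.index]]
    prof = prof.loc[:, prof.notna().sum(axis=0) >= 2]
    keep = [c for c in prof.columns if prof[c].std(ddof=1) > 0]
    prof = normalize_columns(prof[keep]).fillna(0.0)
    if len(prof) < 4:
        raise ValueError("need at least 4 transcripts to cluster")
    labels = _top_split(prof.to_numpy())
    return _split_stats(prof, labels, log_expr.loc[prof.index])
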