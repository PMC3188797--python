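"""Supervised prediction of expression from bin-level chromatin signal.

The estimation core follows the model/results idiom: an
:class:`ExpressionModel` is constructed from a :class:`LabeledDesign`
(one bin's feature matrix, a 40-bin concatenation, or derived coverage
features, together with class labels and log-expression values); ``fit()``
returns an :class:`ExpressionModelResults` that can score new transcripts,
and ``cross_validate()`` returns a :class:`CVReport` of repeated random
half-split performance (AUC for classification, Pearson r for regression).

Classification targets the high/low median split of expression; regression
targets log2(RPKM+1) directly.  Classifiers and regressors are RBF-kernel
support vector machines with predictors standardised on the training half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .binning import BinTensor
from .association import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDesign",
    "CVReport",
    "ExpressionModel",
    "ExpressionModelResults",
    "discretize_expression",
    "roc_auc",
    "cross_validate",
    "train_classifier",
    "train_regressor",
    "evaluate_pcc",
    "variance_explained",
    "bin_design",
    "subset_design",
    "multibin_design",
    "coverage_feature",
]


def discretize_expression(y_value: pd.Series, cutoff: float | None = None) -> pd.Series:
    """High/low labels by the median cutoff (ties go to 'low').

    ``value > cutoff`` -> 'high'; ``value <= cutoff`` -> 'low'.  The default
    cutoff is the median, giving classes balanced to within the number of
    ties at the median.
    """
    y = pd.Series(y_value).astype(float)
    if len(y) < 2:
        raise ValueError("need at least 2 values to discretize")
    if y.nunique() == 1:
        raise ValueError("all expression values identical; no high/low split exists")
    if cutoff is None:
        cutoff = float(y.median())
    return pd.Series(np.where(y > cutoff, "high", "low"), index=y.index, name="class")


@dataclass
class LabeledDesign:
    """Predictor matrix plus classification and regression targets.

    Rows with any missing predictor have been dropped (``n_dropped`` records
    how many).
    """

    X: pd.DataFrame
    y_value: pd.Series
    y_class: pd.Series
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing cells")
        if not (self.X.index.equals(self.y_value.index) and self.X.index.equals(self.y_class.index)):
            raise ValueError("X / y index mismatch")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)


def _make_design(X: pd.DataFrame, expr: ExpressionTable, stage: str) -> LabeledDesign:
    shared = [t for t in X.index if t in expr.rpkm.index]
    X = X.loc[shared]
    before = len(X)
    X = X.dropna(axis=0)
    n_dropped = before - len(X)
    if n_dropped:
        logger.info("dropped %d transcripts with missing predictors", n_dropped)
    y = expr.log_values(stage).loc[X.index]
    return LabeledDesign(X, y, discretize_expression(y), n_dropped)


def bin_design(
    tensor: BinTensor,
    expr: ExpressionTable,
    stage: str,
    bin_label: str,
    features: list[str] | None = None,
) -> LabeledDesign:
    """Design from the feature signals of a single bin."""
    A = tensor.bin_matrix(bin_label)
    if features is not None:
        missing = [f for f in features if f not in A.columns]
        if missing:
            raise KeyError(f"features not in tensor: {missing}")
        A = A[features]
    return _make_design(A, expr, stage)


def subset_design(design: LabeledDesign, features: list[str]) -> LabeledDesign:
    """Restrict a design's predictors to a named feature subset.

    Works both on single-bin designs (columns are feature names) and
    multi-bin designs (columns are ``feature@bin``).
    """
    cols = [
        c for c in design.X.columns if c in features or str(c).split("@")[0] in features
    ]
    if not cols:
        raise KeyError(f"no design columns match subset {features}")
    return LabeledDesign(design.X[cols], design.y_value, design.y_class, design.n_dropped)


def multibin_design(
    tensor: BinTensor,
    expr: ExpressionTable,
    stage: str,
    n_bins: int = 40,
    anchor: str = "TSS",
) -> LabeledDesign:
    """Design concatenating all features over ``n_bins`` anchor-centred bins.

    The default is the 40 bins from 2 kb upstream to 2 kb downstream of the
    TSS; columns are named ``feature@bin``.
    """
    half = n_bins // 2
    labels = [f"{anchor}:u{k}" for k in range(half, 0, -1)] + [
        f"{anchor}:d{k}" for k in range(1, n_bins - half + 1)
    ]
    blocks = []
    for lbl in labels:
        A = tensor.bin_matrix(lbl)
        A.columns = [f"{f}@{lbl}" for f in A.columns]
        blocks.append(A)
    return _make_design(pd.concat(blocks, axis=1), expr, stage)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and AUC from real-valued scores and high/low labels.

    The AUC is the Mann-Whitney pair statistic: the probability that a
    random positive outscores a random negative, ties counting one half.
    ROC thresholds sweep the distinct score values (plus the +/- infinity
    endpoints); returns ``(points, auc)`` with points as (FPR, TPR) rows.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lbl == "high" if isinstance(lbl, str) else bool(lbl) for lbl in labels])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # one operating point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr]), float(auc)


@dataclass
class CVReport:
    """Repeated cross-validation results for one design/model combination."""

    metric: str  # 'AUC' or 'PCC'
    per_repeat: np.ndarray
    roc_points: np.ndarray | None = None
    n: int = 0
    model_kind: str = ""
    seed: int | None = None
    n_redrawn: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_repeat))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.per_repeat, ddof=1))

    def summary(self) -> str:
        lines = [
            f"Cross-validation report ({self.model_kind or 'model'})",
            f"  repeats : {len(self.per_repeat)}",
            f"  n       : {self.n}",
            f"  {self.metric:7s}: {self.mean:.4f} (sd {self.sd:.4f})",
        ]
        if self.seed is not None:
            lines.append(f"  seed    : {self.seed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "per_repeat": [float(v) for v in self.per_repeat],
            "mean": self.mean,
            "sd": self.sd,
            "n": self.n,
            "model_kind": self.model_kind,
            "seed": self.seed,
        }


class ExpressionModel:
    """Support-vector (or ordinary linear) model of expression from signal.

    Parameters
    ----------
    design : LabeledDesign
    kind : {'svm', 'svr', 'ols'}
        'svm' classifies the high/low median split; 'svr' and 'ols' regress
        log2(RPKM+1).
    C, gamma, epsilon, kernel :
        SVM/SVR hyperparameters.  ``gamma`` defaults to 1/p where p is the
        number of predictors (predictors are standardised on the training
        half, so this matches the conventional kernel-width heuristic).
    """

    def __init__(
        self,
        design: LabeledDesign,
        kind: str = "svm",
        C: float = 1.0,
        gamma: float | None = None,
        epsilon: float = 0.1,
        kernel: str = "rbf",
    ):
        if kind not in ("svm", "svr", "ols"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.design = design
        self.kind = kind
        self.C = C
        self.gamma = gamma if gamma is not None else 1.0 / design.X.shape[1]
        self.epsilon = epsilon
        self.kernel = kernel

    def _estimator(self):
        if self.kind == "svm":
            est = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        elif self.kind == "svr":
            est = SVR(kernel=self.kernel, C=self.C, gamma=self.gamma, epsilon=self.epsilon)
        else:
            est = LinearRegression()
        return Pipeline([("scale", StandardScaler()), ("model", est)])

    def fit(self, rows: np.ndarray | None = None) -> "ExpressionModelResults":
        X = self.design.X if rows is None else self.design.X.iloc[rows]
        pipe = self._estimator()
        if self.kind == "svm":
            y = self.design.y_class if rows is None else self.design.y_class.iloc[rows]
            if y.nunique() < 2:
                raise ValueError("training set contains a single class")
            pipe.fit(X.to_numpy(), (y == "high").to_numpy())
        else:
            y = self.design.y_value if rows is None else self.design.y_value.iloc[rows]
            pipe.fit(X.to_numpy(), y.to_numpy())
        return ExpressionModelResults(self, pipe, list(X.columns))

    def cross_validate(
        self,
        n_repeats: int = 100,
        split: float = 0.5,
        seed: int = 0,
        keep_roc: bool = False,
    ) -> CVReport:
        """Repeated random-half cross-validation.

        Each repeat draws a random ``split`` fraction for training and scores
        the held-out rest; classification reports AUC, regression the Pearson
        correlation between predicted and actual log expression.  The split
        sequence is a pure function of ``seed`` and n, so models for
        different bins are compared on identical partitions.  A repeat whose
        halves miss a class is redrawn (and counted).
        """
        d = self.design
        n = d.n
        n_train = int(round(n * split))
        if n_train < 20 or n - n_train < 2:
            raise ValueError(f"too few rows (n={n}) for {split} split")
        rng = np.random.default_rng(seed)
        y_high = (d.y_class == "high").to_numpy()
        per_repeat = np.empty(n_repeats)
        roc_points = None
        n_redrawn = 0
        for r in range(n_repeats):
            while True:
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                if self.kind != "svm":
                    break
                if y_high[tr].any() and (~y_high[tr]).any() and y_high[te].any() and (~y_high[te]).any():
                    break
                n_redrawn += 1
                logger.info("redrew split %d: single-class half", r)
            res = self.fit(tr)
            scores = res.decision_scores(d.X.iloc[te])
            if self.kind == "svm":
                pts, auc = roc_auc(scores, d.y_class.iloc[te])
                per_repeat[r] = auc
                if keep_roc and roc_points is None:
                    roc_points = pts
            else:
                per_repeat[r] = evaluate_pcc(scores, d.y_value.iloc[te].to_numpy())
        return CVReport(
            metric="AUC" if self.kind == "svm" else "PCC",
            per_repeat=per_repeat,
            roc_points=roc_points,
            n=n,
            model_kind=self.kind,
            seed=seed,
            n_redrawn=n_redrawn,
        )


@dataclass
class ExpressionModelResults:
    """A fitted expression model; scores or predicts new signal vectors."""

    model: ExpressionModel
    pipeline: Pipeline
    predictors: list[str] = field(default_factory=list)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Real-valued scores (higher = predicted more highly expressed)."""
        self._check_features(X)
        arr = X[self.predictors].to_numpy()
        if self.model.kind == "svm":
            return self.pipeline.decision_function(arr)
        return self.pipeline.predict(arr)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Class labels (svm) or predicted log2(RPKM+1) (svr/ols)."""
        self._check_features(X)
        arr = X[self.predictors].to_numpy()
        if self.model.kind == "svm":
            return np.where(self.pipeline.predict(arr), "high", "low")
        return self.pipeline.predict(arr)

    def _check_features(self, X: pd.DataFrame) -> None:
        missing = [c for c in self.predictors if c not in X.columns]
        if missing:
            raise ValueError(f"feature-set mismatch; missing predictors: {missing}")

    def summary(self) -> str:
        return (
            f"ExpressionModel(kind={self.model.kind}, C={self.model.C}, "
            f"gamma={self.model.gamma:.4g}) fitted on "
            f"{self.model.design.n} transcripts x {len(self.predictors)} predictors"
        )


def train_classifier(design: LabeledDesign, **kw) -> ExpressionModelResults:
    """Fit an SVM high/low classifier on the full design."""
    if design.n < 20:
        raise ValueError("need at least 20 training rows")
    return ExpressionModel(design, kind="svm", **kw).fit()


def train_regressor(design: LabeledDesign, **kw) -> ExpressionModelResults:
    """Fit an SVR regressor of log expression on the full design."""
    if design.n < 20:
        raise ValueError("need at least 20 training rows")
    return ExpressionModel(design, kind="svr", **kw).fit()


def cross_validate(
    design: LabeledDesign,
    model_kind: str = "svm",
    n_repeats: int = 100,
    split: float = 0.5,
    seed: int = 0,
    **kw,
) -> CVReport:
    """Functional wrapper around :meth:`ExpressionModel.cross_validate`."""
    return ExpressionModel(design, kind=model_kind, **kw).cross_validate(
        n_repeats=n_repeats, split=split, seed=seed
    )


def evaluate_pcc(predicted, actual) -> float:
    """Pearson correlation of predicted vs actual; NaN if degenerate."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.std() == 0 or a.std() == 0:
        return np.nan
    return float(pearsonr(p, a).statistic)


def variance_explained(pcc: float) -> float:
    """Fraction of expression variance explained by the predictions: r^2."""
    return float(pcc) ** 2


def coverage_feature(
    annotations,
    tracks,
    bin_width: int = 100,
    quantile: float = 0.9,
) -> pd.DataFrame:
    """Fraction of each transcript body covered by strong signal.

    The transcript body is tiled with ``bin_width`` bins; per feature, a bin
    is "strong" when its aggregated signal strictly exceeds the feature's
    ``quantile`` quantile over all body bins of all transcripts (default:
    top decile).  Transcripts shorter than one bin get NaN.
    """
    from .binning import Bin, aggregate_probe_signal, aggregate_read_signal

    per_track_values = []
    per_track_masks = []
    for tr in tracks:
        vals_rows, mask_rows = [], []
        for t in annotations:
            nb = t.length // bin_width
            if nb < 1:
                vals_rows.append(np.array([]))
                mask_rows.append(np.array([], dtype=bool))
                continue
            lo = t.start if t.strand == "+" else t.end - nb * bin_width
            bins = [
                Bin(t.chrom, lo + i * bin_width, lo + (i + 1) * bin_width, f"b{i}")
                for i in range(nb)
            ]
            agg = aggregate_probe_signal if tr.assay == "probe" else aggregate_read_signal
            v, msk = agg(tr, bins)
            vals_rows.append(v)
            mask_rows.append(msk)
        per_track_values.append(vals_rows)
        per_track_masks.append(mask_rows)

    out = {}
    ids = [t.transcript_id for t in annotations]
    for j, tr in enumerate(tracks):
        pool = np.concatenate(
            [v[~m] for v, m in zip(per_track_values[j], per_track_masks[j]) if len(v)]
        )
        if len(pool) == 0:
            raise ValueError(f"no body-bin signal for feature {tr.feature_name}")
        thr = float(np.quantile(pool, quantile))
        fracs = []
        for v, m in zip(per_track_values[j], per_track_masks[j]):
            usable = v[~m]
            fracs.append(float(np.mean(usable > thr)) if len(usable) else np.nan)
        out[tr.feature_name] = fracs
    return pd.DataFrame(out, index=ids)
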