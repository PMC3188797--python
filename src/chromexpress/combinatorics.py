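"""Combinatorial effects among histone marks on expression.

Three probes of combinatorial structure at a single bin:

* linear models of log expression with all pairwise products of (standardised)
  mark signals — the interaction model ``y ~ sum(x_i) + sum_{i<j}(x_i x_j)``
  versus the main-effects-only singleton model, and the per-pair model
  ``y ~ x_i + x_j + x_i x_j``;
* a two-component Gaussian-mixture high/low categorisation of each mark
  (falling back to a median split when the signal is not bimodal), and the
  four-group HH/HL/LH/LL expression comparison it induces;
* a normalised joint mutual information ratio
  ``I(E;(H1,H2)) / max(I(E;H1), I(E;H2))`` that measures how much more the
  two marks say about expression together than the better of them alone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .association import welch_t
from .models import LabeledDesign, cross_validate

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionModel",
    "InteractionResults",
    "GMMSplit",
    "fit_interaction_model",
    "fit_singleton_model",
    "fit_pairwise_model",
    "gmm_split",
    "four_group_expression",
    "FourGroupResult",
    "normalized_joint_mi",
]


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    return (X - X.mean()) / X.std(ddof=1)


def _interaction_design(X: pd.DataFrame, pairs: bool = True) -> pd.DataFrame:
    Xs = _standardize(X)
    cols = {c: Xs[c] for c in Xs.columns}
    if pairs:
        for a, b in itertools.combinations(Xs.columns, 2):
            cols[f"{a}:{b}"] = Xs[a] * Xs[b]
    return pd.DataFrame(cols, index=X.index)


def _check_rank(design: pd.DataFrame) -> None:
    arr = design.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name terms involved in the deficiency via near-null singular vectors
        _, s, vt = np.linalg.svd(arr, full_matrices=False)
        tol = s.max() * 1e-10
        bad = set()
        for row in vt[s < tol]:
            bad.update(design.columns[np.abs(row) > 1e-6])
        raise ValueError(f"rank-deficient design; collinear terms: {sorted(bad)}")


class InteractionModel:
    """OLS model of log expression with optional pairwise product terms.

    Features are standardised before products are formed; an intercept is
    always included.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series, interactions: bool = True):
        self.X = X
        self.y = y
        self.interactions = interactions
        m = X.shape[1]
        n_terms = 1 + m + (m * (m - 1) // 2 if interactions else 0)
        if len(X) <= n_terms:
            raise ValueError(
                f"need n > {n_terms} observations for {m} features"
                f"{' with interactions' if interactions else ''}, got {len(X)}"
            )

    def fit(self, alpha: float = 0.001, cv_seed: int | None = 0, cv_repeats: int = 20) -> "InteractionResults":
        design = _interaction_design(self.X, pairs=self.interactions)
        _check_rank(design)
        ols = sm.OLS(self.y.to_numpy(), sm.add_constant(design)).fit()
        cv_pcc = np.nan
        if cv_seed is not None:
            y_class = pd.Series(
                np.where(self.y > self.y.median(), "high", "low"), index=self.y.index
            )
            d = LabeledDesign(design, self.y, y_class)
            cv_pcc = cross_validate(
                d, model_kind="ols", n_repeats=cv_repeats, seed=cv_seed
            ).mean
        return InteractionResults(self, ols, design, alpha, cv_pcc)


@dataclass
class InteractionResults:
    """Fitted interaction/singleton model with per-term inference."""

    model: InteractionModel
    ols: "sm.regression.linear_model.RegressionResultsWrapper"
    design: pd.DataFrame
    alpha: float
    cv_pcc: float

    @property
    def coefficients(self) -> pd.Series:
        return self.ols.params

    @property
    def p_values(self) -> pd.Series:
        return self.ols.pvalues

    @property
    def pair_terms(self) -> list[str]:
        return [c for c in self.design.columns if ":" in c]

    @property
    def significant_pairs(self) -> set[tuple[str, str]]:
        """Product terms with two-sided p below alpha."""
        out = set()
        for term in self.pair_terms:
            if self.ols.pvalues[term] < self.alpha:
                a, b = term.split(":")
                out.add((a, b))
        return out

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for term in self.pair_terms:
            a, b = term.split(":")
            rows.append(
                {
                    "feature_i": a,
                    "feature_j": b,
                    "coef": self.ols.params[term],
                    "p_value": self.ols.pvalues[term],
                    "significant": self.ols.pvalues[term] < self.alpha,
                }
            )
        return pd.DataFrame(rows)

    def summary(self):
        return self.ols.summary()


def fit_interaction_model(
    X: pd.DataFrame, y: pd.Series, alpha: float = 0.001, **kw
) -> InteractionResults:
    """Main effects plus all m(m-1)/2 pairwise products."""
    return InteractionModel(X, y, interactions=True).fit(alpha=alpha, **kw)


def fit_singleton_model(X: pd.DataFrame, y: pd.Series, **kw) -> InteractionResults:
    """Main effects only."""
    return InteractionModel(X, y, interactions=False).fit(**kw)


def fit_pairwise_model(
    xi: pd.Series, xj: pd.Series, y: pd.Series, alpha: float = 0.001
) -> InteractionResults:
    """The 3-term model y ~ x_i + x_j + x_i x_j for one pair of marks."""
    X = pd.DataFrame({xi.name or "xi": xi, xj.name or "xj": xj})
    return InteractionModel(X, y, interactions=True).fit(alpha=alpha, cv_seed=None)


def all_pairs_table(X: pd.DataFrame, y: pd.Series, alpha: float = 0.001) -> pd.DataFrame:
    """Pairwise-model interaction inference for every pair of features."""
    rows = []
    for a, b in itertools.combinations(X.columns, 2):
        res = fit_pairwise_model(X[a], X[b], y, alpha=alpha)
        term = f"{a}:{b}"
        rows.append(
            {
                "feature_i": a,
                "feature_j": b,
                "coef_interaction": res.ols.params[term],
                "p_interaction": res.ols.pvalues[term],
                "significant": res.ols.pvalues[term] < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GMMSplit:
    """High/low categorisation of one mark's signal.

    ``method='mixture'`` when a 2-component Gaussian mixture was preferred
    (BIC better than one component and both weights >= ``weight_min``),
    otherwise ``'median'``.  H is always the component / side with the
    larger mean.
    """

    labels: pd.Series  # 'H' / 'L'
    method: str
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    variances: np.ndarray = field(default_factory=lambda: np.array([]))
    weights: np.ndarray = field(default_factory=lambda: np.array([]))


def gmm_split(
    values: pd.Series | np.ndarray,
    seed: int = 0,
    weight_min: float = 0.1,
    force_method: str | None = None,
) -> GMMSplit:
    """Split a signal into H and L by a 2-component Gaussian mixture.

    EM with k-means initialisation; the mixture is accepted only when its BIC
    beats the single-Gaussian fit and neither weight collapses below
    ``weight_min`` — otherwise (signal not bimodal) the split falls back to
    the median.  Labels are invariant to affine rescaling of the signal.
    """
    x = pd.Series(values).astype(float)
    if len(x) < 50:
        raise ValueError("need at least 50 values for a mixture split")
    arr = x.to_numpy().reshape(-1, 1)
    method = force_method
    if method is None:
        # standardise so EM convergence thresholds are scale-free
        arr_std = (arr - arr.mean()) / (arr.std() if arr.std() > 0 else 1.0)
        gm2 = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(arr_std)
        gm1 = GaussianMixture(n_components=1, random_state=seed).fit(arr_std)
        bimodal = (
            gm2.converged_
            and gm2.bic(arr_std) < gm1.bic(arr_std)
            and gm2.weights_.min() >= weight_min
        )
        if not gm2.converged_:
            logger.info("EM did not converge; falling back to median split")
        method = "mixture" if bimodal else "median"
    if method == "mixture":
        arr_std = (arr - arr.mean()) / (arr.std() if arr.std() > 0 else 1.0)
        gm2 = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(arr_std)
        post = gm2.predict(arr_std)
        hi = int(np.argmax(gm2.means_.ravel()))
        labels = pd.Series(np.where(post == hi, "H", "L"), index=x.index)
        scale = arr.std() if arr.std() > 0 else 1.0
        order = np.argsort(gm2.means_.ravel())
        return GMMSplit(
            labels,
            "mixture",
            means=gm2.means_.ravel()[order] * scale + arr.mean(),
            variances=gm2.covariances_.ravel()[order] * scale**2,
            weights=gm2.weights_.ravel()[order],
        )
    med = float(x.median())
    labels = pd.Series(np.where(x > med, "H", "L"), index=x.index)
    return GMMSplit(labels, "median")


@dataclass
class FourGroupResult:
    """HH/HL/LH/LL expression summaries and pairwise Welch comparisons."""

    group_stats: pd.DataFrame
    tests: pd.DataFrame

    def summary(self) -> str:
        return (
            "Four-group expression comparison\n"
            + self.group_stats.to_string()
            + "\n\nPairwise Welch tests (Holm-adjusted):\n"
            + self.tests.to_string(index=False)
        )


def four_group_expression(
    labels_f1: pd.Series, labels_f2: pd.Series, y: pd.Series
) -> FourGroupResult:
    """Expression by joint H/L category of two marks.

    Groups are named first-mark-label then second-mark-label (HH, HL, LH,
    LL).  All 6 pairwise group comparisons are Welch t-tests; raw and
    Holm-adjusted p-values are both reported.
    """
    idx = labels_f1.index.intersection(labels_f2.index).intersection(y.index)
    g = labels_f1.loc[idx].astype(str) + labels_f2.loc[idx].astype(str)
    yv = y.loc[idx].astype(float)
    stats_rows = {}
    for name in ("HH", "HL", "LH", "LL"):
        vals = yv[g == name]
        stats_rows[name] = {
            "n": len(vals),
            "mean": vals.mean() if len(vals) else np.nan,
            "median": vals.median() if len(vals) else np.nan,
        }
    group_stats = pd.DataFrame(stats_rows).T
    rows = []
    pairs = list(itertools.combinations(("HH", "HL", "LH", "LL"), 2))
    for a, b in pairs:
        va, vb = yv[g == a], yv[g == b]
        if len(va) < 2 or len(vb) < 2:
            rows.append({"group_a": a, "group_b": b, "t": np.nan, "p_raw": np.nan})
            continue
        t, p = welch_t(va, vb)
        rows.append({"group_a": a, "group_b": b, "t": t, "p_raw": p})
    tests = pd.DataFrame(rows)
    ok = tests["p_raw"].notna()
    adj = np.full(len(tests), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(tests.loc[ok, "p_raw"], method="holm")[1]
    tests["p_holm"] = adj
    return FourGroupResult(group_stats, tests)


def _equal_freq_codes(x: np.ndarray, k: int) -> np.ndarray:
    # ordinal ranks break ties deterministically so every bin is populated
    r = rankdata(x, method="ordinal")
    return np.floor((r - 1) * k / len(x)).astype(int)


def _plugin_mi(a: np.ndarray, b: np.ndarray) -> float:
    joint = pd.crosstab(a, b).to_numpy().astype(float)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pa @ pb))
    return float(np.nansum(terms))


def normalized_joint_mi(E, H1, H2, k_bins: int = 3) -> float:
    """I(E;(H1,H2)) / max(I(E;H1), I(E;H2)) with equal-frequency binning.

    Each variable is discretised into ``k_bins`` equal-frequency levels (the
    joint mark variable then has k^2 cells) and plug-in mutual information is
    computed.  The plug-in ratio is always >= 1 where defined; a ratio well
    above 1 means the marks are jointly much more informative about
    expression than either alone.  Returns NaN when both marginal MIs vanish.
    """
    E = np.asarray(E, dtype=float)
    H1 = np.asarray(H1, dtype=float)
    H2 = np.asarray(H2, dtype=float)
    if len(E) < 100:
        raise ValueError("need at least 100 observations")
    if k_bins < 2:
        raise ValueError("k_bins must be >= 2")
    e = _equal_freq_codes(E, k_bins)
    h1 = _equal_freq_codes(H1, k_bins)
    h2 = _equal_freq_codes(H2, k_bins)
    joint = h1 * k_bins + h2
    denom = max(_plugin_mi(e, h1), _plugin_mi(e, h2))
    if denom <= 0:
        return np.nan
    return _plugin_mi(e, joint) / denom
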