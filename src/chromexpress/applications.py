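"""Transfer analyses: stage specificity, operon position, miRNA prediction.

Three ways of asking how far a chromatin-signal model generalises:

* train on one stage's chromatin against each stage's expression in turn —
  accuracy should peak when chromatin and expression come from the same
  stage;
* correlate signal with expression separately for the first, second and
  last genes of operons — only the first gene owns the shared promoter;
* score pre-miRNA loci with a model trained on protein-coding genes,
  using each locus's mean feature signal as its single "bin".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import Bin, BinTensor, TranscriptAnnotation, aggregate_probe_signal, aggregate_read_signal
from .association import AssociationProfile, ExpressionTable, spearman_profile
from .models import (
    CVReport,
    ExpressionModel,
    ExpressionModelResults,
    bin_design,
    evaluate_pcc,
    roc_auc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MirnaLocus",
    "cross_stage_evaluate",
    "differential_subset",
    "operon_position_profiles",
    "OperonProfiles",
    "mirna_signal_matrix",
    "mirna_predict",
    "MirnaPredictions",
]


@dataclass(frozen=True)
class MirnaLocus:
    """A pre-miRNA hairpin locus (~100 nt); the signal window for prediction."""

    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"{self.mirna_id}: empty interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mirna_id}: bad strand {self.strand!r}")

    @classmethod
    def from_annotation(cls, t: TranscriptAnnotation) -> "MirnaLocus":
        return cls(t.transcript_id, t.chrom, t.strand, t.start, t.end)


def cross_stage_evaluate(
    tensor: BinTensor,
    expr: ExpressionTable,
    stages: list[str],
    bin_label: str = "TSS:d1",
    model_kind: str = "svm",
    n_repeats: int = 100,
    seed: int = 0,
    features: list[str] | None = None,
) -> dict[str, CVReport]:
    """Evaluate one stage's chromatin against every stage's expression.

    The tensor carries chromatin signal from a single stage; for each target
    stage a fresh model is trained on that stage's expression labels and
    cross-validated.  The same ``seed`` (hence identical partitions) is used
    for every stage so the AUC/PCC values are directly comparable.  Stages
    absent from the expression table are skipped with a log message.
    """
    out: dict[str, CVReport] = {}
    for stage in stages:
        if stage not in expr.stages:
            logger.warning("stage %s missing from expression table; skipped", stage)
            continue
        design = bin_design(tensor, expr, stage, bin_label, features=features)
        out[stage] = ExpressionModel(design, kind=model_kind).cross_validate(
            n_repeats=n_repeats, seed=seed
        )
    return out


def differential_subset(
    expr: ExpressionTable,
    stage_a: str,
    stage_b: str,
    fold: float = 4.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Transcripts differing at least ``fold``-fold between two stages.

    A pseudocount keeps the ratio defined at zero RPKM; the rule
    ``max + p >= fold * (min + p)`` is symmetric in the two stages.
    """
    a = expr.values(stage_a) + pseudocount
    b = expr.values(stage_b) + pseudocount
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    keep = hi >= fold * lo
    return list(expr.rpkm.index[keep])


@dataclass
class OperonProfiles:
    """Per-position correlation profiles and expression comparisons."""

    profiles: dict[str, AssociationProfile]  # 'first' / 'second' / 'last'
    expression_ratio_first_second: float
    expression_ratio_first_last: float
    median_ratio_first_second: float
    median_ratio_first_last: float
    pcc_first_second: float

    def summary(self) -> str:
        return (
            "Operon position analysis\n"
            f"  mean RPKM ratio first/second  : {self.expression_ratio_first_second:.3f}\n"
            f"  mean RPKM ratio first/last    : {self.expression_ratio_first_last:.3f}\n"
            f"  median RPKM ratio first/second: {self.median_ratio_first_second:.3f}\n"
            f"  median RPKM ratio first/last  : {self.median_ratio_first_last:.3f}\n"
            f"  PCC(first, second) log expr   : {self.pcc_first_second:.3f}\n"
            f"  positions profiled            : {sorted(self.profiles)}"
        )


def operon_position_profiles(
    tensor: BinTensor,
    operons: dict[str, list[str]],
    expr: ExpressionTable,
    stage: str,
    min_pairs: int = 10,
) -> OperonProfiles:
    """Signal-expression correlation by operon position.

    Positions: first = the promoter-bearing gene; last = the final gene
    (a 2-gene operon contributes first + last only); second = index 2 of
    operons with at least 3 genes.  Genes missing from the tensor raise.
    """
    in_tensor = set(tensor.transcript_ids)
    groups: dict[str, list[str]] = {"first": [], "second": [], "last": []}
    for op, genes in operons.items():
        if len(genes) < 2:
            raise ValueError(f"operon {op} has fewer than 2 genes")
        for gid in genes:
            if gid not in in_tensor:
                raise ValueError(f"operon gene {gid!r} absent from tensor")
        groups["first"].append(genes[0])
        groups["last"].append(genes[-1])
        if len(genes) >= 3:
            groups["second"].append(genes[1])

    profiles = {}
    for pos, ids in groups.items():
        if len(ids) >= min_pairs:
            profiles[pos] = spearman_profile(
                tensor.subset_transcripts(ids), expr, stage, min_pairs=min_pairs
            )

    rpkm = expr.values(stage)

    def _ratio(a, b, stat):
        num, den = float(stat(rpkm.loc[a])), float(stat(rpkm.loc[b]))
        return num / den if den > 0 else np.nan

    ratio_fs = med_fs = np.nan
    pcc_fs = np.nan
    if groups["second"]:
        ratio_fs = _ratio(groups["first"], groups["second"], pd.Series.mean)
        med_fs = _ratio(groups["first"], groups["second"], pd.Series.median)
        log_expr = expr.log_values(stage)
        firsts_with_second = [genes[0] for genes in operons.values() if len(genes) >= 3]
        pcc_fs = evaluate_pcc(
            log_expr.loc[firsts_with_second].to_numpy(),
            log_expr.loc[groups["second"]].to_numpy(),
        )
    ratio_fl = _ratio(groups["first"], groups["last"], pd.Series.mean)
    med_fl = _ratio(groups["first"], groups["last"], pd.Series.median)
    return OperonProfiles(profiles, ratio_fs, ratio_fl, med_fs, med_fl, pcc_fs)


def mirna_signal_matrix(loci: list[MirnaLocus], tracks) -> pd.DataFrame:
    """Per-locus mean feature signal over the pre-miRNA interval.

    Probe tracks: mean of probes whose midpoint falls in the locus; read
    tracks: overlap-weighted read count.  One row per locus, one column per
    feature; loci without probe coverage get NaN for that feature.
    """
    rows = {}
    for locus in loci:
        window = [Bin(locus.chrom, locus.start, locus.end, "locus")]
        vals = {}
        for tr in tracks:
            agg = aggregate_probe_signal if tr.assay == "probe" else aggregate_read_signal
            v, msk = agg(tr, window)
            vals[tr.feature_name] = np.nan if msk[0] else float(v[0])
        rows[locus.mirna_id] = vals
    return pd.DataFrame(rows).T


@dataclass
class MirnaPredictions:
    """Model output per miRNA, with accuracy when measurements are given."""

    predictions: pd.Series
    pcc: float = np.nan
    auc: float = np.nan
    n_scored: int = 0

    def summary(self) -> str:
        lines = [f"miRNA predictions for {self.n_scored} loci"]
        if np.isfinite(self.pcc):
            lines.append(f"  PCC vs measured : {self.pcc:.3f}")
        if np.isfinite(self.auc):
            lines.append(f"  AUC vs measured high/low: {self.auc:.3f}")
        return "\n".join(lines)


def mirna_predict(
    signals: pd.DataFrame,
    coding_model: ExpressionModelResults,
    expr_mirna: ExpressionTable | None = None,
    stage: str | None = None,
) -> MirnaPredictions:
    """Apply a protein-coding chromatin model to pre-miRNA signal vectors.

    ``signals`` is the loci x features matrix from
    :func:`mirna_signal_matrix` (or any matrix with the model's predictor
    columns).  Rows with missing features are dropped.  When measured
    expression is supplied, regression models report the Pearson correlation
    with measured log expression and classification models the AUC against
    the measured-median high/low split.
    """
    missing = [c for c in coding_model.predictors if c not in signals.columns]
    if missing:
        raise ValueError(f"feature-set mismatch between loci signals and model: {missing}")
    X = signals[coding_model.predictors].dropna(axis=0)
    scores = coding_model.decision_scores(X)
    preds = pd.Series(scores, index=X.index, name="prediction")
    pcc = np.nan
    auc = np.nan
    if expr_mirna is not None:
        if stage is None:
            raise ValueError("stage required when measured expression is given")
        measured = expr_mirna.log_values(stage)
        shared = [i for i in preds.index if i in measured.index]
        if len(shared) >= 3:
            y = measured.loc[shared]
            if coding_model.model.kind == "svm":
                labels = np.where(y > y.median(), "high", "low")
                _, auc = roc_auc(preds.loc[shared].to_numpy(), labels)
            else:
                pcc = evaluate_pcc(preds.loc[shared].to_numpy(), y.to_numpy())
    return MirnaPredictions(preds, pcc=pcc, auc=auc, n_scored=len(preds))
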