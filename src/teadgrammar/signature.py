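"""YAP1-activity expression signature classifier.

Tumor samples are labelled "high" or "low" YAP1 activity by the sum of
their expression and copy-number ranks (extremes mode keeps the top and
bottom 10%), and a Gaussian naive-Bayes classifier over the signature
genes is evaluated by repeated stratified 2/3-train / 1/3-test random
holdout, with the area under the ROC curve (Mann-Whitney formulation) as
the accuracy measure.  Expression values are log2(x+1)-transformed before
fitting by default, which makes FPKM-like data roughly Gaussian per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CLASSES = ("high", "low")


@dataclass(frozen=True)
class SampleLabeling:
    labels: pd.Series  # per-sample 'high' / 'low' / 'unlabeled'
    ranksum: pd.Series
    top_fraction: float

    def labeled_samples(self) -> pd.Index:
        return self.labels.index[self.labels != "unlabeled"]


@dataclass(frozen=True)
class NBModel:
    """Per-gene class-conditional Gaussian parameters with class priors."""

    genes: pd.Index
    means: pd.DataFrame  # genes x classes
    variances: pd.DataFrame  # genes x classes, floored at epsilon
    priors: dict[str, float]
    epsilon: float
    log_transform: bool = True


@dataclass(frozen=True)
class CVResult:
    aucs: np.ndarray
    mean_auc: float
    n_iterations: int
    train_fraction: float
    seed: int


def ranksum_label(
    expression: pd.Series,
    copy_number: pd.Series,
    top_fraction: float = 0.10,
    mode: str = "extremes",
) -> SampleLabeling:
    """Rank samples by expression-rank + copy-number-rank and label the
    extremes (or split all samples at the median ranksum).

    Average ranks on ties; boundary ties and fully degenerate ranksums are
    broken by sample-identifier order (with a warning in the degenerate
    case).  In "all" mode samples at the median go to the low class.
    """
    if mode not in ("extremes", "all"):
        raise ValueError(f"mode must be 'extremes' or 'all', got {mode!r}")
    if not 0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must lie in (0, 0.5]")
    if not expression.index.equals(copy_number.index):
        copy_number = copy_number.reindex(expression.index)
        if copy_number.isna().any():
            raise ValueError("expression and copy-number cover different samples")
    n = len(expression)
    ranksum = pd.Series(
        rankdata(expression.to_numpy()) + rankdata(copy_number.to_numpy()),
        index=expression.index,
        name="ranksum",
    )
    if ranksum.nunique() == 1:
        warnings.warn(
            "all ranksums identical; high/low labels fall back to sample-id order",
            stacklevel=2,
        )
    # stable order: ranksum ascending, sample id as deterministic tie-break
    order = ranksum.to_frame().assign(_id=ranksum.index.astype(str)).sort_values(
        ["ranksum", "_id"]
    ).index
    labels = pd.Series("unlabeled", index=expression.index, name="label")
    if mode == "extremes":
        k = int(np.floor(top_fraction * n))
        if k < 1:
            raise ValueError(f"top_fraction {top_fraction} labels no samples at n={n}")
        labels.loc[order[:k]] = "low"
        labels.loc[order[-k:]] = "high"
    else:
        median = ranksum.median()
        labels[:] = np.where(ranksum <= median, "low", "high")
        if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
            raise ValueError("median split produced a single class")
    return SampleLabeling(labels, ranksum, top_fraction)


def nb_fit(
    train: pd.DataFrame,
    labels: pd.Series | SampleLabeling,
    epsilon_scale: float = 1e-9,
    log_transform: bool = True,
) -> NBModel:
    """Fit per-gene class-conditional Gaussians on labeled training samples.

    ``train`` is genes x samples.  Variances are unbiased and floored at
    epsilon = epsilon_scale * (global variance of the training values), so
    constant genes cannot produce degenerate densities.
    """
    if isinstance(labels, SampleLabeling):
        labels = labels.labels
    labels = labels.reindex(train.columns).fillna("unlabeled")
    labeled = labels[labels.isin(CLASSES)]
    if any((labeled == c).sum() < 2 for c in CLASSES):
        raise ValueError("need at least 2 training samples in each class")
    X = train[labeled.index].to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    global_var = float(X.var())
    epsilon = max(epsilon_scale * global_var, np.finfo(float).tiny)
    means, variances = {}, {}
    for c in CLASSES:
        Xc = X[:, (labeled == c).to_numpy()]
        means[c] = Xc.mean(axis=1)
        variances[c] = np.maximum(Xc.var(axis=1, ddof=1), epsilon)
    priors = {c: float((labeled == c).mean()) for c in CLASSES}
    return NBModel(
        genes=train.index,
        means=pd.DataFrame(means, index=train.index),
        variances=pd.DataFrame(variances, index=train.index),
        priors=priors,
        epsilon=epsilon,
        log_transform=log_transform,
    )


def nb_predict(model: NBModel, samples: pd.DataFrame | pd.Series) -> pd.Series:
    """Posterior probability of the "high" class, computed in log space."""
    if isinstance(samples, pd.Series):
        samples = samples.to_frame()
    if not model.genes.equals(samples.index):
        missing = model.genes.difference(samples.index)
        if len(missing):
            raise ValueError(f"samples lack model genes: {list(missing)[:5]}...")
        samples = samples.loc[model.genes]
    X = samples.to_numpy(dtype=float)
    if model.log_transform:
        X = np.log2(X + 1.0)
    log_joint = {}
    for c in CLASSES:
        mu = model.means[c].to_numpy()[:, None]
        var = model.variances[c].to_numpy()[:, None]
        log_density = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var)
        log_joint[c] = log_density.sum(axis=0) + np.log(model.priors[c])
    hi, lo = log_joint["high"], log_joint["low"]
    m = np.maximum(hi, lo)
    posterior = np.exp(hi - m) / (np.exp(hi - m) + np.exp(lo - m))
    return pd.Series(posterior, index=samples.columns, name="p_high")


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation: the fraction of
    (positive, negative) pairs where the positive outscores the negative,
    ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def select_features(
    expr: pd.DataFrame,
    labels: pd.Series | SampleLabeling,
    k: int = 10,
    log_transform: bool = True,
) -> list[str]:
    """Top-k genes by absolute standardized mean difference between classes
    (pooled SD); deterministic, with gene order breaking exact ties."""
    if isinstance(labels, SampleLabeling):
        labels = labels.labels
    if k > len(expr.index):
        raise ValueError(f"k={k} exceeds the {len(expr.index)} available genes")
    labels = labels.reindex(expr.columns).fillna("unlabeled")
    labeled = labels[labels.isin(CLASSES)]
    X = expr[labeled.index].to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    hi = X[:, (labeled == "high").to_numpy()]
    lo = X[:, (labeled == "low").to_numpy()]
    pooled_sd = np.sqrt((hi.var(axis=1, ddof=1) + lo.var(axis=1, ddof=1)) / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.abs(hi.mean(axis=1) - lo.mean(axis=1)) / pooled_sd
    smd = np.nan_to_num(smd, nan=0.0, posinf=np.inf)
    order = np.lexsort((np.arange(len(smd)), -smd))
    return [expr.index[i] for i in order[:k]]


def iterated_holdout(
    expr: pd.DataFrame,
    labels: pd.Series | SampleLabeling,
    signature_genes: Sequence[str] | None = None,
    n_iterations: int = 1000,
    train_fraction: float = 2 / 3,
    seed: int = 0,
    select_k: int | None = None,
    log_transform: bool = True,
) -> CVResult:
    """Repeated stratified random holdout evaluation of the naive-Bayes
    signature classifier.

    Each iteration draws a class-stratified train/test split
    (train_fraction per class), fits on the training samples, scores the
    test samples, and records the test AUC.  With ``select_k``, feature
    selection runs inside each training fold only.  Deterministic for a
    fixed seed.
    """
    if isinstance(labels, SampleLabeling):
        labels = labels.labels
    if signature_genes is not None:
        missing = [g for g in signature_genes if g not in expr.index]
        if missing:
            raise ValueError(f"signature genes absent from the matrix: {missing}")
        expr = expr.loc[list(signature_genes)]
    labels = labels.reindex(expr.columns).fillna("unlabeled")
    labeled = labels[labels.isin(CLASSES)]
    idx = {c: labeled.index[labeled == c].to_numpy() for c in CLASSES}
    n_train = {c: int(np.floor(train_fraction * len(idx[c]))) for c in CLASSES}
    for c in CLASSES:
        if n_train[c] < 2 or n_train[c] >= len(idx[c]):
            raise ValueError(
                f"class {c!r}: {len(idx[c])} samples cannot support a "
                f"{train_fraction:.2f} stratified split"
            )
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iterations)
    for it in range(n_iterations):
        train_ids, test_ids = [], []
        for c in CLASSES:
            perm = rng.permutation(idx[c])
            train_ids.extend(perm[: n_train[c]])
            test_ids.extend(perm[n_train[c] :])
        fold_expr = expr
        if select_k is not None:
            fold_genes = select_features(
                expr[train_ids], labeled[train_ids], select_k, log_transform
            )
            fold_expr = expr.loc[fold_genes]
        model = nb_fit(fold_expr[train_ids], labeled[train_ids], log_transform=log_transform)
        scores = nb_predict(model, fold_expr[test_ids])
        aucs[it] = auc(scores.to_numpy(), (labeled[test_ids] == "high").to_numpy())
    return CVResult(aucs, float(aucs.mean()), n_iterations, train_fraction, seed)
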