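"""Array-based validation of DMR sets.

Probes from a beta-value matrix are mapped into DMR intervals; the mapped
probes drive (a) complete-linkage hierarchical clustering of unscaled betas
with tree cutting and TPR/TNR/chi-square evaluation against normal/cancer
labels, and (b) an L1-penalized logistic signature trained on a stratified
70% split with 10-fold cross-validation along a 200-value lambda grid on
[e^-7, e^-2], evaluated by ROC/AUC and by TPR/TNR at a fixed probability
cutoff (default 0.8) with a Fisher's exact test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

LAMBDA_RANGE = (math.exp(-7), math.exp(-2))


def map_probes(manifest: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Map array probes into region intervals.

    ``manifest``: probe_id, chrom, pos (1-based point).  ``regions``: chrom,
    start, end (0-based half-open).  A probe is retained iff its 0-based
    position (pos - 1) falls inside a region; probes on chromosomes absent
    from the regions are excluded with a warning.  Returns probe_id, chrom,
    pos, region chrom/start/end.
    """
    out_rows = []
    region_chroms = set(regions["chrom"])
    unknown = sorted(set(manifest["chrom"]) - region_chroms)
    if unknown:
        logger.warning("probes on chromosomes without regions excluded: %s", unknown)
    for chrom, reg in regions.groupby("chrom", sort=False):
        sub = manifest[manifest["chrom"] == chrom]
        if sub.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        pos0 = sub["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.maximum(idx, 0)])
        for i, (pid, p) in enumerate(zip(sub["probe_id"], sub["pos"])):
            if hit[i]:
                j = idx[i]
                out_rows.append((pid, chrom, int(p), int(starts[j]), int(ends[j])))
    return pd.DataFrame(
        out_rows, columns=["probe_id", "chrom", "pos", "region_start", "region_end"]
    )


@dataclass
class ClusterEvaluation:
    """Hierarchical-clustering evaluation against binary labels."""

    linkage_matrix: np.ndarray
    assignments: pd.Series  # cluster id per sample
    normal_like_cluster: int
    tpr: float
    tnr: float
    chi_square: float
    p_value: float
    table: np.ndarray  # 2x2 (normal-like/cancer-like) x (normal/cancer)


def cluster_evaluate(
    beta: pd.DataFrame,
    labels: pd.Series,
    probes: list[str] | None = None,
    n_cuts: int = 1,
) -> ClusterEvaluation:
    """Cluster samples on unscaled betas and score the cut against labels.

    ``beta``: probes x samples; ``labels``: 'normal'/'cancer' per sample.
    Probes with any missing value among the analysed samples are dropped
    (logged).  Complete-linkage agglomeration on Euclidean distance; the
    tree is cut at its first ``n_cuts`` bifurcations (n_cuts + 1 clusters).
    The cluster holding the majority of normal samples (ties broken toward
    the larger cluster) is "normal-like"; all others pool to "cancer-like".
    TPR = cancers in cancer-like / cancers; TNR = normals in normal-like /
    normals; chi-square is Pearson's (no continuity correction) on the 2x2.
    """
    if probes is not None:
        missing = [p for p in probes if p not in beta.index]
        if missing:
            raise ValueError(f"probes absent from beta matrix: {missing[:5]}...")
        beta = beta.loc[probes]
    labels = labels.loc[beta.columns]
    classes = set(labels)
    if not {"normal", "cancer"} <= classes or labels.nunique() < 2:
        raise ValueError("evaluation needs both normal and cancer samples")
    complete = beta.dropna(axis=0)
    dropped = len(beta) - len(complete)
    if dropped:
        logger.info("dropped %d probes with missing betas", dropped)
    if complete.empty:
        raise ValueError("no complete probes left for clustering")
    X = complete.to_numpy().T  # samples x probes, unscaled
    Z = linkage(pdist(X, metric="euclidean"), method="complete")
    k = n_cuts + 1
    assign = fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(assign, index=beta.columns, name="cluster")
    normal_counts = {
        c: int(((assign == c) & (labels == "normal")).sum()) for c in np.unique(assign)
    }
    sizes = assign.value_counts().to_dict()
    normal_like = max(normal_counts, key=lambda c: (normal_counts[c], sizes[c]))
    in_normal_like = assign == normal_like
    n_normal = int((labels == "normal").sum())
    n_cancer = int((labels == "cancer").sum())
    tn = int((in_normal_like & (labels == "normal")).sum())
    tp = int((~in_normal_like & (labels == "cancer")).sum())
    table = np.array(
        [
            [tn, int((in_normal_like & (labels == "cancer")).sum())],
            [n_normal - tn, tp],
        ]
    )
    chi2, p = _pearson_chi2(table)
    return ClusterEvaluation(
        linkage_matrix=Z,
        assignments=assign,
        normal_like_cluster=int(normal_like),
        tpr=tp / n_cancer,
        tnr=tn / n_normal,
        chi_square=chi2,
        p_value=p,
        table=table,
    )


def _pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df for a 2x2."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected == 0).any():
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df=df))


@dataclass
class SignatureModel:
    """Penalized-logistic signature over array probes.

    Coefficients are reported on the original beta scale (the fit itself is
    standardized); ``probes`` lists the non-zero-coefficient probes at the
    chosen lambda.
    """

    probes: list[str]
    coefficients: dict[str, float]
    intercept: float
    lambda_path: list[float]
    chosen_lambda: float
    cv_deviance: list[float]
    cutoff: float
    train_samples: list[str]
    test_samples: list[str]
    seed: int
    all_probes: list[str] = field(default_factory=list)

    def predict_proba(self, beta: pd.DataFrame) -> pd.Series:
        """Per-sample logistic probability of the cancer class."""
        missing = [p for p in self.probes if p not in beta.index]
        if missing:
            raise ValueError(f"probes missing from matrix: {missing}")
        X = beta.loc[self.probes].to_numpy().T
        coef = np.array([self.coefficients[p] for p in self.probes])
        eta = self.intercept + X @ coef
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=beta.columns)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probes": self.probes,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "chosen_lambda": self.chosen_lambda,
            "cutoff": self.cutoff,
            "lambda_path": self.lambda_path,
            "train_samples": self.train_samples,
            "test_samples": self.test_samples,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            probes=d["probes"], coefficients=d["coefficients"],
            intercept=d["intercept"], lambda_path=d["lambda_path"],
            chosen_lambda=d["chosen_lambda"], cv_deviance=[],
            cutoff=d["cutoff"], train_samples=d["train_samples"],
            test_samples=d["test_samples"], seed=d["seed"],
        )


def _stratified_split(labels: pd.Series, train_frac: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        train_idx.extend(ids[perm[:n_train]])
        test_idx.extend(ids[perm[n_train:]])
    return list(train_idx), list(test_idx)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet objective (1/n) NLL + lam * ||b||_1  <=>  sklearn C = 1/(n*lam)
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-7, max_iter=2000
    )
    clf.fit(X, y)
    return clf


def _binom_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_signature(
    beta: pd.DataFrame,
    labels: pd.Series,
    probes: list[str] | None = None,
    train_frac: float = 0.7,
    n_lambda: int = 200,
    lambda_range: tuple[float, float] = LAMBDA_RANGE,
    folds: int = 10,
    rng_seed: int = 0,
    cutoff: float = 0.8,
    cv_loss: str = "deviance",
) -> SignatureModel:
    """Train the L1-penalized logistic signature.

    A stratified ``train_frac`` split is drawn with the given seed.  For
    each of ``n_lambda`` log-spaced penalties on ``lambda_range``, mean
    held-out binomial deviance (or misclassification with
    ``cv_loss='misclass'``) is computed over seeded ``folds``-fold CV; the
    lambda minimizing it (largest lambda on ties) is refit on the full
    training split.  Probes with any missing value or zero variance are
    dropped with a warning.
    """
    if probes is not None:
        beta = beta.loc[[p for p in probes if p in beta.index]]
    labels = labels.loc[beta.columns]
    y_all = (labels == "cancer").astype(int)
    rng = np.random.default_rng(rng_seed)
    train_ids, test_ids = _stratified_split(labels, train_frac, rng)
    if y_all.loc[train_ids].nunique() < 2:
        raise ValueError("training split lacks one of the classes")
    if len(train_ids) < folds:
        raise ValueError(f"{len(train_ids)} training samples < {folds} folds")
    work = beta[train_ids].dropna(axis=0)
    sd = work.to_numpy().std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("dropping %d constant/missing probes", int(degenerate.sum()))
        work = work.loc[~degenerate]
        sd = sd[~degenerate]
    probe_ids = list(work.index)
    X = work.to_numpy().T
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    Xs = (X - mean) / scale
    y = y_all.loc[train_ids].to_numpy()
    lambdas = np.exp(
        np.linspace(math.log(lambda_range[0]), math.log(lambda_range[1]), n_lambda)
    )
    # seeded, stratified fold assignment
    fold_of = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(len(perm)) % folds
    cv_err = np.zeros(n_lambda)
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        for i, lam in enumerate(lambdas):
            clf = _fit_l1(Xs[tr], y[tr], lam)
            p = clf.predict_proba(Xs[te])[:, 1]
            if cv_loss == "misclass":
                cv_err[i] += float(np.mean((p >= 0.5) != y[te]))
            else:
                cv_err[i] += _binom_deviance(y[te], p)
    cv_err /= folds
    best = np.min(cv_err)
    chosen_idx = int(np.max(np.where(cv_err <= best + 1e-12)[0]))  # sparser on ties
    chosen = float(lambdas[chosen_idx])
    clf = _fit_l1(Xs, y, chosen)
    coef_std = clf.coef_.ravel()
    coef_orig = coef_std / scale
    intercept = float(clf.intercept_[0] - np.dot(coef_std, mean / scale))
    nz = np.flatnonzero(coef_std)
    selected = [probe_ids[i] for i in nz]
    model = SignatureModel(
        probes=selected,
        coefficients={probe_ids[i]: float(coef_orig[i]) for i in nz},
        intercept=intercept,
        lambda_path=[float(x) for x in lambdas],
        chosen_lambda=chosen,
        cv_deviance=[float(x) for x in cv_err],
        cutoff=cutoff,
        train_samples=train_ids,
        test_samples=test_ids,
        seed=rng_seed,
        all_probes=probe_ids,
    )
    logger.info(
        "signature: lambda=%.4g, %d non-zero probes of %d", chosen, len(selected), len(probe_ids)
    )
    return model


def roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """ROC curve over all score thresholds (descending), with (0,0) and
    (1,1) anchors; ties collapse to single points."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y)[order]
    s = np.asarray(scores)[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(y) - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((1 - y).sum(), 1)]
    thr = np.r_[np.inf, s[idx]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def auc_trapezoid(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))


def evaluate_signature(
    model: SignatureModel,
    beta: pd.DataFrame,
    labels: pd.Series,
    cutoff: float | None = None,
) -> dict:
    """Evaluate a trained signature on a test matrix.

    Returns ROC points, trapezoidal AUC (equal to the normalized
    Mann-Whitney statistic on tie-free scores), TPR/TNR at the probability
    cutoff (predicted cancer iff probability >= cutoff), and a two-sided
    Fisher's exact p on the resulting 2x2.
    """
    if cutoff is None:
        cutoff = model.cutoff
    labels = labels.loc[beta.columns]
    prob = model.predict_proba(beta)
    y = (labels == "cancer").astype(int).to_numpy()
    roc = roc_points(prob.to_numpy(), y)
    auc = auc_trapezoid(roc)
    pred = prob.to_numpy() >= cutoff
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    tpr = tp / max(tp + fn, 1)
    tnr = tn / max(tn + fp, 1)
    _, fisher_p = stats.fisher_exact([[tp, fn], [fp, tn]], alternative="two-sided")
    return {
        "roc": roc,
        "auc": auc,
        "tpr": tpr,
        "tnr": tnr,
        "fisher_p": max(float(fisher_p), 1e-300),
        "cutoff": cutoff,
        "table": [[tp, fn], [fp, tn]],
        "probabilities": prob,
    }


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Probes x samples TSV with a header of sample ids and probe ids in the
    first column; missing values as NA."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"probe_id", "chrom", "pos"}
    if not need <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    return df
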