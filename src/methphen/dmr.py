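"""Per-bin differential methylation testing.

Each retained bin is tested with a binomial logistic regression of
(methylated, unmethylated) read counts on a group indicator, optionally with
the donor of origin as a categorical covariate.  The p-value is a 1-df
likelihood-ratio chi-square between the full model and the covariate-only
null.  Multiple testing is corrected with a sliding-linear-model (SLIM)
q-value: q = pi0 x Benjamini-Hochberg transform, with pi0 estimated from the
flat region of the empirical p-value CDF.  DMRs are bins passing both the
q-value and absolute-methylation-difference thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_binning import BinnedMethylationMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
_ETA_CLIP = 30.0


def _binom_half_dev(k: np.ndarray, n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Sum over samples of the binomial deviance contribution 2*[k log(k/n mu)
    + (n-k) log((n-k)/(n(1-mu)))], with 0 log 0 = 0."""
    from scipy.special import xlogy

    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(k, k) - xlogy(k, n * mu) + xlogy(n - k, n - k) - xlogy(n - k, n * (1 - mu))
    return 2.0 * np.nansum(term, axis=-1)


def _fit_binomial_logit(
    X: np.ndarray, meth: np.ndarray, total: np.ndarray,
    max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for binomial-logit GLMs sharing one design matrix.

    X: (n_samples, p); meth/total: (n_bins, n_samples).
    Returns (deviance (n_bins,), converged (n_bins,) bool, beta (n_bins, p)).
    Samples with total == 0 get zero weight.  The linear predictor is clipped
    at +/-30 so complete separation converges to the saturated limit instead
    of overflowing.
    """
    B, n = meth.shape
    p = X.shape[1]
    beta = np.zeros((B, p))
    obs = total > 0
    dev = np.full(B, np.inf)
    converged = np.zeros(B, dtype=bool)
    active = np.ones(B, dtype=bool)
    eye = np.eye(p) * 1e-9
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        b = beta[idx]
        eta = np.clip(b @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = total[idx] * mu * (1 - mu)
        w = np.where(obs[idx], w, 0.0)
        w = np.maximum(w, 1e-12 * obs[idx])
        z = eta + (meth[idx] - total[idx] * mu) / np.where(w > 0, w, 1.0)
        A = np.einsum("ki,bk,kj->bij", X, w, X) + eye
        rhs = np.einsum("ki,bk->bi", X, w * z)
        try:
            b_new = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            b_new = np.array([np.linalg.lstsq(a, r, rcond=None)[0] for a, r in zip(A, rhs)])
        eta_new = np.clip(b_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu_new = 1.0 / (1.0 + np.exp(-eta_new))
        d_new = _binom_half_dev(meth[idx], total[idx], np.where(obs[idx], mu_new, 0.5))
        delta = np.abs(dev[idx] - d_new)
        dev[idx] = d_new
        beta[idx] = b_new
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    bad = ~np.isfinite(dev)
    converged[bad] = False
    return dev, converged, beta


def _pooled_2x2_lrt(meth_a, total_a, meth_b, total_b) -> float:
    """G-test on the pooled group x meth/unmeth 2x2 table (separation
    fallback)."""
    from scipy.special import xlogy

    ka, na = float(np.sum(meth_a)), float(np.sum(total_a))
    kb, nb = float(np.sum(meth_b)), float(np.sum(total_b))
    if na == 0 or nb == 0:
        return 0.0
    p0 = (ka + kb) / (na + nb)

    def half(k, n, mu):
        if n == 0:
            return 0.0
        mu = min(max(mu, 1e-12), 1 - 1e-12)
        return float(xlogy(k, k) - xlogy(k, n * mu) + xlogy(n - k, n - k) - xlogy(n - k, n * (1 - mu)))

    # deviance of the common-proportion fit; the group-wise MLE has deviance 0
    g = 2.0 * (half(ka, na, p0) + half(kb, nb, p0))
    return max(g, 0.0)


def _design_matrices(group: np.ndarray, donor: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + group + donor dummies) and null (without group)
    design matrices."""
    n = len(group)
    cols = [np.ones(n)]
    if donor is not None:
        levels = pd.unique(donor)
        for lv in levels[1:]:
            cols.append((donor == lv).astype(float))
    X_null = np.column_stack(cols)
    X_full = np.column_stack([X_null[:, :1], group.astype(float), X_null[:, 1:]])
    return X_full, X_null


def test_bins(
    meth: np.ndarray,
    total: np.ndarray,
    group: np.ndarray,
    donor: np.ndarray | None = None,
    method: str = "lrt",
) -> pd.DataFrame:
    """Test many bins at once against a shared sample layout.

    meth/total: (n_bins, n_samples) count arrays; group: boolean array, True
    for group A; donor: optional categorical labels.  Returns a frame with
    p_value, meth_diff (pooled A proportion minus pooled B proportion), the
    LRT statistic and a ``fallback`` flag for bins where IRLS failed and the
    pooled 2x2 G-test was used instead.
    """
    if method not in ("lrt", "wald"):
        raise ValueError(f"unknown method: {method!r}")
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    total = np.atleast_2d(np.asarray(total, dtype=float))
    group = np.asarray(group, dtype=bool)
    if donor is not None:
        donor = np.asarray(donor)
        if len(pd.unique(donor)) < 2:
            donor = None
    X_full, X_null = _design_matrices(group, donor)
    dev_full, conv_full, beta_full = _fit_binomial_logit(X_full, meth, total)
    dev_null, conv_null, _ = _fit_binomial_logit(X_null, meth, total)
    lrt = np.maximum(dev_null - dev_full, 0.0)
    ok = conv_full & conv_null & np.isfinite(lrt)
    fallback = ~ok
    if fallback.any():
        for i in np.where(fallback)[0]:
            g = _pooled_2x2_lrt(meth[i, group], total[i, group], meth[i, ~group], total[i, ~group])
            lrt[i] = g
    if method == "lrt":
        p = stats.chi2.sf(lrt, df=1)
    else:
        # Wald on the group coefficient of the full fit
        eta = np.clip(beta_full @ X_full.T, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = total * mu * (1 - mu)
        A = np.einsum("ki,bk,kj->bij", X_full, w, X_full) + np.eye(X_full.shape[1]) * 1e-9
        cov = np.linalg.inv(A)
        se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
        z = beta_full[:, 1] / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[fallback] = stats.chi2.sf(lrt[fallback], df=1)
    p = np.clip(p, P_FLOOR, 1.0)
    sum_ma = meth[:, group].sum(axis=1)
    sum_ta = total[:, group].sum(axis=1)
    sum_mb = meth[:, ~group].sum(axis=1)
    sum_tb = total[:, ~group].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = sum_ma / np.maximum(sum_ta, 1) - sum_mb / np.maximum(sum_tb, 1)
    identical = lrt <= 1e-12
    p = np.where(identical, 1.0, p)
    return pd.DataFrame(
        {"p_value": p, "meth_diff": diff, "lrt": lrt, "fallback": fallback}
    )


def test_bin(
    meth, total, group, donor=None, method: str = "lrt"
) -> tuple[float, float]:
    """Test a single bin; returns (p_value, meth_diff).

    ``group`` is a boolean per-sample vector (True = group A); ``meth_diff``
    is the pooled group-A proportion minus the pooled group-B proportion.
    """
    group = np.asarray(group, dtype=bool)
    total = np.asarray(total, dtype=float)
    if not (total[group] > 0).any() or not (total[~group] > 0).any():
        raise ValueError("both groups need >= 1 sample with total > 0")
    res = test_bins(np.asarray(meth, dtype=float)[None, :], total[None, :], group, donor, method)
    return float(res["p_value"].iloc[0]), float(res["meth_diff"].iloc[0])


def estimate_pi0_slim(
    p_values: np.ndarray,
    n_grid: int = 100,
    window: int = 40,
    lambda_min: float = 0.25,
    min_p: int = 50,
) -> float:
    """Estimate the null proportion pi0 with a sliding linear model.

    The empirical CDF of the p-values is evaluated on a uniform lambda grid;
    straight lines are fit to sliding windows restricted to
    [lambda_min, 1], where signal p-values have flattened out; the smallest
    fitted slope, normalized by the number of tests, estimates pi0.  With
    fewer than ``min_p`` p-values the estimate falls back to 1 (pure BH).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < min_p:
        logger.warning("pi0 estimation: only %d p-values, falling back to pi0=1", p.size)
        return 1.0
    lam = np.arange(1, n_grid + 1) / n_grid
    counts = np.searchsorted(np.sort(p), lam, side="right").astype(float)
    start = int(np.ceil(lambda_min * n_grid))
    slopes = []
    for s in range(start, n_grid - window + 1):
        xs = lam[s : s + window]
        ys = counts[s : s + window]
        xc = xs - xs.mean()
        slopes.append(float(np.dot(xc, ys - ys.mean()) / np.dot(xc, xc)))
    if not slopes:  # window wider than the tail grid
        return 1.0
    pi0 = min(slopes) / p.size
    return float(min(1.0, max(pi0, 0.0)))


def slim_qvalues(p_values: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """SLIM q-values: pi0 x the Benjamini-Hochberg step-up transform.

    Monotone non-decreasing in p and bounded by 1.  Pass ``pi0`` to override
    the sliding-linear-model estimate (pi0=1 gives plain BH).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0_slim(p)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(pi0 * q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclass
class ComparisonSpec:
    """A two-population comparison: group A minus group B, with the donor as
    an optional categorical covariate."""

    group_a: tuple[str, str]  # (phenotype, disease)
    group_b: tuple[str, str]
    use_donor_covariate: bool = True
    q_threshold: float = 0.05
    diff_threshold: float = 0.10
    method: str = "lrt"

    @property
    def name(self) -> str:
        from .io_binning import POPULATION_CODES

        a = POPULATION_CODES.get(self.group_a, "-".join(self.group_a))
        b = POPULATION_CODES.get(self.group_b, "-".join(self.group_b))
        return f"{a}-{b}"

    def validate(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must be disjoint")
        if not 0 < self.q_threshold:
            raise ValueError("q_threshold must be positive")
        if self.diff_threshold < 0:
            raise ValueError("diff_threshold must be non-negative")


@dataclass
class DMRSet:
    """Result of one pairwise comparison.

    ``table`` has one row per tested bin: chrom, start, end, meth_diff,
    p_value, q_value, direction ('hyper' = higher methylation in group A),
    is_dmr, fallback.  ``universe_size`` is the number of tested bins and is
    the background for all enrichment and overlap statistics.
    """

    comparison: str
    table: pd.DataFrame
    universe_size: int
    q_threshold: float = 0.05
    diff_threshold: float = 0.10
    pi0: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["is_dmr"]]

    @property
    def n_dmrs(self) -> int:
        return int(self.table["is_dmr"].sum())

    def dmr_bin_ids(self) -> set[str]:
        d = self.dmrs
        return set(d["chrom"].astype(str) + ":" + d["start"].astype(str))

    def counts(self) -> dict[str, int]:
        d = self.dmrs
        return {
            "n_dmrs": len(d),
            "hyper": int((d["direction"] == "hyper").sum()),
            "hypo": int((d["direction"] == "hypo").sum()),
        }

    def to_bed(self, path) -> None:
        """Write DMRs as BED6+ with score = -log10(q) capped at 300."""
        d = self.dmrs
        score = np.minimum(-np.log10(np.maximum(d["q_value"], P_FLOOR)), 300.0)
        out = pd.DataFrame(
            {
                "chrom": d["chrom"],
                "start": d["start"],
                "end": d["end"],
                "name": self.comparison,
                "score": score.round(4),
                "strand": ".",
                "meth_diff": d["meth_diff"].round(6),
                "p_value": d["p_value"],
                "q_value": d["q_value"],
                "direction": d["direction"],
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)


def call_dmrs(matrix: BinnedMethylationMatrix, spec: ComparisonSpec) -> DMRSet:
    """Test every universe bin for the given comparison and threshold into a
    DMR set (q < q_threshold and |meth_diff| > diff_threshold)."""
    spec.validate()
    pops = list(zip(matrix.samples["phenotype"], matrix.samples["disease"]))
    in_a = np.array([p == spec.group_a for p in pops])
    in_b = np.array([p == spec.group_b for p in pops])
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(
            f"comparison {spec.name}: empty group (available populations: "
            f"{sorted(set(pops))})"
        )
    sel = in_a | in_b
    meth = matrix.meth[:, sel].astype(float)
    total = matrix.total[:, sel].astype(float)
    group = in_a[sel]
    donor = matrix.samples["donor"].to_numpy()[sel] if spec.use_donor_covariate else None
    res = test_bins(meth, total, group, donor, method=spec.method)
    pi0 = estimate_pi0_slim(res["p_value"].to_numpy())
    res["q_value"] = slim_qvalues(res["p_value"].to_numpy(), pi0=pi0)
    res["direction"] = np.where(res["meth_diff"] >= 0, "hyper", "hypo")
    res["is_dmr"] = (res["q_value"] < spec.q_threshold) & (
        res["meth_diff"].abs() > spec.diff_threshold
    )
    table = pd.concat(
        [matrix.bins[["chrom", "start", "end"]].reset_index(drop=True), res], axis=1
    )
    out = DMRSet(
        comparison=spec.name,
        table=table,
        universe_size=len(table),
        q_threshold=spec.q_threshold,
        diff_threshold=spec.diff_threshold,
        pi0=pi0,
        metadata={
            "n_a": int(in_a.sum()),
            "n_b": int(in_b.sum()),
            "diff_definition": "pooled",
            "covariate": "donor" if spec.use_donor_covariate else None,
            "n_fallback": int(res["fallback"].sum()),
        },
    )
    logger.info(
        "%s: %d DMRs (%d hyper, %d hypo) of %d bins; pi0=%.3f, %d fallback fits",
        spec.name, out.n_dmrs, out.counts()["hyper"], out.counts()["hypo"],
        out.universe_size, pi0, out.metadata["n_fallback"],
    )
    return out
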