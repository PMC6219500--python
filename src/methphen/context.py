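"""Genomic-context annotation and enrichment statistics for DMR sets.

Bins are classified against CpG islands (island > shore > shelf > open sea,
with 2-kb flanks), assigned signed distances to the nearest TSS with a
proximal/distal split, tested for interval-track overlap with a directional
hypergeometric test (enriched/depleted label, p floored at 1e-300), and
profiled against a conservation score track with a resampling-based
significance test.

Interval conventions: 0-based half-open, overlap = >= 1 bp intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300

IntervalMap = Mapping[str, np.ndarray]  # chrom -> (n, 2) int array, sorted


@dataclass
class AnnotationBundle:
    """Annotation tracks used for context analysis.

    islands / tracks[name]: per-chromosome (n, 2) interval arrays (0-based
    half-open, sorted by start).  tss: per-chromosome sorted point arrays.
    conservation: per-chromosome (starts, ends, scores) step function.
    """

    islands: dict[str, np.ndarray] = field(default_factory=dict)
    tss: dict[str, np.ndarray] = field(default_factory=dict)
    tracks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    conservation: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    cpg_sites: dict[str, np.ndarray] | None = None

    def write_bed(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_bed(self.islands, outdir / "cpg_islands.bed")
        for name, ivs in self.tracks.items():
            _write_bed(ivs, outdir / f"{name}.bed")
        with open(outdir / "tss.tsv", "w") as fh:
            fh.write("chrom\tpos\n")
            for chrom in sorted(self.tss):
                for p in self.tss[chrom]:
                    fh.write(f"{chrom}\t{int(p)}\n")
        with open(outdir / "conservation.bedGraph", "w") as fh:
            for chrom in sorted(self.conservation):
                s, e, v = self.conservation[chrom]
                for a, b, x in zip(s, e, v):
                    fh.write(f"{chrom}\t{int(a)}\t{int(b)}\t{x:.6g}\n")
        if self.cpg_sites is not None:
            with open(outdir / "cpg_sites.tsv", "w") as fh:
                fh.write("chrom\tpos0\n")
                for chrom in sorted(self.cpg_sites):
                    for p in self.cpg_sites[chrom]:
                        fh.write(f"{chrom}\t{int(p)}\n")


def _write_bed(intervals: IntervalMap, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED file into a per-chromosome sorted interval map."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in out.items()}


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    res = {}
    for c, rows in out.items():
        rows.sort()
        a = np.array(rows)
        res[c] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
    return res


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent intervals of a sorted (n, 2) array."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _gap_to_intervals(starts: np.ndarray, ends: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """bp gap between each bin [start, end) and the nearest interval of a
    merged sorted set.  -1 for >= 1 bp overlap; 0 for touching (adjacent)
    intervals; inf if the set is empty."""
    n = len(starts)
    if len(iv) == 0:
        return np.full(n, np.inf)
    iv_s, iv_e = iv[:, 0], iv[:, 1]
    # candidate to the left: last interval with start < end
    idx = np.searchsorted(iv_s, ends, side="left") - 1
    gap_left = np.full(n, np.inf)
    ok = idx >= 0
    gap_left[ok] = np.maximum(starts[ok] - iv_e[idx[ok]], 0)
    overlap = ok & (iv_e[np.maximum(idx, 0)] > starts)  # iv_s < end by construction
    # candidate to the right: first interval with start >= end
    jdx = np.searchsorted(iv_s, ends, side="left")
    gap_right = np.full(n, np.inf)
    ok2 = jdx < len(iv)
    gap_right[ok2] = iv_s[jdx[ok2]] - ends[ok2]
    gap = np.minimum(gap_left, gap_right)
    gap[overlap] = -1.0
    return gap


def overlaps_track(bins: pd.DataFrame, track: IntervalMap) -> np.ndarray:
    """Boolean per bin: >= 1 bp intersection with any track interval."""
    out = np.zeros(len(bins), dtype=bool)
    starts_all = bins["start"].to_numpy()
    ends_all = bins["end"].to_numpy()
    for chrom, idx in bins.groupby("chrom", sort=False).indices.items():
        iv = track.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        iv = merge_intervals(np.asarray(iv))
        gap = _gap_to_intervals(starts_all[idx], ends_all[idx], iv)
        out[idx] = gap < 0
    return out


def classify_island_context(bins: pd.DataFrame, islands: IntervalMap) -> pd.Series:
    """Classify each bin as island / shore / shelf / open_sea.

    Shores are the 2-kb flanks of islands, shelves the next 2-kb flanks;
    precedence island > shore > shelf.  A bin overlapping a flank by >= 1 bp
    gets that class, i.e. shore iff 0 < gap-to-island < 2000, shelf iff
    2000 <= gap < 4000.
    """
    classes = np.full(len(bins), "open_sea", dtype=object)
    starts_all = bins["start"].to_numpy()
    ends_all = bins["end"].to_numpy()
    for chrom, idx in bins.groupby("chrom", sort=False).indices.items():
        iv = islands.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        gap = _gap_to_intervals(starts_all[idx], ends_all[idx], merge_intervals(np.asarray(iv)))
        cls = np.where(
            gap < 0, "island",
            np.where(gap < 2000, "shore", np.where(gap < 4000, "shelf", "open_sea")),
        )
        classes[idx] = cls
    return pd.Series(classes, index=bins.index, name="island_context")


def tss_distance(
    bins: pd.DataFrame, tss: Mapping[str, np.ndarray], proximal_bp: int = 5000
) -> pd.DataFrame:
    """Signed distance from each bin to its nearest TSS.

    0 if a TSS lies inside the bin; otherwise the bp gap between the bin edge
    and the TSS, positive when the bin lies downstream (higher coordinate)
    of the TSS and negative when upstream.  TSS strand is ignored.  Proximal
    iff |distance| <= proximal_bp.  Bins on chromosomes without any TSS get
    distance NaN and proximal=False.
    """
    if not any(len(v) for v in tss.values()):
        raise ValueError("empty TSS set")
    dist = np.full(len(bins), np.nan)
    starts_all = bins["start"].to_numpy()
    ends_all = bins["end"].to_numpy()
    for chrom, idx in bins.groupby("chrom", sort=False).indices.items():
        pts = np.sort(np.asarray(tss.get(chrom, []), dtype=np.int64))
        if len(pts) == 0:
            continue
        s, e = starts_all[idx], ends_all[idx]
        # nearest point at or left of the bin end
        j = np.searchsorted(pts, e, side="left") - 1
        left_ok = j >= 0
        left_pt = pts[np.maximum(j, 0)]
        inside = left_ok & (left_pt >= s)
        d_left = np.where(left_ok, s - left_pt, np.inf)  # downstream: positive
        k = np.searchsorted(pts, e, side="left")
        right_ok = k < len(pts)
        right_pt = pts[np.minimum(k, len(pts) - 1)]
        d_right = np.where(right_ok, right_pt - e + 1, np.inf)  # upstream: magnitude
        d = np.where(d_left <= d_right, d_left, -d_right)
        d = np.where(inside, 0, d)
        dist[idx] = d
    out = pd.DataFrame({"tss_distance": dist}, index=bins.index)
    out["proximal"] = np.abs(out["tss_distance"]) <= proximal_bp
    out.loc[out["tss_distance"].isna(), "proximal"] = False
    return out


@dataclass
class EnrichmentResult:
    """Directional hypergeometric enrichment of a DMR subset against the
    bin universe for one track."""

    track: str
    k: int  # DMRs overlapping the track
    n: int  # DMRs tested
    K: int  # universe bins overlapping
    N: int  # universe size
    fold: float
    p_value: float
    label: str  # 'E' enriched / 'D' depleted

    def as_dict(self) -> dict:
        return {
            "track": self.track, "k": self.k, "n": self.n, "K": self.K,
            "N": self.N, "fold": self.fold, "p_value": self.p_value,
            "label": self.label,
        }


def hypergeom_enrichment(k: int, n: int, K: int, N: int, track: str = "") -> EnrichmentResult:
    """Directional hypergeometric test of k/n successes against K/N.

    Label E with the upper-tail p when the fold (k/n)/(K/N) exceeds 1, D with
    the lower-tail p when below; at fold exactly 1 the smaller tail is
    reported.  p is floored at 1e-300.
    """
    if N <= 0:
        raise ValueError("empty universe")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    expected = K / N
    fold = (k / n) / expected if n > 0 and expected > 0 else 0.0
    upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    lower = float(stats.hypergeom.cdf(k, N, K, n))
    if fold > 1:
        p, label = upper, "E"
    elif fold < 1:
        p, label = lower, "D"
    else:
        p, label = (upper, "E") if upper <= lower else (lower, "D")
    p = min(max(p, P_FLOOR), 1.0)
    return EnrichmentResult(track=track, k=k, n=n, K=K, N=N, fold=fold, p_value=p, label=label)


def track_enrichment(
    dmr_bins: pd.DataFrame, universe_bins: pd.DataFrame, track: IntervalMap, name: str = ""
) -> EnrichmentResult:
    """Hypergeometric enrichment of DMR bins in a track, against the
    universe of all tested bins (DMR bins must be a subset)."""
    if len(universe_bins) == 0:
        raise ValueError("empty universe")
    k = int(overlaps_track(dmr_bins, track).sum())
    K = int(overlaps_track(universe_bins, track).sum())
    return hypergeom_enrichment(k, len(dmr_bins), K, len(universe_bins), track=name)


def score_at(
    conservation: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    chrom: str,
    pos: np.ndarray,
) -> np.ndarray:
    """Step-function lookup of conservation scores at positions; NaN where
    no interval covers the position."""
    out = np.full(len(pos), np.nan)
    tr = conservation.get(chrom)
    if tr is None:
        return out
    starts, ends, vals = tr
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
    out[ok] = vals[idx[ok]]
    return out


def bin_scores(
    bins: pd.DataFrame,
    conservation: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Mean conservation score within each bin (midpoint-sampled per step
    interval is avoided: the step function is averaged exactly over the
    covered part of the bin; NaN when nothing overlaps)."""
    out = np.full(len(bins), np.nan)
    starts_all = bins["start"].to_numpy()
    ends_all = bins["end"].to_numpy()
    for chrom, idx in bins.groupby("chrom", sort=False).indices.items():
        tr = conservation.get(chrom)
        if tr is None:
            continue
        cs, ce, cv = tr
        for i in idx:
            s, e = starts_all[i], ends_all[i]
            j0 = np.searchsorted(ce, s, side="right")
            j1 = np.searchsorted(cs, e, side="left")
            if j1 <= j0:
                continue
            seg_s = np.maximum(cs[j0:j1], s)
            seg_e = np.minimum(ce[j0:j1], e)
            w = (seg_e - seg_s).astype(float)
            if w.sum() > 0:
                out[i] = float(np.dot(w, cv[j0:j1]) / w.sum())
    return out


def conservation_profile(
    bins: pd.DataFrame,
    conservation: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    flank_bp: int = 2000,
    n_points: int = 81,
) -> pd.DataFrame:
    """Average conservation around bin centres.

    For each offset on a uniform grid spanning +/- flank_bp, the score at
    (bin centre + offset) is looked up on the step function and averaged
    across bins; positions without coverage (including beyond chromosome
    edges) are excluded from the mean.
    """
    if len(bins) == 0:
        raise ValueError("no bins to profile")
    offsets = np.linspace(-flank_bp, flank_bp, n_points).round().astype(np.int64)
    centres = ((bins["start"].to_numpy() + bins["end"].to_numpy()) // 2).astype(np.int64)
    chroms = bins["chrom"].to_numpy()
    sums = np.zeros(n_points)
    counts = np.zeros(n_points)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        c = centres[mask]
        for i, off in enumerate(offsets):
            pos = c + off
            valid = pos >= 0
            vals = score_at(conservation, chrom, pos[valid])
            good = ~np.isnan(vals)
            sums[i] += vals[good].sum()
            counts[i] += good.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": mean, "n": counts.astype(int)})


def conservation_bootstrap(
    dmr_bins: pd.DataFrame,
    universe_bins: pd.DataFrame,
    conservation: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_iter: int = 1000,
    rng_seed: int = 0,
) -> float:
    """Resampling p-value for elevated conservation of DMR bins.

    observed = mean per-bin conservation over the DMR bins; each iteration
    draws an equal number of bins without replacement from the universe
    excluding the DMR bins and records the resample mean.  One-sided,
    add-one corrected: p = (1 + #{resample mean >= observed}) / (n_iter + 1).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    dmr_ids = set(dmr_bins["chrom"].astype(str) + ":" + dmr_bins["start"].astype(str))
    uni_ids = universe_bins["chrom"].astype(str) + ":" + universe_bins["start"].astype(str)
    # canonical order makes p invariant to how the universe was supplied
    pool = (
        universe_bins.loc[~uni_ids.isin(dmr_ids)]
        .sort_values(["chrom", "start"], kind="mergesort")
        .drop_duplicates(["chrom", "start"])
        .reset_index(drop=True)
    )
    n = len(dmr_bins)
    if len(pool) < n:
        raise ValueError(
            f"universe too small: {len(pool)} non-DMR bins for {n} DMR bins"
        )
    obs_scores = bin_scores(dmr_bins, conservation)
    observed = float(np.nanmean(obs_scores))
    pool_scores = bin_scores(pool, conservation)
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_iter):
        pick = rng.choice(len(pool), size=n, replace=False)
        if np.nanmean(pool_scores[pick]) >= observed:
            hits += 1
    return (1 + hits) / (n_iter + 1)
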