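"""Reading per-CpG methylation calls, coverage filtering, destranding and
fixed-width binning into a cross-sample matrix.

Coordinates are 0-based half-open internally; call files and probe manifests
are 1-based and converted at the boundary.  A genomic bin of size ``w``
anchored at 0 covers ``[k*w, (k+1)*w)``; a 1-based position ``p`` falls into
bin ``floor((p-1)/w)``.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "meth", "total"]

#: Population shorthand used throughout: (phenotype, disease) -> label.
POPULATION_CODES = {
    ("basal", "normal"): "NB",
    ("luminal", "normal"): "NL",
    ("basal", "cancer"): "CB",
    ("luminal", "cancer"): "CL",
}


class CallParseError(ValueError):
    """Raised when a call file line cannot be parsed; names the line."""


@dataclass
class MethylationCallSet:
    """Per-sample per-CpG methylation calls.

    ``df`` columns: chrom (str), pos (int, 1-based), strand ('+'/'-'),
    meth (int), total (int), with 0 <= meth <= total.
    """

    sample_id: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CALL_COLUMNS))

    def __post_init__(self) -> None:
        if list(self.df.columns) != CALL_COLUMNS:
            self.df = self.df.reindex(columns=CALL_COLUMNS)
        if len(self.df):
            if (self.df["meth"] > self.df["total"]).any():
                raise ValueError("meth > total in call set")
            if (self.df["meth"] < 0).any() or (self.df["total"] < 0).any():
                raise ValueError("negative counts in call set")

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "MethylationCallSet":
        out = self.df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        return MethylationCallSet(self.sample_id, out.reset_index(drop=True))


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_calls(path: str | Path, dialect: str = "simple", sample_id: str | None = None) -> MethylationCallSet:
    """Read a per-CpG call file.

    Dialects:
      * ``simple`` — tab-delimited chrom, pos (1-based), strand, meth, total;
        an optional header line starting with ``chrom`` or ``#`` is skipped.
      * ``methratio`` — bsmap methratio.py output (chr, pos, strand, context,
        ratio, eff_CT_count, ...); meth is derived by rounding
        ratio x effective coverage.
    """
    path = Path(path)
    if dialect not in ("simple", "methratio"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows: list[tuple] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chr", "chrom", "chromosome"):
                continue
            try:
                if dialect == "simple":
                    if len(fields) < 5:
                        raise ValueError("expected 5 columns")
                    chrom, pos, strand, meth, total = fields[:5]
                    rec = (chrom, int(pos), strand, int(meth), int(total))
                else:
                    if len(fields) < 6:
                        raise ValueError("expected >=6 columns")
                    chrom, pos, strand = fields[0], int(fields[1]), fields[2]
                    ratio = float(fields[4])
                    eff = float(fields[5])
                    total = int(round(eff))
                    meth = min(int(round(ratio * eff)), total)
                    rec = (chrom, pos, strand, meth, total)
            except ValueError as exc:
                raise CallParseError(f"{path}:{lineno}: malformed line ({exc}): {line!r}") from exc
            if rec[3] > rec[4]:
                raise CallParseError(f"{path}:{lineno}: meth > total ({rec[3]} > {rec[4]})")
            if rec[3] < 0 or rec[4] < 0:
                raise CallParseError(f"{path}:{lineno}: negative count")
            rows.append(rec)
    if not rows:
        logger.warning("%s: empty call file", path)
        return MethylationCallSet(sample_id)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return MethylationCallSet(sample_id, df)


def write_calls(calls: MethylationCallSet, path: str | Path) -> None:
    """Write a call set in the simple dialect (with header)."""
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tpos\tstrand\tmeth\ttotal\n")
        for row in calls.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.meth}\t{row.total}\n")


def filter_coverage(
    calls: MethylationCallSet, min_cov: int = 3, high_pct: float = 99.95
) -> MethylationCallSet:
    """Remove low- and high-coverage records.

    Records with total < ``min_cov`` are removed first; then records with
    total strictly above the per-sample ``high_pct`` percentile (linear
    interpolation, computed on the records surviving the low filter) are
    removed.  Idempotent at fixed thresholds.
    """
    if not 0 < high_pct <= 100:
        raise ValueError(f"high_pct must be in (0, 100], got {high_pct}")
    df = calls.df
    if df.empty:
        return MethylationCallSet(calls.sample_id)
    n0 = len(df)
    kept = df[df["total"] >= min_cov]
    n_low = n0 - len(kept)
    if len(kept):
        cut = float(np.percentile(kept["total"].to_numpy(), high_pct))
        out = kept[kept["total"] <= cut]
    else:
        out = kept
    n_high = len(kept) - len(out)
    logger.info(
        "%s: coverage filter removed %d low (<%d) and %d high (>%s pct) of %d records",
        calls.sample_id, n_low, min_cov, n_high, high_pct, n0,
    )
    return MethylationCallSet(calls.sample_id, out.reset_index(drop=True))


def destrand(calls: MethylationCallSet) -> MethylationCallSet:
    """Merge symmetric CpG calls: a reverse-strand call at position p is
    added to the forward-strand call at p-1 (created if absent).  Output is
    all forward strand; total meth/total counts are conserved.
    """
    df = calls.df
    if df.empty or (df["strand"] == "+").all():
        return MethylationCallSet(calls.sample_id, df.copy().reset_index(drop=True))
    work = df.copy()
    rev = work["strand"] == "-"
    work.loc[rev, "pos"] = work.loc[rev, "pos"] - 1
    work["strand"] = "+"
    merged = (
        work.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
        .sum()
    )
    merged["strand"] = "+"
    merged = merged[CALL_COLUMNS]
    return MethylationCallSet(calls.sample_id, merged.reset_index(drop=True))


def bin_calls(calls: MethylationCallSet, bin_size: int = 100) -> pd.DataFrame:
    """Merge calls into non-overlapping ``bin_size`` bp bins anchored at 0.

    Returns a frame with columns chrom, start (0-based), meth, total, n_cpgs,
    one row per covered bin, sorted by genomic position.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    df = calls.df
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "meth", "total", "n_cpgs"])
    start = ((df["pos"] - 1) // bin_size) * bin_size
    grouped = (
        df.assign(start=start)
        .groupby(["chrom", "start"], as_index=False, sort=True)
        .agg(meth=("meth", "sum"), total=("total", "sum"), n_cpgs=("pos", "size"))
    )
    return grouped


@dataclass
class BinnedMethylationMatrix:
    """Bins x samples methylated/total read counts, restricted to bins with
    total coverage > 0 in every sample (the analysis universe).

    ``bins``: frame with chrom, start, end, n_cpgs (distinct CpG sites over
    all samples).  ``meth``/``total``: int arrays of shape (n_bins,
    n_samples), column order matching ``samples['sample_id']``.  ``samples``:
    sample sheet with sample_id, donor, phenotype, disease.
    """

    bins: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame
    bin_size: int = 100
    n_cpgs_covered: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def bin_ids(self) -> pd.Index:
        return pd.Index(
            self.bins["chrom"].astype(str) + ":" + self.bins["start"].astype(str)
        )

    def proportions(self) -> np.ndarray:
        """Per-bin per-sample methylation proportion meth/total."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def population_labels(self) -> pd.Series:
        keys = list(zip(self.samples["phenotype"], self.samples["disease"]))
        return pd.Series(
            [POPULATION_CODES.get(k, f"{k[0]}:{k[1]}") for k in keys],
            index=self.samples.index, name="population",
        )

    def subset_samples(self, mask: np.ndarray) -> "BinnedMethylationMatrix":
        return BinnedMethylationMatrix(
            bins=self.bins,
            meth=self.meth[:, mask],
            total=self.total[:, mask],
            samples=self.samples.loc[mask].reset_index(drop=True),
            bin_size=self.bin_size,
            n_cpgs_covered=self.n_cpgs_covered,
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.bins.copy()
        for j, sid in enumerate(self.sample_ids):
            out[f"{sid}.meth"] = self.meth[:, j]
            out[f"{sid}.total"] = self.total[:, j]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_sheet: pd.DataFrame, bin_size: int = 100) -> "BinnedMethylationMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        sids = [c[:-5] for c in df.columns if c.endswith(".meth")]
        sheet = sample_sheet.set_index("sample_id").loc[sids].reset_index()
        meth = df[[f"{s}.meth" for s in sids]].to_numpy(dtype=np.int64)
        total = df[[f"{s}.total" for s in sids]].to_numpy(dtype=np.int64)
        bins = df[["chrom", "start", "end", "n_cpgs"]].copy()
        return cls(bins=bins, meth=meth, total=total, samples=sheet,
                   bin_size=bin_size, n_cpgs_covered=int(bins["n_cpgs"].sum()))


def build_matrix(
    binned: Mapping[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    bin_size: int = 100,
) -> BinnedMethylationMatrix:
    """Assemble per-sample binned counts into the universal-coverage matrix.

    A bin is retained iff its summed total reads are > 0 in every sample.
    Sample metadata is taken from ``sample_sheet`` (columns sample_id, donor,
    phenotype, disease); a sample absent from the sheet is an error.  The
    result is invariant to the iteration order of ``binned``.
    """
    if len(binned) < 2:
        raise ValueError("build_matrix needs >= 2 samples")
    sheet_ids = set(sample_sheet["sample_id"])
    missing = sorted(set(binned) - sheet_ids)
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    sample_ids = [s for s in sample_sheet["sample_id"] if s in binned]
    frames = []
    for sid in sample_ids:
        f = binned[sid].set_index(["chrom", "start"])
        frames.append(f)
    union = frames[0].index
    for f in frames[1:]:
        union = union.union(f.index)
    union = union.sortlevel()[0]
    n_bins, n_samples = len(union), len(sample_ids)
    meth = np.zeros((n_bins, n_samples), dtype=np.int64)
    total = np.zeros((n_bins, n_samples), dtype=np.int64)
    n_cpgs = np.zeros((n_bins, n_samples), dtype=np.int64)
    for j, f in enumerate(frames):
        aligned = f.reindex(union)
        meth[:, j] = aligned["meth"].fillna(0).to_numpy(dtype=np.int64)
        total[:, j] = aligned["total"].fillna(0).to_numpy(dtype=np.int64)
        n_cpgs[:, j] = aligned["n_cpgs"].fillna(0).to_numpy(dtype=np.int64)
    keep = (total > 0).all(axis=1)
    bins = pd.DataFrame(
        {
            "chrom": union.get_level_values(0)[keep],
            "start": union.get_level_values(1)[keep].astype(np.int64),
        }
    )
    bins["end"] = bins["start"] + bin_size
    bins["n_cpgs"] = n_cpgs[keep].max(axis=1)
    bins = bins.reset_index(drop=True)
    mat = BinnedMethylationMatrix(
        bins=bins,
        meth=meth[keep],
        total=total[keep],
        samples=sample_sheet.set_index("sample_id").loc[sample_ids].reset_index(),
        bin_size=bin_size,
        n_cpgs_covered=int(bins["n_cpgs"].sum()),
    )
    logger.info(
        "build_matrix: %d/%d bins covered in all %d samples (%d CpGs)",
        mat.n_bins, n_bins, n_samples, mat.n_cpgs_covered,
    )
    return mat


def top_variable_bins(matrix: BinnedMethylationMatrix, fraction: float = 0.01) -> pd.DataFrame:
    """Select the most variable bins by across-sample variance of
    methylation proportions.

    Returns ceil(fraction * n_bins) rows of per-sample proportions indexed by
    (chrom, start); ties in variance are broken by genomic order.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    props = matrix.proportions()
    var = np.nanvar(props, axis=1, ddof=1)
    k = math.ceil(fraction * matrix.n_bins)
    # stable sort on -variance keeps genomic order among ties
    order = np.argsort(-var, kind="stable")[:k]
    order = np.sort(order)  # report in genomic order
    out = matrix.bins.iloc[order][["chrom", "start", "end"]].copy()
    for j, sid in enumerate(matrix.sample_ids):
        out[sid] = props[order, j]
    out["variance"] = var[order]
    return out.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, donor, phenotype,
    disease (extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "phenotype", "disease"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
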