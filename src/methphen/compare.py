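"""All pairwise population comparisons and derived DMR classes.

The four cell populations (NB, NL, CB, CL = normal/cancer x basal/luminal)
give six pairwise comparisons over one shared bin universe.  Overlaps
between DMR sets are keyed on identical bin ids and tested with a two-sided
Fisher's exact test on the 2x2 membership table over the universe.  Three
derived classes are computed by set intersection (direction-concordant by
default): phenotype-shared (NL-NB and CL-CB), CL-specific (CL-CB and CL-NL,
with the NL-NB-overlapping subset flagged but kept), and cancer-shared
(CL-NL and CB-NB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import ComparisonSpec, DMRSet, call_dmrs
from .io_binning import BinnedMethylationMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
ODDS_RATIO_CAP = 1e300

POPULATIONS = {
    "NB": ("basal", "normal"),
    "NL": ("luminal", "normal"),
    "CB": ("basal", "cancer"),
    "CL": ("luminal", "cancer"),
}

#: Canonical comparison order; group A first (the "hyper in A" convention).
PAIRWISE_ORDER = [
    ("NL", "NB"),
    ("CL", "CB"),
    ("CL", "NL"),
    ("CB", "NB"),
    ("CL", "NB"),
    ("NL", "CB"),
]


def run_all_pairwise(
    matrix: BinnedMethylationMatrix,
    q_threshold: float = 0.05,
    diff_threshold: float = 0.10,
    use_donor_covariate: bool = True,
    method: str = "lrt",
) -> dict[str, DMRSet]:
    """Call DMRs for all six pairwise comparisons on one matrix.

    All comparisons share the matrix's universe.  Raises if any of the four
    populations is absent, listing those available.
    """
    present = set(matrix.population_labels())
    missing = [p for p in POPULATIONS if p not in present]
    if missing:
        raise ValueError(
            f"missing populations {missing}; available: {sorted(present)}"
        )
    out: dict[str, DMRSet] = {}
    for a, b in PAIRWISE_ORDER:
        spec = ComparisonSpec(
            group_a=POPULATIONS[a],
            group_b=POPULATIONS[b],
            use_donor_covariate=use_donor_covariate,
            q_threshold=q_threshold,
            diff_threshold=diff_threshold,
            method=method,
        )
        out[spec.name] = call_dmrs(matrix, spec)
    return out


def summary_table(dmrsets: dict[str, DMRSet]) -> pd.DataFrame:
    rows = []
    for name, ds in dmrsets.items():
        c = ds.counts()
        rows.append({"comparison": name, **c, "universe": ds.universe_size, "pi0": ds.pi0})
    return pd.DataFrame(rows)


@dataclass
class OverlapResult:
    """Overlap of two DMR sets over a common universe, with Fisher's exact
    test on the 2x2 membership table."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    n_overlap: int
    n_union: int
    universe: int
    odds_ratio: float
    odds_ratio_capped: bool
    fisher_p: float
    direction_concordant_overlap: int

    @property
    def percent_overlap(self) -> float:
        """Overlap as a fraction of the union of the two sets."""
        return self.n_overlap / self.n_union if self.n_union else 0.0

    def as_dict(self) -> dict:
        return {
            "set_a": self.name_a, "set_b": self.name_b, "n_a": self.n_a,
            "n_b": self.n_b, "n_overlap": self.n_overlap, "n_union": self.n_union,
            "universe": self.universe, "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "direction_concordant_overlap": self.direction_concordant_overlap,
            "percent_overlap": self.percent_overlap,
        }


def _dmr_direction_map(ds: DMRSet) -> pd.Series:
    d = ds.dmrs
    ids = d["chrom"].astype(str) + ":" + d["start"].astype(str)
    return pd.Series(d["direction"].to_numpy(), index=ids.to_numpy())


def overlap_sets(a: DMRSet, b: DMRSet) -> OverlapResult:
    """Overlap statistics for two DMR sets sharing a universe.

    The 2x2 table counts universe bins by membership in a x membership in b;
    the p-value is two-sided Fisher's exact; the odds ratio is the sample
    (cross-product) ratio, capped when a cell is empty.  Symmetric in its
    arguments.
    """
    if a.universe_size != b.universe_size:
        raise ValueError(
            f"universe mismatch: {a.universe_size} vs {b.universe_size}"
        )
    ids_a = a.dmr_bin_ids()
    ids_b = b.dmr_bin_ids()
    n_overlap = len(ids_a & ids_b)
    n_a, n_b = len(ids_a), len(ids_b)
    N = a.universe_size
    table = np.array(
        [
            [n_overlap, n_a - n_overlap],
            [n_b - n_overlap, N - n_a - n_b + n_overlap],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    p = min(max(float(p), P_FLOOR), 1.0)
    num = table[0, 0] * table[1, 1]
    den = table[0, 1] * table[1, 0]
    capped = den == 0 and num > 0
    odds = float(num / den) if den > 0 else (ODDS_RATIO_CAP if num > 0 else 0.0)
    da = _dmr_direction_map(a)
    db = _dmr_direction_map(b)
    common = da.index.intersection(db.index)
    concordant = int((da.loc[common] == db.loc[common]).sum())
    return OverlapResult(
        name_a=a.comparison, name_b=b.comparison, n_a=n_a, n_b=n_b,
        n_overlap=n_overlap, n_union=n_a + n_b - n_overlap, universe=N,
        odds_ratio=min(odds, ODDS_RATIO_CAP), odds_ratio_capped=bool(capped),
        fisher_p=p, direction_concordant_overlap=concordant,
    )


@dataclass
class DerivedSets:
    """The three headline DMR classes derived by set algebra.

    Each frame has columns chrom, start, end, direction (from the first
    comparison of the pair); ``cl_specific`` has an extra boolean
    ``in_nl_nb`` flagging bins also differential between NL and NB (kept,
    not removed).
    """

    phenotype_shared: pd.DataFrame
    cl_specific: pd.DataFrame
    cancer_shared: pd.DataFrame
    overlaps: dict[str, OverlapResult] = field(default_factory=dict)
    require_direction: bool = True

    def sizes(self) -> dict[str, int]:
        return {
            "phenotype_shared": len(self.phenotype_shared),
            "cl_specific": len(self.cl_specific),
            "cl_specific_in_nl_nb": int(self.cl_specific["in_nl_nb"].sum()) if len(self.cl_specific) else 0,
            "cancer_shared": len(self.cancer_shared),
        }


def _intersect(a: DMRSet, b: DMRSet, require_direction: bool) -> pd.DataFrame:
    da = a.dmrs.copy()
    da["bin_id"] = da["chrom"].astype(str) + ":" + da["start"].astype(str)
    db = b.dmrs.copy()
    db["bin_id"] = db["chrom"].astype(str) + ":" + db["start"].astype(str)
    merged = da.merge(db[["bin_id", "direction"]], on="bin_id", suffixes=("", "_b"))
    if require_direction:
        merged = merged[merged["direction"] == merged["direction_b"]]
    return (
        merged[["chrom", "start", "end", "direction", "bin_id"]]
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def derive_sets(dmrsets: dict[str, DMRSet], require_direction: bool = True) -> DerivedSets:
    """Derive the phenotype-shared, CL-specific and cancer-shared classes.

    Needs the NL-NB, CL-CB, CL-NL and CB-NB comparisons.  Intersections are
    keyed on bin id, requiring matching direction by default.  The subset of
    CL-specific bins also present in NL-NB is flagged via ``in_nl_nb``.
    """
    needed = ["NL-NB", "CL-CB", "CL-NL", "CB-NB"]
    missing = [n for n in needed if n not in dmrsets]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    phen = _intersect(dmrsets["NL-NB"], dmrsets["CL-CB"], require_direction)
    cl = _intersect(dmrsets["CL-CB"], dmrsets["CL-NL"], require_direction)
    nlnb_ids = dmrsets["NL-NB"].dmr_bin_ids()
    if len(cl):
        cl["in_nl_nb"] = cl["bin_id"].isin(nlnb_ids)
    else:
        cl["in_nl_nb"] = pd.Series(dtype=bool)
    cancer = _intersect(dmrsets["CL-NL"], dmrsets["CB-NB"], require_direction)
    overlaps = {
        "NL-NB_vs_CL-CB": overlap_sets(dmrsets["NL-NB"], dmrsets["CL-CB"]),
        "CL-CB_vs_CL-NL": overlap_sets(dmrsets["CL-CB"], dmrsets["CL-NL"]),
        "CL-NL_vs_CB-NB": overlap_sets(dmrsets["CL-NL"], dmrsets["CB-NB"]),
    }
    out = DerivedSets(
        phenotype_shared=phen,
        cl_specific=cl,
        cancer_shared=cancer,
        overlaps=overlaps,
        require_direction=require_direction,
    )
    logger.info("derived sets: %s", out.sizes())
    return out


def write_derived_beds(derived: DerivedSets, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("phenotype_shared", "cl_specific", "cancer_shared"):
        df = getattr(derived, name)
        with open(outdir / f"{name}.bed", "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}:{row.direction}\n")
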