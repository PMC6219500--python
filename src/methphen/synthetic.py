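"""Synthetic RRBS-style methylation studies with known ground truth.

Generates (a) annotation tracks with clustered CpG sites, islands, TSS
points, interval tracks and a per-bin conservation score; (b) per-sample
per-CpG call files where coverage is negative-binomial (gamma-Poisson) and
methylated counts are beta-binomial around a logit-additive mean combining a
bimodal per-bin baseline, a per-donor random effect and planted region
effects; and (c) array-like beta matrices with informative probes.

Planted effects are specified as target proportion differences delta at a
0.5 baseline: affected populations sit at 0.5 + delta/2 and unaffected at
0.5 - delta/2 on the proportion scale (a symmetric logit offset), so the
realized group difference is delta by construction before sampling noise.
Effect classes are placed on disjoint bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .context import AnnotationBundle, merge_intervals
from .io_binning import MethylationCallSet, CALL_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_POPULATIONS = [
    ("basal", "normal"),
    ("luminal", "normal"),
    ("basal", "cancer"),
    ("luminal", "cancer"),
]

EFFECT_CLASSES = ("phenotype_shared", "cancer_luminal", "cancer_shared")


class GenerationError(RuntimeError):
    pass


@dataclass
class StudyDesign:
    """Layout of a synthetic methylation study.

    One sample exists for every (donor, population) pair not listed in
    ``missing_samples`` (population given as its code, e.g. 'NL').  Donor
    random effects are logit-scale normal with sd ``donor_sigma``; coverage
    is NegBin with the given mean and dispersion theta (var = m + m^2 /
    theta); methylated counts are beta-binomial with correlation
    ``meth_overdispersion`` (0 = pure binomial).
    """

    n_donors: int = 4
    populations: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_POPULATIONS))
    missing_samples: list[tuple[str, str]] = field(default_factory=list)
    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    n_cpgs: int = 10_000
    mean_coverage: float = 7.5
    coverage_dispersion: float = 5.0
    donor_sigma: float = 0.0
    meth_overdispersion: float = 0.05
    bin_size: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome dimensions must be positive")
        if self.n_cpgs < 0:
            raise ValueError("n_cpgs must be non-negative")
        if not 0 <= self.meth_overdispersion < 1:
            raise ValueError("meth_overdispersion must be in [0, 1)")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")

    def donors(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    def samples(self) -> pd.DataFrame:
        """Sample sheet: one row per (donor, population) not marked missing."""
        from .io_binning import POPULATION_CODES

        missing = {(d, p) for d, p in self.missing_samples}
        rows = []
        for donor in self.donors():
            for phe, dis in self.populations:
                code = POPULATION_CODES.get((phe, dis), f"{phe}:{dis}")
                if (donor, code) in missing:
                    continue
                rows.append(
                    {
                        "sample_id": f"{donor}_{code}",
                        "donor": donor,
                        "phenotype": phe,
                        "disease": dis,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class EffectSpec:
    """A class of planted differentially methylated regions.

    ``effect_class``: which populations move — 'phenotype_shared' (luminal
    vs basal, both diseases), 'cancer_luminal' (CL vs everything else) or
    'cancer_shared' (cancer vs normal, both phenotypes).  ``delta`` is the
    target proportion difference; ``direction_mix`` the fraction of regions
    hypermethylated in the affected (first-named) side; ``placement_bias``
    optionally names an annotation track whose bins are preferred for
    placement.
    """

    effect_class: str
    n_regions: int
    delta: float
    direction_mix: float = 2 / 3
    n_bins_per_region: int = 1
    placement_bias: str | None = None

    def validate(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must be in [0, 1]")
        if self.n_regions < 0 or self.n_bins_per_region < 1:
            raise ValueError("region counts must be positive")


@dataclass
class TruthTable:
    """Ground truth of a generated study: planted regions (bin-resolved),
    per-donor logit effects and the sample sheet."""

    regions: pd.DataFrame  # region_id, effect_class, chrom, start, end, direction, delta
    donor_effects: dict[str, float]
    samples: pd.DataFrame

    def region_bin_ids(self, effect_class: str | None = None) -> set[str]:
        df = self.regions
        if effect_class is not None:
            df = df[df["effect_class"] == effect_class]
        return set(df["chrom"].astype(str) + ":" + df["start"].astype(str))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"donor": list(self.donor_effects), "logit_effect": list(self.donor_effects.values())}
        ).to_csv(outdir / "truth_donor_effects.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)


def _logit(p: float | np.ndarray):
    return np.log(p) - np.log1p(-p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def generate_annotation(design: StudyDesign, rng_seed: int | None = None) -> AnnotationBundle:
    """Generate CpG sites and annotation tracks for the design's genome.

    CpG sites are drawn from two spacing regimes: dense clusters inside CpG
    islands (~40% of sites) and a sparse open sea.  TSS points sit mostly at
    island edges; DHS/TFBS/repeat (SINE/LINE/LTR) interval tracks and a
    per-bin conservation step function are random but deterministic for a
    given seed.
    """
    design.validate()
    seed = design.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    L = design.chrom_length
    islands: dict[str, np.ndarray] = {}
    tss: dict[str, np.ndarray] = {}
    cpg_sites: dict[str, np.ndarray] = {}
    tracks: dict[str, dict[str, np.ndarray]] = {
        t: {} for t in ("DHS", "TFBS", "repeat", "SINE", "LINE", "LTR")
    }
    conservation: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    per_chrom = _split_counts(design.n_cpgs, design.n_chromosomes)
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_cpg = per_chrom[c]
        n_islands = max(int(round(L / 50_000)), 1) if n_cpg > 0 else 0
        isl = _random_intervals(rng, n_islands, L, min_len=400, max_len=1500)
        islands[chrom] = isl
        if n_cpg > 0:
            n_island_cpg = int(round(0.4 * n_cpg))
            sites = []
            if len(isl) and n_island_cpg:
                widths = (isl[:, 1] - isl[:, 0]).astype(float)
                alloc = rng.multinomial(n_island_cpg, widths / widths.sum())
                for (s, e), k in zip(isl, alloc):
                    sites.append(rng.integers(s, e, size=k))
            n_open = n_cpg - n_island_cpg
            if n_open > 0:
                sites.append(rng.integers(0, L, size=n_open))
            pos = np.unique(np.concatenate(sites)) if sites else np.array([], dtype=np.int64)
        else:
            pos = np.array([], dtype=np.int64)
        cpg_sites[chrom] = pos.astype(np.int64)
        # TSS: one near most island starts plus scattered extras
        t = []
        for s, _e in isl:
            if rng.random() < 0.7:
                t.append(max(int(s + rng.integers(-200, 200)), 0))
        n_extra = max(L // 100_000, 1)
        t.extend(int(x) for x in rng.integers(0, L, size=n_extra))
        tss[chrom] = np.unique(np.array(t, dtype=np.int64)) if t else np.array([], dtype=np.int64)
        tracks["DHS"][chrom] = _random_intervals(rng, max(L // 20_000, 1), L, 150, 600)
        tracks["TFBS"][chrom] = _random_intervals(rng, max(L // 15_000, 1), L, 50, 300)
        sine = _random_intervals(rng, max(L // 25_000, 1), L, 100, 400)
        line = _random_intervals(rng, max(L // 30_000, 1), L, 300, 2000)
        ltr = _random_intervals(rng, max(L // 40_000, 1), L, 200, 1000)
        tracks["SINE"][chrom] = sine
        tracks["LINE"][chrom] = line
        tracks["LTR"][chrom] = ltr
        tracks["repeat"][chrom] = merge_intervals(np.vstack([sine, line, ltr]))
        n_bins = math.ceil(L / design.bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * design.bin_size
        ends = np.minimum(starts + design.bin_size, L)
        scores = np.clip(rng.beta(1.2, 4.0, size=n_bins), 0, 1)
        conservation[chrom] = (starts, ends, scores)
    return AnnotationBundle(
        islands=islands, tss=tss, tracks=tracks, conservation=conservation, cpg_sites=cpg_sites
    )


def _split_counts(n: int, parts: int) -> list[int]:
    base = n // parts
    out = [base] * parts
    for i in range(n - base * parts):
        out[i] += 1
    return out


def _random_intervals(
    rng: np.random.Generator, n: int, length: int, min_len: int, max_len: int
) -> np.ndarray:
    if n <= 0 or length <= min_len:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.sort(rng.integers(0, length - min_len, size=n))
    lens = rng.integers(min_len, max_len + 1, size=n)
    ends = np.minimum(starts + lens, length)
    return merge_intervals(np.column_stack([starts, ends]))


def _population_side(effect_class: str, phenotype: str, disease: str) -> int:
    """+1 if this population is on the affected (high, for direction +1)
    side of an effect class, else -1."""
    if effect_class == "phenotype_shared":
        return 1 if phenotype == "luminal" else -1
    if effect_class == "cancer_luminal":
        return 1 if (phenotype == "luminal" and disease == "cancer") else -1
    if effect_class == "cancer_shared":
        return 1 if disease == "cancer" else -1
    raise ValueError(effect_class)


def generate_methylation_study(
    design: StudyDesign,
    effects: list[EffectSpec],
    annotation: AnnotationBundle,
    rng_seed: int | None = None,
) -> tuple[dict[str, MethylationCallSet], TruthTable]:
    """Generate one call set per sample plus the ground-truth table.

    Per CpG and sample: total ~ NegBin(mean_coverage, theta); methylated ~
    BetaBinomial(total, mu, rho) with logit(mu) = logit(bin baseline) +
    donor effect + planted effect.  Bin baselines come from a two-component
    Beta mixture concentrated near 0 and 1; planted bins are re-based to 0.5
    and shifted symmetrically (see module docstring).  Effect classes are
    placed on disjoint bins; insufficient room raises GenerationError.
    """
    design.validate()
    for e in effects:
        e.validate()
    seed = design.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    if annotation.cpg_sites is None:
        raise GenerationError("annotation lacks CpG sites; use generate_annotation")
    samples = design.samples()
    if samples.empty:
        raise GenerationError("design yields no samples")
    # flatten CpGs and their bins
    chroms, positions = [], []
    for chrom in sorted(annotation.cpg_sites):
        p = annotation.cpg_sites[chrom]
        chroms.append(np.full(len(p), chrom, dtype=object))
        positions.append(p)
    chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos_arr = (
        np.concatenate(positions).astype(np.int64) if positions else np.array([], dtype=np.int64)
    )
    bin_start = (pos_arr // design.bin_size) * design.bin_size
    bin_key = pd.Series(chrom_arr.astype(str)) + ":" + pd.Series(bin_start).astype(str)
    uniq_bins, bin_idx = np.unique(bin_key.to_numpy(), return_inverse=True)
    n_bins = len(uniq_bins)
    baseline = _bimodal_baseline(rng, n_bins)
    # Donor random effect = shared scalar + per-bin deviation (each with half
    # the variance): the deviation gives every donor its own bin pattern, so
    # samples cluster by donor; the per-bin regression's donor covariate
    # still captures the total effect exactly.
    donor_effects: dict[str, float] = {}
    donor_effect_bins: dict[str, np.ndarray] = {}
    sd = design.donor_sigma / math.sqrt(2.0)
    for d in design.donors():
        if design.donor_sigma > 0:
            base = float(rng.normal(0.0, sd))
            donor_effect_bins[d] = base + rng.normal(0.0, sd, size=n_bins)
            donor_effects[d] = base
        else:
            donor_effect_bins[d] = np.zeros(n_bins)
            donor_effects[d] = 0.0
    # --- plant regions on disjoint bins ---
    bin_chrom = np.array([b.split(":")[0] for b in uniq_bins], dtype=object)
    bin_s = np.array([int(b.split(":")[1]) for b in uniq_bins], dtype=np.int64)
    taken = np.zeros(n_bins, dtype=bool)
    region_rows = []
    effect_delta = np.zeros(n_bins)  # signed: + means high side hyper
    effect_class_of_bin = np.full(n_bins, "", dtype=object)
    for spec in effects:
        candidates = np.where(~taken)[0]
        if spec.placement_bias is not None:
            from .context import overlaps_track

            track = annotation.tracks.get(spec.placement_bias)
            if track is None:
                raise GenerationError(f"placement_bias track {spec.placement_bias!r} not found")
            bins_df = pd.DataFrame(
                {"chrom": bin_chrom, "start": bin_s, "end": bin_s + design.bin_size}
            )
            on_track = overlaps_track(bins_df, track)
            preferred = np.where(~taken & on_track)[0]
            if len(preferred) >= spec.n_regions * spec.n_bins_per_region:
                candidates = preferred
        need = spec.n_regions * spec.n_bins_per_region
        if len(candidates) < need:
            raise GenerationError(
                f"not enough free bins for {spec.effect_class}: {len(candidates)} < {need}"
            )
        chosen = rng.choice(candidates, size=spec.n_regions, replace=False)
        for r, b0 in enumerate(chosen):
            direction = 1 if rng.random() < spec.direction_mix else -1
            bins_of_region = [b0]
            # extend to adjacent free bins when multi-bin regions requested
            for step in range(1, spec.n_bins_per_region):
                nxt = b0 + step
                if nxt < n_bins and not taken[nxt] and bin_chrom[nxt] == bin_chrom[b0]:
                    bins_of_region.append(nxt)
            for b in bins_of_region:
                if taken[b]:
                    raise GenerationError("overlapping planted classes")
                taken[b] = True
                effect_delta[b] = direction * spec.delta
                effect_class_of_bin[b] = spec.effect_class
                region_rows.append(
                    {
                        "region_id": f"{spec.effect_class}_{r}",
                        "effect_class": spec.effect_class,
                        "chrom": bin_chrom[b],
                        "start": int(bin_s[b]),
                        "end": int(bin_s[b]) + design.bin_size,
                        "direction": "hyper" if direction > 0 else "hypo",
                        "delta": spec.delta,
                    }
                )
    planted = effect_delta != 0
    logit_base = _logit(np.clip(baseline, 1e-4, 1 - 1e-4))
    logit_base[planted] = 0.0  # re-base planted bins to 0.5
    # --- sample counts ---
    theta = design.coverage_dispersion
    m = design.mean_coverage
    nb_p = theta / (theta + m)
    rho = design.meth_overdispersion
    call_sets: dict[str, MethylationCallSet] = {}
    for row in samples.itertuples(index=False):
        shift = np.zeros(n_bins)
        for cls in EFFECT_CLASSES:
            in_cls = effect_class_of_bin == cls
            if not in_cls.any():
                continue
            side = _population_side(cls, row.phenotype, row.disease)
            # |effect_delta| is the target difference; sign encodes hyper/hypo
            half = _logit(0.5 + np.abs(effect_delta[in_cls]) / 2.0)
            shift[in_cls] = side * np.sign(effect_delta[in_cls]) * half
        logit_mu_bin = logit_base + donor_effect_bins[row.donor] + shift
        mu = _sigmoid(logit_mu_bin)[bin_idx]
        total = rng.negative_binomial(theta, nb_p, size=len(pos_arr))
        if rho > 0:
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            p = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
        else:
            p = mu
        meth = rng.binomial(total, p)
        covered = total > 0
        df = pd.DataFrame(
            {
                "chrom": chrom_arr[covered],
                "pos": pos_arr[covered] + 1,  # 1-based output
                "strand": "+",
                "meth": meth[covered],
                "total": total[covered],
            }
        )[CALL_COLUMNS]
        call_sets[row.sample_id] = MethylationCallSet(row.sample_id, df)
    truth = TruthTable(
        regions=pd.DataFrame(
            region_rows,
            columns=["region_id", "effect_class", "chrom", "start", "end", "direction", "delta"],
        ),
        donor_effects=donor_effects,
        samples=samples,
    )
    return call_sets, truth


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    low = rng.beta(1.5, 12.0, size=n)
    high = rng.beta(12.0, 1.5, size=n)
    pick_high = rng.random(n) < 0.5
    return np.where(pick_high, high, low)


def write_call_files(call_sets: dict[str, MethylationCallSet], outdir: str | Path) -> dict[str, Path]:
    from .io_binning import write_calls

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, cs in call_sets.items():
        path = outdir / f"{sid}.calls.tsv"
        write_calls(cs, path)
        paths[sid] = path
    return paths


def generate_array_dataset(
    n_normal: int,
    n_cancer: int,
    n_probes: int,
    n_informative: int,
    delta_beta: float,
    rng_seed: int = 0,
    baseline_beta: float | None = None,
    concentration: float = 60.0,
    stage_frac: float = 0.0,
    stage_delta: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate an array-like beta matrix with planted informative probes.

    Informative probes are shifted by ``delta_beta`` in cancer samples
    (clipped to [0, 1]).  Per-sample betas are Beta-distributed around the
    probe/sample mean with the given concentration; a mean of exactly 0 or 1
    yields exactly 0 or 1.  With ``stage_frac`` > 0, that fraction of cancer
    samples is labelled 'extraprostatic' and receives an extra
    ``stage_delta`` shift on the informative probes; the rest are
    'organ_confined'.

    Returns (beta matrix probes x samples, probe manifest, sample sheet,
    truth dict with 'informative_probes' and 'stage_samples').
    """
    if not 0 < delta_beta < 1 and delta_beta != 1.0:
        raise ValueError("delta_beta must be in (0, 1]")
    if n_informative > n_probes:
        raise ValueError("n_informative must be <= n_probes")
    rng = np.random.default_rng(rng_seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    sample_ids = [f"N{i + 1}" for i in range(n_normal)] + [f"T{i + 1}" for i in range(n_cancer)]
    is_cancer = np.array([0] * n_normal + [1] * n_cancer, dtype=bool)
    if baseline_beta is not None:
        base = np.full(n_probes, float(baseline_beta))
    else:
        base = np.where(
            rng.random(n_probes) < 0.5,
            rng.beta(2.0, 8.0, size=n_probes),
            rng.beta(8.0, 2.0, size=n_probes),
        )
    informative = rng.choice(n_probes, size=n_informative, replace=False)
    if baseline_beta is None and n_informative:
        # keep the shift visible: informative baselines away from the ceiling
        base[informative] = rng.uniform(0.1, 1.0 - delta_beta - 0.1, size=n_informative) \
            if delta_beta < 0.8 else 0.0
    stage = np.zeros(len(sample_ids), dtype=bool)
    if stage_frac > 0 and n_cancer > 0:
        n_stage = int(round(stage_frac * n_cancer))
        pick = rng.choice(np.where(is_cancer)[0], size=n_stage, replace=False)
        stage[pick] = True
    mu = np.tile(base[:, None], (1, len(sample_ids)))
    mu[np.ix_(informative, np.where(is_cancer)[0])] += delta_beta
    if stage.any() and n_informative:
        mu[np.ix_(informative, np.where(stage)[0])] += stage_delta
    mu = np.clip(mu, 0.0, 1.0)
    beta = np.empty_like(mu)
    interior = (mu > 0) & (mu < 1)
    a = concentration * mu[interior]
    b = concentration * (1 - mu[interior])
    beta[interior] = rng.beta(a, b)
    beta[~interior] = mu[~interior]  # exact 0/1 at the boundary
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    spacing = 1000
    manifest = pd.DataFrame(
        {"probe_id": probe_ids, "chrom": "chr1", "pos": np.arange(1, n_probes + 1) * spacing}
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": np.where(is_cancer, "cancer", "normal"),
            "stage": [
                ("extraprostatic" if st else "organ_confined") if ca else ""
                for st, ca in zip(stage, is_cancer)
            ],
        }
    )
    truth = {
        "informative_probes": [probe_ids[i] for i in sorted(informative)],
        "stage_samples": [sample_ids[i] for i in np.where(stage)[0]],
    }
    return beta_df, manifest, sheet, truth
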