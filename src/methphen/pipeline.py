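"""Config-driven orchestration of all analysis stages.

Stages run in dependency order (simulate -> bin -> dmr -> annotate ->
compare -> validate -> signature); each output table carries a provenance
header (package version, config hash, seed) and the run closes with a
machine-readable summary (DMR counts per comparison, derived-set sizes,
enrichment tables, clustering and signature metrics).  Fixed seeds give
byte-identical tables across runs: all floats are rounded to 10 significant
digits before serialization.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrays import cluster_evaluate, evaluate_signature, map_probes, train_signature
from .compare import derive_sets, run_all_pairwise, summary_table, write_derived_beds
from .config import PipelineConfig
from .context import classify_island_context, conservation_bootstrap, track_enrichment, tss_distance
from .dmr import DMRSet
from .io_binning import (
    bin_calls,
    build_matrix,
    destrand,
    filter_coverage,
    read_calls,
    read_sample_sheet,
)
from .synthetic import (
    EffectSpec,
    StudyDesign,
    generate_annotation,
    generate_array_dataset,
    generate_methylation_study,
    write_call_files,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if x == 0 or not np.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _provenance(cfg: PipelineConfig) -> str:
    return f"# methphen {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _default_effects(sim: dict) -> list[EffectSpec]:
    specs = []
    for cls, default_n in (
        ("phenotype_shared", 40),
        ("cancer_luminal", 25),
        ("cancer_shared", 25),
    ):
        cfg = sim.get("effects", {}).get(cls, {})
        specs.append(
            EffectSpec(
                effect_class=cls,
                n_regions=int(cfg.get("n_regions", default_n)),
                delta=float(cfg.get("delta", 0.5)),
                direction_mix=float(cfg.get("direction_mix", 2 / 3)),
            )
        )
    return specs


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages and return the summary dict (also written
    to summary.json in the run directory)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("methphen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    (out / "resolved_config.json").write_text(json.dumps(cfg.resolved(), indent=2, default=str))
    try:
        annotation = None
        call_sets = None
        sheet = None
        truth = None
        if cfg.simulate:
            sim = dict(cfg.sim)
            design = StudyDesign(
                n_donors=int(sim.get("n_donors", 4)),
                missing_samples=[tuple(x) for x in sim.get("missing_samples", [])],
                n_chromosomes=int(sim.get("n_chromosomes", 1)),
                chrom_length=int(sim.get("chrom_length", 400_000)),
                n_cpgs=int(sim.get("n_cpgs", 6000)),
                mean_coverage=float(sim.get("mean_coverage", 15.0)),
                coverage_dispersion=float(sim.get("coverage_dispersion", 5.0)),
                donor_sigma=float(sim.get("donor_sigma", 0.3)),
                meth_overdispersion=float(sim.get("meth_overdispersion", 0.02)),
                bin_size=cfg.bin_size,
                seed=cfg.seed,
            )
            annotation = generate_annotation(design, rng_seed=cfg.seed)
            effects = _default_effects(sim)
            call_sets, truth = generate_methylation_study(
                design, effects, annotation, rng_seed=cfg.seed + 1
            )
            sheet = truth.samples
            sim_dir = out / "simulated"
            write_call_files(call_sets, sim_dir / "calls")
            annotation.write_bed(sim_dir / "annotation")
            truth.write(sim_dir / "truth")
            sheet.to_csv(sim_dir / "sample_sheet.tsv", sep="\t", index=False)
            summary["simulated"] = {
                "n_samples": len(sheet),
                "n_regions_planted": len(truth.regions),
            }
            if not (cfg.run_binning or cfg.run_dmr):
                summary["stages"] = ["simulate"]
                return _finish(summary, out)
        else:
            if cfg.calls_dir is None or cfg.sample_sheet is None:
                raise StageError("input", "calls_dir and sample_sheet required when simulate is off")
            sheet = read_sample_sheet(cfg.sample_sheet)
            call_sets = {}
            for row in sheet.itertuples(index=False):
                path = Path(cfg.calls_dir) / f"{row.sample_id}.calls.tsv"
                if not path.exists():
                    raise StageError("input", f"missing call file {path}")
                call_sets[row.sample_id] = read_calls(path, sample_id=row.sample_id)
        matrix = None
        if cfg.run_binning:
            binned = {}
            for sid, cs in call_sets.items():
                filt = filter_coverage(cs, min_cov=cfg.min_cov, high_pct=cfg.high_pct)
                if cfg.destrand:
                    filt = destrand(filt)
                binned[sid] = bin_calls(filt, bin_size=cfg.bin_size)
            matrix = build_matrix(binned, sheet, bin_size=cfg.bin_size)
            matrix.to_tsv(out / "bin_matrix.tsv")
            summary["binning"] = {
                "n_bins_universe": matrix.n_bins,
                "n_cpgs_covered": matrix.n_cpgs_covered,
                "n_samples": len(matrix.sample_ids),
            }
        dmrsets: dict[str, DMRSet] = {}
        if cfg.run_dmr:
            if matrix is None:
                raise StageError("dmr", "binning stage disabled but required")
            dmrsets = run_all_pairwise(
                matrix,
                q_threshold=cfg.q_threshold,
                diff_threshold=cfg.diff_threshold,
                use_donor_covariate=cfg.use_donor_covariate,
            )
            dmr_dir = out / "dmrs"
            dmr_dir.mkdir(exist_ok=True)
            for name, ds in dmrsets.items():
                ds.to_bed(dmr_dir / f"{name}.bed")
            st = summary_table(dmrsets)
            _write_tsv(st, out / "dmr_summary.tsv", cfg)
            summary["dmr_counts"] = {
                name: ds.counts() for name, ds in dmrsets.items()
            }
        if cfg.run_annotate and dmrsets and annotation is not None:
            enrich_rows = []
            focus = dmrsets.get("NL-NB")
            universe = focus.table[["chrom", "start", "end"]]
            ctx = classify_island_context(universe, annotation.islands)
            td = tss_distance(universe, annotation.tss, proximal_bp=cfg.proximal_bp)
            ann_table = pd.concat([universe.reset_index(drop=True), ctx, td], axis=1)
            _write_tsv(ann_table, out / "bin_annotation.tsv", cfg)
            dmr_bins = focus.dmrs[["chrom", "start", "end"]]
            if len(dmr_bins):
                for track_name in ("DHS", "TFBS", "repeat", "SINE", "LINE", "LTR"):
                    tr = annotation.tracks.get(track_name)
                    if tr is None:
                        continue
                    er = track_enrichment(dmr_bins, universe, tr, name=track_name)
                    enrich_rows.append(er.as_dict())
                _write_tsv(pd.DataFrame(enrich_rows), out / "enrichment.tsv", cfg)
                distal = ~td["proximal"].to_numpy()
                dmr_mask = focus.table["is_dmr"].to_numpy()
                dmr_distal = universe[dmr_mask & distal]
                uni_distal = universe[distal]
                if len(dmr_distal) >= 5 and len(uni_distal) >= 3 * len(dmr_distal):
                    p_boot = conservation_bootstrap(
                        dmr_distal, uni_distal, annotation.conservation,
                        n_iter=cfg.n_boot, rng_seed=cfg.seed,
                    )
                    summary["conservation_bootstrap_p"] = p_boot
            summary["annotation"] = {
                "island_context_counts": ctx.value_counts().to_dict(),
                "n_proximal": int(td["proximal"].sum()),
                "enrichment": enrich_rows,
            }
        if cfg.run_compare and dmrsets:
            derived = derive_sets(dmrsets)
            write_derived_beds(derived, out / "derived_sets")
            _write_tsv(
                pd.DataFrame([o.as_dict() for o in derived.overlaps.values()]),
                out / "overlaps.tsv", cfg,
            )
            summary["derived_sets"] = derived.sizes()
            summary["overlaps"] = {
                k: _round_floats(v.as_dict()) for k, v in derived.overlaps.items()
            }
        if cfg.run_validate or cfg.run_signature:
            sa = dict(cfg.sim_array)
            if cfg.simulate:
                beta, manifest, asheet, atruth = generate_array_dataset(
                    n_normal=int(sa.get("n_normal", 80)),
                    n_cancer=int(sa.get("n_cancer", 80)),
                    n_probes=int(sa.get("n_probes", 150)),
                    n_informative=int(sa.get("n_informative", 10)),
                    delta_beta=float(sa.get("delta_beta", 0.3)),
                    rng_seed=cfg.seed + 2,
                )
                labels = asheet.set_index("sample_id")["label"]
            else:
                if cfg.beta_matrix is None:
                    raise StageError("validate", "beta_matrix required when simulate is off")
                from .arrays import read_beta_matrix, read_manifest

                beta = read_beta_matrix(cfg.beta_matrix)
                manifest = read_manifest(cfg.manifest)
                asheet = pd.read_csv(cfg.array_sample_sheet, sep="\t")
                labels = asheet.set_index("sample_id")["label"]
            if cfg.run_validate:
                ev = cluster_evaluate(beta, labels, n_cuts=1)
                summary["clustering"] = {
                    "tpr": ev.tpr, "tnr": ev.tnr,
                    "chi_square": ev.chi_square, "p_value": ev.p_value,
                }
            if cfg.run_signature:
                model = train_signature(
                    beta, labels,
                    train_frac=cfg.train_frac, n_lambda=cfg.n_lambda,
                    lambda_range=(cfg.lambda_min, cfg.lambda_max),
                    folds=cfg.folds, rng_seed=cfg.seed + 3, cutoff=cfg.cutoff,
                )
                model.to_json(out / "signature_model.json")
                res = evaluate_signature(model, beta[model.test_samples], labels)
                _write_tsv(res["roc"], out / "roc_points.tsv", cfg)
                summary["signature"] = {
                    "n_probes_selected": len(model.probes),
                    "chosen_lambda": model.chosen_lambda,
                    "auc": res["auc"], "tpr": res["tpr"], "tnr": res["tnr"],
                    "fisher_p": res["fisher_p"],
                }
        return _finish(summary, out)
    except StageError:
        raise
    except Exception as exc:  # annotate failures with the stage
        raise StageError("pipeline", str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _finish(summary: dict, out: Path) -> dict:
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
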