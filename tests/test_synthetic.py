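import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methphen.io_binning import bin_calls, build_matrix, destrand, filter_coverage, top_variable_bins
from methphen.synthetic import (
    EffectSpec,
    GenerationError,
    StudyDesign,
    generate_annotation,
    generate_array_dataset,
    generate_methylation_study,
    write_call_files,
)


def two_pop_design(**kwargs):
    defaults = dict(
        n_donors=4,
        populations=[("luminal", "normal"), ("basal", "normal")],
        n_chromosomes=1,
        chrom_length=400_000,
        n_cpgs=8_000,
        mean_coverage=15.0,
        donor_sigma=0.0,
        meth_overdispersion=0.0,
        seed=13,
    )
    defaults.update(kwargs)
    return StudyDesign(**defaults)


class TestDesign:
    def test_invalid_designs(self):
        with pytest.raises(ValueError):
            StudyDesign(n_donors=1).validate()
        with pytest.raises(ValueError):
            StudyDesign(mean_coverage=0).validate()
        with pytest.raises(ValueError):
            StudyDesign(chrom_length=0).validate()

    def test_missing_samples(self):
        d = StudyDesign(n_donors=4, missing_samples=[("D4", "NL"), ("D4", "NB")])
        sheet = d.samples()
        assert len(sheet) == 4 * 4 - 2
        assert not ((sheet["donor"] == "D4") & (sheet["phenotype"] == "luminal")
                    & (sheet["disease"] == "normal")).any()

    def test_full_design_sample_count(self):
        assert len(StudyDesign(n_donors=3).samples()) == 12


class TestGenerateAnnotation:
    def test_empty_case(self):
        design = two_pop_design(n_cpgs=0)
        ann = generate_annotation(design)
        assert all(len(v) == 0 for v in ann.cpg_sites.values())

    def test_determinism(self, tmp_path):
        design = two_pop_design()
        a1 = generate_annotation(design)
        a2 = generate_annotation(design)
        a1.write_bed(tmp_path / "a")
        a2.write_bed(tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_island_density_exceeds_open_sea(self):
        design = two_pop_design(n_cpgs=10_000, chrom_length=1_000_000)
        ann = generate_annotation(design)
        islands = ann.islands["chr1"]
        assert len(islands) >= 1
        pos = ann.cpg_sites["chr1"]
        in_island = np.zeros(len(pos), dtype=bool)
        for s, e in islands:
            in_island |= (pos >= s) & (pos < e)
        island_bp = (islands[:, 1] - islands[:, 0]).sum()
        open_bp = design.chrom_length - island_bp
        density_island = in_island.sum() / island_bp
        density_open = (~in_island).sum() / open_bp
        assert density_island > density_open

    def test_coordinates_in_bounds(self):
        design = two_pop_design(n_chromosomes=2)
        ann = generate_annotation(design)
        for chrom in ann.islands:
            for track in list(ann.tracks.values()) + [ann.islands]:
                iv = track.get(chrom)
                if iv is not None and len(iv):
                    assert iv.min() >= 0 and iv.max() <= design.chrom_length

    def test_bad_config(self):
        with pytest.raises(ValueError):
            generate_annotation(two_pop_design(n_cpgs=-5))


class TestGenerateStudy:
    def test_null_case_differences_centred(self):
        design = two_pop_design(n_cpgs=30_000, chrom_length=1_200_000, seed=3)
        ann = generate_annotation(design)
        calls, truth = generate_methylation_study(design, [], ann)
        binned = {s: bin_calls(destrand(filter_coverage(c))) for s, c in calls.items()}
        mat = build_matrix(binned, truth.samples)
        lum = (mat.samples["phenotype"] == "luminal").to_numpy()
        ma, ta = mat.meth[:, lum].sum(1), mat.total[:, lum].sum(1)
        mb, tb = mat.meth[:, ~lum].sum(1), mat.total[:, ~lum].sum(1)
        keep = (ta > 0) & (tb > 0)
        diff = ma[keep] / ta[keep] - mb[keep] / tb[keep]
        n_bins = min(keep.sum(), 10_000)
        assert n_bins >= 1000
        # centred at 0 and mean |diff| consistent with binomial noise
        assert abs(diff.mean()) < 0.01
        p = (ma[keep] + mb[keep]) / (ta[keep] + tb[keep])
        expected_sd = np.sqrt(p * (1 - p) * (1 / ta[keep] + 1 / tb[keep]))
        assert np.mean(np.abs(diff)) < 1.5 * np.mean(expected_sd) + 0.01

    def test_phenotype_effect_magnitude(self):
        """delta=0.5: pooled luminal-basal difference within 3 SE of 0.5 in
        both normal and cancer samples."""
        design = StudyDesign(
            n_donors=3, n_chromosomes=1, chrom_length=300_000, n_cpgs=9_000,
            mean_coverage=25.0, donor_sigma=0.0, meth_overdispersion=0.0, seed=8,
        )
        ann = generate_annotation(design)
        calls, truth = generate_methylation_study(
            design, [EffectSpec("phenotype_shared", 1, 0.5, direction_mix=1.0)], ann
        )
        region = truth.regions.iloc[0]
        sheet = truth.samples
        for disease in ("normal", "cancer"):
            counts = {"luminal": [0, 0], "basal": [0, 0]}
            for row in sheet[sheet["disease"] == disease].itertuples(index=False):
                df = calls[row.sample_id].df
                sel = df[
                    (df["chrom"] == region["chrom"])
                    & (df["pos"] - 1 >= region["start"])
                    & (df["pos"] - 1 < region["end"])
                ]
                counts[row.phenotype][0] += sel["meth"].sum()
                counts[row.phenotype][1] += sel["total"].sum()
            (ml, tl), (mb, tb) = counts["luminal"], counts["basal"]
            assert tl > 0 and tb > 0
            diff = ml / tl - mb / tb
            se = np.sqrt(0.75 * 0.25 / tl + 0.25 * 0.75 / tb)
            assert abs(diff - 0.5) < 3 * se + 1e-9

    def test_donor_clustering(self):
        design = two_pop_design(donor_sigma=1.5, meth_overdispersion=0.02,
                                n_cpgs=15_000, chrom_length=600_000, seed=5)
        ann = generate_annotation(design)
        calls, truth = generate_methylation_study(design, [], ann)
        binned = {s: bin_calls(destrand(filter_coverage(c))) for s, c in calls.items()}
        mat = build_matrix(binned, truth.samples)
        tv = top_variable_bins(mat, 0.05)
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        X = tv[mat.sample_ids].to_numpy().T
        cl = fcluster(linkage(pdist(X), method="complete"), t=4, criterion="maxclust")
        assign = pd.Series(cl, index=mat.sample_ids)
        donors = mat.samples.set_index("sample_id")["donor"]
        pure = sum(
            assign.loc[donors.index[donors == d]].nunique() == 1 for d in donors.unique()
        )
        assert pure >= 3

    def test_determinism_bit_exact(self, tmp_path):
        design = two_pop_design(n_cpgs=2_000, donor_sigma=0.5, meth_overdispersion=0.05)
        ann = generate_annotation(design)
        c1, _ = generate_methylation_study(design, [], ann)
        c2, _ = generate_methylation_study(design, [], ann)
        p1 = write_call_files(c1, tmp_path / "r1")
        p2 = write_call_files(c2, tmp_path / "r2")
        for sid in p1:
            assert p1[sid].read_bytes() == p2[sid].read_bytes()

    def test_counts_valid(self, small_study):
        for cs in small_study["calls"].values():
            assert (cs.df["meth"] <= cs.df["total"]).all()
            assert (cs.df["meth"] >= 0).all()

    def test_coverage_mean_within_5pct(self):
        design = two_pop_design(n_cpgs=12_000, mean_coverage=7.5)
        ann = generate_annotation(design)
        calls, _ = generate_methylation_study(design, [], ann)
        # marginal mean over all CpGs includes zero-coverage sites
        totals = []
        n_sites = len(np.concatenate(list(ann.cpg_sites.values())))
        for cs in calls.values():
            totals.append(cs.df["total"].sum() / n_sites)
        assert abs(np.mean(totals) - 7.5) / 7.5 < 0.05

    def test_truth_regions_map_to_bins(self, small_study):
        truth = small_study["truth"]
        assert len(truth.regions) == 70
        assert (truth.regions["end"] - truth.regions["start"] == 100).all()

    def test_effect_classes_disjoint(self, small_study):
        truth = small_study["truth"]
        ids = truth.regions["chrom"].astype(str) + ":" + truth.regions["start"].astype(str)
        assert ids.is_unique

    def test_too_many_regions_raises(self):
        design = two_pop_design(n_cpgs=100, chrom_length=10_000)
        ann = generate_annotation(design)
        with pytest.raises(GenerationError, match="not enough free bins"):
            generate_methylation_study(
                design, [EffectSpec("phenotype_shared", 10_000, 0.3)], ann
            )

    def test_truth_write(self, small_study, tmp_path):
        small_study["truth"].write(tmp_path)
        assert (tmp_path / "truth_regions.tsv").exists()
        back = pd.read_csv(tmp_path / "truth_regions.tsv", sep="\t")
        assert len(back) == len(small_study["truth"].regions)


class TestGenerateArray:
    def test_null_no_probe_significant(self):
        beta, _, sheet, _ = generate_array_dataset(40, 40, 500, 0, 0.3, rng_seed=6)
        cancer = sheet["label"].to_numpy() == "cancer"
        X = beta.to_numpy()
        diff = X[:, cancer].mean(1) - X[:, ~cancer].mean(1)
        se = np.sqrt(X[:, cancer].var(1, ddof=1) / cancer.sum()
                     + X[:, ~cancer].var(1, ddof=1) / (~cancer).sum())
        assert (np.abs(diff) > 3 * se).mean() < 0.02  # ~ chance level

    def test_boundary_clipping_exact(self):
        beta, _, sheet, truth = generate_array_dataset(
            10, 10, 50, 5, 1.0, rng_seed=2, baseline_beta=0.0
        )
        cancer = sheet.set_index("sample_id")["label"] == "cancer"
        info = truth["informative_probes"]
        assert (beta.loc[info, ~cancer.to_numpy()] == 0.0).all().all()
        assert (beta.loc[info, cancer.to_numpy()] == 1.0).all().all()

    def test_t_statistic_ranking(self):
        beta, _, sheet, truth = generate_array_dataset(150, 150, 200, 10, 0.3, rng_seed=4)
        cancer = sheet["label"].to_numpy() == "cancer"
        t, _ = stats.ttest_ind(beta.to_numpy()[:, cancer], beta.to_numpy()[:, ~cancer], axis=1)
        top20 = set(beta.index[np.argsort(-np.abs(t))[:20]])
        assert set(truth["informative_probes"]) <= top20

    def test_betas_in_unit_interval(self):
        beta, _, _, _ = generate_array_dataset(20, 20, 100, 10, 0.4, rng_seed=1)
        assert float(beta.min().min()) >= 0.0
        assert float(beta.max().max()) <= 1.0

    def test_bad_delta(self):
        with pytest.raises(ValueError):
            generate_array_dataset(5, 5, 10, 2, 1.5)
        with pytest.raises(ValueError):
            generate_array_dataset(5, 5, 10, 2, 0.0)

    def test_informative_exceeds_probes(self):
        with pytest.raises(ValueError):
            generate_array_dataset(5, 5, 10, 20, 0.3)

    def test_stage_labels(self):
        _, _, sheet, truth = generate_array_dataset(
            20, 20, 50, 5, 0.3, rng_seed=3, stage_frac=0.3
        )
        staged = sheet[sheet["stage"] == "extraprostatic"]
        assert len(staged) == 6
        assert set(staged["sample_id"]) == set(truth["stage_samples"])

    def test_determinism(self):
        b1, m1, s1, t1 = generate_array_dataset(15, 15, 40, 5, 0.3, rng_seed=9)
        b2, m2, s2, t2 = generate_array_dataset(15, 15, 40, 5, 0.3, rng_seed=9)
        pd.testing.assert_frame_equal(b1, b2)
        assert t1 == t2
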