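import numpy as np
import pandas as pd
import pytest

from methphen.io_binning import MethylationCallSet, CALL_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_calls(records, sample_id="S1"):
    """records: iterable of (chrom, pos, strand, meth, total)."""
    df = pd.DataFrame(records, columns=CALL_COLUMNS)
    return MethylationCallSet(sample_id, df)


@pytest.fixture
def random_calls(rng):
    """1,000 random forward-strand records on two chromosomes."""
    n = 1000
    chrom = np.where(rng.random(n) < 0.5, "chr1", "chr2")
    pos = rng.integers(1, 100_000, size=n)
    # unique positions per chromosome
    df = pd.DataFrame({"chrom": chrom, "pos": pos}).drop_duplicates()
    total = rng.integers(1, 40, size=len(df))
    meth = rng.binomial(total, 0.4)
    df["strand"] = "+"
    df["meth"] = meth
    df["total"] = total
    return MethylationCallSet("S1", df[CALL_COLUMNS].reset_index(drop=True))


@pytest.fixture(scope="session")
def small_study():
    """A small four-population study with planted effects, binned.

    Session-scoped: generation plus binning takes ~2 s and several test
    modules reuse it read-only.
    """
    from methphen.synthetic import (
        EffectSpec,
        StudyDesign,
        generate_annotation,
        generate_methylation_study,
    )
    from methphen.io_binning import bin_calls, build_matrix, destrand, filter_coverage

    design = StudyDesign(
        n_donors=4,
        n_chromosomes=2,
        chrom_length=400_000,
        n_cpgs=24_000,
        mean_coverage=18.0,
        donor_sigma=0.3,
        meth_overdispersion=0.0,
        seed=97,
    )
    annotation = generate_annotation(design)
    effects = [
        EffectSpec("phenotype_shared", 30, 0.5),
        EffectSpec("cancer_luminal", 20, 0.5),
        EffectSpec("cancer_shared", 20, 0.5),
    ]
    calls, truth = generate_methylation_study(design, effects, annotation)
    binned = {s: bin_calls(destrand(filter_coverage(c))) for s, c in calls.items()}
    matrix = build_matrix(binned, truth.samples)
    return {
        "design": design,
        "annotation": annotation,
        "calls": calls,
        "truth": truth,
        "matrix": matrix,
    }
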