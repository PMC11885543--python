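import numpy as np
import pandas as pd
import pytest

import mitocrypt as mc


@pytest.fixture(scope="session")
def cohort_config():
    """Desk-scale study conditions: 4 donors spanning young to old age.

    The Moran parameters give a fixation timescale of ~54 years, so the
    oldest donor sits beyond one fixation time (homoplasmies present) while
    the youngest has essentially none.
    """
    moran = mc.MoranParams(N=150, t_half=0.25, nu=4e-7, L_mtDNA=16569, seed=0)
    return mc.CohortConfig(
        n_donors=4,
        ages_years=(5.0, 25.0, 50.0, 75.0),
        cells_per_donor=30,
        moran=moran,
        shared_variant_rate=2.0,
        common_variant_sites=(11, 22, 33),
        mean_depth=1500.0,
        depth_dispersion=5.0,
        error_rate=1e-3,
        genome_length=3000,
        seed=42,
    )


@pytest.fixture(scope="session")
def truth(cohort_config):
    return mc.generate_cohort(cohort_config)


@pytest.fixture(scope="session")
def counts(truth):
    return mc.render_base_counts(truth)


@pytest.fixture(scope="session")
def mask(counts):
    return mc.qc_filter(counts, min_depth=200, min_positions=200)


@pytest.fixture(scope="session")
def called(counts, mask, truth):
    return mc.call_variants(counts, mask, truth.reference)


@pytest.fixture(scope="session")
def classified(called, mask):
    return mc.classify_variants(called, mask)


@pytest.fixture(scope="session")
def annotation(truth, cohort_config):
    subs = (
        truth.mutations[["site", "ref", "alt"]]
        .drop_duplicates()
        .rename(columns={"site": "pos"})
    )
    return mc.make_annotation_table(subs, seed=cohort_config.seed)


@pytest.fixture(scope="session")
def annotated(classified, annotation):
    return mc.annotate_variants(classified, annotation)


def make_counts_frame(rows):
    """rows: (cell, donor, pos, A, C, G, T) tuples -> base-count frame."""
    return pd.DataFrame(
        rows, columns=["cell", "donor", "pos", "A", "C", "G", "T"]
    )


@pytest.fixture
def uniform_ref():
    return pd.Series("A", index=np.arange(1, 5001))
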