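"""Shared fixtures: small synthetic datasets with planted truth."""

import pandas as pd
import pytest

from kinasign.differential import log_transform
from kinasign.io import SiteMatrix
from kinasign.simulate import (
    SimulationConfig,
    generate_motif_library,
    generate_proteome_and_sites,
    generate_site_matrix,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=42,
        n_samples_per_group=10,
        n_proteins=20,
        n_sites=300,
        n_kinase_motifs=30,
        n_phosphatase_motifs=5,
        n_sh2_motifs=5,
        active_kinases=["KIN_003"],
        effect_log2fc=2.0,
        noise_sd=0.3,
        missing_rate_base=0.1,
        n_patients=80,
    )


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return generate_motif_library(small_cfg)


@pytest.fixture(scope="session")
def small_sites(small_cfg, small_library):
    _, annotations = generate_proteome_and_sites(small_cfg, small_library)
    matrix = generate_site_matrix(small_cfg, annotations)
    return matrix, annotations


@pytest.fixture(scope="session")
def small_logged(small_sites):
    matrix, annotations = small_sites
    return log_transform(matrix), annotations


@pytest.fixture()
def toy_matrix():
    """3 sites x 4 samples, hand-enterable numbers, no missing values."""
    ann = pd.DataFrame(
        {
            "protein_id": ["P1", "P1", "P2"],
            "residue": ["S", "T", "Y"],
            "position": [8, 20, 8],
            "flank": ["AAAAAAASAAAAAAA", "CCCCCCCTCCCCCCC", "DDDDDDDYDDDDDDD"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="site_id"),
    )
    intens = pd.DataFrame(
        {
            "a1": [8.0, 4.0, 2.0],
            "a2": [16.0, 8.0, 4.0],
            "b1": [2.0, 1.0, 8.0],
            "b2": [4.0, 2.0, 16.0],
        },
        index=ann.index,
    )
    groups = pd.Series(
        ["relapsed", "relapsed", "non-relapsed", "non-relapsed"],
        index=intens.columns,
    )
    return SiteMatrix(ann, intens, groups)

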