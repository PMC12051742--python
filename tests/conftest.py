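import numpy as np
import pytest

from crowdemog.demography import (
    GWS_FASTSIMCOAL,
    build_gws_model,
    build_lsi_model,
)
from crowdemog.synthetic_data import DatasetLayout, generate_dataset


@pytest.fixture(scope="session")
def gws_params():
    return dict(GWS_FASTSIMCOAL)


@pytest.fixture(scope="session")
def gws_model(gws_params):
    return build_gws_model(gws_params)


@pytest.fixture(scope="session")
def lsi_model(gws_params):
    return build_lsi_model(gws_params)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, gws_params):
    """One small GWS dataset shared across read-only tests."""
    outdir = tmp_path_factory.mktemp("ds")
    layout = DatasetLayout(n_contigs=6, loci_per_contig=30,
                           locus_length=2000, barrier_contig="contig6")
    return generate_dataset("gws", gws_params, layout=layout, seed=5,
                            outdir=str(outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
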