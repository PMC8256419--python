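import numpy as np
import pytest

from rwhn.core import RWHNParams, run_rwhn
from rwhn.io_formats import QuantTable, SiteID
from rwhn.netbuild import assemble_multilayer
from rwhn.preprocess import (
    ClusterAssignment,
    cluster_profiles,
    filter_regulated_sites,
    impute_left_censored,
)
from rwhn.synthetic import generate_planted_study


def make_quant(values, conditions=None, proteins=None):
    """Small QuantTable with one site per row on distinct proteins."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    conditions = conditions or [f"t{j}" for j in range(m)]
    proteins = proteins or [f"P{i + 1}" for i in range(n)]
    sites = [SiteID(p, 10 * (i + 1), "S") for i, p in enumerate(proteins)]
    return QuantTable(sites, conditions, values)


def run_study_pipeline(study, seed=7):
    """Preprocess + cluster + assemble + walk for a planted study."""
    qt = filter_regulated_sites(study.quant)
    qt = impute_left_censored(qt, seed=seed)
    clusters = cluster_profiles(qt, len(study.truth), "fcm", seed=seed)
    net = assemble_multilayer(
        qt, clusters, study.ppi, study.lib, study.dag, seed=seed
    )
    result = run_rwhn(net, clusters, RWHNParams())
    return qt, clusters, net, result


def match_clusters(study, clusters: ClusterAssignment) -> dict:
    """Map each recovered cluster label to the majority planted cluster."""
    mapping = {}
    for c in clusters.cluster_ids():
        sites = clusters.sites_in(c)
        truths = [study.true_labels[s] for s in sites]
        mapping[c] = max(set(truths), key=truths.count)
    return mapping


@pytest.fixture(scope="session")
def planted_study():
    return generate_planted_study(seed=1)


@pytest.fixture(scope="session")
def planted_pipeline(planted_study):
    """(qt, clusters, net, result) for the session's planted study."""
    return run_study_pipeline(planted_study)
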