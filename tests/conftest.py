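import numpy as np
import pytest

from cytoconn.connectome import GroupNetwork
from cytoconn.profiles import (
    LabelIndex,
    compare_profiles,
    extract_profile,
    nearest_neighbor_pairs,
    qc_filter,
    regional_profiles,
)
from cytoconn.synthetic_data import (
    make_section,
    make_truth_profiles,
    sample_point_pairs,
)


def make_net(adjacency, weighted=None) -> GroupNetwork:
    """Wrap a plain adjacency (and optional weights) as a group network."""
    A = np.asarray(adjacency, dtype=int)
    W = A.astype(float) if weighted is None else np.asarray(weighted, dtype=float)
    return GroupNetwork(
        binary=A,
        weighted=W,
        prevalence=A.astype(float),
        threshold=0.5,
        region_ids=np.arange(1, A.shape[0] + 1),
    )


def extract_all(section, pairs):
    """Extraction pipeline on one section: profiles with regions and QC
    fields set (degenerate quadrilaterals skipped)."""
    nn = nearest_neighbor_pairs(pairs)
    by_id = {p.pair_id: p for p in pairs}
    index = LabelIndex(section.label_map)
    out = []
    for p in pairs:
        nn_id, nn_dist = nn[p.pair_id]
        if nn_id is None:
            continue
        try:
            prof = extract_profile(section.image, p, by_id[nn_id])
        except ValueError:
            continue
        prof.nn_pair_id = nn_id
        prof.nn_distance = nn_dist
        prof.region, prof.voxel_distance = index.query(p.midpoint)
        out.append(prof)
    return out


@pytest.fixture(scope="session")
def noisefree_section():
    """A six-region noise-free annulus section with its truth curves."""
    truth = make_truth_profiles(6, seed=11)
    section = make_section(truth, noise_sd=0.0, seed=12)
    return section, truth


@pytest.fixture(scope="session")
def recovered_regional(noisefree_section):
    """Regional mean profiles recovered from the noise-free section."""
    section, truth = noisefree_section
    pairs = sample_point_pairs(section, 240, seed=13, stratified=True)
    profiles = extract_all(section, pairs)
    kept = qc_filter(profiles)
    return regional_profiles(kept, min_count=20), truth
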