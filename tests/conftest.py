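import numpy as np
import pytest

from connfusion.connectome import (compute_connectivity_vector,
                                   compute_fingerprint,
                                   extract_roi_timeseries)
from connfusion.synthetic import SyntheticCohortSpec, simulate_cohort


def featurize_cohort(cohort):
    """Compute (fingerprints, vectors, label names) arrays for a cohort.

    Fingerprints are returned as (n, N_regions, H, W, D) with the region
    axis first, ready to be the network's channel axis.
    """
    fps, vecs, labels = [], [], []
    for rec in cohort.records:
        vol = cohort.volumes[rec.subject_id]
        roits = extract_roi_timeseries(vol, cohort.atlas)
        fps.append(np.moveaxis(compute_fingerprint(vol, roits).corr, 3, 0))
        vecs.append(compute_connectivity_vector(roits).values)
        labels.append(rec.label)
    return (np.stack(fps).astype(np.float32),
            np.stack(vecs).astype(np.float32), labels)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast in-memory cohort: 10 subjects, 8^3 grid, 4 regions."""
    spec = SyntheticCohortSpec(grid=(8, 8, 8), n_regions=4, T=40,
                               n_per_group=5, effect_delta=0.6,
                               voxel_noise_sd=0.5, seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return featurize_cohort(tiny_cohort)
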