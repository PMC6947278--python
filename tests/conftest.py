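import numpy as np
import pytest

import octaquant as oq
from octaquant.roi import RegionMask

N_RECOVERY_PHANTOMS = 20


@pytest.fixture(scope="session")
def recovery_measurements():
    """Full-pipeline measurements of the canonical recovery phantoms.

    Twenty noiseless phantoms (seeds 1-20, calibers truncated at 3 px) are
    binarized, skeletonized and measured over the whole raster; shared by
    the parameter-recovery and algebraic-identity checks.
    """
    full = RegionMask.full(500)
    cfg = oq.PipelineConfig()
    rows = []
    for seed in range(1, N_RECOVERY_PHANTOMS + 1):
        img, truth = oq.generate_phantom(oq.recovery_spec(seed))
        mask = oq.binarize_scp(img)
        skel = oq.skeletonize_mask(mask)
        branches = oq.analyze_branches(oq.prune_spurs(skel, cfg.vt_prune_px))
        rows.append(dict(
            pd=oq.perfusion_density(mask, full),
            vld=oq.vessel_length_density(skel, full),
            vdi=oq.vessel_diameter_index(mask, skel, full, 12.0),
            vt=oq.vessel_tortuosity(branches, full),
            truth=truth,
        ))
    return rows


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
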