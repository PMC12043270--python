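import numpy as np
import pytest

from neodmri import phantom_forge
from neodmri.epi_geometry import AcquisitionGeometry


@pytest.fixture(scope="session")
def phantom():
    return phantom_forge.make_phantom((40, 40, 32), seed=1)


@pytest.fixture(scope="session")
def recon_fixture():
    """Small multi-coil slab for parallel-imaging tests.

    48x48 in-plane (divisible by R = 2, 3, 4) and a 12-slice slab
    (divisible by MB = 2, 3, 4), 16 coils, smooth tissue-contrast object.
    """
    ph = phantom_forge.make_phantom((48, 48, 36), seed=3)
    sl = slice(12, 24)
    img = (ph.t2_ms / 200.0)[:, :, sl]
    mask = ph.mask[:, :, sl]
    coils = phantom_forge.make_coils(img.shape, 16, seed=0)
    ref = coils.rss() * img
    geom = AcquisitionGeometry(n_pe=48, n_ro=48, n_slices=12, n_segments=3)
    return {"image": img, "mask": mask, "coils": coils, "reference": ref, "geom": geom}


@pytest.fixture(scope="session")
def recon_nrmse(recon_fixture):
    """NRMSE of the full pipeline for the four candidate accelerations."""
    from neodmri.parallel_recon import reconstruct

    out = {}
    for mb, r in [(2, 2), (3, 2), (2, 3), (4, 2)]:
        geom = recon_fixture["geom"].with_acceleration(MB=mb, R=r)
        ks = phantom_forge.simulate_kspace(recon_fixture["image"], recon_fixture["coils"], geom)
        out[(mb, r)] = reconstruct(
            ks, reference=recon_fixture["reference"], mask=recon_fixture["mask"]
        ).nrmse
    return out
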