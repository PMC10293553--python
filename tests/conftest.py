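import numpy as np
import pytest

import dpkit as dk
from dpkit.chain import FitConfig, fit_chain


@pytest.fixture(scope="session")
def water():
    """Liquid water, registered once for range/kernel tests."""
    return dk.MaterialSpec("Water", {"H": 0.111894, "O": 0.888106}, 1.0)


@pytest.fixture(scope="session")
def energies_12():
    return list(np.logspace(np.log10(10.0), np.log10(3000.0), 12))


@pytest.fixture(scope="session")
def training_dataset(energies_12):
    """Emulated kernels for all training materials on a 12-point energy grid."""
    mats = [dk.material_lookup(lab) for lab in dk.training_labels()]
    return dk.generate_dataset(mats, energies_12, seed=1101)


@pytest.fixture(scope="session")
def ridge_chain(training_dataset):
    """A fixed ridge chain good enough for downstream (beta/VDK) stages."""
    return fit_chain(training_dataset, FitConfig(base="ridge", alpha=1e-2))


@pytest.fixture(scope="session")
def soft_tissue():
    return dk.material_lookup("Soft Tissue")


@pytest.fixture(scope="session")
def demo_nuclide():
    return dk.builtin_nuclides()["demo-mid"]


@pytest.fixture(scope="session")
def beta_kernel_soft(ridge_chain, demo_nuclide, soft_tissue):
    """Beta sDPK for the mid-energy synthetic nuclide in soft tissue."""
    return dk.beta_sdpk(ridge_chain, demo_nuclide.spectrum, soft_tissue)


@pytest.fixture(scope="session")
def vdk_soft(beta_kernel_soft, demo_nuclide, soft_tissue):
    """15³ voxel dose kernel at 1e4 pairs/voxel (covers 1.2·r_N fully)."""
    return dk.build_vdk(
        beta_kernel_soft,
        soft_tissue,
        demo_nuclide.spectrum.e_eff,
        voxel_size_mm=1.0,
        n_pair_samples=10_000,
        seed=7,
        size=15,
    )
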