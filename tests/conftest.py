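import numpy as np
import pytest

from octaline.simdata import SimConfig, TissueOpticsConfig, simulate_dataset


def small_sim(n_bscans: int, seed: int, *, class_mix: float = 0.2,
              alines: int = 256, depth: int = 256, **overrides) -> SimConfig:
    """Reduced-geometry config covering ~the same 358.4 deg circle.

    256 A-lines at 1.4 deg and 256 depth pixels at 19.2 um span the
    native angular/axial extents at quarter sampling, keeping
    protocol-level tests fast.
    """
    kwargs = dict(
        n_bscans=n_bscans,
        alines_per_bscan=alines,
        depth_px=depth,
        angular_step_deg=358.4 / alines,
        axial_step_um=4.8 * (1024 / depth),
        lumen_radius_px_range=(depth // 12, depth // 6),
        class_mix=class_mix,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def flat_optics(mu: float = 2.0) -> dict:
    """Identical optics for every tissue class (null-contrast control)."""
    table = {c: TissueOpticsConfig(c, mu, 1.0, 20)
             for c in ("intimal-thickening", "fibrous", "calcific", "lipid")}
    table["guidewire"] = TissueOpticsConfig("guidewire", 0.0, 1.0, shadow=True)
    return table


@pytest.fixture(scope="session")
def small_pullback():
    """Shared reduced-geometry pullback with default optics."""
    return simulate_dataset(small_sim(8, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
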