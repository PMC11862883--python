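import numpy as np
import pytest

from monosurf import composition as comp

MW = {"DPPC": 734.04, "POPC": 760.08, "POPG": 770.99, "CHOL": 386.65}


@pytest.fixture(scope="session")
def small_mixture() -> comp.MonolayerComposition:
    """A 200-lipid single-leaflet film with the reference mole ratios."""
    return comp.MonolayerComposition.from_counts(
        {"DPPC": 120, "POPC": 40, "POPG": 20, "CHOL": 20}, MW, n_leaflets=1
    )


@pytest.fixture(scope="session")
def reference_mixture() -> comp.MonolayerComposition:
    """The full 2032-molecule two-leaflet reference system."""
    return comp.lung_surfactant()


def make_frameset(coords, box, resnames, beadnames, resids):
    from monosurf.traj import FrameSet

    return FrameSet(
        coords=np.asarray(coords, dtype=float),
        box=np.asarray(box, dtype=float),
        resnames=np.array(resnames, dtype=object),
        beadnames=np.array(beadnames, dtype=object),
        resids=np.array(resids, dtype=int),
    )
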