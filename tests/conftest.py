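import warnings

import numpy as np
import pytest

from explode_orient import (
    DetectorGeometry,
    Rotation,
    assign_charges,
    project_to_detectors,
    simulate_explosion,
    synthesize_cloud,
)


def make_pdb_text(coords, elements, res_names=None):
    """Write minimal fixed-column PDB ATOM/HETATM records."""
    res_names = res_names or ["ALA"] * len(coords)
    lines = []
    for i, ((x, y, z), el, res) in enumerate(zip(coords, elements, res_names), start=1):
        record = "HETATM" if res in ("HOH", "WAT") else "ATOM  "
        name = el.ljust(3)
        lines.append(
            f"{record}{i:5d}  {name}{res:>4s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def geom():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def cloud300():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthesize_cloud(300, rng_seed=42, label="cloud300")


@pytest.fixture(scope="session")
def ejecta300(cloud300):
    charged = assign_charges(cloud300, mean_ionization=1.2, rng_seed=7)
    return simulate_explosion(charged)


@pytest.fixture(scope="session")
def footprint300(ejecta300, geom):
    return project_to_detectors(ejecta300, geom, Rotation.identity())


def make_footprint(counts, orientation=None, label="fake", realization=0):
    """Wrap a hand-made count grid in a Footprint with a chosen orientation."""
    from explode_orient import Footprint

    counts = np.asarray(counts, dtype=np.uint32)
    return Footprint(
        counts=counts,
        orientation=orientation or Rotation.identity(),
        n_detected=int(counts.sum()),
        n_ions=int(counts.sum()),
        source_label=label,
        realization=realization,
    )
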