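import numpy as np
import pytest

from ectodimer.synthetic import ToyDimerSpec, build_toy_dimer, build_toy_ensemble


@pytest.fixture(scope="session")
def default_dimer():
    """Noise-free toy dimer with the default construction parameters."""
    return build_toy_dimer(ToyDimerSpec())


@pytest.fixture(scope="session")
def graded_ensemble():
    """Ten noise-free dimers spanning the conformational range: scissor
    25 -> 10 degrees while the tip separation grows 5 -> 20 Å (the
    juxtaposed -> separated series)."""
    scissors = np.linspace(25.0, 10.0, 10)
    tips = np.linspace(5.0, 20.0, 10)
    specs = [ToyDimerSpec(scissor_angle=float(s), tip_distance=float(t))
             for s, t in zip(scissors, tips)]
    ensemble, truth = build_toy_ensemble(specs)
    return ensemble, truth, specs


def random_rigid_transform(rng):
    """Uniform-ish random proper rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-50, 50, size=3)
    return rot, trans


def apply_rigid_to_structure(structure, rot, trans):
    """Return a copy of the ensemble with every model rigidly moved."""
    from ectodimer.structure_io import EnsembleStructure

    models = []
    for tab in structure.models:
        tab = tab.copy()
        xyz = tab[["x", "y", "z"]].to_numpy(dtype=float)
        tab[["x", "y", "z"]] = xyz @ rot.T + trans
        models.append(tab)
    return EnsembleStructure(models, source_format=structure.source_format,
                             identifier=structure.identifier)
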