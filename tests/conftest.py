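import numpy as np
import pytest

from g4kit.structure_io import AtomRecord, StructureEnsemble
from g4kit.synthetic import BuilderSpec, build_quadruplex


@pytest.fixture(scope="session")
def default_structure() -> StructureEnsemble:
    """Idealized 4 G-quartet + C-quartet monomer at the default geometry."""
    return build_quadruplex(BuilderSpec())


@pytest.fixture(scope="session")
def dimer_structure() -> StructureEnsemble:
    """5'-5' stacked dimer with ions at O5, I and the interface site."""
    return build_quadruplex(
        BuilderSpec(n_cores=2, ions=(("O5", "K"), ("I", "K"), ("OGG", "K")))
    )


def transform_ensemble(ens: StructureEnsemble, rotation: np.ndarray, translation: np.ndarray,
                       model: int | None = None) -> StructureEnsemble:
    """Rigidly transform one model (or all) of an ensemble."""
    models = []
    for mi, atoms in enumerate(ens.models):
        if model is not None and mi != model:
            models.append(list(atoms))
            continue
        new = []
        for a in atoms:
            xyz = rotation @ np.array(a.xyz) + translation
            new.append(AtomRecord(a.serial, a.name, a.element, a.res_name,
                                  a.res_seq, a.chain_id, tuple(xyz), a.model_index, a.het))
        models.append(new)
    return StructureEnsemble(models=models, metadata=ens.metadata)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()
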