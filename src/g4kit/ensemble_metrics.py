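"""Optimal superposition and pairwise RMSD over an NMR-style ensemble.

The pairwise ensemble statistic is the mean, over all unordered model
pairs, of the heavy-atom RMSD after least-squares rigid superposition of
each pair (proper rotations only).  The per-pair values are also returned
so the mean-over-pairs reading can be distinguished from an
RMSD-to-mean-structure reading.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Selection, StructureEnsemble, select

__all__ = ["SuperpositionResult", "PairwiseRMSD", "superpose", "pairwise_rmsd"]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation: x' = R @ x + t
    rmsd: float

    def __post_init__(self) -> None:
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Solves the orthogonal Procrustes problem restricted to proper
    rotations (Kabsch); returns the transform and the post-fit RMSD.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    rmsd = float(rssd / np.sqrt(n))
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


@dataclass(frozen=True)
class PairwiseRMSD:
    mean: float
    pairs: tuple[tuple[int, int, float], ...]  # (model_i, model_j, rmsd), 0-based

    @property
    def to_mean_structure(self) -> float:
        """Alternative reading: mean RMSD of each model to the coordinate
        average of all superposed models (first model as reference frame)."""
        return self._to_mean

    _to_mean: float = float("nan")


def pairwise_rmsd(
    ensemble: StructureEnsemble,
    selection: Selection | str | None = None,
    heavy_only: bool = True,
) -> PairwiseRMSD:
    """Mean pairwise RMSD over all C(M, 2) model pairs of an ensemble.

    The selection (plus an implicit heavy-atom filter unless disabled) is
    applied to every model; each pair is independently superposed before
    its RMSD is recorded.
    """
    sub = ensemble if selection is None else select(ensemble, selection)
    if heavy_only:
        sub = select(sub, Selection(heavy_only=True))
    if sub.n_atoms == 0:
        raise ValueError("selection matched no atoms")
    if sub.n_models < 2:
        raise ValueError("pairwise RMSD needs at least two models")
    coords = [sub.coords(i) for i in range(sub.n_models)]
    pairs = []
    for i, j in itertools.combinations(range(sub.n_models), 2):
        pairs.append((i, j, superpose(coords[i], coords[j]).rmsd))
    mean = float(np.mean([p[2] for p in pairs]))

    # companion statistic: RMSD to the mean structure after superposing
    # everything onto model 0
    aligned = [coords[0]]
    for c in coords[1:]:
        aligned.append(superpose(coords[0], c).apply(c))
    stack = np.array(aligned)
    mean_struct = stack.mean(axis=0)
    to_mean = float(
        np.mean([np.sqrt(np.mean(np.sum((c - mean_struct) ** 2, axis=1))) for c in stack])
    )
    result = PairwiseRMSD(mean=mean, pairs=tuple(pairs))
    object.__setattr__(result, "_to_mean", to_mean)
    return result
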