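"""Rigid-body least-squares superposition (Kabsch) and ensemble fitting.

The overlap analysis compares apo-protein conformers against the RNA pose of
a bound reference complex, so every frame must first be placed in the
reference coordinate system. Fitting is ordinary Kabsch: the proper rotation
and translation minimising the RMSD between paired point sets, with the
standard reflection guard (sign flip of the smallest singular pair when the
determinant would be −1). Atoms correspond across structures by
(chain, residue key, atom name); no sequence alignment is attempted because
ensemble and reference derive from the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, DegenerateGeometryError
from .structure_io import Ensemble, Selection, Structure, BACKBONE, resolve_selection

__all__ = ["RigidTransform", "FitReport", "kabsch", "fit_ensemble"]


@dataclass
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3×3 and translation a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class FitReport:
    """Per-frame RMSD (Å) before and after fitting, on the fit selection."""

    frame_ids: list[str]
    rmsd_before: np.ndarray
    rmsd_after: np.ndarray
    selection: Selection = field(default_factory=Selection)

    def __post_init__(self):
        self.rmsd_before = np.asarray(self.rmsd_before, dtype=float)
        self.rmsd_after = np.asarray(self.rmsd_after, dtype=float)
        if np.any(self.rmsd_after > self.rmsd_before + 1e-9):
            raise ValueError("after-fit RMSD exceeds before-fit RMSD")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_id": self.frame_ids,
            "rmsd_before_A": self.rmsd_before,
            "rmsd_after_A": self.rmsd_after,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(ref_coords: np.ndarray, mob_coords: np.ndarray
           ) -> tuple[RigidTransform, float]:
    """Optimal proper rotation + translation mapping mobile onto reference.

    Returns the transform and the minimised RMSD in Å. Raises
    :class:`DegenerateGeometryError` for fewer than three points or a
    collinear point cloud (rotation underdetermined).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mob_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must both be M×3")
    if ref.shape[0] < 3:
        raise DegenerateGeometryError("Kabsch needs at least 3 paired points")
    cr = ref.mean(axis=0)
    cm = mob.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    scale = max(s[0], np.ptp(ref, axis=0).max(), 1.0)
    if s[1] <= 1e-10 * scale:
        raise DegenerateGeometryError(
            "point cloud is (near-)collinear; rotation is underdetermined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = cr - rot @ cm
    transform = RigidTransform(rot, trans)
    return transform, _rmsd(transform.apply(mob), ref)


def fit_ensemble(ens: Ensemble, reference: Structure,
                 sel: Selection = BACKBONE) -> tuple[Ensemble, FitReport]:
    """Superpose every frame of ``ens`` onto ``reference``.

    The Kabsch fit is computed on the atoms ``sel`` selects in the
    reference, matched into the ensemble topology by
    (chain, residue key, atom name); the per-frame transform then moves all
    atoms of the frame. Unmatched selected atoms raise
    :class:`CorrespondenceError` listing the missing atoms.
    """
    ref_idx = resolve_selection(reference, sel)
    if len(ref_idx) < 3:
        raise DegenerateGeometryError(
            f"fit selection resolves to {len(ref_idx)} reference atoms; need ≥ 3"
        )
    topo_index = {a.atom_key: i for i, a in enumerate(ens.topology.atoms)}
    mob_idx, missing = [], []
    for i in ref_idx:
        key = reference.atoms[i].atom_key
        if key in topo_index:
            mob_idx.append(topo_index[key])
        else:
            missing.append(key)
    if missing:
        raise CorrespondenceError(
            f"{len(missing)} selected reference atoms have no counterpart in the "
            f"ensemble topology (e.g. {missing[:5]})", missing=missing)

    ref_sel = reference.coords[ref_idx]
    fitted = np.empty_like(ens.frames)
    before = np.empty(ens.n_frames)
    after = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        frame = ens.frames[f]
        before[f] = _rmsd(frame[mob_idx], ref_sel)
        transform, after[f] = kabsch(ref_sel, frame[mob_idx])
        fitted[f] = transform.apply(frame)

    topo = ens.topology.copy()
    topo.coords = fitted[0]
    out = Ensemble(topo, fitted, frame_ids=list(ens.frame_ids),
                   label=ens.label, fitted=True)
    return out, FitReport(list(ens.frame_ids), before, after, selection=sel)
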