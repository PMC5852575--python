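"""Per-residue RMSF and geometric hydrogen-bond statistics over ensembles.

RMSF
----
RMSF_i = sqrt( mean_f |x_{i,f} − x̄_i|² ) with x̄_i the time-mean position
of atom i, computed after rigid-body fitting. By default the reference is
the ensemble's own time-mean structure, refined with one fit-to-mean pass
(fit frames to the raw mean, recompute the mean, measure fluctuations).
Per-residue values aggregate atoms by root-mean-square, so they remain
RMS displacements rather than averages of RMS displacements.

Hydrogen bonds
--------------
A geometric criterion in the GROMACS convention: donor–acceptor distance
≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30° (both configurable).
Donors and acceptors are N/O atoms by default; donor hydrogens are found by
covalent distance (≤ 1.25 Å), since multi-model PDB ensembles rarely carry
CONECT records. Structures without hydrogens fall back to the
distance-only criterion, and the output is flagged accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InsufficientFramesError, UsageError
from .structure_io import Ensemble, Selection, Structure, resolve_selection
from .superpose import kabsch

logger = logging.getLogger(__name__)

__all__ = [
    "RMSFProfile",
    "HBondCriteria",
    "HBond",
    "HBondSeries",
    "rmsf",
    "detect_hbonds",
    "hbond_time_average",
]


@dataclass
class RMSFProfile:
    """RMSF values (Å) keyed by residue or by atom."""

    keys: list
    values: np.ndarray
    per_residue: bool
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSF values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        key_col = "residue" if self.per_residue else "atom"
        return pd.DataFrame({
            key_col: ["/".join(map(str, k)) if isinstance(k, tuple) else k
                      for k in self.keys],
            "rmsf_A": self.values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _fit_to_mean(frames: np.ndarray, idx: list[int]) -> np.ndarray:
    """One fit-to-mean refinement pass on the selected atom indices."""
    mean = frames.mean(axis=0)
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        transform, _ = kabsch(mean[idx], frames[f][idx])
        out[f] = transform.apply(frames[f])
    return out


def rmsf(ens: Ensemble, sel: Selection | None = None, *,
         per_residue: bool = True,
         fit_selection: Selection | None = None) -> RMSFProfile:
    """Root-mean-square fluctuation about the time-mean position.

    ``fit_selection`` triggers one fit-to-mean pass before measuring; omit
    it for ensembles already placed in a common frame. ``sel`` restricts
    which atoms are reported (default: all).
    """
    if ens.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    frames = ens.frames
    if fit_selection is not None:
        fit_idx = resolve_selection(ens.topology, fit_selection)
        if len(fit_idx) < 3:
            raise UsageError("fit selection must resolve to ≥ 3 atoms")
        frames = _fit_to_mean(frames, fit_idx)
    sel = sel or Selection()
    idx = resolve_selection(ens.topology, sel)
    if not idx:
        raise UsageError("selection resolves to no atoms")
    mean = frames[:, idx].mean(axis=0)
    msf = np.mean(np.sum((frames[:, idx] - mean) ** 2, axis=2), axis=0)

    meta = {"fitted": fit_selection is not None, "n_frames": ens.n_frames}
    if not per_residue:
        keys = [ens.topology.atoms[i].atom_key for i in idx]
        return RMSFProfile(keys, np.sqrt(msf), per_residue=False, metadata=meta)
    groups: dict[tuple, list[int]] = {}
    for pos, i in enumerate(idx):
        groups.setdefault(ens.topology.atoms[i].residue_key, []).append(pos)
    keys = list(groups)
    vals = np.array([np.sqrt(np.mean(msf[g])) for g in groups.values()])
    return RMSFProfile(keys, vals, per_residue=True, metadata=meta)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond cutoffs (GROMACS-style defaults)."""

    max_da_distance: float = 3.5   # donor–acceptor, Å
    max_hda_angle: float = 30.0    # hydrogen–donor–acceptor, degrees
    donor_elements: frozenset[str] = frozenset({"N", "O"})
    acceptor_elements: frozenset[str] = frozenset({"N", "O"})
    allow_heavy_only: bool = True  # distance-only fallback without hydrogens
    covalent_h_cutoff: float = 1.25  # H attached to donor if within this, Å

    def __post_init__(self):
        if not 0 < self.max_da_distance < 10:
            raise ValueError("max_da_distance must lie in (0, 10) Å")
        if not 0 < self.max_hda_angle < 90:
            raise ValueError("max_hda_angle must lie in (0, 90) degrees")


class HBond(NamedTuple):
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None


def detect_hbonds(structure: Structure, donors_sel: Selection,
                  acceptors_sel: Selection,
                  criteria: HBondCriteria | None = None,
                  coords: np.ndarray | None = None) -> list[HBond]:
    """Geometric hydrogen bonds between two disjoint selections, one frame.

    A bond is recorded when the donor–acceptor distance is within the
    cutoff and, when the donor carries hydrogens, at least one H gives an
    H–D–A angle within the cutoff (the best H is reported). Structures
    without any hydrogen fall back to the distance-only criterion when
    ``criteria.allow_heavy_only``; those bonds carry ``hydrogen=None``.
    """
    criteria = criteria or HBondCriteria()
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    donor_idx = [i for i in resolve_selection(structure, donors_sel)
                 if structure.atoms[i].element.upper() in criteria.donor_elements]
    acc_idx = [i for i in resolve_selection(structure, acceptors_sel)
               if structure.atoms[i].element.upper() in criteria.acceptor_elements]
    if not donor_idx or not acc_idx:
        raise UsageError("donor and acceptor selections must both resolve to "
                         "polar (N/O) atoms")

    h_idx = [i for i, a in enumerate(structure.atoms) if a.element.upper() == "H"]
    have_h = bool(h_idx)
    if not have_h:
        if not criteria.allow_heavy_only:
            raise UsageError("structure has no hydrogens and heavy-atom-only "
                             "mode is disabled")
        logger.warning("no hydrogens present; falling back to the "
                       "distance-only hydrogen-bond criterion")

    attached: dict[int, list[int]] = {}
    if have_h:
        h_tree = cKDTree(xyz[h_idx])
        for d in donor_idx:
            near = h_tree.query_ball_point(xyz[d], criteria.covalent_h_cutoff)
            attached[d] = [h_idx[k] for k in near]

    acc_tree = cKDTree(xyz[acc_idx])
    bonds: list[HBond] = []
    for d in donor_idx:
        if have_h and not attached.get(d):
            continue  # a polar atom with no bonded H cannot donate
        for k in acc_tree.query_ball_point(xyz[d], criteria.max_da_distance):
            a = acc_idx[k]
            if a == d:
                continue
            dist = float(np.linalg.norm(xyz[a] - xyz[d]))
            if not have_h:
                bonds.append(HBond(d, None, a, dist, None))
                continue
            best_h, best_angle = None, None
            for h in attached[d]:
                dh = xyz[h] - xyz[d]
                da = xyz[a] - xyz[d]
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if best_angle is None or angle < best_angle:
                    best_h, best_angle = h, angle
            if best_angle is not None and best_angle <= criteria.max_hda_angle:
                bonds.append(HBond(d, best_h, a, dist, best_angle))
    return bonds


@dataclass
class HBondSeries:
    """Per-frame bond records plus per-residue time-averaged counts."""

    frame_ids: list[str]
    records: pd.DataFrame          # columns: frame_id, donor, hydrogen, acceptor
    residue_means: dict            # residue key → mean bonds per frame
    heavy_atom_only: bool
    criteria: HBondCriteria

    def to_long_csv(self, path) -> None:
        self.records.to_csv(Path(path), index=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": ["/".join(map(str, k)) if isinstance(k, tuple) else k
                        for k in self.residue_means],
            "mean_hbonds_per_frame": list(self.residue_means.values()),
        })

    def to_summary_csv(self, path) -> None:
        self.summary_frame().to_csv(Path(path), index=False)


def _normalise_residue(topology: Structure, residue) -> tuple[str, str]:
    """Accept an int res_id or a (chain, res_id) pair; validate presence."""
    keys = {a.residue_key for a in topology.atoms}
    if isinstance(residue, tuple):
        key = (str(residue[0]), str(residue[1]))
    else:
        matches = sorted({k for k in keys if k[1] == str(residue)})
        if not matches:
            raise KeyError(f"residue {residue!r} not present in topology")
        if len(matches) > 1:
            raise KeyError(f"residue {residue!r} is ambiguous across chains "
                           f"{[m[0] for m in matches]}; pass (chain, res_id)")
        return matches[0]
    if key not in keys:
        raise KeyError(f"residue {residue!r} not present in topology")
    return key


def hbond_time_average(ens: Ensemble, residue_list: Iterable,
                       rna_sel: Selection,
                       criteria: HBondCriteria | None = None) -> HBondSeries:
    """Mean hydrogen-bond count per frame between listed residues and RNA.

    Counts bonds in both donation directions (residue→RNA and RNA→residue).
    A residue whose atoms include no polar N/O contributes 0.00 in every
    frame. Unknown residues raise ``KeyError`` naming the residue.
    """
    criteria = criteria or HBondCriteria()
    topo = ens.topology
    res_keys = [_normalise_residue(topo, r) for r in residue_list]
    rna_idx = set(resolve_selection(topo, rna_sel))
    if not rna_idx:
        raise UsageError("RNA selection resolves to no atoms")
    all_sel = Selection()
    counts = {key: np.zeros(ens.n_frames) for key in res_keys}
    rows = []
    for f in range(ens.n_frames):
        bonds: list[HBond] = []
        # both donation directions: residue→RNA and RNA→residue
        for donors, acceptors in ((all_sel, rna_sel), (rna_sel, all_sel)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    bonds.extend(detect_hbonds(topo, donors, acceptors,
                                               criteria, coords=ens.frames[f]))
                except UsageError:
                    pass
        seen = set()
        for bond in bonds:
            # heavy-only bonds are undirected: dedupe by atom pair; with an
            # explicit hydrogen the D-H-A triplet is the bond's identity
            dedupe = (frozenset((bond.donor, bond.acceptor))
                      if bond.hydrogen is None
                      else (bond.donor, bond.hydrogen, bond.acceptor))
            if dedupe in seen:
                continue
            seen.add(dedupe)
            d_at, a_at = topo.atoms[bond.donor], topo.atoms[bond.acceptor]
            donor_in_rna = bond.donor in rna_idx
            acc_in_rna = bond.acceptor in rna_idx
            if donor_in_rna == acc_in_rna:
                continue  # need exactly one side on the RNA
            res_side = a_at if donor_in_rna else d_at
            key = res_side.residue_key
            if key in counts:
                counts[key][f] += 1
                rows.append({
                    "frame_id": ens.frame_ids[f],
                    "donor": "/".join(d_at.atom_key),
                    "hydrogen": ("" if bond.hydrogen is None
                                 else "/".join(topo.atoms[bond.hydrogen].atom_key)),
                    "acceptor": "/".join(a_at.atom_key),
                })
    records = pd.DataFrame(rows, columns=["frame_id", "donor", "hydrogen",
                                          "acceptor"])
    heavy_only = not any(a.element.upper() == "H" for a in topo.atoms)
    means = {key: float(c.mean()) for key, c in counts.items()}
    return HBondSeries(list(ens.frame_ids), records, means,
                       heavy_atom_only=heavy_only, criteria=criteria)
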