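"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without downloading any
structure: harmonic (Gaussian) conformational ensembles with prescribed
per-atom amplitudes, a matched pair of protein variants in which one
carries an extra atom loop near a pseudo-RNA chain (emulating a splice
isoform with ten additional residues adjacent to the RNA-binding site),
exact donor–H–acceptor geometries for hydrogen-bond tests, and peak-area
tables with known ground-truth editing fractions.

All generators are pure functions of their spec, seed included: the same
spec yields bit-identical output. Harmonic fluctuations are the simplest
ensemble model with a closed-form RMSF (per-atom RMSF = √3·σ for isotropic
per-axis σ), enabling exact parameter-recovery tests; real MD ensembles
are anharmonic, and that simplification is deliberate and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .structure_io import Atom, Ensemble, Structure, build_structure

__all__ = [
    "HarmonicEnsembleSpec",
    "VariantPairSpec",
    "make_harmonic_ensemble",
    "make_variant_pair",
    "make_reference_complex",
    "make_hbond_fixture",
    "make_area_table",
]


@dataclass
class HarmonicEnsembleSpec:
    """Gaussian-fluctuation ensemble around a fixed mean structure.

    ``sigma`` is the isotropic per-axis standard deviation in Å, scalar or
    per-atom array; no net rotation or translation is injected, so the
    frames are already in a common reference frame.
    """

    mean: Structure
    sigma: float | np.ndarray = 0.5
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self):
        sig = np.asarray(self.sigma, dtype=float)
        if np.any(sig < 0):
            raise DomainError("sigma must be non-negative")
        if self.n_frames < 1:
            raise DomainError("n_frames must be ≥ 1")


def make_harmonic_ensemble(spec: HarmonicEnsembleSpec) -> Ensemble:
    """Frames x_{f,i} = mean_i + ε, ε ~ iid N(0, σ_i²) per axis."""
    mean = spec.mean.coords
    n = mean.shape[0]
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (n,))
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(size=(spec.n_frames, n, 3)) * sigma[None, :, None]
    return Ensemble(spec.mean.copy(), mean[None] + noise,
                    label=spec.mean.label or "harmonic")


@dataclass
class VariantPairSpec:
    """Matched variant pair sharing a core, one carrying an extra loop.

    The core is a compact lattice of Cα pseudo-atoms; the pseudo-RNA is a
    rigid chain of phosphorus spheres at ``rna_offset`` Å from the core
    centre. Variant B adds ``loop_atoms`` carbon atoms placed
    ``loop_offset`` Å from the pseudo-RNA centroid on the protein side, so
    B's expected overlap exceeds A's whenever the offset is below the
    contact distance (r_C + r_P = 3.5 Å with Bondi radii). ``rna_atoms``
    defaults to an odd count so the chain centroid coincides with its
    central atom and the offset is a true centre-to-atom distance.
    """

    core_atoms: int = 60
    rna_atoms: int = 21
    rna_offset: float = 9.0      # Å, core centre → RNA axis
    rna_spacing: float = 5.0     # Å between successive pseudo-RNA atoms
    loop_atoms: int = 10         # emulates the ten extra isoform residues
    loop_offset: float = 3.0     # Å, loop atom → pseudo-RNA centroid
    sigma: float = 0.3           # Å, harmonic per-axis fluctuation
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.loop_atoms < 0:
            raise DomainError("loop_atoms must be ≥ 0")
        if self.core_atoms < 4 or self.rna_atoms < 1:
            raise DomainError("core needs ≥ 4 atoms and RNA ≥ 1")
        if self.n_frames < 1 or self.sigma < 0:
            raise DomainError("n_frames ≥ 1 and sigma ≥ 0 required")


# First core residue number; the loop continues after the last core residue,
# mirroring an isoform whose insertion follows the final shared residue.
_CORE_FIRST_RES = 406


def _core_coords(spec: VariantPairSpec) -> np.ndarray:
    """Compact cubic lattice (3.8 Å pitch) centred on the origin."""
    side = int(np.ceil(spec.core_atoms ** (1.0 / 3.0)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
                if len(pts) == spec.core_atoms:
                    break
            if len(pts) == spec.core_atoms:
                break
        if len(pts) == spec.core_atoms:
            break
    pts = np.asarray(pts, dtype=float) * 3.8
    return pts - pts.mean(axis=0)


def _rna_structure(spec: VariantPairSpec) -> Structure:
    n = spec.rna_atoms
    xs = (np.arange(n) - (n - 1) / 2.0) * spec.rna_spacing
    coords = np.column_stack([xs, np.full(n, spec.rna_offset), np.zeros(n)])
    return build_structure(
        coords, names="P", elements="P", res_names="U", chain="R",
        res_ids=range(1, n + 1), label="pseudo_rna",
    )


def _loop_coords(spec: VariantPairSpec, rna_centroid: np.ndarray) -> np.ndarray:
    """Loop atoms on a narrow cone around the protein-facing direction,
    each ``loop_offset`` Å from the pseudo-RNA centroid."""
    coords = []
    for k in range(spec.loop_atoms):
        theta = 2.0 * np.pi * k / max(spec.loop_atoms, 1)
        direction = np.array([0.15 * np.sin(theta), -1.0, 0.15 * np.cos(theta)])
        direction /= np.linalg.norm(direction)
        coords.append(rna_centroid + spec.loop_offset * direction)
    return np.asarray(coords)


def _variant_structure(spec: VariantPairSpec, with_loop: bool,
                       label: str) -> Structure:
    core = _core_coords(spec)
    res_ids = list(range(_CORE_FIRST_RES, _CORE_FIRST_RES + spec.core_atoms))
    coords = core
    if with_loop and spec.loop_atoms > 0:
        rna_centroid = _rna_structure(spec).coords.mean(axis=0)
        coords = np.vstack([core, _loop_coords(spec, rna_centroid)])
        res_ids += list(range(res_ids[-1] + 1, res_ids[-1] + 1 + spec.loop_atoms))
    return build_structure(coords, names="CA", elements="C", res_names="GLY",
                           chain="A", res_ids=res_ids, label=label)


def make_variant_pair(spec: VariantPairSpec | None = None
                      ) -> tuple[Ensemble, Ensemble, Structure]:
    """(ensemble A, ensemble B, pseudo-RNA structure).

    A and B share the core; B additionally carries the loop. Both are
    harmonically fluctuated with the same σ but independent, seed-derived
    noise streams. ``loop_atoms=0`` makes the two statistically identical
    (the exact null used for false-positive control).
    """
    spec = spec or VariantPairSpec()
    seed_a, seed_b = np.random.SeedSequence(spec.seed).spawn(2)
    mean_a = _variant_structure(spec, with_loop=False, label="variant_a")
    mean_b = _variant_structure(spec, with_loop=True, label="variant_b")
    ens_a = make_harmonic_ensemble(HarmonicEnsembleSpec(
        mean_a, sigma=spec.sigma, n_frames=spec.n_frames, seed=seed_a))
    ens_b = make_harmonic_ensemble(HarmonicEnsembleSpec(
        mean_b, sigma=spec.sigma, n_frames=spec.n_frames, seed=seed_b))
    return ens_a, ens_b, _rna_structure(spec)


def make_reference_complex(spec: VariantPairSpec | None = None) -> Structure:
    """Reference protein–RNA complex: the shared core mean plus the
    pseudo-RNA chain, in one structure (chains A and R).

    Only core atoms appear on the protein side, so the same reference fits
    both variants (the loop has no counterpart in the reference, exactly as
    an inserted-isoform loop has none in a shared template).
    """
    spec = spec or VariantPairSpec()
    core = _variant_structure(spec, with_loop=False, label="reference")
    rna = _rna_structure(spec)
    atoms = [*(a for a in core.copy().atoms), *(a for a in rna.copy().atoms)]
    for serial, atom in enumerate(atoms, 1):
        atom.serial = serial
    return Structure(atoms, label="reference_complex")


def make_hbond_fixture(distance: float, angle: float) -> Structure:
    """Minimal donor(N)–H···acceptor(O) geometry across two chains.

    The donor nitrogen sits at the origin (chain A), the acceptor oxygen at
    ``distance`` Å along +x (chain R), and the hydrogen 1.0 Å from the
    donor so that the H–donor–acceptor angle equals ``angle`` degrees.
    """
    if distance <= 1.0:
        raise DomainError("donor–acceptor distance must exceed 1.0 Å")
    if not 0 <= angle <= 90:
        raise DomainError("H–D–A angle must lie in [0, 90] degrees")
    theta = np.radians(angle)
    atoms = [
        Atom(serial=1, name="N", element="N", res_name="GLY", res_id=1,
             chain="A", coords=np.zeros(3)),
        Atom(serial=2, name="H", element="H", res_name="GLY", res_id=1,
             chain="A", coords=np.array([np.cos(theta), np.sin(theta), 0.0])),
        Atom(serial=3, name="O2'", element="O", res_name="U", res_id=1,
             chain="R", coords=np.array([distance, 0.0, 0.0])),
    ]
    return Structure(atoms, label=f"hbond_d{distance}_a{angle}")


def make_area_table(true_fraction: float, n_sites: int = 10,
                    noise_sd: float = 0.0, seed: int = 0,
                    group: str = "synthetic",
                    total_area: float = 1000.0) -> pd.DataFrame:
    """Peak-area table whose expected editing level is 100·true_fraction.

    Per-site edited fractions are true_fraction + N(0, noise_sd²), clipped
    to [0, 1] (negligible bias for the small noise levels used here); the
    A and G areas split ``total_area`` accordingly.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise DomainError("true_fraction must lie in [0, 1]")
    if noise_sd < 0 or n_sites < 1:
        raise DomainError("noise_sd ≥ 0 and n_sites ≥ 1 required")
    rng = np.random.default_rng(seed)
    frac = np.clip(true_fraction + rng.normal(0.0, noise_sd, size=n_sites)
                   if noise_sd > 0 else np.full(n_sites, true_fraction),
                   0.0, 1.0)
    return pd.DataFrame({
        "site": [f"site_{i + 1:03d}" for i in range(n_sites)],
        "group": group,
        "area_A": total_area * (1.0 - frac),
        "area_G": total_area * frac,
    })
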