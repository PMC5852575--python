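"""End-to-end orchestration: fit → overlap series → distributions → shift
report, plus RMSF and hydrogen-bond tables, from a single validated config.

Every run writes the resolved configuration next to its outputs and logs
atom counts, selections and radius provenance, so a result can always be
traced back to its inputs. Given the same config and seed, reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ensemble_stats, occlusion
from .errors import UsageError
from .structure_io import (
    BACKBONE,
    Ensemble,
    RadiusTable,
    Selection,
    Structure,
    read_pdb,
)
from .superpose import fit_ensemble

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "selection_from_dict", "selection_to_dict",
           "run_occlusion_analysis", "run_stats"]


def selection_from_dict(d: dict | None) -> Selection:
    """Build a Selection from a config mapping (all keys optional)."""
    if not d:
        return Selection()
    known = {"chains", "res_range", "atom_names", "elements", "res_names"}
    unknown = set(d) - known
    if unknown:
        raise UsageError(f"unknown selection keys: {sorted(unknown)}")
    res_range = d.get("res_range")
    if res_range is not None:
        res_range = (res_range[0], res_range[1])
    return Selection(
        chains=frozenset(d["chains"]) if d.get("chains") else None,
        res_range=res_range,
        atom_names=frozenset(d["atom_names"]) if d.get("atom_names") else None,
        elements=frozenset(d["elements"]) if d.get("elements") else None,
        res_names=frozenset(d["res_names"]) if d.get("res_names") else None,
    )


def selection_to_dict(sel: Selection) -> dict:
    out = {}
    if sel.chains is not None:
        out["chains"] = sorted(sel.chains)
    if sel.res_range is not None:
        out["res_range"] = list(sel.res_range)
    if sel.atom_names is not None:
        out["atom_names"] = sorted(sel.atom_names)
    if sel.elements is not None:
        out["elements"] = sorted(sel.elements)
    if sel.res_names is not None:
        out["res_names"] = sorted(sel.res_names)
    return out


@dataclass
class RunConfig:
    """Validated inputs for a full analysis run.

    ``ensembles`` maps variant name → multi-model PDB path; ``reference``
    is the single-model protein–RNA complex the frames are fitted onto.
    """

    reference: str
    ensembles: dict[str, str]
    outdir: str
    fit_selection: Selection = BACKBONE
    protein_selection: Selection = field(default_factory=lambda: Selection(chains={"A"}))
    rna_selection: Selection = field(default_factory=lambda: Selection(chains={"R"}))
    radius_table: str = "bondi"          # 'bondi' or a CSV path
    include_zinc: bool = False
    include_hydrogens: bool = True
    binning: str | int = "fd"
    hbond_criteria: ensemble_stats.HBondCriteria = field(
        default_factory=ensemble_stats.HBondCriteria)
    hbond_residues: list = field(default_factory=list)
    seed: int = 0
    plot: bool = False

    def __post_init__(self):
        if not self.ensembles:
            raise UsageError("at least one variant ensemble is required")
        if not isinstance(self.seed, int):
            raise UsageError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        hb = raw.get("hbond_criteria") or {}
        return cls(
            reference=raw["reference"],
            ensembles=dict(raw["ensembles"]),
            outdir=raw.get("outdir", "results"),
            fit_selection=(selection_from_dict(raw["fit_selection"])
                           if raw.get("fit_selection") else BACKBONE),
            protein_selection=selection_from_dict(raw.get("protein_selection")),
            rna_selection=selection_from_dict(
                raw.get("rna_selection") or {"chains": ["R"]}),
            radius_table=raw.get("radius_table", "bondi"),
            include_zinc=bool(raw.get("include_zinc", False)),
            include_hydrogens=bool(raw.get("include_hydrogens", True)),
            binning=raw.get("binning", "fd"),
            hbond_criteria=ensemble_stats.HBondCriteria(**hb),
            hbond_residues=list(raw.get("hbond_residues", [])),
            seed=int(raw.get("seed", 0)),
            plot=bool(raw.get("plot", False)),
        )

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "ensembles": dict(sorted(self.ensembles.items())),
            "outdir": self.outdir,
            "fit_selection": selection_to_dict(self.fit_selection),
            "protein_selection": selection_to_dict(self.protein_selection),
            "rna_selection": selection_to_dict(self.rna_selection),
            "radius_table": self.radius_table,
            "include_zinc": self.include_zinc,
            "include_hydrogens": self.include_hydrogens,
            "binning": self.binning,
            "hbond_criteria": {
                "max_da_distance": self.hbond_criteria.max_da_distance,
                "max_hda_angle": self.hbond_criteria.max_hda_angle,
                "allow_heavy_only": self.hbond_criteria.allow_heavy_only,
            },
            "hbond_residues": list(self.hbond_residues),
            "seed": self.seed,
            "plot": self.plot,
        }

    def write_resolved(self, outdir: Path) -> None:
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    def load_radius_table(self) -> RadiusTable:
        if self.radius_table == "bondi":
            return RadiusTable.bondi()
        return RadiusTable.from_csv(self.radius_table)


def _load_reference(cfg: RunConfig) -> Structure:
    ref = read_pdb(cfg.reference)
    if isinstance(ref, Ensemble):
        logger.info("reference %s is multi-model; using the first model",
                    cfg.reference)
        ref = ref.topology
    return ref


def _load_ensemble(path: str) -> Ensemble:
    obj = read_pdb(path)
    if isinstance(obj, Structure):
        # a single-conformer file is a one-frame ensemble
        return Ensemble(obj, obj.coords[None], label=obj.label)
    return obj


class StageError(UsageError):
    """Wraps an error with the pipeline stage and file it occurred in."""


def _in_stage(stage: str, context: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed on {context}: {exc}") from exc


def run_occlusion_analysis(cfg: RunConfig) -> dict:
    """Fit each variant ensemble onto the reference, compute its overlap
    series and density distribution, and (with two variants) the shift
    report. Returns a dict of computed objects; files land in cfg.outdir.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cfg.load_radius_table()
    reference = _load_reference(cfg)
    logger.info("reference '%s': %d atoms; radius table '%s'",
                reference.label, len(reference), table.name)

    series: dict[str, occlusion.OverlapSeries] = {}
    results: dict = {"series": series, "distributions": {}}
    for name in sorted(cfg.ensembles):
        path = cfg.ensembles[name]
        ens = _in_stage("read", path, _load_ensemble, path)
        fitted, report = _in_stage("fit", path, fit_ensemble,
                                   ens, reference, cfg.fit_selection)
        report.to_csv(outdir / f"{name}_fit_report.csv")
        s = _in_stage(
            "overlap", path, occlusion.ensemble_overlap,
            fitted, reference,
            protein_sel=cfg.protein_selection,
            rna_sel=cfg.rna_selection,
            table=table,
            include_zinc=cfg.include_zinc,
            include_hydrogens=cfg.include_hydrogens,
        )
        logger.info("variant %s: %d frames, %d protein × %d RNA atoms, "
                    "mean overlap %.3f Å³", name, len(s),
                    s.metadata["n_protein_atoms"], s.metadata["n_rna_atoms"],
                    float(s.volumes.mean()))
        s.to_csv(outdir / f"{name}_overlap_series.csv")
        dist = occlusion.overlap_distribution(s, binning=cfg.binning)
        dist.to_csv(outdir / f"{name}_distribution.csv")
        dist.summary_json(outdir / f"{name}_distribution_summary.json")
        series[name] = s
        results["distributions"][name] = dist

    if len(series) == 2:
        (name_a, s_a), (name_b, s_b) = sorted(series.items())
        shift = occlusion.compare_distributions(s_a, s_b)
        payload = {"variant_a": name_a, "variant_b": name_b, **shift.to_dict()}
        (outdir / "shift_report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        results["shift"] = shift
        logger.info("shift %s vs %s: median diff %.3f Å³, p=%.3g (%s)",
                    name_b, name_a, shift.median_diff, shift.p_value,
                    shift.direction)

    if cfg.plot:
        _plot_distributions(results["distributions"],
                            outdir / "overlap_distributions.png")
    cfg.write_resolved(outdir)
    return results


def _plot_distributions(dists: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, dist in sorted(dists.items()):
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        ax.plot(centers, dist.density, drawstyle="steps-mid", label=name)
    ax.set_xlabel("overlap volume (Å³)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_stats(cfg: RunConfig) -> dict:
    """Per-variant RMSF profiles and, when residues are configured, the
    residue × variant hydrogen-bond time-average table."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = _load_reference(cfg)
    results: dict = {"rmsf": {}, "hbonds": {}}
    hbond_columns = {}
    for name in sorted(cfg.ensembles):
        ens = _load_ensemble(cfg.ensembles[name])
        if ens.n_frames >= 2:
            profile = ensemble_stats.rmsf(
                ens, cfg.protein_selection,
                per_residue=True, fit_selection=cfg.fit_selection)
            profile.to_csv(outdir / f"{name}_rmsf.csv")
            results["rmsf"][name] = profile
        if cfg.hbond_residues:
            fitted, _ = fit_ensemble(ens, reference, cfg.fit_selection)
            # H-bond analysis needs the RNA in the frame: splice it in as a
            # static chain at the reference pose
            combined = _with_static_rna(fitted, reference, cfg.rna_selection)
            hb = ensemble_stats.hbond_time_average(
                combined, cfg.hbond_residues, cfg.rna_selection,
                cfg.hbond_criteria)
            results["hbonds"][name] = hb
            hbond_columns[name] = hb.residue_means
    if hbond_columns:
        import pandas as pd

        residues = list(next(iter(hbond_columns.values())).keys())
        data = {"residue": ["/".join(map(str, r)) for r in residues]}
        for name in sorted(hbond_columns):
            data[name] = [hbond_columns[name][r] for r in residues]
        pd.DataFrame(data).to_csv(outdir / "hbond_summary.csv", index=False)
    cfg.write_resolved(outdir)
    return results


def _with_static_rna(ens: Ensemble, reference: Structure,
                     rna_sel: Selection) -> Ensemble:
    """Append the reference RNA atoms, held fixed, to every frame."""
    import numpy as np

    from .structure_io import resolve_selection

    rna_idx = resolve_selection(reference, rna_sel)
    if not rna_idx:
        raise UsageError("RNA selection resolves to no atoms on the reference")
    rna = reference.subset(rna_idx)
    atoms = [*(a for a in ens.topology.copy().atoms),
             *(a for a in rna.copy().atoms)]
    for serial, atom in enumerate(atoms, 1):
        atom.serial = serial
    topo = Structure(atoms, label=ens.label)
    rna_coords = rna.coords[None].repeat(ens.n_frames, axis=0)
    frames = np.concatenate([ens.frames, rna_coords], axis=1)
    return Ensemble(topo, frames, frame_ids=list(ens.frame_ids),
                    label=ens.label, fitted=ens.fitted)
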