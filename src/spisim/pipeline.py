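"""Experiment orchestration: water-layer / damage condition scans.

Reproduces the study design at configurable scale: for each water-layer
thickness (and optionally with the damage stand-in enabled), simulate a
photon-sparse dataset, run several independent EMC reconstructions, align
them to the ground-truth volume, and aggregate the shell R-factor and
self-orientation-disconcurrence into a report.

The ``desk`` preset is sized for a single CPU (a small toy particle, a
31-pixel detector, ~10^3 patterns, rotation refinement capped at 4); the
``full`` preset mirrors the published conditions (81 x 81 detector, 20000
patterns per condition, num_div 16, 120 + 10 EMC iterations) and is
cluster-scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .diffraction import (
    DamagedVolumeModel,
    IntensityVolume,
    default_volume_grid,
    generate_dataset,
    ideal_intensity_volume,
)
from .emc import EMCConfig, run_emc
from .geometry import DetectorGeometry, build_pixel_map
from .metrics import (
    ODConfig,
    ShellSpec,
    align_to_reference,
    disconcurrence,
    shell_r_factor,
)
from .rotations import make_group, sample_rotations
from .scatter import (
    WaterShellSpec,
    add_water_shell,
    make_damage_trajectory,
    make_sase_pulse,
    make_toy_particle,
)

logger = logging.getLogger("spisim.pipeline")

__all__ = ["ExperimentPlan", "Report", "run_experiment", "make_figures", "desk_plan", "full_plan"]


@dataclass
class ExperimentPlan:
    """A condition scan over water-layer thickness, optionally with damage."""

    t_w_list: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 10.0, 20.0)
    damage: bool = False
    n_patterns: int = 1500
    n_sentinels: int = 100
    repeats: int = 3
    seed: int = 0
    scale: str = "desk"

    # sample
    n_atoms: int = 40
    extent_A: float = 30.0
    pdb_path: str | None = None

    # beam / detector / photon budget
    geometry: DetectorGeometry = field(
        default_factory=lambda: DetectorGeometry(
            n_fast=31, n_slow=31, pixel_size_um=1200.0,
            distance_mm=45.0, photon_energy_kev=4.96,
        )
    )
    mean_photons: float = 500.0
    background_fraction: float = 0.05

    # damage stand-in
    pulse_bins: int = 9
    pulse_fdhm_fs: float = 9.0
    expansion_rate: float = 0.25
    ionization_rate: float = 0.3

    emc: EMCConfig = field(
        default_factory=lambda: EMCConfig(
            beta_start=0.1, beta_factor=2.0, beta_period=4,
            num_div_start=2, num_div_cap=4,
            main_iterations=20, final_iterations=8,
        )
    )
    od_level: int = 4
    od_search_level: int = 2
    point_group: str = "C1"
    ground_truth_od: bool = False

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.n_sentinels < 1 or self.n_patterns < 1:
            raise ValueError("pattern counts must be >= 1")

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def desk_plan(**overrides) -> ExperimentPlan:
    """The single-CPU preset (defaults of ExperimentPlan)."""
    return replace(ExperimentPlan(), **overrides) if overrides else ExperimentPlan()


def full_plan(**overrides) -> ExperimentPlan:
    """The full-scale preset mirroring the published study (cluster-scale)."""
    plan = ExperimentPlan(
        n_patterns=20000,
        n_sentinels=500,
        repeats=3,
        scale="full",
        geometry=DetectorGeometry(),  # 81 x 81, 1200 um, 13 cm, 4.96 keV
        emc=EMCConfig(),  # beta 0.01 x1.5, num_div 5..16, 120 + 10 iterations
        od_level=6,
        od_search_level=3,
        point_group="C2",
        n_atoms=3000,
        extent_A=100.0,
    )
    return replace(plan, **overrides) if overrides else plan


@dataclass
class Report:
    """Aggregated per-condition metrics plus provenance."""

    conditions: list[dict]
    provenance: dict
    # central slices (sqrt intensity) of the last reconstruction and ground
    # truth per condition, kept for figures but not serialized to JSON
    slices: dict = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "provenance": self.provenance,
            "conditions": self.conditions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        cols = [
            "t_w", "damage", "delta_theta_mean", "delta_theta_sd",
            "R_A_mean", "R_A_sd", "R_B_mean", "R_B_sd", "R_C_mean", "R_C_sd",
            "align_corr_mean",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for c in self.conditions:
                fh.write(
                    "\t".join(
                        f"{c[k]:.6g}" if isinstance(c[k], float) else str(c[k])
                        for k in cols
                    )
                    + "\n"
                )

    @classmethod
    def from_json(cls, path) -> "Report":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(conditions=payload["conditions"], provenance=payload["provenance"])


def _condition_metrics(plan: ExperimentPlan, particle, t_w: float, pixmap,
                       edge: int, dq: float) -> tuple[dict, dict]:
    """Simulate, reconstruct (x repeats) and score one water-layer condition."""
    shell_seed = plan.seed * 7919 + int(round(10 * t_w)) + 1
    structure = add_water_shell(
        particle, WaterShellSpec(thickness_A=t_w, seed=shell_seed)
    )
    gt = ideal_intensity_volume(structure, edge, dq)

    if plan.damage:
        pulse = make_sase_pulse(plan.pulse_bins, plan.pulse_fdhm_fs, seed=plan.seed)
        traj = make_damage_trajectory(
            structure, pulse, plan.expansion_rate, plan.ionization_rate
        )
        model = DamagedVolumeModel.from_trajectory(gt, traj)
    else:
        model = gt

    recon_set = generate_dataset(
        model, plan.n_patterns, pixmap, plan.mean_photons, seed=plan.seed,
        background_fraction=plan.background_fraction,
        meta={"role": "reconstruction", "t_w": t_w, "damage": plan.damage},
    )
    sentinels = generate_dataset(
        model, plan.n_sentinels, pixmap, plan.mean_photons,
        seed=plan.seed + 104729,
        background_fraction=plan.background_fraction,
        meta={"role": "sentinel", "t_w": t_w, "damage": plan.damage},
    )

    odcfg = ODConfig(
        point_group=make_group(plan.point_group),
        level=plan.od_level,
        search_level=plan.od_search_level,
    )
    align_set = sample_rotations(3)
    dthetas, corrs = [], []
    regions = {"A": [], "B": [], "C": []}
    shell_curves = []
    last_slice = None
    for rep in range(plan.repeats):
        emc_cfg = replace(plan.emc, init_seed=plan.seed * 100 + rep)
        state = run_emc(recon_set, emc_cfg, pixmap)
        aligned, _, corr = align_to_reference(state.volume, gt, align_set)
        res = shell_r_factor(aligned, gt)
        od = disconcurrence(state.volume, None, sentinels, odcfg, pixmap)
        dthetas.append(od.delta_theta)
        corrs.append(corr)
        for k in regions:
            regions[k].append(res.region_means[k])
        shell_curves.append(res.r_values)
        last_slice = np.sqrt(np.maximum(aligned.central_slice(), 0.0))
        logger.info(
            "t_w=%.1f rep=%d corr=%.3f dtheta=%.4f", t_w, rep, corr, od.delta_theta
        )

    curves = np.array(shell_curves)
    cond = {
        "t_w": float(t_w),
        "damage": bool(plan.damage),
        "n_waters": int(structure.n_atoms - particle.n_atoms),
        "delta_theta": [float(x) for x in dthetas],
        "delta_theta_mean": float(np.mean(dthetas)),
        "delta_theta_sd": float(np.std(dthetas, ddof=0)),
        "align_corr_mean": float(np.mean(corrs)),
        "shell_q": [float(x) for x in res.shell_q],
        "shell_r_mean": [float(x) for x in np.nanmean(curves, axis=0)],
        "shell_r_sd": [float(x) for x in np.nanstd(curves, axis=0, ddof=0)],
    }
    for k in regions:
        cond[f"R_{k}_mean"] = float(np.mean(regions[k]))
        cond[f"R_{k}_sd"] = float(np.std(regions[k], ddof=0))
    if plan.ground_truth_od:
        od_gt = disconcurrence(gt, None, sentinels, odcfg, pixmap)
        cond["delta_theta_ground_truth"] = float(od_gt.delta_theta)
    slices = {
        "reconstruction": last_slice,
        "ground_truth": np.sqrt(np.maximum(gt.central_slice(), 0.0)),
        "dq": dq,
    }
    return cond, slices


def run_experiment(plan: ExperimentPlan) -> Report:
    """Execute the full condition scan and aggregate a Report.

    The report is a pure function of (plan, seeds); a failing condition is
    logged and skipped while the others continue.
    """
    if plan.pdb_path is not None:
        from .scatter import read_pdb

        particle = read_pdb(plan.pdb_path)
    else:
        particle = make_toy_particle(plan.n_atoms, plan.extent_A, seed=plan.seed)
    pixmap = build_pixel_map(plan.geometry)
    edge, dq = default_volume_grid(pixmap)
    if plan.emc.volume_edge is not None:
        edge = plan.emc.volume_edge
    if plan.emc.volume_dq is not None:
        dq = plan.emc.volume_dq

    conditions = []
    slices = {}
    for t_w in plan.t_w_list:
        t0 = time.time()
        try:
            cond, sl = _condition_metrics(plan, particle, t_w, pixmap, edge, dq)
        except Exception:  # noqa: BLE001 - other conditions continue
            logger.exception("condition t_w=%s failed; continuing", t_w)
            continue
        logger.info("condition t_w=%s finished in %.1f s", t_w, time.time() - t0)
        conditions.append(cond)
        slices[float(t_w)] = sl
    from . import __version__

    report = Report(
        conditions=conditions,
        provenance={
            "config_hash": plan.config_hash(),
            "seed": plan.seed,
            "scale": plan.scale,
            "version": __version__,
        },
        slices=slices,
    )
    return report


def make_figures(report: Report, outdir, q_circles=(0.08, 0.10)) -> list:
    """Write figure files: central slices with q circles, shell-R curves,
    and the delta-theta vs T_w curve.  Returns the written paths."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if not report.conditions:
        logging.getLogger("spisim.pipeline").warning("empty report; no figures")
        return written

    # shell R-factor curves
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in report.conditions:
        ax.errorbar(
            c["shell_q"], c["shell_r_mean"], yerr=c["shell_r_sd"],
            label=f"T_w = {c['t_w']:g} A",
        )
    for qc in q_circles:
        ax.axvline(qc, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("q (1/A)")
    ax.set_ylabel("shell R-factor")
    ax.legend(fontsize=8)
    p = outdir / "shell_r_factor.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # delta-theta vs water-layer thickness
    fig, ax = plt.subplots(figsize=(5, 4))
    tw = [c["t_w"] for c in report.conditions]
    dt = [c["delta_theta_mean"] for c in report.conditions]
    sd = [c["delta_theta_sd"] for c in report.conditions]
    ax.errorbar(tw, dt, yerr=sd, marker="o")
    ax.set_xlabel("water layer thickness T_w (A)")
    ax.set_ylabel("self-OD delta-theta (rad)")
    p = outdir / "disconcurrence_vs_tw.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # central slices with circles at the region boundaries
    if report.slices:
        n = len(report.slices)
        fig, axes = plt.subplots(2, n, figsize=(3 * n, 6), squeeze=False)
        for j, (t_w, sl) in enumerate(sorted(report.slices.items())):
            for i, key in enumerate(("ground_truth", "reconstruction")):
                img = sl[key]
                ax = axes[i][j]
                half = (img.shape[0] - 1) / 2.0
                ax.imshow(np.log1p(img), cmap="viridis")
                for qc, color in zip(q_circles, ("white", "red")):
                    r = qc / sl["dq"]
                    circ = plt.Circle((half, half), r, fill=False,
                                      ls="--", lw=0.8, color=color)
                    ax.add_patch(circ)
                ax.set_title(f"{key} T_w={t_w:g}", fontsize=8)
                ax.axis("off")
        p = outdir / "central_slices.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
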