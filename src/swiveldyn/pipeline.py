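"""End-to-end orchestration: configured runs of the conformational-analysis
and PMF workflows with a machine-readable report.

A run is described by a JSON :class:`RunConfig`; every effective parameter
is echoed into the :class:`RunReport` together with a hash of the canonical
config, so a run can be repeated identically. Numeric outputs are plain
delimited text and are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ensemble_analysis import cluster_ensemble, collectivity, cross_correlation, run_pca
from .structures import (DomainDefinition, ResidueMap, apply_residue_map,
                         build_ensemble, read_ensemble, read_structure)
from .wham import (EQUILIBRATION_PRESETS, UmbrellaWindow, bootstrap_errors,
                   make_grid, overlap_diagnostics, profile_features,
                   read_window_set, solve, split_half_check)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    verbosity: str = "INFO"
    # conformational analysis inputs
    structures: list = None          # [{"path":..., "chain":..., "map_id":...}]
    ensemble_file: str = None
    residue_maps: str = None         # JSON file of per-structure maps
    domains: str = None              # JSON file of domain ranges
    cluster_cutoff: float = 4.0
    fit_fraction: float = 0.15
    # PMF inputs
    wham_manifest: str = None
    grid_range: list = None          # [[lo, hi]] or [[lo,hi],[lo,hi]]
    bin_width: float = 0.5
    temperature: float = 300.0
    tolerance: float = 1e-6
    bootstrap_resamples: int = 100
    equilibration_preset: str = None  # "standard-1d" | "standard-2d" | None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"known keys: {sorted(known)}")
        if "out_dir" not in data:
            raise ValueError("config must set out_dir")
        return cls(**data)

    def effective(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.effective(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _save_table(path: Path, header: str, array: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(array), delimiter="\t", header=header,
               comments="", fmt="%.10g")


def _load_inputs(config: RunConfig):
    if config.ensemble_file:
        return read_ensemble(config.ensemble_file), None
    if not config.structures:
        raise ValueError("config must list structures or an ensemble_file")
    models = []
    for entry in config.structures:
        model = read_structure(entry["path"], entry.get("chain"),
                               entry.get("model_index", 0))
        map_id = entry.get("map_id")
        if map_id and config.residue_maps:
            model = apply_residue_map(
                model, ResidueMap.from_json(config.residue_maps, map_id))
        models.append(model)
    return build_ensemble(models), models


def run_conformational_analysis(config: RunConfig) -> RunReport:
    """Structures -> ensemble -> clustering + PCA/collectivity + DCCM +
    reaction-coordinate table, all written under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=config.hash(),
                       config=config.effective())
    domains = (DomainDefinition.from_json(config.domains) if config.domains
               else DomainDefinition())

    def stage(name):
        return _Stage(name, report)

    with stage("ensemble"):
        ens, _ = _load_inputs(config)
        from .structures import write_ensemble
        write_ensemble(ens, out / "ensemble.txt")
        report.stages["ensemble"] = {"file": str(out / "ensemble.txt"),
                                     "n_members": ens.n_members,
                                     "n_common_residues": ens.n_residues}

    with stage("cluster"):
        cl = cluster_ensemble(ens, cutoff=config.cluster_cutoff)
        rows = [f"{mid}\t{cl.labels[mid]}\t"
                f"{int(cl.representatives[cl.labels[mid]] == mid)}"
                for mid in ens.member_ids]
        (out / "clusters.tsv").write_text(
            "member\tcluster\trepresentative\n" + "\n".join(rows) + "\n")
        report.stages["cluster"] = {"file": str(out / "clusters.tsv"),
                                    "n_clusters": cl.n_clusters}

    with stage("pca"):
        pca = run_pca(ens, fit_fraction=config.fit_fraction)
        spec = np.column_stack([np.arange(1, pca.n_components + 1),
                                pca.eigenvalues, pca.variance_fractions])
        _save_table(out / "pca_spectrum.tsv",
                    "component\teigenvalue_A2\tvariance_fraction", spec)
        lines = ["component\tdomain\tkappa"]
        present = {num for num, _ in ens.residues}
        for comp in range(min(2, pca.n_components)):
            for name in sorted(domains.ranges):
                dres = [r for r in domains.residues(name) if r in present]
                if len(dres) == 0:
                    continue
                k = collectivity(pca, comp, ens, dres)
                lines.append(f"{comp + 1}\t{name}\t{k:.10g}")
        (out / "collectivity.tsv").write_text("\n".join(lines) + "\n")
        report.stages["pca"] = {
            "spectrum": str(out / "pca_spectrum.tsv"),
            "collectivity": str(out / "collectivity.tsv"),
            "top2_variance_fraction": float(pca.variance_fractions[:2].sum())}

    with stage("dccm"):
        cc = cross_correlation(ens)
        _save_table(out / "dccm.tsv", "", cc.matrix)
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(cc.matrix, vmin=-1, vmax=1, cmap="RdBu_r",
                           origin="lower")
            fig.colorbar(im, ax=ax, label="C_ij")
            ax.set_xlabel("residue index")
            ax.set_ylabel("residue index")
            fig.savefig(out / "dccm.png", dpi=120)
            plt.close(fig)
        except Exception as exc:  # plotting is best-effort
            report.warnings.append(f"dccm heatmap not rendered: {exc}")
        report.stages["dccm"] = {"file": str(out / "dccm.tsv")}

    with stage("reaction_coordinates"):
        from .geometry import CD_PBD_PAIR, NBD1_NBD3_PAIR
        index = {num: i for i, (num, ic) in enumerate(ens.residues) if ic == ""}
        lines = ["member\tdistance_CD_PBD_A\tdistance_NBD1_NBD3_A"]
        for i, mid in enumerate(ens.member_ids):
            vals = []
            for a, b in (CD_PBD_PAIR, NBD1_NBD3_PAIR):
                if a in index and b in index:
                    d = np.linalg.norm(ens.coords[i, index[a]]
                                       - ens.coords[i, index[b]])
                    vals.append(f"{d:.10g}")
                else:
                    vals.append("NA")
            lines.append(f"{mid}\t{vals[0]}\t{vals[1]}")
        (out / "reaction_coordinates.tsv").write_text("\n".join(lines) + "\n")
        report.stages["reaction_coordinates"] = {
            "file": str(out / "reaction_coordinates.tsv")}

    report.write(out / "report.json")
    return report


def run_pmf_analysis(config: RunConfig) -> RunReport:
    """Umbrella windows -> WHAM -> bootstrap errors, overlap, split-half
    consistency, and minima/barrier extraction, written under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=config.hash(),
                       config=config.effective())

    def stage(name):
        return _Stage(name, report)

    with stage("load_windows"):
        if not config.wham_manifest:
            raise ValueError("config must set wham_manifest")
        windows = read_window_set(config.wham_manifest)
        if config.equilibration_preset:
            frac = EQUILIBRATION_PRESETS[config.equilibration_preset]
            windows = [UmbrellaWindow(w.centers, w.force_constants, w.samples,
                                      n_equil=int(frac * len(w.samples)))
                       for w in windows]
        report.stages["load_windows"] = {"n_windows": len(windows),
                                         "ndim": windows[0].ndim}

    with stage("wham"):
        if config.grid_range:
            edges = make_grid([tuple(r) for r in config.grid_range],
                              config.bin_width)
        else:
            pts = np.vstack([w.retained for w in windows])
            edges = make_grid(list(zip(pts.min(axis=0), pts.max(axis=0))),
                              config.bin_width)
        sol, prof = solve(windows, edges, config.temperature,
                          tolerance=config.tolerance)
        report.stages["wham"] = {"iterations": sol.iterations,
                                 "final_residual": sol.final_residual}

    with stage("bootstrap"):
        std = bootstrap_errors(windows, edges, config.temperature,
                               n_resamples=config.bootstrap_resamples,
                               seed=config.seed, tolerance=config.tolerance)
        prof.std = std
        report.stages["bootstrap"] = {
            "n_resamples": config.bootstrap_resamples,
            "max_std": float(np.nanmax(std))}

    with stage("write_pmf"):
        from .wham import grid_centers
        centers = grid_centers(edges)
        cols = [centers[:, d] for d in range(prof.ndim)]
        table = np.column_stack(cols + [prof.free_energy.ravel(),
                                        std.ravel(), prof.counts.ravel()])
        hdr = "\t".join([f"xi{d + 1}_A" for d in range(prof.ndim)]
                        + ["pmf_kcal_mol", "std_kcal_mol", "count"])
        _save_table(out / "pmf.tsv", hdr, table)
        report.stages["write_pmf"] = {"file": str(out / "pmf.tsv")}

    with stage("overlap"):
        ov = overlap_diagnostics(windows, edges)
        lines = ["window_i\twindow_j\toverlap"]
        for (i, j), v in sorted(ov.items()):
            lines.append(f"{i}\t{j}\t{v:.10g}")
        (out / "overlap.tsv").write_text("\n".join(lines) + "\n")
        report.stages["overlap"] = {"file": str(out / "overlap.tsv"),
                                    "min_overlap": float(min(ov.values()))}

    with stage("split_half"):
        _, _, maxdiff = split_half_check(windows, edges, config.temperature,
                                         tolerance=config.tolerance)
        report.stages["split_half"] = {"max_abs_difference": maxdiff}

    with stage("features"):
        feats = profile_features(prof)
        lines = ["position\tfree_energy_kcal_mol"]
        for _, pos, val in feats.minima:
            lines.append("\t".join(f"{p:.10g}" for p in pos)
                         + f"\t{val:.10g}")
        (out / "minima.tsv").write_text("\n".join(lines) + "\n")
        report.stages["features"] = {
            "n_minima": len(feats.minima),
            "minima": [{"position": list(pos), "free_energy": val}
                       for _, pos, val in feats.minima],
            "barriers": [{"between": [list(a), list(b)], "height": h}
                         for (a, b), h in feats.barriers.items()]}

    report.write(out / "report.json")
    return report


class _Stage:
    """Context manager: times a stage and renames its exceptions."""

    def __init__(self, name: str, report: RunReport):
        self.name = name
        self.report = report

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s ...", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.timings[self.name] = time.perf_counter() - self.t0
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, exc) from exc
        return False
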