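"""Analysis pipeline: one tessellation pass feeding every downstream
analysis, with CSV/JSON outputs and a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import StructureError, Topology, Trajectory, read_topology, read_trajectory
from .energetics import first_shell_energy_profile
from .hbonds import HbondCriterion, hbond_profile
from .rdf import com_rdf, kb_analysis, nearest_atom_rdf, shell_decompose_rdf
from .residence import fit_biexponential, residence_autocorrelation, residence_series
from .thermo import solvation_free_energy, thermo_dataframe
from .voronoi import shell_census, shell_map_for, tessellate_frame

log = logging.getLogger("voroshell")

ANALYSES = ("shells", "rdf", "thermo", "residence", "energy", "hbonds")


@dataclass
class RunConfig:
    """Validated parameters of one analysis run."""

    trajectory: str
    topology: str
    format: str | None = None
    analyses: tuple[str, ...] = ANALYSES
    output_dir: str = "voroshell_out"
    max_shell: int = 3
    bin_width: float = 0.1  # Å
    r_max: float | None = None  # Å; default 0.49 × min box edge
    shell_radius: float | None = None  # manual override of the g(r) minimum
    temperature: float = 300.0  # K
    cutoff: float = 14.0  # Å, energy cutoff
    hbond_d_max: float = 2.4  # Å
    hbond_angle_min: float = 135.0  # degrees
    max_lag: float | None = None  # ps
    frame_spacing: float | None = None  # ps override
    min_face_area: float | None = None  # Å^2
    seed: int = 0

    def validate(self) -> None:
        for name in ("trajectory", "topology"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file {getattr(self, name)!r}")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")
        if self.max_shell < 1:
            raise ValueError("max_shell must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _load(config: RunConfig) -> tuple[Trajectory, Topology]:
    topology = read_topology(config.topology)
    trajectory = read_trajectory(config.trajectory, config.format, topology)
    if config.r_max is not None:
        min_edge = min(f.box.min_edge for f in trajectory)
        if config.r_max > 0.5 * min_edge:
            raise ValueError(
                f"r_max = {config.r_max} exceeds half the smallest box edge"
            )
    return trajectory, topology


def run(config: RunConfig) -> dict:
    """Execute the requested analyses in dependency order.

    The Voronoi tessellation is computed once per frame and shared by all
    downstream stages.  Outputs are CSV files plus a JSON manifest; on
    failure partial outputs are removed and the failing stage is named.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t_start = time.time()
    stage = "load"
    try:
        trajectory, topology = _load(config)
        frame_spacing = config.frame_spacing or trajectory.frame_spacing or 1.0

        stage = "tessellation"
        tess_kwargs = {}
        if config.min_face_area is not None:
            tess_kwargs["min_face_area"] = config.min_face_area
        cells = [tessellate_frame(f, topology, **tess_kwargs) for f in trajectory]
        shell_map = shell_map_for(trajectory, topology, cells)
        census = shell_census(
            trajectory, topology, config.max_shell, shell_map, cells
        )

        def emit(name: str, df) -> None:
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)
            log.info("wrote %s", path)

        if "shells" in config.analyses:
            stage = "shells"
            from .voronoi import neighbor_graph_dataframe

            emit("shell_map.csv", shell_map.to_dataframe(topology))
            emit("shell_census.csv", census.to_dataframe())
            emit("neighbor_graph.csv", neighbor_graph_dataframe(cells))

        if "rdf" in config.analyses:
            stage = "rdf"
            import pandas as pd

            for sp in topology.species_labels:
                curve = shell_decompose_rdf(
                    trajectory, topology, sp, shell_map,
                    shells=range(1, config.max_shell + 1),
                    bin_width=config.bin_width, r_max=config.r_max,
                )
                df = curve.to_dataframe()
                try:
                    kb = kb_analysis(curve, R=config.shell_radius)
                    df["CN_running"] = np.interp(
                        curve.bin_centers, kb.r, kb.cn_running
                    )
                    df["KB_running"] = np.interp(
                        curve.bin_centers, kb.r, kb.delta_g_running
                    )
                except ValueError as exc:
                    log.warning("species %s: no KB workup (%s)", sp, exc)
                emit(f"rdf_{sp}.csv", df)
                s_curve = nearest_atom_rdf(
                    trajectory, topology, sp,
                    bin_width=config.bin_width, r_max=config.r_max,
                )
                emit(f"rdf_nearest_atom_{sp}.csv", s_curve.to_dataframe())

        if "thermo" in config.analyses:
            stage = "thermo"
            rows = solvation_free_energy(census, T=config.temperature)
            emit("shell_thermo.csv", thermo_dataframe(rows))

        if "residence" in config.analyses:
            stage = "residence"
            import pandas as pd

            fit_rows = []
            for sp in topology.species_labels:
                series = residence_series(
                    shell_map, topology, sp, frame_spacing=frame_spacing
                )
                curve = residence_autocorrelation(series, config.max_lag)
                emit(f"residence_{sp}.csv", curve.to_dataframe())
                try:
                    fit = fit_biexponential(curve)
                    fit_rows.append({"species": sp, **asdict(fit)})
                except (ValueError, RuntimeError) as exc:
                    log.warning("species %s: no residence fit (%s)", sp, exc)
            if fit_rows:
                path = out_dir / "residence_fits.json"
                path.write_text(json.dumps(fit_rows, indent=2))
                written.append(path)

        if "energy" in config.analyses:
            stage = "energy"
            profile = first_shell_energy_profile(
                trajectory, topology, shell_map, cutoff=config.cutoff
            )
            emit("first_shell_energies.csv", profile.to_dataframe())

        if "hbonds" in config.analyses:
            stage = "hbonds"
            import pandas as pd

            criterion = HbondCriterion(config.hbond_d_max, config.hbond_angle_min)
            profile = hbond_profile(trajectory, topology, criterion)
            emit(
                "hbonds.csv",
                pd.DataFrame(
                    [
                        {
                            "species": sp,
                            "mean_total": hc.mean_total,
                            "mean_solute_donor": hc.mean_donor,
                            "mean_solute_acceptor": hc.mean_acceptor,
                            "sd_total": hc.sd_total,
                        }
                        for sp, hc in sorted(profile.items())
                    ]
                ),
            )

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "n_frames": len(trajectory),
            "n_molecules": topology.n_molecules,
            "species": topology.species_labels,
            "outputs": [p.name for p in written],
            "wall_time_s": round(time.time() - t_start, 3),
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        written.append(path)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
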