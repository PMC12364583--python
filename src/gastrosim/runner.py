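"""Scenario assembly, run orchestration and paired-run comparison.

``build_gastric_simulation`` turns a :class:`SimulationConfig` into a ready
:class:`CoupledSimulation`; ``run`` advances it, streaming tidy CSV series,
optional VTK snapshots and checkpoints into a run directory; ``compare``
reports the paired-run deltas used throughout the study design (with/without
solids, healthy/hypomotile).

Everything is deterministic: there is no random number generator anywhere in
the core, so identical configurations produce byte-identical series.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

from gastrosim import diagnostics
from gastrosim.config import SimulationConfig, save_config
from gastrosim.contact import ContactParameters, default_stiffness
from gastrosim.coupling import CoupledSimulation
from gastrosim.fluid import BoundarySpec, CartesianGrid, FluidProperties, FluidSolver
from gastrosim.geometry import WaveParameters, build_lumen, default_stomach_params
from gastrosim.particles import RigidParticle

__all__ = ["build_gastric_simulation", "run", "compare", "default_damping", "RunResult"]

GRAVITY = (0.0, -9810.0)  # mm/s^2


def default_damping(mass: float, k_n: float, restitution: float = 0.3,
                    delta_ref: float = 0.1) -> float:
    """Linear dashpot sized for a target restitution against an equal body.

    Uses the linear spring-dashpot formula with the Hertz spring linearised
    at overlap ``delta_ref``; food contacts are dissipative (e ~ 0.3).
    """
    m_red = 0.5 * mass
    k_lin = k_n * math.sqrt(delta_ref)
    ln_e = math.log(restitution)
    return -2.0 * ln_e * math.sqrt(m_red * k_lin / (math.pi**2 + ln_e**2))


def initial_particle_positions(lumen, count: int, diameter: float, gap: float,
                               s_centre: float = 88.0) -> np.ndarray:
    """Release arrangement: a 2 x (count/2) close packing in the upper stomach.

    Particles sit near the centreline point at arc coordinate ``s_centre``
    with surface-to-surface gaps ``gap`` (read as a surface gap: centres that
    close would interpenetrate).
    """
    cl = lumen.centreline
    cx = float(np.interp(s_centre, cl.s, cl.points[:, 0]))
    cy = float(np.interp(s_centre, cl.s, cl.points[:, 1]))
    pitch = diameter + gap
    ncols = 2 if count > 1 else 1
    nrows = int(math.ceil(count / ncols))
    xs = []
    for k in range(count):
        col = k % ncols
        row = k // ncols
        x = cx + (col - (ncols - 1) / 2) * pitch
        y = cy + (row - (nrows - 1) / 2) * pitch
        xs.append((x, y))
    return np.array(xs)


@dataclass
class GastricSetup:
    sim: CoupledSimulation
    lumen: object
    grid: CartesianGrid
    config: SimulationConfig
    fluid_mask: np.ndarray      # cells that are lumen fluid at rest


def build_gastric_simulation(cfg: SimulationConfig) -> GastricSetup:
    cfg.validate()
    geo = default_stomach_params()
    w = cfg.waves
    speed = w.speed_mm_s if w.speed_mm_s is not None else w.s_start_mm / w.period_s
    waves = WaveParameters(
        period=w.period_s, speed=speed, width=w.width_mm, amplitude=w.amplitude,
        s_start=w.s_start_mm, chi=cfg.chi,
    )
    lumen = build_lumen(geo, waves)
    cl = lumen.centreline

    h = cfg.numerics.grid_h_mm
    boundary = lumen.boundary_polyline(0.0)
    duo_x = float(cl.points[0, 0])          # duodenal end reaches the box edge
    x_min = boundary[:, 0].min() - 3 * h
    y_min = boundary[:, 1].min() - 3 * h
    y_max = boundary[:, 1].max() + 3 * h
    nx = int(math.ceil((duo_x - x_min) / h))
    ox = duo_x - nx * h
    ny = int(math.ceil((y_max - y_min) / h))
    grid = CartesianGrid(nx=nx, ny=ny, h=h, origin=(ox, float(y_min)))

    props = FluidProperties(rho=cfg.rho_kg_m3 * 1e-6, mu=cfg.mu_mPas * 1e-3)
    cc = grid.cell_centres()
    pm = lumen.map_points(cc)
    phi0 = lumen.fields(pm, 0.0)[0].reshape(nx, ny)
    smap = pm.s.reshape(nx, ny)
    outlet = np.zeros((nx, ny), bool)
    outlet[-2:, :] = phi0[-2:, :] < 0
    inlet = (smap > cl.s_max - 4.0) & (phi0 < 0)
    exterior = phi0 > 2 * h
    edge = np.zeros_like(exterior)
    edge[-2:, :] = True
    ident = (exterior | edge) & ~outlet
    mask = outlet | inlet | ident
    cells = np.where(mask.ravel())[0]
    vals = np.where(inlet.ravel()[cells], cfg.tone_Pa, 0.0)

    solver = FluidSolver(
        grid, props, BoundarySpec(right="open"), cells, vals,
        cfl=cfg.numerics.cfl, dt_cap=cfg.numerics.dt_cap_s,
    )

    particles: list[RigidParticle] = []
    if cfg.include_particles and cfg.particles.count > 0:
        pos = initial_particle_positions(
            lumen, cfg.particles.count, cfg.particles.diameter_mm,
            cfg.particles.initial_gap_mm,
        )
        r = cfg.particles.diameter_mm / 2.0
        rho_s = cfg.particles.density_g_cm3 * 1e-3
        particles = [RigidParticle(id=i, r=r, rho_s=rho_s, x=pos[i]) for i in range(len(pos))]

    if particles:
        mass = particles[0].mass
        k_n = cfg.contact.k_n if cfg.contact.k_n is not None else default_stiffness(mass)
        gamma_n = (cfg.contact.gamma_n if cfg.contact.gamma_n is not None
                   else default_damping(mass, k_n))
    else:
        k_n, gamma_n = 1.0e4, 5.0
    contact = ContactParameters(
        k_n=k_n, gamma_n=gamma_n, g_act=cfg.contact.activation_gap_mm,
        mu_t=cfg.contact.friction,
    )

    # transpyloric plane: just distal of the pylorus, where the tube is straight
    pyl_idx = int(np.argmin(np.abs(cl.s)))
    flux_x = float(cl.points[pyl_idx, 0]) + 2.0

    sim = CoupledSimulation(
        solver, lumen, particles, contact,
        flux_plane_x=flux_x, gravity=GRAVITY,
        resolution_guard=cfg.numerics.resolution_guard,
    )
    fluid_mask = (phi0 < 0) & ~mask
    return GastricSetup(sim=sim, lumen=lumen, grid=grid, config=cfg, fluid_mask=fluid_mask)


@dataclass
class RunResult:
    out_dir: Path
    particles: pd.DataFrame | None
    flux: pd.DataFrame
    contacts: pd.DataFrame | None
    config: SimulationConfig


def run(cfg: SimulationConfig, out_dir, restart_from=None, progress: bool = False) -> RunResult:
    """Run a gastric scenario and write the run directory.

    Outputs: ``config.yaml``, ``flux.csv`` (t, dt, q), ``particles.csv``
    (per output time and particle), ``contacts.csv`` (peak contact forces per
    output interval), ``summary.txt``, ``log.jsonl``, optional VTK snapshots
    under ``fields/`` and checkpoints under ``checkpoints/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup = build_gastric_simulation(cfg)
    sim = setup.sim
    lumen = setup.lumen
    save_config(cfg, out / "config.yaml")
    pd.DataFrame(lumen.boundary_polyline(0.0), columns=["x", "y"]).to_csv(
        out / "boundary_rest.csv", index=False, float_format="%.6g"
    )
    cfg_hash = sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    if restart_from is not None:
        sim.restore(restart_from)

    out_dt = cfg.numerics.output_dt_s
    next_out = (math.floor(sim.state.t / out_dt) + 1) * out_dt
    next_ckpt = None
    if cfg.checkpoint_interval_s:
        (out / "checkpoints").mkdir(exist_ok=True)
        next_ckpt = (math.floor(sim.state.t / cfg.checkpoint_interval_s) + 1) * cfg.checkpoint_interval_s
    next_vtk = None
    if cfg.vtk_interval_s:
        (out / "fields").mkdir(exist_ok=True)
        next_vtk = sim.state.t

    flux_rows, particle_rows, contact_rows, log_rows = [], [], [], []
    fc_peak = np.zeros(len(sim.particles))
    pair_peak: dict = {}
    n_steps = 0
    n_contact_events = 0
    dt_min, dt_max = math.inf, 0.0
    wall_t0 = time.time()

    while sim.state.t < cfg.duration_s - 1e-12:
        rec = sim.step()
        n_steps += 1
        n_contact_events += len(rec.contact_events)
        dt_min = min(dt_min, rec.dt)
        dt_max = max(dt_max, rec.dt)
        flux_rows.append((rec.t, rec.dt, rec.flux))
        for ev in rec.contact_events:
            fmag = float(np.hypot(*ev.f))
            if fmag <= 0.0:
                continue
            fc_peak[ev.body_a] = max(fc_peak[ev.body_a], fmag)
            if ev.body_b >= 0:
                fc_peak[ev.body_b] = max(fc_peak[ev.body_b], fmag)
            key = (ev.body_a, ev.body_b)
            if key not in pair_peak or fmag > pair_peak[key][0]:
                pair_peak[key] = (fmag, ev.point.copy())

        if rec.t + 1e-12 >= next_out:
            if sim.particles:
                xs = np.array([p.x for p in sim.particles])
                s_arc = lumen.arc_coordinate(xs)
                for i, p in enumerate(sim.particles):
                    ld = rec.loads[i]
                    particle_rows.append((
                        rec.t, p.id, p.x[0], p.x[1], float(s_arc[i]),
                        p.v[0], p.v[1], p.omega,
                        ld.p_mean, ld.tau_mean, fc_peak[i],
                        ld.f_pressure[0], ld.f_pressure[1],
                        ld.f_shear[0], ld.f_shear[1], ld.moment,
                    ))
                for (a, b), (fmag, pt) in pair_peak.items():
                    s_ev = float(lumen.arc_coordinate(pt[None, :])[0])
                    contact_rows.append((rec.t, a, b, fmag, pt[0], pt[1], s_ev))
            fc_peak[:] = 0.0
            pair_peak = {}
            next_out += out_dt

        if next_ckpt is not None and rec.t + 1e-12 >= next_ckpt:
            sim.checkpoint(out / "checkpoints" / f"state_{rec.t:09.3f}.npz")
            next_ckpt += cfg.checkpoint_interval_s
        if next_vtk is not None and rec.t + 1e-12 >= next_vtk:
            _write_vtk_snapshot(out / "fields", setup, rec.t)
            next_vtk += cfg.vtk_interval_s
        if progress and n_steps % 2000 == 0:
            print(f"t={rec.t:8.3f}s dt={rec.dt*1e3:5.2f}ms "
                  f"wall={time.time()-wall_t0:7.1f}s", flush=True)

    flux = pd.DataFrame(flux_rows, columns=["t", "dt", "q"])
    flux.to_csv(out / "flux.csv", index=False, float_format="%.9g")
    particles_df = None
    contacts_df = None
    if sim.particles:
        particles_df = pd.DataFrame(
            particle_rows,
            columns=["t", "particle", "x", "y", "s", "vx", "vy", "omega",
                     "p_bar", "tau_bar", "fc_max", "fpx", "fpy", "fsx", "fsy", "mom"],
        )
        particles_df.to_csv(out / "particles.csv", index=False, float_format="%.9g")
        contacts_df = pd.DataFrame(
            contact_rows, columns=["t", "body_a", "body_b", "f_max", "x", "y", "s"]
        )
        contacts_df.to_csv(out / "contacts.csv", index=False, float_format="%.9g")

    h = setup.grid.h
    log_rows.append({
        "config_hash": cfg_hash, "steps": n_steps,
        "wall_seconds": round(time.time() - wall_t0, 3),
        "final_t": sim.state.t,
        "max_speed": sim.state.max_speed(),
        "dt_min": None if n_steps == 0 else dt_min,
        "dt_max": dt_max,
        "cfl_max": sim.state.max_speed() * dt_max / h,
        "contact_events": n_contact_events,
    })
    with open(out / "log.jsonl", "w") as fh:
        for row in log_rows:
            fh.write(json.dumps(row) + "\n")

    _write_summary(out, cfg, particles_df, flux)
    return RunResult(out_dir=out, particles=particles_df, flux=flux,
                     contacts=contacts_df, config=cfg)


def _write_vtk_snapshot(fields_dir: Path, setup: GastricSetup, t: float) -> None:
    from gastrosim.vtkio import write_polylines, write_structured_points

    sim = setup.sim
    g = setup.grid
    uc, vc = sim.solver.centre_velocity(sim.state.u, sim.state.v)
    vel = np.stack([uc, vc], axis=-1)
    write_structured_points(
        fields_dir / f"flow_{t:09.3f}.vtk", g.origin, g.h,
        {"pressure": sim.state.p, "velocity": vel},
    )
    polys = [setup.lumen.boundary_polyline(t)]
    th = np.linspace(0, 2 * math.pi, 33)
    for p in sim.particles:
        polys.append(np.column_stack([p.x[0] + p.r * np.cos(th), p.x[1] + p.r * np.sin(th)]))
    write_polylines(fields_dir / f"outlines_{t:09.3f}.vtk", polys)


def _write_summary(out: Path, cfg: SimulationConfig, particles_df, flux) -> None:
    lines = [f"gastrosim run: scenario={cfg.scenario} motility={cfg.motility} "
             f"mu={cfg.mu_mPas} mPa s, particles={cfg.include_particles}"]
    t_end = float(flux["t"].iloc[-1]) if len(flux) else 0.0
    t0 = diagnostics.ANALYSIS_START
    period = cfg.waves.period_s
    if t_end > t0 + period:
        n_per = int((t_end - t0) / period)
        window = (t0, t0 + n_per * period)
        rate = diagnostics.emptying_rate(flux, window, period, cfg.depth_mm)
        lines.append(f"emptying rate over {window}: {rate:.3f} ml/min")
    if particles_df is not None and not particles_df.empty and t_end > t0:
        rep = diagnostics.min_distance_report(particles_df)
        lines.append("min distance to pylorus (mm, sorted): "
                     + " ".join(f"{v:.1f}" for v in rep.minima)
                     + f"; average {rep.average:.1f}")
        stats = diagnostics.force_statistics(particles_df)
        lines.append(stats.to_string(index=False))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def compare(run_a, run_b, period: float = 20.0, depth_mm: float = 4.0) -> dict:
    """Difference report between two run directories (A minus/over B).

    Emits the emptying-rate delta and ratio, the average-minimum-distance
    excess of A over B in percent, and force-statistic deltas.
    """
    a, b = Path(run_a), Path(run_b)
    flux_a = pd.read_csv(a / "flux.csv")
    flux_b = pd.read_csv(b / "flux.csv")
    t_end = min(flux_a["t"].iloc[-1], flux_b["t"].iloc[-1])
    if abs(flux_a["t"].iloc[-1] - flux_b["t"].iloc[-1]) > 1e-6:
        warnings.warn("runs have different durations; comparing the common window")
    t0 = diagnostics.ANALYSIS_START
    n_per = max(1, int((t_end - t0) / period))
    window = (t0, t0 + n_per * period)
    out: dict = {"window": window}
    rate_a = diagnostics.emptying_rate(flux_a, window, period, depth_mm)
    rate_b = diagnostics.emptying_rate(flux_b, window, period, depth_mm)
    out["emptying_rate_a"] = rate_a
    out["emptying_rate_b"] = rate_b
    out["emptying_rate_delta"] = rate_a - rate_b
    out["emptying_rate_ratio"] = rate_a / rate_b if rate_b != 0 else math.inf

    pa, pb = a / "particles.csv", b / "particles.csv"
    if pa.exists() and pb.exists():
        dfa = pd.read_csv(pa)
        dfb = pd.read_csv(pb)
        dfa = dfa[dfa["t"] <= t_end]
        dfb = dfb[dfb["t"] <= t_end]
        rep_a = diagnostics.min_distance_report(dfa)
        rep_b = diagnostics.min_distance_report(dfb)
        out["min_distance_avg_a"] = rep_a.average
        out["min_distance_avg_b"] = rep_b.average
        out["min_distance_excess_pct"] = diagnostics.percent_excess(rep_a.average, rep_b.average)
        sa = diagnostics.force_statistics(dfa, t_end=t_end).set_index("quantity")
        sb = diagnostics.force_statistics(dfb, t_end=t_end).set_index("quantity")
        out["force_stats_delta"] = (sa - sb).reset_index().to_dict("records")
    return out
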