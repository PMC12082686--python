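"""Config-driven composition of experiments into exchange-rate sweeps.

The driver owns the bookkeeping around the physics modules: building jump
models, powder schemes and sequence specs from a flat configuration mapping,
generating reference grids, chi-square fitting each exchange rate of a sweep
and writing CSV/JSON outputs with the resolved configuration embedded.  All
stochastic-Liouville outputs are deterministic for a fixed config; the only
randomness in the package is the Monte-Carlo validation oracle, seeded from
the config.

The same functions back the ``masjump`` command line::

    masjump simulate -c config.yaml
    masjump sweep -c config.yaml
    masjump fit -c config.yaml -t trajectory.csv
    masjump powder -n 538 --three-angle -o scheme.csv
    masjump oracle -c config.yaml
"""

from __future__ import annotations

import json
import logging
import math
import time
import warnings
from pathlib import Path

import numpy as np

from . import exchange, fitting, sequences, tensors
from .exchange import (JumpModel, Trajectory, averaged_delta,
                       monte_carlo_free_evolution, single_site,
                       three_site_cone, nine_site)
from .fitting import (FitResult, ReferenceGrid, SweepResult, chi2_fit,
                      center_sideband_manifold, default_delta_grid, kex_grid,
                      t1e, transition_region)
from .tensors import Rank2Tensor, RotorSpec, zcw_orientations

log = logging.getLogger("masjump")

EXPERIMENTS = ("cp", "redor", "wpars", "r18_csa", "offmas", "quad")

#: Flat configuration defaults; any key can be overridden from YAML or CLI.
DEFAULTS = {
    "sequence": "cp",
    "delta_hz": 5000.0,          # interaction anisotropy delta/(2 pi)
    "theta_deg": 70.5,
    "kex": 1.0e3,                # single rate, or use kex_min/kex_max for sweeps
    "kex_min": 1.0,
    "kex_max": 5.0e11,
    "nu_r": 20000.0,
    "offset_deg": 0.0,
    "n_crystallites": 144,
    "three_angle": True,
    # nine-site extension (enabled when theta2_deg is set)
    "theta2_deg": None,
    "kex2": None,
    # CP
    "nu1_I": None,               # default derived from the matching rule below
    "nu1_S": None,
    "tilt_deg": 90.0,
    "contact_ms": 1.5,
    # REDOR
    "redor_eps": 0.25,
    "redor_ideal": False,
    "redor_nu1": 100e3,
    "redor_rotors": 64,
    "r1e_window": 0.020,
    # R sequences
    "window_fraction": 0.0,
    "n_blocks": 60,
    # off-MAS
    "J_hz": -90.0,
    "offmas_window": 0.080,
    # quad
    "cqcc_hz": 160e3,
    "b0_t": 18.7,
    "second_order": True,
    "quad_window": 0.150,
    "display_lb": 10.0,
    # fitting
    "fit_grid_n": 101,
    "lb_grid_n": 26,
    "lb_max_offmas": 2000.0,
    "lb_max_quad": 20000.0,
    "transition_threshold": 0.06,
    # misc
    "seed": 1234,
    "cost_budget": 2.0e11,       # crystallites * steps * D^3 warning threshold
    "out_dir": ".",
}


def resolve_config(config: dict | None = None, **overrides) -> dict:
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    if cfg["sequence"] not in EXPERIMENTS:
        raise ValueError(f"unknown sequence {cfg['sequence']!r}; expected one of {EXPERIMENTS}")
    if cfg["nu1_S"] is None:
        # n = 1 zero-quantum match mirroring the 20 kHz MAS pair 93/73 kHz
        cfg["nu1_S"] = round(3.65 * cfg["nu_r"] / 1000.0) * 1000.0
    if cfg["nu1_I"] is None:
        cfg["nu1_I"] = cfg["nu1_S"] + cfg["nu_r"]
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def make_rotor(cfg) -> RotorSpec:
    return RotorSpec(nu_r=cfg["nu_r"], offset_deg=cfg["offset_deg"])


def make_crystallites(cfg):
    return zcw_orientations(cfg["n_crystallites"], three_angle=cfg["three_angle"])


def make_tensor(cfg) -> Rank2Tensor:
    if cfg["sequence"] == "quad":
        return tensors.quad_delta(make_quad_spec(cfg).quad)
    return Rank2Tensor.from_hz(cfg["delta_hz"])


def make_model(cfg, kex: float) -> JumpModel:
    if cfg.get("theta2_deg") is not None:
        k2 = cfg["kex2"] if cfg.get("kex2") is not None else kex
        return nine_site(cfg["theta_deg"], cfg["theta2_deg"], kex, k2)
    return three_site_cone(cfg["theta_deg"], kex)


def make_quad_spec(cfg) -> sequences.QuadSpec:
    q = tensors.QuadrupoleSpec(Cqcc=cfg["cqcc_hz"], B0=cfg["b0_t"],
                               second_order=cfg["second_order"])
    return sequences.QuadSpec(quad=q, window=cfg["quad_window"],
                              display_lb=cfg["display_lb"])


def make_sequence_spec(cfg):
    kind = cfg["sequence"]
    rotor = make_rotor(cfg)
    if kind == "cp":
        n_half = int(round(cfg["contact_ms"] * 1e-3 / (rotor.tau_r / 2)))
        return sequences.CPSpec(nu1_I=cfg["nu1_I"], nu1_S=cfg["nu1_S"],
                                tilt_deg=cfg["tilt_deg"],
                                contact_grid=np.arange(0, n_half + 1) * rotor.tau_r / 2)
    if kind == "redor":
        return sequences.REDORSpec(pi_pulse_nu1=cfg["redor_nu1"],
                                   ideal_pulses=cfg["redor_ideal"],
                                   shift_eps=cfg["redor_eps"],
                                   n_rotor_max=cfg["redor_rotors"])
    if kind == "wpars":
        return sequences.RSequenceSpec(N=10, n=1, nu=3,
                                       window_fraction=cfg["window_fraction"],
                                       target="dipolar", n_block_max=cfg["n_blocks"])
    if kind == "r18_csa":
        return sequences.RSequenceSpec(N=18, n=1, nu=7, target="csa",
                                       n_block_max=cfg["n_blocks"])
    if kind == "offmas":
        return sequences.OffMASSpec(J=cfg["J_hz"], offset_deg=cfg["offset_deg"],
                                    window=cfg["offmas_window"])
    if kind == "quad":
        return make_quad_spec(cfg)
    raise ValueError(kind)


def _estimate_cost(cfg) -> float:
    d = {"cp": 4, "redor": 4, "wpars": 4, "offmas": 4, "r18_csa": 2, "quad": 3}[cfg["sequence"]]
    n_sites = 9 if cfg.get("theta2_deg") is not None else 3
    D = n_sites * d * d
    steps = 200 * max(1, int(cfg.get("n_blocks", 60)))
    return cfg["n_crystallites"] * steps * D**3


def simulate_experiment(cfg, model: JumpModel):
    """Run one experiment; returns ``(primary trajectory, extras dict)``."""
    cost = _estimate_cost(cfg)
    if cost > cfg["cost_budget"]:
        warnings.warn(f"estimated propagation cost {cost:.1e} exceeds budget "
                      f"{cfg['cost_budget']:.1e}; consider a reduced profile")
    kind = cfg["sequence"]
    rotor = make_rotor(cfg)
    crys = make_crystallites(cfg)
    spec = make_sequence_spec(cfg)
    tensor = make_tensor(cfg)
    t0 = time.time()
    if kind == "cp":
        traj = sequences.cp_curve(spec, tensor, model, rotor, crys)
        extras = {}
    elif kind == "redor":
        s, s0, frac = sequences.redor_curves(spec, tensor, model, rotor, crys)
        traj, extras = frac, {"S": s, "S0": s0}
    elif kind == "wpars":
        traj, extras = sequences.wpars_curve(spec, tensor, model, rotor, crys), {}
    elif kind == "r18_csa":
        traj, extras = sequences.r18_csa_curve(spec, tensor, model, rotor, crys), {}
    elif kind == "offmas":
        traj, extras = sequences.offmas_echo(spec, tensor, model, rotor, crys), {}
    elif kind == "quad":
        traj, extras = sequences.quad_fid(spec, model, rotor, crys), {}
    log.info("simulated %s (%d crystallites) in %.1f s", kind, len(crys), time.time() - t0)
    traj.meta["config"] = {k: v for k, v in cfg.items() if not k.startswith("_")}
    traj.meta["kex"] = model.label
    return traj, extras


def reference_grid_for(cfg, t_grid: np.ndarray) -> ReferenceGrid:
    """Exchange-free reference simulations on the configured delta grid."""
    kind = cfg["sequence"]
    rotor = make_rotor(cfg)
    crys = make_crystallites(cfg)
    tensor = make_tensor(cfg)
    scaled = averaged_delta(tensor, make_model(cfg, 0.0)) / (2 * math.pi)
    deltas = default_delta_grid(tensor.delta_hz, scaled, n=cfg["fit_grid_n"],
                                both_signs=(kind == "offmas"))
    spec = make_sequence_spec(cfg)
    if kind == "offmas":
        refs = sequences.offmas_reference(spec, deltas, rotor, crys, t_grid)
        lb = _lb_grid(cfg["lb_max_offmas"], cfg["lb_grid_n"])
        return ReferenceGrid(deltas, refs, t_grid, lb_values=lb)
    if kind == "quad":
        refs = sequences.quad_reference(spec, deltas, rotor, crys, t_grid)
        refs = np.array([center_sideband_manifold(Trajectory(t_grid, r)).signal
                         for r in refs])
        lb = _lb_grid(cfg["lb_max_quad"], cfg["lb_grid_n"])
        return ReferenceGrid(deltas, refs, t_grid, lb_values=lb)
    rows = []
    rigid = single_site()
    for d in deltas:
        sub = dict(cfg)
        sub["delta_hz"] = float(d)
        traj, _ = simulate_experiment(sub, rigid)
        if not np.array_equal(traj.t, t_grid):
            raise ValueError("reference and target time grids differ")
        rows.append(traj.signal)
    return ReferenceGrid(deltas, np.array(rows), t_grid)


def _lb_grid(lb_max: float, n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(1.0, math.log10(lb_max), n - 1)])


def fit_experiment(cfg, traj: Trajectory, grid: ReferenceGrid) -> FitResult:
    kind = cfg["sequence"]
    if kind == "quad":
        target = center_sideband_manifold(traj)
        return chi2_fit(target, grid, truncate=False)
    if kind == "offmas":
        return chi2_fit(traj, grid, truncate=False)
    return chi2_fit(traj, grid, truncate=True)


def run_single(config: dict | None = None, **overrides) -> dict:
    """One experiment at one exchange rate; optional fit; files in ``out_dir``."""
    cfg = resolve_config(config, **overrides)
    model = make_model(cfg, cfg["kex"])
    traj, extras = simulate_experiment(cfg, model)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{cfg['sequence']}_kex{cfg['kex']:.3g}"
    traj.to_csv(out / f"{stem}.csv")
    traj.to_json(out / f"{stem}.json")
    result = {"trajectory": traj, "extras": extras, "config": cfg,
              "files": [str(out / f"{stem}.csv"), str(out / f"{stem}.json")]}
    if cfg.get("fit", False):
        grid = reference_grid_for(cfg, traj.t)
        result["fit"] = fit_experiment(cfg, traj, grid)
    return result


def run_sweep(config: dict | None = None, kex_values=None, write: bool = False,
              **overrides) -> SweepResult:
    """Sweep the exchange rate, fit every point, report the transition region.

    Single-point failures are recorded in the metadata and skipped.
    """
    cfg = resolve_config(config, **overrides)
    if kex_values is None:
        kex_values = kex_grid(cfg["kex_min"], cfg["kex_max"])
    kex_values = np.asarray(kex_values, dtype=float)
    tensor = make_tensor(cfg)
    scaled = averaged_delta(tensor, make_model(cfg, 0.0)) / (2 * math.pi)

    grid = None
    deltas, lbs, r1es, errors = [], [], [], {}
    for kex in kex_values:
        try:
            model = make_model(cfg, kex)
            traj, extras = simulate_experiment(cfg, model)
            if grid is None:
                grid = reference_grid_for(cfg, traj.t)
            fit = fit_experiment(cfg, traj, grid)
            deltas.append(fit.delta_fit)
            lbs.append(fit.lb_fit if fit.lb_fit is not None else np.nan)
            if cfg["sequence"] == "redor":
                T, R, cens = t1e(extras["S0"], window=cfg["r1e_window"])
                r1es.append(R if not cens else np.nan)
            else:
                r1es.append(np.nan)
        except Exception as exc:   # single-point failure: record, continue
            log.warning("kex=%.3g failed: %s", kex, exc)
            errors[float(kex)] = str(exc)
            deltas.append(np.nan)
            lbs.append(np.nan)
            r1es.append(np.nan)
    deltas = np.array(deltas)
    sweep = SweepResult(kex_values=kex_values, delta_fit=deltas,
                        lb_fit=np.array(lbs), r1e=np.array(r1es),
                        meta={"config": cfg, "delta_rigid_hz": tensor.delta_hz,
                              "delta_scaled_hz": scaled, "errors": errors})
    ok = ~np.isnan(deltas)
    if ok.sum() >= 2:
        sub = SweepResult(kex_values=kex_values[ok], delta_fit=deltas[ok])
        # magnitude grids (all but off-MAS) compare |rigid| to |scaled|
        d_r, d_s = tensor.delta_hz, scaled
        if cfg["sequence"] != "offmas":
            d_r, d_s = abs(d_r), abs(d_s)
        sweep.transition = transition_region(sub, d_r, d_s,
                                             threshold=cfg["transition_threshold"])
    if write:
        out = Path(cfg["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        stem = f"sweep_{cfg['sequence']}"
        sweep.to_csv(out / f"{stem}.csv")
        payload = {"config": cfg, "transition": sweep.transition,
                   "delta_rigid_hz": tensor.delta_hz, "delta_scaled_hz": scaled,
                   "kex": kex_values.tolist(), "delta_fit_hz": deltas.tolist(),
                   "errors": errors}
        (out / f"{stem}.json").write_text(json.dumps(payload, indent=1, default=str))
    return sweep


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

try:
    import click
except ImportError:     # pragma: no cover - click is a hard dependency
    click = None

if click is not None:
    @click.group()
    @click.option("-v", "--verbose", is_flag=True)
    def cli(verbose):
        """MAS spin dynamics with N-site jump exchange."""
        logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                            format="%(levelname)s %(message)s")

    def _cfg_from(config, sets):
        cfg = load_config(config) if config else resolve_config()
        for item in sets:
            key, _, val = item.partition("=")
            try:
                cfg[key] = json.loads(val)
            except json.JSONDecodeError:
                cfg[key] = val
        return resolve_config(cfg)

    @cli.command()
    @click.option("-c", "--config", type=click.Path(exists=True))
    @click.option("-s", "--set", "sets", multiple=True, help="override key=value")
    def simulate(config, sets):
        """Run one experiment at one exchange rate."""
        res = run_single(_cfg_from(config, sets))
        click.echo(json.dumps({"files": res["files"],
                               "fit": getattr(res.get("fit"), "__dict__", None)},
                              indent=1, default=str))

    @cli.command()
    @click.option("-c", "--config", type=click.Path(exists=True))
    @click.option("-s", "--set", "sets", multiple=True)
    def sweep(config, sets):
        """Exchange-rate sweep with chi-square fits and transition report."""
        sw = run_sweep(_cfg_from(config, sets), write=True)
        click.echo(sw.to_frame().to_string(index=False))
        click.echo(f"transition region: {sw.transition}")

    @cli.command()
    @click.option("-c", "--config", type=click.Path(exists=True))
    @click.option("-s", "--set", "sets", multiple=True)
    @click.option("-t", "--trajectory", type=click.Path(exists=True), required=True)
    def fit(config, sets, trajectory):
        """Fit an existing trajectory CSV against a generated reference grid."""
        import pandas as pd

        cfg = _cfg_from(config, sets)
        df = pd.read_csv(trajectory)
        sig = (df["signal_real"].to_numpy() + 1j * df["signal_imag"].to_numpy()
               if "signal_real" in df else df["signal"].to_numpy())
        traj = Trajectory(df["t_seconds"].to_numpy(), sig)
        grid = reference_grid_for(cfg, traj.t)
        res = fit_experiment(cfg, traj, grid)
        click.echo(json.dumps(res.__dict__, indent=1, default=str))

    @cli.command()
    @click.option("-n", "--n-target", type=int, default=538)
    @click.option("--three-angle", is_flag=True)
    @click.option("-o", "--output", type=click.Path(), required=True)
    def powder(n_target, three_angle, output):
        """Write a ZCW crystallite set as CSV."""
        crys = zcw_orientations(n_target, three_angle=three_angle)
        tensors.crystallites_to_csv(crys, output)
        click.echo(f"{len(crys)} orientations -> {output}")

    @cli.command()
    @click.option("-c", "--config", type=click.Path(exists=True))
    @click.option("-s", "--set", "sets", multiple=True)
    @click.option("--n-traj", type=int, default=10000)
    def oracle(config, sets, n_traj):
        """Monte-Carlo jump-trajectory cross-check of free dipolar dephasing."""
        cfg = _cfg_from(config, sets)
        rotor = make_rotor(cfg)
        crys = make_crystallites(cfg)
        model = make_model(cfg, cfg["kex"])
        tensor = make_tensor(cfg)
        t_grid = rotor.tau_r * np.arange(0, 33)
        mean, sem = monte_carlo_free_evolution(tensor, model, rotor, crys, t_grid,
                                               n_traj=n_traj, seed=cfg["seed"])
        for t, m, s in zip(t_grid, mean, sem):
            click.echo(f"{t:.6e} {m:+.5f} +- {s:.5f}")
else:   # pragma: no cover
    cli = None
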