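"""Metropolis Monte Carlo over base-pair step parameters.

The chain state is the list of N-1 step-parameter 6-vectors.  Each
sweep updates the steps sequentially; a proposal redraws one step's
6-vector from the sampling model, so the internal (stacking) elasticity
is absorbed in the proposal distribution and the Metropolis energy
contains only the external terms:

* stretching:      E = -F * z                       (force along +z)
* torsional trap:  E += 1/2 * k_rot * (Lk - Lk_t)^2  (link constrained)
* optional tether: E += 1/2 * k_xy * (x^2 + y^2)     (terminal base pair)

with z the helix extension, Lk the ribbon link (twist + Fuller writhe,
re-evaluated after every single-step proposal in constrained mode), and
energies in pN*nm.  A free helix (no force, no trap) accepts every
move.

Simulations follow the tweezers-like protocol: initialize every step at
the database mean, relax under force, optionally ramp the trap target
link toward the desired value in small increments, relax again, then
record one sample per sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .constants import ANGSTROM_PER_NM, kbt
from .geometry import HelixConformation, steps_to_transforms
from .models import FragmentLibrary, GaussianStepModel
from .topology import FullerValidityWarning

__all__ = [
    "SimulationConfig",
    "TraceRecord",
    "energy_force",
    "energy_link_constrained",
    "metropolis_accept",
    "mc_cycle",
    "relax_and_ramp",
    "run_simulation",
    "force_scan",
    "link_scan",
]


def energy_force(z: float, force: float) -> float:
    """Stretching energy (pN*nm): E = -F*z, with z in angstroms, F in pN."""
    return -force * z / ANGSTROM_PER_NM


def energy_link_constrained(
    z: float, force: float, link: float, link_target: float, k_rot: float = 200.0
) -> float:
    """Force + torsional-trap energy (pN*nm); link angles in radians."""
    return energy_force(z, force) + 0.5 * k_rot * (link - link_target) ** 2


def metropolis_accept(
    delta_e: float, temperature: float = 298.0, rng: np.random.Generator | None = None
) -> bool:
    """Standard Metropolis criterion: accept with prob min(1, exp(-dE/kBT))."""
    if delta_e <= 0.0:
        return True
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    return bool(rng.random() < np.exp(-delta_e / kbt(temperature)))


@dataclass
class SimulationConfig:
    """Parameters of one simulation condition.

    ``link_target`` is in radians (``link_target_turns`` is accepted as
    a convenience); ``trap_stiffness`` in pN*nm per rad^2;
    ``xy_constraint_k`` in pN/A (0 disables the tether restraint);
    ``ramp_increment`` in degrees.
    """

    n_bp: int = 3000
    force: float = 0.0  # pN
    link_constrained: bool = False
    link_target: float | None = None  # radians
    trap_stiffness: float = 200.0  # pN*nm / rad^2
    temperature: float = 298.0  # K
    relax_cycles: int = 120
    post_ramp_cycles: int = 50
    ramp_increment: float = 20.0  # degrees
    ramp_cycle_cap: int = 10_000
    n_samples: int = 2000
    seed: int = 0
    xy_constraint_k: float = 0.0  # pN/A
    writhe_method: str = "fuller"
    record_topology: bool = True
    strict_fuller_guard: bool = False

    def __post_init__(self):
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.link_constrained and self.trap_stiffness <= 0:
            raise ValueError("trap_stiffness must be positive when constrained")
        if self.ramp_increment <= 0:
            raise ValueError("ramp_increment must be positive")

    @classmethod
    def with_link_turns(cls, turns: float, **kwargs) -> "SimulationConfig":
        return cls(link_constrained=True, link_target=2.0 * np.pi * turns, **kwargs)


@dataclass
class TraceRecord:
    """Per-cycle observables plus summary statistics.

    ``data`` columns: cycle, z (A), link/twist/writhe (rad), accept_rate.
    Standard errors use block averaging (20 blocks) so that sweep-to-
    sweep correlation does not understate them.
    """

    data: pd.DataFrame
    config: SimulationConfig

    def _block_se(self, x: np.ndarray, nblocks: int = 20) -> float:
        n = len(x)
        nblocks = max(2, min(nblocks, n))
        blocks = np.array_split(x, nblocks)
        bm = np.array([b.mean() for b in blocks])
        return float(bm.std(ddof=1) / np.sqrt(len(bm)))

    @property
    def mean_extension(self) -> float:
        return float(self.data["z"].mean())

    @property
    def se_extension(self) -> float:
        return self._block_se(self.data["z"].to_numpy())

    @property
    def mean_link(self) -> float:
        return float(self.data["link"].mean())

    @property
    def se_link(self) -> float:
        return self._block_se(self.data["link"].to_numpy())

    @property
    def var_link(self) -> float:
        return float(self.data["link"].var(ddof=1))

    @property
    def mean_twist(self) -> float:
        return float(self.data["twist"].mean())

    @property
    def mean_writhe(self) -> float:
        return float(self.data["writhe"].mean())

    @property
    def acceptance(self) -> float:
        return float(self.data["accept_rate"].mean())

    @property
    def torque(self) -> float:
        """Trap torque (pN*nm): k_rot * (Lk_t - <Lk>)."""
        if not self.config.link_constrained:
            raise ValueError("torque is defined for link-constrained runs only")
        return float(
            self.config.trap_stiffness * (self.config.link_target - self.mean_link)
        )

    def summary(self) -> dict:
        out = {
            "mean_z": self.mean_extension,
            "se_z": self.se_extension,
            "mean_link": self.mean_link,
            "se_link": self.se_link,
            "var_link": self.var_link,
            "mean_twist": self.mean_twist,
            "mean_writhe": self.mean_writhe,
            "acceptance": self.acceptance,
        }
        if self.config.link_constrained:
            out["torque"] = self.torque
        return out

    def to_csv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


class _Engine:
    """Mutable simulation state + proposal machinery (internal)."""

    def __init__(self, config: SimulationConfig, model, rng: np.random.Generator):
        self.config = config
        self.model = model
        self.rng = rng
        self.kbt = kbt(config.temperature)
        m = config.n_bp - 1
        if isinstance(model, GaussianStepModel):
            self._means = model.means
            self._factors = model.factors()
            self._ntypes = len(model.step_types)
            self._frag = None
        elif isinstance(model, FragmentLibrary):
            self._frag = [model.fragments[t] for t in model.step_types]
            self._ntypes = len(model.step_types)
            init = np.mean(np.vstack(self._frag), axis=0)
            self._means = init[None, :]
        else:
            raise TypeError(f"unsupported model type: {type(model)!r}")
        # state
        if isinstance(model, GaussianStepModel):
            init = model.mean_params()
        self.params = np.tile(init, (m, 1))
        self.Rs, self.ds = steps_to_transforms(self.params)
        self.origins = np.zeros((config.n_bp, 3))
        self.frames = np.zeros((config.n_bp, 3, 3))
        _kernels.rebuild_frames(self.Rs, self.ds, self.origins, self.frames)
        self.link_target = config.link_target

    def _proposals(self):
        m = self.params.shape[0]
        if self._frag is not None:
            props = np.empty((m, 6))
            types = self.rng.integers(self._ntypes, size=m)
            for i in range(m):
                rows = self._frag[types[i]]
                props[i] = rows[self.rng.integers(rows.shape[0])]
        elif self._ntypes == 1:
            props = self._means[0] + self.rng.standard_normal((m, 6)) @ self._factors[
                0
            ].T
        else:
            types = self.rng.integers(self._ntypes, size=m)
            z = self.rng.standard_normal((m, 6))
            props = self._means[types] + np.einsum(
                "mij,mj->mi", self._factors[types], z
            )
        Rp, dp = steps_to_transforms(props)
        unif = self.rng.random(m)
        return props, Rp, dp, unif

    def sweep(self) -> dict:
        """One full sequential sweep; returns observables of the new state."""
        props, Rp, dp, unif = self._proposals()
        cfg = self.config
        if cfg.link_constrained:
            nacc, lk, tw, wr = _kernels.sweep_link_constrained(
                self.params,
                self.Rs,
                self.ds,
                props,
                Rp,
                dp,
                unif,
                self.origins,
                self.frames,
                cfg.force,
                cfg.trap_stiffness,
                self.link_target,
                cfg.xy_constraint_k,
                self.kbt,
            )
            obs = {
                "z": float(self.origins[-1, 2]),
                "link": float(lk),
                "twist": float(tw),
                "writhe": float(wr),
            }
        else:
            nacc = _kernels.sweep_force(
                self.params,
                self.Rs,
                self.ds,
                props,
                Rp,
                dp,
                unif,
                cfg.force,
                cfg.xy_constraint_k,
                self.kbt,
            )
            _kernels.rebuild_frames(self.Rs, self.ds, self.origins, self.frames)
            obs = {"z": float(self.origins[-1, 2])}
            if cfg.record_topology:
                seg = np.diff(self.origins, axis=0)
                t = seg / np.linalg.norm(seg, axis=1)[:, None]
                l = np.ascontiguousarray(self.frames[:, :, 1])
                tw = float(_kernels.ribbon_twist_sum(t, l))
                if cfg.writhe_method in ("exact", "both"):
                    wr = float(_kernels.exact_writhe_sum(self.origins))
                else:
                    wr = float(_kernels.fuller_writhe_sum(t))
                obs.update(twist=tw, writhe=wr, link=tw + wr)
                if cfg.writhe_method == "both":
                    obs["writhe_fuller"] = float(_kernels.fuller_writhe_sum(t))
            else:
                obs.update(twist=np.nan, writhe=np.nan, link=np.nan)
        obs["accept_rate"] = nacc / self.params.shape[0]
        return obs

    def current_link(self) -> float:
        seg = np.diff(self.origins, axis=0)
        t = seg / np.linalg.norm(seg, axis=1)[:, None]
        l = np.ascontiguousarray(self.frames[:, :, 1])
        return float(
            _kernels.ribbon_twist_sum(t, l) + _kernels.fuller_writhe_sum(t)
        )

    def conformation(self) -> HelixConformation:
        return HelixConformation(
            steps=self.params.copy(),
            origins=self.origins.copy(),
            frames=self.frames.copy(),
        )


def mc_cycle(state: HelixConformation, model, config: SimulationConfig, rng):
    """One sequential MC sweep over an explicit conformation.

    Returns ``(new_state, stats)`` where stats holds the acceptance
    rate and current observables.  This is the transparent (slow-path)
    entry point; :func:`run_simulation` keeps state internal between
    sweeps.
    """
    eng = _Engine(config, model, rng)
    eng.params = np.array(state.steps, float, copy=True)
    eng.Rs, eng.ds = steps_to_transforms(eng.params)
    _kernels.rebuild_frames(eng.Rs, eng.ds, eng.origins, eng.frames)
    stats = eng.sweep()
    return eng.conformation(), stats


def _guard_fuller(config: SimulationConfig):
    if not config.link_constrained or config.writhe_method != "fuller":
        return
    ok = config.force >= 1.0
    if ok:
        return
    msg = (
        f"Fuller writhe at {config.force} pN is outside its validity envelope "
        "(>= 1 pN); constrained links may be wrong modulo 4*pi"
    )
    if config.strict_fuller_guard:
        raise ValueError(msg)
    warnings.warn(msg, FullerValidityWarning, stacklevel=3)


def _relax_and_ramp(engine: _Engine) -> None:
    """Relax under force, then ramp the trap target to the desired link.

    Protocol: ``relax_cycles`` force-only sweeps from the all-means
    initialization; for link-constrained runs, set the trap target to
    the current link, then repeatedly (a) step the target by
    ``ramp_increment`` degrees toward the desired link while it is more
    than one increment away, (b) sweep until the helix link is within
    one increment of the current target; finally ``post_ramp_cycles``
    sweeps at the full constraint.
    """
    cfg = engine.config
    relax_cfg = replace(
        cfg, link_constrained=False, record_topology=False
    )
    saved = engine.config
    engine.config = relax_cfg
    for _ in range(cfg.relax_cycles):
        engine.sweep()
    engine.config = saved
    if not cfg.link_constrained:
        return
    if cfg.link_target is None:
        raise ValueError("link_constrained requires link_target")
    inc = np.radians(cfg.ramp_increment)
    desired = cfg.link_target
    current = engine.current_link()
    engine.link_target = current
    while True:
        gap = desired - engine.link_target
        if abs(gap) <= inc:
            engine.link_target = desired
            break
        engine.link_target += np.sign(gap) * inc
        for cycle in range(cfg.ramp_cycle_cap):
            obs = engine.sweep()
            if abs(obs["link"] - engine.link_target) <= inc:
                break
        else:
            raise RuntimeError(
                f"trap ramp failed to converge at target {engine.link_target:.3f} rad "
                f"(desired {desired:.3f} rad, force {cfg.force} pN)"
            )
    for _ in range(cfg.post_ramp_cycles):
        engine.sweep()


def relax_and_ramp(config: SimulationConfig, model, rng=None) -> HelixConformation:
    """Equilibrate a helix per the relaxation + trap-ramping protocol.

    Returns the equilibrated conformation (no samples recorded).
    """
    _guard_fuller(config)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    engine = _Engine(config, model, rng)
    _relax_and_ramp(engine)
    return engine.conformation()


def run_simulation(config: SimulationConfig, model) -> TraceRecord:
    """Relax (and ramp, if constrained), then record ``n_samples`` sweeps."""
    _guard_fuller(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    engine = _Engine(config, model, rng)
    _relax_and_ramp(engine)
    rows = []
    for cycle in range(config.n_samples):
        obs = engine.sweep()
        obs["cycle"] = cycle
        rows.append(obs)
    data = pd.DataFrame(rows)
    cols = ["cycle", "z", "link", "twist", "writhe", "accept_rate"]
    if "writhe_fuller" in data.columns:
        cols.append("writhe_fuller")
    return TraceRecord(data=data[cols], config=config)


def _scan_seed(seed: int, i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(i,))


def force_scan(
    model,
    forces,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Unconstrained simulations at each force; one summary row each.

    Columns: force (pN), mean_z/se_z (A), mean_link/se_link/var_link,
    mean_twist, mean_writhe (rad), acceptance.
    """
    base = config or SimulationConfig()
    rows = []
    for i, f in enumerate(forces):
        rng_seed = int(_scan_seed(base.seed, i).generate_state(1, np.uint32)[0])
        cfg = replace(base, force=float(f), link_constrained=False, seed=rng_seed)
        trace = run_simulation(cfg, model)
        row = {"force": float(f)}
        row.update(trace.summary())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("force", ignore_index=True)


def natural_link(model, n_bp: int) -> float:
    """Relaxed link anchor (radians): (n_bp - 1) x mean twist parameter."""
    if isinstance(model, GaussianStepModel):
        mean_twist = model.mean_params()[5]
    else:
        mean_twist = np.mean(np.vstack(list(model.fragments.values()))[:, 5])
    return (n_bp - 1) * np.radians(mean_twist)


def link_scan(
    model,
    turns,
    force: float,
    config: SimulationConfig | None = None,
    relative: bool = True,
) -> pd.DataFrame:
    """Link-constrained simulations at fixed force over target links.

    ``turns`` are trap turns; with ``relative=True`` (default) they are
    added to the model's relaxed link (:func:`natural_link`), matching
    the experimental convention of counting magnet rotations from the
    torsionally relaxed state.  Columns: link_target (rad), turns,
    mean_z/se_z (A), mean_link, var_link, torque (pN*nm), acceptance.
    """
    base = config or SimulationConfig()
    anchor = natural_link(model, base.n_bp) if relative else 0.0
    rows = []
    for i, nt in enumerate(turns):
        rng_seed = int(_scan_seed(base.seed, i).generate_state(1, np.uint32)[0])
        cfg = replace(
            base,
            force=float(force),
            link_constrained=True,
            link_target=anchor + 2.0 * np.pi * float(nt),
            seed=rng_seed,
        )
        trace = run_simulation(cfg, model)
        row = {"link_target": cfg.link_target, "turns": float(nt)}
        row.update(trace.summary())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("link_target", ignore_index=True)
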