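"""Deterministic synthetic fixtures: ideal helices, step databases with
planted structure, known-topology ribbons, and closed-form WLC curves.

Everything here is generated from (parameters, seed) so the full
pipeline -- curation, sampling, topology, simulation, fitting -- is
testable with no external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import HelixConformation, reconstruct_helix
from .models import DNA_DEFAULT_MEAN, DNA_DEFAULT_SD, PARAM_COLS, STEP_TYPES
from .topology import RibbonGeometry
from .fits import wlc_extension

__all__ = [
    "make_ideal_helix",
    "make_synthetic_step_db",
    "make_known_topology_ribbon",
    "make_wlc_curve",
]

# A-form-like cluster center used for the planted decoy: strongly
# negative slide with elevated roll and reduced twist -- the signature
# that curation must separate from the B-form cluster.
AFORM_MEAN = np.array([0.00, -1.55, 3.25, 0.10, 8.00, 31.50])
AFORM_SD = np.array([0.40, 0.35, 0.20, 2.50, 3.50, 3.50])


def make_ideal_helix(params, n_bp: int) -> HelixConformation:
    """Helix of ``n_bp`` base pairs repeating a single step parameter set."""
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    return reconstruct_helix(np.tile(np.asarray(params, float), (n_bp - 1, 1)))


def make_synthetic_step_db(
    n_main: int = 900,
    n_decoy: int = 80,
    n_outliers: int = 20,
    main_mean=DNA_DEFAULT_MEAN,
    main_sd=DNA_DEFAULT_SD,
    decoy_mean=AFORM_MEAN,
    decoy_sd=AFORM_SD,
    seed: int = 0,
    with_types: bool = True,
) -> pd.DataFrame:
    """Labeled synthetic step-parameter table for curation tests.

    Three planted populations: a B-like Gaussian main cluster, an
    A-like decoy cluster, and gross outliers (Z-form twists <= 5 deg,
    intercalation-like rises >= 5.5 A, and far 6-sigma excursions).
    The ``label`` column carries the ground truth ('main', 'decoy',
    'outlier'); ``step_type`` is assigned uniformly when requested.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    main = rng.normal(main_mean, main_sd, size=(n_main, 6))
    blocks.append((main, "main"))
    if n_decoy:
        blocks.append((rng.normal(decoy_mean, decoy_sd, size=(n_decoy, 6)), "decoy"))
    if n_outliers:
        out = rng.normal(main_mean, main_sd, size=(n_outliers, 6))
        kinds = rng.integers(3, size=n_outliers)
        out[kinds == 0, 5] = rng.uniform(-2.0, 5.0, size=(kinds == 0).sum())  # twist
        out[kinds == 1, 2] = rng.uniform(5.5, 8.0, size=(kinds == 1).sum())  # rise
        mask = kinds == 2
        cols = rng.integers(6, size=mask.sum())
        signs = rng.choice([-1.0, 1.0], size=mask.sum())
        for r, c, s in zip(np.where(mask)[0], cols, signs):
            out[r, c] = main_mean[c] + s * 6.5 * main_sd[c]
        blocks.append((out, "outlier"))
    rows = np.vstack([b for b, _ in blocks])
    labels = np.concatenate([[lab] * len(b) for b, lab in blocks])
    df = pd.DataFrame(rows, columns=PARAM_COLS)
    df["label"] = labels
    if with_types:
        df["step_type"] = rng.choice(STEP_TYPES, size=len(df))
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def make_known_topology_ribbon(kind: str, **kwargs) -> RibbonGeometry:
    """Closed-form ribbon fixtures for the topology operators.

    kinds:
      'straight_untwisted'        -- Tw = Wr = Lk = 0
      'straight_twisted'          -- Tw = total_twist, Wr = 0
      'planar_polygon'            -- zigzag in the xz-plane, Wr = 0
      'solenoid'                  -- discretized circular helix
    """
    if kind == "straight_untwisted":
        n = kwargs.get("n", 20)
        v = np.c_[np.zeros(n), np.zeros(n), np.arange(n, dtype=float)]
        l = np.tile([0.0, 1.0, 0.0], (n, 1))
        return RibbonGeometry(v, l)
    if kind == "straight_twisted":
        n = kwargs.get("n", 40)
        total = kwargs.get("total_twist", 4.0 * np.pi)
        v = np.c_[np.zeros(n), np.zeros(n), np.arange(n, dtype=float)]
        ang = np.linspace(0.0, total, n)
        l = np.c_[-np.sin(ang), np.cos(ang), np.zeros(n)]
        return RibbonGeometry(v, l)
    if kind == "planar_polygon":
        n = kwargs.get("n", 25)
        x = np.sin(np.linspace(0.0, 4.0, n))
        v = np.c_[x, np.zeros(n), np.linspace(0.0, 8.0, n)]
        l = np.tile([0.0, 1.0, 0.0], (n, 1))
        return RibbonGeometry(v, l)
    if kind == "solenoid":
        n = kwargs.get("n", 60)
        radius = kwargs.get("radius", 2.0)
        pitch = kwargs.get("pitch", 1.5)
        turns = kwargs.get("turns", 3.0)
        th = np.linspace(0.0, 2.0 * np.pi * turns, n)
        v = np.c_[radius * np.cos(th), radius * np.sin(th), pitch * th / (2.0 * np.pi)]
        # ribbon vectors: radially outward (perpendicular-ish to the axis curve)
        l = np.c_[np.cos(th), np.sin(th), np.zeros(n)]
        return RibbonGeometry(v, l)
    raise ValueError(f"unknown ribbon kind: {kind!r}")


def make_wlc_curve(
    A: float,
    S: float,
    L: float,
    forces,
    rel_noise: float = 0.0,
    seed: int = 0,
    model: str = "bouchiat_extensible",
) -> pd.DataFrame:
    """Synthetic force-extension data from a closed-form WLC.

    A in nm, S in pN, L in nm; multiplicative Gaussian noise of
    relative size ``rel_noise`` on the extensions.
    """
    forces = np.asarray(forces, float)
    z = np.atleast_1d(wlc_extension(forces, L, A, S, model=model))
    if rel_noise:
        rng = np.random.default_rng(seed)
        z = z * (1.0 + rng.normal(0.0, rel_noise, size=z.shape))
    return pd.DataFrame({"force": forces, "extension": z})
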