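"""Base-pair-step geometry.

A duplex is abstracted as a stack of rigid base pairs.  Each base pair
carries a right-handed orthonormal frame (columns: short axis x, long
axis y, normal z) and an origin (the base-pair center, in angstroms).
The six step parameters (shift, slide, rise in angstroms; tilt, roll,
twist in degrees) encode the rigid-body transform carrying frame *i*
onto frame *i+1* following the Calladine--El Hassan scheme (CEHS), the
convention used by 3DNA:

* bend magnitude ``Gamma = hypot(tilt, roll)`` about the RollTilt axis,
  at phase ``phi = atan2(tilt, roll)`` from the roll axis;
* rotation (in frame *i* coordinates)
  ``R = Rz(twist/2 - phi) @ Ry(Gamma) @ Rz(twist/2 + phi)``;
* the displacement ``(shift, slide, rise)`` is expressed in the
  mid-step triad ``Rm = Rz(twist/2 - phi) @ Ry(Gamma/2) @ Rz(phi)``.

The first base pair is always placed canonically: origin at 0, normal
along global +z, long axis along global +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepParams",
    "HelixConformation",
    "SuperhelixDescriptors",
    "step_to_transform",
    "transform_to_step",
    "steps_to_transforms",
    "reconstruct_helix",
    "extension",
    "superhelix_descriptors",
    "write_conformation",
]

#: Convenience alias: a step-parameter 6-vector is any array-like of
#: (shift, slide, rise, tilt, roll, twist) in (A, A, A, deg, deg, deg).
StepParams = np.ndarray

PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


def _rz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _as_params(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (6,):
        raise ValueError(f"step parameters must be a 6-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("step parameters must be finite")
    return p


def step_to_transform(params) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, d) carrying base-pair frame i onto frame i+1.

    Both the 3x3 rotation ``R`` and the displacement ``d`` (angstroms)
    are expressed in the coordinates of frame *i*.  Composition rule for
    global placement: ``G_{i+1} = G_i @ R``, ``o_{i+1} = o_i + G_i @ d``.
    """
    p = _as_params(params)
    R, d = steps_to_transforms(p[None, :])
    return R[0], d[0]


def steps_to_transforms(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`step_to_transform` for an (M, 6) parameter array."""
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("expected an (M, 6) array of step parameters")
    if not np.all(np.isfinite(p)):
        raise ValueError("step parameters must be finite")
    disp = p[:, :3]
    tilt, roll, twist = np.radians(p[:, 3]), np.radians(p[:, 4]), np.radians(p[:, 5])
    gamma = np.hypot(tilt, roll)
    phi = np.arctan2(tilt, roll)

    def zyz(a, b, g):
        # Rz(a) @ Ry(b) @ Rz(g), batched
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cg, sg = np.cos(g), np.sin(g)
        R = np.empty(a.shape + (3, 3))
        R[..., 0, 0] = ca * cb * cg - sa * sg
        R[..., 0, 1] = -ca * cb * sg - sa * cg
        R[..., 0, 2] = ca * sb
        R[..., 1, 0] = sa * cb * cg + ca * sg
        R[..., 1, 1] = -sa * cb * sg + ca * cg
        R[..., 1, 2] = sa * sb
        R[..., 2, 0] = -sb * cg
        R[..., 2, 1] = sb * sg
        R[..., 2, 2] = cb
        return R

    R = zyz(twist / 2.0 - phi, gamma, twist / 2.0 + phi)
    Rm = zyz(twist / 2.0 - phi, gamma / 2.0, phi)
    d = np.einsum("mij,mj->mi", Rm, disp)
    return R, d


def transform_to_step(R: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inverse of :func:`step_to_transform`: recover the six parameters.

    Exact (to floating point) for twists in (-180, 180] degrees and bend
    angles Gamma in [0, 180) degrees.
    """
    R = np.asarray(R, dtype=float)
    d = np.asarray(d, dtype=float)
    cos_gamma = np.clip(R[2, 2], -1.0, 1.0)
    gamma = np.arccos(cos_gamma)
    if np.sin(gamma) > 1e-12:
        a = np.arctan2(R[1, 2], R[0, 2])
        b = np.arctan2(R[2, 1], -R[2, 0])
        twist = a + b
        phi = 0.5 * (b - a)
        # (twist, phi) is defined modulo the joint shift
        # (twist + 2*pi, phi + pi); fold twist into (-pi, pi].
        if twist > np.pi:
            twist -= 2.0 * np.pi
            phi += np.pi
        elif twist <= -np.pi:
            twist += 2.0 * np.pi
            phi += np.pi
    else:
        # straight step: pure twist about z
        twist = np.arctan2(R[1, 0], R[0, 0])
        phi = 0.0
    Rm = _rz(twist / 2.0 - phi) @ _ry(gamma / 2.0) @ _rz(phi)
    disp = Rm.T @ d
    tilt = gamma * np.sin(phi)
    roll = gamma * np.cos(phi)
    return np.array(
        [disp[0], disp[1], disp[2], np.degrees(tilt), np.degrees(roll), np.degrees(twist)]
    )


@dataclass
class HelixConformation:
    """A duplex conformation: N-1 steps and the N derived frames.

    ``origins`` is (N, 3) in angstroms; ``frames`` is (N, 3, 3) with the
    frame axes as columns.  Frame 0 is the canonical placement (origin 0,
    identity orientation).
    """

    steps: np.ndarray  # (N-1, 6)
    origins: np.ndarray = field(repr=False)
    frames: np.ndarray = field(repr=False)

    @property
    def n_bp(self) -> int:
        return self.origins.shape[0]

    @property
    def ribbon_vectors(self) -> np.ndarray:
        """Base-pair long axes (frame y columns), shape (N, 3)."""
        return self.frames[:, :, 1]


def reconstruct_helix(steps) -> HelixConformation:
    """Build the full helix from an ordered list of step parameters."""
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    if steps.size == 0:
        raise ValueError("need at least one base-pair step")
    R, d = steps_to_transforms(steps)
    n = steps.shape[0] + 1
    origins = np.zeros((n, 3))
    frames = np.empty((n, 3, 3))
    frames[0] = np.eye(3)
    for i in range(n - 1):
        origins[i + 1] = origins[i] + frames[i] @ d[i]
        frames[i + 1] = frames[i] @ R[i]
    return HelixConformation(steps=steps, origins=origins, frames=frames)


def extension(h: HelixConformation) -> float:
    """Helix extension: z-coordinate of the last base-pair center (A)."""
    return float(h.origins[-1, 2])


@dataclass
class SuperhelixDescriptors:
    """Circular-superhelix description of a repeated-step axis curve."""

    radius: float  # A, distance of base-pair centers from the screw axis
    pitch: float  # A, axial advance per full superhelical turn (nan if straight)
    rise_per_step: float  # A, advance along the screw axis per step
    degenerate: bool  # True when the axis is straight (radius 0, pitch undefined)


def superhelix_descriptors(params, n: int = 100) -> SuperhelixDescriptors:
    """Superhelix traced by base-pair centers of the repeated step ``params``.

    A repeated rigid step is a screw motion; its invariant axis is found
    in closed form and the (constant) distance of base-pair centers from
    that axis is the superhelical radius.  ``n`` is accepted for
    interface compatibility with curve-fitting implementations; the
    closed form does not depend on it.
    """
    R, d = step_to_transform(params)
    # rotation angle and axis of the screw
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-9:
        return SuperhelixDescriptors(
            radius=0.0, pitch=np.nan, rise_per_step=float(np.linalg.norm(d)), degenerate=True
        )
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(axis)
    if norm < 1e-12:  # theta == pi
        w, v = np.linalg.eigh((R + np.eye(3)) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = axis / norm
    rise_axis = float(d @ axis)
    if rise_axis < 0:
        axis, rise_axis = -axis, -rise_axis
    # fixed point of the screw in the plane perpendicular to the axis:
    # (I - R) c = d_perp, solved in min-norm sense (c orthogonal to axis)
    d_perp = d - rise_axis * axis
    c, *_ = np.linalg.lstsq(np.eye(3) - R, d_perp, rcond=None)
    c_perp = c - (c @ axis) * axis
    radius = float(np.linalg.norm(c_perp))
    pitch = rise_axis * 2.0 * np.pi / theta
    return SuperhelixDescriptors(
        radius=radius, pitch=float(pitch), rise_per_step=rise_axis, degenerate=False
    )


def write_conformation(h: HelixConformation, path_or_file) -> None:
    """Dump base-pair centers and frame vectors as plain text (debugging)."""
    import contextlib

    if hasattr(path_or_file, "write"):
        cm = contextlib.nullcontext(path_or_file)
    else:
        cm = open(path_or_file, "w")
    with cm as fh:
        fh.write("# i x y z | x-axis | y-axis | z-axis\n")
        for i in range(h.n_bp):
            o = h.origins[i]
            f = h.frames[i]
            cols = " ".join(
                f"{f[0, j]:10.6f} {f[1, j]:10.6f} {f[2, j]:10.6f}" for j in range(3)
            )
            fh.write(f"{i:5d} {o[0]:12.5f} {o[1]:12.5f} {o[2]:12.5f} {cols}\n")
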