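"""Elastic-rod analysis: A, S, C and g from simulated or measured scans.

The helix is summarized by the elastic rod energy per contour length
(in units of kBT):

    E/kBT = 1/2 * int ds [ A b(s)^2 + B u(s)^2 + C th(s)^2 + 2 D u(s) th(s) ]

with b the bending density, u the fractional extension, th the twist
density (rad/length), A and C the bending/torsional persistence
lengths (nm), B = S/kBT the reduced stretch modulus (S in pN) and
D = g/kBT the dimensionless link-extension coupling (g in pN*nm;
negative g = over-winding upon extension).

Fitters:

* force-extension -> A (and S): Bouchiat et al. 7-term extensible or
  inextensible worm-like chain, or the Odijk high-force form;
* link variance vs force -> C_eff(F) = L / Var(Lk), then the
  Moroz-Nelson high-force expansion -> intrinsic C;
* torque vs target link (link-constrained runs) -> C independently;
* link-vs-force or extension-vs-link slopes -> g, converted through the
  rod relations above.

Contour length convention: L = n_steps * rise-along-the-screw-axis of
the mean step (NOT the axis-curve arc length).  For spring-like
helices (dsRNA) the two differ appreciably; the screw-axis rise is the
one conjugate to the measured extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import KBT_PN_NM
from .geometry import steps_to_transforms, superhelix_descriptors
from .models import GaussianStepModel

__all__ = [
    "ElasticConstants",
    "wlc_extension",
    "fit_wlc",
    "persistence_from_mean_transform",
    "ceff_from_link_fluctuations",
    "moroz_nelson_ceff",
    "fit_moroz_nelson",
    "c_from_torque_slope",
    "g_from_slopes",
    "twist_writhe_partition",
    "contour_length",
]

# Bouchiat et al. correction coefficients to the interpolation formula
# for the worm-like chain force-extension relation.
_BOUCHIAT_A = (-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944, -14.17718)


@dataclass
class ElasticConstants:
    """Fitted mechanical constants with asymptotic fit errors."""

    A: float = np.nan  # bending persistence length, nm
    A_err: float = np.nan
    S: float = np.nan  # stretch modulus, pN
    S_err: float = np.nan
    C: float = np.nan  # torsional persistence length, nm
    C_err: float = np.nan
    g1: float = np.nan  # link-extension coupling from link-vs-force, pN*nm
    g1_err: float = np.nan
    g2: float = np.nan  # link-extension coupling from extension-vs-link, pN*nm
    g2_err: float = np.nan
    contour_length: float = np.nan  # nm

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def contour_length(model_or_params, n_bp: int) -> float:
    """Contour length (nm): n_steps times the mean-step screw-axis rise."""
    if isinstance(model_or_params, GaussianStepModel):
        p = model_or_params.mean_params()
    else:
        p = np.asarray(model_or_params, float)
    rise = superhelix_descriptors(p).rise_per_step  # angstrom
    return (n_bp - 1) * rise / 10.0


def _wlc_ell(fa_over_kbt: float) -> float:
    """Solve the Bouchiat interpolation for relative extension ell."""

    def rhs(ell):
        val = ell - 0.25 + 0.25 / (1.0 - ell) ** 2
        for i, a in enumerate(_BOUCHIAT_A, start=2):
            val += a * ell**i
        return val

    if fa_over_kbt <= 0:
        return 0.0
    return optimize.brentq(
        lambda ell: rhs(ell) - fa_over_kbt, 0.0, 1.0 - 1e-12, xtol=1e-14
    )


def wlc_extension(force, L, A, S=np.inf, model="bouchiat_extensible", kbt=KBT_PN_NM):
    """Model extension (nm) at force (pN) for contour length L (nm).

    ``bouchiat_extensible``: z = L*(ell(F) + F/S) with ell from the
    7-term interpolation; ``inextensible``: same with S -> inf;
    ``odijk``: z = L*(1 - sqrt(kBT/(4*F*A)) + F/S), valid at high force.
    """
    force = np.atleast_1d(np.asarray(force, float))
    if model in ("bouchiat_extensible", "inextensible"):
        ell = np.array([_wlc_ell(f * A / kbt) for f in force])
        stretch = force / S if model == "bouchiat_extensible" else 0.0
        z = L * (ell + stretch)
    elif model == "odijk":
        z = L * (1.0 - np.sqrt(kbt / (4.0 * force * A)) + force / S)
    else:
        raise ValueError(f"unknown WLC model: {model!r}")
    return z if z.size > 1 else float(z[0])


def fit_wlc(
    force,
    extension,
    model: str = "bouchiat_extensible",
    contour_length: float | None = None,
    kbt: float = KBT_PN_NM,
):
    """Nonlinear least squares of a WLC force-extension model.

    ``force`` in pN, ``extension`` in nm.  When ``contour_length`` is
    given it is held fixed; otherwise L is fitted alongside.  Returns a
    dict with A, S, L and their asymptotic standard errors (S is inf
    with zero error for the inextensible model).
    """
    force = np.asarray(force, float)
    ext = np.asarray(extension, float)
    if force.size < 5:
        raise ValueError("need at least 5 force points")
    fit_L = contour_length is None
    L0 = ext.max() * 1.05 if fit_L else contour_length
    A0, S0 = 50.0, 1500.0
    extensible = model != "inextensible"

    def predict(theta):
        A = theta[0]
        k = 1
        S = np.inf
        if extensible:
            S = theta[k]
            k += 1
        L = theta[k] if fit_L else L0
        return wlc_extension(force, L, A, S, model=model, kbt=kbt)

    theta0 = [A0] + ([S0] if extensible else []) + ([L0] if fit_L else [])
    lower = [1e-3] + ([1.0] if extensible else []) + ([1e-3] if fit_L else [])
    res = optimize.least_squares(
        lambda th: predict(th) - ext, theta0, bounds=(lower, np.inf)
    )
    if not res.success:
        raise RuntimeError(f"WLC fit did not converge: {res.message}; residuals {res.fun}")
    # asymptotic covariance from the Jacobian
    dof = max(1, force.size - res.x.size)
    s2 = 2.0 * res.cost / dof
    JTJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(res.x.size, np.nan)
    out = {"A": res.x[0], "A_err": perr[0]}
    k = 1
    if extensible:
        out.update(S=res.x[k], S_err=perr[k])
        k += 1
    else:
        out.update(S=np.inf, S_err=0.0)
    if fit_L:
        out.update(L=res.x[k], L_err=perr[k])
    else:
        out.update(L=L0, L_err=0.0)
    return out


def persistence_from_mean_transform(
    model: GaussianStepModel,
    n_draws: int = 200_000,
    rng: np.random.Generator | None = None,
):
    """Bending persistence length from the averaged step transform.

    Tangent correlations decay per step by the dominant (real)
    eigenvalue lam of the sampler-averaged step rotation matrix, so
    A = -h / ln(lam) with h the screw-axis rise of the mean step.
    Returns (A_nm, A_err_nm); the error is a 10-chunk split of the
    Monte Carlo average.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if model.pooled_mode:
        types = np.zeros(n_draws, dtype=int)
    else:
        types = rng.integers(len(model.step_types), size=n_draws)
    z = rng.standard_normal((n_draws, 6))
    draws = model.means[types] + np.einsum("mij,mj->mi", model.factors()[types], z)
    R, _ = steps_to_transforms(draws)

    def lam_of(Rblock):
        w = np.linalg.eigvals(Rblock.mean(axis=0))
        real = w[np.abs(w.imag) < 1e-9].real
        if real.size == 0:
            raise RuntimeError("no real eigenvalue of the mean rotation")
        return real.max()

    h = superhelix_descriptors(model.mean_params()).rise_per_step / 10.0  # nm
    lam = lam_of(R)
    if lam >= 1.0:
        raise ValueError("mean rotation has no decay (lam >= 1): A undefined/infinite")
    A = -h / np.log(lam)
    chunks = np.array_split(R, 10)
    As = np.array([-h / np.log(lam_of(c)) for c in chunks])
    return float(A), float(As.std(ddof=1) / np.sqrt(len(As)))


def ceff_from_link_fluctuations(var_link, L: float):
    """Effective torsional persistence length C_eff = L / Var(Lk).

    ``var_link`` in rad^2 (scalar or array), L in nm; returns nm.
    """
    var_link = np.asarray(var_link, float)
    if np.any(var_link <= 0):
        raise ValueError("link variance must be positive")
    out = L / var_link
    return out if out.ndim else float(out)


def moroz_nelson_ceff(force, C, A, kbt=KBT_PN_NM):
    """Moroz-Nelson high-force expansion of the effective torsional
    persistence length: C_eff = C * (1 - C/(4A) * sqrt(kBT/(A*F)))."""
    force = np.asarray(force, float)
    return C * (1.0 - (C / (4.0 * A)) * np.sqrt(kbt / (A * force)))


def fit_moroz_nelson(
    force,
    ceff,
    A: float,
    n_points: int = 6,
    kbt: float = KBT_PN_NM,
):
    """Fit the Moroz-Nelson expansion to C_eff(F); returns (C, C_err).

    Being a high-force expansion, only the ``n_points`` highest forces
    are used (default 6; at least 6 points required unless overridden).
    ``A`` is the independently fitted bending persistence length.
    """
    force = np.asarray(force, float)
    ceff = np.asarray(ceff, float)
    if force.size < n_points:
        raise ValueError(f"need at least {n_points} force points")
    order = np.argsort(force)
    sel = order[-n_points:]
    f, c = force[sel], ceff[sel]
    popt, pcov = optimize.curve_fit(
        lambda ff, C: moroz_nelson_ceff(ff, C, A, kbt), f, c, p0=[c.max()]
    )
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def c_from_torque_slope(
    link_scan: pd.DataFrame,
    L: float,
    x: str = "link_target",
    drop_ends: int = 0,
    kbt: float = KBT_PN_NM,
    r2_threshold: float = 0.9,
):
    """Torsional persistence length from the torque-vs-link slope.

    The trap torque k_rot*(Lk_t - <Lk>) is regressed on the target link
    (radians); C = slope * L / kBT.  ``drop_ends`` removes that many
    points from each extreme before fitting (the linear relation breaks
    at high |turns|).  Returns (C_nm, C_err_nm); warns when R^2 falls
    below ``r2_threshold``.
    """
    df = link_scan.sort_values(x)
    if drop_ends:
        df = df.iloc[drop_ends:-drop_ends]
    if len(df) < 3:
        raise ValueError("need at least 3 usable points")
    xv = df[x].to_numpy(float)
    tq = df["torque"].to_numpy(float)
    slope, intercept, se = _linfit(xv, tq)
    pred = slope * xv + intercept
    ss_res = np.sum((tq - pred) ** 2)
    ss_tot = np.sum((tq - tq.mean()) ** 2)
    if ss_tot > 0 and 1.0 - ss_res / ss_tot < r2_threshold:
        import warnings

        warnings.warn(
            f"torque vs link R^2 = {1 - ss_res / ss_tot:.3f}: nonlinear regime?",
            stacklevel=2,
        )
    C = slope * L / kbt
    if C <= 0:
        raise ValueError(f"non-positive torsional stiffness (slope {slope:.3g})")
    return float(C), float(se * L / kbt)


def _linfit(x, y):
    """Least-squares line; returns (slope, intercept, slope_se)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.c_[x, np.ones(n)]
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    dof = max(1, n - 2)
    s2 = np.sum((y - pred) ** 2) / dof
    sxx = np.sum((x - x.mean()) ** 2)
    return float(beta[0]), float(beta[1]), float(np.sqrt(s2 / sxx))


def g_from_slopes(
    scan: pd.DataFrame,
    mode: str,
    S: float,
    C: float,
    L: float,
    kbt: float = KBT_PN_NM,
    drop_ends: int | None = None,
):
    """Link-extension coupling g (pN*nm) from one of two experiments.

    mode='link_vs_force': unconstrained force scan; the link (offset to
    the lowest force) is regressed on force, slope m1 in rad/pN.  The
    rod relations give m1 = -D*L/(C*kBT*B) with B = S/kBT + D^2/C, a
    quadratic in D = g/kBT solved with the stable root.

    mode='extension_vs_link': link-constrained scan at fixed force; the
    extension (nm) is regressed on the target link (rad), slope m2 in
    nm/rad, and g = -m2 * S.  The first and last points are dropped by
    default (the linear relation breaks at high turns).

    Negative g means the helix over-winds upon extension.  Returns
    (g, g_err) with the error propagated linearly from the slope SE.
    """
    if mode == "link_vs_force":
        df = scan.sort_values("force")
        if drop_ends:
            df = df.iloc[drop_ends:-drop_ends]
        if len(df) < 3:
            raise ValueError("need at least 3 usable points")
        x = df["force"].to_numpy(float)
        y = df["mean_link"].to_numpy(float)
        y = y - y[0]
        m1, _, m1_se = _linfit(x, y)

        def g_of(m):
            if m == 0.0:
                return 0.0
            disc = L * L - 4.0 * m * m * kbt * C * S
            if disc < 0:
                raise ValueError("slope too large for the rod relations")
            D = -2.0 * m * C * S / (L + np.sqrt(disc))
            return kbt * D

        g = g_of(m1)
        dg = abs(g_of(m1 + m1_se) - g_of(max(m1 - m1_se, -m1_se))) / 2.0 if m1 else abs(
            g_of(m1_se)
        )
        return float(g), float(dg)
    elif mode == "extension_vs_link":
        drop = 1 if drop_ends is None else drop_ends
        df = scan.sort_values("link_target")
        if drop:
            df = df.iloc[drop:-drop]
        if len(df) < 3:
            raise ValueError("need at least 3 usable points")
        x = df["link_target"].to_numpy(float)
        y = df["mean_z"].to_numpy(float) / 10.0  # nm
        m2, _, m2_se = _linfit(x, y)
        return float(-m2 * S), float(m2_se * S)
    raise ValueError(f"unknown mode: {mode!r}")


def twist_writhe_partition(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean twist and writhe (radians) of a scan.

    Returns a view with the scan's condition column(s) plus mean_twist,
    mean_writhe, and their sum (= mean link, Calugareanu).
    """
    cols = [c for c in ("force", "link_target", "turns") if c in scan.columns]
    out = scan[cols + ["mean_twist", "mean_writhe"]].copy()
    out["twist_plus_writhe"] = out["mean_twist"] + out["mean_writhe"]
    return out
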