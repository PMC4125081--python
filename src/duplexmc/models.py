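"""Step-parameter databases, curation, and sampling models.

A step-parameter database is a table with one row per observed
base-pair step (columns ``shift slide rise tilt roll twist`` in A/deg,
plus optional metadata: ``step_type``, ``resolution``, ``protein``).
Curation filters crystallographic artifacts; the surviving rows are
summarized either as per-step-type multivariate Gaussians (16
dinucleotide types, or one pooled distribution) or kept verbatim as a
fragment library for direct resampling.

The bundled default DNA/RNA models carry the curated-survey means and
standard deviations of the six parameters with a *diagonal* covariance:
the parameter-parameter couplings (off-diagonal covariances) of the
full curated datasets are not included, so mechanical predictions that
hinge on those couplings (notably the stretch modulus and the
link-extension coupling) are not expected to be quantitative with the
bundled models.  Supply a full-covariance model for those.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAM_COLS = ["shift", "slide", "rise", "tilt", "roll", "twist"]

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The 16 dinucleotide step types, 5'->3' on the leading strand.
STEP_TYPES = tuple(a + b for a in _BASES for b in _BASES)

#: Sign flips under strand reversal (shift and tilt negate).
_FLIP = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])


def complement_step_type(step_type: str) -> str:
    """Strand-reversed partner of a dinucleotide step (e.g. AC -> GT)."""
    return _COMP[step_type[1]] + _COMP[step_type[0]]


# Curated-survey default parameter statistics (mean, SD) per column, for
# random-sequence B-DNA and A-RNA duplexes (2.8 A resolution cutoff,
# protein-free structures, A-form cluster removed for DNA).
DNA_DEFAULT_MEAN = np.array([0.00, 0.32, 3.30, -0.05, 1.60, 35.21])
DNA_DEFAULT_SD = np.array([0.57, 0.86, 0.23, 3.56, 5.17, 6.24])
RNA_DEFAULT_MEAN = np.array([0.00, -1.58, 3.22, 0.02, 7.89, 31.72])
RNA_DEFAULT_SD = np.array([0.57, 0.39, 0.20, 2.86, 4.33, 4.25])


@dataclass
class CurationConfig:
    """Filters applied to a raw step-parameter table.

    Rows are dropped when: the source resolution is worse than
    ``resolution_cutoff``; the structure is protein-bound (unless
    included); twist <= ``twist_floor`` (Z-form contamination); rise >=
    ``rise_ceiling`` (intercalation); or any parameter sits more than
    ``sd_outlier_k`` standard deviations from the mean of the
    already-thresholded set (single pass).  For B-form DNA datasets,
    k-means clustering with ``kmeans_k`` clusters separates and removes
    the A-form cluster.
    """

    resolution_cutoff: float = 2.8
    include_protein_bound: bool = False
    twist_floor: float = 5.0  # degrees
    rise_ceiling: float = 5.5  # angstroms
    sd_outlier_k: float = 4.0
    kmeans_k: int = 3
    remove_aform: bool = False
    per_type_sd: bool = False  # SD filter per step type (16-type mode)
    kmeans_seed: int = 0

    def __post_init__(self):
        if self.resolution_cutoff <= 0 or self.rise_ceiling <= 0:
            raise ValueError("cutoffs must be positive")
        if self.sd_outlier_k <= 0 or self.kmeans_k < 2:
            raise ValueError("invalid curation parameters")


def read_step_table(path) -> pd.DataFrame:
    """Read a delimited step-parameter table (whitespace or comma)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PARAM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"step table missing columns: {missing}")
    return df


def write_step_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _aform_clusters(centroids: np.ndarray) -> np.ndarray:
    """Identify A-form-like centroids by their slide.

    In step-parameter space the A-form cluster sits at slide ~ -1.5 A
    (with elevated roll and reduced twist), while B-form centroids stay
    above slide ~ -0.6 A even when k-means subdivides a pure B
    population.  An absolute rule (rather than "remove the most extreme
    cluster") keeps curation idempotent: rerunning on already-curated
    B-form data removes nothing.
    """
    slide = centroids[:, PARAM_COLS.index("slide")]
    return slide < -0.9


def curate(table: pd.DataFrame, cfg: CurationConfig | None = None) -> pd.DataFrame:
    """Apply the curation filters; returns the surviving rows.

    Filter order: metadata (resolution, protein), hard thresholds
    (twist, rise), single-pass SD outlier filter on the thresholded
    set, then optional k-means A-form removal.
    """
    cfg = cfg or CurationConfig()
    df = table.copy()
    if "resolution" in df.columns:
        df = df[df["resolution"] <= cfg.resolution_cutoff]
    if not cfg.include_protein_bound and "protein" in df.columns:
        df = df[~df["protein"].astype(bool)]
    df = df[(df["twist"] > cfg.twist_floor) & (df["rise"] < cfg.rise_ceiling)]
    if len(df) == 0:
        raise ValueError("no rows survive the threshold filters")

    def sd_mask(sub: pd.DataFrame) -> pd.Series:
        x = sub[PARAM_COLS].to_numpy(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        return pd.Series(
            (np.abs(x - mu) <= cfg.sd_outlier_k * sd).all(axis=1), index=sub.index
        )

    if cfg.per_type_sd and "step_type" in df.columns:
        keep = df.groupby("step_type", group_keys=False).apply(sd_mask)
        df = df[keep.reindex(df.index)]
    else:
        df = df[sd_mask(df)]
    if len(df) == 0:
        raise ValueError("no rows survive the SD filter")

    if cfg.remove_aform:
        from sklearn.cluster import KMeans

        x = df[PARAM_COLS].to_numpy(float)
        z = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        km = KMeans(
            n_clusters=cfg.kmeans_k, n_init=10, random_state=cfg.kmeans_seed
        ).fit(z)
        centroids = np.vstack(
            [x[km.labels_ == k].mean(axis=0) for k in range(cfg.kmeans_k)]
        )
        bad = _aform_clusters(centroids)
        df = df[~bad[km.labels_]]
        if len(df) == 0:
            raise ValueError("k-means removed all clusters")
    return df


@dataclass
class GaussianStepModel:
    """Per-step-type multivariate Gaussians over the six step parameters.

    ``step_types`` lists the represented types ('pooled' for a single
    sequence-averaged distribution); ``means`` is (K, 6) in A/deg,
    ``covs`` (K, 6, 6), ``counts`` the number of observations behind
    each type.  16-type and pooled modes are mutually exclusive.
    """

    step_types: tuple
    means: np.ndarray
    covs: np.ndarray
    counts: np.ndarray
    n_unique: int | None = None
    _factors: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covs = np.asarray(self.covs, float).reshape(-1, 6, 6)
        self.counts = np.asarray(self.counts, int).ravel()
        if self.n_unique is None:
            self.n_unique = len(self.step_types)
        for k, c in enumerate(self.covs):
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError(f"covariance for {self.step_types[k]} not symmetric")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError(
                    f"covariance for {self.step_types[k]} not positive semi-definite"
                )

    @property
    def pooled_mode(self) -> bool:
        return self.step_types == ("pooled",)

    def factors(self) -> np.ndarray:
        """PSD square roots of the covariances (K, 6, 6), cached."""
        if self._factors is None:
            fac = np.empty_like(self.covs)
            for k, c in enumerate(self.covs):
                w, v = np.linalg.eigh(c)
                fac[k] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
            self._factors = fac
        return self._factors

    def type_index(self, step_type: str) -> int:
        try:
            return self.step_types.index(step_type)
        except ValueError:
            raise KeyError(f"unknown step type: {step_type!r}") from None

    def pooled(self) -> "GaussianStepModel":
        """Sequence-averaged single Gaussian: the uniform mixture of the
        per-type Gaussians, matched in mean and covariance."""
        if self.pooled_mode:
            return self
        mu = self.means.mean(axis=0)
        second = np.mean(
            [c + np.outer(m, m) for c, m in zip(self.covs, self.means)], axis=0
        )
        return GaussianStepModel(
            step_types=("pooled",),
            means=mu[None, :],
            covs=(second - np.outer(mu, mu))[None, :, :],
            counts=np.array([self.counts.sum()]),
        )

    def mean_params(self) -> np.ndarray:
        """Database-average 6-vector (used to initialize simulations)."""
        return self.means.mean(axis=0)

    def to_json(self, path) -> None:
        payload = {
            "kind": "gaussian_step_model",
            "n_unique": self.n_unique,
            "types": {
                t: {
                    "mean": self.means[k].tolist(),
                    "cov": self.covs[k].tolist(),
                    "n": int(self.counts[k]),
                }
                for k, t in enumerate(self.step_types)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GaussianStepModel":
        with open(path) as fh:
            payload = json.load(fh)
        types = tuple(payload["types"])
        return cls(
            step_types=types,
            means=np.array([payload["types"][t]["mean"] for t in types]),
            covs=np.array([payload["types"][t]["cov"] for t in types]),
            counts=np.array([payload["types"][t]["n"] for t in types]),
            n_unique=payload.get("n_unique"),
        )


@dataclass
class FragmentLibrary:
    """Observed step-parameter rows per step type, resampled verbatim."""

    fragments: dict  # step_type -> (n, 6) array

    def __post_init__(self):
        self.fragments = {
            t: np.atleast_2d(np.asarray(v, float)) for t, v in self.fragments.items()
        }
        for t, v in self.fragments.items():
            if v.shape[0] == 0 or v.shape[1] != 6:
                raise ValueError(f"fragment library for {t!r} must be non-empty (n, 6)")

    @property
    def step_types(self) -> tuple:
        return tuple(self.fragments)

    @classmethod
    def from_table(cls, table: pd.DataFrame, per_type: bool = True) -> "FragmentLibrary":
        if per_type and "step_type" in table.columns:
            groups = {
                t: g[PARAM_COLS].to_numpy(float)
                for t, g in table.groupby("step_type")
            }
        else:
            groups = {"pooled": table[PARAM_COLS].to_numpy(float)}
        return cls(fragments=groups)


def fit_gaussians(table: pd.DataFrame, per_type: bool = True) -> GaussianStepModel:
    """Sample mean + covariance per step type (or pooled over all rows).

    Requires >= 7 rows and a full-rank covariance per fitted type.
    """
    if per_type and "step_type" in table.columns:
        groups = list(table.groupby("step_type"))
    else:
        groups = [("pooled", table)]
    types, means, covs, counts = [], [], [], []
    for t, sub in groups:
        x = sub[PARAM_COLS].to_numpy(float)
        if x.shape[0] < 7:
            raise ValueError(f"step type {t!r}: need >= 7 rows, got {x.shape[0]}")
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1)
        if np.linalg.matrix_rank(cov, tol=1e-10) < 6:
            raise ValueError(f"step type {t!r}: rank-deficient covariance")
        types.append(str(t))
        means.append(mu)
        covs.append(cov)
        counts.append(x.shape[0])
    return GaussianStepModel(
        step_types=tuple(types),
        means=np.array(means),
        covs=np.array(covs),
        counts=np.array(counts),
    )


def symmetrize(model: GaussianStepModel) -> GaussianStepModel:
    """Merge complementary step types using strand-reversal symmetry.

    Each type is pooled with the strand-reversed data of its complement
    (shift and tilt negate; slide, rise, roll, twist are preserved),
    leaving 10 independent distributions mapped back onto the 16 keys.
    Self-complementary (palindromic) types are pooled with their own
    sign-flipped copy, which forces their shift and tilt means to zero.
    Total observation count over unique types is conserved.
    """
    if model.pooled_mode:
        raise ValueError("symmetrize requires a 16-type model")
    idx = {t: k for k, t in enumerate(model.step_types)}
    new_means = model.means.copy()
    new_covs = model.covs.copy()
    new_counts = model.counts.copy()
    done = set()
    F = np.diag(_FLIP)
    for t in model.step_types:
        c = complement_step_type(t)
        if t in done or c not in idx:
            continue
        k1, k2 = idx[t], idx[c]
        m1, m2 = model.means[k1], _FLIP * model.means[k2]
        c1, c2 = model.covs[k1], F @ model.covs[k2] @ F
        n1, n2 = model.counts[k1], model.counts[k2]
        if k1 == k2:  # palindromic: pool with own flipped copy, same n
            n1 = n2 = max(int(n1), 1)
            n_total = model.counts[k1]
        else:
            n_total = n1 + n2
        w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
        mu = w1 * m1 + w2 * m2
        second = w1 * (c1 + np.outer(m1, m1)) + w2 * (c2 + np.outer(m2, m2))
        cov = second - np.outer(mu, mu)
        new_means[k1], new_covs[k1], new_counts[k1] = mu, cov, n_total
        if k2 != k1:
            new_means[k2] = _FLIP * mu
            new_covs[k2] = F @ cov @ F
            new_counts[k2] = n_total
        done.update((t, c))
    n_unique = len({min(t, complement_step_type(t)) for t in model.step_types})
    return GaussianStepModel(
        step_types=model.step_types,
        means=new_means,
        covs=new_covs,
        counts=new_counts,
        n_unique=n_unique,
    )


def draw_step(source, step_type=None, rng: np.random.Generator | None = None):
    """Draw one step-parameter 6-vector.

    ``source`` is a :class:`GaussianStepModel` or
    :class:`FragmentLibrary`.  ``step_type`` selects a dinucleotide
    type; ``None`` (random-sequence mode) picks one of the represented
    types uniformly before drawing.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    if isinstance(source, GaussianStepModel):
        if step_type is None:
            k = int(rng.integers(len(source.step_types)))
        else:
            k = source.type_index(step_type)
        return source.means[k] + source.factors()[k] @ rng.standard_normal(6)
    if isinstance(source, FragmentLibrary):
        types = source.step_types
        if step_type is None:
            t = types[int(rng.integers(len(types)))]
        elif step_type in source.fragments:
            t = step_type
        else:
            raise KeyError(f"unknown step type: {step_type!r}")
        rows = source.fragments[t]
        return rows[int(rng.integers(rows.shape[0]))].copy()
    raise TypeError(f"unsupported sampler source: {type(source)!r}")


def dna_default_model() -> GaussianStepModel:
    """Random-sequence B-DNA default model (diagonal covariance).

    Means/SDs from the curated protein-free 2.8 A survey with the
    A-form cluster removed.  See the module docstring for what the
    missing covariance couplings imply.
    """
    return GaussianStepModel(
        step_types=("pooled",),
        means=DNA_DEFAULT_MEAN[None, :],
        covs=np.diag(DNA_DEFAULT_SD**2)[None, :, :],
        counts=np.array([2964]),
    )


def rna_default_model() -> GaussianStepModel:
    """Random-sequence A-RNA default model (diagonal covariance)."""
    return GaussianStepModel(
        step_types=("pooled",),
        means=RNA_DEFAULT_MEAN[None, :],
        covs=np.diag(RNA_DEFAULT_SD**2)[None, :, :],
        counts=np.array([4503]),
    )
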