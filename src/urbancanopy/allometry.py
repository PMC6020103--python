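"""Tree-volume allometry from terrestrial-LiDAR QSM trees.

Terrestrial laser scanning yields, per tree, a set of quantitative structure
model (QSM) reconstructions whose cylinder volumes estimate woody volume V.
After quality control, those trees calibrate two kinds of model used by the
airborne pipeline:

* a volume allometry ``V = k_Ar * Ar + k_exp * a * b**H`` fitted through the
  origin, where ``Ar`` is projected crown area, ``H`` maximum crown height
  and ``a * b**H`` an exponential height term fitted first;
* height->radius threshold lines ``r = beta + alpha * H`` that drive the
  canopy-splitting stage of individual tree detection: the ``bt_mean`` kind
  is the plain OLS mean line (the hierarchical-clustering radius threshold)
  and the ``split_95pi`` kind is a line through the upper 95% prediction
  bound (a crown wider than this bound for its height is flagged as a merged
  canopy).

Models follow the statsmodels convention: a model object is built from data
and ``fit()`` returns a results object carrying estimates, uncertainties and
a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from sklearn.neighbors import NearestNeighbors

from .metrics import crown_radius

__all__ = [
    "QSMTree", "load_qsm_table", "qsm_trees_from_dataframe",
    "qc_volume_stability", "qc_point_density",
    "ExponentialHeightModel", "fit_exponential_height",
    "ThresholdModel", "ThresholdRegression", "fit_threshold_model",
    "VolumeAllometry", "VolumeAllometryResults",
    "fit_volume_allometry", "predict_volume",
]


# ---------------------------------------------------------------------------
# QSM trees and quality control

@dataclass
class QSMTree:
    """One TLS-measured tree with its QSM reconstruction volumes."""

    id: str
    location: str
    dbh: float               # stem diameter at 1.3 m (m)
    H: float                 # maximum height (m)
    Ar: float                # projected crown area (m^2)
    recon_volumes: np.ndarray | None = None   # up to 10 volumes (m^3)
    V: float | None = None   # mean volume (m^3)
    species: str = ""
    wood_density: float | None = None  # kg m^-3

    def __post_init__(self):
        if self.recon_volumes is not None:
            self.recon_volumes = np.asarray(self.recon_volumes, dtype=float)
            if self.V is None:
                self.V = float(self.recon_volumes.mean())
        if self.V is None:
            raise ValueError("need either recon_volumes or V")
        for name in ("dbh", "H", "Ar", "V"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def r(self) -> float:
        return crown_radius(self.Ar)

    @property
    def v_ci95(self) -> float:
        """95% CI half-width of the reconstruction volumes as a fraction of V."""
        return _ci95_halfwidth(self.recon_volumes) / self.V


def _ci95_halfwidth(volumes: np.ndarray) -> float:
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.size
    if n < 2:
        raise ValueError("need >= 2 reconstruction volumes")
    sem = volumes.std(ddof=1) / np.sqrt(n)
    return float(scipy.stats.t.ppf(0.975, n - 1) * sem)


def qc_volume_stability(tree: QSMTree, max_rel_ci: float = 0.10) -> bool:
    """Reconstruction-stability test.

    Passes when the t-based 95% confidence half-width of the QSM volumes is
    at most ``max_rel_ci`` (10%) of the mean volume.
    """
    if tree.recon_volumes is None:
        raise ValueError("tree has no reconstruction volumes")
    return _ci95_halfwidth(tree.recon_volumes) <= max_rel_ci * tree.V


def qc_point_density(points, slice_height: float = 1.0,
                     max_mean_nn: float = 0.05, k: int = 4,
                     min_slice_points: int = 5):
    """Slice-wise point-density test for a TLS tree cloud.

    For every ``slice_height``-metre z-slice except the uppermost, the mean
    Euclidean distance between each point and its ``k`` closest neighbours
    must be at most ``max_mean_nn`` metres.  Slices with fewer than
    ``min_slice_points`` points are skipped.

    Returns ``(passed, per_slice)`` where ``per_slice`` is a list of
    ``(slice_index, mean_nn_distance)`` tuples for the evaluated slices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 3:
        raise ValueError("need an (n, 3) point array")
    idx = np.floor(pts[:, 2] / slice_height).astype(np.int64)
    top = idx.max()
    per_slice = []
    for s in np.unique(idx):
        if s == top:          # uppermost slice excluded: sparse by nature
            continue
        sl = pts[idx == s]
        if len(sl) < min_slice_points:
            continue
        nn = NearestNeighbors(n_neighbors=min(k + 1, len(sl))).fit(sl)
        dist, _ = nn.kneighbors(sl)
        per_slice.append((int(s), float(dist[:, 1:].mean())))
    passed = all(d <= max_mean_nn for _, d in per_slice)
    return passed, per_slice


_QSM_CSV_VOLS = [f"vol_{i}" for i in range(1, 11)]


def qsm_trees_from_dataframe(df: pd.DataFrame) -> list[QSMTree]:
    """Build QSMTree objects from the tabular schema
    ``id, site, dbh_m, h_m, ar_m2, vol_1..vol_10, species``."""
    trees = []
    vol_cols = [c for c in _QSM_CSV_VOLS if c in df.columns]
    for _, row in df.iterrows():
        vols = row[vol_cols].to_numpy(dtype=float) if vol_cols else None
        trees.append(QSMTree(
            id=str(row["id"]), location=str(row.get("site", "")),
            dbh=float(row["dbh_m"]), H=float(row["h_m"]),
            Ar=float(row["ar_m2"]), recon_volumes=vols,
            species=str(row.get("species", "")),
            wood_density=(float(row["wood_density"])
                          if "wood_density" in row and pd.notna(row["wood_density"])
                          else None)))
    return trees


def load_qsm_table(path) -> list[QSMTree]:
    """Read a QSM-tree CSV (schema: id, site, dbh_m, h_m, ar_m2,
    vol_1..vol_10, species)."""
    return qsm_trees_from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Exponential height term

@dataclass
class ExponentialHeightModel:
    """V = a * b**H; ``b`` is a dimensionless per-metre growth factor."""

    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be positive")

    def predict(self, H) -> np.ndarray:
        return self.a * np.power(self.b, np.asarray(H, dtype=float))


def _fit_exponential(H: np.ndarray, V: np.ndarray) -> ExponentialHeightModel:
    H = np.asarray(H, dtype=float)
    V = np.asarray(V, dtype=float)
    if H.size < 3:
        raise ValueError("need >= 3 trees to fit the exponential height term")
    if (V <= 0).any():
        raise ValueError("volumes must be positive")
    if np.ptp(H) <= 0:
        raise ValueError("degenerate height range")
    # log-linear initialisation, then iteratively reweighted least squares
    # with relative weights: volume scatter grows with tree size
    # (multiplicative error), so each point is weighted by 1/fitted^2
    slope, intercept = np.polyfit(H, np.log(V), 1)
    a, b = float(np.exp(intercept)), float(np.exp(slope))
    f = lambda h, aa, bb: aa * np.power(bb, h)  # noqa: E731
    try:
        for _ in range(3):
            sigma = np.maximum(f(H, a, b), 1e-12)
            popt, _ = scipy.optimize.curve_fit(f, H, V, p0=[a, b],
                                               sigma=sigma, maxfev=10000)
            a2, b2 = float(popt[0]), float(popt[1])
            if not (a2 > 0 and b2 > 0 and np.isfinite(a2)
                    and np.isfinite(b2)):
                break
            if abs(a2 - a) <= 1e-12 * abs(a) and abs(b2 - b) <= 1e-12 * abs(b):
                a, b = a2, b2
                break
            a, b = a2, b2
    except RuntimeError:
        pass
    return ExponentialHeightModel(a, b)


def fit_exponential_height(trees: list[QSMTree]) -> ExponentialHeightModel:
    """Fit V = a * b**H to QSM trees by least squares (log-linear start)."""
    H = np.array([t.H for t in trees])
    V = np.array([t.V for t in trees])
    return _fit_exponential(H, V)


# ---------------------------------------------------------------------------
# Height -> radius threshold lines (canopy splitting)

@dataclass
class ThresholdModel:
    """A line ``r = beta + alpha * H`` over crown height.

    kind ``bt_mean``   : OLS mean line; the radius threshold B_t for
                         hierarchical canopy splitting.
    kind ``split_95pi``: line through the upper 95% prediction bound; crowns
                         with r above this line are treated as merged
                         canopies and split.
    """

    alpha: float
    beta: float
    kind: str = "bt_mean"
    n: int = 0
    alpha_se: float | None = None
    beta_se: float | None = None

    def predict(self, H):
        return self.beta + self.alpha * np.asarray(H, dtype=float)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "kind": self.kind,
                "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(alpha=float(d["alpha"]), beta=float(d["beta"]),
                   kind=d.get("kind", "bt_mean"), n=int(d.get("n", 0)))


class ThresholdRegression:
    """Regression of equivalent crown radius on maximum height.

    Parameters
    ----------
    H, r : array-like
        Training heights (m) and equivalent crown radii (m).
    kind : {"bt_mean", "split_95pi"}
        Which threshold line ``fit()`` should return.
    """

    def __init__(self, H, r, kind: str = "bt_mean"):
        self.H = np.asarray(H, dtype=float)
        self.r = np.asarray(r, dtype=float)
        if kind not in ("bt_mean", "split_95pi"):
            raise ValueError(f"unknown threshold kind {kind!r}")
        if self.H.size != self.r.size:
            raise ValueError("H and r length mismatch")
        if self.H.size < 3:
            raise ValueError("need >= 3 trees to fit a threshold line")
        self.kind = kind

    @classmethod
    def from_trees(cls, trees: list[QSMTree], kind: str = "bt_mean"):
        return cls([t.H for t in trees], [t.r for t in trees], kind=kind)

    def fit(self) -> ThresholdModel:
        X = sm.add_constant(self.H)
        ols = sm.OLS(self.r, X).fit()
        beta, alpha = float(ols.params[0]), float(ols.params[1])
        if self.kind == "bt_mean":
            return ThresholdModel(alpha, beta, "bt_mean", int(ols.nobs),
                                  alpha_se=float(ols.bse[1]),
                                  beta_se=float(ols.bse[0]))
        # upper 95% prediction bound at each training H, linearised by a
        # straight-line fit through the bound points (the exact bound curves
        # with distance from the mean height; the applied criterion is linear)
        upper = ols.get_prediction(X).summary_frame(alpha=0.05)["obs_ci_upper"]
        slope, intercept = np.polyfit(self.H, np.asarray(upper), 1)
        return ThresholdModel(float(slope), float(intercept), "split_95pi",
                              int(ols.nobs))


def fit_threshold_model(trees: list[QSMTree], kind: str) -> ThresholdModel:
    """Fit a height->radius threshold line from QSM trees (see
    :class:`ThresholdRegression`)."""
    return ThresholdRegression.from_trees(trees, kind=kind).fit()


# ---------------------------------------------------------------------------
# Volume allometry (through the origin)

class VolumeAllometry:
    """Multiple linear regression of tree volume on crown metrics.

    ``V = k_Ar * Ar + k_exp * a * b**H`` with the intercept forced through
    the origin so small trees cannot receive negative volumes.  The
    exponential height term ``a * b**H`` is fitted first and then enters the
    linear model as a regressor.
    """

    def __init__(self, V, H, Ar):
        self.V = np.asarray(V, dtype=float)
        self.H = np.asarray(H, dtype=float)
        self.Ar = np.asarray(Ar, dtype=float)
        if not (self.V.size == self.H.size == self.Ar.size):
            raise ValueError("V, H, Ar length mismatch")
        if self.V.size < 4:
            raise ValueError("need >= 4 trees to fit the volume allometry")

    @classmethod
    def from_trees(cls, trees: list[QSMTree]) -> "VolumeAllometry":
        return cls([t.V for t in trees], [t.H for t in trees],
                   [t.Ar for t in trees])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, vol_col: str = "v_m3",
                       h_col: str = "h_m", ar_col: str = "ar_m2"):
        return cls(df[vol_col], df[h_col], df[ar_col])

    def _fit_exp_jointly(self) -> ExponentialHeightModel:
        """Estimate the exponential term jointly with the area term.

        A marginal fit of a*b**H to V would absorb volume that belongs to
        the Ar regressor (crown area itself grows with height), biasing
        both coefficients; so the exponential parameters are refined by
        nonlinear least squares on the full model V = k*Ar + a*b**H,
        initialised from the marginal fit.
        """
        marginal = _fit_exponential(self.H, self.V)
        X2 = np.column_stack([self.Ar, marginal.predict(self.H)])
        k0, s0 = np.linalg.lstsq(X2, self.V, rcond=None)[0]
        p0 = [max(k0, 1e-8), max(s0 * marginal.a, 1e-8), marginal.b]
        try:
            popt, _ = scipy.optimize.curve_fit(
                lambda X, k, a, b: k * X[0] + a * np.power(b, X[1]),
                np.vstack([self.Ar, self.H]), self.V, p0=p0,
                bounds=([-np.inf, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000)
            return ExponentialHeightModel(float(popt[1]), float(popt[2]))
        except RuntimeError:
            return marginal

    def fit(self, exp_model: ExponentialHeightModel | None = None
            ) -> "VolumeAllometryResults":
        """Fit the allometry.

        With ``exp_model`` supplied, the exponential term is held fixed and
        the two linear coefficients come from OLS through the origin.
        Otherwise the exponential parameters are estimated jointly with the
        area coefficient (see :meth:`_fit_exp_jointly`) and the reported
        ``k_exp`` is the OLS coefficient on the fitted exponential values
        (close to 1 by construction).
        """
        exp_model = exp_model or self._fit_exp_jointly()
        X = np.column_stack([self.Ar, exp_model.predict(self.H)])
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError("collinear regressors; cannot identify k_Ar "
                             "and k_exp")
        ols = sm.OLS(self.V, X).fit()
        return VolumeAllometryResults(self, exp_model, ols)


class VolumeAllometryResults:
    """Fitted volume allometry: coefficients, fit statistics, prediction."""

    def __init__(self, model: VolumeAllometry,
                 exp_model: ExponentialHeightModel, ols):
        self.model = model
        self.exp_model = exp_model
        self._ols = ols
        self.k_Ar = float(ols.params[0])
        self.k_exp = float(ols.params[1])
        self.bse = np.asarray(ols.bse, dtype=float)
        self.n = int(ols.nobs)
        resid = np.asarray(ols.resid, dtype=float)
        self.rmse = float(np.sqrt(np.mean(resid ** 2)))
        dof = max(self.n - 2, 1)
        self.residual_sd = float(np.sqrt(resid @ resid / dof))
        # through the origin: R^2 against the uncentred total sum of squares
        self.r2 = float(ols.rsquared)

    # convenience aliases matching the exponential term
    @property
    def a(self) -> float:
        return self.exp_model.a

    @property
    def b(self) -> float:
        return self.exp_model.b

    @property
    def params(self) -> pd.Series:
        return pd.Series({"k_Ar": self.k_Ar, "k_exp": self.k_exp,
                          "a": self.a, "b": self.b})

    def predict(self, H, Ar, return_flags: bool = False):
        """Predict volume (m^3) and its prediction sd for crown metrics.

        Negative raw predictions (possible for implausible metric
        combinations) are clipped to zero; ``return_flags`` additionally
        returns the boolean clipping mask.
        """
        H = np.asarray(H, dtype=float)
        Ar = np.asarray(Ar, dtype=float)
        raw = self.k_Ar * Ar + self.k_exp * self.exp_model.predict(H)
        clipped = raw < 0
        V = np.where(clipped, 0.0, raw)
        sd = np.broadcast_to(self.residual_sd, V.shape).copy()
        if return_flags:
            return V, sd, clipped
        return V, sd

    def summary(self) -> str:
        lines = [
            "Volume allometry  V = k_Ar*Ar + k_exp*(a*b^H)   [through origin]",
            f"n = {self.n}",
            f"k_Ar  = {self.k_Ar:10.5f}  (se {self.bse[0]:.5f})  [m^3 per m^2]",
            f"k_exp = {self.k_exp:10.5f}  (se {self.bse[1]:.5f})",
            f"a     = {self.a:10.5f}  [m^3]",
            f"b     = {self.b:10.5f}  [per m of height]",
            f"R^2 (uncentred) = {self.r2:.4f}",
            f"RMSE = {self.rmse:.3f} m^3   residual sd = {self.residual_sd:.3f} m^3",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"k_Ar": self.k_Ar, "k_exp": self.k_exp,
                "a": self.a, "b": self.b, "r2": self.r2, "rmse": self.rmse,
                "residual_sd": self.residual_sd, "n": self.n}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_fit(self, ax=None):
        """Observed vs fitted volume scatter with the 1:1 line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        fitted, _ = self.predict(self.model.H, self.model.Ar)
        ax.scatter(self.model.V, fitted, s=15, alpha=0.7)
        lim = [0, max(self.model.V.max(), fitted.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("QSM volume (m$^3$)")
        ax.set_ylabel("allometry volume (m$^3$)")
        return ax


@dataclass
class FrozenAllometry:
    """A volume allometry restored from serialized coefficients."""

    k_Ar: float
    k_exp: float
    exp_model: ExponentialHeightModel
    residual_sd: float = 0.0
    r2: float | None = None
    rmse: float | None = None
    n: int = 0

    @property
    def a(self) -> float:
        return self.exp_model.a

    @property
    def b(self) -> float:
        return self.exp_model.b

    def predict(self, H, Ar, return_flags: bool = False):
        return VolumeAllometryResults.predict(self, H, Ar,
                                              return_flags=return_flags)

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenAllometry":
        return cls(k_Ar=float(d["k_Ar"]), k_exp=float(d["k_exp"]),
                   exp_model=ExponentialHeightModel(float(d["a"]),
                                                    float(d["b"])),
                   residual_sd=float(d.get("residual_sd", 0.0)),
                   r2=d.get("r2"), rmse=d.get("rmse"), n=int(d.get("n", 0)))

    @classmethod
    def from_json(cls, path) -> "FrozenAllometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_volume_allometry(trees: list[QSMTree]) -> VolumeAllometryResults:
    """Fit the through-origin volume allometry to a QSM-tree set."""
    return VolumeAllometry.from_trees(trees).fit()


def predict_volume(model, H, Ar):
    """Predict ``(V, pred_sd)`` from a fitted or frozen allometry."""
    return model.predict(H, Ar)
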