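"""Analysis stage: band-weight estimation, the mixed threshold model, and
cross-frequency descriptives.

Three fitted objects, organized model/results style:

* :class:`BandWeightModel` — simplex-constrained least squares for the weights
  omega_j tying the wideband longest delay to the narrowband ones:
  minimize sum_i (sum_j omega_j t_ij - T_i)^2 subject to sum_j omega_j = 1,
  omega_j >= 0.  A convex quadratic program with a unique optimum whenever the
  design has full rank.
* :class:`InterauralThresholdModel` — the linear threshold model
  T_mu = T_lambda + T_beta * rho + gamma_i + N(0, sigma) with participant
  random intercepts, fitted by REML through ``statsmodels`` MixedLM.
* :class:`CFCurveModel` — a monotone parametric curve for the group-mean
  longest delay versus center frequency (default: linear in log2 CF).

``fit_weights`` / ``fit_threshold_model`` / ``correlate_bands`` /
``fit_cf_curve`` are thin functional wrappers over these classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observer import ThresholdMatrix

__all__ = [
    "BandWeightModel",
    "BandWeightResults",
    "InterauralThresholdModel",
    "ThresholdModelResults",
    "CorrelationReport",
    "CFCurveModel",
    "CFCurveResults",
    "fit_weights",
    "predict_Tprime",
    "fit_threshold_model",
    "correlate_bands",
    "fit_cf_curve",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Band weights (simplex-constrained least squares)
# ---------------------------------------------------------------------------


class BandWeightModel:
    """Simplex-constrained least-squares model for the band weights.

    Parameters
    ----------
    matrix : ThresholdMatrix or (ndarray, ndarray)
        Narrowband design ``t_ij`` (participants x bands) and wideband target
        ``T_i``.
    """

    def __init__(self, matrix, cf_labels=None):
        if isinstance(matrix, ThresholdMatrix):
            self.exog = np.asarray(matrix.t_ij, dtype=float)
            self.endog = np.asarray(matrix.T_i, dtype=float)
            self.cf_labels = matrix.cf_labels
        else:
            exog, endog = matrix
            self.exog = np.asarray(exog, dtype=float)
            self.endog = np.asarray(endog, dtype=float)
            self.cf_labels = tuple(cf_labels) if cf_labels is not None else tuple(
                range(self.exog.shape[1])
            )
        if self.exog.ndim != 2 or self.endog.ndim != 1:
            raise ValueError("expected a 2-D design and a 1-D target")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("design and target row counts differ")
        if not (np.all(np.isfinite(self.exog)) and np.all(np.isfinite(self.endog))):
            raise ValueError("non-finite entries in the threshold data")
        n, m = self.exog.shape
        if n < m:
            warnings.warn(
                f"fewer participants ({n}) than bands ({m}); weights are "
                "under-determined",
                stacklevel=2,
            )

    @classmethod
    def from_csv(cls, path) -> "BandWeightModel":
        return cls(ThresholdMatrix.from_csv(path))

    def fit(self, positivity_floor: float = 0.0) -> "BandWeightResults":
        """Solve the constrained problem (deterministic, global optimum).

        ``positivity_floor`` > 0 enforces strict positivity omega_j >= floor
        instead of plain non-negativity.
        """
        A, b = self.exog, self.endog
        n, m = A.shape
        if positivity_floor < 0 or positivity_floor * m > 1:
            raise ValueError("positivity floor must satisfy 0 <= floor <= 1/m")
        ridge = 0.0
        if np.linalg.matrix_rank(A) < m:
            logger.warning(
                "rank-deficient design: solution not unique; returning the "
                "minimum-norm optimum (tiny ridge tie-break)"
            )
            ridge = 1e-9 * float(np.trace(A.T @ A)) / m

        AtA = A.T @ A + ridge * np.eye(m)
        Atb = A.T @ b

        def objective(w):
            r = A @ w - b
            return 0.5 * float(r @ r) + 0.5 * ridge * float(w @ w)

        def grad(w):
            return AtA @ w - Atb

        res = optimize.minimize(
            objective,
            x0=np.full(m, 1.0 / m),
            jac=grad,
            method="SLSQP",
            bounds=[(positivity_floor, 1.0)] * m,
            constraints=[
                {"type": "eq", "fun": lambda w: np.sum(w) - 1.0, "jac": lambda w: np.ones(m)}
            ],
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if not res.success:
            raise RuntimeError(f"constrained least squares failed: {res.message}")
        omega = np.clip(res.x, positivity_floor, None)
        omega = omega / omega.sum()
        residuals = A @ omega - b
        ss_res = float(residuals @ residuals)
        ss_tot = float(np.sum((b - b.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        active = tuple(int(j) for j in np.nonzero(omega <= positivity_floor + 1e-8)[0])
        return BandWeightResults(
            model=self,
            omega=omega,
            residuals=residuals,
            r_squared=r2,
            T_prime=float(np.mean(A @ omega)),
            active_constraints=active,
            objective=0.5 * ss_res,
        )


@dataclass
class BandWeightResults:
    """Fitted simplex weights with diagnostics."""

    model: BandWeightModel
    omega: np.ndarray
    residuals: np.ndarray
    r_squared: float
    T_prime: float
    active_constraints: tuple[int, ...]
    objective: float

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        A = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return A @ self.omega

    def summary(self) -> str:
        lines = ["Band-weight fit (simplex-constrained least squares)", "-" * 52]
        for j, (lbl, w) in enumerate(zip(self.model.cf_labels, self.omega)):
            pin = "  (at bound)" if j in self.active_constraints else ""
            lines.append(f"  omega[{lbl:>6}] = {w: .4f}{pin}")
        lines.append(f"  sum(omega)    = {self.omega.sum():.6f}")
        lines.append(f"  R^2           = {self.r_squared:.4f}")
        lines.append(f"  T' (mean wideband longest delay) = {self.T_prime:.3f} ms")
        if self.active_constraints:
            lines.append(f"  weights pinned at the bound: {self.active_constraints}")
        return "\n".join(lines)


def fit_weights(matrix, positivity_floor: float = 0.0) -> BandWeightResults:
    """Fit the simplex band weights from a threshold matrix."""
    return BandWeightModel(matrix).fit(positivity_floor=positivity_floor)


def predict_Tprime(fit: BandWeightResults, matrix=None) -> float:
    """Model-implied mean wideband longest delay: mean_i sum_j omega_j t_ij."""
    if matrix is None:
        return fit.T_prime
    A = matrix.t_ij if isinstance(matrix, ThresholdMatrix) else np.asarray(matrix, dtype=float)
    if A.shape[1] != fit.omega.shape[0]:
        raise ValueError("matrix column count does not match the fitted weights")
    return float(np.mean(A @ fit.omega))


# ---------------------------------------------------------------------------
# Mixed threshold model
# ---------------------------------------------------------------------------


class InterauralThresholdModel:
    """Linear threshold model with participant random intercepts.

    ``threshold = T_lambda + T_beta * rho + gamma_participant + N(0, sigma)``,
    fitted by REML via ``statsmodels`` MixedLM.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        threshold_col: str = "threshold_ms",
        rho_col: str = "rho",
        group_col: str = "participant",
    ):
        for col in (threshold_col, rho_col, group_col):
            if col not in data.columns:
                raise ValueError(f"column {col!r} missing from the observation table")
        if data[group_col].nunique() < 2:
            raise ValueError("need at least two participants")
        if data[rho_col].nunique() < 2:
            raise ValueError(
                "slope unidentifiable: need at least two distinct interaural "
                "correlation values"
            )
        self.data = data.reset_index(drop=True)
        self.cols = (threshold_col, rho_col, group_col)

    @classmethod
    def from_long_table(cls, df: pd.DataFrame, **kwargs) -> "InterauralThresholdModel":
        return cls(df, **kwargs)

    def fit(self, reml: bool = True) -> "ThresholdModelResults":
        import statsmodels.api as sm

        thr, rho, grp = self.cols
        exog = sm.add_constant(self.data[[rho]].to_numpy())
        with warnings.catch_warnings():
            # boundary variance estimates are legitimate in degenerate scenarios
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                self.data[thr].to_numpy(), exog, groups=self.data[grp].to_numpy()
            )
            res = model.fit(reml=reml)
        gamma_hat = {k: float(np.asarray(v)[0]) for k, v in res.random_effects.items()}
        cov_re = np.asarray(res.cov_re)
        return ThresholdModelResults(
            T_lambda_ms=float(res.params[0]),
            T_beta_ms=float(res.params[1]),
            se_T_lambda=float(res.bse[0]),
            se_T_beta=float(res.bse[1]),
            sigma_ms=float(np.sqrt(res.scale)),
            gamma_sd_ms=float(np.sqrt(cov_re[0, 0])),
            gamma_by_participant=gamma_hat,
            _sm_results=res,
        )


@dataclass
class ThresholdModelResults:
    """REML estimates of the threshold model and their standard errors."""

    T_lambda_ms: float
    T_beta_ms: float
    se_T_lambda: float
    se_T_beta: float
    sigma_ms: float
    gamma_sd_ms: float
    gamma_by_participant: dict = field(default_factory=dict)
    _sm_results: object = None

    def summary(self) -> str:
        lines = [
            "Mixed threshold model: threshold ~ rho + (1 | participant)",
            "-" * 58,
            f"  T_lambda (intercept) = {self.T_lambda_ms: .3f} ms  (SE {self.se_T_lambda:.3f})",
            f"  T_beta   (slope)     = {self.T_beta_ms: .3f} ms  (SE {self.se_T_beta:.3f})",
            f"  sigma (residual SD)  = {self.sigma_ms: .3f} ms",
            f"  participant SD       = {self.gamma_sd_ms: .3f} ms",
        ]
        return "\n".join(lines)

    def predict(self, rho: np.ndarray, participant=None) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        out = self.T_lambda_ms + self.T_beta_ms * rho
        if participant is not None:
            out = out + self.gamma_by_participant.get(participant, 0.0)
        return out


def fit_threshold_model(long_table: pd.DataFrame, **kwargs) -> ThresholdModelResults:
    """Fit the mixed threshold model from a (participant, rho, threshold) table."""
    return InterauralThresholdModel(long_table, **kwargs).fit()


# ---------------------------------------------------------------------------
# Cross-frequency correlations and the CF curve
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    """Pearson correlation of each narrowband column with the wideband vector."""

    cf_labels: tuple
    r: np.ndarray
    p_values: np.ndarray
    n: int
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cf": self.cf_labels, "r": self.r, "p": self.p_values})


def correlate_bands(matrix: ThresholdMatrix) -> CorrelationReport:
    """Correlate each narrowband column with the wideband longest delays."""
    if matrix.n < 3:
        raise ValueError("need at least three participants for a correlation")
    rs, ps, flags = [], [], []
    for j, cf in enumerate(matrix.cf_labels):
        col = matrix.t_ij[:, j]
        if np.std(col) == 0 or np.std(matrix.T_i) == 0:
            rs.append(np.nan)
            ps.append(np.nan)
            flags.append(f"zero-variance column at CF {cf}")
            continue
        r, p = stats.pearsonr(col, matrix.T_i)
        rs.append(float(r))
        ps.append(float(p))
    return CorrelationReport(
        cf_labels=matrix.cf_labels,
        r=np.asarray(rs),
        p_values=np.asarray(ps),
        n=matrix.n,
        flags=tuple(flags),
    )


class CFCurveModel:
    """Parametric curve for group-mean longest delay versus center frequency.

    ``family="loglinear"`` fits ``t = a + b * log2(cf)`` by ordinary least
    squares; ``family="logistic"`` fits a four-parameter logistic decay
    ``t = lo + (hi - lo) / (1 + (cf / c)**s)`` by nonlinear least squares.
    """

    def __init__(self, matrix: ThresholdMatrix | None = None, cf=None, means=None):
        if matrix is not None:
            self.cf = np.asarray(matrix.cf_labels, dtype=float)
            self.means = matrix.t_ij.mean(axis=0)
        else:
            self.cf = np.asarray(cf, dtype=float)
            self.means = np.asarray(means, dtype=float)
        if self.cf.size < 3:
            raise ValueError("need at least three center frequencies")

    def fit(self, family: str = "loglinear") -> "CFCurveResults":
        x, y = self.cf, self.means
        if family == "loglinear":
            lx = np.log2(x)
            res = stats.linregress(lx, y)
            params = {"intercept": float(res.intercept), "slope": float(res.slope)}
            pred = res.intercept + res.slope * lx
        elif family == "logistic":
            if x.size < 4:
                raise ValueError("logistic family needs at least four points")

            def f(cf, lo, hi, c, s):
                return lo + (hi - lo) / (1.0 + (cf / c) ** s)

            p0 = (float(y.min()), float(y.max()), float(np.sqrt(x.min() * x.max())), 1.0)
            bounds = (
                [0.0, 0.0, x.min() / 4.0, 0.05],
                [float(y.max()) * 2, float(y.max()) * 4, x.max() * 4.0, 20.0],
            )
            popt, _ = optimize.curve_fit(
                f, x, y, p0=p0, bounds=bounds, method="trf", maxfev=20000
            )
            params = dict(zip(("lo", "hi", "c", "s"), map(float, popt)))
            pred = f(x, *popt)
        else:
            raise ValueError("family must be 'loglinear' or 'logistic'")
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return CFCurveResults(model=self, family=family, params=params, r_squared=r2)


@dataclass
class CFCurveResults:
    model: CFCurveModel
    family: str
    params: dict
    r_squared: float

    def predict(self, cf) -> np.ndarray:
        cf = np.asarray(cf, dtype=float)
        if self.family == "loglinear":
            return self.params["intercept"] + self.params["slope"] * np.log2(cf)
        p = self.params
        return p["lo"] + (p["hi"] - p["lo"]) / (1.0 + (cf / p["c"]) ** p["s"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.geomspace(self.model.cf.min(), self.model.cf.max(), 200)
        ax.semilogx(self.model.cf, self.model.means, "o", label="group mean")
        ax.semilogx(grid, self.predict(grid), "-", label=f"{self.family} fit")
        ax.set_xlabel("center frequency (Hz)")
        ax.set_ylabel("longest detectable delay (ms)")
        ax.legend()
        return ax


def fit_cf_curve(matrix: ThresholdMatrix, family: str = "loglinear") -> CFCurveResults:
    """Fit the group-mean longest delay versus center frequency curve."""
    return CFCurveModel(matrix).fit(family=family)
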