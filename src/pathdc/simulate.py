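"""Synthetic data with the statistical structure the model assumes.

Child impact trajectories are drawn from a multivariate normal
x ~ N(0, R_x) with a user-chosen correlation matrix, and the parent
trajectory is the linear response y = sum_j b_j x_j + Gaussian noise.
With b scaled so that Var(y) = 1, the population standardized path
coefficients equal b itself, which makes parameter-recovery experiments
direct.  The module also carries a frozen reference fixture of published
four-child decision-analysis results (path coefficients, pairwise
products, decision coefficients) reconstructed from their printed
three-decimal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import PathwayDecisionAnalysis
from .path_model import PathModel

__all__ = [
    "SimulationConfig",
    "exchangeable_correlation",
    "default_config",
    "simulate_dataset",
    "exact_correlated_dataset",
    "ReferenceFixture",
    "reference_fixture",
    "RecoveryResult",
    "recovery_experiment",
]


def exchangeable_correlation(q: int, rho: float) -> np.ndarray:
    """Compound-symmetric correlation matrix (all off-diagonals = rho)."""
    if not -1.0 / (q - 1) < rho < 1.0:
        raise ValueError(f"rho={rho} not in the positive-definite range for q={q}")
    r = np.full((q, q), rho)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic parent/children dataset."""

    r_x: np.ndarray
    b: np.ndarray
    n: int
    noise_sd: float
    seed: int = 0

    def __post_init__(self):
        r_x = np.asarray(self.r_x, dtype=float)
        b = np.asarray(self.b, dtype=float).ravel()
        object.__setattr__(self, "r_x", r_x)
        object.__setattr__(self, "b", b)
        if r_x.ndim != 2 or r_x.shape[0] != r_x.shape[1]:
            raise ValueError("r_x must be square")
        if not np.allclose(r_x, r_x.T, atol=1e-12) or not np.allclose(
            np.diag(r_x), 1.0
        ):
            raise ValueError("r_x must be symmetric with a unit diagonal")
        if np.linalg.eigvalsh(r_x).min() <= 0:
            raise ValueError("r_x must be positive definite")
        if b.shape[0] != r_x.shape[0]:
            raise ValueError("b length must match r_x dimension")
        if self.n < self.q + 2:
            raise ValueError(f"need n >= q + 2 observations (n={self.n}, q={self.q})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def q(self) -> int:
        return self.r_x.shape[0]

    @property
    def y_sd(self) -> float:
        """Population standard deviation of the response."""
        return float(np.sqrt(self.b @ self.r_x @ self.b + self.noise_sd**2))

    @property
    def b_star_pop(self) -> np.ndarray:
        """Population standardized path coefficients b / sd(y)."""
        return self.b / self.y_sd

    @property
    def dc_pop(self) -> np.ndarray:
        """Population decision coefficients implied by r_x and b."""
        bs = self.b_star_pop
        return bs**2 + 2.0 * bs * (self.r_x @ bs - bs)


def default_config(
    q: int = 4,
    n: int = 12,
    rho: float = 0.3,
    r2: float = 0.9,
    seed: int = 0,
) -> SimulationConfig:
    """Study-scale default: a lactation-time-course-sized design.

    q children with exchangeable correlation rho, n contrasts, and
    direct effects of alternating sign scaled so that the population
    response variance is 1 and the population R^2 equals ``r2``
    (hence noise_sd = sqrt(1 - r2)).
    """
    r_x = exchangeable_correlation(q, rho)
    base = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(q)]) * (
        1.0 - 0.5 * (np.arange(q) % 3 == 2)
    )
    scale = np.sqrt(r2 / (base @ r_x @ base))
    return SimulationConfig(
        r_x=r_x, b=base * scale, n=n, noise_sd=float(np.sqrt(1.0 - r2)), seed=seed
    )


def simulate_dataset(
    config: SimulationConfig,
    *,
    child_ids: list[str] | None = None,
    parent_id: str = "y",
) -> pd.DataFrame:
    """Draw one dataset as an impact matrix (children rows + parent row).

    Rows are pathways, columns are contrasts ``t1..tn``; the parent row
    comes last.  Reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(config.r_x)
    x = rng.standard_normal((config.n, config.q)) @ chol.T
    y = x @ config.b + rng.normal(scale=config.noise_sd, size=config.n)
    ids = child_ids or [f"x{j + 1}" for j in range(config.q)]
    if len(ids) != config.q:
        raise ValueError("child_ids length must equal q")
    columns = [f"t{i + 1}" for i in range(config.n)]
    data = np.vstack([x.T, y])
    return pd.DataFrame(
        data, index=pd.Index([*ids, parent_id], name="pathway_id"), columns=columns
    )


def exact_correlated_dataset(
    r_x,
    b,
    n: int,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    child_ids: list[str] | None = None,
    parent_id: str = "y",
) -> pd.DataFrame:
    """Dataset whose *sample* correlations equal ``r_x`` exactly.

    Children are built from an orthonormal zero-mean basis rotated by the
    Cholesky factor of ``r_x`` (sample covariance exactly r_x, ddof=1);
    the parent is X @ b plus a noise direction orthogonal to every child
    in-sample, so cov(x_j, y) = (r_x b)_j exactly.  Useful for fixtures
    where the fitted correlation structure must be known in advance.
    """
    r_x = np.asarray(r_x, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    q = r_x.shape[0]
    if n < q + 2:
        raise ValueError(f"need n >= q + 2 (n={n}, q={q})")
    rng = np.random.default_rng(seed)
    raw = np.column_stack([np.ones(n), rng.standard_normal((n, q + 1))])
    basis, _ = np.linalg.qr(raw)
    z = basis[:, 1 : q + 1] * np.sqrt(n - 1)  # zero-mean, identity sample cov
    chol = np.linalg.cholesky(r_x)
    x = z @ chol.T
    u = basis[:, q + 1] * np.sqrt(n - 1)
    y = x @ b + noise_sd * u
    ids = child_ids or [f"x{j + 1}" for j in range(q)]
    columns = [f"t{i + 1}" for i in range(n)]
    return pd.DataFrame(
        np.vstack([x.T, y]),
        index=pd.Index([*ids, parent_id], name="pathway_id"),
        columns=columns,
    )


# ----------------------------------------------------------------------
# frozen reference fixture (four children, printed to 3 decimals)
# ----------------------------------------------------------------------
_B_STAR = np.array([0.383, -1.097, -2.593, 2.471])
# printed pairwise products r_jk * b_k; row j, column k (diagonal NaN)
_PRODUCTS = np.array(
    [
        [np.nan, -0.162, 2.504, -2.340],
        [0.057, np.nan, -0.198, 0.384],
        [-0.369, -0.084, np.nan, 2.462],
        [-0.362, -0.170, -2.585, np.nan],
    ]
)
# printed doubled products 2 b_j r_jk b_k; cell (3,1)=1.916 restores the
# symmetry its source table breaks by an apparent digit transposition
_DOUBLED = np.array(
    [
        [np.nan, -0.124, 1.916, -1.795],
        [-0.124, np.nan, 0.433, -0.842],
        [1.916, 0.434, np.nan, -12.772],
        [-1.795, -0.843, -12.799, np.nan],
    ]
)
_INDIRECT_SUMS = np.array([0.002, 0.243, 2.009, -3.117])
_R_JY = np.array([0.385, -0.854, -0.584, -0.647])
_RETRO = np.array([-0.700, -0.416, -0.278, 0.506])
_DC = np.array([0.148, 0.670, -3.697, -9.300])
_CHILD_IDS = ("x1", "x2", "x3", "x4")
_FIXTURE_N = 20  # working sample size; the source never states its own


@dataclass(frozen=True)
class ReferenceFixture:
    """Reference four-child decision analysis, values printed to 3 d.p.

    ``r_x`` is reconstructed from the printed products: each off-diagonal
    has two estimates (r_jk = P[j,k]/b_k = P[k,j]/b_j) which differ by
    rounding; the fixture averages them.  ``r_xy`` is the self-consistent
    R_x @ b*, which matches the printed total effects to ~2e-3; the
    printed totals themselves are in ``r_jy_printed``.
    """

    child_ids: tuple[str, ...]
    n: int
    b_star: np.ndarray
    r_x: np.ndarray
    r_xy: np.ndarray
    r_jy_printed: np.ndarray
    products_printed: pd.DataFrame
    doubled_products_printed: pd.DataFrame
    indirect_sums_printed: np.ndarray
    retro_printed: np.ndarray
    dc_expected: np.ndarray

    def model(self, **params) -> PathModel:
        """Fitted :class:`PathModel` built from b* and the reconstructed R_x."""
        est = PathwayDecisionAnalysis.from_coefficients(
            self.r_x, self.b_star, self.n, child_ids=self.child_ids, **params
        )
        return PathModel(
            parent_id="y",
            child_ids=self.child_ids,
            n=self.n,
            r_x=est.r_x_,
            r_xy=est.r_xy_,
            b_star=est.b_star_,
            r2=est.r2_,
            c_diag=est.c_diag_,
            condition_flag=est.condition_flag_,
        )

    def estimator(self, **params) -> PathwayDecisionAnalysis:
        return PathwayDecisionAnalysis.from_coefficients(
            self.r_x, self.b_star, self.n, child_ids=self.child_ids, **params
        )


def reference_fixture() -> ReferenceFixture:
    """Reconstruct the frozen four-child reference analysis."""
    b = _B_STAR
    q = len(b)
    r_x = np.eye(q)
    for j in range(q):
        for k in range(j + 1, q):
            est1 = _PRODUCTS[j, k] / b[k]
            est2 = _PRODUCTS[k, j] / b[j]
            r_x[j, k] = r_x[k, j] = 0.5 * (est1 + est2)
    ids = list(_CHILD_IDS)
    return ReferenceFixture(
        child_ids=_CHILD_IDS,
        n=_FIXTURE_N,
        b_star=b.copy(),
        r_x=r_x,
        r_xy=r_x @ b,
        r_jy_printed=_R_JY.copy(),
        products_printed=pd.DataFrame(_PRODUCTS, index=ids, columns=ids),
        doubled_products_printed=pd.DataFrame(_DOUBLED, index=ids, columns=ids),
        indirect_sums_printed=_INDIRECT_SUMS.copy(),
        retro_printed=_RETRO.copy(),
        dc_expected=_DC.copy(),
    )


# ----------------------------------------------------------------------
# parameter recovery
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RecoveryResult:
    """Bias/RMSE of b* and DC, and selection frequency per alpha."""

    config: SimulationConfig
    replicates: int
    b_star_true: np.ndarray
    dc_true: np.ndarray
    table: pd.DataFrame

    @property
    def b_rmse(self) -> np.ndarray:
        return self.table["b_rmse"].to_numpy()

    @property
    def dc_rmse(self) -> np.ndarray:
        return self.table["dc_rmse"].to_numpy()


def recovery_experiment(
    config: SimulationConfig,
    replicates: int,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> RecoveryResult:
    """Repeatedly simulate and refit; summarize estimator recovery.

    Truth is the population standardized coefficient vector
    ``config.b_star_pop`` and the decision coefficients it implies.
    Selection frequency is the fraction of replicates in which each
    child's |DC| reached its t-based cutoff.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    q = config.q
    b_true = config.b_star_pop
    dc_true = config.dc_pop
    seeds = np.random.SeedSequence(config.seed).generate_state(replicates) % (2**31)
    b_err = np.zeros((replicates, q))
    dc_err = np.zeros((replicates, q))
    sel = {alpha: np.zeros((replicates, q), dtype=bool) for alpha in alphas}
    for i, seed in enumerate(seeds):
        rep_cfg = SimulationConfig(
            r_x=config.r_x, b=config.b, n=config.n,
            noise_sd=config.noise_sd, seed=int(seed),
        )
        data = simulate_dataset(rep_cfg)
        est = PathwayDecisionAnalysis(alphas=alphas).fit(
            data.iloc[:q].to_numpy().T, data.iloc[q].to_numpy()
        )
        b_err[i] = est.b_star_ - b_true
        dc_err[i] = est.dc_ - dc_true
        for alpha in alphas:
            sel[alpha][i] = est.significant_[alpha]
    table = pd.DataFrame(
        {
            "b_bias": b_err.mean(axis=0),
            "b_rmse": np.sqrt((b_err**2).mean(axis=0)),
            "dc_bias": dc_err.mean(axis=0),
            "dc_rmse": np.sqrt((dc_err**2).mean(axis=0)),
            **{
                f"sel_freq_{alpha:g}": sel[alpha].mean(axis=0) for alpha in alphas
            },
        },
        index=pd.Index([f"x{j + 1}" for j in range(q)], name="child_id"),
    )
    return RecoveryResult(
        config=config,
        replicates=replicates,
        b_star_true=b_true,
        dc_true=dc_true,
        table=table,
    )
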