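"""Path-analysis / decision-coefficient estimator.

The model is a standardized multiple linear regression of one parent
pathway's impact trajectory on the trajectories of its q child pathways,
observed over n contrasts (time points or treatments).  Working entirely
on the Pearson correlation scale, the path coefficients b* solve the
normal equations

    R_x b* = R_xy

where R_x is the q x q child-child correlation matrix and R_xy the
child-parent correlation vector.  b*_j is the *direct effect* of child j;
r_jk b*_k are its *indirect effects* through correlated siblings, and the
total effect r_jy = b*_j + sum_{k!=j} r_jk b*_k.

The coefficient of determination decomposes as

    R^2 = sum_j (b*_j)^2  +  sum_{j<t} 2 b*_j r_jt b*_t

(direct plus indirect determination), and the decision coefficient of
child j collects the part of that decomposition attributable to j:

    DC_j = (b*_j)^2 + 2 sum_{t!=j} b*_j r_jt b*_t.

Its sign estimates the impact direction (activated / inhibited); its
magnitude, the decision-making ability of the child for the parent.  A
t-based cutoff decides significance of DC_j:

    cutoff_j(alpha) = 2 t_{alpha/2}(n-q-1) |r_jy - b*_j|
                      sqrt( c_jj (1 - R^2) / (n - q - 1) )

with c_jj the j-th diagonal element of inv(R_x).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PathwayDecisionAnalysis",
    "NearSingularWarning",
    "SingularCorrelationError",
    "DIRECTION_ACTIVATED",
    "DIRECTION_INHIBITED",
    "DIRECTION_NEUTRAL",
]

DIRECTION_ACTIVATED = "activated"
DIRECTION_INHIBITED = "inhibited"
DIRECTION_NEUTRAL = "neutral"


class NearSingularWarning(UserWarning):
    """Correlation matrix close to singular; pseudo-inverse used."""


class SingularCorrelationError(np.linalg.LinAlgError):
    """Correlation matrix (near-)singular in strict mode."""


def _validate_correlation_matrix(r_x: np.ndarray) -> np.ndarray:
    r_x = np.asarray(r_x, dtype=float)
    if r_x.ndim != 2 or r_x.shape[0] != r_x.shape[1]:
        raise ValueError("r_x must be a square matrix")
    if not np.allclose(r_x, r_x.T, atol=1e-10):
        raise ValueError("r_x must be symmetric")
    if not np.allclose(np.diag(r_x), 1.0, atol=1e-10):
        raise ValueError("r_x must have a unit diagonal")
    if np.any(np.abs(r_x) > 1.0 + 1e-10):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return r_x


def _direction_labels(dc: np.ndarray) -> np.ndarray:
    out = np.full(dc.shape, DIRECTION_NEUTRAL, dtype=object)
    out[dc > 0] = DIRECTION_ACTIVATED
    out[dc < 0] = DIRECTION_INHIBITED
    return out


class PathwayDecisionAnalysis(RegressorMixin, BaseEstimator):
    """Standardized path analysis with decision-coefficient scoring.

    Parameters
    ----------
    alphas : tuple of float, default (0.01, 0.05, 0.10)
        Significance levels at which t-based DC cutoffs are pre-computed
        during ``fit`` (two-sided; the upper alpha/2 quantile is used).
    dc_threshold : float, default 0.4
        Fixed |DC| threshold for the integrated selection mode.
    on_singular : {"warn", "raise"}, default "warn"
        Behaviour when the child correlation matrix is near-singular
        (condition number above ``cond_threshold``): fall back to the
        Moore-Penrose pseudo-inverse with a warning, or raise
        :class:`SingularCorrelationError`.
    cond_threshold : float, default 1e12
        Condition-number estimate above which R_x is treated as singular.

    Attributes
    ----------
    child_ids_ : list of str
        Names of the q child pathways (columns of X).
    n_ : int
        Number of observations (contrasts) behind the correlations.
    r_x_ : ndarray of shape (q, q)
        Child-child Pearson correlation matrix.
    r_xy_ : ndarray of shape (q,)
        Child-parent correlations (total effects r_jy).
    b_star_ : ndarray of shape (q,)
        Standardized path coefficients (direct effects).
    c_diag_ : ndarray of shape (q,)
        Diagonal of inv(R_x) (or of its pseudo-inverse when flagged).
    condition_flag_ : bool
        True when the pseudo-inverse fallback was used.
    r2_ : float
        Coefficient of determination, sum_j b*_j r_jy.
    direct_cd_, indirect_cd_ : float
        Direct and indirect parts of the R^2 decomposition.
    subdivision_ : ndarray of shape (q, q)
        Determination-factor table: diagonal (b*_j)^2, off-diagonal
        2 b*_t r_tj b*_j.  Column sums equal ``dc_``.
    dc_ : ndarray of shape (q,)
        Decision coefficients.
    direction_ : ndarray of str
        "activated" / "inhibited" / "neutral" per child, from sign(DC).
    decision_percentage_ : ndarray of shape (q,)
        |DC_j| / sum |DC| * 100.
    cutoffs_ : dict of float -> ndarray
        t-based cutoff vectors for each level in ``alphas`` (only when
        n - q - 1 >= 1).
    significant_ : dict of float -> ndarray of bool
        |DC| >= cutoff per level.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(30, 3))
    >>> y = X @ [1.0, -0.5, 0.2] + rng.normal(scale=0.3, size=30)
    >>> model = PathwayDecisionAnalysis().fit(X, y)
    >>> model.dc_.shape
    (3,)
    """

    def __init__(
        self,
        *,
        alphas: Sequence[float] = (0.01, 0.05, 0.10),
        dc_threshold: float = 0.4,
        on_singular: str = "warn",
        cond_threshold: float = 1e12,
    ):
        self.alphas = alphas
        self.dc_threshold = dc_threshold
        self.on_singular = on_singular
        self.cond_threshold = cond_threshold

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Fit from raw observations.

        Parameters
        ----------
        X : array-like of shape (n_observations, n_children)
            Child pathway impact values; rows are contrasts/time points.
        y : array-like of shape (n_observations,)
            Parent pathway impact values.
        """
        if hasattr(X, "columns"):
            child_ids = [str(c) for c in X.columns]
        else:
            child_ids = None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (observations x children)")
        n, q = X.shape
        if y.shape[0] != n:
            raise ValueError(f"X has {n} observations but y has {y.shape[0]}")
        if n < 3:
            raise ValueError("at least 3 observations are required for correlations")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values must be removed or imputed before fitting")
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [i for i, s in enumerate(sds) if s == 0]
            raise ValueError(f"zero-variance child column(s) at index {bad}")
        if y.std(ddof=1) == 0:
            raise ValueError("parent series y has zero variance")

        corr = np.corrcoef(np.column_stack([X, y]), rowvar=False)
        self.r_x_ = corr[:q, :q].copy()
        np.fill_diagonal(self.r_x_, 1.0)
        self.r_xy_ = corr[:q, q].copy()
        self.n_ = n
        self.n_features_in_ = q
        self.child_ids_ = child_ids or [f"x{j + 1}" for j in range(q)]
        # retained for predict()/score() on the original scale
        self._x_mean = X.mean(axis=0)
        self._x_sd = sds
        self._y_mean = y.mean()
        self._y_sd = y.std(ddof=1)
        self._finalize()
        return self

    @classmethod
    def from_correlations(
        cls,
        r_x,
        r_xy,
        n: int,
        *,
        child_ids: Sequence[str] | None = None,
        **params,
    ) -> "PathwayDecisionAnalysis":
        """Build a fitted model from a correlation structure.

        ``r_xy`` is taken as given and the path coefficients are solved
        from R_x b* = R_xy.
        """
        est = cls(**params)
        est.r_x_ = _validate_correlation_matrix(r_x)
        q = est.r_x_.shape[0]
        r_xy = np.asarray(r_xy, dtype=float).ravel()
        if r_xy.shape[0] != q:
            raise ValueError("r_xy length must match r_x dimension")
        est.r_xy_ = r_xy
        est.n_ = int(n)
        est.n_features_in_ = q
        est.child_ids_ = list(child_ids) if child_ids is not None else [f"x{j + 1}" for j in range(q)]
        est._finalize()
        return est

    @classmethod
    def from_coefficients(
        cls,
        r_x,
        b_star,
        n: int,
        *,
        child_ids: Sequence[str] | None = None,
        **params,
    ) -> "PathwayDecisionAnalysis":
        """Build a fitted model from known path coefficients.

        The child-parent correlations are reconstructed through the
        normal equations, R_xy = R_x b*, so the model is internally
        consistent by construction.
        """
        r_x = _validate_correlation_matrix(r_x)
        b_star = np.asarray(b_star, dtype=float).ravel()
        if b_star.shape[0] != r_x.shape[0]:
            raise ValueError("b_star length must match r_x dimension")
        return cls.from_correlations(
            r_x, r_x @ b_star, n, child_ids=child_ids, **params
        )

    def _finalize(self) -> None:
        """Solve the normal equations and derive every decision statistic."""
        if self.on_singular not in ("warn", "raise"):
            raise ValueError("on_singular must be 'warn' or 'raise'")
        r_x, r_xy = self.r_x_, self.r_xy_
        q = r_x.shape[0]
        cond = np.linalg.cond(r_x)
        self.condition_number_ = float(cond)
        self.condition_flag_ = bool(not np.isfinite(cond) or cond > self.cond_threshold)
        if self.condition_flag_:
            if self.on_singular == "raise":
                raise SingularCorrelationError(
                    "child correlation matrix is (near-)singular: condition "
                    f"number estimate {cond:.3g} exceeds {self.cond_threshold:.3g}; "
                    "reduce the number of children or add contrasts"
                )
            warnings.warn(
                "child correlation matrix is near-singular (condition number "
                f"{cond:.3g}); falling back to the pseudo-inverse, path "
                "coefficients may be inaccurate",
                NearSingularWarning,
                stacklevel=3,
            )
            inv = np.linalg.pinv(r_x, hermitian=True)
            self.b_star_ = inv @ r_xy
        else:
            inv = np.linalg.inv(r_x)
            self.b_star_ = np.linalg.solve(r_x, r_xy)
        self.c_diag_ = np.diag(inv).copy()

        b = self.b_star_
        self.r2_ = float(b @ r_xy)
        self.direct_cd_ = float(np.sum(b**2))
        # pairwise part of the R^2 decomposition: b'R b - sum b^2
        self.indirect_cd_ = float(b @ r_x @ b - self.direct_cd_)
        self.direct_cd_ratio_ = self.direct_cd_ / self.r2_ if self.r2_ else np.nan
        self.indirect_cd_ratio_ = (
            abs(self.indirect_cd_) / self.r2_ if self.r2_ else np.nan
        )

        # effect decomposition: P[j, k] = r_jk b*_k (indirect component)
        self.effect_components_ = r_x * b[np.newaxis, :]
        np.fill_diagonal(self.effect_components_, np.nan)
        self.indirect_sum_ = r_x @ b - b
        self.total_effect_ = r_xy
        # retro-regulation of child j onto its siblings: b_j sum_{k!=j} r_kj
        self.retro_ = b * (r_x.sum(axis=0) - 1.0)

        # determination-factor subdivision; column sums give the DC vector
        s = 2.0 * np.outer(b, b) * r_x
        np.fill_diagonal(s, b**2)
        self.subdivision_ = s
        self.dc_ = s.sum(axis=0)

        self.direction_ = _direction_labels(self.dc_)
        abs_total = np.abs(self.dc_).sum()
        self.decision_percentage_ = (
            np.abs(self.dc_) / abs_total * 100.0 if abs_total > 0 else np.full(q, np.nan)
        )

        self.cutoffs_ = {}
        self.significant_ = {}
        if self.n_ - q - 1 >= 1:
            for alpha in self.alphas:
                cut = self.cutoff(alpha)
                self.cutoffs_[alpha] = cut
                self.significant_[alpha] = np.abs(self.dc_) >= cut
        return None

    # ------------------------------------------------------------------
    # decision statistics
    # ------------------------------------------------------------------
    def cutoff(self, alpha: float) -> np.ndarray:
        """t-based DC significance cutoff at two-sided level ``alpha``.

        Uses the upper alpha/2 quantile of Student's t with n - q - 1
        degrees of freedom.  R^2 > 1 (possible only for reconstructed,
        internally inconsistent correlation structures) is clamped to 1,
        giving zero cutoffs.
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        df = self.n_ - self.n_features_in_ - 1
        if df < 1:
            raise ValueError(
                f"cutoff needs n - q - 1 >= 1 (n={self.n_}, q={self.n_features_in_})"
            )
        t = stats.t.ppf(1.0 - alpha / 2.0, df)
        one_minus_r2 = max(0.0, 1.0 - self.r2_)
        return (
            2.0
            * t
            * np.abs(self.r_xy_ - self.b_star_)
            * np.sqrt(self.c_diag_ * one_minus_r2 / df)
        )

    def select(
        self, *, alpha: float | None = None, threshold: float | None = None
    ) -> tuple[pd.Series, list[str]]:
        """Select impacted children and rank them.

        Exactly one of ``alpha`` (per-child t-based cutoffs) or
        ``threshold`` (fixed |DC| cutoff) may be given; with neither, the
        estimator's ``dc_threshold`` is used.  Returns a boolean Series
        indexed by child id and the ranking by |DC| descending (ties
        broken lexicographically by child id).
        """
        if alpha is not None and threshold is not None:
            raise ValueError("give either alpha or threshold, not both")
        dc = pd.Series(self.dc_, index=self.child_ids_)
        if alpha is not None:
            cut = self.cutoff(alpha)
            flags = dc.abs() >= cut
        else:
            thr = self.dc_threshold if threshold is None else threshold
            flags = dc.abs() >= thr
        order = sorted(self.child_ids_, key=lambda c: (-abs(dc[c]), c))
        return flags, order

    # ------------------------------------------------------------------
    # regression surface
    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Predicted parent impact values on the original scale.

        Only available when the model was fitted from raw data via
        :meth:`fit` (correlation-only constructions carry no scale).
        """
        if not hasattr(self, "_x_mean"):
            raise AttributeError(
                "predict() requires a model fitted from raw data, not from "
                "a correlation structure"
            )
        X = np.asarray(X, dtype=float)
        z = (X - self._x_mean) / self._x_sd
        return self._y_mean + self._y_sd * (z @ self.b_star_)

    def summary(self) -> pd.DataFrame:
        """Per-child summary table of the fitted decision statistics."""
        data = {
            "b_star": self.b_star_,
            "direct_factor": np.diag(self.subdivision_),
            "indirect_factor": self.dc_ - np.diag(self.subdivision_),
            "dc": self.dc_,
            "total_effect": self.total_effect_,
            "indirect_sum": self.indirect_sum_,
            "retro": self.retro_,
            "direction": self.direction_,
            "decision_percentage": self.decision_percentage_,
        }
        for alpha in self.cutoffs_:
            data[f"cutoff_{alpha:g}"] = self.cutoffs_[alpha]
            data[f"significant_{alpha:g}"] = self.significant_[alpha]
        return pd.DataFrame(data, index=pd.Index(self.child_ids_, name="child_id"))
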