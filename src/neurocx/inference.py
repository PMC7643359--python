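"""Fluid-intelligence factor extraction and PLS regression inference.

The statistical stage has two parts.  First, a single *gf* factor is
extracted from six reasoning-test scores as the leading eigenvector of
their correlation matrix, with standardized factor scores.  Second,
*gf* is regressed on the 45 complexity predictors with univariate
partial least squares (PLS1): components are chosen either at the first
local minimum of the cross-validation curve or by van der Voet's
randomization test, and predictor relevance is judged by bootstrap
confidence intervals of the standardized regression coefficients.

The model surface follows the Model/Results convention:
``PLSModel(y, X).fit(k)`` returns a :class:`PLSResults` carrying
coefficients, per-component explained variance of the response,
cross-validation and bootstrap methods, and a ``summary()`` table.

Notes on the bootstrap
----------------------
Subjects are resampled with replacement and the standardization + fit
is repeated per replicate.  Two interval flavours are available:
plain percentile (default) and bias-corrected (BC) percentile.  The BC
variant reproduces a common choice in the applied literature, but for
PLS coefficients under a global null the bootstrap distribution is
median-shrunk toward zero, which makes the BC z0 correction push
intervals *away* from zero and inflates the false-positive rate several
fold; the percentile intervals hold the nominal 5% level, which is why
they are the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import DegenerateBatteryError, EmptyGroupError, SchemaError
from .schema import FEATURE_COLUMNS, SEX_CODES, TEST_NAMES

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# gf factor extraction
# ---------------------------------------------------------------------------


@dataclass
class GfFactorResult:
    """First-factor solution of a six-test battery.

    ``scores`` are standardized (mean 0, SD 1); ``explained_variance_pct``
    is 100 * eigenvalue / 6.
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalue: float
    explained_variance_pct: float
    test_names: tuple[str, ...] = TEST_NAMES

    def summary(self) -> str:
        lines = [
            "gf factor (first principal factor of the score correlation matrix)",
            f"  eigenvalue          {self.eigenvalue:8.3f}",
            f"  explained variance  {self.explained_variance_pct:7.2f}%",
            "  loadings:",
        ]
        for name, lam in zip(self.test_names, self.loadings):
            lines.append(f"    {name:<10s} {lam:6.3f}")
        return "\n".join(lines)


def extract_gf_factor(battery: pd.DataFrame) -> GfFactorResult:
    """Extract the single fluid-intelligence factor from six test scores.

    The battery's correlation matrix is eigen-decomposed; the leading
    eigenvector (scaled to correlation loadings) defines the factor, and
    subject scores are the standardized projections on it.
    """
    cols = [c for c in TEST_NAMES if c in battery.columns]
    if len(cols) != len(TEST_NAMES):
        missing = [c for c in TEST_NAMES if c not in battery.columns]
        raise SchemaError(f"battery is missing test columns: {missing}")
    scores = battery[list(TEST_NAMES)].to_numpy(dtype=float)
    n = scores.shape[0]
    if n < 10:
        raise DegenerateBatteryError(f"factor extraction needs n >= 10, got {n}")
    if np.isnan(scores).any():
        raise DegenerateBatteryError("battery contains missing values")
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [TEST_NAMES[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateBatteryError(f"constant score column(s): {bad}")

    Z = (scores - scores.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    eigenvalue = float(eigvals[-1])
    vec = eigvecs[:, -1]
    if vec.sum() < 0:  # orient the factor with the tests
        vec = -vec
    loadings = vec * np.sqrt(eigenvalue)
    raw = Z @ vec
    factor_scores = (raw - raw.mean()) / raw.std(ddof=1)
    return GfFactorResult(
        scores=factor_scores,
        loadings=loadings,
        eigenvalue=eigenvalue,
        explained_variance_pct=100.0 * eigenvalue / len(TEST_NAMES),
    )


# ---------------------------------------------------------------------------
# PLS1 core
# ---------------------------------------------------------------------------


def _pls1_paths(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on standardized X / centered y.

    Returns (coef_paths, q, t_norms2) where ``coef_paths[k-1]`` are the
    coefficients of the k-component model, ``q[k-1]`` the y-loading of
    component k and ``t_norms2[k-1]`` its squared score norm.
    """
    n, p = Xs.shape
    K = min(n_components, n - 1, p)
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    q = np.zeros(K)
    t_norms2 = np.zeros(K)
    Xr = Xs.copy()
    yr = yc.astype(float).copy()
    actual = 0
    for k in range(K):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            break
        p_k = Xr.T @ t / tt
        q_k = float(yr @ t) / tt
        Xr -= np.outer(t, p_k)
        yr -= q_k * t
        W[:, k], P[:, k], q[k], t_norms2[k] = w, p_k, q_k, tt
        actual += 1
    K = actual
    coef_paths = np.zeros((K, p))
    for k in range(1, K + 1):
        Wk, Pk = W[:, :k], P[:, :k]
        R = np.linalg.solve((Pk.T @ Wk).T, Wk.T).T  # W (P^T W)^{-1}
        coef_paths[k - 1] = R @ q[:k]
    return coef_paths, q[:K], t_norms2[:K]


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateBatteryError("constant predictor column")
    return (X - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PLSModel:
    """Univariate partial least squares regression model.

    Parameters
    ----------
    endog : response vector (gf scores), length n.
    exog : n x p predictor matrix (raw scale; standardized internally).
    feature_names : optional predictor names (defaults to the 45-column
        complexity schema when p matches, else x0..x{p-1}).
    """

    def __init__(self, endog, exog, feature_names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError(
                f"endog has {self.endog.shape[0]} rows, exog {self.exog.shape[0]}"
            )
        p = self.exog.shape[1]
        if feature_names is None:
            feature_names = (
                list(FEATURE_COLUMNS) if p == len(FEATURE_COLUMNS) else [f"x{i}" for i in range(p)]
            )
        if len(feature_names) != p:
            raise ValueError("feature_names length must match exog columns")
        self.feature_names = list(feature_names)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame) -> "PLSModel":
        """Build the model from a 45-predictor feature table."""
        X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        y = table["gf"].to_numpy(dtype=float)
        return cls(y, X, feature_names=list(FEATURE_COLUMNS))

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    def fit(self, n_components: int = 1) -> "PLSResults":
        """Fit with a fixed number of latent variables.

        Requests beyond the usable rank are capped with a warning.
        """
        if n_components < 1:
            raise ValueError("n_components must be >= 1 (use the CV curve for k = 0)")
        max_k = min(self.nobs - 1, self.exog.shape[1])
        if n_components > max_k:
            warnings.warn(
                f"n_components={n_components} capped at {max_k}", stacklevel=2
            )
            n_components = max_k
        Xs, mu, sd = _standardize(self.exog)
        yc = self.endog - self.endog.mean()
        coef_paths, q, t2 = _pls1_paths(Xs, yc, n_components)
        k = coef_paths.shape[0]
        if k < n_components:
            warnings.warn(
                f"rank exhausted after {k} components (requested {n_components})",
                stacklevel=2,
            )
        ss_y = float(yc @ yc)
        yvar = 100.0 * (q**2 * t2) / ss_y if ss_y > 0 else np.zeros(k)
        return PLSResults(
            model=self,
            n_components=k,
            coefficients=coef_paths[k - 1],
            coef_paths=coef_paths,
            y_variance_explained=yvar,
            x_mean=mu,
            x_sd=sd,
            y_mean=float(self.endog.mean()),
        )

    # -- cross-validation ---------------------------------------------------

    def loo_sq_residuals(self, max_components: int) -> np.ndarray:
        """Leave-one-out squared prediction errors, shape (n, K+1).

        Column k holds the squared LOO residual of the k-component
        model; k = 0 predicts the training-fold mean.
        """
        n, p = self.exog.shape
        max_k = min(max_components, n - 2, p)
        if max_k < max_components:
            warnings.warn(
                f"max_components={max_components} capped at {max_k}", stacklevel=2
            )
        out = np.empty((n, max_k + 1))
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            Xt, yt = self.exog[mask], self.endog[mask]
            mask[i] = True
            Xs, mu, sd = _standardize(Xt)
            ybar = yt.mean()
            coef_paths, _, _ = _pls1_paths(Xs, yt - ybar, max_k)
            xi = (self.exog[i] - mu) / sd
            out[i, 0] = (self.endog[i] - ybar) ** 2
            for k in range(1, max_k + 1):
                # rank exhaustion repeats the last attainable model
                kk = min(k, coef_paths.shape[0])
                out[i, k] = (self.endog[i] - (ybar + coef_paths[kk - 1] @ xi)) ** 2
        return out

    def cross_validate(self, max_components: int = 10) -> "CVResult":
        """Leave-one-out CV curve (RMSEP) over 0..max_components."""
        sq = self.loo_sq_residuals(max_components)
        return CVResult(rmsep=np.sqrt(sq.mean(axis=0)), sq_residuals=sq)


@dataclass
class CVResult:
    """Cross-validation curve and per-observation squared residuals."""

    rmsep: np.ndarray
    sq_residuals: np.ndarray

    def __len__(self) -> int:
        return len(self.rmsep)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.rmsep)), self.rmsep, marker="o")
        ax.set_xlabel("number of latent variables")
        ax.set_ylabel("RMSEP (LOO)")
        return ax


def select_ncomp(
    cv: CVResult | np.ndarray,
    method: Literal["local_min", "randomization"] = "local_min",
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> int:
    """Choose the number of latent variables from a CV curve.

    ``local_min``: the smallest k with ``curve[k] < curve[k-1]`` and
    ``curve[k] <= curve[k+1]`` (the last point qualifies if the curve is
    still decreasing).  ``randomization``: van der Voet's paired
    sign-flip test on per-observation squared LOO residuals — the
    smallest k whose error is not significantly worse than the global
    minimum at level ``alpha`` (requires a :class:`CVResult`).
    """
    curve = cv.rmsep if isinstance(cv, CVResult) else np.asarray(cv, dtype=float)
    if len(curve) < 2:
        raise ValueError("CV curve needs at least two entries")
    if np.allclose(curve, curve[0]):
        warnings.warn("flat CV curve: selecting 0 components", stacklevel=2)
        return 0

    if method == "local_min":
        last = len(curve) - 1
        for k in range(1, len(curve)):
            if curve[k] < curve[k - 1] and (k == last or curve[k] <= curve[k + 1]):
                return k
        return 0

    if method == "randomization":
        if not isinstance(cv, CVResult):
            raise ValueError("randomization selection needs per-observation residuals")
        sq = cv.sq_residuals
        press = sq.sum(axis=0)
        k_star = int(press.argmin())
        rng = np.random.default_rng(seed)
        n = sq.shape[0]
        for k in range(len(press)):
            if k == k_star:
                return k
            d = sq[:, k] - sq[:, k_star]
            observed = d.mean()
            signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
            permuted = (signs * d).mean(axis=1)
            p_val = (np.sum(permuted >= observed) + 1) / (n_perm + 1)
            if p_val > alpha:
                return k
        return k_star

    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# results + bootstrap relevance
# ---------------------------------------------------------------------------


@dataclass
class PLSResults:
    """Fitted PLS1 regression.

    ``coefficients`` are on standardized-predictor scale;
    ``y_variance_explained`` holds the percentage of response variance
    captured by each component.
    """

    model: PLSModel
    n_components: int
    coefficients: np.ndarray
    coef_paths: np.ndarray
    y_variance_explained: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        return self.y_mean + ((X - self.x_mean) / self.x_sd) @ self.coefficients

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def rsquared(self) -> float:
        yc = self.model.endog - self.y_mean
        ss = float(yc @ yc)
        return 1.0 - float(self.resid @ self.resid) / ss if ss > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "PLS regression of gf on complexity predictors",
            f"  n obs            {self.model.nobs}",
            f"  latent variables {self.n_components}",
            "  % gf variance per LV: "
            + ", ".join(f"{v:.1f}" for v in self.y_variance_explained)
            + f"  (total {self.y_variance_explained.sum():.1f}%)",
            f"  in-sample R^2    {self.rsquared():.3f}",
        ]
        order = np.argsort(-np.abs(self.coefficients))[:10]
        lines.append("  largest standardized coefficients:")
        for j in order:
            lines.append(
                f"    {self.model.feature_names[j]:<16s} {self.coefficients[j]:+.4f}"
            )
        return "\n".join(lines)

    def bootstrap_relevance(
        self,
        n_boot: int = 10_000,
        ci: float = 95.0,
        seed: int | None = None,
        ci_method: Literal["percentile", "bc"] = "percentile",
    ) -> "RelevanceReport":
        """Bootstrap the coefficients and flag predictors whose CI
        excludes zero (see :func:`bootstrap_coefficients`)."""
        return bootstrap_coefficients(
            self.model.exog,
            self.model.endog,
            self.n_components,
            n_boot=n_boot,
            ci=ci,
            seed=seed,
            ci_method=ci_method,
            feature_names=self.model.feature_names,
            point_estimates=self.coefficients,
        )


@dataclass
class RelevanceReport:
    """Per-predictor bootstrap relevance (Tables-style report).

    ``frame`` columns: predictor, coefficient, ci_low, ci_high, se,
    relevant, sign.
    """

    frame: pd.DataFrame
    n_boot: int
    ci: float
    ci_method: str
    n_components: int
    n_redrawn: int = 0

    def relevant_table(self) -> pd.DataFrame:
        """Relevant predictors sorted by |coefficient| within the
        positive and negative blocks."""
        rel = self.frame[self.frame["relevant"]].copy()
        pos = rel[rel["coefficient"] > 0].sort_values("coefficient", ascending=False)
        neg = rel[rel["coefficient"] < 0].sort_values("coefficient", ascending=True)
        return pd.concat([pos, neg], ignore_index=True)

    def summary(self) -> str:
        rel = self.relevant_table()
        lines = [
            f"bootstrap relevance ({self.ci_method} {self.ci:g}% CI, "
            f"B={self.n_boot}, {self.n_components} LV)",
            f"  relevant predictors: {len(rel)}/{len(self.frame)}",
        ]
        for _, row in rel.iterrows():
            lines.append(
                f"    {row.predictor:<16s} {row.coefficient:+.3f} "
                f"[{row.ci_low:+.3f}; {row.ci_high:+.3f}]  SE {row.se:.3f}"
            )
        return "\n".join(lines)


def bootstrap_coefficients(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_boot: int = 10_000,
    ci: float = 95.0,
    seed: int | None = None,
    ci_method: Literal["percentile", "bc"] = "percentile",
    feature_names: Sequence[str] | None = None,
    point_estimates: np.ndarray | None = None,
) -> RelevanceReport:
    """Bootstrap CIs for PLS1 coefficients with a fixed component count.

    Subjects are resampled with replacement; standardization and the
    fit are repeated per replicate.  Replicates with a degenerate
    (constant) predictor column are redrawn and counted.  A predictor is
    relevant when its interval excludes zero.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError(f"bootstrap needs n >= 10 subjects, got {n}")
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2 for percentile intervals, got {n_boot}")
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]

    if point_estimates is None:
        Xs, _, _ = _standardize(X)
        paths, _, _ = _pls1_paths(Xs, y - y.mean(), n_components)
        point_estimates = paths[-1]

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p))
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            Xb, yb = X[idx], y[idx]
            try:
                Xbs, _, _ = _standardize(Xb)
            except DegenerateBatteryError:
                n_redrawn += 1
                continue
            paths, _, _ = _pls1_paths(Xbs, yb - yb.mean(), n_components)
            boot[b] = paths[-1] if len(paths) else 0.0
            break
        else:  # pragma: no cover - pathological input
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)

    alpha = 1.0 - ci / 100.0
    if ci_method == "percentile":
        lo = np.quantile(boot, alpha / 2, axis=0)
        hi = np.quantile(boot, 1 - alpha / 2, axis=0)
    elif ci_method == "bc":
        prop = np.clip(
            (boot < point_estimates).mean(axis=0), 1 / (n_boot + 1), 1 - 1 / (n_boot + 1)
        )
        z0 = norm.ppf(prop)
        z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
        lo_p = norm.cdf(2 * z0 + z_lo)
        hi_p = norm.cdf(2 * z0 + z_hi)
        lo = np.array([np.quantile(boot[:, j], lo_p[j]) for j in range(p)])
        hi = np.array([np.quantile(boot[:, j], hi_p[j]) for j in range(p)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    se = boot.std(axis=0, ddof=1)
    relevant = (lo > 0) | (hi < 0)
    frame = pd.DataFrame(
        {
            "predictor": names,
            "coefficient": point_estimates,
            "ci_low": lo,
            "ci_high": hi,
            "se": se,
            "relevant": relevant,
            "sign": np.sign(point_estimates).astype(int),
        }
    )
    return RelevanceReport(
        frame=frame,
        n_boot=n_boot,
        ci=ci,
        ci_method=ci_method,
        n_components=n_components,
        n_redrawn=n_redrawn,
    )


# convenience wrappers matching the functional surface ----------------------


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: Sequence[str] | None = None,
) -> PLSResults:
    """Fit a PLS1 model (see :class:`PLSModel`)."""
    return PLSModel(y, X, feature_names=feature_names).fit(n_components)


def cross_validate(X: np.ndarray, y: np.ndarray, max_components: int = 10) -> CVResult:
    """Leave-one-out CV curve for 0..max_components latent variables."""
    if len(np.asarray(y).ravel()) < 5:
        raise ValueError("cross-validation needs at least 5 observations")
    return PLSModel(y, X).cross_validate(max_components)


# ---------------------------------------------------------------------------
# group analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one group PLSR analysis."""

    n_components: int | None = None  # None -> select from the CV curve
    max_components: int = 10
    component_method: Literal["local_min", "randomization"] = "local_min"
    n_perm: int = 10_000
    alpha: float = 0.05
    n_boot: int = 10_000
    ci: float = 95.0
    ci_method: Literal["percentile", "bc"] = "percentile"
    seed: int | None = None
    exclude_subjects: tuple[str, ...] = ()


@dataclass
class GroupAnalysisResult:
    """Fitted model, relevance report and selection diagnostics for one group."""

    group: str
    n_subjects: int
    results: PLSResults
    report: RelevanceReport
    cv: CVResult
    ncomp_local_min: int
    ncomp_randomization: int

    def summary(self) -> str:
        head = (
            f"group = {self.group} (n = {self.n_subjects}); "
            f"LV selection: local-min {self.ncomp_local_min}, "
            f"randomization {self.ncomp_randomization}"
        )
        return "\n".join([head, self.results.summary(), self.report.summary()])


_GROUP_CODES = {"all": None, "men": "M", "women": "W"}


def run_group_analysis(
    table: pd.DataFrame,
    group: Literal["all", "men", "women"] = "all",
    config: AnalysisConfig | None = None,
) -> GroupAnalysisResult:
    """Full PLSR + bootstrap relevance analysis for one sex group.

    Rows are filtered by sex code, predictors standardized within the
    group, components selected by both criteria (the configured one, or
    a user-forced count, decides the fit), and coefficients
    bootstrapped.  No automatic outlier removal is performed; pass
    ``config.exclude_subjects`` to drop listed subjects.
    """
    config = config or AnalysisConfig()
    if group not in _GROUP_CODES:
        raise ValueError(f"unknown group {group!r}")
    bad_codes = set(table["sex"].unique()) - set(SEX_CODES)
    if bad_codes:
        raise SchemaError(f"unknown sex codes: {sorted(bad_codes)}")

    sub = table[~table["subject_id"].astype(str).isin(config.exclude_subjects)]
    code = _GROUP_CODES[group]
    if code is not None:
        sub = sub[sub["sex"] == code]
    n = len(sub)
    if n == 0:
        raise EmptyGroupError(f"group {group!r} contains no subjects")
    if n < 10:
        raise EmptyGroupError(f"group {group!r} has only {n} subjects (need >= 10)")

    model = PLSModel.from_feature_table(sub)
    cv = model.cross_validate(config.max_components)
    k_local = select_ncomp(cv, method="local_min")
    k_rand = select_ncomp(
        cv,
        method="randomization",
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.seed,
    )
    if config.n_components is not None:
        k = config.n_components
    else:
        k = k_local if config.component_method == "local_min" else k_rand
    k = max(k, 1)  # a fitted model needs at least one LV

    results = model.fit(k)
    report = results.bootstrap_relevance(
        n_boot=config.n_boot,
        ci=config.ci,
        seed=config.seed,
        ci_method=config.ci_method,
    )
    return GroupAnalysisResult(
        group=group,
        n_subjects=n,
        results=results,
        report=report,
        cv=cv,
        ncomp_local_min=k_local,
        ncomp_randomization=k_rand,
    )
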