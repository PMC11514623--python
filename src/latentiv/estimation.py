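"""Equation-by-equation 2SLS estimation of MIIV-transformed models.

Everything is computed in moment algebra: from a vector of means and a
covariance matrix (denominator ``n``, the ML convention, so the complete-data
and EM branches agree) the 2SLS slopes for one equation are

    b = (S_xz S_zz^-1 S_zx)^-1 S_xz S_zz^-1 S_zy

with the intercept recovered from the means.  On complete data this equals
the literal observation-level two-stage computation.  The Sargan
overidentification statistic is ``n * R^2`` from the (moment-algebra)
regression of the 2SLS residual on all instruments, with df = instruments
minus regressors; exactly identified equations have no test.  Missing data
are handled by a two-stage procedure: saturated means/covariances are
estimated by EM under multivariate normality, then fed to the same 2SLS
formulas.  Uncertainty comes from a nonparametric bootstrap over rows with
bias-corrected and accelerated (BCa) intervals; instrument sets are frozen
at the original selection so every replicate estimates the same estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import miiv_engine
from .miiv_engine import MIIVSet, TransformedEquation, UnderIdentifiedError
from .sem_model import ModelSpec, RescalePlan, parse_model, rescale_plan, validate_spec

__all__ = [
    "MomentSet",
    "EquationEstimate",
    "ParamEstimate",
    "FitResult",
    "AnalysisConfig",
    "EstimationError",
    "ConstantColumnError",
    "EMConvergenceError",
    "BootstrapFailureError",
    "compute_moments",
    "fit_2sls_equation",
    "sargan_test",
    "holm_adjust",
    "bootstrap_bca",
    "fit_miiv_sem",
    "fit_from_moments",
    "build_system_plan",
]


class EstimationError(RuntimeError):
    pass


class ConstantColumnError(EstimationError):
    pass


class EMConvergenceError(EstimationError):
    def __init__(self, iterations: int):
        self.iterations = iterations
        super().__init__(f"EM did not converge after {iterations} iterations")


class BootstrapFailureError(EstimationError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Estimation settings, mirroring the analysis configuration file."""

    overid_degree: int = 2
    bootstrap_B: int = 5000
    ci: str = "bca"  # "bca" | "percentile"
    ci_level: float = 0.95
    sargan_adjust: str = "holm"  # "holm" | "none"
    missing: str = "twostage"  # "complete" | "listwise" | "twostage"
    seed: int | None = None
    rescale: dict[str, float] | None = None  # None -> model-file defaults

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "overid_degree": self.overid_degree,
            "bootstrap_B": self.bootstrap_B,
            "ci": self.ci,
            "ci_level": self.ci_level,
            "sargan_adjust": self.sargan_adjust,
            "missing": self.missing,
            "seed": self.seed,
            "rescale": self.rescale,
        }


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


@dataclass
class MomentSet:
    """Saturated first and second moments with an effective sample size."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    n_effective: int
    source: str  # "complete" | "listwise" | "twostage_em" | "implied"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.names)
        if self.mean.shape != (p,) or self.cov.shape != (p, p):
            raise ValueError("moment dimensions do not match variable names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")

    def index(self, name: str) -> int:
        return self.names.index(name)


def _cov_n(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / X.shape[0]


def _em_saturated(
    X: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, int]:
    """ML saturated mean/covariance under multivariate normality via EM.

    Convergence: change in observed-data log-likelihood below ``tol``.
    """
    n, p = X.shape
    miss = np.isnan(X)
    if not miss.any():
        return X.mean(axis=0), _cov_n(X), 0
    if miss.all(axis=0).any():
        raise EstimationError("a column is entirely missing")

    mu = np.nanmean(X, axis=0)
    X0 = np.where(miss, mu, X)
    S = _cov_n(X0)
    S[np.diag_indices_from(S)] += 1e-10

    patterns: dict[tuple, np.ndarray] = {}
    for key in {tuple(row) for row in miss}:
        patterns[key] = np.where((miss == np.array(key)).all(axis=1))[0]

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            m = np.array(key)
            o = ~m
            Xo = X[np.ix_(rows, np.where(o)[0])]
            k = len(rows)
            Soo = S[np.ix_(np.where(o)[0], np.where(o)[0])]
            sign, logdet = np.linalg.slogdet(Soo)
            if sign <= 0:
                raise EstimationError("observed-block covariance not positive definite")
            dev = Xo - mu[o]
            sol = np.linalg.solve(Soo, dev.T)  # (po, k)
            ll += -0.5 * (
                k * (o.sum() * np.log(2 * np.pi) + logdet) + np.sum(dev.T * sol)
            )
            filled = np.empty((k, p))
            filled[:, o] = Xo
            if m.any():
                Som = S[np.ix_(np.where(o)[0], np.where(m)[0])]
                B = np.linalg.solve(Soo, Som)  # (po, pm)
                cond_mean = mu[m] + dev @ B
                filled[:, m] = cond_mean
                cond_cov = S[np.ix_(np.where(m)[0], np.where(m)[0])] - Som.T @ B
                sum_xx[np.ix_(np.where(m)[0], np.where(m)[0])] += k * cond_cov
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled
        mu = sum_x / n
        S = sum_xx / n - np.outer(mu, mu)
        if abs(ll - prev_ll) < tol:
            return mu, S, it
        prev_ll = ll
    raise EMConvergenceError(max_iter)


def compute_moments(
    data: pd.DataFrame,
    method: str = "complete",
    columns: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MomentSet:
    """Saturated means and covariances (denominator ``n``) from a data table.

    ``method`` is one of ``complete`` (no missing cells allowed),
    ``listwise`` (drop any row with a missing cell) or ``twostage_em``
    (ML moments under multivariate normality via EM; ``n_effective`` is the
    total row count).
    """
    if columns is not None:
        data = data[list(columns)]
    for c in data.columns:
        if not np.issubdtype(data[c].dtype, np.number):
            raise EstimationError(f"non-numeric column {c!r}")
    X = data.to_numpy(dtype=float)
    names = tuple(data.columns)
    n, p = X.shape
    method = {"twostage": "twostage_em"}.get(method, method)

    if method == "complete":
        if np.isnan(X).any():
            raise EstimationError(
                "missing cells present; use method='listwise' or 'twostage_em'"
            )
        return MomentSet(names, X.mean(axis=0), _cov_n(X), n, "complete")
    if method == "listwise":
        keep = ~np.isnan(X).any(axis=1)
        Xc = X[keep]
        if Xc.shape[0] < p + 1:
            raise EstimationError(
                f"only {Xc.shape[0]} complete rows for {p} variables under listwise deletion"
            )
        return MomentSet(names, Xc.mean(axis=0), _cov_n(Xc), Xc.shape[0], "listwise")
    if method == "twostage_em":
        mu, S, _ = _em_saturated(X, tol=tol, max_iter=max_iter)
        return MomentSet(names, mu, S, n, "twostage_em")
    raise ValueError(f"unknown moments method {method!r}")


# ---------------------------------------------------------------------------
# 2SLS and Sargan in moment algebra (scalar and batched)
# ---------------------------------------------------------------------------


def _tsls_from_moments(mean, cov, y, x, z):
    """Point estimates for one equation from (mean, cov).  Indices are ints."""
    szz = cov[np.ix_(z, z)]
    szx = cov[np.ix_(z, x)]
    szy = cov[np.ix_(z, [y])]
    try:
        A = np.linalg.solve(szz, szx)  # Szz^-1 Szx
        M = szx.T @ A
        b = np.linalg.solve(M, A.T @ szy).ravel()
    except np.linalg.LinAlgError as e:
        raise EstimationError(f"singular moment matrix in 2SLS: {e}") from None
    intercept = mean[y] - mean[list(x)] @ b
    return intercept, b


def _tsls_batched(means, covs, y, x, z):
    """Vectorised 2SLS over a batch of moment sets.

    means: (B, p); covs: (B, p, p).  Returns (intercepts (B,), slopes (B, kx)).
    Batches with singular moment matrices come back as NaN rows.
    """
    B = covs.shape[0]
    zz = covs[:, np.asarray(z)[:, None], np.asarray(z)[None, :]]
    zx = covs[:, np.asarray(z)[:, None], np.asarray(x)[None, :]]
    zy = covs[:, np.asarray(z), y][..., None]
    try:
        A = np.linalg.solve(zz, zx)
        M = np.swapaxes(zx, 1, 2) @ A
        rhs = np.swapaxes(A, 1, 2) @ zy
        b = np.linalg.solve(M, rhs)[..., 0]
    except np.linalg.LinAlgError:
        # fall back to a loop, flagging singular batches
        b = np.full((B, len(x)), np.nan)
        for i in range(B):
            try:
                _, bi = _tsls_from_moments(means[i], covs[i], y, x, z)
                b[i] = bi
            except EstimationError:
                pass
    intercepts = means[:, y] - np.einsum("bk,bk->b", means[:, np.asarray(x)], b)
    return intercepts, b


def _sargan_from_moments(mean, cov, n, y, x, z, b):
    """(stat, df, p) for 2SLS residual-on-instruments from centered moments."""
    df = len(z) - len(x)
    if df <= 0:
        return None, 0, None
    x = list(x)
    szy = cov[np.ix_(z, [y])].ravel()
    szx = cov[np.ix_(z, x)]
    cu = szy - szx @ b  # Cov(z, residual)
    var_u = (
        cov[y, y]
        - 2 * b @ cov[np.ix_(x, [y])].ravel()
        + b @ cov[np.ix_(x, x)] @ b
    )
    if var_u <= 0:
        return 0.0, df, 1.0
    szz = cov[np.ix_(z, z)]
    r2 = float(cu @ np.linalg.solve(szz, cu) / var_u)
    stat = n * r2
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# public per-equation operations
# ---------------------------------------------------------------------------


@dataclass
class EquationEstimate:
    equation_id: str
    outcome: str
    regressor_names: list[str]
    instrument_names: list[str]
    intercept: float
    intercept_id: str
    slopes: dict[str, float]  # param_id -> analysis-scale estimate
    first_stage_r2: dict[str, float]
    residual_variance: float
    sargan_stat: float | None = None
    sargan_df: int = 0
    sargan_p_raw: float | None = None
    sargan_p_holm: float | None = None

    def to_dict(self) -> dict:
        return {
            "equation": self.equation_id,
            "outcome": self.outcome,
            "regressors": list(self.regressor_names),
            "instruments": list(self.instrument_names),
            "intercept": self.intercept,
            "slopes": dict(self.slopes),
            "first_stage_r2": dict(self.first_stage_r2),
            "sargan": {
                "stat": self.sargan_stat,
                "df": self.sargan_df,
                "p_raw": self.sargan_p_raw,
                "p_holm": self.sargan_p_holm,
            },
        }


def fit_2sls_equation(
    equation: TransformedEquation, miivs: MIIVSet, moments: MomentSet
) -> EquationEstimate:
    """2SLS estimates of one transformed equation from saturated moments."""
    status, _ = miiv_engine.identification_status(equation, miivs)
    if status == "under":
        raise UnderIdentifiedError(f"equation {equation.equation_id!r} under-identified")
    idx = {n: i for i, n in enumerate(moments.names)}
    y = idx[equation.outcome]
    x = [idx[r] for r in equation.regressor_names]
    z = [idx[s] for s in miivs.selected]
    intercept, b = _tsls_from_moments(moments.mean, moments.cov, y, x, z)
    var_u = float(
        moments.cov[y, y]
        - 2 * b @ moments.cov[np.ix_(x, [y])].ravel()
        + b @ moments.cov[np.ix_(x, x)] @ b
    )
    fs = {
        name: miiv_engine._first_stage_r2(moments.cov, idx[name], z)
        for name in equation.endogenous_names
    }
    return EquationEstimate(
        equation_id=equation.equation_id,
        outcome=equation.outcome,
        regressor_names=list(equation.regressor_names),
        instrument_names=list(miivs.selected),
        intercept=float(intercept),
        intercept_id=equation.intercept_id,
        slopes={r.param_id: float(bi) for r, bi in zip(equation.regressors, b)},
        first_stage_r2=fs,
        residual_variance=var_u,
    )


def sargan_test(
    estimate: EquationEstimate,
    equation: TransformedEquation,
    miivs: MIIVSet,
    moments: MomentSet,
) -> tuple[float | None, int, float | None]:
    """Sargan overidentification test; (None, 0, None) when exactly identified."""
    idx = {n: i for i, n in enumerate(moments.names)}
    y = idx[equation.outcome]
    x = [idx[r] for r in equation.regressor_names]
    z = [idx[s] for s in miivs.selected]
    b = np.array([estimate.slopes[r.param_id] for r in equation.regressors])
    return _sargan_from_moments(moments.mean, moments.cov, moments.n_effective, y, x, z, b)


def holm_adjust(pvalues: Sequence[float | None]) -> list[float | None]:
    """Holm step-down adjustment; ``None`` entries (undefined tests) pass
    through and do not count toward the family size."""
    ps = np.array([p for p in pvalues if p is not None], dtype=float)
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ps.size == 0:
        return list(pvalues)
    m = ps.size
    order = np.argsort(ps, kind="stable")
    scaled = ps[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(scaled), 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out: list[float | None] = []
    it = iter(restored)
    for p in pvalues:
        out.append(float(next(it)) if p is not None else None)
    return out


# ---------------------------------------------------------------------------
# system plans: the fast path shared by fits, bootstrap and simulations
# ---------------------------------------------------------------------------


@dataclass
class _EquationPlan:
    equation_id: str
    outcome: str
    y: int
    x: list[int]
    z: list[int]
    slope_ids: list[str]
    intercept_id: str
    regressor_names: list[str]
    instrument_names: list[str]
    endogenous_names: list[str]


@dataclass
class SystemPlan:
    """Frozen index-level description of a full MIIV-2SLS fit."""

    names: tuple[str, ...]
    equations: list[_EquationPlan]
    plan_rescale: RescalePlan
    param_order: list[str]  # slopes then intercepts, stable across refits

    def param_meta(self) -> dict[str, tuple[str, str, str]]:
        """param_id -> (equation_id, outcome, regressor-or-'' )"""
        meta = {}
        for eq in self.equations:
            for pid, rname in zip(eq.slope_ids, eq.regressor_names):
                meta[pid] = (eq.equation_id, eq.outcome, rname)
            meta[eq.intercept_id] = (eq.equation_id, eq.outcome, "")
        return meta


# the symbolic stage depends only on model structure; memoize it on the
# serialized grammar so simulation loops pay for sympy once per model
_TRANSFORM_CACHE: dict[str, tuple] = {}


def _transform_cached(spec: ModelSpec):
    key = spec.to_text()
    if key not in _TRANSFORM_CACHE:
        system = miiv_engine.transform(spec)
        eligibility = {
            eq.equation_id: miiv_engine.eligible_miivs(system, spec, eq.equation_id)
            for eq in system
        }
        if len(_TRANSFORM_CACHE) > 64:
            _TRANSFORM_CACHE.clear()
        _TRANSFORM_CACHE[key] = (system, eligibility)
    return _TRANSFORM_CACHE[key]


def build_system_plan(
    spec: ModelSpec,
    moments: MomentSet,
    config: AnalysisConfig,
) -> tuple[SystemPlan, dict[str, MIIVSet], list[TransformedEquation], list[str]]:
    """Transform the model, search and select MIIVs, and freeze everything
    into index arrays against ``moments.names``."""
    problems = validate_spec(spec)
    if problems:
        raise ValueError("invalid model spec: " + "; ".join(problems))
    system, eligibility = _transform_cached(spec)
    idx = {n: i for i, n in enumerate(moments.names)}
    warnings: list[str] = []
    plans: list[_EquationPlan] = []
    miiv_sets: dict[str, MIIVSet] = {}
    for eq in system:
        eligible = eligibility[eq.equation_id]
        sel = miiv_engine.select_miivs(eligible, eq, moments, config.overid_degree)
        warnings.extend(f"{eq.equation_id}: {w}" for w in sel.warnings)
        miiv_sets[eq.equation_id] = sel
        plans.append(
            _EquationPlan(
                equation_id=eq.equation_id,
                outcome=eq.outcome,
                y=idx[eq.outcome],
                x=[idx[r] for r in eq.regressor_names],
                z=[idx[s] for s in sel.selected],
                slope_ids=[r.param_id for r in eq.regressors],
                intercept_id=eq.intercept_id,
                regressor_names=list(eq.regressor_names),
                instrument_names=list(sel.selected),
                endogenous_names=list(eq.endogenous_names),
            )
        )
    order = [pid for p in plans for pid in p.slope_ids]
    order += [p.intercept_id for p in plans]
    factors = config.rescale if config.rescale is not None else spec.rescale_defaults
    return (
        SystemPlan(tuple(moments.names), plans, rescale_plan(spec, dict(factors)), order),
        miiv_sets,
        system,
        warnings,
    )


def _fit_plan_batched(plan: SystemPlan, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Estimate every free coefficient for a batch of moment sets.

    Returns (B, n_params) in ``plan.param_order`` (slopes then intercepts).
    """
    B = covs.shape[0]
    slopes_parts = []
    intercepts = np.empty((B, len(plan.equations)))
    for j, eq in enumerate(plan.equations):
        a, b = _tsls_batched(means, covs, eq.y, eq.x, eq.z)
        slopes_parts.append(b)
        intercepts[:, j] = a
    return np.concatenate(slopes_parts + [intercepts], axis=1)


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------


@dataclass
class ParamEstimate:
    param_id: str
    equation_id: str
    estimate: float  # analysis scale
    estimate_original: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return {
            "param": self.param_id,
            "equation": self.equation_id,
            "estimate": self.estimate,
            "estimate_original_scale": self.estimate_original,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class FitResult:
    equations: list[EquationEstimate]
    params: dict[str, ParamEstimate]
    miiv_sets: dict[str, MIIVSet]
    moments: MomentSet
    config: dict
    bootstrap: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def param(self, param_id: str) -> ParamEstimate:
        return self.params[param_id]

    def to_dict(self) -> dict:
        return {
            "equations": [e.to_dict() for e in self.equations],
            "parameters": {k: v.to_dict() for k, v in self.params.items()},
            "miivs": {k: v.to_dict() for k, v in self.miiv_sets.items()},
            "n_effective": self.moments.n_effective,
            "moments_source": self.moments.source,
            "bootstrap": self.bootstrap,
            "config": self.config,
            "warnings": list(self.warnings),
        }

    def params_frame(self) -> pd.DataFrame:
        rows = [v.to_dict() for v in self.params.values()]
        return pd.DataFrame(rows).set_index("param")

    def to_table(self) -> str:
        """Human-readable coefficient and Sargan table."""
        lines = []
        lines.append(
            f"{'parameter':28s} {'estimate':>10s} {'orig.scale':>11s} "
            f"{'boot SE':>9s} {'CI low':>9s} {'CI high':>9s}"
        )
        for pid, p in self.params.items():
            se = f"{p.se:9.3f}" if p.se is not None else "        -"
            lo = f"{p.ci_low:9.3f}" if p.ci_low is not None else "        -"
            hi = f"{p.ci_high:9.3f}" if p.ci_high is not None else "        -"
            lines.append(
                f"{pid:28s} {p.estimate:10.3f} {p.estimate_original:11.4g} {se} {lo} {hi}"
            )
        lines.append("")
        lines.append(
            f"{'equation':14s} {'Sargan':>8s} {'df':>3s} {'p raw':>8s} {'p Holm':>8s}"
        )
        for e in self.equations:
            if e.sargan_p_raw is None:
                lines.append(f"{e.equation_id:14s} {'exactly identified':>30s}")
            else:
                lines.append(
                    f"{e.equation_id:14s} {e.sargan_stat:8.3f} {e.sargan_df:3d} "
                    f"{e.sargan_p_raw:8.4f} {e.sargan_p_holm:8.4f}"
                )
        return "\n".join(lines)


def _check_constant_columns(data: pd.DataFrame) -> None:
    for c in data.columns:
        col = data[c].dropna()
        if len(col) and float(col.max() - col.min()) == 0.0:
            raise ConstantColumnError(f"column {c!r} is constant")


def _original_scale(plan: SystemPlan, pid: str, value: float, _meta=None) -> float:
    meta = _meta if _meta is not None else plan.param_meta()
    eq_id, outcome, regressor = meta[pid]
    r = plan.plan_rescale
    if regressor:
        return r.slope_to_original(value, outcome, regressor)
    return r.intercept_to_original(value, outcome)


def _assemble_fit(
    spec: ModelSpec,
    plan: SystemPlan,
    system: list[TransformedEquation],
    miiv_sets: dict[str, MIIVSet],
    moments: MomentSet,
    config: AnalysisConfig,
    warnings: list[str],
) -> FitResult:
    estimates: list[EquationEstimate] = []
    for eq in system:
        est = fit_2sls_equation(eq, miiv_sets[eq.equation_id], moments)
        stat, df, p = sargan_test(est, eq, miiv_sets[eq.equation_id], moments)
        est.sargan_stat, est.sargan_df, est.sargan_p_raw = stat, df, p
        estimates.append(est)
    if config.sargan_adjust == "holm":
        adj = holm_adjust([e.sargan_p_raw for e in estimates])
        for e, a in zip(estimates, adj):
            e.sargan_p_holm = a
    params: dict[str, ParamEstimate] = {}
    meta = plan.param_meta()
    for est in estimates:
        for pid, val in est.slopes.items():
            params[pid] = ParamEstimate(
                pid, est.equation_id, val, _original_scale(plan, pid, val, meta)
            )
        params[est.intercept_id] = ParamEstimate(
            est.intercept_id,
            est.equation_id,
            est.intercept,
            _original_scale(plan, est.intercept_id, est.intercept, meta),
        )
    return FitResult(
        equations=estimates,
        params=params,
        miiv_sets=miiv_sets,
        moments=moments,
        config=config.to_dict(),
        warnings=list(warnings),
    )


def fit_from_moments(
    spec: ModelSpec | str,
    moments: MomentSet,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """Full MIIV-2SLS fit from saturated moments (no bootstrap).

    ``moments`` must be on the analysis (rescaled) scale with names covering
    the model's observed variables.
    """
    if isinstance(spec, str):
        spec = parse_model(spec)
    config = config or AnalysisConfig(bootstrap_B=0)
    plan, miiv_sets, system, warn = build_system_plan(spec, moments, config)
    return _assemble_fit(spec, plan, system, miiv_sets, moments, config, warn)


def fit_miiv_sem(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    config: AnalysisConfig | None = None,
) -> FitResult:
    """End-to-end MIIV-2SLS fit from raw (original-scale) data.

    Orchestrates rescaling, moment computation (with the configured
    missing-data handling), latent-to-observed transformation, instrument
    search and selection, per-equation 2SLS, Sargan tests with Holm
    adjustment, and the BCa bootstrap (when ``bootstrap_B > 0``).
    """
    if isinstance(spec, str):
        spec = parse_model(spec)
    config = config or AnalysisConfig()
    missing_cols = [c for c in spec.observed_vars if c not in data.columns]
    if missing_cols:
        raise EstimationError(f"data lacks model columns: {missing_cols}")
    data = data[list(spec.observed_vars)]
    _check_constant_columns(data)
    factors = config.rescale if config.rescale is not None else spec.rescale_defaults
    plan_rescale = rescale_plan(spec, dict(factors))
    data_a = plan_rescale.apply(data)
    moments = compute_moments(data_a, method=config.missing)
    plan, miiv_sets, system, warn = build_system_plan(spec, moments, config)
    fit = _assemble_fit(spec, plan, system, miiv_sets, moments, config, warn)
    if config.bootstrap_B and config.bootstrap_B > 0:
        point = np.array([fit.params[pid].estimate for pid in plan.param_order])
        boot = bootstrap_bca(
            data_a,
            plan,
            point,
            B=config.bootstrap_B,
            seed=config.seed,
            missing=config.missing,
            level=config.ci_level,
            method=config.ci,
        )
        for k, pid in enumerate(plan.param_order):
            p = fit.params[pid]
            p.se = boot["se"][k]
            p.ci_low = boot["ci_low"][k]
            p.ci_high = boot["ci_high"][k]
        fit.bootstrap = {
            "B_successful": boot["B_successful"],
            "B_attempted": boot["B_attempted"],
            "seed": config.seed,
            "method": config.ci,
            "level": config.ci_level,
        }
        fit.warnings.extend(boot["warnings"])
    return fit


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _moments_batch(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Means/covariances (denominator n) for resamples ``X[idx]``; idx (B, n)."""
    Xb = X[idx]  # (B, n, p)
    means = Xb.mean(axis=1)
    covs = np.einsum("bnp,bnq->bpq", Xb, Xb) / idx.shape[1]
    covs -= means[:, :, None] * means[:, None, :]
    return means, covs


def _stats_for_resamples(
    X: np.ndarray, idx: np.ndarray, plan: SystemPlan, missing: str
) -> np.ndarray:
    has_nan = np.isnan(X).any()
    if not has_nan:
        means, covs = _moments_batch(X, idx)
        return _fit_plan_batched(plan, means, covs)
    out = np.full((idx.shape[0], len(plan.param_order)), np.nan)
    for i, rows in enumerate(idx):
        Xi = X[rows]
        try:
            if missing in ("twostage", "twostage_em"):
                mu, S, _ = _em_saturated(Xi)
            else:  # listwise
                Xi = Xi[~np.isnan(Xi).any(axis=1)]
                if Xi.shape[0] < X.shape[1] + 1:
                    continue
                mu, S = Xi.mean(axis=0), _cov_n(Xi)
            out[i] = _fit_plan_batched(plan, mu[None], S[None])[0]
        except EstimationError:
            continue
    return out


def _bca_interval(
    theta_hat: float, boot: np.ndarray, jack: np.ndarray | None, level: float
) -> tuple[float, float]:
    """Textbook BCa interval: bias correction from the bootstrap distribution,
    acceleration from jackknife skewness."""
    alpha = 1.0 - level
    if np.ptp(boot) == 0.0:
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = stats.norm.ppf(prop)
    if jack is not None and np.ptp(jack) > 0:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        a = np.sum(d**3) / denom if denom > 0 else 0.0
    else:
        a = 0.0
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def bootstrap_bca(
    data_analysis: pd.DataFrame | np.ndarray,
    plan: SystemPlan,
    point: np.ndarray,
    B: int = 5000,
    seed: int | None = None,
    missing: str = "complete",
    level: float = 0.95,
    method: str = "bca",
) -> dict:
    """Nonparametric bootstrap over rows for every free coefficient.

    Rows are resampled with replacement and the full system refit per
    replicate with instrument sets frozen at ``plan``.  Failed replicates
    (singular fits, EM non-convergence) are discarded and redrawn until ``B``
    successes or ``2B`` total attempts.  SE is the SD over successes; CIs are
    BCa (default) or raw percentile.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X = np.asarray(data_analysis, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise EstimationError("too few rows to bootstrap")
    rng = np.random.default_rng(seed)

    stats_ok: list[np.ndarray] = []
    attempted = 0
    failures = 0
    while sum(s.shape[0] for s in stats_ok) < B and attempted < 2 * B:
        need = B - sum(s.shape[0] for s in stats_ok)
        chunk = min(max(need, 64), 2 * B - attempted, 2048)
        idx = rng.integers(0, n, size=(chunk, n))
        attempted += chunk
        est = _stats_for_resamples(X, idx, plan, missing)
        ok = np.isfinite(est).all(axis=1)
        failures += int((~ok).sum())
        if ok.any():
            stats_ok.append(est[ok])
    boot = np.concatenate(stats_ok) if stats_ok else np.empty((0, len(point)))
    if boot.shape[0] < B:
        raise BootstrapFailureError(
            f"only {boot.shape[0]} successful replicates in {attempted} attempts "
            f"({failures} failures: singular fits or non-converged moments)"
        )
    boot = boot[:B]

    jack = None
    if method == "bca":
        jack = _jackknife_stats(X, plan, missing)

    se = boot.std(axis=0, ddof=1)
    ci_low = np.empty(len(point))
    ci_high = np.empty(len(point))
    warnings: list[str] = []
    for k in range(len(point)):
        jk = jack[:, k] if jack is not None else None
        if method == "bca":
            lo, hi = _bca_interval(point[k], boot[:, k], jk, level)
        else:
            alpha = 1.0 - level
            lo, hi = (
                float(np.quantile(boot[:, k], alpha / 2)),
                float(np.quantile(boot[:, k], 1 - alpha / 2)),
            )
        if not (lo <= point[k] <= hi):
            warnings.append(
                f"interval for {plan.param_order[k]} excludes the point estimate "
                "(extreme acceleration)"
            )
        ci_low[k], ci_high[k] = lo, hi
    return {
        "se": se,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "B_successful": int(boot.shape[0]),
        "B_attempted": int(attempted),
        "warnings": warnings,
    }


def _jackknife_stats(X: np.ndarray, plan: SystemPlan, missing: str) -> np.ndarray:
    """Leave-one-out estimates of every coefficient (for BCa acceleration)."""
    n, p = X.shape
    if not np.isnan(X).any():
        # vectorised leave-one-out moments via rank-one downdates
        total = X.sum(axis=0)
        S2 = X.T @ X
        means = (total[None, :] - X) / (n - 1)
        S2l = S2[None, :, :] - np.einsum("np,nq->npq", X, X)
        covs = S2l / (n - 1) - means[:, :, None] * means[:, None, :]
        return _fit_plan_batched(plan, means, covs)
    idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
    return _stats_for_resamples(X, idx, plan, missing)
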