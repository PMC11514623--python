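"""Model-implied instrumental variables for latent-variable SEMs.

Three stages live here:

1. :func:`transform` — rewrite the latent model as a system of
   observed-variable regressions.  Each latent is replaced by its scaling
   indicator minus that indicator's error, so every transformed equation has
   a *composite disturbance*: a signed combination of measurement errors
   (eps) and structural disturbances (zeta).  Intercepts and loadings are
   conserved.
2. :func:`eligible_miivs` — find, for one equation, every observed variable
   whose model-implied covariance with that composite disturbance is
   *structurally* zero.  This is decided symbolically (sympy) on the reduced
   form of the original model, so exact algebraic cancellations are honoured
   and sampling noise can never change the instrument set.
3. :func:`select_miivs` — when more instruments are eligible than wanted,
   keep the exogenous regressors and add eligible instruments by greedy
   forward selection on the first-stage R², until the equation carries
   ``#regressors + overid_degree`` instruments.

Only recursive (acyclic) structural models are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .sem_model import ModelSpec

__all__ = [
    "Regressor",
    "TransformedEquation",
    "MIIVSet",
    "transform",
    "eligible_miivs",
    "select_miivs",
    "identification_status",
    "NonRecursiveModelError",
    "UnderIdentifiedError",
]


class NonRecursiveModelError(ValueError):
    """The structural model contains a cycle; only recursive models are supported."""


class UnderIdentifiedError(ValueError):
    """An equation has fewer instruments than regressors."""


@dataclass(frozen=True)
class Regressor:
    name: str
    endogenous: bool
    param_id: str


@dataclass
class TransformedEquation:
    """An observed-variable regression with a composite disturbance.

    ``disturbance`` maps error-term ids to sympy coefficient expressions
    (e.g. ``{"zeta_body": 1, "eps_organs": 1, "eps_TIV": -beta_body_brain}``).
    """

    equation_id: str
    outcome: str
    regressors: list[Regressor]
    intercept_id: str
    disturbance: dict[str, sp.Expr]
    source: str  # "measurement" | "structural"

    @property
    def regressor_names(self) -> list[str]:
        return [r.name for r in self.regressors]

    @property
    def endogenous_names(self) -> list[str]:
        return [r.name for r in self.regressors if r.endogenous]

    @property
    def exogenous_names(self) -> list[str]:
        return [r.name for r in self.regressors if not r.endogenous]


@dataclass
class MIIVSet:
    equation_id: str
    eligible: frozenset[str]
    selected: list[str]
    first_stage_r2_trace: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "equation": self.equation_id,
            "eligible": sorted(self.eligible),
            "selected": list(self.selected),
            "trace": self.first_stage_r2_trace,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# reduced form of the original model (latents kept as latents)
# ---------------------------------------------------------------------------


def _param_symbol(pid: str) -> sp.Symbol:
    return sp.Symbol(pid)


def _reduced_form(spec: ModelSpec) -> dict[str, sp.Expr]:
    """Express every latent and observed variable as a linear combination of
    exogenous sources (``src_<name>`` symbols) and error terms (eps/zeta
    symbols), with coefficients polynomial in the free parameters.
    Intercepts are dropped — only covariance structure matters here."""
    cache: dict[str, sp.Expr] = {}
    in_progress: set[str] = set()

    def expand(name: str) -> sp.Expr:
        if name in cache:
            return cache[name]
        if name in in_progress:
            raise NonRecursiveModelError(
                f"cyclic structural dependency involving {name!r}"
            )
        in_progress.add(name)
        struct = spec.structural_for(name)
        loadings = [m for m in spec.measurement_eqs if m.indicator == name]
        expr: sp.Expr = sp.Integer(0)
        if struct is not None:
            for p in struct.predictors:
                expr += _param_symbol(struct.path_id(p)) * expand(p)
            expr += sp.Symbol(struct.disturbance_term)
        elif loadings:
            for m in loadings:
                coeff = sp.Integer(1) if m.scaling else _param_symbol(m.loading_id)
                expr += coeff * expand(m.latent)
            expr += sp.Symbol(m.error_term)
        else:
            # exogenous source (observed covariate or exogenous latent)
            expr = sp.Symbol(f"src_{name}")
        in_progress.discard(name)
        cache[name] = sp.expand(expr)
        return cache[name]

    # a latent can both have a structural equation and measurement links; the
    # structural equation defines it, so order of the checks above matters.
    for name in list(spec.latents) + list(spec.observed_vars):
        expand(name)
    return cache


def _error_symbols(spec: ModelSpec) -> list[sp.Symbol]:
    syms = [sp.Symbol(m.error_term) for m in spec.measurement_eqs]
    syms += [sp.Symbol(s.disturbance_term) for s in spec.structural_eqs]
    return syms


def _structural_cov(
    spec: ModelSpec,
    expr_a: sp.Expr,
    expr_b: sp.Expr,
) -> sp.Expr:
    """Model-implied covariance of two linear expressions, keeping only error
    terms (sources are exogenous, hence uncorrelated with every error)."""
    err_syms = _error_symbols(spec)
    total: sp.Expr = sp.Integer(0)
    coeffs_a = {s: expr_a.coeff(s) for s in err_syms}
    coeffs_b = {s: expr_b.coeff(s) for s in err_syms}
    for s in err_syms:
        ca, cb = coeffs_a[s], coeffs_b[s]
        if ca != 0 and cb != 0:
            total += ca * cb * sp.Symbol(f"var_{s.name}")
    for a, b in spec.error_covariances:
        ea, eb = spec.error_term_of(a), spec.error_term_of(b)
        sa, sb = sp.Symbol(ea), sp.Symbol(eb)
        cov = sp.Symbol(f"cov_{ea}_{eb}")
        total += coeffs_a[sa] * coeffs_b[sb] * cov
        total += coeffs_a[sb] * coeffs_b[sa] * cov
    return sp.expand(total)


def _disturbance_expr(eq: TransformedEquation) -> sp.Expr:
    return sp.expand(
        sum(coef * sp.Symbol(term) for term, coef in eq.disturbance.items())
    )


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


def transform(spec: ModelSpec) -> list[TransformedEquation]:
    """Rewrite the model as observed-variable equations with composite
    disturbances.  One equation per non-scaling measurement relation and per
    structural relation; latent occurrences are replaced by
    ``scaling_indicator - eps_scaling_indicator``."""
    reduced = _reduced_form(spec)
    equations: list[TransformedEquation] = []

    def substitute(name: str) -> tuple[str, dict[str, sp.Expr]]:
        """Observed stand-in for a name and the error terms the substitution
        injects into the disturbance (with +1 coefficients, to be scaled)."""
        if spec.is_latent(name):
            s = spec.scaling_indicator(name)
            return s, {f"eps_{s}": sp.Integer(1)}
        return name, {}

    raw: list[tuple[str, str, list[tuple[str, str, sp.Expr]], str, dict, str]] = []

    # group by indicator so a cross-loading indicator yields one equation
    # with one regressor per latent it loads on
    scaling_for = {m.indicator for m in spec.measurement_eqs if m.scaling}
    seen_indicators: set[str] = set()
    for m in spec.measurement_eqs:
        if m.indicator in scaling_for or m.indicator in seen_indicators:
            continue
        seen_indicators.add(m.indicator)
        loads = [q for q in spec.measurement_eqs if q.indicator == m.indicator]
        dist: dict[str, sp.Expr] = {m.error_term: sp.Integer(1)}
        regs: list[tuple[str, str, sp.Expr]] = []
        for q in loads:
            lam = _param_symbol(q.loading_id)
            stand_in, injected = substitute(q.latent)
            regs.append((stand_in, q.loading_id, lam))
            for term, one in injected.items():
                dist[term] = dist.get(term, sp.Integer(0)) - lam * one
        raw.append((m.indicator, m.indicator, regs, m.intercept_id, dist, "measurement"))

    for s in spec.structural_eqs:
        out_name, out_injected = substitute(s.outcome)
        dist = {s.disturbance_term: sp.Integer(1)}
        for term, one in out_injected.items():
            dist[term] = dist.get(term, sp.Integer(0)) + one
        regs = []
        for p in s.predictors:
            beta = _param_symbol(s.path_id(p))
            stand_in, injected = substitute(p)
            regs.append((stand_in, s.path_id(p), beta))
            for term, one in injected.items():
                dist[term] = dist.get(term, sp.Integer(0)) - beta * one
        raw.append((s.outcome, out_name, regs, s.intercept_id, dist, "structural"))

    for eq_id, outcome, regs, intercept_id, dist, source in raw:
        dist = {k: sp.expand(v) for k, v in dist.items() if sp.expand(v) != 0}
        u = sp.expand(sum(c * sp.Symbol(t) for t, c in dist.items()))
        regressors = []
        for name, pid, _ in regs:
            cov = _structural_cov(spec, reduced[name], u)
            regressors.append(Regressor(name, endogenous=(cov != 0), param_id=pid))
        equations.append(
            TransformedEquation(eq_id, outcome, regressors, intercept_id, dist, source)
        )
    return equations


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def eligible_miivs(
    system: list[TransformedEquation], spec: ModelSpec, equation_id: str
) -> frozenset[str]:
    """Observed variables structurally uncorrelated with the equation's
    composite disturbance (the equation's own outcome is never eligible)."""
    eq = _find(system, equation_id)
    reduced = _reduced_form(spec)
    u = _disturbance_expr(eq)
    eligible = set()
    for v in spec.observed_vars:
        if v == eq.outcome:
            continue
        if _structural_cov(spec, reduced[v], u) == 0:
            eligible.add(v)
    return frozenset(eligible)


def _find(system: list[TransformedEquation], equation_id: str) -> TransformedEquation:
    for eq in system:
        if eq.equation_id == equation_id:
            return eq
    raise KeyError(f"no transformed equation {equation_id!r}")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _first_stage_r2(cov: np.ndarray, x: int, z: list[int]) -> float:
    """R-squared of the regression of variable x on instruments z, from a
    covariance matrix (centered moments)."""
    if not z:
        return 0.0
    szz = cov[np.ix_(z, z)]
    szx = cov[np.ix_(z, [x])]
    try:
        beta = np.linalg.solve(szz, szx)
    except np.linalg.LinAlgError:
        return float("nan")
    return float((szx.T @ beta).item() / cov[x, x])


def select_miivs(
    eligible: frozenset[str],
    equation: TransformedEquation,
    moments,
    overid_degree: int = 2,
) -> MIIVSet:
    """Greedy forward selection of instruments on the first-stage R².

    Exogenous regressors are always their own instruments.  Remaining slots
    (up to ``#regressors + overid_degree``) are filled from the eligible set,
    each step adding the candidate with the largest minimum R² increment
    across the endogenous regressors' first-stage regressions; ties break by
    the variable-registry order of ``moments.names``.
    """
    if overid_degree < 0:
        raise ValueError("overid_degree must be >= 0")
    names = list(moments.names)
    index = {n: i for i, n in enumerate(names)}
    cov = np.asarray(moments.cov, dtype=float)

    warnings: list[str] = []
    selected = [r.name for r in equation.regressors if not r.endogenous]
    endo = [index[n] for n in equation.endogenous_names]
    candidates = [
        n
        for n in names  # registry order
        if n in eligible and n not in selected and n not in equation.regressor_names
    ]

    n_reg = len(equation.regressors)
    target = n_reg + overid_degree if endo else n_reg
    trace: list[dict] = []

    while len(selected) < target and candidates:
        base = {x: _first_stage_r2(cov, x, [index[s] for s in selected]) for x in endo}
        best_name, best_gain = None, -np.inf
        gains = {}
        for c in candidates:
            zc = [index[s] for s in selected] + [index[c]]
            gain = min(_first_stage_r2(cov, x, zc) - base[x] for x in endo)
            gains[c] = gain
            if np.isfinite(gain) and gain > best_gain + 1e-15:
                best_name, best_gain = c, gain
        if best_name is None:
            warnings.append("no candidate instrument improves the first stage")
            break
        selected.append(best_name)
        candidates.remove(best_name)
        trace.append(
            {
                "added": best_name,
                "min_r2_increment": best_gain,
                "r2_after": {
                    names[x]: _first_stage_r2(
                        cov, x, [index[s] for s in selected]
                    )
                    for x in endo
                },
                "candidate_increments": gains,
            }
        )

    if len(selected) < target:
        warnings.append(
            f"only {len(selected)} instruments available for target {target}"
        )
    if len(selected) < n_reg:
        raise UnderIdentifiedError(
            f"equation {equation.equation_id!r}: {len(selected)} instruments "
            f"for {n_reg} regressors"
        )
    return MIIVSet(
        equation_id=equation.equation_id,
        eligible=frozenset(eligible),
        selected=selected,
        first_stage_r2_trace=trace,
        warnings=warnings,
    )


def identification_status(
    equation: TransformedEquation, miivs: MIIVSet
) -> tuple[str, int]:
    """Classify the equation: ("under", df<0) / ("exact", 0) / ("overidentified", df)."""
    df = len(miivs.selected) - len(equation.regressors)
    if df < 0:
        return ("under", df)
    if df == 0:
        return ("exact", 0)
    return ("overidentified", df)
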