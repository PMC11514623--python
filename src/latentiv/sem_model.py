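"""Model specification for latent-variable structural equation models.

A model is written in a small lavaan-style text grammar, one statement per
line:

``L =~ a + b + c``
    declares latent ``L`` measured by indicators ``a``, ``b``, ``c``.  The
    first indicator listed is the *scaling indicator*: its loading is fixed
    to 1 and its intercept to 0, which gives the latent the units (and mean
    origin) of that indicator.
``y ~ x1 + x2``
    declares a structural equation for outcome ``y`` (latent or observed)
    with a free intercept and free path coefficients.
``a ~~ b``
    declares that the error/disturbance terms of ``a`` and ``b`` covary.
``rescale: name=factor ...``
    records default divisors applied to the data columns before fitting
    (used to reduce disparities in variance across indicators).
``#``
    begins a comment.

Names on the left of ``=~`` are latent; every other name is an observed
variable.  Parameter identifiers are derived from variable names:
``lambda_<indicator>`` for free loadings, ``beta_<outcome>_<predictor>`` for
paths, ``alpha_<name>`` for intercepts, ``eps_<indicator>`` /
``zeta_<outcome>`` for error and disturbance terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MeasurementEquation",
    "StructuralEquation",
    "ModelSpec",
    "ParameterTable",
    "RescalePlan",
    "ModelSyntaxError",
    "parse_model",
    "validate_spec",
    "rescale_plan",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


class ModelSyntaxError(ValueError):
    """Raised when the model text violates the grammar."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MeasurementEquation:
    """One indicator's link to a latent: indicator = alpha + lambda * latent + eps."""

    indicator: str
    latent: str
    scaling: bool  # loading fixed to 1 and intercept fixed to 0

    @property
    def loading_id(self) -> str:
        return f"lambda_{self.indicator}"

    @property
    def intercept_id(self) -> str:
        return f"alpha_{self.indicator}"

    @property
    def error_term(self) -> str:
        return f"eps_{self.indicator}"


@dataclass(frozen=True)
class StructuralEquation:
    """outcome = alpha + sum(beta_i * predictor_i) + zeta."""

    outcome: str
    predictors: tuple[str, ...]

    @property
    def intercept_id(self) -> str:
        return f"alpha_{self.outcome}"

    @property
    def disturbance_term(self) -> str:
        return f"zeta_{self.outcome}"

    def path_id(self, predictor: str) -> str:
        return f"beta_{self.outcome}_{predictor}"


@dataclass(frozen=True)
class ParameterEntry:
    param_id: str
    kind: str  # loading | path | intercept
    status: str  # fixed | free
    value: float | None = None


@dataclass
class ParameterTable:
    entries: list[ParameterEntry] = field(default_factory=list)

    def free_ids(self) -> list[str]:
        return [e.param_id for e in self.entries if e.status == "free"]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ModelSpec:
    """A parsed, validated latent-variable SEM."""

    latents: list[str]
    measurement_eqs: list[MeasurementEquation]
    structural_eqs: list[StructuralEquation]
    observed_vars: list[str]
    error_covariances: list[tuple[str, str]] = field(default_factory=list)
    rescale_defaults: dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def indicators(self, latent: str) -> list[str]:
        return [m.indicator for m in self.measurement_eqs if m.latent == latent]

    def scaling_indicator(self, latent: str) -> str:
        for m in self.measurement_eqs:
            if m.latent == latent and m.scaling:
                return m.indicator
        raise KeyError(f"latent {latent!r} has no scaling indicator")

    def structural_for(self, outcome: str) -> StructuralEquation | None:
        for s in self.structural_eqs:
            if s.outcome == outcome:
                return s
        return None

    def is_latent(self, name: str) -> bool:
        return name in self.latents

    def all_names(self) -> set[str]:
        return set(self.latents) | set(self.observed_vars)

    def error_term_of(self, name: str) -> str | None:
        """Error/disturbance id a variable name refers to in `a ~~ b` statements."""
        for m in self.measurement_eqs:
            if m.indicator == name:
                return m.error_term
        s = self.structural_for(name)
        if s is not None:
            return s.disturbance_term
        return None

    # -- parameters ------------------------------------------------------
    def parameter_table(self) -> ParameterTable:
        entries: list[ParameterEntry] = []
        for m in self.measurement_eqs:
            if m.scaling:
                entries.append(ParameterEntry(m.loading_id, "loading", "fixed", 1.0))
                entries.append(ParameterEntry(m.intercept_id, "intercept", "fixed", 0.0))
            else:
                entries.append(ParameterEntry(m.loading_id, "loading", "free"))
                entries.append(ParameterEntry(m.intercept_id, "intercept", "free"))
        for s in self.structural_eqs:
            entries.append(ParameterEntry(s.intercept_id, "intercept", "free"))
            for p in s.predictors:
                entries.append(ParameterEntry(s.path_id(p), "path", "free"))
        return ParameterTable(entries)

    def free_parameter_ids(self) -> list[str]:
        return self.parameter_table().free_ids()

    # -- serialization ---------------------------------------------------
    def to_text(self) -> str:
        """Serialize back to the grammar (round-trips through parse_model)."""
        lines = []
        if self.rescale_defaults:
            parts = " ".join(f"{k}={v:g}" for k, v in self.rescale_defaults.items())
            lines.append(f"rescale: {parts}")
        for lat in self.latents:
            inds = self.indicators(lat)
            scaling = self.scaling_indicator(lat)
            ordered = [scaling] + [i for i in inds if i != scaling]
            lines.append(f"{lat} =~ " + " + ".join(ordered))
        for s in self.structural_eqs:
            lines.append(f"{s.outcome} ~ " + " + ".join(s.predictors))
        for a, b in self.error_covariances:
            lines.append(f"{a} ~~ {b}")
        return "\n".join(lines) + "\n"


def _check_name(tok: str, lineno: int) -> str:
    if not _NAME_RE.match(tok):
        raise ModelSyntaxError(f"invalid name {tok!r}", lineno)
    return tok


def parse_model(text: str) -> ModelSpec:
    """Parse model text in the grammar above into a validated :class:`ModelSpec`."""
    if not isinstance(text, str):
        raise TypeError("model text must be a string")

    statements: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            statements.append((lineno, line))
    if not statements:
        raise ModelSyntaxError("no statements")

    # first pass: latent declarations establish the latent/observed split
    latents: list[str] = []
    for lineno, line in statements:
        if "=~" in line:
            lhs = line.split("=~", 1)[0].strip()
            _check_name(lhs, lineno)
            if lhs in latents:
                raise ModelSyntaxError(f"latent {lhs!r} declared twice", lineno)
            latents.append(lhs)

    observed: list[str] = []

    def register(name: str) -> None:
        if name not in latents and name not in observed:
            observed.append(name)

    measurement: list[MeasurementEquation] = []
    structural: list[StructuralEquation] = []
    error_covs: list[tuple[str, str]] = []
    rescale: dict[str, float] = {}
    seen_outcomes: set[str] = set()

    for lineno, line in statements:
        if line.lower().startswith("rescale:"):
            for part in line.split(":", 1)[1].split():
                if "=" not in part:
                    raise ModelSyntaxError(f"bad rescale entry {part!r}", lineno)
                name, val = part.split("=", 1)
                _check_name(name, lineno)
                try:
                    factor = float(val)
                except ValueError:
                    raise ModelSyntaxError(f"bad rescale factor {val!r}", lineno) from None
                if factor <= 0:
                    raise ModelSyntaxError("rescale factor must be positive", lineno)
                rescale[name] = factor
        elif "=~" in line:
            lhs, rhs = (s.strip() for s in line.split("=~", 1))
            inds = [t.strip() for t in rhs.split("+")]
            if not inds or any(not t for t in inds):
                raise ModelSyntaxError("empty indicator list", lineno)
            for i, ind in enumerate(inds):
                _check_name(ind, lineno)
                if ind in latents:
                    raise ModelSyntaxError(f"{ind!r} is a latent, not an indicator", lineno)
                if any(m.indicator == ind and m.latent == lhs for m in measurement):
                    raise ModelSyntaxError(f"duplicate indicator {ind!r}", lineno)
                register(ind)
                measurement.append(MeasurementEquation(ind, lhs, scaling=(i == 0)))
        elif "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            _check_name(lhs, lineno)
            _check_name(rhs, lineno)
            error_covs.append((lhs, rhs))
        elif "~" in line:
            lhs, rhs = (s.strip() for s in line.split("~", 1))
            _check_name(lhs, lineno)
            preds = tuple(_check_name(t.strip(), lineno) for t in rhs.split("+"))
            if not preds:
                raise ModelSyntaxError("empty predictor list", lineno)
            if len(set(preds)) != len(preds):
                raise ModelSyntaxError("duplicate predictor", lineno)
            if lhs in seen_outcomes:
                raise ModelSyntaxError(f"outcome {lhs!r} defined twice", lineno)
            seen_outcomes.add(lhs)
            if lhs not in latents:
                register(lhs)
            for p in preds:
                if p not in latents:
                    register(p)
            structural.append(StructuralEquation(lhs, preds))
        else:
            raise ModelSyntaxError(f"unrecognised statement {line!r}", lineno)

    spec = ModelSpec(
        latents=latents,
        measurement_eqs=measurement,
        structural_eqs=structural,
        observed_vars=observed,
        error_covariances=error_covs,
        rescale_defaults=rescale,
    )
    problems = validate_spec(spec)
    if problems:
        raise ModelSyntaxError("; ".join(problems))
    return spec


def validate_spec(spec: ModelSpec) -> list[str]:
    """Return human-readable diagnostics; empty list means the spec is valid."""
    problems: list[str] = []
    known = spec.all_names()

    for lat in spec.latents:
        inds = spec.indicators(lat)
        if not inds:
            problems.append(f"latent {lat!r} has no indicators")
            continue
        n_scaling = sum(
            1 for m in spec.measurement_eqs if m.latent == lat and m.scaling
        )
        if n_scaling == 0:
            problems.append(f"latent {lat!r} lacks scaling indicator")
        elif n_scaling > 1:
            problems.append(f"latent {lat!r} has multiple scaling indicators")

    seen: set[str] = set()
    for s in spec.structural_eqs:
        if s.outcome in seen:
            problems.append(f"outcome {s.outcome!r} defined twice")
        seen.add(s.outcome)
        for name in (s.outcome, *s.predictors):
            if name not in known:
                problems.append(f"unknown name {name!r} in structural equation")
        if s.outcome in s.predictors:
            problems.append(f"outcome {s.outcome!r} predicts itself")

    for a, b in spec.error_covariances:
        for name in (a, b):
            if name not in known:
                problems.append(f"unknown name {name!r} in error covariance")
            elif spec.error_term_of(name) is None:
                problems.append(
                    f"{name!r} has no error term (not an indicator or structural outcome)"
                )
    return problems


@dataclass
class RescalePlan:
    """Per-variable divisors applied to data columns before fitting.

    ``analysis = original / factor``.  Variables not named get factor 1.
    Coefficient back-transform: a slope b on the analysis scale for outcome
    y and regressor x corresponds to ``b * factor_y / factor_x`` on the
    original scale; intercepts scale by ``factor_y``.
    """

    factors: dict[str, float]

    def factor(self, name: str) -> float:
        return self.factors.get(name, 1.0)

    def apply(self, data):
        out = data.copy()
        for name, f in self.factors.items():
            if name in out.columns:
                out[name] = out[name] / f
        return out

    def invert(self, data):
        out = data.copy()
        for name, f in self.factors.items():
            if name in out.columns:
                out[name] = out[name] * f
        return out

    def slope_to_original(self, value: float, outcome: str, regressor: str) -> float:
        return value * self.factor(outcome) / self.factor(regressor)

    def intercept_to_original(self, value: float, outcome: str) -> float:
        return value * self.factor(outcome)

    def __len__(self) -> int:
        return len(self.factors)


def rescale_plan(spec: ModelSpec, factors: dict[str, float] | None = None) -> RescalePlan:
    """Build a rescale plan from explicit factors or the model file's defaults."""
    if factors is None:
        factors = dict(spec.rescale_defaults)
    known = spec.all_names()
    for name, f in factors.items():
        if name not in known:
            raise KeyError(f"unknown variable {name!r} in rescale factors")
        if not (f > 0):
            raise ValueError(f"rescale factor for {name!r} must be positive, got {f}")
        if name in spec.latents:
            raise ValueError(f"cannot rescale latent {name!r}; rescale its indicators")
    return RescalePlan(dict(factors))
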