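"""Synthetic cohorts with the latent-trade-off structure the analysis assumes.

The generator draws from the recursive linear model behind the brain/body
analysis: height drives two latent constructs ("nutritional investment in
brain tissues", indicated by intracranial, cerebrum and cerebellum volumes,
and "nutritional investment in lean body tissues", indicated by summed organ
volumes and skeletal muscle) plus measured fat mass; the brain latent
carries negative causal paths to the body latent and to fat.  Path
coefficients default to the fitted values the analysis is calibrated
against (brain-to-body -0.41, brain-to-fat -0.56, on the analysis scale);
cohort size defaults to 70 with 3 missing-completely-at-random organ cells,
and height to mean 161 cm with CV 4.1%.  Indicator means and error SDs are
physiologically plausible defaults chosen for this generator, not values
asserted about any real cohort.

All structural parameters live on the analysis (rescaled) scale; emitted
tables are on the original measurement scale (cm, cm^3, kg) by inverting
the rescale plan.  :func:`implied_moments` returns the exact population
means/covariances of the model, which is the oracle for every estimator
test: 2SLS applied to these moments must recover the parameters exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import MomentSet

__all__ = ["GeneratorParams", "default_params", "generate", "implied_moments"]

COLUMNS = ("height", "TIV", "cerebrum", "cerebellum", "organs", "SM", "fat")

MODEL_TEXT = """\
# Brain/body nutritional-investment trade-off model.
# Scaling indicators (loading fixed to 1) are listed first: TIV for the
# brain latent, organs for the lean-body latent.
rescale: TIV=100 cerebrum=100 cerebellum=10 organs=100 height=10
brain =~ TIV + cerebrum + cerebellum
body =~ organs + SM
brain ~ height
body ~ brain + height
fat ~ brain + height
"""


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort, on the analysis scale.

    ``path_*`` are structural coefficients, ``loading_*`` free factor
    loadings, ``alpha_*`` intercepts, ``sd_*`` error standard deviations.
    """

    n: int = 70
    # height distribution (original scale: cm)
    height_mean_cm: float = 161.0
    height_cv_pct: float = 4.1
    # structural paths (analysis scale)
    path_brain_to_body: float = -0.41
    path_brain_to_fat: float = -0.56
    path_height_to_brain: float = 0.6
    path_height_to_body: float = 2.2
    path_height_to_fat: float = 1.5
    # free loadings
    loading_cerebrum: float = 0.8
    loading_cerebellum: float = 0.9
    loading_sm: float = 0.55
    # intercepts
    alpha_brain: float = 4.84
    alpha_body: float = -4.475
    alpha_fat: float = 0.97
    alpha_cerebrum: float = -1.2
    alpha_cerebellum: float = -0.05
    alpha_sm: float = 2.25
    # error standard deviations
    sd_zeta_brain: float = 0.9
    sd_zeta_body: float = 2.2
    sd_zeta_fat: float = 5.2
    sd_eps_tiv: float = 0.25
    sd_eps_cerebrum: float = 0.35
    sd_eps_cerebellum: float = 0.8
    sd_eps_organs: float = 0.5
    sd_eps_sm: float = 1.2
    # error shape: "gaussian" or "skewed" (centered, variance-matched gamma)
    error_distribution: str = "gaussian"
    # MCAR missingness
    missing_var: str | None = "organs"
    missing_count: int = 3
    # divisors taking original-scale data to the analysis scale
    rescale_factors: dict = field(
        default_factory=lambda: {
            "TIV": 100.0,
            "cerebrum": 100.0,
            "cerebellum": 10.0,
            "organs": 100.0,
            "height": 10.0,
        }
    )
    # optional generator-side misspecification: (indicator, latent, coefficient)
    cross_loading: tuple | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.height_cv_pct <= 0:
            raise ValueError("height CV must be positive")
        for f in self.__dataclass_fields__:
            if f.startswith("sd_") and getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.missing_var is not None and not (0 <= self.missing_count < self.n):
            raise ValueError("missing count must be in [0, n)")
        if self.error_distribution not in ("gaussian", "skewed"):
            raise ValueError(f"unknown error distribution {self.error_distribution!r}")
        if self.cross_loading is not None:
            ind, lat, _ = self.cross_loading
            if ind not in COLUMNS or lat not in ("brain", "body"):
                raise ValueError(f"bad cross_loading {self.cross_loading!r}")

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)

    # analysis-scale height distribution
    @property
    def height_mean(self) -> float:
        return self.height_mean_cm / self.rescale_factors.get("height", 1.0)

    @property
    def height_sd(self) -> float:
        return self.height_mean * self.height_cv_pct / 100.0

    def true_values(self) -> dict[str, float]:
        """Free-parameter truth keyed by model parameter ids (analysis scale)."""
        return {
            "beta_brain_height": self.path_height_to_brain,
            "beta_body_brain": self.path_brain_to_body,
            "beta_body_height": self.path_height_to_body,
            "beta_fat_brain": self.path_brain_to_fat,
            "beta_fat_height": self.path_height_to_fat,
            "lambda_cerebrum": self.loading_cerebrum,
            "lambda_cerebellum": self.loading_cerebellum,
            "lambda_SM": self.loading_sm,
            "alpha_brain": self.alpha_brain,
            "alpha_body": self.alpha_body,
            "alpha_fat": self.alpha_fat,
            "alpha_cerebrum": self.alpha_cerebrum,
            "alpha_cerebellum": self.alpha_cerebellum,
            "alpha_SM": self.alpha_sm,
        }

    def model_text(self) -> str:
        return MODEL_TEXT


def default_params() -> GeneratorParams:
    """The packaged study conditions: n = 70, calibrated negative paths,
    3 MCAR-missing organ cells."""
    return GeneratorParams()


_ERROR_SDS = {
    "zeta_brain": "sd_zeta_brain",
    "zeta_body": "sd_zeta_body",
    "zeta_fat": "sd_zeta_fat",
    "eps_TIV": "sd_eps_tiv",
    "eps_cerebrum": "sd_eps_cerebrum",
    "eps_cerebellum": "sd_eps_cerebellum",
    "eps_organs": "sd_eps_organs",
    "eps_SM": "sd_eps_sm",
}


def _cross(params: GeneratorParams, indicator: str) -> tuple[str, float] | None:
    if params.cross_loading is not None and params.cross_loading[0] == indicator:
        return params.cross_loading[1], float(params.cross_loading[2])
    return None


def generate(
    params: GeneratorParams | None = None,
    seed: int | None = None,
    return_components: bool = False,
):
    """Draw a cohort on the original measurement scale.

    Columns: height (cm), TIV/cerebrum/cerebellum/organs (cm^3), SM (kg),
    fat (kg).  Same seed, same table, bit for bit.  With
    ``return_components=True`` also returns the analysis-scale latents and
    error draws (for oracle tests)."""
    params = params or default_params()
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n

    def draw(sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.zeros(size)
        if params.error_distribution == "gaussian":
            return rng.normal(0.0, sd, size)
        # centered, variance-matched gamma (skewness 1)
        g = rng.gamma(4.0, 1.0, size)
        return (g - 4.0) / 2.0 * sd

    h = rng.normal(params.height_mean, params.height_sd, n)
    err = {name: draw(getattr(params, fld), n) for name, fld in _ERROR_SDS.items()}

    eta_brain = params.alpha_brain + params.path_height_to_brain * h + err["zeta_brain"]
    eta_body = (
        params.alpha_body
        + params.path_brain_to_body * eta_brain
        + params.path_height_to_body * h
        + err["zeta_body"]
    )
    latent = {"brain": eta_brain, "body": eta_body}

    cols = {
        "height": h,
        "TIV": eta_brain + err["eps_TIV"],
        "cerebrum": params.alpha_cerebrum
        + params.loading_cerebrum * eta_brain
        + err["eps_cerebrum"],
        "cerebellum": params.alpha_cerebellum
        + params.loading_cerebellum * eta_brain
        + err["eps_cerebellum"],
        "organs": eta_body + err["eps_organs"],
        "SM": params.alpha_sm + params.loading_sm * eta_body + err["eps_SM"],
        "fat": params.alpha_fat
        + params.path_brain_to_fat * eta_brain
        + params.path_height_to_fat * h
        + err["zeta_fat"],
    }
    for ind in ("TIV", "cerebrum", "cerebellum", "organs", "SM", "fat"):
        extra = _cross(params, ind)
        if extra is not None:
            cols[ind] = cols[ind] + extra[1] * latent[extra[0]]

    df = pd.DataFrame({c: cols[c] for c in COLUMNS})
    # back to the original measurement scale
    for name, f in params.rescale_factors.items():
        df[name] = df[name] * f
    if params.missing_var is not None and params.missing_count > 0:
        rows = rng.choice(n, size=params.missing_count, replace=False)
        df.loc[rows, params.missing_var] = np.nan

    if return_components:
        components = {"eta_brain": eta_brain, "eta_body": eta_body, **err}
        return df, components
    return df


def implied_moments(
    params: GeneratorParams | None = None, n_effective: int | None = None
) -> MomentSet:
    """Exact population means/covariances of the generator, analysis scale.

    Each variable is written as an affine combination of the independent
    sources (height, disturbances, measurement errors); means and
    covariances follow from the source moments in closed form.
    """
    params = params or default_params()
    params.validate()
    sources = ["height_src"] + list(_ERROR_SDS)
    var = np.array(
        [params.height_sd**2] + [getattr(params, f) ** 2 for f in _ERROR_SDS.values()]
    )
    si = {s: i for i, s in enumerate(sources)}
    k = len(sources)

    def affine(const: float, terms: dict[str, float]) -> tuple[float, np.ndarray]:
        row = np.zeros(k)
        for s, c in terms.items():
            row[si[s]] += c
        return const, row

    def combine(const, parts):
        """parts: list of (coef, (const, row)) plus extra source terms."""
        row = np.zeros(k)
        for coef, (c0, r) in parts:
            const += coef * c0
            row += coef * r
        return const, row

    h = affine(params.height_mean, {"height_src": 1.0})
    eta_brain = combine(
        params.alpha_brain,
        [(params.path_height_to_brain, h), (1.0, affine(0.0, {"zeta_brain": 1.0}))],
    )
    eta_body = combine(
        params.alpha_body,
        [
            (params.path_brain_to_body, eta_brain),
            (params.path_height_to_body, h),
            (1.0, affine(0.0, {"zeta_body": 1.0})),
        ],
    )
    latent = {"brain": eta_brain, "body": eta_body}

    reps = {
        "height": h,
        "TIV": combine(0.0, [(1.0, eta_brain), (1.0, affine(0.0, {"eps_TIV": 1.0}))]),
        "cerebrum": combine(
            params.alpha_cerebrum,
            [(params.loading_cerebrum, eta_brain), (1.0, affine(0.0, {"eps_cerebrum": 1.0}))],
        ),
        "cerebellum": combine(
            params.alpha_cerebellum,
            [
                (params.loading_cerebellum, eta_brain),
                (1.0, affine(0.0, {"eps_cerebellum": 1.0})),
            ],
        ),
        "organs": combine(
            0.0, [(1.0, eta_body), (1.0, affine(0.0, {"eps_organs": 1.0}))]
        ),
        "SM": combine(
            params.alpha_sm,
            [(params.loading_sm, eta_body), (1.0, affine(0.0, {"eps_SM": 1.0}))],
        ),
        "fat": combine(
            params.alpha_fat,
            [
                (params.path_brain_to_fat, eta_brain),
                (params.path_height_to_fat, h),
                (1.0, affine(0.0, {"zeta_fat": 1.0})),
            ],
        ),
    }
    for ind in ("TIV", "cerebrum", "cerebellum", "organs", "SM", "fat"):
        extra = _cross(params, ind)
        if extra is not None:
            reps[ind] = combine(0.0, [(1.0, reps[ind]), (extra[1], latent[extra[0]])])

    mean = np.array([reps[c][0] for c in COLUMNS])
    A = np.vstack([reps[c][1] for c in COLUMNS])
    cov = A @ np.diag(var) @ A.T
    return MomentSet(
        COLUMNS, mean, cov, n_effective or params.n, source="implied"
    )
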