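"""Gender-adjusted regression of a response on age.

Three model families cover the clinical and expression analyses:

* ``linear``      y ~ 1 + age + sex            (muscle-strength decline)
* ``quadratic``   y ~ 1 + age + age^2 + sex    (expression vs age, curvature)
* ``piecewise``   two independent linear fits below/above a fixed breakpoint
                  (default 42.5 years, separating young from mid-life+), no
                  continuity constraint at the break.

All fits are ordinary least squares with sex as an additive binary covariate
(female = 1); coefficients, standard errors and two-sided t-test p-values
are reported per term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_BREAKPOINT = 42.5


@dataclass
class RegressionFit:
    model: str
    terms: pd.DataFrame  # index=term, columns beta, se, p
    n: int
    age_range: tuple[float, float]
    breakpoint: float | None = None
    segments: list["RegressionFit"] = field(default_factory=list)

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])


def _encode_sex(sex) -> np.ndarray:
    s = pd.Series(sex)
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        mapped = s.map({"male": 0.0, "female": 1.0})
        if mapped.isna().any():
            raise ValueError("sex must be 'male'/'female' or binary 0/1")
        return mapped.to_numpy()
    return s.astype(float).to_numpy()


def _ols(y, design: pd.DataFrame, model: str, age_range) -> RegressionFit:
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    terms = pd.DataFrame(
        {"beta": res.params, "se": res.bse, "p": res.pvalues}
    )
    # a perfect (noiseless) fit leaves SEs at 0/NaN; keep p well-defined
    terms["p"] = terms["p"].fillna(0.0)
    return RegressionFit(
        model=model, terms=terms, n=int(res.nobs), age_range=tuple(age_range)
    )


def _design(age: np.ndarray, female: np.ndarray | None, quadratic: bool) -> pd.DataFrame:
    cols = {"intercept": np.ones_like(age), "age": age}
    if quadratic:
        cols["age_sq"] = age**2
    if female is not None:
        cols["sex"] = female
    return pd.DataFrame(cols)


def fit_age_trend(
    response,
    age,
    sex=None,
    model: str = "linear",
    breakpoint: float = DEFAULT_BREAKPOINT,
) -> RegressionFit:
    """OLS fit of a response on age with an optional sex covariate.

    ``model`` is ``"linear"``, ``"quadratic"`` or ``"piecewise"``; piecewise
    fits two independent linear models on the samples at or below and above
    ``breakpoint`` (each segment needs >= 4 samples).  If every subject has
    the same sex the covariate is dropped with a warning.
    """
    y = np.asarray(response, dtype=float)
    age = np.asarray(age, dtype=float)
    female = _encode_sex(sex) if sex is not None else None
    if female is not None and len(np.unique(female)) < 2:
        warnings.warn("sex covariate is constant; dropping it from the design", stacklevel=2)
        female = None

    if model == "piecewise":
        lower = age <= breakpoint
        segments = []
        for name, mask in (("low", lower), ("high", ~lower)):
            if mask.sum() < 4:
                raise ValueError(
                    f"piecewise segment {name!r} "
                    f"({'<=' if name == 'low' else '>'} {breakpoint} y) has "
                    f"{int(mask.sum())} samples; need >= 4"
                )
            seg_female = female[mask] if female is not None else None
            if seg_female is not None and len(np.unique(seg_female)) < 2:
                seg_female = None
            design = _design(age[mask], seg_female, quadratic=False)
            seg = _ols(y[mask], design, "linear", (age[mask].min(), age[mask].max()))
            segments.append(seg)
        fit = RegressionFit(
            model="piecewise",
            terms=pd.concat(
                {"low": segments[0].terms, "high": segments[1].terms}, names=["segment", "term"]
            ),
            n=len(y),
            age_range=(float(age.min()), float(age.max())),
            breakpoint=breakpoint,
            segments=segments,
        )
        return fit

    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")
    n_params = 2 + (model == "quadratic") + (female is not None)
    if len(y) < n_params + 1:
        raise ValueError("too few samples for the requested model")
    design = _design(age, female, quadratic=model == "quadratic")
    fit = _ols(y, design, model, (float(age.min()), float(age.max())))
    return fit


def fit_clinical_slopes(
    clinical: pd.DataFrame, muscles: list[str] | None = None
) -> pd.DataFrame:
    """One gender-adjusted linear fit of MRC score on age per muscle column.

    Returns a table shaped like a clinical regression summary: one row per
    muscle with the age-slope beta, its standard error and p-value.
    """
    if len(clinical) < 10:
        raise ValueError("need >= 10 subjects for clinical slopes")
    if muscles is None:
        muscles = [
            c for c in clinical.columns if c not in ("subject_id", "age_years", "sex")
        ]
    rows = []
    for muscle in muscles:
        if muscle not in clinical.columns:
            raise ValueError(f"muscle column {muscle!r} missing from clinical table")
        fit = fit_age_trend(
            clinical[muscle], clinical["age_years"], clinical["sex"], model="linear"
        )
        rows.append(
            {
                "muscle": muscle,
                "beta": fit.terms.loc["age", "beta"],
                "se": fit.terms.loc["age", "se"],
                "p": fit.terms.loc["age", "p"],
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows).set_index("muscle")
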