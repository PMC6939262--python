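"""Mixed-model comparison of feeding rates against allelic-value predictors.

The analysis compares a null Gaussian linear mixed model of a parent's
feeding rate — nestling age, lay date, time of day, nest social status,
the mate's simultaneously observed rate and its interaction with status,
plus crossed random intercepts for focal individual, social mate and nest —
against focal models that each add one predictor (brood size, TAV, TAV_z,
LAV, P_EPO, pair kinship k_ij, own inbreeding f, optionally with status
interactions).  Support is assessed with the small-sample Akaike criterion:
a focal model is supported when its AICc undercuts the null's by at least
two units.

All models are fitted by maximum likelihood (not REML): the compared models
differ in their fixed effects, and REML likelihoods are not comparable
across fixed-effect structures.  Fitting itself is delegated to
statsmodels' MixedLM, with the three crossed random intercepts expressed as
variance components within a single all-encompassing group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .allelic_value import BroodAllelicValues, standardize_tav
from .synthetic import ObservationSession

__all__ = [
    "ModelSpec",
    "FitResult",
    "ComparisonTable",
    "build_design",
    "fit_lmm",
    "aicc",
    "compare_models",
    "marginal_means",
    "pearson",
    "confidence_interval",
]

#: Reference levels for the categorical covariates.
REFERENCES = {"status": "monogamous", "time_of_day": "morning", "bs_factor": None}

#: Fixed-term vocabulary -> (patsy formula term, columns required).
_TERMS = {
    "age": ("age", ["age"]),
    "lay_date": ("lay_date", ["lay_date"]),
    "time_of_day": ("C(time_of_day, Treatment('morning'))", ["time_of_day"]),
    "status": ("C(status, Treatment('monogamous'))", ["status"]),
    "mate_rate": ("mate_rate", ["mate_rate"]),
    "mate_rate:status": (
        "mate_rate:C(status, Treatment('monogamous'))",
        ["mate_rate", "status"],
    ),
    "bs": ("bs", ["bs"]),
    "bs_factor": ("C(bs)", ["bs"]),
    "tav": ("tav", ["tav"]),
    "tav_z": ("tav_z", ["tav_z"]),
    "tav_z:bs_factor": ("tav_z:C(bs)", ["tav_z", "bs"]),
    "tav_z:status": ("tav_z:C(status, Treatment('monogamous'))", ["tav_z", "status"]),
    "lav": ("lav", ["lav"]),
    "lav:status": ("lav:C(status, Treatment('monogamous'))", ["lav", "status"]),
    "p_epo": ("p_epo", ["p_epo"]),
    "p_epo:status": ("p_epo:C(status, Treatment('monogamous'))", ["p_epo", "status"]),
    "kij": ("kij", ["kij"]),
    "kij:status": ("kij:C(status, Treatment('monogamous'))", ["kij", "status"]),
    "f": ("f", ["f"]),
    "f:status": ("f:C(status, Treatment('monogamous'))", ["f", "status"]),
}

NULL_TERMS = ("age", "lay_date", "time_of_day", "status", "mate_rate", "mate_rate:status")

_RANDOM = {
    "individual": "0 + C(ind_id)",
    "mate": "0 + C(mate_id)",
    "nest": "0 + C(nest_id)",
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` use the vocabulary above; ``centering`` names the
    continuous columns to mean-centre in the design (continuous variables
    appearing in interactions should always be centred).
    """

    label: str
    response: str  # "male_rate" | "female_rate"
    fixed_terms: tuple[str, ...] = NULL_TERMS
    random_terms: tuple[str, ...] = ("individual", "mate", "nest")
    centering: tuple[str, ...] = ("mate_rate",)

    def formula(self) -> str:
        parts = []
        for t in self.fixed_terms:
            if t not in _TERMS:
                raise ValueError(f"unknown model term {t!r}")
            parts.append(_TERMS[t][0])
        rhs = " + ".join(parts) if parts else "1"
        return f"rate ~ {rhs}"

    def with_terms(self, *extra: str, label: str | None = None,
                   centering: tuple[str, ...] | None = None) -> "ModelSpec":
        return replace(
            self,
            label=label or self.label,
            fixed_terms=self.fixed_terms + extra,
            centering=centering if centering is not None else self.centering,
        )


def null_spec(response: str, label: str = "null") -> ModelSpec:
    return ModelSpec(label=label, response=response)


def build_design(
    sessions: Sequence[ObservationSession],
    values: Sequence[BroodAllelicValues],
    spec: ModelSpec,
) -> pd.DataFrame:
    """One model-ready row per session for the spec's response.

    Joins each session to its brood's allelic values, picks the sex-specific
    TAV/inbreeding columns for the response, attaches the mate's observed
    rate, recomputes TAV_z across the broods present, and mean-centres the
    columns named in ``spec.centering``.
    """
    if spec.response not in ("male_rate", "female_rate"):
        raise ValueError(f"unknown response {spec.response!r}")
    cols = [
        "rate", "mate_rate", "age", "lay_date", "time_of_day", "status",
        "bs", "tav", "tav_z", "lav", "p_epo", "kij", "f",
        "ind_id", "mate_id", "nest_id",
    ]
    if not sessions:
        return pd.DataFrame(columns=cols)
    vmap = {v.nest_id: v for v in values}
    male = spec.response == "male_rate"
    tav_attr = "TAV_i" if male else "TAV_j"
    zmap = dict(
        standardize_tav(
            (v.nest_id, v.BS, getattr(v, tav_attr)) for v in values
        )
    )
    # social parent ids come through the values' broods; sessions carry nest ids
    rows = []
    for s in sessions:
        if s.nest_id not in vmap:
            raise KeyError(f"session references unknown nest {s.nest_id!r}")
        v = vmap[s.nest_id]
        ind, mate = (v.male_id, v.female_id) if male else (v.female_id, v.male_id)
        rows.append(
            {
                "rate": s.male_rate if male else s.female_rate,
                "mate_rate": s.female_rate if male else s.male_rate,
                "age": s.nestling_age,
                "lay_date": s.lay_date,
                "time_of_day": s.time_of_day,
                "status": s.status,
                "bs": v.BS,
                "tav": getattr(v, tav_attr),
                "tav_z": zmap[v.nest_id],
                "lav": v.LAV,
                "p_epo": v.P_EPO,
                "kij": v.k_ij,
                "f": v.f_i if male else v.f_j,
                "ind_id": ind,
                "mate_id": mate,
                "nest_id": s.nest_id,
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    for col in spec.centering:
        if col not in df.columns:
            raise ValueError(f"cannot centre unknown column {col!r}")
        df[col] = df[col] - df[col].mean()
    needed = {c for t in spec.fixed_terms for c in _TERMS.get(t, (None, []))[1]}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"design lacks columns {sorted(missing)}")
    return df


@dataclass
class FitResult:
    """Fitted mixed model: likelihood, information criteria, coefficients."""

    spec: ModelSpec
    n_obs: int
    n_params: int  # fixed effects + variance components + residual
    loglik: float
    aic: float
    aicc: float
    coefficients: dict[str, tuple[float, float]]  # term -> (estimate, SE)
    converged: bool
    boundary: bool = False  # some variance component estimated at zero
    _result: object = field(default=None, repr=False, compare=False)
    _design: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 logL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lmm(design: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the spec's Gaussian LMM by maximum likelihood.

    The crossed random intercepts are expressed as variance components
    within a single group spanning the data.  Non-convergence, boundary
    estimates or numerical failure are reported through ``converged``;
    a failed fit carries NaN likelihood rather than raising.
    """
    formula = spec.formula()
    n = len(design)
    if design["rate"].nunique() <= 1:
        # Degenerate response: zero residual variance, nothing to fit.
        return FitResult(spec, n, 0, float("nan"), float("nan"), float("nan"),
                         {}, converged=False, _design=design)
    vc = {name: _RANDOM[name] for name in spec.random_terms}
    boundary = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model = smf.mixedlm(
                formula, design, groups=np.ones(n), vc_formula=vc, re_formula="0"
            )
            result = model.fit(reml=False, method="lbfgs", maxiter=200, disp=False)
            # L-BFGS occasionally stalls near variance boundaries; polish
            # with a derivative-free pass whenever it reports trouble.
            if not result.converged:
                polished = model.fit(
                    reml=False, method="powell", start_params=result.params_object,
                    maxiter=300, disp=False,
                )
                if np.isfinite(polished.llf) and (
                    not np.isfinite(result.llf) or polished.llf >= result.llf
                ):
                    result = polished
        boundary = any(
            issubclass(w.category, ConvergenceWarning) and "boundary" in str(w.message)
            for w in caught
        )
    except (np.linalg.LinAlgError, ValueError, KeyError, IndexError) as exc:
        warnings.warn(f"model {spec.label!r} failed to fit: {exc}")
        return FitResult(spec, n, 0, float("nan"), float("nan"), float("nan"),
                         {}, converged=False, _design=design)
    converged = bool(result.converged) and np.isfinite(result.llf)
    k = len(result.fe_params) + len(vc) + 1
    ll = float(result.llf)
    coefs = {
        _clean_name(name): (float(est), float(se))
        for name, est, se in zip(result.fe_params.index, result.fe_params, result.bse_fe)
    }
    return FitResult(
        spec=spec,
        n_obs=n,
        n_params=k,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        aicc=aicc(ll, k, n),
        coefficients=coefs,
        converged=converged,
        boundary=boundary,
        _result=result,
        _design=design,
    )


def _clean_name(name: str) -> str:
    """Readable coefficient names: strip patsy C()/Treatment noise."""
    out = name
    for col, ref in (("status", "monogamous"), ("time_of_day", "morning")):
        out = out.replace(f"C({col}, Treatment('{ref}'))", col)
    out = out.replace("C(bs)", "bs")
    return out


@dataclass
class ComparisonTable:
    """AICc ranking of a model set against a designated null."""

    null_label: str
    rows: pd.DataFrame  # label, n_obs, n_params, loglik, aicc, delta_aicc, supported
    pairwise: dict[tuple[str, str], float]  # (a, b) -> AICc_a - AICc_b

    def delta(self, a: str, b: str) -> float:
        return self.pairwise[(a, b)]


def compare_models(fits: Sequence[FitResult], null_label: str = "null") -> ComparisonTable:
    """Tabulate AICc differences against the null model.

    ``delta_aicc = AICc_focal - AICc_null``; a focal model is *supported*
    when ``delta_aicc <= -2``.  All fits must share the same observations;
    non-converged fits are dropped with a warning.
    """
    labels = [f.spec.label for f in fits]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels in comparison")
    if null_label not in labels:
        raise ValueError(f"null model {null_label!r} not among fits")
    n_set = {f.n_obs for f in fits}
    if len(n_set) != 1:
        raise ValueError(f"fits use different observation counts: {sorted(n_set)}")
    usable = []
    for f in fits:
        if not f.converged:
            warnings.warn(f"excluding non-converged model {f.spec.label!r} from comparison")
            if f.spec.label == null_label:
                raise ValueError("null model did not converge; comparison impossible")
            continue
        usable.append(f)
    null_aicc = next(f.aicc for f in usable if f.spec.label == null_label)
    rows = pd.DataFrame(
        {
            "label": [f.spec.label for f in usable],
            "n_obs": [f.n_obs for f in usable],
            "n_params": [f.n_params for f in usable],
            "loglik": [f.loglik for f in usable],
            "aicc": [f.aicc for f in usable],
            "delta_aicc": [f.aicc - null_aicc for f in usable],
        }
    )
    rows["supported"] = rows["delta_aicc"] <= -2.0
    pairwise = {
        (a.spec.label, b.spec.label): a.aicc - b.aicc
        for a in usable
        for b in usable
        if a is not b
    }
    return ComparisonTable(null_label=null_label, rows=rows, pairwise=pairwise)


def marginal_means(fit: FitResult, factor: str) -> dict[str, tuple[float, float]]:
    """Least-square means for a factor: predicted response per level at the
    mean of continuous covariates, balanced over the other factors."""
    if fit._result is None or fit._design is None:
        raise ValueError("fit carries no model internals (failed fit?)")
    design = fit._design
    factor_cols = [c for c in ("status", "time_of_day", "bs") if c in _factor_cols(fit.spec)]
    if factor not in factor_cols:
        raise ValueError(f"factor {factor!r} not among this model's factors {factor_cols}")
    result = fit._result
    design_info = result.model.data.design_info
    cont = [
        c for c in design.columns
        if c not in ("rate", "ind_id", "mate_id", "nest_id", *factor_cols)
        and np.issubdtype(design[c].dtype, np.number)
    ]
    others = [c for c in factor_cols if c != factor]
    grids = [sorted(design[c].unique()) for c in others]
    fe = result.fe_params
    cov = np.asarray(result.cov_params().loc[fe.index, fe.index])
    out = {}
    from patsy import build_design_matrices

    for level in sorted(design[factor].unique()):
        combos = list(product(*grids)) if grids else [()]
        frame = pd.DataFrame(
            [
                {factor: level, **dict(zip(others, combo)),
                 **{c: design[c].mean() for c in cont}}
                for combo in combos
            ]
        )
        (X,) = build_design_matrices([design_info], frame)
        c_vec = np.asarray(X).mean(axis=0)
        est = float(c_vec @ fe.values)
        se = float(np.sqrt(c_vec @ cov @ c_vec))
        out[str(level)] = (est, se)
    return out


def _factor_cols(spec: ModelSpec) -> set[str]:
    cols = set()
    for t in spec.fixed_terms:
        if t in ("time_of_day",):
            cols.add("time_of_day")
        if t == "status" or t.endswith(":status"):
            cols.add("status")
        if t == "bs_factor" or t.endswith(":bs_factor"):
            cols.add("bs")
    return cols


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def confidence_interval(
    fit: FitResult, term: str, level: float = 0.85
) -> tuple[float, float]:
    """Wald confidence interval, estimate +/- z_level * SE."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if term not in fit.coefficients:
        raise KeyError(f"unknown term {term!r}; have {sorted(fit.coefficients)}")
    est, se = fit.coefficients[term]
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    return (est - z * se, est + z * se)
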