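"""CITS regression models.

The central model is a Poisson regression with log link and a log
person-time offset fitted to person-year rows.  The exposure covariate
enters linearly on the log-rate scale, so a probability ``p`` of exposure
contributes ``p * beta`` and ``exp(beta)`` is interpreted as the incidence
rate ratio (IRR) for fully exposed versus unexposed.  Two covariate
layouts are supported:

* ``primary_care`` — year of birth, age (year of life), their interaction,
  delivery type, and exposure; suited to probability-based exposure where
  each child contributes one observation per year of life.
* ``hes`` — year of birth, delivery type, and exposure; suited to the
  hospital-indicator exposure where births in a hospital's change year are
  excluded upstream.

Additional variants: ``maternal`` (Poisson with log link on a binary
six-week outcome, estimating risk ratios adjusted for delivery year and
delivery type) and ``continuous`` (OLS difference in means for continuous
outcomes such as length of stay).

Before fitting, person-year rows are aggregated over unique covariate
combinations (events and person-time summed).  For a log-link Poisson
model with an offset this aggregation is exact — the likelihood depends on
the data only through per-cell event and time totals — and it makes fits
on large simulated cohorts take milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Fewer events than this and only summary statistics are reported.
RARE_EVENT_THRESHOLD = 200

#: Two-sided 95% normal quantile used for Wald intervals.
Z_95 = 1.959964

_CONVERGENCE_TOL = 1e-10
_MAX_ITER = 100


def rare_guard(n_events: int) -> bool:
    """True iff the outcome is too rare to model (< 200 children)."""
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return n_events < RARE_EVENT_THRESHOLD


@dataclass
class ModelSpec:
    """Covariate layout for a CITS fit.

    ``year_coding``/``age_coding`` select categorical indicator coding
    (earliest level as reference) or a single linear term.
    """

    variant: str = "primary_care"  # primary_care | hes | maternal | continuous
    year_coding: str = "categorical"  # categorical | linear
    age_coding: str = "categorical"
    include_age: bool | None = None  # default depends on variant
    include_year_age_interaction: bool | None = None
    scale: str = "fixed"  # fixed | quasipoisson

    def __post_init__(self) -> None:
        if self.variant not in ("primary_care", "hes", "maternal",
                                "continuous"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.include_age is None:
            self.include_age = self.variant == "primary_care"
        if self.include_year_age_interaction is None:
            self.include_year_age_interaction = \
                self.variant == "primary_care"


def primary_care_spec(**kw) -> ModelSpec:
    return ModelSpec(variant="primary_care", **kw)


def hes_spec(**kw) -> ModelSpec:
    return ModelSpec(variant="hes", **kw)


def maternal_spec(**kw) -> ModelSpec:
    return ModelSpec(variant="maternal", **kw)


@dataclass
class ModelResult:
    """Exposure effect from one fit: IRR (or mean difference), Wald 95% CI
    on the appropriate scale, p-value and event count.  When the rare
    guard trips, only ``n_events`` and ``rare_flag`` are populated."""

    effect: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    n_events: int
    rare_flag: bool = False
    converged: bool = True
    se_log: float | None = None
    note: str | None = None
    variant: str | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "ci95": list(self.ci95) if self.ci95 else None,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "rare_flag": self.rare_flag,
            "converged": self.converged,
            "se_log": self.se_log,
            "note": self.note,
            "variant": self.variant,
        }


@dataclass
class InteractionResult:
    """Subgroup IRRs by caesarean type plus the interaction test."""

    irr_emergency: float
    ci_emergency: tuple[float, float]
    irr_elective: float
    ci_elective: tuple[float, float]
    interaction_ratio: float
    interaction_p: float
    interaction_se_log: float = float("nan")
    converged: bool = True
    note: str | None = None


# ---------------------------------------------------------------------------
# design matrices


def _dummies(values: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(values, prefix=prefix, drop_first=True, dtype=float)
    return d


def _design(rows: pd.DataFrame, spec: ModelSpec,
            year_col: str = "birth_year") -> pd.DataFrame:
    """Build the covariate matrix (without exposure or intercept)."""
    parts = []
    year = rows[year_col].astype(int)
    if spec.year_coding == "categorical":
        yr = _dummies(year, "year")
        parts.append(yr)
    else:
        parts.append(pd.DataFrame(
            {"year_linear": (year - year.min()).astype(float)}))
    if spec.include_age:
        age = rows["age_year"].astype(int)
        if spec.age_coding == "categorical":
            ag = _dummies(age, "age")
            parts.append(ag)
        else:
            parts.append(pd.DataFrame({"age_linear": age.astype(float)}))
        if spec.include_year_age_interaction:
            if spec.year_coding == "categorical" and \
                    spec.age_coding == "categorical":
                inter = {}
                for yc in parts[0].columns:
                    for ac in parts[1].columns:
                        col = parts[0][yc].to_numpy() * \
                            parts[1][ac].to_numpy()
                        if col.any():
                            inter[f"{yc}:{ac}"] = col
                parts.append(pd.DataFrame(inter, index=rows.index))
            else:
                y = parts[0].iloc[:, 0].to_numpy()
                a = parts[1].iloc[:, 0].to_numpy()
                parts.append(pd.DataFrame({"year:age": y * a},
                                          index=rows.index))
    if "delivery_type" in rows.columns:
        parts.append(pd.DataFrame({
            "caesarean": (rows["delivery_type"] == "caesarean")
            .astype(float)}))
    X = pd.concat(parts, axis=1)
    # constant columns carry no information and break full rank (e.g. an
    # all-caesarean stratum); the intercept absorbs them
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    X.insert(0, "intercept", 1.0)
    return X


def _aggregate(rows: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Sum events and person-time over unique covariate cells (exact for
    log-link Poisson with offset)."""
    g = rows.groupby(keys, observed=True, dropna=False)
    agg = g.agg(events=("event", "sum"),
                time=("time_at_risk", "sum")).reset_index()
    return agg[agg["time"] > 0]


def _fit_poisson(y: np.ndarray, X: pd.DataFrame, offset: np.ndarray,
                 spec: ModelSpec) -> sm.GLM:
    model = sm.GLM(y, X.to_numpy(dtype=float),
                   family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=_MAX_ITER, tol=_CONVERGENCE_TOL)
    if spec.scale == "quasipoisson":
        res = model.fit(maxiter=_MAX_ITER, tol=_CONVERGENCE_TOL,
                        scale="X2")
    return res


def _exposure_result(res, X: pd.DataFrame, n_events: int,
                     spec: ModelSpec) -> ModelResult:
    j = list(X.columns).index("exposure")
    beta = float(res.params[j])
    se = float(res.bse[j])
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return ModelResult(None, None, None, n_events, converged=False,
                           note="exposure coefficient inestimable",
                           variant=spec.variant)
    lo, hi = np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)
    from scipy import stats
    p = 2 * stats.norm.sf(abs(beta / se))
    return ModelResult(float(np.exp(beta)), (float(lo), float(hi)),
                       float(p), n_events,
                       converged=bool(getattr(res, "converged", True)),
                       se_log=se, variant=spec.variant)


# ---------------------------------------------------------------------------
# public fits


def fit_poisson_cits(rows: pd.DataFrame, spec: ModelSpec | None = None,
                     enforce_rare_guard: bool = True) -> ModelResult:
    """Fit the CITS Poisson model to person-year rows.

    ``rows`` must have columns birth_year, age_year (primary-care layout),
    delivery_type, exposure_value, time_at_risk, event; excluded births
    are assumed dropped upstream.
    """
    spec = spec or ModelSpec()
    rows = rows[rows["time_at_risk"] > 0]
    n_events = int(rows["event"].sum())
    if enforce_rare_guard and rare_guard(n_events):
        return ModelResult(None, None, None, n_events, rare_flag=True,
                           variant=spec.variant)
    if rows["exposure_value"].nunique() <= 1:
        return ModelResult(None, None, None, n_events, converged=False,
                           note="no variation in exposure",
                           variant=spec.variant)

    keys = ["birth_year", "delivery_type", "exposure_value"]
    if spec.include_age:
        keys.insert(1, "age_year")
    agg = _aggregate(rows, keys)
    X = _design(agg, spec)
    X["exposure"] = agg["exposure_value"].to_numpy(dtype=float)
    y = agg["events"].to_numpy(dtype=float)
    offset = np.log(agg["time"].to_numpy(dtype=float))
    try:
        res = _fit_poisson(y, X, offset, spec)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return ModelResult(None, None, None, n_events, converged=False,
                           note=f"fit failed: {exc}", variant=spec.variant)
    return _exposure_result(res, X, n_events, spec)


def fit_maternal(deliveries: pd.DataFrame, outcome: str,
                 spec: ModelSpec | None = None,
                 exposure_col: str = "exposure_value",
                 enforce_rare_guard: bool = True) -> ModelResult:
    """Risk-ratio model for a binary six-week postpartum outcome.

    Poisson regression with log link on the binary indicator and unit
    offset, adjusted for year of delivery and delivery type.  Risk ratios
    rather than odds ratios are estimated because postpartum infection is
    not rare after caesarean section.
    """
    spec = spec or ModelSpec(variant="maternal")
    flag_col = f"flag_{outcome}" if f"flag_{outcome}" in deliveries else \
        outcome
    if flag_col not in deliveries:
        raise KeyError(f"no outcome column for {outcome!r}")
    n_events = int(deliveries[flag_col].sum())
    if enforce_rare_guard and rare_guard(n_events):
        return ModelResult(None, None, None, n_events, rare_flag=True,
                           variant=spec.variant)
    if deliveries[exposure_col].nunique() <= 1:
        return ModelResult(None, None, None, n_events, converged=False,
                           note="no variation in exposure",
                           variant=spec.variant)
    work = deliveries[["delivery_year", "delivery_type",
                       exposure_col, flag_col]].rename(
        columns={flag_col: "event", exposure_col: "exposure_value"})
    # each delivery contributes one unit of "time": aggregate to cells
    g = work.groupby(["delivery_year", "delivery_type", "exposure_value"],
                     observed=True)
    agg = g.agg(events=("event", "sum"),
                n=("event", "size")).reset_index()
    # per-stratum zero-event check: strata with events but no variation are
    # handled by the GLM; an all-zero exposed or unexposed arm is flagged
    for e, grp in agg.groupby(agg["exposure_value"] > 0):
        if grp["events"].sum() == 0:
            return ModelResult(None, None, None, n_events, converged=False,
                               note="zero events in an exposure stratum",
                               variant=spec.variant)
    X = _design(agg.rename(columns={"delivery_year": "birth_year"}),
                ModelSpec(variant="maternal", include_age=False,
                          year_coding=spec.year_coding))
    X["exposure"] = agg["exposure_value"].to_numpy(dtype=float)
    y = agg["events"].to_numpy(dtype=float)
    offset = np.log(agg["n"].to_numpy(dtype=float))
    try:
        res = _fit_poisson(y, X, offset, spec)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return ModelResult(None, None, None, n_events, converged=False,
                           note=f"fit failed: {exc}", variant=spec.variant)
    return _exposure_result(res, X, n_events, spec)


def fit_linear_continuous(records: pd.DataFrame, outcome_col: str,
                          spec: ModelSpec | None = None,
                          exposure_col: str = "exposure_value"
                          ) -> ModelResult:
    """OLS adjusted mean difference for a continuous outcome.

    The effect is the exposure coefficient: the difference in means between
    exposed and unexposed, adjusted for year and delivery type.
    """
    spec = spec or ModelSpec(variant="continuous", include_age=False)
    if records[exposure_col].nunique() <= 1:
        return ModelResult(None, None, None, 0, converged=False,
                           note="no variation in exposure",
                           variant="continuous")
    year_col = ("delivery_year" if "delivery_year" in records
                else "birth_year")
    work = records.rename(columns={year_col: "birth_year"})
    X = _design(work, ModelSpec(variant="continuous", include_age=False,
                                year_coding=spec.year_coding))
    X["exposure"] = work[exposure_col].to_numpy(dtype=float)
    y = work[outcome_col].to_numpy(dtype=float)
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        return ModelResult(None, None, None, 0, converged=False,
                           note="rank-deficient design", variant="continuous")
    res = sm.OLS(y, Xm).fit()
    j = list(X.columns).index("exposure")
    beta, se = float(res.params[j]), float(res.bse[j])
    lo, hi = beta - Z_95 * se, beta + Z_95 * se
    return ModelResult(beta, (lo, hi), float(res.pvalues[j]), 0,
                       se_log=se, variant="continuous")


def subgroup_interaction(rows: pd.DataFrame,
                         spec: ModelSpec | None = None) -> InteractionResult:
    """Exposure x caesarean-type interaction on person-year rows.

    Adds an ``exposure x elective`` term to the CITS model; reports the
    IRR within emergency and elective caesarean subgroups and the Wald
    p-value for their ratio.
    """
    spec = spec or ModelSpec()
    cs = rows[rows["delivery_type"] == "caesarean"]
    if len(cs) == 0:
        raise ValueError("no caesarean rows: subgroup analysis undefined")
    for sub in ("elective", "emergency"):
        sub_rows = cs[cs["caesarean_type"] == sub]
        if (sub_rows["exposure_value"] > 0).sum() == 0:
            return InteractionResult(np.nan, (np.nan, np.nan), np.nan,
                                     (np.nan, np.nan), np.nan, np.nan,
                                     converged=False,
                                     note=f"no exposed {sub} births")

    work = rows.copy()
    work["elective"] = (work["caesarean_type"] == "elective").astype(float)
    work["exp_elective"] = work["exposure_value"] * work["elective"]
    keys = ["birth_year", "delivery_type", "exposure_value", "elective",
            "exp_elective"]
    if spec.include_age:
        keys.insert(1, "age_year")
    g = work.groupby(keys, observed=True)
    agg = g.agg(events=("event", "sum"),
                time=("time_at_risk", "sum")).reset_index()
    agg = agg[agg["time"] > 0]
    X = _design(agg, spec)
    X["elective"] = agg["elective"].to_numpy(dtype=float)
    X["exposure"] = agg["exposure_value"].to_numpy(dtype=float)
    X["exp_elective"] = agg["exp_elective"].to_numpy(dtype=float)
    y = agg["events"].to_numpy(dtype=float)
    offset = np.log(agg["time"].to_numpy(dtype=float))
    res = _fit_poisson(y, X, offset, spec)

    cols = list(X.columns)
    je, ji = cols.index("exposure"), cols.index("exp_elective")
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    b_em, b_int = beta[je], beta[ji]
    se_em = np.sqrt(cov[je, je])
    se_el = np.sqrt(cov[je, je] + cov[ji, ji] + 2 * cov[je, ji])
    se_int = np.sqrt(cov[ji, ji])
    from scipy import stats
    return InteractionResult(
        irr_emergency=float(np.exp(b_em)),
        ci_emergency=(float(np.exp(b_em - Z_95 * se_em)),
                      float(np.exp(b_em + Z_95 * se_em))),
        irr_elective=float(np.exp(b_em + b_int)),
        ci_elective=(float(np.exp(b_em + b_int - Z_95 * se_el)),
                     float(np.exp(b_em + b_int + Z_95 * se_el))),
        interaction_ratio=float(np.exp(b_int)),
        interaction_p=float(2 * stats.norm.sf(abs(b_int / se_int))),
        interaction_se_log=float(se_int),
        converged=bool(getattr(res, "converged", True)),
    )
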