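"""Mixed-model inference by maximum likelihood with posterior simulation.

Linear mixed models are fitted by ML (not REML, to favour the fixed-effect
estimates), and uncertainty is propagated by simulating fixed-effect
parameter sets from their joint asymptotic sampling distribution — a
multivariate normal at the ML estimates with the estimated covariance, which
under flat priors is the approximate posterior.  Group contrasts are
summarised by the *derived p*: the fraction of paired simulation draws in
which the first group's estimate exceeds the second's (0.5 = no difference;
below 0.05 or above 0.95 plays the role of a frequentist significance
threshold).

Also here: z-scoring, Lessells & Boag repeatability (intraclass correlation
from one-way ANOVA variance components), and marginal/conditional r² for
mixed models (variance explained by fixed effects alone vs fixed plus random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "FittedLMM",
    "PosteriorDraws",
    "fit_lmm",
    "posterior_sim",
    "credible_interval",
    "derived_p",
    "zscore",
    "unstandardize_slope",
    "RepeatabilityResult",
    "repeatability",
    "r2_nakagawa",
    "run_paper_models",
]


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification.

    ``fixed`` is the right-hand-side formula (e.g. ``"C(experience) * C(day)"``).
    ``random`` lists random-intercept terms: a plain column name, or
    ``"a/b"`` for b nested within a.  ``transform`` ("identity" or "sqrt")
    applies to the response before fitting; columns named in ``zscore_cols``
    (which may include the response) are standardised first.
    """

    response: str
    fixed: str = "1"
    random: tuple[str, ...] = ()
    transform: str = "identity"
    zscore_cols: tuple[str, ...] = ()

    def __post_init__(self):
        if self.transform not in ("identity", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.random:
            raise ValueError("at least one random-intercept term is required")


@dataclass
class FittedLMM:
    params: pd.Series                 # fixed-effect ML estimates
    cov_params: np.ndarray            # their estimated covariance
    vcomps: dict[str, float]          # random-intercept variances
    scale: float                      # residual variance
    fittedvalues: np.ndarray
    resid: np.ndarray
    converged: bool
    singular: bool
    spec: ModelSpec
    design_info: object = field(repr=False)
    exog: np.ndarray = field(repr=False, default=None)
    result: object = field(repr=False, default=None)

    def design_row(self, at: dict) -> np.ndarray:
        """Fixed-effect design row for one covariate combination."""
        (m,) = patsy.build_design_matrices([self.design_info], pd.DataFrame([at]))
        return np.asarray(m)[0]


def _vc_formulae(terms: tuple[str, ...]) -> dict[str, str]:
    vc: dict[str, str] = {}
    for term in terms:
        if "/" in term:
            outer, inner = (t.strip() for t in term.split("/", 1))
            vc[outer] = f"0 + C({outer})"
            vc[f"{outer}:{inner}"] = f"0 + C({outer}):C({inner})"
        else:
            vc[term] = f"0 + C({term})"
    return vc


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FittedLMM:
    """Fit the model by maximum likelihood.

    A single un-nested random term becomes the MixedLM grouping factor;
    crossed or nested structures are expressed as variance components over a
    single all-encompassing group.  Variance components estimated at (or
    within 1e-8 of) the zero boundary mark the fit as singular.
    """
    df = data.copy().reset_index(drop=True)
    for term in spec.random:
        for col in term.split("/"):
            col = col.strip()
            if col not in df.columns:
                raise ValueError(f"grouping factor {col!r} not in data")
            if df[col].nunique() < 2:
                raise ValueError(f"grouping factor {col!r} needs ≥ 2 levels")
    y = df[spec.response].astype(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if spec.transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform requires a non-negative response")
        y = np.sqrt(y)
    df["_y"] = y
    for col in spec.zscore_cols:
        df["_y" if col == spec.response else col] = zscore(
            df["_y" if col == spec.response else col])

    formula = f"_y ~ {spec.fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # we re-flag singular fits
        if len(spec.random) == 1 and "/" not in spec.random[0]:
            md = smf.mixedlm(formula, df, groups=df[spec.random[0]])
            res = md.fit(reml=False)
            vcomps = {spec.random[0]: float(np.asarray(res.cov_re)[0, 0])}
        else:
            df["_ones"] = 1
            md = smf.mixedlm(formula, df, groups="_ones", re_formula="0",
                             vc_formula=_vc_formulae(spec.random))
            res = md.fit(reml=False)
            vcomps = {n: float(v) for n, v in
                      zip(md.exog_vc.names, np.asarray(res.vcomp))}

    k = len(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[:k, :k]
    # a component at (or numerically on) the zero boundary, relative to the
    # total residual + random variance, marks a singular fit
    total_var = float(res.scale) + sum(vcomps.values())
    singular = any(v < 1e-4 * total_var for v in vcomps.values())
    if singular:
        warnings.warn("variance component at the zero boundary; fit is singular",
                      stacklevel=2)
    return FittedLMM(
        params=res.fe_params,
        cov_params=cov_fe,
        vcomps=vcomps,
        scale=float(res.scale),
        fittedvalues=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
        converged=bool(getattr(res, "converged", True)),
        singular=singular,
        spec=spec,
        design_info=md.data.design_info,
        exog=np.asarray(md.exog),
        result=res,
    )


@dataclass
class PosteriorDraws:
    draws: np.ndarray          # n_draws × n_fixed_effects
    names: list[str]
    seed: int
    n_draws: int

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def linear(self, row: np.ndarray) -> np.ndarray:
        """Draws of a linear combination of the fixed effects."""
        return self.draws @ np.asarray(row, dtype=float)


def posterior_sim(fitted: FittedLMM, n_draws: int = 10000, seed: int = 0) -> PosteriorDraws:
    """Simulate fixed-effect parameter sets from the flat-prior posterior.

    Draws come from N(β̂, Cov̂(β̂)); variance components are held at their ML
    estimates.  A covariance that is not positive semi-definite (numerical
    boundary fits) is repaired by clipping negative eigenvalues to zero, with
    a warning.
    """
    beta = fitted.params.to_numpy(dtype=float)
    cov = np.asarray(fitted.cov_params, dtype=float)
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if np.any(w < -1e-10 * max(w.max(), 1.0)):
        warnings.warn("non-PSD fixed-effect covariance repaired by eigenvalue "
                      "clipping", stacklevel=2)
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(beta, cov, size=n_draws, method="svd")
    return PosteriorDraws(draws, list(fitted.params.index), seed, n_draws)


def credible_interval(draw_values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from simulation draws."""
    lo = (1.0 - level) / 2.0
    q = np.quantile(np.asarray(draw_values, float), [lo, 1.0 - lo])
    return float(q[0]), float(q[1])


def derived_p(draws_a, draws_b) -> float:
    """Fraction of paired draws in which a exceeds b."""
    a = np.asarray(draws_a, float)
    b = np.asarray(draws_b, float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be paired (equal length)")
    return float(np.mean(a > b))


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, SD 1 (sample SD, n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=1)
    if not sd > 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def unstandardize_slope(slope_z: float, sd_y: float) -> float:
    """Raw response change per one SD of the predictor.

    For a regression fitted on z-scored x and y, a one-SD increase of the
    predictor changes the raw response by ``slope_z × sd_y`` (in the
    response's units).
    """
    return slope_z * sd_y


@dataclass
class RepeatabilityResult:
    r: float
    se: float
    s2_among: float
    s2_within: float
    n0: float
    truncated: bool = False  # negative among-group component clamped to 0


def repeatability(values, group_labels) -> RepeatabilityResult:
    """Lessells & Boag intraclass correlation from one-way ANOVA.

    s²_A = (MS_among − MS_within) / n₀ with n₀ the Lessells–Boag coefficient
    for unequal group sizes; r = s²_A / (s²_A + MS_within).  A negative
    among-group component is truncated to zero and flagged.  The SE uses the
    standard large-sample one-way ANOVA approximation.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if y.size != g.size:
        raise ValueError("values and group labels must align")
    groups = pd.Series(y).groupby(pd.Series(g))
    sizes = groups.size().to_numpy(dtype=float)
    a = sizes.size
    N = float(sizes.sum())
    if a < 2:
        raise ValueError("need at least 2 groups")
    if not np.any(sizes >= 2):
        raise ValueError("need at least one group with ≥ 2 observations")
    means = groups.mean().to_numpy()
    grand = y.mean()
    ss_a = float(np.sum(sizes * (means - grand) ** 2))
    ss_w = float(sum(((sub - sub.mean()) ** 2).sum() for _, sub in groups))
    ms_a = ss_a / (a - 1)
    ms_w = ss_w / (N - a) if N > a else 0.0
    n0 = (N - float(np.sum(sizes**2)) / N) / (a - 1)
    s2_a = (ms_a - ms_w) / n0
    truncated = s2_a < 0
    s2_a = max(s2_a, 0.0)
    denom = s2_a + ms_w
    r = s2_a / denom if denom > 0 else 1.0
    if denom == 0:  # zero variance everywhere: perfectly repeatable by convention
        r = 1.0
    var_r = (2 * (1 - r) ** 2 * (1 + (n0 - 1) * r) ** 2) / (n0 * (n0 - 1) * (a - 1)) \
        if n0 > 1 else float("nan")
    return RepeatabilityResult(float(r), float(np.sqrt(var_r)), s2_a, ms_w,
                               float(n0), truncated)


def r2_nakagawa(fitted: FittedLMM) -> tuple[float, float]:
    """Marginal and conditional r² of a fitted mixed model.

    r²_marginal = var(fixed predictor) / (var(fixed) + Σ random + residual);
    r²_conditional adds the random-intercept variances to the numerator.
    """
    pred_fixed = fitted.exog @ fitted.params.to_numpy(dtype=float)
    var_f = float(np.var(pred_fixed, ddof=1)) if pred_fixed.size > 1 else 0.0
    var_r = float(sum(fitted.vcomps.values()))
    denom = var_f + var_r + fitted.scale
    if denom <= 0:
        return 1.0, 1.0
    return var_f / denom, (var_f + var_r) / denom


# ---------------------------------------------------------------------------
# The study's model set
# ---------------------------------------------------------------------------

PAIR_DAY_COLUMNS = (
    "pair_id", "experience", "day", "clumping_s",
    "abs_directionality_display",
    "total_stacks_f", "total_stacks_m", "answer_stacks_f", "answer_stacks_m",
    "answer_prop_f", "answer_prop_m",
)


@dataclass
class ModelResult:
    name: str
    fitted: FittedLMM
    draws: PosteriorDraws
    coefficients: pd.DataFrame        # posterior mean + 95% CrI per coefficient
    derived_ps: dict[str, float] = field(default_factory=dict)
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")


def _coef_table(draws: PosteriorDraws) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(draws.names):
        lo, hi = credible_interval(draws.draws[:, j])
        rows.append(dict(coefficient=name, estimate=float(draws.draws[:, j].mean()),
                         cri_lo=lo, cri_hi=hi))
    return pd.DataFrame(rows)


def _fit_and_sim(name, spec, data, n_draws, seed) -> ModelResult:
    fitted = fit_lmm(spec, data)
    draws = posterior_sim(fitted, n_draws=n_draws, seed=seed)
    r2m, r2c = r2_nakagawa(fitted)
    return ModelResult(name, fitted, draws, _coef_table(draws),
                       r2_marginal=r2m, r2_conditional=r2c)


def run_paper_models(
    pair_days: pd.DataFrame,
    state_rates: pd.DataFrame | None = None,
    n_draws: int = 10000,
    seed: int = 0,
) -> dict[str, ModelResult]:
    """Fit the study's five mixed-model analyses on a pair-day table.

    ``pair_days`` needs one row per pair per day with the columns in
    ``PAIR_DAY_COLUMNS``; ``state_rates`` (optional) has one row per
    pair-day-state with a ``rate_per_s`` column of stack-call rates.

    Models: clumping time and |directionality| each against
    experience × day with a pair random intercept; square-root stack rate
    against relative position with crossed day and pair intercepts;
    male-vs-female total stacks and answer stacks with day crossed and pair
    nested in experience; and z-scored answer proportion against z-scored
    clumping per sex, plus a rerun excluding zero-clumping days.

    Group contrasts (new vs established per day; day 1 vs day 7 within each
    experience group) are summarised as derived p's.
    """
    df = pair_days.copy()
    missing = [c for c in PAIR_DAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair_days missing columns {missing}")
    if df["pair_id"].nunique() < 2 or df["day"].nunique() < 2:
        raise ValueError("need at least 2 pairs over at least 2 days")
    df["day"] = df["day"].astype(str)
    days = sorted(df["day"].unique(), key=lambda d: float(d))
    first_day, last_day = days[0], days[-1]
    experiences = sorted(df["experience"].unique())
    has_experience = len(experiences) >= 2
    exp_day_fixed = "C(experience) * C(day)" if has_experience else "C(day)"
    nested_random = ("day", "experience/pair_id") if has_experience \
        else ("day", "pair_id")

    results: dict[str, ModelResult] = {}

    def _group_contrasts(res: ModelResult) -> None:
        """Derived p's for experience-by-day group comparisons."""
        row = res.fitted.design_row
        if has_experience:
            for day in days:
                a = res.draws.linear(row(dict(experience="new", day=day)))
                b = res.draws.linear(row(dict(experience="established", day=day)))
                res.derived_ps[f"new_gt_established_day{day}"] = derived_p(a, b)
        for exp in experiences:
            at_first = dict(experience=exp, day=first_day) if has_experience \
                else dict(day=first_day)
            at_last = dict(experience=exp, day=last_day) if has_experience \
                else dict(day=last_day)
            a = res.draws.linear(row(at_first))
            b = res.draws.linear(row(at_last))
            key = f"{exp}_day{first_day}_gt_day{last_day}" if has_experience \
                else f"day{first_day}_gt_day{last_day}"
            res.derived_ps[key] = derived_p(a, b)
            if not has_experience:
                break

    spec_clump = ModelSpec("clumping_s", exp_day_fixed, ("pair_id",))
    res = _fit_and_sim("clumping", spec_clump, df, n_draws, seed)
    _group_contrasts(res)
    results["clumping"] = res

    sub = df.dropna(subset=["abs_directionality_display"])
    spec_dir = ModelSpec("abs_directionality_display", exp_day_fixed, ("pair_id",))
    res = _fit_and_sim("abs_directionality", spec_dir, sub, n_draws, seed + 1)
    _group_contrasts(res)
    results["abs_directionality"] = res

    if state_rates is not None:
        sr = state_rates.dropna(subset=["rate_per_s"]).copy()
        sr["day"] = sr["day"].astype(str)
        spec_rate = ModelSpec("rate_per_s", "C(state)", ("day", "pair_id"),
                              transform="sqrt")
        res = _fit_and_sim("rate_by_position", spec_rate, sr, n_draws, seed + 2)
        row = res.fitted.design_row
        for s1 in sr["state"].unique():
            for s2 in sr["state"].unique():
                if s1 < s2:
                    a = res.draws.linear(row(dict(state=s1)))
                    b = res.draws.linear(row(dict(state=s2)))
                    res.derived_ps[f"{s1}_gt_{s2}"] = derived_p(a, b)
        results["rate_by_position"] = res

    for name, resp, pred in (("stack_totals", "total_stacks_m", "total_stacks_f"),
                             ("stack_answers", "answer_stacks_m", "answer_stacks_f")):
        spec = ModelSpec(resp, pred, nested_random)
        results[name] = _fit_and_sim(name, spec, df, n_draws, seed + 3)

    for sex in ("m", "f"):
        spec = ModelSpec(f"answer_prop_{sex}", "clumping_s", nested_random,
                         zscore_cols=(f"answer_prop_{sex}", "clumping_s"))
        results[f"answers_vs_clumping_{sex}"] = _fit_and_sim(
            f"answers_vs_clumping_{sex}", spec, df.dropna(
                subset=[f"answer_prop_{sex}"]), n_draws, seed + 4)

    nz = df[df["clumping_s"] > 0].dropna(subset=["answer_prop_m"])
    if nz["pair_id"].nunique() >= 2 and nz["day"].nunique() >= 2 and len(nz) >= 6:
        spec = ModelSpec("answer_prop_m", "clumping_s", nested_random,
                         zscore_cols=("answer_prop_m", "clumping_s"))
        results["answers_vs_clumping_m_nonzero"] = _fit_and_sim(
            "answers_vs_clumping_m_nonzero", spec, nz, n_draws, seed + 5)

    return results
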