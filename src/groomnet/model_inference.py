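"""Multi-model mixed-effects inference over the individual network measures.

Every candidate model is a Gaussian LMM of one response (VSC, DEWD, or
logit-DEWD) on a subset of five binary fixed factors, always with crossed
random intercepts for individual identity and observation time period.
Candidates are all 2^5 = 32 factor subsets including the null model; they
are fitted by maximum likelihood (AICc comparisons across fixed-effect
structures require ML), ranked by AICc, and the models within 10 AICc of
the best form the averaging subset. Coefficients are averaged
conditionally — weights renormalized over the subset models that contain
the term — and each factor's relative variable importance (RVI) is the sum
of Akaike weights over subset models containing it. Final per-term tests
refit by REML and use Type-III F statistics with Satterthwaite denominator
degrees of freedom.

Factor coding (0 = reference level): TPstability stable=0/unstable=1,
ArrivalAgeCat subadult=0/adult=1, Sex F=0/M=1, Origin captive=0/wild=1,
PHCinfant with_conspecifics=0/without_conspecifics=1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mixedlm
from .grooming_network import logit_dewd
from .study_data import ValidationError

logger = logging.getLogger("groomnet")

#: factor name -> (measures-table column, level coded 1)
FACTORS: dict[str, tuple[str, str]] = {
    "TPstability": ("stability", "unstable"),
    "ArrivalAgeCat": ("arrival_age_cat", "adult"),
    "Sex": ("sex", "M"),
    "Origin": ("origin", "wild"),
    "PHCinfant": ("phc_infant", "without_conspecifics"),
}

RESPONSES = ("vsc", "dewd", "dewd_logit")

DELTA_THRESHOLD_DEFAULT = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed-factor subset, interactions."""

    response: str
    fixed_terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValidationError(f"unknown response {self.response!r}")
        unknown = [t for t in self.fixed_terms if t not in FACTORS]
        if unknown:
            raise ValidationError(f"unknown factor(s) {unknown}")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValidationError("duplicate fixed terms")
        for a, b in self.interactions:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValidationError(
                    f"interaction {a}:{b} components must be fixed terms")

    @property
    def terms(self) -> tuple[str, ...]:
        """All coefficient-bearing terms, mains then interactions."""
        return self.fixed_terms + tuple(
            f"{a}:{b}" for a, b in self.interactions)


@dataclass
class FitResult:
    """A fitted candidate: coefficients, variance components, log-likelihood.

    ``k`` counts the intercept, the fixed coefficients, the two
    random-intercept variances and the residual variance.
    """

    spec: ModelSpec
    n: int
    k: int
    loglik: float
    coefficients: pd.DataFrame  # index term, columns estimate/se
    varcomps: dict[str, float]
    converged: bool
    core: mixedlm.CoreFit = field(repr=False)


def enumerate_candidates(factors: tuple[str, ...] = tuple(FACTORS),
                         response: str = "vsc") -> list[ModelSpec]:
    """All factor subsets (including the null model), size then lexicographic."""
    if not factors:
        raise ValidationError("no factors to enumerate")
    if len(set(factors)) != len(factors):
        raise ValidationError("duplicate factor names")
    specs: list[ModelSpec] = []
    for size in range(len(factors) + 1):
        for combo in sorted(itertools.combinations(sorted(factors), size)):
            specs.append(ModelSpec(response=response, fixed_terms=combo))
    return specs


def response_vector(data: pd.DataFrame, response: str) -> pd.Series:
    """Extract the response column, deriving logit-DEWD on demand."""
    if response == "vsc":
        return data["vsc"]
    if response == "dewd":
        return data["dewd"]
    if response == "dewd_logit":
        mask = data["dewd"].notna()
        out = pd.Series(np.nan, index=data.index)
        out[mask] = logit_dewd(data.loc[mask, "dewd"].to_numpy(),
                               data.loc[mask, "n_group"].to_numpy())
        return out
    raise ValidationError(f"unknown response {response!r}")


def design_matrix(data: pd.DataFrame, spec: ModelSpec,
                  coding: str = "treatment"
                  ) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Build (y, X, names, used-rows) for a spec, dropping NaN responses.

    ``treatment`` codes the non-reference level as 1 (used for AICc
    candidates and averaging); ``sum`` codes levels as -0.5/+0.5 so that
    with two-level factors each coefficient's Wald test is the Type-III
    test even in the presence of its interaction.
    """
    if coding not in ("treatment", "sum"):
        raise ValidationError(f"unknown coding {coding!r}")
    y_all = response_vector(data, spec.response)
    used = data[y_all.notna()].copy()
    if used.empty:
        raise ValidationError("no usable rows for response "
                              f"{spec.response!r}")
    y = y_all[y_all.notna()].to_numpy(dtype=float)
    cols = [np.ones(len(used))]
    names = ["(Intercept)"]
    main: dict[str, np.ndarray] = {}
    for term in spec.fixed_terms:
        col, one_level = FACTORS[term]
        levels = set(used[col])
        if len(levels) < 2:
            raise ValidationError(
                f"factor {term} is constant in the data "
                f"(only {sorted(levels)}); design is singular")
        x = (used[col] == one_level).to_numpy(dtype=float)
        if coding == "sum":
            x = x - 0.5
        main[term] = x
        cols.append(x)
        names.append(term)
    for a, b in spec.interactions:
        cols.append(main[a] * main[b])
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    return y, X, names, used


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, reml: bool = False,
            coding: str = "treatment") -> FitResult:
    """Fit one candidate LMM (crossed individual and period intercepts)."""
    y, X, names, used = design_matrix(data, spec, coding=coding)
    core = mixedlm.fit_core(
        y, X, used["individual"].to_numpy(), used["period_code"].to_numpy(),
        reml=reml)
    coef = pd.DataFrame({"estimate": core.beta, "se": core.se}, index=names)
    k = X.shape[1] + 3
    return FitResult(
        spec=spec, n=len(y), k=k, loglik=core.loglik,
        coefficients=coef,
        varcomps={"individual": float(core.varcomps[0]),
                  "period": float(core.varcomps[1]),
                  "residual": float(core.varcomps[2])},
        converged=core.converged, core=core)


def aicc(fit: FitResult) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); needs n > k + 1."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValidationError(
            f"AICc undefined: n={n} too small for k={k}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RankedModelSet:
    """Candidate fits with AICc, ΔAICc and Akaike weights.

    ``order`` ranks models best-first, ties broken by fewer parameters then
    enumeration order; ``subset_mask`` flags models with ΔAICc below the
    averaging threshold.
    """

    fits: list[FitResult]
    aicc: np.ndarray
    delta: np.ndarray
    weight: np.ndarray
    order: np.ndarray
    subset_mask: np.ndarray
    delta_threshold: float

    @property
    def best(self) -> FitResult:
        return self.fits[int(self.order[0])]


def rank_models(fits: list[FitResult],
                delta_threshold: float = DELTA_THRESHOLD_DEFAULT
                ) -> RankedModelSet:
    """Rank candidates by AICc and form the ΔAICc < threshold subset."""
    kept = [f for f in fits if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        logger.warning("%d non-converged candidate fit(s) dropped from "
                       "ranking", dropped)
    if not kept:
        raise ValidationError("no converged candidate fits to rank")
    values = np.array([aicc(f) for f in kept])
    order = np.array(sorted(
        range(len(kept)), key=lambda i: (values[i], kept[i].k, i)))
    delta = values - values.min()
    rel = np.exp(-0.5 * delta)
    weight = rel / rel.sum()
    return RankedModelSet(
        fits=kept, aicc=values, delta=delta, weight=weight, order=order,
        subset_mask=delta < delta_threshold,
        delta_threshold=delta_threshold)


def model_table(ranked: RankedModelSet) -> pd.DataFrame:
    """Candidate table: factor indicators, k, logLik, AICc, ΔAICc, weight."""
    rows = []
    for rank_pos, i in enumerate(ranked.order, start=1):
        fit = ranked.fits[int(i)]
        row: dict[str, object] = {"rank": rank_pos}
        for factor in FACTORS:
            row[factor] = int(factor in fit.spec.fixed_terms)
        row.update(k=fit.k, logLik=fit.loglik, AICc=ranked.aicc[i],
                   delta_AICc=ranked.delta[i], weight=ranked.weight[i],
                   in_subset=bool(ranked.subset_mask[i]))
        rows.append(row)
    return pd.DataFrame(rows)


_Z975 = stats.norm.ppf(0.975)


@dataclass
class AveragedEstimates:
    """Conditionally averaged coefficients plus the RVI block."""

    table: pd.DataFrame  # term, estimate, se, adjusted_se, z, p
    rvi: pd.DataFrame    # factor, rvi, n_containing_models


def _adjusted_se(fit: FitResult, term: str) -> float:
    """Small-sample t-based inflation of a model's SE before pooling."""
    se = float(fit.coefficients.loc[term, "se"])
    df = fit.n - fit.k
    if df <= 0:
        return se
    return se * stats.t.ppf(0.975, df) / _Z975


def average_conditional(ranked: RankedModelSet) -> AveragedEstimates:
    """Average coefficients over the ΔAICc subset, conditional per term.

    For each term the subset weights are renormalized over the models that
    contain it; the pooled SE folds between-model spread into each model's
    (plain or t-adjusted) squared SE.
    """
    sub_idx = [i for i in ranked.order if ranked.subset_mask[i]]
    if not sub_idx:
        raise ValidationError("empty averaging subset")
    terms: list[str] = ["(Intercept)"]
    for i in sub_idx:
        for t in ranked.fits[int(i)].spec.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        contain = [int(i) for i in sub_idx
                   if term in ranked.fits[int(i)].coefficients.index]
        if not contain:
            continue
        w = np.array([ranked.weight[i] for i in contain])
        w = w / w.sum()
        est = np.array([float(ranked.fits[i].coefficients.loc[term,
                                                              "estimate"])
                        for i in contain])
        se = np.array([float(ranked.fits[i].coefficients.loc[term, "se"])
                       for i in contain])
        adj = np.array([_adjusted_se(ranked.fits[i], term)
                        for i in contain])
        mean = float(w @ est)
        pooled = float(w @ np.sqrt(se ** 2 + (est - mean) ** 2))
        pooled_adj = float(w @ np.sqrt(adj ** 2 + (est - mean) ** 2))
        z = abs(mean) / pooled_adj if pooled_adj > 0 else np.inf
        rows.append({"term": term, "estimate": mean, "se": pooled,
                     "adjusted_se": pooled_adj, "z": z,
                     "p": 2.0 * stats.norm.sf(z)})
    table = pd.DataFrame(rows).set_index("term")

    rvi_rows = []
    for factor in FACTORS:
        contain = [int(i) for i in sub_idx
                   if factor in ranked.fits[int(i)].spec.fixed_terms]
        rvi_rows.append({
            "factor": factor,
            "rvi": float(sum(ranked.weight[i] for i in contain)),
            "n_containing_models": len(contain)})
    return AveragedEstimates(table=table,
                             rvi=pd.DataFrame(rvi_rows).set_index("factor"))


def rvi(ranked: RankedModelSet, factor: str) -> float:
    """Sum of Akaike weights over subset models containing the factor."""
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}")
    return float(sum(
        ranked.weight[i] for i in range(len(ranked.fits))
        if ranked.subset_mask[i]
        and factor in ranked.fits[i].spec.fixed_terms))


def vif(data: pd.DataFrame,
        factors: tuple[str, ...] = tuple(FACTORS)) -> pd.Series:
    """Variance inflation factor of each binary predictor on the others.

    Plain (non-generalized) VIF_j = 1/(1 - R_j^2) from an ordinary
    regression of predictor j on the remaining predictors plus intercept;
    perfect collinearity reports infinity.
    """
    cols = {}
    for factor in factors:
        col, one_level = FACTORS[factor]
        cols[factor] = (data[col] == one_level).to_numpy(dtype=float)
    out = {}
    for factor in factors:
        yj = cols[factor]
        others = [cols[f] for f in factors if f != factor]
        X = np.column_stack([np.ones(len(yj))] + others)
        coef, *_ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise ValidationError(f"factor {factor} is constant")
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[factor] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def anova_type3(data: pd.DataFrame, spec: ModelSpec,
                terms: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Type-III Wald F tests with Satterthwaite df (REML refit).

    Factors are sum-coded (-0.5/+0.5) so each two-level term is a single
    orthogonal contrast; F = t^2 with 1 numerator df. When the
    variance-component Hessian is unusable the denominator df falls back
    to the residual rule n - p (flagged in the ``method`` column).
    """
    fit = fit_lmm(data, spec, reml=True, coding="sum")
    available = list(spec.terms)
    if terms is None:
        terms = tuple(available)
    unknown = [t for t in terms if t not in available]
    if unknown:
        raise ValidationError(f"term(s) {unknown} not in the model")
    names = list(fit.coefficients.index)
    rows = []
    for term in terms:
        j = names.index(term)
        L = np.zeros(len(names))
        L[j] = 1.0
        est = float(fit.coefficients.iloc[j]["estimate"])
        var = float(fit.core.cov_beta[j, j])
        F = est ** 2 / var
        df2 = mixedlm.satterthwaite_df(fit.core, L)
        method = "satterthwaite"
        if not np.isfinite(df2):
            df2 = float(fit.n - fit.core.p)
            method = "between_within"
        rows.append({"term": term, "F": F, "df1": 1, "df2": df2,
                     "p": float(stats.f.sf(F, 1, df2)), "method": method})
    return pd.DataFrame(rows).set_index("term")


def fit_interaction_model(data: pd.DataFrame, response: str,
                          pair: tuple[str, str]
                          ) -> tuple[FitResult, pd.DataFrame, pd.DataFrame]:
    """Full five-factor model plus one interaction, fitted apart.

    Returns the REML fit, its Type-III table, and the four predicted cell
    means of the interaction pair (other factors averaged over the data),
    with empty design cells flagged non-estimable.
    """
    a, b = pair
    for f in pair:
        if f not in FACTORS:
            raise ValidationError(f"unknown factor {f!r}")
        col, one_level = FACTORS[f]
        if data[col].nunique() < 2:
            raise ValidationError(f"factor {f} does not vary in the data")
    spec = ModelSpec(response=response, fixed_terms=tuple(FACTORS),
                     interactions=((a, b),))
    fit = fit_lmm(data, spec, reml=True, coding="treatment")
    anova = anova_type3(data, spec)

    y, X, names, used = design_matrix(data, spec, coding="treatment")
    col_a, one_a = FACTORS[a]
    col_b, one_b = FACTORS[b]
    xa = (used[col_a] == one_a).to_numpy(dtype=float)
    xb = (used[col_b] == one_b).to_numpy(dtype=float)
    beta = fit.core.beta
    ja, jb = names.index(a), names.index(b)
    jab = names.index(f"{a}:{b}")
    cells = []
    for va in (0.0, 1.0):
        for vb in (0.0, 1.0):
            occupied = bool(np.any((xa == va) & (xb == vb)))
            xbar = X.mean(axis=0)
            xbar[ja], xbar[jb], xbar[jab] = va, vb, va * vb
            cells.append({
                a: int(va), b: int(vb),
                "predicted_mean": float(xbar @ beta) if occupied
                else np.nan,
                "estimable": occupied})
    return fit, anova, pd.DataFrame(cells)
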