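"""Mating-system fitness statistics over cross tables and trait tables.

Implements the experiment's statistical battery: Pearson chi-square tests of
genotype success against a uniform-success null, a Poisson log-linear
likelihood-ratio test of the microarthropod treatment effect on per-mesocosm
sporophyte counts (with a quasi-Poisson dispersion-corrected variant),
one-sample Kolmogorov-Smirnov goodness-of-fit of fertilization distances to
the normal or lognormal family with parameters estimated from the sample
(asymptotic p plus a parametric-bootstrap correction), and Type II
fixed-effects ANOVA of distances and offspring traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import special
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

from .parentage import CrossTable


@dataclass
class StatResult:
    test: str
    statistic: float
    df: int | tuple
    p_value: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def _counts_frame(table) -> pd.DataFrame:
    if isinstance(table, CrossTable):
        return table.counts
    return table


def chisq_genotype_success(
    table,
    axis: str = "father",
    genotypes: list[str] | None = None,
    mother: str | None = None,
) -> StatResult:
    """Pearson chi-square of genotype success against uniform success.

    ``genotypes`` lists every genotype present in the *design* so that
    parents who sired nothing still contribute an expected count (a male
    fathering zero sporophytes is evidence, not missing data). ``mother``
    optionally restricts the table to one female's sporophytes (the
    per-female test of variation in male success).
    """
    if axis not in ("mother", "father"):
        raise ValueError("axis must be 'mother' or 'father'")
    frame = _counts_frame(table)
    if mother is not None:
        frame = frame[frame["mother"] == mother]
    observed = frame.groupby(axis)["count"].sum() if len(frame) else pd.Series(dtype=float)
    if genotypes is None:
        genotypes = sorted(observed.index)
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes on the tested axis")
    obs = np.array([float(observed.get(g, 0.0)) for g in genotypes])
    if obs.sum() == 0:
        raise ValueError("all expected counts are zero")
    stat, p = sps.chisquare(obs)
    return StatResult(
        test=f"chisq_{axis}_success" + (f"[mother={mother}]" if mother else ""),
        statistic=float(stat),
        df=len(genotypes) - 1,
        p_value=float(p),
        extras={"n": float(obs.sum()), "k": len(genotypes)},
    )


def treatment_count_test(per_mesocosm_counts, quasipoisson: bool = False) -> StatResult:
    """Treatment effect on per-mesocosm sporophyte counts.

    Poisson log-linear model ``count ~ treatment`` tested by the
    likelihood-ratio (deviance difference) against the intercept-only
    model, df = 1. With ``quasipoisson`` the statistic is rescaled by the
    Pearson dispersion and referred to F(1, n-2), the standard
    analysis-of-deviance correction for overdispersed counts.
    """
    frame = pd.DataFrame(per_mesocosm_counts, columns=["treatment", "count"])
    if (frame["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if frame["treatment"].nunique() != 2:
        raise ValueError("both treatments must be represented")
    y = frame["count"].to_numpy(dtype=float)
    x = pd.get_dummies(frame["treatment"], drop_first=True, dtype=float)
    full = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
    lr = float(null.deviance - full.deviance)
    extras = {
        "rate_by_treatment": frame.groupby("treatment")["count"].mean().to_dict(),
    }
    if quasipoisson:
        dispersion = float(full.pearson_chi2 / full.df_resid)
        extras["dispersion"] = dispersion
        f_stat = lr / dispersion
        p = float(sps.f.sf(f_stat, 1, full.df_resid))
        return StatResult("treatment_count_quasipoisson_F", f_stat,
                          (1, int(full.df_resid)), p, extras)
    p = float(sps.chi2.sf(lr, 1))
    return StatResult("treatment_count_poisson_LR", lr, 1, p, extras)


# ------------------------------------------------------- KS goodness of fit


def _ks_statistic_normal(y: np.ndarray) -> float:
    """One-sample KS distance of y to a normal with ML-fitted parameters,
    via both one-sided envelopes at the sorted points."""
    n = len(y)
    ys = np.sort(y)
    mu = ys.mean()
    sigma = ys.std(ddof=0)
    if sigma == 0:
        return 1.0
    cdf = sps.norm.cdf(ys, mu, sigma)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def ks_fit(
    distances,
    family: str = "lognormal",
    bootstrap: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> StatResult:
    """Kolmogorov-Smirnov goodness of fit with parameters fit by maximum
    likelihood from the same sample.

    The KS distance to the ML-fitted lognormal equals the distance of the
    log-data to its ML-fitted normal (monotone transform), so both families
    share one code path. The default p uses the asymptotic Kolmogorov
    distribution, which is conservative when parameters are estimated; the
    ``bootstrap`` flag adds a parametric-bootstrap p that corrects for the
    estimation (the statistic is location-scale pivotal, so standard-normal
    resamples suffice). Extras carry the bias-corrected excess kurtosis of
    the distances.
    """
    x = np.asarray(distances, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if family == "lognormal":
        if (x <= 0).any():
            raise ValueError("lognormal fit requires strictly positive values")
        y = np.log(x)
    elif family == "normal":
        y = x
    else:
        raise ValueError("family must be 'normal' or 'lognormal'")
    n = len(y)
    d = _ks_statistic_normal(y)
    p_asym = float(np.clip(special.kolmogorov(math.sqrt(n) * d), 0.0, 1.0))
    extras = {
        "family": family,
        "excess_kurtosis": float(sps.kurtosis(x, fisher=True, bias=False)),
        "mu_hat": float(y.mean()),
        "sigma_hat": float(y.std(ddof=0)),
        "p_asymptotic": p_asym,
    }
    p = p_asym
    if bootstrap:
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_boot, n))
        sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=0, keepdims=True)
        ss = np.sort(sims, axis=1)
        cdf = sps.norm.cdf(ss)
        i = np.arange(1, n + 1)
        d_boot = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        p = float((1 + (d_boot >= d).sum()) / (n_boot + 1))
        extras["p_bootstrap"] = p
        extras["n_boot"] = n_boot
    return StatResult(f"ks_{family}", d, n, p, extras)


# -------------------------------------------------------------------- ANOVA

_RESPONSES = ("distance_cm", "height_mm", "spore_count", "germination_frac")
_FACTORS = ("treatment", "mother", "father")


def anova(traits: pd.DataFrame, response: str, factors=("treatment", "mother", "father")) -> list[StatResult]:
    """Fixed-effects ANOVA with Type II sums of squares (unbalanced data
    allowed; factors must not be aliased)."""
    if response not in traits.columns:
        raise ValueError(f"unknown response {response!r}")
    factors = list(factors)
    for f in factors:
        if f not in _FACTORS:
            raise ValueError(f"unknown factor {f!r}")
        if traits[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has < 2 levels")
    data = traits[[response, *factors]].copy()
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        # constant response: every factor explains exactly nothing
        return [
            StatResult(test=f"anova[{response}~{f}]", statistic=0.0,
                       df=(int(data[f].nunique() - 1), int(len(data) - 1)),
                       p_value=1.0, extras={"sum_sq": 0.0, "type": "II"})
            for f in factors
        ]
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(
            f"factors {factors} are aliased (confounded) for response {response!r}; "
            "drop or merge a factor"
        )
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    tab = anova_lm(model, typ=2)
    results = []
    for f in factors:
        row = tab.loc[f"C({f})"]
        fval = float(row["F"])
        results.append(
            StatResult(
                test=f"anova[{response}~{f}]",
                statistic=0.0 if math.isnan(fval) else fval,
                df=(int(row["df"]), int(tab.loc["Residual", "df"])),
                p_value=1.0 if math.isnan(row["PR(>F)"]) else float(row["PR(>F)"]),
                extras={"sum_sq": float(row["sum_sq"]), "type": "II"},
            )
        )
    return results


def stats_report(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "df": [str(r.df) for r in results],
            "p_value": [r.p_value for r in results],
            "extras": [repr(r.extras) for r in results],
        }
    )
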