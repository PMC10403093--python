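"""GLM fitting, exhaustive AIC model selection, and site comparisons.

The response variables are the click/click-train parameters; the
candidate explanatory terms are vessel presence, day/night, their
interaction, temperature, synthetic flow velocity, noise level and
recording site.  Source level (a level in dB, roughly symmetric) is
modelled with a gaussian family and identity link; the strictly
positive responses (bandwidth, duration, ICI, clicks per train) with a
gamma family and log link.  (The printed "logit link" of the source
workflow is incompatible with these families and is not taken
literally; the inverse link is selectable.)

``dredge`` enumerates every term subset obeying marginality (the
vessel x day/night interaction requires both main effects), fits each
candidate, and ranks by AICc — the small-sample criterion MuMIn's
dredge ranks by, and the one whose values the published selection table
prints — with Akaike weights normalised over the full candidate set.

Log-likelihood and degree-of-freedom conventions follow R's ``glm``
(so selection tables are comparable with R output): the gaussian
log-likelihood uses the ML variance RSS/n, the gamma one evaluates the
gamma density at the deviance-based dispersion ``dev/n``, and df counts
the coefficients plus one scale/dispersion parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "GLMFit",
    "fit_glm",
    "dredge",
    "compare_sites",
    "DredgeSelector",
]

DEFAULT_TERMS = (
    "vessel",
    "day_night",
    "vessel:day_night",
    "temperature",
    "flow",
    "noise_level",
    "site",
)

_FACTORS = {"vessel", "day_night", "site"}


class AliasingError(ValueError):
    """Rank-deficient design matrix (collinear terms)."""


class FamilyError(ValueError):
    """Response incompatible with the requested family."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family/link and a term subset."""

    response: str
    family: str = "gaussian"
    link: str | None = None
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gamma"):
            raise ValueError(f"unsupported family {self.family!r}")
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects "
                        "(marginality)"
                    )


@dataclass
class GLMFit:
    spec: ModelSpec
    params: pd.Series
    llf: float
    df: int
    aic: float
    aicc: float
    deviance: float
    nobs: int
    fitted: np.ndarray = field(repr=False, default=None)
    bse: pd.Series | None = field(repr=False, default=None)


def _column(data: pd.DataFrame, term: str) -> tuple[np.ndarray, str]:
    if term in _FACTORS:
        vals = data[term]
        levels = sorted(pd.unique(vals.astype(str)))
        if len(levels) > 2:
            raise ValueError(f"factor {term!r} must be two-level")
        ref = levels[0]
        other = levels[-1]
        return (vals.astype(str) == other).to_numpy(float), f"{term}[{other}]"
    return data[term].to_numpy(float), term


def design_matrix(
    data: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded mains + products for ':' interactions."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    built: dict[str, np.ndarray] = {}
    mains = [t for t in terms if ":" not in t]
    for t in sorted(mains):  # canonical order: invariant to listing order
        x, nm = _column(data, t)
        built[t] = x
        cols.append(x)
        names.append(nm)
    for t in sorted(t for t in terms if ":" in t):
        a, b = t.split(":")
        cols.append(built[a] * built[b])
        names.append(t)
    X = np.column_stack(cols)
    return X, names


def _gaussian_ml(y: np.ndarray, X: np.ndarray, names: list[str]):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise AliasingError(
            f"rank-deficient design ({rank} < {X.shape[1]}): "
            f"aliased among {names}"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(y)
    sigma2 = rss / n  # ML variance, matching R's logLik.lm/glm
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return beta, llf, rss, X @ beta


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> GLMFit:
    """Maximum-likelihood GLM fit with R-comparable AIC/AICc.

    ``AIC = -2 logLik + 2 df`` with df counting the intercept, slopes
    and the scale/dispersion parameter;
    ``AICc = AIC + 2 df (df + 1) / (n - df - 1)``.
    """
    cols_needed = {spec.response} | {
        p for t in spec.terms for p in t.split(":")
    }
    sub = data.dropna(subset=[c for c in cols_needed if c in data]).reset_index(
        drop=True
    )
    y = sub[spec.response].to_numpy(float)
    X, names = design_matrix(sub, spec.terms)
    n, p = X.shape
    bse = None

    if spec.family == "gaussian":
        if spec.link not in (None, "identity"):
            raise ValueError("gaussian family supports the identity link")
        beta, llf, dev, mu = _gaussian_ml(y, X, names)
        params = pd.Series(beta, index=names)
    else:
        if np.any(y <= 0):
            raise FamilyError(
                f"gamma family requires strictly positive {spec.response!r}"
            )
        if np.linalg.matrix_rank(X) < p:
            raise AliasingError(f"rank-deficient design: aliased among {names}")
        link = {
            None: sm.families.links.Log(),
            "log": sm.families.links.Log(),
            "inverse": sm.families.links.InversePower(),
            "identity": sm.families.links.Identity(),
        }[spec.link]
        res = sm.GLM(y, X, family=sm.families.Gamma(link=link)).fit()
        mu = np.asarray(res.fittedvalues)
        dev = float(res.deviance)
        disp = dev / n  # R's deviance-based dispersion for the gamma aic
        llf = float(
            np.sum(stats.gamma.logpdf(y, a=1.0 / disp, scale=mu * disp))
        )
        params = pd.Series(np.asarray(res.params), index=names)
        bse = pd.Series(np.asarray(res.bse), index=names)

    df = p + 1  # + scale/dispersion
    aic = -2.0 * llf + 2.0 * df
    denom = n - df - 1
    aicc = aic + (2.0 * df * (df + 1) / denom if denom > 0 else np.inf)
    return GLMFit(spec, params, llf, df, aic, aicc, dev, n, mu, bse)


def enumerate_subsets(
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> list[tuple[str, ...]]:
    """All term subsets obeying marginality, smallest first."""
    mains = [t for t in terms if ":" not in t]
    inters = [t for t in terms if ":" in t]
    out: list[tuple[str, ...]] = []
    for k in range(len(mains) + 1):
        for sub in combinations(mains, k):
            valid = [()]
            for it in inters:
                a, b = it.split(":")
                if a in sub and b in sub:
                    valid = [v + add for v in valid for add in ((), (it,))]
            for v in valid:
                out.append(tuple(sub) + v)
    return out


def dredge(
    data: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    terms: tuple[str, ...] = DEFAULT_TERMS,
    link: str | None = None,
    rank_by: str = "aicc",
    delta_max: float | None = None,
) -> pd.DataFrame:
    """Exhaustive subset selection ranked by AICc (or AIC).

    Returns one row per candidate: the term set, df, logLik, AIC, AICc,
    delta relative to the best model, and the Akaike weight
    ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` computed over the
    *full* candidate set.  ``delta_max`` truncates the report (the
    conventional "delta <= 2" table) after weights are computed.  A
    candidate whose fit fails is excluded with a warning, not an abort.
    The result carries the best :class:`GLMFit` in ``.attrs["best_fit"]``.
    """
    if rank_by not in ("aic", "aicc"):
        raise ValueError("rank_by must be 'aic' or 'aicc'")
    rows = []
    fits: dict[tuple[str, ...], GLMFit] = {}
    prev_ll_by_size: list[float] = []
    for sub in enumerate_subsets(terms):
        spec = ModelSpec(response, family, link, sub)
        try:
            fit = fit_glm(spec, data)
        except (AliasingError, FamilyError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"candidate {sub or ('(null)',)} failed: {exc}", stacklevel=2
            )
            continue
        fits[sub] = fit
        label = sorted(t for t in sub if ":" not in t) + sorted(
            t for t in sub if ":" in t
        )
        rows.append(
            {
                "terms": " + ".join(label) if label else "(null)",
                "_terms": sub,
                "df": fit.df,
                "logLik": fit.llf,
                "AIC": fit.aic,
                "AICc": fit.aicc,
            }
        )
    if not rows:
        raise RuntimeError("every candidate fit failed")
    tab = pd.DataFrame(rows)
    crit = tab["AICc"] if rank_by == "aicc" else tab["AIC"]
    tab["delta"] = crit - crit.min()
    w = np.exp(-tab["delta"] / 2.0)
    tab["weight"] = w / w.sum()
    tab = tab.sort_values(
        ["delta", "df", "terms"], kind="mergesort"
    ).reset_index(drop=True)

    if family == "gaussian":
        # nesting sanity: adding terms can never reduce the ML logLik
        full = max(fits, key=lambda s: len(s))
        for sub_, f in fits.items():
            if set(sub_) <= set(full):
                assert f.llf <= fits[full].llf + 1e-6

    tab.attrs["best_fit"] = fits[tab.iloc[0]["_terms"]]
    tab.attrs["rank_by"] = rank_by
    full_tab = tab.drop(columns="_terms")
    full_tab.attrs = dict(tab.attrs)
    if delta_max is not None:
        rep = full_tab[tab["delta"] <= delta_max].reset_index(drop=True)
        rep.attrs = dict(full_tab.attrs)
        return rep
    return full_tab


@dataclass(frozen=True)
class SiteComparison:
    statistic: float
    pvalue: float
    encoding: str  # 'ns', '>', '<', '>>', '<<' (first sample vs second)


def compare_sites(
    values_a: np.ndarray,
    values_b: np.ndarray,
    test: str = "t",
) -> SiteComparison:
    """Two-sample site comparison with the >, <, >>, << encoding.

    ``0.01 <= p < 0.05`` encodes as '>' or '<' (direction: which sample
    is larger), ``p < 0.01`` as '>>' or '<<'; otherwise 'ns'.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if test == "t":
        if np.std(a) == 0 and np.std(b) == 0:
            raise ValueError("degenerate t-test: zero variance in both groups")
        stat, p = stats.ttest_ind(a, b)
        direction = np.mean(a) > np.mean(b)
    elif test == "mann_whitney":
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            return SiteComparison(len(a) * len(b) / 2.0, 1.0, "ns")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        direction = np.median(a) > np.median(b)
    else:
        raise ValueError(f"unknown test {test!r}")
    if p < 0.01:
        enc = ">>" if direction else "<<"
    elif p < 0.05:
        enc = ">" if direction else "<"
    else:
        enc = "ns"
    return SiteComparison(float(stat), float(p), enc)


class DredgeSelector(BaseEstimator):
    """sklearn-style wrapper around :func:`dredge`.

    ``fit(data)`` runs the exhaustive selection; fitted attributes are
    ``table_`` (the full ranked candidate table), ``report_`` (the
    delta <= ``delta_max`` subset) and ``best_model_`` (a
    :class:`GLMFit`).
    """

    def __init__(
        self,
        response: str = "asl",
        family: str = "gaussian",
        terms: tuple[str, ...] = DEFAULT_TERMS,
        link: str | None = None,
        rank_by: str = "aicc",
        delta_max: float = 2.0,
    ):
        self.response = response
        self.family = family
        self.terms = terms
        self.link = link
        self.rank_by = rank_by
        self.delta_max = delta_max

    def fit(self, X: pd.DataFrame, y=None):
        tab = dredge(
            X, self.response, self.family, self.terms, self.link, self.rank_by
        )
        self.table_ = tab
        self.report_ = tab[tab["delta"] <= self.delta_max].reset_index(
            drop=True
        )
        self.best_model_ = tab.attrs["best_fit"]
        return self
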