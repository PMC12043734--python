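"""Between-family and within-family GxE estimators.

Implements the standard triangulation battery for polygenic-index (PGI)
effects on an outcome:

* **between-family**: OLS across all twins, clustered on twin pair, with
  ancestry principal components, sex and genotyping batch as covariates;
* **within-family**: OLS on co-twin differences within complete DZ pairs
  (algebraically the twin-pair fixed-effects estimator), which removes
  family-level confounding — population stratification, genetic nurture,
  assortative mating;
* **Keller expansion**: in interaction models every covariate is also
  interacted with the exposure and with each moderator, so a GxE term
  cannot proxy a covariate-by-exposure interaction;
* decade/SES **stratified** fits, continuous **birth-year trend**
  interactions, and **logit / ordered-logit** variants for scale
  diagnostics.

Linear inference uses the CR1 cluster-robust sandwich
(Liang–Zeger with the ``(G/(G−1))·((N−1)/(N−K))`` small-sample factor and
t reference with G−1 degrees of freedom); with one observation per cluster
this reduces exactly to HC1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "StratifiedResult",
    "pair_difference",
    "keller_expand",
    "build_design",
    "fit_linear_clustered",
    "fit_between",
    "fit_within",
    "fit_stratified",
    "fit_trend",
    "fit_glm",
    "deciles_per_latent_sd",
    "decade_column",
]

log = logging.getLogger(__name__)

BETWEEN_COVARIATES = tuple(f"pc{i}" for i in range(1, 21)) + ("sex", "batch")
WITHIN_COVARIATES = ("sex_difference", "batch")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative regression specification.

    ``design`` selects the unit of analysis: ``"between"`` fits on twins
    (clustered on pair), ``"within"`` on differenced DZ pairs
    (heteroskedasticity-robust, no cluster nesting).  ``keller=True``
    expands every covariate with exposure- and moderator-interactions when
    moderators are present.
    """

    outcome: str = "edu_decile"
    exposure: str = "pgi"
    moderators: tuple[str, ...] = ()
    covariates: tuple[str, ...] = BETWEEN_COVARIATES
    family: str = "linear"            # linear | logit | ordered_logit
    design: str = "between"           # between | within
    keller: bool = True
    cluster: str | None = "pair_id"
    include_intercept: bool = True

    def __post_init__(self):
        if self.family not in ("linear", "logit", "ordered_logit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.design not in ("between", "within"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "within" and self.cluster not in (None, "pair_id"):
            raise ValueError("within design: unit is the pair; cluster must be pair_id/None")


@dataclass
class FitResult:
    """Point estimates with cluster-robust inference for one fitted model."""

    terms: list[str]
    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    nobs: int
    n_clusters: int
    r2: float | None
    resid_var: float | None
    family: str = "linear"
    design: str = "between"
    exposure: str = "pgi"
    stratum: dict | None = None
    rescaled: bool = False
    dropped: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return self.params[term]

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        df = max(self.n_clusters - 1, 1)
        tcrit = stats.t.ppf(0.5 + level / 2, df)
        return (self.params[term] - tcrit * self.se[term],
                self.params[term] + tcrit * self.se[term])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "estimate": self.params[t],
                "se": self.se[t],
                "p": self.pvalues[t],
                "family": self.family,
                "design": self.design,
                "rescaled": self.rescaled,
                **({} if not self.stratum else
                   {f"stratum_{k}": v for k, v in self.stratum.items()}),
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "params": self.params,
            "se": self.se,
            "pvalues": self.pvalues,
            "nobs": self.nobs,
            "n_clusters": self.n_clusters,
            "r2": self.r2,
            "resid_var": self.resid_var,
            "family": self.family,
            "design": self.design,
            "exposure": self.exposure,
            "stratum": self.stratum,
            "rescaled": self.rescaled,
            "dropped": self.dropped,
            "meta": {k: v for k, v in self.meta.items() if not isinstance(v, np.ndarray)},
        }


@dataclass
class StratifiedResult:
    fits: dict
    skipped: dict

    def frame(self) -> pd.DataFrame:
        frames = [f.to_frame() for f in self.fits.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def decade_column(birth_year) -> np.ndarray:
    return (np.asarray(birth_year) // 10) * 10


# ---------------------------------------------------------------------------
# pair differencing


def pair_difference(
    df: pd.DataFrame,
    outcome: str | Sequence[str] = "edu_decile",
    exposure: str = "pgi",
) -> pd.DataFrame:
    """Difference complete DZ pairs: smaller ``twin_id`` minus larger.

    Keeps only DZ pairs with exactly two twins, both non-missing on the
    outcome(s) and exposure, and with identical batch (discordant-batch
    pairs are flagged and excluded).  Pair-level fields (birth year, batch,
    parental education/split) are carried over; ``sex_difference`` is
    ``"same"`` or ``"mixed"``.
    """
    outcomes = [outcome] if isinstance(outcome, str) else list(outcome)
    dz = df[df["zygosity"] == "DZ"].sort_values(["pair_id", "twin_id"])
    sizes = dz.groupby("pair_id")["twin_id"].transform("size")
    dz = dz[sizes == 2]
    a = dz.groupby("pair_id").nth(0).set_index(dz["pair_id"].unique())
    b = dz.groupby("pair_id").nth(1).set_index(dz["pair_id"].unique())

    ok = a[exposure].notna() & b[exposure].notna()
    for oc in outcomes:
        ok &= a[oc].notna() & b[oc].notna()
    batch_ok = (a["batch"] == b["batch"])
    n_batch_flagged = int((ok & ~batch_ok).sum())
    if n_batch_flagged:
        log.warning("excluded %d DZ pairs with discordant genotyping batch",
                    n_batch_flagged)
    ok &= batch_ok
    a, b = a[ok], b[ok]
    if len(a) == 0:
        raise ValueError("pair_difference: no eligible complete DZ pairs")
    log.info("pair_difference: %d eligible DZ pairs (of %d DZ twins)",
             len(a), (df["zygosity"] == "DZ").sum())

    out = pd.DataFrame({"pair_id": a.index})
    out[f"d_{exposure}"] = (a[exposure] - b[exposure]).to_numpy()
    for oc in outcomes:
        out[f"d_{oc}"] = (a[oc] - b[oc]).to_numpy()
    out["birth_year"] = a["birth_year"].to_numpy()
    out["batch"] = a["batch"].to_numpy()
    out["sex_difference"] = np.where(
        a["sex"].to_numpy() == b["sex"].to_numpy(), "same", "mixed")
    for col in ("parent_edu", "parent_high", "mother_edu", "father_edu"):
        if col in a.columns:
            out[col] = a[col].to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# design construction


def keller_expand(
    exposure: str,
    moderators: Sequence[str],
    covariates: Sequence[str],
    keller: bool = True,
    include_intercept: bool = True,
) -> list[str]:
    """Ordered term list for a (possibly Keller-expanded) GxE design.

    Core block: intercept, exposure, each moderator, exposure×moderator.
    Keller block: each covariate, covariate×exposure, covariate×moderator
    for every moderator.  Without ``keller``, covariates enter as main
    effects only.  Duplicate names raise.
    """
    terms: list[str] = ["const"] if include_intercept else []
    terms.append(exposure)
    for m in moderators:
        terms.append(m)
    for m in moderators:
        terms.append(f"{exposure}:{m}")
    for c in covariates:
        terms.append(c)
    if keller and moderators:
        for c in covariates:
            terms.append(f"{c}:{exposure}")
        for m in moderators:
            for c in covariates:
                terms.append(f"{c}:{m}")
    if len(set(terms)) != len(terms):
        dupes = sorted({t for t in terms if terms.count(t) > 1})
        raise ValueError(f"duplicate design terms: {dupes}")
    return terms


def _expand_categoricals(
    df: pd.DataFrame, cols: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Numeric passthrough; object/categorical columns become drop-first
    dummy columns named ``col[level]`` (levels sorted)."""
    out = {}
    names: list[str] = []
    for c in cols:
        s = df[c]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna().astype(str)))
            for lev in levels[1:]:
                name = f"{c}[{lev}]"
                out[name] = (s.astype(str) == lev).astype(float)
                names.append(name)
        else:
            out[c] = s.astype(float)
            names.append(c)
    return pd.DataFrame(out, index=df.index), names


def build_design(
    df: pd.DataFrame, spec: ModelSpec, exposure_col: str | None = None
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Materialise the design matrix for ``spec`` on complete rows.

    Returns ``(X, y, meta)``.  ``birth_year`` moderators are centered at the
    sample mean (center recorded in ``meta``).  Interaction columns are
    products of their components.
    """
    exposure_col = exposure_col or spec.exposure
    needed = [spec.outcome, exposure_col, *spec.moderators, *spec.covariates]
    if spec.cluster and spec.design == "between":
        needed.append(spec.cluster)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    data = df.dropna(subset=[c for c in needed if c in df.columns]).copy()
    meta: dict = {}

    mods: list[str] = []
    for m in spec.moderators:
        if m == "birth_year":
            center = float(data["birth_year"].mean())
            if float(data["birth_year"].var()) == 0.0:
                raise ValueError("degenerate birth-year variance in trend model")
            data["birth_year_c"] = data["birth_year"] - center
            meta["birth_year_center"] = center
            mods.append("birth_year_c")
        else:
            mods.append(m)

    cov_frame, cov_names = _expand_categoricals(data, spec.covariates)
    base = pd.concat(
        [data[[exposure_col] + [m for m in mods if m != exposure_col]], cov_frame],
        axis=1,
    )
    terms = keller_expand(exposure_col, mods, cov_names, spec.keller,
                          spec.include_intercept)
    X = pd.DataFrame(index=data.index)
    for t in terms:
        if t == "const":
            X[t] = 1.0
        elif ":" in t:
            a_, b_ = t.split(":")
            X[t] = base[a_].to_numpy() * base[b_].to_numpy()
        else:
            X[t] = base[t].astype(float).to_numpy()
    y = data[spec.outcome].astype(float)
    meta["rows"] = data.index
    meta["data"] = data
    return X, y, meta


# ---------------------------------------------------------------------------
# linear fitting


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right rank check: keeps the earliest independent
    columns so the drop order is deterministic."""
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    if k == 0:
        return X, []
    Q = np.empty((n, 0))
    keep_idx: list[int] = []
    dropped: list[str] = []
    for j in range(k):
        col = A[:, j]
        resid = col - Q @ (Q.T @ col) if Q.shape[1] else col.copy()
        norm = np.linalg.norm(col)
        if np.linalg.norm(resid) > max(norm, 1.0) * 1e-9:
            Q = np.column_stack([Q, resid / np.linalg.norm(resid)])
            keep_idx.append(j)
        else:
            dropped.append(X.columns[j])
    if dropped:
        log.warning("dropping collinear design columns: %s", dropped)
    return X.iloc[:, keep_idx], dropped


def fit_linear_clustered(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series | None = None,
    **result_kwargs,
) -> FitResult:
    """OLS with CR1 cluster-robust sandwich standard errors.

    ``groups=None`` treats every row as its own cluster, which reproduces
    HC1 heteroskedasticity-robust errors exactly.  P-values use a t
    reference with G−1 degrees of freedom.  Collinear columns are dropped
    (logged), never silently absorbed.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if groups is None:
        gidx = np.arange(n)
    else:
        _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    G = int(gidx.max()) + 1 if n else 0
    if G < 2:
        raise ValueError("need at least 2 clusters")

    X, dropped = _drop_collinear(X)
    A = X.to_numpy()
    k = A.shape[1]
    XtX = A.T @ A
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (A.T @ y)
    resid = y - A @ beta

    u = A * resid[:, None]
    Sg = np.zeros((G, k))
    np.add.at(Sg, gidx, u)
    meat = Sg.T @ Sg
    c = (G / (G - 1)) * ((n - 1) / (n - k))
    V = c * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))
    tstat = np.divide(beta, se, out=np.full(k, np.nan), where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df=G - 1)

    rss = float(resid @ resid)
    if "const" in X.columns:
        tss = float(((y - y.mean()) ** 2).sum())
    else:
        tss = float((y ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    terms = list(X.columns)
    return FitResult(
        terms=terms,
        params=dict(zip(terms, beta.tolist())),
        se=dict(zip(terms, se.tolist())),
        pvalues=dict(zip(terms, pvals.tolist())),
        nobs=n,
        n_clusters=G,
        r2=r2,
        resid_var=rss / (n - k) if n > k else np.nan,
        dropped=dropped,
        **result_kwargs,
    )


# ---------------------------------------------------------------------------
# the model battery


def fit_between(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Between-family fit on all available twins, clustered on pair."""
    if spec.design != "between":
        raise ValueError("fit_between requires a between-design spec")
    if spec.family != "linear":
        return fit_glm(df, spec)
    X, y, meta = build_design(df, spec)
    groups = meta["data"][spec.cluster] if spec.cluster else None
    res = fit_linear_clustered(
        X, y, groups, family="linear", design="between", exposure=spec.exposure)
    res.meta.update({k: v for k, v in meta.items() if k == "birth_year_center"})
    return res


def fit_within(pairs: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Within-family fit on differenced DZ pairs.

    The exposure and outcome are the differenced columns
    (``d_<exposure>``, ``d_<outcome>``); moderators must be pair-level
    (between-pair) variables.  The unit is the pair, so errors are
    heteroskedasticity-robust without cluster nesting.
    """
    if spec.design != "within":
        raise ValueError("fit_within requires a within-design spec")
    d_outcome = spec.outcome if spec.outcome.startswith("d_") else f"d_{spec.outcome}"
    d_exposure = spec.exposure if spec.exposure.startswith("d_") else f"d_{spec.exposure}"
    if d_outcome not in pairs.columns or d_exposure not in pairs.columns:
        raise KeyError(
            f"pairs frame lacks {d_outcome}/{d_exposure}; run pair_difference first")
    for m in spec.moderators:
        if m.startswith("d_"):
            raise ValueError(f"moderator {m} varies within pair; must be pair-level")
    if spec.family != "linear":
        return fit_glm(pairs, spec)
    wspec = replace(spec, outcome=d_outcome, exposure=d_exposure)
    X, y, meta = build_design(pairs, wspec)
    res = fit_linear_clustered(
        X, y, None, family="linear", design="within", exposure=d_exposure)
    res.meta.update({k: v for k, v in meta.items() if k == "birth_year_center"})
    return res


def _fit_dispatch(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    return fit_within(data, spec) if spec.design == "within" else fit_between(data, spec)


def fit_stratified(
    data: pd.DataFrame,
    spec: ModelSpec,
    strata: Sequence[str] = ("decade",),
    min_n: int = 50,
) -> StratifiedResult:
    """Independent fits per stratum (e.g. birth decade, SES level).

    Strata below ``min_n`` observations are reported in ``skipped`` with
    their size, never silently dropped.
    """
    df = data.copy()
    if "decade" in strata and "decade" not in df.columns:
        df["decade"] = decade_column(df["birth_year"])
    fits: dict = {}
    skipped: dict = {}
    for key, grp in df.groupby(list(strata), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        key = key[0] if len(key) == 1 else key
        if len(grp) < min_n:
            skipped[key] = len(grp)
            continue
        res = _fit_dispatch(grp, spec)
        res.stratum = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        fits[key] = res
    if skipped:
        log.warning("strata below min_n=%d skipped: %s", min_n, skipped)
    return StratifiedResult(fits=fits, skipped=skipped)


def fit_trend(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Continuous PGI × birth-year interaction (per calendar year).

    Birth year is centered at the sample mean before interacting, so main
    effects stay interpretable; the interaction coefficient is unchanged by
    centering.
    """
    tspec = replace(spec, moderators=("birth_year",))
    res = _fit_dispatch(data, tspec)
    exp = res.exposure
    res.meta["trend_term"] = f"{exp}:birth_year_c"
    return res


# ---------------------------------------------------------------------------
# GLM variants


def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Logit (binary) or ordered-logit (ordinal) fit on the same design.

    Coefficients are reported on the untransformed log-odds scale, where a
    latent-scale slope is invariant to the outcome's mean — the basis of
    the floor/ceiling diagnostic.  Errors are cluster-robust on pair.
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if spec.family not in ("logit", "ordered_logit"):
        raise ValueError("fit_glm requires family logit or ordered_logit")
    exposure_col = spec.exposure
    outcome_col = spec.outcome
    if spec.design == "within":
        if not outcome_col.startswith("d_"):
            outcome_col = f"d_{outcome_col}"
        if not exposure_col.startswith("d_"):
            exposure_col = f"d_{exposure_col}"
        spec = replace(spec, outcome=outcome_col, exposure=exposure_col)
    X, y, meta = build_design(data, spec)
    X, dropped = _drop_collinear(X)
    yv = y.to_numpy()
    groups = None
    if spec.cluster and spec.cluster in meta["data"].columns:
        groups = meta["data"][spec.cluster].to_numpy()
        cov_kw = {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    else:
        cov_kw = {"cov_type": "HC1"} if spec.family == "logit" else {}

    if spec.family == "logit":
        uniq = np.unique(yv)
        if not set(uniq) <= {0.0, 1.0}:
            raise ValueError("logit requires a binary 0/1 outcome")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, X.to_numpy()).fit(disp=0, maxiter=200, **cov_kw)
        except (PerfectSeparationError, np.linalg.LinAlgError) as e:
            raise ValueError(f"logit failed (separation?): {e}") from None
        if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 50:
            raise ValueError("logit shows signs of separation (diverging coefficients)")
        terms = list(X.columns)
        params, bse, pv = res.params, res.bse, res.pvalues
        meta_extra = {}
    else:
        Xo = X.drop(columns=["const"], errors="ignore")
        cats = np.unique(yv)
        if len(cats) < 2:
            raise ValueError("ordered_logit requires >= 2 outcome categories")
        mod = OrderedModel(yv, Xo.to_numpy(), distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(method="bfgs", disp=0, maxiter=500, **cov_kw)
        k = Xo.shape[1]
        terms = list(Xo.columns)
        params, bse, pv = res.params[:k], res.bse[:k], res.pvalues[:k]
        meta_extra = {"cutpoints": res.params[k:].tolist()}

    n = len(yv)
    G = len(np.unique(groups)) if groups is not None else n
    out = FitResult(
        terms=terms,
        params=dict(zip(terms, np.asarray(params).tolist())),
        se=dict(zip(terms, np.asarray(bse).tolist())),
        pvalues=dict(zip(terms, np.asarray(pv).tolist())),
        nobs=n,
        n_clusters=G,
        r2=None,
        resid_var=None,
        family=spec.family,
        design=spec.design,
        exposure=exposure_col,
        dropped=dropped,
    )
    out.meta.update(meta_extra)
    out.meta.update({k_: v for k_, v in meta.items() if k_ == "birth_year_center"})
    return out


# ---------------------------------------------------------------------------
# helpers


def deciles_per_latent_sd(
    df: pd.DataFrame, decile_col: str = "edu_decile", latent_col: str = "edu_latent"
) -> float:
    """Jacobian of the decile transform: OLS slope of decile on latent.

    Converts latent-scale generative coefficients to the decile units in
    which registry fits are reported (decile outcomes run 1–10, SD ≈ 2.87
    under uniformity).
    """
    sub = df[[decile_col, latent_col]].dropna()
    x = sub[latent_col].to_numpy()
    y = sub[decile_col].to_numpy()
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))
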