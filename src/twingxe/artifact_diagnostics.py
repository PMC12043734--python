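"""Floor/ceiling diagnostics for dichotomized GxE outcomes.

A linear-probability slope on a dichotomized outcome scales with the
density of the latent distribution at the cut point, so apparent changes
in a PGI effect across strata can be artifacts of drifting prevalence.
On the log-odds scale (logit/ordered logit), a constant latent slope under
logistic errors stays constant regardless of where the outcome is cut.
Contrasting the two scales across thresholds or strata therefore flags
prevalence-driven "interactions".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gxe_estimators import FitResult, fit_linear_clustered

log = logging.getLogger(__name__)

__all__ = ["ScaleReport", "threshold_sweep", "scale_sensitivity", "trend_summary"]


@dataclass
class ScaleReport:
    """Per-threshold/stratum slopes on both scales, plus a concordance
    verdict for cross-stratum trends."""

    table: pd.DataFrame
    verdict: str = "not-compared"
    rule: str = "sign-or-ci"
    trends: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "verdict": self.verdict,
            "rule": self.rule,
            "trends": self.trends,
            "notes": self.notes,
            "table": self.table.to_dict(orient="records"),
        }
        s = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _logit_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return float(res.params[1]), float(res.bse[1])


def threshold_sweep(
    df: pd.DataFrame,
    thresholds: Sequence[float],
    latent_col: str = "edu_latent",
    exposure_col: str = "pgi",
) -> ScaleReport:
    """Dichotomize the latent outcome at each threshold and fit both scales.

    For each cut point ``c`` the outcome ``1[latent > c]`` is regressed on
    the exposure with a linear-probability model (HC1 errors) and a logit;
    the report records both slopes against the resulting prevalence.
    Thresholds outside the latent support are skipped with a note.
    """
    sub = df[[latent_col, exposure_col]].dropna()
    lat = sub[latent_col].to_numpy()
    x = sub[exposure_col].to_numpy()
    lo, hi = lat.min(), lat.max()
    rows, notes = [], []
    for c in thresholds:
        if not (lo < c < hi):
            notes.append(f"threshold {c} outside latent support [{lo:.2f}, {hi:.2f}]; skipped")
            continue
        y = (lat > c).astype(float)
        prev = float(y.mean())
        X = pd.DataFrame({"const": np.ones_like(x), exposure_col: x})
        lin = fit_linear_clustered(X, y, None)
        lo_slope, lo_se = _logit_slope(x, y)
        rows.append(
            {
                "threshold": float(c),
                "prevalence": prev,
                "linear_slope": lin.params[exposure_col],
                "linear_se": lin.se[exposure_col],
                "logodds_slope": lo_slope,
                "logodds_se": lo_se,
            }
        )
    for n in notes:
        log.warning(n)
    return ScaleReport(table=pd.DataFrame(rows), notes=notes)


def trend_summary(estimates: Sequence[float], ses: Sequence[float] | None = None
                  ) -> dict:
    """Slope of stratum-ordered estimates on the stratum index (OLS), with
    a conventional homoskedastic SE and 95% CI."""
    y = np.asarray(estimates, dtype=float)
    k = len(y)
    idx = np.arange(k, dtype=float)
    X = np.column_stack([np.ones(k), idx])
    beta, res_, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(k - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    tcrit = stats.t.ppf(0.975, dof)
    return {
        "slope": float(beta[1]),
        "se": se,
        "ci": (float(beta[1] - tcrit * se), float(beta[1] + tcrit * se)),
    }


def scale_sensitivity(
    fits_linear: Sequence[tuple[float, float]],
    fits_glm: Sequence[tuple[float, float]],
    strata: Sequence | None = None,
) -> ScaleReport:
    """Compare the cross-stratum trend of the exposure slope across scales.

    Inputs are ordered ``(estimate, se)`` pairs per stratum for the linear
    and log-odds fits.  The verdict is ``"discordant"`` when the two trend
    slopes differ in sign, or when one trend's 95% CI excludes the other's
    point estimate; fewer than 3 strata gives ``"insufficient"``.  The rule
    is deterministic given the fitted summaries.
    """
    la = list(fits_linear)
    gl = list(fits_glm)
    if len(la) != len(gl):
        raise ValueError("linear and glm fits must cover the same strata")
    strata = list(strata) if strata is not None else list(range(len(la)))
    table = pd.DataFrame(
        {
            "stratum": strata,
            "linear_slope": [e for e, _ in la],
            "linear_se": [s for _, s in la],
            "logodds_slope": [e for e, _ in gl],
            "logodds_se": [s for _, s in gl],
        }
    )
    if len(la) < 3:
        return ScaleReport(table=table, verdict="insufficient")
    t_lin = trend_summary([e for e, _ in la])
    t_glm = trend_summary([e for e, _ in gl])
    signs_differ = np.sign(t_lin["slope"]) != np.sign(t_glm["slope"])
    ci_excludes = not (t_lin["ci"][0] <= t_glm["slope"] <= t_lin["ci"][1]) \
        or not (t_glm["ci"][0] <= t_lin["slope"] <= t_glm["ci"][1])
    verdict = "discordant" if (signs_differ or ci_excludes) else "concordant"
    return ScaleReport(
        table=table, verdict=verdict,
        trends={"linear": t_lin, "logodds": t_glm},
    )
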