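"""Measurement-error disattenuation of PGI coefficients.

A polygenic index built from finite-GWAS weights measures the latent
genetic value with error, attenuating its coefficients.  For a
standardized (unit-variance) PGI and outcome, multiplying every
PGI-containing coefficient by ``sqrt(h²_SNP / R²_PGI)`` approximates the
estimate one would obtain with a PGI capturing the full SNP heritability:
under the classical error model ``PGI_std = (G+u)/sqrt(1+σ_u²)`` the
observed incremental R² is ``h²/(1+σ_u²)``, so the factor equals
``sqrt(1+σ_u²)`` and exactly undoes the attenuation of the standardized
coefficient.  Standard errors are scaled by the same factor (an
approximation: sampling error in h² and R² themselves is ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

from .gxe_estimators import FitResult

__all__ = ["CorrectionParams", "disattenuation_factor", "rescale_fit"]


@dataclass(frozen=True)
class CorrectionParams:
    """SNP heritability of the outcome and incremental R² of the PGI."""

    h2_snp: float
    r2_pgi: float

    def __post_init__(self):
        if not (0.0 < self.r2_pgi <= 1.0) or not (0.0 < self.h2_snp <= 1.0):
            raise ValueError("h2_snp and r2_pgi must lie in (0, 1]")
        if self.r2_pgi > self.h2_snp:
            raise ValueError("r2_pgi cannot exceed h2_snp")


def disattenuation_factor(params: CorrectionParams) -> float:
    """``sqrt(h²_SNP / R²_PGI) >= 1``."""
    return math.sqrt(params.h2_snp / params.r2_pgi)


def _contains_exposure(term: str, exposure: str) -> bool:
    return exposure in term.split(":")


def rescale_fit(fit: FitResult, params: CorrectionParams) -> FitResult:
    """Multiply every PGI-containing coefficient (and its SE) by the factor.

    Terms are tagged by their components: any term whose ``:``-separated
    parts include the fit's exposure (main effect or interaction) is
    rescaled; all other terms are untouched.  The result is marked
    ``rescaled``; rescaling twice raises.
    """
    if fit.rescaled:
        raise ValueError("fit is already rescaled; refusing to rescale twice")
    f = disattenuation_factor(params)
    new_params = dict(fit.params)
    new_se = dict(fit.se)
    touched = []
    for t in fit.terms:
        if _contains_exposure(t, fit.exposure):
            new_params[t] = fit.params[t] * f
            new_se[t] = fit.se[t] * f
            touched.append(t)
    out = FitResult(
        terms=list(fit.terms),
        params=new_params,
        se=new_se,
        pvalues=dict(fit.pvalues),  # t-statistics are scale-invariant
        nobs=fit.nobs,
        n_clusters=fit.n_clusters,
        r2=fit.r2,
        resid_var=fit.resid_var,
        family=fit.family,
        design=fit.design,
        exposure=fit.exposure,
        stratum=dict(fit.stratum) if fit.stratum else None,
        rescaled=True,
        dropped=list(fit.dropped),
        meta={**fit.meta, "disattenuation_factor": f, "rescaled_terms": touched},
    )
    return out
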