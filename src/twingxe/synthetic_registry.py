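"""Synthetic twin-registry generator.

Simulates genotyped twin pairs with the statistical structure that a
within-family polygenic-index (PGI) design is built to separate:

* **assortative mating** — parental latent genetic values correlated ``r_am``;
* **genetic nurture** — parental genotype affects the offspring outcome
  through the rearing environment (coefficient ``delta_nurture``);
* **population stratification** — ancestry principal components load on both
  the PGI and the outcome;
* **cohort-varying direct effects** — the direct PGI effect β(t) drifts
  linearly in birth year, and a socioeconomic-status (SES) enhancement term
  γ(decade) multiplies the genetic value for twins with highly educated
  parents;
* **PGI measurement error** — a twin-unique and a pair-shared error
  component, plus additive genotyping-batch offsets, with batch assignment
  correlated with birth year;
* **ascertainment** — optional over-sampling of highly educated pairs.

The generator is fully vectorised and bit-reproducible given
``(params, seed)``.  Draw order (one ``numpy`` Generator stream): birth
years, zygosity, batch, sex, parental genetics and education, segregation
deviations, ancestry components, PGI measurement errors, outcome noise,
supplementary-outcome noise, ascertainment uniforms.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .phenotype_transforms import (
    build_decile_reference,
    decile_rank_frame,
    median_split,
)

__all__ = [
    "GenerativeParams",
    "draw_parents",
    "transmit_genotypes",
    "observe_pgi",
    "assign_cohort_batch",
    "generate_phenotypes",
    "ascertain_sample",
    "generate_registry",
    "write_registry",
    "read_registry",
    "REGISTRY_COLUMNS",
]

#: default batch mix per decade: one older array dominating pre-1950 cohorts,
#: two newer arrays splitting the later cohorts.
def _default_batch_map() -> dict[int, dict[str, float]]:
    m: dict[int, dict[str, float]] = {}
    for dec in range(1920, 1950, 10):
        m[dec] = {"omni": 0.94, "core": 0.04, "gsa": 0.02}
    for dec in range(1950, 2000, 10):
        m[dec] = {"omni": 0.10, "core": 0.45, "gsa": 0.45}
    return m


def _default_gamma() -> dict[int, float]:
    # enhancement concentrated in the oldest SES-observed cohorts, gone by
    # the 1960s (comprehensive-school era)
    g = {1920: 0.15, 1930: 0.15, 1940: 0.15, 1950: 0.05}
    g.update({dec: 0.0 for dec in range(1960, 2000, 10)})
    return g


def _default_thresholds() -> dict[int, tuple[float, float]]:
    # (upper-secondary, university) latent cut points per decade; prevalence
    # of an upper-secondary degree rises from ~0.5 to ~0.95 over the century,
    # university from ~0.1 to ~0.35
    cuts = {}
    for i, dec in enumerate(range(1920, 2000, 10)):
        cuts[dec] = (round(0.0 - 0.23 * i, 3), round(1.28 - 0.13 * i, 3))
    return cuts


@dataclass
class GenerativeParams:
    """All simulator knobs.  Defaults encode the study conditions."""

    n_pairs: int = 20_000
    p_mz: float = 0.35
    birth_year_range: tuple[int, int] = (1920, 1989)
    reference_year: int = 1920
    beta0: float = 0.15          # direct PGI effect at reference year (latent-SD per genetic-SD)
    beta_trend: float = 0.0025   # change in direct effect per birth year
    gamma_schedule: dict[int, float] = field(default_factory=_default_gamma)
    delta_nurture: float = 0.05  # effect of g_mother+g_father on offspring outcome
    r_am: float = 0.2            # assortative-mating correlation of parental genetic values
    sigma_meas_unique: float = 0.7
    sigma_meas_shared: float = 0.3
    k_pcs: int = 20
    pc_loadings_pgi: tuple[float, ...] = (0.10, 0.05)
    pc_loadings_y: tuple[float, ...] = (0.10, 0.05)
    ses_main: float = 0.15       # direct effect of (scaled) parental education on outcome
    parent_edu_loading: float = 0.3   # genetic loading of parental education
    parent_edu_min_year: int | None = 1940   # parental education missing before this birth year
    batch_birthyear_map: dict[int, dict[str, float]] = field(default_factory=_default_batch_map)
    batch_shift: dict[str, float] = field(
        default_factory=lambda: {"omni": 0.0, "core": 0.10, "gsa": -0.10}
    )
    ascertain_edu_bias: float = 0.4  # education-years over-representation; 0 disables
    years_per_sd: float = 3.0        # education years per latent SD, for the bias target
    threshold_schedule: dict[int, tuple[float, float]] = field(default_factory=_default_thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")
        if not 0.0 <= self.p_mz <= 1.0:
            raise ValueError("p_mz must lie in [0, 1]")
        if not -1.0 < self.r_am < 1.0:
            raise ValueError("r_am must lie in (-1, 1)")
        for name in ("sigma_meas_unique", "sigma_meas_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError("birth_year_range must be (min, max) with min <= max")
        decades = set(range(lo // 10 * 10, hi // 10 * 10 + 1, 10))
        missing = decades - set(self.gamma_schedule)
        if missing:
            raise ValueError(f"gamma_schedule missing decades: {sorted(missing)}")
        missing = decades - set(self.batch_birthyear_map)
        if missing:
            raise ValueError(f"batch_birthyear_map missing decades: {sorted(missing)}")
        for dec, probs in self.batch_birthyear_map.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"batch probabilities for decade {dec} must sum to 1")

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(o)
        d = dataclasses.asdict(self)
        return json.dumps(d, default=enc, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeParams":
        d = dict(d)
        for key in ("birth_year_range",):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("pc_loadings_pgi", "pc_loadings_y"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("gamma_schedule", "batch_birthyear_map", "threshold_schedule"):
            if key in d:
                d[key] = {int(k): (tuple(v) if isinstance(v, (list, tuple)) else v)
                          for k, v in d[key].items()}
        return cls(**d)


def decade_of(year) -> np.ndarray:
    """Calendar decade of a birth year (floor to the nearest 10)."""
    return (np.asarray(year) // 10) * 10


# ---------------------------------------------------------------------------
# generation stages


def draw_parents(params: GenerativeParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw parental latent genetic values and education deciles.

    ``(g_mother, g_father)`` are bivariate standard normal with correlation
    ``r_am`` (Gaussian copula by construction).  Parental education deciles
    are the within-population decile of ``λ·g + sqrt(1−λ²)·z`` with
    independent noise ``z``, so education is monotone in a noisy function of
    the genetic value.
    """
    n = params.n_pairs
    if n == 0:
        return pd.DataFrame(
            columns=["pair_id", "g_mother", "g_father", "mother_edu", "father_edu"]
        )
    r = params.r_am
    z = rng.standard_normal((n, 2))
    g_m = z[:, 0]
    g_f = r * z[:, 0] + np.sqrt(1.0 - r**2) * z[:, 1]
    lam = params.parent_edu_loading
    noise = rng.standard_normal((n, 2))
    lat_m = lam * g_m + np.sqrt(1.0 - lam**2) * noise[:, 0]
    lat_f = lam * g_f + np.sqrt(1.0 - lam**2) * noise[:, 1]

    def to_decile(x: np.ndarray) -> np.ndarray:
        ranks = np.argsort(np.argsort(x))
        return (ranks * 10) // len(x) + 1

    return pd.DataFrame(
        {
            "pair_id": np.arange(n),
            "g_mother": g_m,
            "g_father": g_f,
            "mother_edu": to_decile(lat_m).astype(float),
            "father_edu": to_decile(lat_f).astype(float),
        }
    )


def transmit_genotypes(
    parents: pd.DataFrame, zygosity: np.ndarray, params: GenerativeParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Meiotic transmission: ``g_child = midparent + s``.

    The segregation deviation ``s ~ N(0, (1−r_am)/2)`` keeps the offspring
    genetic variance at 1 under assortative mating at equilibrium
    (single-generation approximation).  MZ co-twins share one deviation; DZ
    co-twins draw independent deviations, giving co-twin correlation
    ``(1+r_am)/2``.
    """
    mid = 0.5 * (parents["g_mother"].to_numpy() + parents["g_father"].to_numpy())
    sd_seg = np.sqrt((1.0 - params.r_am) / 2.0)
    s = rng.standard_normal((len(mid), 2)) * sd_seg
    mz = np.asarray(zygosity) == "MZ"
    s[mz, 1] = s[mz, 0]
    return mid + s[:, 0], mid + s[:, 1]


def assign_cohort_batch(
    pair_years: np.ndarray, params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw one genotyping batch per pair from the decade-specific mix."""
    decades = decade_of(pair_years)
    batch = np.empty(len(pair_years), dtype=object)
    u = rng.random(len(pair_years))
    for dec in np.unique(decades):
        if int(dec) not in params.batch_birthyear_map:
            raise ValueError(f"decade {dec} missing from batch_birthyear_map")
        probs = params.batch_birthyear_map[int(dec)]
        names = list(probs)
        cum = np.cumsum([probs[b] for b in names])
        idx = decades == dec
        batch[idx] = np.array(names, dtype=object)[np.searchsorted(cum, u[idx])]
    return batch


def observe_pgi(
    g_true: np.ndarray,
    pair_id: np.ndarray,
    batch: np.ndarray,
    pcs: np.ndarray,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Layer measurement error, ancestry loadings and batch offsets on g.

    ``pgi_raw = g + u_pair + u_twin + Σ λ_k·pc_k + shift[batch]`` with the
    pair-shared component drawn once per pair.
    """
    n = len(g_true)
    _, pair_idx = np.unique(pair_id, return_inverse=True)
    n_pairs = pair_idx.max() + 1 if n else 0
    u_pair = rng.standard_normal(n_pairs) * params.sigma_meas_shared
    u_twin = rng.standard_normal(n) * params.sigma_meas_unique
    load = np.zeros(params.k_pcs)
    load[: len(params.pc_loadings_pgi)] = params.pc_loadings_pgi[: params.k_pcs]
    shift = np.array([params.batch_shift.get(b, 0.0) for b in batch])
    return g_true + u_pair[pair_idx] + u_twin + pcs @ load + shift


def generate_phenotypes(
    df: pd.DataFrame, params: GenerativeParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Build the latent education outcome and binary degrees.

    ``edu_latent = β(t)·g + γ(decade)·g·parent_high + δ·(g_m+g_f)
    + ses_main·parent_edu_scaled + Σ λ_k·pc_k + ε`` with β(t) linear in
    birth year and ε scaled so the latent variance is ≈1 at the reference
    configuration (β fixed at β0, γ at the reference decade's value).
    Requires ``parent_high``/``parent_edu`` already present (the generator
    computes them from the simulated parents before this stage).
    """
    need_parents = params.delta_nurture != 0.0
    if need_parents and (df["g_mother"].isna().any() or df["g_father"].isna().any()):
        raise ValueError("delta_nurture != 0 requires parental genetic values")
    g = df["g_true"].to_numpy()
    t = df["birth_year"].to_numpy()
    beta_t = params.beta0 + params.beta_trend * (t - params.reference_year)
    gamma = np.array([params.gamma_schedule[int(d)] for d in decade_of(t)])
    ph = df["parent_high"].to_numpy(dtype=float)
    pe = df["parent_edu"].to_numpy(dtype=float)
    pe_scaled = (pe - 5.5) / 2.872  # decile scale -> approx unit SD
    gsum = df["g_mother"].to_numpy() + df["g_father"].to_numpy()
    load = np.zeros(params.k_pcs)
    load[: len(params.pc_loadings_y)] = params.pc_loadings_y[: params.k_pcs]
    pc_cols = [f"pc{i+1}" for i in range(params.k_pcs)]
    pc_term = df[pc_cols].to_numpy() @ load if params.k_pcs else 0.0

    sys = beta_t * g + gamma * g * ph + params.delta_nurture * gsum \
        + params.ses_main * pe_scaled + pc_term
    ref_dec = int(decade_of(params.reference_year))
    gamma_ref = params.gamma_schedule.get(ref_dec, 0.0)
    sys_ref = params.beta0 * g + gamma_ref * g * ph + params.delta_nurture * gsum \
        + params.ses_main * pe_scaled + pc_term
    sigma_eps = np.sqrt(max(1.0 - float(np.var(sys_ref)), 0.05))
    eps = rng.standard_normal(len(df)) * sigma_eps

    out = df.copy()
    out["edu_latent"] = sys + eps
    dec = decade_of(t)
    thr = np.array([params.threshold_schedule[int(d)] for d in dec])
    out["degree_upper_sec"] = (out["edu_latent"] > thr[:, 0]).astype(int)
    out["degree_university"] = (out["edu_latent"] > thr[:, 1]).astype(int)
    # supplementary channels: GPA tracks the education latent closely,
    # income more loosely
    out["gpa_latent"] = 0.7 * out["edu_latent"] + np.sqrt(1 - 0.49) * rng.standard_normal(len(df))
    out["income_latent"] = 0.5 * out["edu_latent"] + np.sqrt(1 - 0.25) * rng.standard_normal(len(df))
    return out


def ascertain_sample(
    df: pd.DataFrame, params: GenerativeParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Over-sample highly educated pairs by exponential tilting.

    Retention probability is proportional to ``exp(a · pair-mean latent)``
    with ``a`` solved so the retained mean exceeds the population mean by
    ``ascertain_edu_bias / years_per_sd`` latent SDs.  ``bias = 0`` returns
    the input unchanged.
    """
    if params.ascertain_edu_bias == 0:
        return df
    target = params.ascertain_edu_bias / params.years_per_sd
    pm = df.groupby("pair_id")["edu_latent"].mean()
    m = pm.to_numpy()
    mbar = m.mean()

    def shift(a: float) -> float:
        w = np.exp(a * (m - m.max()))
        return float(np.sum(w * m) / np.sum(w) - mbar)

    a_hi = 50.0
    if shift(a_hi) < target:
        warnings.warn(
            f"ascertainment bias {target:.3f} SD unreachable; using best effort",
            RuntimeWarning,
        )
        a = a_hi
    else:
        a = brentq(lambda x: shift(x) - target, 0.0, a_hi)
    p = 0.9 * np.exp(a * (m - m.max()))
    keep_pairs = pm.index.to_numpy()[rng.random(len(m)) < p]
    return df[df["pair_id"].isin(keep_pairs)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# full generation


def generate_registry(
    params: GenerativeParams, seed: int | None = None
) -> pd.DataFrame:
    """Generate a complete twin registry.

    Returns one row per twin.  Simulation-only columns (``g_true``,
    ``g_mother``, ``g_father``, ``edu_latent``, ``gpa_latent``,
    ``income_latent``) are kept in the frame but excluded from the on-disk
    registry format.  Education/GPA/income deciles are ranked against the
    pre-ascertainment population within (birth_year, sex), mimicking
    full-population register referencing.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_pairs
    if n < 1:
        raise ValueError("generate_registry requires n_pairs >= 1")
    lo, hi = params.birth_year_range
    pair_years = rng.integers(lo, hi + 1, size=n)
    zyg = np.where(rng.random(n) < params.p_mz, "MZ", "DZ")
    batch = assign_cohort_batch(pair_years, params, rng)
    # sex: MZ same-sex, DZ independent
    sex = rng.integers(0, 2, size=(n, 2))
    mz = zyg == "MZ"
    sex[mz, 1] = sex[mz, 0]

    parents = draw_parents(params, rng)
    g1, g2 = transmit_genotypes(parents, zyg, params, rng)
    pcs_pair = rng.standard_normal((n, params.k_pcs))  # ancestry is family-level

    def twin_frame(k: int, g: np.ndarray) -> pd.DataFrame:
        d = pd.DataFrame(
            {
                "twin_id": np.arange(n) * 2 + k,
                "pair_id": np.arange(n),
                "zygosity": zyg,
                "sex": np.where(sex[:, k] == 0, "F", "M"),
                "birth_year": pair_years,
                "batch": batch,
                "g_true": g,
            }
        )
        for i in range(params.k_pcs):
            d[f"pc{i+1}"] = pcs_pair[:, i]
        return d

    df = pd.concat([twin_frame(0, g1), twin_frame(1, g2)], ignore_index=True)
    df = df.sort_values(["pair_id", "twin_id"]).reset_index(drop=True)
    df = df.merge(parents, on="pair_id", how="left")

    # parental education: dominance principle + pooled median split
    df["parent_edu"] = df[["mother_edu", "father_edu"]].max(axis=1)
    df["parent_high"] = median_split(df["parent_edu"])

    pcs_mat = df[[f"pc{i+1}" for i in range(params.k_pcs)]].to_numpy()
    df["pgi"] = observe_pgi(
        df["g_true"].to_numpy(), df["pair_id"].to_numpy(), df["batch"].to_numpy(),
        pcs_mat, params, rng,
    )
    df = generate_phenotypes(df, params, rng)

    # population-referenced deciles computed before ascertainment
    for latent, out_col in [
        ("edu_latent", "edu_decile"),
        ("gpa_latent", "gpa_decile"),
        ("income_latent", "income_decile"),
    ]:
        ref = build_decile_reference(df, value_col=latent, by=("birth_year", "sex"))
        df[out_col] = decile_rank_frame(df, ref, value_col=latent, by=("birth_year", "sex"))

    df = ascertain_sample(df, params, rng)

    # registry realism: parental education unavailable for the oldest cohorts
    if params.parent_edu_min_year is not None:
        old = df["birth_year"] < params.parent_edu_min_year
        df.loc[old, ["mother_edu", "father_edu", "parent_edu"]] = np.nan
        df.loc[old, "parent_high"] = np.nan
    return df


# ---------------------------------------------------------------------------
# registry I/O (TSV + JSON sidecar)

REGISTRY_COLUMNS = [
    "twin_id", "pair_id", "zygosity", "sex", "birth_year", "batch", "pgi",
    "mother_edu", "father_edu", "edu_decile", "degree_upper_sec",
    "degree_university", "gpa_decile", "income_decile",
]


def write_registry(df: pd.DataFrame, path: str | Path,
                   params: GenerativeParams | None = None,
                   seed: int | None = None) -> None:
    """Write the registry TSV (fixed column order, empty fields = missing)
    and, when params are given, a JSON sidecar with the generating
    configuration."""
    path = Path(path)
    k = len([c for c in df.columns if c.startswith("pc")])
    cols = REGISTRY_COLUMNS[:7] + [f"pc{i+1}" for i in range(k)] + REGISTRY_COLUMNS[7:]
    out = df.reindex(columns=[c for c in cols if c in df.columns or c.startswith("pc")])
    out.to_csv(path, sep="\t", index=False, na_rep="")
    if params is not None:
        sidecar = json.loads(params.to_json())
        sidecar["seed"] = params.seed if seed is None else seed
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a registry TSV written by :func:`write_registry`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("zygosity", "sex", "batch"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
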