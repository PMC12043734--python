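"""End-to-end study pipeline.

Generates (or ingests) a twin registry, applies the variable transforms,
runs the between/within model battery — pooled, per birth decade, by
parental-education level, and with continuous birth-year trends — then the
measurement-error correction and the floor/ceiling scale diagnostics, and
writes tidy tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .synthetic_registry import (
    GenerativeParams, generate_registry, read_registry, write_registry,
)
from .phenotype_transforms import median_split, standardize_pgi
from .gxe_estimators import (
    WITHIN_COVARIATES, ModelSpec, decade_column,
    fit_between, fit_stratified, fit_trend, fit_within, pair_difference,
)
from .attenuation_correction import CorrectionParams, rescale_fit
from .artifact_diagnostics import scale_sensitivity, threshold_sweep

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "covariates_for", "transform_registry"]


@dataclass
class RunConfig:
    """Pipeline configuration.  Exactly one of ``simulate``/``input_file``."""

    simulate: dict | None = None          # GenerativeParams overrides
    input_file: str | None = None
    outdir: str = "results/run"
    seed: int = 1
    standardize: bool = True
    singleton_policy: str = "merge"
    ses_min_year: int = 1940              # parental-education analyses start here
    ses_trend_window: tuple[int, int] = (1940, 1969)
    correction: dict | None = field(default_factory=lambda: {"h2_snp": 0.16, "r2_pgi": 0.04})
    diagnostics: bool = True
    keller_stratified: bool = True
    min_stratum_n: int = 50
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.input_file is None):
            raise ValueError("config must set exactly one of simulate / input_file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "ses_trend_window" in d:
            d["ses_trend_window"] = tuple(d["ses_trend_window"])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def covariates_for(df: pd.DataFrame, within: bool) -> tuple[str, ...]:
    if within:
        return tuple(c for c in WITHIN_COVARIATES if c in df.columns)
    pcs = tuple(c for c in df.columns if c.startswith("pc") and c[2:].isdigit())
    return pcs + tuple(c for c in ("sex", "batch") if c in df.columns)


@_stage("input")
def _load(config: RunConfig) -> tuple[pd.DataFrame, GenerativeParams | None]:
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides["seed"] = config.seed
        params = GenerativeParams.from_dict(overrides)
        return generate_registry(params, seed=config.seed), params
    path = Path(config.input_file)
    if not path.exists():
        raise FileNotFoundError(f"registry file not found: {path}")
    return read_registry(path), None


@_stage("transform")
def transform_registry(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    if "pgi_raw" not in df.columns:
        df["pgi_raw"] = df["pgi"]
    if config.standardize:
        df = standardize_pgi(df, col="pgi_raw", out_col="pgi",
                             singleton_policy=config.singleton_policy)
    if "parent_edu" not in df.columns:
        df["parent_edu"] = df[["mother_edu", "father_edu"]].max(axis=1)
    if "parent_high" not in df.columns and df["parent_edu"].notna().any():
        df["parent_high"] = median_split(df["parent_edu"])
    df["decade"] = decade_column(df["birth_year"])
    return df


def _table(fits, path: Path, extra: dict | None = None) -> None:
    frames = []
    for f in (fits if isinstance(fits, (list, tuple)) else [fits]):
        t = f.to_frame()
        if extra:
            for k, v in extra.items():
                t[k] = v
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full battery; returns the manifest (also written to disk).

    Deterministic given ``(config, seed)``.  Any stage error aborts with a
    stage-named diagnostic; the manifest is only written on success.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    df, params = _load(config)
    if params is not None:
        write_registry(df, outdir / "registry.tsv", params=params, seed=config.seed)
        artifacts += ["registry.tsv", "registry.tsv.json"]
    df = transform_registry(df, config)

    between = ModelSpec(covariates=covariates_for(df, within=False))
    pairs = pair_difference(df, outcome=["edu_decile"], exposure="pgi")
    pairs["decade"] = decade_column(pairs["birth_year"])
    within = ModelSpec(design="within", covariates=covariates_for(pairs, within=True))

    # main-effect fits per decade (between and within)
    dec_b = fit_stratified(df, between, ("decade",), config.min_stratum_n)
    dec_w = fit_stratified(pairs, within, ("decade",), config.min_stratum_n)
    _table(list(dec_b.fits.values()) + list(dec_w.fits.values()),
           outdir / "decade_fits.tsv")
    artifacts.append("decade_fits.tsv")

    # continuous birth-year trends
    trend_b = fit_trend(df, between)
    trend_w = fit_trend(pairs, within)
    _table([trend_b, trend_w], outdir / "trend_fits.tsv")
    artifacts.append("trend_fits.tsv")

    # PGI x parental-education interactions, pooled and per decade
    ses_df = df[(df["birth_year"] >= config.ses_min_year) & df["parent_high"].notna()]
    ses_pairs = pairs[(pairs["birth_year"] >= config.ses_min_year)
                      & pairs["parent_high"].notna()]
    bspec = ModelSpec(moderators=("parent_high",), keller=config.keller_stratified,
                      covariates=covariates_for(df, within=False))
    wspec = ModelSpec(design="within", moderators=("parent_high",),
                      keller=config.keller_stratified,
                      covariates=covariates_for(pairs, within=True))
    pooled = [fit_between(ses_df, bspec), fit_within(ses_pairs, wspec)]
    for f in pooled:
        f.stratum = {"decade": "pooled"}
    ses_b = fit_stratified(ses_df, bspec, ("decade",), config.min_stratum_n)
    ses_w = fit_stratified(ses_pairs, wspec, ("decade",), config.min_stratum_n)
    table1 = pooled + list(ses_b.fits.values()) + list(ses_w.fits.values())
    _table(table1, outdir / "table1_analogue.tsv")
    artifacts.append("table1_analogue.tsv")

    # SES-specific birth-year trends in the convergence window
    lo, hi = config.ses_trend_window
    ses_trends = []
    for level in (0.0, 1.0):
        sub = ses_df[(ses_df["decade"] >= lo) & (ses_df["decade"] <= hi)
                     & (ses_df["parent_high"] == level)]
        subp = ses_pairs[(ses_pairs["decade"] >= lo) & (ses_pairs["decade"] <= hi)
                         & (ses_pairs["parent_high"] == level)]
        fb = fit_trend(sub, between)
        fb.stratum = {"parent_high": level}
        fw = fit_trend(subp, within)
        fw.stratum = {"parent_high": level}
        ses_trends += [fb, fw]
    _table(ses_trends, outdir / "ses_trend_fits.tsv")
    artifacts.append("ses_trend_fits.tsv")

    # measurement-error correction of the trend fits
    if config.correction:
        cp = CorrectionParams(**config.correction)
        corrected = [rescale_fit(f, cp) for f in [trend_b, trend_w] + pooled]
        _table(corrected, outdir / "corrected_fits.tsv")
        artifacts.append("corrected_fits.tsv")

    # floor/ceiling scale diagnostics
    if config.diagnostics:
        _diagnostics(df, outdir, artifacts, config)

    manifest = {
        "twingxe_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "n_twins": int(len(df)),
        "n_pairs_within": int(len(pairs)),
        "artifacts": artifacts,
        "skipped_strata": {
            "decade_between": {str(k): v for k, v in dec_b.skipped.items()},
            "decade_within": {str(k): v for k, v in dec_w.skipped.items()},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


@_stage("diagnostics")
def _diagnostics(df: pd.DataFrame, outdir: Path, artifacts: list[str],
                 config: RunConfig) -> None:
    if "edu_latent" in df.columns:
        qs = df["edu_latent"].quantile([0.1, 0.3, 0.5, 0.7, 0.9]).to_numpy()
        report = threshold_sweep(df, thresholds=qs)
        report.to_json(outdir / "threshold_sweep.json")
        artifacts.append("threshold_sweep.json")

    # LPM vs logit slopes of the upper-secondary degree across decades
    lin, glm, strata = [], [], []
    for dec, grp in df.groupby("decade"):
        y = grp["degree_upper_sec"]
        if len(grp) < config.min_stratum_n or y.nunique() < 2 \
                or y.mean() in (0.0, 1.0):
            continue
        spec_l = ModelSpec(outcome="degree_upper_sec", keller=False,
                           covariates=(), family="linear")
        spec_g = ModelSpec(outcome="degree_upper_sec", keller=False,
                           covariates=(), family="logit")
        try:
            fl = fit_between(grp, spec_l)
            fg = fit_between(grp, spec_g)
        except ValueError as e:
            log.warning("diagnostic fit skipped for decade %s: %s", dec, e)
            continue
        lin.append((fl.params["pgi"], fl.se["pgi"]))
        glm.append((fg.params["pgi"], fg.se["pgi"]))
        strata.append(int(dec))
    report = scale_sensitivity(lin, glm, strata)
    report.to_json(outdir / "scale_report.json")
    report.to_tsv(outdir / "scale_report.tsv")
    artifacts += ["scale_report.json", "scale_report.tsv"]
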