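"""Penalized-smooth mixed models (GAMMs) for dive metrics.

Three model families are supported, mirroring standard practice for
biologging dive metrics:

* dive depth  ~ Gamma(log link), smooth terms;
* dive duration ~ Gamma(log link), smooth terms;
* hourly dive count ~ negative binomial(log link) with an offset of
  log(covered hours), which models a dive *rate*.

Periodic covariates (time of day, period 24 h; moon phase, period 2*pi) use
cyclic cubic regression splines; other covariates use thin plate regression
splines, all with basis dimension k = 5.  Smoothing parameters are selected
by REML with an additional shrinkage (double) penalty so uninformative terms
are penalized toward zero effective degrees of freedom, giving implicit
variable selection.  Individual variation enters either as a random
intercept per animal or as a random factor smooth (a per-animal cyclic
deviation curve on time of day with a shared smoothing parameter); the two
structures are compared by conditional AIC and percent deviance explained.

Fitting is delegated to mgcv (via ``Rscript``), the reference implementation
of penalized regression splines with REML smoothness selection; this module
owns the model specification, the data contract, and the prediction
surfaces.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: Known periodic covariates and their periods.
DEFAULT_PERIODS = {"time_of_day": (0.0, 24.0), "hour_of_day": (0.0, 24.0),
                   "moon_phase": (0.0, TWO_PI)}


@dataclass(frozen=True)
class SmoothTerm:
    covariate: str
    basis: str = "thin_plate"        # or "cyclic_cubic"
    k: int = 5
    period: tuple | None = None      # (lo, hi) for cyclic bases

    def __post_init__(self):
        if self.basis == "cyclic_cubic" and self.period is None:
            object.__setattr__(self, "period",
                               DEFAULT_PERIODS.get(self.covariate))
            if self.period is None:
                raise ValueError(
                    f"cyclic term {self.covariate!r} needs an explicit period")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one dive-metric model."""

    response: str
    family: str                       # "gamma_log" | "negbin_log"
    terms: tuple
    random: str = "intercept_by_id"   # or "factor_smooth_time_by_id"
    random_time_covariate: str = "time_of_day"
    offset: str | None = None         # column holding log(covered hours)
    id_column: str = "animal_id"

    def __post_init__(self):
        if self.family not in ("gamma_log", "negbin_log"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.random not in ("intercept_by_id", "factor_smooth_time_by_id", "none"):
            raise ValueError(f"unknown random structure {self.random!r}")


def depth_model_spec(random: str = "factor_smooth_time_by_id",
                     covariates=("time_of_day", "moon_phase", "slope",
                                 "current_magnitude", "chl_log10_lag30", "mld")) -> ModelSpec:
    """The standard dive-depth model: Gamma/log with cc + tp smooths, k=5."""
    terms = tuple(
        SmoothTerm(c, "cyclic_cubic" if c in DEFAULT_PERIODS else "thin_plate")
        for c in covariates
    )
    return ModelSpec("depth", "gamma_log", terms, random=random)


def duration_model_spec(random: str = "factor_smooth_time_by_id",
                        covariates=("time_of_day", "moon_phase", "slope",
                                    "current_magnitude", "chl_log10_lag30", "mld")) -> ModelSpec:
    terms = tuple(
        SmoothTerm(c, "cyclic_cubic" if c in DEFAULT_PERIODS else "thin_plate")
        for c in covariates
    )
    return ModelSpec("duration", "gamma_log", terms, random=random)


def rate_model_spec(random: str = "factor_smooth_time_by_id") -> ModelSpec:
    """Hourly dive-count model: negative binomial with log-hours offset."""
    terms = (SmoothTerm("hour_of_day", "cyclic_cubic", period=(0.0, 24.0)),
             SmoothTerm("moon_phase", "cyclic_cubic"))
    return ModelSpec("n_dives", "negbin_log", terms, random=random,
                     random_time_covariate="hour_of_day",
                     offset="log_covered_hours")


@dataclass
class ModelFit:
    """A fitted penalized-smooth model with its per-term summaries."""

    spec: ModelSpec
    edf: dict                 # term label -> effective degrees of freedom
    p_values: dict
    statistics: dict
    deviance_explained: float  # percent
    aic: float
    k_index: dict
    n: int
    covariate_means: dict
    id_levels: list
    workdir: str               # holds the serialized mgcv fit (fit.rds)
    nb_theta: float | None = None

    @property
    def random_label(self) -> str | None:
        spec = self.spec
        if spec.random == "intercept_by_id":
            return f"s({spec.id_column})"
        if spec.random == "factor_smooth_time_by_id":
            return f"s({spec.random_time_covariate},{spec.id_column})"
        return None


def _r_family(family: str) -> str:
    return 'Gamma(link="log")' if family == "gamma_log" else "nb()"


def _build_formula(spec: ModelSpec) -> tuple[str, str]:
    parts = []
    knots = []
    for t in spec.terms:
        if t.basis == "cyclic_cubic":
            parts.append(f's({t.covariate}, bs="cc", k={t.k})')
            knots.append(f"{t.covariate}=c({t.period[0]}, {t.period[1]})")
        elif t.basis == "thin_plate":
            # Shrinkage variant of the thin plate basis: the whole term can
            # be penalized to zero, giving implicit variable selection.
            parts.append(f's({t.covariate}, bs="ts", k={t.k})')
        else:
            raise ValueError(f"unknown basis {t.basis!r}")
    if spec.random == "intercept_by_id":
        parts.append(f's({spec.id_column}, bs="re")')
    elif spec.random == "factor_smooth_time_by_id":
        tc = spec.random_time_covariate
        parts.append(f's({tc}, {spec.id_column}, bs="fs", xt=list(bs="cc"), k=5)')
        if tc not in [t.covariate for t in spec.terms if t.basis == "cyclic_cubic"]:
            period = DEFAULT_PERIODS.get(tc, (0.0, 24.0))
            knots.append(f"{tc}=c({period[0]}, {period[1]})")
    if spec.offset:
        parts.append(f"offset({spec.offset})")
    formula = f"{spec.response} ~ " + " + ".join(parts)
    knots_arg = f"list({', '.join(knots)})" if knots else "NULL"
    return formula, knots_arg


def _run_rscript(script: str, workdir: Path) -> dict:
    script_path = workdir / "job.R"
    script_path.write_text(script)
    proc = subprocess.run(["Rscript", "--vanilla", str(script_path)],
                          capture_output=True, text=True, cwd=workdir)
    out_path = workdir / "out.json"
    if proc.returncode != 0 or not out_path.exists():
        raise RuntimeError(
            f"model fitting failed (exit {proc.returncode}):\n{proc.stderr[-3000:]}")
    return json.loads(out_path.read_text())


def fit_metric_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one dive-metric model by penalized REML with shrinkage selection.

    ``data`` must contain complete cases for the response, every smooth
    covariate, the id column, and the offset column (if any); rows with
    missing values are dropped.  At least two animals are required when a
    random structure is present.
    """
    cols = [spec.response, spec.id_column] + [t.covariate for t in spec.terms]
    if spec.random == "factor_smooth_time_by_id":
        cols.append(spec.random_time_covariate)
    if spec.offset:
        cols.append(spec.offset)
    cols = list(dict.fromkeys(cols))
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns {missing}")
    df = data[cols].dropna().reset_index(drop=True)
    n_ids = df[spec.id_column].nunique()
    if spec.random != "none" and n_ids < 2:
        raise ValueError("random structures require at least 2 animals")

    workdir = Path(tempfile.mkdtemp(prefix="divetrace_gamm_"))
    df.to_csv(workdir / "data.csv", index=False)
    formula, knots_arg = _build_formula(spec)

    script = f"""
suppressMessages({{library(mgcv); library(jsonlite)}})
d <- read.csv("data.csv")
d${spec.id_column} <- factor(d${spec.id_column})
m <- gam({formula}, data=d, family={_r_family(spec.family)},
         method="REML", select=TRUE, knots={knots_arg})
if (!m$converged) stop("REML iteration did not converge")
s <- summary(m)
kc <- tryCatch(k.check(m), error=function(e) NULL)
out <- list(
  edf = as.list(setNames(s$s.table[,"edf"], rownames(s$s.table))),
  stat = as.list(setNames(s$s.table[,3], rownames(s$s.table))),
  p = as.list(setNames(s$s.table[,4], rownames(s$s.table))),
  dev_expl = s$dev.expl * 100,
  aic = AIC(m),
  n = nrow(d),
  k_index = if (is.null(kc)) list() else as.list(setNames(kc[,"k-index"], rownames(kc))),
  theta = if (grepl("Negative Binomial", m$family$family)) m$family$getTheta(TRUE) else NULL,
  id_levels = levels(d${spec.id_column})
)
saveRDS(m, "fit.rds")
write(toJSON(out, digits=12, auto_unbox=TRUE, null="null"), "out.json")
"""
    res = _run_rscript(script, workdir)
    num_cols = df.select_dtypes(include=[np.number]).columns
    means = {c: float(df[c].mean()) for c in num_cols}
    return ModelFit(
        spec=spec,
        edf={k: float(v) for k, v in res["edf"].items()},
        p_values={k: float(v) for k, v in res["p"].items()},
        statistics={k: float(v) for k, v in res["stat"].items()},
        deviance_explained=float(res["dev_expl"]),
        aic=float(res["aic"]),
        k_index={k: float(v) for k, v in (res.get("k_index") or {}).items()
                 if isinstance(v, (int, float))},
        n=int(res["n"]),
        covariate_means=means,
        id_levels=list(res["id_levels"]),
        workdir=str(workdir),
        nb_theta=res.get("theta"),
    )


def compare_random_structures(data: pd.DataFrame, spec: ModelSpec) -> dict:
    """Fit random-intercept and factor-smooth variants; choose by AIC.

    Returns a report with both fits, the AIC difference
    (intercept - factor smooth; positive favors the factor smooth), the
    deviance-explained difference in percentage points, and the selected
    structure.  If one fit fails the report is partial and flagged.
    """
    report: dict = {"flag": None}
    fits = {}
    for structure in ("intercept_by_id", "factor_smooth_time_by_id"):
        try:
            fits[structure] = fit_metric_model(
                data, ModelSpec(spec.response, spec.family, spec.terms,
                                random=structure,
                                random_time_covariate=spec.random_time_covariate,
                                offset=spec.offset, id_column=spec.id_column))
        except RuntimeError as exc:
            report["flag"] = f"{structure} failed: {exc}"
    report["fits"] = fits
    if len(fits) == 2:
        fi, ff = fits["intercept_by_id"], fits["factor_smooth_time_by_id"]
        report["delta_aic"] = fi.aic - ff.aic
        report["delta_deviance_explained"] = ff.deviance_explained - fi.deviance_explained
        report["selected"] = ("factor_smooth_time_by_id"
                              if ff.aic < fi.aic else "intercept_by_id")
    elif fits:
        report["selected"] = next(iter(fits))
    return report


def predict_effects(fit: ModelFit, covariate: str, grid=None,
                    n_points: int = 100, offset_value: float = 0.0) -> pd.DataFrame:
    """Conditional effect curve for one covariate, with a 95% interval.

    All other covariates are held at their training means and the random
    terms are excluded, so the curve is the functional relationship for a
    typical individual.  Returns link-scale estimate and standard error plus
    the response-scale curve and interval.  Grid points outside the observed
    covariate range are flagged ``extrapolated``.
    """
    term = next((t for t in fit.spec.terms if t.covariate == covariate), None)
    if term is None and covariate != fit.spec.random_time_covariate:
        raise ValueError(f"{covariate!r} is not a model covariate")
    workdir = Path(fit.workdir)
    obs = pd.read_csv(workdir / "data.csv")
    lo, hi = float(obs[covariate].min()), float(obs[covariate].max())
    if grid is None:
        if term is not None and term.basis == "cyclic_cubic":
            grid = np.linspace(term.period[0], term.period[1], n_points)
        else:
            grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)

    nd = pd.DataFrame({covariate: grid})
    for c, mean in fit.covariate_means.items():
        if c not in (covariate, fit.spec.response):
            nd[c] = mean
    if fit.spec.offset:
        nd[fit.spec.offset] = offset_value
    nd[fit.spec.id_column] = fit.id_levels[0]
    nd.to_csv(workdir / "newdata.csv", index=False)

    exclude = f'"{fit.random_label}"' if fit.random_label else "NULL"
    script = f"""
suppressMessages({{library(mgcv); library(jsonlite)}})
m <- readRDS("fit.rds")
nd <- read.csv("newdata.csv")
nd${fit.spec.id_column} <- factor(nd${fit.spec.id_column}, levels={_r_char_vec(fit.id_levels)})
p <- predict(m, nd, type="link", se.fit=TRUE, exclude={exclude}, newdata.guaranteed=TRUE)
write(toJSON(list(fit=p$fit, se=p$se.fit), digits=12), "out.json")
"""
    res = _run_rscript(script, workdir)
    est = np.asarray(res["fit"], dtype=float)
    se = np.asarray(res["se"], dtype=float)
    return pd.DataFrame({
        covariate: grid,
        "estimate_link": est,
        "se_link": se,
        "estimate": np.exp(est),
        "lower": np.exp(est - 1.96 * se),
        "upper": np.exp(est + 1.96 * se),
        "extrapolated": (grid < lo) | (grid > hi),
    })


def _r_char_vec(values) -> str:
    inner = ", ".join(f'"{v}"' for v in values)
    return f"c({inner})"
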