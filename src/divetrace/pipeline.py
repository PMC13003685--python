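"""End-to-end orchestration: simulate -> standardize -> rates -> tracks ->
covariates -> near-seafloor -> models, with one seed, stage toggles, and a
bookkeeping manifest.

Every stage writes plain CSV/JSON outputs into the run directory and records
row counts in the manifest, so dives can be audited through the whole chain:
standardized dives = modeled dives + dropped dives with a recorded reason.
A disabled stage loads its outputs from a previous run in the same
directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_log as bl
from . import covariates as cov
from . import gamm, metrics, seafloor, synthetic, track

STAGES = ("simulate", "standardize", "rates", "fit_track",
          "extract_covariates", "classify_seafloor", "fit_models")


@dataclass
class RunConfig:
    """All thresholds and knobs of the pipeline, with standard defaults."""

    out_dir: str = "divetrace_run"
    seed: int = 0
    # scenario
    n_animals: int = 16
    duration_days: float = 13.0
    # standardization
    depth_threshold_m: float = 50.0
    duration_threshold_s: float = 120.0
    # diel band and hourly units
    diel_band_deg: float = 6.0
    hour_coverage_min: float = 0.75
    # track modeling
    max_speed_mps: float = 5.5
    n_imputations: int = 20
    max_ellipse95_km: float = 4.0
    # near-seafloor
    sd_max_m: float = 100.0
    diff_max_m: float = 100.0
    # screening / models
    correlation_threshold: float = 0.5
    basis_dimension: int = 5
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self):
        for name in ("depth_threshold_m", "duration_threshold_s",
                     "hour_coverage_min", "max_ellipse95_km", "sd_max_m",
                     "diff_max_m", "correlation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class Pipeline:
    """Stateful runner; stage methods may be called individually."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"seed": config.seed, "stages": {}, "counts": {}}
        seq = np.random.SeedSequence(config.seed)
        kids = seq.spawn(4)
        self._seed_scenario = int(kids[0].generate_state(1)[0] % (2 ** 31))
        self._seed_impute = int(kids[1].generate_state(1)[0] % (2 ** 31))
        self.scenario = None
        self.std_logs: dict = {}
        self.fits: dict = {}
        self.dive_positions: pd.DataFrame | None = None
        self.imputations: dict = {}
        self.covariate_table: pd.DataFrame | None = None
        self.seafloor_stats: pd.DataFrame | None = None
        self.hour_units: pd.DataFrame | None = None
        self.model_reports: dict = {}

    # -- stage: simulate ---------------------------------------------------

    def simulate(self):
        cfg = synthetic.ScenarioConfig(
            n_animals=self.config.n_animals,
            duration_days=self.config.duration_days,
            seed=self._seed_scenario,
        )
        self.scenario = synthetic.simulate_scenario(cfg)
        bdir = self.out / "behavior"
        bdir.mkdir(exist_ok=True)
        for aid, recs in self.scenario.behavior_logs.items():
            recs.to_csv(bdir / f"{aid}.csv", index=False)
        ldir = self.out / "locations"
        ldir.mkdir(exist_ok=True)
        for aid, obs in self.scenario.observations.items():
            obs.to_csv(ldir / f"{aid}.csv", index=False)
        tdir = self.out / "truth"
        tdir.mkdir(exist_ok=True)
        for aid, tr in self.scenario.truths.items():
            tr.true_dive_table.to_csv(tdir / f"{aid}.csv", index=False)
        self.scenario.metadata.to_csv(self.out / "metadata.csv", index=False)
        self.manifest["counts"]["behavior_records"] = int(
            sum(len(r) for r in self.scenario.behavior_logs.values()))
        self._done("simulate")

    def _load_simulated(self):
        cfg = synthetic.ScenarioConfig(
            n_animals=self.config.n_animals,
            duration_days=self.config.duration_days,
            seed=self._seed_scenario,
        )
        self.scenario = synthetic.simulate_scenario(cfg)

    # -- stage: QC + standardize -------------------------------------------

    def standardize(self):
        self._require_scenario()
        rows = []
        qc_report = {}
        for aid, recs in self.scenario.behavior_logs.items():
            qc = bl.qc_behavior_log(recs)
            qc_report[aid] = {"verdict": qc["verdict"], "n_flags": qc["n_flags"]}
            std = bl.standardize(recs, self.config.depth_threshold_m,
                                 self.config.duration_threshold_s)
            self.std_logs[aid] = std
            rows.append(std.records)
        all_records = pd.concat(rows, ignore_index=True)
        all_records.to_csv(self.out / "standardized.csv", index=False)
        (self.out / "qc.json").write_text(json.dumps(qc_report, indent=1))
        self.manifest["counts"]["standardized_dives"] = int(
            (all_records["kind"] == "dive").sum())
        self._done("standardize")

    def _load_standardized(self):
        df = pd.read_csv(self.out / "standardized.csv",
                         parse_dates=["start", "end"])
        for aid, sub in df.groupby("animal_id"):
            self.std_logs[aid] = bl.StandardizedLog(
                sub.reset_index(drop=True), self.config.depth_threshold_m,
                self.config.duration_threshold_s)

    # -- stage: track fitting, prediction, imputation ----------------------

    def fit_track(self):
        self._require_scenario()
        preds = []
        imp_rows = []
        imp_seq = np.random.SeedSequence(self._seed_impute).spawn(
            len(self.scenario.observations))
        fit_meta = {}
        for (aid, obs), sub_seq in zip(sorted(self.scenario.observations.items()),
                                       imp_seq):
            filtered = track.prefilter_locations(obs, self.config.max_speed_mps)
            fit = track.fit_ctcrw(filtered)
            self.fits[aid] = fit
            fit_meta[aid] = {"beta": fit.beta, "sigma": fit.sigma,
                             "loglik": fit.loglik, "n_locations": len(filtered)}
            dives = self.std_logs[aid].dives
            if dives.empty:
                continue
            times = pd.DatetimeIndex(dives["start"])
            pp = track.predict_positions(fit, times)
            pp.insert(0, "animal_id", aid)
            preds.append(pp)
            imp = track.impute_tracks(
                fit, times, K=self.config.n_imputations,
                seed=int(sub_seq.generate_state(1)[0] % (2 ** 31)))
            self.imputations[aid] = imp
            for k in range(imp.K):
                imp_rows.append(pd.DataFrame({
                    "animal_id": aid, "imputation": k, "time": imp.times,
                    "lon": imp.lon[k], "lat": imp.lat[k],
                }))
        self.dive_positions = pd.concat(preds, ignore_index=True)
        self.dive_positions.to_csv(self.out / "dive_positions.csv", index=False)
        pd.concat(imp_rows, ignore_index=True).to_csv(
            self.out / "imputations.csv", index=False)
        (self.out / "ctcrw_fits.json").write_text(json.dumps(fit_meta, indent=1))
        self.manifest["counts"]["located_dives"] = int(len(self.dive_positions))
        self._done("fit_track")

    def _load_track_outputs(self):
        self.dive_positions = pd.read_csv(self.out / "dive_positions.csv",
                                          parse_dates=["time"])
        imp = pd.read_csv(self.out / "imputations.csv", parse_dates=["time"])
        for aid, sub in imp.groupby("animal_id"):
            ks = sorted(sub["imputation"].unique())
            times = pd.DatetimeIndex(sub[sub["imputation"] == ks[0]]["time"])
            lon = np.stack([sub[sub["imputation"] == k]["lon"].to_numpy() for k in ks])
            lat = np.stack([sub[sub["imputation"] == k]["lat"].to_numpy() for k in ks])
            x = np.zeros_like(lon)
            self.imputations[aid] = track.ImputationSet(times, lon, lat, x, x, 0)

    # -- stage: diel splitting, rates, hour units ---------------------------

    def rates(self):
        self._require_scenario()
        lookup = self._position_lookup()
        diel_rows, hour_rows = [], []
        for aid, std in sorted(self.std_logs.items()):
            recs = std.records
            d = metrics.split_records(recs, "diel", position_lookup=lookup)
            h = metrics.split_records(recs, "clock_hour")
            diel_rows.append(d)
            hour_rows.append(h)
        diel_records = pd.concat(diel_rows, ignore_index=True)
        hour_records = pd.concat(hour_rows, ignore_index=True)
        rates_overall = metrics.dive_rate(diel_records, "overall")
        rates_diel = metrics.dive_rate(diel_records, "diel_category")
        self.hour_units = metrics.build_hour_units(
            hour_records, self.config.hour_coverage_min)
        diel_records.to_csv(self.out / "records_diel.csv", index=False)
        rates_overall.to_csv(self.out / "rates_overall.csv", index=False)
        rates_diel.to_csv(self.out / "rates_diel.csv", index=False)
        self.hour_units.to_csv(self.out / "hour_units.csv", index=False)
        self._diel_records = diel_records
        self.manifest["counts"]["hour_units"] = int(len(self.hour_units))
        self._done("rates")

    # -- stage: covariates ---------------------------------------------------

    def extract_covariates(self):
        self._require_scenario()
        if self.dive_positions is None:
            self._load_track_outputs()
        sc = self.scenario
        dives = []
        for aid, std in sorted(self.std_logs.items()):
            d = std.dives
            pos = self.dive_positions[self.dive_positions["animal_id"] == aid]
            d = d.merge(pos[["time", "lon", "lat", "ellipse95_semi_major_m"]],
                        left_on="start", right_on="time", how="inner")
            dives.append(d)
        dives = pd.concat(dives, ignore_index=True)
        table = cov.dive_covariates(dives, sc.bathymetry, sc.environment)
        n_all = len(table)
        ok_ellipse = table["ellipse95_semi_major_m"] <= self.config.max_ellipse95_km * 1000.0
        ok_flag = ~table["chl_flagged"]
        covar_cols = ["slope", "current_magnitude", "mld", "sst",
                      "chl_log10", "chl_log10_lag30"]
        ok_complete = table[covar_cols].notna().all(axis=1)
        table["dropped_reason"] = ""
        table.loc[~ok_complete, "dropped_reason"] = "missing_covariate"
        table.loc[~ok_flag, "dropped_reason"] = "chl_land_flag"
        table.loc[~ok_ellipse, "dropped_reason"] = "ellipse_gt_4km"
        retained = table[ok_ellipse & ok_flag & ok_complete].copy()
        kept, corr = cov.correlation_screen(
            retained, ["time_of_day", "moon_phase", "slope", "current_magnitude",
                       "chl_log10_lag30", "mld", "chl_log10", "sst"],
            threshold=self.config.correlation_threshold)
        self.covariate_table = table
        self.retained_covariates = kept
        table.to_csv(self.out / "covariates.csv", index=False)
        corr.to_csv(self.out / "covariate_correlations.csv")
        (self.out / "retained_covariates.json").write_text(json.dumps(kept))
        self.manifest["counts"]["covariate_dives_total"] = int(n_all)
        self.manifest["counts"]["covariate_dives_retained"] = int(len(retained))
        self.manifest["counts"]["dropped_ellipse"] = int((~ok_ellipse).sum())
        self.manifest["counts"]["dropped_chl_flag"] = int((ok_ellipse & ~ok_flag).sum())
        self.manifest["counts"]["dropped_missing"] = int(
            (ok_ellipse & ok_flag & ~ok_complete).sum())
        self._done("extract_covariates")

    # -- stage: near-seafloor -----------------------------------------------

    def classify_seafloor(self):
        self._require_scenario()
        if self.covariate_table is None:
            self.covariate_table = pd.read_csv(
                self.out / "covariates.csv", parse_dates=["start", "end", "time"])
        if not self.imputations:
            self._load_track_outputs()
        cand = self.covariate_table[
            self.covariate_table["ellipse95_semi_major_m"]
            <= self.config.max_ellipse95_km * 1000.0]
        stats_rows = []
        for aid, sub in cand.groupby("animal_id"):
            st = seafloor.compute_seafloor_stats(
                sub, self.imputations[aid], self.scenario.bathymetry)
            stats_rows.append(st)
        stats = pd.concat(stats_rows, ignore_index=True)
        probable = seafloor.classify_near_seafloor(
            stats, self.config.sd_max_m, self.config.diff_max_m)
        stats["probable"] = probable
        summary = seafloor.summarize_near_seafloor(stats, probable)
        self.seafloor_stats = stats
        stats.to_csv(self.out / "seafloor_dives.csv", index=False)
        summary.to_csv(self.out / "seafloor_summary.csv", index=False)
        self.manifest["counts"]["seafloor_candidates"] = int(len(stats))
        self.manifest["counts"]["seafloor_probable"] = int(probable.sum())
        self._done("classify_seafloor")

    # -- stage: models --------------------------------------------------------

    def fit_models(self):
        if self.covariate_table is None:
            self.covariate_table = pd.read_csv(
                self.out / "covariates.csv", parse_dates=["start", "end", "time"])
        if self.hour_units is None:
            self.hour_units = pd.read_csv(self.out / "hour_units.csv")
        retained = self.covariate_table[
            self.covariate_table["dropped_reason"].fillna("") == ""].copy()
        kept = getattr(self, "retained_covariates", None) or json.loads(
            (self.out / "retained_covariates.json").read_text())
        smooth_covs = [c for c in kept if c in (
            "time_of_day", "moon_phase", "slope", "current_magnitude",
            "chl_log10_lag30", "mld")]
        mdir = self.out / "models"
        mdir.mkdir(exist_ok=True)
        for response, spec_fn in (("depth", gamm.depth_model_spec),
                                  ("duration", gamm.duration_model_spec)):
            report = gamm.compare_random_structures(
                retained, spec_fn(covariates=tuple(smooth_covs)))
            self._export_model(report, mdir, response)
        units = self.hour_units.copy()
        units["hour_of_day"] = units["hour"] + 0.5
        units["log_covered_hours"] = np.log(units["covered_hours"])
        report = gamm.compare_random_structures(units, gamm.rate_model_spec())
        self._export_model(report, mdir, "hourly_rate")
        self._done("fit_models")

    def _export_model(self, report: dict, mdir: Path, name: str):
        self.model_reports[name] = report
        payload = {"selected": report.get("selected"), "flag": report["flag"]}
        for structure, fit in report["fits"].items():
            payload[structure] = {
                "aic": fit.aic, "deviance_explained": fit.deviance_explained,
                "edf": fit.edf, "p_values": fit.p_values, "n": fit.n,
            }
        if "delta_aic" in report:
            payload["delta_aic"] = report["delta_aic"]
            payload["delta_deviance_explained"] = report["delta_deviance_explained"]
        (mdir / f"{name}.json").write_text(json.dumps(payload, indent=1))
        best = report["fits"].get(report.get("selected"))
        if best is not None:
            for t in best.spec.terms:
                curve = gamm.predict_effects(best, t.covariate, n_points=50)
                curve.to_csv(mdir / f"{name}_{t.covariate}.csv", index=False)

    # -- helpers ---------------------------------------------------------------

    def _position_lookup(self):
        """Positions for diel labels: CTCRW-smoothed if available, else the
        deployment-locality (path start) coordinates."""
        sc = self.scenario

        def lookup(animal_id, times):
            fit = self.fits.get(animal_id)
            if fit is not None:
                pred = track.predict_positions(fit, times)
                return pred["lon"].to_numpy(), pred["lat"].to_numpy()
            path = sc.paths[animal_id]
            return (np.full(len(times), path.lon[0]),
                    np.full(len(times), path.lat[0]))
        return lookup

    def _require_scenario(self):
        if self.scenario is None:
            self._load_simulated()

    def _done(self, stage: str):
        self.manifest["stages"][stage] = "done"
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))


def run(config: RunConfig) -> Pipeline:
    """Execute all enabled stages in order; returns the pipeline object."""
    pipe = Pipeline(config)
    order = [("simulate", pipe.simulate),
             ("standardize", pipe.standardize),
             ("fit_track", pipe.fit_track),
             ("rates", pipe.rates),
             ("extract_covariates", pipe.extract_covariates),
             ("classify_seafloor", pipe.classify_seafloor),
             ("fit_models", pipe.fit_models)]
    for name, fn in order:
        if config.stages.get(name, True):
            fn()
        else:
            loader = {
                "simulate": pipe._load_simulated,
                "standardize": pipe._load_standardized,
                "fit_track": pipe._load_track_outputs,
            }.get(name)
            if loader:
                loader()
            pipe.manifest["stages"][name] = "skipped"
    config.to_yaml(pipe.out / "config.yaml")
    return pipe
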