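"""End-to-end orchestration: simulate/load -> CRQA -> inference -> report.

A run mirrors the hypothesis structure of the analysis this pipeline
implements: H1 speaking-time budgets, H2 gaze-gaze coupling against a shuffle
baseline with a full-record CORM, H3 turn-conditioned profiles with paired
and one-sample CORM tests, H4 pointing budgets, plus exploratory cross-person
pointing-gaze and within-person gaze-pointing couplings.  Dyads with an empty
behavior stream in a given analysis are excluded from that analysis only,
with a logged count; a test with fewer than three usable dyads is skipped
with an explicit report entry.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import recurrence as rec
from . import stats as st
from .series import CategoricalSeries
from .simulate import SyntheticConfig, generate_cohort

MIN_DYADS = 3


class PipelineConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Run-level parameters; defaults are the standard analysis settings
    (10 Hz, +/-15 s lag window in 43 bins, +/-4 s CORM band, 100 shuffles)."""

    rate_hz: float = 10.0
    max_lag_s: float = 15.0
    n_bins: int = 43
    corm_band_s: float = 4.0
    n_shuffles: int = 100
    seed: int = 0
    events_csv: str | None = None
    simulate: SyntheticConfig | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.events_csv is None and self.simulate is None:
            self.simulate = SyntheticConfig(seed=self.seed)
        for name, val in (("L", self.rate_hz * self.max_lag_s),
                          ("B", self.rate_hz * self.corm_band_s)):
            if abs(val - round(val)) > 1e-9:
                raise PipelineConfigError(f"{name} = rate*window must be an integer, got {val}")
        if (2 * self.L + 1) % self.n_bins:
            raise PipelineConfigError(
                f"2L+1 = {2 * self.L + 1} lags not divisible by n_bins = {self.n_bins}")
        if self.n_shuffles < 1:
            raise PipelineConfigError("n_shuffles must be >= 1")

    @property
    def L(self) -> int:
        return int(round(self.rate_hz * self.max_lag_s))

    @property
    def B(self) -> int:
        return int(round(self.rate_hz * self.corm_band_s))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if isinstance(sim, dict):
            sim = SyntheticConfig(**sim)
        return cls(simulate=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReportBundle:
    """All tables, tests and logs of one pipeline run."""

    config: AnalysisConfig
    records: list = field(repr=False, default_factory=list)
    budgets: pd.DataFrame | None = None
    profiles: dict = field(default_factory=dict)       # name -> dyad x bin DataFrame
    mean_rr: dict = field(default_factory=dict)        # name -> per-lag mean rr Series
    corms: pd.DataFrame | None = None
    tests: dict = field(default_factory=dict)          # name -> TestResult
    log: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def tests_table(self) -> pd.DataFrame:
        rows = [t.to_row() for t in self.tests.values()]
        return pd.DataFrame(rows)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.budgets is not None:
            self.budgets.to_csv(out / "budgets.csv", index=False)
        if self.corms is not None:
            self.corms.to_csv(out / "corm.csv", index=False)
        for name, df in self.profiles.items():
            df.to_csv(out / f"profile_{name}.csv")
        for name, s in self.mean_rr.items():
            s.rename("rr").to_csv(out / f"dcrp_{name}.csv")
        if self.tests:
            self.tests_table().to_csv(out / "tests.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        with open(out / "log.txt", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        return out


def load_records(cfg: AnalysisConfig) -> tuple[list[ev.DyadRecord], dict]:
    """Simulate a cohort or rasterize a (possibly multi-dyad) event CSV."""
    if cfg.events_csv is not None:
        df = pd.read_csv(cfg.events_csv, dtype={"category": str, "dyad_id": str})
        records = []
        for dyad_id, sub in df.groupby("dyad_id", sort=True):
            items = sorted(set(sub.loc[sub["track"] != "turn", "category"]))
            table = ev.EventTable(sub, item_set=items or ev.DEFAULT_ITEMS)
            records.append(ev.events_to_series(table, rate_hz=cfg.rate_hz))
        manifest = {"input": "events_csv", "path": str(cfg.events_csv),
                    "n_dyads": len(records)}
        return records, manifest
    sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed)
    records, manifest = generate_cohort(sim)
    manifest = {"input": "simulate", **manifest}
    return records, manifest


def _nonempty(s: CategoricalSeries) -> bool:
    return s.fraction_on() > 0


def _binned_profiles(
    pairs: list[tuple[CategoricalSeries, CategoricalSeries]], cfg: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(dyad x bin) binned rr matrix and the per-lag mean rr over dyads."""
    binned, full = [], []
    for x, y in pairs:
        d = rec.dcrp_fast(x, y, L=cfg.L, n_bins=cfg.n_bins)
        binned.append(d.binned_rr)
        full.append(d.rr)
    return np.array(binned), np.mean(full, axis=0)


def _corm_values(
    pairs: list[tuple[CategoricalSeries, CategoricalSeries]], cfg: AnalysisConfig
) -> np.ndarray:
    return np.array([rec.corm_fast(x, y, B=cfg.B).value for x, y in pairs])


def run_pipeline(cfg: AnalysisConfig, records: list[ev.DyadRecord] | None = None) -> ReportBundle:
    """Execute every analysis stage; returns the full report bundle."""
    if records is None:
        records, manifest = load_records(cfg)
    else:
        manifest = {"input": "records", "n_dyads": len(records)}
    bundle = ReportBundle(config=cfg, records=records)
    bundle.manifest = {"analysis_config": cfg.to_dict(), **manifest}
    log = bundle.log
    n_all = len(records)
    ids = [r.dyad_id for r in records]
    log.append(f"cohort: {n_all} dyads, {records[0].n_samples} samples at "
               f"{records[0].rate_hz:g} Hz (first dyad)")
    bin_lag_s = None

    def add_profile(name, dyad_ids, pairs):
        nonlocal bin_lag_s
        binned, mean_full = _binned_profiles(pairs, cfg)
        d0 = rec.DCRP(L=cfg.L, n_bins=cfg.n_bins, rr=mean_full, rate_hz=cfg.rate_hz)
        bin_lag_s = d0.bin_lags_s
        bundle.profiles[name] = pd.DataFrame(
            binned, index=pd.Index(dyad_ids, name="dyad"),
            columns=pd.Index(np.round(d0.bin_lags_s, 3), name="bin_center_s"))
        bundle.mean_rr[name] = pd.Series(
            mean_full, index=pd.Index(np.round(d0.lags_s, 3), name="lag_s"))
        return binned, d0

    def run_test(label, fn, *args, **kw):
        try:
            res = fn(*args, **kw)
            bundle.tests[label] = res
            log.append(f"{label}: {res.test} = {res.statistic:.4g}, p = {res.p:.4g}"
                       f" (n = {res.n})")
            return res
        except (st.DegenerateInputError, st.DesignError) as e:
            log.append(f"{label}: skipped ({e})")
            return None

    corm_rows = []

    # ---- H1: speaking time -------------------------------------------------
    budgets = []
    for r in records:
        b = ev.time_budget(r)
        b.insert(0, "dyad", r.dyad_id)
        budgets.append(b)
    bundle.budgets = pd.concat(budgets, ignore_index=True)
    sp = bundle.budgets.pivot(index="dyad", columns="actor", values="speaking_frac")
    run_test("H1_speaking_time", st.compare_durations,
             sp["trained"].to_numpy(), sp["untrained"].to_numpy(),
             name="H1_speaking_time")

    # ---- H2: gaze-gaze DCRP vs shuffle baseline, full-record CORM ----------
    gaze_pairs = [(r.gaze_trained, r.gaze_untrained) for r in records]
    gaze_binned, gaze_dcrp = add_profile("gaze", ids, gaze_pairs)
    base_binned = []
    for k, r in enumerate(records):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7001, k]))
        b = rec.shuffle_baseline(r.gaze_trained, r.gaze_untrained,
                                 L=cfg.L, n_bins=cfg.n_bins,
                                 n_shuffles=cfg.n_shuffles, seed=rng)
        base_binned.append(b.binned_rr)
    base_binned = np.array(base_binned)
    bundle.profiles["gaze_shuffled"] = pd.DataFrame(
        base_binned, index=pd.Index(ids, name="dyad"),
        columns=bundle.profiles["gaze"].columns)
    prof = st.CohortProfiles.from_arrays(
        {"gaze": gaze_binned, "shuffled": base_binned}, bin_lag_s, ids)
    try:
        for key, res in st.profile_anova(prof).items():
            bundle.tests[f"H2_gaze_vs_baseline_{key}"] = res
            log.append(f"H2_gaze_vs_baseline_{key}: F = {res.statistic:.4g}, "
                       f"p = {res.p:.4g}, df = {res.df}")
    except st.DesignError as e:
        log.append(f"H2_gaze_vs_baseline ANOVA: skipped ({e})")
    log.append(f"H2 grand DCRP peak: rr = {gaze_dcrp.rr.max():.4f} at lag "
               f"{gaze_dcrp.peak_lag() / cfg.rate_hz:g} s "
               f"(binned argmax at {gaze_dcrp.peak_lag(binned=True) / cfg.rate_hz:g} s)")
    corm_full = _corm_values(gaze_pairs, cfg)
    corm_rows += [("gaze_full", i, v) for i, v in zip(ids, corm_full)]
    run_test("H2_corm_vs_zero", st.corm_vs_zero, corm_full, name="H2_corm_vs_zero")

    # ---- H3: turn-conditioned gaze coupling --------------------------------
    cond_pairs = {
        spk: [rec.condition_on_turn(r, spk, "gaze_trained", "gaze_untrained")
              for r in records]
        for spk in ev.ACTORS
    }
    split_binned = {}
    for spk, pairs in cond_pairs.items():
        split_binned[spk], _ = add_profile(f"gaze_{spk}_speaking", ids, pairs)
    prof3 = st.CohortProfiles.from_arrays(
        {f"{spk}_speaking": split_binned[spk] for spk in ev.ACTORS}, bin_lag_s, ids)
    try:
        for key, res in st.profile_anova(prof3).items():
            bundle.tests[f"H3_turn_by_lag_{key}"] = res
            log.append(f"H3_turn_by_lag_{key}: F = {res.statistic:.4g}, "
                       f"p = {res.p:.4g}, df = {res.df}")
    except st.DesignError as e:
        log.append(f"H3 turn-by-lag ANOVA: skipped ({e})")
    corm_split = {spk: _corm_values(cond_pairs[spk], cfg) for spk in ev.ACTORS}
    for spk in ev.ACTORS:
        corm_rows += [(f"gaze_{spk}_speaking", i, v)
                      for i, v in zip(ids, corm_split[spk])]
    run_test("H3_corm_paired", st.compare_corm_paired,
             corm_split["trained"], corm_split["untrained"], name="H3_corm_paired")
    for spk in ev.ACTORS:
        run_test(f"H3_corm_vs_zero_{spk}_speaking", st.corm_vs_zero,
                 corm_split[spk], name=f"H3_corm_vs_zero_{spk}_speaking")

    # ---- H4: pointing time -------------------------------------------------
    pt = bundle.budgets.pivot(index="dyad", columns="actor", values="pointing_frac")
    if pt.to_numpy().sum() == 0:
        log.append("H4 and pointing analyses: skipped (no pointing in cohort)")
        bundle.corms = pd.DataFrame(corm_rows, columns=["analysis", "dyad", "corm"])
        return bundle
    run_test("H4_pointing_time", st.compare_durations,
             pt["trained"].to_numpy(), pt["untrained"].to_numpy(),
             name="H4_pointing_time")

    # ---- exploratory: cross-person pointing -> gaze ------------------------
    # rows = the trained participant's stream, so positive lags mean the
    # trained stream leads (sign convention of the profile figures)
    cross = {
        "point_trained_gaze_untrained":
            lambda r: (r.point_trained, r.gaze_untrained),
        "gaze_trained_point_untrained":
            lambda r: (r.gaze_trained, r.point_untrained),
    }
    cross_corm = {}
    for name, get in cross.items():
        usable = [r for r in records if _nonempty(get(r)[0]) and _nonempty(get(r)[1])]
        excluded = n_all - len(usable)
        if excluded:
            log.append(f"{name}: excluded {excluded} dyad(s) with an empty stream")
        if len(usable) < MIN_DYADS:
            log.append(f"{name}: skipped (< {MIN_DYADS} usable dyads)")
            continue
        u_ids = [r.dyad_id for r in usable]
        pairs = [get(r) for r in usable]
        add_profile(name, u_ids, pairs)
        vals = _corm_values(pairs, cfg)
        cross_corm[name] = (u_ids, vals)
        corm_rows += [(name, i, v) for i, v in zip(u_ids, vals)]
        run_test(f"corm_vs_zero_{name}", st.corm_vs_zero, vals,
                 name=f"corm_vs_zero_{name}")
    if len(cross_corm) == 2:
        (ids_a, a), (ids_b, b) = cross_corm.values()
        common = [i for i in ids_a if i in ids_b]
        if len(common) >= MIN_DYADS:
            # both profiles in trained-leads orientation (rows = trained stream)
            av = np.array([a[ids_a.index(i)] for i in common])
            bv = np.array([b[ids_b.index(i)] for i in common])
            run_test("cross_person_corm_paired", st.compare_corm_paired, av, bv,
                     name="cross_person_corm_paired")

    # ---- exploratory: within-person pointing vs own gaze -------------------
    # rows = pointing, so positive lags mean pointing leads one's own gaze
    for actor in ev.ACTORS:
        name = f"point_vs_own_gaze_{actor}"
        usable = [r for r in records
                  if _nonempty(getattr(r, f"point_{actor}"))
                  and _nonempty(getattr(r, f"gaze_{actor}"))]
        excluded = n_all - len(usable)
        if excluded:
            log.append(f"{name}: excluded {excluded} dyad(s) with an empty stream")
        if len(usable) < MIN_DYADS:
            log.append(f"{name}: skipped (< {MIN_DYADS} usable dyads)")
            continue
        u_ids = [r.dyad_id for r in usable]
        pairs = [(getattr(r, f"point_{actor}"), getattr(r, f"gaze_{actor}"))
                 for r in usable]
        add_profile(name, u_ids, pairs)
        vals = _corm_values(pairs, cfg)
        corm_rows += [(name, i, v) for i, v in zip(u_ids, vals)]
        run_test(f"corm_vs_zero_{name}", st.corm_vs_zero, vals,
                 name=f"corm_vs_zero_{name}")

    bundle.corms = pd.DataFrame(corm_rows, columns=["analysis", "dyad", "corm"])
    log.append("multiple-testing correction: none applied (reported as-is)")
    return bundle


def plot_outputs(bundle: ReportBundle, out_dir) -> list[Path]:
    """Figures: per-dyad recurrence plots and cohort DCRPs with SE ribbons."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    written = []

    for r in bundle.records:
        rs = rec.recurrence_points(r.gaze_trained, r.gaze_untrained)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(rs.i / cfg.rate_hz, rs.j / cfg.rate_hz, ",", color="k", alpha=0.4)
        ax.set_xlabel("trained gaze time (s)")
        ax.set_ylabel("untrained gaze time (s)")
        ax.set_title(f"recurrence plot, dyad {r.dyad_id}")
        path = out / f"recplot_{r.dyad_id}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    base = bundle.profiles.get("gaze_shuffled")
    for name, df in bundle.profiles.items():
        if name == "gaze_shuffled":
            continue
        lags = df.columns.to_numpy(dtype=float)
        mean = df.mean(axis=0).to_numpy()
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(lags, mean, color="C0", label=name)
        if len(df) > 1:
            se = df.std(axis=0, ddof=1).to_numpy() / math.sqrt(len(df))
            ax.fill_between(lags, mean - se, mean + se, color="C0", alpha=0.3)
        if name == "gaze" and base is not None:
            ax.plot(lags, base.mean(axis=0).to_numpy(), color="0.5", ls="--",
                    label="shuffle baseline")
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_xlabel("lag (s); positive = row stream leads")
        ax.set_ylabel("recurrence rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / f"dcrp_{name}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
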