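"""End-to-end orchestration of the analysis chain on synthetic data.

``run_pipeline`` executes design generation, first-level GLM,
pattern-similarity, behavioral statistics, cross-validated prediction,
task and rest connectivity, and mediation in sequence, writing tidy
TSV outputs plus a manifest (inputs, seeds, versions, output hashes)
so a run is fully reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behav, connectivity, firstlevel, mediation, predict
from . import similarity as sim
from . import synth

log = logging.getLogger("remap")

STAGES = ("synth", "firstlevel", "similarity", "behav", "predict",
          "connectivity", "mediation")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly to JSON."""

    out_dir: str = "remap_out"
    seed: int = 0
    n_subjects: int = 24
    k: int = 4
    n_perm: int = 1000
    n_boot: int = 1000
    n_pairs: int = 72
    stages: tuple[str, ...] = STAGES
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def sim_params(self, seed: int | None = None) -> synth.SimParams:
        kw = dict(self.sim)
        kw.setdefault("n_pairs", self.n_pairs)
        kw.setdefault("n_aversive", self.n_pairs // 2)
        if seed is not None:
            kw["seed"] = seed
        return synth.SimParams(**kw)

    def stage_seed(self, stage: str) -> int:
        # distinct, reproducible per-stage streams below 2**31
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", STAGES))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.to_json(out / "config.json").read_text()),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.monotonic()
        runner = globals()[f"_stage_{stage}"]
        try:
            outputs = runner(config, out, state)
        except Exception:
            log.exception("stage %r failed", stage)
            raise
        for entry in outputs.get("files", []):
            entry["sha256"] = _sha256(out / entry["path"])
        outputs["seconds"] = round(time.monotonic() - t0, 3)
        manifest["stages"][stage] = outputs
        log.info("stage %s done in %.2fs", stage, outputs["seconds"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=_jsonable))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _stage_synth(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("synth")
    params = config.sim_params(seed=seed)
    n = params.n_pairs
    d_init = synth.generate_design("initial", n, seed=seed)
    d_emo = synth.generate_design("emotional", n, seed=seed + 1,
                                  pair_conditions=d_init.pair_conditions())
    state["params"] = params
    state["design_init"] = d_init
    state["design_emo"] = d_emo
    files = []
    for name, d in (("initial", d_init), ("emotional", d_emo)):
        p = synth.write_events_tsv(d, out / f"events_{name}.tsv")
        files.append({"path": p.name})
        files.append({"path": p.with_suffix(".json").name})
    return {
        "seed": seed,
        "summary": {
            "initial_run_duration_s": d_init.total_duration,
            "emotional_run_duration_s": d_emo.total_duration,
        },
        "files": files,
    }


def _stage_firstlevel(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("firstlevel")
    params = state["params"].replace(seed=seed)
    bundle = synth.simulate_timeseries({"emo": state["design_emo"]}, params)
    state["bundle"] = bundle
    n_vol = bundle.n_volumes["emo"]
    X = firstlevel.build_design_matrix(state["design_emo"], bundle.tr, n_vol,
                                       mode="trial")
    res = firstlevel.fit_glm(bundle.seed_ts["emo"], X)
    df = pd.DataFrame({"regressor": res.labels, "beta": res.beta, "t": res.t})
    p = _write_tsv(df, out / "firstlevel_emotional.tsv")
    return {
        "seed": seed,
        "summary": {"n_regressors": len(res.labels), "df": res.df},
        "files": [{"path": p.name}],
    }


def _stage_similarity(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("similarity")
    params = state["params"].replace(seed=seed)
    ps_init, ps_emo = synth.simulate_pattern_sets(
        state["design_init"], state["design_emo"], params)
    state["pattern_sets"] = (ps_init, ps_emo)
    tm = sim.trial_measures(ps_init, ps_emo)
    p = _write_tsv(tm, out / "similarity_trial_measures.tsv")
    wide = tm.pivot(index="measure", columns="condition", values="z")
    return {
        "seed": seed,
        "summary": {
            "pair_specific_aversive_minus_neutral":
                float(wide.loc["pair_specific", "aversive"]
                      - wide.loc["pair_specific", "neutral"]),
        },
        "files": [{"path": p.name}],
    }


def _stage_behav(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("behav")
    rng = np.random.default_rng(seed)
    params = state["params"]
    tables = []
    for s in range(config.n_subjects):
        # subjects differ in reinstatement gain: the individual
        # differences that drive the brain-behavior analyses downstream
        p_s = params.replace(
            seed=int(rng.integers(2**31)),
            rho_aversive=float(np.clip(
                rng.normal(params.rho_aversive, 0.25), 0.0, 1.0)),
            rho_neutral=float(np.clip(
                rng.normal(params.rho_neutral, 0.15), 0.0, 1.0)),
        )
        ps_init, ps_emo = synth.simulate_pattern_sets(
            state["design_init"], state["design_emo"], p_s)
        tmz = sim.trial_measures(ps_init, ps_emo, measures=("pair_specific",),
                                 average_before_transform=False)
        # per-pair reinstatement drives this subject's behavior
        order = ps_init.by_pair().loc[ps_emo.meta["pair_id"]].to_numpy()
        r_pair = np.array([
            np.corrcoef(ps_emo.patterns[i], ps_init.patterns[order[i]])[0, 1]
            for i in range(ps_emo.n_trials)
        ])
        reins = pd.Series(r_pair, index=ps_emo.meta["pair_id"].values)
        tab = synth.simulate_behavior(state["design_emo"], reins, p_s,
                                      subject=f"sub-{s + 1:03d}")
        tables.append(tab)
        tables[-1] = tab.assign(pair_specific_z=float(
            tmz.set_index("condition").loc["aversive", "z"]))
    table = pd.concat(tables, ignore_index=True)
    state["behavior"] = table

    binned = behav.bin_accuracy(table, bin_on="confidence")
    high = binned[binned["bin"] == "high"].pivot(index="subject",
                                                 columns="condition",
                                                 values="accuracy").dropna()
    test = behav.paired_t_dav(high["aversive"], high["neutral"],
                              label="high-confidence accuracy aversive vs neutral")
    p1 = _write_tsv(table, out / "behavior_trials.tsv")
    p2 = _write_tsv(binned, out / "behavior_binned.tsv")
    return {
        "seed": seed,
        "summary": {
            "chance_level_pct": 100 * behav.chance_level(4),
            "paired_t": test.statistic,
            "p": test.p,
            "d_av": test.effect_size,
        },
        "files": [{"path": p1.name}, {"path": p2.name}],
    }


def _subject_level(config: RunConfig, state: dict) -> pd.DataFrame:
    """Per-subject reinstatement and high-confidence memory summaries."""
    table = state["behavior"]
    rows = []
    for subject, sub in table.groupby("subject"):
        hi = sub[sub["confidence"] >= 3]
        rows.append({
            "subject": subject,
            "reinstatement": sub["pair_specific_z"].iloc[0],
            "memory_high_conf": hi["chosen_correct"].mean() if len(hi) else np.nan,
            "memory_aversive": sub.loc[sub["condition"] == "aversive",
                                       "chosen_correct"].mean(),
            "memory_neutral": sub.loc[sub["condition"] == "neutral",
                                      "chosen_correct"].mean(),
        })
    return pd.DataFrame(rows).dropna()


def _stage_predict(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("predict")
    subj = _subject_level(config, state)
    state["subject_level"] = subj
    res = predict.permutation_p(subj["reinstatement"], subj["memory_aversive"],
                                k=config.k, n_perm=config.n_perm, seed=seed)
    p = _write_tsv(subj, out / "subject_level.tsv")
    return {
        "seed": seed,
        "summary": {"r_pred_obs": res.r, "p_perm": res.p, "n_perm": res.n_perm},
        "files": [{"path": p.name}],
    }


def _stage_connectivity(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("connectivity")
    params = state["params"].replace(seed=seed)
    bundle = synth.simulate_timeseries({"emo": state["design_emo"]}, params)
    n_vol = bundle.n_volumes["emo"]
    hrf = firstlevel.canonical_hrf(bundle.tr)
    neural = connectivity.deconvolve_neural(bundle.seed_ts["emo"], hrf,
                                            ridge_lambda=1e-2)
    boxes = connectivity.condition_boxcars(state["design_emo"], n_vol, bundle.tr)
    design = connectivity.build_gppi_design(neural, boxes, bundle.seed_ts["emo"],
                                            hrf, nuisance=bundle.confounds["emo"])
    est = connectivity.fit_gppi_contrast(bundle.target_ts["emo"], design)

    rest_params = connectivity.RestPreprocParams(tr=bundle.tr)
    zs = {}
    for run in ("rest1", "rest2", "rest3"):
        s = connectivity.preprocess_rest(bundle.seed_ts[run],
                                         bundle.confounds[run], rest_params)
        t = connectivity.preprocess_rest(bundle.target_ts[run],
                                         bundle.confounds[run], rest_params)
        zs[run] = float(connectivity.seed_connectivity(s, t).iloc[0])
    diff21 = zs["rest2"] - zs["rest1"]
    diff32 = zs["rest3"] - zs["rest2"]

    df = pd.DataFrame([
        {"quantity": "gppi_contrast_aversive_minus_neutral", "value": est.contrast,
         "t": est.t, "p": est.p},
        {"quantity": "rest_z_rest1", "value": zs["rest1"], "t": np.nan, "p": np.nan},
        {"quantity": "rest_z_rest2", "value": zs["rest2"], "t": np.nan, "p": np.nan},
        {"quantity": "rest_z_rest3", "value": zs["rest3"], "t": np.nan, "p": np.nan},
        {"quantity": "rest_diff_2v1", "value": diff21, "t": np.nan, "p": np.nan},
        {"quantity": "rest_diff_3v2", "value": diff32, "t": np.nan, "p": np.nan},
    ])
    p = _write_tsv(df, out / "connectivity.tsv")
    return {
        "seed": seed,
        "summary": {"gppi_contrast": est.contrast, "rest_diff_2v1": diff21,
                    "rest_diff_3v2": diff32},
        "files": [{"path": p.name}],
    }


def _stage_mediation(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("mediation")
    table = synth.simulate_subject_table(
        max(config.n_subjects, 28),
        path_coefficients={"a1": 0.5, "a2": 0.3, "d21": 0.4, "b1": 0.2,
                           "b2": 0.5, "c_prime": 0.2},
        seed=seed,
    )
    model = mediation.fit_paths(table["X"], table["M1"], table["M2"], table["Y"])
    effects = mediation.bootstrap_indirect(table, n_boot=config.n_boot, seed=seed)
    rows = [{"effect": lbl, "estimate": e.estimate, "ci_low": e.ci[0],
             "ci_high": e.ci[1], "excludes_zero": e.excludes_zero}
            for lbl, e in effects.items()]
    p = _write_tsv(pd.DataFrame(rows), out / "mediation.tsv")
    return {
        "seed": seed,
        "summary": {
            "serial_indirect": effects["X->M1->M2->Y"].estimate,
            "serial_ci": list(effects["X->M1->M2->Y"].ci),
            "c_total": model.c,
        },
        "files": [{"path": p.name}],
    }


def write_report(manifest: dict, path: str | Path | None = None) -> str:
    """Render a plain-text run report, one section per stage."""
    lines = [f"remap pipeline report (version {manifest.get('version', '?')})", ""]
    for stage in STAGES:
        lines.append(f"## {stage}")
        info = manifest.get("stages", {}).get(stage)
        if not info:
            lines.append("skipped")
            lines.append("")
            continue
        lines.append(f"seed: {info.get('seed')}  runtime: {info.get('seconds')}s")
        for key, val in info.get("summary", {}).items():
            lines.append(f"  {key}: {val}")
        for f in info.get("files", []):
            lines.append(f"  file: {f['path']} ({f.get('sha256', '')[:12]})")
        lines.append("")
    report = "\n".join(lines)
    if path is not None:
        Path(path).write_text(report)
    return report
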