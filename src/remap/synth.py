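"""Synthetic designs, patterns, time series and behavior.

Emulates a two-phase sensory-preconditioning study: 72 face-object
pairs encoded incidentally (two 12-min runs), then each face re-paired
with an aversive scream or a neutral voice (36/36, one 16.8-min run),
flanked by three 8-min rest scans at TR = 2 s.  The generators plant
the statistical structure the downstream analyses assume — greater
pair-specific reinstatement and stronger seed-target coupling in the
aversive condition, and memory linked to reinstatement through a
logistic model — so every analysis stage can be exercised and its
recovery properties tested without any imaging data.

Generative model for trial patterns (per pair ``p`` in condition ``c``):

    init(p) = f_p + o_p           + gamma * g_c + noise
    emo(p)  = f_p + rho_c * o_p   + gamma * g_c + noise

where ``f_p`` (face) and ``o_p`` (object) are pair-unique unit-norm
voxel vectors, ``g_c`` a condition-shared vector and the noise i.i.d.
Normal(0, sigma_noise^2) per voxel.  ``rho_c`` is the reinstatement
gain: the fraction of the initial object representation re-expressed
when the face cue reappears during emotional learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .firstlevel import canonical_hrf
from .similarity import PatternSet

__all__ = [
    "SimParams",
    "TrialDesign",
    "TimeSeriesBundle",
    "generate_condition_sequence",
    "generate_design",
    "simulate_pattern_sets",
    "simulate_behavior",
    "simulate_timeseries",
    "simulate_subject_table",
    "write_events_tsv",
]

CONDITIONS = ("aversive", "neutral")

#: per-phase stimulus timing (event kinds with on-screen durations, s)
PHASE_EVENTS = {
    "initial": (("pair", 4.0), ("rating", 2.0)),
    "emotional": (("cue", 2.0), ("face_voice", 2.0), ("rating", 2.0)),
}
#: jittered inter-trial intervals, counterbalanced to their exact mean
PHASE_ITIS = {"initial": (2.0, 4.0, 6.0), "emotional": (6.0, 8.0, 10.0)}


@dataclass(frozen=True)
class SimParams:
    """Free parameters of the synthetic study.

    Defaults encode the emulated design (72 pairs, 36 aversive) and a
    moderate-signal regime: aversive reinstatement gain above neutral,
    aversive seed-target coupling above neutral, and a positive
    logistic link from reinstatement to memory.
    """

    n_pairs: int = 72
    n_aversive: int = 36
    n_voxels: int = 100
    rho_aversive: float = 0.6
    rho_neutral: float = 0.2
    gamma: float = 0.3
    sigma_noise: float = 0.2
    coupling_aversive: float = 0.8
    coupling_neutral: float = 0.3
    beta0: float = -1.0
    beta1: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aversive > self.n_pairs:
            raise ValueError("n_aversive cannot exceed n_pairs")
        for name in ("rho_aversive", "rho_neutral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_noise < 0 or self.gamma < 0:
            raise ValueError("sigma_noise and gamma must be non-negative")
        for name in ("gamma", "sigma_noise", "coupling_aversive",
                     "coupling_neutral", "beta0", "beta1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)

    def rho(self, condition: str) -> float:
        return self.rho_aversive if condition == "aversive" else self.rho_neutral

    def coupling(self, condition: str) -> float:
        return self.coupling_aversive if condition == "aversive" else self.coupling_neutral


@dataclass
class TrialDesign:
    """Ordered trial events of one run."""

    events: pd.DataFrame  # onset, duration, event_kind, condition, pair_id
    tr: float
    phase: str
    total_duration: float

    @property
    def n_trials(self) -> int:
        return self.events["pair_id"].nunique() if len(self.events) else 0

    def trials(self) -> pd.DataFrame:
        """One row per trial: the association stimulus event."""
        kind = "pair" if self.phase == "initial" else "face_voice"
        return self.events[self.events["event_kind"] == kind].reset_index(drop=True)

    def pair_conditions(self) -> dict:
        t = self.trials()
        return dict(zip(t["pair_id"], t["condition"]))


@lru_cache(maxsize=None)
def _seq_feasible(rem_a: int, rem_b: int, last: int, run: int, max_run: int) -> bool:
    """Exact feasibility of completing a two-label sequence under a run cap.

    ``last`` is 0/1 for the label of the trailing run (or -1 at start),
    ``run`` its current length.  Memoized recursion over the small
    state space.
    """
    if rem_a == 0 and rem_b == 0:
        return True
    for lab, rem in ((0, rem_a), (1, rem_b)):
        if rem == 0:
            continue
        if lab == last and run >= max_run:
            continue
        nxt_run = run + 1 if lab == last else 1
        nrem = (rem_a - 1, rem_b) if lab == 0 else (rem_a, rem_b - 1)
        if _seq_feasible(nrem[0], nrem[1], lab, nxt_run, max_run):
            return True
    return False


def generate_condition_sequence(
    n_trials: int,
    n_per_condition: int,
    max_run_len: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-random condition sequence with a same-condition run cap.

    Exactly ``n_per_condition`` trials per condition (two conditions),
    never more than ``max_run_len`` consecutive trials of the same
    condition.  Labels are drawn sequentially with probability
    proportional to the remaining counts, restricted to choices from
    which a valid completion provably exists; deterministic given
    ``seed``.
    """
    if n_per_condition * 2 != n_trials:
        raise ValueError("n_per_condition must be exactly half of n_trials")
    if max_run_len < 1:
        raise ValueError("max_run_len must be >= 1")
    if n_trials == 0:
        return np.array([], dtype=object)
    if not _seq_feasible(n_per_condition, n_per_condition, -1, 0, max_run_len):
        raise ValueError(
            f"no sequence of {n_per_condition}+{n_per_condition} trials satisfies "
            f"max_run_len={max_run_len}"
        )
    rng = np.random.default_rng(seed)
    rem = [n_per_condition, n_per_condition]
    last, run = -1, 0
    out = []
    for _ in range(n_trials):
        allowed = []
        for lab in (0, 1):
            if rem[lab] == 0 or (lab == last and run >= max_run_len):
                continue
            nrem = list(rem)
            nrem[lab] -= 1
            if _seq_feasible(nrem[0], nrem[1], lab, run + 1 if lab == last else 1,
                             max_run_len):
                allowed.append(lab)
        p = np.array([rem[lab] for lab in allowed], float)
        lab = int(rng.choice(allowed, p=p / p.sum()))
        out.append(lab)
        run = run + 1 if lab == last else 1
        last = lab
        rem[lab] -= 1
    return np.array([CONDITIONS[lab] for lab in out], dtype=object)


def _counterbalanced_itis(values, n: int, rng) -> np.ndarray:
    """Equal counts of each jitter value, shuffled: realized mean is exact."""
    if n % len(values) != 0:
        raise ValueError(
            f"n_trials must be divisible by {len(values)} to counterbalance the "
            f"ITI jitters {values}; pad or trim the trial count"
        )
    itis = np.repeat(values, n // len(values)).astype(float)
    rng.shuffle(itis)
    return itis


def generate_design(
    phase: str,
    n_trials: int = 72,
    seed: int = 0,
    pair_conditions: dict | None = None,
    max_run_len: int = 2,
    tr: float = 2.0,
) -> TrialDesign:
    """Generate one run of the initial- or emotional-learning task.

    Initial learning: 4 s face-object pair + 2 s vividness rating, ITIs
    counterbalanced over {2, 4, 6} s (mean exactly 4 s) — 10 s per
    trial, 720 s for 72 trials.  Emotional learning: 2 s face cue +
    2 s face-voice association + 2 s rating, ITIs over {6, 8, 10} s
    (mean exactly 8 s) — 14 s per trial, 1008 s for 72 trials.

    ``pair_conditions`` fixes the pair-to-condition assignment (so the
    two phases stay consistent); otherwise the first half of pair ids
    is aversive.
    """
    if phase not in PHASE_EVENTS:
        raise ValueError(f"phase must be 'initial' or 'emotional', got {phase!r}")
    cols = ["onset", "duration", "event_kind", "condition", "pair_id"]
    if n_trials == 0:
        return TrialDesign(pd.DataFrame(columns=cols), tr, phase, 0.0)
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even (two equal-size conditions)")
    rng = np.random.default_rng(seed)
    seq = generate_condition_sequence(n_trials, n_trials // 2, max_run_len,
                                      seed=int(rng.integers(2**31)))
    itis = _counterbalanced_itis(PHASE_ITIS[phase], n_trials, rng)

    if pair_conditions is None:
        pair_conditions = {
            pid: ("aversive" if pid < n_trials // 2 else "neutral")
            for pid in range(n_trials)
        }
    by_cond = {c: [p for p, pc in pair_conditions.items() if pc == c] for c in CONDITIONS}
    for c in CONDITIONS:
        if len(by_cond[c]) != n_trials // 2:
            raise ValueError("pair_conditions must give equal condition counts")
        rng.shuffle(by_cond[c])

    rows, t = [], 0.0
    for i, cond in enumerate(seq):
        pid = by_cond[cond].pop()
        for kind, dur in PHASE_EVENTS[phase]:
            rows.append((t, dur, kind, cond, pid))
            t += dur
        t += itis[i]
    return TrialDesign(pd.DataFrame(rows, columns=cols), tr, phase, t)


def simulate_pattern_sets(
    design_init: TrialDesign,
    design_emo: TrialDesign,
    params: SimParams,
    roi: str = "roi",
) -> tuple[PatternSet, PatternSet]:
    """Trial t-patterns for both phases under the reinstatement model."""
    if params.n_voxels < 2:
        raise ValueError("n_voxels must be >= 2 for correlations to exist")
    pc_i = design_init.pair_conditions()
    pc_e = design_emo.pair_conditions()
    if set(pc_i) != set(pc_e):
        raise ValueError("designs must share pair ids")
    rng = np.random.default_rng(params.seed)
    nv = params.n_voxels

    def unit(v):
        return v / np.linalg.norm(v)

    g = {c: unit(rng.standard_normal(nv)) for c in CONDITIONS}
    comps = {p: (unit(rng.standard_normal(nv)), unit(rng.standard_normal(nv)))
             for p in sorted(pc_i)}

    def build(design: TrialDesign, emo: bool) -> PatternSet:
        trials = design.trials()
        pats = np.empty((len(trials), nv))
        for i, row in trials.iterrows():
            f_p, o_p = comps[row["pair_id"]]
            w = params.rho(row["condition"]) if emo else 1.0
            pats[i] = (f_p + w * o_p + params.gamma * g[row["condition"]]
                       + params.sigma_noise * rng.standard_normal(nv))
        meta = trials[["pair_id", "condition"]].copy()
        return PatternSet(pats, meta, roi=roi, phase=design.phase)

    return build(design_init, emo=False), build(design_emo, emo=True)


def simulate_behavior(
    design: TrialDesign,
    reinstatement_per_pair: pd.Series | dict,
    params: SimParams,
    subject: str = "sub-01",
    rating_link: float = 0.5,
) -> pd.DataFrame:
    """Behavioral table linked to reinstatement.

    Memory: P(correct) = logistic(beta0 + beta1 * reinstatement).
    Ratings: a latent standard normal correlated ``rating_link`` with
    the (standardized) reinstatement value is cut at equally spaced
    thresholds (-1, 0, 1) into the 1-4 scale.
    """
    reins = pd.Series(reinstatement_per_pair, dtype=float)
    trials = design.trials()
    missing = set(trials["pair_id"]) - set(reins.index)
    if missing:
        raise ValueError(f"missing reinstatement values for pairs {sorted(missing)}")
    rng = np.random.default_rng(params.seed)
    r = reins.loc[trials["pair_id"]].to_numpy()
    p_correct = expit(params.beta0 + params.beta1 * r)
    correct = rng.random(len(r)) < p_correct
    rz = (r - r.mean()) / r.std() if r.std() > 0 else np.zeros_like(r)

    def ratings():
        latent = rating_link * rz + np.sqrt(1 - rating_link**2) * rng.standard_normal(len(r))
        return np.digitize(latent, (-1.0, 0.0, 1.0)) + 1

    return pd.DataFrame({
        "subject": subject,
        "pair_id": trials["pair_id"].to_numpy(),
        "condition": trials["condition"].to_numpy(),
        "vividness": ratings(),
        "confidence": ratings(),
        "chosen_correct": correct,
    })


@dataclass
class TimeSeriesBundle:
    """Seed/target/confound series per run, all sampled at the TR."""

    seed_ts: dict = field(default_factory=dict)
    target_ts: dict = field(default_factory=dict)
    confounds: dict = field(default_factory=dict)
    n_volumes: dict = field(default_factory=dict)
    tr: float = 2.0

    def runs(self) -> list[str]:
        return list(self.seed_ts)


def _confound_frame(n: int, tr: float, rng) -> pd.DataFrame:
    """Six motion + CSF + WM nuisance series: slow drifts plus white noise."""
    t = np.arange(n) * tr
    cols = {}
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "csf", "wm"]
    for name in names:
        period = rng.uniform(60.0, 240.0)
        phase = rng.uniform(0, 2 * np.pi)
        cols[name] = (rng.uniform(0.2, 1.0) * np.cos(2 * np.pi * t / period + phase)
                      + 0.1 * rng.standard_normal(n))
    return pd.DataFrame(cols)


def _task_run(design: TrialDesign, params: SimParams, rng, extra_volumes: int = 5):
    """Seed/target series for one task run under the coupling model.

    The seed reflects HRF-convolved stimulus-driven neural activity;
    the target adds, on top of a baseline dependence on the seed,
    condition-specific coupling restricted to condition epochs — the
    ground truth a gPPI analysis should recover.
    """
    tr = design.tr
    n_vol = int(np.ceil(design.total_duration / tr)) + extra_volumes
    hrf = canonical_hrf(tr)
    t = np.arange(n_vol) * tr

    trials = design.trials()
    box = {c: np.zeros(n_vol) for c in CONDITIONS}
    for _, row in trials.iterrows():
        on = row["onset"]
        box[row["condition"]][(t >= on) & (t < on + 2.0)] = 1.0
    box_all = box["aversive"] + box["neutral"]

    # spontaneous neural fluctuations (unit SD) make condition-specific
    # coupling identifiable over and above the task regressors
    neural = box_all + rng.standard_normal(n_vol)
    kernel = hrf.tr_kernel()

    def conv(x):
        return np.convolve(x, kernel)[:n_vol]

    seed = conv(neural) + params.sigma_noise * rng.standard_normal(n_vol)
    target = 0.3 * seed + params.sigma_noise * rng.standard_normal(n_vol)
    for c in CONDITIONS:
        target = target + params.coupling(c) * conv(neural * box[c])
    return seed, target, n_vol


def _rest_run(n_vol: int, r: float, rng):
    """A seed/target pair with population correlation ``r``."""
    if n_vol < 0:
        raise ValueError("n_volumes must be non-negative")
    a = rng.standard_normal(n_vol)
    b = r * a + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n_vol)
    return a, b


def simulate_timeseries(
    designs: dict,
    params: SimParams,
    rest_corr: tuple[float, float, float] = (0.3, 0.5, 0.6),
    n_rest_volumes: int = 240,
    tr: float = 2.0,
) -> TimeSeriesBundle:
    """Seed/target/confound series for task and rest runs.

    ``designs`` maps task run labels (``init1``, ``init2``, ``emo``) to
    TrialDesigns; three rest runs of ``n_rest_volumes`` volumes are
    appended with the requested seed-target correlations (defaults
    emulate a post-encoding increase in coupling).
    """
    rng = np.random.default_rng(params.seed)
    bundle = TimeSeriesBundle(tr=tr)
    for run, design in designs.items():
        seed, target, n_vol = _task_run(design, params, rng)
        bundle.seed_ts[run] = seed
        bundle.target_ts[run] = target
        bundle.confounds[run] = _confound_frame(n_vol, tr, rng)
        bundle.n_volumes[run] = n_vol
    for i, r in enumerate(rest_corr, start=1):
        run = f"rest{i}"
        seed, target = _rest_run(n_rest_volumes, r, rng)
        bundle.seed_ts[run] = seed
        bundle.target_ts[run] = target
        bundle.confounds[run] = _confound_frame(n_rest_volumes, tr, rng)
        bundle.n_volumes[run] = n_rest_volumes
    return bundle


def simulate_subject_table(
    n_subjects: int,
    path_coefficients: dict | None = None,
    noise: float = 1.0,
    seed: int = 0,
    standardize: bool = False,
) -> pd.DataFrame:
    """Subject-level table under a serial two-mediator path model.

        X ~ N(0,1);  M1 = a1 X + e;  M2 = a2 X + d21 M1 + e;
        Y = c' X + b1 M1 + b2 M2 + e

    with independent Normal(0, noise^2) disturbances.  Coefficients
    default to 0; pass e.g. ``{"a1": 0.5, "d21": 0.4, "b2": 0.5}``.
    """
    c = {k: 0.0 for k in ("a1", "a2", "d21", "b1", "b2", "c_prime")}
    if path_coefficients:
        unknown = set(path_coefficients) - set(c)
        if unknown:
            raise ValueError(f"unknown path coefficients: {sorted(unknown)}")
        c.update(path_coefficients)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal(n_subjects)
    M1 = c["a1"] * X + noise * rng.standard_normal(n_subjects)
    M2 = c["a2"] * X + c["d21"] * M1 + noise * rng.standard_normal(n_subjects)
    Y = (c["c_prime"] * X + c["b1"] * M1 + c["b2"] * M2
         + noise * rng.standard_normal(n_subjects))
    df = pd.DataFrame({
        "subject": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
        "X": X, "M1": M1, "M2": M2, "Y": Y,
    })
    if standardize:
        for col in ("X", "M1", "M2", "Y"):
            df[col] = (df[col] - df[col].mean()) / df[col].std(ddof=0)
    return df


def write_events_tsv(design: TrialDesign, path: str | Path) -> Path:
    """Write a BIDS-style events.tsv plus a JSON sidecar recording the TR."""
    path = Path(path)
    ev = design.events.rename(columns={"event_kind": "trial_type"})
    ev.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "RepetitionTime": design.tr,
        "phase": design.phase,
        "total_duration": design.total_duration,
    }, indent=2))
    return path
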