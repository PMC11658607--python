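"""Forward simulator of dyadic multimodal interaction.

Generates dyad records with a known ground-truth coupling mechanism so every
analysis stage can be verified without real recordings.  The mechanism encodes
speaker-led attention: conversational turns alternate between a trained and an
untrained member with unequal speaking share; whoever currently speaks drives
a semi-Markov gaze walk over the task items (geometric dwell, occasional
off-item excursions); the listener re-fixates the speaker's items after a
fixed follow lag, with a per-transition fidelity below one (otherwise
exploring an item of their own); and pointing happens only during one's own
turns, at the item one's own gaze reached a short lead time earlier, with
per-role pointing-time budgets.

All randomness flows from ``(seed, dyad_seed)`` via numpy's SeedSequence, so
cohorts are reproducible sample-for-sample.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .events import ACTORS, DyadRecord
from .series import OFF_CODE, CategoricalSeries


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


def default_item_labels(n_items: int) -> tuple[str, ...]:
    if n_items <= 26:
        return tuple(chr(ord("A") + k) for k in range(n_items))
    return tuple(f"I{k + 1}" for k in range(n_items))


@dataclass
class SyntheticConfig:
    """Parameters of the dyad generator.

    Defaults emulate the study conditions this pipeline is built for: nine
    task items sampled at 10 Hz, ~5 min 14 s conversations, 18 dyads, a 59%
    trained speaking share, 12% vs 4% pointing-time shares, a 0.5 s listener
    follow lag, and one's own gaze leading one's own pointing by 0.2 s.
    """

    n_items: int = 9
    rate_hz: float = 10.0
    duration_s: float = 314.0
    n_dyads: int = 18
    speaking_share_trained: float = 0.59
    mean_turn_s: float = 8.0
    turn_sigma: float = 0.6          # log-normal shape of turn durations
    item_dwell_mean_s: float = 2.5
    off_prob: float = 0.1
    follow_fidelity: float = 0.8
    follow_lag_s: float = 0.5
    point_frac_trained: float = 0.12
    point_frac_untrained: float = 0.04
    own_gaze_lead_s: float = 0.2
    point_onset_window_s: float = 2.0   # pointing launches within this window
    point_dur_mean_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        rho = self.speaking_share_trained
        if not 0 < rho < 1:
            raise ConfigurationError("speaking_share_trained must be in (0, 1)")
        for name in ("off_prob", "follow_fidelity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("follow_lag_s", "own_gaze_lead_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if min(self.n_items, self.rate_hz, self.duration_s, self.n_dyads,
               self.mean_turn_s, self.item_dwell_mean_s, self.point_dur_mean_s) <= 0:
            raise ConfigurationError("sizes, rates and mean durations must be positive")
        shares = {"trained": rho, "untrained": 1 - rho}
        for actor in ACTORS:
            frac = getattr(self, f"point_frac_{actor}")
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"point_frac_{actor} must be in [0, 1]")
            if frac >= shares[actor]:
                raise ConfigurationError(
                    f"point_frac_{actor} = {frac} exceeds the {actor} speaking "
                    f"share {shares[actor]:.2f}: pointing happens only while speaking")

    @property
    def items(self) -> tuple[str, ...]:
        return default_item_labels(self.n_items)

    @property
    def n_samples(self) -> int:
        return int(math.ceil(self.duration_s * self.rate_hz - 1e-9))


def _turn_track(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample speaker index (0 = trained, 1 = untrained)."""
    n = cfg.n_samples
    rho = cfg.speaking_share_trained
    # role-specific mean durations so the expected trained share equals rho
    means = {0: 2 * rho * cfg.mean_turn_s, 1: 2 * (1 - rho) * cfg.mean_turn_s}
    sigma = cfg.turn_sigma
    speaker = int(rng.integers(2))
    out = np.empty(n, dtype=np.int8)
    k = 0
    while k < n:
        mu = math.log(means[speaker]) - sigma**2 / 2
        dur = max(1, int(round(rng.lognormal(mu, sigma) * cfg.rate_hz)))
        out[k:k + dur] = speaker
        k += dur
        speaker = 1 - speaker
    return out


def _leader_walk(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Semi-Markov item walk as (segment codes, segment lengths) covering n samples."""
    p_leave = 1.0 / (cfg.item_dwell_mean_s * cfg.rate_hz)
    labels, lens = [], []
    prev = -1
    total = 0
    while total < n:
        if rng.random() < cfg.off_prob:
            code = OFF_CODE
        else:
            code = int(rng.integers(cfg.n_items))
            while cfg.n_items > 1 and code == prev:
                code = int(rng.integers(cfg.n_items))
            prev = code
        dur = int(rng.geometric(p_leave))
        labels.append(code)
        lens.append(dur)
        total += dur
    lens[-1] -= total - n
    return np.array(labels, dtype=np.int64), np.array(lens, dtype=np.int64)


def _follower_stream(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    seg_codes: np.ndarray,
    seg_lens: np.ndarray,
    n: int,
) -> np.ndarray:
    """Delayed, imperfect copy of the leader walk (per-sample codes)."""
    codes = seg_codes.copy()
    infidel = rng.random(len(codes)) >= cfg.follow_fidelity
    explore = rng.integers(cfg.n_items, size=len(codes))
    codes[infidel] = explore[infidel]
    per_sample = np.repeat(codes, seg_lens)[:n]
    lag = int(round(cfg.follow_lag_s * cfg.rate_hz))
    out = np.full(n, OFF_CODE, dtype=np.int64)
    if lag < n:
        out[lag:] = per_sample[: n - lag] if lag else per_sample
    return out


def _turn_run_ends(turn: np.ndarray) -> np.ndarray:
    """For each sample, the exclusive end index of its current turn run."""
    n = len(turn)
    ends = np.empty(n, dtype=np.int64)
    end = n
    for k in range(n - 1, -1, -1):
        if k < n - 1 and turn[k] != turn[k + 1]:
            end = k + 1
        ends[k] = end
    return ends


def _pointing_track(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    gaze: np.ndarray,
    turn: np.ndarray,
    speaker_idx: int,
    target_frac: float,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Pointing codes for one role: epochs during own turns at one's gazed item.

    Candidate epochs start at a uniformly random moment within
    ``point_onset_window_s`` of settling on an item, but no earlier than
    ``own_gaze_lead_s`` after the gaze run's onset: own gaze reaches the
    target before the point starts, yet the gesture is launched early enough
    in the dwell that the partner's (gaze-following) attention still arrives
    after it.  Candidates are accepted in random order until the configured
    pointing-time budget is met, then clipped to the own turn and de-overlapped.
    """
    n = len(gaze)
    out = np.full(n, OFF_CODE, dtype=np.int64)
    target = int(round(target_frac * n))
    if target == 0:
        return out, []
    lead = int(round(cfg.own_gaze_lead_s * cfg.rate_hz))
    own = turn == speaker_idx
    run_key = np.where(own & (gaze >= 0), gaze, -1)
    boundaries = np.flatnonzero(np.diff(run_key) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [n]))
    turn_ends = _turn_run_ends(turn)
    candidates = []  # (onset, max_len, item)
    for s, e in zip(starts, stops):
        if run_key[s] < 0 or e - s <= lead:
            continue
        hi = min(e, s + lead + max(1, int(round(cfg.point_onset_window_s * cfg.rate_hz))))
        onset = int(rng.integers(s + lead, hi))
        candidates.append((onset, int(turn_ends[onset] - onset), int(run_key[s])))
    if not candidates:
        return out, []
    order = rng.permutation(len(candidates))
    mean_len = cfg.point_dur_mean_s * cfg.rate_hz

    def realized(epochs: list) -> int:
        total = 0
        for k, (onset, dur, _) in enumerate(epochs):
            stop = onset + dur
            if k + 1 < len(epochs):
                stop = min(stop, epochs[k + 1][0])
            total += stop - onset
        return total

    chosen = []
    for idx in order:
        onset, max_len, item = candidates[idx]
        dur = min(int(rng.geometric(1.0 / mean_len)), max_len)
        if dur <= 0:
            continue
        chosen.append((onset, dur, item))
        chosen.sort()
        if realized(chosen) >= target:
            break
    epochs = []
    for k, (onset, dur, item) in enumerate(chosen):
        stop = onset + dur
        if k + 1 < len(chosen):
            stop = min(stop, chosen[k + 1][0])
        if stop > onset:
            out[onset:stop] = item
            epochs.append((onset, stop, item))
    return out, epochs


def generate_dyad(cfg: SyntheticConfig, dyad_seed: int) -> DyadRecord:
    """Simulate one dyad, deterministic under ``(cfg.seed, dyad_seed)``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(dyad_seed)]))
    n = cfg.n_samples
    items = cfg.items

    turn = _turn_track(cfg, rng)
    seg_codes, seg_lens = _leader_walk(cfg, rng, n)
    leader = np.repeat(seg_codes, seg_lens)[:n]
    followers = {
        actor: _follower_stream(cfg, rng, seg_codes, seg_lens, n) for actor in ACTORS
    }
    gaze = {}
    for idx, actor in enumerate(ACTORS):
        gaze[actor] = np.where(turn == idx, leader, followers[actor])
    point = {}
    epochs = {}
    for idx, actor in enumerate(ACTORS):
        point[actor], epochs[actor] = _pointing_track(
            cfg, rng, gaze[actor], turn, idx, getattr(cfg, f"point_frac_{actor}"))
    # the partner's gaze responds to pointing: one follow lag after a pointing
    # epoch starts, the partner re-fixates the pointed item (same fidelity as
    # gaze following), for the duration of the epoch
    lag = int(round(cfg.follow_lag_s * cfg.rate_hz))
    for idx, actor in enumerate(ACTORS):
        partner = ACTORS[1 - idx]
        for onset, stop, item in epochs[actor]:
            if rng.random() < cfg.follow_fidelity and onset + lag < n:
                gaze[partner][onset + lag:min(stop + lag, n)] = item

    def series(codes: np.ndarray, name: str) -> CategoricalSeries:
        return CategoricalSeries.from_codes(codes, labels=items, rate_hz=cfg.rate_hz, name=name)

    turn_vals = np.where(turn == 0, ACTORS[0], ACTORS[1]).astype(object)
    return DyadRecord(
        dyad_id=f"sim{int(dyad_seed):03d}",
        gaze_trained=series(gaze["trained"], "gaze_trained"),
        gaze_untrained=series(gaze["untrained"], "gaze_untrained"),
        point_trained=series(point["trained"], "point_trained"),
        point_untrained=series(point["untrained"], "point_untrained"),
        turn=CategoricalSeries(turn_vals, labels=ACTORS, rate_hz=cfg.rate_hz, name="turn"),
    )


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[DyadRecord], dict]:
    """Simulate ``cfg.n_dyads`` dyads with per-dyad derived seeds, plus a manifest."""
    records = [generate_dyad(cfg, k) for k in range(cfg.n_dyads)]
    manifest = {
        "generator": "dyadcrqa.simulate",
        "config": asdict(cfg),
        "dyad_seeds": list(range(cfg.n_dyads)),
        "dyad_ids": [r.dyad_id for r in records],
    }
    return records, manifest
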