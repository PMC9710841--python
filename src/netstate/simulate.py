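"""Synthetic badge-and-EMA cohort generator with planted ground truth.

The generator emulates the structure of a six-week workplace sensing
study: 54 employees in a handful of project-team communities wear
badges Monday-Friday (directed detection records with per-direction
detector dropout, which creates realistic reciprocity discrepancies for
the min-count reconciliation to resolve) and answer EMA prompts three
times a day at fixed clock times, scoring five personality states on a
1-7 Likert grid in half-point steps.

The planted signal works through the network: for each participant,
week and trait, the true response volatility is

    sigma_true = baseline_sigma + coefficient * z(driver feature)

where the driver (ego-network efficiency by default) is standardized
within week across participants and sigma is floored at a small
positive value.  Responses follow a first-order latent walk — each
response perturbs the previous one by N(0, sigma_true) — so sigma_true
maps monotonically onto the expected weekly RMSSD that the pipeline
measures.  Isolated participants (no reconciled edges that week) fall
back to baseline volatility; they still answer prompts, which is what
makes some person-week feature rows missing downstream, as in real
badge deposits.

All randomness flows from one root seed through named substreams
(contacts, detector dropout, trait means, EMA innovations), so any week
or module can be regenerated independently and full cohorts are
byte-identical per (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from .io import TRAITS, WorkWeek, work_weeks
from .networks import build_weekly_network

_STREAM_CONTACTS = 1000
_STREAM_DROPOUT = 2000
_STREAM_EMA = 3000
_STREAM_MEANS = 3


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Contact rates are expected true face-to-face contacts per unordered
    pair per workday; ``detector_dropout`` is the probability that one
    side's badge misses a given contact.  ``coefficient`` and
    ``baseline_sigma`` may be per-trait mappings; scalars apply to all
    five traits.
    """

    n_participants: int = 54
    n_weeks: int = 6
    start_monday: date = date(2012, 1, 30)
    block_sizes: tuple[int, ...] = (14, 14, 13, 13)
    within_rate: float = 1.2
    between_rate: float = 0.15
    detector_dropout: float = 0.15
    ema_hours: tuple[int, ...] = (11, 14, 17)
    trait_mean_loc: float = 4.5
    trait_mean_scale: float = 0.8
    driver: str = "efficiency"
    coefficient: float | Mapping[str, float] = 0.5
    baseline_sigma: float | Mapping[str, float] = 0.3
    sigma_floor: float = 0.05
    response_noise: float = 0.1
    seed: int = 2012

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_participants:
            raise ValueError("block sizes must sum to n_participants")
        if not 0.0 <= self.detector_dropout <= 1.0:
            raise ValueError("detector_dropout must be in [0, 1]")
        if min(self.within_rate, self.between_rate) < 0:
            raise ValueError("contact rates must be non-negative")

    def trait_coefficient(self, trait: str) -> float:
        c = self.coefficient
        return float(c[trait]) if isinstance(c, Mapping) else float(c)

    def trait_baseline(self, trait: str) -> float:
        b = self.baseline_sigma
        return float(b[trait]) if isinstance(b, Mapping) else float(b)


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """The same cohort with the network-volatility link switched off."""
    return replace(config or SimConfig(), coefficient=0.0, **overrides)


def participant_ids(config: SimConfig) -> list[int]:
    """Badge-style integer ids 501, 502, ..."""
    return [501 + i for i in range(config.n_participants)]


def _blocks(config: SimConfig) -> np.ndarray:
    labels = np.repeat(np.arange(len(config.block_sizes)), config.block_sizes)
    return labels


def simulate_interactions(config: SimConfig, week: WorkWeek) -> pd.DataFrame:
    """Directed detection records for one work week.

    Per pair and workday, true contacts are Poisson at the block-model
    rate; each true contact yields a record from each side's detector
    independently with probability 1 − dropout.  Timestamps are uniform
    over 09:00-17:59 at minute resolution.
    """
    ids = np.array(participant_ids(config))
    blocks = _blocks(config)
    n = len(ids)
    same = blocks[:, None] == blocks[None, :]
    rates = np.where(same, config.within_rate, config.between_rate)

    rng_c = np.random.default_rng([config.seed, _STREAM_CONTACTS + week.index])
    rng_d = np.random.default_rng([config.seed, _STREAM_DROPOUT + week.index])
    iu, ju = np.triu_indices(n, k=1)
    frames = []
    for day in range(5):
        day_start = pd.Timestamp(week.start_date + timedelta(days=day, hours=9))
        counts = rng_c.poisson(rates[iu, ju])
        a = np.repeat(ids[iu], counts)
        b = np.repeat(ids[ju], counts)
        m = a.size
        minutes = rng_c.integers(0, 9 * 60, size=m)  # 09:00-17:59
        ts = day_start + pd.to_timedelta(minutes, unit="m")
        keep_ab = rng_d.random(m) >= config.detector_dropout
        keep_ba = rng_d.random(m) >= config.detector_dropout
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": np.concatenate([ts[keep_ab], ts[keep_ba]]),
                    "logger_id": np.concatenate([a[keep_ab], b[keep_ba]]),
                    "detected_id": np.concatenate([b[keep_ab], a[keep_ba]]),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["timestamp", "logger_id", "detected_id"], kind="stable").reset_index(drop=True)


def _trait_means(config: SimConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, _STREAM_MEANS])
    vals = rng.normal(config.trait_mean_loc, config.trait_mean_scale, size=(config.n_participants, len(TRAITS)))
    vals = np.clip(vals, 2.0, 6.0)
    return pd.DataFrame(vals, index=participant_ids(config), columns=list(TRAITS))


# Drivers computable per ego without whole-network path enumeration;
# other driver names fall back to the full feature extractor.
_FAST_DRIVERS = {
    "efficiency": lambda net, ego, en: feat.ego_efficiency(en, ego),
    "effective_size": lambda net, ego, en: feat.effective_size(en, ego),
    "constraint": lambda net, ego, en: feat.burt_constraint(en, ego),
    "avg_dyadic_redundancy": lambda net, ego, en: feat.avg_dyadic_redundancy(en, ego),
    "avg_similarity": lambda net, ego, en: feat.avg_similarity(net, ego),
    "reach_efficiency": lambda net, ego, en: feat.reach_efficiency(net, ego, en),
    "size_ego": lambda net, ego, en: float(en.number_of_edges()),
    "degree_centrality": lambda net, ego, en: net.degree(ego) / (net.number_of_nodes() - 1),
}


def _driver_values(config: SimConfig, net) -> tuple[dict[int, float], dict[int, float]]:
    """Raw and within-week standardized driver feature per network node."""
    if net.number_of_nodes() == 0:
        return {}, {}
    fast = _FAST_DRIVERS.get(config.driver)
    if fast is not None:
        from .networks import extract_ego_network

        vals = pd.Series(
            {v: fast(net, v, extract_ego_network(net, v)) for v in net.nodes}, dtype=float
        )
    else:
        rows = feat.weekly_feature_rows(net, net.graph.get("week_index") or 0)
        vals = rows.set_index("participant_id")[config.driver].astype(float)
    raw = dict(vals.items())
    sd = float(vals.std(ddof=0))
    if not np.isfinite(sd) or sd == 0:
        return raw, {pid: 0.0 for pid in vals.index}
    mean = float(vals.mean())
    return raw, {pid: (v - mean) / sd for pid, v in vals.items()}


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 1.0, 7.0)


def simulate_ema(
    config: SimConfig,
    networks: Mapping[int, object],
    week: WorkWeek,
    trait_means: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMA responses and ground truth for one week.

    Returns ``(ema, truth)``: the response log in the canonical EMA
    dialect, and per (participant, week, trait) the true sigma, the raw
    driver value and the planted coefficient.
    """
    if trait_means is None:
        trait_means = _trait_means(config)
    net = networks[week.index]
    raw_driver, z = _driver_values(config, net)

    rng = np.random.default_rng([config.seed, _STREAM_EMA + week.index])
    slots = [
        datetime.combine(week.start_date + timedelta(days=d), datetime.min.time()) + timedelta(hours=h)
        for d in range(5)
        for h in config.ema_hours
    ]
    slots.sort()

    ema_rows, truth_rows = [], []
    for pid in participant_ids(config):
        zi = z.get(pid, 0.0)
        scores = {}
        for trait in TRAITS:
            coef = config.trait_coefficient(trait)
            sigma = max(config.sigma_floor, config.trait_baseline(trait) + coef * zi)
            mean = float(trait_means.loc[pid, trait])
            innov = rng.normal(0.0, sigma, size=len(slots))
            latent = np.clip(mean + np.cumsum(innov), 1.0, 7.0)
            noise = rng.normal(0.0, config.response_noise, size=len(slots))
            scores[trait] = _round_half(latent + noise)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "week": week.index,
                    "trait": trait,
                    "sigma_true": sigma,
                    "driver_value": raw_driver.get(pid, float("nan")),
                    "coefficient": coef,
                }
            )
        for k, ts in enumerate(slots):
            ema_rows.append(
                {"timestamp": ts, "participant_id": pid, **{t: scores[t][k] for t in TRAITS}}
            )
    ema = pd.DataFrame(ema_rows, columns=["timestamp", "participant_id", *TRAITS])
    truth = pd.DataFrame(truth_rows)
    return ema, truth


@dataclass
class SimulatedCohort:
    """Full synthetic dataset in the exact input dialects of the parsers."""

    config: SimConfig
    weeks: list[WorkWeek]
    interactions: pd.DataFrame
    ema: pd.DataFrame
    ground_truth: pd.DataFrame


def simulate_cohort(config: SimConfig | None = None, out_dir: str | Path | None = None) -> SimulatedCohort:
    """Simulate the whole multi-week cohort; optionally write the CSV/YAML
    artifacts (interactions.csv, ema.csv, ground_truth.csv, sim_config.yaml)."""
    config = config or SimConfig()
    weeks = work_weeks(config.start_monday, config.n_weeks)
    trait_means = _trait_means(config)
    inter_frames, ema_frames, truth_frames = [], [], []
    for wk in weeks:
        inter = simulate_interactions(config, wk)
        net = build_weekly_network(inter, week_index=wk.index)
        ema, truth = simulate_ema(config, {wk.index: net}, wk, trait_means)
        inter_frames.append(inter)
        ema_frames.append(ema)
        truth_frames.append(truth)
    cohort = SimulatedCohort(
        config=config,
        weeks=weeks,
        interactions=pd.concat(inter_frames, ignore_index=True),
        ema=pd.concat(ema_frames, ignore_index=True),
        ground_truth=pd.concat(truth_frames, ignore_index=True),
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _fmt_ts(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d %H:%M")
    return out


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.csv",
        "ema": out / "ema.csv",
        "ground_truth": out / "ground_truth.csv",
        "config": out / "sim_config.yaml",
    }
    _fmt_ts(cohort.interactions).to_csv(paths["interactions"], index=False)
    _fmt_ts(cohort.ema).to_csv(paths["ema"], index=False)
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    cfg = asdict(cohort.config)
    cfg["start_monday"] = cohort.config.start_monday.isoformat()
    cfg["block_sizes"] = list(cohort.config.block_sizes)
    cfg["ema_hours"] = list(cohort.config.ema_hours)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
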