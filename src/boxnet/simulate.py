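"""Synthetic nest-box visit-log generator.

Emulates an RFID-monitored barn population of group-living rodents: a few
hundred tagged adults organised into spatially clustered social groups
across four barn sections, each group meeting in its own small cluster of
nest-boxes.  Individuals alternate bouts inside a box (exponential
duration, scaled by an individual sociality trait) with bouts outside, so
dyadic co-occupancy durations carry planted group structure: box choice is
biased towards the home group's box cluster by the ratio of
``within_group_overlap_rate`` to ``between_group_overlap_rate``.

A scripted catastrophe removes a configurable fraction of adults (deaths
plus disappearances, with a configurable per-group bias so losses can
range from mild to near-total in a single group).  Post-event behaviour of
survivors can respond to the loss in two tunable ways, mirroring the
qualitative pattern such events produce:

* low-sociality survivors that lost a large share of their association
  strength add short, weak visits to boxes outside their home cluster
  (many new weak partners, little added strength), at a rate proportional
  to ``response_effect_low_social`` times the individual's loss;
* high-sociality survivors that lost much concentrate their box use onto a
  single favourite box (fewer distinct partners, strength maintained),
  with probability proportional to ``response_effect_high_social`` times
  the loss.

Both effects ramp up across post-event windows.  With both effects at
zero, post-event behaviour of survivors is statistically identical to
their pre-event behaviour — the null scenario used to validate the
permutation machinery downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import DAY_S, WindowSchedule, build_schedule

EVENT_COLUMNS = ["individual_id", "box_id", "section", "entry", "exit"]
ROSTER_COLUMNS = ["individual_id", "sex", "home_group", "home_section",
                  "sociality", "fate"]

# RNG stream tags (SeedSequence spawn keys) so every stochastic stage is
# independently reproducible from the scenario seed alone.
_TAG_ROSTER = 1
_TAG_CATASTROPHE = 2
_TAG_BOUTS = 10_000
_TAG_RESPONSE = 20_000


class ConfigError(ValueError):
    """Raised for an invalid scenario configuration."""


class StateError(RuntimeError):
    """Raised when operations are called out of order."""


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic catastrophe scenario.

    Defaults describe the reference scenario: ~478 tagged adults in 17
    social groups across 4 barn sections of 10 nest-boxes each, 5-day
    observation windows (two before and four after the event, with a 2-day
    excluded gap around the event), and a catastrophe removing about 40%
    of adults (17.8% found dead, 22.4% disappeared).
    """

    n_individuals: int = 478
    n_groups: int = 17
    n_sections: int = 4
    boxes_per_section: int = 10
    window_length_days: float = 5.0
    n_pre_windows: int = 2
    n_post_windows: int = 4
    event_gap_days: float = 2.0
    mortality_fraction: float = 0.178
    disappearance_fraction: float = 0.224
    within_group_overlap_rate: float = 1.0
    between_group_overlap_rate: float = 0.002
    response_effect_low_social: float = 6.0
    response_effect_high_social: float = 6.0
    group_size_dispersion: float = 4.0
    group_loss_bias: float = 1.0
    group_loss_weights: tuple[float, ...] | None = None
    mean_in_box_minutes: float = 30.0
    mean_out_of_box_minutes: float = 240.0
    weak_bout_minutes: float = 5.0
    sociality_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_groups": self.n_groups,
            "n_sections": self.n_sections,
            "boxes_per_section": self.boxes_per_section,
            "n_pre_windows": self.n_pre_windows,
            "n_post_windows": self.n_post_windows,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name in ("mortality_fraction", "disappearance_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1), got {v!r}")
        if self.mortality_fraction + self.disappearance_fraction >= 1.0:
            raise ConfigError("mortality + disappearance fractions must be < 1")
        if self.n_groups > self.n_sections * self.boxes_per_section:
            raise ConfigError("need at least one nest-box per group")
        if self.within_group_overlap_rate < 0 or self.between_group_overlap_rate < 0:
            raise ConfigError("overlap rates must be non-negative")
        if self.within_group_overlap_rate <= 0 and self.between_group_overlap_rate <= 0:
            raise ConfigError("at least one overlap rate must be positive")
        if self.group_loss_weights is not None and len(self.group_loss_weights) != self.n_groups:
            raise ConfigError("group_loss_weights must have one weight per group")
        for name in ("window_length_days", "event_gap_days", "mean_in_box_minutes",
                     "mean_out_of_box_minutes", "weak_bout_minutes",
                     "group_size_dispersion", "group_loss_bias", "sociality_shape"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def schedule(self) -> WindowSchedule:
        return build_schedule(
            n_pre=self.n_pre_windows,
            n_post=self.n_post_windows,
            window_length_days=self.window_length_days,
            event_gap_days=self.event_gap_days,
        )

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        if d["group_loss_weights"] is not None:
            d["group_loss_weights"] = list(d["group_loss_weights"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if d.get("group_loss_weights") is not None:
            d["group_loss_weights"] = tuple(d["group_loss_weights"])
        return cls(**d)


@dataclass(frozen=True)
class Roster:
    """Tagged adults with group/section membership and (after the
    catastrophe) a fate: survivor, dead or disappeared."""

    table: pd.DataFrame
    group_sections: dict[str, int]
    group_boxes: dict[str, tuple[str, ...]]
    catastrophe_applied: bool = False

    @property
    def ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def survivors(self) -> list[str]:
        return list(self.table.loc[self.table["fate"] == "survivor", "individual_id"])

    @property
    def missing(self) -> list[str]:
        """Dead plus disappeared individuals (collectively 'missing')."""
        mask = self.table["fate"].isin(["dead", "disappeared"])
        return list(self.table.loc[mask, "individual_id"])

    def fate_counts(self) -> dict[str, int]:
        return self.table["fate"].value_counts().to_dict()


def _box_id(section: int, j: int) -> str:
    return f"s{section}b{j:02d}"


def _allocate_boxes(config: ScenarioConfig) -> tuple[dict[str, int], dict[str, tuple[str, ...]]]:
    """Assign each group to a section and a disjoint cluster of boxes there.

    Groups are placed round-robin over sections; each section's boxes are
    split as evenly as possible among the groups homed in it.
    """
    groups = [f"g{i:02d}" for i in range(config.n_groups)]
    group_sections: dict[str, int] = {}
    per_section: dict[int, list[str]] = {s: [] for s in range(1, config.n_sections + 1)}
    for i, g in enumerate(groups):
        sec = (i % config.n_sections) + 1
        group_sections[g] = sec
        per_section[sec].append(g)
    group_boxes: dict[str, tuple[str, ...]] = {}
    for sec, gs in per_section.items():
        if not gs:
            continue
        if len(gs) > config.boxes_per_section:
            raise ConfigError("more groups than boxes in a section")
        base, extra = divmod(config.boxes_per_section, len(gs))
        j = 0
        for k, g in enumerate(gs):
            size = base + (1 if k < extra else 0)
            group_boxes[g] = tuple(_box_id(sec, j + m) for m in range(size))
            j += size
    return group_sections, group_boxes


def all_boxes(config: ScenarioConfig) -> list[tuple[str, int]]:
    """All (box_id, section) pairs of the barn."""
    return [
        (_box_id(sec, j), sec)
        for sec in range(1, config.n_sections + 1)
        for j in range(config.boxes_per_section)
    ]


def generate_roster(config: ScenarioConfig) -> Roster:
    """Draw a roster: group memberships, sexes and sociality traits.

    Group sizes are multinomial with Dirichlet-distributed proportions
    (``group_size_dispersion`` is the Dirichlet concentration: smaller
    values produce a wider spread of group sizes), every group non-empty.
    The sociality trait is gamma-distributed with mean 1 (right-skewed),
    scaling an individual's time spent inside boxes.
    """
    rng = np.random.default_rng([config.seed, _TAG_ROSTER])
    group_sections, group_boxes = _allocate_boxes(config)
    groups = list(group_sections)

    props = rng.dirichlet(np.full(config.n_groups, config.group_size_dispersion))
    sizes = rng.multinomial(config.n_individuals - config.n_groups, props) + 1
    assert sizes.sum() == config.n_individuals

    rows = []
    idx = 0
    for g, size in zip(groups, sizes):
        for _ in range(size):
            rows.append((f"m{idx:04d}", g, group_sections[g]))
            idx += 1
    table = pd.DataFrame(rows, columns=["individual_id", "home_group", "home_section"])
    table["sex"] = rng.choice(["F", "M"], size=len(table))
    table["sociality"] = rng.gamma(
        shape=config.sociality_shape, scale=1.0 / config.sociality_shape, size=len(table)
    )
    table["fate"] = "survivor"
    table = table[ROSTER_COLUMNS]
    return Roster(table=table, group_sections=group_sections, group_boxes=group_boxes)


def apply_catastrophe(roster: Roster, config: ScenarioConfig) -> Roster:
    """Assign fates for the catastrophe: dead, disappeared or survivor.

    The number dead is ``round(mortality_fraction * N)`` (half away from
    zero) and likewise for disappearances.  Individuals are sampled
    without replacement with per-group weights drawn from a Dirichlet with
    concentration ``group_loss_bias`` (small values concentrate the loss
    in few groups); ``group_loss_weights`` overrides the draw.
    """
    if roster.catastrophe_applied:
        raise StateError("catastrophe already applied to this roster")
    n = len(roster.table)
    n_dead = round_half_away(config.mortality_fraction * n)
    n_disappeared = round_half_away(config.disappearance_fraction * n)
    if n_dead + n_disappeared > n:
        raise ConfigError("loss fractions exceed the number of individuals")

    rng = np.random.default_rng([config.seed, _TAG_CATASTROPHE])
    groups = list(roster.group_sections)
    if config.group_loss_weights is not None:
        gw = np.asarray(config.group_loss_weights, dtype=float)
        if (gw < 0).any() or gw.sum() <= 0:
            raise ConfigError("group_loss_weights must be non-negative, not all zero")
    else:
        gw = rng.dirichlet(np.full(len(groups), config.group_loss_bias))
    weight_by_group = dict(zip(groups, gw))

    table = roster.table.copy()
    w = table["home_group"].map(weight_by_group).to_numpy(dtype=float)
    # per-capita weight within group, so the group weight sets the group's
    # expected share of losses regardless of its size
    counts = table.groupby("home_group")["individual_id"].transform("size").to_numpy()
    w = w / counts
    if w.sum() <= 0:
        w = np.ones(n)
    p = w / w.sum()
    lost = rng.choice(n, size=n_dead + n_disappeared, replace=False, p=p)
    fates = np.array(["survivor"] * n, dtype=object)
    fates[lost[:n_dead]] = "dead"
    fates[lost[n_dead:]] = "disappeared"
    table["fate"] = fates
    return replace(roster, table=table, catastrophe_applied=True)


# ---------------------------------------------------------------------------
# visit-bout engine


def _box_choice_probs(config: ScenarioConfig, home_boxes: Sequence[str],
                      boxes: Sequence[str]) -> np.ndarray:
    w = np.where(
        np.isin(boxes, list(home_boxes)),
        config.within_group_overlap_rate,
        config.between_group_overlap_rate,
    ).astype(float)
    total = w.sum()
    return w / total if total > 0 else w


def _simulate_bouts(
    rng: np.random.Generator,
    start: float,
    end: float,
    mean_in_s: float,
    mean_out_s: float,
    box_probs: np.ndarray,
    n_boxes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating out/in bouts in [start, end); returns entries, exits, box idx."""
    if box_probs.sum() <= 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    span = end - start
    # draw in batches until the window is covered
    n_guess = max(8, int(span / (mean_in_s + mean_out_s) * 2) + 8)
    entries: list[float] = []
    exits: list[float] = []
    boxes: list[int] = []
    t = start
    while t < end:
        outs = rng.exponential(mean_out_s, size=n_guess)
        ins = rng.exponential(mean_in_s, size=n_guess)
        chosen = rng.choice(n_boxes, size=n_guess, p=box_probs)
        for o, d, b in zip(outs, ins, chosen):
            t += o
            if t >= end:
                break
            entry = t
            t += d
            exit_ = min(t, end)
            if exit_ > entry:
                entries.append(entry)
                exits.append(exit_)
                boxes.append(b)
        # loop again only if the batch did not reach the window end
    return np.array(entries), np.array(exits), np.array(boxes, dtype=int)


def _emit_individual_window(
    config: ScenarioConfig,
    individual_id: str,
    ind_idx: int,
    home_boxes: Sequence[str],
    sociality: float,
    window_index: int,
    start: float,
    end: float,
    redirect_prob: float = 0.0,
    extra_bout_rate_per_day: float = 0.0,
    insularity: float = 0.0,
    prospect_probs: np.ndarray | None = None,
) -> list[tuple]:
    """One individual's visit records for one window.

    ``insularity`` lengthens both in- and out-of-box bouts by the factor
    ``1 + insularity`` (same duty cycle, fewer distinct visits), and
    ``redirect_prob`` re-targets each visit to the individual's own
    favourite home box —
    together the "socially insular" response.  ``extra_bout_rate_per_day``
    adds short prospecting visits drawn over ``prospect_probs`` (the
    "weak new ties" response).  The baseline bout stream is drawn from an
    RNG keyed on (seed, window, individual) only, with the response draws
    on a separate stream, so with all response knobs at zero the output
    is identical to the unperturbed process.
    """
    boxes = all_boxes(config)
    box_ids = [b for b, _ in boxes]
    sections = {b: s for b, s in boxes}
    probs = _box_choice_probs(config, home_boxes, box_ids)

    rng = np.random.default_rng([config.seed, _TAG_BOUTS + window_index, ind_idx])
    stretch = 1.0 + max(0.0, insularity)
    entries, exits, chosen = _simulate_bouts(
        rng,
        start,
        end,
        mean_in_s=config.mean_in_box_minutes * 60.0 * sociality * stretch,
        mean_out_s=config.mean_out_of_box_minutes * 60.0 * stretch,
        box_probs=probs,
        n_boxes=len(box_ids),
    )

    if redirect_prob > 0.0 or extra_bout_rate_per_day > 0.0:
        rng_resp = np.random.default_rng([config.seed, _TAG_RESPONSE + window_index, ind_idx])
        if redirect_prob > 0.0 and len(chosen):
            # concentrate on the individual's own favourite home box; the
            # deterministic per-individual choice spreads insular animals
            # across the cluster instead of piling them into one box
            fav = (
                box_ids.index(home_boxes[ind_idx % len(home_boxes)])
                if len(home_boxes)
                else None
            )
            if fav is not None:
                redirect = rng_resp.random(len(chosen)) < redirect_prob
                chosen = np.where(redirect, fav, chosen)
        if extra_bout_rate_per_day > 0.0:
            n_extra = rng_resp.poisson(extra_bout_rate_per_day * (end - start) / DAY_S)
            if n_extra > 0:
                entries, exits, chosen = _insert_weak_bouts(
                    rng_resp, config, entries, exits, chosen,
                    box_ids, home_boxes, start, end, n_extra,
                    target_probs=prospect_probs,
                )

    order = np.argsort(entries, kind="stable")
    return [
        (
            individual_id,
            box_ids[chosen[i]],
            sections[box_ids[chosen[i]]],
            float(entries[i]),
            float(exits[i]),
        )
        for i in order
    ]


def _insert_weak_bouts(
    rng: np.random.Generator,
    config: ScenarioConfig,
    entries: np.ndarray,
    exits: np.ndarray,
    chosen: np.ndarray,
    box_ids: list[str],
    home_boxes: Sequence[str],
    start: float,
    end: float,
    n_extra: int,
    target_probs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place short prospecting visits inside out-of-box gaps.

    Bouts go to boxes outside the home cluster — drawn over
    ``target_probs`` when given (prospectors join surviving groups) —
    and are truncated to fit the chosen gap, preserving the
    no-self-overlap invariant.
    """
    away = [i for i, b in enumerate(box_ids) if b not in home_boxes] or list(range(len(box_ids)))
    if target_probs is not None:
        w = np.array([target_probs[i] for i in away], dtype=float)
        away_p = w / w.sum() if w.sum() > 0 else np.full(len(away), 1.0 / len(away))
    else:
        away_p = np.full(len(away), 1.0 / len(away))
    # gaps between existing (already time-sorted-ish) visits
    order = np.argsort(entries)
    e_sorted, x_sorted = entries[order], exits[order]
    gap_starts = np.concatenate([[start], x_sorted])
    gap_ends = np.concatenate([e_sorted, [end]])
    lengths = np.clip(gap_ends - gap_starts, 0.0, None)
    if lengths.sum() <= 0:
        return entries, exits, chosen
    new_e, new_x, new_b = [], [], []
    for _ in range(n_extra):
        g = rng.choice(len(lengths), p=lengths / lengths.sum())
        dur = min(rng.exponential(config.weak_bout_minutes * 60.0), lengths[g])
        if dur <= 0:
            continue
        t0 = gap_starts[g] + rng.random() * (lengths[g] - dur)
        new_e.append(t0)
        new_x.append(t0 + dur)
        new_b.append(away[rng.choice(len(away), p=away_p)])
        # shrink the used gap to its remainder after the inserted bout
        gap_ends[g] = t0
        lengths[g] = max(0.0, gap_ends[g] - gap_starts[g])
        if lengths.sum() <= 0:
            break
    return (
        np.concatenate([entries, new_e]),
        np.concatenate([exits, new_x]),
        np.concatenate([chosen, np.array(new_b, dtype=int)]),
    )


def _records_frame(records: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    return df.sort_values(["entry", "individual_id", "box_id"], kind="stable").reset_index(drop=True)


def simulate_window(
    roster: Roster, window_index: int, config: ScenarioConfig
) -> pd.DataFrame:
    """Baseline (no-response) visit records for one window.

    Only individuals with fate ``survivor`` emit; before the catastrophe
    that is everyone.  Raises a range error for a window outside the
    schedule.
    """
    schedule = config.schedule()
    try:
        window = schedule[window_index]
    except KeyError as exc:
        raise IndexError(f"window {window_index} outside the schedule") from exc
    records: list[tuple] = []
    for ind_idx, row in enumerate(roster.table.itertuples(index=False)):
        if row.fate != "survivor":
            continue
        records.extend(
            _emit_individual_window(
                config,
                row.individual_id,
                ind_idx,
                roster.group_boxes[row.home_group],
                row.sociality,
                window_index,
                window.start,
                window.end,
            )
        )
    return _records_frame(records)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_post_event_response(
    roster: Roster,
    baseline_sociality: Mapping[str, float],
    loss_proportion: Mapping[str, float],
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Post-event visit records for all survivors, all post windows.

    ``baseline_sociality`` is each survivor's pre-event network sociality
    (weighted degree in the full pre-event network); ``loss_proportion``
    the share of that strength lost to missing associates.  The two
    response channels scale with the individual's loss and with how
    extreme its sociality is (logistic weights on standardized
    sociality), and ramp linearly over post-event windows.
    """
    if not roster.catastrophe_applied:
        raise StateError("simulate_post_event_response requires apply_catastrophe first")
    schedule = config.schedule()
    survivors = roster.table[roster.table["fate"] == "survivor"]
    soc = np.array([float(baseline_sociality.get(i, 0.0)) for i in survivors["individual_id"]])
    loss = np.array([float(loss_proportion.get(i, 0.0)) for i in survivors["individual_id"]])
    sd = soc.std()
    soc_z = (soc - soc.mean()) / sd if sd > 0 else np.zeros_like(soc)
    low_weight = _logistic(-2.0 * soc_z)   # high for low-sociality individuals
    high_weight = _logistic(2.0 * soc_z)   # high for high-sociality individuals

    # prospectors seek out intact groups: target-box weight is the owning
    # group's survivor share raised to the fourth power, so depleted
    # groups draw almost no visitors while intact groups absorb them
    survivor_share = (
        roster.table.assign(alive=roster.table["fate"] == "survivor")
        .groupby("home_group")["alive"]
        .mean()
    )
    box_ids = [b for b, _ in all_boxes(config)]
    box_share = {b: 0.0 for b in box_ids}
    for g, bxs in roster.group_boxes.items():
        for b in bxs:
            box_share[b] = float(survivor_share.get(g, 0.0)) ** 4
    prospect_probs = np.array([box_share[b] for b in box_ids])

    post = schedule.post_indices
    records: list[tuple] = []
    id_to_idx = {iid: k for k, iid in enumerate(roster.table["individual_id"])}
    for j, w_idx in enumerate(post, start=1):
        ramp = j / len(post)
        window = schedule[w_idx]
        for k, row in enumerate(survivors.itertuples(index=False)):
            extra = config.response_effect_low_social * loss[k] * low_weight[k] * ramp
            insular = config.response_effect_high_social * loss[k] * high_weight[k] * ramp
            records.extend(
                _emit_individual_window(
                    config,
                    row.individual_id,
                    id_to_idx[row.individual_id],
                    roster.group_boxes[row.home_group],
                    row.sociality,
                    w_idx,
                    window.start,
                    window.end,
                    redirect_prob=min(0.95, insular),
                    extra_bout_rate_per_day=extra,
                    insularity=insular,
                    prospect_probs=prospect_probs,
                )
            )
    return _records_frame(records)


@dataclass
class Scenario:
    """A fully simulated scenario: roster with fates, event log, schedule."""

    config: ScenarioConfig
    roster: Roster
    events: pd.DataFrame
    schedule: WindowSchedule
    baseline_sociality: dict[str, float] = field(default_factory=dict)
    loss_proportion: dict[str, float] = field(default_factory=dict)


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Run the full generative pipeline for one scenario.

    Pre-event windows are simulated first; the catastrophe assigns fates;
    each survivor's pre-event sociality (weighted degree) and loss
    proportion are measured on the full network of the last pre-event
    window; post-event windows are then simulated with the configured
    responses.  Disappeared and dead individuals emit nothing after the
    event.
    """
    from . import networks  # local import: networks does not import simulate

    schedule = config.schedule()
    roster = generate_roster(config)
    pre_frames = [simulate_window(roster, i, config) for i in schedule.pre_indices]
    roster = apply_catastrophe(roster, config)

    pre_events = pd.concat(pre_frames, ignore_index=True)
    baseline_window = schedule[schedule.last_pre_index]
    full_pre = networks.build_network(pre_events, baseline_window, roster)
    attrs = networks.loss_attributes(full_pre, roster.missing)
    soc = dict(zip(attrs.index, attrs["pre_event_sociality"].fillna(0.0)))
    loss = dict(zip(attrs.index, attrs["loss_proportion"].fillna(0.0)))

    post_events = simulate_post_event_response(roster, soc, loss, config)
    events = _records_frame(
        list(pre_events.itertuples(index=False, name=None))
        + list(post_events.itertuples(index=False, name=None))
    )
    return Scenario(
        config=config,
        roster=roster,
        events=events,
        schedule=schedule,
        baseline_sociality=soc,
        loss_proportion=loss,
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False,
                  columns=EVENT_COLUMNS,
                  header=["individual_id", "box_id", "section", "entry_epoch_s", "exit_epoch_s"])


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"entry_epoch_s": "entry", "exit_epoch_s": "exit"})
    return df[EVENT_COLUMNS]


def write_roster(roster: Roster, path: str | Path) -> None:
    roster.table.to_csv(path, index=False)


def read_roster(path: str | Path, config: ScenarioConfig | None = None) -> Roster:
    """Read a roster CSV; box-cluster metadata is rebuilt from ``config``
    when given, otherwise left empty (sufficient for network analysis)."""
    table = pd.read_csv(path)[ROSTER_COLUMNS]
    sections = dict(
        table.drop_duplicates("home_group")[["home_group", "home_section"]].itertuples(index=False)
    )
    boxes: dict[str, tuple[str, ...]] = {g: () for g in sections}
    if config is not None:
        _, boxes = _allocate_boxes(config)
    applied = bool((table["fate"] != "survivor").any())
    return Roster(table=table, group_sections=sections, group_boxes=boxes,
                  catastrophe_applied=applied)
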