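"""Synthetic study cohorts with known ground truth.

Three presets encode the qualitative scenarios of the study design:

``new_pair_convergence``
    Eight newly introduced pairs start with an asymmetric calling
    relationship (one bird answers far more than the other) that converges
    toward symmetry over the four observation days, alongside four
    established pairs that are symmetric throughout; clumping time grows in
    new pairs and is high from day one in established ones, and the male's
    answer probability co-varies with clumping.

``established_pair``
    All pairs behave like established ones: symmetric answering and high
    clumping on every day.

``uncoupled_null``
    No answering at all (p_answer = 0) and no group differences; any apparent
    structure downstream is chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import POSITION_STATES, BehaviorTrack, clumping_proportion, rate_by_state
from .exchange import summarize_exchange
from .simulate import (SimConfig, simulate_behavior_track, simulate_pair_calling,
                       write_behavior_csv, write_events_csv)

__all__ = ["PRESETS", "CohortData", "make_cohort", "make_fixture", "analyze_cohort"]

PRESETS = ("new_pair_convergence", "established_pair", "uncoupled_null")

DAYS = (1, 3, 5, 7)
SCORED_WINDOW_S = 3600.0  # two 30-min video sessions per day


@dataclass
class CohortData:
    """In-memory synthetic cohort: events, behaviour and generating truth."""

    preset: str
    events: dict[tuple[str, int], object]      # (pair_id, day) -> PairEventStreams
    behavior: dict[tuple[str, int], BehaviorTrack]
    truth: pd.DataFrame                        # one row per pair-day

    @property
    def pair_days(self) -> list[tuple[str, int]]:
        return list(self.events)


def _preset_params(preset: str, rng: np.random.Generator) -> pd.DataFrame:
    """Per pair-day generating parameters for one cohort."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rows = []
    if preset == "uncoupled_null":
        n_new, n_est = 8, 4
    elif preset == "established_pair":
        n_new, n_est = 0, 4
    else:
        n_new, n_est = 8, 4
    pairs = [(f"N{i+1:02d}", "new") for i in range(n_new)] + \
            [(f"E{i+1:02d}", "established") for i in range(n_est)]
    # day 1 asymmetry of new pairs decays toward symmetry by day 7
    delta_by_day = {1: 0.25, 3: 0.15, 5: 0.08, 7: 0.02}
    for pair_id, exp in pairs:
        sign = 1 if rng.random() < 0.5 else -1
        for day in DAYS:
            if preset == "uncoupled_null":
                p_f = p_m = 0.0
                clump = float(np.clip(rng.normal(500, 400), 0, SCORED_WINDOW_S))
            else:
                base_p = 0.3
                delta = delta_by_day[day] if exp == "new" else 0.02
                p_f = base_p - sign * delta
                p_m = base_p + sign * delta
                if exp == "established":
                    clump = float(np.clip(rng.normal(919, 400), 0, SCORED_WINDOW_S))
                else:
                    grow = {1: 29, 3: 250, 5: 450, 7: 600}[day]
                    clump = float(np.clip(rng.normal(grow, 150), 0, SCORED_WINDOW_S))
                # answering motivation co-varies with contact time
                p_m = float(np.clip(p_m + 0.15 * (clump / SCORED_WINDOW_S - 0.15),
                                    0.02, 0.95))
            rows.append(dict(pair_id=pair_id, experience=exp, day=day,
                             p_answer_f=p_f, p_answer_m=p_m,
                             clumping_target_s=clump))
    return pd.DataFrame(rows)


def make_cohort(
    preset: str,
    seed: int = 0,
    duration_s: float = 3600.0,
    base_rate: float = 0.17,
) -> CohortData:
    """Simulate a full cohort (events + behaviour) for one preset."""
    master = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    params = _preset_params(preset, param_rng)
    events = {}
    behavior = {}
    child_seeds = master.generate_state(2 * len(params)) % (2**31)
    for i, row in params.iterrows():
        cfg = SimConfig(
            duration_s=duration_s, base_rate_f=base_rate, base_rate_m=base_rate,
            p_answer_f=row.p_answer_f, p_answer_m=row.p_answer_m,
            seed=int(child_seeds[2 * i]),
        )
        key = (row.pair_id, int(row.day))
        events[key] = simulate_pair_calling(cfg)
        behavior[key] = _behavior_with_clumping(
            row.clumping_target_s, seed=int(child_seeds[2 * i + 1]))
    return CohortData(preset, events, behavior, params)


def _behavior_with_clumping(clump_target_s: float, seed: int) -> BehaviorTrack:
    """Behaviour track whose expected clumping time matches the target."""
    total = SCORED_WINDOW_S
    other = (total - clump_target_s) / 2.0
    dwell_clump = max(clump_target_s / 6.0, 1.0)  # ~6 bouts per session
    dwell_other = max(other / 6.0, 1.0)
    track = simulate_behavior_track(
        list(POSITION_STATES),
        [dwell_clump, dwell_other, dwell_other],
        total_s=total, seed=seed)
    return BehaviorTrack(track, scored_total_s=total)


def analyze_cohort(cohort: CohortData, call_type: str = "Stack") -> dict[str, pd.DataFrame]:
    """Reduce a cohort to the pair-day table consumed by the model set.

    For each pair-day the stack-call exchange is summarised (answer counts,
    directionality on the ×100 display scale, answer proportions) and the
    behaviour track yields clumping time and per-state call rates.
    """
    rows = []
    rate_rows = []
    for (pair_id, day), streams in cohort.events.items():
        fe = streams.female_events
        me = streams.male_events
        f_stack = fe[fe["call_type"] == call_type]
        m_stack = me[me["call_type"] == call_type]
        summ = summarize_exchange(
            f_stack["onset_s"].to_numpy(), m_stack["onset_s"].to_numpy(),
            f_stack["duration_s"].to_numpy(), m_stack["duration_s"].to_numpy())
        track = cohort.behavior[(pair_id, day)]
        clump_s, _ = clumping_proportion(track)
        truth = cohort.truth
        trow = truth[(truth.pair_id == pair_id) & (truth.day == day)].iloc[0]
        rows.append(dict(
            pair_id=pair_id, experience=trow.experience, day=day,
            clumping_s=clump_s,
            directionality=summ.directionality,
            directionality_display=summ.directionality_display,
            abs_directionality_display=abs(summ.directionality_display),
            n_answers=summ.n_answers, n_answered=summ.n_answered,
            total_stacks_f=len(f_stack), total_stacks_m=len(m_stack),
            answer_stacks_m=summ.n_answers, answer_stacks_f=summ.n_answered,
            answer_prop_m=summ.answer_proportion_partner,
            answer_prop_f=summ.answer_proportion_focal,
            overlap_rate=summ.overlap_rate,
        ))
        # stack rate within each relative-position state (female bird)
        scale = track.scored_total_s / cohort.events[(pair_id, day)].config.duration_s
        onsets = f_stack["onset_s"].to_numpy() * scale  # map onto scored window
        rates = rate_by_state(onsets, track, states=POSITION_STATES)
        for _, r in rates.iterrows():
            rate_rows.append(dict(pair_id=pair_id, day=day, state=r.state,
                                  rate_per_s=r.rate_per_s / scale))
    return {"pair_days": pd.DataFrame(rows), "state_rates": pd.DataFrame(rate_rows)}


def make_fixture(preset: str, seed: int, out_dir, duration_s: float = 3600.0) -> Path:
    """Write a cohort to disk as CSV event tables and behaviour tracks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(preset, seed=seed, duration_s=duration_s)
    for (pair_id, day), streams in cohort.events.items():
        stem = f"{pair_id}_day{day}"
        write_events_csv(streams.female_events, out / f"{stem}_female_events.csv",
                         bird_id=f"{pair_id}F")
        write_events_csv(streams.male_events, out / f"{stem}_male_events.csv",
                         bird_id=f"{pair_id}M")
        write_behavior_csv(cohort.behavior[(pair_id, day)].intervals,
                           out / f"{stem}_behavior.csv")
    cohort.truth.to_csv(out / "ground_truth.csv", index=False)
    return out
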