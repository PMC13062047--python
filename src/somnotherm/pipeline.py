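"""End-to-end convenience layer: score a session and pool cohort results.

These helpers chain the public modules exactly the way the CLI and the
reproduction script do: vigilance scoring → transition detection →
temperature-change classification → group contingency and delta-ratio
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats_report import fisher_exact_rxc
from .synthgen import SyntheticSession
from .transitions import (NEGATIVE, TransitionEvent, build_transition_events,
                          build_transition_contingency, summarize_by_subject)
from .vigilance import VigilanceScorer


@dataclass
class ScoredSession:
    session: SyntheticSession
    hypnogram: "object"  # scored Hypnogram (transition rule applied)
    events: list


def score_and_extract(session: SyntheticSession, epsilon_c: float = 0.1) -> ScoredSession:
    """Score one session's recording and extract its transition events."""
    scorer = VigilanceScorer()
    hyp = scorer.score_recording(session.recording)
    events = build_transition_events(session.recording, hyp,
                                     trace=session.temperature, epsilon_c=epsilon_c)
    return ScoredSession(session, hyp, events)


def analyze_transition_cohorts(sessions_by_group: dict, epsilon_c: float = 0.1) -> dict:
    """Full transition-locked analysis for several genotype groups.

    ``sessions_by_group`` maps a group label to a list of sessions.  Returns
    per-group pooled events, the percentage of temperature-negative
    transitions, per-subject summaries, and (for >= 2 groups) the exact test
    on the group × temperature-class contingency table.
    """
    out: dict = {"groups": {}}
    events_by_group: dict[str, list[TransitionEvent]] = {}
    for group, sessions in sessions_by_group.items():
        events: list[TransitionEvent] = []
        for s in sessions:
            events.extend(score_and_extract(s, epsilon_c).events)
        events_by_group[group] = events
        n = len(events)
        n_neg = sum(1 for e in events if e.temp_class == NEGATIVE)
        out["groups"][group] = {
            "events": events,
            "n_transitions": n,
            "pct_negative": 100.0 * n_neg / n if n else float("nan"),
            "subject_summaries": summarize_by_subject(events) if events else [],
        }
    if len(events_by_group) >= 2 and all(events_by_group.values()):
        table = build_transition_contingency(events_by_group)
        out["contingency"] = table
        out["fisher"] = fisher_exact_rxc(table, drop_empty=True)
    return out
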