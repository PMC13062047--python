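"""Statistical layer: exact contingency tests, Holm–Šidák adjustment,
two-way ANOVA, interictal-spike counting, the warmth-block analysis, and
tidy report generation.

The r×c exact test (Freeman–Halton extension of Fisher's exact test) and
the Holm–Šidák step-down adjustment are implemented from their definitions;
the two-way ANOVA delegates to statsmodels (OLS with Type II sums of
squares; the repeated-measures variant blocks on subject).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import gammaln

from .sigio import NREM, SignalRecording
from .vigilance import percent_time_in_state

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) != self.counts.shape[0] \
                or len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("label lengths do not match the count matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class TestResult:
    method: str
    p_value: float
    statistic: float | None = None
    df: tuple | None = None
    adjusted_p: list | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Freeman–Halton exact test
# ---------------------------------------------------------------------------

def _log_table_prob(counts: np.ndarray, lg_const: float) -> float:
    """log multivariate-hypergeometric probability, margins fixed."""
    return lg_const - gammaln(counts + 1).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield every non-negative integer matrix with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)

    def fill(i, remaining_cols):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if np.all(last >= 0) and last.sum() == row_sums[-1]:
                table[-1] = last
                yield table
            return
        def fill_row(j, left):
            if j == c - 1:
                if 0 <= left <= remaining_cols[-1]:
                    table[i, j] = left
                    yield True
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v)
        for _ in fill_row(0, row_sums[i]):
            new_remaining = [remaining_cols[j] - table[i, j] for j in range(c)]
            yield from fill(i + 1, new_remaining)

    yield from fill(0, list(col_sums))


def fisher_exact_rxc(table: ContingencyTable | np.ndarray,
                     max_enumeration_total: int = 500,
                     monte_carlo: bool = False,
                     n_mc: int = 200_000,
                     seed: int | None = None,
                     drop_empty: bool = False) -> TestResult:
    """Two-sided exact test of independence on an r×c table.

    The two-sided p-value is the total probability, under the multivariate
    hypergeometric distribution with the observed margins, of all tables at
    most as probable as the observed one (probability-ordering criterion;
    the Freeman–Halton extension of Fisher's exact test).  Tables with a
    grand total above ``max_enumeration_total`` require the seeded
    Monte-Carlo mode.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    if drop_empty:
        # all-zero rows/columns carry no information under fixed margins
        counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
        if counts.ndim != 2 or min(counts.shape) < 2:
            raise ValueError("table degenerate after dropping empty rows/columns")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty row or column")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    lg_const = (gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum()
                - gammaln(n + 1))
    log_p_obs = _log_table_prob(counts, lg_const)
    tol = 1e-10

    if monte_carlo or n > max_enumeration_total:
        if not monte_carlo:
            raise ValueError(
                f"table total {n} exceeds the enumeration budget "
                f"({max_enumeration_total}); use monte_carlo=True with a seed")
        rng = np.random.default_rng(seed)
        # sample tables with fixed margins by permuting column memberships
        rows = np.repeat(np.arange(len(row_sums)), row_sums)
        cols = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(cols)
            t = np.zeros_like(counts)
            np.add.at(t, (rows, perm), 1)
            if _log_table_prob(t, lg_const) <= log_p_obs + tol:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        return TestResult("fisher-freeman-halton (monte-carlo)", float(min(p, 1.0)),
                          detail={"n_mc": n_mc, "table_total": int(n)})

    p = 0.0
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _log_table_prob(t, lg_const)
        if lp <= log_p_obs + tol:
            p += np.exp(lp)
    return TestResult("fisher-freeman-halton", float(min(p, 1.0)),
                      detail={"table_total": int(n)})


# ---------------------------------------------------------------------------
# Holm–Šidák
# ---------------------------------------------------------------------------

def holm_sidak(p_values) -> list[float]:
    """Step-down Šidák adjustment, returned in the input order.

    For ascending p(1) <= ... <= p(m):
    ``adj(i) = max_{j<=i} (1 - (1 - p(j))^(m - j + 1))``, clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


# ---------------------------------------------------------------------------
# Two-way ANOVA (delegated)
# ---------------------------------------------------------------------------

def two_way_anova(values, factor_a, factor_b, subject=None,
                  repeated: bool = False) -> dict[str, TestResult]:
    """Two-way ANOVA: main effects and interaction (Type II sums of squares).

    With ``repeated=True`` the design is treated as randomized-block on
    ``subject`` (each subject measured under every level of the repeated
    factor): a subject term absorbs between-subject variance before the
    factorial terms are tested.  Unbalanced data are handled by the Type II
    decomposition.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, float),
                       "a": list(factor_a), "b": list(factor_b)})
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
    formula = "y ~ C(a) * C(b)"
    if repeated:
        if subject is None:
            raise ValueError("repeated=True requires subject identifiers")
        df["subj"] = list(subject)
        formula = "y ~ C(subj) + C(a) * C(b)"
    fit = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)

    def res(term):
        row = aov.loc[term]
        return TestResult(
            "two-way ANOVA (Type II)" + (", subject-blocked" if repeated else ""),
            p_value=float(row["PR(>F)"]), statistic=float(row["F"]),
            df=(float(row["df"]), float(aov.loc["Residual", "df"])),
        )

    return {"factor_a": res("C(a)"), "factor_b": res("C(b)"),
            "interaction": res("C(a):C(b)")}


# ---------------------------------------------------------------------------
# Interictal spike counting
# ---------------------------------------------------------------------------

def count_interictal_spikes(recording: SignalRecording,
                            channel: str | None = None,
                            k_sd: float = 5.0,
                            band_hz: tuple[float, float] = (20.0, 80.0),
                            refractory_s: float = 0.2,
                            ) -> tuple[int, np.ndarray]:
    """Threshold-crossing spike detector on the 20–80 Hz-emphasized signal.

    Events where the band-passed amplitude exceeds ``k_sd`` robust
    (MAD-based) SDs, merged within a 200 ms refractory period.  Candidate
    events must be biphasic — both a positive and a negative excursion
    beyond the threshold within ±40 ms — which rejects one-sided noise
    exceedances.  Deterministic.  Returns ``(count, spike_times_s)``.
    """
    if channel is None:
        non_emg = [l for l in recording.channel_labels if "EMG" not in l.upper()]
        if not non_emg:
            raise ValueError("no ECoG/LFP channel present")
        channel = non_emg[0]
    x = recording.channel(channel)
    if x.size == 0 or not np.isfinite(k_sd):
        return 0, np.empty(0)
    fs = recording.sample_rate_hz
    hi = min(band_hz[1], 0.45 * fs)
    sos = sps.butter(4, [band_hz[0], hi], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, x)
    robust_sd = 1.4826 * np.median(np.abs(f - np.median(f)))
    if robust_sd <= 0:
        return 0, np.empty(0)
    peaks, _ = sps.find_peaks(np.abs(f), height=k_sd * robust_sd,
                              distance=max(1, int(round(refractory_s * fs))))
    half = int(round(0.04 * fs))
    keep = []
    for p in peaks:
        seg = f[max(0, p - half):p + half + 1]
        if seg.max() > k_sd * robust_sd and seg.min() < -k_sd * robust_sd:
            keep.append(p)
    times = np.asarray(keep) / fs
    return int(len(times)), times


# ---------------------------------------------------------------------------
# Warmth-block analysis
# ---------------------------------------------------------------------------

def warmth_experiment(sessions, exclude_start_s: float = 0.0
                      ) -> tuple[pd.DataFrame, dict]:
    """%NREM per ambient block per subject, plus the genotype × temperature ANOVA.

    ``sessions`` is an iterable of objects (or dicts) with ``subject_id``,
    ``genotype``, a scored ``hypnogram`` and ``ambient_blocks``
    ``[(label, duration_s), ...]``.  ``exclude_start_s`` drops the first
    seconds of every block from the analysis (e.g. a drug-absorption
    window).  Returns a tidy table (subject_id, genotype, block, pct_nrem)
    and, when at least two block labels are present, the repeated-measures
    two-way ANOVA (genotype between, temperature within).
    """
    rows = []
    for s in sessions:
        get = s.get if isinstance(s, dict) else lambda k: getattr(s, k)
        hyp, blocks = get("hypnogram"), get("ambient_blocks")
        if not blocks or len({lbl for lbl, _ in blocks}) < 1:
            raise ValueError(f"session {get('subject_id')} has no labelled blocks")
        t0 = 0.0
        for lbl, dur in blocks:
            pct = percent_time_in_state(hyp, NREM, (t0 + exclude_start_s, t0 + dur))
            rows.append({"subject_id": get("subject_id"), "genotype": get("genotype"),
                         "block": lbl, "pct_nrem": pct})
            t0 += dur
    table = pd.DataFrame(rows)
    results: dict = {}
    if not table.empty and table["block"].nunique() >= 2:
        if table["genotype"].nunique() >= 2:
            results["anova"] = two_way_anova(
                table["pct_nrem"], table["genotype"], table["block"],
                subject=table["subject_id"], repeated=True)
        wide = table.pivot_table(index=["subject_id", "genotype"],
                                 columns="block", values="pct_nrem").reset_index()
        if {"RT", "WARM"} <= set(wide.columns):
            wide["warm_minus_rt"] = wide["WARM"] - wide["RT"]
            results["paired_differences"] = {
                g: float(sub["warm_minus_rt"].mean())
                for g, sub in wide.groupby("genotype")
            }
    return table, results


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

def build_report(out_dir,
                 subject_summaries=None,
                 contingency: ContingencyTable | None = None,
                 contingency_test: TestResult | None = None,
                 warmth_table: pd.DataFrame | None = None,
                 extra_results: dict | None = None,
                 config: dict | None = None) -> dict:
    """Write tidy CSV tables and a JSON summary; deterministic given inputs.

    Emits ``per_subject_delta_ratios.csv``, ``transition_contingency.csv``,
    ``percent_nrem_by_block.csv`` (each only when its input is provided)
    and ``summary.json``.  An empty cohort produces empty tables, a valid
    JSON summary and a logged warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config or {}, "results": dict(extra_results or {})}

    cols = ["subject_id", "n_events", "mean_wake_delta_ratio", "mean_nrem_delta_ratio"]
    rows = [{c: getattr(s, c) for c in cols} for s in (subject_summaries or [])]
    if subject_summaries is not None and not rows:
        logger.warning("empty cohort: writing empty report tables")
    pd.DataFrame(rows, columns=cols).to_csv(out_dir / "per_subject_delta_ratios.csv",
                                            index=False)

    if contingency is not None:
        contingency.to_frame().to_csv(out_dir / "transition_contingency.csv")
        summary["contingency"] = {
            "rows": list(contingency.row_labels), "cols": list(contingency.col_labels),
            "counts": contingency.counts.tolist(),
        }
    if contingency_test is not None:
        summary["contingency_test"] = {"method": contingency_test.method,
                                       "p_value": contingency_test.p_value}
    if warmth_table is not None:
        warmth_table.to_csv(out_dir / "percent_nrem_by_block.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
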