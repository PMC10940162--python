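"""Rule-based scoring of per-complex event tables.

Turns manually (or synthetically) scored timelines of surface-anchored
nucleation complexes into the headline frequencies of a reconstitution
assay: nucleation efficiency, minus-end binder colocalization,
microtubule release, re-nucleation, binding→growth-onset delays and
minus-end capping, plus the normalization and relative-abundance
utilities used alongside them.  Scoring is deterministic: identical
tables give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import EventTable

__all__ = [
    "FrequencyResult",
    "CappingObservation",
    "nucleation_efficiency",
    "colocalization_over_time",
    "release_frequency",
    "renucleation_frequency",
    "binding_to_growth_delays",
    "score_capping",
    "capping_efficiency",
    "normalize_to_control",
    "relative_abundance",
]


@dataclass
class FrequencyResult:
    """A scored percentage with per-field-of-view breakdown.

    ``percent`` is the pooled estimate; ``per_fov`` the per-field values;
    ``sem`` the standard error of the mean across fields (NaN with a
    single field).  ``defined=False`` marks an empty denominator
    (undefined, not zero).  ``n``/``n_total`` report the pooled
    numerator/denominator counts.
    """

    percent: float
    sem: float
    per_fov: pd.Series
    n: int
    n_total: int
    defined: bool = True


def _fov_percentages(df: pd.DataFrame, num: pd.Series, den: pd.Series
                     ) -> FrequencyResult:
    n, n_total = int(num.sum()), int(den.sum())
    if n_total == 0:
        return FrequencyResult(np.nan, np.nan, pd.Series(dtype=float),
                               0, 0, defined=False)
    grouped = pd.DataFrame({"num": num, "den": den, "fov": df["fov"]}
                           ).groupby("fov").sum()
    grouped = grouped[grouped["den"] > 0]
    per_fov = 100.0 * grouped["num"] / grouped["den"]
    sem = (per_fov.std(ddof=1) / np.sqrt(len(per_fov))
           if len(per_fov) > 1 else np.nan)
    return FrequencyResult(100.0 * n / n_total, float(sem), per_fov,
                           n, n_total)


def nucleation_efficiency(table: EventTable) -> FrequencyResult:
    """Percent of complexes that nucleated (were active) per field of view.

    Pooled percent plus per-field values with mean ± s.e.m. across
    fields.  Raises on an empty table.
    """
    df = table.data
    if len(df) == 0:
        raise ValueError("event table has no complexes")
    return _fov_percentages(df, df["active"].astype(int),
                            pd.Series(1, index=df.index))


def colocalization_over_time(table: EventTable) -> FrequencyResult:
    """Percent of active complexes that acquired a binder (t_bind present)
    within the observation window."""
    df = table.data
    active = df["active"].astype(bool)
    if not active.any():
        return FrequencyResult(np.nan, np.nan, pd.Series(dtype=float),
                               0, 0, defined=False)
    return _fov_percentages(df, (active & df["t_bind"].notna()).astype(int),
                            active.astype(int))


def release_frequency(table: EventTable,
                      denominator: str = "all_active") -> FrequencyResult:
    """Percent of complexes whose minus end started growing (released).

    ``denominator="all_active"`` scores releases over all active
    complexes; ``"bound_only"`` over complexes that acquired a binder.
    """
    if denominator not in ("all_active", "bound_only"):
        raise ValueError("denominator must be 'all_active' or 'bound_only'")
    df = table.data
    active = df["active"].astype(bool)
    released = active & df["t_growth_onset"].notna()
    den = active if denominator == "all_active" \
        else active & df["t_bind"].notna()
    if not den.any():
        return FrequencyResult(np.nan, np.nan, pd.Series(dtype=float),
                               0, 0, defined=False)
    return _fov_percentages(df, (released & den).astype(int),
                            den.astype(int))


def renucleation_frequency(table: EventTable) -> FrequencyResult:
    """Percent of depolymerized complexes that nucleated again."""
    df = table.data
    dep = df["t_depoly"].notna()
    if not dep.any():
        return FrequencyResult(np.nan, np.nan, pd.Series(dtype=float),
                               0, 0, defined=False)
    return _fov_percentages(df, (dep & df["t_renucleate"].notna()
                                 ).astype(int), dep.astype(int))


def binding_to_growth_delays(table: EventTable, bin_width_s: float = 50.0
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delays between binder arrival and minus-end growth onset.

    Returns (delays_s, hist_counts, hist_edges) over complexes with both
    t_bind and t_growth_onset; histogram bin width defaults to 50 s.
    Negative delays violate the table invariant and raise.
    """
    df = table.data
    both = df["t_bind"].notna() & df["t_growth_onset"].notna()
    delays = (df.loc[both, "t_growth_onset"]
              - df.loc[both, "t_bind"]).to_numpy()
    if (delays < -1e-9).any():
        raise ValueError("negative binding→growth delay in table")
    delays = np.clip(delays, 0.0, None)
    hi = (np.ceil(delays.max() / bin_width_s) * bin_width_s
          if delays.size else bin_width_s)
    edges = np.arange(0.0, hi + bin_width_s / 2, bin_width_s)
    counts, _ = np.histogram(delays, bins=edges)
    return delays, counts, edges


# ---------------------------------------------------------------------------
# capping
# ---------------------------------------------------------------------------

@dataclass
class CappingObservation:
    """One microtubule end monitored for stable complex association.

    ``end_growth_speed`` (µm/min) distinguishes the fast-growing plus end
    from the slow minus end; ``bound_intervals`` are (start, end) seconds
    of complex association within a window of ``window_s`` seconds.
    Intervals separated by gaps of at most ``gap_tolerance_s`` (one frame
    by default, for blinking) are merged on construction.
    """

    microtubule_id: str
    end_id: str
    end_growth_speed: float
    bound_intervals: list[tuple[float, float]]
    window_s: float = 300.0
    gap_tolerance_s: float = 20.0
    fov: int = 0

    def __post_init__(self) -> None:
        ivals = sorted((float(a), float(b)) for a, b in self.bound_intervals)
        for a, b in ivals:
            if b < a:
                raise ValueError("interval end before start")
            if a < -1e-9 or b > self.window_s + 1e-9:
                raise ValueError("bound interval outside window")
        merged: list[tuple[float, float]] = []
        for a, b in ivals:
            if merged and a - merged[-1][1] <= self.gap_tolerance_s:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.bound_intervals = merged

    def longest_bound_s(self) -> float:
        return max((b - a for a, b in self.bound_intervals), default=0.0)


def score_capping(obs: CappingObservation, min_stable_s: float = 120.0,
                  fast_growth_cutoff: float = 0.5) -> bool:
    """Apply the capping rule to one end.

    An end is capped iff it does not display fast growth
    (speed < ``fast_growth_cutoff`` µm/min, the minus-end criterion) and
    some merged bound interval lasts at least ``min_stable_s`` seconds
    (default 120 s, the at-least-2-minutes stability rule).
    """
    if obs.window_s < min_stable_s:
        raise ValueError("observation window shorter than min_stable_s")
    if obs.end_growth_speed >= fast_growth_cutoff:
        return False  # fast growth: scored as a plus end
    return obs.longest_bound_s() >= min_stable_s


def capping_efficiency(observations: Sequence[CappingObservation],
                       min_stable_s: float = 120.0,
                       fast_growth_cutoff: float = 0.5) -> FrequencyResult:
    """Percent of minus ends scored capped, per field of view.

    Minus ends are observations with speed < ``fast_growth_cutoff``;
    fast-growing ends are excluded from the denominator.
    """
    if not observations:
        raise ValueError("no observations")
    rows = []
    for obs in observations:
        is_minus = obs.end_growth_speed < fast_growth_cutoff
        rows.append({"fov": obs.fov, "minus": int(is_minus),
                     "capped": int(score_capping(obs, min_stable_s,
                                                 fast_growth_cutoff))})
    df = pd.DataFrame(rows)
    if df["minus"].sum() == 0:
        return FrequencyResult(np.nan, np.nan, pd.Series(dtype=float),
                               0, 0, defined=False)
    return _fov_percentages(df, df["capped"], df["minus"])


# ---------------------------------------------------------------------------
# normalization utilities
# ---------------------------------------------------------------------------

def normalize_to_control(values: pd.DataFrame,
                         control_means: Mapping[str, float] | None = None,
                         value_col: str = "value",
                         experiment_col: str = "experiment",
                         control_col: str = "is_control") -> pd.DataFrame:
    """Normalize per-cell measurements to the control mean of the same
    experiment.

    ``values`` must carry a value column and an experiment key; the
    control mean per experiment is either supplied via ``control_means``
    or computed from rows flagged in ``control_col``.  Raises naming any
    experiment without a control.  The grand mean of normalized controls
    is one by construction.
    """
    df = values.copy()
    if control_means is None:
        if control_col not in df:
            raise ValueError("need control_means or a control flag column")
        ctl = df[df[control_col].astype(bool)]
        control_means = ctl.groupby(experiment_col)[value_col].mean()
    missing = sorted(set(df[experiment_col]) - set(dict(control_means)))
    if missing:
        raise ValueError(f"no control for experiment(s): {missing}")
    for exp, m in dict(control_means).items():
        if not m > 0:
            raise ValueError(f"nonpositive control mean in {exp!r}")
    df["normalized"] = df[value_col] / df[experiment_col].map(
        dict(control_means))
    return df


def relative_abundance(intensities: Mapping[str, float],
                       reference: str = "GCP6") -> dict[str, float]:
    """Per-component abundance ratios to a reference component.

    Each intensity is divided by the reference component's intensity
    (which maps to 1.0); used for relative iBAQ-style stoichiometry
    estimates.  Raises if the reference is absent or nonpositive.
    """
    if reference not in intensities:
        raise ValueError(f"reference component {reference!r} absent")
    ref = float(intensities[reference])
    if not ref > 0:
        raise ValueError("reference intensity must be positive")
    return {k: float(v) / ref for k, v in intensities.items()}
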