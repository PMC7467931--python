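"""Derived metrics and statistics for simulated trials.

Spatial maps bin somatic activity by track position; place-field stability
across the environment switch is the Pearson correlation between the map of
late environment-A laps and early A' laps. Group comparisons reproduce the
tests used to summarize batches: two-tailed paired t-test, two-sided
Mann-Whitney U, and the Friedman test with Dunn's multiple-comparison post
hoc. Degenerate inputs (constant traces, zero-variance differences) are
flagged rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .protocols import TrialRecord

__all__ = [
    "SpatialMap",
    "GroupComparison",
    "spatial_map",
    "spatial_correlation",
    "environment_summary",
    "environment_peak_summary",
    "ab_a_prime_correlation",
    "input_output_correlation",
    "compare_groups",
    "dunns_posthoc",
    "detect_place_field",
    "io_epoch_means",
    "io_epoch_correlations",
]


@dataclass
class SpatialMap:
    """Occupancy-weighted mean somatic activity per spatial bin."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    occupancy: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.mean_rate)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GroupComparison:
    """Result of a named statistical test on one or more sample groups."""

    test: str
    statistic: float
    p_value: float
    n: tuple
    flagged: bool = False
    note: str = ""
    posthoc: dict = field(default_factory=dict)


def spatial_map(record: TrialRecord, environment: str,
                laps=None, n_bins: int = 50) -> SpatialMap:
    """Bin a trial's somatic activity by position over selected laps.

    ``laps`` selects laps *within* the environment by index (e.g. ``[-2, -1]``
    for the last two); ``None`` uses all laps of that environment.
    """
    if record.lap_index is None:
        raise ValueError("record has no position data (not an exploration trial)")
    env_of_lap = np.asarray(record.lap_environments, dtype=object)
    env_laps = np.flatnonzero(env_of_lap == environment)
    if env_laps.size == 0:
        raise ValueError(f"no laps in environment {environment!r}")
    if laps is not None:
        env_laps = env_laps[np.asarray(laps)]
    mask = np.isin(record.lap_index, env_laps)
    if not mask.any():
        raise ValueError("empty lap selection")
    length = record.params.track_length
    edges = np.linspace(0.0, length, n_bins + 1)
    pos = record.position[mask]
    act = record.r_soma[mask]
    which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    occupancy = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=act, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_rate = np.where(occupancy > 0, sums / np.maximum(occupancy, 1),
                             np.nan)
    return SpatialMap(bin_edges=edges, mean_rate=mean_rate,
                      occupancy=occupancy)


def spatial_correlation(map1: SpatialMap, map2: SpatialMap) -> float:
    """Pearson correlation of two spatial maps with identical binning.

    Returns NaN (flagged undefined) when either map is constant.
    """
    if map1.n_bins != map2.n_bins or not np.allclose(map1.bin_edges,
                                                     map2.bin_edges):
        raise ValueError("spatial maps have mismatched binning")
    a, b = map1.mean_rate, map2.mean_rate
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def ab_a_prime_correlation(record: TrialRecord, n_bins: int = 50,
                           late_laps=(-2, -1), early_laps=(0, 1)) -> float:
    """A-vs-A' stability: correlation of late-A and early-A' spatial maps."""
    m_a = spatial_map(record, "A", laps=list(late_laps), n_bins=n_bins)
    m_ap = spatial_map(record, "A_prime", laps=list(early_laps), n_bins=n_bins)
    return spatial_correlation(m_a, m_ap)


def environment_summary(record: TrialRecord, *,
                        skip_first_formation_lap: bool = True) -> dict:
    """Time-averaged somatic activity within each environment's laps.

    By default the first lap of the first environment is excluded as the
    place-field formation transient.
    """
    if record.lap_index is None:
        raise ValueError("not an exploration record")
    env_of_lap = np.asarray(record.lap_environments, dtype=object)
    out: dict[str, float] = {}
    seen: list[str] = []
    for env in env_of_lap:
        if env not in seen:
            seen.append(env)
    for pos_i, env in enumerate(seen):
        laps = np.flatnonzero(env_of_lap == env)
        if skip_first_formation_lap and pos_i == 0 and laps.size > 1:
            laps = laps[1:]
        mask = np.isin(record.lap_index, laps)
        out[env] = float(record.r_soma[mask].mean())
    return out


def environment_peak_summary(record: TrialRecord, n_bins: int = 50) -> dict:
    """Place-field amplitude per environment: max of the spatial map.

    The track-averaged activity (:func:`environment_summary`) is
    insensitive to whether drive is concentrated in one coherent field or
    scattered across the track; the map peak tracks the amplitude of the
    cell's place field and drops when the field is dispersed by an input
    shuffle.
    """
    env_of_lap = np.asarray(record.lap_environments, dtype=object)
    seen: list[str] = []
    for env in env_of_lap:
        if env not in seen:
            seen.append(env)
    return {env: float(np.nanmax(
        spatial_map(record, env, n_bins=n_bins).mean_rate)) for env in seen}


def input_output_correlation(input_trace, soma_trace) -> float:
    """Pearson correlation between an input trace and the somatic trace."""
    x = np.asarray(input_trace, dtype=float)
    y = np.asarray(soma_trace, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must be equal length and aligned")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def io_epoch_means(record: TrialRecord) -> dict:
    """Mean somatic activity in the baseline and post epochs of an IO trial."""
    epoch = record.extras["epoch"]
    return {
        "baseline": float(record.r_soma[epoch == 0].mean()),
        "post": float(record.r_soma[epoch == 2].mean()),
    }


def io_epoch_correlations(record: TrialRecord) -> dict:
    """SC-output and TA-output correlations in baseline and post epochs."""
    epoch = record.extras["epoch"]
    out = {}
    for name, code in (("baseline", 0), ("post", 2)):
        sel = epoch == code
        out[name] = {
            "sc": input_output_correlation(record.extras["sc_input"][sel],
                                           record.r_soma[sel]),
            "ta": input_output_correlation(record.extras["ta_input"][sel],
                                           record.r_soma[sel]),
        }
    return out


def compare_groups(samples, design: str) -> GroupComparison:
    """Run one of the named group comparisons.

    ``design`` is ``"paired_t"`` (two samples, paired, two-tailed),
    ``"mann_whitney"`` (two independent samples, two-sided, exact for small
    tie-free samples and normal approximation with tie correction
    otherwise), or ``"friedman_with_dunns"`` (>= 3 repeated measures,
    followed by Dunn's pairwise post hoc with Bonferroni adjustment).
    Degenerate inputs yield a flagged result with ``p = 1`` instead of an
    exception.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    ns = tuple(len(a) for a in arrays)
    if any(n < 2 for n in ns):
        raise ValueError("each group needs at least 2 observations")

    if design == "paired_t":
        if len(arrays) != 2 or ns[0] != ns[1]:
            raise ValueError("paired design needs two equal-length samples")
        diff = arrays[0] - arrays[1]
        if np.ptp(diff) == 0:
            return GroupComparison("paired_t", 0.0, 1.0, ns, flagged=True,
                                   note="zero-variance paired differences")
        res = stats.ttest_rel(arrays[0], arrays[1])
        return GroupComparison("paired_t", float(res.statistic),
                               float(res.pvalue), ns)

    if design == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney needs exactly two samples")
        pooled = np.concatenate(arrays)
        if np.ptp(pooled) == 0:
            return GroupComparison("mann_whitney", 0.0, 1.0, ns, flagged=True,
                                   note="all observations tied")
        res = stats.mannwhitneyu(arrays[0], arrays[1],
                                 alternative="two-sided", method="auto")
        return GroupComparison("mann_whitney", float(res.statistic),
                               float(res.pvalue), ns)

    if design == "friedman_with_dunns":
        if len(arrays) < 3:
            raise ValueError("Friedman needs at least three conditions")
        if len(set(ns)) != 1:
            raise ValueError("repeated measures need equal lengths")
        block = np.column_stack(arrays)
        if np.all(np.ptp(block, axis=1) == 0):
            return GroupComparison("friedman", 0.0, 1.0, ns, flagged=True,
                                   note="all conditions identical within blocks")
        res = stats.friedmanchisquare(*arrays)
        posthoc = dunns_posthoc(block)
        return GroupComparison("friedman", float(res.statistic),
                               float(res.pvalue), ns, posthoc=posthoc)

    raise ValueError(f"unknown design {design!r}")


def dunns_posthoc(block: np.ndarray) -> dict:
    """Dunn's multiple-comparison test after a Friedman test.

    ``block`` has shape (n_subjects, k_conditions). Within-subject ranks
    (average ranks on ties) give condition rank sums; each pair is compared
    with z = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n)) and the two-sided
    normal p-value is Bonferroni-adjusted for the k(k-1)/2 comparisons.
    Returns {(i, j): adjusted p}.
    """
    n, k = block.shape
    ranks = stats.rankdata(block, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z)) * m
            out[(i, j)] = float(min(p, 1.0))
    return out


def detect_place_field(smap: SpatialMap, *, peak_over_mean: float = 2.0,
                       min_peak: float = 0.2) -> dict | None:
    """Detect a place field in a spatial map.

    A field is reported when the peak bin exceeds ``peak_over_mean`` times
    the spatial mean and exceeds ``min_peak`` absolutely; otherwise the cell
    is considered silent / untuned and ``None`` is returned. The field width
    is the contiguous (circular) run of bins above half the peak.
    """
    rate = np.asarray(smap.mean_rate, dtype=float)
    ok = np.isfinite(rate)
    if not ok.any():
        return None
    mean = float(rate[ok].mean())
    peak_bin = int(np.nanargmax(rate))
    peak = float(rate[peak_bin])
    if peak < min_peak or (mean > 0 and peak < peak_over_mean * mean):
        return None
    half = peak / 2.0
    above = np.where(ok, rate >= half, False)
    nb = len(rate)
    width = 1
    for d in range(1, nb):
        if above[(peak_bin + d) % nb]:
            width += 1
        else:
            break
    for d in range(1, nb):
        if above[(peak_bin - d) % nb]:
            width += 1
        else:
            break
    width = min(width, nb)
    bin_w = smap.bin_edges[1] - smap.bin_edges[0]
    return {"peak_bin": peak_bin, "peak_rate": peak,
            "width": float(width * bin_w),
            "center": float(smap.bin_centers[peak_bin])}
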