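"""Nonparametric testing ladder used to determine the lower dose limit.

The Mann-Whitney U test is implemented from first principles: an exact
permutation null distribution (count recursion over the Gaussian-binomial
generating function) for small untied samples, and a tie-corrected normal
approximation with a lattice-aware continuity correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .metrics import AccuracyRecord, COMPARTMENTS

logger = logging.getLogger(__name__)

SIDEDNESS = ("two", "one_less", "one_greater")

DEFAULT_BIN_EDGES = (0.35, 0.40, 0.45, 0.50, math.inf)
DEFAULT_INTERVAL_CUTOFF_DAYS = 15.0
DEFAULT_SMALL_N_MIN = 6


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    n1: int
    n2: int
    p_value: float
    sidedness: str
    method: str  # exact | normal_tie_corrected
    mean_a: float | None = None
    mean_b: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.u_statistic < 0 or self.u_statistic > self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")


@lru_cache(maxsize=256)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of the exact null distribution of U over 0..n1*n2 (no ties).

    Coefficients of the Gaussian binomial ``prod_i (1-x^(n2+i)) / (1-x^i)``
    for ``i = 1..n1``; float64 counts are exact while C(n1+n2, n1) < 2^53.
    """
    size = n1 * n2 + 1
    c = np.zeros(size)
    c[0] = 1.0
    for i in range(1, n1 + 1):
        # divide by (1 - x^i): cumulative sum over each residue class mod i
        for r in range(min(i, size)):
            c[r::i] = np.cumsum(c[r::i])
        # multiply by (1 - x^(n2 + i))
        d = n2 + i
        if d < size:
            c[d:] -= c[:-d].copy()
    return c


def _exact_pvalues(u1: float, n1: int, n2: int) -> tuple[float, float]:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    k = int(round(u1))
    p_less = counts[: k + 1].sum() / total
    p_greater = counts[k:].sum() / total
    return float(p_less), float(p_greater)


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    sidedness: str = "two",
    method: str = "auto",
    exact_threshold: int = 20,
) -> TestResult:
    """Mann-Whitney U test of ``sample_a`` against ``sample_b``.

    ``one_less`` tests the alternative that ``sample_a`` is stochastically
    smaller than ``sample_b``; ``one_greater`` the opposite; ``two`` is the
    two-sided test.  ``method='auto'`` uses the exact permutation distribution
    when the smaller sample has at most ``exact_threshold`` observations and
    the pooled data contain no ties, and the tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")

    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if method == "exact" and has_ties:
        raise ValueError("exact method is only available for untied data")
    if method == "auto":
        feasible = min(n1, n2) <= exact_threshold and math.comb(n1 + n2, n1) < 2**52
        method = "exact" if (not has_ties and feasible) else "normal"

    if method == "exact":
        p_less, p_greater = _exact_pvalues(u1, n1, n2)
        used = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all observations identical: the null is saturated
            p_less = p_greater = 1.0
        else:
            sd = math.sqrt(var)
            # continuity correction = half the lattice spacing of U: midranks
            # of even-sized tie groups put U on a half-integer lattice,
            # otherwise U stays integral
            integral = np.allclose(ranks, np.round(ranks))
            cc = 0.5 if integral else 0.25
            p_less = float(norm.cdf((u1 + cc - mu) / sd))
            p_greater = float(norm.sf((u1 - cc - mu) / sd))
        used = "normal_tie_corrected"

    if sidedness == "one_less":
        p = p_less
    elif sidedness == "one_greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))

    return TestResult(
        u_statistic=u1,
        n1=n1,
        n2=n2,
        p_value=min(1.0, max(0.0, p)),
        sidedness=sidedness,
        method=used,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (offered as an option; not used by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Outlier exclusion and confounder screens
# ---------------------------------------------------------------------------


def exclude_outliers_3sigma(
    records: Sequence[AccuracyRecord],
    group_key: Callable[[AccuracyRecord], object] | None = None,
) -> tuple[list[AccuracyRecord], list[AccuracyRecord]]:
    """Single-pass 3-sigma exclusion of accuracy outliers per group.

    The mean and (sample) standard deviation are computed on the full group,
    candidate included; records with ``|x - mean| > 3 sd`` are excluded.
    Groups with fewer than three records are passed through with a warning.
    """
    if group_key is None:
        group_key = lambda r: r.compartment  # noqa: E731
    groups: dict[object, list[AccuracyRecord]] = {}
    for r in records:
        groups.setdefault(group_key(r), []).append(r)

    kept: list[AccuracyRecord] = []
    excluded: list[AccuracyRecord] = []
    for key, group in groups.items():
        if len(group) < 3:
            logger.warning("group %r has %d records; skipping outlier exclusion", key, len(group))
            kept.extend(group)
            continue
        acc = np.array([r.accuracy for r in group])
        mean, sd = acc.mean(), acc.std(ddof=1)
        for r, x in zip(group, acc):
            if sd > 0 and abs(x - mean) > 3.0 * sd:
                logger.info(
                    "excluding outlier %s/%s accuracy %.1f (group mean %.1f, sd %.1f)",
                    r.subject_id, key, x, mean, sd,
                )
                excluded.append(r)
            else:
                kept.append(r)
    return kept, excluded


def _manual(records: Iterable[AccuracyRecord]) -> list[AccuracyRecord]:
    return [r for r in records if r.source == "manual"]


def _split_test(
    records: Sequence[AccuracyRecord],
    predicate: Callable[[AccuracyRecord], bool],
    labels: tuple[str, str],
) -> dict[str, TestResult]:
    results: dict[str, TestResult] = {}
    for comp in COMPARTMENTS:
        comp_records = [r for r in records if r.compartment == comp]
        in_a = [r.accuracy for r in comp_records if predicate(r)]
        in_b = [r.accuracy for r in comp_records if not predicate(r)]
        if not in_a or not in_b:
            raise ValueError(
                f"empty stratum for {comp}: {labels[0]} n={len(in_a)}, {labels[1]} n={len(in_b)}"
            )
        results[comp] = mann_whitney_u(in_a, in_b, sidedness="two")
    return results


def truncation_effect_test(records: Sequence[AccuracyRecord]) -> dict[str, TestResult]:
    """Two-sided test of accuracy, truncated vs untruncated, per compartment."""
    return _split_test(_manual(records) or list(records), lambda r: r.truncated, ("truncated", "untruncated"))


def interval_effect_test(
    records: Sequence[AccuracyRecord], cutoff_days: float = DEFAULT_INTERVAL_CUTOFF_DAYS
) -> dict[str, TestResult]:
    """Two-sided test of accuracy, short vs long scan interval, per compartment."""
    return _split_test(
        _manual(records) or list(records),
        lambda r: abs(r.days_between) < cutoff_days,
        ("short-interval", "long-interval"),
    )


# ---------------------------------------------------------------------------
# Acceptable accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcceptableAccuracy:
    compartment: str
    value: float  # percent
    rule: str  # short_interval | all_days | fixed
    n_used: int
    excluded_subjects: tuple[str, ...] = ()
    reference_sample: tuple[float, ...] = ()


def derive_acceptable_accuracy(
    records: Sequence[AccuracyRecord],
    compartment: str,
    rule: str = "auto",
    cutoff_days: float = DEFAULT_INTERVAL_CUTOFF_DAYS,
    alpha: float = 0.05,
    fixed_value: float | None = None,
) -> AcceptableAccuracy:
    """Mean accuracy of the qualifying manual-record subset.

    ``rule='short_interval'`` keeps only records with a scan interval below
    the cutoff; ``'all_days'`` keeps everything after 3-sigma outlier
    exclusion; ``'auto'`` picks ``short_interval`` when the interval screen
    rejects for this compartment and ``all_days`` otherwise.  If
    ``fixed_value`` is given, derivation is bypassed but the qualifying
    subset is still returned as the reference sample for the dose-bin tests.
    """
    manual = [r for r in _manual(records) if r.compartment == compartment]
    if not manual:
        raise ValueError(f"no manual records for {compartment}")

    if rule == "auto":
        try:
            interval = interval_effect_test(records, cutoff_days)[compartment]
            rule = "short_interval" if interval.p_value < alpha else "all_days"
        except ValueError:  # a stratum is empty: the screen cannot reject
            logger.warning("interval screen not possible for %s; using all records", compartment)
            rule = "all_days"

    if rule == "short_interval":
        subset = [r for r in manual if abs(r.days_between) < cutoff_days]
        subset, dropped = exclude_outliers_3sigma(subset)
    elif rule == "all_days":
        subset, dropped = exclude_outliers_3sigma(manual)
    else:
        raise ValueError("rule must be auto, short_interval or all_days")
    if not subset:
        raise ValueError(f"qualifying subset for {compartment} is empty")

    sample = tuple(float(r.accuracy) for r in subset)
    value = float(np.mean(sample)) if fixed_value is None else float(fixed_value)
    return AcceptableAccuracy(
        compartment=compartment,
        value=value,
        rule=rule if fixed_value is None else "fixed",
        n_used=len(subset),
        excluded_subjects=tuple(r.subject_id for r in dropped),
        reference_sample=sample,
    )


# ---------------------------------------------------------------------------
# Dose-binned acceptability tests and the lower dose limit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseBinResult:
    low: float  # mGy, inclusive
    high: float  # mGy, exclusive
    n: int
    mean: float
    sd: float
    p_value: float
    small_n: bool

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.high) else f"{self.high:g}"
        return f"[{self.low:g}, {hi})"


def dose_bin_tests(
    records: Sequence[AccuracyRecord],
    reference_sample: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    alpha: float = 0.05,
    small_n_min: int = DEFAULT_SMALL_N_MIN,
) -> list[DoseBinResult]:
    """One-sided inferiority tests per SSDE_5.25 bin against the reference.

    Bins are ``[low, high)`` on SSDE_5.25; each bin's accuracies are tested
    with the alternative that they are stochastically *lower* than the
    reference sample, so a large p-value supports acceptability.  Bins with
    fewer than ``small_n_min`` records are flagged; empty bins are skipped.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be increasing with at least two entries")
    ref = np.asarray(reference_sample, dtype=float)
    if ref.size == 0:
        raise ValueError("reference sample is empty")

    results: list[DoseBinResult] = []
    for low, high in zip(edges[:-1], edges[1:]):
        acc = np.array(
            [r.accuracy for r in records if low <= r.ssde_5_25 < high], dtype=float
        )
        if acc.size == 0:
            logger.info("dose bin [%g, %g) is empty; skipped", low, high)
            continue
        test = mann_whitney_u(acc, ref, sidedness="one_less")
        results.append(
            DoseBinResult(
                low=float(low),
                high=float(high),
                n=int(acc.size),
                mean=float(acc.mean()),
                sd=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
                p_value=test.p_value,
                small_n=acc.size < small_n_min,
            )
        )
    return results


@dataclass(frozen=True)
class DoseLimit:
    limit: float | None  # mGy (SSDE_5.25); None when nothing passes
    source: str  # fine_bins | fallback | none
    rationale: str


def determine_dose_limit(
    bin_results: Sequence[DoseBinResult],
    fallback_levels: Sequence[DoseBinResult] = (),
    alpha: float = 0.05,
) -> DoseLimit:
    """Lowest dose at which accuracy is acceptable.

    The limit is the lower edge of the lowest *unflagged* bin such that every
    bin at or above it has ``p >= alpha``.  A small-n bin may sit inside a
    passing run but can never itself establish the limit.  When no fine bin
    qualifies, the lowest passing fallback level (coarse reference data, e.g.
    the 5.25-mm arm) is used; otherwise no limit is reported.
    """
    bins = sorted(bin_results, key=lambda b: b.low)
    if any(b1.high > b2.low + 1e-12 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be disjoint and ordered")

    for i, b in enumerate(bins):
        if b.small_n:
            continue
        run = bins[i:]
        if all(r.p_value >= alpha for r in run):
            return DoseLimit(
                limit=b.low,
                source="fine_bins",
                rationale=(
                    f"all bins at or above {b.low:g} mGy pass the one-sided test at "
                    f"alpha={alpha:g} (p values: "
                    + ", ".join(f"{r.label}: {r.p_value:.3f}" for r in run)
                    + ")"
                ),
            )

    for f in sorted(fallback_levels, key=lambda b: b.low):
        if not f.small_n and f.p_value >= alpha:
            return DoseLimit(
                limit=f.low,
                source="fallback",
                rationale=(
                    f"no fine bin qualifies; fallback level {f.low:g} mGy passes "
                    f"with p={f.p_value:.3f} (n={f.n})"
                ),
            )

    return DoseLimit(limit=None, source="none", rationale="no limit within tested range")


# ---------------------------------------------------------------------------
# Synthetic statistical cohorts (planted threshold)
# ---------------------------------------------------------------------------


def simulate_threshold_records(
    d_star: float,
    rng: np.random.Generator,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    n_per_bin: int = 12,
    ref_mean: float = 94.5,
    ref_sd: float = 4.0,
    n_ref: int = 12,
    drop_below: float = 12.0,
    lift_above: float = 2.0,
    accuracy_sd: float = 4.0,
    compartment: str = "SAT",
) -> tuple[list[AccuracyRecord], list[float]]:
    """Accuracy records whose mean crosses the acceptable level at ``d_star``.

    Records below ``d_star`` are centred ``drop_below`` points under the
    reference mean and records at or above it ``lift_above`` points over it,
    so the recoverable dose limit is the bin containing ``d_star``.
    Doses are spread uniformly inside each finite bin (the last, open-ended
    bin reuses the width of its predecessor).
    """
    from .metrics import make_record

    records: list[AccuracyRecord] = []
    edges = list(bin_edges)
    sid = 0
    for low, high in zip(edges[:-1], edges[1:]):
        width = (high - low) if math.isfinite(high) else (low - edges[edges.index(low) - 1])
        for _ in range(n_per_bin):
            dose = low + rng.uniform(0.0, width)
            centre = ref_mean + (lift_above if dose >= d_star else -drop_below)
            acc = float(np.clip(rng.normal(centre, accuracy_sd), 1.0, 100.0))
            records.append(
                make_record(
                    f"synth{sid:03d}",
                    compartment,
                    100.0,
                    100.0 - (100.0 - acc),
                    source="auto",
                    ssde_5_25=dose,
                    thickness=1.25,
                    denoised=True,
                )
            )
            sid += 1
    reference = np.clip(rng.normal(ref_mean, ref_sd, n_ref), 1.0, 100.0).tolist()
    return records, reference
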