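"""Aggregation conventions and nonparametric tests for behavioural summaries.

Group values are reported as median ± m.a.d. (unscaled median absolute
deviation), aggregated first within and then between animals.  Paired medians
are compared with Wilcoxon's signed-rank test (exact null distribution up to
n = 25, normal approximation above), independent groups with the
Mann-Whitney U test, correlations with Spearman's rho, and multiple
comparisons are flagged under Benjamini-Hochberg FDR and Bonferroni control
at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ParameterError, UndefinedResultError


@dataclass
class GroupSummary:
    """Per-animal medians with their across-animal median ± m.a.d."""

    per_animal_medians: dict
    median: float
    mad: float
    n_animals: int


def mad(values) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    x = np.asarray(values, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def aggregate_median_mad(values_by_animal: Mapping) -> GroupSummary:
    """First-within-then-between-animal aggregation to median ± m.a.d.

    Each animal's entry is either a flat sequence of values (median taken
    directly) or a mapping of video -> values (median per video, then median
    across videos).  The group median and unscaled m.a.d. are taken across
    the per-animal medians.
    """
    if not values_by_animal:
        raise InsufficientDataError("no animals provided")
    per_animal: dict = {}
    for animal, values in values_by_animal.items():
        if isinstance(values, Mapping):
            vids = [np.median(np.asarray(v, dtype=float)) for v in values.values() if len(v)]
            if not vids:
                raise InsufficientDataError(f"animal {animal!r} has no values")
            per_animal[animal] = float(np.median(vids))
        else:
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise InsufficientDataError(f"animal {animal!r} has no values")
            per_animal[animal] = float(np.median(arr))
    meds = np.array(list(per_animal.values()))
    return GroupSummary(per_animal, float(np.median(meds)), mad(meds), len(meds))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test with exact small-sample null
# ---------------------------------------------------------------------------

@dataclass
class SignedRankResult:
    W: float          # smaller of the two signed-rank sums
    p: float          # two-sided
    n: int            # nonzero differences used
    exact: bool


def _signed_rank_cdf_exact(ranks: np.ndarray, w: float) -> float:
    """P(W+ <= w) under the null, by dynamic programming over 2^n signings.

    Ranks are mid-ranked on ties, so doubling makes them integers; the
    distribution of the doubled positive-rank sum is built by convolution.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cutoff = int(np.floor(2 * w + 1e-9))
    return float(counts[: cutoff + 1].sum())


def signed_rank_test(paired_a, paired_b, exact_max_n: int = 25) -> SignedRankResult:
    """Wilcoxon's signed-rank test for paired samples.

    Zero differences are dropped and tied magnitudes mid-ranked.  W is the
    smaller of the positive- and negative-rank sums; the two-sided p-value is
    exact (full enumeration of the 2^n sign assignments, via convolution) for
    n <= ``exact_max_n`` and a tie-corrected normal approximation above.

    Raises :class:`UndefinedResultError` when all differences are zero.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedResultError("all paired differences are zero")
    if n < 2:
        raise InsufficientDataError("need >= 2 nonzero differences")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = min(1.0, 2.0 * _signed_rank_cdf_exact(ranks, w))
        return SignedRankResult(w, p, n, exact=True)
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    z = (w - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))
    return SignedRankResult(w, p, n, exact=False)


# ---------------------------------------------------------------------------
# Mann-Whitney U and Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class RankStats:
    U: float | None = None
    U_p: float | None = None
    rho: float | None = None
    rho_p: float | None = None


def mann_whitney_u(group_a, group_b) -> RankStats:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankStats(U=float(res.statistic), U_p=float(res.pvalue))


def spearman_rho(paired_x, paired_y) -> RankStats:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("constant input: rank correlation undefined")
    res = scipy.stats.spearmanr(x, y)
    return RankStats(rho=float(res.statistic), rho_p=float(res.pvalue))


def rank_stats(group_a=None, group_b=None, paired_x=None, paired_y=None) -> RankStats:
    """Convenience wrapper: U test on groups and/or Spearman rho on pairs."""
    out = RankStats()
    if group_a is not None and group_b is not None:
        u = mann_whitney_u(group_a, group_b)
        out.U, out.U_p = u.U, u.U_p
    if paired_x is not None and paired_y is not None:
        r = spearman_rho(paired_x, paired_y)
        out.rho, out.rho_p = r.rho, r.rho_p
    return out


# ---------------------------------------------------------------------------
# Grip-type fractions
# ---------------------------------------------------------------------------

@dataclass
class GripFractions:
    """Per-D1-instance and per-hold grip composition."""

    d1_fractions: dict[str, float]     # thumb_hold / pincer / indeterminate
    hold_fractions: dict[str, float]   # symmetric / mixed / indeterminate
    n_holds: int
    n_instances: int


def grip_fractions(ethograms: Sequence) -> GripFractions:
    """Grip-type composition over all labelled holding phases.

    Per-D1 fractions count each hand of each hold as one instance, with
    indeterminate instances kept in the denominator (which is why thumb and
    pincer fractions need not sum to 1).  Per-hold, *symmetric* means both
    hands used the same non-indeterminate grip, *mixed* both classified but
    different, and *indeterminate* at least one hand unclassifiable.
    """
    instances: list[str] = []
    holds: list[tuple[str, str]] = []
    for eth in ethograms:
        for seg in eth.segments:
            if seg.phase != "holding":
                continue
            grips = (seg.grip_left, seg.grip_right)
            if all(g == "absent" for g in grips):
                continue
            holds.append(grips)
            instances.extend(g for g in grips if g != "absent")
    if not holds:
        raise InsufficientDataError("no holding phases carry grip labels")
    n_inst = len(instances)
    d1 = {
        cat: sum(g == cat for g in instances) / n_inst
        for cat in ("thumb_hold", "pincer", "indeterminate")
    }
    n_holds = len(holds)
    symmetric = sum(
        l == r and l not in ("indeterminate", "absent") for l, r in holds
    )
    mixed = sum(
        l != r and "indeterminate" not in (l, r) and "absent" not in (l, r)
        for l, r in holds
    )
    hold_fr = {
        "symmetric": symmetric / n_holds,
        "mixed": mixed / n_holds,
        "indeterminate": (n_holds - symmetric - mixed) / n_holds,
    }
    return GripFractions(d1, hold_fr, n_holds, n_inst)


# ---------------------------------------------------------------------------
# Multiple-comparison flags
# ---------------------------------------------------------------------------

@dataclass
class AdjustedPValues:
    fdr_flags: list[bool]
    bonferroni_flags: list[bool]
    alpha: float


def adjust_pvalues(p_list, alpha: float = 0.05) -> AdjustedPValues:
    """Benjamini-Hochberg and Bonferroni significance flags at ``alpha``.

    Any Bonferroni-flagged p-value is necessarily BH-flagged as well.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    fdr = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    bonf = p <= alpha / p.size
    return AdjustedPValues(list(map(bool, fdr)), list(map(bool, bonf)), alpha)
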