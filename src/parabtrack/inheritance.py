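"""Sibling-cell ParA inheritance statistics.

At each observed division the two newborn sisters are compared: total ParA
(summed pixel intensity), maximum ParA pixel intensity, birth size and
growth rate.  Which sister inherits the parent's local ParA *maximum* is
decided geometrically — the daughter whose axial segment (relative to the
division plane) contains the parent's last pre-division maximum position.

Under purely size-based (random) inheritance the probability that a given
daughter receives a randomly located maximum equals its share of the parent
length, so summing the larger sister's share over all divisions predicts
the expected number of larger-sister inheritances; comparing this with the
observed count tests whether maximum inheritance needs any mechanism beyond
asymmetric division itself.  Group comparisons report both the paired
Wilcoxon signed-rank test and Welch's t-test, and population cell-size
comparisons use Kruskal-Wallis with Dunn's rank-sum post-hoc procedure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lineage import LineageTree, growth_rate
from .profiles import AxialProfile, para_maximum, smooth_profile

logger = logging.getLogger(__name__)

NOMINAL_WIDTH_UM = 0.5  # rod width used to convert length to area


@dataclass
class SiblingPair:
    """Matched newborn sisters with their ParA and size attributes."""

    parent_id: int
    daughter_a: int
    daughter_b: int
    total_parA: dict[int, float]
    max_parA: dict[int, float]
    birth_length: dict[int, float]
    birth_area: dict[int, float]
    growth_rate: dict[int, float]
    high_total_inheritor: int
    max_inheritor: int
    larger: int
    max_tie: bool = False

    @property
    def smaller(self) -> int:
        return self.daughter_b if self.larger == self.daughter_a else self.daughter_a

    def low_total_inheritor(self) -> int:
        return (self.daughter_b if self.high_total_inheritor == self.daughter_a
                else self.daughter_a)

    def low_max_inheritor(self) -> int:
        return (self.daughter_b if self.max_inheritor == self.daughter_a
                else self.daughter_a)


def classify_max_inheritor(
    max_position_um: float,
    plane_position_um: float,
    daughter_new_side: int,
    daughter_old_side: int,
    larger_daughter: int,
) -> tuple[int, bool]:
    """Which daughter's segment contains the parent's ParA maximum.

    Positions are measured from the parent's new pole; the new-side
    daughter occupies ``[0, plane)``.  A maximum exactly at the plane is a
    tie, broken to the larger daughter and flagged.
    """
    if math.isclose(max_position_um, plane_position_um):
        return larger_daughter, True
    if max_position_um < plane_position_um:
        return daughter_new_side, False
    return daughter_old_side, False


def _division_geometry(tree: LineageTree, parent_id: int) -> tuple[int, int, float]:
    """(new-side daughter, old-side daughter, plane position) for one division.

    The daughter adjacent to the parent's new pole carries the opposite
    ``new_pole_end`` label (its own new pole is the plane); its birth
    length is the plane's distance from the parent's new pole.
    """
    d1, d2 = tree.children[parent_id]
    parent_pole = tree.cells[parent_id].new_pole_end
    if tree.cells[d1].new_pole_end != parent_pole:
        near, far = d1, d2
    else:
        near, far = d2, d1
    return near, far, tree.cells[near].birth_length


def sibling_attributes(
    tree: LineageTree,
    parent_id: int,
    birth_profiles: dict[int, AxialProfile],
    parent_last_profile: AxialProfile,
    smoothing_sigma_px: float = 2.0,
    nominal_width_um: float = NOMINAL_WIDTH_UM,
) -> SiblingPair | None:
    """Build a :class:`SiblingPair` for one division.

    ``birth_profiles`` maps each daughter id to its birth-frame ParA
    profile; ``parent_last_profile`` is the parent's last pre-division ParA
    profile (used, smoothed, to place the inherited maximum).  Returns None
    when a birth profile is missing.
    """
    if parent_id not in tree.children:
        return None
    d1, d2 = tree.children[parent_id]
    if d1 not in birth_profiles or d2 not in birth_profiles:
        logger.warning("division %d: missing birth profile, pair excluded", parent_id)
        return None
    total = {d: float(birth_profiles[d].intensities.sum()) for d in (d1, d2)}
    peak = {d: float(birth_profiles[d].intensities.max()) for d in (d1, d2)}
    length = {d: tree.cells[d].birth_length for d in (d1, d2)}
    area = {d: length[d] * nominal_width_um for d in (d1, d2)}
    rate = {
        d: growth_rate(tree.cells[d].times, tree.cells[d].lengths)[0] for d in (d1, d2)
    }
    larger = d1 if length[d1] >= length[d2] else d2
    high_total = d1 if total[d1] >= total[d2] else d2
    near, far, plane = _division_geometry(tree, parent_id)
    max_pos = para_maximum(smooth_profile(parent_last_profile, smoothing_sigma_px))
    if math.isnan(max_pos):
        logger.warning("division %d: flat parent ParA profile, pair excluded", parent_id)
        return None
    inheritor, tie = classify_max_inheritor(max_pos, plane, near, far, larger)
    return SiblingPair(
        parent_id=parent_id, daughter_a=d1, daughter_b=d2,
        total_parA=total, max_parA=peak,
        birth_length=length, birth_area=area, growth_rate=rate,
        high_total_inheritor=high_total, max_inheritor=inheritor,
        larger=larger, max_tie=tie,
    )


@dataclass
class InheritancePrediction:
    """Size-based null prediction for larger-sister maximum inheritance."""

    n_divisions: int
    expected_larger_count: float
    observed_larger_count: int
    standard_error: float  # sqrt(sum p_i (1 - p_i)) of the Poisson-binomial null


def predict_random_inheritance(pairs: list[SiblingPair]) -> InheritancePrediction:
    """Expected vs observed larger-sister inheritances of the ParA maximum.

    Per division the larger sister's inheritance probability under random
    placement is her share of the parent size (the two daughters' shares
    sum to 1 because parent size is taken as the sum of the two birth
    sizes).  Zero-size daughters exclude the pair.
    """
    probs, observed = [], 0
    for p in pairs:
        s_larger = p.birth_length[p.larger]
        s_smaller = p.birth_length[p.smaller]
        if s_larger <= 0 or s_smaller <= 0:
            continue
        probs.append(s_larger / (s_larger + s_smaller))
        observed += int(p.max_inheritor == p.larger)
    probs_arr = np.asarray(probs)
    return InheritancePrediction(
        n_divisions=len(probs),
        expected_larger_count=float(probs_arr.sum()),
        observed_larger_count=observed,
        standard_error=float(np.sqrt((probs_arr * (1 - probs_arr)).sum())),
    )


def simulate_random_inheritance(
    n_divisions: int,
    asymmetry: float = 0.6,
    jitter_sd: float = 0.03,
    seed: int = 0,
) -> InheritancePrediction:
    """Monte-Carlo check of the size-based null.

    Each simulated division draws the larger sister's share (a jittered,
    truncated asymmetry fraction) and places the maximum uniformly along
    the parent; the larger sister inherits when the maximum falls in her
    share.  By the law of large numbers the observed/expected ratio tends
    to 1.
    """
    rng = np.random.default_rng(seed)
    q = np.clip(asymmetry + rng.normal(0, jitter_sd, n_divisions), 0.5, 0.95)
    u = rng.uniform(0, 1, n_divisions)
    observed = int(np.sum(u < q))
    return InheritancePrediction(
        n_divisions=n_divisions,
        expected_larger_count=float(q.sum()),
        observed_larger_count=observed,
        standard_error=float(np.sqrt((q * (1 - q)).sum())),
    )


def compare_inheritor_groups(
    pairs: list[SiblingPair],
    attribute: str = "growth_rate",
    grouping: str = "total",
) -> dict:
    """Paired high- vs low-inheritor comparison of a sibling attribute.

    ``attribute`` is ``area``, ``length`` or ``growth_rate``; ``grouping``
    picks how siblings are split: by total-ParA inheritance (``total``), by
    maximum-region inheritance (``max``) or by size (``size``).  Reports
    both the paired Wilcoxon signed-rank test and Welch's t-test.
    """
    if len(pairs) < 6:
        raise ValueError("need at least 6 sibling pairs")
    attr_col = {"area": "birth_area", "length": "birth_length",
                "growth_rate": "growth_rate"}[attribute]
    pick = {
        "total": lambda p: (p.high_total_inheritor, p.low_total_inheritor()),
        "max": lambda p: (p.max_inheritor, p.low_max_inheritor()),
        "size": lambda p: (p.larger, p.smaller),
    }[grouping]
    hi, lo = [], []
    for p in pairs:
        a, b = pick(p)
        vals = getattr(p, attr_col)
        hi.append(vals[a])
        lo.append(vals[b])
    hi_arr, lo_arr = np.asarray(hi), np.asarray(lo)
    ok = np.isfinite(hi_arr) & np.isfinite(lo_arr)
    hi_arr, lo_arr = hi_arr[ok], lo_arr[ok]
    welch = stats.ttest_ind(hi_arr, lo_arr, equal_var=False)
    diffs = hi_arr - lo_arr
    if np.all(diffs == 0):
        wil_stat, wil_p = math.nan, math.nan
        note = "all pairs tied; signed-rank test undefined"
    else:
        wil = stats.wilcoxon(hi_arr, lo_arr)
        wil_stat, wil_p = float(wil.statistic), float(wil.pvalue)
        note = ""
    return {
        "attribute": attribute,
        "grouping": grouping,
        "n_pairs": int(hi_arr.size),
        "mean_high": float(hi_arr.mean()),
        "mean_low": float(lo_arr.mean()),
        "welch_t": float(welch.statistic),
        "welch_p": float(welch.pvalue),
        "wilcoxon_stat": wil_stat,
        "wilcoxon_p": wil_p,
        "note": note,
    }


# ---------------------------------------------------------------------------
# Population size comparisons (Kruskal-Wallis + Dunn's method)
# ---------------------------------------------------------------------------

def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided p-values are
    Bonferroni-adjusted over all pairs (the adjustment used is recorded in
    the output).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_rank, sizes, i0 = {}, {}, 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = float(ranks[i0:i0 + n].mean())
        sizes[g] = n
        i0 += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p_raw": p, "p_adj": min(1.0, p * m),
                     "adjustment": "bonferroni"})
    return pd.DataFrame(rows)


def _letter_classes(
    names: list[str], medians: dict[str, float], sig: set[frozenset]
) -> dict[str, str]:
    """Greedy compact-letter display: non-different groups share a letter."""
    ordered = sorted(names, key=lambda g: -medians[g])
    classes: list[list[str]] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(frozenset((g, h)) not in sig for h in cls):
                cls.append(g)
                placed = True
                break
        if not placed:
            classes.append([g])
    letters = {}
    for label, cls in zip("ABCDEFGH", classes):
        for g in cls:
            letters[g] = label
    return letters


def compare_size_distributions(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_group_size: int = 5,
) -> dict:
    """Kruskal-Wallis H across strains plus Dunn's pairwise post-hoc tests.

    Groups with fewer than ``min_group_size`` observations are excluded
    (warning).  Returns H (tie-corrected), its p-value, the Dunn table and
    letter classes in which mutually non-different groups share a letter.
    """
    kept = {}
    for g, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < min_group_size:
            logger.warning("group %r has %d < %d observations, excluded",
                           g, vals.size, min_group_size)
            continue
        kept[g] = vals
    if len(kept) < 2:
        raise ValueError("need at least 2 groups")
    samples = list(kept.values())
    if all(np.array_equal(samples[0], s) for s in samples[1:]):
        h_stat, h_p = 0.0, 1.0  # identical groups carry no rank information
    else:
        kw = stats.kruskal(*samples)
        h_stat, h_p = float(kw.statistic), float(kw.pvalue)
    dunn = dunn_test(kept)
    sig = {
        frozenset((r.group1, r.group2))
        for r in dunn.itertuples() if r.p_adj < alpha
    }
    medians = {g: float(np.median(v)) for g, v in kept.items()}
    return {
        "H": h_stat,
        "p": h_p,
        "n_groups": len(kept),
        "medians": medians,
        "dunn": dunn,
        "letters": _letter_classes(list(kept), medians, sig),
        "alpha": alpha,
    }
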