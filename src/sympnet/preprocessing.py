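"""Cohort assembly: exclusion cascade, redundant-item merging, symptom flags.

Redundancy ("topological overlap") is handled before any network is fitted:
pairs of items that correlate highly *and* show statistically
indistinguishable correlation patterns with every other item carry no unique
information, and leaving both in the network biases edge and centrality
estimates. Detection follows the dependent-correlations procedure of the
goldbricker family: for each highly correlated pair, the two items'
correlations with every third item are compared with the Hittner
back-transformed z test for overlapping dependent correlations, and the pair
is declared redundant when fewer than a set fraction of those comparisons
differ significantly. Flagged pairs are merged by per-subject averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import spearman_corr

__all__ = [
    "ExclusionReport",
    "RedundancyReport",
    "apply_exclusions",
    "detect_redundant_pairs",
    "merge_items",
    "flag_burdensome",
    "validate_ratings",
]


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check that all non-missing severities are integers in [0, 6]."""
    vals = ratings.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (
        (finite < 0).any() or (finite > 6).any() or (finite != np.round(finite)).any()
    ):
        bad = np.argwhere(
            ~np.isnan(vals) & ((vals < 0) | (vals > 6) | (vals != np.round(vals)))
        )[0]
        raise ValueError(
            f"severity out of 0-6 integer range at row {bad[0]}, "
            f"column {ratings.columns[bad[1]]!r}"
        )
    if ratings.columns.duplicated().any():
        raise ValueError("duplicate item labels")
    return ratings


@dataclass
class ExclusionReport:
    """Ordered per-criterion removal counts for an exclusion cascade."""

    steps: list[tuple[str, int]]
    n_initial: int
    n_final: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps, columns=["criterion", "n_removed"])
        df.attrs["n_initial"] = self.n_initial
        df.attrs["n_final"] = self.n_final
        return df


def apply_exclusions(
    subject_flags: pd.DataFrame,
    order: list[str],
    ratings: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame | pd.Series, ExclusionReport]:
    """Drop subjects at the first exclusion criterion they meet.

    ``subject_flags`` holds one boolean column per criterion; ``order`` fixes
    the attribution: a subject meeting several criteria is counted only under
    the earliest. Returns the retained ratings (or, when no ratings are
    supplied, the boolean keep-mask) together with the per-criterion report.
    """
    if not order:
        raise ValueError("order must name at least one criterion")
    missing = [c for c in order if c not in subject_flags.columns]
    if missing:
        raise KeyError(f"unknown exclusion criteria: {missing}")
    n_initial = len(subject_flags)
    remaining = pd.Series(True, index=subject_flags.index)
    steps = []
    for crit in order:
        hit = remaining & subject_flags[crit].astype(bool)
        steps.append((crit, int(hit.sum())))
        remaining &= ~hit
    report = ExclusionReport(steps=steps, n_initial=n_initial, n_final=int(remaining.sum()))
    if ratings is None:
        return remaining, report
    return ratings.loc[remaining[remaining].index], report


def _hittner_p(r_jk: float, r_jh: float, r_kh: float, n: int) -> float:
    """Two-sided p for H0: rho_jk == rho_jh (overlapping dependent correlations).

    Back-transformed z statistic (Hittner-May-Silver form of the Steiger
    test): the two correlations share variable j, and r_kh enters through the
    covariance of the Fisher-z estimates.
    """
    clip = 1.0 - 1e-12
    z1 = np.arctanh(np.clip(r_jk, -clip, clip))
    z2 = np.arctanh(np.clip(r_jh, -clip, clip))
    if z1 == z2:
        return 1.0
    rbar = np.tanh((z1 + z2) / 2.0)
    denom = (1.0 - rbar**2) ** 2
    c = (r_kh * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_kh**2)) / denom
    var = 2.0 * (1.0 - c)
    if var <= 0:
        return 0.0  # degenerate near-collinear case: difference is decisive
    z = (z1 - z2) * np.sqrt((n - 3) / var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class RedundancyReport:
    """Candidate pairs with test outcomes and the resulting merge plan."""

    pairs: pd.DataFrame  # item_a, item_b, correlation, frac_significant, verdict
    merge_map: dict[str, str] = field(default_factory=dict)
    r_min: float = 0.5
    alpha: float = 0.05
    prop_max: float = 0.25

    @property
    def flagged(self) -> list[tuple[str, str]]:
        sel = self.pairs[self.pairs["verdict"] == "redundant"]
        return list(zip(sel["item_a"], sel["item_b"]))


def detect_redundant_pairs(
    ratings: pd.DataFrame,
    r_min: float = 0.50,
    alpha: float = 0.05,
    prop_max: float = 0.25,
) -> RedundancyReport:
    """Flag item pairs that are statistical near-duplicates.

    A pair is a candidate when its Spearman correlation is >= ``r_min``; it is
    flagged redundant when fewer than ``prop_max`` of its dependent-correlation
    comparisons against all third items differ at level ``alpha``. Resolution
    is greedy from the highest-correlation candidate down; an item already in
    a composite is ineligible for further pairing, so the merge map is a
    partition.
    """
    if ratings.shape[1] < 3:
        raise ValueError("need at least 3 items")
    complete = ratings.dropna(axis=0, how="any")
    n = len(complete)
    if n < 50:
        raise ValueError(f"need >= 50 complete cases, got {n}")
    items = list(ratings.columns)
    constant = [c for c in items if complete[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant items excluded from redundancy testing: {constant}")
    usable = [c for c in items if c not in constant]
    sub = complete[usable]
    R = pd.DataFrame(
        spearman_corr(sub).matrix, index=usable, columns=usable
    )
    cands = []
    for a_i in range(len(usable)):
        for b_i in range(a_i + 1, len(usable)):
            a, b = usable[a_i], usable[b_i]
            if R.loc[a, b] >= r_min:
                cands.append((float(R.loc[a, b]), a, b))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: set[str] = set()
    rows = []
    merge_map: dict[str, str] = {}
    for r_ab, a, b in cands:
        others = [c for c in usable if c not in (a, b)]
        pvals = [
            _hittner_p(float(R.loc[a, c]), float(R.loc[b, c]), float(R.loc[a, b]), n)
            for c in others
        ]
        frac_sig = float(np.mean([p < alpha for p in pvals])) if pvals else 0.0
        if a in taken or b in taken:
            verdict = "ineligible"
        elif frac_sig < prop_max:
            verdict = "redundant"
            taken.update((a, b))
            composite = f"{a}+{b}"
            merge_map[a] = composite
            merge_map[b] = composite
        else:
            verdict = "distinct"
        rows.append((a, b, r_ab, frac_sig, verdict))
    pairs = pd.DataFrame(
        rows, columns=["item_a", "item_b", "correlation", "frac_significant", "verdict"]
    )
    return RedundancyReport(
        pairs=pairs, merge_map=merge_map, r_min=r_min, alpha=alpha, prop_max=prop_max
    )


def merge_items(ratings: pd.DataFrame, merge_map: dict[str, str]) -> pd.DataFrame:
    """Replace each composite's member items with their per-subject average.

    The composite is missing whenever any member is missing (conservative);
    non-merged items pass through unchanged. Column order keeps each composite
    at the position of its first member.
    """
    unknown = [k for k in merge_map if k not in ratings.columns]
    if unknown:
        raise KeyError(f"merge_map references unknown items: {unknown}")
    groups: dict[str, list[str]] = {}
    for item, comp in merge_map.items():
        groups.setdefault(comp, []).append(item)
    for comp, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"composite {comp!r} has a single member {members}")
    out: dict[str, pd.Series] = {}
    done: set[str] = set()
    for col in ratings.columns:
        if col in done:
            continue
        if col in merge_map:
            comp = merge_map[col]
            members = [c for c in ratings.columns if merge_map.get(c) == comp]
            out[comp] = ratings[members].mean(axis=1, skipna=False)
            done.update(members)
        else:
            out[col] = ratings[col]
            done.add(col)
    return pd.DataFrame(out, index=ratings.index)


def flag_burdensome(
    ratings: pd.DataFrame, subscale_items: list[str], cutoff: float = 6
) -> pd.Series:
    """Flag subjects whose subscale sum strictly exceeds ``cutoff``.

    The default cutoff of 6 mirrors the clinically validated threshold for
    burdensome depressive symptomatology on a 10-item severity subscale.
    Subjects missing any subscale item are flagged missing (pd.NA), never
    silently False.
    """
    missing = [c for c in subscale_items if c not in ratings.columns]
    if missing:
        raise KeyError(f"subscale items not present: {missing}")
    total = ratings[subscale_items].sum(axis=1, skipna=False)
    flag = pd.Series(pd.NA, index=ratings.index, dtype="boolean")
    ok = total.notna()
    flag[ok] = total[ok] > cutoff
    return flag
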