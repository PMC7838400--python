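"""Resampling inference for damage-modularity relationships and hub topography.

The damage-modularity analysis asks, across lesion masks, whether masks that
hit global (PC) or local (WD) hubs harder produce systematically different
modularity. Its significance machinery:

* ``permutation_p`` — permutation test of a single Pearson correlation,
  permuting one variable; one-sided in the direction of the observed r by
  default (two-sided available). Uses the add-one correction
  p = (1 + #extreme) / (n_perm + 1), so p is never exactly zero.
* ``group_permutation_p`` — for a pseudo-lesion cohort with one modularity
  column per control subject: the statistic is the mean over controls of the
  per-control correlation, and the null permutes the *mask-level* damage
  vector once per permutation, shared across controls (masks are the
  exchangeable units).
* ``bootstrap_compare`` — compares the real group's single correlation to
  the bootstrap distribution of the pseudo group's mean correlation
  (resample the per-control correlations with replacement); two-sided by
  tail doubling, capped at 1.
* ``group_ttests`` — paired/independent two-sided t-tests with Bonferroni
  correction; zero-variance inputs are reported as degenerate rather than
  silently NaN.
* ``compare_hub_sets`` — lost/new/shared hubs between two groups plus a
  1-df chi-square goodness-of-fit of the second set's left/right counts
  against 50/50 (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, IncompatibleInputError, ParameterError


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise IncompatibleInputError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero-variance input to correlation")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson correlation."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


SIDES = ("one_sided", "two_sided", "greater", "less")


def permutation_p(
    x,
    y,
    n_perm: int = 10_000,
    side: str = "one_sided",
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation p-value for the Pearson correlation of x and y.

    Permutes ``y``. ``side='one_sided'`` tests in the direction of the
    observed r (r* >= r_obs for positive r_obs, r* <= r_obs for negative) —
    the convention that reproduces the printed p-values this pipeline
    emulates, but note it is equivalent to a two-sided test at twice the
    nominal level, so its null rejection rate at alpha is about 2*alpha.
    ``side='greater'`` / ``side='less'`` test a pre-specified direction and
    are exactly calibrated; ``side='two_sided'`` uses |r*| >= |r_obs|.
    Returns (r_obs, p) with the add-one correction.
    """
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}, got {side!r}")
    x, y = _check_pair(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    xs, ys = _standardize(x), _standardize(y)
    r_obs = float(xs @ ys) / n
    perms = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    r_null = perms @ xs / n
    extreme = _extreme_mask(r_null, r_obs, side)
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return r_obs, p


def _extreme_mask(r_null: np.ndarray, r_obs: float, side: str) -> np.ndarray:
    if side == "two_sided":
        return np.abs(r_null) >= abs(r_obs) - 1e-12
    if side == "greater" or (side == "one_sided" and r_obs >= 0):
        return r_null >= r_obs - 1e-12
    return r_null <= r_obs + 1e-12


def permutation_p_exhaustive(x, y, side: str = "one_sided") -> tuple[float, float]:
    """Exact permutation p over all n! permutations (small n only).

    Independent oracle for :func:`permutation_p`; p = #extreme / n!
    (the identity permutation is part of the enumeration, so no add-one
    term is needed).
    """
    from itertools import permutations

    x, y = _check_pair(x, y)
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}, got {side!r}")
    n = len(x)
    if n > 8:
        raise ParameterError("exhaustive enumeration limited to n <= 8")
    xs, ys = _standardize(x), _standardize(y)
    r_obs = float(xs @ ys) / n
    r_all = np.array([xs @ ys[list(pm)] / n for pm in permutations(range(n))])
    return r_obs, float(_extreme_mask(r_all, r_obs, side).mean())


def group_permutation_p(
    damage,
    q_matrix,
    n_perm: int = 10_000,
    side: str = "one_sided",
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float, float]:
    """Mean per-control correlation with a mask-permutation null.

    ``damage`` is the per-mask damage score (length n_masks); ``q_matrix``
    is n_masks x n_controls of modularity values. Returns
    (per-control r values, mean r, p). Each permutation shuffles the damage
    vector once and recomputes all per-control correlations, preserving the
    dependence between controls under the null.
    """
    damage = np.asarray(damage, dtype=float)
    q_matrix = np.atleast_2d(np.asarray(q_matrix, dtype=float))
    if q_matrix.shape[0] != len(damage):
        raise IncompatibleInputError(
            f"q_matrix has {q_matrix.shape[0]} rows for {len(damage)} masks"
        )
    if damage.std() == 0:
        raise DegenerateInputError("zero-variance damage vector")
    for c in range(q_matrix.shape[1]):
        if q_matrix[:, c].std() == 0:
            raise DegenerateInputError(f"zero-variance modularity column for control {c}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(damage)
    ds = _standardize(damage)
    qs = np.apply_along_axis(_standardize, 0, q_matrix)
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}, got {side!r}")
    r_per_control = ds @ qs / n
    mean_r = float(r_per_control.mean())
    perms = rng.permuted(np.tile(ds, (n_perm, 1)), axis=1)
    null_means = (perms @ qs / n).mean(axis=1)
    extreme = _extreme_mask(null_means, mean_r, side)
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return r_per_control, mean_r, p


def bootstrap_compare(
    real_r: float,
    pseudo_rs,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided bootstrap p for real-vs-pseudo correlation difference.

    Resamples the per-control pseudo correlations with replacement, takes
    the mean each time, and doubles the smaller tail probability of
    ``real_r`` under that bootstrap distribution (capped at 1).
    """
    pseudo_rs = np.asarray(pseudo_rs, dtype=float)
    if len(pseudo_rs) < 2:
        raise DegenerateInputError("need >= 2 pseudo correlations to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(pseudo_rs), size=(n_boot, len(pseudo_rs)))
    boot_means = pseudo_rs[idx].mean(axis=1)
    lo = int((boot_means <= real_r + 1e-12).sum())
    hi = int((boot_means >= real_r - 1e-12).sum())
    return min(1.0, 2.0 * min(lo, hi) / n_boot)


def group_ttests(
    q_by_group: dict[str, np.ndarray],
    comparisons: list[tuple[str, str, str]],
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Two-sided t-tests between groups with Bonferroni correction.

    ``comparisons`` lists (group_a, group_b, design) with design
    ``'paired'`` or ``'independent'``. Bonferroni multiplies by
    ``n_comparisons`` (default: the number of comparisons), capping at 1.
    Zero-variance (exactly constant) contrasts are flagged degenerate with
    NaN statistics instead of raising.
    """
    if n_comparisons is None:
        n_comparisons = len(comparisons)
    rows = []
    for a, b, design in comparisons:
        xa = np.asarray(q_by_group[a], dtype=float)
        xb = np.asarray(q_by_group[b], dtype=float)
        degenerate = False
        if design == "paired":
            if len(xa) != len(xb):
                raise IncompatibleInputError(
                    f"paired groups {a}/{b} have lengths {len(xa)}/{len(xb)}"
                )
            diff = xa - xb
            df = len(diff) - 1
            if np.std(diff) == 0 or len(diff) < 2:
                degenerate = True
                t, p = np.nan, np.nan
            else:
                res = stats.ttest_rel(xa, xb)
                t, p = float(res.statistic), float(res.pvalue)
        elif design == "independent":
            df = len(xa) + len(xb) - 2
            if (np.std(np.concatenate([xa, xb])) == 0) or min(len(xa), len(xb)) < 2:
                degenerate = True
                t, p = np.nan, np.nan
            else:
                res = stats.ttest_ind(xa, xb)
                t, p = float(res.statistic), float(res.pvalue)
        else:
            raise ParameterError(f"design must be paired or independent, got {design!r}")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "design": design,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * n_comparisons) if not degenerate else np.nan,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HubComparison:
    """Lost/new/shared hubs between set A and set B plus B's laterality."""

    lost: set[int]
    new: set[int]
    shared: set[int]
    rh_fraction_A: float
    rh_fraction_B: float
    chi2_B: float
    p_B: float


def _rh_fraction(nodes: set[int], node_table: pd.DataFrame) -> float:
    if not nodes:
        return float("nan")
    hemi = node_table.set_index("node_id")["hemisphere"]
    return float((hemi.loc[sorted(nodes)] == "R").mean())


def compare_hub_sets(hubs_A, hubs_B, node_table: pd.DataFrame) -> HubComparison:
    """Lost (A not B), new (B not A), shared hubs; chi-square of B's laterality.

    The chi-square is the 1-df goodness-of-fit of B's left/right hub counts
    against an even split, without continuity correction.
    """
    A = {int(n) for n in hubs_A}
    B = {int(n) for n in hubs_B}
    known = set(node_table["node_id"].tolist())
    if not A <= known or not B <= known:
        raise ParameterError("hub sets contain nodes absent from the node table")
    hemi = node_table.set_index("node_id")["hemisphere"]
    if B:
        n_r = int((hemi.loc[sorted(B)] == "R").sum())
        n_l = len(B) - n_r
        chi2, p = stats.chisquare([n_l, n_r])
        chi2, p = float(chi2), float(p)
    else:
        chi2, p = float("nan"), float("nan")
    return HubComparison(
        lost=A - B,
        new=B - A,
        shared=A & B,
        rh_fraction_A=_rh_fraction(A, node_table),
        rh_fraction_B=_rh_fraction(B, node_table),
        chi2_B=chi2,
        p_B=p,
    )
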