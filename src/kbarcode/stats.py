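"""Nonparametric comparisons of abundance groups and fold-change tables.

Abundance distributions across samples are rarely normal, so group
differences use the Mann–Whitney U test throughout: exact by full
enumeration of the permutation null when both groups are small (≤ 10),
tie-corrected normal approximation otherwise.  Fold changes are log2
ratios with a pseudocount so zero abundances stay finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .barcode import ParameterError

logger = logging.getLogger("kbarcode")

EXACT_MAX_N = 10
DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Mann–Whitney comparison of one feature between two groups."""

    feature: str
    group_a: list[float]
    group_b: list[float]
    u_a: float
    u_b: float
    p_value: float
    median_a: float
    median_b: float


@dataclass
class VolcanoRow:
    """Mean paired log2 fold change and its significance for one genome."""

    genome_id: str
    phylogroup: str
    n_pairs: int
    mean_log2fc: float
    p_value: float
    significant: bool


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U_x = #{(i,j): x_i > y_j} + ½·#ties, via midranks."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[:nx].sum()
    return float(rx - nx * (nx + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation p by enumerating all C(n, n_x) group assignments.

    Handles ties correctly because the null distribution is built from the
    observed pooled values themselves.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = nx * (nx + 1) / 2.0
    u_obs = float(ranks[:nx].sum() - offset)
    us = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(nx + ny), nx)),
        dtype=float,
        count=math.comb(nx + ny, nx),
    )
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    if alternative == "less":
        return float(p_le)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann–Whitney U test; returns (U_x, p).

    method="auto" enumerates the full permutation null when both groups
    have ≤ 10 observations and otherwise uses the tie-corrected normal
    approximation (with continuity correction).  U_x counts pairs where x
    exceeds y, ties contributing ½; U_x + U_y = n_x · n_y always.
    """
    if alternative not in {"two-sided", "less", "greater"}:
        raise ParameterError(f"unknown alternative {alternative!r}")
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ParameterError("Mann–Whitney groups must be non-empty")
    u_x = _u_statistic(xa, ya)
    if method == "exact" or (
        method == "auto" and max(xa.size, ya.size) <= EXACT_MAX_N
    ):
        return u_x, _exact_p(xa, ya, alternative)
    res = sps.mannwhitneyu(xa, ya, alternative=alternative, method="asymptotic")
    return u_x, float(res.pvalue)


def compare_groups(
    values_by_feature: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    alternative: str = "two-sided",
) -> list[GroupComparison]:
    """Mann–Whitney comparison per feature (genome or phylogroup)."""
    out = []
    for feature, (a, b) in sorted(values_by_feature.items()):
        ua, p = mann_whitney_u(a, b, alternative=alternative)
        out.append(
            GroupComparison(
                feature=feature,
                group_a=list(map(float, a)),
                group_b=list(map(float, b)),
                u_a=ua,
                u_b=len(a) * len(b) - ua,
                p_value=p,
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
            )
        )
    return out


def default_pseudocount(values: Sequence[float]) -> float:
    """Half the smallest nonzero value — the default log2 fold-change eps."""
    nz = [v for v in values if v > 0]
    if not nz:
        raise ParameterError("cannot derive a pseudocount from all-zero values")
    return min(nz) / 2.0


def fold_change(before: float, after: float, eps: float) -> float:
    """log2((after + eps) / (before + eps)); eps keeps zeros finite."""
    if eps <= 0:
        raise ParameterError("pseudocount eps must be > 0")
    if before < 0 or after < 0:
        raise ParameterError("abundances must be non-negative")
    return math.log2((after + eps) / (before + eps))


def volcano_table(
    abundance: pd.DataFrame,
    design: pd.DataFrame,
    before_tp=None,
    after_tp=None,
    phylogroups: Mapping[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    eps: float | None = None,
    alternative: str = "two-sided",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-genome mean paired log2 fold change with Mann–Whitney p.

    ``abundance`` is a long table (columns sample_id, genome_id,
    normalized); ``design`` maps samples to (subject, time_point).  The two
    compared time points default to the two smallest in the design.  For
    each genome the fold change is averaged over subjects present at both
    time points; p comes from a two-sided Mann–Whitney U on the before
    vs after value groups across subjects.  Genomes missing in more than
    half of the pairs are excluded (logged).  Raw p is compared with
    ``alpha`` unless ``bh_correct`` applies Benjamini–Hochberg first.
    """
    tps = sorted(design["time_point"].unique())
    if before_tp is None:
        before_tp = tps[0]
    if after_tp is None:
        after_tp = tps[1]
    merged = abundance.merge(
        design[["sample_id", "subject", "time_point"]], on="sample_id", how="inner"
    )
    merged = merged[merged["time_point"].isin([before_tp, after_tp])]
    subjects = sorted(merged["subject"].unique())
    n_subjects = len(subjects)
    if n_subjects < 3:
        raise ParameterError("volcano_table needs >= 3 paired subjects")
    if eps is None:
        eps = default_pseudocount(merged["normalized"].tolist())

    rows = []
    pvals = []
    for genome, sub in merged.groupby("genome_id", sort=True):
        wide = sub.pivot_table(
            index="subject", columns="time_point", values="normalized", aggfunc="first"
        )
        paired = wide.dropna(subset=[before_tp, after_tp])
        if len(paired) <= n_subjects / 2:
            logger.warning(
                "volcano_table: %s present in only %d/%d pairs; excluded",
                genome,
                len(paired),
                n_subjects,
            )
            continue
        before = paired[before_tp].to_numpy(dtype=float)
        after = paired[after_tp].to_numpy(dtype=float)
        fcs = [fold_change(b, a, eps) for b, a in zip(before, after)]
        _, p = mann_whitney_u(before, after, alternative=alternative)
        pg = phylogroups.get(str(genome), "") if phylogroups else ""
        rows.append(
            {
                "genome_id": str(genome),
                "phylogroup": pg,
                "n_pairs": len(paired),
                "mean_log2fc": float(np.mean(fcs)),
                "p_value": p,
            }
        )
        pvals.append(p)
    df = pd.DataFrame(
        rows, columns=["genome_id", "phylogroup", "n_pairs", "mean_log2fc", "p_value"]
    )
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["significant"] = reject
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def group_comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.feature,
                "n_a": len(c.group_a),
                "n_b": len(c.group_b),
                "u_a": c.u_a,
                "u_b": c.u_b,
                "p_value": c.p_value,
                "median_a": c.median_a,
                "median_b": c.median_b,
            }
            for c in comparisons
        ]
    )
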