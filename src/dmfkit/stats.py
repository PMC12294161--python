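"""Per-fragment one-way ANOVA and differentially-methylated-fragment calling.

Each retained fragment contributes one methylation percentage per sample.
Group differences are scored with the classical one-way ANOVA F statistic,
``F = MS_between / MS_within`` on ``(k-1, N-k)`` degrees of freedom, applied
to raw percentages (no variance-stabilising transform by default).  A
fragment is called a DMF for a pairwise contrast when its raw p-value falls
below ``p_thresh`` and the difference of group means reaches ``min_diff``
percentage points; no multiplicity adjustment is applied by default, the
rationale being that with very small cohorts a stringent raw-p threshold
avoids discarding true positives.  A Benjamini-Hochberg option is provided
for users who prefer FDR control.

Fragments whose within-group variance is exactly zero while the group means
differ are flagged ``degenerate`` (F is infinite, p reported as 0) so that
downstream filtering can treat them explicitly rather than silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import FragmentMatrix

__all__ = [
    "FStatResult",
    "anova_f",
    "test_all_fragments",
    "call_dmfs",
    "adjust_bh",
]

_DEGENERATE_RTOL = 1e-12  # SS_within below this fraction of SS_total counts as zero


@dataclass(frozen=True)
class FStatResult:
    """One-way ANOVA F-test result for a single fragment."""

    f: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


def _f_decomposition(
    x: np.ndarray, group_idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised between/within sums of squares.

    ``x`` is (n_fragments, n_samples); ``group_idx`` maps each sample column
    to 0..k-1.  Returns (ssb, ssw, group_means) where group_means is
    (n_fragments, k).
    """
    n = x.shape[1]
    counts = np.bincount(group_idx, minlength=k).astype(float)
    sums = np.zeros((x.shape[0], k))
    sqs = np.zeros((x.shape[0], k))
    for g in range(k):
        cols = group_idx == g
        sums[:, g] = x[:, cols].sum(axis=1)
        sqs[:, g] = (x[:, cols] ** 2).sum(axis=1)
    grand = x.sum(axis=1) / n
    means = sums / counts
    ssb = ((means - grand[:, None]) ** 2 * counts).sum(axis=1)
    ssw = (sqs - counts * means**2).sum(axis=1)
    ssw = np.maximum(ssw, 0.0)  # guard tiny negative rounding
    return ssb, ssw, means


def _f_and_p(
    ssb: np.ndarray, ssw: np.ndarray, df1: int, df2: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sst = ssb + ssw
    degenerate = (ssw <= _DEGENERATE_RTOL * sst) & (ssb > 0)
    constant = sst <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    f = np.where(degenerate, np.inf, f)
    f = np.where(constant, 0.0, f)
    p = np.empty_like(f)
    regular = ~(degenerate | constant)
    p[regular] = sps.f.sf(f[regular], df1, df2)
    p[degenerate] = 0.0
    p[constant] = 1.0
    return f, p, degenerate


def anova_f(values_by_group: list[np.ndarray]) -> FStatResult:
    """One-way ANOVA F-test across ``k >= 2`` groups of percentages.

    Each group needs at least two finite values.  If all values are
    identical F = 0 and p = 1; if the groups are internally constant but
    differ between each other the result is flagged degenerate with p = 0.
    """
    k = len(values_by_group)
    if k < 2:
        raise ValueError("at least two groups are required")
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    x = np.concatenate(groups)[None, :]
    group_idx = np.concatenate(
        [np.full(g.size, i, dtype=int) for i, g in enumerate(groups)]
    )
    n = x.shape[1]
    df1, df2 = k - 1, n - k
    ssb, ssw, _ = _f_decomposition(x, group_idx, k)
    f, p, degenerate = _f_and_p(ssb, ssw, df1, df2)
    return FStatResult(
        f=float(f[0]), df1=df1, df2=df2, p=float(p[0]), degenerate=bool(degenerate[0])
    )


def test_all_fragments(
    matrix: FragmentMatrix, groups: list[str] | None = None
) -> pd.DataFrame:
    """F-test every fragment across the given groups (default: all groups).

    The matrix must be complete over the selected groups (run
    ``filter_complete`` first); a missing value is an error naming the
    fragment.  Returns a DataFrame indexed by fragment id with columns
    ``f``, ``df1``, ``df2``, ``p``, ``degenerate`` plus one
    ``mean_<group>`` column per group.  Raw p-values only; see
    :func:`adjust_bh` for an optional FDR adjustment.
    """
    sheet = matrix.sheet
    groups = groups if groups is not None else sheet.groups
    sheet.require_testable(groups)
    samples: list[str] = []
    group_idx: list[int] = []
    for gi, g in enumerate(groups):
        for s in sheet.samples_for(g):
            samples.append(s)
            group_idx.append(gi)
    x = matrix.percent[samples].to_numpy(float)
    bad = ~np.isfinite(x)
    if bad.any():
        frag = matrix.percent.index[np.argmax(bad.any(axis=1))]
        raise ValueError(
            f"missing value in fragment {frag}; apply filter_complete first"
        )
    gidx = np.asarray(group_idx)
    k = len(groups)
    df1, df2 = k - 1, x.shape[1] - k
    ssb, ssw, means = _f_decomposition(x, gidx, k)
    f, p, degenerate = _f_and_p(ssb, ssw, df1, df2)
    out = pd.DataFrame(
        {"f": f, "df1": df1, "df2": df2, "p": p, "degenerate": degenerate},
        index=matrix.percent.index,
    )
    for gi, g in enumerate(groups):
        out[f"mean_{g}"] = means[:, gi]
    return out


def call_dmfs(
    matrix: FragmentMatrix,
    case_group: str,
    ref_group: str,
    p_thresh: float = 0.05,
    min_diff: float = 10.0,
    strict_diff: bool = False,
) -> pd.DataFrame:
    """Pairwise DMF calling: F-test case vs reference plus threshold flags.

    Returns one record per fragment with columns ``contrast``,
    ``mean_case``, ``mean_ref``, ``delta`` (case minus reference, percentage
    points), ``f``, ``df1``, ``df2``, ``p``, ``degenerate``, ``direction``
    (hyper for delta > 0, hypo for delta < 0, unchanged for exact 0) and
    ``passes``.  The difference threshold is inclusive (``|delta| >=
    min_diff``) unless ``strict_diff``.  Fragment coordinates are attached
    when the matrix carries them.
    """
    for g in (case_group, ref_group):
        if g not in matrix.sheet.groups:
            raise KeyError(f"unknown group {g!r}")
    res = test_all_fragments(matrix, groups=[case_group, ref_group])
    delta = res[f"mean_{case_group}"] - res[f"mean_{ref_group}"]
    if strict_diff:
        big_enough = delta.abs() > min_diff
    else:
        big_enough = delta.abs() >= min_diff
    out = pd.DataFrame(
        {
            "contrast": f"{case_group}_vs_{ref_group}",
            "mean_case": res[f"mean_{case_group}"],
            "mean_ref": res[f"mean_{ref_group}"],
            "delta": delta,
            "f": res["f"],
            "df1": res["df1"],
            "df2": res["df2"],
            "p": res["p"],
            "degenerate": res["degenerate"],
            "direction": np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "unchanged")),
            "passes": (res["p"] < p_thresh) & big_enough,
        },
        index=res.index,
    )
    if len(matrix.fragments):
        coords = matrix.fragments.loc[out.index, ["chrom", "start", "end"]]
        out = pd.concat([coords, out], axis=1)
    return out


def adjust_bh(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")
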