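"""Joint analysis of two disease-vs-control DMF sets.

Two pairwise contrasts against a shared reference (here Long COVID vs HC and
ME/CFS vs HC) are intersected on exact fragment coordinates.  For every
common fragment the per-contrast methylation differences delta_A and delta_B
(percentage points, case minus reference) give the cross-cohort difference
``delta_AB = delta_A - delta_B``, a concordance class (both hypermethylated,
both hypomethylated, or opposite directions), and — for same-direction
records — which cohort shows the larger magnitude of change.  Fragments
whose cross-cohort difference exceeds a threshold (strictly >10 pp by
default) form the "divergent" subset, reported sorted by delta_AB ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VennCounts",
    "ConcordanceSummary",
    "intersect_dmfs",
    "cross_cohort_diff",
    "select_divergent",
    "concordance_summary",
    "pearson_common",
    "inventory_by_region",
]


@dataclass(frozen=True)
class VennCounts:
    """Sizes of the two DMF sets' exclusive and shared parts."""

    only_a: int
    common: int
    only_b: int

    def __post_init__(self) -> None:
        if min(self.only_a, self.common, self.only_b) < 0:
            raise ValueError("Venn counts must be non-negative")

    @property
    def size_a(self) -> int:
        return self.only_a + self.common

    @property
    def size_b(self) -> int:
        return self.only_b + self.common


@dataclass(frozen=True)
class ConcordanceSummary:
    """Direction/concordance tallies over common-fragment records.

    ``both_hyper``/``both_hypo``/``opposite`` partition the records with two
    non-zero deltas; exact-zero deltas fall into ``unchanged`` rather than
    being forced into a direction.  Within the same-direction classes the
    ``*_larger_a``/``*_larger_b`` counts compare |delta_A| with |delta_B|;
    opposite-direction records are split by which cohort is the
    hypermethylated one.
    """

    n: int
    both_hyper: int
    both_hypo: int
    opposite: int
    unchanged: int
    hyper_larger_a: int
    hyper_larger_b: int
    hyper_tie: int
    hypo_larger_a: int
    hypo_larger_b: int
    hypo_tie: int
    opposite_hyper_a: int
    opposite_hyper_b: int


def _key_frame(records: pd.DataFrame) -> pd.DataFrame:
    req = {"chrom", "start", "end"}
    if not req <= set(records.columns):
        raise ValueError(f"DMF records need columns {sorted(req)}")
    return records


def intersect_dmfs(
    set_a: pd.DataFrame, set_b: pd.DataFrame, passing_only: bool = True
) -> tuple[pd.DataFrame, VennCounts]:
    """Intersect two DMF tables on exact fragment coordinates.

    With ``passing_only`` (default) each table is first restricted to its
    threshold-passing records.  Fragment identity is exact coordinate
    equality — both sets must derive from the same catalog; a fragment id
    appearing in both tables with different coordinates is an error.
    Returns the common records (columns suffixed ``_a``/``_b`` plus
    ``delta_ab``) and the Venn counts.
    """
    a, b = _key_frame(set_a), _key_frame(set_b)
    if passing_only and "passes" in a.columns:
        a = a[a["passes"]]
    if passing_only and "passes" in b.columns:
        b = b[b["passes"]]
    a = a.copy()
    b = b.copy()
    a["_key"] = [f"{c}:{s}-{e}" for c, s, e in zip(a["chrom"], a["start"], a["end"])]
    b["_key"] = [f"{c}:{s}-{e}" for c, s, e in zip(b["chrom"], b["start"], b["end"])]
    if a.index.name == "fragment_id" and b.index.name == "fragment_id":
        shared_ids = a.index.intersection(b.index)
        if len(shared_ids):
            ka = a.loc[shared_ids, "_key"]
            kb = b.loc[shared_ids, "_key"]
            if not (ka == kb).all():
                raise ValueError(
                    "coordinate mismatch between DMF sets; were they derived "
                    "from the same fragment catalog?"
                )
    meta_cols = [c for c in ("location", "gene_id", "tss_distance") if c in a.columns]
    common = a.merge(
        b.drop(columns=meta_cols, errors="ignore"),
        on=["_key", "chrom", "start", "end"],
        suffixes=("_a", "_b"),
    )
    common = common.set_index("_key").rename_axis("fragment_id")
    common["delta_ab"] = cross_cohort_diff(common["delta_a"], common["delta_b"])
    counts = VennCounts(
        only_a=len(a) - len(common), common=len(common), only_b=len(b) - len(common)
    )
    return common, counts


def cross_cohort_diff(delta_a, delta_b):
    """Cross-cohort methylation difference, ``delta_A - delta_B`` (pp)."""
    return delta_a - delta_b


def select_divergent(
    common: pd.DataFrame, min_cross_diff: float = 10.0
) -> pd.DataFrame:
    """Records with ``|delta_AB|`` strictly above the threshold.

    Sorted ascending by ``delta_ab`` (most extreme negative divergence
    first), the conventional presentation for cross-cohort tables.
    """
    if "delta_ab" not in common.columns:
        common = common.assign(
            delta_ab=cross_cohort_diff(common["delta_a"], common["delta_b"])
        )
    out = common[common["delta_ab"].abs() > min_cross_diff]
    return out.sort_values("delta_ab", kind="mergesort")


def concordance_summary(records: pd.DataFrame) -> ConcordanceSummary:
    """Tally direction concordance and magnitude comparisons; see class doc."""
    da = records["delta_a"].to_numpy(float)
    db = records["delta_b"].to_numpy(float)
    both_hyper = (da > 0) & (db > 0)
    both_hypo = (da < 0) & (db < 0)
    opposite = ((da > 0) & (db < 0)) | ((da < 0) & (db > 0))
    unchanged = (da == 0) | (db == 0)
    larger_a = np.abs(da) > np.abs(db)
    larger_b = np.abs(db) > np.abs(da)
    tie = np.abs(da) == np.abs(db)
    return ConcordanceSummary(
        n=len(records),
        both_hyper=int(both_hyper.sum()),
        both_hypo=int(both_hypo.sum()),
        opposite=int(opposite.sum()),
        unchanged=int(unchanged.sum()),
        hyper_larger_a=int((both_hyper & larger_a).sum()),
        hyper_larger_b=int((both_hyper & larger_b).sum()),
        hyper_tie=int((both_hyper & tie).sum()),
        hypo_larger_a=int((both_hypo & larger_a).sum()),
        hypo_larger_b=int((both_hypo & larger_b).sum()),
        hypo_tie=int((both_hypo & tie).sum()),
        opposite_hyper_a=int((opposite & (da > 0)).sum()),
        opposite_hyper_b=int((opposite & (db > 0)).sum()),
    )


def pearson_common(common: pd.DataFrame, mode: str = "cohort_means") -> float:
    """Pearson correlation across the common fragments.

    ``cohort_means`` (default) correlates the per-fragment mean methylation
    of cohort A against cohort B (columns ``mean_case_a``/``mean_case_b``);
    ``deltas`` correlates the two contrasts' methylation differences.
    """
    if len(common) < 3:
        raise ValueError("need at least 3 common fragments")
    if mode == "cohort_means":
        x = common["mean_case_a"].to_numpy(float)
        y = common["mean_case_b"].to_numpy(float)
    elif mode == "deltas":
        x = common["delta_a"].to_numpy(float)
        y = common["delta_b"].to_numpy(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a vector")
    return float(sps.pearsonr(x, y).statistic)


def inventory_by_region(
    records: pd.DataFrame, location_col: str = "location"
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-region record lists plus direction tallies.

    Returns ``(tables, tally)`` where ``tables`` maps each region label to
    its records and ``tally`` counts hyper-in-both, hypo-in-both and
    discordant records per label.
    """
    if location_col not in records.columns:
        raise ValueError(f"records lack a {location_col!r} column")
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for label, sub in records.groupby(location_col, sort=True):
        tables[str(label)] = sub
        summ = concordance_summary(sub)
        rows.append(
            {
                "location": label,
                "n": summ.n,
                "hyper_in_both": summ.both_hyper,
                "hypo_in_both": summ.both_hypo,
                "discordant": summ.opposite,
            }
        )
    return tables, pd.DataFrame(rows).set_index("location")
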