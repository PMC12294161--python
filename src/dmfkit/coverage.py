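"""Per-CpG bisulphite calls and their aggregation to fragment methylation.

The input dialect is the Bismark coverage file: six tab-separated columns,
``chrom, start(1-based), end, percent_methylated, count_methylated,
count_unmethylated``.  Counts are primary; the percent column is only
cross-checked.  Calls are aggregated to per-sample fragment methylation by
read-count-weighted pooling over the fragment's CpGs, and a fragment x
sample matrix is assembled with explicit missingness: a percentage is
present only when the per-sample coverage thresholds (minimum total reads,
minimum distinct covered CpGs) are met.  The complete-coverage filter then
keeps exactly the fragments measurable in every sample of every group.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import FragmentCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageParseError",
    "SampleSheet",
    "FragmentMatrix",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "destrand_calls",
    "aggregate_to_fragments",
    "build_matrix",
    "filter_complete",
    "global_summaries",
]


class CoverageParseError(ValueError):
    """Raised when a coverage file line cannot be interpreted."""


@dataclass
class SampleSheet:
    """Sample-to-group assignment with optional age/sex metadata.

    ``frame`` columns: ``sample_id``, ``group`` and optionally ``age``,
    ``sex``.  Sample ids must be unique and every sample needs a group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sample_id", "group"}
        if not req <= set(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(req)}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        if self.frame["group"].isna().any() or (self.frame["group"] == "").any():
            raise ValueError("every sample must have a group label")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.frame["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def samples_for(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        sel = self.frame["group"] == group
        return list(self.frame.loc[sel, "sample_id"])

    def require_testable(self, groups: list[str] | None = None) -> None:
        """Check the >=2 groups / >=2 samples-per-group requirement."""
        groups = groups if groups is not None else self.groups
        if len(groups) < 2:
            raise ValueError("at least two groups are required")
        for g in groups:
            if len(self.samples_for(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype={"sample_id": str, "group": str}))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_bismark_coverage(
    path: str | Path,
    destrand: bool = False,
    cpg_positions: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Parse a Bismark coverage file into per-CpG calls.

    Returns a DataFrame with columns ``chrom``, ``pos`` (0-based plus-strand
    C of the CpG), ``meth``, ``unmeth``.  The percent column is ignored in
    favour of the counts; a disagreement beyond 0.5 percentage points is
    logged as a warning.  With ``destrand=True``, calls on the minus-strand
    C (position p+1 of a CpG whose plus-strand C is at p) are merged onto p;
    supplying ``cpg_positions`` (per-chromosome sorted plus-strand C
    coordinates, e.g. from a located catalog) makes destranding exact,
    otherwise a p/p+1 adjacency heuristic is used.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CoverageParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated columns"
                )
            chrom, start_s, end_s, pct_s, meth_s, unmeth_s = parts[:6]
            try:
                start = int(start_s)
                end = int(end_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise CoverageParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if start > end:
                raise CoverageParseError(
                    f"{path}: line {lineno}: start > end ({start} > {end})"
                )
            if min(start, end, meth, unmeth) < 0:
                raise CoverageParseError(f"{path}: line {lineno}: negative value")
            total = meth + unmeth
            if total > 0 and abs(pct - 100.0 * meth / total) > 0.5:
                logger.warning(
                    "%s: line %d: percent column (%.2f) disagrees with counts "
                    "(%.2f); counts win", path, lineno, pct, 100.0 * meth / total,
                )
            rows.append((chrom, start - 1, meth, unmeth))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    if destrand:
        calls = destrand_calls(calls, cpg_positions)
    return calls


def write_bismark_coverage(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls back out in the coverage dialect (1-based, counts primary)."""
    total = calls["meth"] + calls["unmeth"]
    pct = np.where(total > 0, 100.0 * calls["meth"] / total.replace(0, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"] + 1,
            "end": calls["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": calls["meth"],
            "unmeth": calls["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def destrand_calls(
    calls: pd.DataFrame, cpg_positions: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Merge minus-strand CpG calls onto the plus-strand C coordinate.

    Idempotent: once merged, no call sits at a known minus-strand position.
    """
    if calls.empty:
        return calls.copy()
    parts = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        sub = sub.copy()
        if cpg_positions is not None and chrom in cpg_positions:
            plus = np.asarray(cpg_positions[chrom])
            is_minus = np.isin(sub["pos"].to_numpy() - 1, plus) & ~np.isin(
                sub["pos"].to_numpy(), plus
            )
        else:
            present = set(sub["pos"])
            # heuristic: p is a minus-strand call if p-1 is also present and
            # p-1 itself is not preceded by a call (i.e. p-1 looks plus-strand)
            is_minus = sub["pos"].map(
                lambda p: (p - 1) in present and (p - 2) not in present
            ).to_numpy()
        sub.loc[is_minus, "pos"] -= 1
        merged = sub.groupby("pos", as_index=False)[["meth", "unmeth"]].sum()
        merged.insert(0, "chrom", chrom)
        parts.append(merged)
    return pd.concat(parts, ignore_index=True)


def _cpg_to_fragment(catalog: FragmentCatalog) -> pd.DataFrame:
    """Long table mapping every catalog CpG to its fragment row index."""
    if catalog.cpg_positions is None:
        raise ValueError("catalog has no CpG positions; run locate_cpgs first")
    chroms = np.repeat(
        catalog.frame["chrom"].to_numpy(),
        [len(p) for p in catalog.cpg_positions],
    )
    frag_idx = np.repeat(
        np.arange(len(catalog)), [len(p) for p in catalog.cpg_positions]
    )
    pos = (
        np.concatenate(catalog.cpg_positions)
        if len(catalog.cpg_positions)
        else np.empty(0, dtype=int)
    )
    return pd.DataFrame({"chrom": chroms, "pos": pos, "frag_idx": frag_idx})


def aggregate_to_fragments(
    calls: pd.DataFrame,
    catalog: FragmentCatalog,
    min_total_reads: int = 10,
    min_cpgs: int = 2,
    weighted: bool = True,
) -> pd.DataFrame:
    """Aggregate one sample's CpG calls to per-fragment methylation.

    Returns a DataFrame indexed by ``fragment_id`` with columns ``percent``
    (NaN when thresholds unmet), ``total_reads`` and ``n_cpgs`` (distinct
    covered CpGs).  The default is read-count-weighted pooling,
    ``100 * sum(meth) / sum(meth + unmeth)``, which conserves counts;
    ``weighted=False`` averages per-CpG percentages instead.  Calls at
    positions not belonging to any catalog CpG are ignored (off-fragment
    CpGs), with a debug log of how many.
    """
    mapping = _cpg_to_fragment(catalog)
    covered = calls[(calls["meth"] + calls["unmeth"]) > 0]
    joined = covered.merge(mapping, on=["chrom", "pos"], how="left")
    off = joined["frag_idx"].isna()
    if off.any():
        logger.debug("%d calls at positions outside catalog CpGs ignored", off.sum())
    joined = joined[~off]
    grp = joined.groupby("frag_idx")
    meth = grp["meth"].sum()
    total = meth + grp["unmeth"].sum()
    ncpg = grp["pos"].nunique()

    n = len(catalog)
    total_all = np.zeros(n)
    ncpg_all = np.zeros(n, dtype=int)
    pct_all = np.full(n, np.nan)
    idx = grp.indices.keys()
    idx = np.asarray(list(idx), dtype=int)
    if len(idx):
        total_all[idx] = total.to_numpy()
        ncpg_all[idx] = ncpg.to_numpy()
        if weighted:
            pct_all[idx] = 100.0 * meth.to_numpy() / total.to_numpy()
        else:
            per_cpg = joined.assign(
                pct=100.0 * joined["meth"] / (joined["meth"] + joined["unmeth"])
            )
            pct_all[idx] = per_cpg.groupby("frag_idx")["pct"].mean().to_numpy()
    ok = (total_all >= min_total_reads) & (ncpg_all >= min_cpgs)
    pct_all[~ok] = np.nan
    return pd.DataFrame(
        {"percent": pct_all, "total_reads": total_all, "n_cpgs": ncpg_all},
        index=pd.Index(catalog.frame["fragment_id"], name="fragment_id"),
    )


@dataclass
class FragmentMatrix:
    """Fragments x samples methylation percentages with explicit missingness.

    ``percent`` is NaN wherever per-sample coverage thresholds were unmet;
    ``coverage`` and ``cpg_count`` are the companion total-read and
    distinct-covered-CpG matrices.  ``fragments`` carries the catalog
    coordinates aligned to the row index (fragment ids).
    """

    percent: pd.DataFrame
    coverage: pd.DataFrame
    cpg_count: pd.DataFrame
    sheet: SampleSheet
    fragments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.percent.columns) != self.sheet.samples:
            missing = set(self.sheet.samples) - set(self.percent.columns)
            if missing:
                raise ValueError(f"matrix lacks samples {sorted(missing)}")
            self.percent = self.percent[self.sheet.samples]
            self.coverage = self.coverage[self.sheet.samples]
            self.cpg_count = self.cpg_count[self.sheet.samples]
        vals = self.percent.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("methylation percentages must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.percent)

    def subset(self, fragment_ids) -> "FragmentMatrix":
        return replace(
            self,
            percent=self.percent.loc[fragment_ids],
            coverage=self.coverage.loc[fragment_ids],
            cpg_count=self.cpg_count.loc[fragment_ids],
            fragments=self.fragments.loc[fragment_ids]
            if len(self.fragments)
            else self.fragments,
        )

    def write(self, path: str | Path) -> None:
        """Persist the percent matrix as TSV ('NA' for missing)."""
        self.percent.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read(
        cls,
        path: str | Path,
        sheet: SampleSheet,
        fragments: pd.DataFrame | None = None,
    ) -> "FragmentMatrix":
        pct = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        shape = pd.DataFrame(np.nan, index=pct.index, columns=pct.columns)
        return cls(
            percent=pct,
            coverage=shape.copy(),
            cpg_count=shape.copy(),
            sheet=sheet,
            fragments=fragments if fragments is not None else pd.DataFrame(),
        )


def build_matrix(
    calls_by_sample: dict[str, pd.DataFrame],
    catalog: FragmentCatalog,
    sheet: SampleSheet,
    min_total_reads: int = 10,
    min_cpgs: int = 2,
    weighted: bool = True,
) -> FragmentMatrix:
    """Assemble the fragment x sample matrix from per-sample call tables."""
    missing = set(sheet.samples) - set(calls_by_sample)
    if missing:
        raise ValueError(f"no calls for samples {sorted(missing)}")
    pct, cov, ncpg = {}, {}, {}
    for sample in sheet.samples:
        agg = aggregate_to_fragments(
            calls_by_sample[sample], catalog, min_total_reads, min_cpgs, weighted
        )
        pct[sample] = agg["percent"]
        cov[sample] = agg["total_reads"]
        ncpg[sample] = agg["n_cpgs"]
    fragments = catalog.frame.set_index("fragment_id")
    return FragmentMatrix(
        percent=pd.DataFrame(pct),
        coverage=pd.DataFrame(cov),
        cpg_count=pd.DataFrame(ncpg),
        sheet=sheet,
        fragments=fragments,
    )


def filter_complete(
    matrix: FragmentMatrix, groups: list[str] | None = None
) -> FragmentMatrix:
    """Keep fragments with data for every sample in every (selected) group."""
    groups = groups if groups is not None else matrix.sheet.groups
    samples: list[str] = []
    for g in groups:
        members = matrix.sheet.samples_for(g)
        if not members:
            raise ValueError(f"group {g!r} has no samples")
        samples.extend(members)
    keep = matrix.percent[samples].notna().all(axis=1)
    return matrix.subset(matrix.percent.index[keep])


def global_summaries(
    matrix: FragmentMatrix, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group (optionally per-region) medians and quartiles.

    All (fragment, sample) percentages of a group are pooled; the optional
    ``annotations`` frame (indexed like the matrix, with a ``location``
    column) adds a region stratification.
    """
    if not len(matrix):
        raise ValueError("matrix is empty")
    rows = []
    strata: list[tuple[str | None, pd.Index]] = [(None, matrix.percent.index)]
    if annotations is not None:
        ann = annotations.reindex(matrix.percent.index)
        for label, sub in ann.groupby("location"):
            strata.append((str(label), sub.index))
    for group in matrix.sheet.groups:
        cols = matrix.sheet.samples_for(group)
        for label, idx in strata:
            vals = matrix.percent.loc[idx, cols].to_numpy(float).ravel()
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "group": group,
                    "region": label if label is not None else "all",
                    "n_values": vals.size,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)
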