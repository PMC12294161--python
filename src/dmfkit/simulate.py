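"""Seeded synthetic RRBS cohorts with known ground truth.

The generator emulates the statistical structure a fragment-level
differential-methylation analysis assumes, without any sequencing:

* a genome whose CCGG sites are placed so that a requested number of
  fragments falls inside the 40-220 bp RRBS size window, with CpG-dense
  fragment bodies;
* gene models laid out so that promoter, exon, intron, exon/intron-boundary
  and intergenic fragments all occur;
* a bimodal methylation baseline — a high mode (~89 %) for gene bodies and
  intergenic DNA, a low mode (~15 %) for promoter fragments — matching the
  globally hypermethylated / promoter-hypomethylated landscape of PBMC
  methylomes;
* per-CpG read counts drawn negative-binomially around a mean coverage, and
  methylated counts drawn beta-binomially with dispersion ``rho`` to model
  extra-binomial biological variability across individuals;
* planted fragment-level group effects for two disease contrasts against a
  common reference, 10-37 percentage points, a 2:1 hyper:hypo ratio and a
  configurable shared fraction between the contrasts (mirroring, at reduced
  scale, a 429/214-with-118-shared overlap structure).

Everything is deterministic given the seed: the same configuration writes
byte-identical FASTA, BED12, coverage and truth files.

Fragments selected to carry planted effects have their baselines redrawn
from a mid-range band wide enough for the effect in either direction, so
the planted size survives clipping exactly; differential fragments sitting
in variable-methylation regions rather than at the saturated ~89 % mode is
also what cohort studies observe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, annotate_catalog
from .coverage import SampleSheet, write_bismark_coverage
from .digest import FragmentCatalog, Genome, digest, size_select

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "RecoveryReport",
    "simulate_genome",
    "plant_truth",
    "simulate_cohort",
    "simulate_dataset",
    "evaluate_recovery",
    "delta_slope",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed is mandatory.

    Defaults describe three cohorts of five samples at 30x mean CpG
    coverage — the design of a small matched patient study — with 42 and 21
    planted DMFs for the two disease contrasts of which 12 are shared
    (a 429/214/118 overlap structure at one-tenth scale).
    """

    seed: int
    n_fragments: int = 600
    n_chromosomes: int = 2
    frag_len_range: tuple[int, int] = (40, 220)
    long_len_range: tuple[int, int] = (260, 800)
    long_fragment_rate: float = 0.15
    cpg_rate: float = 0.08
    group_sizes: dict = field(
        default_factory=lambda: {"HC": 5, "ME": 5, "LC": 5}
    )
    ref_group: str = "HC"
    high_mode: float = 0.89
    low_mode: float = 0.15
    baseline_concentration: float = 60.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.2
    rho: float = 0.05
    dropout: float = 0.02
    n_dmf: dict = field(default_factory=lambda: {"LC": 42, "ME": 21})
    n_shared: int = 12
    effect_range: tuple[float, float] = (10.0, 37.0)
    hyper_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.long_fragment_rate, self.cpg_rate, self.rho, self.dropout,
                  self.hyper_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_shared > min(self.n_dmf.values(), default=0):
            raise ValueError("n_shared cannot exceed the smaller contrast's DMFs")
        if self.ref_group in self.n_dmf:
            raise ValueError("effects are planted in case groups, not the reference")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("frag_len_range", "long_len_range", "effect_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for key in ("frag_len_range", "long_len_range", "effect_range"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _random_body(rng: np.random.Generator, length: int, cpg_rate: float) -> str:
    """Random fragment body of exactly ``length`` bp, CpG-enriched, CCGG-free."""
    out = bytearray()
    while len(out) < length:
        if rng.random() < cpg_rate:
            out += b"CG"
        else:
            out.append(_BASES[rng.integers(4)])
    seq = out[:length].decode()
    while "CCGG" in seq:  # break accidental MspI sites
        i = seq.index("CCGG")
        seq = seq[:i] + "CA" + seq[i + 2 :]
    return seq


def _spacer(rng: np.random.Generator, length: int) -> str:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    while "CCGG" in seq:
        i = seq.index("CCGG")
        seq = seq[:i] + "CA" + seq[i + 2 :]
    return seq


_GENE_GAP = 8000
_GENE_SPAN = 12000
_EXON_LEN = 300
_INTRON_LEN = 400


def _place_genes(chrom: str, chrom_len: int, counter: int) -> list[GeneModel]:
    """Deterministic gene layout: alternating-strand genes separated by gaps.

    Gaps are wide enough that their interiors are intergenic (outside every
    span and promoter window); exon/intron alternation inside each span
    guarantees exon, intron and boundary fragments.
    """
    models = []
    pos = _GENE_GAP
    while pos + _GENE_SPAN + 1000 < chrom_len:
        strand = "+" if counter % 2 == 0 else "-"
        start, end = pos, pos + _GENE_SPAN
        exons = []
        e = start
        while e < end:
            exons.append((e, min(e + _EXON_LEN, end)))
            e += _EXON_LEN + _INTRON_LEN
        if exons[-1][1] < end:  # exons must reach the span end (TSS convention)
            exons.append((end - _EXON_LEN, end))
        models.append(
            GeneModel(f"GENE{counter:03d}", chrom, strand, start, end, tuple(exons))
        )
        counter += 1
        pos = end + _GENE_GAP
    return models


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, list[GeneModel]]:
    """Build the synthetic genome and its gene models.

    Chromosomes are chains of ``CCGG + body`` segments: each in-size body
    yields one doubly-cut fragment inside the size window, and occasional
    long bodies yield oversize fragments removed by size selection.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    per_chrom = int(np.ceil(config.n_fragments / config.n_chromosomes))
    seqs: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_counter = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        parts = [_spacer(rng, 300)]
        made = 0
        while made < per_chrom:
            parts.append("CCGG")
            if rng.random() < config.long_fragment_rate:
                length = int(rng.integers(*config.long_len_range, endpoint=True))
                parts.append(_random_body(rng, length - 4, config.cpg_rate / 4))
            else:
                length = int(rng.integers(*config.frag_len_range, endpoint=True))
                parts.append(_random_body(rng, length - 4, config.cpg_rate))
                made += 1
        parts.append("CCGG")
        parts.append(_spacer(rng, 300))
        seq = "".join(parts)
        seqs[chrom] = seq
        new_models = _place_genes(chrom, len(seq), gene_counter)
        gene_counter += len(new_models)
        models.extend(new_models)
    return Genome(seqs), models


def _feasible_baseline(rng: np.random.Generator, effect: float) -> float:
    """Baseline with headroom for ``effect`` (fraction) in either direction."""
    lo = max(0.15, effect + 0.03)
    hi = min(0.85, 0.97 - effect)
    if lo >= hi:
        lo, hi = effect + 0.01, 0.99 - effect
    return float(rng.uniform(lo, hi))


def plant_truth(
    config: SimulationConfig,
    catalog: FragmentCatalog,
    annotations: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw baselines and planted effects; return (truth table, mu matrix).

    ``mu`` is fragments x groups (methylation fractions, clipped to
    [0.001, 0.999]); the truth table has one row per planted
    fragment-contrast with direction and effect size in percentage points.
    All fragments absent from the truth table are null.
    """
    frag_ids = catalog.frame["fragment_id"].to_numpy()
    n = len(frag_ids)
    ann = annotations.reindex(catalog.frame["fragment_id"])
    is_promoter = (ann["location"] == "promoter").to_numpy()

    conc = config.baseline_concentration
    mode = np.where(is_promoter, config.low_mode, config.high_mode)
    baseline = rng.beta(mode * conc, (1 - mode) * conc)

    cases = list(config.n_dmf)
    n_cpg = catalog.frame["n_cpg"].to_numpy()
    eligible = np.flatnonzero(n_cpg >= 3)
    n_only = {c: config.n_dmf[c] - config.n_shared for c in cases}
    total_needed = config.n_shared + sum(n_only.values())
    if total_needed > len(eligible):
        raise ValueError("not enough eligible fragments to plant effects")
    chosen = rng.choice(eligible, size=total_needed, replace=False)
    shared = chosen[: config.n_shared]
    offset = config.n_shared
    only: dict[str, np.ndarray] = {}
    for c in cases:
        only[c] = chosen[offset : offset + n_only[c]]
        offset += n_only[c]

    lo, hi = config.effect_range
    mu = {g: baseline.copy() for g in [config.ref_group, *config.group_sizes]}
    rows = []

    def plant(idx: int, case: str, sign: int, effect_pp: float) -> None:
        mu[case][idx] = baseline[idx] + sign * effect_pp / 100.0
        rows.append(
            {
                "fragment_id": frag_ids[idx],
                "chrom": catalog.frame["chrom"].iloc[idx],
                "start": catalog.frame["start"].iloc[idx],
                "end": catalog.frame["end"].iloc[idx],
                "contrast": case,
                "direction": "hyper" if sign > 0 else "hypo",
                "effect_pp": effect_pp,
                "shared": idx in shared_set,
            }
        )

    shared_set = set(shared.tolist())
    for idx in shared:
        sign = 1 if rng.random() < config.hyper_fraction else -1
        effects = rng.uniform(lo, hi, size=len(cases))
        baseline[idx] = _feasible_baseline(rng, effects.max() / 100.0)
        for g in mu:
            mu[g][idx] = baseline[idx]
        for case, e in zip(cases, effects):
            plant(idx, case, sign, float(e))
    for case in cases:
        for idx in only[case]:
            sign = 1 if rng.random() < config.hyper_fraction else -1
            e = float(rng.uniform(lo, hi))
            baseline[idx] = _feasible_baseline(rng, e / 100.0)
            for g in mu:
                mu[g][idx] = baseline[idx]
            plant(idx, case, sign, e)

    mu_frame = pd.DataFrame(
        {g: np.clip(v, 0.001, 0.999) for g, v in mu.items()},
        index=pd.Index(frag_ids, name="fragment_id"),
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "fragment_id", "chrom", "start", "end",
            "contrast", "direction", "effect_pp", "shared",
        ],
    )
    return truth, mu_frame


def _default_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    for g, size in config.group_sizes.items():
        for i in range(size):
            rows.append({"sample_id": f"{g}{i + 1:02d}", "group": g})
    return SampleSheet(pd.DataFrame(rows))


def simulate_cohort(
    config: SimulationConfig,
    catalog: FragmentCatalog,
    mu: pd.DataFrame,
    sheet: SampleSheet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], SampleSheet]:
    """Draw per-sample per-CpG calls around the fragment methylation matrix.

    Per CpG: total reads ~ NegBin(mean=coverage_mean, dispersion), then
    methylated reads ~ BetaBinomial(total, mu_fragment_group, rho).  A small
    per-(sample, fragment) dropout probability removes whole fragments,
    creating the missingness the complete-coverage filter later prunes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sheet = sheet if sheet is not None else _default_sheet(config)
    if catalog.cpg_positions is None:
        raise ValueError("catalog needs located CpGs")
    counts = [len(p) for p in catalog.cpg_positions]
    frag_of_cpg = np.repeat(np.arange(len(catalog)), counts)
    chrom_of_cpg = np.repeat(catalog.frame["chrom"].to_numpy(), counts)
    pos = (
        np.concatenate(catalog.cpg_positions)
        if len(catalog)
        else np.empty(0, dtype=int)
    )
    nb_n = 1.0 / config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    inv = 1.0 / config.rho - 1.0
    calls: dict[str, pd.DataFrame] = {}
    for sample, group in zip(sheet.samples, sheet.frame["group"]):
        mu_frag = mu[group].to_numpy()
        mu_cpg = mu_frag[frag_of_cpg]
        total = rng.negative_binomial(nb_n, nb_p, size=len(pos))
        dropped = rng.random(len(catalog)) < config.dropout
        total[dropped[frag_of_cpg]] = 0
        p = rng.beta(mu_cpg * inv, (1 - mu_cpg) * inv)
        meth = rng.binomial(total, p)
        keep = total > 0
        calls[sample] = pd.DataFrame(
            {
                "chrom": chrom_of_cpg[keep],
                "pos": pos[keep],
                "meth": meth[keep],
                "unmeth": (total - meth)[keep],
            }
        )
    return calls, sheet


@dataclass
class SimulatedDataset:
    """Everything one seeded simulation produced, ready for the pipeline."""

    config: SimulationConfig
    genome: Genome
    models: list[GeneModel]
    catalog: FragmentCatalog
    annotations: pd.DataFrame
    truth: pd.DataFrame
    mu: pd.DataFrame
    sheet: SampleSheet
    calls_by_sample: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA, BED12 gene models, coverage TSVs, sheet and truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        with open(outdir / "genes.bed", "w") as fh:
            for m in self.models:
                sizes = ",".join(str(e - s) for s, e in m.exons)
                offs = ",".join(str(s - m.start) for s, e in m.exons)
                fh.write(
                    f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\t"
                    f"{m.start}\t{m.end}\t0\t{len(m.exons)}\t{sizes}\t{offs}\n"
                )
        covdir = outdir / "coverage"
        covdir.mkdir(exist_ok=True)
        for sample, calls in self.calls_by_sample.items():
            write_bismark_coverage(calls, covdir / f"{sample}.cov")
        self.sheet.to_csv(outdir / "samples.csv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator under a single seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    genome, models = simulate_genome(config, rng)
    catalog = size_select(digest(genome), *config.frag_len_range)
    annotations = annotate_catalog(catalog, models)
    truth, mu = plant_truth(config, catalog, annotations, rng)
    calls, sheet = simulate_cohort(config, catalog, mu, None, rng)
    return SimulatedDataset(
        config=config,
        genome=genome,
        models=models,
        catalog=catalog,
        annotations=annotations,
        truth=truth,
        mu=mu,
        sheet=sheet,
        calls_by_sample=calls,
    )


@dataclass
class RecoveryReport:
    """How well DMF calling recovered the planted truth.

    Sensitivity is computed over planted fragment-contrasts that were
    evaluable (present in the tested matrix): fragments lost to coverage are
    a property of the coverage model, not the caller.  The unconditional
    figure over all planted records is reported alongside.
    """

    per_contrast: pd.DataFrame
    sensitivity: float
    sensitivity_unconditional: float
    fdp: float | None
    direction_accuracy: float | None
    hyper_hypo_ratio: float | None
    venn_called_shared: tuple[int, int, int] | None = None

    def sensitivity_at(self, min_effect: float) -> float:
        sub = self.detail[self.detail["effect_pp"] >= min_effect]
        sub = sub[sub["evaluable"]]
        return float(sub["called"].mean()) if len(sub) else float("nan")

    detail: pd.DataFrame = field(default_factory=pd.DataFrame)


def evaluate_recovery(
    called: dict[str, pd.DataFrame], truth: pd.DataFrame
) -> RecoveryReport:
    """Score called DMF tables (keyed by case group) against the truth table."""
    details = []
    fdp_num = fdp_den = 0
    for case, table in called.items():
        tsub = truth[truth["contrast"] == case].copy()
        passing = table[table["passes"].astype(bool)] if "passes" in table.columns else table
        called_ids = set(passing.index)
        evaluable_ids = set(table.index)
        tsub["evaluable"] = tsub["fragment_id"].isin(evaluable_ids)
        tsub["called"] = tsub["fragment_id"].isin(called_ids)
        est_dir = passing["direction"]
        tsub["direction_ok"] = [
            (fid in called_ids) and est_dir.loc[fid] == d
            for fid, d in zip(tsub["fragment_id"], tsub["direction"])
        ]
        details.append(tsub)
        truth_ids = set(tsub["fragment_id"])
        fdp_num += len(called_ids - truth_ids)
        fdp_den += len(called_ids)
    detail = (
        pd.concat(details, ignore_index=True)
        if details
        else truth.iloc[0:0].assign(evaluable=False, called=False, direction_ok=False)
    )
    per_rows = []
    for case, sub in detail.groupby("contrast"):
        ev = sub[sub["evaluable"]]
        tp = sub[sub["called"]]
        per_rows.append(
            {
                "contrast": case,
                "n_planted": len(sub),
                "n_evaluable": len(ev),
                "n_called": int(sub["called"].sum()),
                "sensitivity": float(ev["called"].mean()) if len(ev) else np.nan,
                "direction_accuracy": float(tp["direction_ok"].mean())
                if len(tp)
                else np.nan,
            }
        )
    ev = detail[detail["evaluable"]]
    tp = detail[detail["called"]]
    ratios = []
    for case, table in called.items():
        passing = table[table["passes"].astype(bool)] if "passes" in table.columns else table
        n_hypo = int((passing["direction"] == "hypo").sum())
        if n_hypo:
            ratios.append((passing["direction"] == "hyper").sum() / n_hypo)
    return RecoveryReport(
        per_contrast=pd.DataFrame(per_rows),
        sensitivity=float(ev["called"].mean()) if len(ev) else 0.0,
        sensitivity_unconditional=float(detail["called"].mean())
        if len(detail)
        else 0.0,
        fdp=(fdp_num / fdp_den) if fdp_den else None,
        direction_accuracy=float(tp["direction_ok"].mean()) if len(tp) else None,
        hyper_hypo_ratio=float(np.mean(ratios)) if ratios else None,
        detail=detail,
    )


def delta_slope(
    truth: pd.DataFrame, called: dict[str, pd.DataFrame]
) -> float:
    """OLS slope of estimated delta on planted signed effect (target: 1).

    Uses every evaluable planted fragment regardless of whether it was
    called, so threshold selection cannot bias the slope upward.
    """
    xs, ys = [], []
    for case, table in called.items():
        tsub = truth[truth["contrast"] == case]
        for fid, direction, e in zip(
            tsub["fragment_id"], tsub["direction"], tsub["effect_pp"]
        ):
            if fid in table.index:
                xs.append(e if direction == "hyper" else -e)
                ys.append(table.loc[fid, "delta"])
    if len(xs) < 3:
        raise ValueError("too few evaluable planted fragments for a slope")
    slope, _ = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    return float(slope)
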