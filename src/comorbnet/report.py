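"""Descriptive tables and full-pipeline orchestration.

Descriptive outputs mirror the cohort-characterisation tables of a claims
study: a prevalence table of the most visited diseases (counts and weighted
percentages, split by sex) and an age distribution over 10-year bands with
weighted mean ± SD per stratum.  Percentages are printed to two decimals with
half-away-from-zero rounding, matching conventional table typography.

:func:`run_pipeline` chains the whole analysis: ETL → per-sex sampling →
Ising network estimation → centrality → positive subgraph → fast-greedy
communities, writing every artifact (TSV tables, edge lists, GraphML, a JSON
manifest and a plain-text log) into one output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import centrality as centrality_mod
from .community import fast_greedy, positive_subgraph
from .etl import (ComorbidityMatrix, DiseasePanel, ExclusionReport,
                  PipelineError, load_panel, read_records, run_etl,
                  sample_by_sex)
from .ising import IsingNetwork, fit_ising

__all__ = [
    "percent",
    "prevalence_table",
    "prevalence_table_from_counts",
    "age_distribution",
    "age_distribution_from_counts",
    "PipelineConfig",
    "PipelineBundle",
    "run_pipeline",
]

DEFAULT_BANDS: tuple[tuple[int, int], ...] = ((60, 69), (70, 79), (80, 89), (90, 99))


def percent(count: float, denominator: float, ndigits: int = 2) -> float:
    """100·count/denominator rounded half-away-from-zero to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    raw = Decimal(100) * Decimal(count) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(raw.quantize(quantum, rounding=ROUND_HALF_UP))


def prevalence_table(records: pd.DataFrame, top_k: int = 10,
                     names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Top-``top_k`` diseases by patient count, with sex split and percentages.

    One deduplicated record equals one (patient, disease) pair, so patient
    counts double as visit counts after cleaning.  Percentages use the total
    number of processed records as denominator.
    """
    denom = len(records)
    per = records.groupby("code").agg(
        total=("patient_id", "nunique"))
    sex_piv = records.pivot_table(index="code", columns="sex",
                                  values="patient_id", aggfunc="nunique",
                                  fill_value=0)
    for s in ("male", "female"):
        per[s] = sex_piv[s] if s in sex_piv else 0
    per = per.reset_index().sort_values(["total", "code"],
                                        ascending=[False, True])
    per = per.head(top_k).reset_index(drop=True)
    per["percent"] = [percent(t, denom) for t in per["total"]]
    if names:
        per.insert(1, "disease", per["code"].map(lambda c: names.get(c, c)))
    return per[[c for c in ("code", "disease", "total", "percent", "male",
                            "female") if c in per.columns]]


def prevalence_table_from_counts(
    counts: Mapping[str, tuple[int, int, int]],
    denominator: int,
) -> pd.DataFrame:
    """Rebuild a prevalence table from printed (total, male, female) counts.

    Verifies the male + female = total identity for every row and recomputes
    the percentage column from the counts.
    """
    rows = []
    for name, (total, male, female) in counts.items():
        if male + female != total:
            raise ValueError(
                f"{name}: male {male} + female {female} != total {total}")
        rows.append((name, total, percent(total, denominator), male, female))
    df = pd.DataFrame(rows, columns=["disease", "total", "percent",
                                     "male", "female"])
    return df.sort_values(["total", "disease"],
                          ascending=[False, True]).reset_index(drop=True)


@dataclass
class AgeDistribution:
    """Band counts/percents by sex plus weighted mean ± SD per stratum."""

    bands: pd.DataFrame          # band, total, pct, male, pct_male, female, pct_female
    means: pd.DataFrame          # stratum, n, mean, sd

    def mean_of(self, stratum: str) -> tuple[float, float]:
        row = self.means.set_index("stratum").loc[stratum]
        return float(row["mean"]), float(row["sd"])


def age_distribution(records: pd.DataFrame,
                     bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
                     ) -> AgeDistribution:
    """Record-weighted age structure: band percentages are shares of the
    grand total (so male and female band percentages sum to the overall one)."""
    denom = len(records)
    rows = []
    for lo, hi in bands:
        sub = records[(records["age"] >= lo) & (records["age"] <= hi)]
        tot = len(sub)
        male = int((sub["sex"] == "male").sum())
        female = int((sub["sex"] == "female").sum())
        rows.append((f"{lo}-{hi}", tot, percent(tot, denom),
                     male, percent(male, denom), female, percent(female, denom)))
    band_df = pd.DataFrame(rows, columns=["band", "total", "percent", "male",
                                          "percent_male", "female",
                                          "percent_female"])
    means = []
    for stratum, sub in (("total", records),
                         ("male", records[records["sex"] == "male"]),
                         ("female", records[records["sex"] == "female"])):
        ages = sub["age"].to_numpy(dtype=float)
        if len(ages):
            means.append((stratum, len(ages), float(ages.mean()),
                          float(ages.std(ddof=0))))
        else:
            means.append((stratum, 0, float("nan"), float("nan")))
    return AgeDistribution(band_df, pd.DataFrame(
        means, columns=["stratum", "n", "mean", "sd"]))


def age_distribution_from_counts(
    band_counts: Mapping[tuple[int, int], tuple[int, int, int]],
) -> pd.DataFrame:
    """Band percentages recomputed from printed (total, male, female) counts."""
    denom = sum(t for t, _, _ in band_counts.values())
    rows = []
    for (lo, hi), (tot, male, female) in band_counts.items():
        if male + female != tot:
            raise ValueError(f"band {lo}-{hi}: male + female != total")
        rows.append((f"{lo}-{hi}", tot, percent(tot, denom),
                     male, percent(male, denom), female, percent(female, denom)))
    return pd.DataFrame(rows, columns=["band", "total", "percent", "male",
                                       "percent_male", "female",
                                       "percent_female"])


def pooled_mean(stratum_means: Mapping[str, tuple[float, int]]) -> float:
    """Count-weighted pooled mean from per-stratum (mean, n) pairs."""
    num = sum(m * n for m, n in stratum_means.values())
    den = sum(n for _, n in stratum_means.values())
    return num / den


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class PipelineConfig:
    """All hyperparameters of the end-to-end analysis in one place."""

    seed: int = 20230601
    min_prevalence: float = 0.01
    age_range: tuple[int, int] = (60, 99)
    n_top: int = 5
    n_comorbid: int = 40
    n_per_sex: int = 150_000
    ebic_gamma: float = 0.25
    rule: str = "AND"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    gamma_res: float = 1.0
    prevalence_denominator: str = "patients"
    panel_path: str | None = None
    input_path: str | None = None
    output_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.age_range, list):
            cfg.age_range = tuple(cfg.age_range)
        return cfg


@dataclass
class PipelineBundle:
    """Everything a finished run produced, per sex stratum."""

    config: PipelineConfig
    panel: DiseasePanel
    report: ExclusionReport
    matrix: ComorbidityMatrix
    networks: dict[str, IsingNetwork] = field(default_factory=dict)
    centrality: dict[str, pd.DataFrame] = field(default_factory=dict)
    partitions: dict[str, object] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 records: pd.DataFrame | None = None) -> PipelineBundle:
    """Execute the full analysis and write all artifacts.

    ``records`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.input_path`` is read.  Any stage failure is re-raised
    with the stage name; artifacts written before the failure remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pipeline start {time.strftime('%Y-%m-%d %H:%M:%S')}",
                 f"config: {asdict(config)}"]
    stage = "load"
    try:
        if records is None:
            if config.input_path is None:
                raise PipelineError("no records and no input_path configured")
            records = read_records(config.input_path)
        panel_cfg, rules = load_panel(config.panel_path)

        stage = "etl"
        matrix, panel, report = run_etl(
            records, rules,
            min_prevalence=config.min_prevalence,
            age_range=config.age_range,
            n_top=config.n_top, n_comorbid=config.n_comorbid,
            prevalence_denominator=config.prevalence_denominator,
            panel_names=panel_cfg.names)
        report.to_tsv(outdir / "exclusion_report.tsv")
        log_lines.append(str(report))

        stage = "sample"
        sampled = sample_by_sex(matrix, config.n_per_sex, config.seed)
        log_lines.append(f"sampled rows: {sampled.n_patients} "
                         f"(n_per_sex={config.n_per_sex}, seed={config.seed})")

        bundle = PipelineBundle(config, panel, report, sampled)
        for sex in ("male", "female"):
            mask = (sampled.sex == sex).to_numpy()
            stratum = ComorbidityMatrix(sampled.data[mask], sampled.sex[mask])
            if stratum.n_patients == 0:
                log_lines.append(f"{sex}: empty stratum, skipped")
                continue

            stage = f"fit:{sex}"
            net = fit_ising(stratum, ebic_gamma=config.ebic_gamma,
                            rule=config.rule, n_lambda=config.n_lambda,
                            lambda_min_ratio=config.lambda_min_ratio)
            net.to_edgelist_tsv(outdir / f"network_{sex}.tsv")
            net.to_thresholds_tsv(outdir / f"thresholds_{sex}.tsv")
            net.to_graphml(outdir / f"network_{sex}.graphml")
            bundle.networks[sex] = net

            stage = f"centrality:{sex}"
            table = centrality_mod.centrality_table(net)
            centrality_mod.centrality_table_to_tsv(
                table, outdir / f"centrality_{sex}.tsv")
            bundle.centrality[sex] = table

            stage = f"community:{sex}"
            pos = positive_subgraph(net)
            part = fast_greedy(pos, config.gamma_res)
            part.to_tsv(outdir / f"communities_{sex}.tsv")
            part.to_graphml(outdir / f"communities_{sex}.graphml", net)
            bundle.partitions[sex] = part
            log_lines.append(
                f"{sex}: n={stratum.n_patients} edges={len(net.edge_list())} "
                f"negative_dropped={pos.dropped_negative} "
                f"Q={part.q:.4f} communities={part.n_communities}")

        manifest = {
            "config": asdict(config),
            "panel": panel.codes,
            "stages": report.stages,
            "outputs": sorted(f.name for f in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log_lines.append("pipeline complete")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        bundle.paths = {f.stem: str(f) for f in outdir.iterdir()}
        return bundle
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
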