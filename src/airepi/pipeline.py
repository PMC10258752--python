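"""Pipeline driver: read -> filter -> normalize -> metrics -> association.

All stage parameters live in :class:`RunConfig`, which round-trips
through YAML unchanged. Every run writes a manifest recording the
parameter values, seeds and per-stage subject accounting so that a run
is reproducible from its outputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    METRIC_COLUMNS,
    fit_linear_ari,
    fit_poisson_ari,
)
from .episodes import (
    call_episodes,
    completeness,
    cumulative_ari,
    read_diary_table,
    write_episode_table,
    year_end_day,
)
from .errors import DepthError, ValidationError
from .io import downsample_reads, filter_repertoire, read_clonotype_table
from .metrics import repertoire_metrics
from .pgen import load_model

logger = logging.getLogger(__name__)

METRICS_TSV_COLUMNS = [
    "subject_id",
    "locus",
    "clonality",
    "shannon_bits",
    "simpson_diversity",
    "richness",
    "evenness",
    "mean_cdr3_len_aa",
    "shm_fraction",
    "mean_pgen",
    "public_fraction",
]


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    repertoire_dir: str = ""
    diary_path: str = ""
    covariates_path: str = ""
    out_dir: str = "out"
    model_path: str | None = None
    locus: str = "TRB"
    normalize_target: int | None = 50_000
    min_count: int = 2
    productive_only: bool = True
    identity_threshold_pct: float = 98.0
    gap_days: int = 3
    min_completeness: float = 0.8
    public_threshold: float = 1e-9
    follow_up_years: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")
        if self.gap_days < 1 or self.gap_days > 14:
            raise ValidationError("gap_days must lie in [1, 14]")
        if not (0.0 <= self.min_completeness <= 1.0):
            raise ValidationError("min_completeness must lie in [0, 1]")
        if not (0.0 <= self.identity_threshold_pct <= 100.0):
            raise ValidationError("identity_threshold_pct must lie in [0, 100]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def compute_metrics_table(reps, pgen_model=None, public_threshold: float = 1e-9) -> pd.DataFrame:
    """Metrics bundle per repertoire as a deterministic table."""
    rows = []
    for rep in sorted(reps, key=lambda r: r.subject_id):
        m = repertoire_metrics(rep, pgen_model=pgen_model, public_threshold=public_threshold)
        rows.append(
            {
                "subject_id": rep.subject_id,
                "locus": rep.locus,
                "clonality": m.clonality,
                "shannon_bits": m.shannon_bits,
                "simpson_diversity": m.simpson_diversity,
                "richness": m.richness,
                "evenness": m.evenness,
                "mean_cdr3_len_aa": m.mean_cdr3_len_aa,
                "shm_fraction": m.shm_fraction,
                "mean_pgen": m.mean_pgen,
                "public_fraction": m.public_fraction,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_TSV_COLUMNS)


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the metrics TSV byte-deterministically (repr for floats)."""
    out = table.copy()
    for col in out.columns:
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest.

    Writes ``metrics.tsv``, ``episodes.tsv``, ``effects.json`` and
    ``run_manifest.json`` under ``config.out_dir``. Subjects whose
    repertoire is shallower than ``normalize_target`` or whose diary
    completeness is not above ``min_completeness`` are excluded from the
    association stage and listed in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "airepi_version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    # --- repertoires ------------------------------------------------------
    rep_dir = Path(config.repertoire_dir)
    paths = sorted(rep_dir.glob("*.tsv"))
    if not paths:
        raise ValidationError(f"no repertoire TSVs found under {rep_dir}")
    model = load_model(config.model_path) if config.model_path else None

    reps, too_shallow = [], []
    for path in paths:
        rep = read_clonotype_table(path, locus=config.locus)
        rep = filter_repertoire(
            rep, min_count=config.min_count, productive_only=config.productive_only
        )
        if config.normalize_target is not None:
            try:
                rep = downsample_reads(rep, config.normalize_target, seed=config.seed)
            except DepthError as err:
                logger.warning("excluding %s: %s", rep.subject_id, err)
                too_shallow.append(rep.subject_id)
                continue
        reps.append(rep)
    manifest["stages"]["repertoires"] = {
        "input": len(paths),
        "included": len(reps),
        "excluded_shallow": sorted(too_shallow),
    }

    metrics_table = compute_metrics_table(
        reps, pgen_model=model, public_threshold=config.public_threshold
    )
    write_metrics_table(metrics_table, out / "metrics.tsv")

    # --- diaries and episodes --------------------------------------------
    diaries = read_diary_table(config.diary_path)
    window = (0, year_end_day(config.follow_up_years))
    episodes_by_subject = {
        sid: call_episodes(diary, gap_days=config.gap_days)
        for sid, diary in sorted(diaries.items())
    }
    write_episode_table(episodes_by_subject, out / "episodes.tsv")

    completeness_by_subject = {
        sid: completeness(diary, window) for sid, diary in diaries.items()
    }
    complete_ids = {
        sid for sid, c in completeness_by_subject.items() if c > config.min_completeness
    }
    manifest["stages"]["diaries"] = {
        "input": len(diaries),
        "included": len(complete_ids),
        "excluded_incomplete": sorted(set(diaries) - complete_ids),
    }

    # --- cohort table -----------------------------------------------------
    covariates = pd.read_csv(config.covariates_path, sep="\t")
    year_ends = [year_end_day(y) for y in range(1, config.follow_up_years + 1)]
    ari_rows = []
    for sid, eps in episodes_by_subject.items():
        counts = cumulative_ari(eps, year_ends)
        row = {"subject_id": sid, "completeness": completeness_by_subject[sid]}
        for y, n in zip(range(1, config.follow_up_years + 1), counts):
            row[f"ari_year{y}"] = int(n)
        ari_rows.append(row)
    cohort = (
        metrics_table.merge(pd.DataFrame(ari_rows), on="subject_id", how="inner")
        .merge(covariates, on="subject_id", how="inner")
    )
    analysis = cohort[cohort["subject_id"].isin(complete_ids)].reset_index(drop=True)
    manifest["stages"]["association"] = {
        "input": len(cohort),
        "included": len(analysis),
        "excluded": sorted(set(cohort["subject_id"]) - set(analysis["subject_id"])),
    }

    # --- association ------------------------------------------------------
    effects: dict = {}
    if len(analysis) >= 3:
        for metric in METRIC_COLUMNS:
            linear = fit_linear_ari(analysis, metric, outcome_year=config.follow_up_years)
            poisson = fit_poisson_ari(
                analysis, metric, interval_ends=list(range(1, config.follow_up_years + 1))
            )
            effects[metric] = {
                "linear": [asdict(e) for e in linear],
                "poisson": {
                    str(year): [asdict(e) for e in ests]
                    for year, ests in poisson.items()
                },
            }
    else:
        logger.warning("association skipped: only %d complete subjects", len(analysis))
    with open(out / "effects.json", "w") as fh:
        json.dump(effects, fh, indent=1, sort_keys=True)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
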