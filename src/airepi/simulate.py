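"""Synthetic cohorts with known ground truth.

Clone abundances are Dirichlet-multinomial: a per-subject symmetric
Dirichlet draw (concentration optionally jittered on the log scale to
spread evenness across subjects) feeds a multinomial read sampler.
Sequences come from the toy recombination model, so generation
probabilities are exactly computable. Infection episodes per child are
Poisson with log-rate ``beta0 + beta_metric * z + beta_sib * sib`` where
``z`` is the standardized true repertoire evenness, and are planted into
a daily diary so that the first episode day carries one A-symptom and
every later episode day two B-symptoms — each episode day qualifies, and
both halves of the ARI day rule are exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .association import standardize
from .episodes import DayRecord, SymptomDiary, write_diary_table, year_end_day
from .errors import ScenarioError, ValidationError
from .io import Clonotype, Repertoire, write_clonotype_table
from .metrics import repertoire_metrics
from .pgen import GenerativeModel, sample_rearrangement, save_model

__all__ = [
    "CohortScenario",
    "default_generative_model",
    "simulate_repertoire",
    "simulate_cohort",
    "write_cohort",
]


def default_generative_model() -> GenerativeModel:
    """Toy model whose junctions always translate in frame.

    Segment remnants are 6 nt (2 codons) with no trimming and insertion
    lengths restricted to multiples of 3, so every generated junction has
    length 12..18 nt and a stop-free translation is possible (random
    insertions may still create stops; such clones are marked
    non-productive).
    """
    return GenerativeModel(
        v_segments=[
            ("TRBV1", "TGTGCC", 0.5),
            ("TRBV2", "TGCAGT", 0.3),
            ("TRBV3", "TGTTCC", 0.2),
        ],
        j_segments=[
            ("TRBJ1", "TTCGGG", 0.4),
            ("TRBJ2", "TACACC", 0.35),
            ("TRBJ3", "TTTGGC", 0.25),
        ],
        insertion_length_probs=np.array([0.05, 0, 0, 0.55, 0, 0, 0.40]),
        insertion_base_probs=np.array([0.25, 0.25, 0.25, 0.25]),
        v_trim_probs=np.array([1.0]),
        j_trim_probs=np.array([1.0]),
    )


@dataclass
class CohortScenario:
    """Knobs of the synthetic cohort generator."""

    n_subjects: int = 120
    clone_concentration: float = 1.0  # symmetric Dirichlet alpha (evenness knob)
    concentration_log_sd: float = 1.0  # per-subject log-normal jitter on alpha
    n_clones: int = 300
    reads_per_subject: int = 5000
    shm_mutated_fraction: float = 0.0
    v_gene_probs: tuple | None = None  # overrides the model's V probabilities
    beta0: float = 3.4
    beta_metric: float = -0.1
    beta_sib: float = 0.15
    sibling_prob: float = 0.4
    episode_duration_days: int = 5
    min_separation_days: int = 4  # > default calling gap of 3
    diary_missing_prob: float = 0.05
    follow_up_days: int = 4 * 365
    locus: str = "TRB"
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1 or self.n_subjects < 1:
            raise ValidationError("n_subjects and n_clones must be >= 1")
        if self.clone_concentration <= 0:
            raise ValidationError("clone_concentration must be > 0")
        if not (0 <= self.diary_missing_prob <= 1):
            raise ValidationError("diary_missing_prob must lie in [0, 1]")
        if not (0 <= self.shm_mutated_fraction <= 1):
            raise ValidationError("shm_mutated_fraction must lie in [0, 1]")


def _scenario_model(scenario: CohortScenario) -> GenerativeModel:
    model = default_generative_model()
    if scenario.v_gene_probs is not None:
        probs = list(scenario.v_gene_probs)
        if len(probs) != len(model.v_segments):
            raise ValidationError(
                f"v_gene_probs needs {len(model.v_segments)} entries"
            )
        model = GenerativeModel(
            v_segments=[
                (n, s, float(p)) for (n, s, _), p in zip(model.v_segments, probs)
            ],
            j_segments=model.j_segments,
            insertion_length_probs=model.insertion_length_probs,
            insertion_base_probs=model.insertion_base_probs,
            v_trim_probs=model.v_trim_probs,
            j_trim_probs=model.j_trim_probs,
        )
    return model


def _translate(cdr3_nt: str) -> tuple[str, bool]:
    if len(cdr3_nt) % 3 != 0:
        return "", False
    aa = str(Seq(cdr3_nt).translate())
    return aa, "*" not in aa


def simulate_repertoire(
    scenario: CohortScenario,
    subject_seed: int,
    subject_id: str = "S0",
) -> tuple[Repertoire, dict]:
    """One subject's repertoire plus its generating truth.

    Returns ``(repertoire, truth)`` where truth holds the subject's
    Dirichlet concentration, the full frequency vector and its Pielou
    evenness (log base 2) — the ground-truth breadth the analysis is
    expected to recover as 1 - clonality.
    """
    rng = np.random.default_rng(subject_seed)
    model = _scenario_model(scenario)

    alpha = scenario.clone_concentration * float(
        np.exp(rng.normal(0.0, scenario.concentration_log_sd))
    )
    freqs = rng.dirichlet(np.full(scenario.n_clones, alpha))
    counts = rng.multinomial(scenario.reads_per_subject, freqs)

    # distinct CDR3 sequences from the generative model
    seen: dict[str, tuple] = {}
    attempts = 0
    while len(seen) < scenario.n_clones:
        seq, events = sample_rearrangement(model, rng)
        seen.setdefault(seq, events)
        attempts += 1
        if attempts > 200 * scenario.n_clones:
            raise ScenarioError(
                f"could not draw {scenario.n_clones} distinct sequences; "
                "the generative model's support is too small"
            )
    sequences = list(seen.items())

    mutated = rng.random(scenario.n_clones) < scenario.shm_mutated_fraction
    identities = np.where(
        mutated, rng.uniform(90.0, 98.0, scenario.n_clones), 100.0
    )

    clonotypes = {}
    for (seq, events), count, ident in zip(sequences, counts, identities):
        if count == 0:
            continue
        aa, productive = _translate(seq)
        clonotypes[seq] = Clonotype(
            cdr3_nt=seq,
            cdr3_aa=aa,
            v_gene=events[0],
            j_gene=events[4],
            read_count=int(count),
            productive=productive,
            v_identity_pct=float(ident),
        )
    rep = Repertoire(
        subject_id=subject_id,
        locus=scenario.locus,
        clonotypes=clonotypes,
        seed=subject_seed,
    )
    log_f = np.log2(freqs, out=np.full_like(freqs, 0.0), where=freqs > 0)
    h = float(-(freqs * log_f).sum())
    truth = {
        "alpha": alpha,
        "frequencies": freqs,
        "evenness": h / np.log2(scenario.n_clones) if scenario.n_clones > 1 else 0.0,
    }
    return rep, truth


def _plant_episodes(rng, n_episodes, scenario: CohortScenario) -> list[tuple[int, int]]:
    """Non-overlapping episode spans with ≥ min_separation_days between them."""
    if n_episodes == 0:
        return []
    dur, sep = scenario.episode_duration_days, scenario.min_separation_days
    required = n_episodes * dur + (n_episodes - 1) * sep
    if required > scenario.follow_up_days:
        raise ScenarioError(
            f"{n_episodes} episodes of {dur} days with separation {sep} do not "
            f"fit into {scenario.follow_up_days} follow-up days"
        )
    slack = scenario.follow_up_days - required
    gaps = rng.multinomial(slack, np.full(n_episodes + 1, 1.0 / (n_episodes + 1)))
    spans = []
    day = 0
    for k in range(n_episodes):
        day += int(gaps[k]) + (sep if k > 0 else 0)
        spans.append((day, day + dur - 1))
        day += dur
    return spans


def _diary_from_episodes(
    rng, subject_id: str, spans, scenario: CohortScenario
) -> SymptomDiary:
    episode_day = {}
    for start, end in spans:
        for day in range(start, end + 1):
            episode_day[day] = "A" if day == start else "B"
    days = []
    for day in range(scenario.follow_up_days):
        recorded = rng.random() >= scenario.diary_missing_prob
        if not recorded:
            days.append(DayRecord(day=day, recorded=False))
            continue
        kind = episode_day.get(day)
        if kind == "A":
            days.append(
                DayRecord(day=day, recorded=True, a_symptoms=frozenset({"fever"}))
            )
        elif kind == "B":
            days.append(
                DayRecord(
                    day=day,
                    recorded=True,
                    b_symptoms=frozenset({"dry_cough", "runny_blocked_nose"}),
                )
            )
        else:
            days.append(DayRecord(day=day, recorded=True))
    return SymptomDiary(subject_id, days)


def simulate_cohort(scenario: CohortScenario):
    """End-to-end synthetic inputs plus the generating truth.

    Returns ``(repertoires, diaries, table, truth)``: per-subject
    repertoires and diaries keyed by subject id, a cohort table with
    computed repertoire metrics, covariates and cumulative planted ARI
    counts per year, and a truth record (betas, per-subject z, planted
    episode spans, true evenness).
    """
    master = np.random.default_rng(scenario.seed)
    subject_ids = [f"S{i:04d}" for i in range(scenario.n_subjects)]
    subject_seeds = master.integers(0, 2**63 - 1, size=scenario.n_subjects)

    reps, truths = {}, {}
    for sid, sseed in zip(subject_ids, subject_seeds):
        rep, truth = simulate_repertoire(scenario, int(sseed), subject_id=sid)
        reps[sid] = rep
        truths[sid] = truth

    evenness_true = np.array([truths[sid]["evenness"] for sid in subject_ids])
    z = standardize(evenness_true)
    sib = (master.random(scenario.n_subjects) < scenario.sibling_prob).astype(int)
    sex = np.where(master.random(scenario.n_subjects) < 0.5, "F", "M")

    rates = np.exp(scenario.beta0 + scenario.beta_metric * z + scenario.beta_sib * sib)
    n_episodes = master.poisson(rates)

    diaries, spans_by_subject = {}, {}
    for i, sid in enumerate(subject_ids):
        spans = _plant_episodes(master, int(n_episodes[i]), scenario)
        spans_by_subject[sid] = spans
        diaries[sid] = _diary_from_episodes(master, sid, spans, scenario)

    rows = []
    for i, sid in enumerate(subject_ids):
        m = repertoire_metrics(reps[sid])
        starts = [s for s, _ in spans_by_subject[sid]]
        row = {
            "subject_id": sid,
            "older_siblings": int(sib[i]),
            "sex": sex[i],
            "completeness": None,  # filled by the pipeline from the diary
            "clonality": m.clonality,
            "shannon_bits": m.shannon_bits,
            "simpson_diversity": m.simpson_diversity,
            "richness": m.richness,
            "evenness": m.evenness,
        }
        for y in (1, 2, 3, 4):
            row[f"ari_year{y}"] = sum(1 for s in starts if s <= year_end_day(y))
        rows.append(row)
    table = pd.DataFrame(rows)

    truth = {
        "betas": {
            "beta0": scenario.beta0,
            "beta_metric": scenario.beta_metric,
            "beta_sib": scenario.beta_sib,
        },
        "z": dict(zip(subject_ids, z.tolist())),
        "evenness": dict(zip(subject_ids, evenness_true.tolist())),
        "alpha": {sid: truths[sid]["alpha"] for sid in subject_ids},
        "older_siblings": dict(zip(subject_ids, sib.tolist())),
        "n_episodes": dict(zip(subject_ids, [int(n) for n in n_episodes])),
        "planted_episodes": {
            sid: [list(span) for span in spans_by_subject[sid]]
            for sid in subject_ids
        },
    }
    return reps, diaries, table, truth


def write_cohort(scenario: CohortScenario, out_dir: str | Path) -> dict:
    """Simulate and write all pipeline inputs under ``out_dir``.

    Layout: ``repertoires/<subject>.tsv`` (AIRR TSV), ``diary.tsv``
    (long format), ``covariates.tsv``, ``model.yaml`` (the generative
    model the sequences came from) and ``truth.json``.
    """
    out = Path(out_dir)
    (out / "repertoires").mkdir(parents=True, exist_ok=True)
    reps, diaries, table, truth = simulate_cohort(scenario)
    save_model(_scenario_model(scenario), out / "model.yaml")
    for sid, rep in sorted(reps.items()):
        write_clonotype_table(rep, out / "repertoires" / f"{sid}.tsv")
    write_diary_table(diaries, out / "diary.tsv")
    table[["subject_id", "older_siblings", "sex"]].to_csv(
        out / "covariates.tsv", sep="\t", index=False
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
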