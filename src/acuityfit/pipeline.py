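"""End-to-end study pipeline: simulate or ingest choices -> fit -> criteria -> report.

The contract of a run is a pair of numeric tables plus a manifest:

* ``summary.csv``   — one row per subject x condition with the Weibull
  maximum-likelihood threshold (cpd at 75% correct), upper asymptote,
  convergence flag and fitted parameters;
* ``criteria.csv``  — one row per subject x condition with the model-free
  alternative estimate (highest frequency with a significantly biased
  choice count) and its exact p-value;
* ``manifest.json`` — config hash, seeds and library versions, enough to
  re-run the pipeline byte-identically.

Individual subjects that cannot be fitted are flagged in their row, never
aborting the cohort — in a real study some subjects simply never perform
above chance and are excluded, while the rest proceed.

Choice data travel as CSV with columns ``subject_id, species, condition,
frequency_cpd, n_correct, n_total``; a converter ingests XLSX workbooks of
per-subject choice counts (or trial-level sequences, truncated to the first
20 choices per frequency) into the same schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binomial import DEFAULT_ALPHA, significance_threshold_acuity
from .fitting import THRESHOLD_LEVEL, fit_all
from .observer import (
    STUDY_PROFILES,
    TRIALS_PER_FREQUENCY,
    ChoiceData,
    make_study_fixture,
)

__all__ = [
    "StudyConfig",
    "SubjectSpec",
    "default_study_config",
    "choices_to_frame",
    "choices_from_frame",
    "read_choices_csv",
    "write_choices_csv",
    "run_pipeline",
    "convert_supplementary",
]

logger = logging.getLogger(__name__)

CHOICE_COLUMNS = ["subject_id", "species", "condition", "frequency_cpd", "n_correct", "n_total"]


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: which study condition and what true acuity."""

    subject_id: str
    profile: str  # key of STUDY_PROFILES
    true_threshold: float  # cpd at 75% correct

    def __post_init__(self) -> None:
        if self.profile not in STUDY_PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a pipeline run."""

    subjects: tuple[SubjectSpec, ...] = ()
    alpha: float = DEFAULT_ALPHA
    level: float = THRESHOLD_LEVEL
    trials_per_freq: int = TRIALS_PER_FREQUENCY
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.level <= 0.8:
            raise ValueError(f"threshold level must lie in (0.5, 0.8], got {self.level}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.trials_per_freq < 1:
            raise ValueError("trials_per_freq must be >= 1")

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {"subject_id": s.subject_id, "profile": s.profile,
                 "true_threshold": s.true_threshold}
                for s in self.subjects
            ],
            "alpha": self.alpha,
            "level": self.level,
            "trials_per_freq": self.trials_per_freq,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        subjects = tuple(
            SubjectSpec(s["subject_id"], s["profile"], float(s["true_threshold"]))
            for s in d.get("subjects", [])
        )
        return cls(
            subjects=subjects,
            alpha=float(d.get("alpha", DEFAULT_ALPHA)),
            level=float(d.get("level", THRESHOLD_LEVEL)),
            trials_per_freq=int(d.get("trials_per_freq", TRIALS_PER_FREQUENCY)),
            seed=int(d.get("seed", 0)),
        )


def default_study_config(seed: int = 0) -> StudyConfig:
    """A cohort shaped like the study: 7 dogs and 7 humans, bright and dim.

    True thresholds are spread evenly over each condition's observed acuity
    range (dogs 5.5-19.5 cpd bright and 1.8-3.5 cpd dim; humans 32.1-44.2
    bright and 5.9-9.9 dim).
    """
    def spread(lo, hi, n):
        return np.linspace(lo, hi, n)

    subjects = []
    for i, thr in enumerate(spread(5.5, 19.5, 7)):
        subjects.append(SubjectSpec(f"dog{i + 1}", "dog_bright", round(float(thr), 2)))
    for i, thr in enumerate(spread(1.8, 3.5, 7)):
        subjects.append(SubjectSpec(f"dog{i + 1}", "dog_dim", round(float(thr), 2)))
    for i, thr in enumerate(spread(32.1, 44.2, 7)):
        subjects.append(SubjectSpec(f"human{i + 1}", "human_bright", round(float(thr), 2)))
    for i, thr in enumerate(spread(5.9, 9.9, 7)):
        subjects.append(SubjectSpec(f"human{i + 1}", "human_dim", round(float(thr), 2)))
    return StudyConfig(subjects=tuple(subjects), seed=seed)


# ---------------------------------------------------------------------------
# choice-data CSV schema

def choices_to_frame(datasets: list[ChoiceData]) -> pd.DataFrame:
    if not datasets:
        return pd.DataFrame(columns=CHOICE_COLUMNS)
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)


def choices_from_frame(frame: pd.DataFrame) -> list[ChoiceData]:
    missing = [c for c in CHOICE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"choice table is missing required columns: {missing}")
    out = []
    for (sid, sp, cond), grp in frame.groupby(
        ["subject_id", "species", "condition"], sort=True
    ):
        records = tuple(
            (float(r.frequency_cpd), int(r.n_correct), int(r.n_total))
            for r in grp.sort_values("frequency_cpd").itertuples()
        )
        out.append(ChoiceData(str(sid), str(sp), str(cond), records))
    return out


def read_choices_csv(path) -> list[ChoiceData]:
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface a readable message
        raise ValueError(f"could not parse choice CSV {path}: {exc}") from exc
    return choices_from_frame(frame)


def write_choices_csv(datasets: list[ChoiceData], path) -> None:
    choices_to_frame(datasets).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the pipeline

def simulate_cohort(config: StudyConfig) -> list[ChoiceData]:
    """Simulate every subject in the config, each from a distinct derived seed."""
    out = []
    for i, s in enumerate(config.subjects):
        sub_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
        )
        out.append(
            make_study_fixture(
                s.profile,
                s.true_threshold,
                sub_seed,
                trials_per_freq=config.trials_per_freq,
                subject_id=s.subject_id,
            )
        )
    return out


def criteria_table(datasets: list[ChoiceData], alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """One highest-significant-frequency row per subject x condition."""
    rows = []
    for d in datasets:
        cr = significance_threshold_acuity(d, alpha=alpha)
        rows.append(
            {
                "subject_id": d.subject_id,
                "species": d.species,
                "condition": d.condition,
                "binomial_threshold_cpd": cr.frequency,
                "k": cr.k,
                "n": cr.n,
                "p_value": cr.p_value,
                "significant": cr.significant,
                "alpha": cr.alpha,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: StudyConfig,
    input_source: str | Path = "simulate",
    out_dir: str | Path = "acuityfit_out",
    *,
    plots: bool = False,
) -> dict:
    """Run simulate-or-ingest -> fit -> criteria -> report; return the bundle.

    ``input_source`` is either the literal string ``"simulate"`` or a path
    to a choice CSV.  Writes ``summary.csv``, ``criteria.csv`` and
    ``manifest.json`` (and per-subject plots when asked) under ``out_dir``
    and returns ``{"summary": DataFrame, "criteria": DataFrame,
    "manifest": dict, "datasets": [...]}``.
    """
    if str(input_source) == "simulate":
        if not config.subjects:
            raise ValueError("simulate mode requires config.subjects to be non-empty")
        datasets = simulate_cohort(config)
        source_desc = "simulate"
    else:
        datasets = read_choices_csv(input_source)
        source_desc = str(input_source)
        if not datasets:
            raise ValueError(f"no subjects found in {input_source}")

    logger.info("fitting %d subject x condition datasets", len(datasets))
    summary = fit_all(datasets, level=config.level)
    for _, row in summary.loc[~summary["converged"]].iterrows():
        logger.warning(
            "subject %s (%s) could not be fitted; row flagged, cohort continues",
            row["subject_id"], row["condition"],
        )
    criteria = criteria_table(datasets, alpha=config.alpha)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "input": source_desc,
        "n_subjects": len(datasets),
        "n_not_converged": int((~summary["converged"]).sum()),
        "versions": {
            "acuityfit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    criteria.to_csv(out / "criteria.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if plots:
        from .plotting import plot_subject_fit

        fig_dir = out / "figs"
        fig_dir.mkdir(exist_ok=True)
        for d in datasets:
            plot_subject_fit(
                d, level=config.level,
                path=fig_dir / f"{d.subject_id}_{d.condition}.png",
            )

    return {"summary": summary, "criteria": criteria, "manifest": manifest, "datasets": datasets}


# ---------------------------------------------------------------------------
# supplementary-workbook conversion (best effort, layout described not seen)

_COLUMN_ALIASES = {
    "subject_id": {"subject_id", "subject", "name", "dog", "individual", "id"},
    "frequency_cpd": {"frequency_cpd", "frequency", "freq", "cpd", "spatial_frequency"},
    "n_correct": {"n_correct", "correct", "k", "n_corr", "correct_choices"},
    "n_total": {"n_total", "total", "n", "trials", "n_trials"},
    "choice": {"choice", "response", "outcome", "correct01"},
}


def _canon(col: str) -> str | None:
    low = str(col).strip().lower().replace(" ", "_")
    for canon, aliases in _COLUMN_ALIASES.items():
        if low in aliases:
            return canon
    return None


def convert_supplementary(
    workbook_path,
    sheet_map: dict[str, dict],
    *,
    max_choices_per_freq: int = 20,
) -> tuple[list[ChoiceData], list[str]]:
    """Convert an XLSX workbook of individual choice data to the pipeline schema.

    ``sheet_map`` maps sheet names to ``{"species": ..., "condition": ...}``.
    Three layouts are recognized per sheet, tried in order:

    1. long counts   — columns subject / frequency / n_correct [/ n_total];
    2. long trials   — columns subject / frequency / choice (0/1 per trial),
       aggregated keeping only the first ``max_choices_per_freq`` choices
       per frequency in sheet order;
    3. wide counts   — first column subject names, remaining headers numeric
       frequencies, cells = correct counts out of ``max_choices_per_freq``.

    Returns the converted datasets plus a list of human-readable issues
    (rows that failed invariants, truncations applied); nothing is silently
    dropped.
    """
    path = Path(workbook_path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        book = pd.read_excel(path, sheet_name=None)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"could not read workbook {path}: {exc}") from exc
    if not book:
        raise ValueError(f"workbook {path} contains no sheets")

    missing = [s for s in sheet_map if s not in book]
    if missing:
        raise ValueError(
            f"workbook {path} is missing expected sheets {missing}; found {list(book)}"
        )

    datasets: list[ChoiceData] = []
    issues: list[str] = []
    for sheet, meta in sheet_map.items():
        frame = book[sheet]
        species, condition = meta["species"], meta["condition"]
        canon = {c: _canon(c) for c in frame.columns}
        named = set(filter(None, canon.values()))

        if {"subject_id", "frequency_cpd", "n_correct"} <= named:
            frame = frame.rename(columns={c: v for c, v in canon.items() if v})
            if "n_total" not in frame.columns:
                frame["n_total"] = max_choices_per_freq
            long = frame[["subject_id", "frequency_cpd", "n_correct", "n_total"]].copy()
        elif {"subject_id", "frequency_cpd", "choice"} <= named:
            frame = frame.rename(columns={c: v for c, v in canon.items() if v})
            parts = []
            for (sid, f), grp in frame.groupby(["subject_id", "frequency_cpd"], sort=True):
                choices = grp["choice"].astype(int).tolist()
                if len(choices) > max_choices_per_freq:
                    issues.append(
                        f"{sheet}: {sid} at {f} cpd has {len(choices)} choices; "
                        f"truncated to first {max_choices_per_freq}"
                    )
                    choices = choices[:max_choices_per_freq]
                parts.append((sid, float(f), sum(choices), len(choices)))
            long = pd.DataFrame(
                parts, columns=["subject_id", "frequency_cpd", "n_correct", "n_total"]
            )
        else:
            # wide layout: subjects down the first column, frequencies across
            first = frame.columns[0]
            freq_cols = []
            for c in frame.columns[1:]:
                try:
                    freq_cols.append((c, float(c)))
                except (TypeError, ValueError):
                    issues.append(f"{sheet}: ignored non-numeric column header {c!r}")
            if not freq_cols:
                raise ValueError(
                    f"sheet {sheet!r} matches no known layout: expected long counts "
                    "(subject/frequency/n_correct), long trials "
                    "(subject/frequency/choice) or wide counts "
                    "(subject column + numeric frequency headers)"
                )
            parts = []
            for _, row in frame.iterrows():
                sid = str(row[first])
                for col, f in freq_cols:
                    if pd.isna(row[col]):
                        continue
                    parts.append((sid, f, int(row[col]), max_choices_per_freq))
            long = pd.DataFrame(
                parts, columns=["subject_id", "frequency_cpd", "n_correct", "n_total"]
            )

        for sid, grp in long.groupby("subject_id", sort=True):
            records = []
            for r in grp.sort_values("frequency_cpd").itertuples(index=False):
                f, k, n = float(r.frequency_cpd), int(r.n_correct), int(r.n_total)
                if not (f > 0 and 0 <= k <= n):
                    issues.append(
                        f"{sheet}: {sid} row (freq={f}, k={k}, n={n}) violates "
                        "invariants; excluded"
                    )
                    continue
                if n > max_choices_per_freq:
                    issues.append(
                        f"{sheet}: {sid} at {f} cpd reports n={n} > "
                        f"{max_choices_per_freq}; counts kept as given "
                        "(trial order unknown, cannot truncate counts)"
                    )
                records.append((f, k, n))
            if records:
                datasets.append(
                    ChoiceData(str(sid), species, condition, tuple(records))
                )
            else:
                issues.append(f"{sheet}: subject {sid} had no valid rows")
    for issue in issues:
        logger.warning("%s", issue)
    return datasets, issues
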