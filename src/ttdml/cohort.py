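"""Cohort domain types and the long-format CSV reader/writer.

A cohort lives on disk as three UTF-8 CSVs plus a vocabulary YAML:

* ``static.csv``        — patient_id, variable, value (one row per static var)
* ``longitudinal.csv``  — patient_id, time_min (<= 0), variable, value
* ``outcomes.csv``      — patient_id, ttd_minutes (> 0), era_year
* ``vocabulary.yaml``   — ordered channel lists and categorical encodings

Times are minutes relative to terminal extubation (extubation = 0, history
times <= 0). Time-to-death (TTD) is minutes from extubation to circulatory
death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocabulary import ChannelVocabulary, default_vocabulary

logger = logging.getLogger(__name__)

STATIC_FILE = "static.csv"
LONGITUDINAL_FILE = "longitudinal.csv"
OUTCOMES_FILE = "outcomes.csv"
VOCABULARY_FILE = "vocabulary.yaml"


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort violates the CSV dialect."""


@dataclass
class StaticProfile:
    """Static variables aligned to ``vocabulary.static_names``."""

    values: np.ndarray  # shape (l,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class LongitudinalSeries:
    """Irregularly-sampled multichannel series with observation masks.

    ``values[i, j]`` is only meaningful where ``mask[i, j] == 1``;
    unobserved entries are NaN until imputation.
    """

    times: np.ndarray   # (n,) strictly increasing, all <= 0
    values: np.ndarray  # (n, k)
    mask: np.ndarray    # (n, k) in {0, 1}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.mask.shape:
            raise ValueError("inconsistent series shapes")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times/values length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("observation times must be strictly increasing")

    @property
    def n_observations(self) -> int:
        return len(self.times)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class PatientRecord:
    patient_id: str
    static: StaticProfile
    series: LongitudinalSeries
    ttd_minutes: float
    era_year: int

    def __post_init__(self) -> None:
        if not self.ttd_minutes > 0:
            raise ValueError(f"ttd_minutes must be positive, got {self.ttd_minutes}")


@dataclass
class Cohort:
    records: list[PatientRecord]
    vocabulary: ChannelVocabulary
    provenance: str = "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, ids_or_mask) -> "Cohort":
        if isinstance(ids_or_mask, (set, frozenset)):
            records = [r for r in self.records if r.patient_id in ids_or_mask]
        else:
            records = [r for r, keep in zip(self.records, ids_or_mask) if keep]
        return Cohort(records, self.vocabulary, self.provenance, dict(self.meta))


def read_cohort(
    static_path,
    longitudinal_path,
    outcomes_path,
    vocabulary: ChannelVocabulary | None = None,
) -> Cohort:
    """Read a cohort from the three-CSV long format.

    One record is created per patient present in ``outcomes.csv``; patients
    without outcome rows are skipped with a warning, patients with no
    longitudinal rows are rejected. Longitudinal rows are grouped per
    patient, time-sorted, and duplicate (patient, time, variable) triples
    resolved by keeping the last row (logged).
    """
    vocab = vocabulary or default_vocabulary()
    static_df = pd.read_csv(static_path, dtype={"patient_id": str})
    long_df = pd.read_csv(longitudinal_path, dtype={"patient_id": str})
    out_df = pd.read_csv(outcomes_path, dtype={"patient_id": str})

    for df, cols, name in (
        (static_df, {"patient_id", "variable", "value"}, "static"),
        (long_df, {"patient_id", "time_min", "variable", "value"}, "longitudinal"),
        (out_df, {"patient_id", "ttd_minutes", "era_year"}, "outcomes"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise CohortFormatError(f"{name} file missing columns {sorted(missing)}")

    known_long = set(vocab.longitudinal_names)
    known_static = set(vocab.static_names)
    bad = long_df.loc[~long_df["variable"].isin(known_long)]
    if len(bad):
        row = bad.iloc[0]
        raise CohortFormatError(
            f"unknown longitudinal variable {row['variable']!r} "
            f"(patient {row['patient_id']}, time {row['time_min']})"
        )
    bad = static_df.loc[~static_df["variable"].isin(known_static)]
    if len(bad):
        row = bad.iloc[0]
        raise CohortFormatError(
            f"unknown static variable {row['variable']!r} (patient {row['patient_id']})"
        )
    if (long_df["time_min"] > 0).any():
        raise CohortFormatError("longitudinal time_min values must be <= 0")

    n_dups = long_df.duplicated(["patient_id", "time_min", "variable"]).sum()
    if n_dups:
        logger.info("resolved %d duplicate (patient, time, variable) rows (kept last)", n_dups)
        long_df = long_df.drop_duplicates(["patient_id", "time_min", "variable"], keep="last")

    long_groups = dict(tuple(long_df.groupby("patient_id", sort=False)))
    static_groups = dict(tuple(static_df.groupby("patient_id", sort=False)))

    seen_with_long = set(long_groups) | set(static_groups)
    k = vocab.n_longitudinal
    long_index = {n: i for i, n in enumerate(vocab.longitudinal_names)}
    static_index = {n: i for i, n in enumerate(vocab.static_names)}

    records: list[PatientRecord] = []
    for _, row in out_df.iterrows():
        pid = row["patient_id"]
        g = long_groups.get(pid)
        if g is None or not len(g):
            raise CohortFormatError(f"patient {pid!r} has no longitudinal rows")
        times = np.sort(g["time_min"].unique())
        t_pos = {t: i for i, t in enumerate(times)}
        values = np.full((len(times), k), np.nan)
        mask = np.zeros((len(times), k))
        for t, var, val in zip(g["time_min"], g["variable"], g["value"]):
            i, j = t_pos[t], long_index[var]
            values[i, j] = float(val)
            mask[i, j] = 1.0
        statics = np.full(vocab.n_static, np.nan)
        sg = static_groups.get(pid)
        if sg is not None:
            for var, val in zip(sg["variable"], sg["value"]):
                statics[static_index[var]] = float(val)
        records.append(
            PatientRecord(
                patient_id=pid,
                static=StaticProfile(statics),
                series=LongitudinalSeries(times, values, mask),
                ttd_minutes=float(row["ttd_minutes"]),
                era_year=int(row["era_year"]),
            )
        )

    skipped = seen_with_long - set(out_df["patient_id"])
    if skipped:
        logger.warning("skipped %d patients without outcome rows", len(skipped))
    return Cohort(records, vocab, provenance="file")


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a cohort to ``out_dir`` in the long CSV dialect.

    Round-trips through :func:`read_cohort` up to row order.
    """
    if not len(cohort):
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = cohort.vocabulary

    static_rows, long_rows, out_rows = [], [], []
    for rec in cohort:
        for name, val in zip(vocab.static_names, rec.static.values):
            if np.isfinite(val):
                static_rows.append((rec.patient_id, name, val))
        s = rec.series
        obs = np.argwhere(s.mask > 0)
        for i, j in obs:
            long_rows.append(
                (rec.patient_id, s.times[i], vocab.longitudinal_names[j], s.values[i, j])
            )
        out_rows.append((rec.patient_id, rec.ttd_minutes, rec.era_year))

    paths = {
        "static": out / STATIC_FILE,
        "longitudinal": out / LONGITUDINAL_FILE,
        "outcomes": out / OUTCOMES_FILE,
        "vocabulary": out / VOCABULARY_FILE,
    }
    pd.DataFrame(static_rows, columns=["patient_id", "variable", "value"]).to_csv(
        paths["static"], index=False)
    pd.DataFrame(long_rows, columns=["patient_id", "time_min", "variable", "value"]).to_csv(
        paths["longitudinal"], index=False)
    pd.DataFrame(out_rows, columns=["patient_id", "ttd_minutes", "era_year"]).to_csv(
        paths["outcomes"], index=False)
    vocab.to_yaml(paths["vocabulary"])
    return paths


def read_cohort_dir(cohort_dir) -> Cohort:
    """Read a cohort from a directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    vocab_path = d / VOCABULARY_FILE
    vocab = ChannelVocabulary.from_yaml(vocab_path) if vocab_path.exists() else None
    return read_cohort(d / STATIC_FILE, d / LONGITUDINAL_FILE, d / OUTCOMES_FILE, vocab)
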