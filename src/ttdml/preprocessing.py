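"""Cohort preprocessing: labels, imputation, normalization, splits.

Conventions (fixed across the package):

* TTD bins are half-open ``[lo, hi)``: with default edges (30, 60, 120),
  TTD = 30 min falls in category 1 and TTD = 120 min in category 3.
* Imputation is forward-fill, then backward-fill, then mean-fill per
  channel; channel means come from the *training split only* so the test
  split never leaks into any statistic.
* The temporal split trains on era years strictly before the cutoff and
  evaluates on the cutoff year onward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, LongitudinalSeries, PatientRecord
from .vocabulary import BINARY, ChannelVocabulary

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES: tuple[float, ...] = (30.0, 60.0, 120.0)
EXTENDED_BIN_EDGES: tuple[float, ...] = (30.0, 60.0, 120.0, 180.0, 240.0)
DEFAULT_CUTOFF_YEAR = 2021


def categorize_ttd(ttd_minutes: float, bin_edges=DEFAULT_BIN_EDGES) -> int:
    """Ordinal TTD category: the number of bin edges <= TTD.

    Half-open bins [lo, hi): e.g. with default edges, [0,30) -> 0,
    [30,60) -> 1, [60,120) -> 2, [120,inf) -> 3.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not ttd_minutes > 0:
        raise ValueError(f"ttd_minutes must be positive, got {ttd_minutes}")
    if len(edges) and not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    return int(np.searchsorted(edges, ttd_minutes, side="right"))


def categorize_cohort(cohort: Cohort, bin_edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    return np.array([categorize_ttd(r.ttd_minutes, bin_edges) for r in cohort])


@dataclass
class NormalizationStats:
    """Per-channel and per-static means/sds computed on the training split."""

    channel_mean: np.ndarray
    channel_sd: np.ndarray
    static_mean: np.ndarray
    static_sd: np.ndarray
    vocabulary: ChannelVocabulary

    @classmethod
    def fit(cls, train: Cohort) -> "NormalizationStats":
        vocab = train.vocabulary
        k, l = vocab.n_longitudinal, vocab.n_static
        sums = np.zeros(k)
        sq = np.zeros(k)
        counts = np.zeros(k)
        for rec in train:
            s = rec.series
            obs = s.mask > 0
            vals = np.where(obs, s.values, 0.0)
            sums += vals.sum(axis=0)
            sq += (vals * vals).sum(axis=0)
            counts += obs.sum(axis=0)
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        var = np.where(counts > 1, sq / np.maximum(counts, 1) - mean**2, 0.0)
        sd = np.sqrt(np.clip(var, 0.0, None))
        degenerate = sd < 1e-8
        if degenerate.any():
            logger.info("degenerate channels get sd=1: %s",
                        [vocab.longitudinal_names[i] for i in np.where(degenerate)[0]])
        sd = np.where(degenerate, 1.0, sd)

        statics = np.array([rec.static.values for rec in train])
        s_mean = np.nanmean(np.where(np.isfinite(statics), statics, np.nan), axis=0)
        s_mean = np.where(np.isfinite(s_mean), s_mean, 0.0)
        with np.errstate(invalid="ignore"):
            s_sd = np.nanstd(np.where(np.isfinite(statics), statics, np.nan), axis=0)
        s_sd = np.where(np.isfinite(s_sd) & (s_sd > 1e-8), s_sd, 1.0)
        # binary variables are passed through untouched
        for j, name in enumerate(vocab.longitudinal_names):
            if vocab.kind(name) == BINARY:
                sd[j] = 1.0
        for j, name in enumerate(vocab.static_names):
            if vocab.kind(name) == BINARY:
                s_mean[j], s_sd[j] = 0.0, 1.0
        return cls(mean, sd, s_mean, s_sd, vocab)

    def normalize_values(self, values: np.ndarray) -> np.ndarray:
        out = values.copy()
        for j, name in enumerate(self.vocabulary.longitudinal_names):
            if self.vocabulary.kind(name) != BINARY:
                out[:, j] = (out[:, j] - self.channel_mean[j]) / self.channel_sd[j]
        return out

    def denormalize_values(self, values: np.ndarray) -> np.ndarray:
        out = values.copy()
        for j, name in enumerate(self.vocabulary.longitudinal_names):
            if self.vocabulary.kind(name) != BINARY:
                out[:, j] = out[:, j] * self.channel_sd[j] + self.channel_mean[j]
        return out

    def normalize_statics(self, statics: np.ndarray) -> np.ndarray:
        return (statics - self.static_mean) / self.static_sd


def impute_series(series: LongitudinalSeries,
                  stats: NormalizationStats) -> LongitudinalSeries:
    """Forward-fill, then backward-fill, then train-mean-fill per channel.

    Masks are preserved unchanged: the fill only removes NaNs from the
    value matrix, the model still sees which entries were truly observed.
    """
    vals = np.where(series.mask > 0, series.values, np.nan)
    n, k = vals.shape
    out = vals.copy()
    for j in range(k):
        col = out[:, j]
        obs_idx = np.where(np.isfinite(col))[0]
        if len(obs_idx) == 0:
            out[:, j] = stats.channel_mean[j]
            continue
        # forward fill
        last = np.maximum.accumulate(
            np.where(np.isfinite(col), np.arange(n), -1))
        filled = np.where(last >= 0, col[np.maximum(last, 0)], np.nan)
        # backward fill leading gap from first observation
        filled[: obs_idx[0]] = col[obs_idx[0]]
        out[:, j] = filled
    return LongitudinalSeries(series.times.copy(), out, series.mask.copy())


@dataclass
class PreparedPatient:
    """Model-ready view of one patient.

    ``values`` are imputed (and optionally z-scored), ``mask`` is the raw
    observation mask, ``delta_t`` the gaps in minutes (0 for the first
    observation), ``statics`` the (optionally z-scored) static vector.
    """

    patient_id: str
    times: np.ndarray
    delta_t: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    statics: np.ndarray
    label: int
    ttd_minutes: float
    era_year: int

    @property
    def n_observations(self) -> int:
        return len(self.times)


@dataclass
class PreprocessConfig:
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    cutoff_year: int = DEFAULT_CUTOFF_YEAR
    horizon_min: float | None = None
    normalize: bool = True


def prepare_patient(record: PatientRecord, stats: NormalizationStats,
                    config: PreprocessConfig | None = None) -> PreparedPatient:
    config = config or PreprocessConfig()
    series = impute_series(record.series, stats)
    values = stats.normalize_values(series.values) if config.normalize else series.values
    statics = np.where(np.isfinite(record.static.values),
                       record.static.values, stats.static_mean)
    if config.normalize:
        statics = stats.normalize_statics(statics)
    dt = np.diff(series.times, prepend=series.times[:1])
    return PreparedPatient(
        patient_id=record.patient_id,
        times=series.times,
        delta_t=dt,
        values=values,
        mask=series.mask,
        statics=statics,
        label=categorize_ttd(record.ttd_minutes, config.bin_edges),
        ttd_minutes=record.ttd_minutes,
        era_year=record.era_year,
    )


def prepare_cohort(cohort: Cohort, stats: NormalizationStats,
                   config: PreprocessConfig | None = None) -> list[PreparedPatient]:
    config = config or PreprocessConfig()
    out = []
    for rec in cohort:
        if config.horizon_min is not None:
            truncated, empty = truncate_history(rec.series, config.horizon_min)
            if empty:
                logger.warning("patient %s has no observations before the %g-min "
                               "horizon; dropped", rec.patient_id, config.horizon_min)
                continue
            rec = PatientRecord(rec.patient_id, rec.static, truncated,
                                rec.ttd_minutes, rec.era_year)
        out.append(prepare_patient(rec, stats, config))
    return out


def temporal_split(cohort: Cohort,
                   cutoff_year: int = DEFAULT_CUTOFF_YEAR) -> tuple[Cohort, Cohort]:
    """Train on era years < cutoff, evaluate on years >= cutoff."""
    train = cohort.subset([r.era_year < cutoff_year for r in cohort])
    test = cohort.subset([r.era_year >= cutoff_year for r in cohort])
    if not len(train):
        raise ValueError(f"temporal split: empty train side (all years >= {cutoff_year})")
    if not len(test):
        raise ValueError(f"temporal split: empty test side (all years < {cutoff_year})")
    return train, test


def truncate_history(series: LongitudinalSeries,
                     horizon_min: float) -> tuple[LongitudinalSeries, bool]:
    """Drop observations within the final ``horizon_min`` minutes.

    Keeps rows with time <= -horizon_min, emulating prediction made
    ``horizon_min`` minutes before extubation. Returns the truncated series
    and a flag marking a patient left with zero observations.
    """
    if not horizon_min > 0:
        raise ValueError("horizon_min must be positive")
    keep = series.times <= -horizon_min
    if not keep.any():
        return LongitudinalSeries(np.empty(0), np.empty((0, series.n_channels)),
                                  np.empty((0, series.n_channels))), True
    return LongitudinalSeries(series.times[keep], series.values[keep],
                              series.mask[keep]), False
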