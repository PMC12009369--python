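"""Model interpretation: permutation importance and the patient phenoscape.

Permutation importance swaps, across patients, the *entire trajectory* of
one longitudinal channel (observation times, values and mask together), or
the value of one static variable, and measures the drop in ROC-AUC of a
grouped binary task. Trajectory-level permutation preserves within-series
autocorrelation, so the score reflects the importance of the variable, not
of its sampling pattern alone.

The phenoscape is the set of latent phenotypes of a cohort, embedded in
2-D by a neighborhood-preserving method (UMAP by default, PCA available),
clustered (k-means on the *phenotypes*, not the 2-D coordinates), and
annotated with scalar trajectory summaries for inter-cluster comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, LongitudinalSeries, PatientRecord
from .evaluation import BinaryTask, group_probability
from .preprocessing import (NormalizationStats, PreprocessConfig,
                            prepare_cohort)

logger = logging.getLogger(__name__)

TRANSFORMS = ("range", "mean", "min", "max")


def summarize_channel(series: LongitudinalSeries, channel_idx: int,
                      transform: str) -> float:
    """Scalar summary of one channel's *observed* values.

    ``range`` is the mean of the five highest observations minus the mean
    of the five lowest; ``min``/``max`` are the means of the five
    lowest/highest; ``mean`` averages all observations. With fewer than
    five observations the top and bottom sets coincide, so ``range``
    degenerates: it falls back to max - min (logged at debug level).
    Returns NaN when the channel was never observed.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    obs = series.values[series.mask[:, channel_idx] > 0, channel_idx]
    if len(obs) == 0:
        return float("nan")
    srt = np.sort(obs)
    if transform == "mean":
        return float(obs.mean())
    if transform == "min":
        return float(srt[:5].mean())
    if transform == "max":
        return float(srt[-5:].mean())
    if len(obs) < 5:
        logger.debug("range transform with %d < 5 observations: using max - min",
                     len(obs))
        return float(srt[-1] - srt[0])
    return float(srt[-5:].mean() - srt[:5].mean())


# ---------------------------------------------------------------------------
# Permutation importance


def _channel_events(record: PatientRecord) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    s = record.series
    out = {}
    for j in range(s.n_channels):
        obs = s.mask[:, j] > 0
        out[j] = (s.times[obs].copy(), s.values[obs, j].copy())
    return out


def _series_from_events(events: dict[int, tuple[np.ndarray, np.ndarray]],
                        k: int) -> LongitudinalSeries | None:
    all_times = np.unique(np.concatenate(
        [t for t, _ in events.values()] or [np.empty(0)]))
    if len(all_times) == 0:
        return None
    pos = {t: i for i, t in enumerate(all_times)}
    values = np.full((len(all_times), k), np.nan)
    mask = np.zeros((len(all_times), k))
    for j, (times, vals) in events.items():
        for t, v in zip(times, vals):
            values[pos[t], j] = v
            mask[pos[t], j] = 1.0
    return LongitudinalSeries(all_times, values, mask)


def permute_variable(cohort: Cohort, variable: str,
                     perm: np.ndarray) -> Cohort:
    """Reassign one variable across patients according to ``perm``.

    For a longitudinal variable, patient i receives patient perm[i]'s whole
    trajectory of that channel (times, values, mask); for a static
    variable, just the value. The identity permutation reproduces the
    cohort exactly.
    """
    vocab = cohort.vocabulary
    k = vocab.n_longitudinal
    records = cohort.records
    if variable in vocab.static_names:
        j = vocab.static_index(variable)
        new_records = []
        for i, rec in enumerate(records):
            statics = rec.static.values.copy()
            statics[j] = records[perm[i]].static.values[j]
            new_records.append(PatientRecord(
                rec.patient_id, type(rec.static)(statics), rec.series,
                rec.ttd_minutes, rec.era_year))
        return Cohort(new_records, vocab, cohort.provenance, dict(cohort.meta))
    if variable not in vocab.longitudinal_names:
        raise ValueError(f"unknown variable {variable!r}")
    j = vocab.longitudinal_index(variable)
    donor_events = [_channel_events(rec) for rec in records]
    new_records = []
    for i, rec in enumerate(records):
        events = _channel_events(rec)
        events[j] = donor_events[perm[i]][j]
        series = _series_from_events(events, k)
        if series is None:  # patient would lose every observation
            series = rec.series
        new_records.append(PatientRecord(
            rec.patient_id, rec.static, series, rec.ttd_minutes, rec.era_year))
    return Cohort(new_records, vocab, cohort.provenance, dict(cohort.meta))


def truncate_cohort(cohort: Cohort, horizon_min: float) -> Cohort:
    """Apply history truncation at the cohort level, dropping patients left
    with no observations."""
    from .preprocessing import truncate_history

    records = []
    for rec in cohort:
        series, empty = truncate_history(rec.series, horizon_min)
        if empty:
            continue
        records.append(PatientRecord(rec.patient_id, rec.static, series,
                                     rec.ttd_minutes, rec.era_year))
    return Cohort(records, cohort.vocabulary, cohort.provenance,
                  dict(cohort.meta))


def permutation_importance(model, cohort: Cohort, stats: NormalizationStats,
                           variable: str, task: BinaryTask,
                           config: PreprocessConfig | None = None,
                           n_repeats: int = 5, seed: int = 0,
                           baseline_probs: np.ndarray | None = None) -> dict:
    """Drop in ROC-AUC when one variable is permuted across patients.

    Delta = baseline ROC-AUC - permuted ROC-AUC, averaged over
    ``n_repeats`` independent permutations. Any history truncation is
    applied before permuting, so the patient set is identical for the
    baseline and every permutation.
    """
    from sklearn.metrics import roc_auc_score

    config = config or PreprocessConfig()
    if config.horizon_min is not None:
        cohort = truncate_cohort(cohort, config.horizon_min)
        config = PreprocessConfig(bin_edges=config.bin_edges,
                                  cutoff_year=config.cutoff_year,
                                  horizon_min=None,
                                  normalize=config.normalize)
    rng = np.random.default_rng(np.random.PCG64([seed, 0x1A7]))
    prepared = prepare_cohort(cohort, stats, config)
    ttd = np.array([p.ttd_minutes for p in prepared])
    y = task.labels(ttd)
    if baseline_probs is None:
        baseline_probs = model.predict_proba(prepared)
    base_auc = roc_auc_score(y, group_probability(baseline_probs, task))
    deltas = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(cohort))
        permuted = permute_variable(cohort, variable, perm)
        probs = model.predict_proba(prepare_cohort(permuted, stats, config))
        deltas.append(base_auc - roc_auc_score(y, group_probability(probs, task)))
    deltas = np.array(deltas)
    return {"variable": variable, "task": task.name,
            "baseline_auc": float(base_auc),
            "delta_mean": float(deltas.mean()),
            "delta_sd": float(deltas.std()),
            "deltas": deltas.tolist()}


def importance_table(model, cohort: Cohort, stats: NormalizationStats,
                     tasks: list[BinaryTask],
                     variables: list[str] | None = None,
                     config: PreprocessConfig | None = None,
                     n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Permutation importance of every variable for every binary task.

    Returns a long table (variable, kind, task, baseline/delta statistics)
    with a per-task rank, 1 = most important.
    """
    vocab = cohort.vocabulary
    config = config or PreprocessConfig()
    if variables is None:
        variables = list(vocab.longitudinal_names) + list(vocab.static_names)
    prepared = prepare_cohort(cohort, stats, config)
    baseline_probs = model.predict_proba(prepared)
    rows = []
    for v_idx, variable in enumerate(variables):
        kind = "static" if variable in vocab.static_names else "longitudinal"
        for task in tasks:
            res = permutation_importance(
                model, cohort, stats, variable, task, config,
                n_repeats=n_repeats, seed=seed + 7919 * v_idx,
                baseline_probs=baseline_probs)
            rows.append({"variable": variable, "kind": kind, **{
                k: res[k] for k in ("task", "baseline_auc", "delta_mean",
                                    "delta_sd")}})
    table = pd.DataFrame(rows)
    table["rank"] = table.groupby("task")["delta_mean"].rank(
        ascending=False, method="min").astype(int)
    return table


# ---------------------------------------------------------------------------
# Phenoscape


def extract_phenotypes(model, patients) -> np.ndarray:
    """Latent phenotype matrix (n_patients x phenotype_dim)."""
    return model.encode(patients)


def embed_2d(phenotypes: np.ndarray, method: str = "umap",
             seed: int = 0, **kwargs) -> np.ndarray:
    """Two-dimensional neighborhood-preserving embedding of the phenotypes.

    Delegates to UMAP (default) or PCA; deterministic for a fixed seed.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = len(phenotypes)
    if n < 10:
        raise ValueError("embedding needs at least 10 patients")
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed).fit_transform(phenotypes)
    if method == "umap":
        import umap

        n_neighbors = int(kwargs.pop("n_neighbors", min(15, n - 1)))
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed, n_jobs=1, **kwargs)
        return np.asarray(reducer.fit_transform(phenotypes), dtype=float)
    raise ValueError(f"unknown embedding method {method!r}")


@dataclass
class PhenoscapeView:
    """Per-patient 2-D coordinates, cluster labels and coloring scalars."""

    table: pd.DataFrame  # patient_id, x, y, cluster, label, log_ttd, summaries

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


DEFAULT_COLOR_SUMMARIES = (("pulse", "range"), ("pulse", "mean"),
                           ("spo2", "min"), ("gcs", "mean"), ("map", "max"))


def build_phenoscape(model, cohort: Cohort, stats: NormalizationStats,
                     config: PreprocessConfig | None = None,
                     color_summaries=DEFAULT_COLOR_SUMMARIES,
                     method: str = "umap", n_clusters: int = 3,
                     seed: int = 0,
                     ttd_filter_max: float | None = None) -> PhenoscapeView:
    """Embed, cluster and annotate a cohort's latent phenotypes.

    ``ttd_filter_max`` restricts the view to patients below a TTD cutoff
    (the zoomed-in analysis of the short-TTD group).
    """
    from sklearn.cluster import KMeans

    config = config or PreprocessConfig()
    if ttd_filter_max is not None:
        cohort = cohort.subset([r.ttd_minutes < ttd_filter_max for r in cohort])
    if config.horizon_min is not None:
        cohort = truncate_cohort(cohort, config.horizon_min)
        config = PreprocessConfig(bin_edges=config.bin_edges,
                                  cutoff_year=config.cutoff_year,
                                  horizon_min=None, normalize=config.normalize)
    prepared = prepare_cohort(cohort, stats, config)
    phenotypes = extract_phenotypes(model, prepared)
    coords = embed_2d(phenotypes, method=method, seed=seed)
    clusters = KMeans(n_clusters=n_clusters, random_state=seed,
                      n_init=10).fit_predict(phenotypes)
    vocab = cohort.vocabulary
    rows = []
    for i, (rec, prep) in enumerate(zip(cohort, prepared)):
        row = {"patient_id": rec.patient_id, "x": coords[i, 0], "y": coords[i, 1],
               "cluster": int(clusters[i]), "label": prep.label,
               "ttd_minutes": rec.ttd_minutes,
               "log_ttd": float(np.log(rec.ttd_minutes))}
        for channel, transform in color_summaries:
            j = vocab.longitudinal_index(channel)
            row[f"{channel}_{transform}"] = summarize_channel(rec.series, j, transform)
        for name in vocab.static_names:
            row[name] = rec.static.values[vocab.static_index(name)]
        rows.append(row)
    view = PhenoscapeView(pd.DataFrame(rows))
    view.phenotypes = phenotypes  # kept for clustering-based comparisons
    return view


def cluster_and_compare(view: PhenoscapeView,
                        variables: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster means and pairwise independent t-tests.

    Returns (means table indexed by cluster, long p-value table with one
    row per variable and cluster pair). Pairs where either cluster has
    fewer than two members are skipped.
    """
    table = view.table
    if variables is None:
        exclude = {"patient_id", "x", "y", "cluster"}
        variables = [c for c in table.columns if c not in exclude]
    means = table.groupby("cluster")[variables].mean()
    clusters = sorted(table["cluster"].unique())
    rows = []
    for a_idx, a in enumerate(clusters):
        for b in clusters[a_idx + 1:]:
            va = table.loc[table["cluster"] == a]
            vb = table.loc[table["cluster"] == b]
            for var in variables:
                xa = va[var].dropna().to_numpy()
                xb = vb[var].dropna().to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    logger.info("skipping t-test %s clusters %s/%s: <2 members",
                                var, a, b)
                    continue
                t_stat, p = sps.ttest_ind(xa, xb, equal_var=False)
                rows.append({"variable": var, "cluster_a": a, "cluster_b": b,
                             "t": float(t_stat), "p_value": float(p)})
    return means, pd.DataFrame(rows)
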