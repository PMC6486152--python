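"""Nuclear-intensity normalization, positivity calls and marker partitions.

The processing chain mirrors how fixed and live-imaged embryo intensities are
prepared for analysis:

1. z-attenuation correction — within each embryo and channel, log intensity
   is regressed on the nucleus z coordinate and the fitted slope is removed
   relative to the embryo's median z (attenuation with depth is
   multiplicative, so the correction is exact for exponential decay);
2. per-embryo standardization to mean 0, sd 1, so embryos imaged with
   different gains are comparable;
3. positivity thresholding, either a manual per-batch threshold (the analogue
   of ordering cells by intensity and fixing a cutoff per imaging session) or
   an automatic two-component Gaussian mixture on log intensities;
4. derived partitions: Venn subsets over three markers, per-embryo
   percent-positive, and the mosaic-cassette rule that maps three antibody
   calls (RFP/GFP/HA) to unrecombined / wildtype / LOF / GOF labels.

Mitotic/pyknotic nuclei flagged in an ``excluded`` column never receive calls
and are excluded from every fit and summary.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSpec",
    "ZeroVarianceError",
    "correct_z_attenuation",
    "standardize_embryo",
    "call_positive",
    "venn_partition",
    "percent_positive_per_embryo",
    "assign_mosaic_cassette",
    "quantify_table",
]

CASSETTE_LABELS = ("unrecombined", "wildtype", "LOF", "GOF")


class ZeroVarianceError(ValueError):
    """An embryo (or batch) has no intensity variance to standardize/fit."""


@dataclass
class ThresholdSpec:
    """How to call a channel positive.

    ``manual`` mode uses ``manual_value`` (a number, or a mapping from batch
    key to number) on the corrected-intensity scale.  ``auto`` mode fits a
    two-component Gaussian mixture to log corrected intensities per batch and
    thresholds at the equal-posterior point between the component means; if
    the mixture degenerates it falls back to the midpoint of the widest gap
    between adjacent order statistics, with a warning.
    """

    mode: str = "manual"
    manual_value: float | dict | None = None
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "auto"):
            raise ValueError("mode must be 'manual' or 'auto'")
        if self.mode == "manual":
            if self.manual_value is None:
                raise ValueError("manual mode requires manual_value")
            if isinstance(self.manual_value, (int, float)) and not np.isfinite(
                self.manual_value
            ):
                raise ValueError("manual threshold must be finite")


def _excluded_mask(df: pd.DataFrame) -> pd.Series:
    if "excluded" in df:
        return df["excluded"].fillna(False).astype(bool)
    return pd.Series(False, index=df.index)


def correct_z_attenuation(
    records: pd.DataFrame, channel: str, eps: float | None = None
) -> pd.DataFrame:
    """Remove the per-embryo log-linear depth trend from one channel.

    Within each embryo, OLS of log(I + eps) on z over non-excluded nuclei
    (all frames pooled); corrected log intensity is the observed value minus
    ``slope * (z - median z)``, so the embryo's intensity scale is preserved.
    ``eps`` defaults to 0 when all intensities are positive and to 1
    otherwise.  Returns a copy with a ``{channel}_corr`` column.

    Embryos whose nuclei all share one z (no depth range) keep their observed
    intensities, with a warning.
    """
    df = records.copy()
    excluded = _excluded_mask(df)
    out = np.full(len(df), np.nan)
    for embryo, idx in df.groupby("embryo_id", sort=False).groups.items():
        sub = df.loc[idx]
        fit = sub.loc[~excluded.loc[idx]]
        if len(fit) < 3 or fit["z_um"].nunique() < 2:
            if fit["z_um"].nunique() < 2:
                warnings.warn(
                    f"embryo {embryo!r}: no z range; correction is identity",
                    stacklevel=2,
                )
                out[df.index.get_indexer(idx)] = sub[channel].values
                continue
            raise ValueError(
                f"embryo {embryo!r}: need >= 3 nuclei with distinct z "
                f"to fit the attenuation model"
            )
        e = eps
        if e is None:
            e = 0.0 if fit[channel].min() > 0 else 1.0
        if (fit[channel] + e).min() <= 0:
            raise ValueError(
                f"embryo {embryo!r}: nonpositive intensities after offset"
            )
        logi = np.log(fit[channel].values + e)
        z = fit["z_um"].values
        slope, _ = np.polyfit(z, logi, 1)
        zmed = float(np.median(z))
        all_log = np.log(sub[channel].values + e)
        corr = np.exp(all_log - slope * (sub["z_um"].values - zmed)) - e
        out[df.index.get_indexer(idx)] = corr
    df[f"{channel}_corr"] = out
    return df


def standardize_embryo(
    records: pd.DataFrame, channel: str, source: str | None = None
) -> pd.DataFrame:
    """Per-embryo mean-0 / sd-1 standardization (sample sd, all frames pooled).

    ``source`` defaults to ``{channel}_corr`` when present, else the raw
    channel.  Raises :class:`ZeroVarianceError` naming the embryo when there
    is nothing to scale.  Adds a ``{channel}_std`` column.
    """
    df = records.copy()
    col = source or (
        f"{channel}_corr" if f"{channel}_corr" in df else channel
    )
    excluded = _excluded_mask(df)
    out = np.full(len(df), np.nan)
    for embryo, idx in df.groupby("embryo_id", sort=False).groups.items():
        vals = df.loc[idx, col]
        fit = vals[~excluded.loc[idx]]
        if len(fit) < 2:
            raise ZeroVarianceError(
                f"embryo {embryo!r}: need >= 2 nuclei to standardize"
            )
        mu = float(fit.mean())
        sd = float(fit.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ZeroVarianceError(
                f"embryo {embryo!r}: zero intensity variance in {col}"
            )
        out[df.index.get_indexer(idx)] = (vals.values - mu) / sd
    df[f"{channel}_std"] = out
    return df


def _gap_midpoint(logs: np.ndarray) -> float:
    s = np.sort(logs)
    gaps = np.diff(s)
    i = int(np.argmax(gaps))
    return float(0.5 * (s[i] + s[i + 1]))


def _mixture_threshold(values: np.ndarray, random_state: int) -> float:
    """Equal-posterior cut of a 2-component Gaussian mixture on logs."""
    from sklearn.mixture import GaussianMixture

    logs = np.log(values)
    gm = GaussianMixture(
        n_components=2, n_init=3, random_state=random_state
    ).fit(logs.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    labels = gm.predict(logs.reshape(-1, 1))
    if len(np.unique(labels)) < 2 or (m2 - m1) < 1e-9:
        warnings.warn(
            "degenerate intensity mixture; falling back to the widest "
            "order-statistics gap",
            stacklevel=3,
        )
        return float(np.exp(_gap_midpoint(logs)))
    w = gm.weights_[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])

    def post_diff(x: float) -> float:
        from scipy.stats import norm

        return w[1] * norm.pdf(x, m2, sd[1]) - w[0] * norm.pdf(x, m1, sd[0])

    from scipy.optimize import brentq

    lo, hi = m1, m2
    try:
        if post_diff(lo) * post_diff(hi) > 0:
            raise ValueError
        cut = brentq(post_diff, lo, hi)
    except ValueError:
        warnings.warn(
            "no equal-posterior crossing between the mixture means; "
            "falling back to the widest order-statistics gap",
            stacklevel=3,
        )
        return float(np.exp(_gap_midpoint(logs)))
    return float(np.exp(cut))


def call_positive(
    records: pd.DataFrame,
    channel: str,
    spec: ThresholdSpec,
    batch_col: str | None = None,
    source: str | None = None,
) -> pd.DataFrame:
    """Boolean positivity per nucleus: positive iff intensity > threshold.

    Thresholding is per experiment batch (``batch_col`` grouping; the whole
    table is one batch when absent), mirroring independent thresholding of
    embryo sets processed and imaged in parallel.  Excluded nuclei get NA.
    Adds ``{channel}_pos`` (nullable boolean) and records the threshold used
    in ``df.attrs['thresholds']``.
    """
    df = records.copy()
    col = source or (
        f"{channel}_corr" if f"{channel}_corr" in df else channel
    )
    excluded = _excluded_mask(df)
    pos = pd.array([pd.NA] * len(df), dtype="boolean")
    thresholds: dict = {}
    groups = (
        df.groupby(batch_col, sort=False).groups.items()
        if batch_col
        else [("__all__", df.index)]
    )
    for batch, idx in groups:
        vals = df.loc[idx, col].values
        ok = ~excluded.loc[idx].values
        if spec.mode == "manual":
            thr = spec.manual_value
            if isinstance(thr, dict):
                thr = thr[batch]
            thr = float(thr)
        else:
            fit_vals = vals[ok]
            fit_vals = fit_vals[fit_vals > 0]
            if len(fit_vals) < 4:
                raise ValueError(
                    f"batch {batch!r}: too few nuclei for automatic "
                    f"thresholding"
                )
            thr = _mixture_threshold(fit_vals, spec.random_state)
        thresholds[batch] = thr
        take = df.index.get_indexer(idx)
        pos[take] = vals > thr
        pos[take[~ok]] = pd.NA
    df[f"{channel}_pos"] = pos
    df.attrs.setdefault("thresholds", {})[channel] = thresholds
    return df


def venn_partition(
    calls: pd.DataFrame | Sequence,
    channels: Sequence[str] = ("ch1", "ch2", "ch3"),
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-nucleus Venn label and counts over the 8 marker subsets.

    ``calls`` is either a DataFrame with ``{ch}_pos`` columns or a sequence
    of three aligned boolean vectors.  Excluded (NA-call) nuclei are dropped.
    Returns (labels, summary); the summary has one row per subset with counts
    and percentages of the total and of nuclei positive for >= 1 marker.
    """
    if isinstance(calls, pd.DataFrame):
        cols = []
        for ch in channels:
            c = f"{ch}_pos" if f"{ch}_pos" in calls else ch
            cols.append(calls[c])
        mat = pd.concat(cols, axis=1)
    else:
        vecs = [pd.Series(v) for v in calls]
        if len({len(v) for v in vecs}) > 1:
            raise ValueError("call vectors have mismatched lengths")
        mat = pd.concat(vecs, axis=1)
        mat.columns = list(channels)[: mat.shape[1]]
    if mat.shape[1] != 3:
        raise ValueError("venn_partition requires exactly three channels")
    mat = mat.dropna().astype(bool)
    names = list(channels)
    if len(mat) == 0:
        labels = pd.Series(dtype="object")
    else:
        labels = mat.apply(
            lambda row: "+".join(n for n, v in zip(names, row) if v) or "none",
            axis=1,
        )
    subset_names = ["none"] + [
        "+".join(c)
        for k in (1, 2, 3)
        for c in itertools.combinations(names, k)
    ]
    counts = labels.value_counts().reindex(subset_names, fill_value=0)
    total = int(len(mat))
    any_pos = int(total - counts["none"])
    summary = pd.DataFrame(
        {
            "subset": subset_names,
            "count": counts.values,
            "pct_of_total": 100.0 * counts.values / total if total else 0.0,
            "pct_of_any_positive": [
                (100.0 * c / any_pos if (any_pos and s != "none") else np.nan)
                for s, c in zip(subset_names, counts.values)
            ],
        }
    )
    assert int(summary["count"].sum()) == total
    return labels, summary


def percent_positive_per_embryo(
    calls: pd.DataFrame, channel: str
) -> pd.Series:
    """100 * positives / non-excluded nuclei, per embryo."""
    col = f"{channel}_pos" if f"{channel}_pos" in calls else channel
    sub = calls[["embryo_id", col]].dropna(subset=[col])
    counts = sub.groupby("embryo_id")[col].agg(["sum", "count"])
    if (counts["count"] == 0).any():
        raise ValueError("embryo with zero non-excluded nuclei")
    return 100.0 * counts["sum"] / counts["count"]


def assign_mosaic_cassette(rfp, gfp, ha) -> pd.Series:
    """Map three antibody calls to the mosaic recombination cassette.

    HA marks the gain-of-function cassette and cross-reacts with the other
    two antibodies, so any HA-positive nucleus (including triple positives)
    is GOF; GFP without HA is the loss-of-function cassette; RFP alone is the
    recombined wildtype cassette; all-negative nuclei are unrecombined.
    Total on all 8 input patterns.
    """
    rfp = pd.Series(rfp).astype(bool)
    gfp = pd.Series(gfp).astype(bool).values
    ha = pd.Series(ha).astype(bool).values
    out = np.where(
        ha, "GOF", np.where(gfp, "LOF", np.where(rfp.values, "wildtype",
                                                 "unrecombined"))
    )
    return pd.Series(out, index=rfp.index, name="cassette")


def quantify_table(
    nuclei: pd.DataFrame,
    channels: Sequence[str] = ("ch1", "ch2", "ch3"),
    z_correct: bool = True,
    spec: ThresholdSpec | None = None,
    batch_col: str | None = None,
) -> pd.DataFrame:
    """Full per-channel pipeline: correction, standardization, calls, Venn.

    Convenience wrapper used by the command-line interface; adds
    ``{ch}_corr``, ``{ch}_std``, ``{ch}_pos`` and ``venn_label`` columns.
    """
    df = nuclei.copy()
    for ch in channels:
        if z_correct:
            df = correct_z_attenuation(df, ch)
        else:
            df[f"{ch}_corr"] = df[ch]
        df = standardize_embryo(df, ch)
        if spec is not None:
            df = call_positive(df, ch, spec, batch_col=batch_col)
    if spec is not None and len(channels) == 3:
        labels, _ = venn_partition(df, channels)
        df["venn_label"] = labels.reindex(df.index)
    return df
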