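"""Descriptive statistics, detection frequencies and composition profiles.

All statistics are computed over the substituted data, i.e. with
nondetects included as their substituted concentration (0 under the
survey's convention), so medians of mostly-censored congeners are 0 by
construction. Sigma-OPEs for a sample is the plain sum of its congener
concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ConcentrationTable, CrustRiskError, ValidationError

logger = logging.getLogger(__name__)

GROUP_KEYS = ("species", "region", "month", "year", "congener")


class UndefinedCompositionError(CrustRiskError):
    """Composition shares requested for an all-zero table."""


@dataclass(frozen=True)
class SummaryStats:
    """Distribution summary for one group of concentration values."""

    n: int
    mean: float
    minimum: float
    median: float
    maximum: float
    sd: float
    detection_frequency: float


def _stats(values: np.ndarray, detected: np.ndarray) -> SummaryStats:
    n = len(values)
    return SummaryStats(
        n=n,
        mean=float(np.mean(values)),
        minimum=float(np.min(values)),
        median=float(np.median(values)),
        maximum=float(np.max(values)),
        sd=float(np.std(values, ddof=1)) if n > 1 else 0.0,
        detection_frequency=float(np.mean(detected)),
    )


def summarize(table: ConcentrationTable,
              by: Iterable[str] = ()) -> dict[object, SummaryStats]:
    """Group summaries of concentrations.

    With "congener" in ``by`` the values are that congener's per-sample
    concentrations; otherwise each sample contributes its Sigma-OPEs
    (its detection flag then meaning "any congener detected"). Group
    keys are tuples in (species, region, month, year, congener) order,
    collapsed to scalars for a single grouping key; the empty grouping
    yields the single key "all".
    """
    by = list(by)
    unknown = set(by) - set(GROUP_KEYS)
    if unknown:
        raise ValidationError(f"unknown grouping keys: {sorted(unknown)}")
    keys = [k for k in GROUP_KEYS if k in by]

    if "congener" in keys:
        df = table.data
        values_col, det_col = "concentration", "detected"
    else:
        sums = table.sum_opes()
        any_det = table.detected_wide().any(axis=1)
        df = table.sample_meta()
        df = df.assign(sum_opes=sums, any_detected=any_det).reset_index()
        values_col, det_col = "sum_opes", "any_detected"

    if df.empty:
        logger.warning("summarize: empty table, no groups to report")
        return {}
    out: dict[object, SummaryStats] = {}
    if not keys:
        out["all"] = _stats(df[values_col].to_numpy(float),
                            df[det_col].to_numpy(bool))
        return out
    for key, grp in df.groupby(keys, sort=True):
        if grp.empty:  # pragma: no cover - pandas drops empty groups
            logger.warning("summarize: empty group %s omitted", key)
            continue
        label = key[0] if len(keys) == 1 else tuple(key)
        out[label] = _stats(grp[values_col].to_numpy(float),
                            grp[det_col].to_numpy(bool))
    return out


def congener_means(table: ConcentrationTable) -> pd.Series:
    """All-sample mean per congener, catalog order (nondetects as substituted)."""
    return table.to_wide().mean(axis=0).reindex(list(table.catalog.abbrevs))


def class_composition(table: ConcentrationTable) -> dict[str, float]:
    """Percent of Sigma-OPEs contributed by each chemical class.

    Shares are ratios of sums of per-congener mean concentrations, so
    they are invariant to sample order and to overall rescaling.
    """
    means = congener_means(table)
    total = float(means.sum())
    if total <= 0:
        raise UndefinedCompositionError("composition undefined for all-zero table")
    classes = table.catalog.classes()
    by_class = means.groupby(means.index.map(classes)).sum()
    shares = {cls: float(100.0 * by_class.get(cls, 0.0) / total)
              for cls in ("chlorinated", "alkyl", "aryl", "brominated")}
    return shares


def congener_share(table: ConcentrationTable, subset: Iterable[str]) -> float:
    """Percent of Sigma-OPEs contributed by a set of congeners."""
    subset = list(subset)
    unknown = set(subset) - set(table.catalog.abbrevs)
    if unknown:
        raise ValidationError(f"congeners not in catalog: {sorted(unknown)}")
    means = congener_means(table)
    total = float(means.sum())
    if total <= 0:
        raise UndefinedCompositionError("share undefined for all-zero table")
    return float(100.0 * means.loc[subset].sum() / total) if subset else 0.0


def detection_frequency_table(table: ConcentrationTable) -> pd.DataFrame:
    """Proportion of samples with a detect, per species x congener.

    Rows are species present in the table, columns the catalog order;
    unaffected by the substitution policy (it only moves nondetect
    concentrations, never flags).
    """
    if table.data.empty:
        raise ValidationError("detection frequencies undefined for empty table")
    freq = (table.data.groupby(["species", "congener"], sort=True)["detected"]
            .mean().unstack("congener"))
    return freq.reindex(columns=list(table.catalog.abbrevs))


def plot_class_composition(shares: Mapping[str, float], path: str) -> None:
    """Minimal stacked-bar export of class shares (diagnostic, not styled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    bottom = 0.0
    for cls, share in shares.items():
        ax.bar(["all samples"], [share], bottom=bottom, label=cls)
        bottom += share
    ax.set_ylabel("% of ΣOPEs")
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_detection_frequencies(freq: pd.DataFrame, path: str) -> None:
    """Minimal grouped-bar export of detection frequencies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = freq.T.plot.bar(figsize=(10, 4))
    ax.set_ylabel("detection frequency")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
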