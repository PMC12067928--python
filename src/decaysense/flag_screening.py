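"""Flag-molecule screening: normalization, 3xSD calls, AD/HC ratios, panel ranking.

Each compound well's half-life is divided by the same sample's no-compound
(vehicle) half-life, giving a dimensionless normalized ratio.  A compound is
a "flag" molecule when its ratio deviates from the across-compound mean by
more than three sample standard deviations — i.e. it perturbs the probe's
decay conspicuously more than the library at large.

For disease screening, the per-compound mean ratio over AD samples is
divided by the mean ratio over HC samples; compounds are ranked by
|log(score)| so that ratios of 2.0 and 0.5 are equally informative, and the
top-n form the diagnostic panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import BASELINE


@dataclass(frozen=True)
class ScreeningResult:
    """3xSD flag call for one compound."""

    compound_id: str
    normalized_ratio: float
    deviation: float  # ratio minus the across-compound mean
    flagged: bool
    threshold: float  # the 3 x SD value applied


@dataclass(frozen=True)
class PanelSelection:
    """Ordered top-n compound panel with its ranking scores."""

    ranked: tuple[str, ...]
    scores: tuple[float, ...]  # AD/HC score of each ranked compound, same order
    n: int


def normalize_half_life(t_compound: float, t_baseline: float) -> float:
    """Ratio of with-compound to no-compound half-life for the same sample."""
    if not t_baseline > 0:
        raise ValueError(f"baseline half-life must be positive, got {t_baseline}")
    if not t_compound > 0:
        raise ValueError(f"compound half-life must be positive, got {t_compound}")
    return t_compound / t_baseline


def normalized_ratio_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, compound) normalized ratios from a plate fit table.

    Replicate half-lives are averaged per (sample, compound); each sample's
    compounds are then divided by that sample's mean vehicle-well half-life.
    Non-converged wells are dropped before averaging.

    Returns a DataFrame with columns ``sample_id, compound_id, ratio``.
    """
    ok = fits[fits["converged"]]
    mean_hl = ok.groupby(["sample_id", "compound_id"])["half_life"].mean()
    rows = []
    for sample_id, sub in mean_hl.groupby(level="sample_id"):
        sub = sub.droplevel("sample_id")
        if BASELINE not in sub.index:
            raise ValueError(f"sample {sample_id!r} has no converged {BASELINE} well")
        base = sub.loc[BASELINE]
        for compound_id, hl in sub.items():
            if compound_id == BASELINE:
                continue
            rows.append((sample_id, compound_id, normalize_half_life(hl, base)))
    return pd.DataFrame(rows, columns=["sample_id", "compound_id", "ratio"])


def call_flags(ratios: Mapping[str, float]) -> list[ScreeningResult]:
    """Call flag molecules by the 3xSD rule over per-compound normalized ratios.

    Center is the mean of all ratios; threshold is three times their sample
    (n-1) standard deviation; a compound is flagged when |ratio - mean|
    exceeds the threshold.  An all-identical input gives SD = 0 and no flags.
    """
    ids = list(ratios)
    if len(ids) < 2:
        raise ValueError("flag calling needs at least 2 compounds (SD undefined)")
    values = np.array([float(ratios[c]) for c in ids])
    if np.ptp(values) == 0.0:  # degenerate: SD is exactly 0, nothing flagged
        center, threshold = float(values[0]), 0.0
    else:
        center = float(values.mean())
        threshold = 3.0 * float(values.std(ddof=1))
    return [
        ScreeningResult(
            compound_id=c,
            normalized_ratio=float(v),
            deviation=float(v - center),
            flagged=bool(abs(v - center) > threshold),
            threshold=threshold,
        )
        for c, v in zip(ids, values)
    ]


def ad_hc_ratio_screen(
    ad_ratios: Mapping[str, float], hc_ratios: Mapping[str, float]
) -> dict[str, float]:
    """Per-compound AD-to-HC score: mean normalized ratio in AD over that in HC."""
    if set(ad_ratios) != set(hc_ratios):
        raise ValueError("AD and HC ratio tables cover different compound sets")
    scores = {}
    for compound in ad_ratios:
        hc = float(hc_ratios[compound])
        if not hc > 0:
            raise ValueError(f"non-positive HC ratio for compound {compound!r}")
        scores[compound] = float(ad_ratios[compound]) / hc
    return scores


def select_top_n(scores: Mapping[str, float], n: int) -> PanelSelection:
    """Rank compounds by |log(score)| descending and keep the top n.

    Deviations above and below 1 count equally; ties break on compound id
    (lexicographic), making the ranking deterministic.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if n > len(scores):
        raise ValueError(f"panel size {n} exceeds compound count {len(scores)}")
    order = sorted(scores, key=lambda c: (-abs(np.log(float(scores[c]))), c))
    ranked = tuple(order[:n])
    return PanelSelection(ranked=ranked, scores=tuple(float(scores[c]) for c in ranked), n=n)


def screen_library(
    fits: pd.DataFrame,
    metadata: pd.DataFrame,
    ad_label: str = "AD",
    hc_label: str = "HC",
) -> pd.DataFrame:
    """Library-wide AD/HC screen from a fit table plus sample metadata.

    Computes per-sample normalized ratios, averages them within each group,
    scores each compound as mean(AD)/mean(HC), and attaches 3xSD flag calls
    on the scores.  Returns one row per compound: ``compound_id, ratio_ad,
    ratio_hc, score, flagged``.
    """
    ratios = normalized_ratio_table(fits)
    groups = metadata["group"]
    ratios = ratios.join(groups, on="sample_id")
    by_group = ratios.groupby(["compound_id", "group"])["ratio"].mean().unstack("group")
    for label in (ad_label, hc_label):
        if label not in by_group.columns:
            raise ValueError(f"no samples with group {label!r} in the fit table")
    scores = ad_hc_ratio_screen(
        by_group[ad_label].to_dict(), by_group[hc_label].to_dict()
    )
    calls = {r.compound_id: r for r in call_flags(scores)}
    out = pd.DataFrame(
        {
            "compound_id": list(scores),
            "ratio_ad": [by_group.at[c, ad_label] for c in scores],
            "ratio_hc": [by_group.at[c, hc_label] for c in scores],
            "score": [scores[c] for c in scores],
            "flagged": [calls[c].flagged for c in scores],
        }
    )
    return out.sort_values("compound_id", ignore_index=True)


def baseline_half_life(fits: pd.DataFrame, sample_id: str) -> float:
    """Mean converged vehicle-well half-life for one sample."""
    sub = fits[
        (fits["sample_id"] == sample_id)
        & (fits["compound_id"] == BASELINE)
        & fits["converged"]
    ]
    if sub.empty:
        raise ValueError(f"sample {sample_id!r} has no converged {BASELINE} well")
    return float(sub["half_life"].mean())
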