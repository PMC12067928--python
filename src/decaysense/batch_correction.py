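"""Additive batch-baseline correction of the half-life feature matrix.

Model: the half-life of sample j (group g) in batch i decomposes as

    x_ij = mu_i + Delta_g + eps_ij,

where mu_i is an additive per-batch baseline (environment/equipment drift),
Delta_g is the group effect under the identifiability convention
Delta_HC + Delta_AD = 0, and eps_ij is zero-mean noise.  Averaging x over
the batch's HC samples and separately over its AD samples and taking half
the sum cancels the group effects exactly (and the noise in expectation),
giving the baseline estimator

    mu_i = ( mean_HC(x) + mean_AD(x) ) / 2,

applied independently to every compound column.  The corrected feature is
z_ij = x_ij - mu_i, which removes batch shifts while preserving all
within-batch differences.

Estimation and application are split so a model fitted on training samples
can be applied to held-out ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import BatchModelError


@dataclass(frozen=True)
class BatchModel:
    """Per-batch, per-compound baselines mu_i.

    ``baselines`` is a DataFrame indexed by batch id with one column per
    compound.  The group-effect convention (sum of anchor-group effects is
    zero) is recorded for provenance.
    """

    baselines: pd.DataFrame
    hc_label: str = "HC"
    ad_label: str = "AD"

    def __post_init__(self) -> None:
        if self.baselines.isna().any().any():
            raise BatchModelError("non-finite batch baseline")


def _check_alignment(X: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    missing = X.index.difference(metadata.index)
    if len(missing):
        raise KeyError(f"samples absent from metadata: {list(missing)}")
    return metadata.loc[X.index]


def estimate_batch_baselines(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    hc_label: str = "HC",
    ad_label: str = "AD",
) -> BatchModel:
    """Estimate mu_i per batch and compound from the anchor groups.

    ``X`` is samples x compounds (half-lives, minutes), indexed by sample id;
    ``metadata`` carries ``group`` and ``batch_id`` per sample.  Every batch
    must contain at least one sample of each anchor group, otherwise the
    estimator is undefined there and a :class:`BatchModelError` names the
    batch.  Samples from other groups (MS, DB, ...) are ignored during
    estimation.
    """
    meta = _check_alignment(X, metadata)
    rows = {}
    for batch_id, batch_meta in meta.groupby("batch_id", sort=True):
        hc = batch_meta.index[batch_meta["group"] == hc_label]
        ad = batch_meta.index[batch_meta["group"] == ad_label]
        if len(hc) == 0 or len(ad) == 0:
            raise BatchModelError(
                f"batch {batch_id!r} lacks {'HC' if len(hc) == 0 else 'AD'} "
                f"anchor samples; baseline undefined"
            )
        rows[batch_id] = 0.5 * (X.loc[hc].mean(axis=0) + X.loc[ad].mean(axis=0))
    baselines = pd.DataFrame(rows).T
    baselines.index.name = "batch_id"
    return BatchModel(baselines=baselines, hc_label=hc_label, ad_label=ad_label)


def correct_batches(X: pd.DataFrame, metadata: pd.DataFrame, model: BatchModel) -> pd.DataFrame:
    """Subtract each sample's batch baseline: z_ij = x_ij - mu_i per compound.

    Annotations live in ``metadata`` and are untouched; the returned frame
    has the same index and columns as ``X``.
    """
    meta = _check_alignment(X, metadata)
    unknown = set(meta["batch_id"]) - set(model.baselines.index)
    if unknown:
        raise KeyError(f"batches not covered by the model: {sorted(unknown)}")
    missing_cols = X.columns.difference(model.baselines.columns)
    if len(missing_cols):
        raise KeyError(f"compounds not covered by the model: {list(missing_cols)}")
    mu = model.baselines.loc[meta["batch_id"], X.columns]
    mu.index = X.index
    return X - mu


def fit_correct(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    hc_label: str = "HC",
    ad_label: str = "AD",
) -> tuple[pd.DataFrame, BatchModel]:
    """Convenience: estimate baselines on ``X`` and return (corrected X, model)."""
    model = estimate_batch_baselines(X, metadata, hc_label=hc_label, ad_label=ad_label)
    return correct_batches(X, metadata, model), model
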