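"""Synthetic assay experiments with known ground truth.

The generator emits complete experiments — plates of decay traces plus
sample metadata — whose statistical structure matches what the analysis
assumes, so every pipeline stage can be exercised and checked against
planted parameters without any external data.

Generative model for the true half-life of sample s (group g, batch i)
against compound c:

    T(s, c) = T_base(g) * effect(c, g) * exp(eps) + mu_i,

with eps ~ Normal(0, sigma_log^2) i.i.d. per well.  Group effects are
multiplicative on half-life (additive in log space, where a "balanced"
configuration realises the sum-to-zero convention of the batch model),
while batch offsets mu_i are additive on the feature, matching the additive
decomposition the correction step assumes.  Vehicle (no-compound) wells use
effect = 1.  Disease samples default to shorter half-lives than controls.

Traces are drawn from the one-phase decay model, ``amplitude *
exp(-ln2 * t / T) + plateau``, with multiplicative Gaussian detector noise
on intensity (default SD 2% of amplitude) on a 5–180 min grid at 5-min
steps; the acquisition step is a generator choice, as instruments report
only the imaging window.  A feature-level shortcut
(:func:`simulate_feature_matrix`) emits the same half-life matrix without
trace synthesis, for fast statistical tests; the two paths share one
random-draw order, so with zero trace noise the fitted features of the
trace path match the shortcut to optimizer precision.

All randomness flows from ``config.seed``: the same configuration and seed
reproduce the experiment byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_io import BASELINE, DecayTrace, WellRecord, write_metadata, write_plate


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic experiment.

    Defaults mirror the study conditions the analysis targets: 31 disease
    (AD) and 37 control (HC) serum samples, a 96-compound library (up to
    1,024 supported), control half-life 13.15 min with disease samples
    shifted shorter, traces on a 5–180 min grid at 5-min steps.
    """

    n_per_group: dict = field(default_factory=lambda: {"AD": 31, "HC": 37})
    n_compounds: int = 96
    n_batches: int = 4
    base_half_life_hc: float = 13.15  # minutes, control baseline
    group_fold_ad: float = 0.9  # multiplicative AD shift on all compounds (< 1: shorter)
    flag_compounds: tuple = ()  # compound ids with an extra AD-specific effect
    flag_fold_ad: float = 2.0  # multiplicative effect of flag compounds in AD samples
    batch_offsets: tuple = (0.5, -0.5, 1.0, -1.0)  # additive minutes, one per batch
    noise_sd_log: float = 0.05  # SD of eps on log half-life
    trace_noise_frac: float = 0.02  # intensity noise SD as a fraction of amplitude
    t_start: float = 5.0
    t_stop: float = 180.0
    t_step: float = 5.0
    amplitude_range: tuple = (800.0, 1200.0)
    plateau_range: tuple = (20.0, 80.0)
    seed: int = 0

    def compound_ids(self) -> list[str]:
        width = len(str(self.n_compounds))
        return [f"C{i + 1:0{width}d}" for i in range(self.n_compounds)]

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)

    def __post_init__(self) -> None:
        if len(self.batch_offsets) != self.n_batches:
            raise ValueError("need one batch offset per batch")
        if self.t_stop <= self.t_start or self.t_step <= 0:
            raise ValueError("invalid time grid")
        unknown = set(self.flag_compounds) - set(self.compound_ids())
        if unknown:
            raise ValueError(f"flag compounds not in the library: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of one simulated experiment."""

    true_half_lives: pd.DataFrame  # long: sample_id, compound_id, half_life
    flag_compounds: tuple
    batch_offsets: dict  # batch_id -> additive minutes
    group_effects: dict  # group -> multiplicative baseline fold

    def to_json(self, path: str | Path) -> None:
        payload = {
            "flag_compounds": list(self.flag_compounds),
            "batch_offsets": self.batch_offsets,
            "group_effects": self.group_effects,
            "true_half_lives": self.true_half_lives.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _metadata(config: SimulationConfig) -> pd.DataFrame:
    # round-robin within each group so every populated batch holds both
    # anchor groups whenever both have >= n_batches members
    rows = []
    i = 0
    for group in sorted(config.n_per_group):
        for j in range(config.n_per_group[group]):
            rows.append((f"S{i + 1:03d}", group, f"B{j % config.n_batches + 1}"))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "group", "batch_id"]).set_index(
        "sample_id"
    )


def _draw_half_lives(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw true half-lives for every (sample, compound) cell plus vehicle wells.

    Returns (metadata, long table with columns sample_id, compound_id,
    half_life); vehicle wells appear under the BASELINE compound id.  The
    draw order is fixed (samples outer, BASELINE then compounds inner) so
    both simulation paths consume the stream identically.
    """
    meta = _metadata(config)
    compounds = config.compound_ids()
    flag_set = set(config.flag_compounds)
    offsets = {f"B{i + 1}": float(config.batch_offsets[i]) for i in range(config.n_batches)}
    rows = []
    for sample_id, (group, batch_id) in meta.iterrows():
        base = config.base_half_life_hc
        if group == "AD":
            base *= config.group_fold_ad
        mu = offsets[batch_id]
        for compound_id in [BASELINE] + compounds:
            effect = 1.0
            if group == "AD" and compound_id in flag_set:
                effect = config.flag_fold_ad
            eps = rng.normal(0.0, config.noise_sd_log) if config.noise_sd_log > 0 else 0.0
            half_life = base * effect * np.exp(eps) + mu
            if half_life <= 0:
                raise ValueError(
                    f"configuration yields non-positive half-life "
                    f"({half_life:.3g} min) for sample {sample_id}, compound {compound_id}"
                )
            rows.append((sample_id, compound_id, float(half_life)))
    table = pd.DataFrame(rows, columns=["sample_id", "compound_id", "half_life"])
    return meta, table


def simulate_feature_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Emit the half-life feature matrix directly, skipping trace synthesis.

    Returns ``(X, metadata, ground_truth)`` with ``X`` samples x compounds
    (vehicle wells excluded from the matrix but present in the ground
    truth).  Distributionally identical to fitting the trace-level
    simulation in the zero-trace-noise limit.
    """
    rng = np.random.default_rng(config.seed)
    meta, table = _draw_half_lives(config, rng)
    X = (
        table[table["compound_id"] != BASELINE]
        .pivot(index="sample_id", columns="compound_id", values="half_life")
        .loc[meta.index]
    )
    X.columns.name = None
    truth = _ground_truth(config, table)
    return X, meta, truth


def _ground_truth(config: SimulationConfig, table: pd.DataFrame) -> GroundTruth:
    return GroundTruth(
        true_half_lives=table,
        flag_compounds=tuple(config.flag_compounds),
        batch_offsets={
            f"B{i + 1}": float(config.batch_offsets[i]) for i in range(config.n_batches)
        },
        group_effects={"HC": 1.0, "AD": float(config.group_fold_ad)},
    )


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[WellRecord], pd.DataFrame, GroundTruth]:
    """Generate a full trace-level experiment.

    For every (sample, compound) cell and every per-sample vehicle well, a
    decay trace is synthesized from the drawn true half-life with random
    amplitude and plateau and multiplicative intensity noise.  When
    ``out_dir`` is given, writes ``plate.csv``, ``metadata.csv`` and
    ``ground_truth.json`` there.
    """
    rng = np.random.default_rng(config.seed)
    meta, table = _draw_half_lives(config, rng)
    times = config.time_grid()
    records = []
    for n, (sample_id, compound_id, half_life) in enumerate(
        table.itertuples(index=False)
    ):
        amplitude = rng.uniform(*config.amplitude_range)
        plateau = rng.uniform(*config.plateau_range)
        clean = amplitude * np.exp(-np.log(2.0) * times / half_life) + plateau
        if config.trace_noise_frac > 0:
            clean = clean + rng.normal(
                0.0, config.trace_noise_frac * amplitude, size=len(times)
            )
        records.append(
            WellRecord(
                well_id=f"W{n + 1:05d}",
                sample_id=sample_id,
                compound_id=compound_id,
                replicate=1,
                trace=DecayTrace(times, clean),
            )
        )
    truth = _ground_truth(config, table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_plate(records, out_dir / "plate.csv")
        write_metadata(meta, out_dir / "metadata.csv")
        truth.to_json(out_dir / "ground_truth.json")
    return records, meta, truth


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a configuration from a plain mapping (e.g. parsed YAML/JSON)."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    payload = dict(payload)
    for key in ("flag_compounds", "batch_offsets"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimulationConfig(**payload)
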