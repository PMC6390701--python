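"""Synthetic reciprocal-screen generator with ground truth.

Emulates the bias structure the analysis is built to remove: an assay-wide
background absorbance, additive per-bait-preparation (row) and
per-prey-preparation (column) biases — drawn independently for the bait and
prey preparations of the same protein, since each preparation is a distinct
biochemical object — measurement noise, and a small set of truly
interacting pairs whose wells carry an added signal in one or both
orientations.  Absorbance cannot go negative, so values are clipped at
zero (a deliberate, documented deviation from pure additivity).

Optionally the generator appends the screen's control wells: prey-only
negative-control wells (bait id ``NEG_CTRL``) and a positive-control well
with a strong fixed interaction between a dedicated bait/prey pair,
standing in for the known BAK1-BIR4 interaction used on real plates.

The generative model is the additive counterpart of the median-polish
decomposition; a right-skewed ``lognormal-additive`` noise family is
available to probe robustness to skewed absorbance noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InteractionRecord

NEG_CONTROL_BAIT = "NEG_CTRL"
POS_CONTROL_PAIR = ("POSCTRL_BAK1", "POSCTRL_BIR4")

#: Added absorbance at the positive-control well, well clear of any noise.
POS_CONTROL_EFFECT = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults are a desk-scale screen: 50 proteins (2,500 wells), an
    assay-wide background of 0.25 A650 (a typical colorimetric plate
    background), preparation biases of 0.05 A650 spread, measurement noise
    of 0.02 A650, and 30 truly interacting pairs at +0.16 A650 — eight
    noise standard deviations, a clear but not caricatured binding signal.
    """

    n_proteins: int = 50
    overall_background: float = 0.25  # A650
    row_effect_sd: float = 0.05  # per-bait-preparation bias spread, A650
    col_effect_sd: float = 0.05  # per-prey-preparation bias spread, A650
    noise_sd: float = 0.02  # measurement noise, A650
    noise_family: str = "normal"  # or "lognormal-additive"
    n_true_pairs: int = 30
    effect_size: float = 0.16  # added A650 at interacting wells (8 x noise_sd)
    asym_fraction: float = 0.0  # fraction of true pairs in one orientation only
    include_controls: bool = True
    seed: int = 0

    def validate(self) -> None:
        n_unordered = self.n_proteins * (self.n_proteins - 1) // 2 + self.n_proteins
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.n_true_pairs < 0 or self.n_true_pairs > n_unordered:
            raise ValueError(
                f"n_true_pairs must be in [0, {n_unordered}] for "
                f"{self.n_proteins} proteins"
            )
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if min(self.row_effect_sd, self.col_effect_sd) < 0:
            raise ValueError("effect sds must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.noise_family not in ("normal", "lognormal-additive"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        if not 0 <= self.asym_fraction <= 1:
            raise ValueError("asym_fraction must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth: planted pairs with orientation flag and effect size.

    ``orientations`` maps each unordered pair (lexicographically ordered) to
    ``"both"``, ``"bait-prey-only"`` (pair[0] as bait carries the effect) or
    ``"prey-bait-only"``.
    """

    orientations: dict[tuple[str, str], str] = field(default_factory=dict)
    effect_size: float = 0.0

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.orientations)


def _protein_ids(n: int) -> list[str]:
    return [f"ECD{i:03d}" for i in range(1, n + 1)]


def _draw_noise(rng: np.random.Generator, family: str, sd: float, size) -> np.ndarray:
    if family == "normal":
        return rng.normal(0.0, sd, size=size)
    # right-skewed additive noise: centred, variance-matched lognormal(0, 1)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=size)
    ln_mean = math.exp(0.5)
    ln_sd = math.sqrt((math.e - 1.0) * math.e)
    return (raw - ln_mean) / ln_sd * sd


def simulate_screen(
    config: SimulationConfig, truth: TruthTable | None = None
) -> tuple[list[InteractionRecord], TruthTable]:
    """Generate one screen's worth of long-format records plus ground truth.

    Every (bait, prey) well of the n x n design receives
    ``background + row_bias + col_bias + noise (+ effect if planted)``,
    clipped at zero.  Identical configs produce identical output.

    Passing an existing ``truth`` replants the same pairs and orientations
    under fresh biases and noise — a retest screen of the same underlying
    interactions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = _protein_ids(n)

    row_bias = rng.normal(0.0, config.row_effect_sd, size=n)
    col_bias = rng.normal(0.0, config.col_effect_sd, size=n)
    noise = _draw_noise(rng, config.noise_family, config.noise_sd, (n, n))

    values = (
        config.overall_background
        + row_bias[:, None]
        + col_bias[None, :]
        + noise
    )

    index = {pid: i for i, pid in enumerate(ids)}
    if truth is not None:
        unknown = {p for pair in truth.pairs for p in pair} - set(ids)
        if unknown:
            raise ValueError(
                f"truth references proteins outside the simulated screen: "
                f"{sorted(unknown)[:5]}"
            )
        orientations = dict(truth.orientations)
        effect = truth.effect_size
        for (a, b), orient in orientations.items():
            i, j = index[a], index[b]
            if orient in ("both", "bait-prey-only"):
                values[i, j] += effect
            if i != j and orient in ("both", "prey-bait-only"):
                values[j, i] += effect
    else:
        effect = config.effect_size
        # plant true interactions on unordered pairs (self-pairs allowed)
        all_pairs = [
            (i, j) for i, j in itertools.combinations_with_replacement(range(n), 2)
        ]
        chosen_idx = rng.choice(
            len(all_pairs), size=config.n_true_pairs, replace=False
        )
        orientations = {}
        for k in sorted(chosen_idx):
            i, j = all_pairs[k]
            pair = (ids[i], ids[j])
            if i == j:
                # a self-pair is a single well covering both directions
                orientations[pair] = "both"
                values[i, i] += effect
                continue
            if rng.random() < config.asym_fraction:
                if rng.random() < 0.5:
                    orientations[pair] = "bait-prey-only"
                    values[i, j] += effect
                else:
                    orientations[pair] = "prey-bait-only"
                    values[j, i] += effect
            else:
                orientations[pair] = "both"
                values[i, j] += effect
                values[j, i] += effect

    values = np.clip(values, 0.0, None)

    records = [
        InteractionRecord(ids[i], ids[j], float(values[i, j]))
        for i in range(n)
        for j in range(n)
    ]

    if config.include_controls:
        # prey-only wells: no bait adsorbed, so no row bias
        ctrl_noise = _draw_noise(rng, config.noise_family, config.noise_sd, n)
        for j in range(n):
            v = max(0.0, config.overall_background + col_bias[j] + ctrl_noise[j])
            records.append(InteractionRecord(NEG_CONTROL_BAIT, ids[j], v))
        pos_noise = float(_draw_noise(rng, config.noise_family, config.noise_sd, 1)[0])
        pos_value = max(
            0.0, config.overall_background + POS_CONTROL_EFFECT + pos_noise
        )
        records.append(InteractionRecord(*POS_CONTROL_PAIR, pos_value))

    return records, TruthTable(orientations=orientations, effect_size=effect)


def write_truth(truth: TruthTable, path) -> None:
    """Write a truth table as TSV (id_a, id_b, orientation, effect_size)."""
    pd.DataFrame(
        [
            {"id_a": a, "id_b": b, "orientation": o, "effect_size": truth.effect_size}
            for (a, b), o in sorted(truth.orientations.items())
        ],
        columns=["id_a", "id_b", "orientation", "effect_size"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    """Read a truth table written by :func:`write_truth`."""
    df = pd.read_csv(path, sep="\t")
    orientations = {
        tuple(sorted((a, b))): o
        for a, b, o in zip(df["id_a"], df["id_b"], df["orientation"])
    }
    effect = float(df["effect_size"].iloc[0]) if len(df) else 0.0
    return TruthTable(orientations=orientations, effect_size=effect)


def split_control_records(
    records: list[InteractionRecord],
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Separate screen wells from control wells (negative and positive)."""
    control_ids = {NEG_CONTROL_BAIT, *POS_CONTROL_PAIR}
    screen = [r for r in records if r.bait_id not in control_ids]
    controls = [r for r in records if r.bait_id in control_ids]
    return screen, controls


def evaluate_recovery(hits: pd.DataFrame, truth: TruthTable) -> dict:
    """Compare called hits to the planted ground truth.

    Returns sensitivity for symmetric plants (called bidirectional),
    sensitivity for one-orientation plants (called unidirectional), the
    false-positive rate among non-planted pairs — the fraction called
    *bidirectional*, the screen's high-confidence class — and the full
    plant-orientation x called-class confusion counts.
    """
    hit_ids = set(hits["id_a"]) | set(hits["id_b"])
    truth_ids = {p for pair in truth.pairs for p in pair}
    if not truth_ids <= hit_ids:
        raise ValueError(
            f"truth references proteins absent from the hit table: "
            f"{sorted(truth_ids - hit_ids)[:5]}"
        )
    called = {
        tuple(sorted(t)): cls
        for t, cls in zip(zip(hits["id_a"], hits["id_b"]), hits["hit_class"])
    }
    confusion: dict[tuple[str, str], int] = {}
    for pair, orient in truth.orientations.items():
        plant = "both" if orient == "both" else "one-orientation"
        cls = called.get(pair, "none")
        confusion[(plant, cls)] = confusion.get((plant, cls), 0) + 1
    n_both = sum(1 for o in truth.orientations.values() if o == "both")
    n_one = len(truth.orientations) - n_both
    sens_bid = confusion.get(("both", "bidirectional"), 0) / n_both if n_both else math.nan
    sens_uni = (
        confusion.get(("one-orientation", "unidirectional"), 0) / n_one
        if n_one
        else math.nan
    )
    non_planted = hits[
        [tuple(sorted(t)) not in truth.pairs for t in zip(hits["id_a"], hits["id_b"])]
    ]
    n_null = len(non_planted)
    fp_bid = int((non_planted["hit_class"] == "bidirectional").sum())
    fp_uni = int((non_planted["hit_class"] == "unidirectional").sum())
    confusion[("non-planted", "bidirectional")] = fp_bid
    confusion[("non-planted", "unidirectional")] = fp_uni
    return {
        "sensitivity_bidirectional": sens_bid,
        "sensitivity_unidirectional": sens_uni,
        "false_positive_rate": fp_bid / n_null if n_null else math.nan,
        "unidirectional_false_call_rate": fp_uni / n_null if n_null else math.nan,
        "n_planted_both": n_both,
        "n_planted_one_orientation": n_one,
        "n_non_planted": n_null,
        "confusion": confusion,
    }
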