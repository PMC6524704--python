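"""Synthetic peptidome time courses with known ground truth.

The generator emulates the statistical structure of a yeast-extract
peptidome monitored by spectral counting over a fermentation: a pool of
peptides (default 4,600) with lengths between 6 and 30 peaked near 10,
heavy-tailed per-peptide base rates so that roughly 80% of peptides
identified in a sample carry a single spectrum and well under 1% carry
more than ten, observed in 3 replicates at timepoints {0, 3, 4, 5, 6} h.

Class-level kinetic profiles are planted on the physicochemical barcode
structure the downstream analysis uses, mirroring the biology the
pipeline is meant to detect: classes of short, positively charged
peptides (net-charge digit 3, length digit 1) are eligible "decreasing"
— the transporter-substrate signature — while classes of negatively
charged, proline-rich peptides (charge digit 1, proline digit 3) are
eligible "increasing", the signature of accumulating protease products.
Profiles are planted on the largest eligible classes (profiled classes
in such a study are the peptide-rich ones) and planted classes are
rescaled to a realistic peak abundance (tens of spectra per sample at
the trajectory maximum, like the exemplar trajectories such studies
print), because a kinetic trend is only observable on classes abundant
enough to quantify. All remaining classes are constant.

Counts are Poisson around base_rate x profile_multiplier(t), independent
across replicates and timepoints, so the differential module's model is
correctly specified and recovery is a well-posed check. A negative-
binomial switch introduces overdispersion for robustness probing.

Sequence composition is sampled i.i.d. per position (uniform by default,
optionally yeast-proteome-like frequencies); real peptides are proteome
substrings, but every descriptor is composition-based, so positional
structure is irrelevant downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .barcoding import DEFAULT_SCHEME, IntervalScheme, assign_barcode
from .properties import AMINO_ACIDS, DEFAULT_CONFIG, PropertyConfig, \
    compute_property_vector

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_peptides",
    "plant_profiles",
    "simulate_counts",
    "generate_dataset",
    "YEAST_RESIDUE_FREQS",
]

#: Approximate S. cerevisiae proteome amino-acid frequencies.
YEAST_RESIDUE_FREQS: Mapping[str, float] = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.064, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.065, "K": 0.073, "L": 0.096,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.090, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic peptidome.

    Defaults reproduce the target dataset's shape: peptide pool size,
    length law peaked near 10 within [6, 30], an abundance law whose
    identified peptides are ~80% singletons with <1% above ten spectra,
    3 replicates x 5 timepoints, and ~4-fold planted effects.
    """

    n_peptides: int = 4600
    #: gamma(shape, scale) offset by min_length, discretized; mode at
    #: min_length + (shape - 1) * scale = 10.
    length_shape: float = 5.0
    length_scale: float = 1.0
    min_length: int = 6
    max_length: int = 30
    #: residue sampling frequencies; None means uniform over the 20.
    residue_freqs: Mapping[str, float] | None = None
    #: heavy-tailed base-rate law: lognormal bulk plus an abundant
    #: lognormal component (fraction `abundant_fraction`).
    rate_median: float = 0.14
    rate_sigma: float = 0.8
    abundant_fraction: float = 0.015
    abundant_median: float = 2.5
    abundant_sigma: float = 0.8
    replicates: int = 3
    timepoints: tuple[float, ...] = (0.0, 3.0, 4.0, 5.0, 6.0)
    #: ~4-fold drop (or rise) by the final timepoint.
    fold_change: float = 4.0
    #: number of classes planted per profile, taken from the largest
    #: eligible classes.
    n_decreasing: int = 12
    n_increasing: int = 12
    n_fluctuating: int = 12
    #: peak class rate (spectra per sample at the trajectory maximum) of
    #: planted classes: lognormal(log median, sigma), median per profile.
    #: Increasing classes peak highest — accumulating hydrolysis products
    #: are the most spectra-rich profile per class in this kind of data.
    planted_rate_median: Mapping[str, float] = field(
        default_factory=lambda: {
            "decreasing": 25.0,
            "increasing": 30.0,
            "fluctuating": 22.0,
        }
    )
    planted_rate_sigma: float = 0.2
    pulse_peak: float = 3.0
    pulse_time: float = 4.0
    pulse_width: float = 1.0
    #: negative-binomial dispersion (variance = mu + mu^2/size); None
    #: keeps plain Poisson counts.
    nb_size: float | None = None
    property_config: PropertyConfig = DEFAULT_CONFIG
    scheme: IntervalScheme = DEFAULT_SCHEME


DEFAULT_SIM_CONFIG = SimulationConfig()


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: per-class profile labels, per-peptide rates.

    ``classes`` is indexed by class code with column ``label``;
    ``peptides`` is indexed by sequence with columns ``class`` and
    ``base_rate``. Every emitted observation's sequence appears here.
    """

    classes: pd.DataFrame
    peptides: pd.DataFrame

    def multiplier(self, label: str, t: float, config: SimulationConfig) -> float:
        return _profile_multiplier(label, t, config)


def _profile_multiplier(label: str, t: float, config: SimulationConfig) -> float:
    k = np.log(config.fold_change) / max(config.timepoints)
    if label == "decreasing":
        return float(np.exp(-k * t))
    if label == "increasing":
        return float(np.exp(k * t))
    if label == "fluctuating":
        gauss = np.exp(-((t - config.pulse_time) ** 2)
                       / (2.0 * config.pulse_width ** 2))
        return float(1.0 + (config.pulse_peak - 1.0) * gauss)
    if label == "constant":
        return 1.0
    raise ValueError(f"unknown profile label {label!r}")


def generate_peptides(
    config: SimulationConfig = DEFAULT_SIM_CONFIG,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample distinct peptide sequences with base rates.

    Returns a DataFrame indexed by sequence with column ``base_rate``.
    Lengths follow the discretized offset gamma law truncated to
    [min_length, max_length]; base rates the two-component lognormal.
    """
    rng = np.random.default_rng() if rng is None else rng
    if config.min_length < 1 or config.max_length < config.min_length:
        raise ValueError("infeasible length bounds")
    if config.length_shape <= 0 or config.length_scale <= 0:
        raise ValueError("length law needs positive shape and scale")
    alphabet = np.array(list(AMINO_ACIDS))
    if config.residue_freqs is None:
        probs = None
    else:
        probs = np.array([config.residue_freqs[a] for a in alphabet])
        probs = probs / probs.sum()

    sequences: list[str] = []
    seen: set[str] = set()
    while len(sequences) < config.n_peptides:
        need = config.n_peptides - len(sequences)
        lengths = config.min_length + np.floor(
            rng.gamma(config.length_shape, config.length_scale, size=need)
        ).astype(int)
        lengths = np.clip(lengths, config.min_length, config.max_length)
        for n in lengths:
            seq = "".join(rng.choice(alphabet, size=n, p=probs))
            if seq not in seen:  # pool holds distinct peptides
                seen.add(seq)
                sequences.append(seq)

    n = len(sequences)
    rates = rng.lognormal(np.log(config.rate_median), config.rate_sigma, n)
    hot = rng.random(n) < config.abundant_fraction
    rates[hot] = rng.lognormal(
        np.log(config.abundant_median), config.abundant_sigma, int(hot.sum())
    )
    out = pd.DataFrame({"base_rate": rates}, index=pd.Index(sequences, name="sequence"))
    return out


def plant_profiles(
    peptides: pd.DataFrame,
    config: SimulationConfig = DEFAULT_SIM_CONFIG,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Assign each barcode class a kinetic profile.

    Eligibility follows the barcode: net-charge digit 3 with length
    digit 1 -> decreasing; net-charge digit 1 with proline digit 3 ->
    increasing. The ``n_decreasing`` / ``n_increasing`` largest eligible
    classes (by member count, ties broken by class code) receive the
    trend; ``n_fluctuating`` of the largest remaining classes pulse;
    everything else is constant. Member base rates of each planted class
    are rescaled so the class's peak-trajectory rate equals a draw from
    the planted-rate law — a trend is only observable on a class
    abundant enough to quantify. The truth table covers every peptide.
    """
    rng = np.random.default_rng() if rng is None else rng
    barcodes = {
        seq: assign_barcode(
            compute_property_vector(seq, config.property_config), config.scheme
        )
        for seq in peptides.index
    }
    classes = sorted(set(barcodes.values()))
    members: dict[str, list[str]] = {c: [] for c in classes}
    for seq, cls in barcodes.items():
        members[cls].append(seq)

    def largest(pool: list[str], n: int) -> list[str]:
        ranked = sorted(pool, key=lambda c: (-len(members[c]), c))
        return ranked[:n]

    eligible_dec = [c for c in classes if c[4] == "3" and c[0] == "1"]
    eligible_inc = [c for c in classes if c[4] == "1" and c[8] == "3"]
    planted_dec = largest(eligible_dec, config.n_decreasing)
    planted_inc = largest(
        [c for c in eligible_inc if c not in set(planted_dec)],
        config.n_increasing,
    )
    taken = set(planted_dec) | set(planted_inc)
    planted_fluc = largest(
        [c for c in classes if c not in taken], config.n_fluctuating
    )

    labels: dict[str, str] = {c: "constant" for c in classes}
    labels.update({c: "decreasing" for c in planted_dec})
    labels.update({c: "increasing" for c in planted_inc})
    labels.update({c: "fluctuating" for c in planted_fluc})

    # Rescale planted classes to a realistic peak abundance. The profile
    # multiplier peaks at 1 (decreasing, at t=0), fold_change (increasing,
    # at the last timepoint) or pulse_peak (fluctuating), so the base
    # (t=0) class rate is target / peak_multiplier.
    rates = peptides["base_rate"].copy()
    peak_mult = {
        "decreasing": 1.0,
        "increasing": config.fold_change,
        "fluctuating": config.pulse_peak,
    }
    for cls in (*planted_dec, *planted_inc, *planted_fluc):
        target = rng.lognormal(
            np.log(config.planted_rate_median[labels[cls]]),
            config.planted_rate_sigma,
        )
        base_target = target / peak_mult[labels[cls]]
        current = rates[members[cls]].sum()
        rates[members[cls]] *= base_target / current

    class_frame = pd.DataFrame(
        {"label": [labels[c] for c in classes]},
        index=pd.Index(classes, name="class"),
    )
    peptide_frame = pd.DataFrame(
        {
            "class": [barcodes[s] for s in peptides.index],
            "base_rate": rates,
        },
        index=peptides.index,
    )
    return GroundTruth(classes=class_frame, peptides=peptide_frame)


def simulate_counts(
    truth: GroundTruth,
    config: SimulationConfig = DEFAULT_SIM_CONFIG,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the observation table from the planted model.

    Count(peptide i, replicate r, timepoint t) ~ Poisson(base_rate_i *
    multiplier(profile_i, t)), independent across r and t (negative
    binomial with the same mean when ``nb_size`` is set). Only non-zero
    counts are emitted: a peptide with zero spectra is simply not
    identified in that sample.
    """
    rng = np.random.default_rng() if rng is None else rng
    label_of = truth.classes["label"]
    rates = truth.peptides["base_rate"].to_numpy()
    classes = truth.peptides["class"].to_numpy()
    sequences = truth.peptides.index.to_numpy()
    mult = np.array(
        [
            [
                _profile_multiplier(label_of[cls], t, config)
                for t in config.timepoints
            ]
            for cls in classes
        ]
    )
    frames = []
    for r in range(1, config.replicates + 1):
        for j, t in enumerate(config.timepoints):
            mu = rates * mult[:, j]
            if config.nb_size is None:
                counts = rng.poisson(mu)
            else:
                size = config.nb_size
                counts = rng.negative_binomial(
                    size, size / (size + mu)
                )
            nz = counts > 0
            frames.append(
                pd.DataFrame(
                    {
                        "sequence": sequences[nz],
                        "replicate": r,
                        "timepoint_h": t,
                        "spectra": counts[nz],
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out[["sequence", "replicate", "timepoint_h", "spectra"]]


def generate_dataset(
    config: SimulationConfig = DEFAULT_SIM_CONFIG,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """End-to-end generation: peptides -> planted truth -> observations.

    A fixed *seed* fixes the full output (sequences, truth and counts)
    exactly.
    """
    rng = np.random.default_rng(seed)
    peptides = generate_peptides(config, rng)
    truth = plant_profiles(peptides, config, rng)
    psm = simulate_counts(truth, config, rng)
    return psm, truth
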