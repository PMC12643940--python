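"""Synthetic flow-cytometry data with known ground truth.

Every simulator here emulates one assay of the study design — stained/isotype
event distributions, the 362-marker arrayed screen (3 AML vs 3 NBM donors),
the 50-case expression cohort, and bead-spiked coculture killing assays — and
emits a machine-readable truth table so each downstream stage can be tested
against planted parameters without any external data.

Intensities are log-normal: a component with linear-scale location ``m``
(its median) and log-scale s.d. ``s`` draws ``m * exp(s * Z)``. Log-normal
mixtures are the standard first-order model for compensated cytometry
channels; instrument artifacts (doublets, time drift, spillover) are not
emulated.

Determinism: every sample draws from its own ``numpy`` ``SeedSequence``
sub-stream keyed by (arm, donor, marker, role), so regenerating with the same
seed is byte-identical and adding samples never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .events import EventTable

__all__ = [
    "PopulationSpec",
    "ScreenSimConfig",
    "CohortSimConfig",
    "CocultureSimConfig",
    "simulate_events",
    "simulate_screen",
    "simulate_screen_events",
    "simulate_cohort",
    "simulate_coculture",
]

# Default log-normal parameters: isotype background centred at 100 a.u. with
# log-s.d. 0.6 overlaps realistically with a 1.5x-shifted stained signal.
BACKGROUND_LOCATION = 100.0
BACKGROUND_SIGMA = 0.6
BASELINE_SIGNAL_FOLD = 1.5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class PopulationSpec:
    """A log-normal mixture over one or more channels.

    ``components`` is a list of ``(weight, locations, scales)`` where
    ``locations`` and ``scales`` map channel -> linear-scale median and
    log-scale s.d. Weights must sum to 1.
    """

    components: Sequence[tuple[float, Mapping[str, float], Mapping[str, float]]]
    n_events: int
    seed: int

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("PopulationSpec needs >= 1 component")
        weights = [w for w, _, _ in self.components]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError(f"component weights must be >= 0 and sum to 1, got {weights}")
        for _, locs, scales in self.components:
            if set(locs) != set(scales):
                raise ConfigurationError("locations and scales must cover the same channels")
            if any(s < 0 for s in scales.values()) or any(m <= 0 for m in locs.values()):
                raise ConfigurationError("locations must be > 0 and scales >= 0")
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")


def simulate_events(spec: PopulationSpec, sample_id: str = "sim") -> EventTable:
    """Draw an event table from a log-normal mixture.

    The component index of every event is recorded in
    ``metadata["component"]`` so tests can compare against the planted
    mixture.
    """
    return _simulate_mixture(spec, _rng(spec.seed), sample_id=sample_id)


# ---------------------------------------------------------------------------
# Arrayed antibody screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study-design parameters of the arrayed surface-marker screen.

    Defaults follow the screen design: 362 markers assayed on 3 AML and
    3 NBM donors. ``planted_effects`` maps marker name -> multiplicative
    shift of the stained signal in AML donors (1.0 = null). ``donor_sigma``
    is donor-level log-scale variability of each marker's signal.
    """

    markers: Sequence[str] = field(default_factory=lambda: [f"M{i:03d}" for i in range(1, 363)])
    donors_per_arm: int = 3
    events_per_sample: int = 5000
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    background_location: float = BACKGROUND_LOCATION
    background_sigma: float = BACKGROUND_SIGMA
    signal_fold: float = BASELINE_SIGNAL_FOLD
    signal_sigma: float = BACKGROUND_SIGMA
    donor_sigma: float = 0.1
    positivity_quantile: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError("duplicate marker names")
        if self.donors_per_arm < 1:
            raise ConfigurationError("need >= 1 donor per arm")
        unknown = set(self.planted_effects) - set(self.markers)
        if unknown:
            raise ConfigurationError(f"planted effects for unknown markers: {sorted(unknown)}")
        if any(e <= 0 for e in self.planted_effects.values()):
            raise ConfigurationError("planted effects must be > 0")


_ARMS = ("AML", "NBM")
_ROLE_ISOTYPE, _ROLE_STAINED, _ROLE_DONOR = 0, 1, 2


def _signal_location(config: ScreenSimConfig, arm: str, marker: str) -> float:
    loc = config.background_location * config.signal_fold
    if arm == "AML":
        loc *= float(config.planted_effects.get(marker, 1.0))
    return loc


def _donor_factor(config: ScreenSimConfig, arm_i: int, donor: int, marker_i: int) -> float:
    rng = _rng(config.seed, arm_i, donor, marker_i, _ROLE_DONOR)
    return float(np.exp(config.donor_sigma * rng.standard_normal()))


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full screen and return (stats, truth).

    ``stats`` is a tidy per-sample table (marker, arm, donor, mfi,
    pct_positive, n_events) with MFI the arithmetic mean of stained events
    and %positive the fraction strictly above the per-donor isotype
    ``positivity_quantile`` threshold — the same quantities ``flow_core``
    computes from materialized event tables. ``truth`` lists each marker's
    planted AML fold.
    """
    n_ev = config.events_per_sample
    rows = []
    for arm_i, arm in enumerate(_ARMS):
        for donor in range(config.donors_per_arm):
            iso = config.background_location * np.exp(
                config.background_sigma * _rng(config.seed, arm_i, donor, 0, _ROLE_ISOTYPE).standard_normal(n_ev)
            )
            threshold = float(np.quantile(iso, config.positivity_quantile))
            for marker_i, marker in enumerate(config.markers):
                loc = _signal_location(config, arm, marker) * _donor_factor(config, arm_i, donor, marker_i + 1)
                x = loc * np.exp(
                    config.signal_sigma * _rng(config.seed, arm_i, donor, marker_i + 1, _ROLE_STAINED).standard_normal(n_ev)
                )
                rows.append(
                    {
                        "marker": marker,
                        "arm": arm,
                        "donor": f"{arm}{donor + 1}",
                        "mfi": float(x.mean()),
                        "pct_positive": 100.0 * float(np.mean(x > threshold)),
                        "n_events": n_ev,
                    }
                )
    stats = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "marker": list(config.markers),
            "planted_fold": [float(config.planted_effects.get(m, 1.0)) for m in config.markers],
        }
    )
    return stats, truth


def simulate_screen_events(
    config: ScreenSimConfig,
) -> tuple[dict[tuple[str, str, str], EventTable], dict[tuple[str, str], EventTable]]:
    """Materialize the screen's raw event tables (small configs only).

    Returns ``(stained, isotypes)`` where ``stained`` maps
    (arm, donor, marker) -> stained EventTable and ``isotypes`` maps
    (arm, donor) -> the donor's shared isotype-control table. Draws use the
    same sub-streams as :func:`simulate_screen`, so statistics computed from
    these tables reproduce its output exactly.
    """
    stained: dict[tuple[str, str, str], EventTable] = {}
    isotypes: dict[tuple[str, str], EventTable] = {}
    n_ev = config.events_per_sample
    for arm_i, arm in enumerate(_ARMS):
        for donor in range(config.donors_per_arm):
            donor_id = f"{arm}{donor + 1}"
            iso = config.background_location * np.exp(
                config.background_sigma * _rng(config.seed, arm_i, donor, 0, _ROLE_ISOTYPE).standard_normal(n_ev)
            )
            isotypes[(arm, donor_id)] = EventTable.from_arrays(
                iso[:, None], ["PE"], sample_id=f"{donor_id}-isotype"
            )
            for marker_i, marker in enumerate(config.markers):
                loc = _signal_location(config, arm, marker) * _donor_factor(config, arm_i, donor, marker_i + 1)
                x = loc * np.exp(
                    config.signal_sigma * _rng(config.seed, arm_i, donor, marker_i + 1, _ROLE_STAINED).standard_normal(n_ev)
                )
                stained[(arm, donor_id, marker)] = EventTable.from_arrays(
                    x[:, None], ["PE"], sample_id=f"{donor_id}-{marker}"
                )
    return stained, isotypes


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """A cohort of stained/isotype sample pairs with planted shift fractions.

    ``class_mix`` gives the (high, intermediate, negative) proportions;
    class counts are allocated deterministically by largest remainder.
    Planted shift fractions are drawn uniformly inside each class band,
    keeping at least ``boundary_margin`` from the 10%/50% call boundaries.
    """

    n_samples: int = 50
    class_mix: tuple[float, float, float] = (0.24, 0.34, 0.42)  # high, intermediate, negative
    events_per_sample: int = 10_000
    boundary_margin: float = 0.03
    background_location: float = BACKGROUND_LOCATION
    background_sigma: float = BACKGROUND_SIGMA
    positive_fold: float = 20.0  # location of the shifted component vs background
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise ConfigurationError(f"class mix must be >= 0 and sum to 1: {self.class_mix}")
        if not 0.0 < self.boundary_margin < 0.05:
            raise ConfigurationError("boundary_margin must be in (0, 0.05)")


def _largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    exact = [n * p for p in proportions]
    counts = [int(np.floor(e)) for e in exact]
    remainders = sorted(
        range(len(proportions)), key=lambda i: (exact[i] - counts[i], -i), reverse=True
    )
    for i in range(n - sum(counts)):
        counts[remainders[i]] += 1
    return counts


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[dict[str, tuple[EventTable, EventTable]], pd.DataFrame]:
    """Simulate a cohort; returns (samples, truth).

    ``samples`` maps sample_id -> (stained, isotype) event tables; ``truth``
    has columns sample_id, true_fraction, true_call. The stained table is a
    two-component mixture: ``true_fraction`` of events from a far-shifted
    positive component, the rest from the isotype background.
    """
    n_high, n_int, n_neg = _largest_remainder(config.n_samples, config.class_mix)
    m = config.boundary_margin
    bands = (
        [("high", 0.50 + m, min(1.0, 0.97))] * n_high
        + [("intermediate", 0.10 + m, 0.50 - m)] * n_int
        + [("negative", 0.0, 0.10 - m)] * n_neg
    )
    bg_loc, bg_sig = config.background_location, config.background_sigma
    pos_loc = bg_loc * config.positive_fold

    samples: dict[str, tuple[EventTable, EventTable]] = {}
    truth_rows = []
    for i, (call, lo, hi) in enumerate(bands):
        sid = f"S{i + 1:03d}"
        frac = float(_rng(config.seed, i, 0).uniform(lo, hi))
        spec = PopulationSpec(
            components=[
                (frac, {"PE": pos_loc}, {"PE": bg_sig}),
                (1.0 - frac, {"PE": bg_loc}, {"PE": bg_sig}),
            ],
            n_events=config.events_per_sample,
            seed=config.seed,
        )
        # dedicated sub-streams per sample for the stained and isotype draws
        stained = _simulate_mixture(spec, _rng(config.seed, i, 1), sample_id=sid)
        iso = bg_loc * np.exp(bg_sig * _rng(config.seed, i, 2).standard_normal(config.events_per_sample))
        isotype = EventTable.from_arrays(iso[:, None], ["PE"], sample_id=f"{sid}-isotype")
        samples[sid] = (stained, isotype)
        truth_rows.append({"sample_id": sid, "true_fraction": frac, "true_call": call})
    return samples, pd.DataFrame(truth_rows)


def _simulate_mixture(spec: PopulationSpec, rng: np.random.Generator, sample_id: str) -> EventTable:
    channels = sorted(spec.components[0][1])
    weights = np.array([w for w, _, _ in spec.components])
    comp = rng.choice(len(spec.components), size=spec.n_events, p=weights)
    data = np.empty((spec.n_events, len(channels)))
    for ci, (_, locs, scales) in enumerate(spec.components):
        mask = comp == ci
        n = int(mask.sum())
        for j, ch in enumerate(channels):
            data[mask, j] = locs[ch] * np.exp(scales[ch] * rng.standard_normal(n))
    return EventTable.from_arrays(data, channels, sample_id=sample_id, metadata={"component": comp.copy()})


# ---------------------------------------------------------------------------
# Coculture killing assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CocultureSimConfig:
    """Planted parameters of a bead-quantified killing/activation assay.

    ``killing_fraction`` k thins the treated wells' true AML cell number
    binomially to (1-k) of the control. Each well acquires a random
    ``acquisition_fraction`` of its cells and of the spiked beads.
    Activation truth: fractions of T cells double-positive / single-positive
    for CD25 and CD69.
    """

    killing_fraction: float = 0.0
    n_cells: int = 50_000  # true AML cells per control well
    beads_added: int = 50_000
    replicates: int = 4
    acquisition_fraction: float = 0.2
    n_tcells: int = 5000
    frac_double_positive: float = 0.2
    frac_cd25_only: float = 0.1
    frac_cd69_only: float = 0.1
    background_location: float = BACKGROUND_LOCATION
    background_sigma: float = BACKGROUND_SIGMA
    positive_fold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("killing_fraction", "acquisition_fraction", "frac_double_positive", "frac_cd25_only", "frac_cd69_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.frac_double_positive + self.frac_cd25_only + self.frac_cd69_only > 1.0:
            raise ConfigurationError("activation fractions exceed 1")
        if self.replicates < 1 or self.n_cells < 1 or self.beads_added < 1:
            raise ConfigurationError("replicates, n_cells and beads_added must be >= 1")


def simulate_coculture(config: CocultureSimConfig) -> dict:
    """Simulate control and treated coculture wells.

    Returns a dict with:

    ``samples``
        list of :class:`~flowscreen.coculture.CocultureSample` (control
        condition "control", treated condition "treated").
    ``tcell_tables``
        sample_id -> CD25/CD69 :class:`EventTable` of gated T cells.
    ``activation_thresholds``
        (cd25, cd69) thresholds separating the planted positive component.
    ``truth``
        planted killing fraction, true cell numbers per well, activation
        fractions.
    """
    from .coculture import CocultureSample

    bg, sig, pos = config.background_location, config.background_sigma, config.background_location * config.positive_fold
    # Positive and background log-normals are well separated at the geometric
    # midpoint of the two locations.
    thr = float(np.sqrt(bg * pos))

    samples: list[CocultureSample] = []
    tcell_tables: dict[str, EventTable] = {}
    true_cells: dict[str, int] = {}
    for cond_i, (condition, is_control) in enumerate([("control", True), ("treated", False)]):
        for rep in range(1, config.replicates + 1):
            rng = _rng(config.seed, cond_i, rep)
            n_true = config.n_cells if is_control else int(rng.binomial(config.n_cells, 1.0 - config.killing_fraction))
            cell_events = int(rng.binomial(n_true, config.acquisition_fraction)) if n_true else 0
            bead_events = int(rng.binomial(config.beads_added, config.acquisition_fraction))
            sid = f"{condition}-r{rep}"
            samples.append(
                CocultureSample(
                    sample_id=sid,
                    condition=condition,
                    dose=0.0,
                    aml_events=cell_events,
                    bead_events=bead_events,
                    beads_added=config.beads_added,
                    replicate=rep,
                    is_control=is_control,
                )
            )
            true_cells[sid] = n_true
            tcell_tables[sid] = _simulate_tcells(config, rng, sid)
    return {
        "samples": samples,
        "tcell_tables": tcell_tables,
        "activation_thresholds": (thr, thr),
        "truth": {
            "killing_fraction": config.killing_fraction,
            "true_cells": true_cells,
            "frac_double_positive": config.frac_double_positive,
            "frac_cd25_only": config.frac_cd25_only,
            "frac_cd69_only": config.frac_cd69_only,
        },
    }


def _simulate_tcells(config: CocultureSimConfig, rng: np.random.Generator, sample_id: str) -> EventTable:
    bg, sig, pos = config.background_location, config.background_sigma, config.background_location * config.positive_fold
    n = config.n_tcells
    u = rng.random(n)
    p_dp, p_25, p_69 = config.frac_double_positive, config.frac_cd25_only, config.frac_cd69_only
    cd25_pos = u < p_dp + p_25
    cd69_pos = (u < p_dp) | ((u >= p_dp + p_25) & (u < p_dp + p_25 + p_69))
    cd25 = np.where(cd25_pos, pos, bg) * np.exp(sig * rng.standard_normal(n))
    cd69 = np.where(cd69_pos, pos, bg) * np.exp(sig * rng.standard_normal(n))
    return EventTable.from_arrays(
        np.column_stack([cd25, cd69]), ["CD25", "CD69"], sample_id=sample_id
    )
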