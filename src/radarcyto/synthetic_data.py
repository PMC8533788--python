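"""Synthetic bone-marrow event data with the statistical structure the
radar analysis assumes.

Real pediatric BCP-ALL flow data are confidential and not deposited, so
every downstream stage of this package is exercised on simulated bone
marrow instead. The generator emulates:

* normal B-cell maturation (hematogone stages I/II and mature B cells),
  erythroid precursors and the remaining nucleated background;
* leukemic blast populations whose marker expression follows published
  per-position category profiles (fractions of cases negative / weak /
  positive / bright for each marker at each radar "predilection"
  position), with two antibody tubes;
* cytogenetics-linked position frequencies (hyperdiploid cases favour
  tube-1 position 1 and tube-2 position 3; t(12;21) cases tube-1
  position 2 and tube-2 position 1; "B-other" cases tube-2 position 4)
  and the B-other group's multi-subclone structure;
* MRD-style marrow composition at Day 15 (no hematogones, only mature
  B cells survive the early-induction marrow) and Day 33 (regenerating
  marrow with hematogones back);
* paired-examiner gating noise, modelled as jitter on gate thresholds.

Fluorescence intensities are drawn per marker from Gaussians on an
arcsinh-like transformed scale; the expression-category means are
negative=0.0, weak=1.0, positive=2.5, bright=4.0 (sd 0.35), which gives
cleanly separable but overlapping peaks. Scatter channels (FSC-A/FSC-H/
SSC-A) are Gaussian per population on an instrument-like linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs_io import ChannelMeta, EventMatrix

__all__ = [
    "CATEGORIES",
    "CATEGORY_MEANS",
    "CATEGORY_SD",
    "POSITIVITY_THRESHOLD",
    "CaseRecord",
    "PopulationSpec",
    "SubtypeProfile",
    "SyntheticSpec",
    "SUBTYPES",
    "REFERENCE_COHORT_COUNTS",
    "REFERENCE_MRD_DAY15_COUNTS",
    "REFERENCE_MRD_DAY33_COUNTS",
    "blast_category_probs",
    "default_population_fractions",
    "generate_bm_sample",
    "generate_cohort",
    "generate_examiner_pair",
    "population_of",
    "sample_blast_phenotype",
    "tube_markers",
]

# ---------------------------------------------------------------------
# intensity scale
# ---------------------------------------------------------------------

CATEGORIES = ("negative", "weak", "positive", "bright")
CATEGORY_MEANS = {"negative": 0.0, "weak": 1.0, "positive": 2.5, "bright": 4.0}
CATEGORY_SD = 0.35
#: default positivity cut: midpoint of the negative and positive means
POSITIVITY_THRESHOLD = 0.5 * (CATEGORY_MEANS["negative"] + CATEGORY_MEANS["positive"])

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

# ---------------------------------------------------------------------
# per-position blast expression-category tables (percent of cases)
# rows: position; columns: negative, weak, positive, bright.
# A few source columns do not sum to 100% (worst: tube-1 CD66c position 1
# at 111.2%); each row is renormalized to a probability vector.
# ---------------------------------------------------------------------

_TUBE1_CATEGORY_PCT: dict[str, list[list[float]]] = {
    "CD66c": [
        [3.7, 51.9, 55.6, 0.0], [93.3, 6.7, 0.0, 0.0], [33.3, 0.0, 66.7, 0.0],
        [100.0, 0.0, 0.0, 0.0], [75.0, 0.0, 25.0, 0.0], [66.7, 33.3, 0.0, 0.0],
    ],
    "CD34": [
        [11.1, 7.4, 74.1, 7.4], [33.3, 40.0, 26.7, 0.0], [0.0, 0.0, 100.0, 0.0],
        [66.7, 33.3, 0.0, 0.0], [0.0, 0.0, 100.0, 0.0], [100.0, 0.0, 0.0, 0.0],
    ],
    "CD10": [
        [0.0, 7.4, 66.7, 25.9], [0.0, 0.0, 0.0, 100.0], [0.0, 0.0, 16.7, 83.3],
        [0.0, 0.0, 0.0, 100.0], [25.0, 75.0, 0.0, 0.0], [0.0, 0.0, 100.0, 0.0],
    ],
    "CD38": [
        [25.9, 25.9, 48.2, 0.0], [13.3, 0.0, 86.7, 0.0], [16.7, 16.7, 66.7, 0.0],
        [33.3, 0.0, 66.7, 0.0], [0.0, 0.0, 100.0, 0.0], [0.0, 33.3, 66.7, 0.0],
    ],
    "CD45": [
        [11.1, 88.9, 0.0, 0.0], [26.7, 0.0, 73.3, 0.0], [33.3, 66.7, 0.0, 0.0],
        [66.7, 33.3, 0.0, 0.0], [0.0, 100.0, 0.0, 0.0], [0.0, 100.0, 0.0, 0.0],
    ],
}

_TUBE2_CATEGORY_PCT: dict[str, list[list[float]]] = {
    "CD58": [
        [6.3, 37.5, 56.3, 0.0], [0.0, 0.0, 100.0, 0.0],
        [0.0, 14.3, 85.7, 0.0], [8.0, 28.0, 64.0, 0.0],
    ],
    "CD123": [
        [87.5, 12.5, 0.0, 0.0], [67.5, 33.3, 0.0, 0.0],
        [28.6, 28.6, 42.8, 0.0], [48.0, 16.0, 36.0, 0.0],
    ],
    "CD33": [
        [62.5, 37.5, 0.0, 0.0], [100.0, 0.0, 0.0, 0.0],
        [71.4, 28.6, 0.0, 0.0], [80.0, 16.0, 4.0, 0.0],
    ],
    "CD81": [
        [0.0, 6.3, 93.8, 0.0], [0.0, 0.0, 100.0, 0.0],
        [0.0, 7.2, 71.4, 21.4], [0.0, 0.0, 36.0, 64.0],
    ],
}

N_POSITIONS = {1: 6, 2: 4}


def blast_category_probs(tube: int) -> dict[str, np.ndarray]:
    """Per-marker (n_positions x 4) expression-category probabilities,
    renormalized row-wise (source percentages occasionally exceed 100%)."""
    table = {1: _TUBE1_CATEGORY_PCT, 2: _TUBE2_CATEGORY_PCT}[tube]
    out = {}
    for marker, rows in table.items():
        arr = np.asarray(rows, dtype=float)
        out[marker] = arr / arr.sum(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------
# panels and normal-population profiles
# ---------------------------------------------------------------------

_TUBE1_FLUOR = ("syto", "CD19", "CD10", "CD20", "CD34", "CD38", "CD45", "CD66c")
_TUBE2_FLUOR = ("syto", "CD19", "CD45", "CD58", "CD123", "CD33", "CD81")


def tube_markers(tube: int, include_scatter: bool = True) -> tuple[str, ...]:
    fluor = {1: _TUBE1_FLUOR, 2: _TUBE2_FLUOR}[tube]
    return tuple(SCATTER_CHANNELS) + fluor if include_scatter else fluor


_N, _W, _P, _B = (CATEGORY_MEANS[c] for c in CATEGORIES)

# fixed marker means for the non-blast populations (transformed scale)
_TUBE1_NORMAL_MEANS: dict[str, dict[str, float]] = {
    "hematogone_I":   {"syto": _P, "CD19": _P, "CD10": _B, "CD20": _N,
                       "CD34": _P, "CD38": _B, "CD45": _W, "CD66c": _N},
    "hematogone_II":  {"syto": _P, "CD19": _P, "CD10": _P, "CD20": _W,
                       "CD34": _N, "CD38": _P, "CD45": _P, "CD66c": _N},
    "mature_B":       {"syto": _P, "CD19": _P, "CD10": _N, "CD20": _P,
                       "CD34": _N, "CD38": _W, "CD45": _B, "CD66c": _N},
    "erythroid":      {"syto": _P, "CD19": _N, "CD10": _N, "CD20": _N,
                       "CD34": _N, "CD38": _W, "CD45": _N, "CD66c": _N},
    "other_nucleated": {"syto": _P, "CD19": _N, "CD10": _N, "CD20": _N,
                        "CD34": _N, "CD38": _W, "CD45": _P, "CD66c": 0.5},
}

_TUBE2_NORMAL_MEANS: dict[str, dict[str, float]] = {
    "hematogone_I":   {"syto": _P, "CD19": _P, "CD45": _W, "CD58": _P,
                       "CD123": _N, "CD33": _N, "CD81": _B},
    "hematogone_II":  {"syto": _P, "CD19": _P, "CD45": _P, "CD58": _P,
                       "CD123": _N, "CD33": _N, "CD81": _B},
    "mature_B":       {"syto": _P, "CD19": _P, "CD45": _B, "CD58": _P,
                       "CD123": _N, "CD33": _N, "CD81": _P},
    "erythroid":      {"syto": _P, "CD19": _N, "CD45": _N, "CD58": _W,
                       "CD123": _N, "CD33": _N, "CD81": _N},
    "other_nucleated": {"syto": _P, "CD19": _N, "CD45": _P, "CD58": _W,
                        "CD123": 0.5, "CD33": 0.8, "CD81": _W},
}

# markers whose blast expression is *not* position-dependent
_BLAST_BACKBONE = {
    1: {"syto": _P, "CD19": _P, "CD20": 0.5},
    2: {"syto": _P, "CD19": _P, "CD45": _W},
}

#: heterogeneous background marrow gets wider peaks than a clean category
#: — but only on markers it genuinely expresses at variable levels;
#: B-lineage markers are robustly negative on non-B cells
_OTHER_SD = 0.8
_B_LINEAGE_MARKERS = frozenset({"CD19", "CD10", "CD20", "CD34"})

# (FSC-A mean, FSC-A sd, SSC-A mean, SSC-A sd) per population
_SCATTER_PARAMS = {
    "blast":           (55_000, 8_000, 22_000, 6_000),
    "hematogone_I":    (48_000, 6_000, 18_000, 5_000),
    "hematogone_II":   (50_000, 6_000, 18_000, 5_000),
    "mature_B":        (52_000, 6_000, 20_000, 5_000),
    "erythroid":       (35_000, 6_000, 12_000, 4_000),
    "other_nucleated": (70_000, 15_000, 60_000, 20_000),
    "debris":          (15_000, 5_000, 8_000, 3_000),
}
_FSC_H_RATIO_SD = 0.02  # FSC-H/FSC-A spread for singlets


# ---------------------------------------------------------------------
# reference cohort bookkeeping (single-center cohort of 72 children)
# ---------------------------------------------------------------------

REFERENCE_COHORT_COUNTS: dict[str, int] = {
    "high hyperdiploidy": 22,
    "t(12;21)": 18,
    "t(1;19)": 3,
    "B-other": 19,
    "KMT2A rearrangement": 1,
    "iAMP21": 2,
    "t(9;22)": 6,
    "t(1;9)": 1,
}

REFERENCE_MRD_DAY15_COUNTS: dict[str, int] = {
    "FLR": 20, "FMR": 37, "FHR": 12, "N/A": 3,
}

REFERENCE_MRD_DAY33_COUNTS: dict[str, int] = {
    "lt0.1": 53, "mid": 7, "ge10": 3, "N/A": 9,
}


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One cellular population of a marrow sample."""

    name: str
    fraction: float
    marker_means: Mapping[str, float]
    marker_sds: Mapping[str, float]

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.name}: fraction must be in [0,1]")
        for mk, sd in self.marker_sds.items():
            if not sd > 0:
                raise ValueError(f"{self.name}: sd for {mk} must be positive")


def _check_probs(name: str, probs: Sequence[float], n: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a {n}-vector")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return arr


@dataclass(frozen=True)
class SubtypeProfile:
    """Cytogenetic subtype: position predilections per tube, subclone
    multiplicity, and (shared) per-position marker-category tables."""

    subtype: str
    position_probs_tube1: Sequence[float]
    position_probs_tube2: Sequence[float]
    n_subclones_dist: Mapping[int, float]

    def __post_init__(self):
        object.__setattr__(
            self, "position_probs_tube1",
            _check_probs(f"{self.subtype}.position_probs_tube1",
                         self.position_probs_tube1, N_POSITIONS[1]),
        )
        object.__setattr__(
            self, "position_probs_tube2",
            _check_probs(f"{self.subtype}.position_probs_tube2",
                         self.position_probs_tube2, N_POSITIONS[2]),
        )
        ks = sorted(self.n_subclones_dist)
        if not ks or any(k not in (1, 2, 3) for k in ks):
            raise ValueError("n_subclones_dist supports counts {1,2,3}")
        if abs(sum(self.n_subclones_dist.values()) - 1.0) > 1e-9:
            raise ValueError("n_subclones_dist must sum to 1")

    def position_probs(self, tube: int) -> np.ndarray:
        return {1: self.position_probs_tube1, 2: self.position_probs_tube2}[tube]

    def marker_category_probs(self, tube: int) -> dict[str, np.ndarray]:
        return blast_category_probs(tube)


SUBTYPES: dict[str, SubtypeProfile] = {
    # hyperdiploid blasts usually sit in tube-1 position 1 and tube-2
    # position 3; predilections are clear majorities, matching the strong
    # per-gate differences between subtypes the protocol is built to show
    "hyperdiploid": SubtypeProfile(
        "hyperdiploid",
        [0.65, 0.05, 0.09, 0.07, 0.07, 0.07],
        [0.08, 0.07, 0.70, 0.15],
        {1: 0.90, 2: 0.10},
    ),
    # t(12;21)/ETV6-RUNX1 favours tube-1 position 2 and tube-2 position 1
    "ETV6_RUNX1": SubtypeProfile(
        "ETV6_RUNX1",
        [0.05, 0.68, 0.07, 0.07, 0.07, 0.06],
        [0.72, 0.10, 0.08, 0.10],
        {1: 0.90, 2: 0.10},
    ),
    # B-other: weak tube-1 predilection, tube-2 position 4; often
    # genuinely polyclonal (2-3 subclones)
    "B_other": SubtypeProfile(
        "B_other",
        [0.10, 0.04, 0.12, 0.32, 0.21, 0.21],
        [0.08, 0.07, 0.15, 0.70],
        {1: 0.25, 2: 0.45, 3: 0.30},
    ),
    # Ph+/t(9;22): CD66c/CD123-skewed positions
    "Ph_pos": SubtypeProfile(
        "Ph_pos",
        [0.35, 0.05, 0.40, 0.05, 0.10, 0.05],
        [0.10, 0.10, 0.40, 0.40],
        {1: 0.70, 2: 0.20, 3: 0.10},
    ),
    "other": SubtypeProfile(
        "other",
        [1 / 6] * 6,
        [0.25] * 4,
        {1: 0.70, 2: 0.20, 3: 0.10},
    ),
}

TIMEPOINTS = ("diagnosis", "day15", "day33")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated bone-marrow sample."""

    n_events: int
    blast_fraction: float
    timepoint: str = "diagnosis"
    subtype: str = "hyperdiploid"
    seed: int = 0
    tube: int = 1
    position: int | None = None
    n_subclones: int | None = None
    examiner_noise_sd: float = 0.05
    debris_fraction: float = 0.0
    doublet_fraction: float = 0.0

    def __post_init__(self):
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for name in ("blast_fraction", "debris_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.tube not in (1, 2):
            raise ValueError("tube must be 1 or 2")
        if self.position is not None and not (
            1 <= self.position <= N_POSITIONS[self.tube]
        ):
            raise ValueError(
                f"position must be in 1..{N_POSITIONS[self.tube]} for tube {self.tube}"
            )
        if self.n_subclones is not None and self.n_subclones not in (1, 2, 3):
            raise ValueError("n_subclones must be in {1,2,3}")
        if self.examiner_noise_sd < 0:
            raise ValueError("examiner_noise_sd must be >= 0")


@dataclass
class CaseRecord:
    """One patient-sample in a simulated cohort."""

    case_id: str
    subtype: str
    timepoint: str
    blast_fraction: float
    position_tube1: int
    position_tube2: int
    n_subclones: int
    # filled in by downstream analysis stages
    blast_pct: float | None = None
    mrd_category: str | None = None
    assigned_position: int | None = None
    n_clusters: int | None = None
    heterogeneous: bool | None = None


def population_of(label: str) -> str:
    """Strip subclone (``blast/2``) and artifact (``|doublet``) suffixes."""
    return str(label).split("|")[0].split("/")[0]


# ---------------------------------------------------------------------
# sample composition
# ---------------------------------------------------------------------

_BASE_FRACTIONS = {
    # no hematogones at Day 15: early-induction marrow holds only mature
    # B cells besides blasts on the B lineage
    "day15": {"mature_B": 0.04, "erythroid": 0.25, "other_nucleated": 0.71},
    # regenerating marrow at Day 33: hematogones are back
    "day33": {"hematogone_I": 0.03, "hematogone_II": 0.05, "mature_B": 0.05,
              "erythroid": 0.22, "other_nucleated": 0.65},
    "diagnosis": {"hematogone_I": 0.015, "hematogone_II": 0.025,
                  "mature_B": 0.04, "erythroid": 0.22, "other_nucleated": 0.70},
}


def default_population_fractions(timepoint: str, blast_fraction: float
                                 ) -> dict[str, float]:
    """Population fractions of nucleated events for one timepoint; the
    non-blast background is scaled to ``1 - blast_fraction``."""
    base = _BASE_FRACTIONS[timepoint]
    out = {name: frac * (1.0 - blast_fraction) for name, frac in base.items()}
    out["blast"] = blast_fraction
    return out


def sample_blast_phenotype(rng: np.random.Generator, subtype: str, tube: int,
                           position: int, n_subclones: int = 1
                           ) -> list[dict[str, str]]:
    """Draw the per-case expression category of every position-dependent
    marker, for each subclone.

    The base subclone's categories follow the per-position tables. Each
    additional subclone copies the base and jointly shifts a pair of
    distinct markers to the far category (negative <-> positive side).
    Subclonal immunophenotype shifts involve several antigens moving
    together (e.g. a CD34+/CD38-low clone beside a CD34-/CD38+ one);
    that correlated, multi-marker structure is also what makes the
    shift visible to a PCA-based population separator — a change
    confined to a single channel carries no correlation signal after
    channel standardization.
    """
    probs = blast_category_probs(tube)
    markers = list(probs)
    base = {
        mk: str(rng.choice(CATEGORIES, p=probs[mk][position - 1]))
        for mk in markers
    }
    clones = [base]
    shift_markers = rng.permutation(markers)
    per_clone = 2  # markers shifted together by each extra subclone
    for k in range(1, n_subclones):
        clone = dict(base)
        for i in range(per_clone):
            mk = str(shift_markers[((k - 1) * per_clone + i) % len(markers)])
            clone[mk] = ("bright" if CATEGORY_MEANS[clone[mk]] < 2.0
                         else "negative")
        clones.append(clone)
    return clones


def _blast_population_means(tube: int, categories: Mapping[str, str]
                            ) -> dict[str, float]:
    means = dict(_BLAST_BACKBONE[tube])
    for mk, cat in categories.items():
        means[mk] = CATEGORY_MEANS[cat]
    return means


def _panel_channels(tube: int) -> list[ChannelMeta]:
    chans = [ChannelMeta(marker=c, detector=c, is_scatter=True)
             for c in SCATTER_CHANNELS]
    chans += [ChannelMeta(marker=mk, detector=mk, is_scatter=False)
              for mk in tube_markers(tube, include_scatter=False)]
    return chans


def _draw_population(rng: np.random.Generator, name: str, n: int, tube: int,
                     marker_means: Mapping[str, float],
                     sd_default: float) -> np.ndarray:
    fluor = tube_markers(tube, include_scatter=False)
    fsc_mu, fsc_sd, ssc_mu, ssc_sd = _SCATTER_PARAMS[population_of(name)]
    fsc = np.clip(rng.normal(fsc_mu, fsc_sd, n), 1.0, None)
    fsc_h = fsc * rng.normal(1.0, _FSC_H_RATIO_SD, n)
    ssc = np.clip(rng.normal(ssc_mu, ssc_sd, n), 1.0, None)
    cols = [fsc, fsc_h, ssc]
    for mk in fluor:
        # the nucleic-acid dye is uniformly tight on nucleated cells and
        # lineage-exclusion markers are robustly negative off-lineage;
        # only genuinely variable markers get a population's broad spread
        sd = sd_default
        if mk == "syto" or mk in _B_LINEAGE_MARKERS:
            sd = CATEGORY_SD
        cols.append(rng.normal(marker_means.get(mk, 0.0), sd, n))
    return np.column_stack(cols)


def generate_bm_sample(spec: SyntheticSpec) -> EventMatrix:
    """Simulate one bone-marrow sample with per-event truth labels.

    Labels are population names; blast subclones carry a ``/k`` suffix
    (``blast/0`` .. ``blast/2``) and doublets a ``|doublet`` suffix —
    :func:`population_of` strips both.
    """
    rng = np.random.default_rng(spec.seed)
    profile = SUBTYPES[spec.subtype]

    position = spec.position
    if position is None:
        position = int(rng.choice(N_POSITIONS[spec.tube],
                                  p=profile.position_probs(spec.tube))) + 1
    n_subclones = spec.n_subclones
    if n_subclones is None:
        ks = sorted(profile.n_subclones_dist)
        n_subclones = int(rng.choice(
            ks, p=[profile.n_subclones_dist[k] for k in ks]))

    clone_categories = sample_blast_phenotype(
        rng, spec.subtype, spec.tube, position, n_subclones)
    # subclone mixture weights: roughly balanced, jittered
    w = 0.7 + rng.random(n_subclones)
    w /= w.sum()

    normal_means = {1: _TUBE1_NORMAL_MEANS, 2: _TUBE2_NORMAL_MEANS}[spec.tube]
    fractions: dict[str, float] = {}
    means: dict[str, dict[str, float]] = {}
    sds: dict[str, float] = {}
    live = 1.0 - spec.debris_fraction
    for name, frac in default_population_fractions(
            spec.timepoint, spec.blast_fraction).items():
        if name == "blast":
            for k in range(n_subclones):
                lab = f"blast/{k}"
                fractions[lab] = live * frac * w[k]
                means[lab] = _blast_population_means(
                    spec.tube, clone_categories[k])
                sds[lab] = CATEGORY_SD
        else:
            fractions[name] = live * frac
            means[name] = normal_means[name]
            sds[name] = _OTHER_SD if name == "other_nucleated" else CATEGORY_SD
    if spec.debris_fraction > 0:
        fractions["debris"] = spec.debris_fraction
        means["debris"] = {mk: 0.0 for mk in tube_markers(spec.tube, False)}
        # debris is syto-negative by construction
        means["debris"]["syto"] = 0.0
        sds["debris"] = CATEGORY_SD

    names = list(fractions)
    counts = rng.multinomial(spec.n_events, [fractions[n] for n in names])
    blocks, labels = [], []
    for name, n in zip(names, counts):
        if n == 0:
            continue
        blocks.append(_draw_population(rng, name, n, spec.tube,
                                       means[name], sds[name]))
        labels.append(np.full(n, name, dtype=object))
    values = np.vstack(blocks)
    label_arr = np.concatenate(labels)

    if spec.doublet_fraction > 0:
        dbl = rng.random(len(values)) < spec.doublet_fraction
        dbl &= label_arr != "debris"
        values[dbl, 0] *= 2.0  # FSC-A doubles, FSC-H does not
        label_arr = label_arr.copy()
        label_arr[dbl] = [lab + "|doublet" for lab in label_arr[dbl]]

    perm = rng.permutation(len(values))
    return EventMatrix(values[perm], _panel_channels(spec.tube),
                       labels=label_arr[perm])


# ---------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------

_BLAST_FRACTION_RANGES = {
    # diagnosis marrows are blast-rich; MRD timepoints span decades
    "diagnosis": (0.5, 0.9, "uniform"),
    "day15": (0.002, 0.15, "log"),
    "day33": (0.0002, 0.05, "log"),
}


def _draw_blast_fraction(rng: np.random.Generator, timepoint: str) -> float:
    lo, hi, kind = _BLAST_FRACTION_RANGES[timepoint]
    if kind == "log":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def generate_cohort(n_per_subtype: Mapping[str, int],
                    timepoint: str = "diagnosis",
                    seed: int = 0,
                    n_events: int = 3000,
                    tube: int = 1,
                    blast_fraction: float | None = None,
                    ) -> list[tuple[CaseRecord, EventMatrix]]:
    """Simulate a cohort of cases: per case, a radar position per tube and
    a subclone count are drawn from the subtype's profile, then an event
    matrix is generated for the requested tube. Deterministic given seed."""
    rng = np.random.default_rng(seed)
    for st in n_per_subtype:
        if st not in SUBTYPES:
            raise KeyError(f"unknown subtype {st!r}")
        if n_per_subtype[st] < 0:
            raise ValueError("case counts must be >= 0")
    cohort: list[tuple[CaseRecord, EventMatrix]] = []
    for subtype in n_per_subtype:
        profile = SUBTYPES[subtype]
        for i in range(n_per_subtype[subtype]):
            pos1 = int(rng.choice(N_POSITIONS[1],
                                  p=profile.position_probs(1))) + 1
            pos2 = int(rng.choice(N_POSITIONS[2],
                                  p=profile.position_probs(2))) + 1
            ks = sorted(profile.n_subclones_dist)
            n_sub = int(rng.choice(
                ks, p=[profile.n_subclones_dist[k] for k in ks]))
            bf = (blast_fraction if blast_fraction is not None
                  else _draw_blast_fraction(rng, timepoint))
            case_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec(
                n_events=n_events, blast_fraction=bf, timepoint=timepoint,
                subtype=subtype, seed=case_seed, tube=tube,
                position={1: pos1, 2: pos2}[tube], n_subclones=n_sub,
            )
            record = CaseRecord(
                case_id=f"{subtype}-{i:03d}", subtype=subtype,
                timepoint=timepoint, blast_fraction=bf,
                position_tube1=pos1, position_tube2=pos2, n_subclones=n_sub,
            )
            cohort.append((record, generate_bm_sample(spec)))
    return cohort


def cohort_table(cohort: list[tuple[CaseRecord, EventMatrix]]) -> pd.DataFrame:
    """Case table (one row per case) for reporting and determinism checks."""
    rows = [vars(rec).copy() for rec, _ in cohort]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# two-examiner simulation
# ---------------------------------------------------------------------

def _gated_blast_pct(m: EventMatrix, syto_thr: float, cd19_thr: float,
                     cd10_thr: float) -> float:
    """Day-15-style threshold gate: blasts are CD19+/CD10+ events among
    syto-positive nucleated events (no hematogones interfere at Day 15)."""
    nucleated = m.get("syto") > syto_thr
    denom = int(nucleated.sum())
    if denom == 0:
        return 0.0
    blasts = nucleated & (m.get("CD19") > cd19_thr) & (m.get("CD10") > cd10_thr)
    return 100.0 * float(blasts.sum()) / denom


def generate_examiner_pair(m: EventMatrix, noise_sd: float, seed: int
                           ) -> tuple[float, float]:
    """Blast percentages obtained by two examiners who apply the same gate
    with independently jittered thresholds to the same events. With
    ``noise_sd == 0`` the two results are identical by construction."""
    if m.n_events == 0:
        raise ValueError("sample has no events")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    markers = {c.marker for c in m.channels}
    if "CD10" not in markers:
        raise ValueError("examiner simulation expects a tube-1 panel (CD10)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        jitter = rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else np.zeros(3)
        out.append(_gated_blast_pct(
            m,
            POSITIVITY_THRESHOLD + jitter[0],
            POSITIVITY_THRESHOLD + jitter[1],
            POSITIVITY_THRESHOLD + jitter[2],
        ))
    return out[0], out[1]
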