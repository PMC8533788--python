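"""Pre-gating chain and sample-quality filters.

Events enter the radar analysis through the chain
singlets -> syto-positive nucleated cells -> CD19-positive B cells,
and whole samples are excluded when fewer than 30,000 syto-positive
events were acquired or erythroid precursors fall below 2% (a marker of
hemodilution). Boundary semantics are inclusive: exactly 30,000 events
and exactly 2% pass.

Default thresholds derive from the synthetic generator's intensity
scale (positivity cut = midpoint of the negative and positive category
means); on real data they live in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_abs_deviation

from .fcs_io import EventMatrix
from .synthetic_data import POSITIVITY_THRESHOLD, population_of

__all__ = [
    "GateResult",
    "QCReport",
    "MIN_SYTO_EVENTS",
    "MIN_ERYTHROID_FRACTION",
    "gate_b_cells",
    "gate_nucleated",
    "gate_singlets",
    "qc_check",
]

MIN_SYTO_EVENTS = 30_000
MIN_ERYTHROID_FRACTION = 0.02


@dataclass
class GateResult:
    """Boolean event mask with its place in the gating hierarchy."""

    mask: np.ndarray
    name: str
    parent: str | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class QCReport:
    syto_positive_count: int
    erythroid_fraction: float
    passed: bool
    reasons: list[str] = field(default_factory=list)
    erythroid_is_proxy: bool = False

    def __post_init__(self):
        if self.passed != (not self.reasons):
            raise ValueError("passed must mirror an empty reasons list")


def _require(m: EventMatrix, *markers: str) -> None:
    present = {c.marker for c in m.channels}
    missing = [mk for mk in markers if mk not in present]
    if missing:
        raise KeyError(f"required channel(s) missing: {missing}")


def gate_singlets(m: EventMatrix, ratio_tolerance: float = 5.0) -> GateResult:
    """Keep events whose FSC-H/FSC-A ratio sits within ``ratio_tolerance``
    MADs of the median ratio. Doublets (double area, single height) fall
    far below the median and are cut."""
    _require(m, "FSC-A", "FSC-H")
    if m.n_events == 0:
        return GateResult(np.zeros(0, dtype=bool), "singlets")
    fsc_a = m.get("FSC-A")
    ratio = m.get("FSC-H") / np.where(fsc_a == 0, np.nan, fsc_a)
    ratio = np.nan_to_num(ratio, nan=np.inf)
    med = float(np.median(ratio[np.isfinite(ratio)]))
    mad = float(median_abs_deviation(ratio[np.isfinite(ratio)]))
    mad = max(mad, 1e-12)
    mask = np.abs(ratio - med) <= ratio_tolerance * mad
    return GateResult(mask, "singlets")


def gate_nucleated(m: EventMatrix,
                   syto_threshold: float = POSITIVITY_THRESHOLD,
                   parent: GateResult | None = None) -> GateResult:
    """Syto-positive (nucleated, live) events."""
    _require(m, "syto")
    mask = m.get("syto") > syto_threshold
    if parent is not None:
        mask = mask & parent.mask
    return GateResult(mask, "nucleated",
                      parent=None if parent is None else parent.name)


def gate_b_cells(m: EventMatrix, parent: GateResult,
                 cd19_threshold: float = POSITIVITY_THRESHOLD) -> GateResult:
    """CD19-positive B cells within the nucleated gate."""
    _require(m, "CD19")
    mask = (m.get("CD19") > cd19_threshold) & parent.mask
    return GateResult(mask, "b_cells", parent=parent.name)


def _erythroid_fraction(m: EventMatrix, nucleated: np.ndarray,
                        syto_threshold: float) -> tuple[float, bool]:
    denom = int(nucleated.sum())
    if denom == 0:
        return 0.0, False
    if m.labels is not None:
        pops = np.array([population_of(l) for l in m.labels], dtype=object)
        return float((pops[nucleated] == "erythroid").mean()), False
    # proxy on real data: CD45-negative, low-SSC nucleated events
    _require(m, "CD45", "SSC-A")
    ssc = m.get("SSC-A")
    low_ssc = ssc <= np.percentile(ssc[nucleated], 25)
    proxy = nucleated & (m.get("CD45") <= syto_threshold) & low_ssc
    return float(proxy[nucleated].mean()), True


def qc_check(m: EventMatrix,
             syto_threshold: float = POSITIVITY_THRESHOLD,
             min_syto_events: int = MIN_SYTO_EVENTS,
             min_erythroid_fraction: float = MIN_ERYTHROID_FRACTION
             ) -> QCReport:
    """Sample-quality report: insufficient syto+ events or an erythroid
    fraction below the floor mark a hemodiluted/inadequate sample.

    Erythroid precursors are read from truth labels on synthetic data and
    from a CD45-negative/low-SSC proxy gate otherwise (flagged as such)."""
    nucleated = gate_nucleated(m, syto_threshold).mask
    count = int(nucleated.sum())
    frac, is_proxy = _erythroid_fraction(m, nucleated, syto_threshold)
    reasons = []
    if count < min_syto_events:
        reasons.append(
            f"insufficient syto+ events ({count} < {min_syto_events})")
    if frac < min_erythroid_fraction:
        reasons.append(
            f"low erythroid precursors ({100 * frac:.2f}% < "
            f"{100 * min_erythroid_fraction:.0f}%)")
    return QCReport(
        syto_positive_count=count,
        erythroid_fraction=frac,
        passed=not reasons,
        reasons=reasons,
        erythroid_is_proxy=is_proxy,
    )
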