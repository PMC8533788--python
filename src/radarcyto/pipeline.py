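"""End-to-end analysis pipelines on synthetic marrow.

These functions wire the stages together the way the protocol runs in
practice: merge one normal and three leukemic marrows, gate B cells,
optimize the radar layout on the merged reference, partition the
abnormal region into position gates from a diagnosis cohort, classify
each case by plurality position, count subclones on APS projections,
and quantify MRD. They are the substrate of the test suite and of the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aps, gating, mrd_stats, radar, synthetic_data
from .fcs_io import EventMatrix, merge_samples
from .synthetic_data import (
    CaseRecord,
    SyntheticSpec,
    generate_bm_sample,
    generate_cohort,
    population_of,
)

__all__ = [
    "ReferenceBundle",
    "aps_calls_for_cohort",
    "blast_mask",
    "build_position_gates",
    "build_reference",
    "case_blast_points",
    "classify_cohort",
    "mrd_dilution_recovery",
    "normal_region_of",
]

NORMAL_B_POPULATIONS = ("hematogone_I", "hematogone_II", "mature_B")


def blast_mask(m: EventMatrix) -> np.ndarray:
    if m.labels is None:
        raise ValueError("event matrix carries no truth labels")
    return np.array([population_of(l) == "blast" for l in m.labels])


@dataclass
class ReferenceBundle:
    """Merged gated reference plus the optimized layout for one tube."""

    merged: EventMatrix          # gated B-lineage events of 4 samples
    layout: radar.RadarLayout
    default: radar.RadarLayout
    scaler: radar.PercentileScaler
    sep_labels: np.ndarray       # population labels used by the objective
    normal_labels: list[str]
    path_labels: list[str]

    def points(self, layout: radar.RadarLayout | None = None) -> np.ndarray:
        return radar.project_star(
            self.merged, layout or self.layout, self.scaler)

    def is_normal(self) -> np.ndarray:
        return np.isin(self.sep_labels, self.normal_labels)


def _gate_b_lineage(m: EventMatrix) -> EventMatrix:
    singlets = gating.gate_singlets(m)
    nucleated = gating.gate_nucleated(m, parent=singlets)
    b = gating.gate_b_cells(m, parent=nucleated)
    return m.subset(b.mask)


def build_reference(seed: int = 0, tube: int = 1,
                    n_events_normal: int = 20_000,
                    n_events_all: int = 8_000,
                    restarts: int = 10) -> ReferenceBundle:
    """Merge one normal and three BCP-ALL diagnosis marrows, gate B
    cells, and optimize the radar layout on the merged pool.

    The three leukemic samples span the three large cytogenetic groups
    so the optimized layout is not tuned to a single phenotype.
    """
    rng = np.random.default_rng(seed)
    normal = generate_bm_sample(SyntheticSpec(
        n_events=n_events_normal, blast_fraction=0.0, timepoint="diagnosis",
        subtype="other", seed=int(rng.integers(2**31 - 1)), tube=tube))
    alls = [
        generate_bm_sample(SyntheticSpec(
            n_events=n_events_all, blast_fraction=0.7, timepoint="diagnosis",
            subtype=st, seed=int(rng.integers(2**31 - 1)), tube=tube))
        for st in ("hyperdiploid", "ETV6_RUNX1", "B_other")
    ]
    gated = [_gate_b_lineage(s) for s in [normal] + alls]
    merged = merge_samples(
        gated, origin_ids=["normal", "all_1", "all_2", "all_3"])

    # separation objective: normal maturation stages vs per-sample blasts
    sep = np.array(
        [population_of(l) for l in merged.labels], dtype=object)
    is_blast = sep == "blast"
    sep[is_blast] = np.char.add(
        "blast@", merged.origin[is_blast].astype(str))
    path_labels = sorted(set(sep[is_blast]))
    normal_labels = [p for p in NORMAL_B_POPULATIONS
                     if (sep == p).sum() >= 50]

    work = EventMatrix(merged.values, merged.channels,
                       origin=merged.origin, labels=sep)
    scaler = radar.PercentileScaler.fit(
        work, [c.marker for c in work.channels if not c.is_scatter])
    cfg = radar.OptimizerConfig(restarts=restarts, seed=seed)
    layout = radar.optimize_layout(
        work, normal_labels, path_labels, config=cfg, scaler=scaler)
    deflt = radar.default_layout(layout_markers(work))
    return ReferenceBundle(
        merged=work, layout=layout, default=deflt, scaler=scaler,
        sep_labels=sep, normal_labels=normal_labels, path_labels=path_labels)


def layout_markers(m: EventMatrix) -> list[str]:
    """Markers eligible as radar axes: fluorescence minus the syto dye."""
    from .fcs_io import canonical_marker

    return [c.marker for c in m.channels
            if not c.is_scatter and canonical_marker(c.marker) != "syto"]


def normal_region_of(bundle: ReferenceBundle, quantile: float = 97.5,
                     pad: float = 0.05):
    """Union of the per-population convex hulls (slightly buffered) of
    the reference's normal B cells in optimized radar space — the region
    position gates must avoid.

    Hulls are taken per maturation stage, not over the pooled normals:
    hematogones I/II and mature B cells form separate islands, and one
    global hull would fence off the blast territory between them."""
    from shapely.geometry import MultiPoint
    from shapely.ops import unary_union

    pts = bundle.points()
    hulls = []
    for pop in bundle.normal_labels:
        p = pts[bundle.sep_labels == pop]
        center = p.mean(axis=0)
        radii = np.hypot(*(p - center).T)
        keep = radii <= np.percentile(radii, quantile)
        hulls.append(MultiPoint(p[keep].tolist()).convex_hull.buffer(pad))
    return unary_union(hulls)


def case_blast_points(case_events: EventMatrix, layout: radar.RadarLayout,
                      scaler: radar.PercentileScaler) -> np.ndarray:
    """Radar coordinates of one case's blasts (truth-labelled)."""
    blasts = case_events.subset(blast_mask(case_events))
    return radar.project_star(blasts, layout, scaler)


@dataclass
class PositionReference:
    """Layout + position gates calibrated on per-position blast
    prototypes, used to classify new cases by predilection position."""

    tube: int
    layout: radar.RadarLayout
    scaler: radar.PercentileScaler
    gates: radar.PositionGateSet
    #: gate label -> planted position whose prototype seeded the gate
    gate_to_position: dict[int, int]


def build_position_reference(seed: int = 0, tube: int = 1,
                             n_per_position: int = 60,
                             n_events_normal: int = 20_000,
                             restarts: int = 16,
                             n_angles: int = 24) -> PositionReference:
    """Calibrate the position-classification stage for one tube.

    A calibration set of per-case blast centroids (``n_per_position``
    phenotype draws from each position's category table) is combined
    with gated normal B cells; the layout is optimized with the
    ``all_pairs`` objective so that positions stay apart from each other
    as well as from the normal stages. Gates are the Voronoi cells of
    the per-position centroid prototypes, clipped away from the normal
    region.
    """
    rng = np.random.default_rng(seed)
    normal = generate_bm_sample(SyntheticSpec(
        n_events=n_events_normal, blast_fraction=0.0, timepoint="diagnosis",
        subtype="other", seed=int(rng.integers(2**31 - 1)), tube=tube))
    gated = _gate_b_lineage(normal)
    fluor_idx = gated.fluorescence_indices()
    channels = [gated.channels[i] for i in fluor_idx]
    marker_names = [c.marker for c in channels]

    k = synthetic_data.N_POSITIONS[tube]
    rows, labs = [], []
    for pos in range(1, k + 1):
        for _ in range(n_per_position):
            cats = synthetic_data.sample_blast_phenotype(
                rng, "other", tube, pos, 1)[0]
            means = synthetic_data._blast_population_means(tube, cats)
            rows.append([means.get(mk, 0.0) for mk in marker_names])
            labs.append(f"pos{pos}")
    normal_rows = gated.values[:, fluor_idx]
    normal_labs = [population_of(l) for l in gated.labels]
    work = EventMatrix(
        np.vstack([normal_rows, np.asarray(rows, dtype=float)]),
        channels,
        labels=np.array(normal_labs + labs, dtype=object),
    )
    normal_labels = [p for p in NORMAL_B_POPULATIONS
                     if normal_labs.count(p) >= 50]
    position_labels = [f"pos{p}" for p in range(1, k + 1)]

    scaler = radar.PercentileScaler.fit(work, marker_names)
    cfg = radar.OptimizerConfig(restarts=restarts, seed=seed,
                                pairs="all_pairs", n_angles=n_angles,
                                min_events=min(50, n_per_position))
    layout = radar.optimize_layout(work, normal_labels, position_labels,
                                   config=cfg, scaler=scaler)

    pts = radar.project_star(work, layout, scaler)
    lab_arr = np.asarray(work.labels, dtype=object)
    prototypes = np.array([
        pts[lab_arr == f"pos{p}"].mean(axis=0) for p in range(1, k + 1)
    ])
    # normal region: per-stage hulls of the normal B cells
    from shapely.geometry import MultiPoint
    from shapely.ops import unary_union

    hulls = []
    for pop in normal_labels:
        p = pts[lab_arr == pop]
        center = p.mean(axis=0)
        radii = np.hypot(*(p - center).T)
        keep = radii <= np.percentile(radii, 97.5)
        hulls.append(MultiPoint(p[keep].tolist()).convex_hull.buffer(0.05))
    gates = radar.define_position_gates(
        prototypes, tube, unary_union(hulls), seed=seed)
    # map each gate (angle-ordered label) back to the planted position
    # whose prototype it contains / is nearest to
    gate_to_position = {}
    for label, poly in gates.gates.items():
        from shapely.geometry import Point

        d = [poly.distance(Point(*prototypes[p])) for p in range(k)]
        gate_to_position[label] = int(np.argmin(d)) + 1
    return PositionReference(tube=tube, layout=layout, scaler=scaler,
                             gates=gates, gate_to_position=gate_to_position)


def classify_cohort(cohort, posref: PositionReference) -> list[CaseRecord]:
    """Assign every case its plurality predilection position (in planted
    position numbering, via the gate->position map); returns the updated
    records.

    A case whose blasts all land outside every gate (possible for an
    extreme phenotype draw near the clipped plot margin) falls back to
    the gate polygon nearest its blast centroid instead of failing the
    whole cohort."""
    from shapely.geometry import Point

    records = []
    for rec, events in cohort:
        pts = case_blast_points(events, posref.layout, posref.scaler)
        try:
            gate = radar.assign_position(pts, posref.gates)
        except ValueError:
            center = Point(*pts.mean(axis=0))
            gate = min(posref.gates.gates,
                       key=lambda g: posref.gates.gates[g].distance(center))
        rec.assigned_position = posref.gate_to_position[gate]
        records.append(rec)
    return records


def aps_calls_for_cohort(cohort, seed: int = 0) -> list[CaseRecord]:
    """APS projection + subclone count per case; flags heterogeneity."""
    records = []
    for i, (rec, events) in enumerate(cohort):
        blasts = events.subset(blast_mask(events))
        proj = aps.aps_project(blasts)
        call = aps.count_clusters(proj, seed=seed + i)
        rec.n_clusters = call.n_clusters
        rec.heterogeneous = call.n_clusters > 1
        records.append(rec)
    return records


#: MRD gating demands clear positivity: midway between the weak and
#: positive category means, above the spread of CD19-dim background
MRD_GATE_THRESHOLD = 0.5 * (synthetic_data.CATEGORY_MEANS["weak"]
                            + synthetic_data.CATEGORY_MEANS["positive"])


def mrd_dilution_recovery(planted_fractions, n_events: int = 100_000,
                          seeds=(0, 1, 2), subtype: str = "hyperdiploid",
                          ) -> list[dict]:
    """Planted-vs-recovered blast fractions on Day-15-style dilutions.

    As in clinical flow-MRD, follow-up gating tracks the leukemia-
    associated immunophenotype established at diagnosis: the spiked
    blasts carry the canonical hematogone-like LAIP (CD10 bright /
    CD34 positive, the position-3 profile) and are gated as clearly
    CD19+/CD10+ events among syto-positive nucleated cells.
    """
    out = []
    for frac in planted_fractions:
        for seed in seeds:
            m = generate_bm_sample(SyntheticSpec(
                n_events=n_events, blast_fraction=frac, timepoint="day15",
                subtype=subtype, seed=seed, position=3, n_subclones=1))
            nucleated = gating.gate_nucleated(m).mask
            blasts = (nucleated
                      & (m.get("CD19") > MRD_GATE_THRESHOLD)
                      & (m.get("CD10") > MRD_GATE_THRESHOLD))
            res = mrd_stats.quantify_blasts(blasts, nucleated, "day15")
            out.append({
                "planted_pct": 100.0 * frac,
                "recovered_pct": res.blast_pct,
                "category": res.category,
                "seed": seed,
                "rel_error": abs(res.blast_pct - 100.0 * frac)
                / (100.0 * frac),
            })
    return out
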