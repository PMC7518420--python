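"""Biofilm-positivity classification and per-sample scoring.

A tissue is biofilm positive when bacteria at more than the threshold
volumetric density (default 1e9 per ml) sit in direct epithelial
contact (within 1 um of the epithelium) over at least the minimum span
of the epithelial surface (default 200 um). The classifier
parameterizes the mucosal edge by arc length, marks edge positions
contacted by a bacterium within the contact band, merges contacted runs
across configurable gaps, and evaluates both the span and the band
density of each run.

The per-sample score sheet mirrors a clinical screening table: mucus
grade (0-2 in half steps), bacterial abundance grade per 200 um of
epithelium, percent biofilm coverage, and a DAPI-without-Cy3 quality
flag. The composite score defaults to the abundance grade and is
compared against the >2.5 positivity cutoff; the combiner is pluggable
since published scoring schemes weight the columns differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyCompartmentError, ParameterError, ValidationError
from .masks import EdgeContour

ML_PER_UM3 = 1e-12

VALID_MUCUS_GRADES = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class BiofilmCriteria:
    """Operational thresholds of the biofilm positivity rule."""

    density_threshold_per_ml: float = 1e9
    contact_band_um: float = 1.0
    min_span_um: float = 200.0
    score_cutoff: float = 2.5
    gap_tolerance_um: float = 5.0

    def __post_init__(self) -> None:
        for name in ("density_threshold_per_ml", "contact_band_um", "min_span_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.gap_tolerance_um < 0:
            raise ParameterError("gap_tolerance_um must be >= 0")


@dataclass
class BiofilmCall:
    """Classifier output for one sample."""

    positive: bool
    max_contiguous_span_um: float
    band_density_per_ml: float
    spans: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SampleScore:
    """One row of the per-sample score sheet."""

    sample_id: str
    mucus_grade: float
    abundance_grade: float
    coverage_pct: float
    dapi_without_cy3: bool
    composite_score: float
    biofilm_positive: bool
    notes: str = ""

    def as_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mucus_grade": self.mucus_grade,
            "abundance_grade": self.abundance_grade,
            "coverage_pct": self.coverage_pct,
            "dapi_without_cy3": self.dapi_without_cy3,
            "notes": self.notes,
        }


def classify_biofilm(
    mucosal_edge: EdgeContour,
    bacteria_centers: Sequence | np.ndarray,
    criteria: BiofilmCriteria | None = None,
    *,
    section_thickness_um: float = 5.0,
) -> BiofilmCall:
    """Apply the density-over-span positivity rule along the epithelium.

    The mucosal edge is parameterized by arc length. An edge position is
    "contacted" when at least one bacterium center lies within
    ``contact_band_um`` of it; maximal contacted runs may bridge
    uncontacted gaps up to ``gap_tolerance_um``. Each run's band density
    is its bacterium count divided by the run's band volume
    (span * band width * section thickness, in ml). Positive iff some
    run reaches both ``min_span_um`` and a density strictly above
    ``density_threshold_per_ml``. Deterministic.
    """
    criteria = criteria or BiofilmCriteria()
    if len(mucosal_edge) == 0:
        raise EmptyCompartmentError("mucosal edge is empty")

    centers = np.asarray(bacteria_centers, dtype=float).reshape(-1, 2)
    if len(centers) == 0:
        return BiofilmCall(False, 0.0, 0.0, [])

    px = mucosal_edge.pixel_size_um
    edge_pts = mucosal_edge.points.astype(float)
    arc = mucosal_edge.arc_length_um()
    band_px = criteria.contact_band_um / px

    tree = cKDTree(centers)
    nearest_bact_dist, _ = tree.query(edge_pts)
    contacted = nearest_bact_dist <= band_px
    if not contacted.any():
        return BiofilmCall(False, 0.0, 0.0, [])

    # arc position of each contacting bacterium = arc of its nearest edge point
    edge_tree = cKDTree(edge_pts)
    bact_edge_dist, bact_edge_idx = edge_tree.query(centers)
    contacting = bact_edge_dist <= band_px
    bact_arc = arc[bact_edge_idx[contacting]]

    # split contacted edge positions into runs bridging small gaps
    s = arc[contacted]
    s.sort()
    breaks = np.flatnonzero(np.diff(s) > criteria.gap_tolerance_um)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(s) - 1]))

    total = mucosal_edge.total_length_um()
    spans: list[tuple[float, float]] = []
    best_span = 0.0
    best_density = 0.0
    positive = False
    for i0, i1 in zip(starts, ends):
        lo = max(0.0, s[i0] - criteria.contact_band_um)
        hi = min(total, s[i1] + criteria.contact_band_um)
        span_um = hi - lo
        count = int(np.count_nonzero((bact_arc >= lo) & (bact_arc <= hi)))
        volume_ml = span_um * criteria.contact_band_um * section_thickness_um * ML_PER_UM3
        density = count / volume_ml if volume_ml > 0 else 0.0
        spans.append((float(lo), float(hi)))
        if span_um > best_span:
            best_span = span_um
            best_density = density
        if span_um >= criteria.min_span_um and density > criteria.density_threshold_per_ml:
            positive = True
            best_span = max(best_span, span_um)
            best_density = density

    return BiofilmCall(
        positive=positive,
        max_contiguous_span_um=float(best_span),
        band_density_per_ml=float(best_density),
        spans=spans,
    )


def coverage_percent(call: BiofilmCall, total_edge_length_um: float) -> float:
    """Percent of the epithelial edge covered by contacted spans."""
    if total_edge_length_um <= 0:
        raise ParameterError("total_edge_length_um must be > 0")
    covered = sum(hi - lo for lo, hi in call.spans)
    return float(np.clip(100.0 * covered / total_edge_length_um, 0.0, 100.0))


def abundance_grade_from_count(count: int, edge_length_um: float) -> float:
    """Grade bacterial abundance per 200 um of epithelial edge.

    0 = none, 1 = <=5 bacteria, 2 = <=20 bacteria, 3 = more (the
    published scale stops at 2; grade 3 extrapolates it for denser
    fields).
    """
    if edge_length_um <= 0:
        raise ParameterError("edge_length_um must be > 0")
    per_200um = count * 200.0 / edge_length_um
    if per_200um == 0:
        return 0.0
    if per_200um <= 5:
        return 1.0
    if per_200um <= 20:
        return 2.0
    return 3.0


def default_combiner(
    mucus_grade: float,
    abundance_grade: float,
    coverage_pct: float,
    dapi_without_cy3: bool,
) -> float:
    """Composite score = abundance grade (the quality flag does not score)."""
    return float(abundance_grade)


def score_sample(
    sample_id: str,
    mucus_grade: float,
    abundance_grade: float,
    coverage_pct: float,
    dapi_without_cy3: bool,
    criteria: BiofilmCriteria | None = None,
    notes: str = "",
    combiner: Optional[Callable[[float, float, float, bool], float]] = None,
) -> SampleScore:
    """Build a validated score-sheet row and call positivity on it."""
    criteria = criteria or BiofilmCriteria()
    if float(mucus_grade) not in VALID_MUCUS_GRADES:
        raise ValidationError(
            f"mucus_grade {mucus_grade!r} not in {VALID_MUCUS_GRADES}"
        )
    if abundance_grade < 0:
        raise ValidationError("abundance_grade must be >= 0")
    if not 0.0 <= float(coverage_pct) <= 100.0:
        raise ValidationError(f"coverage_pct {coverage_pct!r} outside [0, 100]")
    combine = combiner or default_combiner
    composite = float(
        combine(float(mucus_grade), float(abundance_grade), float(coverage_pct), bool(dapi_without_cy3))
    )
    return SampleScore(
        sample_id=str(sample_id),
        mucus_grade=float(mucus_grade),
        abundance_grade=float(abundance_grade),
        coverage_pct=float(coverage_pct),
        dapi_without_cy3=bool(dapi_without_cy3),
        composite_score=composite,
        biofilm_positive=composite > criteria.score_cutoff,
        notes=notes,
    )
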