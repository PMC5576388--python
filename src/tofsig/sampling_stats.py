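"""Cross-sectional sampling of wall SIG and the accompanying statistics.

The evaluation workflow samples the wall map on a structured design:
cross-section planes ("levels") perpendicular to a user-supplied vessel
axis at a fixed spacing (default six levels, 2.5 mm apart), and within
each level a fixed number of angular sites (default twelve, 30 degrees
apart) measured from a reference azimuth.  Each (level, site) cell takes
the SIG of the wall point nearest to that plane/azimuth locus.  Group
differences use Welch's two-sample t-test and agreement with a reference
wall map (e.g. CFD wall shear stress) uses Pearson correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError
from .sig_core import WallPointSet

__all__ = [
    "CrossSectionTable",
    "sample_cross_sections",
    "GroupComparison",
    "compare_groups",
    "correlate",
]


@dataclasses.dataclass
class CrossSectionTable:
    """Structured samples: one row per (level, angular site).

    ``frame`` columns: ``level`` (1-based), ``angle_deg`` in [0, 360),
    ``x, y, z`` (mm position of the chosen wall point), ``sig`` (SI/mm)
    and optionally ``reference``.  Levels whose slab contained no wall
    point are absent from the frame and listed in ``missing_levels``.
    """

    frame: pd.DataFrame
    missing_levels: list[int]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _orthonormal_frame(axis_direction, reference_azimuth=None):
    u = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ParameterError("axis direction must be nonzero")
    u = u / norm
    if reference_azimuth is None:
        # any vector not parallel to the axis
        trial = np.array([1.0, 0.0, 0.0])
        if abs(u @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        reference_azimuth = trial
    e1 = np.asarray(reference_azimuth, dtype=float)
    e1 = e1 - (e1 @ u) * u
    n1 = np.linalg.norm(e1)
    if n1 == 0:
        raise ParameterError("reference azimuth is parallel to the axis")
    e1 /= n1
    e2 = np.cross(u, e1)
    return u, e1, e2


def sample_cross_sections(
    wps: WallPointSet,
    axis_point: Sequence[float],
    axis_direction: Sequence[float],
    n_levels: int = 6,
    level_spacing: float = 2.5,
    sites_per_level: int = 12,
    reference_azimuth: Sequence[float] | None = None,
    reference: np.ndarray | None = None,
) -> CrossSectionTable:
    """Sample wall SIG at ``n_levels`` x ``sites_per_level`` structured sites.

    Level plane ``l`` (1-based) is perpendicular to the axis at
    ``axis_point + (l-1) * level_spacing * axis_direction``; its candidate
    wall points are those within ``level_spacing / 2`` of the plane along
    the axis.  Site azimuths are equally spaced starting at
    ``reference_azimuth`` (projected perpendicular to the axis).  Each
    site takes the wall point nearest to the site's radial ray — ties
    broken by lexicographic position, so the result is invariant to
    wall-point ordering.  Flagged wall points are never sampled.

    ``reference`` optionally supplies one externally computed scalar per
    wall point (e.g. CFD wall shear stress); the chosen point's value is
    carried into a ``reference`` column.
    """
    if level_spacing <= 0:
        raise ParameterError("level_spacing must be positive")
    if n_levels < 1 or sites_per_level < 1:
        raise ParameterError("n_levels and sites_per_level must be >= 1")
    u, e1, e2 = _orthonormal_frame(axis_direction, reference_azimuth)
    p0 = np.asarray(axis_point, dtype=float)

    valid = wps.valid
    pts = wps.positions[valid]
    sig = wps.sig_scalar[valid]
    ref = None if reference is None else np.asarray(reference, float)[valid]
    if len(pts) == 0:
        return CrossSectionTable(
            frame=pd.DataFrame(
                columns=["level", "angle_deg", "x", "y", "z", "sig"]
            ),
            missing_levels=list(range(1, n_levels + 1)),
        )

    rel = pts - p0
    s = rel @ u  # axial coordinate, mm
    a = rel @ e1
    b = rel @ e2
    r = np.hypot(a, b)
    phi = np.arctan2(b, a)  # point azimuth, radians from reference azimuth

    angles = np.arange(sites_per_level) * (360.0 / sites_per_level)
    rows = []
    missing: list[int] = []
    half = level_spacing / 2.0
    for level in range(1, n_levels + 1):
        s_l = (level - 1) * level_spacing
        in_slab = np.abs(s - s_l) <= half
        if not in_slab.any():
            missing.append(level)
            continue
        idx = np.flatnonzero(in_slab)
        axial_off = s[idx] - s_l
        for angle in angles:
            theta = np.deg2rad(angle)
            dphi = phi[idx] - theta
            # in-plane distance from each point to the site's radial ray
            cos_d = np.cos(dphi)
            inplane = np.where(cos_d > 0, r[idx] * np.abs(np.sin(dphi)), r[idx])
            dist = np.hypot(axial_off, inplane)
            # ties broken by lexicographic position so the choice does not
            # depend on wall-point ordering (exact ties occur on symmetric
            # phantoms)
            cand = pts[idx]
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], dist))
            best = idx[int(order[0])]
            row = {
                "level": level,
                "angle_deg": float(angle),
                "x": pts[best, 0],
                "y": pts[best, 1],
                "z": pts[best, 2],
                "sig": sig[best],
            }
            if ref is not None:
                row["reference"] = ref[best]
            rows.append(row)
    return CrossSectionTable(frame=pd.DataFrame(rows), missing_levels=missing)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Mean +/- SD per group with Welch's t statistic and two-sided p."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_groups(a, b) -> GroupComparison:
    """Welch (unequal-variance) two-sample t-test between scalar samples.

    Means and sample SDs (ddof=1) are reported alongside t and the
    two-sided p so results can be quoted in mean +/- SD form.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each sample needs n >= 2 for a t-test")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # both samples constant and equal: no evidence of difference
        t, p = 0.0, 1.0
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p.

    Raises :class:`DegenerateInputError` for n < 3 or zero variance in
    either sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise DegenerateInputError("samples must be paired (equal length)")
    if len(x) < 3:
        raise DegenerateInputError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
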