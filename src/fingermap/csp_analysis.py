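"""Chemical-shift-perturbation analysis of a titration.

The combined amide CSP for a residue between two states is

    CSP = sqrt( dH^2 + (alpha_N * dN)^2 )

with ``alpha_N`` (default 0.14) scaling the 15N dimension onto the 1H
scale — the community-standard weighting for backbone amides.  The
endpoint compared against the apo reference is the highest-ratio
titration point, i.e. the one closest to saturation.

Under fast exchange a residue's peak moves along the straight segment
between its free and bound positions, so per-residue trajectories
through the titration should be collinear; :func:`peak_trajectories`
fits a total-least-squares line per residue in the alpha-scaled
(1H, 15N) plane and reports the maximum perpendicular deviation as a
fast-exchange diagnostic.

Hotspot calling is an explicit, reported choice: either a
mean + k*SD threshold over the profile (default k = 1) or a quantile
threshold.  The full ranked profile is always retained alongside the
call, since published interface lists are ranked rather than
thresholded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .shift_io import AmidePeak, TitrationSeries

DEFAULT_ALPHA_N = 0.14


@dataclass
class CSPConfig:
    """Weighting of the 15N dimension in the combined CSP."""

    alpha_n: float = DEFAULT_ALPHA_N

    def __post_init__(self) -> None:
        if not 0 < self.alpha_n <= 1:
            raise DataError(f"alpha_n must be in (0, 1], got {self.alpha_n}")


@dataclass
class CSPProfile:
    """Combined CSP (ppm) per residue between two sample states."""

    values: dict[int, float]
    config: CSPConfig
    reference_label: str = "apo"
    endpoint_label: str = "endpoint"
    omitted: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r, v in self.values.items():
            if v < 0:
                raise DataError(f"negative CSP for residue {r}")

    def relative(self) -> dict[int, float]:
        """CSP divided by the profile maximum (the figures' y-axis)."""
        vmax = max(self.values.values(), default=0.0)
        if vmax == 0:
            return {r: 0.0 for r in self.values}
        return {r: v / vmax for r, v in self.values.items()}

    def ranked(self) -> list[tuple[int, float]]:
        return sorted(self.values.items(), key=lambda kv: kv[1], reverse=True)


@dataclass
class HotspotCall:
    """Residues whose CSP strictly exceeds the stated threshold."""

    hotspots: frozenset[int]
    threshold_value: float
    method: str


def combined_csp(
    reference: list[AmidePeak],
    endpoint: list[AmidePeak],
    config: CSPConfig | None = None,
    reference_label: str = "apo",
    endpoint_label: str = "endpoint",
) -> CSPProfile:
    """Combined amide CSP per residue, endpoint minus reference.

    Residues present in only one list are omitted from the profile and
    reported in ``profile.omitted``; fully disjoint lists are an error.
    """
    config = config or CSPConfig()
    ref = {p.residue_number: p for p in reference}
    end = {p.residue_number: p for p in endpoint}
    shared = sorted(set(ref) & set(end))
    if not shared:
        raise DataError("reference and endpoint peak lists share no residues")
    values = {}
    for r in shared:
        dh = end[r].h_ppm - ref[r].h_ppm
        dn = end[r].n_ppm - ref[r].n_ppm
        values[r] = math.hypot(dh, config.alpha_n * dn)
    omitted = sorted(set(ref) ^ set(end))
    return CSPProfile(values, config, reference_label, endpoint_label, omitted)


def csp_from_series(series: TitrationSeries, config: CSPConfig | None = None) -> CSPProfile:
    """CSP of the final (highest-ratio) point against the apo point."""
    last = series.points[-1]
    return combined_csp(
        series.apo.peaks,
        last.peaks,
        config,
        reference_label="apo",
        endpoint_label=f"ratio {last.ratio:g}",
    )


@dataclass
class Trajectory:
    """One residue's titration path in the alpha-scaled amide plane."""

    residue: int
    ratios: list[float]
    h_ppm: list[float]
    n_ppm: list[float]
    max_perpendicular: float  # ppm, 1H scale
    flagged: bool


def peak_trajectories(
    series: TitrationSeries,
    config: CSPConfig | None = None,
    noise_estimate: float | None = None,
    flag_factor: float = 3.0,
) -> tuple[dict[int, Trajectory], list[int]]:
    """Per-residue trajectories with a collinearity diagnostic.

    Each residue's points (h, alpha*n) get a total-least-squares line
    (principal axis through the centroid); the statistic is the largest
    perpendicular distance to it.  A residue is flagged when the
    statistic exceeds ``flag_factor`` times the noise estimate
    (default noise: 0.004 ppm on the 1H scale, a typical peak-position
    uncertainty).  Residues with < 2 points are excluded and returned
    in the second element.
    """
    config = config or CSPConfig()
    noise = 0.004 if noise_estimate is None else noise_estimate
    tol = flag_factor * noise
    trajectories: dict[int, Trajectory] = {}
    excluded: list[int] = []
    for r in series.residues():
        ratios, hs, ns = [], [], []
        for pt in series.points:
            pk = pt.peak_map().get(r)
            if pk is not None:
                ratios.append(pt.ratio)
                hs.append(pk.h_ppm)
                ns.append(pk.n_ppm)
        if len(ratios) < 2:
            excluded.append(r)
            continue
        xy = np.column_stack([hs, np.asarray(ns) * config.alpha_n])
        centred = xy - xy.mean(axis=0)
        # principal axis via SVD; perpendicular distances are the
        # projections onto the minor axis
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        if len(ratios) == 2 or s[0] == 0:
            stat = 0.0
        else:
            perp = centred @ vt[1]
            stat = float(np.max(np.abs(perp)))
        trajectories[r] = Trajectory(r, ratios, hs, ns, stat, stat > tol)
    return trajectories, excluded


def call_hotspots(
    profile: CSPProfile,
    method: str = "ksd",
    k: float = 1.0,
    q: float = 0.9,
) -> HotspotCall:
    """Call interface hotspots from a CSP profile.

    ``method="ksd"``: threshold = mean + k*SD of all CSPs (population
    SD over the profile); ``method="quantile"``: threshold = the q-th
    quantile.  Residues strictly above the threshold are returned.
    """
    if not profile.values:
        raise DataError("empty CSP profile")
    vals = np.asarray(list(profile.values.values()), float)
    if method == "ksd":
        if len(vals) < 2:
            raise DataError("ksd hotspot method needs >= 2 residues (SD undefined)")
        threshold = float(vals.mean() + k * vals.std(ddof=0))
        descriptor = f"mean+{k:g}*SD"
    elif method == "quantile":
        if not 0 < q < 1:
            raise DataError("quantile q must be in (0, 1)")
        threshold = float(np.quantile(vals, q))
        descriptor = f"quantile q={q:g}"
    else:
        raise DataError(f"unknown hotspot method {method!r}")
    hot = frozenset(r for r, v in profile.values.items() if v > threshold)
    return HotspotCall(hot, threshold, descriptor)
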