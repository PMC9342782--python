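"""Synthetic spread-nucleus generator with ground truth.

Emulates the statistical structure of three-color dSTORM spreads of
spermatocyte nuclei so that every analysis stage can be scored against
known truth without raw data:

* synaptonemal-complex axes as smooth random curves; synapsed axes as
  two lateral elements that cross with a fixed coil period (2.1 um in
  wild type, 1.0 um in the HORMAD1-knockout preset);
* DSB sites placed along the axes with ~900 nm spacing, each assigned a
  DxRy configuration from the observed mixture (D1R1 69%, D2R1 15%,
  D1R2 6%, remainder D2R2);
* nanofoci realized as 2-D Gaussian localization clusters with per-role
  geometry: a close D-R separation of ~45 nm, a close-far separation of
  ~300 nm with the far focus collinear beyond the single focus, and far
  foci markedly smaller than close foci;
* per-localization precision uniform in 10-25 nm, uniform background,
  and bright fiducial beads visible in every channel.

Per-nanofocus localization counts are negative-binomial
(over-dispersed blinking) with role-specific means chosen so that
nanofoci cross the fixed segmentation thresholds the way real foci do
(see the methods note); the knockout preset keeps 40% of sites and
shrinks foci by 15% in area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .axes import CENTERLINE, LATERAL, UNSYNAPSED, AxisPolyline, CoilRecord, midline
from .locio import Genotype, LocalizationTable, Stage
from .nanofoci import DMC1, RAD51
from .roidetect import ROI

__all__ = [
    "GeneratorParams",
    "TrueNanofocus",
    "TrueSite",
    "SyntheticGroundTruth",
    "simulate_axes",
    "simulate_nucleus",
    "simulate_dataset",
]

SYCP3 = "SYCP3"

WT_STAGES = [Stage.leptotene, Stage.early_zygotene, Stage.mid_zygotene,
             Stage.late_zygotene, Stage.early_pachytene]
KO_STAGES = [Stage.leptotene_like, Stage.zygotene_like, Stage.early_pachytene_like]
#: synapsed-axis fraction by stage (loose morphology-based progression)
_SYNAPSIS_BY_STAGE = {
    Stage.leptotene: 0.0, Stage.early_zygotene: 0.25, Stage.mid_zygotene: 0.5,
    Stage.late_zygotene: 0.75, Stage.early_pachytene: 1.0,
    Stage.leptotene_like: 0.0, Stage.zygotene_like: 0.0,
    Stage.early_pachytene_like: 0.25, Stage.unknown: 0.5,
}


@dataclass
class GeneratorParams:
    """All tunable knobs of the nucleus generator (lengths in nm unless
    suffixed otherwise)."""

    n_axes: int = 12
    axis_length_range_um: tuple[float, float] = (7.0, 11.0)
    axis_step_nm: float = 150.0
    axis_heading_sd: float = 0.05  # radians per step; gentle curvature
    field_um: float = 25.0
    coil_spacing_um: float = 2.1
    lateral_half_sep_nm: float = 100.0
    axis_loc_per_nm: float = 1.5
    axis_width_nm: float = 30.0
    axis_double_ridge: bool = False
    ridge_offset_nm: float = 60.0

    roi_spacing_nm: tuple[float, float] = (900.0, 150.0)  # mean, sd
    min_site_sep_nm: float = 750.0  # across-axis exclusion (spread overlap)
    site_retention: float = 1.0  # knockout preset thins sites
    configuration_mixture: dict = field(
        default_factory=lambda: {"D1R1": 0.69, "D2R1": 0.15, "D1R2": 0.06, "D2R2": 0.10}
    )
    dr_sep_nm: tuple[float, float] = (45.0, 8.0)  # close D-R separation
    close_far_sep_nm: tuple[float, float] = (300.0, 40.0)
    site_normal_offset_sd_nm: float = 20.0  # RAD51 rides the axis; DMC1 hangs off it
    site_tangent_jitter_sd_nm: float = 60.0
    collinear_jitter_deg: float = 12.0

    cluster_sigma_close_nm: float = 45.0
    cluster_sigma_far_nm: float = 20.0
    count_mean_close: float = 8000.0
    count_mean_far: float = 1800.0
    count_dispersion: float = 50.0
    precision_range_nm: tuple[float, float] = (10.0, 25.0)

    background_per_um2: float = 20.0
    n_fiducials: int = 4
    fiducial_locs_per_channel: int = 25_000
    fiducial_sigma_nm: float = 70.0

    genotype: Genotype = Genotype.wild_type
    channels: tuple[str, str, str] = (SYCP3, RAD51, DMC1)

    def __post_init__(self) -> None:
        probs = np.array(list(self.configuration_mixture.values()), float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("configuration mixture must sum to 1")
        if probs.min() < 0:
            raise ValueError("mixture probabilities must be non-negative")

    @classmethod
    def preset(cls, genotype: str | Genotype) -> "GeneratorParams":
        """Genotype presets: the knockout has ~40% of wild-type sites,
        15% smaller foci and a 1.0 um coil period."""
        genotype = Genotype(genotype)
        if genotype == Genotype.wild_type:
            return cls(genotype=genotype)
        if genotype == Genotype.hormad1_ko:
            return cls(
                genotype=genotype,
                site_retention=0.4,
                coil_spacing_um=1.0,
                cluster_sigma_close_nm=45.0 * np.sqrt(0.85),
                cluster_sigma_far_nm=20.0 * np.sqrt(0.85),
                count_mean_close=8000.0 * 0.85,
                count_mean_far=1800.0 * 0.85,
            )
        raise ValueError(f"no preset for genotype {genotype}")


@dataclass
class TrueNanofocus:
    channel: str
    role: str  # single / close / far
    center: np.ndarray
    sigma: float
    n_localizations: int


@dataclass
class TrueSite:
    site_id: str
    label: str
    fragment_id: str
    arc_nm: float
    nanofoci: list[TrueNanofocus]

    @property
    def center(self) -> np.ndarray:
        """Localization-weighted mean of nanofocus centers (the coordinate
        the detected density peak is expected near)."""
        w = np.array([nf.n_localizations for nf in self.nanofoci], float)
        c = np.array([nf.center for nf in self.nanofoci])
        return (c * w[:, None]).sum(axis=0) / w.sum()

    def roi(self, diameter: float = 750.0, nucleus_id: str = "") -> ROI:
        x, y = self.center
        return ROI(self.site_id, nucleus_id, (float(x), float(y)), diameter)


@dataclass
class SyntheticGroundTruth:
    nucleus_id: str
    sites: list[TrueSite]
    polylines: list[AxisPolyline]
    centerlines: list[AxisPolyline]
    coil_records: list[CoilRecord]
    fiducials: np.ndarray  # (n, 2)
    seed: int
    stage: Stage

    @property
    def site_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.sites]).reshape(-1, 2)


# ---------------------------------------------------------------------------
# axes


def _random_curve(rng: np.random.Generator, length_nm: float, p: GeneratorParams) -> np.ndarray:
    field_nm = p.field_um * 1000.0
    margin = 1500.0
    pos = rng.uniform(margin, field_nm - margin, 2)
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = max(2, int(round(length_nm / p.axis_step_nm)))
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, p.axis_heading_sd)
        step = p.axis_step_nm * np.array([np.cos(heading), np.sin(heading)])
        nxt = pts[-1] + step
        # steer back toward the field when drifting out
        for k in range(2):
            if nxt[k] < margin or nxt[k] > field_nm - margin:
                center = field_nm / 2
                heading = np.arctan2(center - pts[-1][1], center - pts[-1][0])
                heading += rng.normal(0.0, 0.3)
                nxt = pts[-1] + p.axis_step_nm * np.array([np.cos(heading), np.sin(heading)])
                break
        pts.append(nxt)
    return np.asarray(pts)


def _resample_arc(pts: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    seg = np.diff(pts, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    arcs = np.linspace(0, s[-1], n)
    x = np.interp(arcs, s, pts[:, 0])
    y = np.interp(arcs, s, pts[:, 1])
    return np.column_stack([x, y]), arcs


def simulate_axes(
    params: GeneratorParams,
    seed: int | np.random.Generator = 0,
    nucleus_id: str = "nucleus",
    stage: Stage = Stage.unknown,
) -> tuple[list[AxisPolyline], list[AxisPolyline], list[CoilRecord]]:
    """Generate the nucleus's axis scaffold.

    Returns (polylines as drawn: laterals + axials, site-carrying
    centerlines, per-synapsed-axis coil records). A synapsed axis is a
    centerline plus two laterals offset +/- ``lateral_half_sep * sin(pi
    s / coil_spacing)`` along the normal, so the laterals cross every
    coil period; its length snaps to a whole number of periods, making
    the true spacing exactly the coil period.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    syn_frac = _SYNAPSIS_BY_STAGE[stage]
    c_nm = params.coil_spacing_um * 1000.0
    drawn: list[AxisPolyline] = []
    centerlines: list[AxisPolyline] = []
    coils: list[CoilRecord] = []
    for i in range(params.n_axes):
        length = rng.uniform(*params.axis_length_range_um) * 1000.0
        synapsed = rng.random() < syn_frac
        if synapsed:
            # snap to an integer number of coil periods
            n_periods = max(2, int(round(length / c_nm)))
            length = n_periods * c_nm
        raw = _random_curve(rng, length, params)
        n_samp = max(2, int(round(length / 50.0)))
        pts, arcs = _resample_arc(raw, n_samp)
        if synapsed:
            center = AxisPolyline(f"axis_{i}", nucleus_id, pts, CENTERLINE, pair_id=f"pair_{i}")
            tang = np.gradient(pts, axis=0)
            tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            off = params.lateral_half_sep_nm * np.sin(np.pi * arcs / c_nm)[:, None] * normal
            for side, tag in ((off, "a"), (-off, "b")):
                lat_pts = pts + side
                keep = np.concatenate(
                    [[True], np.hypot(*np.diff(lat_pts, axis=0).T) > 1e-6]
                )
                drawn.append(
                    AxisPolyline(
                        f"axis_{i}{tag}", nucleus_id, lat_pts[keep], LATERAL,
                        pair_id=f"pair_{i}",
                    )
                )
            centerlines.append(center)
            n_twists = n_periods - 1  # interior lateral crossings
            coils.append(CoilRecord(nucleus_id, length / 1000.0, n_twists))
        else:
            ax = AxisPolyline(f"axis_{i}", nucleus_id, pts, UNSYNAPSED)
            drawn.append(ax)
            centerlines.append(ax)
    return drawn, centerlines, coils


# ---------------------------------------------------------------------------
# sites and localizations


def _negbin(rng: np.random.Generator, mean: float, r: float) -> int:
    return int(rng.negative_binomial(r, r / (r + mean))) or 1


def _site_nanofoci(
    rng: np.random.Generator, label: str, anchor: np.ndarray, tangent: np.ndarray,
    p: GeneratorParams,
) -> list[TrueNanofocus]:
    normal = np.array([-tangent[1], tangent[0]])
    base = (
        anchor
        + rng.normal(0, p.site_normal_offset_sd_nm) * normal
        + rng.normal(0, p.site_tangent_jitter_sd_nm) * tangent
    )

    def unit(angle: float) -> np.ndarray:
        return np.array([np.cos(angle), np.sin(angle)])

    def close_nf(channel: str, center: np.ndarray, role: str = "single") -> TrueNanofocus:
        return TrueNanofocus(
            channel, role, center, p.cluster_sigma_close_nm,
            _negbin(rng, p.count_mean_close, p.count_dispersion),
        )

    def far_nf(channel: str, center: np.ndarray) -> TrueNanofocus:
        return TrueNanofocus(
            channel, "far", center, p.cluster_sigma_far_nm,
            _negbin(rng, p.count_mean_far, p.count_dispersion),
        )

    dr = rng.normal(*p.dr_sep_nm)
    theta = rng.uniform(0, 2 * np.pi)
    jit = np.radians(p.collinear_jitter_deg)
    if label == "D1R1":
        r_c = base
        d_c = base + dr * unit(theta)
        return [close_nf(RAD51, r_c), close_nf(DMC1, d_c)]
    if label == "D2R1":
        # dumbbell: close D near R, far D collinear beyond R
        r_c = base
        d_close = base + dr * unit(theta)
        sep = rng.normal(*p.close_far_sep_nm)
        d_far = d_close + sep * unit(theta + np.pi + rng.normal(0, jit))
        return [close_nf(RAD51, r_c), close_nf(DMC1, d_close, "close"), far_nf(DMC1, d_far)]
    if label == "D1R2":
        d_c = base
        r_close = base + dr * unit(theta)
        sep = rng.normal(*p.close_far_sep_nm)
        r_far = r_close + sep * unit(theta + np.pi + rng.normal(0, 2.5 * jit))
        return [close_nf(DMC1, d_c), close_nf(RAD51, r_close, "close"), far_nf(RAD51, r_far)]
    if label == "D2R2":
        r_c = base
        d_c = base + dr * unit(theta)
        sep = rng.normal(*p.close_far_sep_nm)
        shift = sep * unit(theta + np.pi + rng.normal(0, jit))
        return [
            close_nf(RAD51, r_c, "close"), close_nf(DMC1, d_c, "close"),
            far_nf(RAD51, r_c + shift), far_nf(DMC1, d_c + shift),
        ]
    raise ValueError(f"unknown configuration label {label!r}")


def simulate_nucleus(
    params: GeneratorParams,
    seed: int = 0,
    nucleus_id: str = "sim_0",
    stage: Stage | None = None,
    emit_localizations: bool = True,
) -> tuple[LocalizationTable, SyntheticGroundTruth]:
    """Simulate one spread nucleus end to end.

    Emits SYCP3 (axis), RAD51 and DMC1 localizations for every DSB site,
    plus axis, background and fiducial localizations, into a single
    table whose ``source`` column traces each row to its origin. With
    ``emit_localizations=False`` only the ground truth (sites, axes,
    coils, bead positions) is built - the same truth the full run would
    produce for this seed - and the table is empty.
    """
    rng = np.random.default_rng(seed)
    if stage is None:
        pool = KO_STAGES if params.genotype == Genotype.hormad1_ko else WT_STAGES
        stage = pool[int(rng.integers(len(pool)))]
    drawn, centerlines, coils = simulate_axes(params, rng, nucleus_id, stage)

    # ROI sites along the centerlines
    labels = list(params.configuration_mixture)
    probs = np.array([params.configuration_mixture[k] for k in labels])
    sites: list[TrueSite] = []
    anchors: list[np.ndarray] = []
    mean_sp, sd_sp = params.roi_spacing_nm
    for line in centerlines:
        arc = rng.uniform(300.0, mean_sp)
        while arc < line.length - 300.0:
            if rng.random() < params.site_retention:
                anchor = line.point_at(arc)
                # drop sites that would overlap a site on another axis
                # (on real spreads such regions are not analyzable)
                clear = all(
                    np.hypot(*(anchor - a)) >= params.min_site_sep_nm for a in anchors
                )
                if clear:
                    tangent = line.tangent_at(arc)
                    label = labels[int(rng.choice(len(labels), p=probs))]
                    nfs = _site_nanofoci(rng, label, anchor, tangent, params)
                    sites.append(
                        TrueSite(f"site_{len(sites)}", label, line.fragment_id, arc, nfs)
                    )
                    anchors.append(anchor)
            arc += max(200.0, rng.normal(mean_sp, sd_sp))

    field_nm_ = params.field_um * 1000.0
    beads_early = rng.uniform(1000.0, field_nm_ - 1000.0, (params.n_fiducials, 2))
    if not emit_localizations:
        df = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in
             [("channel", str), ("frame", int), ("x_nm", float),
              ("y_nm", float), ("precision_nm", float), ("source", str)]}
        )
        table = LocalizationTable(nucleus_id, df, genotype=params.genotype, stage=stage)
        truth = SyntheticGroundTruth(
            nucleus_id, sites, drawn, centerlines, coils, beads_early, seed, stage
        )
        return table, truth

    rows_xy: list[np.ndarray] = []
    rows_meta: list[tuple[str, str]] = []  # (channel, source)

    def emit(channel: str, xy: np.ndarray, source: str) -> None:
        if len(xy):
            rows_xy.append(xy)
            rows_meta.append((channel, source))

    lo_p, hi_p = params.precision_range_nm
    # recombinase nanofoci
    for site in sites:
        for nf in site.nanofoci:
            n = nf.n_localizations
            binding = nf.center + rng.normal(0, nf.sigma, (n, 2))
            emit(nf.channel, binding, f"site:{site.site_id}")

    # axis channel: localizations along each drawn polyline
    for line in drawn:
        n = max(2, int(round(line.length * params.axis_loc_per_nm)))
        arcs = rng.uniform(0, line.length, n)
        pts = line.point_at(arcs)
        tang = np.array([line.tangent_at(float(a)) for a in np.linspace(0, line.length, 64)])
        # approximate per-point normals by interpolating coarse tangents
        idx = np.minimum((arcs / line.length * 63).astype(int), 63)
        nrm = np.column_stack([-tang[idx, 1], tang[idx, 0]])
        offset = rng.normal(0, params.axis_width_nm, n)
        if params.axis_double_ridge:
            offset = offset + rng.choice([-1.0, 1.0], n) * params.ridge_offset_nm
        emit(SYCP3, pts + offset[:, None] * nrm, f"axis:{line.fragment_id}")

    # background + fiducials
    field_nm = field_nm_
    area_um2 = params.field_um**2
    beads = beads_early
    for channel in params.channels:
        n_bg = rng.poisson(params.background_per_um2 * area_um2)
        emit(channel, rng.uniform(0, field_nm, (n_bg, 2)), "background")
        for b, bead in enumerate(beads):
            pos = bead + rng.normal(0, params.fiducial_sigma_nm,
                                    (params.fiducial_locs_per_channel, 2))
            emit(channel, pos, f"fiducial:{b}")

    n_total = sum(len(a) for a in rows_xy)
    xy_all = np.vstack(rows_xy) if rows_xy else np.zeros((0, 2))
    channel_col = np.concatenate(
        [np.full(len(a), m[0]) for a, m in zip(rows_xy, rows_meta)]
    ) if rows_xy else np.array([], str)
    source_col = np.concatenate(
        [np.full(len(a), m[1]) for a, m in zip(rows_xy, rows_meta)]
    ) if rows_xy else np.array([], str)
    precision = rng.uniform(lo_p, hi_p, n_total)
    noisy = xy_all + rng.normal(0, 1.0, xy_all.shape) * precision[:, None]
    df = pd.DataFrame(
        {
            "channel": pd.Categorical(channel_col),
            "frame": rng.integers(0, 12_000, n_total),
            "x_nm": noisy[:, 0],
            "y_nm": noisy[:, 1],
            "precision_nm": precision,
            "source": pd.Categorical(source_col),
        }
    ).sort_values(["channel", "frame"], kind="stable").reset_index(drop=True)

    table = LocalizationTable(nucleus_id, df, genotype=params.genotype, stage=stage)
    truth = SyntheticGroundTruth(
        nucleus_id, sites, drawn, centerlines, coils, beads, seed, stage
    )
    return table, truth


def simulate_dataset(
    params: GeneratorParams,
    n_nuclei: int,
    seed: int = 0,
    stages: Sequence[Stage] | None = None,
) -> list[tuple[LocalizationTable, SyntheticGroundTruth]]:
    """Simulate a cohort of nuclei with per-nucleus sub-seeds derived from
    ``seed`` (reproducible, independent streams)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_nuclei)]
    out = []
    for i, s in enumerate(child_seeds):
        stage = stages[i % len(stages)] if stages else None
        out.append(simulate_nucleus(params, s, f"sim_{i}", stage))
    return out
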