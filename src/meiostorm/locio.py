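"""Localization-table data model and I/O.

A dSTORM acquisition yields one row per accepted blink event: the fitted
fluorophore position (nm), the acquisition frame it appeared in, the fit
uncertainty ("precision", nm) and the channel (protein) it belongs to.
This module reads/writes such tables, merges repeated blinks of a single
fluorophore (grouping), and registers channels onto a common coordinate
frame using fiducial beads.

Coordinate convention (shared by all modules): nm units, origin at the
image top-left, y increasing downward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Stage",
    "LocalizationTable",
    "FiducialSet",
    "ChannelTransform",
    "FormatError",
    "AlignmentError",
    "read_localizations",
    "write_localizations",
    "group_blinks",
    "align_channels",
    "drift_correct",
]

#: Canonical column order of the normalized table.
COLUMNS = ["channel", "frame", "x_nm", "y_nm", "precision_nm"]
OPTIONAL_COLUMNS = ["z_nm", "photons"]

#: ThunderSTORM CSV export column names.
THUNDERSTORM_COLUMNS = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "z [nm]": "z_nm",
    "uncertainty [nm]": "precision_nm",
    "intensity [photon]": "photons",
}


class Genotype(str, enum.Enum):
    wild_type = "wild_type"
    hormad1_ko = "hormad1_ko"
    other = "other"


class Stage(str, enum.Enum):
    leptotene = "leptotene"
    early_zygotene = "early_zygotene"
    mid_zygotene = "mid_zygotene"
    late_zygotene = "late_zygotene"
    early_pachytene = "early_pachytene"
    leptotene_like = "leptotene_like"
    zygotene_like = "zygotene_like"
    early_pachytene_like = "early_pachytene_like"
    unknown = "unknown"

    @property
    def is_leptotene(self) -> bool:
        return self in (Stage.leptotene, Stage.leptotene_like)


class FormatError(ValueError):
    """Input file does not conform to the declared dialect."""


class AlignmentError(ValueError):
    """Channel registration could not be estimated."""


@dataclass
class LocalizationTable:
    """Per-nucleus point cloud of blink events.

    ``data`` is a DataFrame with columns ``channel, frame, x_nm, y_nm,
    precision_nm`` (plus optional ``z_nm``/``photons``). Invariants
    (precision > 0, frame >= 0, finite coordinates) are checked at
    construction.
    """

    nucleus_id: str
    data: pd.DataFrame
    genotype: Genotype = Genotype.other
    stage: Stage = Stage.unknown

    def __post_init__(self) -> None:
        if isinstance(self.genotype, str):
            self.genotype = Genotype(self.genotype)
        if isinstance(self.stage, str):
            self.stage = Stage(self.stage)
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing column(s): {missing}")
        df = self.data
        if len(df):
            bad = df.index[~(df["precision_nm"] > 0)]
            if len(bad):
                raise FormatError(
                    f"non-positive precision at row(s) {list(bad[:5])}"
                )
            bad = df.index[df["frame"] < 0]
            if len(bad):
                raise FormatError(f"negative frame at row(s) {list(bad[:5])}")
            xy = df[["x_nm", "y_nm"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                rows = df.index[~np.isfinite(xy).all(axis=1)]
                raise FormatError(
                    f"non-finite coordinate at row(s) {list(rows[:5])}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].unique())

    def channel_data(self, channel: str) -> pd.DataFrame:
        return self.data[self.data["channel"] == channel]

    def xy(self, channel: str | None = None) -> np.ndarray:
        df = self.data if channel is None else self.channel_data(channel)
        return df[["x_nm", "y_nm"]].to_numpy(float)

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        return replace(self, data=self.data[mask].reset_index(drop=True))


@dataclass
class FiducialSet:
    """Per-channel fiducial-bead centroids (nm), used for registration."""

    beads: Mapping[str, np.ndarray]  # channel -> (n, 2) array

    def __post_init__(self) -> None:
        self.beads = {k: np.asarray(v, float).reshape(-1, 2) for k, v in self.beads.items()}


@dataclass
class ChannelTransform:
    """Affine map x -> A x + t taking one channel onto the base channel."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rms: float
    n_beads: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, float) @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(np.eye(2), np.zeros(2), 0.0, 0)


# ---------------------------------------------------------------------------
# I/O


def read_localizations(
    path: str | Path,
    dialect: str = "generic_csv",
    *,
    nucleus_id: str | None = None,
    channel: str | None = None,
    genotype: Genotype | str = Genotype.other,
    stage: Stage | str = Stage.unknown,
    column_map: Mapping[str, str] | None = None,
    unit_factors: Mapping[str, float] | None = None,
) -> LocalizationTable:
    """Read a delimited localization file into a :class:`LocalizationTable`.

    ``generic_csv`` expects the normalized header (``nucleus_id, channel,
    frame, x_nm, y_nm, precision_nm``, extra columns kept); a custom
    ``column_map`` (raw name -> normalized name) with per-column
    ``unit_factors`` may be supplied for other generic exports.
    ``thunderstorm_csv`` reads the ThunderSTORM export dialect; because
    that format carries no channel column, ``channel`` must be given (or
    is taken from the file stem).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if dialect == "thunderstorm_csv":
        mapping = dict(THUNDERSTORM_COLUMNS)
        for col in ("frame", "x [nm]", "y [nm]", "uncertainty [nm]"):
            if col not in raw.columns:
                raise FormatError(f"thunderstorm_csv: missing column {col!r}")
        df = raw.rename(columns=mapping)
        df = df[[c for c in df.columns if c in COLUMNS + OPTIONAL_COLUMNS]]
        df["channel"] = channel if channel is not None else path.stem
    elif dialect == "generic_csv":
        df = raw.rename(columns=dict(column_map or {}))
        if unit_factors:
            for col, factor in unit_factors.items():
                if col in df.columns:
                    df[col] = df[col] * factor
        if "channel" not in df.columns:
            if channel is None:
                raise FormatError("generic_csv: missing column 'channel'")
            df["channel"] = channel
        for col in ("frame", "x_nm", "y_nm", "precision_nm"):
            if col not in df.columns:
                raise FormatError(f"generic_csv: missing column {col!r}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if nucleus_id is None:
        nucleus_id = (
            str(df["nucleus_id"].iloc[0]) if "nucleus_id" in df.columns and len(df) else path.stem
        )
    df = df.drop(columns=[c for c in ("nucleus_id",) if c in df.columns])

    for col in ("frame", "x_nm", "y_nm", "precision_nm"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric value in column {col!r} at row(s) {list(rows[:5])}"
            ) from exc
    if len(df):
        bad = df.index[~(df["precision_nm"] > 0)]
        if len(bad):
            raise FormatError(f"precision <= 0 at row(s) {list(bad[:5])}")
    keep = COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].reset_index(drop=True)
    return LocalizationTable(nucleus_id, df, genotype=genotype, stage=stage)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write the normalized CSV (fixed header, nucleus_id first)."""
    df = table.data.copy()
    df.insert(0, "nucleus_id", table.nucleus_id)
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Blink grouping


def group_blinks(
    table: LocalizationTable,
    max_on: int = 50,
    off_gap: int = 2,
    capture_radius: float = 400.0,
) -> LocalizationTable:
    """Merge runs of blinks from one fluorophore into single localizations.

    Consecutive localizations of the same channel within ``capture_radius``
    (nm) of an open group's running mean, separated by at most ``off_gap``
    dark frames, and spanning at most ``max_on`` frames in total, are
    replaced by one localization at their inverse-variance weighted mean
    with combined precision ``(sum sigma_i^-2)^-1/2`` and the first frame.
    A localization joins the earliest open group it satisfies. Photon
    counts, when present, are summed.
    """
    if max_on < 0 or off_gap < 0 or capture_radius < 0:
        raise ValueError("grouping parameters must be non-negative")
    has_photons = "photons" in table.data.columns
    out_rows: list[tuple] = []
    for channel, df in table.data.groupby("channel", sort=False):
        df = df.sort_values("frame", kind="stable")
        frames = df["frame"].to_numpy(int)
        xy = df[["x_nm", "y_nm"]].to_numpy(float)
        prec = df["precision_nm"].to_numpy(float)
        photons = df["photons"].to_numpy(float) if has_photons else None
        # open groups: [first_frame, last_frame, sum_w, sum_wx, sum_wy, photons]
        open_groups: list[list] = []
        closed: list[list] = []
        for i in range(len(df)):
            f = frames[i]
            w = prec[i] ** -2
            still_open = []
            for g in open_groups:
                if f - g[1] - 1 > off_gap:
                    closed.append(g)
                else:
                    still_open.append(g)
            open_groups = still_open
            joined = False
            for g in open_groups:
                mean = np.array([g[3], g[4]]) / g[2]
                if (
                    f - g[0] + 1 <= max_on
                    and np.hypot(*(xy[i] - mean)) <= capture_radius
                ):
                    g[1] = f
                    g[2] += w
                    g[3] += w * xy[i, 0]
                    g[4] += w * xy[i, 1]
                    if photons is not None:
                        g[5] += photons[i]
                    joined = True
                    break
            if not joined:
                open_groups.append(
                    [f, f, w, w * xy[i, 0], w * xy[i, 1],
                     photons[i] if photons is not None else 0.0]
                )
        closed.extend(open_groups)
        for g in closed:
            row = [channel, g[0], g[3] / g[2], g[4] / g[2], g[2] ** -0.5]
            if has_photons:
                row.append(g[5])
            out_rows.append(tuple(row))
    cols = COLUMNS + (["photons"] if has_photons else [])
    out = pd.DataFrame(out_rows, columns=cols)
    out = out.sort_values(["channel", "frame"], kind="stable").reset_index(drop=True)
    return replace(table, data=out)


# ---------------------------------------------------------------------------
# Channel alignment


def _match_beads(
    base: np.ndarray, other: np.ndarray, match_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pair beads across channels by mutual proximity; unmatched dropped."""
    from scipy.spatial import cKDTree

    tree = cKDTree(base)
    dist, idx = tree.query(other, distance_upper_bound=match_radius)
    ok = np.isfinite(dist)
    return base[idx[ok]], other[ok]


def estimate_transform(
    base_beads: np.ndarray,
    other_beads: np.ndarray,
    model: str = "translation",
    match_radius: float = 500.0,
) -> ChannelTransform:
    """Least-squares map superimposing ``other_beads`` onto ``base_beads``."""
    b, o = _match_beads(np.asarray(base_beads, float), np.asarray(other_beads, float), match_radius)
    if model == "translation":
        if len(b) < 2:
            raise AlignmentError(f"translation model needs >= 2 matched beads, got {len(b)}")
        t = (b - o).mean(axis=0)
        A = np.eye(2)
    elif model == "affine":
        if len(b) < 3:
            raise AlignmentError(f"affine model needs >= 3 matched beads, got {len(b)}")
        X = np.hstack([o, np.ones((len(o), 1))])
        coef, *_ = np.linalg.lstsq(X, b, rcond=None)
        A = coef[:2].T
        t = coef[2]
    else:
        raise ValueError(f"unknown model {model!r}")
    resid = o @ A.T + t - b
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return ChannelTransform(A, np.asarray(t, float), rms, len(b))


def align_channels(
    tables: Mapping[str, LocalizationTable],
    fiducials: FiducialSet,
    base_channel: str,
    model: str = "translation",
    match_radius: float = 500.0,
) -> tuple[dict[str, LocalizationTable], dict[str, ChannelTransform]]:
    """Register every channel onto ``base_channel`` using fiducial beads.

    Returns the transformed tables (base unchanged) and the per-channel
    transforms with bead-residual RMS.
    """
    if base_channel not in fiducials.beads:
        raise AlignmentError(f"no fiducials for base channel {base_channel!r}")
    base = fiducials.beads[base_channel]
    out_tables: dict[str, LocalizationTable] = {}
    transforms: dict[str, ChannelTransform] = {}
    for channel, table in tables.items():
        if channel == base_channel:
            out_tables[channel] = table
            transforms[channel] = ChannelTransform.identity()
            continue
        if channel not in fiducials.beads:
            raise AlignmentError(f"no fiducials for channel {channel!r}")
        tf = estimate_transform(base, fiducials.beads[channel], model, match_radius)
        new_xy = tf.apply(table.xy())
        df = table.data.copy()
        df[["x_nm", "y_nm"]] = new_xy
        out_tables[channel] = replace(table, data=df)
        transforms[channel] = tf
    return out_tables, transforms


def drift_correct(table: LocalizationTable) -> LocalizationTable:
    """Identity pass-through: drift correction is applied upstream by the
    acquisition software; this hook exists so pipelines can declare the step."""
    return table
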