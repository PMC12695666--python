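"""Readers/writers for interchange formats, region configs and seed plumbing.

All interchange is plain delimited text: BED6 for CTCF sites, one TSV per
distance time series plus a manifest, TSVs for intervals, aligned curves and
deviation surfaces.  Coordinates are 0-based half-open at every boundary.
Floats are written with 17 significant digits so write-read round-trips are
bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .extrusion import CTCFSite, build_ctcf_landscape
from .synth import DistanceTimeSeries

__all__ = [
    "RegionConfig",
    "read_ctcf_bed",
    "write_series_set",
    "read_series_set",
    "write_intervals",
    "write_surface",
    "stage_seeds",
]

_SERIES_COLS = [
    "time_s", "x1", "y1", "z1", "x2", "y2", "z2",
    "sigma1_nm", "sigma2_nm", "distance_nm", "sigma_d_nm", "valid",
]


@dataclass
class RegionConfig:
    """One labeled genomic region: anchors, reporters, CTCF site file."""

    label: str
    chromosome: str
    start: int
    end: int
    anchor_a: int
    anchor_b: int
    reporter_a: int
    reporter_b: int
    ctcf_bed: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.anchor_a < self.anchor_b < self.end:
            raise ValueError("require start < anchor_a < anchor_b < end")

    @property
    def separation(self) -> int:
        return self.anchor_b - self.anchor_a

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_yaml(cls, path: str) -> "RegionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def load_sites(self, genomewide_residence: float = 2.5,
                   occupancy_target: float = 0.5) -> list[CTCFSite]:
        """CTCF landscape in region-local coordinates (bp from ``start``)."""
        if self.ctcf_bed is None:
            return []
        peaks = read_ctcf_bed(self.ctcf_bed)
        local = [(p - self.start, o, s) for p, o, s in peaks if self.start <= p < self.end]
        return build_ctcf_landscape(local, genomewide_residence, occupancy_target)


def read_ctcf_bed(path: str) -> list[tuple[int, str, float]]:
    """Parse BED6 into (midpoint bp, orientation, strength) peaks.

    0-based half-open intervals; the score column is the peak strength and
    the strand column the motif orientation ('.' is rejected because an
    orientation is required for blocking).
    """
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                score = float(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed numeric field") from exc
            strand = parts[5]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{ln}: strand '{strand}' invalid; orientation is required"
                )
            peaks.append(((start + end) // 2, strand, score))
    return peaks


def write_series_set(directory: str, series_set: list[DistanceTimeSeries]) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for i, s in enumerate(series_set):
        name = f"series_{i:05d}.tsv"
        n = len(s.times)
        nan3 = np.full((n, 3), np.nan)
        df = pd.DataFrame(
            {
                "time_s": s.times,
                "x1": (s.spots1 if s.spots1 is not None else nan3)[:, 0],
                "y1": (s.spots1 if s.spots1 is not None else nan3)[:, 1],
                "z1": (s.spots1 if s.spots1 is not None else nan3)[:, 2],
                "x2": (s.spots2 if s.spots2 is not None else nan3)[:, 0],
                "y2": (s.spots2 if s.spots2 is not None else nan3)[:, 1],
                "z2": (s.spots2 if s.spots2 is not None else nan3)[:, 2],
                "sigma1_nm": s.sigma1 if s.sigma1 is not None else np.full(n, np.nan),
                "sigma2_nm": s.sigma2 if s.sigma2 is not None else np.full(n, np.nan),
                "distance_nm": s.distance,
                "sigma_d_nm": s.sigma_d,
                "valid": s.valid.astype(int),
            }
        )
        df.to_csv(os.path.join(directory, name), sep="\t", index=False,
                  float_format="%.17g")
        manifest.append(
            {"file": name, "region": s.region, "condition": s.condition, "seed": s.seed}
        )
    pd.DataFrame(manifest).to_csv(
        os.path.join(directory, "manifest.tsv"), sep="\t", index=False
    )


def read_series_set(directory: str) -> list[DistanceTimeSeries]:
    """Read a series directory written by :func:`write_series_set`.

    NaN-distance rows are flagged invalid rather than dropped; a mixed-cadence
    manifest raises a comparability error.
    """
    man = pd.read_csv(os.path.join(directory, "manifest.tsv"), sep="\t")
    out = []
    cadences = set()
    for row in man.itertuples():
        df = pd.read_csv(os.path.join(directory, row.file), sep="\t",
                         float_precision="round_trip")
        missing = [c for c in _SERIES_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{row.file}: missing required columns {missing}")
        valid = df["valid"].to_numpy().astype(bool) & np.isfinite(
            df["distance_nm"].to_numpy()
        )
        s = DistanceTimeSeries(
            times=df["time_s"].to_numpy(float),
            distance=df["distance_nm"].to_numpy(float),
            sigma_d=df["sigma_d_nm"].to_numpy(float),
            valid=valid,
            condition=str(row.condition),
            region="" if pd.isna(row.region) else str(row.region),
            seed=int(row.seed),
            spots1=df[["x1", "y1", "z1"]].to_numpy(float),
            spots2=df[["x2", "y2", "z2"]].to_numpy(float),
            sigma1=df["sigma1_nm"].to_numpy(float),
            sigma2=df["sigma2_nm"].to_numpy(float),
        )
        cadences.add(round(s.frame_interval, 6))
        out.append(s)
    if len(cadences) > 1:
        import warnings

        warnings.warn(f"mixed cadences in manifest: {sorted(cadences)}", stacklevel=2)
    return out


def write_intervals(path: str, series_ids, intervals_set, frame_interval: float) -> None:
    rows = []
    for sid, ivs in zip(series_ids, intervals_set):
        for iv in ivs:
            rows.append(
                {
                    "series_id": sid,
                    "start_s": iv.start_frame * frame_interval,
                    "end_s": iv.end_frame * frame_interval,
                    "left_censored": int(iv.left_censored),
                    "right_censored": int(iv.right_censored),
                }
            )
    pd.DataFrame(rows, columns=["series_id", "start_s", "end_s",
                                "left_censored", "right_censored"]).to_csv(
        path, sep="\t", index=False
    )


def write_surface(path: str, surface) -> None:
    rows = []
    for i, rho in enumerate(surface.densities):
        for j, tau in enumerate(surface.residences):
            row = {
                "density_per_mb": rho,
                "residence_min": tau,
                "motor_speed_kb_s": surface.motor_speed,
                "score": surface.scores[i, j],
                "assessed": int(surface.assessed[i, j]),
            }
            for k, v in surface.sub_scores.items():
                row[f"sub_{k}"] = v[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def stage_seeds(master: int, stages: tuple[str, ...]) -> dict[str, int]:
    """Derive one child seed per named stage from a master seed.

    Children are spawned in the listed order from a single SeedSequence, so
    the mapping is a pure function of (master, stages) and reruns are
    bit-reproducible.
    """
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(stages))
    return {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(stages, children)
    }
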