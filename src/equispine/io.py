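"""Marker-trajectory container and on-disk dialects.

The package works internally in metres with z up; trajectory files store
coordinates in millimetres (motion-capture convention).  The unit boundary is
exactly this module.  Missing marker samples are explicit gaps (NaN rows) in
memory and empty cells in the TSV dialect.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

#: markers required by the full pipeline (head and spine chain plus the pelvic
#: T-strip); ``withers_left``/``withers_right`` are optional extras.
REQUIRED_MARKERS: tuple[str, ...] = (
    "head",
    "withers",
    "T12",
    "T15",
    "T18",
    "L3",
    "L5",
    "tuber_sacrale",
    "tuber_coxae_left",
    "tuber_coxae_right",
    "S5",
)

#: the cranio-caudal spine chain used for three-point angles, cranial first.
SPINE_CHAIN: tuple[str, ...] = (
    "withers",
    "T12",
    "T15",
    "T18",
    "L3",
    "L5",
    "tuber_sacrale",
    "S5",
)

_MM_PER_M = 1000.0


class IncompleteMarkerSetError(ValueError):
    """A required marker is absent from a trajectory file or set."""


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (inconsistent columns, bad header...)."""


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one measurement: horse, day, trial and path."""

    horse: str = "unknown"
    day: int = 1
    trial: int = 1
    path: str = "straight"  # straight | left | right
    radius: float | None = None  # circle radius [m], None on the straight

    @property
    def measurement_id(self) -> str:
        return f"{self.horse}-d{self.day}-t{self.trial}-{self.path}"


@dataclass
class MarkerTrajectorySet:
    """Per-marker 3-D position time series for one measurement.

    Parameters
    ----------
    positions
        Mapping from marker name to a float array of shape ``(n_frames, 3)``
        holding (x, y, z) in metres, z up.  Gap frames are all-NaN rows.
    rate
        Sampling frequency in Hz.
    meta
        Trial metadata.
    """

    positions: dict[str, np.ndarray]
    rate: float
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        counts = {v.shape[0] for v in self.positions.values()}
        if len(counts) > 1:
            raise ValueError(f"markers have differing frame counts: {sorted(counts)}")
        for k, v in self.positions.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"marker {k!r} must have shape (n, 3), got {v.shape}")

    @property
    def markers(self) -> list[str]:
        return list(self.positions)

    @property
    def n_frames(self) -> int:
        if not self.positions:
            return 0
        return next(iter(self.positions.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.positions[marker]

    def require(self, markers: Iterable[str] = REQUIRED_MARKERS) -> None:
        for m in markers:
            if m not in self.positions:
                raise IncompleteMarkerSetError(f"incomplete marker set: {m}")

    def gap_mask(self, marker: str) -> np.ndarray:
        """Boolean mask of gap (missing) frames for one marker."""
        return np.isnan(self.positions[marker]).any(axis=1)

    def interpolate_gaps(self, max_gap: int = 10) -> "MarkerTrajectorySet":
        """Linearly interpolate gaps of at most ``max_gap`` frames.

        Longer gaps in required markers make the trial unusable and raise
        ``ValueError``; gaps at the ends of the recording are never filled.
        """
        out: dict[str, np.ndarray] = {}
        for name, pos in self.positions.items():
            pos = pos.copy()
            bad = np.isnan(pos).any(axis=1)
            if bad.any():
                runs = _gap_runs(bad)
                for start, stop in runs:
                    length = stop - start
                    interior = start > 0 and stop < len(bad)
                    if length > max_gap or not interior:
                        if name in REQUIRED_MARKERS:
                            raise ValueError(
                                f"marker {name!r} has an unrecoverable gap of "
                                f"{length} frames at frame {start}"
                            )
                        continue
                    t = np.arange(start, stop)
                    for c in range(3):
                        pos[t, c] = np.interp(t, [start - 1, stop], [pos[start - 1, c], pos[stop, c]])
            out[name] = pos
        return MarkerTrajectorySet(out, self.rate, self.meta)

    def transformed(self, fn) -> "MarkerTrajectorySet":
        """Apply ``fn(array (n,3)) -> array (n,3)`` to every marker."""
        return MarkerTrajectorySet(
            {k: np.asarray(fn(v), dtype=float) for k, v in self.positions.items()},
            self.rate,
            self.meta,
        )

    def with_meta(self, **kwargs) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(self.positions, self.rate, replace(self.meta, **kwargs))


_MIRROR_PATH = {"left": "right", "right": "left", "straight": "straight"}


def mirror_lateral(t: MarkerTrajectorySet, axis: int = 1) -> MarkerTrajectorySet:
    """Reflect a trajectory set through the vertical plane along the given
    lab axis (default y).

    A reflected horse's anatomical left is the image of the original's right,
    so paired ``_left``/``_right`` markers swap names; the path label swaps
    between left and right circles.
    """
    flip = np.ones(3)
    flip[axis] = -1.0
    positions: dict[str, np.ndarray] = {}
    for name, pos in t.positions.items():
        if name.endswith("_left"):
            name = name[: -len("_left")] + "_right"
        elif name.endswith("_right"):
            name = name[: -len("_right")] + "_left"
        positions[name] = pos * flip
    meta = replace(t.meta, path=_MIRROR_PATH.get(t.meta.path, t.meta.path))
    return MarkerTrajectorySet(positions, t.rate, meta)


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_trajectories(t: MarkerTrajectorySet, path: str | Path) -> Path:
    """Write a trajectory set as tab-separated text (millimetres).

    Column order is deterministic: frame, time, then ``<marker>_X/_Y/_Z`` per
    marker in declared order.  Metadata goes into ``#``-commented header lines.
    Gap samples become empty cells.
    """
    path = Path(path)
    buf = _stdio.StringIO()
    m = t.meta
    buf.write(f"# rate_hz\t{t.rate:g}\n")
    buf.write(f"# horse\t{m.horse}\n")
    buf.write(f"# day\t{m.day}\n")
    buf.write(f"# trial\t{m.trial}\n")
    buf.write(f"# path\t{m.path}\n")
    if m.radius is not None:
        buf.write(f"# radius_m\t{m.radius:g}\n")
    cols = ["frame", "time"]
    for name in t.markers:
        cols += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
    buf.write("\t".join(cols) + "\n")
    n = t.n_frames
    mats = [t.positions[name] * _MM_PER_M for name in t.markers]
    for i in range(n):
        cells = [str(i), f"{i / t.rate:.6f}"]
        for mat in mats:
            row = mat[i]
            if np.isnan(row).any():
                cells += ["", "", ""]
            else:
                cells += [f"{row[0]:.6f}", f"{row[1]:.6f}", f"{row[2]:.6f}"]
        buf.write("\t".join(cells) + "\n")
    path.write_text(buf.getvalue())
    return path


def read_trajectories(
    path: str | Path,
    dialect: str = "tsv",
    require: Iterable[str] | None = REQUIRED_MARKERS,
) -> MarkerTrajectorySet:
    """Read a trajectory file, converting millimetres to metres.

    ``require`` lists markers that must be present (pass ``None`` to skip the
    check, e.g. for small fixture files).
    """
    if dialect == "c3d":
        return _read_c3d(path, require)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta_kv[parts[0].strip()] = parts[1].strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise TrajectoryParseError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            rows.append(cells)
    if header is None:
        raise TrajectoryParseError(f"{path.name}: no column header found")
    marker_names: list[str] = []
    for col in header[2:]:
        if col.endswith("_X"):
            marker_names.append(col[:-2])
    rate = float(meta_kv.get("rate_hz", 100.0))
    meta = TrialMeta(
        horse=meta_kv.get("horse", "unknown"),
        day=int(meta_kv.get("day", 1)),
        trial=int(meta_kv.get("trial", 1)),
        path=meta_kv.get("path", "straight"),
        radius=float(meta_kv["radius_m"]) if "radius_m" in meta_kv else None,
    )
    n = len(rows)
    positions: dict[str, np.ndarray] = {}
    for j, name in enumerate(marker_names):
        c0 = 2 + 3 * j
        mat = np.full((n, 3), np.nan)
        for i, cells in enumerate(rows):
            triple = cells[c0 : c0 + 3]
            if all(c.strip() for c in triple):
                mat[i] = [float(c) for c in triple]
        positions[name] = mat / _MM_PER_M
    t = MarkerTrajectorySet(positions, rate, meta)
    if require is not None:
        t.require(require)
    return t


def _read_c3d(path: str | Path, require: Iterable[str] | None) -> MarkerTrajectorySet:
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D import requires the optional 'ezc3d' package "
            "(pip install equispine[c3d]); the TSV dialect needs no extras"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]  # pragma: no cover
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])  # pragma: no cover
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames), millimetres  # pragma: no cover
    positions = {  # pragma: no cover
        name: pts[:3, j, :].T / _MM_PER_M for j, name in enumerate(labels)
    }
    t = MarkerTrajectorySet(positions, rate)  # pragma: no cover
    if require is not None:  # pragma: no cover
        t.require(require)
    return t  # pragma: no cover
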