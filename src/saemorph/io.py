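"""Readers and writers for measurement tables and contour records.

Conventions: the canonical length unit is the micrometre; pixel-space inputs
require an explicit ``um_per_pixel`` factor (the magnification is never
guessed).  Measurement tables are comma-separated UTF-8 with a "." decimal
separator.  Contours are stored as JSON-lines — one object per structure
with an explicit vertex array — which keeps fixtures human-inspectable and
streaming-friendly.  Coordinates are continuous Cartesian with y increasing
downward (image convention); every computed quantity is isometry-invariant,
so the orientation of the y axis is cosmetic.

Column aliases map common upstream export headers (ImageJ "Results" tables
and similar) onto the canonical names; the dictionary can be extended per
call for other tools.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .contours import Contour
from .errors import DomainError

__all__ = [
    "COLUMN_ALIASES",
    "MeasurementTable",
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "read_contours",
    "write_contours",
    "read_imagej_rois",
]

logger = logging.getLogger(__name__)

# upstream header -> canonical column
COLUMN_ALIASES: dict[str, str] = {
    "Area": "area",
    "area_um2": "area",
    "Perim.": "perimeter",
    "Perimeter": "perimeter",
    "perim": "perimeter",
    "MinFeret": "feret_min",
    "Min Feret": "feret_min",
    "FeretMin": "feret_min",
    "Feret": "feret_max",
    "MaxFeret": "feret_max",
    "FeretMax": "feret_max",
    "X": "centroid_x",
    "XM": "centroid_x",
    "Y": "centroid_y",
    "YM": "centroid_y",
    "Label": "id",
    "ID": "id",
    "Type": "structure_type",
}

REQUIRED_COLUMNS = ("area", "perimeter")
NUMERIC_COLUMNS = ("area", "perimeter", "feret_min", "feret_max", "centroid_x", "centroid_y")


@dataclass
class MeasurementTable:
    """A typed measurement table plus the rows rejected while parsing."""

    data: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def read_measurements(
    path, sep: str = ",", aliases: dict[str, str] | None = None
) -> MeasurementTable:
    """Read a delimited measurement table, mapping known header aliases.

    Rows whose required numeric fields fail to parse are reported with their
    1-based file line number (header = line 1) and excluded from ``data``.
    A missing required column raises :class:`DomainError` naming it.
    """
    alias_map = dict(COLUMN_ALIASES)
    if aliases:
        alias_map.update(aliases)
    df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=False)
    df = df.rename(columns={c: alias_map.get(c, c) for c in df.columns})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DomainError(f"missing required column {col!r} in {path}")
    rejected: list[tuple[int, str]] = []
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    for idx in df.index[bad]:
        line_no = int(idx) + 2  # header occupies line 1
        rejected.append((line_no, "non-numeric or missing required field"))
        logger.warning("rejected line %d of %s: unparseable required field", line_no, path)
    df = df[~bad].reset_index(drop=True)
    if "id" not in df.columns:
        df.insert(0, "id", df.index.astype(str))
    if "structure_type" not in df.columns:
        df["structure_type"] = "fiber_outer"
    return MeasurementTable(data=df, rejected=rejected)


def write_measurements(data, path) -> Path:
    """Write a measurement table (DataFrame or MeasurementTable) as CSV.

    Floats are written with full ``repr`` precision, so a write/read cycle
    reproduces values exactly.
    """
    df = data.data if isinstance(data, MeasurementTable) else data
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_contours(contours, path) -> Path:
    """Write contours as JSON-lines: {"id", "structure_type", "vertices"}."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in contours:
            rec = {
                "id": c.id,
                "structure_type": c.structure_type,
                "vertices": [[float(x), float(y)] for x, y in c.vertices],
            }
            fh.write(json.dumps(rec) + "\n")
    return path


def read_contours(path, um_per_pixel: float = 1.0) -> list[Contour]:
    """Read JSON-lines contour records, applying the pixel-to-um scale.

    Self-intersecting polygons are flagged (``contour.simple = False``) with
    a logged warning but are still returned; an empty file yields an empty
    list.  A malformed line raises :class:`DomainError` with its line number.
    """
    if um_per_pixel <= 0:
        raise DomainError(f"um_per_pixel must be positive, got {um_per_pixel}")
    contours: list[Contour] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                vertices = np.asarray(rec["vertices"], dtype=float) * um_per_pixel
                contour = Contour(
                    vertices=vertices,
                    structure_type=rec.get("structure_type", "fiber_outer"),
                    id=rec.get("id"),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise DomainError(f"malformed contour record at line {line_no} of {path}: {exc}") from exc
            if not Polygon(contour.vertices).is_valid:
                contour.simple = False
                logger.warning(
                    "contour %r (line %d of %s) is self-intersecting", contour.id, line_no, path
                )
            contours.append(contour)
    return contours


def read_imagej_rois(path, um_per_pixel: float) -> list[Contour]:
    """Read polygon ROIs from an ImageJ .roi file or .zip archive.

    Requires the optional ``roifile`` package; a clear ImportError is raised
    when it is not installed.
    """
    try:
        import roifile
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading ImageJ ROI archives requires the optional 'roifile' package "
            "(pip install saemorph[roi])"
        ) from exc
    if um_per_pixel <= 0:
        raise DomainError(f"um_per_pixel must be positive, got {um_per_pixel}")
    rois = roifile.roiread(path)
    if not isinstance(rois, list):
        rois = [rois]
    contours = []
    for roi in rois:
        contours.append(
            Contour(
                vertices=np.asarray(roi.coordinates(), dtype=float) * um_per_pixel,
                structure_type="fiber_outer",
                id=roi.name,
            )
        )
    return contours


@dataclass
class RunConfig:
    """Resolved run parameters; serialisable and logged by every CLI run."""

    um_per_pixel: float = 1.0
    series_terms: int = 4
    newton_tolerance: float = 1e-10
    newton_max_iter: int = 100
    pairing_max_distance: float | None = None
    containment: bool = False
    bin_width: float = 0.5
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.um_per_pixel <= 0 or self.bin_width <= 0:
            raise DomainError("um_per_pixel and bin_width must be positive")
        if self.series_terms < 1 or self.newton_max_iter < 1:
            raise DomainError("series_terms and newton_max_iter must be >= 1")
        if self.newton_tolerance <= 0:
            raise DomainError("newton_tolerance must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))
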