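"""Micrograph and particle-coordinate I/O.

Micrographs are read from MRC2014 (modes 0/1/2/6) or 8/16-bit grayscale
rasters (PNG/TIFF); picked coordinates are exchanged as RELION-dialect
STAR loops with ``_rlnCoordinateX``/``_rlnCoordinateY`` and the pick
confidence in ``_rlnAutopickFigureOfMerit``.

Coordinate convention: 0-based pixels, x = column, y = row, origin at the
top-left of the original micrograph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _mrc, _star

_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

COORD_X = "_rlnCoordinateX"
COORD_Y = "_rlnCoordinateY"
FOM = "_rlnAutopickFigureOfMerit"
DIAMETER = "_rlnParticleDiameter"


@dataclass
class Micrograph:
    """A single 2D micrograph: the unit of all processing."""

    pixels: np.ndarray
    pixel_size: float | None = None
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be 2D")

    @property
    def height(self):
        return self.pixels.shape[0]

    @property
    def width(self):
        return self.pixels.shape[1]

    @property
    def shape(self):
        return self.pixels.shape

    def with_pixels(self, pixels):
        return Micrograph(pixels=np.asarray(pixels), pixel_size=self.pixel_size,
                          id=self.id)


@dataclass
class Particle:
    """One picked particle in original-micrograph pixel coordinates."""

    x: float
    y: float
    radius: float
    confidence: float = 1.0

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"particle radius must be positive, got {self.radius}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class ParticleSet:
    """Picked particles of one micrograph plus its frame size."""

    micrograph_id: str
    particles: list[Particle] = field(default_factory=list)
    source_shape: tuple[int, int] = (0, 0)

    def __len__(self):
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def validate(self):
        h, w = self.source_shape
        for p in self.particles:
            if not (0 <= p.x < w and 0 <= p.y < h):
                raise ValueError(
                    f"particle ({p.x}, {p.y}) outside micrograph frame {self.source_shape}"
                )
        return self


def read_micrograph(path) -> Micrograph:
    """Load an MRC or grayscale raster micrograph.

    Pixel intensities are left unscaled (normalization is a preprocessing
    concern); the MRC pixel size is propagated when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"micrograph file not found: {path}")
    suffix = path.suffix.lower()
    pixel_size = None
    if suffix in _RASTER_SUFFIXES:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # collapse identical channels / drop alpha
            data = data[..., :3].mean(axis=-1)
        data = data.astype(np.float32)
    else:
        try:
            data, pixel_size = _mrc.read_mrc(path)
        except _mrc.MRCError:
            raise
        except OSError as exc:
            raise IOError(f"could not read micrograph {path}: {exc}") from exc
    if not np.all(np.isfinite(data)):
        raise IOError(f"micrograph {path} contains non-finite pixel values")
    if data.max() == data.min():
        warnings.warn(f"micrograph {path} is constant-valued", stacklevel=2)
    return Micrograph(pixels=data, pixel_size=pixel_size, id=path.stem)


def write_micrograph(m: Micrograph, path) -> None:
    """Write a micrograph as float32 mode-2 MRC."""
    _mrc.write_mrc(path, np.asarray(m.pixels, dtype=np.float32), m.pixel_size)


def write_star(pset: ParticleSet, path, diameter_column=False,
               diameter_in_angstrom=False, pixel_size=None) -> None:
    """Write a ParticleSet as a single-block STAR coordinate loop.

    With ``diameter_column``, ``_rlnParticleDiameter`` is emitted in
    pixels, or in Angstrom when ``diameter_in_angstrom`` is set and a
    pixel size is available.
    """
    columns = [COORD_X, COORD_Y, FOM]
    scale = 1.0
    if diameter_column:
        columns.append(DIAMETER)
        if diameter_in_angstrom:
            if not pixel_size:
                raise ValueError("diameter in Angstrom requires a pixel size")
            scale = float(pixel_size)
    rows = []
    for p in pset.particles:
        row = [f"{p.x:.6f}", f"{p.y:.6f}", f"{p.confidence:.6f}"]
        if diameter_column:
            row.append(f"{2.0 * p.radius * scale:.6f}")
        rows.append(row)
    _star.write_star_loop(path, columns, rows)


def read_star(path, source_shape, default_radius=10.0,
              micrograph_id=None) -> ParticleSet:
    """Read a STAR coordinate loop back into a ParticleSet.

    Rows without a diameter column get ``default_radius``; unknown extra
    columns are ignored.
    """
    columns, rows = _star.read_star_loop(path)
    if COORD_X not in columns or COORD_Y not in columns:
        raise _star.StarError(
            f"{path}: missing coordinate columns; found {columns}"
        )
    ix, iy = columns.index(COORD_X), columns.index(COORD_Y)
    ic = columns.index(FOM) if FOM in columns else None
    idm = columns.index(DIAMETER) if DIAMETER in columns else None
    particles = []
    for row in rows:
        conf = float(row[ic]) if ic is not None else 1.0
        radius = float(row[idm]) / 2.0 if idm is not None else default_radius
        particles.append(
            Particle(
                x=float(row[ix]),
                y=float(row[iy]),
                radius=radius,
                confidence=min(max(conf, 0.0), 1.0),
            )
        )
    name = micrograph_id if micrograph_id is not None else Path(path).stem
    return ParticleSet(
        micrograph_id=name, particles=particles, source_shape=tuple(source_shape)
    )


def rescale_coordinates(pset: ParticleSet, from_shape, to_shape) -> ParticleSet:
    """Map coordinates between frames (e.g. network frame <-> original).

    x scales by the width ratio, y by the height ratio and the radius by
    the geometric mean of the two factors, which preserves the
    equivalent-circle area under anisotropic resizes.
    """
    fh, fw = from_shape
    th, tw = to_shape
    if min(fh, fw, th, tw) <= 0:
        raise ValueError("shapes must be positive")
    sx, sy = tw / fw, th / fh
    sr = math.sqrt(sx * sy)
    particles = [
        replace(p, x=p.x * sx, y=p.y * sy, radius=p.radius * sr)
        for p in pset.particles
    ]
    return ParticleSet(
        micrograph_id=pset.micrograph_id,
        particles=particles,
        source_shape=(th, tw),
    )
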