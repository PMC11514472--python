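"""Multi-resolution Hi-C contact store, sliding-window planning and tile rendering.

The store keeps one dense symmetric matrix of raw (unnormalised) contact
counts per resolution, where resolution is the bin size in bp and bin ``b``
covers the zero-based half-open genomic interval ``[b*res, (b+1)*res)``.
On disk a store is a directory with a ``manifest.json`` plus one
little-endian float32 row-major matrix per resolution (``res_<N>.mat``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import BoundsError, FormatError, IntegrityError, ParameterError

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class Window:
    """One sliding window along the contact-map diagonal (1-based index)."""

    index: int
    start: int
    end: int
    resolution: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionMatrix:
    """A rectangular block of contact counts with its genomic footprint."""

    resolution: int
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    values: np.ndarray


@dataclass
class Tile:
    """Rendered heatmap window.

    ``pixels`` holds the normalised intensity ``min(v, ceiling)/ceiling`` in
    [0, 1]; the white-to-red RGB ramp is applied only when saving to PNG, so
    rendering stays exactly reproducible.
    """

    pixels: np.ndarray
    resolution: int
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    ceiling: float
    tile_id: str = ""

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def to_rgb(self) -> np.ndarray:
        """White→red linear ramp: intensity 0 is white, 1 is pure red."""
        t = self.pixels
        chan = np.rint(255.0 * (1.0 - t)).astype(np.uint8)
        rgb = np.empty(t.shape + (3,), dtype=np.uint8)
        rgb[..., 0] = 255
        rgb[..., 1] = chan
        rgb[..., 2] = chan
        return rgb

    def metadata(self) -> dict:
        return {
            "resolution": self.resolution,
            "x_start": self.x_start,
            "x_end": self.x_end,
            "y_start": self.y_start,
            "y_end": self.y_end,
            "ceiling": self.ceiling,
            "tile_id": self.tile_id,
        }

    def save(self, png_path: str | Path) -> None:
        """Write the PNG plus a JSON sidecar with the genomic footprint."""
        from PIL import Image

        png_path = Path(png_path)
        Image.fromarray(self.to_rgb(), mode="RGB").save(png_path)
        sidecar = png_path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.metadata(), indent=1))


class ContactStore:
    """Symmetric contact matrices for one assembly at several resolutions."""

    def __init__(self, genome_length: int, matrices: Mapping[int, np.ndarray]):
        if genome_length <= 0:
            raise ParameterError("genome_length must be positive")
        if not matrices:
            raise ParameterError("at least one resolution is required")
        resolutions = sorted(matrices)
        if len(set(resolutions)) != len(matrices):
            raise ParameterError("duplicate resolutions")
        self.genome_length = int(genome_length)
        self.resolutions: list[int] = [int(r) for r in resolutions]
        self._matrices: dict[int, np.ndarray] = {}
        for res in self.resolutions:
            mat = np.asarray(matrices[res], dtype=np.float64)
            side = n_bins(genome_length, res)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise IntegrityError(f"matrix at {res} bp is not square")
            if mat.shape[0] != side:
                raise IntegrityError(
                    f"matrix at {res} bp has side {mat.shape[0]}, "
                    f"expected ceil({genome_length}/{res}) = {side}"
                )
            if not np.allclose(mat, mat.T, atol=_SYMMETRY_TOL, rtol=0.0):
                raise IntegrityError(f"matrix at {res} bp is not symmetric")
            if (mat < 0).any():
                raise IntegrityError(f"matrix at {res} bp has negative counts")
            self._matrices[res] = mat

    def matrix(self, resolution: int) -> np.ndarray:
        try:
            return self._matrices[resolution]
        except KeyError:
            raise ParameterError(
                f"unknown resolution {resolution}; have {self.resolutions}"
            ) from None


def n_bins(length: int, resolution: int) -> int:
    """Number of bins covering ``[0, length)`` at ``resolution`` bp/bin."""
    return -(-int(length) // int(resolution))


def fetch_region(
    store: ContactStore,
    resolution: int,
    x: tuple[int, int],
    y: tuple[int, int],
) -> RegionMatrix:
    """Extract the raw contact block for the bins overlapping two intervals.

    Intervals are zero-based half-open bp; no normalisation is applied.
    """
    xs, xe = map(int, x)
    ys, ye = map(int, y)
    Lg = store.genome_length
    for s, e in ((xs, xe), (ys, ye)):
        if not (0 <= s < e <= Lg):
            raise BoundsError(f"interval [{s}, {e}) outside genome [0, {Lg})")
    mat = store.matrix(resolution)
    bx0, bx1 = xs // resolution, n_bins(xe, resolution)
    by0, by1 = ys // resolution, n_bins(ye, resolution)
    block = mat[bx0:bx1, by0:by1].copy()
    return RegionMatrix(resolution, xs, xe, ys, ye, block)


def quantile_threshold(values, q: float = 0.95) -> float:
    """Linear-interpolated quantile with 1-based rank ``k = q*n``.

    When ``k`` is integral the value at that rank is returned directly;
    otherwise the two neighbouring order statistics are interpolated.
    ``k < 1`` returns the minimum.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ParameterError("quantile of an empty collection")
    srt = np.sort(arr)
    n = srt.size
    k = q * n
    if k <= 1.0:
        return float(srt[0])
    if float(k).is_integer():
        return float(srt[int(k) - 1])
    lo = srt[math.floor(k) - 1]
    hi = srt[min(math.ceil(k), n) - 1]
    return float(lo + (k - math.floor(k)) * (hi - lo))


def plan_windows(genome_length: int, resolution: int) -> list[Window]:
    """Sliding windows of length ``700*res`` stepping ``400*res`` along the diagonal.

    ``X_i = 400*res*(i-1)``; generation stops once a window reaches the end of
    the genome, with the last window clipped to ``genome_length``.
    """
    if genome_length <= 0 or resolution <= 0:
        raise ParameterError("genome_length and resolution must be positive")
    step = 400 * resolution
    span = 700 * resolution
    windows: list[Window] = []
    i = 1
    while True:
        start = step * (i - 1)
        if start >= genome_length:
            break
        end = start + span
        if end >= genome_length:
            windows.append(Window(i, start, genome_length, resolution))
            break
        windows.append(Window(i, start, end, resolution))
        i += 1
    return windows


def select_global_resolution(genome_length: int, resolutions: Sequence[int]) -> int:
    """Smallest resolution whose 1440-bin canvas covers the genome.

    Returns the smallest ``r`` with ``r*1440 >= genome_length``; when the
    genome exceeds every canvas, the coarsest resolution is returned with a
    warning (the global image is then larger than 1440 bins per side).
    """
    if not resolutions:
        raise ParameterError("empty resolution list")
    for r in sorted(resolutions):
        if r * 1440 >= genome_length:
            return int(r)
    coarsest = int(max(resolutions))
    warnings.warn(
        f"genome length {genome_length} exceeds {coarsest}*1440; "
        "falling back to the coarsest resolution",
        stacklevel=2,
    )
    return coarsest


def render_tile(region: RegionMatrix, ceiling: float, tile_id: str = "") -> Tile:
    """Map a contact block onto the white→red ramp, clipping at ``ceiling``."""
    if not ceiling > 0:
        raise ParameterError("colour ceiling must be positive")
    pixels = np.clip(region.values, 0.0, ceiling) / float(ceiling)
    return Tile(
        pixels=pixels,
        resolution=region.resolution,
        x_start=region.x_start,
        x_end=region.x_end,
        y_start=region.y_start,
        y_end=region.y_end,
        ceiling=float(ceiling),
        tile_id=tile_id,
    )


# ---------------------------------------------------------------------------
# On-disk archive: manifest.json + res_<N>.mat (LE float32, row-major).


def save_store(store: ContactStore, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "hic-curator-archive",
        "version": 1,
        "genome_length": store.genome_length,
        "resolutions": store.resolutions,
        "dtype": "<f4",
        "layout": "row-major",
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for res in store.resolutions:
        store.matrix(res).astype("<f4").tofile(path / f"res_{res}.mat")
    return path


def open_store(path: str | Path) -> ContactStore:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json under {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
        Lg = int(manifest["genome_length"])
        resolutions = [int(r) for r in manifest["resolutions"]]
        dtype = manifest.get("dtype", "<f4")
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad manifest in {path}: {exc}") from exc
    matrices = {}
    for res in resolutions:
        mat_path = path / f"res_{res}.mat"
        if not mat_path.exists():
            raise FormatError(f"missing matrix file {mat_path.name}")
        flat = np.fromfile(mat_path, dtype=dtype)
        side = n_bins(Lg, res)
        if flat.size != side * side:
            raise IntegrityError(
                f"{mat_path.name}: {flat.size} values, expected {side}x{side}"
            )
        matrices[res] = flat.reshape(side, side)
    return ContactStore(Lg, matrices)
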