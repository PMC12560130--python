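"""Frame container I/O: 16-bit grayscale TIFF plus a sidecar calibration file.

The sidecar is plain text (key = value) holding the affine row->nm
calibration and the per-aperture detector-column ranges, so that real
instrument frames in the same container can be consumed by the readout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .layout import ChipLayout
from .render import HyperspectralFrame

_SIDECAR_SUFFIX = ".calib.txt"


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(_SIDECAR_SUFFIX)


def write_frame(frame: HyperspectralFrame, path: str | Path) -> Path:
    """Write a frame as 16-bit grayscale TIFF + sidecar; returns the sidecar path."""
    path = Path(path)
    peak = float(frame.intensity.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    counts = np.round(frame.intensity * scale).astype(np.uint16)
    tifffile.imwrite(path, counts)

    lines = [
        f"intercept_nm = {frame.calibration[0]!r}",
        f"slope_nm_per_row = {frame.calibration[1]!r}",
        f"intensity_scale = {scale!r}",
        "roles = " + ",".join(frame.layout.aperture_roles),
        "sensor_ids = "
        + ",".join(f"{ap}:{sid}" for ap, sid in sorted(frame.layout.sensor_ids.items())),
        "columns = "
        + ",".join(
            f"{ap}:{start}-{stop}"
            for ap, (start, stop) in sorted(frame.layout.column_pixel_map.items())
        ),
    ]
    sidecar = _sidecar_path(path)
    sidecar.write_text("\n".join(lines) + "\n")
    return sidecar


def read_frame(path: str | Path) -> HyperspectralFrame:
    """Read a frame written by :func:`write_frame` (or a real frame in
    the same container)."""
    path = Path(path)
    counts = tifffile.imread(path).astype(float)
    fields: dict[str, str] = {}
    for line in _sidecar_path(path).read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()

    roles = tuple(fields["roles"].split(","))
    sensor_ids = {
        int(k): int(v)
        for k, v in (item.split(":") for item in fields["sensor_ids"].split(","))
    }
    columns = {}
    for item in fields["columns"].split(","):
        ap, _, rng = item.partition(":")
        start, _, stop = rng.partition("-")
        columns[int(ap)] = (int(start), int(stop))
    layout = ChipLayout(
        aperture_roles=roles, sensor_ids=sensor_ids, column_pixel_map=columns
    )
    layout.validate()

    scale = float(fields.get("intensity_scale", "1.0"))
    return HyperspectralFrame(
        intensity=counts / scale,
        calibration=(float(fields["intercept_nm"]), float(fields["slope_nm_per_row"])),
        layout=layout,
    )
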