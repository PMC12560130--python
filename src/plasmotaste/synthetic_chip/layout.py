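"""Chip geometry: 55 slit apertures, alternating sensors and light references."""

from __future__ import annotations

from dataclasses import dataclass, field

N_APERTURES = 55
N_EDGE_BLANKS = 4  # per side
N_SENSORS = 24
N_REFERENCES = 23

ROLE_EDGE_BLANK = "edge_blank"
ROLE_SENSOR = "sensor"
ROLE_REFERENCE = "reference"


@dataclass(frozen=True)
class ChipLayout:
    """Aperture geometry and role map of the sensor chip.

    The chip carries 55 slit apertures.  The outer four on each side are
    blanks; the inner 47 strictly alternate between sensor elements (24)
    and empty light references (23), beginning and ending with a sensor.

    Attributes
    ----------
    aperture_roles:
        Role of each aperture in physical order, one of ``edge_blank``,
        ``sensor`` or ``reference``.
    sensor_ids:
        Map aperture index (0-based) -> sensor id (1..24).
    aperture_pitch_um, slit_width_um, slit_height_um:
        Slit geometry in micrometres.
    column_pixel_map:
        Map aperture index -> half-open detector-column range
        ``(start, stop)``.
    """

    aperture_roles: tuple[str, ...]
    sensor_ids: dict[int, int]
    aperture_pitch_um: float = 750.0
    slit_width_um: float = 25.0
    slit_height_um: float = 500.0
    column_pixel_map: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_apertures(self) -> int:
        return len(self.aperture_roles)

    @property
    def sensor_apertures(self) -> list[int]:
        return [i for i, r in enumerate(self.aperture_roles) if r == ROLE_SENSOR]

    @property
    def reference_apertures(self) -> list[int]:
        return [i for i, r in enumerate(self.aperture_roles) if r == ROLE_REFERENCE]

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_apertures)

    @property
    def n_references(self) -> int:
        return len(self.reference_apertures)

    def aperture_of_sensor(self, sensor_id: int) -> int:
        for ap, sid in self.sensor_ids.items():
            if sid == sensor_id:
                return ap
        raise KeyError(f"no aperture carries sensor id {sensor_id}")

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated layout invariant."""
        n = self.n_apertures
        if n != N_APERTURES:
            raise ValueError(f"expected {N_APERTURES} apertures, got {n}")
        for i in range(N_EDGE_BLANKS):
            if self.aperture_roles[i] != ROLE_EDGE_BLANK:
                raise ValueError(f"aperture {i} must be an edge blank")
            if self.aperture_roles[n - 1 - i] != ROLE_EDGE_BLANK:
                raise ValueError(f"aperture {n - 1 - i} must be an edge blank")
        inner = self.aperture_roles[N_EDGE_BLANKS : n - N_EDGE_BLANKS]
        for j, role in enumerate(inner):
            expected = ROLE_SENSOR if j % 2 == 0 else ROLE_REFERENCE
            if role != expected:
                raise ValueError(
                    f"inner aperture {j + N_EDGE_BLANKS} has role {role!r}, "
                    f"expected {expected!r} (strict alternation)"
                )
        if self.n_sensors != N_SENSORS:
            raise ValueError(f"expected {N_SENSORS} sensors, got {self.n_sensors}")
        if self.n_references != N_REFERENCES:
            raise ValueError(
                f"expected {N_REFERENCES} references, got {self.n_references}"
            )
        ids = sorted(self.sensor_ids.values())
        if ids != list(range(1, N_SENSORS + 1)):
            raise ValueError("sensor_ids must be a bijection onto 1..24")
        if set(self.sensor_ids) != set(self.sensor_apertures):
            raise ValueError("sensor_ids keys must be exactly the sensor apertures")


def default_layout(
    *,
    columns_per_aperture: int = 5,
    column_gap: int = 2,
) -> ChipLayout:
    """Build the default 55-aperture chip layout.

    Apertures are 25 x 500 um slits at a 750 um pitch.  The detector
    column map assigns each aperture ``columns_per_aperture`` contiguous
    pixel columns separated by ``column_gap`` dark columns.
    """
    roles = [ROLE_EDGE_BLANK] * N_EDGE_BLANKS
    for j in range(N_APERTURES - 2 * N_EDGE_BLANKS):
        roles.append(ROLE_SENSOR if j % 2 == 0 else ROLE_REFERENCE)
    roles.extend([ROLE_EDGE_BLANK] * N_EDGE_BLANKS)

    sensor_ids: dict[int, int] = {}
    next_id = 1
    for i, role in enumerate(roles):
        if role == ROLE_SENSOR:
            sensor_ids[i] = next_id
            next_id += 1

    stride = columns_per_aperture + column_gap
    column_pixel_map = {
        i: (i * stride, i * stride + columns_per_aperture) for i in range(len(roles))
    }

    layout = ChipLayout(
        aperture_roles=tuple(roles),
        sensor_ids=sensor_ids,
        column_pixel_map=column_pixel_map,
    )
    layout.validate()
    return layout
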