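"""Bit-exact controller-message serialization, logger .DAT I/O, NMEA parsing.

The lidar controller emits one fixed-width ASCII message per sweep and
sensor: a 23-byte header (unit address, controller milliseconds, the
session soil reference ZREF and the instantaneous soil displacement SREF)
followed by one zero-padded 4-digit millimetre distance per optical angle.
For the operating 251-point sweep the message is exactly 1278 bytes; the
full-FOV 751-point message is 3778 bytes.

The data logger wraps each message in a comma-separated record carrying a
timestamp, record number and the GNSS position parsed from GNGGA/GNRMC
sentences; those records form the .DAT files this module reads and writes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import utm
from .errors import ChecksumError, ParameterError, ParseError
from .sweep_geometry import SensorGeometry

HEADER_BYTES = 23
BYTES_PER_POINT = 5
MAX_FIELD_MM = 9999  # 4-digit field width bound (device raw max is 16383)

UTM_ZONE = 12
_ZONE_LON_MIN = -114.0
_ZONE_LON_MAX = -108.0


# ---------------------------------------------------------------------------
# Controller messages


@dataclass(frozen=True)
class ControllerMessage:
    """One serialized-sweep payload from a lidar unit.

    ``distances`` holds one integer millimetre value per optical angle,
    each in ``[0, 9999]`` (the serialized field width).
    """

    address: str
    timestamp_ms: int
    zref_mm: int
    sref_mm: int
    distances: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "distances", np.asarray(self.distances, dtype=np.int64)
        )

    def __eq__(self, other):
        if not isinstance(other, ControllerMessage):
            return NotImplemented
        return (
            self.address == other.address
            and self.timestamp_ms == other.timestamp_ms
            and self.zref_mm == other.zref_mm
            and self.sref_mm == other.sref_mm
            and np.array_equal(self.distances, other.distances)
        )


def serialized_size(n_points: int) -> int:
    """Byte length of a serialized message with ``n_points`` distances."""
    return HEADER_BYTES + BYTES_PER_POINT * n_points


def _check_field(name: str, value: int, width: int) -> None:
    if not 0 <= int(value) < 10**width:
        raise ParameterError(
            f"{name}={value} does not fit a {width}-digit unsigned field"
        )


def serialize_message(msg: ControllerMessage) -> bytes:
    """Serialize to the fixed-width ASCII wire format.

    Layout: ``$`` + address(2) + ``,`` + milliseconds(8) + ``,`` + zref(4)
    + ``,`` + sref(4) + ``,`` (23 bytes), then each distance as 4
    zero-padded digits followed by ``,`` (a newline after the last).
    """
    if len(msg.address) != 2:
        raise ParameterError(f"address must be 2 characters, got {msg.address!r}")
    _check_field("timestamp_ms", msg.timestamp_ms, 8)
    _check_field("zref_mm", msg.zref_mm, 4)
    _check_field("sref_mm", msg.sref_mm, 4)
    d = msg.distances
    if d.ndim != 1 or d.size == 0:
        raise ParameterError("distances must be a non-empty 1-D array")
    if d.min() < 0 or d.max() > MAX_FIELD_MM:
        bad = int(d.min() if d.min() < 0 else d.max())
        raise ParameterError(
            f"distance {bad} outside 4-digit field range [0, {MAX_FIELD_MM}]"
        )
    header = f"${msg.address},{msg.timestamp_ms:08d},{msg.zref_mm:04d},{msg.sref_mm:04d},"
    return header.encode("ascii") + encode_distance_block(d[None, :]).tobytes()


def encode_distance_block(d: np.ndarray) -> np.ndarray:
    """Vectorized payload encoder: (n, m) ints → (n, 5m) ASCII bytes.

    Each row is the distance payload of one message (comma separators,
    newline after the last field).
    """
    d = np.asarray(d, dtype=np.int64)
    n, m = d.shape
    out = np.empty((n, m, 5), dtype=np.uint8)
    out[:, :, 0] = d // 1000 + 48
    out[:, :, 1] = (d // 100) % 10 + 48
    out[:, :, 2] = (d // 10) % 10 + 48
    out[:, :, 3] = d % 10 + 48
    out[:, :, 4] = ord(",")
    out[:, -1, 4] = ord("\n")
    return out.reshape(n, 5 * m)


def decode_distance_block(payloads: np.ndarray) -> np.ndarray:
    """Vectorized payload decoder: (n, 5m) ASCII bytes → (n, m) int32."""
    b = np.asarray(payloads, dtype=np.uint8)
    n, w = b.shape
    if w % 5:
        raise ParseError(f"payload width {w} is not a multiple of 5")
    digits = b.reshape(n, w // 5, 5)[:, :, :4].astype(np.int32) - 48
    if digits.min() < 0 or digits.max() > 9:
        raise ParseError("non-digit byte inside distance field")
    return digits @ np.array([1000, 100, 10, 1], dtype=np.int32)


def parse_message(raw: bytes | str) -> ControllerMessage:
    """Exact inverse of :func:`serialize_message`."""
    if isinstance(raw, str):
        raw = raw.encode("ascii")
    if len(raw) < HEADER_BYTES:
        raise ParseError("message truncated inside header", offset=len(raw))
    if raw[0:1] != b"$":
        raise ParseError("message does not start with '$'", offset=0)
    for pos in (3, 12, 17, 22):
        if raw[pos : pos + 1] != b",":
            raise ParseError("missing header delimiter", offset=pos)
    address = raw[1:3].decode("ascii")
    try:
        timestamp_ms = int(raw[4:12])
        zref_mm = int(raw[13:17])
        sref_mm = int(raw[18:22])
    except ValueError as exc:
        raise ParseError(f"non-numeric header field: {exc}", offset=4) from None
    payload = raw[HEADER_BYTES:]
    if not payload.endswith(b"\n"):
        payload = payload + b"\n" if len(payload) % 5 == 4 else payload
    if len(payload) == 0 or len(payload) % 5:
        raise ParseError(
            "payload truncated mid-field", offset=HEADER_BYTES + len(payload)
        )
    arr = np.frombuffer(payload, dtype=np.uint8)[None, :]
    seps = arr[0, 4::5]
    if not (np.all(seps[:-1] == ord(",")) and seps[-1] in (ord(","), ord("\n"))):
        bad = int(np.argmax(seps[:-1] != ord(","))) * 5 + 4
        raise ParseError("bad payload separator", offset=HEADER_BYTES + bad)
    distances = decode_distance_block(arr)[0]
    return ControllerMessage(address, timestamp_ms, zref_mm, sref_mm, distances)


# ---------------------------------------------------------------------------
# NMEA 0183


def nmea_checksum(sentence: str) -> str:
    """Two-hex-digit XOR checksum of the characters between ``$`` and ``*``."""
    body = sentence
    if body.startswith("$"):
        body = body[1:]
    body = body.split("*", 1)[0]
    cs = 0
    for ch in body:
        cs ^= ord(ch)
    return f"{cs:02X}"


def _validate_nmea(sentence: str) -> list[str]:
    sentence = sentence.strip()
    if not sentence.startswith("$") or "*" not in sentence:
        raise ParseError(f"not an NMEA sentence: {sentence[:20]!r}")
    body, claimed = sentence[1:].rsplit("*", 1)
    if nmea_checksum(sentence) != claimed.upper():
        raise ChecksumError(
            f"NMEA checksum mismatch: computed {nmea_checksum(sentence)}, "
            f"sentence claims {claimed}"
        )
    return body.split(",")


def _dm_to_degrees(field_value: str, hemisphere: str) -> float:
    """Convert an NMEA ``ddmm.mmmm`` latitude/longitude field to degrees."""
    if "." not in field_value or len(field_value.split(".")[0]) < 3:
        raise ParseError(f"malformed ddmm.mmmm field {field_value!r}")
    head = field_value.split(".")[0]
    deg = int(head[:-2])
    minutes = float(field_value[len(head) - 2 :])
    value = deg + minutes / 60.0
    if hemisphere in ("S", "W"):
        value = -value
    elif hemisphere not in ("N", "E"):
        raise ParseError(f"bad hemisphere indicator {hemisphere!r}")
    return value


def parse_nmea_position(gngga: str, gnrmc: str):
    """Extract (latitude, longitude, fix quality, UTC time) from a GGA/RMC pair.

    Both sentences must pass checksum validation; a mismatch raises
    :class:`ChecksumError`, which callers count and skip rather than treat
    as fatal.  Position and fix quality come from the GGA sentence; the RMC
    sentence is validated for checksum and its status flag.
    """
    gga = _validate_nmea(gngga)
    rmc = _validate_nmea(gnrmc)
    if not gga[0].endswith("GGA"):
        raise ParseError(f"expected a GGA sentence, got {gga[0]!r}")
    if not rmc[0].endswith("RMC"):
        raise ParseError(f"expected an RMC sentence, got {rmc[0]!r}")
    if len(rmc) > 2 and rmc[2] not in ("A", ""):
        raise ParseError(f"RMC reports invalid fix status {rmc[2]!r}")
    lat = _dm_to_degrees(gga[2], gga[3])
    lon = _dm_to_degrees(gga[4], gga[5])
    quality = int(gga[6]) if gga[6] else 0
    return lat, lon, quality, gga[1]


def _degrees_to_dm(value: float, width: int) -> tuple[str, bool]:
    """Degrees → (``ddmm.mmmmm`` text, is_negative) with carry handling."""
    neg = value < 0
    v = abs(value)
    deg = int(v)
    minutes = (v - deg) * 60.0
    if round(minutes, 7) >= 60.0:
        deg += 1
        minutes = 0.0
    # RTK receivers report sub-mm minute precision; keep it so positions
    # survive the NMEA round trip at centimetre fidelity.
    return f"{deg:0{width}d}{minutes:010.7f}", neg


def make_gngga(lat: float, lon: float, utc: str, quality: int = 4,
               n_sats: int = 12, hdop: float = 0.8, alt_m: float = 361.6) -> str:
    """Synthesize a GNGGA sentence (used by the session simulator)."""
    lat_s, lat_neg = _degrees_to_dm(lat, 2)
    lon_s, lon_neg = _degrees_to_dm(lon, 3)
    body = (
        f"GNGGA,{utc},{lat_s},{'S' if lat_neg else 'N'},"
        f"{lon_s},{'W' if lon_neg else 'E'},{quality},{n_sats:02d},"
        f"{hdop:.1f},{alt_m:.1f},M,-25.0,M,1.0,0000"
    )
    return f"${body}*{nmea_checksum(body)}"


def make_gnrmc(lat: float, lon: float, utc: str, date: str = "250918",
               speed_knots: float = 0.93, course: float = 0.0) -> str:
    """Synthesize a GNRMC sentence (used by the session simulator)."""
    lat_s, lat_neg = _degrees_to_dm(lat, 2)
    lon_s, lon_neg = _degrees_to_dm(lon, 3)
    body = (
        f"GNRMC,{utc},A,{lat_s},{'S' if lat_neg else 'N'},"
        f"{lon_s},{'W' if lon_neg else 'E'},{speed_knots:.2f},{course:.1f},"
        f"{date},,,R"
    )
    return f"${body}*{nmea_checksum(body)}"


# ---------------------------------------------------------------------------
# UTM


def to_utm(latitude, longitude):
    """WGS84 geodetic → UTM zone 12N easting/northing in metres.

    Coordinates outside the zone's longitude band are still projected with
    the zone forced to 12N, with a warning.
    """
    lon_arr = np.atleast_1d(np.asarray(longitude, dtype=float))
    if np.any((lon_arr < _ZONE_LON_MIN) | (lon_arr >= _ZONE_LON_MAX)):
        warnings.warn(
            "longitude outside the UTM zone 12 band; projecting with zone "
            "forced to 12N",
            stacklevel=2,
        )
    return utm.latlon_to_utm(latitude, longitude, zone=UTM_ZONE, northern=True)


def from_utm(easting, northing):
    """Inverse of :func:`to_utm` (zone 12N)."""
    return utm.utm_to_latlon(easting, northing, zone=UTM_ZONE, northern=True)


# ---------------------------------------------------------------------------
# Logger .DAT files


@dataclass(frozen=True)
class LoggerRecord:
    """One logger record: timestamp, position fix and the raw lidar message."""

    logger_timestamp: str
    record_number: int
    latitude: float
    longitude: float
    gnss_quality: int
    easting: float
    northing: float
    message: str  # serialized controller message, no trailing newline

    def parsed(self) -> ControllerMessage:
        return parse_message(self.message)


_DAT_FIELDS = [
    "TIMESTAMP", "RECORD", "Latitude", "Longitude", "GnssQuality",
    "Easting", "Northing", "LidarMessage",
]


def write_dat(records, path, station: str = "FurrowScan",
              table: str = "lidar") -> None:
    """Write logger records as a .DAT text file with a 4-line preamble."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC)
        w.writerow(["TOA5", station, "CR1000X", "0", "CR1000X.Std.01.02",
                    "sim", "0", table])
        w.writerow(_DAT_FIELDS)
        w.writerow(["TS", "RN", "degrees", "degrees", "unitless", "m", "m", ""])
        w.writerow(["", "", "Smp", "Smp", "Smp", "Smp", "Smp", "Smp"])
        for r in records:
            w.writerow([
                r.logger_timestamp, r.record_number, repr(r.latitude),
                repr(r.longitude), r.gnss_quality, repr(r.easting),
                repr(r.northing), r.message,
            ])


def read_dat(path) -> tuple[list[LoggerRecord], int]:
    """Read a .DAT file; returns ``(records, n_skipped)``.

    Lines that are too short or fail numeric conversion are skipped and
    counted rather than aborting the read.
    """
    path = Path(path)
    records: list[LoggerRecord] = []
    skipped = 0
    with path.open("r", newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if i < 4:  # preamble
                continue
            if len(row) < len(_DAT_FIELDS):
                skipped += 1
                continue
            try:
                records.append(LoggerRecord(
                    logger_timestamp=row[0],
                    record_number=int(float(row[1])),
                    latitude=float(row[2]),
                    longitude=float(row[3]),
                    gnss_quality=int(float(row[4])),
                    easting=float(row[5]),
                    northing=float(row[6]),
                    message=row[7],
                ))
            except (ValueError, IndexError):
                skipped += 1
    return records, skipped


def reformat(records: list[LoggerRecord], geom: SensorGeometry | None = None):
    """Reformat logger records into a flat table with parsed angle columns.

    Returns a :class:`pandas.DataFrame` with logger metadata, the parsed
    message header fields, UTM position, and one ``d###`` column per optical
    angle (distances in mm).  This is the pipeline's "reformatting" stage.
    """
    import pandas as pd

    if geom is None:
        geom = SensorGeometry()
    n_pts = geom.n_angles
    payloads = np.empty((len(records), 5 * n_pts), dtype=np.uint8)
    meta = []
    for i, r in enumerate(records):
        raw = r.message.encode("ascii")
        if len(raw) != serialized_size(n_pts) - 1:  # no trailing newline stored
            raise ParseError(
                f"record {r.record_number}: message length {len(raw)} does not "
                f"match {n_pts}-point format", offset=len(raw),
            )
        payloads[i] = np.frombuffer(raw[HEADER_BYTES:] + b"\n", dtype=np.uint8)
        meta.append((
            r.logger_timestamp, r.record_number, r.latitude, r.longitude,
            r.gnss_quality, r.easting, r.northing, raw[1:3].decode(),
            int(raw[4:12]), int(raw[13:17]), int(raw[18:22]),
        ))
    distances = decode_distance_block(payloads) if records else \
        np.empty((0, n_pts), dtype=np.int32)
    df = pd.DataFrame(meta, columns=[
        "timestamp", "record", "latitude", "longitude", "gnss_quality",
        "easting", "northing", "address", "controller_ms", "zref_mm",
        "sref_mm",
    ])
    angle_cols = pd.DataFrame(
        distances, columns=[f"d{j:03d}" for j in range(n_pts)], index=df.index
    )
    return pd.concat([df, angle_cols], axis=1)
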