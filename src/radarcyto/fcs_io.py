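"""Cytometry event I/O and preprocessing.

Reads and writes list-mode event data as FCS 3.0/3.1 or CSV, applies
spillover compensation and arcsinh intensity transforms, and merges
samples on marker identity (so a tube whose panel swapped one reagent
name-for-name still lines up channel by channel).

The FCS support here is deliberately small: list mode (``$MODE L``),
floating-point data (``$DATATYPE F`` or ``D``), little- or big-endian.
That covers files this package writes and the common export dialect of
modern instruments; integer/packed dialects are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMeta",
    "EventMatrix",
    "FCSParseError",
    "canonical_marker",
    "compensate",
    "merge_samples",
    "read_events",
    "transform_arcsinh",
    "write_events",
]

_SCATTER_RE = re.compile(r"^(fsc|ssc)", re.IGNORECASE)


class FCSParseError(ValueError):
    """Raised when an FCS file violates the keyword/data conventions."""


def canonical_marker(name: str) -> str:
    """Canonical form used for marker matching: case-insensitive,
    leading/trailing/internal whitespace collapsed. Combined reagents
    (e.g. ``CD66c+CD123``) stay verbatim and match as one marker."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class ChannelMeta:
    """One acquired parameter: an antigen/stain or a scatter channel."""

    marker: str
    detector: str = ""
    is_scatter: bool | None = None

    def __post_init__(self):
        if not str(self.marker).strip():
            raise ValueError("marker name must be non-empty")
        if self.is_scatter is None:
            object.__setattr__(
                self, "is_scatter", bool(_SCATTER_RE.match(self.marker))
            )


@dataclass
class EventMatrix:
    """Events x channels matrix with per-channel metadata.

    ``origin`` (sample-of-origin id) and ``labels`` (truth population
    labels on synthetic data) are optional per-event annotations.
    """

    values: np.ndarray
    channels: list[ChannelMeta]
    origin: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"channel count ({len(self.channels)}) does not match matrix "
                f"width ({self.values.shape[1]})"
            )
        if np.isnan(self.values).any():
            raise ValueError("event matrix contains NaN after ingest")
        keys = [canonical_marker(c.marker) for c in self.channels]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate marker names within tube: {dupes}")
        for name in ("origin", "labels"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=object)
                if a.shape != (self.values.shape[0],):
                    raise ValueError(f"{name} length must equal event count")
                setattr(self, name, a)

    # -- introspection -------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def marker_index(self, marker: str) -> int:
        key = canonical_marker(marker)
        for i, c in enumerate(self.channels):
            if canonical_marker(c.marker) == key:
                return i
        raise KeyError(f"marker {marker!r} not present in event matrix")

    def get(self, marker: str) -> np.ndarray:
        """Column of intensities for one marker."""
        return self.values[:, self.marker_index(marker)]

    def fluorescence_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if not c.is_scatter]

    # -- manipulation --------------------------------------------------
    def subset(self, mask: np.ndarray) -> "EventMatrix":
        mask = np.asarray(mask)
        return EventMatrix(
            self.values[mask],
            list(self.channels),
            None if self.origin is None else self.origin[mask],
            None if self.labels is None else self.labels[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        return df


# ---------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels.csv")


def _read_csv(path: Path) -> EventMatrix:
    df = pd.read_csv(path)
    if df.shape[1] == 0:
        raise FCSParseError(f"{path}: CSV has no columns")
    channels = [ChannelMeta(marker=str(c), detector=str(c)) for c in df.columns]
    labels = origin = None
    side = _sidecar_path(path)
    if side.exists():
        sdf = pd.read_csv(side, dtype=str)
        if len(sdf) != len(df):
            raise FCSParseError(
                f"{side}: sidecar has {len(sdf)} rows, data has {len(df)}"
            )
        if "label" in sdf.columns:
            labels = sdf["label"].to_numpy(dtype=object)
        if "origin" in sdf.columns:
            origin = sdf["origin"].to_numpy(dtype=object)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FCSParseError(f"{path}: non-numeric CSV value ({e})") from None
    return EventMatrix(values, channels, origin=origin, labels=labels)


def _write_csv(path: Path, m: EventMatrix) -> None:
    m.to_dataframe().to_csv(path, index=False)
    if m.labels is not None or m.origin is not None:
        n = m.n_events
        sdf = pd.DataFrame(
            {
                "label": m.labels if m.labels is not None else [""] * n,
                "origin": m.origin if m.origin is not None else [""] * n,
            }
        )
        sdf.to_csv(_sidecar_path(path), index=False)


# ---------------------------------------------------------------------
# FCS 3.0 / 3.1
# ---------------------------------------------------------------------

_DTYPES = {"F": 4, "D": 8}


def _read_fcs(path: Path) -> EventMatrix:
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FCSParseError(f"{path}: file shorter than an FCS header")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FCSParseError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo, hi):
        txt = raw[lo:hi].decode("ascii", "replace").strip()
        return int(txt) if txt else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_begin:
        raise FCSParseError(f"{path}: invalid TEXT segment offsets")

    text = raw[text_begin : text_end + 1].decode("latin-1")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    kw = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts), 2)
    }

    def _need(key):
        if key not in kw:
            raise FCSParseError(f"{path}: missing required keyword {key}")
        return kw[key]

    if _need("$MODE").strip().upper() != "L":
        raise FCSParseError(f"{path}: only list mode ($MODE L) is supported")
    datatype = _need("$DATATYPE").strip().upper()
    if datatype not in _DTYPES:
        raise FCSParseError(
            f"{path}: unsupported $DATATYPE {datatype!r} (need F or D)"
        )
    byteord = _need("$BYTEORD").strip()
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FCSParseError(f"{path}: unsupported $BYTEORD {byteord!r}")
    par = int(_need("$PAR"))
    tot = int(_need("$TOT"))

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    itemsize = _DTYPES[datatype]
    expected = par * tot * itemsize
    available = data_end - data_begin + 1
    if available < expected:
        raise FCSParseError(
            f"{path}: $TOT={tot} x $PAR={par} needs {expected} data bytes "
            f"but the DATA segment holds {available}"
        )
    buf = raw[data_begin : data_begin + expected]
    values = np.frombuffer(buf, dtype=f"{endian}f{itemsize}").reshape(tot, par)

    channels = []
    for j in range(1, par + 1):
        detector = kw.get(f"$P{j}N", f"P{j}").strip()
        stain = kw.get(f"$P{j}S", "").strip()
        channels.append(ChannelMeta(marker=stain or detector, detector=detector))

    labels = origin = None
    side = _sidecar_path(Path(path))
    if side.exists():
        sdf = pd.read_csv(side, dtype=str)
        if len(sdf) == tot:
            if "label" in sdf.columns:
                labels = sdf["label"].to_numpy(dtype=object)
            if "origin" in sdf.columns:
                origin = sdf["origin"].to_numpy(dtype=object)
    return EventMatrix(
        np.ascontiguousarray(values, dtype=float), channels,
        origin=origin, labels=labels,
    )


def _write_fcs(path: Path, m: EventMatrix, datatype: str = "D") -> None:
    if datatype not in _DTYPES:
        raise ValueError("datatype must be 'F' (float32) or 'D' (float64)")
    n, p = m.values.shape
    itemsize = _DTYPES[datatype]
    payload = np.ascontiguousarray(m.values, dtype=f"<f{itemsize}").tobytes()

    delim = "/"
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 10,  # placeholder, fixed width
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": datatype,
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(p),
        "$TOT": str(n),
    }
    maxval = float(np.max(np.abs(m.values))) if m.values.size else 1.0
    rng_kw = str(int(10 ** np.ceil(np.log10(max(maxval, 1.0) + 1))))
    for j, c in enumerate(m.channels, start=1):
        name = c.detector or c.marker
        for text_val in (name, c.marker):
            if delim in text_val:
                raise ValueError(
                    f"channel name {text_val!r} contains the TEXT delimiter"
                )
        kw[f"$P{j}N"] = name
        kw[f"$P{j}S"] = c.marker
        kw[f"$P{j}B"] = str(itemsize * 8)
        kw[f"$P{j}E"] = "0,0"
        kw[f"$P{j}R"] = rng_kw

    def _render(kws: dict[str, str]) -> str:
        body = delim.join(x for pair in kws.items() for x in pair)
        return delim + body + delim

    text_begin = 64
    text = _render(kw)
    data_begin = text_begin + len(text)
    data_end = data_begin + len(payload) - 1
    kw["$BEGINDATA"] = f"{data_begin:010d}"
    kw["$ENDDATA"] = f"{data_end:010d}"
    text = _render(kw)
    assert text_begin + len(text) == data_begin  # placeholder width is fixed

    header = "FCS3.1".ljust(10)
    for off in (text_begin, text_begin + len(text) - 1, data_begin, data_end, 0, 0):
        header += f"{off:>8d}" if off <= 99_999_999 else f"{0:>8d}"
    blob = header.encode("ascii")
    blob += b" " * (text_begin - len(blob))
    blob += text.encode("latin-1") + payload
    Path(path).write_bytes(blob)

    if m.labels is not None or m.origin is not None:
        sdf = pd.DataFrame(
            {
                "label": m.labels if m.labels is not None else [""] * n,
                "origin": m.origin if m.origin is not None else [""] * n,
            }
        )
        sdf.to_csv(_sidecar_path(Path(path)), index=False)


# ---------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".fcs":
        return "fcs"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer event-file format from {path.name!r}")


def read_events(path, fmt: str | None = None) -> EventMatrix:
    """Read an event file (FCS 3.0/3.1 or CSV with a marker header row).

    A ``<name>.labels.csv`` sidecar with ``label``/``origin`` columns is
    picked up automatically when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "fcs":
        return _read_fcs(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_events(path, m: EventMatrix, fmt: str | None = None,
                 datatype: str = "D") -> None:
    """Write events as FCS 3.1 (list mode, floating point) or CSV.

    Truth labels/origins, which FCS cannot carry, go to a
    ``<name>.labels.csv`` sidecar next to the file.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "fcs":
        _write_fcs(path, m, datatype=datatype)
    elif fmt == "csv":
        _write_csv(path, m)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def compensate(m: EventMatrix, spillover, markers=None) -> EventMatrix:
    """Apply spillover compensation: ``values' = values @ inv(S)`` on the
    fluorescence channels.

    ``spillover`` is a square matrix over the fluorescence channels —
    either a pandas DataFrame whose columns name the markers, or a bare
    array in the order given by ``markers`` (default: the matrix's
    fluorescence channels in channel order).
    """
    if isinstance(spillover, pd.DataFrame):
        markers = [str(c) for c in spillover.columns]
        S = spillover.to_numpy(dtype=float)
    else:
        S = np.asarray(spillover, dtype=float)
    fl = m.fluorescence_indices()
    if markers is None:
        idx = fl
    else:
        idx = [m.marker_index(name) for name in markers]
        if set(idx) != set(fl):
            raise ValueError(
                "spillover channels must be exactly the fluorescence channels"
            )
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] != len(idx):
        raise ValueError(
            f"spillover must be square of dimension {len(idx)} "
            f"(got {S.shape})"
        )
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ValueError("singular spillover matrix") from None
    if not np.isfinite(S_inv).all() or np.linalg.cond(S) > 1e12:
        raise ValueError("singular (ill-conditioned) spillover matrix")
    values = m.values.copy()
    values[:, idx] = values[:, idx] @ S_inv
    return replace(m, values=values)


def transform_arcsinh(m: EventMatrix, cofactor: float = 150.0,
                      markers=None) -> EventMatrix:
    """``x -> asinh(x / cofactor)`` on fluorescence channels; scatter is
    left untouched. Cofactor 150 suits conventional cytometers."""
    if not cofactor > 0:
        raise ValueError("cofactor must be positive")
    idx = (
        m.fluorescence_indices()
        if markers is None
        else [m.marker_index(name) for name in markers]
    )
    values = m.values.copy()
    values[:, idx] = np.arcsinh(values[:, idx] / float(cofactor))
    return replace(m, values=values)


def merge_samples(samples: list[EventMatrix], origin_ids=None) -> EventMatrix:
    """Concatenate samples on marker identity.

    All samples must share the same marker set (matched canonically by
    marker name, not by detector); channel order is canonicalized to the
    first sample's. The origin column records each event's sample.
    """
    if not samples:
        raise ValueError("merge_samples needs at least one sample")
    if origin_ids is None:
        origin_ids = [f"sample_{i}" for i in range(len(samples))]
    if len(origin_ids) != len(samples):
        raise ValueError("origin_ids length must match samples")

    ref = samples[0]
    ref_keys = [canonical_marker(c.marker) for c in ref.channels]
    ref_names = {canonical_marker(c.marker): c.marker for c in ref.channels}
    blocks, origins, labels, any_labels = [], [], [], False
    for s in samples:
        names = {canonical_marker(c.marker): c.marker for c in s.channels}
        if set(names) != set(ref_keys):
            missing = sorted(ref_names[k] for k in set(ref_keys) - set(names))
            extra = sorted(names[k] for k in set(names) - set(ref_keys))
            raise ValueError(
                f"marker-set mismatch: missing {missing}, unexpected {extra}"
            )
        if s.labels is not None:
            any_labels = True
    for s, oid in zip(samples, origin_ids):
        perm = [s.marker_index(k) for k in ref_keys]
        blocks.append(s.values[:, perm])
        if s.origin is not None:
            origins.append(s.origin)
        else:
            origins.append(np.full(s.n_events, oid, dtype=object))
        if any_labels:
            labels.append(
                s.labels
                if s.labels is not None
                else np.full(s.n_events, "", dtype=object)
            )
    return EventMatrix(
        np.vstack(blocks),
        list(ref.channels),
        origin=np.concatenate(origins),
        labels=np.concatenate(labels) if any_labels else None,
    )
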