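"""Core data types for time-tagged photon streams and bursts.

A :class:`PhotonStream` is the universal interchange object of the package:
an ordered sequence of photon macrotimes (in microseconds) with a detection
channel (donor/acceptor) and an excitation-period label (donor/acceptor
excitation, as used in pulsed interleaved excitation, PIE). Both the
simulator and external readers produce this representation; all downstream
analysis (burst search, variance traces, correlations) consumes it.

Streams are stored on disk in an HDF5 container with a photon-HDF5-flavoured
layout: ``/photon_data/timestamps`` holds integer nanoseconds (bit-exact
round trips) and ``/photon_data/detectors`` holds a small integer per photon
whose mapping to (channel, excitation) is recorded in dataset attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List

import h5py
import numpy as np

#: channel codes
DONOR, ACCEPTOR = 0, 1
#: excitation-period codes
DONOR_EX, ACCEPTOR_EX = 0, 1

_NS_PER_US = 1000


class PhotonStreamError(ValueError):
    """Invalid photon-stream content or container."""


class EmptyStreamError(PhotonStreamError):
    """File or stream contains zero photons."""


class ChannelMappingError(PhotonStreamError):
    """Container does not declare how detector ids map to channels."""


@dataclass
class PhotonStream:
    """Ordered time-tagged photons with channel and excitation labels.

    Parameters
    ----------
    times : ndarray of float64
        Photon macrotimes in microseconds, sorted ascending.
    channel : ndarray of int8
        ``DONOR`` (0) or ``ACCEPTOR`` (1) per photon.
    excitation : ndarray of int8
        ``DONOR_EX`` (0) or ``ACCEPTOR_EX`` (1) per photon (PIE half-period).
    duration_s : float
        Total trace length in seconds.
    metadata : dict
        Correction parameters and, for simulated data, ground truth.
    """

    times: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray
    duration_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.int8)
        self.excitation = np.asarray(self.excitation, dtype=np.int8)
        n = self.times.size
        if self.channel.size != n or self.excitation.size != n:
            raise PhotonStreamError(
                "channel/excitation arrays must match the number of photons"
            )
        if n and np.any(np.diff(self.times) < 0):
            raise PhotonStreamError("macrotimes must be sorted ascending")
        if n and (self.times[0] < 0 or self.times[-1] > self.duration_s * 1e6):
            raise PhotonStreamError("macrotimes outside [0, duration]")

    @property
    def n_photons(self) -> int:
        return int(self.times.size)

    def slice(self, start: int, stop: int) -> "PhotonStream":
        """Half-open photon-index slice, preserving absolute times."""
        return PhotonStream(
            self.times[start:stop],
            self.channel[start:stop],
            self.excitation[start:stop],
            self.duration_s,
            self.metadata,
        )


@dataclass
class Burst:
    """A contiguous photon slice of a stream, with raw and corrected counts.

    Raw counts are split by (channel, excitation): ``n_dd_raw``/``n_da_raw``
    are donor/acceptor-channel counts after donor excitation (the classical
    d_i and a_i), ``n_aa_raw`` is the acceptor-channel count after acceptor
    excitation. Corrected counts, the FRET efficiency E, the PIE
    stoichiometry and the bleaching diagnostics are filled in by
    :func:`trbva.burst_pipeline.correct_burst`.
    """

    start: int          # photon index, inclusive
    stop: int           # photon index, exclusive
    t_start: float      # us, first photon
    t_stop: float       # us, last photon
    n_dd_raw: int
    n_da_raw: int
    n_aa_raw: int
    n_aex_raw: int      # all photons after acceptor excitation (any channel)
    sum_t_dex: float    # us, summed macrotimes of donor-excitation photons
    sum_t_aex: float    # us, summed macrotimes of acceptor-excitation photons
    # corrected quantities (NaN until correct_burst is applied)
    n_dd: float = np.nan
    n_da: float = np.nan
    n_aa: float = np.nan
    E: float = np.nan
    s_pie: float = np.nan
    alpha_pie: float = np.nan
    sigma_pie: float = np.nan
    clamped: bool = False

    @property
    def a_i(self) -> int:
        """Raw acceptor count after donor excitation."""
        return self.n_da_raw

    @property
    def d_i(self) -> int:
        """Raw donor count after donor excitation."""
        return self.n_dd_raw

    @property
    def n_i(self) -> int:
        """Total raw photons after donor excitation."""
        return self.n_dd_raw + self.n_da_raw

    @property
    def duration_us(self) -> float:
        return self.t_stop - self.t_start

    @property
    def duration_ms(self) -> float:
        return (self.t_stop - self.t_start) * 1e-3

    @property
    def eps_raw(self) -> float:
        """Raw proximity ratio a_i / n_i (always in [0, 1])."""
        return self.n_da_raw / max(self.n_i, 1)


def write_photon_stream(stream: PhotonStream, path) -> None:
    """Write a stream to an HDF5 container (timestamps as integer ns)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        ts = np.round(stream.times * _NS_PER_US).astype(np.int64)
        d_ts = g.create_dataset("timestamps", data=ts)
        d_ts.attrs["timestamps_unit"] = 1e-9  # seconds per unit
        det = (stream.channel.astype(np.int8)
               + 2 * stream.excitation.astype(np.int8))
        d_det = g.create_dataset("detectors", data=det.astype(np.int8))
        # detector id -> (spectral channel, excitation period)
        d_det.attrs["spectral_ch"] = np.array([0, 1, 0, 1], dtype=np.int8)
        d_det.attrs["excitation_ch"] = np.array([0, 0, 1, 1], dtype=np.int8)
        f.attrs["acquisition_duration_s"] = float(stream.duration_s)
        f.attrs["has_acceptor_excitation"] = bool(
            np.any(stream.excitation == ACCEPTOR_EX)
        )
        f.create_dataset(
            "metadata", data=json.dumps(stream.metadata, default=_json_default)
        )


def read_photon_stream(path, dialect: str = "internal") -> PhotonStream:
    """Read a stream written by :func:`write_photon_stream` or a compatible
    photon-HDF5-style file.

    Parameters
    ----------
    dialect : {"internal", "photon_hdf5"}
        ``internal`` expects integer-nanosecond timestamps; ``photon_hdf5``
        additionally honours a ``timestamps_unit`` attribute (seconds per
        clock unit). Both require the detector-mapping attributes
        ``spectral_ch`` and ``excitation_ch`` on the detectors dataset.
    """
    if dialect not in ("internal", "photon_hdf5"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with h5py.File(path, "r") as f:
        try:
            d_ts = f["photon_data/timestamps"]
            d_det = f["photon_data/detectors"]
        except KeyError as exc:
            raise PhotonStreamError(f"{path}: missing photon_data group") from exc
        ts = d_ts[()]
        if ts.size == 0:
            raise EmptyStreamError(f"{path}: contains zero photons")
        if ("spectral_ch" not in d_det.attrs
                or "excitation_ch" not in d_det.attrs):
            raise ChannelMappingError(
                f"{path}: detectors dataset lacks spectral_ch/excitation_ch "
                "mapping attributes"
            )
        spectral = np.asarray(d_det.attrs["spectral_ch"], dtype=np.int8)
        excit = np.asarray(d_det.attrs["excitation_ch"], dtype=np.int8)
        det = d_det[()].astype(np.int64)
        if dialect == "photon_hdf5":
            unit_s = float(d_ts.attrs.get("timestamps_unit", 1e-9))
        else:
            unit_s = 1e-9
        if unit_s == 1e-9:
            times = ts.astype(np.float64) / 1000.0  # exact ns -> us
        else:
            times = ts.astype(np.float64) * (unit_s * 1e6)
        if np.any(np.diff(ts) < 0):
            raise PhotonStreamError(f"{path}: timestamps not sorted")
        duration_s = float(
            f.attrs.get("acquisition_duration_s", times[-1] * 1e-6)
        )
        metadata = {}
        if "metadata" in f:
            raw = f["metadata"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            metadata = json.loads(raw)
    return PhotonStream(
        times=times,
        channel=spectral[det],
        excitation=excit[det],
        duration_s=duration_s,
        metadata=metadata,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def bursts_to_frame(bursts: List[Burst]):
    """Burst list -> pandas DataFrame (one row per burst)."""
    import pandas as pd

    cols = [
        "start", "stop", "t_start", "t_stop",
        "n_dd_raw", "n_da_raw", "n_aa_raw", "n_aex_raw",
        "n_dd", "n_da", "n_aa", "E", "s_pie", "alpha_pie", "sigma_pie",
        "clamped",
    ]
    data = {c: [getattr(b, c) for b in bursts] for c in cols}
    frame = pd.DataFrame(data)
    frame["eps_raw"] = [b.eps_raw for b in bursts]
    return frame
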