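"""Single-molecule FRET burst analysis with pulsed interleaved excitation (PIE).

Photons from freely diffusing dual-labelled molecules arrive in bursts as
molecules transit the confocal volume.  Each photon carries a detection
channel (donor or acceptor emission) and an excitation slot (donor or
acceptor laser of the interleaved pair).  Bursts are located with the
all-photon burst search (APBS), photon counts are partitioned into
F_DD / F_DA / F_AA, and corrected FRET efficiency E and stoichiometry S are
computed per burst:

    F_corr = F_DA - Lk * F_DD - DE * F_AA
    E = F_corr / (F_corr + gamma * F_DD)
    S = (F_corr + gamma * F_DD) / (F_corr + gamma * F_DD + F_AA)

where Lk is donor leakage into the acceptor channel, DE is direct acceptor
excitation at the donor wavelength and gamma the detection/quantum-yield
imbalance between the two channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("protconf")

# photon tag encodings (uint8)
DONOR_EM = 0
ACCEPTOR_EM = 1
DONOR_EX = 0
ACCEPTOR_EX = 1

CHANNEL_NAMES = {DONOR_EM: "donor_em", ACCEPTOR_EM: "acceptor_em"}
EXCITATION_NAMES = {DONOR_EX: "donor_ex", ACCEPTOR_EX: "acceptor_ex"}

#: measurement defaults: APBS 0.5 ms integration window, bursts kept only
#: above 35 total counts (strict), local-count region threshold m = 10
DEFAULT_WINDOW_MS = 0.5
DEFAULT_MIN_COUNTS = 35
DEFAULT_REGION_THRESHOLD = 10

#: stoichiometry gate retaining dual-labelled molecules
DEFAULT_S_MIN = 0.25
DEFAULT_S_MAX = 0.75


@dataclass(frozen=True)
class PhotonStream:
    """Time-tagged, channel-tagged, excitation-tagged photon records.

    ``timestamps`` are int64 nanoseconds since measurement start, strictly
    increasing; ``channel`` and ``excitation`` are uint8 codes from the
    module-level enums.
    """

    timestamps: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=np.int64)
        ch = np.asarray(self.channel, dtype=np.uint8)
        ex = np.asarray(self.excitation, dtype=np.uint8)
        if not (len(t) == len(ch) == len(ex)):
            raise ValueError("timestamps/channel/excitation must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(ch) and not np.all((ch == DONOR_EM) | (ch == ACCEPTOR_EM)):
            raise ValueError("invalid channel codes")
        if len(ex) and not np.all((ex == DONOR_EX) | (ex == ACCEPTOR_EX)):
            raise ValueError("invalid excitation codes")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "channel", ch)
        object.__setattr__(self, "excitation", ex)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_ns(self) -> int:
        return 0 if len(self) == 0 else int(self.timestamps[-1])

    # ---- I/O ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "timestamp_ns": self.timestamps,
                "channel": [CHANNEL_NAMES[c] for c in self.channel],
                "excitation": [EXCITATION_NAMES[e] for e in self.excitation],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhotonStream":
        df = pd.read_csv(path)
        ch_map = {v: k for k, v in CHANNEL_NAMES.items()}
        ex_map = {v: k for k, v in EXCITATION_NAMES.items()}
        return cls(
            df["timestamp_ns"].to_numpy(np.int64),
            df["channel"].map(ch_map).to_numpy(np.uint8),
            df["excitation"].map(ex_map).to_numpy(np.uint8),
        )

    def to_hdf5(self, path: str | Path) -> None:
        """Write a Photon-HDF5-style file (timestamps int64 ns, detector uint8)."""
        with h5py.File(path, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=self.timestamps, dtype="int64")
            g.create_dataset("detectors", data=self.channel, dtype="uint8")
            g.create_dataset("excitation", data=self.excitation, dtype="uint8")
            g.attrs["timestamps_unit_ns"] = 1.0

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            g = f["photon_data"]
            return cls(g["timestamps"][:], g["detectors"][:], g["excitation"][:])


@dataclass(frozen=True)
class Burst:
    """Contiguous photon cluster: half-open index range [start, stop)."""

    start: int
    stop: int
    start_time_ns: int
    stop_time_ns: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("burst stop index must exceed start index")

    @property
    def n_photons(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class ChannelCounts:
    """PIE partition of burst photons.

    ``f_dd``: donor emission under donor excitation; ``f_da``: acceptor
    emission under donor excitation; ``f_aa``: acceptor emission under
    acceptor excitation.  Donor emission under acceptor excitation carries no
    FRET information and is reported separately as a diagnostic.
    """

    f_dd: int
    f_da: int
    f_aa: int
    f_d_aex: int = 0

    def __post_init__(self) -> None:
        for v in (self.f_dd, self.f_da, self.f_aa, self.f_d_aex):
            if v < 0:
                raise ValueError("photon counts must be non-negative")


@dataclass(frozen=True)
class CorrectionSet:
    """Spectral/instrumental corrections: leakage Lk, direct excitation DE,
    gamma factor.  Defaults are the calibrated values for the AF555/AF647
    instrument (DNA-ruler calibration)."""

    lk: float = 0.08
    de: float = 0.15
    gamma: float = 0.85

    def __post_init__(self) -> None:
        if not (0 <= self.lk < 1 and 0 <= self.de < 1):
            raise ValueError("Lk and DE must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def neutral(cls) -> "CorrectionSet":
        return cls(lk=0.0, de=0.0, gamma=1.0)


@dataclass(frozen=True)
class ESPoint:
    """Corrected (E, S) for one burst.  E may fall slightly outside [0, 1]
    after correction; ``valid`` is False when the corrected denominator
    vanished (no usable signal)."""

    e: float
    s: float
    counts: ChannelCounts
    burst: Burst | None = None
    valid: bool = True


# --------------------------------------------------------------------------
# burst search
# --------------------------------------------------------------------------

def find_bursts(
    stream: PhotonStream,
    window_ms: float = DEFAULT_WINDOW_MS,
    min_counts: int = DEFAULT_MIN_COUNTS,
    region_threshold: int = DEFAULT_REGION_THRESHOLD,
) -> list[Burst]:
    """All-photon burst search (APBS).

    A photon is in a burst region when the window of width ``window_ms``
    centred on it contains at least ``region_threshold`` photons (all
    channels pooled).  Maximal runs of in-region photons are formed, runs
    closer in time than one window width are concatenated, and only runs
    with strictly more than ``min_counts`` photons are returned.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if min_counts < 0:
        raise ValueError("min_counts must be non-negative")
    t = stream.timestamps
    n = len(t)
    if n == 0:
        return []
    half = int(round(window_ms * 1e6 / 2))  # ns
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    in_region = (hi - lo) >= region_threshold

    idx = np.flatnonzero(in_region)
    if idx.size == 0:
        return []
    # maximal runs of in-region photons: a run breaks on an out-of-region
    # photon or on a silent stretch of at least one window width
    breaks = np.flatnonzero((np.diff(idx) > 1)
                            | (np.diff(t[idx]) >= 2 * half))
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, stops)]

    # concatenate runs separated by less than one window width
    gap_ns = 2 * half
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if t[a] - t[merged[-1][1] - 1] < gap_ns:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    bursts = [
        Burst(a, b, int(t[a]), int(t[b - 1]))
        for a, b in merged
        if (b - a) > min_counts
    ]
    logger.debug("APBS: %d photons -> %d regions -> %d bursts", n, len(runs), len(bursts))
    return bursts


def find_bursts_binned(
    stream: PhotonStream,
    bin_ms: float = DEFAULT_WINDOW_MS,
    min_counts: int = DEFAULT_MIN_COUNTS,
    region_threshold: int = DEFAULT_REGION_THRESHOLD,
) -> list[Burst]:
    """Alternative APBS reading: fixed time bins of width ``bin_ms`` instead
    of a sliding window.  Consecutive bins holding at least
    ``region_threshold`` photons form a region; regions with more than
    ``min_counts`` photons are bursts."""
    t = stream.timestamps
    if len(t) == 0:
        return []
    width = int(round(bin_ms * 1e6))
    bins = t // width
    uniq, first_idx, counts = np.unique(bins, return_index=True, return_counts=True)
    hot = counts >= region_threshold
    bursts: list[Burst] = []
    i = 0
    while i < len(uniq):
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(uniq) and hot[j + 1] and uniq[j + 1] == uniq[j] + 1:
            j += 1
        a = int(first_idx[i])
        b = int(first_idx[j] + counts[j])
        if (b - a) > min_counts:
            bursts.append(Burst(a, b, int(t[a]), int(t[b - 1])))
        i = j + 1
    return bursts


# --------------------------------------------------------------------------
# per-burst photon partition and corrected E/S
# --------------------------------------------------------------------------

def integrate_burst(stream: PhotonStream, burst: Burst) -> ChannelCounts:
    """Tally the channel x excitation combinations inside one burst."""
    if burst.start < 0 or burst.stop > len(stream):
        raise IndexError("burst indices out of stream range")
    ch = stream.channel[burst.start : burst.stop]
    ex = stream.excitation[burst.start : burst.stop]
    f_dd = int(np.sum((ch == DONOR_EM) & (ex == DONOR_EX)))
    f_da = int(np.sum((ch == ACCEPTOR_EM) & (ex == DONOR_EX)))
    f_aa = int(np.sum((ch == ACCEPTOR_EM) & (ex == ACCEPTOR_EX)))
    f_d_aex = int(np.sum((ch == DONOR_EM) & (ex == ACCEPTOR_EX)))
    return ChannelCounts(f_dd, f_da, f_aa, f_d_aex)


def compute_es(counts: ChannelCounts, corr: CorrectionSet | None = None) -> ESPoint:
    """Corrected FRET efficiency and stoichiometry for one burst."""
    if corr is None:
        corr = CorrectionSet()
    f_corr = counts.f_da - corr.lk * counts.f_dd - corr.de * counts.f_aa
    den_e = f_corr + corr.gamma * counts.f_dd
    den_s = den_e + counts.f_aa
    if den_e == 0 or den_s == 0:
        return ESPoint(np.nan, np.nan, counts, valid=False)
    return ESPoint(float(f_corr / den_e), float(den_e / den_s), counts)


def filter_stoichiometry(
    points: Sequence[ESPoint],
    s_min: float = DEFAULT_S_MIN,
    s_max: float = DEFAULT_S_MAX,
) -> list[ESPoint]:
    """Keep dual-labelled molecules: s_min <= S <= s_max (inclusive)."""
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    return [p for p in points if p.valid and s_min <= p.s <= s_max]


# --------------------------------------------------------------------------
# convenience: stream -> gated burst table
# --------------------------------------------------------------------------

def analyze_stream(
    stream: PhotonStream,
    window_ms: float = DEFAULT_WINDOW_MS,
    min_counts: int = DEFAULT_MIN_COUNTS,
    region_threshold: int = DEFAULT_REGION_THRESHOLD,
    corr: CorrectionSet | None = None,
    s_min: float = DEFAULT_S_MIN,
    s_max: float = DEFAULT_S_MAX,
) -> pd.DataFrame:
    """Run burst search, PIE partition, correction and S-gating.

    Returns one row per burst with columns (burst_id, t_start_ns, t_stop_ns,
    n_photons, F_DD, F_DA, F_AA, E, S, kept_flag); ``kept_flag`` marks
    bursts surviving the stoichiometry gate.
    """
    if corr is None:
        corr = CorrectionSet()
    bursts = find_bursts(stream, window_ms, min_counts, region_threshold)
    rows = []
    for i, b in enumerate(bursts):
        c = integrate_burst(stream, b)
        p = compute_es(c, corr)
        kept = bool(p.valid and s_min <= p.s <= s_max)
        rows.append(
            (i, b.start_time_ns, b.stop_time_ns, b.n_photons,
             c.f_dd, c.f_da, c.f_aa, p.e, p.s, kept)
        )
    df = pd.DataFrame(
        rows,
        columns=["burst_id", "t_start_ns", "t_stop_ns", "n_photons",
                 "F_DD", "F_DA", "F_AA", "E", "S", "kept_flag"],
    )
    logger.info(
        "stream: %d photons, %d bursts, %d kept after S-gate [%g, %g]",
        len(stream), len(df), int(df["kept_flag"].sum()) if len(df) else 0,
        s_min, s_max,
    )
    return df
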