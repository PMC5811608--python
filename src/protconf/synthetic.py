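"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) PIE photon streams from freely diffusing molecules in a
two-state (closed/open) conformational mixture, with spectral crosstalk,
direct acceptor excitation, detection-efficiency (gamma) imbalance and
background applied in the forward direction; (ii) toy two-domain structures
with exactly known inter-site distances; (iii) noisy Debye scattering
curves; and (iv) chromogenic progress curves with a parabolic onset.

Bursts are generated directly — burst arrivals as a Poisson process,
per-burst brightness from a configurable size law — rather than by
simulating diffusion through the confocal volume: the downstream analysis
only ever sees photon clusters.

Forward corruption order (the inverse corrections in :mod:`protconf.burst`
undo it in expectation): FRET partition -> leakage -> direct excitation ->
gamma as detection-efficiency imbalance -> background.  Concretely, a
donor-excitation event takes the FRET pathway with probability E*; FRET
photons are detected with efficiency eta_A = gamma/(1+Lk) * eta_D; donor
photons are detected with efficiency eta_D and then routed to the acceptor
channel with probability Lk/(1+Lk), so E[leak] = Lk * E[F_DD]; direct
excitation adds Binomial(F_AA, DE) photons to F_DA.  With those choices the
standard (Lk, DE, gamma) inversion is exact in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .burst import (
    ACCEPTOR_EM,
    ACCEPTOR_EX,
    DONOR_EM,
    DONOR_EX,
    Burst,
    CorrectionSet,
    PhotonStream,
)
from .kinetics import KineticParams, ProgressCurve, progress_model
from .saxs import SAXSProfile, debye_profile
from .structure import StructureModel

logger = logging.getLogger("protconf")

#: species codes in the ground truth
DUAL, DONOR_ONLY, ACCEPTOR_ONLY = 0, 1, 2


@dataclass(frozen=True)
class SimConfig:
    """Generative study conditions for a PIE smFRET measurement.

    Defaults emulate the prothrombin experiment: a two-state conformational
    mixture with the closed form at E = 0.58 occupying 80 % and the open
    form at E = 0.16 occupying 20 %, embedded corrections
    (Lk, DE, gamma) = (0.08, 0.15, 0.85), and modest single-labelled
    impurities and background.
    """

    duration_s: float = 30.0
    burst_rate: float = 40.0                    # bursts / s
    burst_size_mean: float = 100.0              # excitation events / burst
    burst_size_sigma: float = 0.4               # log-normal shape (size_law="lognormal")
    size_law: str = "lognormal"                 # or "geometric"
    burst_duration_ms: float = 1.0
    states: tuple[tuple[float, float], ...] = ((0.8, 0.58), (0.2, 0.16))
    donor_only_fraction: float = 0.10
    acceptor_only_fraction: float = 0.10
    embed_corrections: CorrectionSet = field(default_factory=CorrectionSet)
    background_rates: tuple[float, float] = (200.0, 200.0)  # photons/s per detection channel
    donor_excitation_duty: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 0 or self.burst_rate < 0 or self.burst_size_mean <= 0:
            raise ValueError("duration, burst_rate and burst_size_mean must be non-negative")
        occ = sum(f for f, _ in self.states)
        if abs(occ - 1.0) > 1e-9:
            raise ValueError("state occupancies must sum to 1")
        for f, e in self.states:
            if f < 0 or not (0.0 <= e <= 1.0):
                raise ValueError("occupancies must be >= 0 and true_E in [0, 1]")
        if not (0.0 <= self.donor_only_fraction <= 1.0
                and 0.0 <= self.acceptor_only_fraction <= 1.0
                and self.donor_only_fraction + self.acceptor_only_fraction <= 1.0):
            raise ValueError("species fractions must lie in [0, 1] and sum to <= 1")
        if any(r < 0 for r in self.background_rates):
            raise ValueError("background rates must be non-negative")
        if self.size_law not in ("lognormal", "geometric"):
            raise ValueError("size_law must be 'lognormal' or 'geometric'")


@dataclass
class GroundTruth:
    """Per emitted burst: time span, species and (for dual bursts) state."""

    t_start_ns: np.ndarray
    t_stop_ns: np.ndarray
    species: np.ndarray          # DUAL / DONOR_ONLY / ACCEPTOR_ONLY
    state: np.ndarray            # index into config.states; -1 for single-labelled
    true_e: np.ndarray           # nan for single-labelled
    config: SimConfig

    def __len__(self) -> int:
        return len(self.t_start_ns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start_ns": self.t_start_ns,
                "t_stop_ns": self.t_stop_ns,
                "species": self.species,
                "state": self.state,
                "true_e": self.true_e,
            }
        )

    def match_bursts(self, bursts: Sequence[Burst]) -> np.ndarray:
        """Index of the emitted burst with maximal time overlap for each
        found burst; -1 where a found burst overlaps no emitted one."""
        out = np.full(len(bursts), -1, dtype=int)
        for i, b in enumerate(bursts):
            overlap = (np.minimum(self.t_stop_ns, b.stop_time_ns)
                       - np.maximum(self.t_start_ns, b.start_time_ns))
            j = int(np.argmax(overlap))
            if overlap[j] > 0:
                out[i] = j
        return out


def _detection_efficiencies(corr: CorrectionSet) -> tuple[float, float]:
    """(eta_D, eta_A) realizing the requested gamma = eta_A (1+Lk) / eta_D."""
    eta_a = corr.gamma / (1.0 + corr.lk)
    if eta_a <= 1.0:
        return 1.0, eta_a
    return 1.0 / eta_a, 1.0


def simulate_photon_stream(config: SimConfig) -> tuple[PhotonStream, GroundTruth]:
    """Forward-simulate a PIE photon stream plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    corr = config.embed_corrections
    eta_d, eta_a = _detection_efficiencies(corr)
    p_leak = corr.lk / (1.0 + corr.lk)

    duration_ns = int(round(config.duration_s * 1e9))
    if duration_ns == 0:
        empty = np.zeros(0, dtype=np.int64)
        stream = PhotonStream(empty, empty.astype(np.uint8), empty.astype(np.uint8))
        truth = GroundTruth(empty, empty, empty.astype(int), empty.astype(int),
                            np.zeros(0), config)
        return stream, truth

    n_bursts = rng.poisson(config.burst_rate * config.duration_s)
    t0 = np.sort(rng.integers(0, duration_ns, n_bursts)).astype(np.int64)
    burst_len_ns = int(round(config.burst_duration_ms * 1e6))

    # species and state assignment
    u = rng.random(n_bursts)
    species = np.full(n_bursts, DUAL, dtype=int)
    species[u < config.donor_only_fraction] = DONOR_ONLY
    species[(u >= config.donor_only_fraction)
            & (u < config.donor_only_fraction + config.acceptor_only_fraction)] = ACCEPTOR_ONLY
    occ = np.array([f for f, _ in config.states])
    evals = np.array([e for _, e in config.states])
    state = rng.choice(len(occ), size=n_bursts, p=occ)
    state[species != DUAL] = -1
    true_e = np.where(species == DUAL, evals[np.clip(state, 0, None)], np.nan)

    # per-burst excitation-event budgets
    if config.size_law == "lognormal":
        mu = np.log(config.burst_size_mean) - 0.5 * config.burst_size_sigma ** 2
        sizes = np.maximum(1, np.round(
            rng.lognormal(mu, config.burst_size_sigma, n_bursts)).astype(int))
    else:
        sizes = 1 + rng.geometric(1.0 / config.burst_size_mean, n_bursts)

    ts_parts: list[np.ndarray] = []
    ch_parts: list[np.ndarray] = []
    ex_parts: list[np.ndarray] = []
    for k in range(n_bursts):
        n = sizes[k]
        n_dex = rng.binomial(n, config.donor_excitation_duty)
        n_aex = n - n_dex
        f_dd = f_da = f_aa = 0
        if species[k] == DUAL:
            f_aa = n_aex  # acceptor detection efficiency reference = 1
            n_fret = rng.binomial(n_dex, true_e[k])
            f_da_fret = rng.binomial(n_fret, eta_a)
            n_don = rng.binomial(n_dex - n_fret, eta_d)
            n_leak = rng.binomial(n_don, p_leak)
            f_dd = n_don - n_leak
            f_da = f_da_fret + n_leak + rng.binomial(f_aa, corr.de)
        elif species[k] == DONOR_ONLY:
            n_don = rng.binomial(n_dex, eta_d)
            n_leak = rng.binomial(n_don, p_leak)
            f_dd = n_don - n_leak
            f_da = n_leak
        else:  # ACCEPTOR_ONLY
            f_aa = n_aex
            f_da = rng.binomial(f_aa, corr.de)
        m = f_dd + f_da + f_aa
        if m == 0:
            continue
        t = t0[k] + np.sort(rng.integers(0, burst_len_ns, m)).astype(np.int64)
        ch = np.concatenate([
            np.full(f_dd, DONOR_EM), np.full(f_da, ACCEPTOR_EM),
            np.full(f_aa, ACCEPTOR_EM)]).astype(np.uint8)
        ex = np.concatenate([
            np.full(f_dd, DONOR_EX), np.full(f_da, DONOR_EX),
            np.full(f_aa, ACCEPTOR_EX)]).astype(np.uint8)
        perm = rng.permutation(m)
        ts_parts.append(t)
        ch_parts.append(ch[perm])
        ex_parts.append(ex[perm])

    # background: Poisson per detection channel, excitation slot Bernoulli 1/2
    for ch_code, rate in zip((DONOR_EM, ACCEPTOR_EM), config.background_rates):
        n_bg = rng.poisson(rate * config.duration_s)
        if n_bg == 0:
            continue
        t = rng.integers(0, duration_ns, n_bg).astype(np.int64)
        ts_parts.append(t)
        ch_parts.append(np.full(n_bg, ch_code, dtype=np.uint8))
        ex_parts.append(rng.integers(0, 2, n_bg).astype(np.uint8))

    if ts_parts:
        ts = np.concatenate(ts_parts)
        ch = np.concatenate(ch_parts)
        ex = np.concatenate(ex_parts)
        order = np.argsort(ts, kind="stable")
        ts, ch, ex = ts[order], ch[order], ex[order]
        # enforce strictly increasing int64 ns stamps with minimal nudges
        dup = np.flatnonzero(np.diff(ts) <= 0)
        while dup.size:
            ts[dup + 1] = ts[dup] + 1
            dup = np.flatnonzero(np.diff(ts) <= 0)
    else:
        ts = np.zeros(0, dtype=np.int64)
        ch = np.zeros(0, dtype=np.uint8)
        ex = np.zeros(0, dtype=np.uint8)

    stream = PhotonStream(ts, ch, ex)
    truth = GroundTruth(t0, t0 + burst_len_ns, species, state, true_e, config)
    logger.info("simulated %d photons in %d bursts (%.0f s)",
                len(stream), n_bursts, config.duration_s)
    return stream, truth


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------

def generate_toy_structure(
    n_atoms_per_domain: int = 50,
    domain_radius: float = 12.0,
    separation: float = 54.0,
    site_pairs: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
) -> StructureModel:
    """Two compact pseudo-atom clusters along x, ``separation`` apart.

    Each pseudo-atom is one residue carrying a single CA carbon.  The first
    atom of each domain sits exactly at its domain centre, so the distance
    between residues 1 and ``n_atoms_per_domain + 1`` equals ``separation``
    by construction.  ``site_pairs`` (atom index pairs) are validated to be
    distinct; the default labelled sites are the two centres.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if n_atoms_per_domain < 1:
        raise ValueError("need at least one atom per domain")
    if site_pairs:
        for i, j in site_pairs:
            if i == j:
                raise ValueError(f"labelled sites overlap (atom {i})")
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    xyz = []
    for c in centers:
        pts = [c]
        m = n_atoms_per_domain - 1
        if m:
            r = domain_radius * rng.random(m) ** (1.0 / 3.0)
            v = rng.normal(size=(m, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts.extend(c + r[:, None] * v)
        xyz.append(np.array(pts))
    xyz = np.vstack(xyz)
    n = 2 * n_atoms_per_domain
    return StructureModel(
        element=np.full(n, "C", dtype=object),
        name=np.full(n, "CA", dtype=object),
        resnum=np.arange(1, n + 1),
        chain=np.full(n, "A", dtype=object),
        xyz=xyz,
        radius=np.full(n, 1.7),
        domains={"domain1": (1, n_atoms_per_domain),
                 "domain2": (n_atoms_per_domain + 1, n)},
    )


# --------------------------------------------------------------------------
# SAXS and kinetics observables
# --------------------------------------------------------------------------

def simulate_saxs_curve(
    structure: StructureModel,
    q_max: float = 0.3,
    n_points: int = 100,
    noise_fraction: float = 0.02,
    seed: int = 0,
) -> SAXSProfile:
    """Debye forward profile with multiplicative Gaussian noise.

    The sigma column is set to the known noise level (absent when
    ``noise_fraction`` is zero, in which case the profile is exactly the
    noiseless forward model).
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    q = np.linspace(q_max / n_points, q_max, n_points)
    clean = debye_profile(structure, q)
    if noise_fraction == 0:
        return clean
    rng = np.random.default_rng(seed)
    sigma = noise_fraction * clean.i
    i_noisy = clean.i + sigma * rng.standard_normal(n_points)
    return SAXSProfile(q, i_noisy, sigma)


def simulate_progress_curve(
    params: KineticParams,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ProgressCurve:
    """Chromogenic progress curve: coupled activation/hydrolysis model plus
    Gaussian absorbance noise of the stated standard deviation."""
    clean = progress_model(params, np.asarray(times, float))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    a = clean.a + noise_sd * rng.standard_normal(len(clean.a))
    return ProgressCurve(clean.t, a, np.full(len(a), noise_sd))
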