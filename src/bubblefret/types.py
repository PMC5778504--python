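"""Domain containers shared across the pipeline.

The atomic experimental object is an :class:`AlexTrace`: one immobilized
molecule's three-channel intensity record under alternating-laser excitation
(DD = donor-excitation donor-emission, DA = donor-excitation
acceptor-emission, AA = acceptor-excitation acceptor-emission), one value per
alternation period ("frame").  Ground truth for simulated molecules lives in
:class:`GroundTruth`; the kinetic model that generated it is a
:class:`KineticScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CATEGORIES = ("closed", "intermediate", "open")


@dataclass(frozen=True)
class KineticScheme:
    """Labelled conformational states with true E* levels and a CTMC rate matrix.

    ``rate_matrix`` holds off-diagonal first-order rate constants k_ij (s^-1);
    diagonals are the negative row sums, so rows sum to zero.  The exit rate of
    state i is ``-rate_matrix[i, i]`` and the mean sojourn its reciprocal.
    """

    state_labels: tuple[str, ...]
    state_fret: np.ndarray
    state_category: tuple[str, ...]
    rate_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        fret = np.asarray(self.state_fret, dtype=float)
        q = np.asarray(self.rate_matrix, dtype=float)
        p0 = np.asarray(self.initial_distribution, dtype=float)
        k = len(self.state_labels)
        if k < 1:
            raise ValueError("scheme needs at least one state")
        if fret.shape != (k,) or q.shape != (k, k) or p0.shape != (k,):
            raise ValueError("inconsistent scheme dimensions")
        if np.any(fret < 0) or np.any(fret > 1):
            raise ValueError("state_fret must lie in [0, 1]")
        off = q[~np.eye(k, dtype=bool)]
        if off.size and np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(q.sum(axis=1)) > 1e-9):
            raise ValueError("rate matrix rows must sum to 0")
        if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < -1e-12):
            raise ValueError("initial_distribution must be a probability vector")
        for c in self.state_category:
            if c not in CATEGORIES:
                raise ValueError(f"unknown state category {c!r}")
        object.__setattr__(self, "state_fret", fret)
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "initial_distribution", p0)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.rate_matrix)

    @classmethod
    def from_rates(
        cls,
        state_labels: Sequence[str],
        state_fret: Sequence[float],
        state_category: Sequence[str],
        rates: dict[tuple[str, str], float] | None = None,
        initial_distribution: Sequence[float] | str = "stationary",
    ) -> "KineticScheme":
        """Build a scheme from a ``{(from, to): k_ij}`` rate dictionary.

        ``initial_distribution="stationary"`` solves pi Q = 0 (a static,
        all-zero-rate scheme falls back to uniform).
        """
        labels = tuple(state_labels)
        k = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        q = np.zeros((k, k))
        for (src, dst), rate in (rates or {}).items():
            if src == dst:
                raise ValueError("rates are off-diagonal only")
            q[idx[src], idx[dst]] = float(rate)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if isinstance(initial_distribution, str):
            if initial_distribution != "stationary":
                raise ValueError(initial_distribution)
            p0 = stationary_distribution(q)
        else:
            p0 = np.asarray(initial_distribution, dtype=float)
        return cls(labels, np.asarray(state_fret, float), tuple(state_category), q, p0)

    def scaled(self, factor: float) -> "KineticScheme":
        """Multiply every rate by ``factor`` (e.g. mutant speed-ups)."""
        q = self.rate_matrix * float(factor)
        return KineticScheme(
            self.state_labels, self.state_fret, self.state_category, q,
            stationary_distribution(q),
        )


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC: solve pi Q = 0, sum(pi) = 1."""
    q = np.asarray(rate_matrix, dtype=float)
    k = q.shape[0]
    if np.allclose(q, 0):
        return np.full(k, 1.0 / k)
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class PhotophysicsParams:
    """Detection and photophysics parameters of the emulated TIRF/EMCCD setup.

    Counts-per-photon default (4.55) matches an EMCCD at EM gain 300; photon
    shot-noise variance is inflated by ``excess_noise_factor`` to approximate
    the EM register.  ``photons_per_frame_dex`` is the mean detected photon
    budget of the FRET pair per green-excitation frame and sets the per-frame
    E* width (~0.07 at 100 photons with excess noise 2).
    """

    photons_per_frame_dex: float = 100.0
    photons_per_frame_aex: float = 50.0
    donor_bleach_rate: float = 0.02
    acceptor_bleach_rate: float = 0.03
    blink_on_rate: float = 0.0
    blink_off_rate: float = 0.0
    quench_states: frozenset[str] = frozenset()
    quench_factor: float = 0.1
    background_per_channel: float = 20.0
    camera_gain: float = 4.55
    read_noise_sd: float = 10.0
    excess_noise_factor: float = 2.0
    shot_noise: bool = True  # False renders noiseless mean counts

    def __post_init__(self) -> None:
        nonneg = (
            self.photons_per_frame_dex, self.photons_per_frame_aex,
            self.donor_bleach_rate, self.acceptor_bleach_rate,
            self.blink_on_rate, self.blink_off_rate,
            self.background_per_channel, self.read_noise_sd,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("rates and counts must be >= 0")
        if self.camera_gain <= 0:
            raise ValueError("camera_gain must be > 0")
        if not 0.0 <= self.quench_factor <= 1.0:
            raise ValueError("quench_factor must lie in [0, 1]")
        if self.excess_noise_factor < 1.0:
            raise ValueError("excess_noise_factor must be >= 1")
        object.__setattr__(self, "quench_states", frozenset(self.quench_states))


@dataclass(frozen=True)
class Subpopulation:
    label: str
    proportion: float
    scheme: KineticScheme


@dataclass(frozen=True)
class ScenarioConfig:
    """A named experimental condition: subpopulation mix + photophysics."""

    name: str
    subpopulations: tuple[Subpopulation, ...]
    photophysics: PhotophysicsParams = PhotophysicsParams()
    alternation_rate_hz: float = 100.0
    n_molecules: int = 100
    max_duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subpopulations:
            raise ValueError("scenario needs at least one subpopulation")
        if self.alternation_rate_hz <= 0:
            raise ValueError("alternation_rate_hz must be > 0")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be > 0")
        if self.max_duration_s <= 0:
            raise ValueError("max_duration_s must be > 0")
        total = sum(s.proportion for s in self.subpopulations)
        if total <= 0:
            raise ValueError("subpopulation proportions must sum > 0")
        if abs(total - 1.0) > 1e-9:
            subs = tuple(
                Subpopulation(s.label, s.proportion / total, s.scheme)
                for s in self.subpopulations
            )
            object.__setattr__(self, "subpopulations", subs)

    @property
    def frame_period_s(self) -> float:
        # One frame = one full alternation period (one DD/DA + one AA readout).
        return 1.0 / self.alternation_rate_hz


@dataclass
class GroundTruth:
    """Per-molecule truth for parameter-recovery testing."""

    subpopulation: str
    scheme: KineticScheme
    events: list[tuple[int, float, float]]  # (state, entry time, exit time)
    state_index: np.ndarray                 # dominant true state per frame
    frame_fret: np.ndarray                  # occupancy-weighted true E* per frame
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None

    @property
    def true_dwells(self) -> list[tuple[str, float]]:
        return [
            (self.scheme.state_category[s], t1 - t0) for s, t0, t1 in self.events
        ]

    @property
    def is_dynamic(self) -> bool:
        """True when the scheme can interconvert between distinct E* levels."""
        if self.scheme.n_states < 2 or np.allclose(self.scheme.rate_matrix, 0):
            return False
        f = self.scheme.state_fret
        return float(np.ptp(f)) >= 0.1

    @property
    def static_label(self) -> str:
        cat = self.scheme.state_category[int(np.argmax(self.scheme.initial_distribution))]
        return f"static_{cat}"

    @property
    def true_class(self) -> str:
        return "dynamic" if self.is_dynamic else self.static_label


@dataclass
class AlexTrace:
    """One molecule's DD/DA/AA camera-count series."""

    DD: np.ndarray
    DA: np.ndarray
    AA: np.ndarray
    frame_period_s: float
    molecule_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.DD = np.asarray(self.DD, dtype=float)
        self.DA = np.asarray(self.DA, dtype=float)
        self.AA = np.asarray(self.AA, dtype=float)
        if not (len(self.DD) == len(self.DA) == len(self.AA)):
            raise ValueError("channel series must have equal length")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be > 0")
        for arr in (self.DD, self.DA, self.AA):
            if not np.all(np.isfinite(arr)):
                raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.DD)

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self.DD))

    @property
    def time_s(self) -> np.ndarray:
        return self.frame_index * self.frame_period_s


@dataclass
class FretSeries:
    """Per-frame apparent FRET efficiency E* and stoichiometry S."""

    efficiency: np.ndarray
    stoichiometry: np.ndarray
    valid: np.ndarray
    frame_period_s: float
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.efficiency) == len(self.stoichiometry) == len(self.valid)):
            raise ValueError("series length mismatch")

    def __len__(self) -> int:
        return len(self.efficiency)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_valid == 0
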