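"""Temperature replica-exchange molecular dynamics (REMD).

A ladder of temperatures is propagated in parallel with Langevin dynamics;
every ``exchange_interval`` MD steps, neighboring temperature slots attempt
a Metropolis configuration swap with probability

    p = min(1, exp[(β_i − β_j)(E_i − E_j)]),   β = 1/(k_B T),

which preserves detailed balance across the extended ensemble. Attempts
alternate between even pairs (0,1),(2,3),… and odd pairs (1,2),(3,4),…, so
with 64 replicas an even-parity sweep tries exactly 32 pairs. Accepted swaps
exchange configurations between temperature slots and rescale velocities by
√(T_new/T_old). Frames are recorded per temperature slot, i.e. already
demultiplexed by temperature, and the leading burn-in fraction is discarded
before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FS_PER_PS, KB
from .errors import SimulationError
from .system import (
    BeadSystem,
    RestraintSet,
    Trajectory,
    _maxwell_velocities,
    baoab_propagate,
    potential_energy,
)

__all__ = [
    "RemdProtocol",
    "ReplicaLadder",
    "ExchangeStats",
    "RemdResult",
    "make_ladder",
    "exchange_probability",
    "attempt_exchanges",
    "run_remd",
    "replica_mixing_report",
    "STUDY_PROTOCOL",
]


@dataclass(frozen=True)
class RemdProtocol:
    """Parameters of one replica-exchange run."""

    n_replicas: int = 8
    t_min: float = 300.0
    t_max: float = 400.0
    exchange_interval: int = 1000  # MD steps between swap attempts
    steps_per_replica: int = 100_000
    burn_in_fraction: float = 0.5
    dt_fs: float = 2.0
    friction_ps: float = 1.0
    stride: int = 10  # steps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")

    def summary(self) -> dict:
        """Protocol arithmetic: per-replica and aggregate simulated time."""
        per_replica_ns = self.steps_per_replica * self.dt_fs * 1e-6
        total_ns = self.n_replicas * per_replica_ns
        return {
            "n_replicas": self.n_replicas,
            "t_min_K": self.t_min,
            "t_max_K": self.t_max,
            "exchange_interval_steps": self.exchange_interval,
            "pairs_per_even_attempt": self.n_replicas // 2,
            "per_replica_ns": per_replica_ns,
            "total_simulated_ns": total_ns,
            "total_simulated_us": total_ns * 1e-3,
            "burn_in_ns_per_replica": per_replica_ns * self.burn_in_fraction,
        }


#: The full-scale study conditions: 64 replicas spanning 300–400 K, 30 ns per
#: replica at dt = 2 fs with swaps attempted every 1000 steps and the first
#: half discarded as thermalization (aggregate 1.92 μs). Far beyond desk
#: scale; kept for protocol arithmetic and as the reference configuration.
STUDY_PROTOCOL = RemdProtocol(
    n_replicas=64,
    t_min=300.0,
    t_max=400.0,
    exchange_interval=1000,
    steps_per_replica=15_000_000,
    burn_in_fraction=0.5,
    dt_fs=2.0,
    friction_ps=1.0,
)


@dataclass(frozen=True)
class ReplicaLadder:
    temperatures: np.ndarray  # K, strictly ascending

    @property
    def betas(self) -> np.ndarray:
        """Inverse temperatures, mol·kcal⁻¹."""
        return 1.0 / (KB * self.temperatures)

    @property
    def n(self) -> int:
        return len(self.temperatures)


def make_ladder(t_min: float, t_max: float, n: int) -> ReplicaLadder:
    """Geometric temperature ladder T_i = t_min·(t_max/t_min)^(i/(n−1)).

    Geometric spacing gives near-uniform exchange acceptance for systems
    whose heat capacity varies weakly with temperature.
    """
    if n < 1:
        raise ValueError("need at least one replica")
    if n == 1:
        if t_min != t_max:
            raise ValueError("single-rung ladder requires t_min == t_max")
        return ReplicaLadder(np.array([float(t_min)]))
    if t_min == t_max:
        raise ValueError("degenerate ladder: t_min == t_max with n >= 2")
    i = np.arange(n)
    temps = t_min * (t_max / t_min) ** (i / (n - 1))
    temps[0], temps[-1] = t_min, t_max  # exact endpoints
    return ReplicaLadder(temps)


def exchange_probability(beta_i: float, beta_j: float, e_i: float, e_j: float) -> float:
    """Metropolis swap probability min(1, exp[(β_i − β_j)(E_i − E_j)])."""
    arg = (beta_i - beta_j) * (e_i - e_j)
    if not math.isfinite(arg):
        raise ValueError("non-finite exchange argument")
    return min(1.0, math.exp(min(arg, 0.0))) if arg < 0 else 1.0


@dataclass
class ExchangeStats:
    """Per-pair attempt/acceptance counts and replica↔temperature bookkeeping."""

    attempts: np.ndarray  # (n_rungs - 1,)
    acceptances: np.ndarray  # (n_rungs - 1,)
    occupancy: np.ndarray  # (n_replicas, n_rungs) epochs spent at each rung
    replica_rung_series: list = field(default_factory=list)  # per epoch: rung of each replica
    records: list = field(default_factory=list)  # (step, pair, dE, dbeta, accepted)

    def validate(self) -> None:
        if np.any(self.acceptances > self.attempts):
            raise ValueError("acceptances exceed attempts")


def _pairs_for_parity(n: int, parity: str) -> list[tuple[int, int]]:
    if parity == "even":
        start = 0
    elif parity == "odd":
        start = 1
    else:
        raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")
    return [(i, i + 1) for i in range(start, n - 1, 2)]


def attempt_exchanges(
    x: np.ndarray,
    v: np.ndarray,
    energies: np.ndarray,
    ladder: ReplicaLadder,
    parity: str,
    rng: np.random.Generator,
) -> list[tuple[int, int, float, bool]]:
    """Attempt neighbor swaps between temperature slots, in place.

    ``x``, ``v`` and ``energies`` are indexed by temperature slot; accepted
    swaps exchange rows i and j and rescale the swapped velocities by
    √(T_new/T_old). Returns (i, j, probability, accepted) per pair.
    """
    betas = ladder.betas
    temps = ladder.temperatures
    outcomes = []
    for i, j in _pairs_for_parity(ladder.n, parity):
        p = exchange_probability(betas[i], betas[j], float(energies[i]), float(energies[j]))
        accepted = bool(rng.random() < p)
        if accepted:
            x[[i, j]] = x[[j, i]]
            si = math.sqrt(temps[i] / temps[j])  # config arriving at slot i came from j
            sj = math.sqrt(temps[j] / temps[i])
            vi, vj = v[j] * si, v[i] * sj
            v[i], v[j] = vi, vj
            energies[[i, j]] = energies[[j, i]]
        outcomes.append((i, j, p, accepted))
    return outcomes


@dataclass
class RemdResult:
    """Per-temperature trajectories (demultiplexed) plus exchange statistics."""

    trajectories: list[Trajectory]
    stats: ExchangeStats
    ladder: ReplicaLadder
    protocol: RemdProtocol

    def production(self, rung: int) -> Trajectory:
        """Trajectory at one temperature rung with burn-in discarded."""
        return self.trajectories[rung].discard_burn_in(self.protocol.burn_in_fraction)


def run_remd(
    system: BeadSystem,
    restraints: RestraintSet,
    protocol: RemdProtocol,
    initial_coords: np.ndarray | None = None,
) -> RemdResult:
    """Run the replica-exchange protocol on a bead system.

    All replicas start from the same coordinates (``initial_coords`` or the
    system's build coordinates), are propagated ``exchange_interval`` steps
    between swap attempts with parity alternating per attempt, and frames
    are stored per temperature slot. Fully deterministic for a given seed:
    one stream drives the batched dynamics, an independently derived stream
    drives the swap decisions.
    """
    system.finalize()
    restraints.validate(system.n_beads)
    ladder = make_ladder(protocol.t_min, protocol.t_max, protocol.n_replicas)
    n = ladder.n
    rng_dyn = np.random.default_rng(protocol.seed)
    rng_exch = np.random.default_rng(np.random.SeedSequence([protocol.seed, 0x5EED]))

    x0 = system.positions if initial_coords is None else np.asarray(initial_coords, float)
    x = np.repeat(x0[None, ...], n, axis=0).copy()
    v = _maxwell_velocities(system.masses, ladder.temperatures, x.shape, rng_dyn)

    n_epochs = protocol.steps_per_replica // protocol.exchange_interval
    attempts = np.zeros(max(n - 1, 0), int)
    acceptances = np.zeros(max(n - 1, 0), int)
    occupancy = np.zeros((n, n), int)
    rung_series = []
    records = []
    replica_of_slot = np.arange(n)  # which walker currently sits at each rung
    frames_per_slot: list[list[np.ndarray]] = [[] for _ in range(n)]

    for epoch in range(n_epochs):
        x, v, rec = baoab_propagate(
            system,
            restraints,
            x,
            v,
            ladder.temperatures,
            protocol.friction_ps,
            protocol.dt_fs,
            protocol.exchange_interval,
            rng_dyn,
            record_stride=protocol.stride,
        )
        bad = ~np.all(np.isfinite(x), axis=(1, 2))
        if np.any(bad):
            raise SimulationError(
                f"non-finite coordinates in replica slot {int(np.argmax(bad))} "
                f"after step {(epoch + 1) * protocol.exchange_interval}"
            )
        if rec is not None:
            for slot in range(n):
                frames_per_slot[slot].append(rec[slot])
        energies, _ = potential_energy(system, restraints, x)
        energies = np.atleast_1d(np.asarray(energies, float))
        if n > 1:
            parity = "even" if epoch % 2 == 0 else "odd"
            outcomes = attempt_exchanges(x, v, energies, ladder, parity, rng_exch)
            step = (epoch + 1) * protocol.exchange_interval
            for (i, j, p, acc) in outcomes:
                attempts[i] += 1
                acceptances[i] += int(acc)
                records.append((step, (i, j), p, acc))
                if acc:
                    replica_of_slot[[i, j]] = replica_of_slot[[j, i]]
        rung_of_replica = np.empty(n, int)
        rung_of_replica[replica_of_slot] = np.arange(n)
        occupancy[np.arange(n), rung_of_replica] += 1
        rung_series.append(rung_of_replica.copy())

    stats = ExchangeStats(
        attempts=attempts,
        acceptances=acceptances,
        occupancy=occupancy,
        replica_rung_series=rung_series,
        records=records,
    )
    stats.validate()
    trajectories = []
    for slot in range(n):
        frames = (
            np.concatenate(frames_per_slot[slot], axis=0)
            if frames_per_slot[slot]
            else np.zeros((0, system.n_beads, 3))
        )
        trajectories.append(
            Trajectory(
                frames=frames,
                dt_ps=protocol.dt_fs * protocol.stride / FS_PER_PS,
                temperature=float(ladder.temperatures[slot]),
                labels=system.labels,
                masses=system.masses,
                seed_info=f"remd:seed={protocol.seed}:rung={slot}",
                metadata={"protocol": protocol.summary(), "rung": slot},
            )
        )
    return RemdResult(trajectories=trajectories, stats=stats, ladder=ladder, protocol=protocol)


def replica_mixing_report(stats: ExchangeStats) -> dict:
    """Mixing diagnostics: per-pair acceptance and occupancy uniformity.

    The uniformity statistic is the chi-square of the replica→rung occupancy
    against the uniform expectation (epochs / n_rungs per cell).
    """
    if stats.attempts.size == 0 or int(stats.attempts.sum()) == 0:
        return {"pairs": [], "mean_acceptance": None, "chi2_uniformity": None,
                "min_rungs_visited": None}
    with np.errstate(invalid="ignore"):
        rates = np.where(stats.attempts > 0, stats.acceptances / np.maximum(stats.attempts, 1), np.nan)
    n_replicas, n_rungs = stats.occupancy.shape
    epochs = stats.occupancy.sum(axis=1)
    expected = epochs[:, None] / n_rungs
    chi2 = float(np.sum((stats.occupancy - expected) ** 2 / expected))
    visited = np.count_nonzero(stats.occupancy, axis=1)
    return {
        "pairs": [
            {"pair": (i, i + 1), "attempts": int(stats.attempts[i]),
             "acceptance": float(rates[i]) if stats.attempts[i] else None}
            for i in range(len(stats.attempts))
        ],
        "mean_acceptance": float(np.nanmean(rates)),
        "chi2_uniformity": chi2,
        "min_rungs_visited": int(visited.min()),
    }
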