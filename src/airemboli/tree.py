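"""Monte-Carlo transport of air emboli through a Murray's-law arterial tree.

The middle cerebral artery territory is idealised as a symmetric binary tree:
at each bifurcation daughter diameters shrink by 2^(1/3) (Murray's law), so
that with a patient-matched root diameter and 19 generations the tree ends in
524,288 terminal arterioles of ~30 um.  Flow is Poiseuille throughout, driven
by a fixed root pressure against a zero reference at the outlets.

Emboli enter at the root, advance at the local mean flow speed, choose a
daughter at each bifurcation with probability proportional to the daughter
flows, and lodge where limiting static friction K*A_wall (stiction, with
A_wall the bubble-wall contact area of the deformed bubble) can hold the
pressure force dp*pi*r^2 across the blocked vessel.  Lodged bubbles shrink by
diffusion (see :mod:`airemboli.dissolution`), are re-checked as they shrink,
and can remobilise and travel deeper.  The observable is the fraction of
terminal arterioles receiving no flow, tracked over time; ensembles of runs
give a mean and a percentile 95% confidence band.

The solver never materialises the million-vessel tree: only vessels on paths
to blockages are represented explicitly, with closed-form effective
resistances for the untouched (pristine) symmetric subtrees hanging off them.
Flow and pressure on any vessel are recovered exactly from this sparse
representation, and the solve is exact, not iterative.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .dissolution import GasParams, dissolve_time, shrink_rate

__all__ = [
    "VesselTree",
    "EmbolusState",
    "FlowState",
    "SimParams",
    "ObstructionSeries",
    "build_tree",
    "vessel_resistance",
    "solve_flow",
    "route_at_bifurcation",
    "contact_area",
    "is_lodged",
    "Simulation",
    "run_simulation",
    "run_ensemble",
]

MMHG_TO_PA = 133.322
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)
REMOVAL_RADIUS = 1.0e-6        # m; emboli below this are considered dissolved
MAX_GENERATIONS = 24

Vessel = tuple[int, int]       # (generation, index within generation)


@dataclass(frozen=True)
class VesselTree:
    """Symmetric Murray's-law bifurcating tree with Poiseuille resistances."""

    root_diameter: float            # m
    generations: int = 19           # bifurcation generations below the root
    length_to_diameter: float = 20.0
    viscosity: float = 3.5e-3       # Pa s
    input_pressure: float = 100.0   # mmHg at the root entry
    outlet_pressure: float = 0.0    # mmHg at every terminal outlet

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.generations > MAX_GENERATIONS:
            raise ValueError(
                f"generations > {MAX_GENERATIONS} would require "
                f"{2**self.generations:,} terminals; refusing"
            )
        if self.root_diameter <= 0:
            raise ValueError("root diameter must be positive")

    # -- geometry ------------------------------------------------------------
    def diameter(self, g: int) -> float:
        return self.root_diameter * MURRAY_RATIO**g

    def length(self, g: int) -> float:
        return self.length_to_diameter * self.diameter(g)

    def cross_section(self, g: int) -> float:
        d = self.diameter(g)
        return 0.25 * math.pi * d * d

    @property
    def n_terminals(self) -> int:
        return 2**self.generations

    @property
    def input_pressure_pa(self) -> float:
        return self.input_pressure * MMHG_TO_PA

    @property
    def outlet_pressure_pa(self) -> float:
        return self.outlet_pressure * MMHG_TO_PA

    # -- resistances ---------------------------------------------------------
    def resistance(self, g: int) -> float:
        return vessel_resistance(self.diameter(g), self.length(g), self.viscosity)

    def pristine_resistance(self, g: int) -> float:
        """Effective resistance of an untouched subtree rooted at generation g."""
        return self._pristine[g]

    @property
    def _pristine(self) -> list[float]:
        cached = object.__getattribute__(self, "__dict__").get("_pristine_cache")
        if cached is None:
            r = [0.0] * (self.generations + 1)
            r[self.generations] = self.resistance(self.generations)
            for g in range(self.generations - 1, -1, -1):
                r[g] = self.resistance(g) + 0.5 * r[g + 1]
            object.__getattribute__(self, "__dict__")["_pristine_cache"] = r
            cached = r
        return cached


def build_tree(root_diameter_mm: float, generations: int = 19, **kwargs) -> VesselTree:
    """Construct a tree from a root (MCA) diameter given in mm."""
    return VesselTree(root_diameter=root_diameter_mm * 1e-3, generations=generations, **kwargs)


def vessel_resistance(diameter: float, length: float, viscosity: float) -> float:
    """Poiseuille resistance 128*mu*L/(pi*d^4) in Pa s/m^3."""
    if diameter <= 0 or length <= 0 or viscosity <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    return 128.0 * viscosity * length / (math.pi * diameter**4)


@dataclass
class EmbolusState:
    """A gas embolus in transit through (or lodged in) the tree."""

    radius: float                  # m, equivalent spherical radius
    location: tuple[int, int, float]   # (generation, vessel index, axial fraction)
    entry_time: float              # s
    lodged: bool = False
    settled: bool = False          # parked at a terminal outlet, no longer blocking

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def vessel(self) -> Vessel:
        return (self.location[0], self.location[1])


@dataclass
class SimParams:
    """Monte-Carlo simulation controls."""

    stiction_coefficient: float = 10.0    # K, N/m^2
    time_step: float = 0.1                # s
    ensemble_size: int = 30
    radius_noise_rel_sd: float = 0.40     # log-normal multiplier, relative SD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stiction_coefficient <= 0 or self.time_step <= 0:
            raise ValueError("stiction coefficient and time step must be positive")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")
        if self.radius_noise_rel_sd < 0:
            raise ValueError("radius_noise_rel_sd must be >= 0")


@dataclass
class ObstructionSeries:
    """Percentage of unperfused terminal arterioles over time, with 95% CI."""

    times: np.ndarray
    mean_percent: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def __post_init__(self) -> None:
        ok = (
            (self.ci_low <= self.mean_percent + 1e-12)
            & (self.mean_percent <= self.ci_high + 1e-12)
            & (self.ci_low >= -1e-12)
            & (self.ci_high <= 100.0 + 1e-9)
        )
        if not np.all(ok):
            raise ValueError("CI bounds must satisfy 0 <= low <= mean <= high <= 100")

    @property
    def peak_percent(self) -> float:
        return float(np.max(self.mean_percent)) if self.mean_percent.size else 0.0


class FlowState:
    """Exact flows and pressures for a tree with a given blocked set.

    Holds explicit values only on materialised vessels (ancestors of blocked
    or otherwise requested vessels); everything else is recovered from the
    symmetric pristine subtrees.
    """

    def __init__(self, tree: VesselTree, blocked: frozenset[Vessel], extra=()):
        self.tree = tree
        self.blocked = blocked
        mat: set[Vessel] = set()
        for v in set(blocked) | set(extra):
            g, i = v
            while True:
                mat.add((g, i))
                if g == 0:
                    break
                g, i = g - 1, i >> 1
        mat.add((0, 0))
        self._mat = mat
        self._reff: dict[Vessel, float] = {}
        self._flow: dict[Vessel, float] = {}
        self._p_down: dict[Vessel, float] = {}
        self._solve()

    # -- solving -------------------------------------------------------------
    def _solve(self) -> None:
        tree, blocked = self.tree, self.blocked
        G = tree.generations
        reff = self._reff
        for v in sorted(self._mat, key=lambda x: -x[0]):
            g, i = v
            if v in blocked:
                reff[v] = math.inf
                continue
            if g == G:
                reff[v] = tree.resistance(g)
                continue
            cond = 0.0
            for child in ((g + 1, 2 * i), (g + 1, 2 * i + 1)):
                rc = reff.get(child, tree.pristine_resistance(g + 1))
                if math.isfinite(rc) and rc > 0:
                    cond += 1.0 / rc
            reff[v] = tree.resistance(g) + (1.0 / cond if cond > 0 else math.inf)

        p_in, p_out = tree.input_pressure_pa, tree.outlet_pressure_pa
        stack: list[tuple[Vessel, float]] = [((0, 0), p_in)]
        while stack:
            v, p_entry = stack.pop()
            g, i = v
            if v in blocked or not math.isfinite(reff[v]):
                q = 0.0
            else:
                q = (p_entry - p_out) / reff[v]
            self._flow[v] = q
            # downstream node: no drop if no flow; a blocked subtree floats at outlet pressure
            p_down = p_out if v in blocked else p_entry - q * tree.resistance(g)
            self._p_down[v] = p_down
            if g < G:
                for child in ((g + 1, 2 * i), (g + 1, 2 * i + 1)):
                    if child in self._mat:
                        stack.append((child, p_down))

    # -- queries -------------------------------------------------------------
    def flow(self, v: Vessel) -> float:
        """Volumetric flow (m^3/s) through any vessel, materialised or not."""
        if v in self._flow:
            return self._flow[v]
        # climb to the nearest materialised ancestor
        g, i = v
        steps_from_child = 0
        while (g, i) not in self._mat:
            g, i = g - 1, i >> 1
            steps_from_child += 1
        anc = (g, i)
        if self._flow[anc] == 0.0:
            return 0.0
        # the child of anc towards v is pristine; below it flow halves per level
        q_child = (self._p_down[anc] - self.tree.outlet_pressure_pa) / self.tree.pristine_resistance(g + 1)
        return q_child / 2.0 ** (steps_from_child - 1)

    def entry_pressure(self, v: Vessel) -> float:
        """Pressure (Pa) at the upstream node of a materialised vessel."""
        g, i = v
        if g == 0:
            return self.tree.input_pressure_pa
        return self._p_down[(g - 1, i >> 1)]

    def pressure_drop_if_blocked(self, v: Vessel) -> float:
        """Pressure differential across vessel v were it blocked (its subtree
        then carries no flow and floats at outlet pressure)."""
        probe = FlowState(self.tree, frozenset(self.blocked | {v}), extra=(v,))
        return probe.entry_pressure(v) - self.tree.outlet_pressure_pa

    def root_flow(self) -> float:
        return self._flow[(0, 0)]

    def downstream_pressure(self, v: Vessel) -> float:
        """Pressure (Pa) at the downstream node of a materialised vessel."""
        return self._p_down[v]

    def obstructed_fraction(self) -> float:
        """Fraction of terminal arterioles with zero flow."""
        if not self.blocked:
            return 0.0
        G = self.tree.generations
        total = 0
        for v in self.blocked:
            g, i = v
            # count only maximal blocked vessels (no blocked proper ancestor)
            gg, ii = g, i
            shadowed = False
            while gg > 0:
                gg, ii = gg - 1, ii >> 1
                if (gg, ii) in self.blocked:
                    shadowed = True
                    break
            if not shadowed:
                total += 2 ** (G - g)
        return min(1.0, total / self.tree.n_terminals)


def solve_flow(tree: VesselTree, blocked=frozenset(), extra=()) -> FlowState:
    """Exact two-pass flow solve for a given set of blocked vessels."""
    return FlowState(tree, frozenset(blocked), extra=extra)


def route_at_bifurcation(flow_left: float, flow_right: float, rng: np.random.Generator):
    """Choose a daughter branch with probability proportional to its flow.

    Returns "left" or "right", or None if both flows are zero (the embolus
    halts).  An exact tie is a fair coin by construction.
    """
    if flow_left < 0 or flow_right < 0:
        raise ValueError("flows must be non-negative")
    total = flow_left + flow_right
    if total == 0.0:
        return None
    return "left" if rng.random() < flow_left / total else "right"


def contact_area(volume: float, vessel_radius: float) -> float:
    """Wall-contact area (m^2) of a bubble deformed into a vessel.

    A bubble whose equivalent sphere fits inside the vessel touches the wall
    nowhere.  A larger bubble is modelled as a cylinder with hemispherical
    caps filling the lumen: the cylindrical section of length
    L_c = (V - (4/3) pi r^3) / (pi r^2) is in contact, giving 2 pi r L_c.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    r = vessel_radius
    sphere_volume = (4.0 / 3.0) * math.pi * r**3
    if volume <= sphere_volume:
        return 0.0
    contact_length = (volume - sphere_volume) / (math.pi * r * r)
    return 2.0 * math.pi * r * contact_length


def is_lodged(
    embolus_volume: float,
    vessel_radius: float,
    pressure_drop: float,
    stiction_coefficient: float,
) -> bool:
    """Stiction criterion: K*A_wall must match the pressure force dp*pi*r^2.

    An undeformed bubble (no wall contact) never lodges; a deformed bubble
    with no pressure differential across it always does.
    """
    if pressure_drop < 0:
        raise ValueError("pressure drop must be >= 0")
    a_wall = contact_area(embolus_volume, vessel_radius)
    if a_wall == 0.0:
        return False
    return stiction_coefficient * a_wall >= pressure_drop * math.pi * vessel_radius**2


class Simulation:
    """Time-stepped state of one tree, its emboli and its blockages."""

    def __init__(
        self,
        tree: VesselTree,
        sim_params: SimParams | None = None,
        gas_params: GasParams | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.tree = tree
        self.params = sim_params or SimParams()
        self.gas = gas_params or GasParams()
        self.rng = rng or np.random.default_rng(self.params.rng_seed)
        self.time = 0.0
        self.emboli: list[EmbolusState] = []     # free + lodged
        self.settled: list[EmbolusState] = []
        self._settled_removal: list[tuple[float, int]] = []   # heap of (time, id)
        self._blocked_count: dict[Vessel, int] = {}
        self._state = solve_flow(tree)
        self.cleared_count = 0

    # -- blockage bookkeeping --------------------------------------------------
    @property
    def blocked(self) -> frozenset[Vessel]:
        return frozenset(self._blocked_count)

    def _block(self, v: Vessel) -> None:
        self._blocked_count[v] = self._blocked_count.get(v, 0) + 1

    def _unblock(self, v: Vessel) -> None:
        n = self._blocked_count[v] - 1
        if n == 0:
            del self._blocked_count[v]
        else:
            self._blocked_count[v] = n

    def _resolve(self) -> None:
        self._state = solve_flow(self.tree, self.blocked)

    def obstructed_fraction(self) -> float:
        return self._state.obstructed_fraction()

    # -- embolus lifecycle -----------------------------------------------------
    def inject(self, diameter_um: float, noisy: bool = True) -> EmbolusState:
        """Introduce a bubble at the root entry, with sizing-uncertainty noise."""
        radius = 0.5 * diameter_um * 1e-6
        s = self.params.radius_noise_rel_sd
        if noisy and s > 0:
            log_sd = math.sqrt(math.log(1.0 + s * s))
            radius *= self.rng.lognormal(mean=-0.5 * log_sd**2, sigma=log_sd)
        emb = EmbolusState(radius=radius, location=(0, 0, 0.0), entry_time=self.time)
        if radius < REMOVAL_RADIUS:
            self.cleared_count += 1
            return emb
        self.emboli.append(emb)
        self._check_entry_lodging(emb, (0, 0))
        return emb

    def _check_entry_lodging(self, emb: EmbolusState, v: Vessel) -> bool:
        """Stiction check on vessel entry; blocks the vessel if it holds."""
        r_vessel = 0.5 * self.tree.diameter(v[0])
        if contact_area(emb.volume, r_vessel) == 0.0:
            return False
        dp = self._state.pressure_drop_if_blocked(v)
        if is_lodged(emb.volume, r_vessel, max(dp, 0.0), self.params.stiction_coefficient):
            emb.lodged = True
            emb.location = (v[0], v[1], 0.0)
            self._block(v)
            self._resolve()
            return True
        return False

    def _settle(self, emb: EmbolusState) -> None:
        """Park an embolus at a terminal outlet until it dissolves."""
        emb.settled = True
        emb.lodged = False
        self.emboli.remove(emb)
        self.settled.append(emb)
        t_gone = self.time + dissolve_time(2.0 * emb.radius * 1e6, self.gas)
        heapq.heappush(self._settled_removal, (t_gone, id(emb)))

    def _advance_free(self, emb: EmbolusState, dt: float) -> None:
        """Move a free embolus along the tree for up to ``dt`` seconds."""
        budget = dt
        G = self.tree.generations
        while budget > 0:
            g, i, frac = emb.location
            v = (g, i)
            q = self._state.flow(v)
            if q <= 0:
                return
            speed = q / self.tree.cross_section(g)
            remaining = (1.0 - frac) * self.tree.length(g)
            t_exit = remaining / speed
            if t_exit > budget:
                emb.location = (g, i, frac + speed * budget / self.tree.length(g))
                return
            budget -= t_exit
            if g == G:
                # terminal outlet: too big for the capillary bed -> impacts and
                # blocks until it shrinks below the lumen; else parks and dissolves
                r_vessel = 0.5 * self.tree.diameter(G)
                emb.location = (g, i, 1.0)
                if emb.radius > r_vessel:
                    emb.lodged = True
                    self._block(v)
                    self._resolve()
                else:
                    self._settle(emb)
                return
            left, right = (g + 1, 2 * i), (g + 1, 2 * i + 1)
            choice = route_at_bifurcation(
                self._state.flow(left), self._state.flow(right), self.rng
            )
            if choice is None:
                emb.location = (g, i, 1.0)
                return
            child = left if choice == "left" else right
            emb.location = (child[0], child[1], 0.0)
            if self._check_entry_lodging(emb, child):
                return

    def _shrink_all(self, dt: float) -> None:
        """Diffusive shrinkage of every active embolus; removal below 1 um."""
        gone: list[EmbolusState] = []
        for emb in self.emboli:
            emb.radius = max(emb.radius + shrink_rate(emb.radius, self.gas) * dt, 0.0)
            if emb.radius < REMOVAL_RADIUS:
                gone.append(emb)
        changed = False
        for emb in gone:
            if emb.lodged:
                self._unblock(emb.vessel)
                changed = True
            self.emboli.remove(emb)
            self.cleared_count += 1
        if changed:
            self._resolve()

    def _recheck_lodged(self) -> None:
        """Re-apply the stiction criterion to lodged emboli after shrinkage."""
        changed = False
        for emb in list(self.emboli):
            if not emb.lodged:
                continue
            g, i, _ = emb.location
            v = (g, i)
            r_vessel = 0.5 * self.tree.diameter(g)
            if g == self.tree.generations and emb.location[2] >= 1.0:
                # outlet impaction: purely geometric criterion
                if emb.radius <= r_vessel:
                    emb.lodged = False
                    self._unblock(v)
                    self._resolve()
                    self._settle(emb)
                    changed = True
                continue
            dp = self._state.entry_pressure(v) - self.tree.outlet_pressure_pa
            if not is_lodged(emb.volume, r_vessel, max(dp, 0.0), self.params.stiction_coefficient):
                emb.lodged = False
                self._unblock(v)
                self._resolve()
                changed = True
        if changed:
            self._resolve()

    def _drop_dissolved_settled(self) -> None:
        while self._settled_removal and self._settled_removal[0][0] <= self.time:
            _, eid = heapq.heappop(self._settled_removal)
            for k, emb in enumerate(self.settled):
                if id(emb) == eid:
                    del self.settled[k]
                    self.cleared_count += 1
                    break

    def step(self, dt: float | None = None) -> None:
        """Advance the state by one time step."""
        dt = self.params.time_step if dt is None else dt
        for emb in [e for e in self.emboli if not e.lodged]:
            self._advance_free(emb, dt)
        self.time += dt
        self._shrink_all(dt)
        self._recheck_lodged()
        self._drop_dissolved_settled()


def run_simulation(
    event_schedule: list[tuple[float, float]],
    tree: VesselTree,
    sim_params: SimParams | None = None,
    gas_params: GasParams | None = None,
    rng: np.random.Generator | None = None,
    t_end: float | None = None,
) -> ObstructionSeries:
    """One Monte-Carlo realisation of a schedule of (time s, diameter um) events.

    Each bubble enters the root at its event time with its radius multiplied
    by log-normal noise representing the sizing uncertainty.  The returned
    series records the percentage of unperfused terminals at every time step
    (for a single run the CI collapses onto the trajectory itself).
    """
    params = sim_params or SimParams()
    sched = sorted(event_schedule)
    if any(t < 0 for t, _ in sched):
        raise ValueError("schedule times must be >= 0")
    if t_end is None:
        t_end = (sched[-1][0] if sched else 0.0) + 60.0
    sim = Simulation(tree, params, gas_params, rng)
    dt = params.time_step
    n_steps = int(math.ceil(t_end / dt))
    times = np.arange(1, n_steps + 1) * dt
    percent = np.empty(n_steps)
    next_event = 0
    for k in range(n_steps):
        while next_event < len(sched) and sched[next_event][0] <= sim.time:
            sim.inject(sched[next_event][1])
            next_event += 1
        sim.step(dt)
        percent[k] = 100.0 * sim.obstructed_fraction()
    return ObstructionSeries(
        times=times, mean_percent=percent, ci_low=percent.copy(), ci_high=percent.copy()
    )


def run_ensemble(
    event_schedule: list[tuple[float, float]],
    tree: VesselTree,
    sim_params: SimParams | None = None,
    gas_params: GasParams | None = None,
    t_end: float | None = None,
) -> ObstructionSeries:
    """Ensemble of runs: mean and percentile 95% CI at every time point.

    Per-run seeds derive deterministically from ``sim_params.rng_seed``, so
    repeated calls are bit-identical.
    """
    params = sim_params or SimParams()
    seeds = np.random.SeedSequence(params.rng_seed).spawn(params.ensemble_size)
    runs = []
    for ss in seeds:
        series = run_simulation(
            event_schedule, tree, params, gas_params,
            rng=np.random.default_rng(ss), t_end=t_end,
        )
        runs.append(series.mean_percent)
    stacked = np.vstack(runs)
    mean = stacked.mean(axis=0)
    lo = np.minimum(np.percentile(stacked, 2.5, axis=0), mean)
    hi = np.maximum(np.percentile(stacked, 97.5, axis=0), mean)
    return ObstructionSeries(times=series.times, mean_percent=mean, ci_low=lo, ci_high=hi)
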