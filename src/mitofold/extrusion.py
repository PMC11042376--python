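"""Discrete 1D lattice simulation of loop extrusion by multiple SMC species.

The chromosome is a lattice of sites (default 1 kb/site). Loop-extruding
complexes (condensin I, condensin II, extrusive cohesin) occupy two sites —
their left and right legs — and translocate outward, reeling chromatin into a
loop. Cohesive cohesins and CTCF act as obstacles: cohesive cohesin is an
immobile site-blocking particle, CTCF an orientation-dependent barrier that
stalls extrusive cohesin only when approached from its motif-facing side.

Encounters between a moving leg and an occupant are resolved by a
:class:`CollisionPolicy`, a rule matrix over ordered species pairs with
outcomes ``bypass``, ``stall``, ``unload_obstacle``, ``push_obstacle`` and
``unload_self`` — the four "rules of engagement" scenarios (unload, push,
bypass, stall) are presets over this matrix. Chromosome ends always stall.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Outcome",
    "SpeciesConfig",
    "CollisionPolicy",
    "Extruder",
    "Obstacle",
    "LatticeState",
    "LoopTrajectory",
    "ExtrusionEngine",
    "ConfigurationError",
    "resolve_encounter",
    "step_lattice",
    "run_prophase_scenario",
    "nested_loop_experiment",
    "loop_statistics",
    "required_processivity_ratio",
    "prophase_policy",
    "DEFAULT_POLICY",
]

EXTRUDER_SPECIES = ("condensin_I", "condensin_II", "cohesin_extrusive")
OBSTACLE_SPECIES = ("cohesin_cohesive", "ctcf_barrier")
ALL_SPECIES = EXTRUDER_SPECIES + OBSTACLE_SPECIES


class ConfigurationError(ValueError):
    """Raised for inconsistent species, policy or rate configuration."""


class Outcome(str, enum.Enum):
    BYPASS = "bypass"
    STALL = "stall"
    UNLOAD_OBSTACLE = "unload_obstacle"
    PUSH_OBSTACLE = "push_obstacle"
    UNLOAD_SELF = "unload_self"


@dataclass
class SpeciesConfig:
    """Abundance and kinetics of one SMC species or barrier.

    Parameters
    ----------
    density:
        Complexes per Mb placed at activation time.
    speed:
        Extrusion speed per leg in kb/s. The total reeling rate of a
        two-sided complex is twice this value.
    loading_rate:
        Stochastic loading events per site per second (after activation).
    unloading_rate:
        Per bound complex per second.
    two_sided:
        Whether both legs translocate. One-sided extruders keep the left
        leg fixed.
    mobile:
        Obstacle species (cohesive cohesin, CTCF) are immobile.
    """

    name: str
    density: float = 0.0
    speed: float = 0.0
    loading_rate: float = 0.0
    unloading_rate: float = 0.0
    two_sided: bool = True
    mobile: bool = True

    def __post_init__(self) -> None:
        if self.name not in ALL_SPECIES:
            raise ConfigurationError(f"unknown species {self.name!r}")
        if self.density < 0 or self.loading_rate < 0 or self.unloading_rate < 0:
            raise ConfigurationError("densities and rates must be >= 0")
        if self.name in OBSTACLE_SPECIES:
            self.mobile = False
        if not self.mobile and self.speed != 0:
            raise ConfigurationError("immobile species must have speed 0")

    @property
    def is_extruder(self) -> bool:
        return self.name in EXTRUDER_SPECIES


class CollisionPolicy:
    """Rule matrix resolving encounters between ordered species pairs."""

    def __init__(self, rules: dict[tuple[str, str], str | Outcome] | None = None):
        self.rules: dict[tuple[str, str], Outcome] = {}
        for pair, out in (rules or {}).items():
            self.set(pair[0], pair[1], out)

    def set(self, mover: str, occupant: str, outcome: str | Outcome) -> None:
        if mover not in ALL_SPECIES or occupant not in ALL_SPECIES:
            raise ConfigurationError(f"unknown species pair ({mover}, {occupant})")
        self.rules[(mover, occupant)] = Outcome(outcome)

    def outcome(self, mover: str, occupant: str) -> Outcome:
        try:
            return self.rules[(mover, occupant)]
        except KeyError:
            raise ConfigurationError(
                f"collision policy has no rule for ({mover!r}, {occupant!r})"
            ) from None

    def copy(self) -> "CollisionPolicy":
        return CollisionPolicy(dict(self.rules))


def _default_rules() -> dict[tuple[str, str], str]:
    rules: dict[tuple[str, str], str] = {}
    # condensin-condensin encounters stall (consecutive, non-overlapping loops)
    for a in ("condensin_I", "condensin_II"):
        for b in ("condensin_I", "condensin_II"):
            rules[(a, b)] = "stall"
        rules[(a, "cohesin_cohesive")] = "bypass"   # Rule 1: bypass cohesive cohesin
        rules[(a, "cohesin_extrusive")] = "unload_obstacle"
        rules[(a, "ctcf_barrier")] = "bypass"        # condensins ignore CTCF
    rules[("cohesin_extrusive", "cohesin_extrusive")] = "stall"
    rules[("cohesin_extrusive", "cohesin_cohesive")] = "bypass"
    rules[("cohesin_extrusive", "condensin_I")] = "stall"
    rules[("cohesin_extrusive", "condensin_II")] = "stall"
    rules[("cohesin_extrusive", "ctcf_barrier")] = "stall"  # orientation-gated
    return rules


DEFAULT_POLICY = CollisionPolicy(_default_rules())


def prophase_policy(scenario: str) -> CollisionPolicy:
    """Policy preset for the four condensin-vs-extrusive-cohesin scenarios."""
    outcomes = {
        "unload": "unload_obstacle",
        "push": "push_obstacle",
        "bypass": "bypass",
        "stall": "stall",
    }
    if scenario not in outcomes:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    policy = DEFAULT_POLICY.copy()
    for cond in ("condensin_I", "condensin_II"):
        policy.set(cond, "cohesin_extrusive", outcomes[scenario])
    return policy


@dataclass
class Extruder:
    species: str
    left: int
    right: int
    status: str = "extruding"
    # cumulative sites translocated by this complex
    translocated: int = 0


@dataclass
class Obstacle:
    species: str
    pos: int
    orientation: str = "."  # '+'/'-' for CTCF motif orientation


@dataclass
class LatticeState:
    """Snapshot of every complex and barrier on the lattice."""

    lattice_length: int
    site_bp: int
    extruders: list[Extruder] = field(default_factory=list)
    obstacles: list[Obstacle] = field(default_factory=list)
    time: int = 0

    def validate(self) -> None:
        for ex in self.extruders:
            if not (0 <= ex.left <= ex.right < self.lattice_length):
                raise ValueError(f"extruder legs out of order or bounds: {ex}")
        for ob in self.obstacles:
            if not 0 <= ob.pos < self.lattice_length:
                raise ValueError(f"obstacle out of bounds: {ob}")


@dataclass
class Frame:
    time_s: float
    loops: np.ndarray          # (n, 2) site intervals [left, right]
    species: list[str]
    statuses: list[str]
    obstacles: list[Obstacle]
    anchored_cohesins: int
    translocated_sites: int
    n_bound: int


@dataclass
class LoopTrajectory:
    site_bp: int
    lattice_length: int
    frames: list[Frame] = field(default_factory=list)

    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])


def _update_status(status: str, leg: int, moved: bool) -> str:
    stalled_left = status in ("stalled_left", "stalled_both")
    stalled_right = status in ("stalled_right", "stalled_both")
    if leg == 0:
        stalled_left = not moved
    else:
        stalled_right = not moved
    if stalled_left and stalled_right:
        return "stalled_both"
    if stalled_left:
        return "stalled_left"
    if stalled_right:
        return "stalled_right"
    return "extruding"


class ExtrusionEngine:
    """Stochastic update loop over a :class:`LatticeState`.

    The time step is chosen so that the fastest leg moves at most one site
    per step with probability <= 1; slower species move probabilistically.
    Legs are updated in a freshly shuffled order each step (seeded), which
    is the tie-break when two legs contest one site.
    """

    def __init__(
        self,
        lattice_length: int,
        species: Iterable[SpeciesConfig],
        policy: CollisionPolicy = DEFAULT_POLICY,
        site_bp: int = 1000,
        seed: int = 0,
        dt: float | None = None,
        ctcf_loss_rate: float = 0.0,
        push_cohesive: bool = False,
    ):
        self.species = {sp.name: sp for sp in species}
        self.policy = policy
        self.site_bp = int(site_bp)
        self.L = int(lattice_length)
        self.rng = np.random.default_rng(seed)
        self.ctcf_loss_rate = ctcf_loss_rate
        self.push_cohesive = push_cohesive
        site_kb = self.site_bp / 1000.0
        vmax = max((sp.speed for sp in self.species.values()), default=0.0)
        if dt is None:
            dt = site_kb / vmax if vmax > 0 else 1.0
        self.dt = float(dt)
        self.move_prob = {
            name: sp.speed * self.dt / site_kb for name, sp in self.species.items()
        }
        for name, p in self.move_prob.items():
            if p > 1 + 1e-9:
                raise ConfigurationError(
                    f"per-step move probability {p:.3f} > 1 for {name}; "
                    "use a smaller time step"
                )
        self.state = LatticeState(self.L, self.site_bp)
        # occupancy: -1 free, otherwise an occupant token
        self.occ = np.full(self.L, -1, dtype=np.int64)
        self.total_translocated = 0
        self._loading_on: set[str] = set()

    # ---- occupant tokens: extruder legs are 2*i (left) and 2*i+1 (right);
    # ---- obstacles are -(j+2)
    def _token_owner(self, token: int) -> tuple[str, int]:
        if token >= 0:
            return ("leg", token)
        return ("obstacle", -token - 2)

    # ------------------------------------------------------------------ setup
    def add_extruder(self, species: str, left: int, right: int) -> Extruder:
        ex = Extruder(species, left, right)
        idx = len(self.state.extruders)
        if self.occ[left] != -1 or (right != left and self.occ[right] != -1):
            raise ValueError("cannot place extruder on occupied sites")
        self.state.extruders.append(ex)
        self.occ[left] = 2 * idx
        self.occ[right] = 2 * idx + 1
        return ex

    def add_obstacle(self, species: str, pos: int, orientation: str = ".") -> Obstacle:
        ob = Obstacle(species, pos, orientation)
        idx = len(self.state.obstacles)
        if species != "ctcf_barrier":
            if self.occ[pos] != -1:
                raise ValueError("cannot place obstacle on occupied site")
            self.occ[pos] = -(idx + 2)
        self.state.obstacles.append(ob)
        return ob

    def load_at_density(self, species: str) -> int:
        """Place ``density`` complexes per Mb at random free site pairs."""
        sp = self.species[species]
        n = self.rng.poisson(sp.density * self.L * self.site_bp / 1e6)
        placed = 0
        for _ in range(n):
            placed += self._load_one(species)
        self._loading_on.add(species)
        return placed

    def _load_one(self, species: str) -> int:
        for _ in range(50):
            s = int(self.rng.integers(0, self.L - 1))
            if self.occ[s] == -1 and self.occ[s + 1] == -1:
                self.add_extruder(species, s, s + 1)
                return 1
        return 0

    # ------------------------------------------------------------- collisions
    def _ctcf_blocks(self, mover_species: str, target: int, direction: int) -> bool:
        if mover_species != "cohesin_extrusive":
            return False
        for ob in self.state.obstacles:
            if ob.species == "ctcf_barrier" and ob.pos == target:
                if ob.orientation == "+" and direction < 0:
                    return True
                if ob.orientation == "-" and direction > 0:
                    return True
        return False

    def _unload_extruder(self, idx: int) -> None:
        ex = self.state.extruders[idx]
        if ex.status == "unloaded":
            return
        for pos, token in ((ex.left, 2 * idx), (ex.right, 2 * idx + 1)):
            if 0 <= pos < self.L and self.occ[pos] == token:
                self.occ[pos] = -1
        ex.status = "unloaded"

    def _remove_obstacle(self, idx: int) -> None:
        ob = self.state.obstacles[idx]
        if ob.species != "ctcf_barrier" and 0 <= ob.pos < self.L:
            if self.occ[ob.pos] == -(idx + 2):
                self.occ[ob.pos] = -1
        ob.pos = -1

    def _occupant_species(self, token: int) -> str:
        kind, idx = self._token_owner(token)
        if kind == "leg":
            return self.state.extruders[idx // 2].species
        return self.state.obstacles[idx].species

    def _push_chain(self, start: int, direction: int, mover_species: str) -> bool:
        """Displace the contiguous occupant chain starting at ``start``.

        Returns True if the chain moved (mover may advance). A chain
        containing a cohesive cohesin is unpushable unless ``push_cohesive``;
        a chain against the chromosome end converts to stall.
        """
        chain = []
        pos = start
        while 0 <= pos < self.L and self.occ[pos] != -1:
            token = self.occ[pos]
            sp = self._occupant_species(token)
            if sp == "cohesin_cohesive" and not self.push_cohesive:
                return False
            chain.append((pos, token))
            pos += direction
        if not (0 <= pos < self.L):
            return False  # push against chromosome end -> stall
        # shift the chain one site, farthest occupant first
        for cpos, token in reversed(chain):
            self.occ[cpos + direction] = token
            self.occ[cpos] = -1
            kind, idx = self._token_owner(token)
            if kind == "leg":
                ex = self.state.extruders[idx // 2]
                if idx % 2 == 0:
                    ex.left = cpos + direction
                else:
                    ex.right = cpos + direction
                # a pushed extrusive cohesin loses its CTCF anchoring simply
                # by being displaced off the CTCF site
            else:
                self.state.obstacles[idx].pos = cpos + direction
        return True

    def _attempt_move(self, ex_idx: int, leg: int) -> bool:
        """One unit move of one leg; returns True if the leg advanced."""
        ex = self.state.extruders[ex_idx]
        if ex.status == "unloaded":
            return False
        direction = -1 if leg == 0 else +1
        pos = ex.left if leg == 0 else ex.right
        target = pos + direction
        token = 2 * ex_idx + leg
        if not (0 <= target < self.L):
            return False  # chromosome end: stall
        if self._ctcf_blocks(ex.species, target, direction):
            return False
        guard = 0
        while True:
            guard += 1
            if guard > self.L:
                return False
            occ_token = self.occ[target]
            if occ_token == -1:
                break
            occ_sp = self._occupant_species(occ_token)
            out = self.policy.outcome(ex.species, occ_sp)
            if out is Outcome.STALL:
                return False
            if out is Outcome.UNLOAD_SELF:
                self._unload_extruder(ex_idx)
                return False
            if out is Outcome.UNLOAD_OBSTACLE:
                kind, idx = self._token_owner(occ_token)
                if kind == "leg":
                    self._unload_extruder(idx // 2)
                else:
                    self._remove_obstacle(idx)
                continue  # target may now be free
            if out is Outcome.PUSH_OBSTACLE:
                if not self._push_chain(target, direction, ex.species):
                    return False
                continue
            if out is Outcome.BYPASS:
                nxt = target + direction
                if not (0 <= nxt < self.L):
                    return False
                target = nxt
                continue
        # move
        self.occ[pos] = -1
        self.occ[target] = token
        if leg == 0:
            ex.left = target
        else:
            ex.right = target
        ex.translocated += abs(target - pos)
        self.total_translocated += abs(target - pos)
        return True

    # ------------------------------------------------------------------ step
    def step(self) -> None:
        st = self.state
        # movement: shuffled leg order, probabilistic unit moves
        legs = []
        for i, ex in enumerate(st.extruders):
            if ex.status == "unloaded" or not self.species[ex.species].mobile:
                continue
            legs.append((i, 1))
            if self.species[ex.species].two_sided:
                legs.append((i, 0))
        if legs:
            order = self.rng.permutation(len(legs))
            probs = self.rng.random(len(legs))
            for k in order:
                i, leg = legs[k]
                ex = st.extruders[i]
                if probs[k] >= self.move_prob[ex.species]:
                    continue
                moved = self._attempt_move(i, leg)
                if ex.status == "unloaded":
                    continue
                ex.status = _update_status(ex.status, leg, moved)
        # unloading
        for i, ex in enumerate(st.extruders):
            if ex.status == "unloaded":
                continue
            q = self.species[ex.species].unloading_rate * self.dt
            if q > 0 and self.rng.random() < q:
                self._unload_extruder(i)
        # stochastic loading
        for name in list(self._loading_on):
            sp = self.species[name]
            if sp.loading_rate <= 0:
                continue
            lam = sp.loading_rate * self.dt * self.L
            for _ in range(self.rng.poisson(lam)):
                self._load_one(name)
        # background CTCF loss
        if self.ctcf_loss_rate > 0:
            q = self.ctcf_loss_rate * self.dt
            for idx, ob in enumerate(self.state.obstacles):
                if ob.species == "ctcf_barrier" and ob.pos >= 0:
                    if self.rng.random() < q:
                        ob.pos = -1
        st.time += 1

    def run(self, n_steps: int) -> None:
        for _ in range(int(n_steps)):
            self.step()

    # -------------------------------------------------------------- recording
    def bound_extruders(self) -> list[Extruder]:
        return [ex for ex in self.state.extruders if ex.status != "unloaded"]

    def anchored_cohesin_count(self, anchor_pairs: Sequence[tuple[int, int]]) -> int:
        """Cohesins whose legs sit exactly on a convergent CTCF anchor pair."""
        anchors = set(anchor_pairs)
        n = 0
        for ex in self.bound_extruders():
            if ex.species == "cohesin_extrusive" and (ex.left, ex.right) in anchors:
                n += 1
        return n

    def snapshot(self, anchor_pairs: Sequence[tuple[int, int]] = ()) -> Frame:
        bound = self.bound_extruders()
        loops = np.array([[ex.left, ex.right] for ex in bound], dtype=np.int64)
        loops = loops.reshape(-1, 2)
        return Frame(
            time_s=self.state.time * self.dt,
            loops=loops,
            species=[ex.species for ex in bound],
            statuses=[ex.status for ex in bound],
            obstacles=[dataclasses.replace(ob) for ob in self.state.obstacles],
            anchored_cohesins=self.anchored_cohesin_count(anchor_pairs),
            translocated_sites=self.total_translocated,
            n_bound=len(bound),
        )

    def check_invariants(self) -> None:
        for i, ex in enumerate(self.state.extruders):
            if ex.status == "unloaded":
                continue
            assert 0 <= ex.left <= ex.right < self.L, f"leg order violated: {ex}"
            assert self.occ[ex.left] == 2 * i and self.occ[ex.right] == 2 * i + 1


# ------------------------------------------------------------------ operations

def resolve_encounter(engine: ExtrusionEngine, ex_idx: int, leg: int) -> bool:
    """Resolve one unit move of one extruder leg against whatever occupies
    the next site, per the engine's collision policy. Returns whether the
    leg advanced."""
    return engine._attempt_move(ex_idx, leg)


def step_lattice(engine: ExtrusionEngine, n_steps: int = 1) -> LatticeState:
    engine.run(n_steps)
    return engine.state


def loop_statistics(frame: Frame, lattice_length: int, site_bp: int = 1000) -> dict:
    """Summary statistics of one trajectory frame.

    ``coverage_fraction`` is the fraction of sites inside the union of all
    loops; ``extruded_length_per_extruder`` is cumulative translocation
    divided by currently bound complexes (in kb).
    """
    site_kb = site_bp / 1000.0
    out: dict[str, float | None] = {
        "mean_loop_kb": None,
        "median_loop_kb": None,
        "coverage_fraction": 0.0,
        "gap_lengths_kb": [],
        "loops_per_mb": 0.0,
        "extruded_length_per_extruder_kb": None,
    }
    loops = frame.loops
    if frame.n_bound > 0:
        out["extruded_length_per_extruder_kb"] = (
            frame.translocated_sites * site_kb / frame.n_bound
        )
    if len(loops) == 0:
        return out
    sizes = (loops[:, 1] - loops[:, 0]) * site_kb
    out["mean_loop_kb"] = float(np.mean(sizes))
    out["median_loop_kb"] = float(np.median(sizes))
    out["loops_per_mb"] = len(loops) / (lattice_length * site_kb / 1000.0)
    # union coverage and gaps
    order = np.argsort(loops[:, 0])
    covered = 0
    gaps = []
    cursor = 0
    for a, b in loops[order]:
        if a > cursor:
            gaps.append((a - cursor) * site_kb)
        if b > cursor:
            covered += b - max(a, cursor)
            cursor = b
    if cursor < lattice_length:
        gaps.append((lattice_length - cursor) * site_kb)
    out["coverage_fraction"] = covered / lattice_length
    out["gap_lengths_kb"] = gaps
    return out


def run_prophase_scenario(
    scenario: str,
    g2_fixture,
    duration_s: float = 1800.0,
    seed: int = 0,
    sampling_times: Sequence[float] | None = None,
    condensin_density: float = 2.5,
    condensin_speed: float = 1.5,
    cohesin_unloading_rate: float = 1.0 / 1800.0,
    ctcf_loss_rate: float = 1.0 / 1800.0,
) -> LoopTrajectory:
    """Simulate prophase condensin loading onto a G2-like cohesin landscape.

    The fixture provides CTCF sites and extrusive cohesins parked at
    convergent CTCF anchor pairs (Hi-C dots). Condensin II loads at t=0 and
    its encounters with those cohesins follow the chosen scenario
    (``unload``/``push``/``bypass``/``stall``). A slow background pathway
    (first-order cohesin unloading and CTCF loss) acts in all scenarios;
    unloaded cohesin does not rebind.
    """
    policy = prophase_policy(scenario)
    species = [
        SpeciesConfig("condensin_II", density=condensin_density, speed=condensin_speed),
        SpeciesConfig(
            "cohesin_extrusive", density=0.0, speed=condensin_speed,
            unloading_rate=cohesin_unloading_rate,
        ),
    ]
    eng = ExtrusionEngine(
        g2_fixture.lattice_length,
        species,
        policy,
        site_bp=g2_fixture.site_bp,
        seed=seed,
        ctcf_loss_rate=ctcf_loss_rate,
    )
    for pos, orient in zip(g2_fixture.ctcf_sites, g2_fixture.ctcf_orientations):
        eng.add_obstacle("ctcf_barrier", int(pos), orient)
    # legs sit one site inside the convergent CTCF pair, so the barriers
    # block their outward motion and the loop spans the anchor pair
    anchor_pairs = [(int(a) + 1, int(b) - 1)
                    for a, b in g2_fixture.anchored_cohesins]
    for left, right in anchor_pairs:
        eng.add_extruder("cohesin_extrusive", left, right)
    eng.load_at_density("condensin_II")
    if sampling_times is None:
        sampling_times = np.linspace(0, duration_s, 13)
    traj = LoopTrajectory(eng.site_bp, eng.L)
    traj.frames.append(eng.snapshot(anchor_pairs))
    for t in sorted(sampling_times):
        n_target = int(round(t / eng.dt))
        if n_target > eng.state.time:
            eng.run(n_target - eng.state.time)
            traj.frames.append(eng.snapshot(anchor_pairs))
    return traj


def nested_loop_experiment(
    lattice_length_mb: float = 10.0,
    condensin_II_first_duration_s: float = 600.0,
    total_duration_s: float = 1200.0,
    seed: int = 0,
    density_II: float = 2.5,
    density_I: float = 10.0,
    speed_kb_s: float = 1.5,
    policy: CollisionPolicy | None = None,
    site_bp: int = 1000,
    n_frames: int = 9,
) -> LoopTrajectory:
    """Condensin II extrudes first; condensin I loads later (NEB mimic)."""
    L = int(lattice_length_mb * 1e6 / site_bp)
    species = [
        SpeciesConfig("condensin_II", density=density_II, speed=speed_kb_s),
        SpeciesConfig("condensin_I", density=density_I, speed=speed_kb_s),
    ]
    eng = ExtrusionEngine(
        L, species, policy or DEFAULT_POLICY, site_bp=site_bp, seed=seed
    )
    eng.load_at_density("condensin_II")
    traj = LoopTrajectory(site_bp, L)
    times = np.linspace(0, total_duration_s, n_frames)
    loaded_I = False
    traj.frames.append(eng.snapshot())
    for t in times[1:]:
        if t > condensin_II_first_duration_s and not loaded_I:
            n_target = int(round(condensin_II_first_duration_s / eng.dt))
            if n_target > eng.state.time:
                eng.run(n_target - eng.state.time)
            eng.load_at_density("condensin_I")
            loaded_I = True
        n_target = int(round(t / eng.dt))
        if n_target > eng.state.time:
            eng.run(n_target - eng.state.time)
        traj.frames.append(eng.snapshot())
    return traj


def required_processivity_ratio(
    seeds: Sequence[int] = range(20),
    coverage_target: float = 0.98,
    density_per_mb: float = 2.5,
    speed_kb_s: float = 1.5,
    lattice_mb: float = 40.0,
    max_duration_s: float = 3600.0,
    site_bp: int = 1000,
    check_every_steps: int = 5,
) -> dict:
    """How many times its loop must a condensin extrude to close most gaps.

    Single species, loaded at once, no unloading: inter-condensin gaps are
    near-exponential and each closes at twice the leg speed, so the last
    few percent of coverage (the rod-morphology criterion) take several
    mean gap lengths of extrusion. The experiment measures the extrusion
    capacity per condensin, 2 x leg speed x time, at the moment coverage
    first reaches ``coverage_target``, in units of the saturated-array mean
    loop size. Exponential-gap theory puts the ratio at ln(1/(1-target)):
    closing most gaps costs ~4-5 average loop lengths.
    """
    L = int(lattice_mb * 1e6 / site_bp)
    ratios = []
    capacities = []
    sat_loops = []
    for seed in seeds:
        sp = [SpeciesConfig("condensin_II", density=density_per_mb,
                            speed=speed_kb_s)]
        eng = ExtrusionEngine(L, sp, site_bp=site_bp, seed=seed)
        eng.load_at_density("condensin_II")
        t_star = None
        max_steps = int(max_duration_s / eng.dt)
        while eng.state.time < max_steps:
            eng.run(check_every_steps)
            stats = loop_statistics(eng.snapshot(), L, site_bp)
            if stats["coverage_fraction"] >= coverage_target:
                t_star = eng.state.time * eng.dt
                break
        if t_star is None:
            continue  # seed never reached the target (isolated end gaps)
        # saturated array: run on until loops stop growing
        eng.run(int(600 / eng.dt))
        sat = loop_statistics(eng.snapshot(), L, site_bp)["mean_loop_kb"]
        capacity_kb = 2 * speed_kb_s * t_star
        capacities.append(capacity_kb)
        sat_loops.append(sat)
        ratios.append(capacity_kb / sat)
    if not ratios:
        raise RuntimeError("no seed reached the coverage target")
    return {
        "ratio": float(np.mean(ratios)),
        "ratio_sd": float(np.std(ratios)),
        "required_processivity_kb": float(np.mean(capacities)),
        "saturated_mean_loop_kb": float(np.mean(sat_loops)),
        "n_seeds": len(ratios),
    }


def nesting_fraction(frame: Frame, inner_species: str = "condensin_I",
                     outer_species: str = "condensin_II") -> float | None:
    """Fraction of inner-species loops contained in an outer-species loop."""
    inner = [tuple(iv) for iv, sp in zip(frame.loops, frame.species) if sp == inner_species]
    outer = [tuple(iv) for iv, sp in zip(frame.loops, frame.species) if sp == outer_species]
    if not inner:
        return None
    n_nested = sum(
        any(o[0] <= i[0] and i[1] <= o[1] for o in outer) for i in inner
    )
    return n_nested / len(inner)
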