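"""Tick-based contagion of a health behavior with gender-specific dynamics.

Each tick, every influenced agent independently attempts to pass the behavior
across each of its links; the per-link transmission probability depends on the
gender composition of the link (male–male 0.20, female–female 0.25,
male–female 0.10 by default).  An uninfluenced agent with ``j`` influenced
neighbours is therefore influenced with probability
``1 - prod_j (1 - spread_chance[link])`` in one tick.  Influenced agents may
fail to persevere with a gender-specific resistance chance (male 0.10, female
0.20) and re-enter the uninfluenced pool, after which they can be influenced
again.  Two readings of the one-shot persistence description are supported:

``per_tick``
    every influenced non-seed agent re-draws perseverance each tick;

``on_influence``
    a newly influenced agent draws perseverance once: with probability equal
    to its resistance chance it reverts at the next tick and re-enters
    diffusion, otherwise it is permanently persisted.

Updates are synchronous: both the infection and the reversion phase read only
the tick-start state.  Initially influential agents ("seeds") are committed to
the intervention and immune to reversion by default.

A run stops at equilibrium (the influenced fraction's consecutive per-tick
changes all below ``equilibrium_tol`` percentage points across a trailing
window), at absorption (everyone influenced and nobody able to revert), or at
``max_ticks``.  Diffusion speed is measured in percentage points of the
population per tick over the ticks elapsed until the equilibrium window
*began* — the quiet detection window itself adds no spread and is excluded
from the elapsed time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .centrality import SeedSet

__all__ = [
    "DiffusionParams",
    "AgentState",
    "Trajectory",
    "diffusion_step",
    "run_diffusion",
    "summarize_run",
    "write_trajectory_csv",
]

#: canonical link-type keys
MM, FF, MF = "male-male", "female-female", "male-female"


@dataclass(frozen=True)
class DiffusionParams:
    """Contagion parameters (defaults are the study's published values)."""

    spread_chance: dict = field(default_factory=lambda: {MM: 0.20, FF: 0.25, MF: 0.10})
    resistance_chance: dict = field(default_factory=lambda: {"male": 0.10,
                                                             "female": 0.20})
    reversion_mode: str = "on_influence"
    seeds_immune: bool = True
    max_ticks: int = 500
    equilibrium_window: int = 10
    equilibrium_tol: float = 0.5  # percentage points of the population per tick

    def validate(self) -> None:
        for val in list(self.spread_chance.values()) + list(
                self.resistance_chance.values()):
            if not 0 <= val <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.reversion_mode not in ("per_tick", "on_influence"):
            raise ValueError(f"unknown reversion_mode {self.reversion_mode!r}")
        if not self.max_ticks >= self.equilibrium_window >= 1:
            raise ValueError("need max_ticks >= equilibrium_window >= 1")


class _CompiledNetwork:
    """CSR adjacency with per-directed-edge log survival probabilities."""

    def __init__(self, net: nx.Graph, params: DiffusionParams):
        self.nodes = sorted(net.nodes)
        self.index = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        genders = nx.get_node_attributes(net, "gender")
        self.female = np.array(
            [genders.get(u, "M") == "F" for u in self.nodes], dtype=bool)
        self.resistance = np.where(
            self.female, params.resistance_chance["female"],
            params.resistance_chance["male"])
        adj = [[] for _ in range(n)]
        for u, v in net.edges:
            iu, iv = self.index[u], self.index[v]
            adj[iu].append(iv)
            adj[iv].append(iu)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        self.indptr[1:] = np.cumsum([len(a) for a in adj])
        self.nbr = np.array([w for a in adj for w in a], dtype=np.int64)
        src = np.repeat(np.arange(n), np.diff(self.indptr))
        link_female = self.female[src].astype(int) + self.female[self.nbr].astype(int)
        s = np.choose(link_female, [params.spread_chance[MM],
                                    params.spread_chance[MF],
                                    params.spread_chance[FF]])
        with np.errstate(divide="ignore"):
            self.log_surv = np.log1p(-s)  # -inf for spread chance 1
        self.src = src
        self.n = n


@dataclass
class AgentState:
    """Per-agent status plus bookkeeping for the reversion modes."""

    influenced: np.ndarray
    seed: np.ndarray
    persisted: np.ndarray       # on_influence: permanently committed
    pending_revert: np.ndarray  # on_influence: will revert at next tick

    @classmethod
    def initial(cls, n: int, seed_idx: np.ndarray,
                seeds_immune: bool) -> "AgentState":
        influenced = np.zeros(n, dtype=bool)
        influenced[seed_idx] = True
        seed = influenced.copy()
        persisted = seed.copy() if seeds_immune else np.zeros(n, dtype=bool)
        return cls(influenced, seed, persisted, np.zeros(n, dtype=bool))


def _step(state: AgentState, comp: _CompiledNetwork, params: DiffusionParams,
          rng: np.random.Generator) -> None:
    """One synchronous tick, in place; both phases read tick-start state."""
    inf0 = state.influenced
    # infection phase: P(infected) = 1 - prod over influenced neighbours (1 - s)
    contrib = np.where(inf0[comp.nbr], comp.log_surv, 0.0)
    log_not = np.bincount(comp.src, weights=contrib, minlength=comp.n)
    p_inf = -np.expm1(log_not)
    newly = (~inf0) & (rng.random(comp.n) < p_inf)

    if params.reversion_mode == "per_tick":
        at_risk = inf0 & ~state.seed if params.seeds_immune else inf0
        reverting = at_risk & (rng.random(comp.n) < comp.resistance)
        state.influenced = (inf0 & ~reverting) | newly
    else:  # on_influence
        reverting = state.pending_revert & inf0
        draws = rng.random(comp.n) < comp.resistance
        immune = state.seed if params.seeds_immune else np.zeros(comp.n, bool)
        will_revert = newly & draws & ~immune
        state.persisted = state.persisted | (newly & ~will_revert)
        state.pending_revert = will_revert
        state.influenced = (inf0 & ~reverting) | newly


def diffusion_step(state: AgentState, net: nx.Graph, params: DiffusionParams,
                   rng: np.random.Generator) -> AgentState:
    """Public single-step update on a networkx graph (compiles the network)."""
    params.validate()
    comp = _CompiledNetwork(net, params)
    _step(state, comp, params, rng)
    return state


@dataclass
class Trajectory:
    """Per-tick influenced counts (overall and per gender) of one run."""

    counts: np.ndarray
    counts_female: np.ndarray
    counts_male: np.ndarray
    n: int
    n_female: int
    n_male: int
    stop_reason: str
    stop_tick: int
    ticks_elapsed: int  # time to equilibrium onset / absorption

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n

    def gender_onset_tick(self, window: int, tol_points: float) -> dict[str, int]:
        """First tick at which each gender's own curve became stable.

        Applies the run's equilibrium rule (all consecutive changes within a
        trailing window below ``tol_points`` percentage points of the
        *subgroup*) to each gender curve; falls back to the run's elapsed
        ticks when a subgroup never stabilizes within the recorded horizon.
        """
        out = {}
        for label, counts, size in (("female", self.counts_female, self.n_female),
                                    ("male", self.counts_male, self.n_male)):
            if size == 0:
                out[label] = self.ticks_elapsed
                continue
            frac = counts / size
            changes = np.abs(np.diff(frac))
            quiet = changes < tol_points / 100.0
            onset = self.ticks_elapsed
            for t in range(window, len(frac)):
                if quiet[t - window:t].all():
                    onset = t - window
                    break
            out[label] = max(onset, 1)
        return out


def run_diffusion(net: nx.Graph, seeds: SeedSet | set, params: DiffusionParams,
                  rng: np.random.Generator | int | None = None) -> Trajectory:
    """Iterate the contagion to equilibrium, absorption or the tick limit."""
    params.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    comp = _CompiledNetwork(net, params)
    seed_nodes = seeds.nodes if isinstance(seeds, SeedSet) else set(seeds)
    unknown = [u for u in seed_nodes if u not in comp.index]
    if unknown:
        raise ValueError(f"seed nodes not in network: {unknown[:5]}")
    if not seed_nodes:
        warnings.warn("empty seed set: nothing can spread")
    seed_idx = np.array(sorted(comp.index[u] for u in seed_nodes), dtype=np.int64)
    state = AgentState.initial(comp.n, seed_idx, params.seeds_immune)

    female = comp.female
    counts, counts_f, counts_m = [], [], []

    def record():
        counts.append(int(state.influenced.sum()))
        counts_f.append(int((state.influenced & female).sum()))
        counts_m.append(int((state.influenced & ~female).sum()))

    record()
    window = params.equilibrium_window
    tol = params.equilibrium_tol / 100.0
    stop_reason, stop_tick, ticks_elapsed = "max_ticks", params.max_ticks, None

    for t in range(1, params.max_ticks + 1):
        _step(state, comp, params, rng)
        record()
        if state.influenced.all():
            if params.reversion_mode == "on_influence":
                absorbed = state.persisted.all()
            else:
                at_risk = (~state.seed if params.seeds_immune
                           else np.ones(comp.n, bool))
                absorbed = not (comp.resistance[at_risk] > 0).any()
            if absorbed:
                stop_reason, stop_tick, ticks_elapsed = "absorbed", t, t
                break
        if t >= window:
            recent = np.abs(np.diff(np.array(counts[t - window:t + 1]) / comp.n))
            if (recent < tol).all():
                stop_reason, stop_tick = "equilibrium", t
                ticks_elapsed = t - window
                break
    if ticks_elapsed is None:
        ticks_elapsed = params.max_ticks
    ticks_elapsed = max(ticks_elapsed, 1) if len(counts) > 1 else 0

    return Trajectory(
        counts=np.array(counts), counts_female=np.array(counts_f),
        counts_male=np.array(counts_m), n=comp.n,
        n_female=int(female.sum()), n_male=int((~female).sum()),
        stop_reason=stop_reason, stop_tick=stop_tick,
        ticks_elapsed=ticks_elapsed)


def summarize_run(traj: Trajectory, success_mode: str = "final_fraction",
                  success_threshold: float = 0.95,
                  window: int = 10, tol_points: float = 0.5) -> dict:
    """Per-run success and diffusion-speed metrics.

    ``speed`` is 100 * (final - initial influenced fraction) / ticks elapsed,
    in percentage points of the whole population per tick.  Per-gender speeds
    come in two conventions:

    * ``speed_female`` / ``speed_male`` — that gender's *population-share*
      contribution per tick of its own stabilization time (the gender curve's
      equilibrium onset); these are the results-table-style per-gender rows, whose
      published values lie below the population row;
    * ``speed_female_subgroup`` / ``speed_male_subgroup`` — subgroup
      denominator with the global elapsed time; these recombine exactly to
      ``speed`` when weighted by subgroup shares.
    """
    if traj.ticks_elapsed == 0:
        raise ValueError("undefined speed: zero ticks elapsed")
    f0, f1 = traj.counts[0] / traj.n, traj.counts[-1] / traj.n
    speed = 100.0 * (f1 - f0) / traj.ticks_elapsed
    onset = traj.gender_onset_tick(window, tol_points)

    out = {"ticks_elapsed": traj.ticks_elapsed, "stop_reason": traj.stop_reason,
           "final_fraction": f1, "speed": speed}
    for label, c, size in (("female", traj.counts_female, traj.n_female),
                           ("male", traj.counts_male, traj.n_male)):
        delta_pop = (c[-1] - c[0]) / traj.n
        out[f"speed_{label}"] = 100.0 * delta_pop / onset[label]
        if size > 0:
            delta_sub = (c[-1] - c[0]) / size
            out[f"speed_{label}_subgroup"] = 100.0 * delta_sub / traj.ticks_elapsed
        else:
            out[f"speed_{label}_subgroup"] = 0.0

    if success_mode == "final_fraction":
        out["success"] = 100.0 * f1
    elif success_mode == "replicate_threshold":
        out["success"] = 100.0 * float(f1 >= success_threshold)
    else:
        raise ValueError(f"unknown success_mode {success_mode!r}")
    return out


def write_trajectory_csv(traj: Trajectory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tick,n_influenced,n_influenced_female,n_influenced_male,"
                 "stop_reason\n")
        last = len(traj.counts) - 1
        for t in range(len(traj.counts)):
            reason = traj.stop_reason if t == last else ""
            fh.write(f"{t},{traj.counts[t]},{traj.counts_female[t]},"
                     f"{traj.counts_male[t]},{reason}\n")
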