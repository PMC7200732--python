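"""The stochastic simulation loop.

A circular array of ``n`` trees of ``k`` species.  Each step: a random
ten percent (by default) of adults die; all adults (including the dying,
censused at the step start) cast seed and microbial propagules with
power-law kernels; each vacated cell recruits one seedling with
probability proportional to local seed rain times microbially mediated
survival; the recruit's microbiome is initialized from the local
propagule pool filtered by compatibility-scaled competitive ability; and
every tree's mutualist and pathogen communities advance one step of
Lotka–Volterra competition.

All stochasticity flows from one root seed through named substreams
(initialization, mortality, recruitment) so intervention experiments are
counterfactually comparable: a run and its intervened twin are identical
up to the intervention step under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import dispersal, microbes, recruitment
from .parameters import ParameterSet

__all__ = ["LatticeState", "Trajectory", "Simulation", "run", "initialize_recruit_microbiome"]

#: Substream order is part of the determinism contract.
SUBSTREAMS = ("initialization", "mortality", "recruitment")


@dataclass
class LatticeState:
    """Snapshot of the lattice: who lives where, with which microbiomes."""

    species: np.ndarray      # (n,) int species ids in [0, k)
    age: np.ndarray          # (n,) steps since recruitment
    mutualists: np.ndarray   # (n, k) per-tree mutualist abundances
    pathogens: np.ndarray    # (n, k) per-tree pathogen abundances
    step_count: int = 0

    @property
    def n(self) -> int:
        return self.species.shape[0]

    def abundances(self, k: int) -> np.ndarray:
        return np.bincount(self.species, minlength=k)

    def copy(self) -> "LatticeState":
        return LatticeState(
            species=self.species.copy(),
            age=self.age.copy(),
            mutualists=self.mutualists.copy(),
            pathogens=self.pathogens.copy(),
            step_count=self.step_count,
        )


@dataclass
class Trajectory:
    """Per-step plant abundances plus the final lattice state."""

    abundance: np.ndarray          # (recorded_steps, k) counts
    final_state: LatticeState
    params: ParameterSet
    events: list = field(default_factory=list)

    @property
    def steps_recorded(self) -> int:
        return self.abundance.shape[0]


def replacement_count(n: int, fraction: float) -> int:
    """Number of adults replaced per step: round-half-up of fraction*n."""
    return int(np.floor(fraction * n + 0.5))


def initialize_recruit_microbiome(
    local: np.ndarray,
    e_c_column: np.ndarray,
    mode: str = "filtered",
) -> np.ndarray:
    """Initial microbiome of a new recruit for one guild.

    In the default ``filtered`` mode each taxon's share of the local
    community is weighted by its compatibility with the recruit raised to
    the competitive-ability exponent (``e[i, recruit]**c``): the recruit's
    own taxa establish at their local propagule abundance while poorly
    compatible taxa start near zero and must re-invade by immigration.
    ``rescaled`` renormalizes the filtered community to the local guild
    total (initialization redistributes rather than removes abundance);
    ``inherit`` passes the local community through unchanged.
    """
    if mode == "inherit":
        return local.copy()
    unscaled = local * e_c_column
    if mode == "filtered":
        return unscaled
    if mode == "rescaled":
        total = unscaled.sum()
        if total <= 0:
            return np.zeros_like(local)
        return unscaled * (local.sum() / total)
    raise ValueError(f"unknown recruit_init mode {mode!r}")


class Simulation:
    """Mutable simulation object; one instance per run."""

    def __init__(self, params: ParameterSet, seed: int | None = None):
        self.params = params
        root = np.random.SeedSequence(params.rng_seed if seed is None else seed)
        streams = root.spawn(len(SUBSTREAMS))
        self.rng = {
            name: np.random.default_rng(s) for name, s in zip(SUBSTREAMS, streams)
        }
        self.kernel_plant = dispersal.build_kernel(params.b_t, params.n)
        self.kernel_mut = dispersal.build_kernel(params.mutualists.b, params.n)
        self.kernel_path = dispersal.build_kernel(params.pathogens.b, params.n)
        self.comp_mut = microbes.compatibility_matrix(params.mutualists, params.k)
        self.comp_path = microbes.compatibility_matrix(params.pathogens, params.k)
        # Intervention switches (toggled by the experiments layer).
        self.mutualist_effects = True
        self.pathogen_effects = True
        self.freeze_microbiomes = False
        # Per-species fixed recruit microbiomes: (k, k) arrays or None.
        self.fixed_recruit_mutualists: np.ndarray | None = None
        self.fixed_recruit_pathogens: np.ndarray | None = None
        self.state = self._initialize()

    # ------------------------------------------------------------------
    def _initialize(self) -> LatticeState:
        p = self.params
        rng = self.rng["initialization"]
        # Equal totals: as-even-as-possible species counts at random positions.
        counts = np.full(p.k, p.n // p.k)
        remainder = p.n - counts.sum()
        if remainder:
            counts[rng.choice(p.k, size=remainder, replace=False)] += 1
        species = rng.permutation(np.repeat(np.arange(p.k), counts))
        # Every guild's k taxa start at equal abundance, 1/k of carrying capacity.
        fields = np.full((p.n, p.k), 1.0 / p.k)
        return LatticeState(
            species=species.astype(np.int64),
            age=np.zeros(p.n, dtype=np.int64),
            mutualists=fields.copy(),
            pathogens=fields.copy(),
        )

    # ------------------------------------------------------------------
    def theta_fields(self, state: LatticeState | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Microbial effects theta_m, theta_p of every cell on every species.

        Returns two (n, k) arrays: entry [x, j] is the effect of cell x's
        community on a species-j seedling.  Intervention switches that
        remove a guild's effect zero the corresponding array.
        """
        state = self.state if state is None else state
        theta_m = state.mutualists @ self.comp_mut.e if self.mutualist_effects else np.zeros((state.n, self.params.k))
        theta_p = state.pathogens @ self.comp_path.e if self.pathogen_effects else np.zeros((state.n, self.params.k))
        return theta_m, theta_p

    def survival_scores(self, state: LatticeState | None = None) -> np.ndarray:
        """(n, k) survival score of a species-j seedling at every cell x."""
        theta_m, theta_p = self.theta_fields(state)
        return recruitment.survival_score(
            theta_m, theta_p, self.params.zeta[None, :],
            self.params.g, self.params.h,
            literal_logistic=self.params.literal_logistic,
        )

    # ------------------------------------------------------------------
    def step(self) -> None:
        p = self.params
        state = self.state
        n_replace = replacement_count(p.n, p.replacement_fraction)

        # 1. Mortality: uniform sample without replacement, blind to age/species.
        deaths = (
            self.rng["mortality"].choice(p.n, size=n_replace, replace=False)
            if n_replace
            else np.empty(0, dtype=np.int64)
        )

        # 2. Seed rain from the step-start census (dying adults still cast seed).
        rain = dispersal.seed_rain(state.species, p.k, self.kernel_plant, p.seeds_per_tree)

        # 3. Propagule immigration onto every cell.  All-zero fields stay
        # zero under both immigration and competition, so deleted-microbe
        # runs skip the integrator entirely.
        fields_empty = not (state.mutualists.any() or state.pathogens.any())
        if not self.freeze_microbiomes and not fields_empty:
            mode = "conservative" if p.propagule_mode == "transient" else p.propagule_mode
            mut_after = microbes.immigrate(
                state.mutualists, self.kernel_mut, p.mutualists.gamma, mode
            )
            path_after = microbes.immigrate(
                state.pathogens, self.kernel_path, p.pathogens.gamma, mode
            )
            if p.propagule_mode == "transient":
                # Propagule pool influences recruitment only; adults keep
                # their pre-immigration communities.
                mut_local, path_local = mut_after, path_after
            else:
                state.mutualists, state.pathogens = mut_after, path_after
                mut_local, path_local = mut_after, path_after
        else:
            mut_local, path_local = state.mutualists, state.pathogens

        # 4. Recruitment at vacated cells (simultaneous, from the shared census).
        if n_replace:
            theta_m = (
                mut_local[deaths] @ self.comp_mut.e
                if self.mutualist_effects else np.zeros((n_replace, p.k))
            )
            theta_p = (
                path_local[deaths] @ self.comp_path.e
                if self.pathogen_effects else np.zeros((n_replace, p.k))
            )
            scores = recruitment.survival_score(
                theta_m, theta_p, p.zeta[None, :], p.g, p.h,
                literal_logistic=p.literal_logistic,
            )
            weights = rain[deaths] * scores
            totals = weights.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise recruitment.NoCandidateError("a vacated cell received no seeds")
            probs = weights / totals
            # Inverse-CDF draws: one uniform per cell keeps the stream
            # consumption identical across intervention variants.
            u = self.rng["recruitment"].random(n_replace)
            cdf = np.cumsum(probs, axis=1)
            recruits = np.minimum(
                (u[:, None] > cdf).sum(axis=1), p.k - 1
            ).astype(np.int64)

            # 5. Recruit microbiome initialization.
            for idx, cell in enumerate(deaths):
                j = recruits[idx]
                if self.fixed_recruit_mutualists is not None:
                    state.mutualists[cell] = self.fixed_recruit_mutualists[j]
                    state.pathogens[cell] = self.fixed_recruit_pathogens[j]
                else:
                    state.mutualists[cell] = initialize_recruit_microbiome(
                        mut_local[cell], self.comp_mut.e_c[:, j], p.recruit_init
                    )
                    state.pathogens[cell] = initialize_recruit_microbiome(
                        path_local[cell], self.comp_path.e_c[:, j], p.recruit_init
                    )
            state.age += 1
            state.age[deaths] = 0
            state.species[deaths] = recruits
        else:
            state.age += 1

        # 6. Within-host competition on every tree.
        if not self.freeze_microbiomes and not fields_empty:
            state.mutualists = microbes.competition_step(
                state.mutualists, state.species, p.mutualists, self.comp_mut
            )
            state.pathogens = microbes.competition_step(
                state.pathogens, state.species, p.pathogens, self.comp_path
            )
        state.step_count += 1

    # ------------------------------------------------------------------
    def settle(self, steps: int) -> None:
        """Run ``steps`` time steps without host mortality.

        Microbial competition and propagule immigration proceed while the
        plant community is held fixed — the protocol under which feedback
        is measured.  Consumes no random draws, so it does not perturb
        the determinism contract of a subsequent (hypothetical) run.
        """
        saved = self.params
        self.params = saved.replace(replacement_fraction=0.0)
        try:
            for _ in range(steps):
                self.step()
        finally:
            self.params = saved

    # ------------------------------------------------------------------
    def run(
        self,
        steps: int | None = None,
        callbacks: Sequence[Callable[["Simulation", int], None]] = (),
    ) -> Trajectory:
        """Execute ``steps`` time steps, recording abundances each step.

        ``callbacks`` are invoked before every step with the simulation
        and the absolute index (``state.step_count``) of the step about
        to execute; they may mutate the intervention switches (used for
        ablation experiments).  The absolute index makes triggers fire
        correctly even when a run is split across several ``run`` calls.
        """
        p = self.params
        steps = p.steps if steps is None else steps
        abundance = np.empty((steps + 1, p.k), dtype=np.int64)
        abundance[0] = self.state.abundances(p.k)
        for t in range(steps):
            for cb in callbacks:
                cb(self, self.state.step_count)
            self.step()
            abundance[t + 1] = self.state.abundances(p.k)
        return Trajectory(abundance=abundance, final_state=self.state, params=p)


def run(
    params: ParameterSet,
    seed: int | None = None,
    callbacks: Sequence[Callable[[Simulation, int], None]] = (),
    steps: int | None = None,
) -> Trajectory:
    """Convenience wrapper: build a Simulation and run it."""
    return Simulation(params, seed=seed).run(steps=steps, callbacks=callbacks)
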