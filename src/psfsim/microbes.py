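"""Microbial host-compatibility, seedling effects, and within-host dynamics.

Each plant species is the preferred host of exactly one mutualist taxon
and one pathogen taxon.  A guild's compatibility matrix has 1 on the
preferred-host diagonal and the guild affinity ``s`` everywhere else.
On every adult, the guild's taxa compete in a Lotka–Volterra system whose
growth rates and competition coefficients are scaled by powers of the
compatibility with the resident host; taxa are decoupled across guilds
and across trees except through propagule immigration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dispersal import Kernel, deposit
from .parameters import GuildTraits

__all__ = [
    "CompatibilityMatrix",
    "compatibility_matrix",
    "immigrate",
    "effect_theta",
    "competition_step",
    "competition_rhs",
]


def _scaled_power(e: np.ndarray, exponent: float) -> np.ndarray:
    """e**exponent with the convention 0**exponent := 0.

    A strict specialist (s=0) must have zero growth and zero competitive
    effect on non-preferred hosts even for exponents <= 0, where the
    literal power would be undefined or infinite.
    """
    e = np.asarray(e, dtype=float)
    out = np.zeros_like(e)
    nz = e > 0
    out[nz] = e[nz] ** exponent
    return out


@dataclass(frozen=True)
class CompatibilityMatrix:
    """Per-guild compatibility e[i, j] of microbe taxon i with host species j."""

    e: np.ndarray      # (k, k), 1 on diagonal, s off-diagonal
    e_q: np.ndarray    # e**q with 0**q := 0 (growth-rate scaling)
    e_c: np.ndarray    # e**c with 0**c := 0 (competitive-ability scaling)

    @property
    def k(self) -> int:
        return self.e.shape[0]


def compatibility_matrix(traits: GuildTraits, k: int) -> CompatibilityMatrix:
    """Build the guild's k x k compatibility matrix and its scaled powers."""
    e = np.full((k, k), traits.s, dtype=float)
    np.fill_diagonal(e, 1.0)
    return CompatibilityMatrix(
        e=e,
        e_q=_scaled_power(e, traits.q),
        e_c=_scaled_power(e, traits.c),
    )


def immigrate(
    field: np.ndarray,
    kernel: Kernel,
    gamma: float,
    mode: str = "conservative",
) -> np.ndarray:
    """Apply one step of propagule dispersal to every cell's community.

    ``gamma`` is the proportion of each cell's microbes dispersed as
    propagules.  In the default ``conservative`` mode that fraction
    leaves its source and arrives kernel-weighted elsewhere::

        F <- (1 - gamma) * F + gamma * deposit(F)

    which conserves the lattice total exactly and keeps abundances at the
    carrying-capacity scale.  ``additive`` keeps the source intact and
    adds ``gamma * deposit(F)`` on top (arrivals only); taxa whose
    within-host decline rate is near zero then accumulate propagule mass
    far above carrying capacity, so this variant exists for auditability
    only.
    """
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"fecundity gamma = {gamma} must be in [0, 1)")
    if mode == "conservative":
        return (1.0 - gamma) * field + gamma * deposit(field, kernel)
    if mode == "additive":
        return field + gamma * deposit(field, kernel)
    raise ValueError(f"unknown propagule mode {mode!r}")


def effect_theta(local_abundances: np.ndarray, e_row: np.ndarray) -> float:
    """Total effect of one cell's community on a focal seedling species.

    The dot product of the local per-taxon abundance vector with each
    taxon's compatibility with the seedling's species.
    """
    local = np.asarray(local_abundances, dtype=float)
    if np.any(local < 0):
        raise ValueError("negative microbial abundance")
    return float(local @ np.asarray(e_row, dtype=float))


def competition_rhs(
    F: np.ndarray,
    host_species: np.ndarray,
    traits: GuildTraits,
    comp: CompatibilityMatrix,
) -> np.ndarray:
    """Right-hand side of the within-host Lotka–Volterra system.

    For taxon i on a tree whose resident adult is species j::

        dF_i/dt = r * e[i,j]**q * F_i * (1 - (F_i + alpha * sum_{n != i} e[n,j]**c * F_n))

    Vectorized over trees: ``F`` is (n_trees, k), ``host_species`` the
    resident species id per tree.
    """
    e_q = comp.e_q[:, host_species].T      # (n, k)
    e_c = comp.e_c[:, host_species].T      # (n, k)
    weighted = e_c * F
    others = weighted.sum(axis=1, keepdims=True) - weighted
    bracket = 1.0 - (F + traits.alpha * others)
    return traits.r * e_q * F * bracket


def competition_step(
    F: np.ndarray,
    host_species: np.ndarray,
    traits: GuildTraits,
    comp: CompatibilityMatrix,
    dt: float = 1.0,
    substeps: int = 10,
) -> np.ndarray:
    """Integrate one guild's dynamics for one simulation time step.

    Classical RK4 with ``substeps`` sub-intervals; negative intermediate
    values (possible when strong competition overshoots) are clamped to
    zero, making extinction absorbing.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    F = np.asarray(F, dtype=float)
    scalar_input = F.ndim == 1
    if scalar_input:
        F = F[None, :]
        host_species = np.atleast_1d(host_species)
    h = dt / substeps
    for _ in range(substeps):
        k1 = competition_rhs(F, host_species, traits, comp)
        k2 = competition_rhs(np.maximum(F + 0.5 * h * k1, 0.0), host_species, traits, comp)
        k3 = competition_rhs(np.maximum(F + 0.5 * h * k2, 0.0), host_species, traits, comp)
        k4 = competition_rhs(np.maximum(F + h * k3, 0.0), host_species, traits, comp)
        F = np.maximum(F + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError(
            "microbial integration produced non-finite abundances; "
            "reduce the sub-step"
        )
    return F[0] if scalar_input else F
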