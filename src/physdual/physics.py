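"""Analytical non-bonded interaction energies.

Implements the two physics terms fused into the model: the Coulomb
electrostatic energy

    E_Coul = sum_{i,j} k_e * q_i * q_j / (eps_r * r_ij)

with k_e = 332.0636 kcal mol^-1 A e^-2 (the standard electrostatic
conversion factor folding in 1/(4 pi eps_0)) and relative permittivity
eps_r = 4 as an implicit-solvent approximation, and the 12-6
Lennard-Jones energy

    E_LJ = sum_{i,j} 4 eps_ij [ (sigma_ij/r_ij)^12 - (sigma_ij/r_ij)^6 ]

with Lorentz-Berthelot combining rules for mixed atom types. Every pair
term is multiplied by a C1-continuous switching function that takes the
interaction smoothly to zero between r_on = 6 A and the r_off = 8 A
cutoff, so the truncated potential has no discontinuity and gradients are
defined everywhere. Analytic position gradients are provided for both
terms and are validated against central finite differences.

All energies are in kcal/mol, distances in angstrom, charges in
elementary-charge units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ComputationError, InputError
from .ligand import LigandGraph

__all__ = [
    "COULOMB_CONSTANT",
    "ChargedParticle",
    "LJTypeParameters",
    "NonbondedConfig",
    "EnergyBreakdown",
    "MinMaxScaler",
    "combine_lj",
    "switching_factor",
    "switching_derivative",
    "coulomb_energy",
    "lj_energy",
    "coulomb_gradient",
    "lj_gradient",
    "total_physical_energy",
    "fit_minmax",
    "apply_minmax",
    "gradient_check",
    "load_lj_table",
    "default_lj_table",
    "lj_type_for_element",
    "ligand_particles",
    "exclusion_pairs",
]

#: kcal mol^-1 A e^-2; the 1/(4 pi eps_0) factor in practical MM units.
COULOMB_CONSTANT = 332.0636

_CLASH_DISTANCE = 0.5  # A; closer pairs signal broken geometry


@dataclass(frozen=True)
class LJTypeParameters:
    """12-6 Lennard-Jones parameters: size sigma (A), well depth (kcal/mol)."""

    sigma: float
    epsilon_well: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise InputError(f"LJ sigma must be positive, got {self.sigma}")
        if self.epsilon_well < 0:
            raise InputError(f"LJ well depth must be >= 0, got {self.epsilon_well}")


@dataclass(frozen=True)
class ChargedParticle:
    position: tuple[float, float, float]
    charge: float
    lj_type: str

    def __post_init__(self):
        if not all(math.isfinite(x) for x in self.position) or not math.isfinite(
            self.charge
        ):
            raise InputError("particle position and charge must be finite")


@dataclass(frozen=True)
class NonbondedConfig:
    dielectric: float = 4.0
    coulomb_constant: float = COULOMB_CONSTANT
    r_on: float = 6.0
    r_off: float = 8.0
    exclusion_policy: str = "bonded12_13"  # or "none"

    def __post_init__(self):
        if not (0 < self.r_on < self.r_off):
            raise InputError(f"require 0 < r_on < r_off, got {self.r_on}, {self.r_off}")
        if self.dielectric <= 0:
            raise InputError("dielectric must be positive")
        if self.exclusion_policy not in ("none", "bonded12_13"):
            raise InputError(f"unknown exclusion policy {self.exclusion_policy!r}")


@dataclass(frozen=True)
class EnergyBreakdown:
    e_coul: float
    e_lj: float
    e_phys: float
    n_pairs_evaluated: int

    def to_dict(self) -> dict:
        return {
            "e_coul_kcal_mol": self.e_coul,
            "e_lj_kcal_mol": self.e_lj,
            "e_phys_kcal_mol": self.e_phys,
            "n_pairs_evaluated": self.n_pairs_evaluated,
        }


def combine_lj(a: LJTypeParameters, b: LJTypeParameters) -> LJTypeParameters:
    """Lorentz-Berthelot mixing: arithmetic-mean sigma, geometric-mean depth."""
    return LJTypeParameters(
        sigma=0.5 * (a.sigma + b.sigma),
        epsilon_well=math.sqrt(a.epsilon_well * b.epsilon_well),
    )


def switching_factor(r, config: NonbondedConfig = NonbondedConfig()):
    """C1 switching multiplier: 1 below r_on, 0 above r_off.

    Uses the classical polynomial
    (r_off^2 - r^2)^2 (r_off^2 + 2 r^2 - 3 r_on^2) / (r_off^2 - r_on^2)^3
    whose value and first derivative are continuous at both boundaries.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    ron2, roff2 = config.r_on**2, config.r_off**2
    r2 = r**2
    s = (roff2 - r2) ** 2 * (roff2 + 2 * r2 - 3 * ron2) / (roff2 - ron2) ** 3
    out = np.where(r <= config.r_on, 1.0, np.where(r >= config.r_off, 0.0, s))
    return float(out) if out.ndim == 0 else out


def switching_derivative(r, config: NonbondedConfig = NonbondedConfig()):
    """dS/dr of :func:`switching_factor`; zero outside the switching window."""
    r = np.asarray(r, dtype=float)
    ron2, roff2 = config.r_on**2, config.r_off**2
    r2 = r**2
    ds = 12.0 * r * (roff2 - r2) * (ron2 - r2) / (roff2 - ron2) ** 3
    out = np.where((r <= config.r_on) | (r >= config.r_off), 0.0, ds)
    return float(out) if out.ndim == 0 else out


def _as_arrays(particles: list[ChargedParticle]):
    pos = np.array([p.position for p in particles], dtype=float)
    q = np.array([p.charge for p in particles], dtype=float)
    return pos, q


def _pair_lists(particles_a, particles_b, exclude):
    """Enumerate interacting index pairs (ia into a, ib into b).

    Intra mode (``particles_b is None`` or the same object): unordered pairs
    i < j once, minus excluded pairs. Cross mode: full a x b product.
    """
    intra = particles_b is None or particles_b is particles_a
    na = len(particles_a)
    if intra:
        ii, jj = np.triu_indices(na, k=1)
        if exclude:
            keep = np.array(
                [(int(i), int(j)) not in exclude for i, j in zip(ii, jj)]
            )
            ii, jj = ii[keep], jj[keep]
        return intra, ii, jj
    nb = len(particles_b)
    ii, jj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    return intra, ii.ravel(), jj.ravel()


def _pair_geometry(pos_a, pos_b, ii, jj, what: str):
    d = pos_a[ii] - pos_b[jj]
    r = np.sqrt((d**2).sum(axis=1))
    if np.any(r < _CLASH_DISTANCE):
        k = int(np.argmin(r))
        raise ComputationError(
            f"{what}: pair ({int(ii[k])}, {int(jj[k])}) at {r[k]:.3f} A is below "
            f"the {_CLASH_DISTANCE} A clash guard; geometry looks broken"
        )
    return d, r


def _lj_pair_params(particles_a, particles_b, ii, jj, table):
    def params(p):
        try:
            return table[p.lj_type]
        except KeyError:
            raise InputError(
                f"LJ type {p.lj_type!r} missing from the parameter table"
            ) from None

    pa = [params(p) for p in particles_a]
    pb = pa if particles_b is None or particles_b is particles_a else [
        params(p) for p in particles_b
    ]
    sig_a = np.array([p.sigma for p in pa])
    eps_a = np.array([p.epsilon_well for p in pa])
    sig_b = np.array([p.sigma for p in pb])
    eps_b = np.array([p.epsilon_well for p in pb])
    sigma = 0.5 * (sig_a[ii] + sig_b[jj])
    eps = np.sqrt(eps_a[ii] * eps_b[jj])
    return sigma, eps


def coulomb_energy(
    particles_a: list[ChargedParticle],
    particles_b: list[ChargedParticle] | None = None,
    config: NonbondedConfig = NonbondedConfig(),
    exclude: set[tuple[int, int]] | None = None,
) -> float:
    """Switched, dielectric-screened Coulomb sum in kcal/mol."""
    if not particles_a:
        return 0.0
    pos_a, q_a = _as_arrays(particles_a)
    intra, ii, jj = _pair_lists(particles_a, particles_b, exclude)
    pos_b, q_b = (pos_a, q_a) if intra else _as_arrays(particles_b)
    if len(ii) == 0:
        return 0.0
    _, r = _pair_geometry(pos_a, pos_b, ii, jj, "coulomb_energy")
    s = switching_factor(r, config)
    terms = config.coulomb_constant * q_a[ii] * q_b[jj] / (config.dielectric * r) * s
    return float(terms.sum())


def lj_energy(
    particles_a: list[ChargedParticle],
    particles_b: list[ChargedParticle] | None = None,
    config: NonbondedConfig = NonbondedConfig(),
    table: dict[str, LJTypeParameters] | None = None,
    exclude: set[tuple[int, int]] | None = None,
) -> float:
    """Switched 12-6 Lennard-Jones sum in kcal/mol."""
    if table is None:
        table = default_lj_table()
    if not particles_a:
        return 0.0
    pos_a, _ = _as_arrays(particles_a)
    intra, ii, jj = _pair_lists(particles_a, particles_b, exclude)
    pos_b = pos_a if intra else _as_arrays(particles_b)[0]
    if len(ii) == 0:
        return 0.0
    _, r = _pair_geometry(pos_a, pos_b, ii, jj, "lj_energy")
    sigma, eps = _lj_pair_params(particles_a, particles_b, ii, jj, table)
    sr6 = (sigma / r) ** 6
    terms = 4.0 * eps * (sr6**2 - sr6) * switching_factor(r, config)
    return float(terms.sum())


def _accumulate_gradient(n_a, n_b, intra, ii, jj, d, r, dE_dr):
    ga = np.zeros((n_a, 3))
    gb = ga if intra else np.zeros((n_b, 3))
    unit = d / r[:, None]
    contrib = dE_dr[:, None] * unit
    np.add.at(ga, ii, contrib)
    np.add.at(gb, jj, -contrib)
    return (ga, None) if intra else (ga, gb)


def coulomb_gradient(
    particles_a,
    particles_b=None,
    config: NonbondedConfig = NonbondedConfig(),
    exclude=None,
):
    """Analytic dE_Coul/dposition; returns (grads_a, grads_b or None)."""
    pos_a, q_a = _as_arrays(particles_a)
    intra, ii, jj = _pair_lists(particles_a, particles_b, exclude)
    pos_b, q_b = (pos_a, q_a) if intra else _as_arrays(particles_b)
    if len(ii) == 0:
        return np.zeros((len(particles_a), 3)), None if intra else np.zeros(
            (len(particles_b), 3)
        )
    d, r = _pair_geometry(pos_a, pos_b, ii, jj, "coulomb_gradient")
    pref = config.coulomb_constant * q_a[ii] * q_b[jj] / config.dielectric
    s, ds = switching_factor(r, config), switching_derivative(r, config)
    dE_dr = pref * (ds / r - s / r**2)
    return _accumulate_gradient(len(pos_a), len(pos_b), intra, ii, jj, d, r, dE_dr)


def lj_gradient(
    particles_a,
    particles_b=None,
    config: NonbondedConfig = NonbondedConfig(),
    table=None,
    exclude=None,
):
    """Analytic dE_LJ/dposition; returns (grads_a, grads_b or None)."""
    if table is None:
        table = default_lj_table()
    pos_a, _ = _as_arrays(particles_a)
    intra, ii, jj = _pair_lists(particles_a, particles_b, exclude)
    pos_b = pos_a if intra else _as_arrays(particles_b)[0]
    if len(ii) == 0:
        return np.zeros((len(particles_a), 3)), None if intra else np.zeros(
            (len(particles_b), 3)
        )
    d, r = _pair_geometry(pos_a, pos_b, ii, jj, "lj_gradient")
    sigma, eps = _lj_pair_params(particles_a, particles_b, ii, jj, table)
    sr6 = (sigma / r) ** 6
    v = 4.0 * eps * (sr6**2 - sr6)
    dv_dr = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
    s, ds = switching_factor(r, config), switching_derivative(r, config)
    dE_dr = dv_dr * s + v * ds
    return _accumulate_gradient(len(pos_a), len(pos_b), intra, ii, jj, d, r, dE_dr)


def exclusion_pairs(graph: LigandGraph, policy: str = "bonded12_13") -> set[tuple[int, int]]:
    """Intra-molecular pairs excluded from non-bonded sums.

    ``bonded12_13`` drops directly bonded (1-2) and angle (1-3) pairs; 1-4
    and beyond interact unscaled. ``none`` excludes nothing.
    """
    if policy == "none":
        return set()
    neighbors: dict[int, set[int]] = {a.index: set() for a in graph.atoms}
    for b in graph.bonds:
        neighbors[b.i].add(b.j)
        neighbors[b.j].add(b.i)
    pairs = set(graph.bonded_pairs())
    for center, nbrs in neighbors.items():
        for i in nbrs:
            for j in nbrs:
                if i < j:
                    pairs.add((i, j))
    return pairs


def lj_type_for_element(element: str) -> str:
    """Element-keyed atom typing for the shipped parameter table."""
    return element.lower()


def ligand_particles(graph: LigandGraph) -> list[ChargedParticle]:
    """Charged particles for a ligand with coordinates and charges assigned."""
    if graph.coords is None:
        raise InputError(
            f"ligand {graph.record.id!r}: no coordinates; run embed_conformer first"
        )
    if any(a.partial_charge is None for a in graph.atoms):
        raise InputError(
            f"ligand {graph.record.id!r}: no charges; run assign_gasteiger_charges first"
        )
    return [
        ChargedParticle(
            position=tuple(graph.coords[a.index]),
            charge=a.partial_charge,
            lj_type=lj_type_for_element(a.element),
        )
        for a in graph.atoms
    ]


def _count_pairs(particles_a, particles_b, config, exclude) -> int:
    pos_a, _ = _as_arrays(particles_a)
    intra, ii, jj = _pair_lists(particles_a, particles_b, exclude)
    if len(ii) == 0:
        return 0
    pos_b = pos_a if intra else _as_arrays(particles_b)[0]
    d = pos_a[ii] - pos_b[jj]
    r = np.sqrt((d**2).sum(axis=1))
    return int((r < config.r_off).sum())


def total_physical_energy(
    ligand: LigandGraph,
    protein_context: list[ChargedParticle] | None = None,
    config: NonbondedConfig = NonbondedConfig(),
    table: dict[str, LJTypeParameters] | None = None,
) -> EnergyBreakdown:
    """E_phys = E_Coul + E_LJ for a ligand, optionally in a protein context.

    Without ``protein_context`` the breakdown is the intra-ligand non-bonded
    sum under the configured exclusion policy (computable from SMILES alone,
    the default pipeline mode). With a context, ligand-protein cross terms
    are added on top.
    """
    if table is None:
        table = default_lj_table()
    particles = ligand_particles(ligand)
    exclude = exclusion_pairs(ligand, config.exclusion_policy)
    e_c = coulomb_energy(particles, None, config, exclude)
    e_l = lj_energy(particles, None, config, table, exclude)
    n_pairs = _count_pairs(particles, None, config, exclude)
    if protein_context:
        e_c += coulomb_energy(particles, protein_context, config)
        e_l += lj_energy(particles, protein_context, config, table)
        n_pairs += _count_pairs(particles, protein_context, config, None)
    return EnergyBreakdown(
        e_coul=e_c, e_lj=e_l, e_phys=e_c + e_l, n_pairs_evaluated=n_pairs
    )


@dataclass
class MinMaxScaler:
    """Linear [0,1] rescaling with clipping outside the fitted range."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.upper > self.lower:
            raise InputError(
                f"degenerate scaler range [{self.lower}, {self.upper}]"
            )

    def apply(self, value):
        x = (np.asarray(value, dtype=float) - self.lower) / (self.upper - self.lower)
        out = np.clip(x, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def fit_minmax(values) -> MinMaxScaler:
    """Fit a scaler to observed values; needs at least two distinct ones."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2 or values.min() == values.max():
        raise InputError(
            "min-max fit needs at least two distinct values "
            f"(got {values.size} values, range [{values.min() if values.size else float('nan')}, "
            f"{values.max() if values.size else float('nan')}])"
        )
    return MinMaxScaler(lower=float(values.min()), upper=float(values.max()))


def apply_minmax(scaler: MinMaxScaler, value):
    return scaler.apply(value)


def gradient_check(
    energy_op: str,
    particles: list[ChargedParticle],
    config: NonbondedConfig = NonbondedConfig(),
    table: dict[str, LJTypeParameters] | None = None,
    step: float = 1e-4,
) -> float:
    """Max relative deviation of analytic vs central finite-difference gradients.

    ``energy_op`` is "coulomb" or "lj". Relative deviation is measured
    against the larger of the finite-difference magnitude and 1e-8 so
    near-zero components do not blow up the ratio.
    """
    if energy_op == "coulomb":
        energy = lambda ps: coulomb_energy(ps, None, config)
        analytic = coulomb_gradient(particles, None, config)[0]
    elif energy_op == "lj":
        energy = lambda ps: lj_energy(ps, None, config, table)
        analytic = lj_gradient(particles, None, config, table)[0]
    else:
        raise InputError(f"unknown energy op {energy_op!r}; use 'coulomb' or 'lj'")
    worst = 0.0
    for k, p in enumerate(particles):
        for axis in range(3):
            for sign, store in ((+1, "hi"), (-1, "lo")):
                pos = list(p.position)
                pos[axis] += sign * step
                moved = particles.copy()
                moved[k] = ChargedParticle(tuple(pos), p.charge, p.lj_type)
                if store == "hi":
                    e_hi = energy(moved)
                else:
                    e_lo = energy(moved)
            fd = (e_hi - e_lo) / (2 * step)
            denom = max(abs(fd), 1e-8)
            worst = max(worst, abs(analytic[k, axis] - fd) / denom)
    return worst


def load_lj_table(path) -> dict[str, LJTypeParameters]:
    """Read a plain-text table of ``type sigma epsilon`` rows (# comments)."""
    table: dict[str, LJTypeParameters] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise InputError(
                    f"{path}:{lineno}: expected 'type sigma epsilon', got {raw!r}"
                )
            try:
                table[parts[0]] = LJTypeParameters(float(parts[1]), float(parts[2]))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
    return table


_DEFAULT_TABLE: dict[str, LJTypeParameters] | None = None


def default_lj_table() -> dict[str, LJTypeParameters]:
    """The packaged element-keyed table of GAFF-like LJ parameters."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("physdual").joinpath("data/lj_params.txt")
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = load_lj_table(path)
    return _DEFAULT_TABLE
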