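"""Charge-state spectra of the adduct-laden dimer: synthesis, template
deconvolution, and stoichiometry assignment.

A native mass spectrum of a ~130 kDa homodimer shows, for each molecular
species, a ladder of peaks at (M + z * m_proton) / z over a narrow envelope
of charge states z (around 29+ for this mass, ~4500 m/z).  Species differ by
small adducts: copper(II) (observed shift ~65 Da per ion), ADP and vanadate
in the nucleotide-trapped state, and bound lipids (KDL ~2.2 kDa).

Deconvolution here is a template fit: candidate species compositions are
rendered into noiseless template spectra on the observed m/z grid and their
non-negative abundances obtained by NNLS.  This is a deliberately simple
zero-charge deconvolution for known candidate species, not an iterative
blind deconvolution of unknown masses.

Masses are average (not isotope-resolved) and peaks Gaussian, appropriate
for instruments that do not resolve isotopes on a 130 kDa complex.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "PROTON_MASS",
    "COPPER_SHIFT_DA",
    "COPPER_ELEMENTAL_DA",
    "DEFAULT_ADDUCTS",
    "LIPID_MASSES",
    "AdductTable",
    "SpeciesComposition",
    "MassSpectrum",
    "DeconvolvedAbundances",
    "ChargeEnvelope",
    "SpectrumNoise",
    "assign_composition",
    "synthesize_spectrum",
    "deconvolve_template",
    "intensities_to_mole_fractions",
]

PROTON_MASS = 1.00728  # Da

# The copper adduct is modelled with the observed ~65 Da shift by default;
# metal binding with proton displacement makes the effective neutral shift
# ambiguous, so the elemental mass is provided for callers who prefer it.
COPPER_SHIFT_DA = 65.0
COPPER_ELEMENTAL_DA = 63.546

# average masses (Da) of the lipid titrants
LIPID_MASSES = {
    "KDL": 2236.8,    # Kdo2-lipid A
    "TOCDL": 1457.0,  # tetraoleoyl cardiolipin 72:4
    "POPG": 749.0,
    "POPA": 675.0,
    "POPC": 760.1,
    "POPE": 718.0,
    "POPS": 762.0,
}


@dataclass(frozen=True)
class AdductTable:
    """Named adduct species with masses (Da) and per-dimer count maxima.

    Default maxima allow one copper, ADP and vanadate per subunit (two per
    dimer); lipid maxima are supplied by the caller via ``max_counts``.
    """

    masses: dict[str, float]
    max_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.masses)) != len(self.masses):
            raise ValueError("adduct names must be unique")
        for name, m in self.masses.items():
            if not (m > 0 and math.isfinite(m)):
                raise ValueError(f"adduct mass must be positive, got {name}={m}")

    def max_count(self, name: str) -> int:
        return self.max_counts.get(name, 2)

    def with_lipid(self, lipid: str, mass: float | None = None,
                   max_count: int = 3) -> "AdductTable":
        masses = dict(self.masses)
        masses[lipid] = float(mass if mass is not None else LIPID_MASSES[lipid])
        maxima = dict(self.max_counts)
        maxima[lipid] = max_count
        return AdductTable(masses, maxima)


DEFAULT_ADDUCTS = AdductTable(
    masses={"Cu": COPPER_SHIFT_DA, "ADP": 427.20, "VO4": 114.94},
    max_counts={"Cu": 2, "ADP": 2, "VO4": 2},
)


def _fmt_part(name: str, count: int) -> str:
    sep = "-" if name[-1].isdigit() else ""
    return f"{name}{sep}{count}"


@dataclass(frozen=True)
class SpeciesComposition:
    """Integer adduct stoichiometry on the dimer with its derived total mass."""

    base_mass: float
    counts: tuple[tuple[str, int], ...]  # (adduct name, count), fixed order
    adduct_masses: tuple[tuple[str, float], ...]

    @classmethod
    def create(cls, base_mass: float, counts: dict[str, int],
               adducts: AdductTable) -> "SpeciesComposition":
        for name, c in counts.items():
            if name not in adducts.masses:
                raise KeyError(f"unknown adduct {name!r}")
            if c < 0:
                raise ValueError(f"negative count for {name}")
        names = [n for n in adducts.masses if counts.get(n, 0) > 0]
        return cls(
            base_mass=float(base_mass),
            counts=tuple((n, counts[n]) for n in names),
            adduct_masses=tuple((n, adducts.masses[n]) for n in names),
        )

    @property
    def total_mass(self) -> float:
        mass = dict(self.adduct_masses)
        return self.base_mass + sum(c * mass[n] for n, c in self.counts)

    def count(self, name: str) -> int:
        return dict(self.counts).get(name, 0)

    @property
    def n_adducts(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def name(self) -> str:
        if not self.counts:
            return "apo"
        return "_".join(_fmt_part(n, c) for n, c in self.counts)

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@dataclass(frozen=True)
class MassSpectrum:
    """m/z (Th) vs intensity with the Gaussian peak width used to build it."""

    mz: np.ndarray
    intensity: np.ndarray
    peak_sigma: float

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be equal-length 1-d arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def write(self, path) -> None:
        np.savetxt(path, np.column_stack([self.mz, self.intensity]),
                   fmt="%.6f", header="mz_Th intensity")

    @classmethod
    def read(cls, path, peak_sigma: float = float("nan")) -> "MassSpectrum":
        arr = np.loadtxt(path)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{path}: expected two-column m/z, intensity text")
        return cls(arr[:, 0], arr[:, 1], peak_sigma)


@dataclass(frozen=True)
class DeconvolvedAbundances:
    species: tuple[SpeciesComposition, ...]
    abundance: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance, dtype=float)
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "abundance", ab)

    def as_dict(self) -> dict[str, float]:
        return {sp.name: float(a) for sp, a in zip(self.species, self.abundance)}


@dataclass(frozen=True)
class ChargeEnvelope:
    """Gaussian weight over integer charge states (default centred near 29+,
    the charge the ~130 kDa dimer takes around 4500 m/z)."""

    mean: float = 29.0
    width: float = 2.0

    def weight(self, z: np.ndarray | int) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.exp(-0.5 * ((z - self.mean) / self.width) ** 2)


@dataclass(frozen=True)
class SpectrumNoise:
    """Multiplicative log-normal noise on intensities plus an additive baseline."""

    multiplicative_sigma: float = 0.05
    baseline: float = 0.002  # fraction of the maximum intensity

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = intensity * np.exp(rng.normal(0.0, self.multiplicative_sigma,
                                            intensity.size))
        scale = intensity.max() if intensity.size else 0.0
        out = out + np.abs(rng.normal(0.0, self.baseline * scale, intensity.size))
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# stoichiometry assignment
# ---------------------------------------------------------------------------

def default_tolerance(adducts: AdductTable) -> float:
    """0.4 x the smallest mass separation among adducts (and zero), so a Cu
    ladder cannot be cross-assigned to a lipid adduct."""
    masses = sorted(adducts.masses.values())
    gaps = [masses[0]] + [b - a for a, b in zip(masses, masses[1:])]
    gaps = [g for g in gaps if g > 0]
    return 0.4 * min(gaps)


def assign_composition(observed_mass: float, base_mass: float,
                       adducts: AdductTable,
                       tolerance: float | None = None,
                       max_counts: dict[str, int] | None = None,
                       ) -> SpeciesComposition | None:
    """Best adduct stoichiometry explaining ``observed_mass``, or None.

    Exhaustively enumerates all count combinations within the per-adduct
    maxima and returns the composition minimising the absolute mass error,
    provided it is within ``tolerance``; ties broken by fewest total adducts,
    then lexicographic adduct order.  Never forces an assignment: an
    observed mass outside tolerance returns None (unassigned).
    """
    if tolerance is None:
        tolerance = default_tolerance(adducts)
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    names = sorted(adducts.masses)
    maxima = [
        (max_counts or {}).get(n, adducts.max_count(n)) for n in names
    ]
    best = None  # (abs error, total adducts, count tuple)
    for combo in itertools.product(*(range(m + 1) for m in maxima)):
        predicted = base_mass + sum(c * adducts.masses[n]
                                    for n, c in zip(names, combo))
        key = (abs(observed_mass - predicted), sum(combo), combo)
        if best is None or key < best:
            best = key
    if best is None or best[0] > tolerance:
        return None
    return SpeciesComposition.create(base_mass, dict(zip(names, best[2])), adducts)


# ---------------------------------------------------------------------------
# forward synthesis and template deconvolution
# ---------------------------------------------------------------------------

def _species_mass(sp) -> float:
    return sp.total_mass if isinstance(sp, SpeciesComposition) else float(sp)


def _render(masses: np.ndarray, weights: np.ndarray, charges: np.ndarray,
            envelope: ChargeEnvelope, peak_sigma: float,
            mz: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mz)
    env = envelope.weight(charges)
    for m, w in zip(masses, weights):
        centers = (m + charges * PROTON_MASS) / charges
        for c, e in zip(centers, env):
            out += (w * e) * np.exp(-0.5 * ((mz - c) / peak_sigma) ** 2)
    return out


def synthesize_spectrum(species, charge_range=range(25, 34),
                        envelope: ChargeEnvelope | None = None,
                        peak_sigma: float = 1.5,
                        mz_grid: np.ndarray | None = None,
                        noise: SpectrumNoise | None = None,
                        seed: int | None = None,
                        grid_step: float = 0.4,
                        grid_pad: float = 25.0) -> MassSpectrum:
    """Forward-model a charge-state spectrum from (species, abundance) pairs.

    Each species contributes Gaussian peaks at (M + z * 1.00728)/z for every
    charge in ``charge_range``, weighted by abundance times a Gaussian charge
    envelope.  Without ``noise`` the output is deterministic; with it, the
    stated seed fully determines the spectrum.
    """
    species = list(species)
    if not species:
        raise ValueError("species list must not be empty")
    envelope = envelope or ChargeEnvelope()
    charges = np.asarray(sorted(charge_range), dtype=float)
    if charges.size == 0:
        raise ValueError("charge_range must not be empty")
    masses = np.array([_species_mass(sp) for sp, _ in species])
    weights = np.array([float(a) for _, a in species])
    if np.any(weights < 0):
        raise ValueError("abundances must be >= 0")
    if mz_grid is None:
        lo = (masses.min() + charges.max() * PROTON_MASS) / charges.max() - grid_pad
        hi = (masses.max() + charges.min() * PROTON_MASS) / charges.min() + grid_pad
        mz_grid = np.arange(lo, hi, grid_step)
    intensity = _render(masses, weights, charges, envelope, peak_sigma, mz_grid)
    if noise is not None:
        rng = np.random.default_rng(seed)
        intensity = noise.apply(intensity, rng)
    return MassSpectrum(mz_grid, intensity, peak_sigma)


def deconvolve_template(spectrum: MassSpectrum,
                        candidates: list[SpeciesComposition],
                        charge_range=range(25, 34),
                        envelope: ChargeEnvelope | None = None,
                        peak_sigma: float | None = None) -> DeconvolvedAbundances:
    """Non-negative least-squares fit of candidate template spectra.

    Each candidate composition is rendered (noiselessly, unit abundance) on
    the observed m/z grid; NNLS recovers the abundances.  A rank-deficient
    template matrix raises an error naming the colliding candidates.
    """
    if not candidates:
        raise ValueError("candidate list must not be empty")
    envelope = envelope or ChargeEnvelope()
    sigma = peak_sigma if peak_sigma is not None else spectrum.peak_sigma
    if not (sigma > 0):
        raise ValueError("peak_sigma must be known and positive for deconvolution")
    charges = np.asarray(sorted(charge_range), dtype=float)
    templates = np.column_stack([
        _render(np.array([c.total_mass]), np.array([1.0]), charges,
                envelope, sigma, spectrum.mz)
        for c in candidates
    ])
    if np.linalg.matrix_rank(templates) < len(candidates):
        norms = np.linalg.norm(templates, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        corr = (templates / safe).T @ (templates / safe)
        pairs = [
            f"{candidates[i].name} ~ {candidates[j].name}"
            for i in range(len(candidates)) for j in range(i + 1, len(candidates))
            if corr[i, j] > 1 - 1e-10
        ]
        raise ValueError("template matrix is rank-deficient; colliding candidates: "
                         + (", ".join(pairs) or "near-collinear set"))
    abundance, residual = nnls(templates, spectrum.intensity)
    return DeconvolvedAbundances(tuple(candidates), abundance, float(residual))


def intensities_to_mole_fractions(abundances: DeconvolvedAbundances,
                                  lipid_name: str) -> np.ndarray:
    """Mole fractions by bound-lipid count, marginalising metal/nucleotide states.

    Abundances of compositions sharing a ``lipid_name`` count are summed
    (copper/ADP/vanadate occupancy pooled) and divided by the grand total.
    """
    total = float(abundances.abundance.sum())
    if total <= 0:
        raise ValueError("total abundance is zero; cannot form mole fractions")
    n_max = max(sp.count(lipid_name) for sp in abundances.species)
    f = np.zeros(n_max + 1)
    for sp, a in zip(abundances.species, abundances.abundance):
        f[sp.count(lipid_name)] += a
    return f / total
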