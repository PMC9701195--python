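"""Ground-truthed synthetic titration datasets and raw spectra.

The generator realises the sequential binding model as the data-generating
process: for a known K_D vector it computes exact depletion-corrected mole
fractions at each titration point, perturbs them with seeded noise, and
renormalises.  A truth sidecar accompanies every dataset so recovery tests
are self-checking.  Defaults mirror a triplicate native-MS titration of a
~130 kDa homodimer at 0.3 uM with up to six sequential lipid-binding
events.

Two entry points apply noise at different levels deliberately: the tabular
generator perturbs mole fractions directly (testing the fitting stage in
isolation), while the spectral generator perturbs peak intensities (testing
deconvolution plus fitting end to end).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .binding import BindingModel, TitrationPoint, TitrationSeries, predict_abundances
from .spectra import (
    AdductTable,
    ChargeEnvelope,
    DEFAULT_ADDUCTS,
    MassSpectrum,
    SpeciesComposition,
    SpectrumNoise,
    synthesize_spectrum,
)

__all__ = [
    "MSBA_DIMER_MASS_DA",
    "TruthRecord",
    "SpectralParams",
    "default_schedule",
    "generate_titration",
    "generate_spectra_dataset",
    "condition_base_counts",
]

logger = logging.getLogger(__name__)

# average mass of the E. coli MsbA homodimer (2 x ~64.5 kDa)
MSBA_DIMER_MASS_DA = 128_900.0


def default_schedule(kd1: float, n_points: int = 8) -> tuple[float, ...]:
    """Zero point plus geometric spacing from 0.05 uM to ~4 x K_D1.

    Geometric spacing concentrates points where successive binding events
    turn on, which is what makes the later K_Ds identifiable.
    """
    if n_points < 4:
        raise ValueError("schedule needs at least 4 points")
    return (0.0, *np.geomspace(0.05, 4.0 * kd1, n_points - 1))


@dataclass(frozen=True)
class TruthRecord:
    """Known K_Ds and design of a synthetic titration experiment."""

    kd: tuple[float, ...] = (0.6, 1.2)       # uM, per sequential event
    p_total: float = 0.3                     # uM dimer, post-mix
    schedule: tuple[float, ...] = field(default_factory=lambda: default_schedule(0.6))
    noise_sigma: float = 0.02                # s.d. added to mole fractions
    seed: int = 0
    lipid_name: str = "KDL"
    condition: str = "copper-loaded"

    def __post_init__(self) -> None:
        if not all(k > 0 for k in self.kd):
            raise ValueError("all true K_Ds must be positive")
        if 0.0 not in self.schedule:
            raise ValueError("the titration schedule must include l_total = 0")
        if self.p_total <= 0:
            raise ValueError("p_total must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def model(self) -> BindingModel:
        return BindingModel.from_kd(self.kd)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["kd"] = tuple(d["kd"])
        d["schedule"] = tuple(d["schedule"])
        return cls(**d)


def _noisy_fractions(f: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, int]:
    if sigma == 0:
        return f, 0
    noisy = f + rng.normal(0.0, sigma, f.size)
    clipped = int(np.sum(noisy < 0))
    noisy = np.clip(noisy, 0.0, None)
    total = noisy.sum()
    if total <= 0:  # pathological draw; fall back to the exact fractions
        return f, clipped
    return noisy / total, clipped


def generate_titration(truth: TruthRecord, n_replicates: int = 3,
                       ) -> list[TitrationSeries]:
    """Seeded replicate titrations drawn around the exact model predictions.

    Each replicate uses an independent child RNG stream spawned from the
    truth seed, so datasets are fully reproducible and replicates mutually
    independent.  Noise driving a fraction negative is clipped at zero and
    the vector renormalised; clip events are logged.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = truth.model
    streams = np.random.SeedSequence(truth.seed).spawn(n_replicates)
    replicates = []
    n_clipped = 0
    for r, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        points = []
        for l_total in truth.schedule:
            exact = predict_abundances(
                model, TitrationPoint(l_total, truth.p_total,
                                      (1.0,) + (0.0,) * model.n_max))
            noisy, clipped = _noisy_fractions(exact, truth.noise_sigma, rng)
            n_clipped += clipped
            points.append(TitrationPoint(l_total, truth.p_total, tuple(noisy)))
        replicates.append(TitrationSeries(
            points=tuple(points), replicate_id=f"rep{r}",
            lipid_name=truth.lipid_name, condition=truth.condition))
    if n_clipped:
        logger.info("clipped %d negative mole fraction(s) to zero", n_clipped)
    return replicates


# ---------------------------------------------------------------------------
# spectral datasets
# ---------------------------------------------------------------------------

def condition_base_counts(condition: str) -> dict[str, int]:
    """Fixed metal/nucleotide occupancy of the dimer for a named condition."""
    table = {
        "apo": {},
        "copper-loaded": {"Cu": 2},
        "vanadate-trapped": {"Cu": 2, "ADP": 2, "VO4": 2},
    }
    if condition not in table:
        raise KeyError(f"unknown condition {condition!r}; "
                       f"expected one of {sorted(table)}")
    return table[condition]


@dataclass(frozen=True)
class SpectralParams:
    """Instrument-side parameters of the forward spectral model."""

    base_mass: float = MSBA_DIMER_MASS_DA
    adducts: AdductTable = field(default_factory=lambda: DEFAULT_ADDUCTS)
    charge_range: tuple[int, int] = (25, 33)   # inclusive
    envelope: ChargeEnvelope = field(default_factory=ChargeEnvelope)
    peak_sigma: float = 1.5                    # Th
    noise: SpectrumNoise | None = field(default_factory=SpectrumNoise)

    @property
    def charges(self) -> range:
        return range(self.charge_range[0], self.charge_range[1] + 1)


def _point_species(truth: TruthRecord, params: SpectralParams,
                   ) -> list[SpeciesComposition]:
    adducts = params.adducts.with_lipid(truth.lipid_name,
                                        max_count=len(truth.kd))
    base = condition_base_counts(truth.condition)
    out = []
    for n in range(len(truth.kd) + 1):
        counts = dict(base)
        counts[truth.lipid_name] = n
        out.append(SpeciesComposition.create(params.base_mass, counts, adducts))
    return out


def generate_spectra_dataset(truth: TruthRecord,
                             params: SpectralParams | None = None,
                             n_replicates: int = 3,
                             out_dir: str | Path | None = None):
    """Raw spectra per titration point plus a manifest tying files to design.

    Exact mole fractions (noise applied at the intensity level, not the
    fraction level) are rendered into charge-state spectra; the manifest maps
    each spectrum to its l_total, replicate, and candidate species so the
    deconvolution stage is self-contained.  Returns (spectra, manifest) where
    ``spectra`` is a dict keyed like the manifest entries; when ``out_dir``
    is given, files are also written there.
    """
    params = params or SpectralParams()
    if len(truth.schedule) == 0:
        raise ValueError("empty titration schedule")
    exact_truth = TruthRecord(**{**asdict(truth), "noise_sigma": 0.0})
    replicates = generate_titration(exact_truth, n_replicates)
    species = _point_species(truth, params)

    streams = np.random.SeedSequence([truth.seed, 0x5bec]).spawn(
        n_replicates * len(truth.schedule))
    spectra: dict[str, MassSpectrum] = {}
    entries = []
    k = 0
    for series in replicates:
        for point in series.points:
            key = f"{truth.lipid_name}_{series.replicate_id}_L{point.l_total:g}uM.txt"
            seed = int(streams[k].generate_state(1)[0] % (2**31))
            k += 1
            spec = synthesize_spectrum(
                list(zip(species, point.f_obs)),
                charge_range=params.charges, envelope=params.envelope,
                peak_sigma=params.peak_sigma, noise=params.noise, seed=seed)
            spectra[key] = spec
            entries.append({
                "file": key,
                "replicate": series.replicate_id,
                "l_total_uM": point.l_total,
                "p_total_uM": point.p_total,
            })
    manifest = {
        "lipid": truth.lipid_name,
        "condition": truth.condition,
        "base_mass_Da": params.base_mass,
        "peak_sigma_Th": params.peak_sigma,
        "charge_range": list(params.charge_range),
        "envelope": {"mean": params.envelope.mean, "width": params.envelope.width},
        "species": [sp.name for sp in species],
        "n_lipid_max": len(truth.kd),
        "spectra": entries,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, spec in spectra.items():
            spec.write(out_dir / key)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "truth.json").write_text(truth.to_json())
    return spectra, manifest
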