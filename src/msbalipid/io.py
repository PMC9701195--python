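"""Readers, writers, configuration schema, and the staged pipeline.

File conventions: concentrations in uM, masses in Da, m/z in Th, with units
embedded in column headers.  Titration observations travel as a tidy
TSV/CSV with columns
``lipid, condition, replicate, l_total_uM, p_total_uM, n_bound, intensity``;
spectra as two-column text; configuration as YAML or JSON validated against
a strict schema (unknown keys rejected).  Every pipeline run writes a
manifest recording the config hash and seed, so a rerun with identical
inputs is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import binding, conservation, spectra, synth

__all__ = [
    "ParseError",
    "TITRATION_COLUMNS",
    "read_titration_table",
    "write_titration_table",
    "series_to_frame",
    "fits_to_frame",
    "residual_table",
    "summary_to_dict",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "PIPELINE_STAGES",
]

logger = logging.getLogger(__name__)

TITRATION_COLUMNS = ("lipid", "condition", "replicate",
                     "l_total_uM", "p_total_uM", "n_bound", "intensity")


class ParseError(ValueError):
    """Malformed input table or spectrum file."""


# ---------------------------------------------------------------------------
# titration tables
# ---------------------------------------------------------------------------

def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = {"csv": ","}.get(path.suffix.lstrip(".").lower(), "\t")
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def read_titration_table(path: str | Path) -> list[binding.TitrationSeries]:
    """Load a tidy titration table into one TitrationSeries per replicate.

    Intensities within a (lipid, condition, replicate, l_total) group are
    converted to mole fractions by dividing each by the group total; a
    missing bound-lipid count is treated as zero intensity.
    """
    df = _read_frame(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col in ("l_total_uM", "p_total_uM", "n_bound", "intensity"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # header occupies line 1
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {row}")
        if parsed.isna().any():
            row = int(df.index[parsed.isna()][0]) + 2
            raise ParseError(f"{path}: empty value in column {col!r} at line {row}")
        df[col] = parsed
    if (df["n_bound"] % 1 != 0).any() or (df["n_bound"] < 0).any():
        raise ParseError(f"{path}: n_bound must be non-negative integers")
    if (df["intensity"] < 0).any():
        raise ParseError(f"{path}: intensities must be non-negative")

    series_list = []
    for (lipid, condition, replicate), grp in df.groupby(
            ["lipid", "condition", "replicate"], sort=True):
        n_max = int(grp["n_bound"].max())
        points = []
        for l_total, pg in grp.groupby("l_total_uM", sort=True):
            total = pg["intensity"].sum()
            if total <= 0:
                raise ParseError(
                    f"{path}: zero total intensity for {lipid}/{replicate} "
                    f"at l_total={l_total}")
            f = np.zeros(n_max + 1)
            for _, row in pg.iterrows():
                f[int(row["n_bound"])] += row["intensity"]
            points.append(binding.TitrationPoint(
                float(l_total), float(pg["p_total_uM"].iloc[0]),
                tuple(f / total)))
        series_list.append(binding.TitrationSeries(
            points=tuple(points), replicate_id=str(replicate),
            lipid_name=str(lipid), condition=str(condition)))
    return series_list


def series_to_frame(series_list: Sequence[binding.TitrationSeries],
                    ) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for p in s.points:
            for n, f in enumerate(p.f_obs):
                rows.append({
                    "lipid": s.lipid_name, "condition": s.condition,
                    "replicate": s.replicate_id, "l_total_uM": p.l_total,
                    "p_total_uM": p.p_total, "n_bound": n, "intensity": f,
                })
    return pd.DataFrame(rows, columns=list(TITRATION_COLUMNS))


def write_titration_table(series_list: Sequence[binding.TitrationSeries],
                          path: str | Path) -> None:
    series_to_frame(series_list).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fit outputs
# ---------------------------------------------------------------------------

def fits_to_frame(fits: dict[str, binding.FitResult]) -> pd.DataFrame:
    """One row per replicate per binding event: fitted K_D plus fit flags."""
    rows = []
    for rep, fit in fits.items():
        for n, kd in enumerate(fit.kd, start=1):
            rows.append({"replicate": rep, "event": n, "kd_uM": kd,
                         "chi2": fit.chi2, "converged": fit.converged,
                         "boundary": fit.boundary, "n_points": fit.n_points})
    return pd.DataFrame(rows)


def residual_table(series: binding.TitrationSeries,
                   fit: binding.FitResult) -> pd.DataFrame:
    """Per-point observed vs fitted mole fractions, for residual plots."""
    rows = []
    for p in series.points:
        f_calc = binding.predict_abundances(fit.model, p)
        f_obs = np.asarray(p.f_obs)
        f_obs = np.concatenate([f_obs, np.zeros(len(f_calc) - len(f_obs))]) \
            if len(f_obs) < len(f_calc) else f_obs
        for n in range(len(f_calc)):
            rows.append({
                "replicate": series.replicate_id, "l_total_uM": p.l_total,
                "n_bound": n, "f_obs": f_obs[n], "f_calc": f_calc[n],
                "residual": f_obs[n] - f_calc[n],
            })
    return pd.DataFrame(rows)


def summary_to_dict(summary: binding.ReplicateSummary) -> dict:
    return {
        "kd_mean_uM": list(summary.kd_mean),
        "kd_sd_uM": list(summary.kd_sd) if summary.kd_sd is not None else None,
        "n_replicates": summary.n_replicates,
        "n_excluded": summary.n_excluded,
    }


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    kd_uM: list[float] = [0.6, 1.2]
    p_total_uM: float = 0.3
    schedule_uM: list[float] | None = None
    noise_sigma: float = 0.02
    n_replicates: int = 3
    lipid: str = "KDL"
    condition: str = "copper-loaded"
    emit_spectra: bool = False

    @field_validator("kd_uM")
    @classmethod
    def _positive(cls, v):
        if not v or any(k <= 0 for k in v):
            raise ValueError("kd_uM must be non-empty and positive")
        return v


class SpectraConfig(_Strict):
    base_mass_Da: float = synth.MSBA_DIMER_MASS_DA
    lipid_mass_Da: float | None = None
    peak_sigma_Th: float = 1.5
    charge_min: int = 25
    charge_max: int = 33
    envelope_mean: float = 29.0
    envelope_width: float = 2.0
    noise_multiplicative_sigma: float = 0.05
    noise_baseline: float = 0.002


class FitStageConfig(_Strict):
    n_max: int | None = None
    kd_min_uM: float = 1e-3
    kd_max_uM: float = 1e4
    pooled: bool = False


class ConserveConfig(_Strict):
    msa_fasta: str | None = None
    reference_id: str | None = None
    positions: list[int] = [83, 87, 188, 236, 238, 240, 243]
    motif_fasta: str | None = None
    motif: str = "MH"


class PipelineConfig(_Strict):
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "results"
    titration_table: str | None = None   # input for `fit` when not simulating
    spectra_dir: str | None = None       # input for `deconvolve`
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    spectra: SpectraConfig = Field(default_factory=SpectraConfig)
    fit: FitStageConfig = Field(default_factory=FitStageConfig)
    conserve: ConserveConfig = Field(default_factory=ConserveConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

PIPELINE_STAGES = ("simulate", "deconvolve", "fit", "conserve")


def _truth_from_config(cfg: PipelineConfig) -> synth.TruthRecord:
    sim = cfg.simulate
    schedule = tuple(sim.schedule_uM) if sim.schedule_uM is not None \
        else synth.default_schedule(sim.kd_uM[0])
    return synth.TruthRecord(
        kd=tuple(sim.kd_uM), p_total=sim.p_total_uM, schedule=schedule,
        noise_sigma=sim.noise_sigma, seed=cfg.seed,
        lipid_name=sim.lipid, condition=sim.condition)


def _spectral_params(cfg: PipelineConfig) -> synth.SpectralParams:
    sp = cfg.spectra
    return synth.SpectralParams(
        base_mass=sp.base_mass_Da,
        charge_range=(sp.charge_min, sp.charge_max),
        envelope=spectra.ChargeEnvelope(sp.envelope_mean, sp.envelope_width),
        peak_sigma=sp.peak_sigma_Th,
        noise=spectra.SpectrumNoise(sp.noise_multiplicative_sigma,
                                    sp.noise_baseline),
    )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    truth = _truth_from_config(cfg)
    replicates = synth.generate_titration(truth, cfg.simulate.n_replicates)
    table = out / "titration.tsv"
    write_titration_table(replicates, table)
    (out / "truth.json").write_text(truth.to_json())
    artifacts = {"titration_table": str(table), "truth": str(out / "truth.json")}
    if cfg.simulate.emit_spectra:
        spectra_dir = out / "spectra"
        synth.generate_spectra_dataset(truth, _spectral_params(cfg),
                                       cfg.simulate.n_replicates, spectra_dir)
        artifacts["spectra_dir"] = str(spectra_dir)
    return artifacts


def _candidates_from_manifest(manifest: dict, cfg: PipelineConfig):
    lipid = manifest["lipid"]
    lipid_mass = cfg.spectra.lipid_mass_Da
    if lipid_mass is None:
        lipid_mass = spectra.LIPID_MASSES.get(lipid)
    if lipid_mass is None:
        raise ParseError(f"no mass known for lipid {lipid!r}; set spectra.lipid_mass_Da")
    adducts = spectra.DEFAULT_ADDUCTS.with_lipid(
        lipid, lipid_mass, max_count=manifest["n_lipid_max"])
    base = synth.condition_base_counts(manifest["condition"])
    cands = []
    for n in range(manifest["n_lipid_max"] + 1):
        counts = dict(base)
        counts[lipid] = n
        cands.append(spectra.SpeciesComposition.create(
            manifest["base_mass_Da"], counts, adducts))
    return lipid, cands


def _stage_deconvolve(cfg: PipelineConfig, out: Path, spectra_dir: Path) -> dict:
    manifest_path = spectra_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"deconvolve stage needs {manifest_path} (run simulate with "
            "emit_spectra, or point spectra_dir at a dataset)")
    manifest = json.loads(manifest_path.read_text())
    lipid, candidates = _candidates_from_manifest(manifest, cfg)
    envelope = spectra.ChargeEnvelope(*manifest.get(
        "envelope", {"mean": 29.0, "width": 2.0}).values())
    charge_lo, charge_hi = manifest["charge_range"]

    rows, dec_rows = [], []
    for entry in manifest["spectra"]:
        fpath = spectra_dir / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"spectrum file missing: {fpath}")
        spec = spectra.MassSpectrum.read(fpath, manifest["peak_sigma_Th"])
        dec = spectra.deconvolve_template(
            spec, candidates, charge_range=range(charge_lo, charge_hi + 1),
            envelope=envelope)
        for sp, a in zip(dec.species, dec.abundance):
            dec_rows.append({"file": entry["file"], "composition": sp.name,
                             "abundance": a, "residual_norm": dec.residual_norm})
            rows.append({
                "lipid": lipid, "condition": manifest["condition"],
                "replicate": entry["replicate"],
                "l_total_uM": entry["l_total_uM"],
                "p_total_uM": entry["p_total_uM"],
                "n_bound": sp.count(lipid), "intensity": a,
            })
    table = out / "titration_deconvolved.tsv"
    pd.DataFrame(rows, columns=list(TITRATION_COLUMNS)).to_csv(
        table, sep="\t", index=False)
    dec_table = out / "deconvolution.tsv"
    pd.DataFrame(dec_rows).to_csv(dec_table, sep="\t", index=False)
    return {"titration_table": str(table), "deconvolution": str(dec_table)}


def _stage_fit(cfg: PipelineConfig, out: Path, table: Path) -> dict:
    if not table.exists():
        raise FileNotFoundError(
            f"fit stage needs a titration table; {table} does not exist")
    series_list = read_titration_table(table)
    options = binding.FitOptions(log10_ka_bounds=(
        -np.log10(cfg.fit.kd_max_uM), -np.log10(cfg.fit.kd_min_uM)))
    results = {}
    for key in sorted({(s.lipid_name, s.condition) for s in series_list}):
        group = [s for s in series_list if (s.lipid_name, s.condition) == key]
        n_max = cfg.fit.n_max or max(binding.infer_n_max(s) for s in group)
        if cfg.fit.pooled:
            fits = {"pooled": binding.fit_pooled(group, n_max, options)}
        else:
            fits = {s.replicate_id: binding.fit_series(s, n_max, options)
                    for s in group}
        summary = binding.aggregate_replicates(list(fits.values())) \
            if len(fits) >= 1 else None
        tag = f"{key[0]}_{key[1]}".strip("_").replace(" ", "-")
        fits_to_frame(fits).to_csv(out / f"fits_{tag}.tsv", sep="\t", index=False)
        pd.concat([residual_table(s, fits[next(iter(fits))] if cfg.fit.pooled
                                  else fits[s.replicate_id])
                   for s in group]).to_csv(
            out / f"residuals_{tag}.tsv", sep="\t", index=False)
        results[tag] = {
            "lipid": key[0], "condition": key[1], "n_max": n_max,
            "replicates": {
                rep: {"kd_uM": list(f.kd), "chi2": f.chi2,
                      "converged": f.converged, "boundary": f.boundary}
                for rep, f in fits.items()},
            "summary": summary_to_dict(summary),
        }
        if n_max >= 2:
            results[tag]["cooperativity"] = {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in binding.cooperativity_profile(summary).items()}
    path = out / "fit_summary.json"
    path.write_text(json.dumps(results, indent=2))
    return {"fit_summary": str(path)}


def _stage_conserve(cfg: PipelineConfig, out: Path) -> dict:
    cc = cfg.conserve
    artifacts = {}
    if cc.msa_fasta:
        aln = conservation.read_alignment(cc.msa_fasta)
        if cc.reference_id is None:
            raise ParseError("conserve.reference_id is required with msa_fasta")
        cols = conservation.map_reference_positions(aln, cc.reference_id,
                                                    cc.positions)
        profiles = conservation.site_frequencies(aln, cols, cc.positions)
        path = out / "site_profiles.tsv"
        conservation.profiles_to_frame(profiles).to_csv(path, sep="\t",
                                                        index=False)
        artifacts["site_profiles"] = str(path)
    if cc.motif_fasta:
        seqs = conservation.read_sequences(cc.motif_fasta)
        matches, count = conservation.scan_nterm_histidine(seqs, cc.motif)
        path = out / "motif_scan.json"
        path.write_text(json.dumps({"motif": cc.motif, "count": count,
                                    "n_sequences": len(seqs),
                                    "matches": matches}, indent=2))
        artifacts["motif_scan"] = str(path)
    return artifacts


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = PIPELINE_STAGES) -> dict:
    """Run the requested stages in dependency order; returns artifact paths.

    An empty stage list is a successful no-op.  Every run writes
    ``run_manifest.json`` recording the config hash and seed; deterministic
    stages rerun with an identical config produce byte-identical artifacts.
    """
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; "
                         f"choose from {PIPELINE_STAGES}")
    ordered = [s for s in PIPELINE_STAGES if s in stages]
    out = Path(config.out_dir)
    artifacts: dict = {}
    if not ordered:
        return artifacts
    out.mkdir(parents=True, exist_ok=True)
    for stage in ordered:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            artifacts.update(_stage_simulate(config, out))
        elif stage == "deconvolve":
            spectra_dir = Path(artifacts.get("spectra_dir")
                               or config.spectra_dir or (out / "spectra"))
            artifacts.update(_stage_deconvolve(config, out, spectra_dir))
        elif stage == "fit":
            table = Path(artifacts.get("titration_table")
                         or config.titration_table or (out / "titration.tsv"))
            artifacts.update(_stage_fit(config, out, table))
        elif stage == "conserve":
            artifacts.update(_stage_conserve(config, out))
    (out / "run_manifest.json").write_text(json.dumps({
        "config_hash": config.config_hash(), "seed": config.seed,
        "stages": ordered, "artifacts": artifacts,
        "config": config.model_dump()}, indent=2))
    return artifacts
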