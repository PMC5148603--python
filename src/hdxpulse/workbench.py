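"""Configuration, I/O and the pipelines tying the stages together.

Interchange formats are plain delimited text: a peptide table (protein,
start, end, sequence?, charge?, plus_met?), a spectra CSV (preset,
replicate, time_min, mass_da, intensity) and TSV result tables carrying
provenance columns (preset, seed, software version).  Every run writes its
resolved configuration next to its results so a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .deconvolution import (
    CENTROID_WINDOW,
    DELTA_BIC_THRESHOLD,
    SIGMA_BOUNDS,
    reference_sigma_bounds,
    select_model,
)
from .isotopes import IsotopeEnvelope, PeptideSpec, centroid_mass
from .kinetics import (
    DEPLETION_CUTOFF,
    LINEAR_PHASE_CAP,
    EfficacyEstimate,
    assemble_time_course,
    efficacy_regression,
    initial_rate,
    subtract_spontaneous,
)
from .simulate import (
    DEFAULT_P_FOLDED,
    KINETIC_PRESETS,
    LabelingCondition,
    NoiseModel,
    SyntheticSpectrum,
    get_preset,
    reference_envelopes,
    simulate_pulse_spectra,
)

logger = logging.getLogger("hdxpulse.workbench")

#: Incubation time grids (minutes) for the kinetic efficacy pipelines:
#: initial rates are estimated from early time points only, where substrate
#: depletion is negligible at every concentration, so the through-origin
#: rate fit stays in its linear regime (the depletion cutoff remains active
#: as a guard; see docs/methods.md for the design rationale).
WT_COURSE_TIMES = (0.5, 0.625, 0.75, 0.875, 1.0)
E15K_COURSE_TIMES = (0.5, 0.625, 0.75, 0.875, 1.0)
#: Inhibitor concentration series (uM) of the two kinetic study designs.
WT_CONCENTRATIONS = (1.0, 0.5, 0.25)
E15K_CONCENTRATIONS = (2.0, 1.0, 0.5)


@dataclasses.dataclass
class RunConfig:
    """Fully serializable run configuration."""

    seed: int = 1
    presets: list[str] = dataclasses.field(default_factory=list)
    replicates: int = 3
    d2o_fraction: float = 0.70
    pulse_duration_s: float = 10.0
    p_folded: float = DEFAULT_P_FOLDED
    noise_cv: float = 0.03
    noise_baseline: float = 0.005
    delta_bic: float = DELTA_BIC_THRESHOLD
    centroid_window_da: float = CENTROID_WINDOW
    sigma_min_da: float = SIGMA_BOUNDS[0]
    sigma_max_da: float = SIGMA_BOUNDS[1]
    sigma_from_references: bool = True
    depletion_cutoff: float = DEPLETION_CUTOFF
    linear_phase_cap_min: float = LINEAR_PHASE_CAP
    output_dir: str = "results"

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def labeling(self) -> LabelingCondition:
        return LabelingCondition(
            d2o_fraction=self.d2o_fraction, pulse_duration_s=self.pulse_duration_s
        )

    def noise(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            cv=self.noise_cv,
            baseline=self.noise_baseline,
            seed=self.seed if seed is None else seed,
        )


# --------------------------------------------------------------------------
# Tabular I/O
# --------------------------------------------------------------------------

def write_peptide_table(peptides: Sequence[PeptideSpec], path) -> None:
    rows = [
        {
            "protein": p.protein,
            "start": p.start,
            "end": p.end,
            "sequence": p.sequence or "",
            "charge": p.charge if p.charge is not None else "",
            "n_exchangeable": p.n_exchangeable if p.n_exchangeable is not None else "",
            "plus_met": int(p.plus_met),
        }
        for p in peptides
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peptide_table(path) -> list[PeptideSpec]:
    """Read a delimited peptide table; coordinate violations report line numbers."""
    frame = pd.read_csv(path)
    required = {"protein", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"peptide table lacks required columns: {sorted(missing)}")
    peptides = []
    for index, row in frame.iterrows():
        line = index + 2  # header is line 1
        try:
            sequence = row.get("sequence")
            sequence = None if pd.isna(sequence) or sequence == "" else str(sequence)
            charge = row.get("charge")
            charge = None if pd.isna(charge) or charge == "" else int(charge)
            n_exch = row.get("n_exchangeable")
            n_exch = None if pd.isna(n_exch) or n_exch == "" else int(n_exch)
            plus_met = row.get("plus_met")
            plus_met = False if pd.isna(plus_met) else bool(int(plus_met))
            peptides.append(
                PeptideSpec(
                    protein=str(row["protein"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sequence=sequence,
                    charge=charge,
                    n_exchangeable=n_exch,
                    plus_met=plus_met,
                )
            )
        except (ValueError, TypeError) as error:
            raise ValueError(f"invalid peptide on line {line}: {error}") from error
    return peptides


def read_spectra(path, peptide: PeptideSpec | None = None) -> list[SyntheticSpectrum]:
    """Read a spectra CSV, grouped by (preset, replicate, time).

    Dialect rules: negative intensities are rejected; out-of-order masses
    are sorted with a warning; duplicate masses within one spectrum are
    summed with a warning.  An empty file is an explicit error.
    """
    frame = pd.read_csv(path)
    required = {"preset", "replicate", "time_min", "mass_da", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"spectra file lacks required columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"spectra file {path} contains no spectra")
    if (frame["intensity"] < 0).any():
        raise ValueError("negative intensities are not allowed")
    spectra = []
    for (preset, replicate, time_min), group in frame.groupby(
        ["preset", "replicate", "time_min"], sort=True
    ):
        masses = group["mass_da"].to_numpy(dtype=float)
        intensities = group["intensity"].to_numpy(dtype=float)
        if not np.all(np.diff(masses) > 0):
            order = np.argsort(masses, kind="stable")
            masses, intensities = masses[order], intensities[order]
            if np.all(np.diff(masses) > 0):
                warnings.warn(
                    f"unsorted masses in spectrum {preset}/{replicate}/{time_min}; sorted",
                    stacklevel=2,
                )
            else:
                unique, inverse = np.unique(masses, return_inverse=True)
                summed = np.zeros_like(unique)
                np.add.at(summed, inverse, intensities)
                masses, intensities = unique, summed
                warnings.warn(
                    f"duplicate masses in spectrum {preset}/{replicate}/{time_min}; summed",
                    stacklevel=2,
                )
        spectra.append(
            SyntheticSpectrum(
                envelope=IsotopeEnvelope(masses, intensities, normalized=False),
                peptide=peptide,
                replicate=int(replicate),
                time_min=float(time_min),
                preset=str(preset),
                condition={"kind": "file", "source": str(path)},
            )
        )
    return spectra


def _provenance(frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    from . import __version__

    frame = frame.copy()
    frame["seed"] = seed
    frame["software_version"] = __version__
    return frame


# --------------------------------------------------------------------------
# Pipelines
# --------------------------------------------------------------------------

def deconvolve_spectra(
    spectra: Iterable[SyntheticSpectrum],
    init: Sequence[float],
    config: RunConfig | None = None,
    sigma_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Run model-selected deconvolution on every spectrum.

    Returns one row per spectrum with the fitted model, unfolded fraction,
    component centroids, residual and flags.
    """
    config = config or RunConfig()
    if sigma_bounds is None:
        sigma_bounds = (config.sigma_min_da, config.sigma_max_da)
    rows = []
    attempted = converged = flagged = 0
    for spectrum in spectra:
        attempted += 1
        fit = select_model(
            spectrum.envelope,
            init,
            delta_bic=config.delta_bic,
            centroid_window=config.centroid_window_da,
            sigma_bounds=sigma_bounds,
        )
        converged += fit.converged
        flagged += bool(fit.flags)
        centroid_folded = fit.components[0].centroid
        centroid_unfolded = (
            fit.components[1].centroid if len(fit.components) > 1 else float("nan")
        )
        rows.append(
            {
                "preset": spectrum.preset,
                "replicate": spectrum.replicate,
                "time_min": spectrum.time_min,
                "model": fit.model,
                "fraction_unfolded": fit.unfolded_fraction,
                "centroid_folded": centroid_folded,
                "centroid_unfolded": centroid_unfolded,
                "residual": fit.residual,
                "converged": fit.converged,
                "flags": ";".join(fit.flags),
            }
        )
    logger.info(
        "deconvolution: %d attempted, %d converged, %d flagged",
        attempted, converged, flagged,
    )
    return pd.DataFrame(rows)


def pulse_recovery(
    preset_name: str,
    replicates: int = 50,
    seed: int = 1,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Simulate replicate pulse spectra for one preset and deconvolve each.

    The central fraction-recovery round trip: the preset's generating
    fraction is the truth the deconvolution chain must reproduce.
    """
    config = config or RunConfig()
    labeling = config.labeling()
    folded, unfolded = reference_envelopes(
        labeling=labeling, p_folded=config.p_folded
    )
    init = (centroid_mass(folded), centroid_mass(unfolded))
    sigma_bounds = (
        reference_sigma_bounds(folded, unfolded)
        if config.sigma_from_references
        else None
    )
    spectra = simulate_pulse_spectra(
        preset_name,
        labeling=labeling,
        replicates=replicates,
        noise=config.noise(seed),
        p_folded=config.p_folded,
    )
    table = deconvolve_spectra(spectra, init, config, sigma_bounds=sigma_bounds)
    return _provenance(table, seed)


def kinetic_course_table(
    variant: str,
    concentrations: Sequence[float],
    times: Sequence[float],
    replicates: int = 3,
    seed: int = 1,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Simulate and deconvolve time courses for a kinetic preset series."""
    config = config or RunConfig()
    labeling = config.labeling()
    folded, unfolded = reference_envelopes(labeling=labeling, p_folded=config.p_folded)
    init = (centroid_mass(folded), centroid_mass(unfolded))
    sigma_bounds = (
        reference_sigma_bounds(folded, unfolded)
        if config.sigma_from_references
        else None
    )
    base = KINETIC_PRESETS[variant]
    frames = []
    conditions = [(conc, False) for conc in concentrations] + [(None, True)]
    for conc, is_control in conditions:
        preset = dataclasses.replace(
            base,
            name=f"{variant}_spont" if is_control else f"{variant}_{conc:g}uM",
            efficacy=0.0 if is_control else base.efficacy,
            inhibitor_conc_um=1.0 if is_control else conc,
        )
        spectra = simulate_pulse_spectra(
            preset,
            labeling=labeling,
            times=times,
            replicates=replicates,
            noise=config.noise(seed),
            p_folded=config.p_folded,
        )
        table = deconvolve_spectra(spectra, init, config, sigma_bounds=sigma_bounds)
        table["inhibitor_conc_um"] = 0.0 if is_control else conc
        table["substrate_conc_um"] = base.substrate_conc_um
        table["variant"] = variant
        frames.append(table)
    return _provenance(pd.concat(frames, ignore_index=True), seed)


def efficacy_pipeline(
    variant: str = "wt",
    concentrations: Sequence[float] | None = None,
    times: Sequence[float] | None = None,
    replicates: int = 3,
    seed: int = 1,
    config: RunConfig | None = None,
) -> EfficacyEstimate:
    """Full simulate -> deconvolve -> subtract -> rates -> regression chain.

    The E15K-like variant restricts rates to the early linear phase
    (depletion cutoff plus the linear-phase time cap); the wild-type-like
    variant uses the depletion cutoff alone.
    """
    config = config or RunConfig()
    if concentrations is None:
        concentrations = (
            WT_CONCENTRATIONS if variant == "wt" else E15K_CONCENTRATIONS
        )
    if times is None:
        times = WT_COURSE_TIMES if variant == "wt" else E15K_COURSE_TIMES
    table = kinetic_course_table(
        variant, concentrations, times, replicates=replicates, seed=seed, config=config
    )
    spont = assemble_time_course(
        table[table["inhibitor_conc_um"] == 0.0],
        condition_cols=("inhibitor_conc_um", "substrate_conc_um"),
    )
    max_time = config.linear_phase_cap_min if variant == "e15k" else None
    substrate = float(KINETIC_PRESETS[variant].substrate_conc_um)
    rates = {}
    for conc in concentrations:
        course = assemble_time_course(
            table[table["inhibitor_conc_um"] == conc],
            condition_cols=("inhibitor_conc_um", "substrate_conc_um"),
        )
        corrected = subtract_spontaneous(course, spont)
        rates[float(conc)] = initial_rate(
            corrected,
            depletion_cutoff=config.depletion_cutoff,
            max_time=max_time,
            substrate_conc_um=substrate,
        )
    return efficacy_regression(rates, substrate)


def efficacy_summary_frame(estimate: EfficacyEstimate, seed: int) -> pd.DataFrame:
    rows = [
        {
            "inhibitor_conc_um": conc,
            "rate_per_min": rate.rate,
            "molar_rate_um_per_min": rate.molar_rate,
            "rate_stderr": rate.stderr,
            "n_points": rate.n,
            "included_times_min": ";".join(f"{t:g}" for t in rate.included_times),
            "excluded": ";".join(f"{t:g}:{reason}" for t, reason in rate.excluded),
        }
        for conc, rate in sorted(estimate.rates.items())
    ]
    frame = pd.DataFrame(rows)
    frame["efficacy"] = estimate.efficacy
    frame["efficacy_stderr"] = estimate.stderr
    frame["intercept"] = estimate.intercept
    frame["r_squared"] = estimate.r_squared
    frame["through_origin_efficacy"] = estimate.through_origin_efficacy
    return _provenance(frame, seed)
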