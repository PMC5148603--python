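"""Seeded synthetic spectra and time courses for every experimental condition.

Two kinds of presets drive the generator:

* **Empirical presets** pin the true unfolded fraction of the diagnostic
  hydrolase-domain peptide to a printed study value (e.g. 29% spontaneous
  unfolding after 30 min at 25 C).  They bypass the kinetic model because
  the measured spontaneous fractions at 5 and 30 min are not mutually
  consistent under a single first-order rate.
* **Kinetic presets** generate whole time courses from a two-state model:
  the folded pool decays with rate ``k_spont + efficacy * [I] / [S]``, with
  an optional first-order decay of inhibitor activity (``k_decay``) to
  emulate the E15K variant's time-dependent loss of unfolding activity.

Pulse labeling snapshots the folded/unfolded populations: the folded state
is partially exchanged (EX2-like, incorporation probability ``p_folded``),
the unfolded state exchanges fully at the D2O fraction of the buffer, and
the observed envelope is the population-weighted mixture.  Continuous
labeling instead mixes a gradually exchanging closed state with a
cooperatively opened, fully exchanged state (mixed EX1/EX2).

Every stochastic call is seeded; identical (seed, preset, time, replicate)
tuples produce bit-identical spectra.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEUTERIUM_MASS_SHIFT
from .isotopes import (
    ElementalComposition,
    IsotopeEnvelope,
    PeptideSpec,
    apply_deuteration,
    averagine_composition,
    centroid_mass,
    composition_from_sequence,
    mix_envelopes,
    natural_envelope,
)

#: Intensity of the tallest stick before noise (arbitrary counts).
BASE_INTENSITY = 1000.0

#: Folded-state pulse incorporation probability.  Gives ~14 Da centroid
#: separation from the fully exchanged state of the diagnostic peptide.
DEFAULT_P_FOLDED = 0.25

#: Default incubation time grid (minutes) for kinetic time courses.
DEFAULT_KINETIC_TIMES = (0.5, 2.5, 5.0, 10.0, 15.0, 30.0)


@dataclasses.dataclass(frozen=True)
class LabelingCondition:
    """Deuterium-labeling parameters of a run."""

    d2o_fraction: float = 0.70
    pulse_duration_s: float = 10.0
    temperature_c: float = 25.0
    continuous_times_s: tuple[float, ...] = (10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        if not 0 < self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must be in (0, 1]")
        if not self.pulse_duration_s > 0:
            raise ValueError("pulse_duration_s must be positive")


@dataclasses.dataclass(frozen=True)
class EmpiricalPreset:
    """A condition whose true unfolded fraction is pinned to a study value."""

    name: str
    description: str
    time_min: float
    fraction: float
    sd: float | None = None
    inhibitor: str | None = None
    inhibitor_conc_um: float | None = None
    protectant: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class KineticPreset:
    """Two-state unfolding parameters.

    ``efficacy`` is the catalytic unfolding efficacy in substrate molecules
    unfolded per inhibitor molecule per minute; ``k_decay`` is a first-order
    decay rate of inhibitor activity (per minute; 0 = stable inhibitor).
    """

    name: str
    k_spont: float
    efficacy: float
    inhibitor_conc_um: float = 1.0
    substrate_conc_um: float = 10.0
    k_decay: float = 0.0

    def __post_init__(self) -> None:
        for field in ("k_spont", "efficacy", "k_decay"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be nonnegative")
        if self.inhibitor_conc_um <= 0 or self.substrate_conc_um <= 0:
            raise ValueError("concentrations must be positive")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Per-peak multiplicative Gaussian noise plus an additive baseline.

    ``cv`` is the coefficient of variation of each stick intensity;
    ``baseline`` is the standard deviation of additive noise as a fraction
    of the tallest stick.  A seed is mandatory for every stochastic call.
    """

    cv: float = 0.03
    baseline: float = 0.005
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cv < 0 or self.baseline < 0:
            raise ValueError("cv and baseline must be nonnegative")
        if self.seed is None:
            raise ValueError("NoiseModel requires an explicit integer seed")


@dataclasses.dataclass(frozen=True)
class SyntheticSpectrum:
    """One noisy replicate envelope with full condition metadata."""

    envelope: IsotopeEnvelope
    peptide: PeptideSpec | None
    replicate: int
    time_min: float
    preset: str
    condition: dict


@dataclasses.dataclass(frozen=True)
class RegionParams:
    """Continuous-labeling parameters for one peptide/region.

    ``protection_factor`` slows EX2 exchange of the closed state;
    ``k_open_per_s`` is the rate of cooperative (EX1) opening.
    """

    peptide: PeptideSpec
    protection_factor: float
    k_open_per_s: float

    def __post_init__(self) -> None:
        if self.protection_factor < 1:
            raise ValueError("protection_factor must be >= 1")
        if self.k_open_per_s < 0:
            raise ValueError("k_open_per_s must be nonnegative")


# --------------------------------------------------------------------------
# Preset registries.  Empirical fractions are the study's printed unfolded
# percentages; kinetic parameters are the printed efficacies plus a
# spontaneous rate calibrated so the spontaneous curve passes through
# 29% at 30 min.
# --------------------------------------------------------------------------

EMPIRICAL_PRESETS: dict[str, EmpiricalPreset] = {
    p.name: p
    for p in (
        EmpiricalPreset("spont_5", "10 uM LPL alone, 5 min, 25 C", 5.0, 0.070, sd=0.007),
        EmpiricalPreset("spont_30", "10 uM LPL alone, 30 min, 25 C", 30.0, 0.29),
        EmpiricalPreset(
            "spont_30_dose", "buffer-only control of the dose series, 30 min",
            30.0, 0.286, sd=0.013,
        ),
        EmpiricalPreset(
            "wt1uM_5", "1 uM ANGPTL4 wt, 5 min", 5.0, 0.603, sd=0.023,
            inhibitor="ANGPTL4_wt", inhibitor_conc_um=1.0,
        ),
        EmpiricalPreset(
            "wt0p25uM_30", "0.25 uM ANGPTL4 wt, 30 min", 30.0, 0.74, sd=0.06,
            inhibitor="ANGPTL4_wt", inhibitor_conc_um=0.25,
        ),
        EmpiricalPreset(
            "wt2uM_10", "2 uM ANGPTL4 wt, 10 min", 10.0, 0.87, sd=0.02,
            inhibitor="ANGPTL4_wt", inhibitor_conc_um=2.0,
        ),
        EmpiricalPreset(
            "wt2uM_10_gpihbp1", "2 uM ANGPTL4 wt + 30 uM GPIHBP1 1-131, 10 min",
            10.0, 0.08, sd=0.02, inhibitor="ANGPTL4_wt", inhibitor_conc_um=2.0,
            protectant="GPIHBP1_1-131",
        ),
        EmpiricalPreset(
            "wt2uM_10_LU", "2 uM ANGPTL4 wt + 30 uM GPIHBP1 LU domain, 10 min",
            10.0, 0.79, sd=0.07, inhibitor="ANGPTL4_wt", inhibitor_conc_um=2.0,
            protectant="GPIHBP1_34-131",
        ),
        EmpiricalPreset(
            "wt2uM_10_acidic", "2 uM ANGPTL4 wt + 30 uM GPIHBP1 acidic domain, 10 min",
            10.0, 0.69, sd=0.12, inhibitor="ANGPTL4_wt", inhibitor_conc_um=2.0,
            protectant="GPIHBP1_1-33",
        ),
    )
}

KINETIC_PRESETS: dict[str, KineticPreset] = {
    "wt": KineticPreset("wt", k_spont=0.0114, efficacy=1.6),
    # k_decay chosen so E15K progress curves flatten over tens of minutes.
    "e15k": KineticPreset("e15k", k_spont=0.0114, efficacy=0.6, k_decay=0.05),
}


def preset_registry() -> dict[str, EmpiricalPreset | KineticPreset]:
    """Immutable view of every named preset (empirical and kinetic)."""
    registry: dict[str, EmpiricalPreset | KineticPreset] = {}
    registry.update(EMPIRICAL_PRESETS)
    registry.update(KINETIC_PRESETS)
    return registry


def get_preset(name: str) -> EmpiricalPreset | KineticPreset:
    registry = preset_registry()
    if name not in registry:
        known = ", ".join(sorted(registry))
        raise KeyError(f"unknown preset {name!r}; available presets: {known}")
    return registry[name]


def diagnostic_peptide() -> PeptideSpec:
    """Stand-in for the hydrolase-domain diagnostic peptide (residues 131-165).

    The true sequence is not published; an averagine composition at 3800 Da
    with 31 exchangeable amides reproduces the envelope geometry, which is
    all that fraction recovery depends on.
    """
    return PeptideSpec("LPL", 131, 165, n_exchangeable=31)


def peptide_composition(
    peptide: PeptideSpec, target_mass: float | None = None
) -> ElementalComposition:
    """Composition from sequence when known, else an averagine stand-in."""
    if peptide.sequence is not None:
        return composition_from_sequence(peptide.sequence)
    if target_mass is None:
        target_mass = peptide.length * 111.1254
    return averagine_composition(target_mass)


_DIAGNOSTIC_MASS = 3800.0


def _natural_for(peptide: PeptideSpec) -> IsotopeEnvelope:
    if peptide.key == ("LPL", 131, 165) and peptide.sequence is None:
        return natural_envelope(peptide_composition(peptide, _DIAGNOSTIC_MASS))
    return natural_envelope(peptide_composition(peptide))


def reference_envelopes(
    peptide: PeptideSpec | None = None,
    labeling: LabelingCondition | None = None,
    p_folded: float = DEFAULT_P_FOLDED,
) -> tuple[IsotopeEnvelope, IsotopeEnvelope]:
    """Noiseless folded and unfolded envelopes used as deconvolution references."""
    peptide = peptide or diagnostic_peptide()
    labeling = labeling or LabelingCondition()
    if p_folded >= labeling.d2o_fraction:
        raise ValueError(
            "p_folded must be below the D2O fraction so the states are separable"
        )
    base = _natural_for(peptide)
    folded = apply_deuteration(base, peptide.exchangeable, p_folded)
    unfolded = apply_deuteration(base, peptide.exchangeable, labeling.d2o_fraction)
    return folded, unfolded


def two_state_fraction(t, preset: KineticPreset):
    """Unfolded fraction u(t) of the two-state model at time ``t`` (minutes).

    ``u(t) = 1 - exp(-(k_spont * t + k_cat_eff * g(t)))`` with
    ``k_cat_eff = efficacy * [I] / [S]`` and ``g(t) = (1 - exp(-k_decay t)) /
    k_decay`` (or ``t`` for a stable inhibitor).  u(0) = 0 and u is monotone
    nondecreasing in t, efficacy and inhibitor concentration.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    k_cat_eff = preset.efficacy * preset.inhibitor_conc_um / preset.substrate_conc_um
    if preset.k_decay > 0:
        g = (1.0 - np.exp(-preset.k_decay * t)) / preset.k_decay
    else:
        g = t
    u = 1.0 - np.exp(-(preset.k_spont * t + k_cat_eff * g))
    return float(u) if u.ndim == 0 else u


def _spectrum_rng(seed: int, preset: str, time_index: int, replicate: int):
    tag = zlib.crc32(preset.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, time_index, replicate])
    )


def _apply_noise(envelope: IsotopeEnvelope, rng, noise: NoiseModel) -> IsotopeEnvelope:
    scale = BASE_INTENSITY / envelope.abundances.max()
    intensity = envelope.abundances * scale
    intensity = intensity * (1.0 + noise.cv * rng.standard_normal(intensity.size))
    intensity = intensity + noise.baseline * BASE_INTENSITY * rng.standard_normal(
        intensity.size
    )
    return IsotopeEnvelope(
        envelope.masses, np.clip(intensity, 0.0, None), normalized=False
    )


def simulate_pulse_spectra(
    preset: EmpiricalPreset | KineticPreset | str,
    peptide: PeptideSpec | None = None,
    labeling: LabelingCondition | None = None,
    times: Sequence[float] | None = None,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    p_folded: float = DEFAULT_P_FOLDED,
) -> list[SyntheticSpectrum]:
    """Replicate pulse-label spectra for one preset.

    The observed envelope at each time is the mixture of the partially
    exchanged folded state and the fully exchanged unfolded state, weighted
    by the preset's true fraction (empirical) or the two-state model
    (kinetic), with per-peak noise applied on top.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if noise is None:
        raise ValueError("a seeded NoiseModel is required")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    peptide = peptide or diagnostic_peptide()
    labeling = labeling or LabelingCondition()
    folded, unfolded = reference_envelopes(peptide, labeling, p_folded)
    if times is None:
        times = (
            [preset.time_min]
            if isinstance(preset, EmpiricalPreset)
            else list(DEFAULT_KINETIC_TIMES)
        )
    spectra: list[SyntheticSpectrum] = []
    for time_index, t in enumerate(times):
        if isinstance(preset, EmpiricalPreset):
            w = preset.fraction
            condition = {
                "kind": "empirical",
                "inhibitor": preset.inhibitor,
                "inhibitor_conc_um": preset.inhibitor_conc_um,
                "protectant": preset.protectant,
                "true_fraction": w,
            }
        else:
            w = two_state_fraction(t, preset)
            condition = {
                "kind": "kinetic",
                "inhibitor": preset.name,
                "inhibitor_conc_um": preset.inhibitor_conc_um,
                "substrate_conc_um": preset.substrate_conc_um,
                "true_fraction": w,
            }
        condition.update(
            d2o_fraction=labeling.d2o_fraction,
            pulse_duration_s=labeling.pulse_duration_s,
            p_folded=p_folded,
            seed=noise.seed,
        )
        mixture = mix_envelopes(folded, unfolded, w)
        for replicate in range(1, replicates + 1):
            rng = _spectrum_rng(noise.seed, preset.name, time_index, replicate)
            spectra.append(
                SyntheticSpectrum(
                    envelope=_apply_noise(mixture, rng, noise),
                    peptide=peptide,
                    replicate=replicate,
                    time_min=float(t),
                    preset=preset.name,
                    condition=condition,
                )
            )
    return spectra


def simulate_continuous_labeling(
    region_params: Iterable[RegionParams],
    labeling: LabelingCondition | None = None,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    k_int_per_s: float = 1.0,
) -> list[SyntheticSpectrum]:
    """Continuous-labeling spectra for a set of peptides/regions.

    Closed-state incorporation follows EX2 kinetics slowed by the protection
    factor, ``p_closed(t) = d2o * (1 - exp(-k_int t / PF))``; a cooperatively
    opened fraction ``w(t) = 1 - exp(-k_open t)`` is labeled at the full D2O
    fraction.  ``k_open = 0`` gives pure EX2 (unimodal centroid drift);
    a large protection factor with ``k_open > 0`` gives pure EX1 (two fixed
    centroids with shifting weights).
    """
    if noise is None:
        raise ValueError("a seeded NoiseModel is required")
    labeling = labeling or LabelingCondition()
    spectra: list[SyntheticSpectrum] = []
    for region in region_params:
        peptide = region.peptide
        base = _natural_for(peptide)
        n_exch = peptide.exchangeable
        open_env = apply_deuteration(base, n_exch, labeling.d2o_fraction)
        preset_tag = f"continuous:{peptide.protein}:{peptide.start}-{peptide.end}"
        for time_index, t in enumerate(labeling.continuous_times_s):
            p_closed = labeling.d2o_fraction * (
                1.0 - np.exp(-k_int_per_s * t / region.protection_factor)
            )
            closed_env = apply_deuteration(base, n_exch, float(p_closed))
            w = 1.0 - np.exp(-region.k_open_per_s * t)
            mixture = mix_envelopes(closed_env, open_env, float(w))
            condition = {
                "kind": "continuous",
                "time_s": float(t),
                "protection_factor": region.protection_factor,
                "k_open_per_s": region.k_open_per_s,
                "d2o_fraction": labeling.d2o_fraction,
                "p_closed": float(p_closed),
                "w_open": float(w),
                "seed": noise.seed,
            }
            for replicate in range(1, replicates + 1):
                rng = _spectrum_rng(noise.seed, preset_tag, time_index, replicate)
                spectra.append(
                    SyntheticSpectrum(
                        envelope=_apply_noise(mixture, rng, noise),
                        peptide=peptide,
                        replicate=replicate,
                        time_min=float(t) / 60.0,
                        preset=preset_tag,
                        condition=condition,
                    )
                )
    return spectra


#: Destabilized N-terminal helix of the 159-residue inhibitor construct.
HELIX1_SPAN = (19, 43)
#: Second, more stable helical region.
HELIX2_SPAN = (85, 111)
#: Protein length used by the continuous-labeling presets.
ANGPTL_LENGTH = 159


def angptl_region_presets(
    variant: str = "wt", protein_length: int = ANGPTL_LENGTH
) -> list[RegionParams]:
    """Tiled peptide map with per-region exchange parameters.

    Peptides overlapping the N-terminal helix (residues 19-43) open
    cooperatively; the E15K-like variant opens that helix ten times faster,
    which is the only parameter difference from the wild-type-like preset.
    """
    if variant not in ("wt", "e15k"):
        raise ValueError("variant must be 'wt' or 'e15k'")
    helix1_k_open = 5e-4 if variant == "wt" else 5e-3
    peptides: list[PeptideSpec] = []
    start = 1
    while start + 11 <= protein_length:
        peptides.append(PeptideSpec("ANGPTL4", start, start + 11))
        start += 8
    if peptides[-1].end < protein_length:
        peptides.append(PeptideSpec("ANGPTL4", protein_length - 11, protein_length))
    regions = []
    for peptide in peptides:
        if peptide.start <= HELIX1_SPAN[1] and peptide.end >= HELIX1_SPAN[0]:
            regions.append(RegionParams(peptide, 2000.0, helix1_k_open))
        elif peptide.start <= HELIX2_SPAN[1] and peptide.end >= HELIX2_SPAN[0]:
            regions.append(RegionParams(peptide, 5000.0, 1e-4))
        else:
            regions.append(RegionParams(peptide, 10.0, 0.0))
    return regions


def write_fixtures(
    output_dir,
    presets: Sequence[str] | None = None,
    seed: int = 1,
    replicates: int = 3,
    noise_cv: float = 0.03,
    noise_baseline: float = 0.005,
) -> dict:
    """Write spectra CSV, peptide table and a JSON manifest; idempotent per seed."""
    from . import __version__
    from .workbench import write_peptide_table

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if presets is None:
        presets = sorted(EMPIRICAL_PRESETS)
    rows = []
    peptides: dict[tuple, PeptideSpec] = {}
    for name in presets:
        noise = NoiseModel(cv=noise_cv, baseline=noise_baseline, seed=seed)
        for spectrum in simulate_pulse_spectra(name, replicates=replicates, noise=noise):
            peptides[spectrum.peptide.key] = spectrum.peptide
            for mass, intensity in zip(
                spectrum.envelope.masses, spectrum.envelope.abundances
            ):
                rows.append(
                    {
                        "preset": spectrum.preset,
                        "replicate": spectrum.replicate,
                        "time_min": spectrum.time_min,
                        "mass_da": mass,
                        "intensity": intensity,
                    }
                )
    spectra_path = output_dir / "spectra.csv"
    pd.DataFrame(rows).to_csv(spectra_path, index=False)
    peptide_path = output_dir / "peptides.csv"
    write_peptide_table(list(peptides.values()), peptide_path)
    manifest = {
        "seed": int(seed),
        "replicates": int(replicates),
        "noise": {"cv": noise_cv, "baseline": noise_baseline},
        "presets": list(presets),
        "version": __version__,
        "files": {"spectra": spectra_path.name, "peptides": peptide_path.name},
    }
    with open(output_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
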