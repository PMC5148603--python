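"""Continuous-labeling uptake analytics.

Deuterium uptake of each peptide is the centroid-mass shift from the
undeuterated envelope; relative uptake divides by the uptake of a fully
exchanged control.  Peptide-level values are projected onto the primary
sequence as residue heat maps, compared across protein variants with
butterfly differences under a max-replicate-SD significance rule, and
screened for cooperative (EX1) unfolding with an envelope-width metric.

Coverage gaps are always rendered as missing, never as zero uptake.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEUTERIUM_MASS_SHIFT
from .isotopes import IsotopeEnvelope, PeptideSpec, centroid_mass, envelope_variance

logger = logging.getLogger("hdxpulse.uptake")

#: Max-over-time envelope variance must exceed the earliest variance by this
#: factor to call a series EX1-containing.
EX1_VARIANCE_FACTOR = 2.0


@dataclasses.dataclass(frozen=True)
class UptakeRecord:
    """Per-peptide deuterium uptake at one labeling time."""

    peptide: PeptideSpec
    time_s: float
    uptake_da: float
    relative_uptake: float
    sd: float
    n: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclasses.dataclass(frozen=True)
class ResidueHeatmap:
    """Residue x time matrix of relative uptake with peptide provenance."""

    values: pd.DataFrame  # index: residue (1-based); columns: time_s
    provenance: dict[int, tuple[tuple[str, int, int], ...]]


@dataclasses.dataclass(frozen=True)
class DifferentialResult:
    """Per-peptide uptake differences (variant - reference) with significance."""

    table: pd.DataFrame  # columns: protein, start, end, time_s, difference_da, significant
    threshold_da: float


def relative_uptake(uptake_da: float, control_uptake_da: float) -> float:
    """Uptake as a fraction of the fully exchanged control (may exceed 1 with noise)."""
    if not control_uptake_da > 0:
        raise ValueError("control uptake must be positive")
    ratio = uptake_da / control_uptake_da
    if ratio > 1:
        logger.debug("relative uptake %.3f exceeds 1 (noise); not clipped", ratio)
    return ratio


def full_deuteration_uptake(peptide: PeptideSpec, d2o_fraction: float = 0.70) -> float:
    """Theoretical uptake (Da) of a maximally exchanged control."""
    return peptide.exchangeable * d2o_fraction * DEUTERIUM_MASS_SHIFT


def _thresholded_centroid(envelope: IsotopeEnvelope, intensity_floor: float) -> float:
    """Centroid of the sticks above ``intensity_floor`` of the tallest stick.

    Near-baseline sticks carry additive noise at a long mass lever arm and
    would dominate the centroid variance; thresholding them is the standard
    centroiding safeguard.
    """
    keep = envelope.abundances >= intensity_floor * envelope.abundances.max()
    return centroid_mass(
        IsotopeEnvelope(envelope.masses[keep], envelope.abundances[keep], normalized=False)
    )


def uptake_records_from_spectra(
    spectra: Iterable,
    reference_centroids: Mapping[tuple[str, int, int], float],
    control_uptakes: Mapping[tuple[str, int, int], float],
    intensity_floor: float = 0.01,
) -> list[UptakeRecord]:
    """Aggregate replicate spectra into per-(peptide, time) uptake records."""
    groups: dict[tuple, list] = {}
    peptides: dict[tuple, PeptideSpec] = {}
    for spectrum in spectra:
        time_s = float(spectrum.condition.get("time_s", spectrum.time_min * 60.0))
        key = (spectrum.peptide.key, time_s)
        groups.setdefault(key, []).append(spectrum)
        peptides[spectrum.peptide.key] = spectrum.peptide
    records = []
    for (pkey, time_s), members in sorted(groups.items()):
        reference = reference_centroids[pkey]
        uptakes = np.array(
            [
                _thresholded_centroid(m.envelope, intensity_floor) - reference
                for m in members
            ]
        )
        mean = float(uptakes.mean())
        sd = float(uptakes.std(ddof=1)) if uptakes.size > 1 else float("nan")
        rel = relative_uptake(mean, control_uptakes[pkey])
        flags = ("relative_above_1",) if rel > 1 else ()
        records.append(
            UptakeRecord(
                peptide=peptides[pkey],
                time_s=time_s,
                uptake_da=mean,
                relative_uptake=rel,
                sd=sd,
                n=int(uptakes.size),
                flags=flags,
            )
        )
    return records


def heatmap_matrix(
    records: Sequence[UptakeRecord],
    protein_length: int,
    rule: str = "mean",
) -> ResidueHeatmap:
    """Project peptide relative uptake onto residues.

    ``rule='mean'`` averages all covering peptides per residue (unweighted);
    ``rule='shortest'`` takes the shortest covering peptide, which tends to
    localize uptake more sharply.  Residues covered by no peptide are NaN.
    """
    if rule not in ("mean", "shortest"):
        raise ValueError("rule must be 'mean' or 'shortest'")
    times = sorted({r.time_s for r in records})
    values = pd.DataFrame(
        np.nan, index=pd.RangeIndex(1, protein_length + 1, name="residue"), columns=times
    )
    provenance: dict[int, set] = {}
    for record in records:
        peptide = record.peptide
        if peptide.start < 1 or peptide.end > protein_length:
            raise ValueError(
                f"peptide {peptide.key} outside protein of length {protein_length}"
            )
    for time_s in times:
        at_time = [r for r in records if r.time_s == time_s]
        for residue in range(1, protein_length + 1):
            covering = [
                r for r in at_time if r.peptide.start <= residue <= r.peptide.end
            ]
            if not covering:
                continue
            if rule == "shortest":
                shortest = min(covering, key=lambda r: r.peptide.length)
                values.loc[residue, time_s] = shortest.relative_uptake
            else:
                values.loc[residue, time_s] = float(
                    np.mean([r.relative_uptake for r in covering])
                )
            provenance.setdefault(residue, set()).update(
                r.peptide.key for r in covering
            )
    return ResidueHeatmap(
        values=values,
        provenance={k: tuple(sorted(v)) for k, v in provenance.items()},
    )


def significance_threshold(sds: Sequence[float]) -> float:
    """Largest replicate SD across peptides/datasets, used symmetrically about 0."""
    values = [s for s in sds if np.isfinite(s)]
    if not values:
        raise ValueError("at least one finite SD is required")
    return float(max(values))


def butterfly_differences(
    reference: Sequence[UptakeRecord],
    variant: Sequence[UptakeRecord],
    threshold_da: float | None = None,
    bins: Mapping[tuple[str, int, int], str] | None = None,
) -> DifferentialResult:
    """Per-peptide, per-time uptake differences (variant - reference).

    Only (peptide, time) pairs present in both inputs are compared;
    mismatches are logged.  The significance threshold defaults to the
    largest replicate SD across both datasets.  An optional ``bins``
    mapping labels peptides (e.g. by their degree of bimodality) so that
    downstream grouping can stratify the comparison.
    """
    ref_map = {(r.peptide.key, r.time_s): r for r in reference}
    var_map = {(r.peptide.key, r.time_s): r for r in variant}
    shared = sorted(set(ref_map) & set(var_map))
    if not shared:
        raise ValueError("reference and variant share no (peptide, time) pairs")
    dropped = (set(ref_map) ^ set(var_map))
    if dropped:
        logger.info("butterfly comparison drops %d unmatched pairs", len(dropped))
    if threshold_da is None:
        threshold_da = significance_threshold(
            [r.sd for r in list(reference) + list(variant)]
        )
    rows = []
    for key, time_s in shared:
        difference = var_map[(key, time_s)].uptake_da - ref_map[(key, time_s)].uptake_da
        row = {
            "protein": key[0],
            "start": key[1],
            "end": key[2],
            "time_s": time_s,
            "difference_da": difference,
            "significant": bool(abs(difference) > threshold_da),
        }
        if bins is not None:
            row["bin"] = bins.get(key)
        rows.append(row)
    return DifferentialResult(table=pd.DataFrame(rows), threshold_da=float(threshold_da))


def ex1_width_metric(
    envelopes_by_time: Mapping[float, IsotopeEnvelope],
    factor: float = EX1_VARIANCE_FACTOR,
) -> tuple[pd.DataFrame, str | None]:
    """Envelope variance over time and an EX1/EX2 classification.

    For a two-state mixture the variance obeys
    ``sigma^2 + w (1 - w) d^2`` (components' variance plus the separation
    term), so cooperative EX1 opening inflates the width at intermediate
    opened fractions.  A series is called "EX1-containing" when the maximum
    variance exceeds the earliest-time variance by ``factor``; with fewer
    than 2 time points only the metric is returned.
    """
    if not envelopes_by_time:
        raise ValueError("at least one envelope is required")
    times = sorted(envelopes_by_time)
    variances = [envelope_variance(envelopes_by_time[t]) for t in times]
    table = pd.DataFrame({"time_s": times, "variance_da2": variances})
    if len(times) < 2:
        return table, None
    classification = (
        "EX1-containing" if max(variances) > factor * variances[0] else "EX2"
    )
    return table, classification


def sequence_coverage(peptides: Sequence[PeptideSpec], protein_length: int) -> float:
    """Percentage of residues covered by the union of the peptides."""
    covered = np.zeros(protein_length, dtype=bool)
    for peptide in peptides:
        if peptide.start < 1 or peptide.end > protein_length:
            raise ValueError(
                f"peptide {peptide.key} outside protein of length {protein_length}"
            )
        covered[peptide.start - 1 : peptide.end] = True
    return float(covered.sum()) / protein_length * 100.0


def butterfly_plot(result: DifferentialResult, path) -> None:
    """Write a butterfly plot of per-peptide differences to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    table = result.table.sort_values(["start", "end"])
    for time_s, group in table.groupby("time_s"):
        midpoints = (group["start"] + group["end"]) / 2.0
        ax.plot(midpoints, group["difference_da"], marker="o", label=f"{time_s:g} s")
    ax.axhspan(-result.threshold_da, result.threshold_da, color="0.85", zorder=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("residue (peptide midpoint)")
    ax.set_ylabel("uptake difference (Da)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_plot(heatmap: ResidueHeatmap, path) -> None:
    """Write a residue-by-time relative-uptake heat map to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    data = heatmap.values.to_numpy(dtype=float).T
    image = ax.imshow(
        data, aspect="auto", origin="lower", cmap="coolwarm", vmin=0.0, vmax=1.0,
        extent=(0.5, heatmap.values.index.max() + 0.5, -0.5, data.shape[0] - 0.5),
    )
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels([f"{t:g} s" for t in heatmap.values.columns])
    ax.set_xlabel("residue")
    fig.colorbar(image, ax=ax, label="relative uptake")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
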