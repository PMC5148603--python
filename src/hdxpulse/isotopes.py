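"""Peptide compositions and isotope-envelope arithmetic.

An :class:`IsotopeEnvelope` is a stick spectrum in *neutral-mass* space:
an ordered list of (mass, relative abundance) pairs.  Everything the
pulse-labeling pipeline measures — centroids, bimodality, deuterium
uptake — is computed on these envelopes; conversion to m/z is an explicit
boundary operation (:func:`to_mz` / :func:`from_mz`) because charge is
instrument metadata, not chemistry.

Deuteration is modeled as a binomial convolution: every exchangeable
backbone amide incorporates deuterium independently with one probability
``p_incorp`` (capped by the D2O fraction of the labeling buffer).  This is
deliberately coarser than a per-site rate spectrum but is sufficient to
reproduce the bimodal folded/unfolded phenomenology that the deconvolution
stage quantifies.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import binom

from .constants import (
    AVERAGINE_UNIT,
    AVERAGINE_UNIT_MASS,
    AVERAGE_MASS,
    DEUTERIUM_MASS_SHIFT,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    RESIDUE_COMPOSITIONS,
    WATER,
)

_NORM_TOL = 1e-9
#: Peaks closer than this (Da) are merged into one abundance-weighted stick
#: during the deuteration convolution.  Within one nominal isotopologue bin
#: the deuterium/13C fine structure spans well under 0.1 Da for peptides of
#: interest, while adjacent bins are ~1 Da apart, so 0.3 Da cleanly separates
#: the two regimes.
MERGE_TOLERANCE = 0.3


class ElementalComposition(dict):
    """Nonnegative integer element counts over C, H, N, O, S.

    Behaves as a plain ``dict`` (element symbol -> count); zero counts are
    dropped so an empty composition is falsy.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        super().__init__()
        merged: dict[str, int] = {}
        if counts:
            merged.update(counts)
        merged.update(kwargs)
        for element, count in merged.items():
            if element not in ISOTOPES:
                raise ValueError(f"unsupported element {element!r}")
            count = int(count)
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")
            if count:
                self[element] = self.get(element, 0) + count

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        total = dict(self)
        for element, count in other.items():
            total[element] = total.get(element, 0) + count
        return ElementalComposition(total)

    @property
    def n_atoms(self) -> int:
        return sum(self.values())

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.items())

    @property
    def average_mass(self) -> float:
        return sum(AVERAGE_MASS[el] * n for el, n in self.items())

    def formula(self) -> str:
        return "".join(f"{el}{self[el]}" for el in ("C", "H", "N", "O", "S") if el in self)


def composition_from_sequence(sequence: str) -> ElementalComposition:
    """Elemental composition of a free peptide (residues + one water)."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    total: dict[str, int] = dict(WATER)
    for position, letter in enumerate(sequence, start=1):
        residue = RESIDUE_COMPOSITIONS.get(letter)
        if residue is None:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {position}"
            )
        for element, count in residue.items():
            total[element] = total.get(element, 0) + count
    return ElementalComposition(total)


def averagine_composition(target_mass: float) -> ElementalComposition:
    """Integer averagine stand-in composition for a peptide of unknown sequence.

    The averagine unit is scaled to ``target_mass`` and each element count is
    rounded to the nearest integer, which keeps the average mass within one
    averagine-unit mass of the target.
    """
    if not target_mass > 0:
        raise ValueError("target_mass must be positive")
    scale = target_mass / AVERAGINE_UNIT_MASS
    counts = {el: round(f * scale) for el, f in AVERAGINE_UNIT.items()}
    return ElementalComposition(counts)


def n_exchangeable_amides(sequence: str) -> int:
    """Backbone amides available for exchange: length - 1 - non-N-terminal prolines."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    for position, letter in enumerate(sequence, start=1):
        if letter not in RESIDUE_COMPOSITIONS:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {position}"
            )
    return len(sequence) - 1 - sequence[1:].count("P")


@dataclasses.dataclass(frozen=True)
class PeptideSpec:
    """A peptic peptide in mature-protein coordinates (1-based, inclusive).

    ``plus_met`` marks peptides that retain the initiator methionine of a
    bacterially expressed construct; it is excluded from the residue
    numbering, so the flag carries the +1 residue without shifting
    coordinates.  ``n_exchangeable`` overrides the amide count for peptides
    whose sequence is not known (such as the diagnostic hydrolase-domain
    peptide, for which only envelope geometry matters).
    """

    protein: str
    start: int
    end: int
    sequence: str | None = None
    charge: int | None = None
    n_exchangeable: int | None = None
    plus_met: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} exceeds end {self.end}")
        if self.start < 1:
            raise ValueError("residue numbering is 1-based")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"residue span {self.start}-{self.end}"
            )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if self.n_exchangeable is not None and not (
            0 <= self.n_exchangeable <= self.length - 1
        ):
            raise ValueError("n_exchangeable must be in [0, length - 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.protein, self.start, self.end)

    @property
    def exchangeable(self) -> int:
        """Resolved exchangeable-amide count (override > sequence > length-1)."""
        if self.n_exchangeable is not None:
            return self.n_exchangeable
        if self.sequence is not None:
            return n_exchangeable_amides(self.sequence)
        return self.length - 1


@dataclasses.dataclass(frozen=True)
class IsotopeEnvelope:
    """Stick spectrum: strictly increasing neutral masses with abundances.

    ``normalized`` envelopes sum to 1 (within 1e-9).  ``degenerate`` flags
    the single-peak envelope returned for an empty composition.
    """

    masses: np.ndarray
    abundances: np.ndarray
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        abundances = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "abundances", abundances)
        if masses.ndim != 1 or masses.shape != abundances.shape:
            raise ValueError("masses and abundances must be 1-D arrays of equal length")
        if np.any(abundances < 0):
            raise ValueError("abundances must be nonnegative")
        if masses.size > 1 and not np.all(np.diff(masses) > 0):
            raise ValueError("masses must be strictly increasing")
        if self.normalized and masses.size:
            total = float(abundances.sum())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"normalized envelope sums to {total}, not 1")
            if abs(total - 1.0) > _NORM_TOL:
                object.__setattr__(self, "abundances", abundances / total)

    @property
    def n_peaks(self) -> int:
        return int(self.masses.size)

    def normalize(self) -> "IsotopeEnvelope":
        total = float(self.abundances.sum())
        if total <= 0:
            raise ValueError("cannot normalize an envelope with zero total abundance")
        return IsotopeEnvelope(
            self.masses, self.abundances / total, normalized=True,
            degenerate=self.degenerate,
        )


def _merge_peaks(
    masses: np.ndarray, abundances: np.ndarray, tol: float = MERGE_TOLERANCE
) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than ``tol`` into abundance-weighted sticks.

    Weighted merging preserves the total abundance and the centroid exactly.
    """
    keep = abundances > 0
    masses, abundances = masses[keep], abundances[keep]
    order = np.argsort(masses, kind="stable")
    masses, abundances = masses[order], abundances[order]
    if masses.size == 0:
        return masses, abundances
    starts = np.flatnonzero(np.concatenate(([True], np.diff(masses) > tol)))
    total = np.add.reduceat(abundances, starts)
    weighted = np.add.reduceat(abundances * masses, starts)
    return weighted / total, total


def _convolve(p1, m1, p2, m2):
    """Convolve two binned distributions carrying per-bin mean masses."""
    p = np.convolve(p1, p2)
    weighted = np.convolve(p1 * m1, p2) + np.convolve(p1, p2 * m2)
    mean = np.divide(weighted, p, out=np.zeros_like(weighted), where=p > 0)
    return p, mean


def _element_distribution(element: str) -> tuple[np.ndarray, np.ndarray]:
    isotopes = ISOTOPES[element]
    mono = isotopes[0][0]
    offsets = [round(mass - mono) for mass, _ in isotopes]
    p = np.zeros(max(offsets) + 1)
    m = np.zeros_like(p)
    for (mass, abundance), offset in zip(isotopes, offsets):
        p[offset] = abundance
        m[offset] = mass
    return p, m


def _repeat_convolve(p, m, n: int):
    """n-fold self-convolution by binary exponentiation."""
    result_p, result_m = np.array([1.0]), np.array([0.0])
    while n:
        if n & 1:
            result_p, result_m = _convolve(result_p, result_m, p, m)
        n >>= 1
        if n:
            p, m = _convolve(p, m, p, m)
    return result_p, result_m


def natural_envelope(
    composition: Mapping[str, int], truncation: float = 1e-5
) -> IsotopeEnvelope:
    """Natural isotopic distribution of a composition.

    Per-element isotope distributions are convolved in nominal-mass bins;
    each bin carries the abundance-weighted mean mass of its isotopologues.
    Peaks below ``truncation`` of the maximum are dropped, then the envelope
    is renormalized.
    """
    if not 0 < truncation < 1:
        raise ValueError("truncation must be in (0, 1)")
    composition = ElementalComposition(composition)
    if not composition:
        return IsotopeEnvelope(
            np.array([0.0]), np.array([1.0]), normalized=True, degenerate=True
        )
    p, m = np.array([1.0]), np.array([0.0])
    for element in sorted(composition):
        ep, em = _element_distribution(element)
        ep, em = _repeat_convolve(ep, em, composition[element])
        p, m = _convolve(p, m, ep, em)
    keep = p >= truncation * p.max()
    p, m = p[keep], m[keep]
    return IsotopeEnvelope(m, p / p.sum(), normalized=True)


def apply_deuteration(
    envelope: IsotopeEnvelope, n_amides: int, p_incorp: float
) -> IsotopeEnvelope:
    """Convolve an envelope with Binomial(n_amides, p_incorp) deuterium uptake.

    Peaks land at multiples of the H->D mass difference; the centroid shifts
    by exactly ``n_amides * p_incorp * 1.00628`` Da.
    """
    if not 0 <= p_incorp <= 1:
        raise ValueError("p_incorp must be in [0, 1]")
    if n_amides < 0:
        raise ValueError("n_amides must be nonnegative")
    if n_amides == 0 or p_incorp == 0:
        return envelope
    k = np.arange(n_amides + 1)
    pmf = binom.pmf(k, n_amides, p_incorp)
    masses = (envelope.masses[:, None] + k[None, :] * DEUTERIUM_MASS_SHIFT).ravel()
    abundances = (envelope.abundances[:, None] * pmf[None, :]).ravel()
    keep = abundances > 1e-15 * abundances.max()
    merged_m, merged_a = _merge_peaks(masses[keep], abundances[keep])
    if envelope.normalized:
        merged_a = merged_a / merged_a.sum()
    return IsotopeEnvelope(
        merged_m, merged_a, normalized=envelope.normalized,
        degenerate=envelope.degenerate,
    )


def mix_envelopes(
    folded: IsotopeEnvelope, unfolded: IsotopeEnvelope, w_unfolded: float
) -> IsotopeEnvelope:
    """Pointwise mixture (1-w)*folded + w*unfolded of two normalized envelopes."""
    if not 0 <= w_unfolded <= 1:
        raise ValueError("w_unfolded must be in [0, 1]")
    if not (folded.normalized and unfolded.normalized):
        raise ValueError("both envelopes must be normalized")
    if w_unfolded == 0:
        return folded
    if w_unfolded == 1:
        return unfolded
    masses = np.concatenate([folded.masses, unfolded.masses])
    abundances = np.concatenate(
        [(1 - w_unfolded) * folded.abundances, w_unfolded * unfolded.abundances]
    )
    # Cross-envelope peaks within a fraction of the inputs' own stick spacing
    # are the same isotopologue bin and merge; capping the tolerance at half
    # the smallest intra-envelope gap guarantees the merge can never collapse
    # structure that either input resolves.
    def _min_gap(env: IsotopeEnvelope) -> float:
        return float(np.diff(env.masses).min()) if env.n_peaks > 1 else np.inf

    tol = min(MERGE_TOLERANCE, 0.49 * min(_min_gap(folded), _min_gap(unfolded)))
    merged_m, merged_a = _merge_peaks(masses, abundances, tol=tol)
    return IsotopeEnvelope(merged_m, merged_a / merged_a.sum(), normalized=True)


def centroid_mass(envelope: IsotopeEnvelope) -> float:
    """Abundance-weighted mean mass (Da)."""
    if envelope.n_peaks == 0:
        raise ValueError("cannot take the centroid of an empty envelope")
    total = float(envelope.abundances.sum())
    if total <= 0:
        raise ValueError("envelope has zero total abundance")
    return float(np.dot(envelope.masses, envelope.abundances) / total)


def envelope_variance(envelope: IsotopeEnvelope) -> float:
    """Second central moment of the envelope about its centroid (Da^2)."""
    centroid = centroid_mass(envelope)
    weights = envelope.abundances / envelope.abundances.sum()
    return float(np.dot(weights, (envelope.masses - centroid) ** 2))


def to_mz(envelope: IsotopeEnvelope, charge: int) -> IsotopeEnvelope:
    """View the envelope on the m/z axis for a given positive charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mz = (envelope.masses + charge * PROTON_MASS) / charge
    return IsotopeEnvelope(
        mz, envelope.abundances, normalized=envelope.normalized,
        degenerate=envelope.degenerate,
    )


def from_mz(envelope: IsotopeEnvelope, charge: int) -> IsotopeEnvelope:
    """Inverse of :func:`to_mz`: recover the neutral-mass envelope."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    masses = envelope.masses * charge - charge * PROTON_MASS
    return IsotopeEnvelope(
        masses, envelope.abundances, normalized=envelope.normalized,
        degenerate=envelope.degenerate,
    )


def write_envelope(envelope: IsotopeEnvelope, path) -> None:
    """Serialize as two-column delimited text with a header line."""
    with open(path, "w") as handle:
        handle.write("mass_da,abundance\n")
        for mass, abundance in zip(envelope.masses, envelope.abundances):
            handle.write(f"{float(mass)!r},{float(abundance)!r}\n")


def read_envelope(path, normalized: bool | None = None) -> IsotopeEnvelope:
    """Read a two-column (mass_da, abundance) envelope file."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        raise ValueError(f"empty envelope file: {path}")
    masses, abundances = data[:, 0], data[:, 1]
    if normalized is None:
        normalized = abs(float(abundances.sum()) - 1.0) <= 1e-6
    return IsotopeEnvelope(masses, abundances, normalized=normalized)
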