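"""Monoisotopic peptide mass arithmetic and TMT six-plex constants.

Residue masses are the standard monoisotopic values for the 20 amino acids.
Static labelling follows the six-plex TMT workflow: the tag (+229.1629 Da)
sits on every peptide N-terminus and every lysine side chain, and cysteines
carry carbamidomethyl (+57.02146 Da) from alkylation. Methionine oxidation
(+15.9949 Da) is the one variable modification considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

# standard monoisotopic residue (i.e. amino acid - water) masses, Da
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AMINO_ACIDS = "".join(sorted(RESIDUE_MASS))

WATER = 18.0105646863
PROTON = 1.00727646688

TMT_DELTA = 229.1629          # six-plex TMT tag, N-terminus and lysine
CARBAMIDOMETHYL_DELTA = 57.02146
OXIDATION_DELTA = 15.9949

#: canonical six-plex reporter-ion m/z values, keyed by nominal channel label
REPORTER_MZ: dict[int, float] = {
    126: 126.12773,
    127: 127.13108,
    128: 128.13443,
    129: 129.13779,
    130: 130.14114,
    131: 131.13818,
}

CHANNELS: tuple[int, ...] = tuple(REPORTER_MZ)


@dataclass(frozen=True)
class ModificationSpec:
    """A mass modification: static mods hit every eligible site, variable
    mods are enumerated in both states by the search-space builder."""

    name: str
    target: str          # "nterm" or a single residue letter
    delta_mass: float    # Da, monoisotopic
    mode: str            # "static" | "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("static", "variable"):
            raise ValueError(f"unknown modification mode: {self.mode!r}")
        if self.target != "nterm" and self.target not in RESIDUE_MASS:
            raise ValueError(f"unknown modification target: {self.target!r}")


TMT_NTERM = ModificationSpec("TMT6plex", "nterm", TMT_DELTA, "static")
TMT_K = ModificationSpec("TMT6plex", "K", TMT_DELTA, "static")
CARBAMIDOMETHYL_C = ModificationSpec("Carbamidomethyl", "C", CARBAMIDOMETHYL_DELTA, "static")
OXIDATION_M = ModificationSpec("Oxidation", "M", OXIDATION_DELTA, "variable")

STATIC_MODS: tuple[ModificationSpec, ...] = (TMT_NTERM, TMT_K, CARBAMIDOMETHYL_C)
VARIABLE_MODS: tuple[ModificationSpec, ...] = (OXIDATION_M,)


def validate_sequence(sequence: str) -> None:
    """Raise ValueError naming the first residue outside the 20-letter alphabet."""
    if not sequence:
        raise ValueError("empty peptide/protein sequence")
    for ch in sequence:
        if ch not in RESIDUE_MASS:
            raise ValueError(f"invalid residue {ch!r} in sequence")


def peptide_mass(sequence: str,
                 modifications: Iterable[tuple[object, ModificationSpec]] = ()) -> float:
    """Monoisotopic mass of a peptide with explicit (site, modification) pairs.

    ``site`` is either the string ``"nterm"`` or a 0-based residue index; an
    index whose residue does not match the modification target is an error.
    Mass is additive: sum of residue masses + water + sum of mod deltas.
    """
    validate_sequence(sequence)
    mass = sum(RESIDUE_MASS[ch] for ch in sequence) + WATER
    for site, mod in modifications:
        if site == "nterm":
            if mod.target != "nterm":
                raise ValueError(f"{mod.name} does not target the N-terminus")
        else:
            idx = int(site)  # type: ignore[arg-type]
            if not 0 <= idx < len(sequence):
                raise ValueError(f"modification site {idx} outside peptide")
            if sequence[idx] != mod.target:
                raise ValueError(
                    f"{mod.name} targets {mod.target!r} but residue {idx} is "
                    f"{sequence[idx]!r}")
        mass += mod.delta_mass
    return mass


def static_modified_mass(sequence: str, n_oxidations: int = 0) -> float:
    """Mass under the workflow's static mods (TMT N-term + K, CAM-C) plus
    ``n_oxidations`` methionine oxidations."""
    validate_sequence(sequence)
    if n_oxidations > sequence.count("M"):
        raise ValueError("more oxidations than methionines")
    mass = sum(RESIDUE_MASS[ch] for ch in sequence) + WATER + TMT_DELTA
    mass += TMT_DELTA * sequence.count("K")
    mass += CARBAMIDOMETHYL_DELTA * sequence.count("C")
    mass += OXIDATION_DELTA * n_oxidations
    return mass


def mz_from_mass(mono_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mono_mass + charge * PROTON) / charge


def residue_masses_with_mods(sequence: str,
                             oxidized_sites: Sequence[int] = ()) -> np.ndarray:
    """Per-residue mass array including static mods (TMT on K, CAM on C) and
    oxidation at the given methionine indices. The N-terminal TMT is NOT
    folded in here; fragment builders add it to the b-ion series."""
    masses = np.array([RESIDUE_MASS[ch] for ch in sequence], dtype=float)
    for i, ch in enumerate(sequence):
        if ch == "K":
            masses[i] += TMT_DELTA
        elif ch == "C":
            masses[i] += CARBAMIDOMETHYL_DELTA
    for i in oxidized_sites:
        if sequence[i] != "M":
            raise ValueError(f"oxidation site {i} is not methionine")
        masses[i] += OXIDATION_DELTA
    return masses


def fragment_mz(sequence: str, oxidized_sites: Sequence[int] = ()) -> np.ndarray:
    """Singly charged b- and y-ion m/z values for a TMT-labelled peptide.

    Returns the 2*(n-1) internal fragment ions, sorted ascending. A length-1
    peptide has no internal fragments and yields an empty array.
    """
    n = len(sequence)
    if n < 2:
        return np.empty(0, dtype=float)
    res = residue_masses_with_mods(sequence, oxidized_sites)
    prefix = np.cumsum(res)
    # b_i = TMT(nterm) + sum(res[:i]) + proton, i = 1..n-1
    b = TMT_DELTA + prefix[:-1] + PROTON
    # y_i = sum(res[n-i:]) + water + proton, i = 1..n-1
    suffix = prefix[-1] - prefix[:-1]
    y = suffix + WATER + PROTON
    return np.sort(np.concatenate([b, y]))


def ppm_error(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical
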