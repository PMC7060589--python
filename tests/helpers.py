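"""Independent oracles and small builders shared across test modules."""

from __future__ import annotations

import numpy as np

from tmtquant.digest_search import PSM, PeptideCandidate
from tmtquant.io import Spectrum
from tmtquant import chemistry as chem


def brute_force_digest(sequence: str, max_missed_cleavages: int) -> set[str]:
    """Enumerate every substring and keep the valid tryptic peptides.

    A substring is a tryptic peptide when it starts at the protein
    N-terminus or right after a cleavage site, ends at the C-terminus or at
    a cleavage site, and contains at most ``max_missed_cleavages`` internal
    cleavage sites. A cleavage site sits after K/R not followed by P. This
    deliberately re-derives the rule from scratch rather than reusing the
    implementation's segment logic.
    """
    n = len(sequence)

    def is_site(i: int) -> bool:  # cut between residue i-1 and i
        return 0 < i < n and sequence[i - 1] in "KR" and sequence[i] != "P"

    peptides = set()
    for a in range(n):
        if not (a == 0 or is_site(a)):
            continue
        for b in range(a + 1, n + 1):
            if not (b == n or is_site(b)):
                continue
            internal = sum(1 for i in range(a + 1, b) if is_site(i))
            if internal <= max_missed_cleavages:
                peptides.add(sequence[a:b])
    return peptides


def make_candidate(sequence: str, accessions=("P1",), oxidized=()) -> PeptideCandidate:
    return PeptideCandidate(
        sequence=sequence, accessions=tuple(accessions), missed_cleavages=0,
        oxidized_sites=tuple(oxidized),
        mono_mass=chem.static_modified_mass(sequence, len(oxidized)))


def make_psm(scan: int, score: float, decoy: bool = False,
             sequence: str = "ELVISK", accession: str | None = None,
             reporters=None) -> PSM:
    acc = accession or ("REV_P1" if decoy else "P1")
    cand = PeptideCandidate(
        sequence=sequence, accessions=(acc,), missed_cleavages=0,
        oxidized_sites=(), mono_mass=chem.static_modified_mass(sequence))
    psm = PSM(scan_number=scan, peptide=cand, score=score,
              precursor_error_ppm=0.0, charge=2)
    if reporters is not None:
        psm.reporter_intensities = np.asarray(reporters, dtype=float)
    return psm


def make_spectrum(scan: int, mode: str, precursor_mz: float,
                  peaks, charge: int = 2) -> Spectrum:
    return Spectrum(scan_number=scan, mode=mode, precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    peaks=np.asarray(peaks, dtype=float).reshape(-1, 2))


def spectrum_from_peptide(sequence: str, charge: int = 2, scan: int = 1,
                          which: str = "by") -> Spectrum:
    """CID spectrum containing the peptide's own fragment ladder (or just
    the b- or y-ion half)."""
    res = chem.residue_masses_with_mods(sequence)
    prefix = np.cumsum(res)
    b = chem.TMT_DELTA + prefix[:-1] + chem.PROTON
    y = (prefix[-1] - prefix[:-1]) + chem.WATER + chem.PROTON
    ions = {"by": np.concatenate([b, y]), "b": b, "y": y}[which]
    ions = np.sort(ions)
    mass = chem.static_modified_mass(sequence)
    return make_spectrum(scan, "CID", chem.mz_from_mass(mass, charge),
                         np.column_stack([ions, np.ones_like(ions)]), charge)
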