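"""Spectrum container plus MGF and FASTA input/output.

The MGF dialect written and read here is the plain Mascot generic format:
``BEGIN IONS`` / ``TITLE=... scan=N mode=CID|HCD`` / ``PEPMASS=<mz>`` /
``CHARGE=<z>+`` followed by ``m/z intensity`` peak lines. The fragmentation
mode and scan number are carried in the TITLE, which is how paired CID/HCD
scan streams are reconstructed downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Spectrum:
    """One fragmentation scan (CID or HCD) with its peak list."""

    scan_number: int
    mode: str                 # "CID" | "HCD"
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray         # shape (n, 2): m/z ascending, intensity >= 0
    title: str = ""

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.shape[0] and np.any(np.diff(self.peaks[:, 0]) < 0):
            self.peaks = self.peaks[np.argsort(self.peaks[:, 0], kind="stable")]
        if self.mode not in ("CID", "HCD"):
            raise ValueError(f"unknown scan mode {self.mode!r}")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


_SCAN_RE = re.compile(r"scan=(\d+)")
_MODE_RE = re.compile(r"mode=(CID|HCD)")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into Spectrum objects, in file order."""
    spectra: list[Spectrum] = []
    title = ""
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []
    in_block = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, title, pepmass, charge, peaks = True, "", None, None, []
            elif line == "END IONS":
                if pepmass is None or charge is None:
                    raise ValueError(f"scan block missing PEPMASS/CHARGE in {path}")
                scan_m = _SCAN_RE.search(title)
                mode_m = _MODE_RE.search(title)
                if not scan_m or not mode_m:
                    raise ValueError(f"TITLE must carry scan= and mode=: {title!r}")
                spectra.append(Spectrum(
                    scan_number=int(scan_m.group(1)),
                    mode=mode_m.group(1),
                    precursor_mz=pepmass,
                    precursor_charge=charge,
                    peaks=np.array(peaks, dtype=float).reshape(-1, 2),
                    title=title,
                ))
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[len("TITLE="):]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[len("PEPMASS="):].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[len("CHARGE="):].rstrip("+"))
                elif "=" not in line:
                    mz_s, int_s = line.split()[:2]
                    peaks.append((float(mz_s), float(int_s)))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            title = sp.title or f"scan={sp.scan_number} mode={sp.mode}"
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.4f}\n")
            fh.write("END IONS\n")


@dataclass
class ProteinRecord:
    """One protein in the target+decoy search space."""

    accession: str
    description: str
    sequence: str
    is_decoy: bool = False


DECOY_PREFIX = "REV_"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(
            accession=rec.id,
            description=desc,
            sequence=seq,
            is_decoy=rec.id.startswith(DECOY_PREFIX),
        ))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.description)
        for p in proteins
    ]
    # 60-column wrapping is SeqIO's fasta default
    SeqIO.write(recs, str(path), "fasta")


def iter_scan_pairs_stream(spectra: list[Spectrum]) -> Iterator[Spectrum]:
    """Spectra sorted by scan number (stable for equal numbers)."""
    return iter(sorted(spectra, key=lambda s: s.scan_number))
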