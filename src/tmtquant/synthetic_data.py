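"""Synthetic proteomes, ground-truth designs and paired CID/HCD spectra.

The generator emulates the statistical structure the quantification
pipeline assumes, with known ground truth so every downstream stage can be
tested without any real data:

* proteins are built from tryptic "blocks" (5-18 residues without K/R,
  terminated by K or R, never followed by proline), so every protein has at
  least four cleavage sites and its zero-missed-cleavage digest is exactly
  the block list — each block's TMT-labelled mass falls in [600, 4000] Da
  by construction;
* a configurable fraction of proteins carries true group effects of
  magnitude ``effect_log2`` (half up, half down) for IR vs sham, and a
  fraction of those additionally for TALE vs IR;
* every selected peptide yields one CID scan (clean singly charged b/y
  ladder, no reporters) followed by an HCD scan on the same precursor
  carrying the six reporter peaks, whose intensities are
  base x group multiplier x duplicate factor x lognormal noise;
* a chosen fraction of proteins gets one duplicate channel scaled by 1.5 so
  their duplicate-label variation (0.4 at zero noise) trips the 30% QC rule;
* independent replicate sets share the ground truth but re-draw all noise
  from set-specific sub-seeds; every draw is fixed by ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chemistry as chem
from .digest_search import digest_protein
from .io import ProteinRecord, Spectrum, write_fasta, write_mgf
from .quantify import GROUPS, ChannelDesign

# residues allowed inside a tryptic block (no K/R so cleavage sites are
# exactly the block ends; no P at block start so no suppressed cleavage)
_BLOCK_ALPHABET = [aa for aa in chem.AMINO_ACIDS if aa not in "KR"]
_BLOCK_START_ALPHABET = [aa for aa in _BLOCK_ALPHABET if aa != "P"]

QC_FAILURE_SCALE = 1.5   # rep-2 channel scale => duplicate variation 0.4


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 100
    frac_de_ir: float = 0.2
    frac_de_tale: float = 0.5     # fraction of the IR-affected proteins
    effect_log2: float = 1.0
    noise_sigma: float = 0.1      # lognormal sigma on each reporter intensity
    duplicate_sigma: float = 0.0  # extra lognormal sigma between duplicate labels
    n_sets: int = 2
    seed: int = 0
    qc_failure_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frac_de_ir", "frac_de_tale", "qc_failure_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.noise_sigma < 0 or self.duplicate_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.n_sets < 1:
            raise ValueError("need at least one replicate set")


@dataclass(frozen=True)
class GroundTruth:
    accession: str
    group_multipliers: tuple[float, float, float]   # (sham, IR, TALE), linear
    true_label_ir: str      # up | down | null, for IR vs sham
    true_label_tale: str    # up | down | null, for TALE vs IR

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.group_multipliers):
            raise ValueError("group multipliers must be strictly positive")
        if self.true_label_ir != _label(self.group_multipliers[1],
                                        self.group_multipliers[0]):
            raise ValueError("IR label inconsistent with multipliers")
        if self.true_label_tale != _label(self.group_multipliers[2],
                                          self.group_multipliers[1]):
            raise ValueError("TALE label inconsistent with multipliers")


def _label(num: float, den: float) -> str:
    lr = math.log2(num / den)
    if lr > 0:
        return "up"
    if lr < 0:
        return "down"
    return "null"


def _rng(config: SimulationConfig, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=spawn_key))


def generate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Random tryptic-block proteins, lengths in [50, 500], deterministic
    under the config seed."""
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be at least 1")
    rng = _rng(config, 0)
    proteins = []
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        n_blocks = int(rng.integers(5, 16))
        parts: list[str] = []
        total = 0
        b = 0
        while b < n_blocks or total < 50:
            body_len = int(rng.integers(5, 19))
            if total + body_len + 1 > 500:
                break
            body = "".join(rng.choice(_BLOCK_ALPHABET, size=body_len))
            head = str(rng.choice(_BLOCK_START_ALPHABET))
            block = head + body[1:] + str(rng.choice(["K", "R"]))
            parts.append(block)
            total += len(block)
            b += 1
        seq = "".join(parts)
        acc = f"SYN{i + 1:0{width}d}"
        proteins.append(ProteinRecord(accession=acc,
                                      description="synthetic protein",
                                      sequence=seq))
    return proteins


def assign_ground_truth(proteins: Sequence[ProteinRecord],
                        config: SimulationConfig) -> list[GroundTruth]:
    """Pick round(frac_de_ir * n) proteins for true IR effects (half up,
    half down, ties to up) and, among those, round(frac_de_tale * n_ir) for
    additional TALE effects; everything else is null."""
    n = len(proteins)
    rng = _rng(config, 1)
    n_ir = round(config.frac_de_ir * n)
    ir_idx = rng.choice(n, size=n_ir, replace=False)
    n_up = (n_ir + 1) // 2
    up_set = set(ir_idx[:n_up].tolist())
    ir_set = set(ir_idx.tolist())
    n_tale = round(config.frac_de_tale * n_ir)
    tale_idx = rng.choice(ir_idx, size=n_tale, replace=False) if n_tale else []
    tale_up_set = set(np.asarray(tale_idx)[: (n_tale + 1) // 2].tolist())
    tale_set = set(np.asarray(tale_idx).tolist())

    e = 2.0 ** config.effect_log2
    truths = []
    for i, prot in enumerate(proteins):
        sham = 1.0
        if i in ir_set:
            ir = sham * (e if i in up_set else 1.0 / e)
        else:
            ir = sham
        if i in tale_set:
            tale = ir * (e if i in tale_up_set else 1.0 / e)
        else:
            tale = ir
        truths.append(GroundTruth(
            accession=prot.accession,
            group_multipliers=(sham, ir, tale),
            true_label_ir=_label(ir, sham),
            true_label_tale=_label(tale, ir)))
    return truths


def selected_peptides(protein: ProteinRecord,
                      mass_range: tuple[float, float] = (600.0, 4000.0)
                      ) -> list[str]:
    """Zero-missed-cleavage peptides whose TMT-labelled mass is in range —
    the peptides the simulator turns into scan pairs."""
    out = []
    for pep, _start, _mc in digest_protein(protein.sequence, 0):
        m = chem.static_modified_mass(pep)
        if mass_range[0] <= m <= mass_range[1]:
            out.append(pep)
    return out


def simulate_spectra(proteins: Sequence[ProteinRecord],
                     truths: Sequence[GroundTruth],
                     design: ChannelDesign,
                     config: SimulationConfig) -> list[list[Spectrum]]:
    """Paired CID/HCD scan streams, one list per replicate set."""
    if not proteins:
        raise ValueError("cannot simulate spectra from an empty proteome")
    if len(proteins) != len(truths):
        raise ValueError("proteins and ground truths must align")

    # QC-failure proteins chosen once so both sets fail the same proteins
    qc_rng = _rng(config, 3)
    n_fail = round(config.qc_failure_frac * len(proteins))
    fail_idx = set(qc_rng.choice(len(proteins), size=n_fail,
                                 replace=False).tolist())
    fail_group = {i: GROUPS[int(qc_rng.integers(len(GROUPS)))]
                  for i in sorted(fail_idx)}

    mult = {t.accession: dict(zip(GROUPS, t.group_multipliers)) for t in truths}
    channel_info = [(ch, *design.mapping[ch]) for ch in chem.CHANNELS]

    sets: list[list[Spectrum]] = []
    for s in range(config.n_sets):
        rng = _rng(config, 2, s)
        scans: list[Spectrum] = []
        scan_no = 0
        for i, prot in enumerate(proteins):
            # systematic offset between a sample's two TMT labels
            dup = {g: math.exp(rng.normal(0.0, config.duplicate_sigma))
                   if config.duplicate_sigma > 0 else 1.0 for g in GROUPS}
            for pep in selected_peptides(prot):
                base = 10.0 ** rng.uniform(4.0, 6.0)
                mass = chem.static_modified_mass(pep)
                charge = 2 if mass <= 2400.0 else 3
                prec_mz = chem.mz_from_mass(mass, charge)
                ladder = chem.fragment_mz(pep)
                scan_no += 1
                scans.append(Spectrum(
                    scan_number=scan_no, mode="CID", precursor_mz=prec_mz,
                    precursor_charge=charge,
                    peaks=np.column_stack([ladder, np.ones_like(ladder)]),
                    title=f"scan={scan_no} mode=CID pep={pep}"))
                reporters = []
                for ch, group, rep in channel_info:
                    inten = base * mult[prot.accession][group]
                    if rep == 2:
                        inten *= dup[group]
                        if i in fail_idx and group == fail_group[i]:
                            inten *= QC_FAILURE_SCALE
                    if config.noise_sigma > 0:
                        inten *= math.exp(rng.normal(0.0, config.noise_sigma))
                    reporters.append((chem.REPORTER_MZ[ch], inten))
                scan_no += 1
                scans.append(Spectrum(
                    scan_number=scan_no, mode="HCD", precursor_mz=prec_mz,
                    precursor_charge=charge,
                    peaks=np.array(reporters),
                    title=f"scan={scan_no} mode=HCD pep={pep}"))
        sets.append(scans)
    return sets


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "accession": t.accession,
        "mult_sham": t.group_multipliers[0],
        "mult_ir": t.group_multipliers[1],
        "mult_tale": t.group_multipliers[2],
        "true_label_ir": t.true_label_ir,
        "true_label_tale": t.true_label_tale,
    } for t in truths])


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path,
                    design: ChannelDesign | None = None) -> dict[str, Path]:
    """Run the full generator and write FASTA, ground-truth TSV and one MGF
    per replicate set. Returns the paths written."""
    design = design or ChannelDesign()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = generate_proteome(config)
    truths = assign_ground_truth(proteins, config)
    sets = simulate_spectra(proteins, truths, design, config)
    paths = {"fasta": out / "proteome.fasta", "truth": out / "ground_truth.tsv"}
    write_fasta(proteins, paths["fasta"])
    truth_table(truths).to_csv(paths["truth"], sep="\t", index=False)
    for s, scans in enumerate(sets, start=1):
        p = out / f"set{s}.mgf"
        write_mgf(scans, p)
        paths[f"mgf_set{s}"] = p
    return paths
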