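"""Reporter-ion quantification from paired CID/HCD scans.

HCD scans carry the six-plex reporter ions; the immediately preceding CID
scan on the same precursor carries the sequence ions used for
identification. Quantification therefore pairs each HCD scan with its CID
partner, extracts the six reporter intensities from +/-20 ppm windows around
the canonical reporter m/z values, inserts them into the CID peak list, and
aggregates to protein level: arithmetic channel means across all
quantifiable spectra of a protein subgroup, a duplicate-label QC rule that
drops proteins whose two same-sample channels disagree by more than 30%,
and log2 group ratios (IR vs sham, TALE vs IR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemistry as chem
from .digest_search import PSM
from .io import Spectrum

log = logging.getLogger(__name__)

GROUPS = ("sham", "IR", "TALE")


@dataclass(frozen=True)
class ChannelDesign:
    """Mapping of reporter channel -> (group, duplicate index).

    The default is the study design: each biological sample is labelled
    twice, with 126/129 on sham, 127/130 on ischemia-reperfusion (IR) and
    128/131 on the dietary-fiber intervention (TALE).
    """

    mapping: Mapping[int, tuple[str, int]] = field(default_factory=lambda: {
        126: ("sham", 1), 129: ("sham", 2),
        127: ("IR", 1), 130: ("IR", 2),
        128: ("TALE", 1), 131: ("TALE", 2),
    })

    def __post_init__(self) -> None:
        if set(self.mapping) != set(chem.CHANNELS):
            raise ValueError("design must cover exactly channels 126..131")
        for g in GROUPS:
            reps = sorted(r for grp, r in self.mapping.values() if grp == g)
            if reps != [1, 2]:
                raise ValueError(f"group {g} must have exactly two duplicate channels")

    def channels_for(self, group: str) -> tuple[int, int]:
        chans = sorted(ch for ch, (g, _r) in self.mapping.items() if g == group)
        return chans[0], chans[1]


@dataclass(frozen=True)
class QuantConfig:
    reporter_window_ppm: float = 20.0
    duplicate_variation_max: float = 0.30
    reporter_mz: Mapping[int, float] = field(
        default_factory=lambda: dict(chem.REPORTER_MZ))

    def __post_init__(self) -> None:
        if self.reporter_window_ppm <= 0:
            raise ValueError("reporter window must be positive")
        if not 0 < self.duplicate_variation_max < 1:
            raise ValueError("variation threshold must lie in (0,1)")


@dataclass
class MergedSpectrum:
    cid_scan: int
    hcd_scan: int
    peaks: np.ndarray                   # CID peaks + inserted reporter peaks
    reporter_intensities: np.ndarray    # six-vector, NaN = missing


@dataclass
class ProteinQuant:
    accession: str
    n_spectra: int
    channel_means: np.ndarray           # six-vector in channel order 126..131
    group_means: np.ndarray             # (sham, IR, TALE)
    group_variation: np.ndarray         # duplicate-label variation per group
    qc_pass: bool
    qc_reason: str = ""
    log2_ir_vs_sham: float = math.nan
    log2_tale_vs_ir: float = math.nan


def pair_cid_hcd(scans: Sequence[Spectrum], mz_tol: float = 1e-4
                 ) -> tuple[list[tuple[Spectrum, Spectrum]], list[Spectrum]]:
    """Pair each HCD scan with the nearest preceding unclaimed CID scan that
    shares its precursor m/z (within ``mz_tol`` Th) with no CID in between.

    Returns (pairs, unpaired scans). A second HCD claiming an already-paired
    CID is reported unpaired with a warning.
    """
    ordered = sorted(scans, key=lambda s: s.scan_number)
    pairs: list[tuple[Spectrum, Spectrum]] = []
    unpaired: list[Spectrum] = []
    last_cid: Spectrum | None = None
    last_cid_claimed = False
    for sp in ordered:
        if sp.mode == "CID":
            if last_cid is not None and not last_cid_claimed:
                unpaired.append(last_cid)
            last_cid, last_cid_claimed = sp, False
        else:  # HCD
            if (last_cid is not None
                    and abs(sp.precursor_mz - last_cid.precursor_mz) <= mz_tol):
                if last_cid_claimed:
                    log.warning("scan %d: CID %d already paired; keeping first",
                                sp.scan_number, last_cid.scan_number)
                    unpaired.append(sp)
                else:
                    pairs.append((last_cid, sp))
                    last_cid_claimed = True
            else:
                unpaired.append(sp)
    if last_cid is not None and not last_cid_claimed:
        unpaired.append(last_cid)
    return pairs, unpaired


def extract_reporters(hcd: Spectrum, config: QuantConfig = QuantConfig()
                      ) -> np.ndarray:
    """Six reporter intensities from ppm windows around the canonical m/z.

    Within each window the most intense peak wins; ties break by smaller
    absolute ppm error. A channel with no in-window peak is NaN.
    """
    if hcd.mode != "HCD":
        raise ValueError(f"scan {hcd.scan_number} is not an HCD scan")
    out = np.full(len(chem.CHANNELS), np.nan)
    mz, inten = hcd.mz, hcd.intensity
    t = config.reporter_window_ppm * 1e-6
    for i, ch in enumerate(chem.CHANNELS):
        target = config.reporter_mz[ch]
        lo = np.searchsorted(mz, target * (1 - t), side="left")
        hi = np.searchsorted(mz, target * (1 + t), side="right")
        if hi > lo:
            window = slice(lo, hi)
            cand_int = inten[window]
            cand_err = np.abs(mz[window] - target)
            # max intensity, then smallest |ppm error|
            best = min(range(hi - lo), key=lambda j: (-cand_int[j], cand_err[j]))
            out[i] = cand_int[best]
    return out


def merge_into_cid(pair: tuple[Spectrum, Spectrum],
                   reporters: np.ndarray,
                   config: QuantConfig = QuantConfig()) -> MergedSpectrum:
    """Insert the found reporter peaks (at canonical m/z) into the CID peak
    list, preserving every CID peak and m/z ordering."""
    cid, hcd = pair
    inserted = [(config.reporter_mz[ch], reporters[i])
                for i, ch in enumerate(chem.CHANNELS)
                if not math.isnan(reporters[i])]
    peaks = cid.peaks
    if inserted:
        peaks = np.vstack([cid.peaks, np.array(inserted, dtype=float)])
        peaks = peaks[np.argsort(peaks[:, 0], kind="stable")]
    return MergedSpectrum(cid_scan=cid.scan_number, hcd_scan=hcd.scan_number,
                          peaks=peaks, reporter_intensities=reporters)


def attach_reporters(psms: Iterable[PSM], spectra: Sequence[Spectrum],
                     config: QuantConfig = QuantConfig()) -> list[PSM]:
    """Fill each PSM's reporter vector from its CID scan's paired HCD scan."""
    pairs, _ = pair_cid_hcd(spectra)
    by_cid = {cid.scan_number: hcd for cid, hcd in pairs}
    out = []
    for p in psms:
        hcd = by_cid.get(p.scan_number)
        p.reporter_intensities = (extract_reporters(hcd, config)
                                  if hcd is not None
                                  else np.full(len(chem.CHANNELS), np.nan))
        out.append(p)
    return out


def aggregate_protein(accession: str, psms: Sequence[PSM],
                      design: ChannelDesign = ChannelDesign()
                      ) -> ProteinQuant | None:
    """Per-channel arithmetic means over the protein's quantifiable PSMs.

    A PSM missing any reporter channel is excluded from every channel so the
    six means stay comparable; a protein with no complete PSM is dropped.
    """
    vectors = [p.reporter_intensities for p in psms
               if p.reporter_intensities is not None
               and not np.any(np.isnan(p.reporter_intensities))]
    if not vectors:
        log.info("protein %s dropped: no PSM with a complete reporter vector",
                 accession)
        return None
    mat = np.vstack(vectors)
    channel_means = mat.mean(axis=0)
    group_means = np.empty(len(GROUPS))
    for gi, g in enumerate(GROUPS):
        a, b = design.channels_for(g)
        ia, ib = chem.CHANNELS.index(a), chem.CHANNELS.index(b)
        group_means[gi] = 0.5 * (channel_means[ia] + channel_means[ib])
    return ProteinQuant(
        accession=accession, n_spectra=mat.shape[0],
        channel_means=channel_means, group_means=group_means,
        group_variation=np.full(len(GROUPS), np.nan), qc_pass=False)


def duplicate_variation(a: float, b: float) -> float:
    """|a - b| over the pair mean; NaN when both intensities are zero."""
    m = 0.5 * (a + b)
    if m == 0:
        return math.nan
    return abs(a - b) / m


def duplicate_qc(pq: ProteinQuant, design: ChannelDesign = ChannelDesign(),
                 config: QuantConfig = QuantConfig()) -> ProteinQuant:
    """Exclude the protein if any group's duplicate-label variation exceeds
    the 30% threshold (or is undefined)."""
    variation = np.empty(len(GROUPS))
    for gi, g in enumerate(GROUPS):
        a, b = design.channels_for(g)
        ia, ib = chem.CHANNELS.index(a), chem.CHANNELS.index(b)
        variation[gi] = duplicate_variation(pq.channel_means[ia],
                                            pq.channel_means[ib])
    pq.group_variation = variation
    if np.any(np.isnan(variation)):
        pq.qc_pass, pq.qc_reason = False, "zero-intensity duplicate pair"
    elif np.any(variation > config.duplicate_variation_max):
        worst = GROUPS[int(np.nanargmax(variation))]
        pq.qc_pass = False
        pq.qc_reason = (f"duplicate variation {variation.max():.3f} > "
                        f"{config.duplicate_variation_max:g} in {worst}")
    else:
        pq.qc_pass, pq.qc_reason = True, ""
    return pq


def compute_ratios(pq: ProteinQuant) -> ProteinQuant:
    """log2(IR/sham) and log2(TALE/IR) from group means; requires QC pass
    and strictly positive denominators."""
    sham, ir, tale = pq.group_means
    if not pq.qc_pass:
        return pq
    if sham <= 0 or ir <= 0 or tale <= 0:
        pq.qc_pass, pq.qc_reason = False, "non-positive group mean"
        return pq
    pq.log2_ir_vs_sham = math.log2(ir / sham)
    pq.log2_tale_vs_ir = math.log2(tale / ir)
    return pq


def quantify_proteins(by_protein: Mapping[str, Sequence[PSM]],
                      spectra: Sequence[Spectrum],
                      design: ChannelDesign = ChannelDesign(),
                      config: QuantConfig = QuantConfig()) -> pd.DataFrame:
    """Full quantification stage: reporter attachment, aggregation, QC,
    ratios. Returns one row per protein (QC failures retained, flagged)."""
    all_psms = sorted({id(p): p for ps in by_protein.values() for p in ps}.values(),
                      key=lambda p: p.scan_number)
    attach_reporters(all_psms, spectra, config)
    rows = []
    for acc in sorted(by_protein):
        pq = aggregate_protein(acc, by_protein[acc], design)
        if pq is None:
            continue
        pq = compute_ratios(duplicate_qc(pq, design, config))
        row = {"accession": acc, "n_spectra": pq.n_spectra}
        for i, ch in enumerate(chem.CHANNELS):
            row[f"ch{ch}"] = pq.channel_means[i]
        for gi, g in enumerate(GROUPS):
            row[f"mean_{g}"] = pq.group_means[gi]
            row[f"var_{g}"] = pq.group_variation[gi]
        row.update(qc_pass=pq.qc_pass, qc_reason=pq.qc_reason,
                   log2_ir_vs_sham=pq.log2_ir_vs_sham,
                   log2_tale_vs_ir=pq.log2_tale_vs_ir)
        rows.append(row)
    cols = (["accession", "n_spectra"]
            + [f"ch{ch}" for ch in chem.CHANNELS]
            + [f"mean_{g}" for g in GROUPS] + [f"var_{g}" for g in GROUPS]
            + ["qc_pass", "qc_reason", "log2_ir_vs_sham", "log2_tale_vs_ir"])
    return pd.DataFrame(rows, columns=cols)
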