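"""Differential-expression calling from two independent MS replicate sets.

Only proteins quantified (and QC-passing) in both sets are considered;
their log2 contrasts are averaged across sets before thresholding. A
protein is called up/down for the IR-vs-sham contrast when its averaged
log2 ratio is strictly beyond +/-0.6 and it carries at least two accepted
spectra in each set; the TALE-vs-IR contrast is evaluated with the same
rule, but only among proteins already called in the IR contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NULL = "null"
CLASS_NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class DEConfig:
    log2_threshold: float = 0.6      # strict inequality
    min_peptides: int = 2
    require_both_sets: bool = True

    def __post_init__(self) -> None:
        if self.log2_threshold <= 0:
            raise ValueError("log2 threshold must be positive")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


def intersect_sets(quant_set1: pd.DataFrame, quant_set2: pd.DataFrame
                   ) -> pd.DataFrame:
    """Proteins present and QC-passing in both sets, with contrasts averaged
    and evidence taken as the smaller spectrum count across sets."""
    cols = ["accession", "n_spectra", "log2_ir_vs_sham", "log2_tale_vs_ir", "qc_pass"]
    s1 = quant_set1[cols]
    s2 = quant_set2[cols]
    s1 = s1[s1["qc_pass"].astype(bool)]
    s2 = s2[s2["qc_pass"].astype(bool)]
    merged = s1.merge(s2, on="accession", suffixes=("_1", "_2"))
    if merged.empty:
        log.warning("empty intersection between the two replicate sets")
    out = pd.DataFrame({
        "accession": merged["accession"],
        "mean_log2_ir_vs_sham": 0.5 * (merged["log2_ir_vs_sham_1"]
                                       + merged["log2_ir_vs_sham_2"]),
        "mean_log2_tale_vs_ir": 0.5 * (merged["log2_tale_vs_ir_1"]
                                       + merged["log2_tale_vs_ir_2"]),
        "n_spectra_min": np.minimum(merged["n_spectra_1"], merged["n_spectra_2"]),
    })
    return out.sort_values("accession", ignore_index=True)


def _classify(log2: np.ndarray, evidence_ok: np.ndarray, threshold: float
              ) -> np.ndarray:
    cls = np.full(log2.shape, CLASS_NULL, dtype=object)
    cls[evidence_ok & (log2 > threshold)] = CLASS_UP
    cls[evidence_ok & (log2 < -threshold)] = CLASS_DOWN
    return cls


def call_ir_related(common: pd.DataFrame, config: DEConfig = DEConfig()
                    ) -> pd.DataFrame:
    """Classify the IR-vs-sham contrast: up / down / null."""
    out = common.copy()
    ok = out["n_spectra_min"].to_numpy() >= config.min_peptides
    out["class_ir"] = _classify(out["mean_log2_ir_vs_sham"].to_numpy(),
                                ok, config.log2_threshold)
    return out


def call_tale_affected(calls: pd.DataFrame, config: DEConfig = DEConfig()
                       ) -> pd.DataFrame:
    """Classify TALE-vs-IR among IR-related proteins only; everything else
    is marked not_evaluated."""
    out = calls.copy()
    ok = out["n_spectra_min"].to_numpy() >= config.min_peptides
    cls = _classify(out["mean_log2_tale_vs_ir"].to_numpy(),
                    ok, config.log2_threshold)
    cls[(out["class_ir"] == CLASS_NULL).to_numpy()] = CLASS_NOT_EVALUATED
    out["class_tale"] = cls
    return out


def summarize_counts(calls: pd.DataFrame) -> dict:
    """Count table mirroring the study's headline numbers: common proteins,
    IR-related up/down/total, TALE-affected up/down/total."""
    ir_up = int((calls.get("class_ir", pd.Series(dtype=object)) == CLASS_UP).sum())
    ir_down = int((calls.get("class_ir", pd.Series(dtype=object)) == CLASS_DOWN).sum())
    tale = calls.get("class_tale", pd.Series(dtype=object))
    tale_up = int((tale == CLASS_UP).sum())
    tale_down = int((tale == CLASS_DOWN).sum())
    return {
        "n_common_proteins": int(len(calls)),
        "ir_up": ir_up, "ir_down": ir_down, "ir_total": ir_up + ir_down,
        "tale_up": tale_up, "tale_down": tale_down,
        "tale_total": tale_up + tale_down,
        "tale_threshold_note": ("TALE contrast uses the same +/-0.6 strict "
                                "threshold and >=2-spectra rule as the IR "
                                "contrast"),
    }


def differential_analysis(quant_set1: pd.DataFrame, quant_set2: pd.DataFrame,
                          config: DEConfig = DEConfig()
                          ) -> tuple[pd.DataFrame, dict]:
    common = intersect_sets(quant_set1, quant_set2)
    calls = call_tale_affected(call_ir_related(common, config), config)
    return calls, summarize_counts(calls)
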