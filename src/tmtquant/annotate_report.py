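"""Category summaries for DE protein lists and end-to-end orchestration.

Ontology annotations come from a user-supplied TSV snapshot
(accession / ontology / term) rather than a live database query, so the
category percentages are reproducible against a fixed file. Percentages
are shares of classified term hits within one ontology: a protein mapping
to k terms contributes k hits, and proteins without any annotation are
reported separately as unannotated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .differential import CLASS_DOWN, CLASS_UP, DEConfig, differential_analysis
from .digest_search import (SearchConfig, proteins_to_table, psms_to_table,
                            search_mgf)
from .io import read_fasta, read_mgf
from .quantify import ChannelDesign, QuantConfig, quantify_proteins
from .synthetic_data import (SimulationConfig, assign_ground_truth,
                             generate_proteome, simulate_spectra,
                             simulate_to_dir)

log = logging.getLogger(__name__)

ONTOLOGIES = ("molecular_function", "biological_process", "cellular_component")


def load_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "ontology", "term"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad = set(ann["ontology"]) - set(ONTOLOGIES)
    if bad:
        raise ValueError(f"unknown ontologies in annotation table: {sorted(bad)}")
    return ann


def summarize_categories(proteins: Sequence[str], annotations: pd.DataFrame,
                         ontology: str) -> tuple[pd.DataFrame, list[str]]:
    """(term, count, percent) table for one ontology plus the unannotated
    accessions. Percent base = total term hits in the list, not proteins."""
    if ontology not in ONTOLOGIES:
        raise ValueError(f"unknown ontology {ontology!r}")
    prots = list(proteins)
    sub = annotations[(annotations["ontology"] == ontology)
                      & annotations["accession"].isin(prots)]
    annotated = set(sub["accession"])
    unannotated = sorted(p for p in prots if p not in annotated)
    counts = (sub.groupby("term").size().rename("count").reset_index()
              .sort_values(["count", "term"], ascending=[False, True],
                           ignore_index=True))
    total = counts["count"].sum()
    counts["percent"] = 100.0 * counts["count"] / total if total else 0.0
    return counts, unannotated


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs; hashable into a manifest."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    de: DEConfig = field(default_factory=DEConfig)
    annotations_path: str | None = None
    out_dir: str = "tmtquant_run"


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["quant"]["reporter_mz"] = {str(k): v
                                 for k, v in d["quant"]["reporter_mz"].items()}
    d["search"]["charges"] = list(d["search"]["charges"])
    d.pop("out_dir")  # the output location does not define the computation
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> search -> quantify (per set) -> DE call -> annotate.

    Writes all stage tables plus a manifest (config hash, seed, version,
    stage record counts) under ``config.out_dir`` and returns the manifest.
    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = ChannelDesign()
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        proteins = generate_proteome(config.sim)
        truths = assign_ground_truth(proteins, config.sim)
        sets = simulate_spectra(proteins, truths, design, config.sim)
        simulate_to_dir(config.sim, out)  # persist FASTA/truth/MGF inputs
        counts["proteins_simulated"] = len(proteins)
        counts["scans_per_set"] = len(sets[0])
        log.info("simulate: %d proteins, %d scans/set (%.1fs)",
                 len(proteins), len(sets[0]), time.perf_counter() - t0)

        quant_tables = []
        for s, scans in enumerate(sets, start=1):
            stage = f"search set {s}"
            t0 = time.perf_counter()
            accepted, by_protein = search_mgf(proteins, scans, config.search)
            psms_to_table(accepted).to_csv(out / f"psms_set{s}.tsv",
                                           sep="\t", index=False)
            proteins_to_table(by_protein).to_csv(
                out / f"proteins_set{s}.tsv", sep="\t", index=False)
            counts[f"accepted_psms_set{s}"] = len(accepted)
            counts[f"accepted_proteins_set{s}"] = len(by_protein)
            log.info("%s: %d PSMs, %d proteins (%.1fs)", stage,
                     len(accepted), len(by_protein), time.perf_counter() - t0)

            stage = f"quantify set {s}"
            qt = quantify_proteins(by_protein, scans, design, config.quant)
            qt.to_csv(out / f"quant_set{s}.tsv", sep="\t", index=False)
            counts[f"quantified_proteins_set{s}"] = int(len(qt))
            counts[f"qc_pass_proteins_set{s}"] = int(qt["qc_pass"].sum())
            quant_tables.append(qt)

        stage = "differential"
        if len(quant_tables) < 2:
            raise ValueError("differential calling needs two replicate sets")
        calls, summary = differential_analysis(quant_tables[0],
                                               quant_tables[1], config.de)
        calls.to_csv(out / "de_table.tsv", sep="\t", index=False)
        (out / "de_summary.json").write_text(json.dumps(summary, indent=2))
        counts["common_proteins"] = summary["n_common_proteins"]
        counts["ir_related"] = summary["ir_total"]
        counts["tale_affected"] = summary["tale_total"]

        if config.annotations_path:
            stage = "annotate"
            ann = load_annotations(config.annotations_path)
            for direction, cls in (("up", CLASS_UP), ("down", CLASS_DOWN)):
                accs = calls.loc[calls["class_ir"] == cls, "accession"]
                for ont in ONTOLOGIES:
                    table, unann = summarize_categories(list(accs), ann, ont)
                    path = out / f"categories_ir_{direction}_{ont}.tsv"
                    with open(path, "w") as fh:
                        fh.write("# percent = 100 * term hits / total term "
                                 "hits in this ontology for this list; "
                                 f"unannotated proteins: {len(unann)}\n")
                        table.to_csv(fh, sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg = _config_dict(config)
    manifest = {
        "version": __version__,
        "seed": config.sim.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
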