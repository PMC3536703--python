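"""End-to-end pipeline: simulate -> call splicing -> expression -> motifs.

``run_pipeline`` wires the stages in the analysis order of a
splicing-sensitive microarray study: event calling and classification,
gene-level differential expression, then motif analysis of the classified
exon sets (word enrichment and the positional RNA map of the configured
motif, by default the Rbfox element TGCATG).  All stage outputs are TSV
with a header and stable column order; a JSON manifest records the
resolved parameters and the SHA-256 of every artifact.  Every source of
randomness flows from the single configured seed, so a rerun with the same
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import diffexpr, io, motifmap, splicecall
from .synthdata import SimulationConfig, gen_exon_sequences, gen_probe_dataset, sample_columns

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of a full pipeline run.

    Stage parameters mirror the module defaults; unknown keys in a YAML
    config are rejected.  ``seed`` governs every random draw.
    """

    outdir: str = "sepmap_run"
    seed: int = 0
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_sepscore: float = splicecall.SEPSCORE_THRESHOLD
    bg_q: float = splicecall.BACKGROUND_Q
    min_fold: float = diffexpr.FOLD_THRESHOLD
    max_q: float = diffexpr.Q_THRESHOLD
    motif: str = "TGCATG"
    span: int = motifmap.DEFAULT_SPAN
    width: int = motifmap.DEFAULT_WIDTH
    step: int = motifmap.DEFAULT_STEP
    n_samplings: int = motifmap.DEFAULT_N_SAMPLINGS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        sim = kwargs.pop("simulation", {})
        if isinstance(sim, SimulationConfig):
            sim_cfg = sim
        else:
            sim = dict(sim)
            for key in ("plant_window", "background_base_composition"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            try:
                sim_cfg = SimulationConfig(**sim)
            except TypeError as exc:
                raise ValueError(f"bad simulation configuration: {exc}") from exc
        return cls(simulation=sim_cfg, **kwargs)

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run simulate -> splice -> expr -> motifmap and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): resolved
    parameters, per-stage summaries and output hashes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("resolved configuration: %s", json.dumps(config.resolved(), sort_keys=True))

    sim = replace(config.simulation, seed=config.seed)
    stages: list[dict[str, Any]] = []

    # Stage 1: simulate probe data and matched exon sequences.
    table, truth = gen_probe_dataset(sim)
    tg_cols, wt_cols = sample_columns(sim)
    io.write_probe_table(table, outdir / "probe_table.tsv")

    # Sequences: exons of events whose true splicing shift is toward
    # skipping carry the planted motif in their downstream intron.
    neg_ids = list(truth.event_sepscore.index[truth.event_sepscore < 0])
    other_ids = list(truth.event_sepscore.index[truth.event_sepscore >= 0])
    records, seq_truth = gen_exon_sequences(
        sim,
        group_sizes={"test": len(neg_ids), "background": len(other_ids)},
        ids={"test": neg_ids, "background": other_ids},
    )
    truth.planted_motifs = seq_truth.planted_motifs
    io.write_exon_sequences(records, outdir / "sequences.fasta", outdir / "exons.bed")
    io.write_truth(truth, outdir)
    stages.append(
        {
            "stage": "simulate",
            "n_probes": int(len(table)),
            "n_events": int(truth.event_sepscore.size),
            "n_genes": int(truth.gene_log2fc.size),
        }
    )

    # Stage 2: Sepscore calling and classification.
    calls = splicecall.permutation_qvalues(table, tg_cols, wt_cols)
    calls["class_label"] = splicecall.classify_events(
        calls, min_sepscore=config.min_sepscore, bg_q=config.bg_q
    )
    events = calls.rename_axis("event_id").reset_index()
    events.insert(1, "event_type", "cassette")
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    n_called = int(len(splicecall.call_events(calls, config.min_sepscore)))
    stages.append(
        {
            "stage": "splice",
            "n_called": n_called,
            "class_counts": calls["class_label"].value_counts().to_dict(),
        }
    )

    # Stage 3: SAM-style differential expression.
    genes = diffexpr.differential_expression(
        table, tg_cols, wt_cols, min_fold=config.min_fold, max_q=config.max_q
    )
    genes.rename_axis("gene_id").reset_index().to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    stages.append({"stage": "expr", "n_selected": int(genes["selected"].sum())})

    # Stage 4: motif analysis on the classified exon sets.
    label_of = dict(zip(events["event_id"], events["class_label"]))
    by_class: dict[str, list] = {}
    for rec in records:
        by_class.setdefault(label_of.get(rec.exon_id, "unclassified"), []).append(rec)
    test_set = by_class.get("repressed", [])
    induced_set = by_class.get("induced", [])
    bg_set = by_class.get("background", [])
    motif_summary: dict[str, Any] = {
        "stage": "motifmap",
        "n_repressed": len(test_set),
        "n_induced": len(induced_set),
        "n_background": len(bg_set),
    }
    if test_set and bg_set:
        words = motifmap.word_enrichment(
            test_set, bg_set, window=(0, config.span)
        )
        words.to_csv(outdir / "words.tsv", sep="\t", index=False)

        rmap = motifmap.build_rna_map(
            test_set, config.motif, span=config.span, width=config.width, step=config.step
        )
        sizes = [len(test_set)]
        if induced_set:
            sizes.append(len(induced_set))
        sample_size = min(min(sizes), len(bg_set))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        rmap = motifmap.attach_envelope(
            rmap, bg_set, sample_size, n_samplings=config.n_samplings, rng=rng
        )
        rmap.to_frame().to_csv(outdir / "rna_map.tsv", sep="\t", index=False)
        runs = motifmap.detect_enriched_windows(rmap)
        motif_summary.update(
            {
                "top_word": words.iloc[0]["word"],
                "top_word_p": float(words.iloc[0]["p"]),
                "enriched_runs": [
                    {"interval": list(r.interval), "peak_window_start": r.peak_window_start}
                    for r in runs
                ],
                "sample_size": sample_size,
            }
        )
    else:
        logger.warning(
            "motif stage skipped: empty repressed (%d) or background (%d) set",
            len(test_set),
            len(bg_set),
        )
        motif_summary["skipped"] = True
    stages.append(motif_summary)

    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "parameters": config.resolved(),
        "stages": stages,
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
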