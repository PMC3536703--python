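"""Synthetic splicing-microarray datasets with known ground truth.

The generator emulates the statistical structure of a two-genotype
splicing-sensitive microarray study (transgenic ``TG`` vs wild-type ``WT``,
three biological replicates per group): probe-level intensities on a
log-normal scale, per-probe affinity offsets, i.i.d. replicate noise on the
log2 scale, planted splicing shifts on a subset of cassette events and
planted expression shifts on a subset of genes.  A companion generator
produces cassette-exon sequence sets with a motif planted at a controlled
offset inside the downstream intron, for exercising the word-enrichment and
RNA-map stages.

Planting a splicing change of magnitude s moves the event's inclusion
probes by +s/2 and its skip probes by -s/2 (log2) in the transgenic group,
so the true Sepscore equals s while the host gene's overall expression is
untouched.  Expression changes move constitutive probes only.  Every
simulated gene, event and exon has exactly one ground-truth entry, and a
given seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifmap import ExonSequenceRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "gen_probe_dataset",
    "gen_exon_sequences",
    "sample_columns",
    "GROUPS",
]

GROUPS = ("TG", "WT")
ROLES = ("inclusion", "skip", "constitutive")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """A simulation parameter is out of its valid range; names the field."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"invalid configuration field {fld!r}: {message}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study.

    Probe-count and noise defaults describe a splicing-sensitive array in
    which each cassette event is interrogated by exon-body plus junction
    probe sets (~16 probes per inclusion/skip role) with ~0.2 log2 units of
    replicate noise per measurement, and a planted separation of 0.6
    Sepscore units on 10% of events.  The sequence side plants one motif
    copy 70-90 nt into the downstream intron of half the "test" exons, the
    positional signature of an intronic splicing-enhancer map.
    """

    n_genes: int = 1000
    n_events: int = 1000
    n_replicates_per_group: int = 3
    probes_per_role: int = 16
    baseline_log2_mean: float = 8.0
    probe_sd: float = 0.5
    replicate_sd: float = 0.2
    frac_de_genes: float = 0.1
    de_log2fc: float = 1.5
    frac_changed_events: float = 0.1
    planted_sepscore: float = 0.6
    exon_len: int = 100
    intron_span: int = 150
    motif: str = "TGCATG"
    plant_window: tuple[int, int] = (70, 90)
    plant_prob: float = 0.5
    background_base_composition: tuple[float, float, float, float] = (
        0.25,
        0.25,
        0.25,
        0.25,
    )
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for fld in ("n_genes", "n_events", "probes_per_role", "exon_len"):
            if int(getattr(self, fld)) < 1:
                raise ConfigurationError(fld, "must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("n_replicates_per_group", "must be >= 2")
        for fld in ("probe_sd", "replicate_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(fld, "must be >= 0")
        for fld in ("frac_de_genes", "frac_changed_events", "plant_prob"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(fld, "must be a proportion in [0, 1]")
        motif = self.motif.upper()
        if not motif or set(motif) - set("ACGT"):
            raise ConfigurationError("motif", "must be a nonempty A/C/G/T word")
        if self.intron_span < len(motif):
            raise ConfigurationError("intron_span", "shorter than the motif")
        lo, hi = self.plant_window
        if not (0 <= lo <= hi <= self.intron_span - len(motif)):
            raise ConfigurationError(
                "plant_window",
                f"must lie within [0, {self.intron_span - len(motif)}] with start <= end",
            )
        comp = np.asarray(self.background_base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any():
            raise ConfigurationError(
                "background_base_composition", "needs 4 nonnegative proportions"
            )
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "background_base_composition", "must sum to 1 within 1e-9"
            )


@dataclass
class GroundTruth:
    """Planted effects: one entry per simulated gene, event and exon."""

    gene_log2fc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    event_sepscore: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    planted_motifs: dict[str, list[int]] = field(default_factory=dict)


def sample_columns(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Column names (TG replicates, WT replicates) of the intensity table."""
    n = config.n_replicates_per_group
    return (
        [f"TG_rep{i + 1}" for i in range(n)],
        [f"WT_rep{i + 1}" for i in range(n)],
    )


def gen_probe_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a probe x sample intensity table with known planted effects.

    Returns a DataFrame with annotation columns ``probe_id, gene_id,
    event_id, role`` followed by one positive linear-scale intensity column
    per sample, and the ground truth of planted log2 fold changes and
    Sepscores.  Events are assigned to genes round-robin; each event carries
    ``probes_per_role`` inclusion and skip probes, each gene the same number
    of constitutive probes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates_per_group
    ppr = config.probes_per_role
    tg_cols, wt_cols = sample_columns(config)
    samples = tg_cols + wt_cols

    gene_ids = np.array([f"gene_{i + 1:05d}" for i in range(config.n_genes)])
    event_ids = np.array([f"event_{i + 1:05d}" for i in range(config.n_events)])
    event_gene = gene_ids[np.arange(config.n_events) % config.n_genes]

    # Planted truth.
    n_de = int(round(config.frac_de_genes * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    gene_fc = np.zeros(config.n_genes)
    gene_fc[de_idx] = config.de_log2fc

    n_changed = int(round(config.frac_changed_events * config.n_events))
    ch_idx = rng.choice(config.n_events, size=n_changed, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_changed)
    event_s = np.zeros(config.n_events)
    event_s[ch_idx] = signs * config.planted_sepscore

    # Probe layout: per event, inclusion then skip block; per gene a
    # constitutive block.
    ev_rep = np.repeat(np.arange(config.n_events), 2 * ppr)
    ev_roles = np.tile(
        np.repeat(np.array(["inclusion", "skip"]), ppr), config.n_events
    )
    gene_rep = np.repeat(np.arange(config.n_genes), ppr)

    rows_event_gene = event_gene[ev_rep]
    rows_gene = np.concatenate([rows_event_gene, gene_ids[gene_rep]])
    rows_event = np.concatenate(
        [event_ids[ev_rep], np.full(config.n_genes * ppr, "", dtype=object)]
    )
    rows_role = np.concatenate([ev_roles, np.full(config.n_genes * ppr, "constitutive")])
    n_probes = rows_role.size
    probe_ids = np.array([f"probe_{i + 1:07d}" for i in range(n_probes)])

    # log2 signal = baseline + probe affinity + group effect + noise.
    affinity = rng.normal(0.0, config.probe_sd, size=n_probes)
    base = config.baseline_log2_mean + affinity

    tg_shift = np.zeros(n_probes)
    half = event_s[ev_rep] / 2.0
    tg_shift[: ev_rep.size] = np.where(ev_roles == "inclusion", half, -half)
    tg_shift[ev_rep.size :] = gene_fc[gene_rep]

    log2 = np.empty((n_probes, 2 * n_rep))
    noise = rng.normal(0.0, config.replicate_sd, size=(n_probes, 2 * n_rep))
    log2[:, :n_rep] = base[:, None] + tg_shift[:, None] + noise[:, :n_rep]
    log2[:, n_rep:] = base[:, None] + noise[:, n_rep:]

    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": rows_gene,
            "event_id": rows_event,
            "role": rows_role,
        }
    )
    table[samples] = 2.0 ** log2

    truth = GroundTruth(
        gene_log2fc=pd.Series(gene_fc, index=gene_ids, name="log2fc"),
        event_sepscore=pd.Series(event_s, index=event_ids, name="sepscore"),
    )
    return table, truth


def _random_bases(
    rng: np.random.Generator, n: int, length: int, composition: Sequence[float]
) -> np.ndarray:
    idx = rng.choice(4, size=(n, length), p=np.asarray(composition, dtype=float))
    return _BASES[idx]


def gen_exon_sequences(
    config: SimulationConfig,
    group_sizes: Mapping[str, int],
    ids: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[ExonSequenceRecord], GroundTruth]:
    """Simulate cassette-exon sequence sets with planted motif positions.

    ``group_sizes`` maps a class label to the number of exons to generate
    (e.g. ``{"test": 300, "background": 800}``).  Every class except
    ``"background"`` receives, per exon with probability ``plant_prob``, one
    motif copy written at a uniformly random start offset inside
    ``plant_window`` of the downstream intron (window bounds inclusive).
    The remaining sequence is i.i.d. from ``background_base_composition``;
    spontaneous motif occurrences elsewhere are left in place and are not
    listed in the truth, which records planted positions only.

    ``ids`` optionally supplies the exon identifiers per class; by default
    they are ``{label}_{i:05d}``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from the probe stream
    motif = config.motif.upper()
    mbytes = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    lo, hi = config.plant_window
    span = config.intron_span

    records: list[ExonSequenceRecord] = []
    truth = GroundTruth()
    for label in group_sizes:
        n = int(group_sizes[label])
        if n < 0:
            raise ValueError(f"group size for {label!r} must be >= 0")
        if ids is not None:
            exon_ids = list(ids[label])
            if len(exon_ids) != n:
                raise ValueError(f"ids for {label!r} do not match group size")
        else:
            exon_ids = [f"{label}_{i + 1:05d}" for i in range(n)]

        total_len = span + config.exon_len + span
        seqs = _random_bases(rng, n, total_len, config.background_base_composition)
        plant = (
            rng.random(n) < config.plant_prob
            if label != "background"
            else np.zeros(n, dtype=bool)
        )
        pos = rng.integers(lo, hi + 1, size=n)
        ds_off = span + config.exon_len
        for i in range(n):
            if plant[i]:
                p = int(pos[i])
                seqs[i, ds_off + p : ds_off + p + mbytes.size] = mbytes
            s = seqs[i].tobytes().decode("ascii")
            records.append(
                ExonSequenceRecord(
                    exon_id=exon_ids[i],
                    upstream_intron=s[:span],
                    exon_seq=s[span:ds_off],
                    downstream_intron=s[ds_off:],
                    class_label=label,
                )
            )
            truth.planted_motifs[exon_ids[i]] = [int(pos[i])] if plant[i] else []
    return records, truth
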