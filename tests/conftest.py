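"""Shared fixtures: hand-built probe tables with known Sepscores."""

import numpy as np
import pandas as pd
import pytest

TG = ["TG_rep1", "TG_rep2", "TG_rep3"]
WT = ["WT_rep1", "WT_rep2", "WT_rep3"]


def make_probe_table(events, genes=None, samples=TG + WT):
    """Build a probe table from explicit per-probe intensities.

    ``events`` maps event_id -> {"inclusion": [probe rows], "skip": [...]}
    where each probe row is a list of linear intensities, one per sample.
    ``genes`` maps gene_id -> list of constitutive probe rows.
    """
    rows = []
    values = []
    i = 0
    for event_id, roles in events.items():
        for role, probes in roles.items():
            for probe in probes:
                i += 1
                rows.append((f"p{i:04d}", f"gene_of_{event_id}", event_id, role))
                values.append(probe)
    for gene_id, probes in (genes or {}).items():
        for probe in probes:
            i += 1
            rows.append((f"p{i:04d}", gene_id, "", "constitutive"))
            values.append(probe)
    table = pd.DataFrame(rows, columns=["probe_id", "gene_id", "event_id", "role"])
    table[list(samples)] = np.asarray(values, dtype=float)
    return table


@pytest.fixture
def flat_event_table():
    """One event, identical intensities in both groups (true Sepscore 0)."""
    return make_probe_table(
        {
            "ev1": {
                "inclusion": [[100] * 6, [200] * 6],
                "skip": [[50] * 6, [80] * 6],
            }
        }
    )


@pytest.fixture
def doubled_inclusion_table():
    """Inclusion probes exactly 2x in the TG group; skip unchanged (S = +1)."""
    return make_probe_table(
        {
            "ev1": {
                "inclusion": [[200] * 3 + [100] * 3, [400] * 3 + [200] * 3],
                "skip": [[50] * 6, [70] * 6],
            }
        }
    )
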