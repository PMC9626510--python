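"""Bundled reference tables used as arithmetic fixtures and simulator anchors."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_run_accuracy_table", "load_participant_means", "load_latency_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("arp300.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_run_accuracy_table() -> pd.DataFrame:
    """Per-run AR single-extraction accuracies (percent) for 15 participants,
    indexed by participant, one column per run."""
    df = _read("ar_sepcnn_run_accuracy.csv").set_index("participant")
    df = df.drop(columns="mean")
    df.columns = [int(c.removeprefix("run")) for c in df.columns]
    return df


def load_participant_means() -> pd.Series:
    """Reference per-participant mean accuracies (percent).

    One row of the source table is not self-consistent with its per-run
    values, so the reference means are kept verbatim rather than recomputed.
    """
    return _read("ar_sepcnn_run_accuracy.csv").set_index("participant")["mean"]


def load_latency_table() -> pd.DataFrame:
    """Per-participant mean P300 peak latency (ms) in the CS and AR
    environments; the column means anchor the simulator defaults."""
    return _read("p300_latency_ms.csv").set_index("participant")
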