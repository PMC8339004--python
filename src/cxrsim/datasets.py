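"""Published reader-study benchmark tables.

Detection counts (TP/FP/FN at the operating threshold) and wAFROC figures
of merit for nine radiologists and two CNN baselines on the 201-image
synthetic-radiograph study set these tools reproduce.  The tables ship with
the package so aggregate observer statistics can be recomputed without the
original study artifacts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("cxrsim.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def reader_detection_counts(readers_only: bool = False) -> pd.DataFrame:
    """TP/FP/FN detection counts per observer (nine readers, two CNNs)."""
    df = _load("reader_detection_counts.csv")
    return df[df["kind"] == "reader"].reset_index(drop=True) if readers_only else df


def wafroc_foms(readers_only: bool = False) -> pd.DataFrame:
    """wAFROC figures of merit and wLLF at the FPF = 0.2 operating point."""
    df = _load("wafroc_foms.csv")
    return df[df["kind"] == "reader"].reset_index(drop=True) if readers_only else df
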