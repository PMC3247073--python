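"""Shared delimited-table reading with lossless float parsing."""

import csv
from pathlib import Path

import pandas as pd


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table (comma, tab, semicolon or whitespace),
    parsing floats with correct rounding so write/read round-trips exactly."""
    head = Path(path).open().readline()
    try:
        delim = csv.Sniffer().sniff(head, delimiters=",;\t ").delimiter
    except csv.Error:
        delim = ","
    return pd.read_csv(path, sep=delim, float_precision="round_trip",
                       skipinitialspace=True)
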