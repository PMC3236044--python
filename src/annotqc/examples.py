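"""Shipped example data: published annotation-report rows.

A small reference table of annotation-report measures for complete
prokaryotic genomes (two well-annotated model organisms plus the per-column
extreme cases).  Useful as a sanity anchor for the measure arithmetic and
as a ready-made cohort for the comparison statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_annotation_report_examples() -> pd.DataFrame:
    """The example measure table, one row per genome."""
    path = resources.files("annotqc.data").joinpath("annotation_report_examples.tsv")
    with path.open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#")
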