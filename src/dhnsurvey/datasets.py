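"""Bundled reference tables.

``load_table1`` returns the published survey of the 117 wheat-group dehydrin
genes (bread wheat Ta, wild emmer Td, T. urartu Tu, Ae. tauschii Aet): gene
name, locus ID, structural type, genomic position, strand and the published
truncation / mis-annotation flags.  ``type_corrected`` carries the published
manual re-annotation where one exists (TaDHN12-A3, whose annotated first 28
residues hid its Y-segment); it is "." elsewhere.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_table1() -> pd.DataFrame:
    """The bundled 117-gene dehydrin survey table as a DataFrame."""
    ref = resources.files("dhnsurvey") / "data" / "table1_wheat_dhn.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    return df
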