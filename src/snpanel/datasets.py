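"""Bundled reference data.

`load_core_markers` returns the published statistics table of the 41
core cauliflower KASP markers (marker, position, alleles, PIC, MAF,
gene diversity, observed heterozygosity over 329 market cultivars) —
the standing regression target for the statistics formulas.

`CANDIDATE_VARIANT_TYPE_PCT` is the published substitution-type
spectrum (percent) of the 1662-SNP candidate pool from the same
cauliflower resequencing panel.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CANDIDATE_VARIANT_TYPE_PCT: dict[str, float] = {
    "A/G": 27.02,
    "C/T": 25.51,
    "A/T": 13.36,
    "A/C": 12.10,
    "G/T": 11.50,
    "C/G": 10.53,
}


def load_core_markers() -> pd.DataFrame:
    """The 41-row core KASP marker statistics table."""
    ref = resources.files("snpanel.data").joinpath("core_markers.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
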