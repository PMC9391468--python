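"""Packaged reference tables."""

from importlib import resources as _res

import pandas as pd

#: Motifs obtained for chromatin pseudostates, reported alongside the
#: per-mark counts (printed input, not a computed quantity).
N_PSEUDOSTATE_MOTIFS = 103


def load_thymocyte_motif_counts() -> pd.DataFrame:
    """The published per-dataset bookkeeping table: histone modification,
    thymocyte cell type, sample / peak / significant-motif counts."""
    with _res.files(__package__).joinpath("thymocyte_motif_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
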