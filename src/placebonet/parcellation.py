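"""Packaged AAL cortical parcellation bookkeeping.

The analysis operates on 78 cortical regions of the Automated Anatomical
Labeling (AAL) atlas (subcortical labels excluded). The packaged fixture
fixes the region order used by every table and correlation matrix in the
package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_parcellation", "region_names", "N_REGIONS"]

N_REGIONS = 78


def load_parcellation() -> pd.DataFrame:
    """Load the AAL-78 cortical region table.

    Returns a DataFrame with columns ``index`` (1-based atlas position),
    ``region`` (unique label), ``hemisphere`` ('L'/'R') and ``cortical``.
    """
    with resources.files("placebonet.data").joinpath("aal78.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    if len(tab) != N_REGIONS or tab["region"].duplicated().any():
        raise ValueError("packaged parcellation fixture is corrupt")
    if not (tab["cortical"] == 1).all():
        raise ValueError("fixture must contain cortical regions only")
    return tab


def region_names() -> list[str]:
    """Region labels in canonical (fixture) order."""
    return load_parcellation()["region"].tolist()
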