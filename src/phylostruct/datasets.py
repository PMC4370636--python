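"""Packaged example data.

``load_caatinga_sites`` returns the published site-level summary of 13
Caatinga floristic surveys: coordinates and substrate class of each site
together with the reported net relatedness (NRI) and nearest taxon (NTI)
indices for the whole flora and for the woody / herbaceous subsets.  The
underlying species lists are not distributed, so this table supports the
spatial stages of the pipeline (distance classes, correlograms, PCNM) and
serves as a worked example; it cannot regenerate the indices themselves.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .spatial import SiteTable

__all__ = ["load_caatinga_sites", "caatinga_site_table"]

DIVERSITY_COLUMNS = ["NRI_all", "NRI_wood", "NRI_herb",
                     "NTI_all", "NTI_wood", "NTI_herb"]


def load_caatinga_sites() -> pd.DataFrame:
    """The 13-site summary table (index: site id)."""
    ref = resources.files("phylostruct") / "data" / "caatinga_sites.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def caatinga_site_table() -> SiteTable:
    """The same data wrapped as a SiteTable (diversity indices ride along as
    extra columns)."""
    return SiteTable(load_caatinga_sites())
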