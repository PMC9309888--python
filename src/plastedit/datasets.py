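"""Small bundled reference tables.

``published_editing_counts`` holds the per-type base-conversion edit
counts reported for the three green-plastid dinoflagellates
(*L. chlorophorum*, strains TGD and MGD); ``mgd_repeat_unit`` is the
84-bp tandem-repeat unit from the unresolved region of the MGD plastid
genome; ``protein_categories`` is the 30 photosynthetic / 20
non-photosynthetic split of the 50 plastid-encoded proteins used in the
branch-length contrast.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def published_editing_counts() -> pd.DataFrame:
    """Per-conversion edit counts for the three dinoflagellate plastids."""
    with resources.as_file(_DATA / "published_editing_counts.tsv") as p:
        return pd.read_csv(p, sep="\t", index_col="conversion")


def mgd_repeat_unit() -> str:
    """The 84-bp repeat unit from the MGD plastid genome's gap region."""
    return (_DATA / "mgd_repeat_unit.txt").read_text().strip()


def protein_categories() -> dict[str, str]:
    """Protein name -> photosynthetic / non_photosynthetic."""
    with resources.as_file(_DATA / "protein_categories.tsv") as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["protein"], df["category"]))
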