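"""Packaged reference data.

``load_published_counts`` returns the published conditional birth counts for
Indian- and Chinese-born mothers in the four diaspora countries (second
births after one daughter and third births after two daughters, by census or
survey round), together with the ratio each source table printed —
``published_csr`` is missing for the one suppressed cell (under 100 births).
These counts serve as regression fixtures for the estimator, not as inputs
to it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_counts"]


def load_published_counts() -> pd.DataFrame:
    """Published diaspora CSR cell counts with the printed ratios."""
    ref = resources.files("csrkit.data").joinpath("table2_counts.csv")
    with ref.open("rb") as fh:
        df = pd.read_csv(fh)
    df["published_csr"] = df["published_csr"].astype("Int64")
    return df
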