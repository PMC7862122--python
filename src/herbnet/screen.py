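"""ADME screening of candidate compounds.

Compounds are retained when their predicted oral bioavailability (OB, a
percentage) and drug-likeness (DL, a unitless similarity score) both reach
the screening thresholds.  The conventional cutoffs in herbal network
pharmacology are OB 30 % and DL 0.18; comparison is inclusive (>=) by
default, with a strict mode available.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = ("id", "ob", "dl")


def _validate(compounds: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in compounds.columns:
            raise ValidationError(f"compound table is missing column {col!r}")
    if compounds["id"].duplicated().any():
        dupes = sorted(compounds.loc[compounds["id"].duplicated(), "id"].unique())
        raise ValidationError(f"duplicate compound ids: {dupes}")
    bad_ob = compounds[(compounds["ob"] < 0) | (compounds["ob"] > 100) | compounds["ob"].isna()]
    if len(bad_ob):
        rec = bad_ob.iloc[0]
        raise ValidationError(
            f"compound {rec['id']!r} has OB {rec['ob']!r} outside the percent scale [0, 100]"
        )
    bad_dl = compounds[(compounds["dl"] < 0) | compounds["dl"].isna()]
    if len(bad_dl):
        rec = bad_dl.iloc[0]
        raise ValidationError(f"compound {rec['id']!r} has negative DL {rec['dl']!r}")


def filter_adme(
    compounds: pd.DataFrame,
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Return the compounds passing both ADME cutoffs.

    Input order is preserved and the input frame is not modified.  With
    ``inclusive`` (default) a record on the boundary is kept; in strict
    mode the comparison is ``>``.
    """
    if not (math.isfinite(ob_min) and math.isfinite(dl_min)):
        raise ValidationError("ob_min and dl_min must be finite")
    _validate(compounds)
    if inclusive:
        mask = (compounds["ob"] >= ob_min) & (compounds["dl"] >= dl_min)
    else:
        mask = (compounds["ob"] > ob_min) & (compounds["dl"] > dl_min)
    return compounds.loc[mask].copy()
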