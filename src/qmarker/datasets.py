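"""Packaged reference tables for the Gentiana scabra (GSB) quality study.

The package ships the published 44-batch quality-marker content table
(swertiamarin, gentiopicroside and sweroside in mg per g of dried root
powder), the three HPLC calibration curves, and the published downstream
tables (min-max normalized values, proportion matrix, PCA eigenvalues,
composite scores) that the quality-evaluation stages are validated
against.  All tables are plain CSV inside the package; each file is
checksummed so silent corruption is detected at load time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

ANALYTES = ("swertiamarin", "gentiopicroside", "sweroside")

_CHECKSUMS = {
    "calibration_curves.csv": "15f39e76dc1ff9a5c4583a7f260ec8fac42405946ff0a910ba6ed882b6c4ad37",
    "gsb_contents.csv": "f9e4ea934f1324f9c4f49dbe409889a3215aa76389a85a12919fcf494df4513c",
    "gsb_normalized_published.csv": "24d481f55b23bf35b873f030289995b5ede93ea3175aafb820ae6cffa64e6a88",
    "gsb_pca_published.csv": "0c379c4fe0079ab2d1483d8ab7d575d9e590daed0435c3b4aca7cdcd5a707dc7",
    "gsb_proportions_published.csv": "645b5eb6d1829ced55e17651d7535839ae946450f79616b388c85a7a9ff9ee09",
    "gsb_scores_published.csv": "b85324524a80df2d8c8a42d5737502376219544c3e5aabfbe22ea649c3192daa",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("qmarker.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {_CHECKSUMS[name]}"
        )
    with ref.open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_contents(with_total: bool = False) -> pd.DataFrame:
    """The 44-batch Q-marker content table (mg/g), batches S1..S44.

    Parameters
    ----------
    with_total
        If True, keep the published per-batch total column; otherwise
        return just the three analyte columns.
    """
    df = _read("gsb_contents.csv", index_col="batch")
    return df if with_total else df[list(ANALYTES)]


def load_calibration_curves() -> pd.DataFrame:
    """Published slope/intercept (mAU vs mg/mL) per analyte."""
    return _read("calibration_curves.csv", index_col="analyte")


def load_published_normalized() -> pd.DataFrame:
    """Published min-max normalized content matrix (3-decimal)."""
    return _read("gsb_normalized_published.csv", index_col="batch")


def load_published_proportions() -> pd.DataFrame:
    """Published proportion ("specific gravity") matrix (3-decimal)."""
    return _read("gsb_proportions_published.csv", index_col="batch")


def load_published_pca() -> pd.DataFrame:
    """Published correlation-PCA eigenvalues and variance contributions."""
    return _read("gsb_pca_published.csv", index_col="component")


def load_published_scores() -> pd.DataFrame:
    """Published first-PC scores, composite scores and ranks per batch."""
    return _read("gsb_scores_published.csv", index_col="batch")
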