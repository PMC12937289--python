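"""Small text-ingest helpers shared by the CSV readers."""

from __future__ import annotations

import io
import os
from typing import Any

import pandas as pd

# Characters that typeset tables commonly use for the ASCII hyphen-minus:
# Unicode minus, en dash, em dash, non-breaking hyphen.
_MINUS_VARIANTS = str.maketrans({c: "-" for c in "−–—‑"})


def normalize_minus(text: str) -> str:
    """Replace Unicode minus/dash variants with ASCII ``-``."""
    return text.translate(_MINUS_VARIANTS)


def read_csv_clean(path_or_buf: Any) -> pd.DataFrame:
    """``pd.read_csv`` with minus-sign normalization on the raw text."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(os.fspath(path_or_buf), encoding="utf-8") as fh:
            text = fh.read()
    return pd.read_csv(io.StringIO(normalize_minus(text)))
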