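"""Variable transforms used ahead of linear modelling.

The transform is determined by what the variable measures: relative
proportions use arcsin(sqrt(x)), absolute amounts in micrograms use
ln(x + 0.01), and expression intensities use sqrt(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LN_SHIFT = 0.01

TRANSFORMS = ("arcsin_sqrt", "ln_shift", "sqrt", "identity")

# dataset kind -> mandatory transform tag
TRANSFORM_FOR_KIND = {
    "relative_proportion": "arcsin_sqrt",
    "amount_ug": "ln_shift",
    "expression": "sqrt",
}


@dataclass(frozen=True)
class TransformedVariable:
    name: str
    raw: np.ndarray
    tag: str
    transformed: np.ndarray


def _check_domain(values: np.ndarray, ok: np.ndarray, tag: str) -> None:
    bad = np.flatnonzero(~ok & ~np.isnan(values))
    if bad.size:
        raise ValueError(
            f"{tag}: value {values[bad[0]]!r} at index {int(bad[0])} "
            "is outside the transform domain"
        )


def apply_transform(values, tag: str, name: str = "x") -> TransformedVariable:
    """Apply an elementwise transform; NaN propagates, out-of-domain raises.

    ``arcsin_sqrt`` requires values in [0, 1]; ``sqrt`` requires values
    >= 0; ``ln_shift`` computes ln(x + 0.01) and requires x > -0.01.
    """
    raw = np.asarray(values, dtype=float)
    if tag == "identity":
        out = raw.copy()
    elif tag == "arcsin_sqrt":
        _check_domain(raw, (raw >= 0) & (raw <= 1), tag)
        out = np.arcsin(np.sqrt(raw))
    elif tag == "sqrt":
        _check_domain(raw, raw >= 0, tag)
        out = np.sqrt(raw)
    elif tag == "ln_shift":
        _check_domain(raw, raw > -LN_SHIFT, tag)
        out = np.log(raw + LN_SHIFT)
    else:
        raise ValueError(f"unknown transform tag {tag!r}")
    return TransformedVariable(name=name, raw=raw, tag=tag, transformed=out)


def validate_transform_plan(kind: str, tag: str) -> None:
    """Reject transforms that do not match what the variable measures."""
    if kind not in TRANSFORM_FOR_KIND:
        raise ValueError(f"unknown dataset kind {kind!r}")
    required = TRANSFORM_FOR_KIND[kind]
    if tag != required:
        raise ValueError(
            f"variables of kind {kind!r} must use the {required!r} "
            f"transform, not {tag!r}"
        )
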