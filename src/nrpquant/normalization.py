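"""Ratiometric protein-content correction for tissue reductive-capacity values.

Tissue homogenates are spotted at a fixed volume, so the measured integrated
density confounds reductive capacity with protein loading. The correction
rescales each sample's density by the ratio of a representative protein
concentration to the sample's own:

    corrected_i = density_i * (p_ref / p_i)

This simple ratiometric form assumes the signal is linear in protein
content, which only holds over a narrow loading range. The correction is
therefore *gated*: it is justified for a sample only when its protein
concentration disperses from the representative value by strictly less than
a tolerance (default 50%). A linearity pre-check (OLS of density on protein
over the justified samples) is included in the output for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, JustificationError

__all__ = ["ProteinTable", "check_dispersion", "ratiometric_correct"]


@dataclass(frozen=True)
class ProteinTable:
    """Per-sample protein concentrations plus the representative reference value.

    Units are arbitrary but must be uniform across entries. When
    ``reference_value`` is None it defaults to the median protein
    concentration of the batch (an explicit named sample can be designated
    instead via ``reference_label``).
    """

    entries: tuple[tuple[str, float], ...]
    reference_value: float | None = None
    reference_label: str | None = None

    def __post_init__(self) -> None:
        ent = tuple((str(lbl), float(p)) for lbl, p in self.entries)
        labels = [lbl for lbl, _ in ent]
        if len(set(labels)) != len(labels):
            raise DataError("sample labels must be unique")
        if any(p <= 0 for _, p in ent):
            raise DataError("protein concentrations must be > 0")
        object.__setattr__(self, "entries", ent)
        if self.reference_label is not None:
            lookup = dict(ent)
            if self.reference_label not in lookup:
                raise KeyError(f"reference sample {self.reference_label!r} not in table")
            object.__setattr__(self, "reference_value", lookup[self.reference_label])
        elif self.reference_value is None:
            object.__setattr__(
                self, "reference_value", float(np.median([p for _, p in ent]))
            )
        if self.reference_value <= 0:
            raise DataError("reference protein value must be > 0")

    def protein(self, label: str) -> float:
        for lbl, p in self.entries:
            if lbl == label:
                return p
        raise KeyError(f"no protein entry for sample {label!r}")


def check_dispersion(table: ProteinTable, tolerance: float = 0.5) -> pd.DataFrame:
    """Flag which samples qualify for ratiometric correction.

    Sample i is justified iff |p_i - p_ref| / p_ref < tolerance, with a
    *strict* inequality: a sample sitting exactly at the tolerance boundary
    is not justified. Returns a DataFrame with columns
    ``label, protein, deviation_frac, justified``.
    """
    if tolerance <= 0:
        raise DataError("tolerance must be > 0")
    p_ref = table.reference_value
    rows = []
    for lbl, p in table.entries:
        dev = abs(p - p_ref) / p_ref
        rows.append({"label": lbl, "protein": p, "deviation_frac": dev,
                     "justified": bool(dev < tolerance)})
    return pd.DataFrame(rows)


def ratiometric_correct(
    densities: dict[str, float],
    table: ProteinTable,
    tolerance: float = 0.5,
    allow_unjustified: bool = False,
) -> pd.DataFrame:
    """Apply the protein-loading correction density * (p_ref / p_i).

    The multiplication by p_ref (rather than dividing by bare p_i) keeps the
    output on the original integrated-density scale, so a sample loaded at
    exactly the reference protein level is returned unchanged.

    By default every sample must pass the dispersion rule; with
    ``allow_unjustified=True`` failing samples are still corrected but
    flagged in the output. The returned frame carries a ``linearity_r2``
    attribute (``.attrs``): R^2 of density on protein over the justified
    samples, the audit check of the linearity assumption.
    """
    flags = check_dispersion(table, tolerance).set_index("label")
    missing = [lbl for lbl in densities if lbl not in flags.index]
    if missing:
        raise KeyError(f"no protein entry for samples: {missing}")
    unjustified = [lbl for lbl in densities if not flags.loc[lbl, "justified"]]
    if unjustified and not allow_unjustified:
        raise JustificationError(
            f"samples fail the dispersion rule: {unjustified}; "
            "pass allow_unjustified=True to correct them anyway (flagged)")

    p_ref = table.reference_value
    rows = []
    for lbl, d in densities.items():
        p = table.protein(lbl)
        rows.append({"label": lbl, "raw": float(d), "protein": p,
                     "justified": bool(flags.loc[lbl, "justified"]),
                     "corrected": float(d) * (p_ref / p)})
    out = pd.DataFrame(rows)

    just = out[out["justified"]]
    if len(just) >= 3 and np.ptp(just["protein"].to_numpy()) > 0:
        res = stats.linregress(just["protein"], just["raw"])
        out.attrs["linearity_r2"] = float(res.rvalue**2)
    else:
        out.attrs["linearity_r2"] = float("nan")
    out.attrs["reference_protein"] = p_ref
    return out
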