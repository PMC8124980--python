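"""Behavioural indices of the CARAS-R perception-of-differences test.

The test yields a count of correct answers ``A`` (hits) and errors ``E``.
Two derived indices are used for screening:

* effectiveness ``AE = A - E`` — raw performance penalised by errors;
* impulsivity-control index ``ICI = (A - E) / (A + E) * 100`` — the
  percentage of effective responding among all responses.  Low ICI marks
  an impulsive response style (many answers, many of them wrong).

Published norm tables convert these to age-banded enneatypes; those norms
are not reproduced here, so binary effective/impulsive classification
takes explicit raw-score cutoffs supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CarasScores",
    "compute_ae",
    "compute_ici",
    "classify",
    "score_table",
]


def compute_ae(a: int, e: int) -> int:
    """Effectiveness index ``A - E``."""
    if a < 0 or e < 0:
        raise ValueError(f"counts must be non-negative, got A={a}, E={e}")
    return a - e


def compute_ici(a: int, e: int) -> float:
    """Impulsivity-control index ``(A - E) / (A + E) * 100`` (percent).

    Ranges from -100 (all responses wrong) through 0 (as many errors as
    hits) to 100 (error-free responding).  Undefined when ``A + E == 0``.
    """
    if a < 0 or e < 0:
        raise ValueError(f"counts must be non-negative, got A={a}, E={e}")
    if a + e == 0:
        raise ZeroDivisionError("ICI is undefined for A + E = 0")
    return (a - e) / (a + e) * 100.0


def classify(
    ae: float, ici: float, effectiveness_cutoff: float, impulsivity_cutoff: float
) -> tuple[bool, bool]:
    """Binary (effective, impulsive) classification at raw-score cutoffs.

    A child is *effective* when ``AE >= effectiveness_cutoff`` and
    *impulsive* when ``ICI < impulsivity_cutoff``.  The cutoffs stand in
    for the unpublished enneatype norms and must be chosen by the caller.
    """
    return ae >= effectiveness_cutoff, ici < impulsivity_cutoff


@dataclass(frozen=True)
class CarasScores:
    """Raw counts plus derived indices and optional classification."""

    a: int
    e: int
    ae: int
    ici: float
    effective: bool | None = None
    impulsive: bool | None = None

    @classmethod
    def from_counts(
        cls,
        a: int,
        e: int,
        effectiveness_cutoff: float | None = None,
        impulsivity_cutoff: float | None = None,
    ) -> "CarasScores":
        ae = compute_ae(a, e)
        ici = compute_ici(a, e)
        eff = imp = None
        if effectiveness_cutoff is not None and impulsivity_cutoff is not None:
            eff, imp = classify(ae, ici, effectiveness_cutoff, impulsivity_cutoff)
        return cls(a=a, e=e, ae=ae, ici=ici, effective=eff, impulsive=imp)


def score_table(
    table: pd.DataFrame,
    effectiveness_cutoff: float | None = None,
    impulsivity_cutoff: float | None = None,
) -> pd.DataFrame:
    """Add AE/ICI (and classifications, when cutoffs are given) to a raw table.

    ``table`` needs columns ``A`` and ``E``; the result appends ``AE``,
    ``ICI`` and, with both cutoffs, boolean ``effective``/``impulsive``
    columns.  ICI keeps full precision here; writers round it to one
    decimal for display.
    """
    missing = {"A", "E"} - set(table.columns)
    if missing:
        raise ValueError(f"score table is missing columns: {sorted(missing)}")
    out = table.copy()
    out["AE"] = [compute_ae(int(a), int(e)) for a, e in zip(out["A"], out["E"])]
    out["ICI"] = [compute_ici(int(a), int(e)) for a, e in zip(out["A"], out["E"])]
    if effectiveness_cutoff is not None and impulsivity_cutoff is not None:
        flags = [
            classify(ae, ici, effectiveness_cutoff, impulsivity_cutoff)
            for ae, ici in zip(out["AE"], out["ICI"])
        ]
        out["effective"] = [f[0] for f in flags]
        out["impulsive"] = [f[1] for f in flags]
    return out
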