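"""Per-variant functional weights S_i for the four test variants.

Schemes
-------
unweighted
    S_i = 1 for every variant, synonymous or not.
binary
    S_i = 1 for nonsynonymous variants, 0 otherwise.
sift
    S_i = 1 - SIFT score for nonsynonymous variants (SIFT scores near 0 mean
    damaging, so the weight is flipped to "probability of damage"), 0 for
    synonymous variants.
polyphen
    S_i = PolyPhen-2 score (already a posterior probability of damage) for
    nonsynonymous variants, 0 for synonymous variants.

Nonsynonymous variants lacking a score are imputed with the median raw
score (0.1 for SIFT, 0.2 for PolyPhen-2) BEFORE the scheme transform, so a
missing SIFT score yields weight 0.9 and a missing PolyPhen score 0.2.
The constants are overridable so users can supply their dataset's medians.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

SCHEMES = ("unweighted", "binary", "sift", "polyphen")

SIFT_IMPUTE_DEFAULT = 0.1
POLYPHEN_IMPUTE_DEFAULT = 0.2

SIFT_DAMAGING_BELOW = 0.05
POLYPHEN_BENIGN_MAX = 0.2
POLYPHEN_PROBABLY_MIN = 0.85


def make_weights(
    scheme: str,
    annotation: pd.DataFrame,
    *,
    sift_impute: float = SIFT_IMPUTE_DEFAULT,
    polyphen_impute: float = POLYPHEN_IMPUTE_DEFAULT,
) -> np.ndarray:
    """Return the weight vector S for a gene's (or dataset's) variants.

    ``annotation`` rows must carry ``is_nonsynonymous`` and, for the score
    schemes, ``sift_score`` / ``polyphen_score`` (NaN = missing, imputed).
    Output is aligned to the row order, with every S_i in [0, 1].
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; expected one of {SCHEMES}")
    n = len(annotation)
    nonsyn = annotation["is_nonsynonymous"].to_numpy(dtype=bool)
    if scheme == "unweighted":
        return np.ones(n)
    if scheme == "binary":
        return nonsyn.astype(float)
    col = "sift_score" if scheme == "sift" else "polyphen_score"
    impute = sift_impute if scheme == "sift" else polyphen_impute
    scores = annotation[col].to_numpy(dtype=float)
    present = ~np.isnan(scores)
    if ((scores[present] < 0) | (scores[present] > 1)).any():
        raise ValidationError(f"{col} outside [0,1]")
    scores = np.where(present, scores, impute)
    weights = (1.0 - scores) if scheme == "sift" else scores
    return np.where(nonsyn, weights, 0.0)


def classify_sift(score: float | None) -> str:
    """SIFT qualitative call: ``damaging`` iff score < 0.05, else ``tolerated``.

    A missing score returns ``unclassified`` rather than raising.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "unclassified"
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"SIFT score {score} outside [0,1]")
    return "damaging" if score < SIFT_DAMAGING_BELOW else "tolerated"


def classify_polyphen(score: float | None) -> str:
    """PolyPhen-2 qualitative call from its posterior probability.

    Intervals: benign on [0, 0.2], possibly_damaging on (0.2, 0.85),
    probably_damaging on [0.85, 1]. Missing returns ``unclassified``.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "unclassified"
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"PolyPhen-2 score {score} outside [0,1]")
    if score <= POLYPHEN_BENIGN_MAX:
        return "benign"
    if score < POLYPHEN_PROBABLY_MIN:
        return "possibly_damaging"
    return "probably_damaging"


def classify_all(scores: Sequence[float], algorithm: str) -> list[str]:
    """Vector version of the qualitative classifiers."""
    fn = classify_sift if algorithm == "sift" else classify_polyphen
    return [fn(s) for s in scores]
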