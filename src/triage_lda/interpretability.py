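"""Likert encoding and linearly weighted Cohen kappa for paired raters.

Two ordinal scales are supported: rater confidence on 0..4 and description
similarity on -3..-1, 1..3 (no zero code). For kappa, categories are
treated as consecutive ordinal ranks; linear weighted kappa is invariant
under affine re-indexing of the ranks, so the similarity scale's missing
zero collapses harmlessly to adjacent ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

CONFIDENCE_SCALE = {
    "not confident at all": 0,
    "slightly confident": 1,
    "somewhat confident": 2,
    "moderately confident": 3,
    "very confident": 4,
}

SIMILARITY_SCALE = {
    "very dissimilar": -3,
    "moderately dissimilar": -2,
    "slightly dissimilar": -1,
    "slightly similar": 1,
    "moderately similar": 2,
    "very similar": 3,
}

SCALES = {"confidence": CONFIDENCE_SCALE, "similarity": SIMILARITY_SCALE}

#: ordered category codes per scale
CATEGORIES = {
    "confidence": tuple(sorted(CONFIDENCE_SCALE.values())),
    "similarity": tuple(sorted(SIMILARITY_SCALE.values())),
}


def encode_likert(labels: Sequence[str], scale: str) -> list[int]:
    """Map textual Likert labels to their numeric codes (case-insensitive)."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {sorted(SCALES)}")
    mapping = SCALES[scale]
    codes = []
    for label in labels:
        key = label.strip().lower()
        if key not in mapping:
            raise ValueError(f"unknown label {label!r} for scale {scale!r}")
        codes.append(mapping[key])
    return codes


def average_rating(codes: Sequence[int]) -> float:
    if len(codes) == 0:
        raise ValueError("cannot average an empty code list")
    return float(np.mean(codes))


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    se: float
    ci_low: float
    ci_high: float
    n_items: int
    n_categories: int

    def ci_clipped(self) -> tuple[float, float]:
        """CI with the lower bound clipped at 0 for display parity."""
        return (max(0.0, self.ci_low), self.ci_high)


def weighted_kappa(
    r1: Sequence[int], r2: Sequence[int], categories: Sequence[int]
) -> KappaResult:
    """Cohen kappa with linear weights over ordered categories.

    Weights are w_ij = 1 - |i - j| / (m - 1) on the consecutive ranks of
    ``categories``. The standard error is the Fleiss-Cohen large-sample
    (non-null) variance for weighted kappa; CI = kappa +/- 1.96 SE.
    """
    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2):
        raise ValueError("rating vectors differ in length")
    n = len(r1)
    if n < 2:
        raise ValueError("need at least 2 paired ratings")
    cats = list(categories)
    m = len(cats)
    rank = {c: i for i, c in enumerate(cats)}
    for code in (*r1, *r2):
        if code not in rank:
            raise ValueError(f"code {code!r} not in categories {cats}")

    w = 1.0 - np.abs(np.subtract.outer(np.arange(m), np.arange(m))) / (m - 1)
    obs = np.zeros((m, m))
    for a, b in zip(r1, r2):
        obs[rank[a], rank[b]] += 1
    obs /= n
    pa = obs.sum(axis=1)
    pb = obs.sum(axis=0)
    exp = np.outer(pa, pb)

    p_o = float((w * obs).sum())
    p_e = float((w * exp).sum())
    if p_e >= 1.0 - 1e-15:
        raise ZeroDivisionError(
            "expected agreement is 1 (no variance in either rater): kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt asymptotic variance for weighted kappa
    wbar_row = w @ pb  # expected weight of rater-1 category i
    wbar_col = pa @ w  # expected weight of rater-2 category j
    term = (w - np.add.outer(wbar_row, wbar_col) * (1.0 - kappa)) ** 2
    var = ((obs * term).sum() - (kappa - p_e * (1.0 - kappa)) ** 2) / (
        n * (1.0 - p_e) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=float(kappa),
        p_observed=p_o,
        p_expected=p_e,
        se=se,
        ci_low=float(kappa - 1.96 * se),
        ci_high=float(kappa + 1.96 * se),
        n_items=n,
        n_categories=m,
    )


# ---------------------------------------------------------------------------
# ratings table
# ---------------------------------------------------------------------------


def load_ratings(path=None) -> pd.DataFrame:
    """Load a paired-rater ratings table (CSV).

    Columns: topic, rater, confidence_label, similarity_label. With no path,
    the bundled two-rater study fixture is returned.
    """
    if path is None:
        with resources.files("triage_lda.data").joinpath("topic_ratings.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    expected = {"topic", "rater", "confidence_label", "similarity_label"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    return df


def rater_codes(df: pd.DataFrame, scale: str) -> dict[str, list[int]]:
    """Per-rater Likert codes in topic order for one scale."""
    col = f"{scale}_label"
    out = {}
    topics = list(dict.fromkeys(df["topic"]))
    for rater, grp in df.groupby("rater", sort=True):
        by_topic = dict(zip(grp["topic"], grp[col]))
        if set(by_topic) != set(topics):
            raise ValueError(f"rater {rater!r} does not cover every topic")
        out[str(rater)] = encode_likert([by_topic[t] for t in topics], scale)
    return out


def agreement_report(df: pd.DataFrame) -> dict[str, KappaResult]:
    """Weighted kappa per scale for a two-rater ratings table."""
    report = {}
    for scale in ("confidence", "similarity"):
        codes = rater_codes(df, scale)
        if len(codes) != 2:
            raise ValueError(f"expected exactly 2 raters, found {sorted(codes)}")
        (r1, r2) = codes.values()
        report[scale] = weighted_kappa(r1, r2, CATEGORIES[scale])
    return report
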